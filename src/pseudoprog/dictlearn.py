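"""Class-specific + shared discriminative dictionary learning.

Three unit-norm atom blocks are learned jointly from labeled patch columns:
``D_p`` (PsP-specific), ``D_t`` (TTP-specific) and ``D_s`` (shared).  The
training objective is

    sum_PsP [ ||y - D a||^2 + ||y - D_p a_p - D_s a_s||^2 ]
  + sum_TTP [ symmetric ]
  + eta * sum_{blocks i != j} ||D_i^T D_j||_F^2

with codes constrained to the permitted sub-dictionary: a PsP patch may only
use D_p and D_s atoms (its D_t coefficients are exactly zero) and
symmetrically for TTP, so the two fidelity terms per sample coincide.  The
cross-block Gram penalty pushes the blocks toward mutual incoherence, which
is what makes the specific blocks discriminative.

Optimization alternates structured sparse coding (orthogonal matching
pursuit on the permitted sub-dictionary; an L1/LARS path is retained as an
option) with sequential atom updates.  Each atom solves the regularized
normal system ``(||beta||^2 I + eta G_other) d = E beta^T`` (Woodbury, since
``G_other`` is a low-rank Gram), is renormalized, and is accepted only if it
does not increase the monitored objective — so the recorded objective trace
is non-increasing by construction, except on iterations where unused atoms
are replaced by the worst-reconstructed patch (those are flagged in the
trace).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .patches import PatchMatrix

PSP = "PsP"
TTP = "TTP"

# residual tolerance used by the training-time OMP coding step
_TRAIN_SIGMA = math.exp(-6)
# slack for the accept-if-improved atom guard (absolute, per atom)
_GUARD_EPS = 1e-10


@dataclass
class LearnConfig:
    """Dictionary-learning hyperparameters.

    ``Kp``/``Kt``/``Ks`` are the specific and shared block sizes (atoms),
    ``sparsity_k`` the nonzeros per code, ``eta`` the incoherence weight,
    ``lambda1`` the L1 weight of the optional LARS coding path
    (``coding='l1'``).  Defaults: Kp = Kt = 100, Ks = 10% of Kp, k = 10,
    eta = 0.15.
    """

    Kp: int = 100
    Kt: int = 100
    Ks: int = 10
    sparsity_k: int = 10
    lambda1: float = 0.05
    eta: float = 0.15
    max_iters: int = 30
    rel_tol: float = 1e-4
    seed: int = 0
    coding: str = "omp"

    def __post_init__(self) -> None:
        if self.Kp < 1 or self.Kt < 1:
            raise ValueError("Kp and Kt must be >= 1")
        if self.Ks < 0:
            raise ValueError("Ks must be >= 0")
        if self.sparsity_k > self.Kp + self.Ks or self.sparsity_k > self.Kt + self.Ks:
            raise ValueError("sparsity_k must not exceed either permitted sub-dictionary size")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.coding not in ("omp", "l1"):
            raise ValueError("coding must be 'omp' or 'l1'")

    def replace(self, **kw) -> "LearnConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class StructuredDictionary:
    """Unit-norm atom blocks D_p (m x Kp), D_t (m x Kt), D_s (m x Ks)."""

    D_p: np.ndarray
    D_t: np.ndarray
    D_s: np.ndarray

    def __post_init__(self) -> None:
        m = self.D_p.shape[0]
        if self.D_t.shape[0] != m or self.D_s.shape[0] != m:
            raise ValueError("all blocks must share the atom length m")

    @property
    def m(self) -> int:
        return self.D_p.shape[0]

    @property
    def Kp(self) -> int:
        return self.D_p.shape[1]

    @property
    def Kt(self) -> int:
        return self.D_t.shape[1]

    @property
    def Ks(self) -> int:
        return self.D_s.shape[1]

    @property
    def K(self) -> int:
        return self.Kp + self.Kt + self.Ks

    @property
    def full(self) -> np.ndarray:
        """Overall dictionary D = [D_p, D_t, D_s] (m x K)."""
        return np.hstack([self.D_p, self.D_t, self.D_s])

    @property
    def D_ps(self) -> np.ndarray:
        """PsP compound dictionary [D_p, D_s]."""
        return np.hstack([self.D_p, self.D_s])

    @property
    def D_ts(self) -> np.ndarray:
        """TTP compound dictionary [D_t, D_s]."""
        return np.hstack([self.D_t, self.D_s])

    def permitted_indices(self, label: str) -> np.ndarray:
        """Column indices (into the full dictionary) a patch of the given
        class may use: own specific block plus the shared block."""
        shared = np.arange(self.Kp + self.Kt, self.K)
        if label == PSP:
            return np.concatenate([np.arange(self.Kp), shared])
        if label == TTP:
            return np.concatenate([np.arange(self.Kp, self.Kp + self.Kt), shared])
        raise ValueError(f"unknown class {label!r}")

    def check_unit_norm(self, tol: float = 1e-10) -> None:
        dev = np.abs(np.linalg.norm(self.full, axis=0) - 1.0)
        if dev.max() > tol:
            raise ValueError(f"atom norms deviate from 1 by up to {dev.max():.2e}")

    def copy(self) -> "StructuredDictionary":
        return StructuredDictionary(self.D_p.copy(), self.D_t.copy(), self.D_s.copy())

    @staticmethod
    def from_full(D: np.ndarray, Kp: int, Kt: int, Ks: int) -> "StructuredDictionary":
        return StructuredDictionary(D[:, :Kp], D[:, Kp : Kp + Kt], D[:, Kp + Kt : Kp + Kt + Ks])


@dataclass
class TrainTrace:
    """Per-iteration record of the monitored objective.

    ``objective_per_iter`` is non-increasing (within the solver's guard
    slack) except at iterations listed in ``replacement_iterations``, where
    unused atoms were re-seeded from worst-reconstructed patches.
    """

    objective_per_iter: list = field(default_factory=list)
    replacement_iterations: list = field(default_factory=list)
    atom_replacements: int = 0
    converged: bool = False


def _columns(Y: PatchMatrix | np.ndarray) -> np.ndarray:
    return Y.columns if isinstance(Y, PatchMatrix) else np.asarray(Y, dtype=float)


def _normalize_cols(M: np.ndarray) -> np.ndarray:
    return M / np.linalg.norm(M, axis=0, keepdims=True)


def initialize_dictionary(
    Yp: PatchMatrix | np.ndarray,
    Yt: PatchMatrix | np.ndarray,
    config: LearnConfig,
) -> StructuredDictionary:
    """Seed the blocks from randomly chosen patch columns.

    D_p draws only from PsP patches, D_t only from TTP patches, D_s from a
    mixed pool of both; exact-duplicate columns are skipped.  Deterministic
    given ``config.seed``.
    """
    Yp, Yt = _columns(Yp), _columns(Yt)
    if Yp.shape[1] < config.Kp + config.Ks:
        raise ValueError(
            f"need at least Kp+Ks={config.Kp + config.Ks} PsP patches, got {Yp.shape[1]}"
        )
    if Yt.shape[1] < config.Kt + config.Ks:
        raise ValueError(
            f"need at least Kt+Ks={config.Kt + config.Ks} TTP patches, got {Yt.shape[1]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    def draw(pool: np.ndarray, k: int, taken: list[np.ndarray]) -> np.ndarray:
        order = rng.permutation(pool.shape[1])
        chosen: list[np.ndarray] = []
        for j in order:
            col = pool[:, j]
            if any(np.array_equal(col, c) for c in chosen) or any(
                np.array_equal(col, c) for c in taken
            ):
                continue
            chosen.append(col)
            if len(chosen) == k:
                break
        if len(chosen) < k:
            raise ValueError(f"could not draw {k} distinct atoms from {pool.shape[1]} patches")
        return np.stack(chosen, axis=1)

    D_p = draw(Yp, config.Kp, [])
    D_t = draw(Yt, config.Kt, [])
    taken = [D_p[:, j] for j in range(config.Kp)] + [D_t[:, j] for j in range(config.Kt)]
    mixed = np.hstack([Yp, Yt])
    D_s = draw(mixed, config.Ks, taken) if config.Ks > 0 else np.empty((Yp.shape[0], 0))
    return StructuredDictionary(_normalize_cols(D_p), _normalize_cols(D_t),
                                _normalize_cols(D_s) if config.Ks > 0 else D_s)


def _l1_code(Y: np.ndarray, D_sub: np.ndarray, lambda1: float) -> np.ndarray:
    """LARS-based L1 coding of each column: min 1/2||y - D a||^2 + lambda1 ||a||_1."""
    from sklearn.linear_model import LassoLars

    m = Y.shape[0]
    A = np.zeros((D_sub.shape[1], Y.shape[1]))
    est = LassoLars(alpha=lambda1 / m, fit_intercept=False)
    for i in range(Y.shape[1]):
        est.fit(D_sub, Y[:, i])
        A[:, i] = est.coef_
    return A


def _code(
    Y: np.ndarray,
    dictionary: StructuredDictionary,
    class_of_Y: str,
    config: LearnConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Structured coding returning (full K x N codes, residual norms)."""
    from .encoding import omp_batch

    perm = dictionary.permitted_indices(class_of_Y)
    if config.sparsity_k > perm.size:
        raise ValueError(
            f"sparsity_k={config.sparsity_k} exceeds permitted sub-dictionary size {perm.size}"
        )
    sub = dictionary.full[:, perm]
    if config.coding == "l1":
        A_sub = _l1_code(Y, sub, config.lambda1)
        resid = np.linalg.norm(Y - sub @ A_sub, axis=0)
    else:
        A_sub, resid = omp_batch(Y, sub, config.sparsity_k, _TRAIN_SIGMA)
    A = np.zeros((dictionary.K, Y.shape[1]))
    A[perm] = A_sub
    return A, resid


def code_with_structure(
    Y: PatchMatrix | np.ndarray,
    dictionary: StructuredDictionary,
    class_of_Y: str,
    config: LearnConfig,
) -> np.ndarray:
    """Sparse-code patches of one class over their permitted sub-dictionary.

    Returns the full K x N coefficient matrix with exact zeros in the
    wrong-class band (the hard structural constraint).
    """
    return _code(_columns(Y), dictionary, class_of_Y, config)[0]


def _solve_atom(b: np.ndarray, c: float, U: np.ndarray, eta: float) -> np.ndarray:
    """Solve ``(c I + eta * U U^T) d = b`` for the atom direction.

    ``U`` stacks the other blocks' atoms; the system is solved through the
    Woodbury identity so only a K_other x K_other system is factorized.
    The caller renormalizes the result.
    """
    if eta == 0 or U.shape[1] == 0:
        return b / c
    M = U.T @ U + (c / eta) * np.eye(U.shape[1])
    return (b - U @ np.linalg.solve(M, U.T @ b)) / c


def cross_gram(Di: np.ndarray, Dj: np.ndarray) -> float:
    """Cross-block Gram mass ||D_i^T D_j||_F^2."""
    return float(np.sum((Di.T @ Dj) ** 2))


def incoherence(dictionary: StructuredDictionary) -> float:
    """Ordered-pair cross-block Gram mass sum_{i != j} ||D_i^T D_j||_F^2
    over the three blocks (each unordered pair counted twice)."""
    return 2.0 * (
        cross_gram(dictionary.D_p, dictionary.D_t)
        + cross_gram(dictionary.D_p, dictionary.D_s)
        + cross_gram(dictionary.D_t, dictionary.D_s)
    )


def objective(
    Yp: PatchMatrix | np.ndarray,
    Yt: PatchMatrix | np.ndarray,
    Ap: np.ndarray,
    At: np.ndarray,
    dictionary: StructuredDictionary,
    config: LearnConfig,
) -> float:
    """Monitored training objective.

    Both fidelity terms per sample (full-dictionary and permitted
    sub-dictionary reconstruction) are evaluated and their coincidence under
    the hard structural constraint is asserted, not assumed.  The L1 path
    adds ``lambda1 * sum |a|``; the OMP path replaces it by the hard <= k
    support constraint, contributing nothing to the value.
    """
    Yp, Yt = _columns(Yp), _columns(Yt)
    D = dictionary.full
    total = 0.0
    for Y, A, label in ((Yp, Ap, PSP), (Yt, At, TTP)):
        if Y.shape[1] == 0:
            continue
        perm = dictionary.permitted_indices(label)
        r_full = float(np.sum((Y - D @ A) ** 2))
        r_perm = float(np.sum((Y - D[:, perm] @ A[perm]) ** 2))
        if not math.isclose(r_full, r_perm, rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(
                "structural zero pattern violated: full-dictionary and permitted "
                f"sub-dictionary fidelities differ ({r_full} vs {r_perm})"
            )
        total += r_full + r_perm
        if config.coding == "l1":
            total += config.lambda1 * float(np.abs(A).sum())
    return total + config.eta * incoherence(dictionary)


def update_atoms(
    Yp: PatchMatrix | np.ndarray,
    Yt: PatchMatrix | np.ndarray,
    Ap: np.ndarray,
    At: np.ndarray,
    dictionary: StructuredDictionary,
    config: LearnConfig,
) -> tuple[StructuredDictionary, int]:
    """One block-sequential pass of atom updates (D_p, D_t, D_s in order).

    Each used atom is re-estimated from the rank-one residual with the
    incoherence-regularized normal system and renormalized; the update is
    kept only if it lowers the monitored objective (guard), so non-increase
    is guaranteed.  Atoms unused by any permitted sample are replaced by the
    currently worst-reconstructed permitted patch (ties: lowest column
    index); the replacement count is returned so callers can exempt those
    iterations from monotonicity checks.
    """
    Yp, Yt = _columns(Yp), _columns(Yt)
    new_dict, n_replaced, _ = _update_atoms_impl(Yp, Yt, Ap, At, dictionary, config)
    return new_dict, n_replaced


def _update_atoms_impl(
    Yp: np.ndarray,
    Yt: np.ndarray,
    Ap: np.ndarray,
    At: np.ndarray,
    dictionary: StructuredDictionary,
    config: LearnConfig,
) -> tuple[StructuredDictionary, int, np.ndarray]:
    """Atom-update pass; also returns the maintained residual
    ``R = [Yp, Yt] - D_new @ [Ap, At]`` so callers can monitor the
    objective without recomputing the reconstruction."""
    Np, Nt = Yp.shape[1], Yt.shape[1]
    Y = np.hstack([Yp, Yt])
    A = np.hstack([Ap, At])
    Kp, Kt, Ks, K = dictionary.Kp, dictionary.Kt, dictionary.Ks, dictionary.K
    D = dictionary.full.copy()
    R = Y - D @ A
    eta = config.eta
    n_replaced = 0

    # permitted sample ranges are contiguous: PsP block sees columns
    # [0, Np), TTP block [Np, Np+Nt), shared block everything
    blocks = (
        (np.arange(0, Kp), 0, Np),
        (np.arange(Kp, Kp + Kt), Np, Np + Nt),
        (np.arange(Kp + Kt, K), 0, Np + Nt),
    )
    for atom_idx, c0, c1 in blocks:
        if atom_idx.size == 0 or c1 == c0:
            continue
        other = np.setdiff1d(np.arange(K), atom_idx)
        U = D[:, other]
        Rv = R[:, c0:c1]  # view
        Av = A[:, c0:c1]
        Yv = Y[:, c0:c1]
        for g in atom_idx:
            beta_row = Av[g]
            sup = np.flatnonzero(beta_row)
            if sup.size == 0:
                # unused atom: re-seed from the worst-reconstructed patch
                res_norms = np.einsum("ij,ij->j", Rv, Rv)
                jstar = int(np.argmax(res_norms))
                col = Yv[:, jstar]
                nrm = np.linalg.norm(col)
                if nrm > 0:
                    D[:, g] = col / nrm
                    n_replaced += 1
                continue
            beta = beta_row[sup]
            c = float(beta @ beta)
            b = Rv @ beta_row + D[:, g] * c  # E_j beta^T (dense matvec on the view)
            d = _solve_atom(b, c, U, eta)
            nrm = float(np.linalg.norm(d))
            if nrm < 1e-12:
                continue
            d = d / nrm
            d_old = D[:, g]
            # guarded objective change: fidelity counted twice (the two
            # coinciding terms), incoherence over ordered block pairs
            delta = -4.0 * float((d - d_old) @ b)
            if eta > 0 and U.shape[1] > 0:
                pu_new = U.T @ d
                pu_old = U.T @ d_old
                delta += 2.0 * eta * float(pu_new @ pu_new - pu_old @ pu_old)
            if delta <= _GUARD_EPS * (1.0 + c):
                Rv[:, sup] += np.outer(d_old - d, beta)
                D[:, g] = d
    return StructuredDictionary.from_full(D, Kp, Kt, Ks), n_replaced, R


def learn(
    Yp: PatchMatrix | np.ndarray,
    Yt: PatchMatrix | np.ndarray,
    config: LearnConfig | None = None,
) -> tuple[StructuredDictionary, TrainTrace]:
    """Alternating optimization: structured coding, then atom updates.

    Stops at ``max_iters`` or when the relative objective change falls
    below ``rel_tol`` on a replacement-free iteration.  The per-sample
    coding step keeps the previous iteration's code whenever it fits the
    current dictionary better than the fresh greedy code, which (together
    with the atom guard) makes the monitored trace non-increasing.
    """
    config = config or LearnConfig()
    Yp_c, Yt_c = _columns(Yp), _columns(Yt)
    Np = Yp_c.shape[1]
    dictionary = initialize_dictionary(Yp_c, Yt_c, config)
    trace = TrainTrace()
    Ap_prev = At_prev = None
    R_prev = None  # residual of previous codes under the current dictionary
    J_prev = None

    for it in range(1, config.max_iters + 1):
        Ap, res_p = _code(Yp_c, dictionary, PSP, config)
        At, res_t = _code(Yt_c, dictionary, TTP, config)
        if R_prev is not None:
            # per column, keep the previous iteration's code when it fits
            # the current dictionary better than the fresh greedy code
            r_old = np.linalg.norm(R_prev, axis=0)
            Ap = _keep_better_cols(Ap, Ap_prev, res_p, r_old[:Np])
            At = _keep_better_cols(At, At_prev, res_t, r_old[Np:])
        dictionary, n_rep, R = _update_atoms_impl(Yp_c, Yt_c, Ap, At, dictionary, config)
        if config.coding == "l1":
            J = objective(Yp_c, Yt_c, Ap, At, dictionary, config)
        else:
            J = 2.0 * float(np.sum(R * R)) + config.eta * incoherence(dictionary)
        trace.objective_per_iter.append(J)
        if n_rep > 0:
            trace.replacement_iterations.append(it)
            trace.atom_replacements += n_rep
        if (
            J_prev is not None
            and n_rep == 0
            and abs(J - J_prev) <= config.rel_tol * max(abs(J_prev), 1e-12)
        ):
            trace.converged = True
            break
        J_prev = J
        Ap_prev, At_prev, R_prev = Ap, At, R
    return dictionary, trace


def save_dictionary(dictionary: StructuredDictionary, path, config: LearnConfig | None = None,
                    trace: TrainTrace | None = None) -> None:
    """Persist a structured dictionary as an array archive carrying block
    sizes, a config echo and the training trace."""
    import json as _json

    payload = {
        "D_p": dictionary.D_p, "D_t": dictionary.D_t, "D_s": dictionary.D_s,
    }
    if config is not None:
        payload["config_json"] = np.array(_json.dumps(dataclasses.asdict(config)))
    if trace is not None:
        payload["objective_per_iter"] = np.asarray(trace.objective_per_iter)
        payload["replacement_iterations"] = np.asarray(trace.replacement_iterations, dtype=int)
        payload["converged"] = np.array(trace.converged)
    np.savez_compressed(path, **payload)


def load_dictionary(path) -> tuple[StructuredDictionary, TrainTrace | None]:
    """Load a dictionary written by :func:`save_dictionary`."""
    with np.load(path, allow_pickle=False) as npz:
        d = StructuredDictionary(npz["D_p"], npz["D_t"], npz["D_s"])
        trace = None
        if "objective_per_iter" in npz:
            trace = TrainTrace(
                objective_per_iter=npz["objective_per_iter"].tolist(),
                replacement_iterations=npz["replacement_iterations"].tolist(),
                atom_replacements=len(npz["replacement_iterations"]),
                converged=bool(npz["converged"]),
            )
    return d, trace


def _keep_better_cols(
    A_new: np.ndarray, A_old: np.ndarray, r_new: np.ndarray, r_old: np.ndarray
) -> np.ndarray:
    """Column-wise code selection by residual norm under the current
    dictionary (strictly smaller wins; ties keep the fresh code)."""
    worse = r_new > r_old
    if np.any(worse):
        A_new = A_new.copy()
        A_new[:, worse] = A_old[:, worse]
    return A_new
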