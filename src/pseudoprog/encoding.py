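"""Sparse encoding: orthogonal matching pursuit and the dual-encoding scheme.

Every patch is encoded twice, over the PsP+shared compound dictionary
``D_ps = [D_p, D_s]`` and over the TTP+shared compound ``D_ts = [D_t, D_s]``.
The discriminative code of a patch is the concatenation of the two
class-specific coefficient blocks with the shared-block coefficients
discarded: shared atoms absorb what both classes have in common and carry no
discriminative information.  Encoding never sees labels — it is a pure
function of (patches, dictionary, config).

OMP here is the orthogonal variant: at each greedy step the atom most
correlated with the current residual is added (ties broken by lowest atom
index) and the coefficients are refit by least squares on the whole selected
support, so residual norms are non-increasing per step.  Pursuit stops at
``sparsity_k`` atoms or when the residual norm drops to ``sigma``, whichever
triggers first.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .patches import PatchMatrix

if TYPE_CHECKING:  # pragma: no cover - avoid circular import at runtime
    from .dictlearn import StructuredDictionary


@dataclass
class EncodeConfig:
    """Encoding parameters: nonzeros per code and the residual tolerance.

    ``sigma`` defaults to e^-6 (the natural constant raised to -6,
    ~2.48e-3); pass 1e-6 explicitly for the stricter reading.
    """

    sparsity_k: int = 10
    sigma: float = math.exp(-6)

    def __post_init__(self) -> None:
        if self.sparsity_k < 1:
            raise ValueError("sparsity_k must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def replace(self, **kw) -> "EncodeConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class DiscriminativeCodeMatrix:
    """(Kp+Kt) x N matrix of per-patch discriminative codes.

    Rows 1..Kp hold the PsP-specific coefficients from the D_ps encoding,
    rows Kp+1..Kp+Kt the TTP-specific coefficients from the D_ts encoding;
    shared-dictionary coefficients are nowhere present.  Column provenance
    (subject id) is inherited from the patch matrix.
    """

    codes: np.ndarray
    Kp: int
    Kt: int
    subject_ids: np.ndarray

    @property
    def n_features(self) -> int:
        return self.codes.shape[0]

    @property
    def n_patches(self) -> int:
        return self.codes.shape[1]

    def for_subject(self, subject_id: str) -> np.ndarray:
        return self.codes[:, self.subject_ids == subject_id]


def omp_batch(
    Y: np.ndarray,
    D: np.ndarray,
    sparsity_k: int,
    sigma: float = math.exp(-6),
) -> tuple[np.ndarray, np.ndarray]:
    """Batch orthogonal matching pursuit.

    Encodes every column of ``Y`` (m x N) over the unit-norm dictionary
    ``D`` (m x K).  Returns (K x N coefficient matrix, length-N residual
    norms).  Implemented with the Gram-matrix recursion so the inner loop
    touches only K x K and N x k x k arrays.
    """
    Y = np.asarray(Y, dtype=float)
    D = np.asarray(D, dtype=float)
    if Y.ndim != 2 or D.ndim != 2:
        raise ValueError("Y and D must be 2-D arrays")
    if not np.all(np.isfinite(Y)):
        raise ValueError("NaN or Inf in input signals")
    m, N = Y.shape
    K = D.shape[1]
    if D.shape[0] != m:
        raise ValueError(f"dimension mismatch: signals of length {m}, atoms of length {D.shape[0]}")
    if sparsity_k > K:
        raise ValueError(f"sparsity_k={sparsity_k} exceeds dictionary size K={K}")

    A = np.zeros((K, N))
    if N == 0:
        return A, np.zeros(0)

    G = D.T @ D                       # K x K
    H = D.T @ Y                       # K x N
    ynorm2 = np.einsum("ij,ij->j", Y, Y)
    res2 = ynorm2.copy()
    support = np.full((N, sparsity_k), -1, dtype=np.intp)
    coef = np.zeros((N, sparsity_k))
    nsel = np.zeros(N, dtype=np.intp)
    corr = H.copy()                   # correlations with current residual
    chosen = np.zeros((K, N), dtype=bool)
    active = res2 > sigma**2

    for step in range(sparsity_k):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        absc = np.abs(corr[:, idx])
        absc[chosen[:, idx]] = -1.0   # never reselect an atom
        sel = np.argmax(absc, axis=0)               # first max = lowest index on ties
        ok = absc[sel, np.arange(idx.size)] > 1e-13  # residual orthogonal to all atoms
        idx, sel = idx[ok], sel[ok]
        if idx.size == 0:
            active[:] = False
            break
        support[idx, step] = sel
        chosen[sel, idx] = True
        nsel[idx] = step + 1
        j = step + 1
        S = support[idx, :j]                         # (n, j)
        Gs = G[S[:, :, None], S[:, None, :]]         # (n, j, j)
        hs = H[S, idx[:, None]]                      # (n, j)
        try:
            x = np.linalg.solve(Gs, hs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            x = np.stack([np.linalg.lstsq(Gs[i], hs[i], rcond=None)[0] for i in range(len(idx))])
        coef[idx, :j] = x
        # residual correlations: H - G[:, S] @ x, and residual norm update
        corr[:, idx] = H[:, idx] - np.einsum("knj,nj->kn", G[:, S], x)
        res2[idx] = np.maximum(ynorm2[idx] - np.einsum("nj,nj->n", x, hs), 0.0)
        finished = res2[idx] <= sigma**2
        active[idx[finished]] = False

    cols = np.repeat(np.arange(N), nsel)
    rows = support[support >= 0]
    A[rows, cols] = coef[np.nonzero(support >= 0)]
    return A, np.sqrt(res2)


def omp(y: np.ndarray, D_sub: np.ndarray, config: EncodeConfig | None = None) -> np.ndarray:
    """Encode a single vector over a unit-norm sub-dictionary; returns the
    length-K' sparse coefficient vector."""
    config = config or EncodeConfig()
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    A, _ = omp_batch(y, D_sub, config.sparsity_k, config.sigma)
    return A[:, 0]


def _patch_columns(patches: PatchMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(patches, PatchMatrix):
        return patches.columns, patches.subject_ids
    Y = np.asarray(patches, dtype=float)
    return Y, np.full(Y.shape[1], "", dtype=object)


def dual_encode(
    patches: PatchMatrix | np.ndarray,
    dictionary: StructuredDictionary,
    config: EncodeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, DiscriminativeCodeMatrix]:
    """Encode every patch over both compound dictionaries.

    Returns ``(A_ps, A_ts, disc)`` where ``A_ps`` is the (Kp+Ks) x N code
    block over [D_p, D_s], ``A_ts`` the (Kt+Ks) x N block over [D_t, D_s],
    and ``disc`` the discriminative matrix stacking the D_p rows of A_ps on
    the D_t rows of A_ts (shared rows discarded).
    """
    config = config or EncodeConfig()
    Y, subject_ids = _patch_columns(patches)
    if Y.shape[0] != dictionary.m:
        raise ValueError(
            f"patch length {Y.shape[0]} does not match atom length {dictionary.m}"
        )
    A_ps, _ = omp_batch(Y, dictionary.D_ps, config.sparsity_k, config.sigma)
    A_ts, _ = omp_batch(Y, dictionary.D_ts, config.sparsity_k, config.sigma)
    codes = np.vstack([A_ps[: dictionary.Kp], A_ts[: dictionary.Kt]])
    disc = DiscriminativeCodeMatrix(
        codes=codes, Kp=dictionary.Kp, Kt=dictionary.Kt, subject_ids=subject_ids
    )
    return A_ps, A_ts, disc


def save_codes(disc: DiscriminativeCodeMatrix, path) -> None:
    """Persist a discriminative code matrix as a compressed sparse column
    archive with the (Kp, Kt) header and the column -> subject index."""
    from scipy import sparse

    sp = sparse.csc_matrix(disc.codes)
    np.savez_compressed(
        path,
        data=sp.data, indices=sp.indices, indptr=sp.indptr, shape=sp.shape,
        Kp=disc.Kp, Kt=disc.Kt,
        subject_ids=np.asarray(disc.subject_ids, dtype="U64"),
    )


def load_codes(path) -> DiscriminativeCodeMatrix:
    """Load a code matrix written by :func:`save_codes`."""
    from scipy import sparse

    with np.load(path, allow_pickle=False) as npz:
        sp = sparse.csc_matrix(
            (npz["data"], npz["indices"], npz["indptr"]), shape=tuple(npz["shape"])
        )
        return DiscriminativeCodeMatrix(
            codes=sp.toarray(),
            Kp=int(npz["Kp"]),
            Kt=int(npz["Kt"]),
            subject_ids=npz["subject_ids"].astype(object),
        )


def residual_pair(
    patches: PatchMatrix | np.ndarray,
    dictionary: StructuredDictionary,
    config: EncodeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch reconstruction residual norms under the two compound
    dictionaries, ``(r_ps, r_ts)`` — the diagnostic behind the class
    consistency of dual encoding: PsP-like patches reconstruct better under
    [D_p, D_s] and symmetrically for TTP."""
    config = config or EncodeConfig()
    Y, _ = _patch_columns(patches)
    _, r_ps = omp_batch(Y, dictionary.D_ps, config.sparsity_k, config.sigma)
    _, r_ts = omp_batch(Y, dictionary.D_ts, config.sparsity_k, config.sigma)
    return r_ps, r_ts
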