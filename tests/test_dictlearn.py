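"""Structured dictionary learning: initialization, structured coding, atom
updates, the monitored objective and its descent."""

import numpy as np
import pytest

from pseudoprog.dictlearn import (
    PSP,
    TTP,
    LearnConfig,
    StructuredDictionary,
    _solve_atom,
    code_with_structure,
    cross_gram,
    incoherence,
    initialize_dictionary,
    learn,
    objective,
    update_atoms,
)
from tests.conftest import normalized_columns, random_dictionary


def small_config(**kw):
    base = dict(Kp=2, Kt=2, Ks=1, sparsity_k=2, eta=0.1, max_iters=5, seed=0)
    base.update(kw)
    return LearnConfig(**base)


# ---------------------------------------------------------------- initialize


def test_initialization_draws_atoms_from_class_pools(rng):
    Yp = normalized_columns(rng, 16, 10)
    Yt = normalized_columns(rng, 16, 10)
    d = initialize_dictionary(Yp, Yt, small_config())
    assert d.full.shape == (16, 5)
    assert np.abs(np.linalg.norm(d.full, axis=0) - 1).max() < 1e-10
    for j in range(d.Kp):
        assert any(np.allclose(d.D_p[:, j], Yp[:, i]) for i in range(10))
    for j in range(d.Kt):
        assert any(np.allclose(d.D_t[:, j], Yt[:, i]) for i in range(10))
    # deterministic given seed
    d2 = initialize_dictionary(Yp, Yt, small_config())
    np.testing.assert_array_equal(d.full, d2.full)


def test_initialization_requires_enough_patches(rng):
    Yp = normalized_columns(rng, 16, 2)
    Yt = normalized_columns(rng, 16, 10)
    with pytest.raises(ValueError, match="Kp\\+Ks"):
        initialize_dictionary(Yp, Yt, small_config())


# -------------------------------------------------------- structured coding


def test_codes_of_one_class_never_touch_other_specific_block(rng):
    cfg = small_config()
    d = random_dictionary(rng, 16, 2, 2, 1)
    Yp = normalized_columns(rng, 16, 8)
    A = code_with_structure(Yp, d, PSP, cfg)
    assert np.all(A[2:4] == 0)  # D_t band exactly zero
    At = code_with_structure(Yp, d, TTP, cfg)
    assert np.all(At[0:2] == 0)


def test_atom_column_codes_as_its_own_indicator(rng):
    d = random_dictionary(rng, 16, 3, 3, 1)
    cfg = small_config(Kp=3, Kt=3, Ks=1)
    A = code_with_structure(d.D_p[:, [1]], d, PSP, cfg)
    assert A[1, 0] == pytest.approx(1.0)
    recon = d.full @ A[:, 0]
    np.testing.assert_allclose(recon, d.D_p[:, 1], atol=1e-10)


def test_single_nonzero_code_is_max_correlation_atom(rng):
    d = random_dictionary(rng, 16, 4, 4, 2)
    cfg = small_config(Kp=4, Kt=4, Ks=2, sparsity_k=1)
    y = normalized_columns(rng, 16, 1)
    A = code_with_structure(y, d, PSP, cfg)
    perm = d.permitted_indices(PSP)
    corr = np.abs(d.full[:, perm].T @ y[:, 0])
    g = perm[int(np.argmax(corr))]
    assert np.flatnonzero(A[:, 0]).tolist() == [g]
    assert A[g, 0] == pytest.approx(float(d.full[:, g] @ y[:, 0]))


def test_sparsity_exceeding_permitted_subdictionary_rejected(rng):
    d = random_dictionary(rng, 16, 2, 2, 1)  # permitted sub-dictionary: 3 atoms
    with pytest.raises(ValueError, match="exceeds permitted"):
        code_with_structure(normalized_columns(rng, 16, 3), d,
                            PSP, small_config(Kp=4, Kt=4, Ks=2, sparsity_k=5))


# -------------------------------------------------------------- atom update


def test_eta_zero_update_is_normalized_rank_one_fit(rng):
    # single-atom blocks: E_j reduces to the class data itself
    d = random_dictionary(rng, 8, 1, 1, 0)
    Yp = normalized_columns(rng, 8, 5)
    Yt = normalized_columns(rng, 8, 4)
    Ap = np.zeros((2, 5)); Ap[0] = rng.standard_normal(5)
    At = np.zeros((2, 4)); At[1] = rng.standard_normal(4)
    cfg = small_config(Kp=1, Kt=1, Ks=0, sparsity_k=1, eta=0.0)
    new, n_rep = update_atoms(Yp, Yt, Ap, At, d, cfg)
    assert n_rep == 0
    b_p = Yp @ Ap[0]
    np.testing.assert_allclose(new.D_p[:, 0], b_p / np.linalg.norm(b_p), atol=1e-10)
    b_t = Yt @ At[1]
    np.testing.assert_allclose(new.D_t[:, 0], b_t / np.linalg.norm(b_t), atol=1e-10)


def test_incoherence_weight_shrinks_cross_block_projection(rng):
    # solver toy: one atom updated against two orthonormal other-block atoms
    U, _ = np.linalg.qr(rng.standard_normal((12, 2)))
    b = rng.standard_normal(12)
    c = 1.7
    prev = np.inf
    for eta in (0.0, 0.1, 1.0, 10.0, 100.0):
        dvec = _solve_atom(b, c, U, eta)
        dvec = dvec / np.linalg.norm(dvec)
        proj = float(np.sum((U.T @ dvec) ** 2))
        assert proj <= prev + 1e-12
        prev = proj


def test_unused_atom_replaced_by_worst_reconstructed_patch(rng):
    d = random_dictionary(rng, 8, 2, 1, 0)
    Yp = normalized_columns(rng, 8, 6)
    Yt = normalized_columns(rng, 8, 4)
    Ap = np.zeros((3, 6)); Ap[1] = rng.standard_normal(6)  # atom 0 unused
    At = np.zeros((3, 4)); At[2] = rng.standard_normal(4)
    cfg = small_config(Kp=2, Kt=1, Ks=0, sparsity_k=1, eta=0.0)
    R = Yp - d.full @ Ap
    jstar = int(np.argmax(np.einsum("ij,ij->j", R, R)))
    new, n_rep = update_atoms(Yp, Yt, Ap, At, d, cfg)
    assert n_rep >= 1
    np.testing.assert_allclose(new.D_p[:, 0], Yp[:, jstar], atol=1e-10)


# ----------------------------------------------------------------- objective


def brute_force_objective(Yp, Yt, Ap, At, d, cfg):
    """Independent term-by-term evaluation: explicit per-sample loops."""
    blocks = [d.D_p, d.D_t, d.D_s]
    total = 0.0
    for Y, A, spec in ((Yp, Ap, 0), (Yt, At, 1)):
        for i in range(Y.shape[1]):
            y = Y[:, i]
            a = A[:, i]
            full = y - d.full @ a
            a_spec = a[spec * d.Kp : spec * d.Kp + [d.Kp, d.Kt][spec]]
            a_sh = a[d.Kp + d.Kt :]
            own = y - blocks[spec] @ a_spec - d.D_s @ a_sh
            total += float(full @ full) + float(own @ own)
    inco = 0.0
    for i in range(3):
        for j in range(3):
            if i != j:
                inco += float(np.sum((blocks[i].T @ blocks[j]) ** 2))
    return total + cfg.eta * inco


def test_objective_matches_bruteforce_oracle(rng):
    d = random_dictionary(rng, 12, 3, 3, 2)
    cfg = small_config(Kp=3, Kt=3, Ks=2, eta=0.2)
    Yp = normalized_columns(rng, 12, 8)
    Yt = normalized_columns(rng, 12, 7)
    Ap = code_with_structure(Yp, d, PSP, cfg)
    At = code_with_structure(Yt, d, TTP, cfg)
    got = objective(Yp, Yt, Ap, At, d, cfg)
    want = brute_force_objective(Yp, Yt, Ap, At, d, cfg)
    assert got == pytest.approx(want, abs=1e-10)


def test_objective_asserts_structural_zero_pattern(rng):
    d = random_dictionary(rng, 12, 3, 3, 2)
    cfg = small_config(Kp=3, Kt=3, Ks=2)
    Yp = normalized_columns(rng, 12, 5)
    Yt = normalized_columns(rng, 12, 5)
    Ap = code_with_structure(Yp, d, PSP, cfg)
    At = code_with_structure(Yt, d, TTP, cfg)
    Ap[3, 0] = 0.5  # leak into the TTP band
    with pytest.raises(AssertionError, match="structural zero"):
        objective(Yp, Yt, Ap, At, d, cfg)


def test_objective_at_eta_zero_is_twice_residual_mass(rng):
    d = random_dictionary(rng, 12, 3, 3, 2)
    cfg = small_config(Kp=3, Kt=3, Ks=2, eta=0.0)
    Yp = normalized_columns(rng, 12, 6)
    Yt = normalized_columns(rng, 12, 6)
    Ap = code_with_structure(Yp, d, PSP, cfg)
    At = code_with_structure(Yt, d, TTP, cfg)
    res = np.sum((Yp - d.full @ Ap) ** 2) + np.sum((Yt - d.full @ At) ** 2)
    assert objective(Yp, Yt, Ap, At, d, cfg) == pytest.approx(2 * res, abs=1e-10)


# --------------------------------------------------------------------- learn


def test_perfectly_representable_data_reaches_zero_objective(rng):
    atoms = normalized_columns(rng, 10, 3)
    Yp = atoms[:, rng.integers(0, 3, size=12)]
    Yt_atoms = normalized_columns(rng, 10, 3)
    Yt = Yt_atoms[:, rng.integers(0, 3, size=12)]
    cfg = LearnConfig(Kp=3, Kt=3, Ks=0, sparsity_k=1, eta=0.0, max_iters=4, seed=1)
    _, trace = learn(Yp, Yt, cfg)
    assert trace.objective_per_iter[0] == pytest.approx(0.0, abs=1e-18)


def test_objective_descends_on_random_data(rng):
    Yp = normalized_columns(rng, 40, 150)
    Yt = normalized_columns(rng, 40, 150)
    cfg = LearnConfig(Kp=12, Kt=12, Ks=3, sparsity_k=5, eta=0.15,
                      max_iters=20, rel_tol=1e-15, seed=2)
    _, trace = learn(Yp, Yt, cfg)
    obj = np.array(trace.objective_per_iter)
    assert len(obj) == 20
    for it in range(1, len(obj)):
        if (it + 1) in trace.replacement_iterations:
            continue
        assert obj[it] <= obj[it - 1] + 1e-8 * abs(obj[it - 1])


def test_learn_is_deterministic(rng):
    Yp = normalized_columns(rng, 24, 60)
    Yt = normalized_columns(rng, 24, 60)
    cfg = LearnConfig(Kp=8, Kt=8, Ks=2, sparsity_k=4, max_iters=6, seed=5)
    d1, t1 = learn(Yp, Yt, cfg)
    d2, t2 = learn(Yp, Yt, cfg)
    np.testing.assert_array_equal(d1.full, d2.full)
    assert t1.objective_per_iter == t2.objective_per_iter


def test_incoherence_penalty_reduces_cross_gram_small(rng):
    wins = 0
    for seed in range(5):
        r = np.random.default_rng(200 + seed)
        Yp = normalized_columns(r, 30, 120)
        Yt = normalized_columns(r, 30, 120)
        masses = []
        for eta in (0.15, 0.0):
            cfg = LearnConfig(Kp=8, Kt=8, Ks=2, sparsity_k=4, eta=eta,
                              max_iters=8, seed=seed)
            d, _ = learn(Yp, Yt, cfg)
            masses.append(cross_gram(d.D_p, d.D_t))
        wins += masses[0] < masses[1]
    assert wins >= 4


def test_trained_codes_keep_structural_purity(rng):
    Yp = normalized_columns(rng, 24, 50)
    Yt = normalized_columns(rng, 24, 50)
    cfg = LearnConfig(Kp=6, Kt=6, Ks=2, sparsity_k=3, max_iters=5, seed=3)
    d, _ = learn(Yp, Yt, cfg)
    d.check_unit_norm()
    Ap = code_with_structure(Yp, d, PSP, cfg)
    At = code_with_structure(Yt, d, TTP, cfg)
    assert np.all(Ap[6:12] == 0)
    assert np.all(At[0:6] == 0)


def test_l1_coding_path_respects_structure(rng):
    Yp = normalized_columns(rng, 20, 30)
    Yt = normalized_columns(rng, 20, 30)
    cfg = LearnConfig(Kp=5, Kt=5, Ks=2, sparsity_k=3, lambda1=0.05,
                      coding="l1", max_iters=2, seed=4)
    d, trace = learn(Yp, Yt, cfg)
    A = code_with_structure(Yp, d, PSP, cfg)
    assert np.all(A[5:10] == 0)
    assert np.isfinite(trace.objective_per_iter).all()


def test_incoherence_counts_ordered_block_pairs(rng):
    d = random_dictionary(rng, 10, 3, 3, 2)
    manual = 2 * (
        cross_gram(d.D_p, d.D_t) + cross_gram(d.D_p, d.D_s) + cross_gram(d.D_t, d.D_s)
    )
    assert incoherence(d) == pytest.approx(manual, rel=1e-12)
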