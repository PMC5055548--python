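"""Pooling, DX scoring, sequential feature selection and the mean-FA
baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudoprog.features import (
    dx_scores,
    mean_fa_baseline,
    pool_cohort,
    pool_subject,
    select_features,
)
from pseudoprog.encoding import DiscriminativeCodeMatrix
from pseudoprog.patches import PatchConfig, raw_patch_grid
from pseudoprog.phantom import PhantomConfig, SpatioTemporalVolume, generate_subject


# ------------------------------------------------------------------ pooling


def test_pooling_formulas_on_reference_row():
    row = np.array([[0.2, -0.9, 0.5]])
    assert pool_subject(row, "max").H[0] == pytest.approx(0.9)
    assert pool_subject(row, "sqrt").H[0] == pytest.approx(np.sqrt(1.10 / 3))
    assert pool_subject(row, "mean").H[0] == pytest.approx(1.6 / 3)
    assert pool_subject(row, "sum").H[0] == pytest.approx(1.6)
    comb = pool_subject(row, "comb").H
    assert comb.shape == (4,)
    np.testing.assert_allclose(comb, [0.9, np.sqrt(1.10 / 3), 1.6 / 3, 1.6])


def test_all_zero_row_pools_to_zero():
    row = np.zeros((3, 5))
    for method in ("max", "sqrt", "mean", "sum", "comb"):
        assert np.all(pool_subject(row, method).H == 0)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
def test_pooling_identities(row):
    codes = np.asarray(row)[None, :]
    n = codes.shape[1]
    h_sum = pool_subject(codes, "sum").H[0]
    h_mean = pool_subject(codes, "mean").H[0]
    h_sqrt = pool_subject(codes, "sqrt").H[0]
    h_max = pool_subject(codes, "max").H[0]
    assert h_sum == pytest.approx(n * h_mean, rel=1e-12, abs=1e-12)
    assert h_sqrt <= h_max + 1e-12  # power-mean inequality
    perm = np.random.default_rng(0).permutation(n)
    assert pool_subject(codes[:, perm], "max").H[0] == h_max


def test_pooling_rejects_empty_subject_and_unknown_method(rng):
    with pytest.raises(ValueError, match="zero retained"):
        pool_subject(np.empty((4, 0)), "max", subject_id="s9")
    with pytest.raises(ValueError, match="unknown pooling"):
        pool_subject(np.ones((2, 2)), "median")


def test_pool_cohort_row_order_follows_subject_order(rng):
    codes = rng.standard_normal((4, 6))
    disc = DiscriminativeCodeMatrix(
        codes=codes, Kp=2, Kt=2,
        subject_ids=np.array(["a", "a", "b", "b", "b", "a"], dtype=object),
    )
    X = pool_cohort(disc, ["b", "a"], "max")
    np.testing.assert_allclose(X[0], np.abs(codes[:, 2:5]).max(axis=1))
    np.testing.assert_allclose(X[1], np.abs(codes[:, [0, 1, 5]]).max(axis=1))


# ---------------------------------------------------------------- DX scores


def test_dx_reference_values():
    # class means 3 and 1 with unit class SDs -> DX = (3-1)^2 / (1+1) = 2
    h = np.sqrt(2) / 2
    X = np.array([[3 + h], [3 - h], [1 + h], [1 - h]])
    y = np.array(["A", "A", "B", "B"])
    assert dx_scores(X, y)[0] == pytest.approx(2.0)
    m = np.array([[3.0], [3.0], [3.0], [3.0]])
    assert dx_scores(m + np.array([[0.1], [-0.1], [0.1], [-0.1]]), y)[0] == 0.0


def test_dx_matches_bruteforce_oracle(rng):
    X = rng.standard_normal((20, 50))
    y = np.array(["pos"] * 9 + ["neg"] * 11)
    got = dx_scores(X, y, positive_label="pos")
    for f in range(50):
        a, b = X[:9, f], X[9:, f]
        want = (a.mean() - b.mean()) ** 2 / (a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2)
        assert got[f] == pytest.approx(want, abs=1e-12)


def test_dx_invariant_under_affine_feature_maps(rng):
    X = rng.standard_normal((16, 8))
    y = np.array(["A"] * 8 + ["B"] * 8)
    base = dx_scores(X, y)
    np.testing.assert_allclose(dx_scores(-3.7 * X + 11.0, y), base, rtol=1e-9)


def test_dx_degenerate_denominators():
    y = np.array(["A", "A", "B", "B"])
    sep = np.array([[1.0], [1.0], [0.0], [0.0]])  # zero sds, distinct means
    assert dx_scores(sep, y)[0] == np.inf
    const = np.ones((4, 1))
    assert dx_scores(const, y)[0] == 0.0


def test_dx_requires_two_subjects_per_class():
    X = np.ones((3, 2))
    with pytest.raises(ValueError, match=">= 2 subjects"):
        dx_scores(X, np.array(["A", "B", "B"]))
    with pytest.raises(ValueError, match="two classes"):
        dx_scores(X, np.array(["A", "A", "A"]))


# ---------------------------------------------------------------- selection


def test_perfect_feature_ranked_first_and_selected(rng):
    n = 20
    y = np.array(["A"] * 10 + ["B"] * 10)
    X = rng.standard_normal((n, 5))
    X[:, 2] = np.where(y == "A", 5.0, -5.0) + 0.01 * rng.standard_normal(n)
    ranking = select_features(X, y, n_folds=5, seed=0)
    assert ranking.order[0] == 2
    assert ranking.accuracy_curve[0] == pytest.approx(1.0)
    assert ranking.selected.tolist() == [2]


def test_ranking_order_follows_dx_with_index_tiebreak():
    y = np.array(["A"] * 4 + ["B"] * 4)
    X = np.zeros((8, 3))
    X[:, 0] = [5, 5, 5, 5, -5, -5, -5, -5]          # huge DX
    X[:, 1] = [1, 2, 1, 2, -1, -2, -1, -2]          # moderate DX
    X[:, 2] = np.arange(8) * 0.01                    # tiny DX
    ranking = select_features(X, y, n_folds=2, seed=0)
    assert ranking.order.tolist() == [0, 1, 2]
    assert np.all((ranking.accuracy_curve >= 0) & (ranking.accuracy_curve <= 1))


def test_selection_reproducible_under_fixed_seed(rng):
    X = rng.standard_normal((24, 10))
    y = np.array(["A"] * 12 + ["B"] * 12)
    r1 = select_features(X, y, n_folds=4, seed=3)
    r2 = select_features(X, y, n_folds=4, seed=3)
    np.testing.assert_array_equal(r1.selected, r2.selected)
    np.testing.assert_array_equal(r1.accuracy_curve, r2.accuracy_curve)


def test_max_prefix_caps_the_scan(rng):
    X = rng.standard_normal((16, 12))
    y = np.array(["A"] * 8 + ["B"] * 8)
    ranking = select_features(X, y, n_folds=4, seed=1, max_prefix=5)
    assert len(ranking.accuracy_curve) == 5
    assert len(ranking.selected) <= 5


# ----------------------------------------------------------- mean-FA baseline


def test_constant_image_gives_constant_mean_fa_features():
    vol = SpatioTemporalVolume(np.full((26, 26, 3), 0.37), "s0", "PsP")
    X = mean_fa_baseline([vol], PatchConfig(s=13, stride=13, t=3))
    assert X.shape == (1, 4)
    np.testing.assert_allclose(X, 0.37)


def test_mean_fa_feature_count_on_cropped_grid(rng):
    vol = SpatioTemporalVolume(rng.uniform(0, 1, (164, 143, 3)), "s0", "TTP")
    X = mean_fa_baseline([vol], PatchConfig(s=13, stride=13, t=3))
    assert X.shape == (1, 132)


def test_lesion_covering_mean_fa_features_have_top_dx():
    cfg = PhantomConfig(
        image_height=52, image_width=52, lesion_radius=10, lesion_center_jitter=0,
        background_texture_sd=0.0, temporal_drift_sd=0.0, noise_sd=0.005,
        n_psp=4, n_ttp=4,
    )
    pc = PatchConfig(s=13, stride=13, t=3)
    vols, masks = [], []
    for i, label in enumerate(["PsP"] * 4 + ["TTP"] * 4):
        v, m = generate_subject(label, cfg, np.random.default_rng(50 + i), f"s{i}")
        vols.append(v)
        masks.append(m)
    X = mean_fa_baseline(vols, pc)
    dx = dx_scores(X, np.array([v.label for v in vols]))
    _, rows, cols = raw_patch_grid(vols[0].values, pc)
    top = int(np.argmax(dx))
    r, c = rows[top], cols[top]
    assert masks[0][r : r + 13, c : c + 13].any()
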