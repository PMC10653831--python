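"""Coverage normalization for ordination, NMDS, PERMANOVA, PERMDISP."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from damdiff.ordination import (
    apply_scaling,
    euclidean_distance_matrix,
    fit_sample_scaling,
    nmds,
    normalized_beta_matrix,
    pairwise_permanova,
    permanova,
    permdisp,
    quantile_normalize,
)


# ---------------------------------------------------------------------------
# quantile normalization


def test_quantile_normalize_identity_on_identical_samples():
    x = np.array([[3.0], [1.0], [2.0]]) @ np.ones((1, 3))
    assert np.allclose(quantile_normalize(x), x)


def test_quantile_normalize_hand_example():
    x = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    out = quantile_normalize(x)
    assert np.allclose(out[:, 0], [2.5, 3.5, 4.5])
    assert np.allclose(out[:, 1], [2.5, 3.5, 4.5])


def test_quantile_normalize_sorted_vectors_identical():
    rng = np.random.default_rng(0)
    x = rng.gamma(3, 10, size=(500, 4))
    out = quantile_normalize(x)
    ref = np.sort(out[:, 0])
    for j in range(1, 4):
        assert np.allclose(np.sort(out[:, j]), ref)


def test_quantile_normalize_ties_get_spanned_mean():
    x = np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
    out = quantile_normalize(x)
    ref = np.sort(x, axis=0).mean(axis=1)  # [1, 1.5, 4]
    # first sample: two tied lowest values share mean(ref[0:2]) = 1.25
    assert np.allclose(out[:, 0], [1.25, 1.25, 4.0])


def test_quantile_normalize_rejects_missing():
    with pytest.raises(ValueError):
        quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# scaling regression


def test_fit_sample_scaling_exact_lines():
    x = np.array([10.0, 20.0, 30.0])
    assert fit_sample_scaling(x, x) == pytest.approx((1.0, 0.0), abs=1e-12)
    assert fit_sample_scaling(x, 2 * x + 3) == pytest.approx((2.0, 3.0), abs=1e-10)
    with pytest.raises(ValueError):
        fit_sample_scaling(np.ones(5), np.arange(5.0))


def test_fit_sample_scaling_matches_normal_equations():
    rng = np.random.default_rng(5)
    x = rng.uniform(10, 100, 200)
    y = 1.7 * x - 4.0 + rng.normal(0, 2, 200)
    slope, intercept = fit_sample_scaling(x, y)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert slope == pytest.approx(beta[0], abs=1e-10)
    assert intercept == pytest.approx(beta[1], abs=1e-10)


def test_apply_scaling_identity_and_ratio_preservation():
    cov = np.array([[50.0], [40.0]])
    met = np.array([[45.0], [20.0]])
    _, _, beta = apply_scaling(cov, met, [(1.0, 0.0)])
    assert np.allclose(beta, met / cov)
    # pure scaling (slope 2, intercept 0) preserves the ratio
    _, _, beta2 = apply_scaling(cov, met, [(2.0, 0.0)])
    assert np.allclose(beta2, met / cov)


def test_apply_scaling_positive_intercept_pulls_beta_up():
    cov = np.array([[50.0]])
    met = np.array([[45.0]])
    _, _, beta = apply_scaling(cov, met, [(1.0, 5.0)])
    assert beta[0, 0] == pytest.approx(50 / 55)
    assert beta[0, 0] > 45 / 50  # high-beta site moves toward 1


def test_apply_scaling_drops_nonpositive_coverage():
    cov = np.array([[2.0]])
    met = np.array([[1.0]])
    covp, metp, beta = apply_scaling(cov, met, [(1.0, -5.0)])
    assert np.isnan(beta[0, 0])


def test_normalized_beta_stays_in_unit_interval():
    rng = np.random.default_rng(9)
    cov = rng.integers(20, 120, size=(300, 4)).astype(float)
    met = np.floor(cov * rng.uniform(0.3, 1.0, size=(300, 4)))
    beta, scaling = normalized_beta_matrix(cov, met)
    ok = ~np.isnan(beta)
    assert np.all((beta[ok] >= 0) & (beta[ok] <= 1))
    assert len(scaling) == 4


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_embeds_square_exactly():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    D = squareform(pdist(pts))
    _, stress, history = nmds(D, n_starts=10, seed=0)
    assert stress < 1e-4
    assert all(history[i + 1] <= history[i] + 1e-9 for i in range(len(history) - 1))


def test_nmds_three_points_stress_zero():
    D = squareform(pdist(np.array([[0, 0], [3, 0], [1, 5.0]])))
    _, stress, _ = nmds(D, n_starts=5, seed=1)
    assert stress < 1e-5


def test_nmds_input_validation():
    with pytest.raises(ValueError):
        nmds(np.array([[0.0, np.inf], [np.inf, 0.0]]))
    with pytest.raises(ValueError):
        nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


# ---------------------------------------------------------------------------
# PERMANOVA


def oracle_pseudo_f(D, labels):
    """Independent route: within-group sums of squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (D[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    k = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def oracle_exact_p(D, labels):
    labels = np.asarray(labels)
    f_obs = oracle_pseudo_f(D, labels)
    hits = total = 0
    for pm in itertools.permutations(range(len(labels))):
        hits += oracle_pseudo_f(D, labels[list(pm)]) >= f_obs - 1e-12
        total += 1
    return hits / total


def test_permanova_exact_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(6, 3))
    pts[3:] += 1.5
    D = squareform(pdist(pts))
    labels = ["a"] * 3 + ["b"] * 3
    f, p = permanova(D, labels, method="exact")
    assert f == pytest.approx(oracle_pseudo_f(D, labels), abs=1e-10)
    assert p == pytest.approx(oracle_exact_p(D, labels), abs=1e-12)


def test_permanova_matches_scikit_bio_statistic():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(7)
    pts = rng.normal(size=(9, 4))
    D = squareform(pdist(pts))
    labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
    f, _ = permanova(D, labels, n_perm=99, seed=0)
    r = skbio_permanova(DistanceMatrix(D), labels, permutations=99)
    assert f == pytest.approx(float(r["test statistic"]), abs=1e-10)


def test_permanova_separated_clusters_hit_enumeration_minimum():
    rng = np.random.default_rng(1)
    pts = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
    D = squareform(pdist(pts))
    _, p = permanova(D, ["a"] * 3 + ["b"] * 3, method="exact")
    # 2 of the 20 distinct partitions (the labelling and its swap) reach F_obs
    assert p == pytest.approx(0.1)


def test_permanova_null_p_roughly_uniform():
    rng = np.random.default_rng(4)
    ps = []
    for i in range(40):
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        _, p = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=i)
        ps.append(p)
    assert 0.3 < np.mean(ps) < 0.7


def test_permanova_monte_carlo_within_binomial_error_of_exact():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(7, 2))
    pts[4:] += 1.0
    D = squareform(pdist(pts))
    labels = ["a"] * 4 + ["b"] * 3
    _, p_exact = permanova(D, labels, method="exact")
    _, p_mc = permanova(D, labels, n_perm=999, seed=0)
    se = np.sqrt(p_exact * (1 - p_exact) / 999)
    assert abs(p_mc - p_exact) < 4 * se + 2 / 999


def test_permanova_validation():
    with pytest.raises(ValueError):
        permanova(np.zeros((3, 3)), ["a", "a", "a"])


# ---------------------------------------------------------------------------
# PERMDISP


def test_permdisp_centroid_distances_match_direct_computation():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(10, 3))
    labels = ["a"] * 5 + ["b"] * 5
    D = squareform(pdist(pts))
    res = permdisp(D, labels)
    direct = np.zeros(10)
    for g in ("a", "b"):
        idx = [i for i, l in enumerate(labels) if l == g]
        c = pts[idx].mean(axis=0)
        direct[idx] = np.linalg.norm(pts[idx] - c, axis=1)
    assert np.allclose(res["distances"], direct, atol=1e-8)


def test_permdisp_mirror_groups_equal_dispersion():
    pts = np.array([[1, 0], [2, 0], [3, 0.5], [-1, 0], [-2, 0], [-3, -0.5]], float)
    res = permdisp(squareform(pdist(pts)), ["a"] * 3 + ["b"] * 3)
    assert res["anova_F"] == pytest.approx(0.0, abs=1e-10)
    assert res["anova_p"] > 0.99


def test_permdisp_singleton_group_flagged():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(5, 2))
    res = permdisp(squareform(pdist(pts)), ["a"] * 4 + ["b"])
    assert res["singleton_groups"] == ["b"]
    assert res["distances"][4] == 0.0


def test_pairwise_permanova_covers_all_pairs():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(9, 2))
    D = squareform(pdist(pts))
    df = pairwise_permanova(D, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, n_perm=99)
    assert len(df) == 3
    assert set(map(tuple, df[["group_a", "group_b"]].values)) == {
        ("a", "b"), ("a", "c"), ("b", "c"),
    }


def test_distance_matrix_requires_complete_case():
    with pytest.raises(ValueError):
        euclidean_distance_matrix(np.array([[0.5, np.nan], [0.4, 0.6]]))
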