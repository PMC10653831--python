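"""Differential methylation: LRT, multiple testing, call rule, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from damdiff.differential import (
    DifferentialMethylation,
    adjust_pvalues,
    call_differential,
    compare_groups,
    logistic_test,
    logistic_test_vectorized,
    slim_pi0,
)
from damdiff.methylation import SampleDesign, filter_min_coverage, normalize_coverage_median
from damdiff.simulate import SimConfig, SimGroup, simulate_methylome


def analytic_2x2_lrt_p(m1, c1, m2, c2):
    """Closed-form two-proportion binomial likelihood-ratio test."""

    def ll(m, c, p):
        out = 0.0
        if m > 0:
            out += m * np.log(p)
        if c - m > 0:
            out += (c - m) * np.log(1 - p)
        return out

    p1, p2, p0 = m1 / c1, m2 / c2, (m1 + m2) / (c1 + c2)
    g = 2 * (ll(m1, c1, p1) + ll(m2, c2, p2) - ll(m1, c1, p0) - ll(m2, c2, p0))
    return stats.chi2.sf(max(g, 0.0), 1)


def test_identical_groups_give_null_result():
    p, d = logistic_test([(48, 50), (48, 50)], ["a", "b"])
    assert d == 0.0
    assert p == pytest.approx(1.0)


def test_one_sample_per_group_matches_analytic_lrt():
    rng = np.random.default_rng(4)
    for _ in range(50):
        c1, c2 = rng.integers(5, 100, 2)
        m1, m2 = rng.integers(0, c1 + 1), rng.integers(0, c2 + 1)
        p, d = logistic_test([(m1, c1), (m2, c2)], ["ref", "trt"])
        assert p == pytest.approx(analytic_2x2_lrt_p(m1, c1, m2, c2), abs=1e-8)
        assert d == pytest.approx(100 * (m2 / c2 - m1 / c1))


def test_lrt_matches_statsmodels_glm():
    """Independent route: per-sample binomial GLM fit by IRLS."""
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    for _ in range(10):
        cov = rng.integers(20, 80, size=6).astype(float)
        met = rng.binomial(cov.astype(int), rng.uniform(0.5, 0.95)).astype(float)
        codes = np.array([0, 0, 0, 1, 1, 1])
        p_mine, _, _ = logistic_test_vectorized(met[None, :], cov[None, :], codes)
        endog = np.column_stack([met, cov - met])
        exog = sm.add_constant(codes.astype(float))
        full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((6, 1)), family=sm.families.Binomial()).fit()
        lrt = 2 * (full.llf - null.llf)
        assert p_mine[0] == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-6)


def test_complete_separation_yields_finite_extreme_p():
    p, d = logistic_test([(0, 50), (50, 50)], ["a", "b"])
    assert np.isfinite(p) and p < 1e-10
    assert d == 100.0


def test_zero_group_coverage_site_skipped_with_reason():
    cov = [[np.nan, 20.0, 20.0, 20.0], [20.0, 20.0, 20.0, 20.0]]
    met = [[np.nan, 10.0, 10.0, 10.0], [18.0, 18.0, 18.0, 18.0]]
    t = make_table(cov, met, samples=["r1", "r2", "t1", "t2"])
    d = SampleDesign(("r1", "r2", "t1", "t2"), ("ref", "ref", "trt", "trt"))
    res = DifferentialMethylation(t, d, "ref", "trt").fit(adjust="BH")
    assert res.frame["call"].tolist() == ["not_tested", "not_significant"]
    assert res.frame["reason"].tolist() == ["missing_sample", "ok"]


# ---------------------------------------------------------------------------
# multiple testing


def brute_force_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def test_bh_hand_ladder():
    assert adjust_pvalues([0.05], "BH").tolist() == [0.05]
    q = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
    assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(6)
    for n in (1, 2, 17, 333, 1000):
        p = rng.uniform(size=n)
        assert adjust_pvalues(p, "BH").tolist() == pytest.approx(brute_force_bh(list(p)))


def test_bh_monotone_in_p_after_sorting():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=500)
    q = adjust_pvalues(p, "BH")
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_slim_pi0_near_one_on_uniform_and_q_close_to_bh():
    rng = np.random.default_rng(12)
    p = rng.uniform(size=3000)
    pi0 = slim_pi0(p)
    assert 0.9 <= pi0 <= 1.0
    q_slim = adjust_pvalues(p, "SLIM")
    q_bh = adjust_pvalues(p, "BH")
    assert np.all(q_slim <= q_bh + 1e-12)
    assert np.max(np.abs(q_slim - q_bh)) < 0.12


def test_slim_detects_signal_fraction():
    rng = np.random.default_rng(13)
    p = np.concatenate([rng.uniform(size=1600), rng.beta(0.05, 10, size=400)])
    assert slim_pi0(p) < 0.93


def test_slim_falls_back_to_bh_on_short_input():
    p = [0.01, 0.5, 0.9]
    assert adjust_pvalues(p, "SLIM").tolist() == adjust_pvalues(p, "BH").tolist()


def test_adjust_edge_cases():
    assert adjust_pvalues([], "BH").size == 0
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5], "BH")
    with pytest.raises(ValueError):
        adjust_pvalues([0.5], "bonferroni")


# ---------------------------------------------------------------------------
# calling


@pytest.mark.parametrize(
    "q,diff,call",
    [
        (0.01, 15, "increased"),
        (0.01, 10, "not_significant"),  # strict >
        (0.05, 15, "not_significant"),  # strict <
        (0.06, 50, "not_significant"),
        (0.01, -15, "decreased"),
        (0.01, -10, "not_significant"),
    ],
)
def test_call_rule_boundaries(q, diff, call):
    df = pd.DataFrame({"q_value": [q], "meth_diff": [float(diff)]})
    assert call_differential(df).loc[0, "call"] == call


# ---------------------------------------------------------------------------
# full comparison


def _sim_table(seed, n_sites=600, n_diff=0, drift=0.1, beta=0.97):
    cfg = SimConfig(
        n_sites=n_sites,
        seed=seed,
        beta_high_mean=beta,
        n_differential=n_diff,
        groups={
            "reference": SimGroup(3, drift, False),
            "treatment": SimGroup(3, drift, True),
        },
    )
    table, design, truth = simulate_methylome(n_sites, cfg)
    table = normalize_coverage_median(filter_min_coverage(table))
    return table, design, truth


def test_identical_groups_zero_calls():
    table, design, _ = _sim_table(seed=21, drift=0.0)
    res = compare_groups(table, design, "reference", "treatment", adjust="BH")
    assert (res["call"].isin(["not_significant", "not_tested"])).all()


def test_antisymmetry_of_group_swap():
    table, design, _ = _sim_table(seed=22, n_diff=10)
    ab = compare_groups(table, design, "reference", "treatment", adjust="BH")
    ba = compare_groups(table, design, "treatment", "reference", adjust="BH")
    assert np.allclose(ab["meth_diff"], -ba["meth_diff"], equal_nan=True)
    assert np.allclose(ab["p_value"], ba["p_value"], equal_nan=True)


def test_parameter_recovery_injected_sites():
    table, design, truth = _sim_table(seed=23, n_sites=1000, n_diff=15)
    res = compare_groups(table, design, "reference", "treatment", adjust="BH")
    true_idx = set(truth.group_beta.index[truth.differential])
    called = set(res[res["call"].isin(["increased", "decreased"])].index)
    assert len(true_idx & called) / len(true_idx) >= 0.8
    assert len(called - true_idx) / max(len(called), 1) <= 0.05


def test_null_pipeline_type_I_error_below_nominal():
    """filter -> normalize -> test -> BH -> call makes ~no false calls."""
    table, design, _ = _sim_table(seed=24, n_sites=800, drift=0.0, beta=0.9)
    res = compare_groups(table, design, "reference", "treatment", adjust="BH")
    n_calls = res["call"].isin(["increased", "decreased"]).sum()
    assert n_calls / len(res) <= 0.05


def test_reference_group_missing_raises():
    table, design, _ = _sim_table(seed=25, n_sites=60)
    with pytest.raises(ValueError):
        DifferentialMethylation(table, design, "nope", "treatment")


def test_results_summary_and_tsv(tmp_path):
    table, design, _ = _sim_table(seed=26, n_sites=120)
    res = DifferentialMethylation(table, design, "reference", "treatment").fit(adjust="BH")
    s = res.summary()
    assert "reference" in s and "increased" in s
    out = tmp_path / "diff.tsv"
    res.to_tsv(out)
    back = pd.read_csv(out, sep="\t", comment="#")
    assert {"meth_diff", "p_value", "q_value", "call"} <= set(back.columns)
    assert len(back) == table.n_sites
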