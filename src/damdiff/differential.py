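"""Per-site differential methylation by binomial logistic regression.

Each adenine is tested independently: per-sample (methylated, coverage)
counts enter a binomial logistic model with group membership as the only
covariate, and significance comes from the likelihood-ratio chi-square of
the group model against the intercept-only model.  Because the model has a
single categorical factor, the maximum-likelihood fitted probability of
each group is its pooled methylated/coverage ratio, so the likelihood
ratio has a closed form over group totals that is identical (to machine
precision) to iterating a GLM per site; the closed form is what is
evaluated, vectorized across sites.

A site is called differentially methylated when its multiplicity-adjusted
q-value falls below ``q_cut`` (default 0.05) and the pooled percent
methylation difference exceeds ``diff_cut`` percentage points (default
10) in absolute value — both thresholds strict.

The model/results surface follows statsmodels conventions:
``DifferentialMethylation(table, design, reference, treatment).fit()``
returns a :class:`DifferentialResults` carrying per-site estimates,
p/q-values, calls and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import MethylationTable, SampleDesign

__all__ = [
    "logistic_test",
    "logistic_test_vectorized",
    "adjust_pvalues",
    "slim_pi0",
    "call_differential",
    "compare_groups",
    "DifferentialMethylation",
    "DifferentialResults",
]


# ---------------------------------------------------------------------------
# likelihood-ratio test


def _binom_ll(m: np.ndarray, c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) = 0 convention."""
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.zeros(np.broadcast(m, c, p).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(m > 0, m * np.log(p), 0.0)
        t2 = np.where(c - m > 0, (c - m) * np.log1p(-p), 0.0)
    return t1 + t2


def logistic_test_vectorized(
    methylated: np.ndarray, coverage: np.ndarray, group_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-vs-intercept binomial LRT for many sites at once.

    Parameters
    ----------
    methylated, coverage : (n_sites, n_samples) arrays
    group_index : (n_samples,) integer array of group codes 0..k-1

    Returns
    -------
    p_values, lrt_statistics, group_pooled_beta (n_sites, k)
    """
    methylated = np.asarray(methylated, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    groups = np.unique(group_index)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    Mg = np.stack(
        [methylated[:, group_index == g].sum(axis=1) for g in groups], axis=1
    )
    Cg = np.stack(
        [coverage[:, group_index == g].sum(axis=1) for g in groups], axis=1
    )
    if np.any(Cg <= 0):
        raise ValueError("zero total coverage in a group at some site; filter first")
    M, C = Mg.sum(axis=1), Cg.sum(axis=1)
    pg = Mg / Cg
    p0 = (M / C)[:, None]
    lrt = 2.0 * (_binom_ll(Mg, Cg, pg).sum(axis=1) - _binom_ll(Mg, Cg, p0).sum(axis=1))
    lrt = np.maximum(lrt, 0.0)  # guard tiny negative round-off
    pvals = stats.chi2.sf(lrt, df=k - 1)
    return pvals, lrt, pg


def logistic_test(
    site_counts: list[tuple[int, int]], groups: list, reference=None
) -> tuple[float, float]:
    """Binomial logistic LRT for one site.

    ``site_counts`` is one ``(methylated, coverage)`` pair per sample and
    ``groups`` the per-sample labels (two levels).  Returns ``(p_value,
    meth_diff)`` where ``meth_diff`` is 100 * (pooled beta of the
    treatment level - pooled beta of the reference level); the reference
    defaults to the first label encountered.
    """
    m = np.array([mc[0] for mc in site_counts], dtype=float)[None, :]
    c = np.array([mc[1] for mc in site_counts], dtype=float)[None, :]
    labels = list(dict.fromkeys(groups))  # order-preserving unique
    if reference is None:
        reference = labels[0]
    treatment = [g for g in labels if g != reference]
    if len(treatment) != 1:
        raise ValueError("logistic_test expects exactly two group levels")
    codes = np.array([0 if g == reference else 1 for g in groups])
    pvals, _lrt, pg = logistic_test_vectorized(m, c, codes)
    meth_diff = 100.0 * (pg[0, 1] - pg[0, 0])
    return float(pvals[0]), float(meth_diff)


# ---------------------------------------------------------------------------
# multiple testing


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def slim_pi0(
    p: np.ndarray, *, n_bins: int = 20, window: int = 6, lambda_min: float = 0.05
) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The empirical CDF of the p-values is evaluated on a lambda grid; a
    window slides over the grid and an OLS line is fitted to the CDF within
    each window.  In the region dominated by null p-values the CDF is
    linear with slope pi0, so the estimate is taken from the best-fitting
    (smallest residual) window among those in the upper half of the grid,
    bounded into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    grid = np.linspace(lambda_min, 0.95, n_bins)
    cdf = np.searchsorted(np.sort(p), grid, side="right") / m
    best_slope, best_sse = 1.0, np.inf
    for lo in range(0, n_bins - window + 1):
        x, y = grid[lo : lo + window], cdf[lo : lo + window]
        slope, intercept = np.polyfit(x, y, 1)
        sse = float(np.sum((y - (slope * x + intercept)) ** 2))
        # prefer upper-grid windows: the signal inflates the CDF slope at
        # small lambda, so only the flat tail identifies pi0
        if grid[lo] >= 0.35 and sse < best_sse and slope > 0:
            best_slope, best_sse = slope, sse
    return float(min(max(best_slope, 1.0 / m), 1.0))


def adjust_pvalues(p_values, method: str = "BH", *, min_slim_n: int = 100) -> np.ndarray:
    """q-values by BH or by the SLIM pi0-scaled procedure.

    SLIM computes q_i = pi0 * BH_i (the step-up ladder scaled by the
    estimated null proportion).  Because the pi0 fit is unstable on short
    p-vectors, inputs below ``min_slim_n`` fall back to BH even when SLIM
    is requested.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.upper()
    if method == "BH" or (method == "SLIM" and p.size < min_slim_n):
        return _bh(p)
    if method == "SLIM":
        return np.minimum(slim_pi0(p) * _bh(p), 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# calling


@dataclass(frozen=True)
class DifferentialResult:
    chrom: str
    pos: int
    strand: str
    meth_diff: float
    p_value: float
    q_value: float
    call: str  # increased | decreased | not_significant


def call_differential(
    results: pd.DataFrame, q_cut: float = 0.05, diff_cut: float = 10.0
) -> pd.DataFrame:
    """Apply the q/difference call rule to a results frame.

    ``increased`` requires q < q_cut and meth_diff > diff_cut;
    ``decreased`` q < q_cut and meth_diff < -diff_cut; everything else is
    ``not_significant``.  Both comparisons are strict.
    """
    call = np.where(
        (results["q_value"] < q_cut) & (results["meth_diff"] > diff_cut),
        "increased",
        np.where(
            (results["q_value"] < q_cut) & (results["meth_diff"] < -diff_cut),
            "decreased",
            "not_significant",
        ),
    )
    out = results.copy()
    out["call"] = call
    return out


def compare_groups(
    table: MethylationTable,
    design: SampleDesign,
    reference_group: str,
    treatment_group: str,
    *,
    q_cut: float = 0.05,
    diff_cut: float = 10.0,
    adjust: str = "SLIM",
) -> pd.DataFrame:
    """Full per-site differential comparison between two groups.

    The table is expected to be coverage-filtered, normalized, and purged
    of mutated sites.  Sites with zero pooled coverage in either group are
    skipped with a reason code column.  Returns a frame indexed like the
    table with columns meth_diff, p_value, q_value, call.
    """
    model = DifferentialMethylation(
        table, design, reference=reference_group, treatment=treatment_group
    )
    res = model.fit(q_cut=q_cut, diff_cut=diff_cut, adjust=adjust)
    return res.frame


class DifferentialMethylation:
    """Model object for a two-group differential methylation comparison.

    Parameters
    ----------
    table : MethylationTable
        Filtered/normalized counts.
    design : SampleDesign
        Sample-to-group map covering every table sample.
    reference, treatment : str
        Group labels; ``meth_diff`` is treatment minus reference.
    """

    def __init__(
        self,
        table: MethylationTable,
        design: SampleDesign,
        reference: str,
        treatment: str,
    ):
        design.validate_against(table)
        ref_samples = [s for s in table.samples if design.group_of(s) == reference]
        trt_samples = [s for s in table.samples if design.group_of(s) == treatment]
        if not ref_samples:
            raise ValueError(f"reference group {reference!r} has no samples in table")
        if not trt_samples:
            raise ValueError(f"treatment group {treatment!r} has no samples in table")
        self.table = table
        self.design = design
        self.reference = reference
        self.treatment = treatment
        self.ref_samples = ref_samples
        self.trt_samples = trt_samples

    def fit(
        self, *, q_cut: float = 0.05, diff_cut: float = 10.0, adjust: str = "SLIM"
    ) -> "DifferentialResults":
        cols = self.ref_samples + self.trt_samples
        cov = self.table.coverage[cols].to_numpy(dtype=float)
        met = self.table.methylated[cols].to_numpy(dtype=float)
        codes = np.array([0] * len(self.ref_samples) + [1] * len(self.trt_samples))

        # testability mask: every sample observed, positive pooled coverage
        # per group (missing cells exclude a site rather than being imputed)
        observed = ~np.isnan(cov).any(axis=1)
        cov0 = np.nan_to_num(cov)
        pooled_ok = (cov0[:, codes == 0].sum(axis=1) > 0) & (
            cov0[:, codes == 1].sum(axis=1) > 0
        )
        testable = observed & pooled_ok

        n = len(cov)
        pvals = np.full(n, np.nan)
        diffs = np.full(n, np.nan)
        flags = np.full(n, "ok", dtype=object)
        flags[~observed] = "missing_sample"
        flags[observed & ~pooled_ok] = "zero_group_coverage"
        if testable.any():
            p, _lrt, pg = logistic_test_vectorized(
                met[testable], cov[testable], codes
            )
            pvals[testable] = p
            diffs[testable] = 100.0 * (pg[:, 1] - pg[:, 0])

        q = np.full(n, np.nan)
        if testable.any():
            q[testable] = adjust_pvalues(pvals[testable], method=adjust)

        frame = pd.DataFrame(
            {
                "meth_diff": diffs,
                "p_value": pvals,
                "q_value": q,
                "reason": flags,
            },
            index=self.table.coverage.index,
        )
        frame = call_differential(frame, q_cut=q_cut, diff_cut=diff_cut)
        frame.loc[~testable, "call"] = "not_tested"
        return DifferentialResults(self, frame, q_cut=q_cut, diff_cut=diff_cut, adjust=adjust)


class DifferentialResults:
    """Fitted per-site differential methylation results.

    Attributes
    ----------
    frame : pandas.DataFrame
        Indexed by (chrom, pos, strand) with meth_diff (percentage
        points, treatment - reference), p_value, q_value, call, reason.
    """

    def __init__(self, model, frame: pd.DataFrame, *, q_cut, diff_cut, adjust):
        self.model = model
        self.frame = frame
        self.q_cut = q_cut
        self.diff_cut = diff_cut
        self.adjust = adjust

    @property
    def n_increased(self) -> int:
        return int((self.frame["call"] == "increased").sum())

    @property
    def n_decreased(self) -> int:
        return int((self.frame["call"] == "decreased").sum())

    def called(self, direction: str | None = None) -> pd.DataFrame:
        if direction is None:
            return self.frame[self.frame["call"].isin(["increased", "decreased"])]
        return self.frame[self.frame["call"] == direction]

    def summary(self) -> str:
        f = self.frame
        tested = int((f["call"] != "not_tested").sum())
        lines = [
            "Differential methylation (binomial logistic LRT)",
            "=" * 48,
            f"reference:      {self.model.reference} ({len(self.model.ref_samples)} samples)",
            f"treatment:      {self.model.treatment} ({len(self.model.trt_samples)} samples)",
            f"adjustment:     {self.adjust}",
            f"call rule:      q < {self.q_cut} and |diff| > {self.diff_cut} pp",
            f"sites tested:   {tested} / {len(f)}",
            f"increased:      {self.n_increased}",
            f"decreased:      {self.n_decreased}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# damdiff differential: {self.model.treatment} vs "
                f"{self.model.reference}; adjust={self.adjust}; "
                f"q_cut={self.q_cut}; diff_cut={self.diff_cut}\n"
            )
            self.frame.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.6g")
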