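"""Feature-level methylation statistics.

Covers the M-value transform, rank tests of features against the
genome-wide median, promoter-aligned methylation profiles, one-tailed
Fisher enrichment of differential sites within feature classes, and a
generic hypergeometric term over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "m_value",
    "feature_location_test",
    "feature_location_tests",
    "kruskal_across_features",
    "promoter_profile",
    "enrichment_fisher",
    "EnrichmentRow",
    "nearest_gene",
    "term_overrepresentation",
]

M_NEG_INF = -np.inf


def m_value(beta, offset: float = 0.001):
    """Variance-stabilizing log-ratio transform of the methylation level.

    M = log2(beta / (1 - beta + offset)).  The offset keeps beta = 1
    finite (M = log2(1/offset) ~ 9.97 at the default); beta = 0 maps to
    -inf, which the rank-based downstream tests tolerate as the most
    extreme value.  Strictly increasing in beta on (0, 1].
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        m = np.log2(b / (1.0 - b + offset))
    return m if m.ndim else float(m)


def feature_location_test(
    m_values_in_feature, genome_wide_median_m: float, *, exact_max_n: int = 25
) -> float:
    """One-sample Wilcoxon signed-rank test of a feature against the
    genome-wide median M-value (two-sided).

    Differences of exactly zero are discarded (Wilcoxon convention); if
    every value sits at the median the test is degenerate and p = 1.  The
    exact null distribution is used for n <= ``exact_max_n``, the normal
    approximation with continuity correction above.
    """
    x = np.asarray(list(m_values_in_feature), dtype=float)
    d = x - genome_wide_median_m
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    mode = "exact" if len(d) <= exact_max_n else "approx"
    res = stats.wilcoxon(d, correction=(mode == "approx"), mode=mode)
    return float(res.pvalue)


def feature_location_tests(
    m_by_feature: dict[str, "np.ndarray | list"], genome_wide_median_m: float
) -> pd.DataFrame:
    """Run the location test for every feature and BH-adjust across them."""
    from .differential import adjust_pvalues

    rows = []
    for feature, vals in m_by_feature.items():
        vals = np.asarray(list(vals), dtype=float)
        rows.append((feature, len(vals), float(np.median(vals)),
                     feature_location_test(vals, genome_wide_median_m)))
    df = pd.DataFrame(rows, columns=["feature_type", "n_sites", "median_m", "p_value"])
    df["q_value"] = adjust_pvalues(df["p_value"].to_numpy(), method="BH")
    return df


def kruskal_across_features(m_values_by_group: dict[str, "np.ndarray | list"]) -> tuple[float, float]:
    """Kruskal-Wallis H and p across feature classes (tie-corrected).

    When every observation is tied the statistic is defined as 0 (p = 1)
    rather than raising.
    """
    groups = [np.asarray(list(v), dtype=float) for v in m_values_by_group.values()]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def promoter_profile(
    tss_offsets,
    betas,
    *,
    window: int = 300,
    half_bandwidth: int = 25,
) -> pd.DataFrame:
    """Median methylation by position relative to the TSS, plus a smooth.

    ``tss_offsets`` are strand-aware signed offsets (negative = upstream
    of the TSS in the direction of transcription); sites outside
    [-window, window] are ignored.  The per-offset median beta is smoothed
    by a running median over +/- ``half_bandwidth`` bp of occupied
    offsets, a robust stand-in for quantile-regression spline smoothing
    that affects visualization only.
    """
    off = np.asarray(list(tss_offsets), dtype=int)
    b = np.asarray(list(betas), dtype=float)
    keep = np.abs(off) <= window
    off, b = off[keep], b[keep]
    if len(off) == 0:
        return pd.DataFrame(columns=["offset", "median_beta", "smoothed"])
    per = (
        pd.DataFrame({"offset": off, "beta": b})
        .groupby("offset")["beta"]
        .median()
        .sort_index()
    )
    positions = per.index.to_numpy()
    med = per.to_numpy()
    smoothed = np.array(
        [
            np.median(med[(positions >= x - half_bandwidth) & (positions <= x + half_bandwidth)])
            for x in positions
        ]
    )
    return pd.DataFrame({"offset": positions, "median_beta": med, "smoothed": smoothed})


@dataclass(frozen=True)
class EnrichmentRow:
    feature_type: str
    n_feature_sites: int
    n_hits: int
    fisher_p: float
    q_value: float
    direction: str


def _hypergeom_enrich_p(k: int, K: int, n: int, N: int) -> float:
    """One-tailed (enrichment) hypergeometric p: P[X >= k] with X ~
    Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_fisher(
    differential_sites: set,
    feature_membership: dict[str, set],
    total_sites: set,
    *,
    direction: str = "increased",
) -> list[EnrichmentRow]:
    """One-tailed Fisher enrichment of differential sites per feature class.

    For each feature class the 2x2 table partitions ``total_sites`` (the
    conditioning universe, normally the post-filter tested set) into
    differential/not x in-feature/not; the one-tailed p is the
    hypergeometric upper tail, identical to Fisher's exact test with the
    'greater' alternative.  BH correction is applied across features
    within the direction.  Feature classes with zero sites in the universe
    are skipped.
    """
    from .differential import adjust_pvalues

    diff = set(differential_sites) & set(total_sites)
    if set(differential_sites) - set(total_sites):
        raise ValueError("differential sites must be a subset of the universe")
    N, n = len(total_sites), len(diff)
    rows = []
    for feature, members in feature_membership.items():
        members = set(members) & set(total_sites)
        K = len(members)
        if K == 0:
            continue
        k = len(members & diff)
        rows.append((feature, K, k, _hypergeom_enrich_p(k, K, n, N)))
    if not rows:
        return []
    q = adjust_pvalues([r[3] for r in rows], method="BH")
    return [
        EnrichmentRow(f, K, k, p, float(qv), direction)
        for (f, K, k, p), qv in zip(rows, q)
    ]


def nearest_gene(
    site_pos: int,
    gene_intervals: list[tuple[int, int, str]],
    genome_length: int,
) -> str:
    """Containing gene, else the gene whose boundary is nearest on the
    circular chromosome (ties broken toward the downstream gene, i.e. the
    one starting after the site on the + strand).

    ``gene_intervals`` are 0-based half-open (start, end, gene_id).
    """
    if not gene_intervals:
        raise ValueError("no genes supplied")
    L = genome_length

    def circ_dist(a: int, b: int) -> int:
        d = abs(a - b) % L
        return min(d, L - d)

    best_id, best_key = None, None
    for start, end, gid in gene_intervals:
        if start <= site_pos < end or (end > L and site_pos < end % L):
            return gid
        d = min(circ_dist(site_pos, start), circ_dist(site_pos, end - 1))
        downstream = (start - site_pos) % L  # small when gene starts just after site
        key = (d, downstream)
        if best_key is None or key < best_key:
            best_id, best_key = gid, key
    return best_id


def term_overrepresentation(
    gene_set: set,
    gene_to_terms: dict[str, set],
    universe: set,
    *,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Terms with identical member sets (within the universe) are collapsed
    to a single row; q-values are BH over the tested terms.  Rows with
    q < ``q_cut`` are returned sorted by p.
    """
    from .differential import adjust_pvalues

    gene_set = set(gene_set)
    universe = set(universe)
    if gene_set - universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not gene_set:
        return pd.DataFrame(
            columns=["term", "n_term", "n_hits", "p_value", "q_value", "genes"]
        )
    term_members: dict[str, frozenset] = {}
    for gene, terms in gene_to_terms.items():
        if gene not in universe:
            continue
        for t in terms:
            term_members.setdefault(t, frozenset())
            term_members[t] = term_members[t] | {gene}
    # deduplicate terms with identical membership, keeping the first name
    seen: dict[frozenset, str] = {}
    for t in sorted(term_members):
        members = frozenset(term_members[t])
        seen.setdefault(members, t)
    N, n = len(universe), len(gene_set)
    rows = []
    for members, t in seen.items():
        K = len(members)
        hits = members & gene_set
        p = _hypergeom_enrich_p(len(hits), K, n, N)
        rows.append((t, K, len(hits), p, ",".join(sorted(hits))))
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_hits", "p_value", "genes"])
    df["q_value"] = adjust_pvalues(df["p_value"].to_numpy(), method="BH")
    df = df[df["q_value"] < q_cut].sort_values("p_value").reset_index(drop=True)
    return df[["term", "n_term", "n_hits", "p_value", "q_value", "genes"]]
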