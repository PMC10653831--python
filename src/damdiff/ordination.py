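"""Methylome ordination: coverage normalization, NMDS, PERMANOVA, PERMDISP.

Beta-values depend on coverage, so before ordination the per-sample
coverage distributions are equalized by quantile normalization, a linear
scaling equation (OLS of normalized on raw coverage) is fitted per sample,
and that affine map is applied to both the coverage and the methylated
read counts; normalized beta-values are their ratio.  Samples are then
compared through the Euclidean distance matrix of normalized beta-values:
non-metric multidimensional scaling for visualization, PERMANOVA for
group-centroid (location) differences, and PERMDISP (multivariate
dispersion via principal-coordinates embedding, ANOVA and Tukey HSD on
distances to group centroids) for epimutational drift.

The fitted surface is ``MethylomeOrdination(table, design).fit()`` ->
:class:`OrdinationResults` with a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "fit_sample_scaling",
    "apply_scaling",
    "normalized_beta_matrix",
    "euclidean_distance_matrix",
    "nmds",
    "permanova",
    "permdisp",
    "pcoa_embedding",
    "MethylomeOrdination",
    "OrdinationResults",
]


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of a sites x samples matrix.

    Each sample's values are replaced by the across-sample mean of the
    order statistics at their rank; a tie group spanning several ranks
    receives the mean of the order-statistic means it spans.  After the
    transform every sample has an identical sorted vector.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete-case matrix")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(len(col), dtype=int)
        ranks[order] = np.arange(len(col))
        # ties: average the reference values their sorted positions span
        vals = col[order]
        out_sorted = reference.copy()
        start = 0
        for end in range(1, len(vals) + 1):
            if end == len(vals) or vals[end] != vals[start]:
                if end - start > 1:
                    out_sorted[start:end] = reference[start:end].mean()
                start = end
        out[:, j] = out_sorted[ranks]
    return out


def fit_sample_scaling(raw: np.ndarray, normalized: np.ndarray) -> tuple[float, float]:
    """OLS line (slope, intercept) of normalized coverage on raw coverage."""
    x = np.asarray(raw, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("constant raw coverage: scaling slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def apply_scaling(
    coverage: np.ndarray,
    methylated: np.ndarray,
    scaling: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply each sample's affine scaling to its coverage and methylated
    counts and return (coverage', methylated', normalized beta).

    Both count types get the same map (the fitted scaling equation), with
    the results floored at 0 and methylated capped at coverage so beta
    stays in [0, 1].  Cells whose scaled coverage is <= 0 become NaN.
    """
    cov = np.asarray(coverage, dtype=float).copy()
    met = np.asarray(methylated, dtype=float).copy()
    for j, (b, a) in enumerate(scaling):
        cov[:, j] = a + b * cov[:, j]
        met[:, j] = a + b * met[:, j]
    met = np.clip(met, 0.0, None)
    met = np.minimum(met, cov)
    bad = cov <= 0
    cov[bad] = np.nan
    met[bad] = np.nan
    with np.errstate(invalid="ignore"):
        beta = met / cov
    return cov, met, beta


def normalized_beta_matrix(coverage: np.ndarray, methylated: np.ndarray):
    """Quantile-normalize coverage, fit per-sample scaling, apply it.

    Returns ``(beta, scaling)`` where scaling is one (slope, intercept)
    per sample.
    """
    qcov = quantile_normalize(coverage)
    scaling = [
        fit_sample_scaling(coverage[:, j], qcov[:, j]) for j in range(coverage.shape[1])
    ]
    _, _, beta = apply_scaling(coverage, methylated, scaling)
    return np.clip(beta, 0.0, 1.0), scaling


def euclidean_distance_matrix(beta: np.ndarray) -> np.ndarray:
    """Between-sample Euclidean distances over sites (columns = samples)."""
    from scipy.spatial.distance import pdist, squareform

    if np.isnan(beta).any():
        raise ValueError("distance matrix requires complete-case beta values")
    return squareform(pdist(beta.T, metric="euclidean"))


# ---------------------------------------------------------------------------
# NMDS


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / denom)


def nmds(
    distance_matrix: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
):
    """Non-metric multidimensional scaling by SMACOF majorization.

    Alternates isotonic regression of configuration distances on the
    rank order of the input dissimilarities (the disparities) with a
    Guttman-transform update of the configuration, minimizing Kruskal
    stress-1.  The best of ``n_starts`` random restarts is returned.

    Returns
    -------
    coords : (n, k) array
    stress : float  (Kruskal stress-1 of the best start)
    history : list of per-iteration stress values for the best start
    """
    from sklearn.isotonic import IsotonicRegression

    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric zero-diagonal distance matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best = (np.inf, None, None)
    for _ in range(max(1, n_starts)):
        X = rng.normal(size=(n, k)) * (np.mean(delta) if delta.size else 1.0)
        history = []
        prev = np.inf
        for _it in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            d_full = np.sqrt((diff**2).sum(-1))
            d = d_full[iu]
            # monotone disparities in the order of the input dissimilarities
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            # scale so the stress denominator is configuration-invariant
            denom = float(np.sum(d**2))
            if denom > 0 and np.sum(dhat**2) > 0:
                dhat = dhat * math.sqrt(denom / float(np.sum(dhat**2)))
            s = _stress1(d, dhat)
            history.append(s)
            if prev - s < tol:
                break
            prev = s
            # Guttman transform
            Dhat = np.zeros((n, n))
            Dhat[iu] = dhat
            Dhat = Dhat + Dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_full > 0, Dhat / d_full, 0.0)
            B = -ratio
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
            X -= X.mean(axis=0)
        if history and history[-1] < best[0]:
            best = (history[-1], X, history)
    stress, X, history = best
    return X, float(stress), history


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _pseudo_f(G: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Anderson's pseudo-F from the Gower-centered matrix and group codes."""
    n = len(G)
    H = np.zeros((n, n))
    for g in range(k):
        idx = np.where(codes == g)[0]
        H[np.ix_(idx, idx)] = 1.0 / len(idx)
    ss_total = float(np.trace(G))
    ss_among = float(np.sum(H * G))  # tr(HG) since H symmetric idempotent blockwise
    ss_within = ss_total - ss_among
    if ss_within <= 0:
        return np.inf
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    distance_matrix: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    *,
    method: str = "permutation",
):
    """Permutational multivariate analysis of variance on a distance matrix.

    ``method='permutation'`` draws ``n_perm`` random label permutations and
    reports p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    ``method='exact'`` enumerates every distinct permutation (feasible for
    small n) and reports the exact fraction with F >= F_obs.
    """
    D = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 groups")
    G = _gower_center(D)
    f_obs = _pseudo_f(G, codes, k)
    n = len(codes)
    if method == "exact":
        perms = itertools.permutations(range(n))
        hits = total = 0
        for pm in perms:
            f = _pseudo_f(G, codes[list(pm)], k)
            hits += f >= f_obs - 1e-12
            total += 1
        return float(f_obs), hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f = _pseudo_f(G, rng.permutation(codes), k)
        hits += f >= f_obs - 1e-12
    return float(f_obs), (1 + hits) / (n_perm + 1)


def pairwise_permanova(D: np.ndarray, labels, n_perm=999, seed=0) -> pd.DataFrame:
    """Unadjusted pairwise PERMANOVA contrasts on subsets of the samples."""
    labels = np.asarray(labels)
    rows = []
    for a, b in itertools.combinations(sorted(set(labels)), 2):
        idx = np.where((labels == a) | (labels == b))[0]
        f, p = permanova(D[np.ix_(idx, idx)], labels[idx], n_perm=n_perm, seed=seed)
        rows.append((a, b, f, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "p_value"])


# ---------------------------------------------------------------------------
# PERMDISP


def pcoa_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-coordinates embedding keeping negative-eigenvalue axes.

    Returns ``(real_axes, imag_axes, eigenvalues)``: coordinates on the
    positive-eigenvalue axes and on the negative ones (scaled by
    sqrt(|eigenvalue|)); squared distances in the embedding are
    real-part minus imaginary-part contributions.
    """
    G = _gower_center(np.asarray(D, dtype=float))
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    eps = max(1e-10, 1e-8 * abs(vals).max() if len(vals) else 0)
    pos = vals > eps
    neg = vals < -eps
    real_axes = vecs[:, pos] * np.sqrt(vals[pos])
    imag_axes = vecs[:, neg] * np.sqrt(-vals[neg])
    return real_axes, imag_axes, vals


def permdisp(distance_matrix: np.ndarray, labels):
    """Multivariate homogeneity of group dispersions.

    Samples are embedded by principal-coordinates analysis (negative
    eigenvalues kept on imaginary axes, the standard real/imaginary
    split); each sample's distance to its group centroid is computed in
    that space; the distances are compared by one-way ANOVA and pairwise
    Tukey HSD.  Singleton groups get distance 0 and are flagged.

    Returns a dict with keys ``distances`` (pandas Series by sample
    index), ``anova_F``, ``anova_p``, ``tukey`` (DataFrame group_a,
    group_b, p_adj), ``singleton_groups``.
    """
    D = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    real, imag, _vals = pcoa_embedding(D)
    n = len(labels)
    dist = np.zeros(n)
    singletons = []
    for g in uniq:
        idx = np.where(labels == g)[0]
        if len(idx) == 1:
            singletons.append(str(g))
            dist[idx] = 0.0
            continue
        cr = real[idx].mean(axis=0) if real.size else np.zeros(0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[idx] - cr) ** 2).sum(axis=1) if real.size else 0.0
        di2 = ((imag[idx] - ci) ** 2).sum(axis=1) if imag.size else 0.0
        dist[idx] = np.sqrt(np.maximum(dr2 - di2, 0.0))
    groups = [dist[labels == g] for g in uniq]
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(dist, labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )[["group1", "group2", "p-adj"]]
    tukey.columns = ["group_a", "group_b", "p_adj"]
    tukey["p_adj"] = tukey["p_adj"].astype(float)
    return {
        "distances": dist,
        "anova_F": float(f_stat),
        "anova_p": float(p),
        "tukey": tukey,
        "singleton_groups": singletons,
    }


# ---------------------------------------------------------------------------
# model/results surface


class MethylomeOrdination:
    """Ordination model over a complete-case methylation table.

    Normalizes beta-values (quantile normalization of coverage + the
    per-sample scaling regression), builds the Euclidean between-sample
    distance matrix, and on ``fit()`` runs NMDS, overall and pairwise
    PERMANOVA, and PERMDISP.
    """

    def __init__(self, table, design):
        design.validate_against(table)
        cov = table.coverage.to_numpy(dtype=float)
        met = table.methylated.to_numpy(dtype=float)
        keep = ~np.isnan(cov).any(axis=1)
        self.table = table
        self.design = design
        self.samples = table.samples
        self.labels = np.array([design.group_of(s) for s in self.samples])
        self._cov = cov[keep]
        self._met = met[keep]

    def fit(self, *, k: int = 2, n_starts: int = 20, n_perm: int = 999, seed: int = 0):
        beta, scaling = normalized_beta_matrix(self._cov, self._met)
        D = euclidean_distance_matrix(beta)
        coords, stress, history = nmds(D, k=k, n_starts=n_starts, seed=seed)
        f_obs, p_overall = permanova(D, self.labels, n_perm=n_perm, seed=seed)
        pairwise = pairwise_permanova(D, self.labels, n_perm=n_perm, seed=seed)
        disp = permdisp(D, self.labels)
        return OrdinationResults(
            model=self,
            scaling=scaling,
            distance_matrix=D,
            coordinates=coords,
            stress=stress,
            stress_history=history,
            permanova_F=f_obs,
            permanova_p=p_overall,
            pairwise_permanova=pairwise,
            permdisp=disp,
        )


@dataclass
class OrdinationResults:
    model: MethylomeOrdination
    scaling: list
    distance_matrix: np.ndarray
    coordinates: np.ndarray
    stress: float
    stress_history: list
    permanova_F: float
    permanova_p: float
    pairwise_permanova: pd.DataFrame
    permdisp: dict

    def summary(self) -> str:
        lines = [
            "Methylome ordination (Euclidean on normalized beta-values)",
            "=" * 58,
            f"samples: {len(self.model.samples)}; groups: {sorted(map(str, set(self.model.labels)))}",
            f"NMDS stress-1: {self.stress:.4f}",
            f"PERMANOVA (overall): pseudo-F = {self.permanova_F:.3f}, p = {self.permanova_p:.4f}",
            "pairwise PERMANOVA (unadjusted):",
        ]
        for _, r in self.pairwise_permanova.iterrows():
            lines.append(
                f"  {r.group_a} vs {r.group_b}: F = {r.pseudo_F:.3f}, p = {r.p_value:.4f}"
            )
        lines.append(
            f"PERMDISP ANOVA: F = {self.permdisp['anova_F']:.3f}, "
            f"p = {self.permdisp['anova_p']:.4f}"
        )
        lines.append("PERMDISP Tukey HSD:")
        for _, r in self.permdisp["tukey"].iterrows():
            lines.append(f"  {r.group_a} vs {r.group_b}: p-adj = {r.p_adj:.4f}")
        return "\n".join(lines)

    def coordinates_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"NMDS{i+1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "sample", self.model.samples)
        df.insert(1, "group", self.model.labels)
        return df
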