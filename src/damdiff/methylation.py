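"""Per-site methylation count tables: ingestion, filtering, normalization.

The container is a pair of aligned pandas DataFrames (coverage and
methylated read counts) indexed by (chrom, 0-based adenine position,
strand) with one column per sample.  The methylation level beta =
methylated / coverage is always derived from the counts, never trusted
from an input file.  Cells a sample did not observe are NaN, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MethylationTable",
    "SampleDesign",
    "read_calls",
    "read_design",
    "filter_min_coverage",
    "normalize_coverage_median",
    "drop_mutated_sites",
]

log = logging.getLogger(__name__)

SITE_INDEX = ["chrom", "pos", "strand"]


class MethylationTable:
    """Adenine-by-sample methylation counts.

    Parameters
    ----------
    coverage, methylated : pandas.DataFrame
        Aligned frames with a (chrom, pos, strand) MultiIndex and one
        column per sample.  ``0 <= methylated <= coverage`` cell-wise;
        missing cells are NaN in both frames.
    """

    def __init__(self, coverage: pd.DataFrame, methylated: pd.DataFrame):
        if not coverage.index.equals(methylated.index) or list(coverage.columns) != list(
            methylated.columns
        ):
            raise ValueError("coverage and methylated frames must be aligned")
        with np.errstate(invalid="ignore"):
            bad = (methylated.to_numpy() > coverage.to_numpy()) | (
                methylated.to_numpy() < 0
            )
        if np.any(np.nan_to_num(bad.astype(float)) > 0):
            raise ValueError("methylated count outside [0, coverage] in some cell")
        if (np.isnan(coverage.to_numpy()) != np.isnan(methylated.to_numpy())).any():
            raise ValueError("missingness of coverage and methylated must agree")
        self.coverage = coverage
        self.methylated = methylated

    # -- basic protocol ----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.coverage.columns)

    @property
    def n_sites(self) -> int:
        return len(self.coverage)

    @property
    def beta(self) -> pd.DataFrame:
        """Methylated read fraction; NaN where coverage is 0 or missing."""
        cov = self.coverage.where(self.coverage > 0)
        return self.methylated / cov

    def pooled_beta(self, samples: list[str] | None = None) -> pd.Series:
        """Per-site beta pooling reads over the given samples."""
        cols = samples or self.samples
        cov = self.coverage[cols].sum(axis=1, min_count=1)
        met = self.methylated[cols].sum(axis=1, min_count=1)
        return met / cov.where(cov > 0)

    def copy(self) -> "MethylationTable":
        return MethylationTable(self.coverage.copy(), self.methylated.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MethylationTable {self.n_sites} sites x {len(self.samples)} samples>"

    # -- construction ------------------------------------------------------
    @classmethod
    def from_samples(cls, per_sample: dict[str, pd.DataFrame]) -> "MethylationTable":
        """Merge one-sample frames (columns coverage, methylated) on the
        union of their site keys; absent sites become missing cells."""
        cov = {}
        met = {}
        for name, df in per_sample.items():
            cov[name] = df["coverage"]
            met[name] = df["methylated"]
        coverage = pd.DataFrame(cov).sort_index()
        methylated = pd.DataFrame(met).reindex(coverage.index)
        return cls(coverage, methylated)

    def to_tsv(self, path) -> None:
        """Write the documented long-format TSV (one row per cell)."""
        beta = self.beta
        with open(path, "w") as fh:
            fh.write("# damdiff methylation table; counts are post-processing\n")
            fh.write("chrom\tpos\tstrand\tsample\tcoverage\tmethylated\tbeta\n")
            for sample in self.samples:
                sub = pd.DataFrame(
                    {
                        "coverage": self.coverage[sample],
                        "methylated": self.methylated[sample],
                        "beta": beta[sample],
                    }
                ).dropna()
                for (chrom, pos, strand), row in sub.iterrows():
                    fh.write(
                        f"{chrom}\t{pos}\t{strand}\t{sample}\t"
                        f"{int(row.coverage)}\t{int(row.methylated)}\t{row.beta:.6g}\n"
                    )


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-group assignment (optionally with population labels)."""

    samples: tuple[str, ...]
    groups: tuple[str, ...]
    populations: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in design")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")
        if self.populations is not None and len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")

    def group_of(self, sample: str) -> str:
        return self.groups[self.samples.index(sample)]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.samples, self.groups) if g == group]

    def validate_against(self, table: MethylationTable) -> None:
        missing = set(table.samples) - set(self.samples)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")


def read_design(path) -> SampleDesign:
    """Read a 2-3 column TSV: sample, group[, population]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "sample" not in cols or "group" not in cols:
        raise ValueError("design file needs 'sample' and 'group' columns")
    pops = tuple(df["population"]) if "population" in cols else None
    return SampleDesign(tuple(df["sample"]), tuple(df["group"]), pops)


class CallValidationError(ValueError):
    pass


def read_calls(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read one sample's per-site calls into a (chrom,pos,strand)-indexed frame.

    Dialects
    --------
    ``tsv``
        5 columns: chrom, 0-based position, strand, coverage, methylated
        (header optional; lines starting with ``#`` ignored).
    ``bedmethyl``
        9+ column bedMethyl: chrom, start, end, name, score, strand,
        thickStart, thickEnd, rgb[, coverage, pct]. Coverage is column 10;
        the methylated count is recomputed from coverage x percent
        (column 11), rounded to the nearest read.

    Zero-coverage rows become missing cells (dropped here; the merge step
    re-introduces NaN where other samples observe the site).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                if dialect == "tsv":
                    if f[0] in ("chrom", "chr"):  # header
                        continue
                    chrom, pos, strand = f[0], int(f[1]), f[2]
                    coverage, methylated = int(f[3]), int(f[4])
                elif dialect == "bedmethyl":
                    if len(f) < 11:
                        raise CallValidationError(
                            f"{path}:{lineno}: bedMethyl needs >= 11 columns"
                        )
                    chrom, pos, strand = f[0], int(f[1]), f[5]
                    coverage = int(f[9])
                    methylated = int(round(coverage * float(f[10]) / 100.0))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (IndexError, ValueError) as e:
                if isinstance(e, CallValidationError):
                    raise
                raise CallValidationError(f"{path}:{lineno}: malformed record") from e
            if methylated > coverage or methylated < 0:
                raise CallValidationError(
                    f"{path}:{lineno}: methylated {methylated} > coverage {coverage}"
                )
            if coverage == 0:
                continue
            rows.append((chrom, pos, strand, coverage, methylated))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "coverage", "methylated"])
    if df.duplicated(SITE_INDEX).any():
        dup = df[df.duplicated(SITE_INDEX)].iloc[0]
        raise CallValidationError(
            f"{path}: duplicate record for {dup.chrom}:{dup.pos}:{dup.strand}"
        )
    return df.set_index(SITE_INDEX).sort_index()


def filter_min_coverage(table: MethylationTable, min_reads: int = 10) -> MethylationTable:
    """Keep only sites where *every* sample has coverage >= ``min_reads``.

    The retention rule is per-sample-all: a missing cell fails the filter,
    so the surviving matrix is complete-case.  The default of 10 reads is
    the conventional reliability floor for per-site calls.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = (table.coverage >= min_reads).all(axis=1) & table.coverage.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_min_coverage: dropped %d of %d sites", dropped, table.n_sites)
    if keep.sum() == 0:
        log.warning("filter_min_coverage: no sites survive the %d-read filter", min_reads)
    return MethylationTable(table.coverage[keep], table.methylated[keep])


def normalize_coverage_median(table: MethylationTable) -> MethylationTable:
    """Scale each sample's counts so per-sample median coverages agree.

    For sample i with median coverage m_i, the target is
    m* = median_i(m_i) and the factor f_i = m*/m_i.  Coverage and
    methylated counts are both multiplied by f_i and rounded to the
    nearest integer (ties to even), methylated clipped to [0, coverage],
    keeping the counts valid binomial data for the downstream logistic
    model.  Identical samples are left untouched (f_i = 1).
    """
    if len(table.samples) < 2:
        raise ValueError("normalization needs >= 2 samples")
    medians = table.coverage.median(axis=0, skipna=True)
    if (medians <= 0).any() or medians.isna().any():
        bad = medians[(medians <= 0) | medians.isna()].index.tolist()
        raise ValueError(f"degenerate sample(s) with zero median coverage: {bad}")
    target = float(np.median(medians.to_numpy()))
    factors = target / medians
    cov = np.rint(table.coverage * factors)
    met = np.rint(table.methylated * factors)
    met = met.clip(lower=0).where(met <= cov, cov)
    # rounding may produce coverage 0 at tiny counts; keep cells missing there
    zero = cov <= 0
    cov = cov.where(~zero)
    met = met.where(~zero)
    out = MethylationTable(cov, met)
    out.scaling_factors = factors  # recorded for output metadata
    return out


def drop_mutated_sites(
    table: MethylationTable, mutated_positions: set[tuple[str, int]] | list[tuple[str, int]]
) -> MethylationTable:
    """Remove every adenine whose (chrom, position) is flagged as mutated.

    Callers pass both adenines of any palindrome hit by a mutation (see
    :func:`damdiff.mutation_context.mutated_adenines`), so a hit anywhere
    in the motif removes the whole pair from all samples.
    """
    mutated = set(mutated_positions)
    if not mutated:
        return table
    idx = table.coverage.index
    keep = [(c, p) not in mutated for c, p, _s in idx]
    return MethylationTable(table.coverage[keep], table.methylated[keep])
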