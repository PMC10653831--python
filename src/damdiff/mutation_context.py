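"""Mutation sequence context and GATC gain/loss analysis.

Each variant is annotated with the five flanking nucleotides on either
side (on a circular reference), the same window with the alternate allele
substituted, and whether the change creates or destroys a GATC motif.
Per-background fractions of GATC-affecting mutations come with bootstrap
percentile confidence intervals (resampling individual mutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutationRecord",
    "GatcRateSummary",
    "flanking_context",
    "gatc_change",
    "gatc_fraction",
    "shared_vs_unique",
    "mutated_adenines",
    "read_vcf",
    "annotate_variants",
]

MOTIF = "GATC"


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    pos0: int
    ref: str
    alt: str
    ref_context: str
    alt_context: str
    gatc_effect: str  # gain | loss | none
    clone: str = ""
    population: str = ""


@dataclass(frozen=True)
class GatcRateSummary:
    group: str
    n_mutations: int
    n_gatc: int
    percent: float
    ci_low: float
    ci_high: float


class RefMismatchError(ValueError):
    pass


def _circular_slice(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start : start + length]
    return seq[start:] + seq[: (start + length) % L]


def flanking_context(
    chrom: str, pos0: int, ref: str, alt: str, genome: str, flank: int = 5
) -> tuple[str, str]:
    """Reference and alternate sequence windows around a variant.

    The reference window is ``flank`` bases, the reference allele, then
    ``flank`` bases, wrapping across the origin of the circular sequence;
    the alternate window substitutes the alternate allele (so for indels
    the two windows differ in length).  Raises
    :class:`RefMismatchError` when the stated reference allele disagrees
    with the genome.
    """
    ref, alt = ref.upper(), alt.upper()
    genome = genome.upper()
    observed = _circular_slice(genome, pos0, len(ref))
    if observed != ref:
        raise RefMismatchError(
            f"{chrom}:{pos0}: reference allele {ref!r} but genome has {observed!r}"
        )
    up = _circular_slice(genome, pos0 - flank, flank)
    down = _circular_slice(genome, pos0 + len(ref), flank)
    return up + ref + down, up + alt + down


def _count_overlapping(seq: str, lo: int, hi: int, motif: str = MOTIF) -> int:
    """Motif occurrences whose span intersects positions [lo, hi)."""
    k = len(motif)
    n = 0
    for s in range(len(seq) - k + 1):
        if seq[s : s + k] == motif and s < hi and s + k > lo:
            n += 1
    return n


def gatc_change(ref_context: str, alt_context: str, flank: int = 5) -> str:
    """Classify a variant's effect on GATC motifs overlapping it.

    Counts motif occurrences overlapping the variant allele in the
    reference and alternate windows; more in the alternate means
    ``gain``, fewer ``loss``, equal ``none``.  A flank of 5 exceeds the
    4-bp motif, so the windowed count equals a whole-genome recount.
    """
    ref_len = len(ref_context) - 2 * flank
    alt_len = len(alt_context) - 2 * flank
    n_ref = _count_overlapping(ref_context.upper(), flank, flank + max(ref_len, 1))
    n_alt = _count_overlapping(alt_context.upper(), flank, flank + max(alt_len, 1))
    if n_alt > n_ref:
        return "gain"
    if n_alt < n_ref:
        return "loss"
    return "none"


def gatc_fraction(
    is_gatc_event,
    group: str = "",
    *,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> GatcRateSummary:
    """Percent of mutations affecting GATC sites, with a bootstrap CI.

    ``is_gatc_event`` is one boolean per mutation (the resampling unit);
    the CI is the 2.5/97.5 percentile of the bootstrap distribution of
    the percentage.  The point estimate is reported to one decimal.
    """
    flags = np.asarray(list(is_gatc_event), dtype=bool)
    n = len(flags)
    if n == 0:
        raise ValueError("no mutations in group")
    pct = 100.0 * flags.sum() / n
    rng = np.random.default_rng(seed)
    boots = 100.0 * rng.choice(flags, size=(n_boot, n), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return GatcRateSummary(group, n, int(flags.sum()), round(pct, 1), float(lo), float(hi))


def shared_vs_unique(mutations_by_clone: dict[str, set]) -> dict[str, set]:
    """Partition a population's mutations into shared vs clone-unique.

    Mutations present in every clone are 'shared' (they predate
    subpopulation divergence); each remaining mutation is attributed to
    the clone(s) carrying it.  Conservation: shared plus the union of
    unique sets equals the union of all clone sets.
    """
    if len(mutations_by_clone) < 2:
        raise ValueError("need >= 2 clones to partition shared vs unique")
    sets = list(mutations_by_clone.values())
    shared = set.intersection(*sets)
    out = {"shared": shared}
    for clone, muts in mutations_by_clone.items():
        out[clone] = set(muts) - shared
    return out


def mutated_adenines(
    records: list[MutationRecord], sites, genome_length: int, motif_len: int = 4
) -> set[tuple[str, int]]:
    """Adenine positions belonging to any palindrome hit by a mutation.

    A mutation hits a motif when its reference span intersects the
    motif's 4-bp footprint (circularly); both adenines of every hit pair
    are returned, for removal from differential analysis.
    """
    out: set[tuple[str, int]] = set()
    L = genome_length
    spans = []
    for r in records:
        start = r.pos0 % L
        spans.append((r.chrom, start, start + max(len(r.ref), 1)))
    for site in sites:
        foot = [(site.start + i) % L for i in range(motif_len)]
        for chrom, lo, hi in spans:
            if chrom != site.chrom:
                continue
            positions = {p % L for p in range(lo, hi)}
            if positions & set(foot):
                out.add((site.chrom, site.plus_adenine))
                out.add((site.chrom, site.minus_adenine))
                break
    return out


def read_vcf(path) -> list[tuple[str, int, str, str, str]]:
    """Read (chrom, pos0, ref, alt, sample_hint) tuples from a VCF.

    Multi-allelic records are decomposed into one tuple per alternate
    allele.  Positions are converted to the package's 0-based convention.
    """
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append((rec.chrom, rec.pos - 1, rec.ref, alt, ""))
    return out


def annotate_variants(
    variants: list[tuple],
    genome: str,
    flank: int = 5,
    *,
    clones: list[str] | None = None,
    populations: list[str] | None = None,
) -> list[MutationRecord]:
    """Build :class:`MutationRecord` objects for (chrom,pos0,ref,alt) tuples."""
    records = []
    for i, v in enumerate(variants):
        chrom, pos0, ref, alt = v[0], v[1], v[2], v[3]
        rc, ac = flanking_context(chrom, pos0, ref, alt, genome, flank)
        records.append(
            MutationRecord(
                chrom,
                pos0,
                ref.upper(),
                alt.upper(),
                rc,
                ac,
                gatc_change(rc, ac, flank),
                clone=clones[i] if clones else "",
                population=populations[i] if populations else "",
            )
        )
    return records
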