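"""GATC motif scanning, adenine indexing, feature annotation and state calls.

Dam methyltransferase methylates the adenine of GATC on both strands of the
palindrome.  The unit of analysis downstream is the strand-specific adenine:
for a motif whose G sits at 0-based position ``start`` on the forward strand,
the forward-strand adenine is ``start + 1`` and the reverse-strand adenine is
``start + 2`` (the A of the reverse-complement reading).  Bacterial
chromosomes are circular, so motifs spanning the origin are real sites and
are reported with their start taken modulo the genome length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GatcSite",
    "FeatureAnnotation",
    "MethylationState",
    "scan_motifs",
    "adenine_positions",
    "annotate_sites",
    "classify_pair_state",
    "tally_states",
    "read_feature_bed",
    "write_sites_bed",
]

_IUPAC = set("ACGTRYSWKMBDHVN")
_UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class GatcSite:
    """One palindromic GATC occurrence and its two methylatable adenines."""

    chrom: str
    start: int          # 0-based position of the G on the forward strand
    plus_adenine: int   # start+1 mod L
    minus_adenine: int  # start+2 mod L
    pair_id: int

    def __post_init__(self):
        if self.plus_adenine < 0 or self.minus_adenine < 0:
            raise ValueError("adenine positions must be non-negative")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A feature label attached to one adenine of a site.

    ``tss_offset`` is the signed strand-aware distance to the nearest
    transcription start site (negative = upstream of the TSS), or None when
    no promoter annotation is available.
    """

    pair_id: int
    adenine: int
    strand: str
    feature_type: str
    feature_name: str = ""
    tss_offset: int | None = None


@dataclass(frozen=True)
class MethylationState:
    pair_id: int
    state: str  # methylated | hemimethylated | hypomethylated_both | undetermined


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def scan_motifs(
    genome_sequence: str,
    motif: str = "GATC",
    *,
    circular: bool = True,
    chrom: str = "chromosome",
) -> list[GatcSite]:
    """Find every forward-strand occurrence of ``motif``.

    With ``circular=True`` occurrences spanning the origin are included,
    each reported once with ``start`` in ``[0, L)``.  Overlapping
    occurrences are all reported.  Ambiguous bases (N etc.) never match.

    Parameters
    ----------
    genome_sequence : str
        The chromosome sequence (IUPAC letters, case-insensitive).
    motif : str
        Motif to scan for; must be unambiguous DNA of length >= 2.
    """
    seq = _validate_sequence(genome_sequence)
    motif = motif.upper()
    if len(motif) < 2 or set(motif) - _UNAMBIGUOUS:
        raise ValueError(f"motif must be unambiguous DNA of length >= 2, got {motif!r}")
    L = len(seq)
    if L == 0:
        return []
    k = len(motif)
    # search the doubled sequence so origin-spanning hits appear, then
    # de-duplicate starts mod L
    search = seq + (seq[: k - 1] if circular and L >= k else "")
    starts = sorted(
        {m.start() % L for m in re.finditer(f"(?={re.escape(motif)})", search)}
    )
    sites = [
        GatcSite(chrom, s, (s + 1) % L, (s + 2) % L, pair_id=i)
        for i, s in enumerate(starts)
    ]
    return sites


def adenine_positions(site: GatcSite) -> list[tuple[int, str]]:
    """The two methylatable adenines as ``(position, strand)`` records."""
    return [(site.plus_adenine, "+"), (site.minus_adenine, "-")]


@dataclass(frozen=True)
class FeatureInterval:
    """A 0-based half-open genomic interval with a type label (BED6+1)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    feature_type: str = "gene"


class BedParseError(ValueError):
    pass


def read_feature_bed(path) -> list[FeatureInterval]:
    """Read a BED6+ file whose 7th column carries the feature type.

    Falls back to feature_type='gene' for plain BED3-6 lines.  Raises
    :class:`BedParseError` naming the offending line number.
    """
    out: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from e
            if start < 0 or end < start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append(
                FeatureInterval(
                    chrom=f[0],
                    start=start,
                    end=end,
                    name=f[3] if len(f) > 3 else ".",
                    strand=f[5] if len(f) > 5 else ".",
                    feature_type=f[6] if len(f) > 6 else "gene",
                )
            )
    return out


def annotate_sites(
    sites: Sequence[GatcSite],
    features: Sequence[FeatureInterval],
    *,
    tss_positions: Sequence[tuple[str, int, str]] | None = None,
    warn_unknown_chrom: bool = True,
) -> list[FeatureAnnotation]:
    """Attach overlapping feature labels to every adenine of every site.

    Each adenine receives one annotation per overlapping interval; adenines
    overlapping no interval of type ``gene`` are labelled ``intergenic``.
    When ``tss_positions`` (chrom, 0-based TSS, strand) are supplied, each
    annotation also carries the strand-aware offset to the nearest TSS
    (negative upstream of the TSS in the direction of transcription).
    """
    import warnings

    known_chroms = {s.chrom for s in sites}
    by_chrom: dict[str, list[FeatureInterval]] = {}
    for iv in features:
        if iv.chrom not in known_chroms:
            if warn_unknown_chrom:
                warnings.warn(f"feature on unknown chromosome {iv.chrom!r} skipped")
            continue
        by_chrom.setdefault(iv.chrom, []).append(iv)

    def nearest_tss_offset(chrom: str, pos: int) -> int | None:
        if not tss_positions:
            return None
        best = None
        for tchrom, tpos, tstrand in tss_positions:
            if tchrom != chrom:
                continue
            off = pos - tpos if tstrand != "-" else tpos - pos
            if best is None or abs(off) < abs(best):
                best = off
        return best

    out: list[FeatureAnnotation] = []
    for site in sites:
        for pos, strand in adenine_positions(site):
            overlapping = [
                iv for iv in by_chrom.get(site.chrom, ()) if iv.start <= pos < iv.end
            ]
            off = nearest_tss_offset(site.chrom, pos)
            in_gene = any(iv.feature_type == "gene" for iv in overlapping)
            for iv in overlapping:
                out.append(
                    FeatureAnnotation(site.pair_id, pos, strand, iv.feature_type, iv.name, off)
                )
            if not in_gene:
                out.append(FeatureAnnotation(site.pair_id, pos, strand, "intergenic", "", off))
    return out


def classify_pair_state(
    beta_plus: float | None,
    beta_minus: float | None,
    threshold: float = 0.60,
    *,
    pair_id: int = -1,
) -> MethylationState:
    """Classify a palindrome from its two strand-specific methylation levels.

    Both strands at or above ``threshold`` -> methylated; exactly one below
    -> hemimethylated; both below -> hypomethylated_both.  A missing strand
    (coverage-filtered) yields state ``undetermined``, which tallies exclude.
    """
    if beta_plus is None or beta_minus is None or not (
        beta_plus == beta_plus and beta_minus == beta_minus  # NaN guard
    ):
        return MethylationState(pair_id, "undetermined")
    for b in (beta_plus, beta_minus):
        if not 0.0 <= b <= 1.0:
            raise ValueError(f"beta out of [0,1]: {b}")
    low = int(beta_plus < threshold) + int(beta_minus < threshold)
    state = ("methylated", "hemimethylated", "hypomethylated_both")[low]
    return MethylationState(pair_id, state)


def tally_states(states: Iterable[MethylationState]) -> dict[str, int]:
    """Count pairs per state, ignoring undetermined pairs."""
    counts = {"methylated": 0, "hemimethylated": 0, "hypomethylated_both": 0}
    for s in states:
        if s.state in counts:
            counts[s.state] += 1
    return counts


def write_sites_bed(sites: Sequence[GatcSite], path, motif_len: int = 4) -> None:
    """Write sites as BED with the pair_id in the name field."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.start + motif_len}\tpair_{s.pair_id}\t0\t+\n")
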