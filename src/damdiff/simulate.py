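"""Synthetic genomes, methylomes, and mutation sets with known truth.

The methylome generator emulates the statistical structure of a
near-saturated bacterial 6mA methylome measured by long-read sequencing:

* per-adenine baseline methylation drawn from a two-component mixture —
  a dominant component concentrated near beta = 0.97 (the genome-wide
  median of a healthy Dam methylome) and a small broad hypomethylated
  component below 0.60;
* negative-binomial read coverage with mean ~57 reads per adenine;
* binomial methylated-read counts given coverage and the sample's true
  beta;
* per-group epimutational drift as Normal noise on the logit of beta,
  so perturbed values stay inside (0, 1) without ad-hoc clipping;
* optional injected differential sites with a fixed beta shift in the
  treatment group(s).

Every draw flows from one seed; identical configs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation import MethylationTable, SampleDesign

__all__ = [
    "SimGroup",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_methylome",
    "simulate_mutations",
    "write_vcf",
]


@dataclass(frozen=True)
class SimGroup:
    """One sample group: replicate count, drift scale, treatment flag."""

    n_samples: int = 3
    drift_sd: float = 0.1   # sd of logit-scale per-site per-sample noise
    treatment: bool = False  # receives the differential-site beta shift


@dataclass
class SimConfig:
    """Study conditions for the synthetic methylome.

    Defaults reproduce the regime the pipeline is designed for: coverage
    centred at 57 reads, baseline methylation median ~0.97 with ~3% of
    adenines hypomethylated (< 0.60), three replicates per group.
    """

    n_sites: int = 2000
    seed: int = 0
    coverage_mean: float = 57.0
    coverage_dispersion: float = 20.0  # NB size parameter; var = m + m^2/size
    beta_high_mean: float = 0.97
    beta_high_concentration: float = 60.0
    hypo_weight: float = 0.03
    hypo_max: float = 0.60
    n_differential: int = 0
    delta_beta: float = -0.3
    groups: dict = field(
        default_factory=lambda: {
            "reference": SimGroup(3, 0.1, False),
            "treatment": SimGroup(3, 0.1, True),
        }
    )

    def validate(self) -> None:
        if not 0 <= self.hypo_weight <= 1:
            raise ValueError("hypo_weight must be in [0,1]")
        if not 0 < self.beta_high_mean < 1:
            raise ValueError("beta_high_mean must be in (0,1)")
        if not 0 < self.hypo_max <= 1:
            raise ValueError("hypo_max must be in (0,1]")
        if self.n_differential > self.n_sites:
            raise ValueError("more differential sites than sites")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        for name, g in self.groups.items():
            if g.n_samples < 1 or g.drift_sd < 0:
                raise ValueError(f"invalid group {name!r}")


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated table."""

    baseline_beta: np.ndarray            # (n_sites,)
    group_beta: pd.DataFrame             # n_sites x groups, pre-drift
    differential: np.ndarray             # bool flags per site
    drift: pd.DataFrame                  # n_sites x samples, logit-scale noise


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genome(length: int, gc: float = 0.5, seed: int | None = 0) -> str:
    """I.i.d. circular nucleotide sequence at the given GC fraction."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0,1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _draw_coverage(rng, shape, mean, size):
    # NB as gamma-Poisson mixture
    lam = rng.gamma(shape=size, scale=mean / size, size=shape)
    return rng.poisson(lam)


def simulate_methylome(
    sites, config: SimConfig, seed: int | None = None
) -> tuple[MethylationTable, SampleDesign, SimTruth]:
    """Simulate a per-adenine count table for every configured sample.

    ``sites`` may be a list of GatcSite objects (each contributing its two
    adenines) or an integer number of adenine rows; ``seed`` overrides
    ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if isinstance(sites, int):
        if sites < 1:
            raise ValueError("need >= 1 site")
        index = pd.MultiIndex.from_tuples(
            [("sim", i, "+" if i % 2 == 0 else "-") for i in range(sites)],
            names=["chrom", "pos", "strand"],
        )
    else:
        rows = []
        for s in sites:
            rows.append((s.chrom, s.plus_adenine, "+"))
            rows.append((s.chrom, s.minus_adenine, "-"))
        if not rows:
            raise ValueError("need >= 1 site")
        index = pd.MultiIndex.from_tuples(rows, names=["chrom", "pos", "strand"])
    n = len(index)

    # baseline mixture
    m, c = config.beta_high_mean, config.beta_high_concentration
    high = rng.beta(m * c, (1 - m) * c, size=n)
    hypo = config.hypo_max * rng.beta(2.0, 2.0, size=n)
    is_hypo = rng.random(n) < config.hypo_weight
    baseline = np.where(is_hypo, hypo, high)
    baseline = np.clip(baseline, 1e-4, 1 - 1e-4)

    diff_flags = np.zeros(n, dtype=bool)
    if config.n_differential:
        # inject effects only where the shift keeps beta inside (0,1)
        shifted = baseline + config.delta_beta
        eligible = np.where((shifted > 0.01) & (shifted < 0.99))[0]
        if len(eligible) < config.n_differential:
            raise ValueError("not enough sites can absorb the configured delta_beta")
        chosen = rng.choice(eligible, size=config.n_differential, replace=False)
        diff_flags[chosen] = True

    group_beta = {}
    for name, g in config.groups.items():
        b = baseline.copy()
        if g.treatment:
            b = np.where(diff_flags, np.clip(b + config.delta_beta, 1e-3, 1 - 1e-3), b)
        group_beta[name] = b
    group_beta = pd.DataFrame(group_beta, index=index)

    cov_frames, met_frames, drift_cols = {}, {}, {}
    sample_names, sample_groups = [], []
    for name, g in config.groups.items():
        for r in range(g.n_samples):
            sample = f"{name}_{r + 1}"
            sample_names.append(sample)
            sample_groups.append(name)
            noise = rng.normal(0.0, g.drift_sd, size=n) if g.drift_sd > 0 else np.zeros(n)
            beta_s = _expit(_logit(group_beta[name].to_numpy()) + noise)
            cov = _draw_coverage(rng, n, config.coverage_mean, config.coverage_dispersion)
            cov = np.maximum(cov, 1)
            met = rng.binomial(cov, beta_s)
            cov_frames[sample] = pd.Series(cov, index=index, dtype=float)
            met_frames[sample] = pd.Series(met, index=index, dtype=float)
            drift_cols[sample] = noise

    table = MethylationTable(pd.DataFrame(cov_frames), pd.DataFrame(met_frames))
    design = SampleDesign(tuple(sample_names), tuple(sample_groups))
    truth = SimTruth(
        baseline_beta=baseline,
        group_beta=group_beta,
        differential=diff_flags,
        drift=pd.DataFrame(drift_cols, index=index),
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# mutations


def _count_motifs_circular(seq: str, motif: str = "GATC") -> int:
    k = len(motif)
    doubled = seq + seq[: k - 1]
    return sum(1 for i in range(len(seq)) if doubled[i : i + k] == motif)


def simulate_mutations(
    genome: str,
    n_mutations: int,
    gatc_target_fraction: float = 0.0,
    seed: int | None = 0,
    motif: str = "GATC",
):
    """Random SNVs, a configured fraction engineered to gain/lose motifs.

    Motif-affecting mutations are constructed by editing a base inside an
    existing motif (loss) or completing a one-mismatch near-motif (gain);
    the truth label of every variant is established by a full-genome
    motif recount on the mutated sequence, independent of the windowed
    classifier under test.

    Returns ``(variants, truth_effects)`` with variants as
    (chrom, pos0, ref, alt) tuples.
    """
    genome = genome.upper()
    L = len(genome)
    if n_mutations > L:
        raise ValueError("more mutations than genome positions")
    rng = np.random.default_rng(seed)
    k = len(motif)
    doubled = genome + genome[: k - 1]
    base_count = _count_motifs_circular(genome, motif)

    def effect_of(pos, alt):
        mutated = genome[:pos] + alt + genome[pos + 1 :]
        delta = _count_motifs_circular(mutated, motif) - base_count
        return "gain" if delta > 0 else "loss" if delta < 0 else "none"

    motif_starts = [i for i in range(L) if doubled[i : i + k] == motif]
    near_gain = []  # (pos, required base) single-substitution motif creators
    for i in range(L):
        window = doubled[i : i + k]
        if len(window) < k:
            continue
        mism = [j for j in range(k) if window[j] != motif[j]]
        if len(mism) == 1:
            near_gain.append(((i + mism[0]) % L, motif[mism[0]]))

    n_target = int(round(n_mutations * gatc_target_fraction))
    if n_target and not motif_starts and not near_gain:
        raise ValueError("genome offers no motif gain/loss positions")

    variants, effects, used = [], [], set()

    def try_add(pos, alt, want):
        if pos in used or genome[pos] == alt:
            return False
        eff = effect_of(pos, alt)
        if want is not None and eff != want:
            return False
        used.add(pos)
        variants.append(("sim", pos, genome[pos], alt))
        effects.append(eff)
        return True

    attempts = 0
    while sum(e != "none" for e in effects) < n_target and attempts < 50 * max(n_target, 1):
        attempts += 1
        if rng.random() < 0.5 and motif_starts:
            start = int(rng.choice(motif_starts))
            pos = (start + int(rng.integers(k))) % L
            alt = rng.choice([b for b in "ACGT" if b != genome[pos]])
            try_add(pos, alt, "loss")
        elif near_gain:
            pos, need = near_gain[int(rng.integers(len(near_gain)))]
            try_add(pos, need, "gain")
    if sum(e != "none" for e in effects) < n_target:
        raise ValueError("insufficient motif positions for the requested fraction")

    while len(variants) < n_mutations:
        pos = int(rng.integers(L))
        alt = rng.choice([b for b in "ACGT" if b != genome[pos]])
        try_add(pos, alt, "none")

    order = np.argsort([v[1] for v in variants])
    variants = [variants[i] for i in order]
    effects = [effects[i] for i in order]
    return variants, effects


def write_vcf(variants, path, chrom_length: int, chrom: str = "sim") -> None:
    """Write (chrom, pos0, ref, alt) tuples as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _c, pos0, ref, alt in variants:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
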