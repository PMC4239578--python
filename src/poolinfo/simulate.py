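"""Synthetic pooled-population data with the structure of a haplotype-mixing study.

Two populations are modelled as mixtures of three haplotypes in proportions
1:2:3 and 3:2:1, so a variant carried by one haplotype segregates at frequency
1/6, 1/3 or 1/2 depending on the carrier.  With these mixing vectors a variant
on the first or third haplotype is *divergent* (frequencies 1/6 vs 1/2), while
one on the middle haplotype has frequency 1/3 in both populations and is part
of the null.  Sequencing is reduced to its per-site statistical core: read
depth per pool is Poisson around the nominal coverage, each read draws its
allele from the pool's true frequency, and each read base is substituted with
the per-base error rate to a uniformly chosen different nucleotide.  Mapping,
quality and coverage-bias artifacts of real pipelines are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, TextIO, Tuple

import numpy as np

from .counts import NUCLEOTIDES, AlleleCounts

__all__ = [
    "SimulationConfig",
    "TrueSite",
    "mixing_frequencies",
    "simulate_site_counts",
    "simulate_dataset",
    "write_mpileup",
    "write_truth_tsv",
    "read_truth_tsv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    mix_p / mix_q
        Haplotype proportions in each population (defaults 1:2:3 and 3:2:1).
    coverage
        Mean per-pool read depth (Poisson).
    error_rate
        Per-base substitution probability.
    divergent_fraction
        Fraction of sites carrying a haplotype-specific variant whose mixed
        frequencies differ between the populations.
    null_polymorphic_fraction
        Among the remaining (non-divergent) sites, the fraction carrying a
        variant shared at equal frequency by both populations — the analogue
        of a variant on the equally weighted middle haplotype; the rest are
        monomorphic reference sites.
    """

    n_sites: int
    seed: int
    mix_p: Tuple[float, ...] = (1.0, 2.0, 3.0)
    mix_q: Tuple[float, ...] = (3.0, 2.0, 1.0)
    coverage: float = 20.0
    error_rate: float = 0.01
    divergent_fraction: float = 0.5
    null_polymorphic_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        if len(self.mix_p) != len(self.mix_q):
            raise ValueError("mixing vectors must have the same length")
        if min(self.mix_p) <= 0 or min(self.mix_q) <= 0:
            raise ValueError("haplotype proportions must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        for name in ("divergent_fraction", "null_polymorphic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TrueSite:
    """Ground truth for one simulated site."""

    true_freq_p: float
    true_freq_q: float
    is_divergent: bool
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self) -> None:
        for f in (self.true_freq_p, self.true_freq_q):
            if not (0.0 <= f <= 1.0):
                raise ValueError("true frequencies must lie in [0, 1]")
        if self.is_divergent != (self.true_freq_p != self.true_freq_q):
            raise ValueError("is_divergent must match whether the true frequencies differ")


def mixing_frequencies(proportions: Sequence[float], carrier: int) -> float:
    """Frequency of a variant carried by haplotype ``carrier`` (1-based) in the mix."""
    if min(proportions) <= 0:
        raise ValueError("haplotype proportions must be positive")
    if not (1 <= carrier <= len(proportions)):
        raise ValueError(f"carrier {carrier} out of range 1..{len(proportions)}")
    return proportions[carrier - 1] / sum(proportions)


def _sample_pool(
    ref: str, alt: str, freq: float, coverage: float, error_rate: float, rng: np.random.Generator
) -> AlleleCounts:
    depth = int(rng.poisson(coverage))
    if depth == 0:
        return AlleleCounts()
    n_alt = int(rng.binomial(depth, freq)) if freq > 0 else 0
    bases = np.array([alt] * n_alt + [ref] * (depth - n_alt))
    if error_rate > 0:
        errs = np.flatnonzero(rng.random(depth) < error_rate)
        for idx in errs:
            others = [b for b in NUCLEOTIDES if b != bases[idx]]
            bases[idx] = others[rng.integers(3)]
    alleles, counts = np.unique(bases, return_counts=True)
    return AlleleCounts(counts={str(a): int(k) for a, k in zip(alleles, counts)})


def simulate_site_counts(
    site: TrueSite, coverage: float, error_rate: float, rng: np.random.Generator
) -> Tuple[AlleleCounts, AlleleCounts]:
    """Draw per-pool read counts for one site: Poisson depth, binomial allele
    sampling at the true frequency, then per-read substitution error."""
    pool_p = _sample_pool(site.ref, site.alt, site.true_freq_p, coverage, error_rate, rng)
    pool_q = _sample_pool(site.ref, site.alt, site.true_freq_q, coverage, error_rate, rng)
    return pool_p, pool_q


def _divergent_carriers(config: SimulationConfig) -> List[int]:
    carriers = [
        h
        for h in range(1, len(config.mix_p) + 1)
        if mixing_frequencies(config.mix_p, h) != mixing_frequencies(config.mix_q, h)
    ]
    if not carriers:
        raise ValueError("mixing vectors admit no divergent haplotype")
    return carriers


def _shared_frequencies(config: SimulationConfig) -> List[float]:
    return sorted({mixing_frequencies(config.mix_p, h) for h in range(1, len(config.mix_p) + 1)})


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[List[TrueSite], List[Tuple[AlleleCounts, AlleleCounts]]]:
    """Simulate truth and per-pool counts for ``config.n_sites`` sites.

    Divergent sites draw their carrier haplotype uniformly among haplotypes
    whose mixed frequencies differ; non-divergent sites are either shared
    polymorphisms (equal frequency drawn from the mixing grid) or monomorphic
    reference sites.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    carriers = _divergent_carriers(config)
    shared = _shared_frequencies(config)
    truth: List[TrueSite] = []
    counts: List[Tuple[AlleleCounts, AlleleCounts]] = []
    for _ in range(config.n_sites):
        ref = NUCLEOTIDES[rng.integers(4)]
        alt = [b for b in NUCLEOTIDES if b != ref][rng.integers(3)]
        if rng.random() < config.divergent_fraction:
            h = carriers[rng.integers(len(carriers))]
            fp = mixing_frequencies(config.mix_p, h)
            fq = mixing_frequencies(config.mix_q, h)
        elif rng.random() < config.null_polymorphic_fraction:
            fp = fq = shared[rng.integers(len(shared))]
        else:
            fp = fq = 0.0
        site = TrueSite(
            true_freq_p=fp, true_freq_q=fq, is_divergent=(fp != fq), ref=ref, alt=alt
        )
        truth.append(site)
        counts.append(
            simulate_site_counts(site, config.coverage, config.error_rate, rng)
        )
    return truth, counts


def _encode_pool(counts: AlleleCounts, ref: str) -> Tuple[int, str, str]:
    depth = counts.total
    if depth == 0:
        return 0, "*", "*"
    parts = []
    for allele in counts.alleles():
        k = counts.get(allele)
        if allele == ref:
            # split reference reads between strands, as samtools would
            parts.append("." * (k - k // 2) + "," * (k // 2))
        else:
            parts.append(allele * k)
    parts.append("*" * counts.deletions)
    parts.append(">" * counts.skips)
    bases = "".join(parts)
    return depth, bases, "I" * depth


def write_mpileup(
    truth: Sequence[TrueSite],
    counts: Sequence[Tuple[AlleleCounts, AlleleCounts]],
    sink: TextIO,
    chrom: str = "sim",
) -> None:
    """Encode simulated counts as mpileup text that re-parses to the same counts."""
    if len(truth) != len(counts):
        raise ValueError("truth and counts must have the same length")
    for pos, (site, pair) in enumerate(zip(truth, counts), start=1):
        fields = [chrom, str(pos), site.ref]
        for pool in pair:
            depth, bases, quals = _encode_pool(pool, site.ref)
            fields += [str(depth), bases, quals]
        sink.write("\t".join(fields) + "\n")


def write_truth_tsv(truth: Sequence[TrueSite], sink: TextIO, chrom: str = "sim") -> None:
    sink.write("#chrom\tpos\tref\talt\ttrue_freq_p\ttrue_freq_q\tis_divergent\n")
    for pos, site in enumerate(truth, start=1):
        sink.write(
            f"{chrom}\t{pos}\t{site.ref}\t{site.alt}\t{site.true_freq_p:.6g}\t"
            f"{site.true_freq_q:.6g}\t{int(site.is_divergent)}\n"
        )


def read_truth_tsv(stream) -> List[TrueSite]:
    truth = []
    for line in stream:
        if not line.strip() or line.startswith("#"):
            continue
        _, _, ref, alt, fp, fq, div = line.rstrip("\n").split("\t")
        truth.append(
            TrueSite(
                true_freq_p=float(fp),
                true_freq_q=float(fq),
                is_divergent=bool(int(div)),
                ref=ref,
                alt=alt,
            )
        )
    return truth
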