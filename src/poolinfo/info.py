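"""Information-theoretic and classical per-site statistics for diagnostic SNPs.

The central quantity is the *expected site information* (ESI): the expected
number of bits of evidence that observing one allele at a site contributes to
assigning an individual to one of two populations.  For allele frequency
vectors ``p`` and ``q`` in the two populations,

    ESI(p, q) = sum_i ((p_i + q_i) / 2) * |log2(p_i / q_i)|

i.e. the per-allele Bayesian log-odds update, averaged over alleles with the
populations taken as equally likely a priori.  ESI is symmetric, non-negative,
zero exactly when the frequencies agree, and additive over independent sites.

Alongside it this module provides the classical measures a practitioner would
compare against: Wright's two-deme F_ST, Fisher's exact test on read counts,
per-site nucleotide diversity, and the absolute frequency difference.
Everything here takes *known* frequencies or raw counts; estimation under
sampling noise lives in :mod:`poolinfo.conservative`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

from scipy import stats as _stats

from .counts import AlleleCounts, as_count_mapping

__all__ = [
    "FrequencyVector",
    "SiteStats",
    "allele_log_odds",
    "expected_site_information",
    "peak_allele_information",
    "total_information",
    "nucleotide_diversity",
    "abs_frequency_difference",
    "fst_two_pop",
    "fisher_exact_p",
    "frequencies_from_counts",
]

_FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyVector:
    """Allele frequencies for one population at one site.

    Frequencies must be in [0, 1] and sum to 1; alleles with frequency zero may
    be listed explicitly so that two populations can share one allele set.
    """

    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.freqs:
            raise ValueError("frequency vector needs at least one allele")
        total = 0.0
        for allele, f in self.freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency of {allele!r} outside [0, 1]: {f}")
            total += f
        if abs(total - 1.0) > _FREQ_SUM_TOL:
            raise ValueError(f"frequencies sum to {total}, not 1")
        object.__setattr__(self, "freqs", dict(self.freqs))

    def __getitem__(self, allele: str) -> float:
        return self.freqs[allele]

    @property
    def alleles(self) -> frozenset:
        return frozenset(self.freqs)

    @classmethod
    def biallelic(cls, p: float, alleles: Tuple[str, str] = ("A", "C")) -> "FrequencyVector":
        """Two-allele vector (p, 1 - p) over the given allele labels."""
        return cls({alleles[0]: p, alleles[1]: 1.0 - p})


@dataclass
class SiteStats:
    """All per-site statistics computed for one pair of pools.

    ``esi`` may be +inf (an allele seen in exactly one pool); ``csi`` is always
    finite.  ``fst`` is NaN at monomorphic sites, where it is undefined.
    """

    esi: float
    csi: float
    fst: float
    fisher_p: float
    diversity: float
    abs_diff: float
    coverage_per_pool: Tuple[int, ...]

    @property
    def total_coverage(self) -> int:
        return sum(self.coverage_per_pool)


FreqLike = Union[FrequencyVector, float]


def _as_vector(x: FreqLike) -> FrequencyVector:
    if isinstance(x, FrequencyVector):
        return x
    return FrequencyVector.biallelic(float(x))


def allele_log_odds(p_i: float, q_i: float) -> float:
    """Signed log-odds update, in bits, from observing one allele.

    Returns ``log2(p_i / q_i)``: positive values favour the first population.
    One-sided zeros give signed infinities; an allele absent from both
    populations contributes nothing (0/0 -> 0 by convention).
    """
    for name, v in (("p_i", p_i), ("q_i", q_i)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} outside [0, 1]: {v}")
    if p_i == 0.0 and q_i == 0.0:
        return 0.0
    if q_i == 0.0:
        return math.inf
    if p_i == 0.0:
        return -math.inf
    return math.log2(p_i / q_i)


def _union_items(p: FrequencyVector, q: FrequencyVector) -> Iterable[Tuple[float, float]]:
    if p.alleles != q.alleles:
        raise ValueError(
            f"inconsistent allele sets: {sorted(p.alleles)} vs {sorted(q.alleles)}"
        )
    return [(p[a], q[a]) for a in sorted(p.alleles)]


def expected_site_information(p: FreqLike, q: FreqLike) -> float:
    """Expected site information (ESI), in bits.

    Each allele's absolute log-odds is weighted by its mean frequency across
    the two populations.  Scalars are interpreted as biallelic frequencies
    (p, 1-p).  Returns +inf when any allele is present in exactly one
    population; 0 exactly when the frequency vectors agree.
    """
    pv, qv = _as_vector(p), _as_vector(q)
    total = 0.0
    for pi, qi in _union_items(pv, qv):
        if pi == 0.0 and qi == 0.0:
            continue
        lod = allele_log_odds(pi, qi)
        if math.isinf(lod):
            return math.inf
        total += 0.5 * (pi + qi) * abs(lod)
    return total


def peak_allele_information(p: FreqLike, q: FreqLike) -> float:
    """Largest single-allele log-odds magnitude at the site, in bits.

    The most informative single observation possible at the site: the maximum
    over alleles of ``|log2(p_i/q_i)|``.  +inf on one-sided zeros; 0 exactly
    when the frequencies agree.
    """
    pv, qv = _as_vector(p), _as_vector(q)
    best = 0.0
    for pi, qi in _union_items(pv, qv):
        if pi == 0.0 and qi == 0.0:
            continue
        best = max(best, abs(allele_log_odds(pi, qi)))
    return best


def total_information(site_values: Sequence[float]) -> float:
    """Sum of per-site information values (ESI is additive across independent sites)."""
    values = list(site_values)
    if any(not math.isfinite(v) for v in values):
        raise ValueError("total information requires finite per-site values")
    return float(sum(values))


def nucleotide_diversity(p: float, q: float) -> float:
    """Per-site nucleotide diversity p(1-q) + (1-p)q.

    The probability that one allele drawn from each population differ.  Equals
    0.5 whenever p = 0.5 regardless of q, which is why it fails as a
    divergence measure.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return p * (1.0 - q) + (1.0 - p) * q


def abs_frequency_difference(p: float, q: float) -> float:
    """Absolute allele-frequency difference |p - q|."""
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return abs(p - q)


def fst_two_pop(p: float, q: float) -> float:
    """Wright's two-deme F_ST from one allele's frequencies.

    Var({p, q}) / (pbar (1 - pbar)), with the population variance (divide by
    2) and pbar = (p + q)/2.  NaN at monomorphic sites (pbar in {0, 1}),
    where differentiation is undefined.  Invariant under exchanging p and q
    and under complementing both frequencies, so the choice of which allele
    of a biallelic site to track does not matter.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    pbar = 0.5 * (p + q)
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return math.nan
    var = 0.5 * ((p - pbar) ** 2 + (q - pbar) ** 2)
    return var / denom


def fisher_exact_p(counts: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of read counts.

    Two-sidedness by the point-probability method: the sum of hypergeometric
    probabilities no larger than that of the observed table.
    """
    table = [[int(v) for v in row] for row in counts]
    if len(table) != 2 or any(len(row) != 2 for row in table):
        raise ValueError("expected a 2x2 table")
    if any(v < 0 for row in table for v in row):
        raise ValueError("counts must be non-negative")
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        raise ValueError("empty table margin: each pool needs at least one read")
    return float(_stats.fisher_exact(table, alternative="two-sided")[1])


def frequencies_from_counts(counts: "AlleleCounts | Mapping[str, int]") -> FrequencyVector:
    """Point-estimate allele frequencies from read counts.

    Deletions, skips and indel tallies are excluded: only nucleotide calls are
    SNP-eligible.  Raises on zero depth (no data at the site).
    """
    mapping = as_count_mapping(counts)
    total = sum(mapping.values())
    if total <= 0:
        raise ValueError("no SNP-eligible reads at site")
    return FrequencyVector({a: k / total for a, k in mapping.items() if k > 0})
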