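"""Conservative site information (CSI): a finite lower bound on ESI from counts.

Point-estimate allele frequencies from pooled reads overstate divergence: an
allele absent from one pool's reads makes the log-odds infinite even when its
true frequency is merely small, and sequencing errors manufacture apparent
alleles.  For SNP panel design it matters more that selected sites are truly
informative than that their information is estimated precisely, so CSI scores
each allele by the *worst case* over an error-widened Agresti-Coull confidence
box: the smallest |log2(p/q)| compatible with the interval for each pool's
frequency.  Overlapping intervals contribute nothing; a zero endpoint is never
placed in a denominator, so CSI is finite for every input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy import stats as _stats

from .counts import AlleleCounts, as_count_mapping

__all__ = [
    "BinomialInterval",
    "EstimatorConfig",
    "agresti_coull",
    "widen_by_error",
    "conservative_allele_log_odds",
    "conservative_site_information",
]


@dataclass(frozen=True)
class BinomialInterval:
    """Agresti-Coull confidence interval for one allele frequency.

    Built from ``x`` successes in ``n`` trials at normal quantile ``z``:
    adjusted trials ``n_tilde = n + z**2``, adjusted proportion
    ``p_tilde = (x + z**2/2) / n_tilde``, bounds ``p_tilde +- z*sqrt(p_tilde
    (1 - p_tilde) / n_tilde)`` clamped to [0, 1].
    """

    x: int
    n: int
    z: float
    n_tilde: float
    p_tilde: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    def overlaps(self, other: "BinomialInterval") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the conservative estimator.

    epsilon
        Per-base substitution error rate; both interval limits are shifted
        outward by this amount (an error can both create and mask an allele).
    confidence
        Coverage probability of the Agresti-Coull interval.
    """

    epsilon: float = 0.01
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in [0, 0.5): {self.epsilon}")
        if not (0.5 < self.confidence < 1.0):
            raise ValueError(f"confidence must be in (0.5, 1): {self.confidence}")

    @property
    def z(self) -> float:
        return float(_stats.norm.ppf(0.5 + self.confidence / 2.0))


def agresti_coull(x: int, n: int, confidence: float = 0.95) -> BinomialInterval:
    """Agresti-Coull interval for ``x`` successes out of ``n`` trials."""
    if n <= 0:
        raise ValueError("no data: n must be positive")
    if not (0 <= x <= n):
        raise ValueError(f"x={x} outside [0, n={n}]")
    if not (0.5 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0.5, 1): {confidence}")
    z = float(_stats.norm.ppf(0.5 + confidence / 2.0))
    n_tilde = n + z * z
    p_tilde = (x + z * z / 2.0) / n_tilde
    halfwidth = z * math.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return BinomialInterval(
        x=x,
        n=n,
        z=z,
        n_tilde=n_tilde,
        p_tilde=p_tilde,
        lower=max(0.0, p_tilde - halfwidth),
        upper=min(1.0, p_tilde + halfwidth),
    )


def widen_by_error(ci: BinomialInterval, epsilon: float) -> BinomialInterval:
    """Shift both limits outward by the sequencing error rate, clamped to [0, 1]."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return BinomialInterval(
        x=ci.x,
        n=ci.n,
        z=ci.z,
        n_tilde=ci.n_tilde,
        p_tilde=ci.p_tilde,
        lower=max(0.0, ci.lower - epsilon),
        upper=min(1.0, ci.upper + epsilon),
    )


def conservative_allele_log_odds(ci_p: BinomialInterval, ci_q: BinomialInterval) -> float:
    """Smallest |log2(p/q)| over frequencies inside the two intervals, in bits.

    Zero when the intervals overlap (no divergence is guaranteed); otherwise
    the log-ratio of the two nearest endpoints.  When the lower interval is
    degenerate at 0 the contribution is defined as 0 — the maximally
    conservative reading — so the result is always finite.
    """
    if ci_p.overlaps(ci_q):
        return 0.0
    if ci_p.lower > ci_q.upper:
        near_high, near_low = ci_p.lower, ci_q.upper
    else:
        near_high, near_low = ci_q.lower, ci_p.upper
    if near_low == 0.0:
        return 0.0
    return abs(math.log2(near_high / near_low))


def conservative_site_information(
    counts_p: "AlleleCounts | Mapping[str, int]",
    counts_q: "AlleleCounts | Mapping[str, int]",
    config: EstimatorConfig = EstimatorConfig(),
) -> float:
    """Conservative site information (CSI) from raw per-pool read counts, in bits.

    For each allele observed in either pool, a per-allele binomial interval
    (count against SNP-eligible depth) is built for each pool, widened by the
    error rate, and scored by its worst-case log-odds; terms are weighted by
    the mean of the two point-estimate frequencies and summed.  Always finite
    and non-negative; 0 when every allele's intervals overlap.
    """
    cp, cq = as_count_mapping(counts_p), as_count_mapping(counts_q)
    n_p, n_q = sum(cp.values()), sum(cq.values())
    if n_p <= 0 or n_q <= 0:
        raise ValueError("zero SNP-eligible depth in a pool")
    total = 0.0
    alleles = sorted({a for a, k in cp.items() if k > 0} | {a for a, k in cq.items() if k > 0})
    for allele in alleles:
        x_p, x_q = cp.get(allele, 0), cq.get(allele, 0)
        ci_p = widen_by_error(agresti_coull(x_p, n_p, config.confidence), config.epsilon)
        ci_q = widen_by_error(agresti_coull(x_q, n_q, config.confidence), config.epsilon)
        weight = 0.5 * (x_p / n_p + x_q / n_q)
        total += weight * conservative_allele_log_odds(ci_p, ci_q)
    return total
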