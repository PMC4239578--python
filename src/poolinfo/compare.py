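"""Score simulated or parsed sites with every statistic and evaluate the results.

This module glues the estimators together the way a study would use them:
compute ESI/CSI/F_ST/Fisher/diversity per site, filter by total coverage,
tabulate how well CSI separates truly divergent sites from the null, and check
the false-positive arithmetic of p-value thresholds.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd

from .conservative import EstimatorConfig, conservative_site_information
from .counts import AlleleCounts, as_count_mapping
from .info import (
    FrequencyVector,
    SiteStats,
    abs_frequency_difference,
    expected_site_information,
    fisher_exact_p,
    fst_two_pop,
    nucleotide_diversity,
)
from .simulate import TrueSite

__all__ = [
    "paired_frequencies",
    "score_site",
    "score_sites",
    "expected_false_positives",
    "filter_by_coverage",
    "separation_table",
    "calibration_table",
    "stats_frame",
]

CountsLike = Union[AlleleCounts, Mapping[str, int]]


def paired_frequencies(
    counts_p: CountsLike, counts_q: CountsLike
) -> Tuple[FrequencyVector, FrequencyVector]:
    """Point-estimate frequency vectors over the union allele set of two pools.

    Alleles seen in only one pool get an explicit zero in the other, so the
    vectors share an allele set and one-sided absences surface as infinite ESI
    rather than as an error.
    """
    cp, cq = as_count_mapping(counts_p), as_count_mapping(counts_q)
    n_p, n_q = sum(cp.values()), sum(cq.values())
    if n_p <= 0 or n_q <= 0:
        raise ValueError("zero SNP-eligible depth in a pool")
    alleles = sorted(
        {a for a, k in cp.items() if k > 0} | {a for a, k in cq.items() if k > 0}
    )
    fp = FrequencyVector({a: cp.get(a, 0) / n_p for a in alleles})
    fq = FrequencyVector({a: cq.get(a, 0) / n_q for a in alleles})
    return fp, fq


def _major_allele(cp: Mapping[str, int], cq: Mapping[str, int]) -> str:
    pooled = {a: cp.get(a, 0) + cq.get(a, 0) for a in set(cp) | set(cq)}
    return max(sorted(pooled), key=pooled.get)


def score_site(
    counts_p: CountsLike,
    counts_q: CountsLike,
    config: EstimatorConfig = EstimatorConfig(),
) -> SiteStats:
    """All statistics for one site from per-pool counts.

    The scalar pairwise measures (F_ST, Fisher, diversity, |p-q|) track the
    overall major allele against the rest; for a biallelic site F_ST,
    diversity and |p-q| are invariant under that choice.  A pool with zero
    depth yields all-NaN statistics.
    """
    cp, cq = as_count_mapping(counts_p), as_count_mapping(counts_q)
    n_p, n_q = sum(cp.values()), sum(cq.values())
    if n_p == 0 or n_q == 0:
        nan = math.nan
        return SiteStats(nan, nan, nan, nan, nan, nan, (n_p, n_q))
    freq_p, freq_q = paired_frequencies(cp, cq)
    esi = expected_site_information(freq_p, freq_q)
    csi = conservative_site_information(cp, cq, config)
    major = _major_allele(cp, cq)
    p_hat, q_hat = cp.get(major, 0) / n_p, cq.get(major, 0) / n_q
    fst = fst_two_pop(p_hat, q_hat)
    fisher = fisher_exact_p(
        [[cp.get(major, 0), n_p - cp.get(major, 0)], [cq.get(major, 0), n_q - cq.get(major, 0)]]
    )
    return SiteStats(
        esi=esi,
        csi=csi,
        fst=fst,
        fisher_p=fisher,
        diversity=nucleotide_diversity(p_hat, q_hat),
        abs_diff=abs_frequency_difference(p_hat, q_hat),
        coverage_per_pool=(n_p, n_q),
    )


def score_sites(
    counts: Sequence[Tuple[CountsLike, CountsLike]],
    config: EstimatorConfig = EstimatorConfig(),
) -> List[SiteStats]:
    """Score every site; one SiteStats per input pair, in order."""
    return [score_site(cp, cq, config) for cp, cq in counts]


def expected_false_positives(n_sites: int, alpha: float) -> float:
    """Expected null sites below a p-value threshold: n_sites * alpha."""
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return n_sites * alpha


def _total_depth(item) -> float:
    if isinstance(item, SiteStats):
        return sum(item.coverage_per_pool)
    if isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], SiteStats):
        return sum(item[1].coverage_per_pool)
    if hasattr(item, "depths"):
        return sum(item.depths)
    return sum(item)


def filter_by_coverage(records: Iterable, center: float, halfwidth: float) -> List:
    """Keep sites whose total depth lies in [center - halfwidth, center + halfwidth].

    Bounds inclusive; input order preserved.  Accepts SiteStats,
    (SiteRecord, SiteStats) pairs, SiteRecords, or plain depth tuples.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    lo, hi = center - halfwidth, center + halfwidth
    return [r for r in records if lo <= _total_depth(r) <= hi]


def separation_table(
    stats: Sequence[SiteStats],
    truth: Sequence[TrueSite],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Count divergent and non-divergent sites with CSI at or above each threshold.

    The ratio column (divergent over non-divergent count) is the operational
    reading of "separation" from a score histogram; NaN when no null site
    clears the threshold.
    """
    if len(stats) != len(truth):
        raise ValueError(
            f"stats ({len(stats)}) and truth ({len(truth)}) must align"
        )
    rows = []
    for thr in thresholds:
        div = sum(
            1 for s, t in zip(stats, truth) if t.is_divergent and s.csi == s.csi and s.csi >= thr
        )
        non = sum(
            1
            for s, t in zip(stats, truth)
            if not t.is_divergent and s.csi == s.csi and s.csi >= thr
        )
        rows.append(
            {
                "threshold": thr,
                "divergent": div,
                "non_divergent": non,
                "ratio": div / non if non > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def calibration_table(
    stats: Sequence[SiteStats],
    truth: Sequence[TrueSite],
    alphas: Sequence[float] = (0.05, 1e-2, 1e-3),
) -> pd.DataFrame:
    """Observed vs expected counts of null sites with Fisher p below each alpha."""
    if len(stats) != len(truth):
        raise ValueError("stats and truth must align")
    null_p = [
        s.fisher_p
        for s, t in zip(stats, truth)
        if not t.is_divergent and s.fisher_p == s.fisher_p
    ]
    rows = []
    for alpha in alphas:
        observed = sum(1 for p in null_p if p < alpha)
        rows.append(
            {
                "alpha": alpha,
                "n_null": len(null_p),
                "observed": observed,
                "expected": expected_false_positives(len(null_p), alpha),
            }
        )
    return pd.DataFrame(rows)


def stats_frame(stats: Sequence[SiteStats]) -> pd.DataFrame:
    """Tidy DataFrame of per-site statistics (one row per site)."""
    return pd.DataFrame(
        {
            "esi": [s.esi for s in stats],
            "csi": [s.csi for s in stats],
            "fst": [s.fst for s in stats],
            "fisher_p": [s.fisher_p for s in stats],
            "diversity": [s.diversity for s in stats],
            "abs_diff": [s.abs_diff for s in stats],
            "total_coverage": [sum(s.coverage_per_pool) for s in stats],
        }
    )
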