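"""Per-site, per-pool allele counts: the observation unit of all estimation.

In pooled sequencing (Pool-seq) the reads covering one genomic position in one
pool are the sample from that population's allele distribution.  ``AlleleCounts``
tallies those reads by nucleotide, keeping deletions, reference skips and indel
events separate so that the SNP-eligible depth (substitutions only) is well
defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

NUCLEOTIDES: Tuple[str, ...] = ("A", "C", "G", "T")


@dataclass
class AlleleCounts:
    """Read tallies at one site in one pool.

    Parameters
    ----------
    counts
        Reads per nucleotide (A/C/G/T only).
    deletions
        Reads showing a deletion placeholder (``*``) at this position.
    indel_events
        Number of ``+n``/``-n`` insertion/deletion runs attached to reads at
        this position (the inserted/deleted bases are not counted as alleles).
    skips
        Reference skips (``>``/``<``) and ambiguous ``N`` calls.
    """

    counts: Dict[str, int] = field(default_factory=dict)
    deletions: int = 0
    indel_events: int = 0
    skips: int = 0

    def __post_init__(self) -> None:
        for allele, k in self.counts.items():
            if allele not in NUCLEOTIDES:
                raise ValueError(f"unknown allele symbol {allele!r}")
            if k < 0:
                raise ValueError(f"negative count for allele {allele!r}")
        if min(self.deletions, self.indel_events, self.skips) < 0:
            raise ValueError("negative tally")

    @property
    def depth(self) -> int:
        """SNP-eligible depth: reads assigned to a nucleotide."""
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        """All placed reads, including deletion placeholders and skips."""
        return self.depth + self.deletions + self.skips

    def get(self, allele: str, default: int = 0) -> int:
        return self.counts.get(allele, default)

    def alleles(self) -> Iterator[str]:
        """Alleles observed at least once, in fixed A/C/G/T order."""
        return (a for a in NUCLEOTIDES if self.counts.get(a, 0) > 0)

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "AlleleCounts":
        return cls(counts=dict(counts))


def as_count_mapping(obj: "AlleleCounts | Mapping[str, int]") -> Mapping[str, int]:
    """Accept either an ``AlleleCounts`` or a plain ``{allele: count}`` mapping."""
    if isinstance(obj, AlleleCounts):
        return obj.counts
    return obj
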