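"""Reading samtools mpileup text and writing per-site statistic tables.

An mpileup line carries ``chrom pos ref`` followed by ``depth bases quals``
for each sample.  The base string is decoded per the pileup grammar: ``.``/``,``
are reference matches (forward/reverse strand), letters are substitutions,
``^X`` marks a read start (X is mapping quality, consumed), ``$`` a read end,
``+n``/``-n`` an indel run of n bases attached to the preceding read, ``*`` a
deletion placeholder and ``>``/``<`` reference skips.  Strand case is merged —
the information statistic consumes frequencies only — and base qualities are
parsed but unused.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Sequence, TextIO, Tuple, Union

from .counts import NUCLEOTIDES, AlleleCounts
from .info import SiteStats

logger = logging.getLogger(__name__)

__all__ = [
    "PileupParseError",
    "SiteRecord",
    "parse_base_string",
    "parse_mpileup_line",
    "read_mpileup",
    "write_stats_tsv",
    "open_text",
]


class PileupParseError(ValueError):
    """Malformed mpileup input, with the offending line/column when known."""


@dataclass
class SiteRecord:
    """One mpileup line: a genomic coordinate with per-pool allele counts."""

    chrom: str
    pos: int
    ref: str
    pools: List[AlleleCounts]
    depths: List[int]
    quals: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"mpileup positions are 1-based; got {self.pos}")


def parse_base_string(bases: str, ref: str, line_no: int = 0) -> AlleleCounts:
    """Decode one pool's encoded base column into allele counts."""
    counts = {a: 0 for a in NUCLEOTIDES}
    deletions = indel_events = skips = 0
    ref = ref.upper()
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(
                    f"line {line_no}: dangling '^' at column {i} of base string"
                )
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"line {line_no}: '{c}' not followed by a length at column {i}"
                )
            run = int(bases[i + 1 : j])
            if j + run > n:
                raise PileupParseError(
                    f"line {line_no}: truncated indel run at column {i}"
                )
            indel_events += 1
            i = j + run
            continue
        if c in ".,":
            if ref in NUCLEOTIDES:
                counts[ref] += 1
            else:
                skips += 1
        elif c.upper() in NUCLEOTIDES:
            counts[c.upper()] += 1
        elif c in "Nn":
            skips += 1
        elif c in "*#":
            deletions += 1
        elif c in "><":
            skips += 1
        else:
            raise PileupParseError(
                f"line {line_no}: unrecognized pileup symbol {c!r} at column {i}"
            )
        i += 1
    return AlleleCounts(
        counts={a: k for a, k in counts.items() if k > 0},
        deletions=deletions,
        indel_events=indel_events,
        skips=skips,
    )


def parse_mpileup_line(line: str, n_pools: int = 2, line_no: int = 0) -> SiteRecord:
    """Parse one mpileup line holding ``n_pools`` samples."""
    fields = line.rstrip("\n").split("\t")
    expected = 3 + 3 * n_pools
    if len(fields) != expected:
        raise PileupParseError(
            f"line {line_no}: expected {expected} tab-separated fields for "
            f"{n_pools} pools, found {len(fields)}"
        )
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(f"line {line_no}: non-numeric position {pos_s!r}") from None
    pools: List[AlleleCounts] = []
    depths: List[int] = []
    quals: List[str] = []
    for k in range(n_pools):
        depth_s, bases, qual = fields[3 + 3 * k : 6 + 3 * k]
        try:
            depth = int(depth_s)
        except ValueError:
            raise PileupParseError(
                f"line {line_no}: non-numeric depth {depth_s!r} in pool {k + 1}"
            ) from None
        if depth == 0:
            # samtools writes "0  *  *" for empty columns; nothing to decode
            counts = AlleleCounts()
        else:
            counts = parse_base_string(bases, ref, line_no=line_no)
            if counts.total != depth:
                raise PileupParseError(
                    f"line {line_no}: pool {k + 1} decodes to {counts.total} reads "
                    f"but declares depth {depth}"
                )
        pools.append(counts)
        depths.append(depth)
        quals.append(qual)
    try:
        record = SiteRecord(chrom=chrom, pos=pos, ref=ref, pools=pools, depths=depths, quals=quals)
    except ValueError as exc:
        raise PileupParseError(f"line {line_no}: {exc}") from None
    return record


def read_mpileup(
    stream: Iterable[str], n_pools: int = 2, strict: bool = False
) -> Iterator[SiteRecord]:
    """Lazily parse an mpileup stream.

    In tolerant mode (default) malformed lines are skipped with a logged
    warning; in strict mode the parse error propagates.
    """
    for line_no, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            yield parse_mpileup_line(line, n_pools=n_pools, line_no=line_no)
        except PileupParseError as exc:
            if strict:
                raise
            logger.warning("skipping malformed mpileup line: %s", exc)


def open_text(path: str, mode: str = "rt") -> Union[TextIO, IO[str]]:
    """Open plain or gzip text by file suffix."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


STATS_COLUMNS = ("esi", "csi", "fst", "fisher_p", "diversity")


def _fmt(value: float) -> str:
    if value != value:  # NaN
        return "NA"
    if value == float("inf"):
        return "inf"
    return f"{value:.4f}"


def _counts_summary(counts: AlleleCounts) -> str:
    parts = [f"{a}:{counts.get(a)}" for a in counts.alleles()]
    return ",".join(parts) if parts else "."


def write_stats_tsv(
    records: Iterable[Tuple[SiteRecord, SiteStats]], sink: TextIO
) -> int:
    """Write one row of statistics per site; returns the number of data rows."""
    header = ["#chrom", "pos", "ref"]
    header += ["depth1", "counts1", "depth2", "counts2"]
    header += list(STATS_COLUMNS)
    sink.write("\t".join(header) + "\n")
    n_rows = 0
    for record, stats in records:
        row = [record.chrom, str(record.pos), record.ref]
        for pool, depth in zip(record.pools[:2], record.depths[:2]):
            row += [str(depth), _counts_summary(pool)]
        row += [_fmt(getattr(stats, col)) for col in STATS_COLUMNS]
        sink.write("\t".join(row) + "\n")
        n_rows += 1
    return n_rows
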