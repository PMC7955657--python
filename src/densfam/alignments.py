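"""Reading, validating and grouping tabular local-alignment records.

The input format is the 12-column BLAST tabular output (``-outfmt 6``):
``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``.  Only the identifier, coordinate and E-value columns are
consumed; coordinates are 1-based and inclusive, and alignments are reduced
to their envelope (gap structure inside an alignment is ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class AlignmentTableError(ValueError):
    """A malformed record in an alignment table, with its line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True, slots=True)
class Region:
    """A contiguous interval on a named sequence, 1-based and inclusive."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.seq_id}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def intersection_length(self, other: "Region") -> int:
        """Number of residues shared with *other* (sequence ids not checked)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def union_length(self, other: "Region") -> int:
        """Residues covered by either interval; a gap between them does not count."""
        return self.length + other.length - self.intersection_length(other)


@dataclass(frozen=True, slots=True)
class Alignment:
    """One local pairwise alignment between a query and a search sequence.

    Holds the two aligned envelopes: ``query_region`` on the query sequence
    and ``search_region`` on the search (database) sequence, plus the
    alignment E-value.
    """

    query_id: str
    search_id: str
    query_region: Region
    search_region: Region
    evalue: float

    def __post_init__(self) -> None:
        if self.query_region.seq_id != self.query_id:
            raise ValueError("query_region must lie on the query sequence")
        if self.search_region.seq_id != self.search_id:
            raise ValueError("search_region must lie on the search sequence")
        if not (self.evalue >= 0):
            raise ValueError(f"negative or NaN E-value: {self.evalue}")

    @property
    def key(self) -> tuple:
        """A hashable identity used to match alignments across runs."""
        return (
            self.query_id,
            self.search_id,
            self.query_region.start,
            self.query_region.end,
            self.search_region.start,
            self.search_region.end,
            self.evalue,
        )


@dataclass(slots=True)
class QueryAlignmentSet:
    """All alignments of a single query sequence, in input order."""

    query_id: str
    alignments: list[Alignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for aln in self.alignments:
            if aln.query_id != self.query_id:
                raise ValueError(
                    f"alignment of query {aln.query_id!r} in set for {self.query_id!r}"
                )

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)


def _parse_row(fields: Sequence[str], line: int) -> Alignment:
    if len(fields) < 11:
        raise AlignmentTableError(
            f"expected >= 11 tab-separated columns, got {len(fields)}", line
        )
    qid, sid = fields[0], fields[1]
    try:
        qs, qe, ss, se = (int(fields[i]) for i in (6, 7, 8, 9))
        evalue = float(fields[10])
    except ValueError as exc:
        raise AlignmentTableError(f"non-numeric field: {exc}", line) from None
    # BLAST reports sstart > send on the reverse strand; normalize.
    if qs > qe:
        qs, qe = qe, qs
    if ss > se:
        ss, se = se, ss
    if qs <= 0 or ss <= 0:
        raise AlignmentTableError(
            f"non-positive coordinate in {qid} vs {sid}: "
            f"q={qs}-{qe} s={ss}-{se}", line
        )
    if not math.isfinite(evalue) or evalue < 0:
        raise AlignmentTableError(f"invalid E-value {fields[10]!r}", line)
    return Alignment(
        query_id=qid,
        search_id=sid,
        query_region=Region(qid, qs, qe),
        search_region=Region(sid, ss, se),
        evalue=evalue,
    )


def read_alignment_table(
    path: str | Path,
    evalue_max: float = 0.1,
    drop_self: bool = False,
) -> list[Alignment]:
    """Read a BLAST outfmt-6 TSV, keeping rows with ``evalue < evalue_max``.

    The E-value filter is a strict inequality.  Coordinates are normalized
    so that start <= end on both sequences; input row order is preserved.
    With ``drop_self=True``, rows where the query aligns to itself are
    discarded.  An empty file yields an empty list.

    Raises
    ------
    AlignmentTableError
        On a malformed row (wrong column count, non-numeric coordinate,
        non-positive coordinate, invalid E-value), naming the line.
    """
    out: list[Alignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            aln = _parse_row(raw.split("\t"), lineno)
            if aln.evalue >= evalue_max:
                continue
            if drop_self and aln.query_id == aln.search_id:
                continue
            out.append(aln)
    return out


def write_alignment_table(alignments: Iterable[Alignment], path: str | Path) -> None:
    """Write alignments back as 12-column outfmt-6 TSV.

    Only the columns densfam consumes are meaningful; pident/length/mismatch/
    gapopen/bitscore are filled with placeholder values so that the file
    round-trips through :func:`read_alignment_table`.
    """
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    [
                        a.query_id,
                        a.search_id,
                        "100.0",
                        str(a.query_region.length),
                        "0",
                        "0",
                        str(a.query_region.start),
                        str(a.query_region.end),
                        str(a.search_region.start),
                        str(a.search_region.end),
                        repr(a.evalue),  # shortest representation that round-trips
                        "0.0",
                    ]
                )
                + "\n"
            )


def group_by_query(alignments: Iterable[Alignment]) -> list[QueryAlignmentSet]:
    """Partition alignments into one :class:`QueryAlignmentSet` per query.

    Sets appear in order of first appearance of their query; alignments keep
    their input order within each set.
    """
    by_query: dict[str, QueryAlignmentSet] = {}
    for aln in alignments:
        qset = by_query.get(aln.query_id)
        if qset is None:
            qset = by_query[aln.query_id] = QueryAlignmentSet(aln.query_id)
        qset.alignments.append(aln)
    return list(by_query.values())


def dedup_same_search(qset: QueryAlignmentSet, mu1: float = 0.2) -> QueryAlignmentSet:
    """Collapse near-duplicate alignments to the same search sequence.

    When two alignments of the query hit the *same* search sequence and
    their query regions lie within ``mu1`` of each other (interval-overlap
    distance), only the lower-E-value alignment is kept.  Resolution is
    greedy in ascending E-value (ties broken by input order): a retained
    alignment suppresses every same-search-sequence alignment within
    ``mu1`` of it, which makes the rule deterministic for chains of
    overlaps.  The retained alignments are returned in input order.
    """
    from densfam.primary import region_distance  # local import; no cycle at call time

    if not 0 < mu1 < 1:
        raise ValueError(f"mu1 must be in (0,1), got {mu1}")
    order = sorted(range(len(qset.alignments)), key=lambda i: (qset.alignments[i].evalue, i))
    kept_by_search: dict[str, list[Alignment]] = {}
    kept_idx: set[int] = set()
    for i in order:
        aln = qset.alignments[i]
        rivals = kept_by_search.setdefault(aln.search_id, [])
        if any(region_distance(aln.query_region, r.query_region) < mu1 for r in rivals):
            continue
        rivals.append(aln)
        kept_idx.add(i)
    return QueryAlignmentSet(
        qset.query_id,
        [a for i, a in enumerate(qset.alignments) if i in kept_idx],
    )
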