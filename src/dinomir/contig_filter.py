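"""Exact-overlap contig assembly and the long-unidirectional-contig filter.

mRNA degradation fragments in a stranded library tile their source
transcript, so they assemble into long contigs whose member reads all lie in
the same orientation. Genuine Dicer products do not: at most a guide/star
pair merges, and it does so in opposite orientations. Removing the members
of long single-direction contigs therefore strips degradation fragments from
the candidate pool while keeping duplex-forming small RNAs.

Assembly is greedy agglomeration on exact overlaps only (100% identity over
at least ``min_overlap`` bases, default 14): repeatedly merge the pair of
units with the longest exact suffix-prefix overlap or containment,
considering both orientations, until none remains. Ties are broken by the
lexicographically smallest merged sequence.
"""

from __future__ import annotations

import heapq
import itertools
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .collapse_filter import CollapsedSet
from .sequence_io import CollapsedRead, revcomp

Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class Overlap:
    """Best exact overlap placing ``b`` (possibly reverse-complemented)
    relative to ``a``; ``offset`` is b's start on a's coordinates and may be
    negative when b hangs off (or contains) a's 5' end."""

    length: int
    orientation: Orientation
    offset: int
    kind: Literal["suffix_prefix", "containment"]


@dataclass(frozen=True)
class ContigMember:
    read_id: str
    seq: str  # read sequence as collapsed (its own 5'->3')
    offset: int  # 0-based start on the contig forward strand
    orientation: Orientation

    def oriented_seq(self) -> str:
        return self.seq if self.orientation == "forward" else revcomp(self.seq)


@dataclass
class Contig:
    seq: str
    members: list[ContigMember]

    @property
    def length(self) -> int:
        return len(self.seq)

    def is_unidirectional(self) -> bool:
        return len({m.orientation for m in self.members}) == 1

    def validate(self) -> None:
        for m in self.members:
            sub = self.seq[m.offset : m.offset + len(m.seq)]
            if sub != m.oriented_seq():
                raise AssertionError(
                    f"member {m.read_id} inconsistent with contig at offset {m.offset}"
                )


@dataclass
class ContigFilterResult:
    contigs: list[Contig]
    removed_read_ids: set[str]
    retained: CollapsedSet
    median_contig_length: float
    flagged_contigs: list[Contig] = field(default_factory=list)


def find_overlap(a: str, b: str, min_overlap: int) -> Overlap | None:
    """Longest exact merge relationship between a and b, or None.

    Considers, for b forward and b reverse-complemented: containment of one
    sequence in the other, and suffix-prefix overlaps in both orders
    (a's suffix == b's prefix, and b's suffix == a's prefix). Only overlaps
    of length >= min_overlap qualify; containment length is the shorter
    sequence's length and qualifies regardless once >= min_overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    best: Overlap | None = None

    def consider(cand: Overlap) -> None:
        nonlocal best
        if cand.length < min_overlap:
            return
        if best is None or cand.length > best.length:
            best = cand

    for orientation in ("forward", "reverse"):
        b_or = b if orientation == "forward" else revcomp(b)
        # containment
        if len(b_or) <= len(a):
            pos = a.find(b_or)
            if pos != -1:
                consider(Overlap(len(b_or), orientation, pos, "containment"))
        else:
            pos = b_or.find(a)
            if pos != -1:
                consider(Overlap(len(a), orientation, -pos, "containment"))
        # a suffix == b prefix  (b extends a's 3' end)
        max_k = min(len(a), len(b_or)) - 1
        for k in range(max_k, min_overlap - 1, -1):
            if best is not None and k <= best.length:
                break
            if a.endswith(b_or[:k]):
                consider(Overlap(k, orientation, len(a) - k, "suffix_prefix"))
                break
        # b suffix == a prefix  (b extends a's 5' end)
        for k in range(max_k, min_overlap - 1, -1):
            if best is not None and k <= best.length:
                break
            if b_or.endswith(a[:k]):
                consider(Overlap(k, orientation, -(len(b_or) - k), "suffix_prefix"))
                break
    return best


def _flip_members(members: list[ContigMember], seq_len: int) -> list[ContigMember]:
    flipped = []
    for m in members:
        ori: Orientation = "reverse" if m.orientation == "forward" else "forward"
        flipped.append(
            ContigMember(m.read_id, m.seq, seq_len - (m.offset + len(m.seq)), ori)
        )
    return flipped


def _merge(a: Contig, b: Contig, ov: Overlap) -> Contig:
    b_seq = b.seq if ov.orientation == "forward" else revcomp(b.seq)
    b_members = b.members if ov.orientation == "forward" else _flip_members(b.members, len(b.seq))
    shift = -min(0, ov.offset)  # move everything right if b starts before a
    b_start = ov.offset + shift
    length = max(len(a.seq) + shift, b_start + len(b_seq))
    if ov.offset >= 0:
        tail = b_seq[len(a.seq) - ov.offset :] if ov.offset + len(b_seq) > len(a.seq) else ""
        seq = a.seq + tail
    else:
        tail = a.seq[len(b_seq) + ov.offset :] if -ov.offset + len(a.seq) > len(b_seq) else ""
        seq = b_seq + tail
    assert len(seq) == length
    members = [
        ContigMember(m.read_id, m.seq, m.offset + shift, m.orientation) for m in a.members
    ] + [ContigMember(m.read_id, m.seq, m.offset + b_start, m.orientation) for m in b_members]
    return Contig(seq=seq, members=members)


def _best_merge(a: Contig, b: Contig, min_overlap: int) -> tuple[int, str, Contig] | None:
    ov = find_overlap(a.seq, b.seq, min_overlap)
    if ov is None:
        return None
    merged = _merge(a, b, ov)
    return ov.length, merged.seq, merged


def assemble_contigs(cs: CollapsedSet, min_overlap: int = 14) -> list[Contig]:
    """Greedy longest-overlap-first agglomeration over a collapsed set.

    Returns multi-member contigs only; reads that merged with nothing are
    left out (they remain candidates on their own).
    """
    units: dict[int, Contig] = {}
    for i, cr in enumerate(cs.reads):
        rid = cr.id or cr.seq
        units[i] = Contig(seq=cr.seq, members=[ContigMember(rid, cr.seq, 0, "forward")])
    alive = set(units)
    next_uid = len(units)
    heap: list[tuple[int, str, int, int]] = []
    plans: dict[tuple[int, int], Contig] = {}

    def push_pair(i: int, j: int) -> None:
        res = _best_merge(units[i], units[j], min_overlap)
        if res is None:
            return
        length, mseq, merged = res
        plans[(i, j)] = merged
        heapq.heappush(heap, (-length, mseq, i, j))

    for i, j in itertools.combinations(sorted(alive), 2):
        push_pair(i, j)

    while heap:
        neg_len, _, i, j = heapq.heappop(heap)
        if i not in alive or j not in alive:
            plans.pop((i, j), None)
            continue
        merged = plans.pop((i, j))
        alive.discard(i)
        alive.discard(j)
        del units[i], units[j]
        uid = next_uid
        next_uid += 1
        units[uid] = merged
        for k in sorted(alive):
            push_pair(k, uid)
        alive.add(uid)

    contigs = [c for c in units.values() if len(c.members) >= 2]
    contigs.sort(key=lambda c: (-c.length, c.seq))
    return contigs


def filter_long_unidirectional(
    cs: CollapsedSet,
    contigs: list[Contig],
    length_threshold: int | str = "median",
) -> ContigFilterResult:
    """Remove members of contigs longer than the threshold whose reads all
    share one orientation.

    ``length_threshold="median"`` uses the median multi-member contig length;
    the comparison is strict (length > threshold). Singleton reads and
    members of bidirectional or short contigs are retained.
    """
    if contigs:
        median_len = float(statistics.median(c.length for c in contigs))
    else:
        median_len = 0.0
    threshold = median_len if length_threshold == "median" else float(length_threshold)
    flagged = [c for c in contigs if c.length > threshold and c.is_unidirectional()]
    removed = {m.read_id for c in flagged for m in c.members}
    kept = [cr for cr in cs.reads if (cr.id or cr.seq) not in removed]
    retained = CollapsedSet(reads=kept, total_input=sum(cr.count for cr in kept))
    return ContigFilterResult(
        contigs=contigs,
        removed_read_ids=removed,
        retained=retained,
        median_contig_length=median_len,
        flagged_contigs=flagged,
    )
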