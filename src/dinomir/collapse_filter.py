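"""Collapse reads to unique sequences with copy counts; minimum-abundance filter.

Collapsing is strand-literal: the library is directional, so a read and its
reverse complement are distinct species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .sequence_io import CollapsedRead, Read, rank_collapsed


@dataclass
class CollapsedSet:
    reads: list[CollapsedRead] = field(default_factory=list)
    total_input: int = 0

    def __post_init__(self) -> None:
        seqs = [cr.seq for cr in self.reads]
        if len(seqs) != len(set(seqs)):
            raise ValueError("collapsed set contains duplicate sequences")
        if sum(cr.count for cr in self.reads) != self.total_input:
            raise ValueError("sum of counts must equal total_input")

    def __len__(self) -> int:
        return len(self.reads)

    def by_seq(self) -> dict[str, CollapsedRead]:
        return {cr.seq: cr for cr in self.reads}


def collapse(reads: Iterable[Read | str]) -> CollapsedSet:
    """Tally distinct sequences; order by descending count, ties by sequence."""
    counts: Counter[str] = Counter(r.seq if isinstance(r, Read) else r for r in reads)
    collapsed = rank_collapsed(
        CollapsedRead(seq=s, count=c) for s, c in counts.items()
    )
    return CollapsedSet(reads=collapsed, total_input=sum(counts.values()))


def filter_min_count(cs: CollapsedSet, min_copies: int) -> CollapsedSet:
    """Drop collapsed reads present in fewer than ``min_copies`` copies.

    A read with count == min_copies is kept (strictly-fewer removal rule).
    """
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    kept = [cr for cr in cs.reads if cr.count >= min_copies]
    return CollapsedSet(reads=kept, total_input=sum(cr.count for cr in kept))
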