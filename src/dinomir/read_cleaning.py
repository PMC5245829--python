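"""The read-cleaning cascade with per-stage accounting.

Stages run in a fixed order on the raw stranded small-RNA library:

1. adapter trimming (3' adapter; reads reduced to nothing are dropped)
2. rRNA subtraction
3. tRNA subtraction
4. polyA removal (reads with a run of > ``polya_max_run`` consecutive A)
5. size selection (``size_min``..``size_max`` nt inclusive)
6. second rRNA and tRNA cleaning (trimming/selection can expose matches)
7. organelle (mitochondrial/plastid) subtraction

Reference subtraction matches a read as a contiguous substring of any
reference sequence on either strand with at most ``subtraction_max_mismatches``
mismatches and no gaps — adequate for <=26-nt reads and fully deterministic,
in place of a heuristic external aligner. Reads containing N can only match
at mismatch budget > 0 (N pairs with nothing).

The report reproduces the classic cascade accounting table: surviving count
and percent-of-initial (half-up, one decimal) after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Sequence

from .sequence_io import Read, ReferenceSet, revcomp


class ConfigError(ValueError):
    """The cascade configuration is inconsistent or incomplete."""


# TruSeq small-RNA 3' adapter (RA3), the library-prep default.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class CascadeConfig:
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    polya_max_run: int = 6
    size_min: int = 18
    size_max: int = 26
    subtraction_max_mismatches: int = 0
    adapter_min_overlap: int = 3
    rrna: ReferenceSet | None = None
    trna: ReferenceSet | None = None
    organelle: ReferenceSet | None = None
    second_pass: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.size_min <= self.size_max):
            raise ConfigError("require 1 <= size_min <= size_max")
        if self.polya_max_run < 0:
            raise ConfigError("polya_max_run must be >= 0")
        if not self.adapter:
            raise ConfigError("adapter must be non-empty")


@dataclass
class CleaningReport:
    """Ordered (stage, surviving count, percent-of-initial) accounting."""

    initial_count: int
    stages: list[tuple[str, int, float]] = field(default_factory=list)
    removed_ids: dict[str, set[str]] = field(default_factory=dict)

    def add_stage(self, name: str, count: int, removed: set[str] | None = None) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError("stage counts must be non-increasing")
        pct = percent_of_initial(count, self.initial_count) if self.initial_count > 0 else 0.0
        self.stages.append((name, count, pct))
        if removed is not None:
            self.removed_ids[name] = removed

    def count_after(self, stage: str) -> int:
        for name, count, _ in self.stages:
            if name == stage:
                return count
        raise KeyError(stage)


def percent_of_initial(count: int, initial: int) -> float:
    """Percent of the initial library, rounded half-up to one decimal."""
    if initial <= 0:
        raise ValueError("initial count must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    pct = Decimal(100 * count) / Decimal(initial)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def trim_adapter(read: Read, adapter: str, min_overlap: int = 3) -> Read | None:
    """Remove the 3' adapter; return the 5' remainder or None if nothing is left.

    The full adapter is searched as an internal substring (leftmost
    occurrence wins); failing that, the longest adapter prefix of length
    >= ``min_overlap`` anchored at the read's 3' end is trimmed. A read
    without any adapter match is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = read.seq.find(adapter)
    if pos == -1:
        for k in range(min(len(adapter) - 1, len(read.seq)), min_overlap - 1, -1):
            if read.seq.endswith(adapter[:k]):
                pos = len(read.seq) - k
                break
    if pos == -1:
        return read
    if pos == 0:
        return None
    qual = read.qual[:pos] if read.qual is not None else None
    return Read(id=read.id, seq=read.seq[:pos], qual=qual)


def has_polya(seq: str, max_run: int) -> bool:
    """True iff the sequence contains a run of A strictly longer than max_run."""
    if max_run < 0:
        raise ValueError("max_run must be >= 0")
    return "A" * (max_run + 1) in seq


def _matches_with_mismatches(read: str, ref: str, max_mm: int) -> bool:
    n, m = len(read), len(ref)
    if n > m:
        return False
    for start in range(m - n + 1):
        mm = 0
        window = ref[start : start + n]
        for a, b in zip(read, window):
            if a != b or a == "N":
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def matches_reference(seq: str, ref: ReferenceSet, max_mismatches: int = 0) -> bool:
    """True iff seq occurs in any reference entry, either strand, as a
    contiguous substring with <= max_mismatches mismatches (no gaps)."""
    rc = revcomp(seq)
    for _, ref_seq in ref.records:
        if max_mismatches == 0:
            if ("N" not in seq and seq in ref_seq) or ("N" not in rc and rc in ref_seq):
                return True
            if "N" in seq and (
                _matches_with_mismatches(seq, ref_seq, 0)
                or _matches_with_mismatches(rc, ref_seq, 0)
            ):
                return True
        else:
            if _matches_with_mismatches(seq, ref_seq, max_mismatches) or _matches_with_mismatches(
                rc, ref_seq, max_mismatches
            ):
                return True
    return False


def subtract_reference(
    reads: Iterable[Read], ref: ReferenceSet, max_mismatches: int = 0
) -> tuple[list[Read], int]:
    """Split reads into (survivors, removed count) by reference matching.

    Order of survivors is preserved.
    """
    if not ref.records:
        raise ConfigError(f"reference set {ref.name!r} is empty")
    survivors: list[Read] = []
    removed = 0
    # memoize per distinct sequence: libraries are highly redundant
    cache: dict[str, bool] = {}
    for read in reads:
        hit = cache.get(read.seq)
        if hit is None:
            hit = matches_reference(read.seq, ref, max_mismatches)
            cache[read.seq] = hit
        if hit:
            removed += 1
        else:
            survivors.append(read)
    return survivors, removed


def size_select(reads: Iterable[Read], size_min: int, size_max: int) -> list[Read]:
    """Retain reads with size_min <= length <= size_max (inclusive)."""
    return [r for r in reads if size_min <= len(r.seq) <= size_max]


def run_cascade(
    reads: Iterable[Read], config: CascadeConfig, track_removed: bool = False
) -> tuple[list[Read], CleaningReport]:
    """Execute the full cascade and return (survivors, report).

    Stage order and the report rows mirror the cascade accounting table;
    subtraction stages are skipped (and absent from the report) when their
    reference set is not configured.
    """
    current = list(reads)
    report = CleaningReport(initial_count=len(current))
    report.add_stage("High quality reads", len(current), set() if track_removed else None)

    def ids(rs: Sequence[Read]) -> set[str]:
        return {r.id for r in rs}

    def record(name: str, before: Sequence[Read], after: Sequence[Read]) -> None:
        removed = (ids(before) - ids(after)) if track_removed else None
        report.add_stage(name, len(after), removed)

    before = current
    trimmed = [t for t in (trim_adapter(r, config.adapter, config.adapter_min_overlap) for r in current) if t is not None]
    # trimming changes sequences but keeps ids; removal here = empty remainder
    record("Adapter trimming", before, trimmed)
    current = trimmed

    if config.rrna is not None:
        survivors, _ = subtract_reference(current, config.rrna, config.subtraction_max_mismatches)
        record("rRNA removal", current, survivors)
        current = survivors
    if config.trna is not None:
        survivors, _ = subtract_reference(current, config.trna, config.subtraction_max_mismatches)
        record("tRNA removal", current, survivors)
        current = survivors

    survivors = [r for r in current if not has_polya(r.seq, config.polya_max_run)]
    record(f"polyA removal (>{config.polya_max_run} bases)", current, survivors)
    current = survivors

    survivors = size_select(current, config.size_min, config.size_max)
    record(f"Size selection ({config.size_min}–{config.size_max} nt)", current, survivors)
    current = survivors

    if config.second_pass and (config.rrna is not None or config.trna is not None):
        survivors = current
        if config.rrna is not None:
            survivors, _ = subtract_reference(survivors, config.rrna, config.subtraction_max_mismatches)
        if config.trna is not None:
            survivors, _ = subtract_reference(survivors, config.trna, config.subtraction_max_mismatches)
        record("Second rRNA and tRNA cleaning", current, survivors)
        current = survivors

    if config.organelle is not None:
        survivors, _ = subtract_reference(current, config.organelle, config.subtraction_max_mismatches)
        record("Organelle RNA cleaning", current, survivors)
        current = survivors

    return current, report
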