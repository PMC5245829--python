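"""Strand-aware profiling of small RNAs on reference transcripts.

Reads from a directional library are mapped to each transcript on both
strands: a sense mapping is an exact (or <= ``max_mismatches``) contiguous
match of the read to the transcript, an antisense mapping is a match of the
read's reverse complement. Per-transcript profiles accumulate count-weighted
totals, strand-specific coverage, duplex partners between antisense and
sense reads, and a qualitative mapping-pattern class:

* ``A`` — every read in the same direction (pure mRNA-fragment signature);
* ``B`` — very few antisense reads;
* ``C`` — numerous antisense reads (fraction above ``many_threshold``,
  default 20%).

A position-frequency matrix (PFM) with a majority consensus summarizes a set
of near-identical small RNAs, anchored gaplessly on their longest common
substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .collapse_filter import CollapsedSet
from .duplex_search import DuplexAlignment, DuplexPair, pair_duplex
from .sequence_io import CollapsedRead, revcomp

Strand = Literal["sense", "antisense"]
BASES = "ACGT"


@dataclass(frozen=True)
class ReadMapping:
    read_id: str
    seq: str  # the read as sequenced
    count: int
    transcript_id: str
    start: int  # 0-based on the transcript
    strand: Strand
    mismatches: int = 0


@dataclass
class TranscriptProfile:
    transcript_id: str
    length: int
    total_reads: int = 0
    antisense_reads: int = 0
    sense_coverage: np.ndarray | None = None
    antisense_coverage: np.ndarray | None = None
    mappings: list[ReadMapping] = field(default_factory=list)
    duplex_partner_pairs: list[tuple[ReadMapping, ReadMapping, DuplexAlignment]] = field(
        default_factory=list
    )
    utr3_antisense: int | None = None

    @property
    def sense_reads(self) -> int:
        return self.total_reads - self.antisense_reads

    @property
    def antisense_fraction(self) -> float:
        if self.total_reads == 0:
            raise ValueError("profile has no mapped reads")
        return self.antisense_reads / self.total_reads


def _occurrences(query: str, target: str, max_mm: int) -> Iterable[tuple[int, int]]:
    n, m = len(query), len(target)
    if n > m:
        return
    if max_mm == 0:
        pos = target.find(query)
        while pos != -1:
            yield pos, 0
            pos = target.find(query, pos + 1)
        return
    for start in range(m - n + 1):
        mm = 0
        for a, b in zip(query, target[start : start + n]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            yield start, mm


def map_reads(
    reads: CollapsedSet | Iterable[CollapsedRead],
    transcript: tuple[str, str],
    max_mismatches: int = 0,
) -> list[ReadMapping]:
    """All sense and antisense occurrences of each read on one transcript.

    Multi-occurrence reads yield one mapping per occurrence.
    """
    tid, tseq = transcript
    if not tseq:
        raise ValueError(f"transcript {tid!r} is empty")
    items = reads.reads if isinstance(reads, CollapsedSet) else list(reads)
    mappings: list[ReadMapping] = []
    for cr in items:
        rid = cr.id or cr.seq
        for start, mm in _occurrences(cr.seq, tseq, max_mismatches):
            mappings.append(ReadMapping(rid, cr.seq, cr.count, tid, start, "sense", mm))
        rc = revcomp(cr.seq)
        for start, mm in _occurrences(rc, tseq, max_mismatches):
            mappings.append(ReadMapping(rid, cr.seq, cr.count, tid, start, "antisense", mm))
    mappings.sort(key=lambda m: (m.start, m.strand, m.seq))
    return mappings


def profile_transcript(
    mappings: Sequence[ReadMapping],
    transcript: tuple[str, str],
    utr3_start: int | None = None,
    weighted: bool = True,
) -> TranscriptProfile:
    """Accumulate strand-aware totals and coverage for one transcript.

    Totals weight each collapsed read by its copy count (``weighted=False``
    counts unique mapped species instead). ``utr3_start`` (0-based) enables
    counting antisense mappings that start in the 3' UTR.
    """
    tid, tseq = transcript
    if utr3_start is not None and not (0 <= utr3_start <= len(tseq)):
        raise ValueError(f"utr3_start {utr3_start} outside transcript of length {len(tseq)}")
    prof = TranscriptProfile(transcript_id=tid, length=len(tseq))
    prof.sense_coverage = np.zeros(len(tseq), dtype=np.int64)
    prof.antisense_coverage = np.zeros(len(tseq), dtype=np.int64)
    utr3 = 0
    for m in mappings:
        if m.transcript_id != tid:
            raise ValueError(f"mapping for {m.transcript_id!r} given to profile of {tid!r}")
        w = m.count if weighted else 1
        prof.total_reads += w
        span = slice(m.start, m.start + len(m.seq))
        if m.strand == "antisense":
            prof.antisense_reads += w
            prof.antisense_coverage[span] += w
            if utr3_start is not None and m.start >= utr3_start:
                utr3 += w
        else:
            prof.sense_coverage[span] += w
    prof.mappings = list(mappings)
    prof.utr3_antisense = utr3 if utr3_start is not None else None
    return prof


def find_sense_partners(
    profile: TranscriptProfile,
    max_mismatches: int = 3,
    max_bulges: int = 1,
    overhang: int = 2,
) -> list[tuple[ReadMapping, ReadMapping, DuplexAlignment]]:
    """Duplex partners between antisense- and sense-mapped reads.

    Each antisense read is tested against every sense read with the duplex
    geometry test; all valid (sense, antisense, alignment) triples are
    returned and recorded on the profile.
    """
    sense = [m for m in profile.mappings if m.strand == "sense"]
    antisense = [m for m in profile.mappings if m.strand == "antisense"]
    pairs: list[tuple[ReadMapping, ReadMapping, DuplexAlignment]] = []
    tested: set[tuple[str, str]] = set()
    for am in antisense:
        for sm in sense:
            key = (sm.seq, am.seq)
            if key in tested:
                continue
            tested.add(key)
            aln = pair_duplex(sm.seq, am.seq, max_mismatches, max_bulges, overhang)
            if aln is not None:
                pairs.append((sm, am, aln))
    profile.duplex_partner_pairs = pairs
    return pairs


def classify_pattern(
    profile: TranscriptProfile,
    few_threshold: float = 0.05,
    many_threshold: float = 0.20,
) -> str:
    """Classify the read-mapping pattern of a transcript.

    ``A``: zero antisense reads; ``C``: antisense fraction strictly above
    ``many_threshold``; ``B``: anything in between. ``few_threshold`` only
    annotates how small a "very few" class B is expected to be; it does not
    move the A/B or B/C boundaries.
    """
    frac = profile.antisense_fraction  # raises on empty profile
    if profile.antisense_reads == 0:
        return "A"
    if frac > many_threshold:
        return "C"
    return "B"


@dataclass
class PositionFrequencyMatrix:
    length: int
    counts: np.ndarray  # 4 x L, rows A,C,G,T
    n_sequences: int
    consensus: str
    identities: list[bool]  # columns where one base has frequency 1.0

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _longest_common_substring(seqs: Sequence[str]) -> str:
    base = min(seqs, key=len)
    for k in range(len(base), 0, -1):
        for i in range(len(base) - k + 1):
            sub = base[i : i + k]
            if all(sub in s for s in seqs):
                return sub
    return ""


def build_pfm(sequences: Sequence[str]) -> PositionFrequencyMatrix:
    """Gapless PFM of near-identical sequences anchored on their longest
    common substring; consensus is the per-column majority base, ties broken
    alphabetically. Ragged ends make column sums <= n_sequences."""
    if not sequences:
        raise ValueError("need at least one sequence")
    core = _longest_common_substring(sequences)
    if core:
        offsets = [s.index(core) for s in sequences]
    else:
        offsets = [0] * len(sequences)
    lead = max(offsets)
    length = max(lead - off + len(s) for s, off in zip(sequences, offsets))
    counts = np.zeros((4, length), dtype=np.int64)
    idx = {b: i for i, b in enumerate(BASES)}
    for s, off in zip(sequences, offsets):
        start = lead - off
        for j, base in enumerate(s):
            if base in idx:
                counts[idx[base], start + j] += 1
    cons = []
    identities = []
    n = len(sequences)
    for col in range(length):
        col_counts = counts[:, col]
        best = int(np.argmax(col_counts))  # argmax takes the first max: alphabetical
        cons.append(BASES[best])
        identities.append(int(col_counts[best]) == n)
    return PositionFrequencyMatrix(
        length=length,
        counts=counts,
        n_sequences=n,
        consensus="".join(cons),
        identities=identities,
    )
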