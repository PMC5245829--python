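"""Dicer-geometry duplex detection among candidate small RNAs.

A Dicer product is an antiparallel duplex whose two strands each carry a
2-nt single-stranded 3' overhang. Writing ``pairA = a[:-2]`` and
``pairB = b[:-2]`` (the pairing regions, after setting the overhangs aside),
the two strands form a duplex when ``pairA`` aligns globally against
``revcomp(pairB)`` with at most ``max_mismatches`` mismatched positions and
at most ``max_bulges`` single-base gaps. A gap models one unpaired (bulged)
base on the longer strand, never at the ends of the pairing region — a
terminal gap would change the overhang length. Only Watson–Crick pairs count
(A:T, G:C); G:T wobble and anything involving N score as mismatches. The
overhang bases themselves are unpaired by definition and unconstrained in
sequence.

Geometry forces the two strands to differ in length by at most
``max_bulges`` bases, so the all-pairs search only compares length classes
L-1, L, L+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal

from .collapse_filter import CollapsedSet
from .sequence_io import ALPHABET, CollapsedRead, revcomp

OVERHANG = 2  # nt, at both 3' ends


@dataclass(frozen=True)
class DuplexAlignment:
    mismatches: int
    bulges: tuple[tuple[Literal["A", "B"], int], ...] = ()
    overhang_a: int = OVERHANG
    overhang_b: int = OVERHANG

    @property
    def n_bulges(self) -> int:
        return len(self.bulges)


@dataclass(frozen=True)
class DuplexPair:
    read_a: CollapsedRead
    read_b: CollapsedRead
    alignment: DuplexAlignment

    @property
    def abundance_ratio(self) -> Fraction:
        return Fraction(self.read_a.count, self.read_b.count)


def _check_alphabet(seq: str) -> None:
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        raise ValueError(f"non-alphabet characters: {bad}")


def _hamming(x: str, y: str) -> int:
    # N never pairs: positions equal to N count as mismatches even vs N
    return sum(1 for a, b in zip(x, y) if a != b or a == "N")


def pair_duplex(
    a: str,
    b: str,
    max_mismatches: int = 3,
    max_bulges: int = 1,
    overhang: int = OVERHANG,
) -> DuplexAlignment | None:
    """Test whether two small RNAs form a duplex with 2-nt 3' overhangs.

    Returns the minimum-mismatch :class:`DuplexAlignment` (ties broken by the
    leftmost bulge position), or None if no alignment satisfies the mismatch
    and bulge budgets or the pairing-region lengths differ by more than
    ``max_bulges``.
    """
    _check_alphabet(a)
    _check_alphabet(b)
    pair_a = a[:-overhang] if overhang else a
    pair_b = b[:-overhang] if overhang else b
    if len(a) <= overhang or len(b) <= overhang:
        return None
    if abs(len(pair_a) - len(pair_b)) > max_bulges:
        return None
    x = pair_a
    y = revcomp(pair_b)  # complementarity becomes identity

    if len(x) == len(y):
        # one gap on each strand would be two bulges; ungapped only
        mm = _hamming(x, y)
        if mm <= max_mismatches:
            return DuplexAlignment(mismatches=mm)
        return None

    # one strand has a single bulged base: delete one internal base of the
    # longer string and compare; alignment columns 0 and L-1 are off-limits
    if len(x) > len(y):
        longer, shorter, bulge_strand = x, y, "A"
    else:
        longer, shorter, bulge_strand = y, x, "B"
    best: tuple[int, int] | None = None  # (mismatches, deletion index)
    for p in range(1, len(longer) - 1):
        mm = _hamming(longer[:p], shorter[:p]) + _hamming(longer[p + 1 :], shorter[p:])
        if mm <= max_mismatches and (best is None or mm < best[0]):
            best = (mm, p)
            if mm == 0:
                break
    if best is None:
        return None
    mm, p = best
    if bulge_strand == "A":
        pos = p  # index in pairA's own 5'->3' coordinates
    else:
        pos = len(pair_b) - 1 - p  # y is revcomp(pairB); map back to pairB
    return DuplexAlignment(mismatches=mm, bulges=((bulge_strand, pos),))


def find_duplexes(
    candidates: CollapsedSet,
    max_mismatches: int = 3,
    max_bulges: int = 1,
    overhang: int = OVERHANG,
) -> list[DuplexPair]:
    """Enumerate all duplex-forming pairs in a candidate set.

    Candidates are partitioned by length; each sequence is tested against
    candidates of lengths L-1, L and L+1 (the only geometrically possible
    partners). Every unordered pair is emitted once; a sequence may pair
    with itself if its own geometry allows it.
    """
    by_len: dict[int, list[CollapsedRead]] = {}
    for cr in candidates.reads:
        by_len.setdefault(len(cr.seq), []).append(cr)
    for lst in by_len.values():
        lst.sort(key=lambda cr: cr.seq)

    pairs: list[DuplexPair] = []
    seen: set[tuple[str, str]] = set()
    for length in sorted(by_len):
        for delta in (0, 1):  # delta -1 already covered from the shorter class
            partner_len = length + delta
            if partner_len not in by_len:
                continue
            group_a = by_len[length]
            group_b = by_len[partner_len]
            for ia, cra in enumerate(group_a):
                start = ia if delta == 0 else 0
                for crb in group_b[start:]:
                    key = tuple(sorted((cra.seq, crb.seq)))
                    if key in seen:
                        continue
                    aln = pair_duplex(cra.seq, crb.seq, max_mismatches, max_bulges, overhang)
                    if aln is not None:
                        seen.add(key)
                        pairs.append(DuplexPair(read_a=cra, read_b=crb, alignment=aln))
    pairs.sort(key=lambda p: (p.read_a.seq, p.read_b.seq))
    return pairs


def candidate_mirnas(pairs: Iterable[DuplexPair]) -> tuple[set[str], dict[int, int]]:
    """Unique duplex-participating sequences and their length histogram."""
    uniq: set[str] = set()
    for p in pairs:
        uniq.add(p.read_a.seq)
        uniq.add(p.read_b.seq)
    hist: dict[int, int] = {}
    for s in uniq:
        hist[len(s)] = hist.get(len(s), 0) + 1
    return uniq, hist


@dataclass(frozen=True)
class AbundanceCall:
    ratio: float
    guide: CollapsedRead
    star: CollapsedRead
    tie: bool


def abundance_asymmetry(pair: DuplexPair) -> AbundanceCall:
    """Guide/star abundance ratio; the more abundant strand is the putative
    guide (miRNA), the other the passenger (miRNA*). Equal counts are a tie
    (guide assignment arbitrary, flagged)."""
    a, b = pair.read_a, pair.read_b
    if a.count >= b.count:
        guide, star = a, b
    else:
        guide, star = b, a
    return AbundanceCall(
        ratio=guide.count / star.count, guide=guide, star=star, tie=a.count == b.count
    )
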