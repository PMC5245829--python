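"""Independent brute-force oracles for cross-checking the implementation.

These enumerate explicitly (every gap placement, every relative shift) in
complementarity space, deliberately sharing no code with the package.
"""

from __future__ import annotations

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def _mismatches(x: str, y: str) -> int:
    """Mismatches of two explicit alignment rows (may contain '-')."""
    mm = 0
    for p, q in zip(x, y):
        if p == "-" or q == "-":
            continue  # the bulged base is unpaired, not a mismatch
        if (p, q) not in WC:
            mm += 1
    return mm


def oracle_pair(a: str, b: str, max_mm: int = 3, max_bulges: int = 1,
                overhang: int = 2) -> int | None:
    """Minimum mismatch count over every admissible duplex alignment, or None.

    Pairing regions are compared antiparallel base-to-base (a 5'->3' vs b
    3'->5') using Watson-Crick lookup; one '-' may be inserted at any
    internal column of the shorter region.
    """
    if len(a) <= overhang or len(b) <= overhang:
        return None
    pa = a[:-overhang] if overhang else a
    pb_rev = (b[:-overhang] if overhang else b)[::-1]
    diff = len(pa) - len(pb_rev)
    if abs(diff) > max_bulges:
        return None
    alignments: list[tuple[str, str]] = []
    if diff == 0:
        alignments.append((pa, pb_rev))
    else:
        if diff > 0:
            shorter, side = pb_rev, "b"
        else:
            shorter, side = pa, "a"
        L = max(len(pa), len(pb_rev))
        for gap_col in range(1, L - 1):
            g = shorter[:gap_col] + "-" + shorter[gap_col:]
            alignments.append((pa, g) if side == "b" else (g, pb_rev))
    best: int | None = None
    for x, y in alignments:
        mm = _mismatches(x, y)
        if mm <= max_mm and (best is None or mm < best):
            best = mm
    return best


def oracle_all_pairs(seqs_with_counts, max_mm: int = 3, max_bulges: int = 1,
                     overhang: int = 2) -> dict[tuple[str, str], int]:
    """Exhaustive O(n^2) duplex enumeration over (seq, count) items."""
    seqs = sorted({s for s, _ in seqs_with_counts})
    out: dict[tuple[str, str], int] = {}
    for i, a in enumerate(seqs):
        for b in seqs[i:]:
            mm = oracle_pair(a, b, max_mm, max_bulges, overhang)
            if mm is not None:
                out[(a, b)] = mm
    return out


def oracle_best_overlap(a: str, b: str, min_overlap: int) -> int | None:
    """Longest exact merge overlap between a and b over every shift and both
    orientations of b; None if below min_overlap."""
    best = None
    for b_or in (b, rc(b)):
        for d in range(-(len(b_or) - 1), len(a)):
            lo, hi = max(0, d), min(len(a), d + len(b_or))
            if hi - lo < min_overlap:
                continue
            if a[lo:hi] == b_or[lo - d : hi - d]:
                if best is None or hi - lo > best:
                    best = hi - lo
    return best
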