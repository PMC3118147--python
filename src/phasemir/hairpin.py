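"""Stem-loop precursor representation: arms, terminal loop, miR* location.

A :class:`Hairpin` couples a precursor sequence with a secondary structure
and the span of the terminal loop of the main stem.  The main stem is the
maximal nested path carrying the most paired positions; side branches of a
multiloop therefore sit entirely on one arm.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .sequences import RnaSequence
from .structure import SecondaryStructure, fold, parse_dotbracket

Interval = tuple[int, int]


class Arm(Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    SPANS_LOOP = "spans_loop"


def _main_stem_loop(struct: SecondaryStructure) -> Interval:
    """Terminal-loop span of the main stem (the heaviest nested pair path)."""
    if not struct.pairs:
        raise ValueError("structure has no pairs; not a hairpin")
    ordered = sorted(struct.pairs)

    def children_of(lo: int, hi: int) -> list[Interval]:
        out = []
        last_end = lo - 1
        for i, j in ordered:
            if i > last_end and lo <= i and j <= hi:
                out.append((i, j))
                last_end = j
        return out

    def weight(i: int, j: int) -> int:
        return sum(1 for a, b in ordered if i <= a and b <= j)

    lo, hi = -1, struct.length
    while True:
        kids = [
            (i, j)
            for (i, j) in ordered
            if lo < i and j < hi
            and not any(a < i and j < b and lo < a and b < hi for a, b in ordered)
        ]
        if not kids:
            return (lo + 1, hi)
        best = max(kids, key=lambda p: (weight(*p), -p[0]))
        lo, hi = best


@dataclass(frozen=True)
class Hairpin:
    seq: RnaSequence
    struct: SecondaryStructure
    loop_span: Interval

    def __post_init__(self):
        if len(self.seq) != self.struct.length:
            raise ValueError("sequence / structure length mismatch")
        lo, hi = self.loop_span
        if not (0 <= lo <= hi <= len(self.seq)):
            raise ValueError("loop_span out of bounds")

    @classmethod
    def from_structure(cls, seq: RnaSequence, struct: SecondaryStructure) -> "Hairpin":
        return cls(seq, struct, _main_stem_loop(struct))

    @classmethod
    def from_dotbracket(cls, seq: RnaSequence, db: str) -> "Hairpin":
        return cls.from_structure(seq, parse_dotbracket(db))

    @classmethod
    def by_folding(cls, seq: RnaSequence) -> "Hairpin":
        return cls.from_structure(seq, fold(seq))


def arm_of(h: Hairpin, interval: Interval) -> Arm:
    """Classify an interval as 5'-arm, 3'-arm, or loop-spanning."""
    start, end = interval
    if not (0 <= start < end <= len(h.seq)):
        raise ValueError(f"interval {interval} out of bounds")
    loop_lo, loop_hi = h.loop_span
    if end <= loop_lo:
        return Arm.FIVE_PRIME
    if start >= loop_hi:
        return Arm.THREE_PRIME
    return Arm.SPANS_LOOP


def locate_star(h: Hairpin, mir: Interval) -> Interval:
    """Locate miR*: the antisense stem segment corresponding to miR.

    The base interval is the minimal span containing all partners of paired
    miR positions, widened by the count of unpaired residues at each miR end
    (mirroring terminal bulges onto the star side), then shifted by +2 in
    the 3' genomic direction: the standard 2-nt 3'-overhang geometry of a
    Dicer duplex, applied symmetrically at both duplex ends.
    """
    m0, m1 = mir
    if arm_of(h, mir) is Arm.SPANS_LOOP:
        raise ValueError("miR interval overlaps the terminal loop")
    partner = h.struct.partner
    paired = [i for i in range(m0, m1) if i in partner]
    if not paired:
        raise ValueError("miR entirely unpaired")
    u5 = paired[0] - m0          # unpaired residues at miR 5' end
    u3 = (m1 - 1) - paired[-1]   # unpaired residues at miR 3' end
    partners = [partner[i] for i in paired]
    lo, hi = min(partners), max(partners) + 1
    # miR 5' end faces the star's high (3') end on either arm
    hi += u5
    lo -= u3
    lo += 2
    hi += 2
    return (max(lo, 0), min(hi, len(h.seq)))
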