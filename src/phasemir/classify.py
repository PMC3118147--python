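"""Five-type precursor classification and the nine-partition scheme.

Type-1 stem-loops of the MIR159/319 lineage carry a "bi-duplex" conservation
pattern: the miR:miR* duplex near the base and a second conserved duplex —
the Alternative Conserved Regions ACR5:ACR3 — near the terminal loop.  The
classification keys on D, the loop-spanning distance between miR and miR*
(short precursors, D <= 60, lack the elongated stem entirely), and on whether
the loop-proximal regions retain sequence and/or structural conservation:

    D > 60, seq yes, str yes  -> type 1
    D <= 60                   -> type 2
    D > 60, seq yes, str no   -> type 3
    D > 60, seq no,  str yes  -> type 4
    D > 60, seq no,  str no   -> type 5

Type-1 precursors are tiled by nine named partitions, 5'->3' for a miR on
the 3' arm: sp1, miR*, sp2, ACR5, sp3 (spanning the loop), ACR3, sp4, miR,
sp5; mirrored when the miR sits on the 5' arm.
"""
from __future__ import annotations

from dataclasses import dataclass

from .hairpin import Arm, Hairpin, Interval, arm_of, locate_star
from .scan import loop_gap

D_THRESHOLD = 60

PARTITION_NAMES_3P = ("sp1", "miR*", "sp2", "ACR5", "sp3", "ACR3", "sp4", "miR", "sp5")
PARTITION_NAMES_5P = ("sp1", "miR", "sp2", "ACR3", "sp3", "ACR5", "sp4", "miR*", "sp5")
CONSERVED_PARTITIONS = ("miR", "miR*", "ACR5", "ACR3")


@dataclass(frozen=True)
class AcrConsensus:
    """Consensus residues of the two ACRs plus the detection thresholds.

    ``identity`` is the minimum fraction of matching residues for sequence
    conservation; ``pairing`` the minimum fraction of ACR5 positions paired
    into the ACR3 window (and vice versa) for structural conservation.
    """

    acr5: str
    acr3: str
    identity: float = 0.6
    pairing: float = 0.6
    length_slack: int = 2

    def __post_init__(self):
        for v in (self.identity, self.pairing):
            if not 0 < v <= 1:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class TypeRecord:
    precursor_id: str
    D: int
    seq_conserved: bool
    str_conserved: bool
    type_label: int


@dataclass(frozen=True)
class PartitionScheme:
    """Nine ordered, disjoint intervals tiling the precursor exactly."""

    precursor_id: str
    intervals: dict[str, Interval]
    mir_on_five_prime: bool

    def __post_init__(self):
        order = PARTITION_NAMES_5P if self.mir_on_five_prime else PARTITION_NAMES_3P
        prev_end = 0
        for name in order:
            s, e = self.intervals[name]
            if s != prev_end or e < s:
                raise ValueError(f"partitions do not tile: gap/overlap at {name}")
            prev_end = e
        for name in CONSERVED_PARTITIONS:
            s, e = self.intervals[name]
            if not 18 <= e - s <= 26:
                raise ValueError(f"conserved partition {name} length {e - s} outside [18, 26]")

    @property
    def order(self) -> tuple[str, ...]:
        return PARTITION_NAMES_5P if self.mir_on_five_prime else PARTITION_NAMES_3P

    @property
    def length(self) -> int:
        return self.intervals[self.order[-1]][1]

    def to_bed_rows(self) -> list[tuple[str, int, int, str]]:
        return [(self.precursor_id, *self.intervals[n], n) for n in self.order]


def compute_D(h: Hairpin, mir: Interval) -> int:
    """Loop-spanning distance: nucleotides strictly between the loop-proximal
    ends of miR and miR*."""
    star = locate_star(h, mir)
    return loop_gap(h, mir, star)


def _identity(window: str, consensus: str) -> float:
    matches = sum(1 for a, b in zip(window, consensus) if a == b)
    return matches / max(len(window), len(consensus))


def _best_window(region: str, offset: int, consensus: str, slack: int) -> tuple[Interval, float]:
    """Best ungapped window of length len(consensus) +- slack within region."""
    best: tuple[Interval, float] = ((offset, offset + len(consensus)), -1.0)
    for wl in range(len(consensus) - slack, len(consensus) + slack + 1):
        if wl <= 0:
            continue
        for s in range(0, len(region) - wl + 1):
            ident = _identity(region[s:s + wl], consensus)
            if ident > best[1]:
                best = ((offset + s, offset + s + wl), ident)
    return best


def detect_acr(
    h: Hairpin, mir: Interval, cons: AcrConsensus
) -> tuple[bool, bool, Interval | None, Interval | None]:
    """Assess sequence and structural conservation of the loop-proximal ACRs.

    Sequence conservation: both arms carry a window with identity >= the
    threshold against the respective consensus (best ungapped window with
    +-length_slack nt slack).  Structural conservation: the candidate ACR
    windows pair with each other at >= the pairing threshold, and the stem
    connecting the ACR duplex to the miR duplex contains no multiloop (no
    intervening position pairs outside the connecting span).  When sequence
    identity is too weak to place the ACRs, loop-abutting windows of the
    consensus length are used as structural candidates.
    """
    star = locate_star(h, mir)
    D = loop_gap(h, mir, star)
    if D <= D_THRESHOLD:
        raise ValueError(
            f"D = {D} <= {D_THRESHOLD}: no elongated loop-proximal region (type 2)"
        )
    loop_lo, loop_hi = h.loop_span
    mir_arm = arm_of(h, mir)
    # ACR3 sits on the miR arm, ACR5 on the miR* arm, both loop-proximal
    if mir_arm is Arm.THREE_PRIME:
        region_acr5 = (star[1], loop_lo)   # 5' arm, between miR* and loop
        region_acr3 = (loop_hi, mir[0])    # 3' arm, between loop and miR
    else:
        region_acr3 = (mir[1], loop_lo)    # 5' arm, between miR and loop
        region_acr5 = (loop_hi, star[0])   # 3' arm, between loop and miR*

    s5 = h.seq.residues[region_acr5[0]:region_acr5[1]]
    s3 = h.seq.residues[region_acr3[0]:region_acr3[1]]
    acr5_iv, id5 = _best_window(s5, region_acr5[0], cons.acr5, cons.length_slack)
    acr3_iv, id3 = _best_window(s3, region_acr3[0], cons.acr3, cons.length_slack)
    seq_conserved = id5 >= cons.identity and id3 >= cons.identity

    if seq_conserved:
        cand5, cand3 = acr5_iv, acr3_iv
    else:
        # structural candidates: windows abutting the terminal loop
        def _loop_abutting(region: Interval, width: int, before_loop: bool) -> Interval:
            w = min(width, region[1] - region[0])
            return (region[1] - w, region[1]) if before_loop else (region[0], region[0] + w)

        if mir_arm is Arm.THREE_PRIME:
            cand5 = _loop_abutting(region_acr5, len(cons.acr5), True)
            cand3 = _loop_abutting(region_acr3, len(cons.acr3), False)
        else:
            cand3 = _loop_abutting(region_acr3, len(cons.acr3), True)
            cand5 = _loop_abutting(region_acr5, len(cons.acr5), False)

    partner = h.struct.partner
    in5 = set(range(*cand5))
    in3 = set(range(*cand3))
    frac5 = sum(1 for i in in5 if partner.get(i) in in3) / max(len(in5), 1)
    frac3 = sum(1 for j in in3 if partner.get(j) in in5) / max(len(in3), 1)

    # connecting stem between the ACR duplex and the miR duplex: intervening
    # positions must not pair outside the combined gap span (no multiloop)
    arm5_cand, arm3_cand = (cand5, cand3) if mir_arm is Arm.THREE_PRIME else (cand3, cand5)
    arm5_base = star[1] if mir_arm is Arm.THREE_PRIME else mir[1]
    arm3_base = mir[0] if mir_arm is Arm.THREE_PRIME else star[0]
    connecting = set(range(arm5_base, arm5_cand[0])) | set(range(arm3_cand[1], arm3_base))
    no_multiloop = all(partner[i] in connecting for i in connecting if i in partner)
    str_conserved = min(frac5, frac3) >= cons.pairing and no_multiloop

    out5 = cand5 if (seq_conserved or str_conserved) else None
    out3 = cand3 if (seq_conserved or str_conserved) else None
    return (seq_conserved, str_conserved, out5, out3)


def classify(h: Hairpin, mir: Interval, cons: AcrConsensus) -> TypeRecord:
    """Apply the five-type decision table."""
    star = locate_star(h, mir)
    D = loop_gap(h, mir, star)
    if D <= D_THRESHOLD:
        return TypeRecord(h.seq.id, D, False, False, 2)
    seq_c, str_c, _, _ = detect_acr(h, mir, cons)
    label = {(True, True): 1, (True, False): 3, (False, True): 4, (False, False): 5}[
        (seq_c, str_c)
    ]
    return TypeRecord(h.seq.id, D, seq_c, str_c, label)


def classify_from_flags(precursor_id: str, D: int, seq_conserved: bool, str_conserved: bool) -> TypeRecord:
    """Decision table on precomputed (D, seq, str) flags."""
    if D <= D_THRESHOLD:
        return TypeRecord(precursor_id, D, seq_conserved, str_conserved, 2)
    label = {(True, True): 1, (True, False): 3, (False, True): 4, (False, False): 5}[
        (seq_conserved, str_conserved)
    ]
    return TypeRecord(precursor_id, D, seq_conserved, str_conserved, label)


def build_partitions(
    h: Hairpin, mir: Interval, acr5: Interval, acr3: Interval
) -> PartitionScheme:
    """Tile a type-1 precursor with the nine named partitions.

    The conserved partitions are the located miR, miR*, ACR5 and ACR3
    intervals; sp1..sp5 fill the gaps in 5'->3' order (sp3 spans the terminal
    loop).  Zero-length space partitions are permitted.
    """
    star = locate_star(h, mir)
    mir_on_5p = arm_of(h, mir) is Arm.FIVE_PRIME
    if mir_on_5p:
        conserved = [("miR", mir), ("ACR3", acr3), ("ACR5", acr5), ("miR*", star)]
    else:
        conserved = [("miR*", star), ("ACR5", acr5), ("ACR3", acr3), ("miR", mir)]
    ordered = sorted(conserved, key=lambda kv: kv[1][0])
    if [n for n, _ in ordered] != [n for n, _ in conserved]:
        raise ValueError("conserved intervals out of expected arm order")
    for (_, a), (_, b) in zip(ordered, ordered[1:]):
        if a[1] > b[0]:
            raise ValueError(f"conserved intervals overlap: {a} and {b}")

    L = len(h.seq)
    intervals: dict[str, Interval] = {}
    sp_names = iter(("sp1", "sp2", "sp3", "sp4", "sp5"))
    prev_end = 0
    for name, (s, e) in ordered:
        intervals[next(sp_names)] = (prev_end, s)
        intervals[name] = (s, e)
        prev_end = e
    intervals[next(sp_names)] = (prev_end, L)
    return PartitionScheme(h.seq.id, intervals, mir_on_5p)
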