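"""Mature-miRNA homolog scanning and the seven modified miRcheck rules.

The scan finds approximate occurrences of a known ~21-nt mature miRNA in a
candidate sequence (unit-cost Levenshtein over the best-matching window, both
strands), extracts flanking context, and filters the folded stem-loop with
seven structural rules before calling homolog / candidate status:

1. miR and miR* each lie within a single arm;
2. <= 6 unpaired bases in the miR;
3. <= 3 bulges (maximal runs of unpaired miR bases);
4. length difference between miR and miR* <= 3;
5. <= 3 asymmetrically unpaired miR bases (unpaired miR bases not mirrored
   by unpaired star-side bases between the same flanking pairs);
6. longest contiguous unpaired run in the miR <= 3;
7. loop-spanning distance between miR and miR* in [5, 300].

A stem-loop passing the rules is a homolog at edit distance <= 3 and a
candidate at exactly 4; looser matches are rejected.  An additional
stability screen (>= 50% of miR u miR* positions paired, configurable)
replaces the original manual inspection of loose structures; it is reported
separately from the seven rules and applied at status-calling time.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import groupby

from .hairpin import Arm, Hairpin, Interval, arm_of, locate_star
from .sequences import RnaSequence, reverse_complement


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance; 'N' matches nothing (cost 1)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (ai == b[j - 1] and ai != "N") else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def shared_nucleotides(a: str, b: str) -> int:
    """Identical-nucleotide count under the best ungapped sliding offset."""
    best = 0
    for off in range(-(len(b) - 1), len(a)):
        matches = sum(
            1
            for i in range(max(0, off), min(len(a), off + len(b)))
            if a[i] == b[i - off] and a[i] != "N"
        )
        best = max(best, matches)
    return best


@dataclass(frozen=True)
class MatureQuery:
    id: str
    residues: str

    def __post_init__(self):
        r = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", r)
        if not 18 <= len(r) <= 26:
            raise ValueError(f"mature query length {len(r)} outside [18, 26]")


@dataclass(frozen=True)
class ScanParams:
    flank_len: int = 350
    max_edit_homolog: int = 3
    edit_candidate: int = 4

    def __post_init__(self):
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")
        if self.max_edit_homolog >= self.edit_candidate:
            raise ValueError("homolog threshold must be below candidate threshold")


@dataclass(frozen=True)
class MircheckParams:
    max_unpaired_mir: int = 6
    max_bulges_mir: int = 3
    max_len_diff: int = 3
    max_asym_unpaired: int = 3
    max_contig_unpaired: int = 3
    min_mir_star_dist: int = 5
    max_mir_star_dist: int = 300
    min_duplex_paired_fraction: float = 0.5  # stability screen (manual-step stand-in)


class Status(Enum):
    HOMOLOG = "homolog"
    CANDIDATE = "candidate"
    REJECTED = "rejected"


@dataclass
class RuleResult:
    value: float
    passed: bool


@dataclass
class MircheckReport:
    rules: dict[int, RuleResult]
    overall: bool
    mir: Interval
    star: Interval | None
    mir_arm: Arm | None
    stable: bool

    def rule(self, k: int) -> RuleResult:
        return self.rules[k]


@dataclass(frozen=True)
class Match:
    start: int
    end: int
    distance: int
    strand: str  # '+' or '-'


@dataclass
class HomologHit:
    source_id: str
    interval: Interval
    strand: str
    edit_distance: int
    status: Status
    assigned_name: str | None
    mircheck: MircheckReport | None


# ---------------------------------------------------------------------------
# approximate window matching


def _windows_for_strand(target: str, query: str, max_edits: int) -> list[tuple[int, int, int]]:
    """All (start, end, distance) windows with Levenshtein <= max_edits.

    For each start, a prefix DP of the query against a bounded slice of the
    target yields the distance for every candidate end.
    """
    n, m = len(target), len(query)
    out: dict[tuple[int, int], int] = {}
    lo_len = max(1, m - max_edits)
    hi_len = m + max_edits
    for s in range(n):
        limit = min(n, s + hi_len)
        seg = target[s:limit]
        prev = list(range(len(seg) + 1))
        rows = [prev]
        for i in range(1, m + 1):
            qi = query[i - 1]
            cur = [i] + [0] * len(seg)
            for j in range(1, len(seg) + 1):
                cj = seg[j - 1]
                cost = 0 if (qi == cj and qi != "N" and cj != "N") else 1
                cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            prev = cur
        for wl in range(lo_len, len(seg) + 1):
            d = prev[wl]
            if d <= max_edits:
                key = (s, s + wl)
                if key not in out or d < out[key]:
                    out[key] = d
    return [(s, e, d) for (s, e), d in out.items()]


def merge_windows(windows: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge transitively overlapping windows to the locally best one.

    Representative of a cluster: minimal distance, ties to leftmost start,
    then shortest interval.
    """
    if not windows:
        return []
    ws = sorted(windows)
    clusters: list[list[tuple[int, int, int]]] = []
    cur = [ws[0]]
    cur_end = ws[0][1]
    for w in ws[1:]:
        if w[0] < cur_end:
            cur.append(w)
            cur_end = max(cur_end, w[1])
        else:
            clusters.append(cur)
            cur = [w]
            cur_end = w[1]
    clusters.append(cur)
    return [min(c, key=lambda w: (w[2], w[0], w[1] - w[0])) for c in clusters]


def find_matches(target: RnaSequence, query: MatureQuery, max_edits: int) -> list[Match]:
    """Report every merged window of ``target`` within ``max_edits`` of the query.

    Both the given strand and its reverse complement are scanned; minus-strand
    hits are reported in plus-strand coordinates with strand '-'.
    """
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    t = target.residues
    if not t:
        return []
    hits: list[Match] = []
    for strand, text in (("+", t), ("-", reverse_complement(t))):
        merged = merge_windows(_windows_for_strand(text, query.residues, max_edits))
        for s, e, d in merged:
            if strand == "-":
                s, e = len(t) - e, len(t) - s
            hits.append(Match(s, e, d, strand))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def extract_flanks(
    target: RnaSequence, hit: Interval, flank_len: int
) -> tuple[RnaSequence, int]:
    """Extract hit +- flank_len (truncated at the ends); returns the extract
    and the hit's offset within it."""
    s, e = hit
    if not (0 <= s < e <= len(target)):
        raise ValueError(f"invalid hit interval {hit}")
    lo = max(0, s - flank_len)
    hi = min(len(target), e + flank_len)
    sub = RnaSequence(f"{target.id}:{lo}-{hi}", target.residues[lo:hi], allow_n=True)
    return sub, s - lo


# ---------------------------------------------------------------------------
# miRcheck rules


def _unpaired_runs(h: Hairpin, mir: Interval) -> list[tuple[int, int]]:
    """Maximal runs of unpaired positions within the miR, half-open."""
    partner = h.struct.partner
    runs = []
    for unpaired, grp in groupby(range(*mir), key=lambda i: i not in partner):
        grp = list(grp)
        if unpaired:
            runs.append((grp[0], grp[-1] + 1))
    return runs


def _asymmetric_count(h: Hairpin, runs: list[tuple[int, int]]) -> int:
    """Unpaired miR bases in excess of the star-side gap between the same
    flanking pairs."""
    partner = h.struct.partner
    total = 0
    for a, b in runs:
        left = next((i for i in range(a - 1, -1, -1) if i in partner), None)
        right = next((i for i in range(b, h.struct.length) if i in partner), None)
        if left is None or right is None:
            continue
        star_gap = abs(partner[left] - partner[right]) - 1
        total += max(0, (b - a) - star_gap)
    return total


def loop_gap(h: Hairpin, mir: Interval, star: Interval) -> int:
    """Nucleotides strictly between the loop-proximal ends of miR and miR*."""
    if arm_of(h, mir) is Arm.THREE_PRIME:
        return mir[0] - star[1]
    return star[0] - mir[1]


def evaluate_mircheck(
    h: Hairpin, mir: Interval, params: MircheckParams = MircheckParams()
) -> MircheckReport:
    """Measure the seven rules on a located miR interval.

    A locate_star failure (miR unpaired or loop-spanning) is reported as a
    rule-1 failure with all structure-dependent rules failed.
    """
    m0, m1 = mir
    if not (0 <= m0 < m1 <= len(h.seq)):
        raise ValueError(f"miR interval {mir} out of bounds")
    try:
        star = locate_star(h, mir)
        mir_arm = arm_of(h, mir)
    except ValueError:
        rules = {k: RuleResult(float("nan"), False) for k in range(1, 8)}
        return MircheckReport(rules, False, mir, None, None, False)

    partner = h.struct.partner
    # rule 1 concerns the *paired bases* of miR and miR*: their spans, not
    # the overhang-extended star interval, must each sit within one arm
    paired_mir = [i for i in range(m0, m1) if i in partner]
    partners = [partner[i] for i in paired_mir]
    mir_paired_span = (min(paired_mir), max(paired_mir) + 1)
    star_paired_span = (min(partners), max(partners) + 1)
    mir_arm = arm_of(h, mir_paired_span)
    star_arm = arm_of(h, star_paired_span)
    runs = _unpaired_runs(h, mir)
    unpaired = sum(b - a for a, b in runs)
    longest = max((b - a for a, b in runs), default=0)
    len_diff = abs((m1 - m0) - (star[1] - star[0]))
    asym = _asymmetric_count(h, runs)
    dist = loop_gap(h, mir, star)

    arms_ok = mir_arm is not Arm.SPANS_LOOP and star_arm is not Arm.SPANS_LOOP and mir_arm is not star_arm
    rules = {
        1: RuleResult(0.0 if arms_ok else 1.0, arms_ok),
        2: RuleResult(unpaired, unpaired <= params.max_unpaired_mir),
        3: RuleResult(len(runs), len(runs) <= params.max_bulges_mir),
        4: RuleResult(len_diff, len_diff <= params.max_len_diff),
        5: RuleResult(asym, asym <= params.max_asym_unpaired),
        6: RuleResult(longest, longest <= params.max_contig_unpaired),
        7: RuleResult(dist, params.min_mir_star_dist <= dist <= params.max_mir_star_dist),
    }
    overall = all(r.passed for r in rules.values())

    duplex = set(range(m0, m1)) | set(range(star[0], star[1]))
    paired_frac = sum(1 for i in duplex if i in partner) / len(duplex)
    stable = paired_frac >= params.min_duplex_paired_fraction
    return MircheckReport(rules, overall, mir, star, mir_arm, stable)


def call_status(
    edit_distance: int,
    report: MircheckReport,
    params: ScanParams = ScanParams(),
    require_stable: bool = True,
) -> Status:
    """Homolog (d <= 3) / candidate (d == 4) / rejected, gated on the rules."""
    if not report.overall or (require_stable and not report.stable):
        return Status.REJECTED
    if edit_distance <= params.max_edit_homolog:
        return Status.HOMOLOG
    if edit_distance == params.edit_candidate:
        return Status.CANDIDATE
    return Status.REJECTED


def assign_name(residues: str, references: list[MatureQuery]) -> str:
    """Closest reference by Levenshtein distance; ties break lexicographically."""
    if not references:
        raise ValueError("references must be non-empty")
    return min(references, key=lambda r: (levenshtein(residues, r.residues), r.id)).id


def scan_target(
    target: RnaSequence,
    queries: list[MatureQuery],
    scan_params: ScanParams = ScanParams(),
    mircheck_params: MircheckParams = MircheckParams(),
    structure_for=None,
) -> list[HomologHit]:
    """End-to-end scan of one target against a set of mature queries.

    ``structure_for(extract)`` may supply an external dot-bracket structure
    for an extracted precursor; the built-in folder is the default.
    """
    hits: list[HomologHit] = []
    max_edits = scan_params.edit_candidate
    for query in queries:
        for match in find_matches(target, query, max_edits):
            if match.strand == "-":
                work = target.reverse_complement()
                s = len(target) - match.end
                e = len(target) - match.start
            else:
                work = target
                s, e = match.start, match.end
            extract, offset = extract_flanks(work, (s, e), scan_params.flank_len)
            mir = (offset, offset + (e - s))
            if "N" in extract.residues:
                continue
            precursor = RnaSequence(extract.id, extract.residues)
            if structure_for is not None:
                db = structure_for(precursor)
                h = Hairpin.from_dotbracket(precursor, db)
            else:
                try:
                    h = Hairpin.by_folding(precursor)
                except ValueError:
                    continue
            report = evaluate_mircheck(h, mir, mircheck_params)
            status = call_status(match.distance, report, scan_params)
            name = assign_name(precursor.residues[mir[0]:mir[1]], queries)
            hits.append(
                HomologHit(target.id, (match.start, match.end), match.strand,
                           match.distance, status, name, report)
            )
    return hits
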