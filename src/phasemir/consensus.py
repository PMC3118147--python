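"""Structural-alignment post-processing: gap filtering, consensus, pairs.

Given a structural alignment of precursor stem-loops, this module removes
columns that are more than 75% gap, computes a per-column consensus residue
and information content, and detects the consensus secondary structure as
the maximum-support non-crossing set of column pairs, with each selected
pair classed ``consensus`` (one canonical pair type dominates) or
``covarying`` (two or more canonical pair types among supporting rows —
compensatory substitutions preserving the pairing).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = {"-", ".", "~"}
CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class StructuralAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str = "stockholm") -> "StructuralAlignment":
        aln = AlignIO.read(str(path), fmt)
        rows = tuple(str(rec.seq).upper().replace("T", "U") for rec in aln)
        return cls(tuple(rec.id for rec in aln), rows)


@dataclass(frozen=True)
class ConsensusParams:
    max_gap_fraction: float = 0.75
    consensus_residue_fraction: float = 0.8
    min_pair_support: float = 0.75
    min_covary_types: int = 2
    min_loop: int = 3


@dataclass
class PairCall:
    i: int
    j: int
    support: float
    pair_types: int
    klass: str  # 'consensus' | 'covarying'


@dataclass
class ConsensusResult:
    column_map: tuple[int, ...]            # filtered index -> original index
    consensus: tuple[str | None, ...]      # per kept column
    information: tuple[float, ...]         # bits, per kept column
    pairs: list[PairCall]                  # on kept-column indices


def filter_columns(
    aln: StructuralAlignment, params: ConsensusParams = ConsensusParams()
) -> tuple[StructuralAlignment, tuple[int, ...]]:
    """Drop columns whose gap fraction strictly exceeds the threshold.

    A column with exactly 75% gaps is kept ("more than a 75% gap" removed).
    """
    kept = [
        j
        for j in range(aln.n_cols)
        if sum(c in GAP_CHARS for c in aln.column(j)) / aln.n_rows
        <= params.max_gap_fraction + 1e-12
    ]
    if not kept:
        raise ValueError("all columns removed by gap filter")
    rows = tuple("".join(r[j] for j in kept) for r in aln.rows)
    return StructuralAlignment(aln.ids, rows), tuple(kept)


def column_consensus(column: str, params: ConsensusParams = ConsensusParams()) -> tuple[str | None, float]:
    """(consensus residue or None, information content in bits).

    IC = (2 - Shannon entropy of the non-gap residue distribution) scaled
    by the non-gap fraction; consensus requires the top residue to reach
    the residue-fraction threshold among non-gap entries.
    """
    residues = [c for c in column if c not in GAP_CHARS]
    if not residues:
        return None, 0.0
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    n = len(residues)
    entropy = -sum((k / n) * math.log2(k / n) for k in counts.values())
    ic = (2.0 - entropy) * (n / len(column))
    top_res, top_k = max(sorted(counts.items()), key=lambda kv: kv[1])
    cons = top_res if top_k / n >= params.consensus_residue_fraction - 1e-12 else None
    return cons, max(ic, 0.0)


def consensus_sequence(
    aln: StructuralAlignment, params: ConsensusParams = ConsensusParams()
) -> tuple[tuple[str | None, ...], tuple[float, ...]]:
    """Per-column consensus residues and information content (bits)."""
    cons, ics = [], []
    for j in range(aln.n_cols):
        c, ic = column_consensus(aln.column(j), params)
        cons.append(c)
        ics.append(ic)
    return tuple(cons), tuple(ics)


def pair_support(aln: StructuralAlignment, i: int, j: int) -> tuple[float, int]:
    """(canonical-pair support, number of distinct canonical pair types).

    Rows with a gap in either column are excluded from the denominator; the
    pair is ineligible (support 0) when fewer than half the rows have both
    columns present.
    """
    types: dict[tuple[str, str], int] = {}
    both = 0
    for r in aln.rows:
        a, b = r[i], r[j]
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        both += 1
        if (a, b) in CANONICAL:
            types[(a, b)] = types.get((a, b), 0) + 1
    if both / aln.n_rows < 0.5 or both == 0:
        return 0.0, 0
    return sum(types.values()) / both, len(types)


def detect_pairs(
    aln: StructuralAlignment, params: ConsensusParams = ConsensusParams()
) -> list[PairCall]:
    """Maximum-total-support non-crossing pair set over candidate columns.

    Candidates are column pairs with canonical-pair support >= the threshold
    and hairpin spacing j - i > min_loop; a Nussinov-style weighted DP picks
    the non-crossing subset maximizing summed support.
    """
    n = aln.n_cols
    cand: dict[tuple[int, int], tuple[float, int]] = {}
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            sup, ntypes = pair_support(aln, i, j)
            if sup >= params.min_pair_support - 1e-12:
                cand[(i, j)] = (sup, ntypes)
    if not cand:
        return []

    W = np.zeros((n, n + 1))
    for span in range(params.min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i, j]  # leave j unpaired: W over [i, j-1]
            # W[i][j] stored as W[i, j+1]; recurrence over last column j
            best = W[i, j]
            for k in range(i, j - params.min_loop):
                if (k, j) in cand:
                    left = W[i, k] if k > i else 0.0
                    inner = W[k + 1, j] if k + 1 <= j - 1 else 0.0
                    cand_score = left + cand[(k, j)][0] + inner
                    if cand_score > best + 1e-15:
                        best = cand_score
            W[i, j + 1] = best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j_excl: int) -> None:
        while j_excl - i > params.min_loop + 1:
            j = j_excl - 1
            if abs(W[i, j_excl] - W[i, j]) < 1e-12:
                j_excl = j
                continue
            for k in range(i, j - params.min_loop):
                if (k, j) in cand:
                    left = W[i, k] if k > i else 0.0
                    inner = W[k + 1, j] if k + 1 <= j - 1 else 0.0
                    if abs(W[i, j_excl] - (left + cand[(k, j)][0] + inner)) < 1e-12:
                        pairs.append((k, j))
                        trace(k + 1, j)
                        j_excl = k
                        break
            else:
                j_excl = j

    trace(0, n)
    out = []
    for i, j in sorted(pairs):
        sup, ntypes = cand[(i, j)]
        klass = "covarying" if ntypes >= params.min_covary_types else "consensus"
        out.append(PairCall(i, j, sup, ntypes, klass))
    return out


def consensus_result(
    aln: StructuralAlignment, params: ConsensusParams = ConsensusParams()
) -> ConsensusResult:
    filtered, colmap = filter_columns(aln, params)
    cons, ics = consensus_sequence(filtered, params)
    pairs = detect_pairs(filtered, params)
    return ConsensusResult(colmap, cons, ics, pairs)


def consensus_dotbracket(result: ConsensusResult) -> str:
    chars = ["."] * len(result.consensus)
    for p in result.pairs:
        chars[p.i] = "("
        chars[p.j] = ")"
    return "".join(chars)


def write_stockholm(
    aln: StructuralAlignment, result: ConsensusResult, path: str | Path
) -> None:
    """Write the filtered alignment with a #=GC SS_cons consensus line."""
    kept = result.column_map
    msa = MultipleSeqAlignment(
        [
            SeqRecord(Seq("".join(row[j] for j in kept)), id=rid, description="")
            for rid, row in zip(aln.ids, aln.rows)
        ]
    )
    msa.column_annotations["secondary_structure"] = consensus_dotbracket(result)
    AlignIO.write(msa, str(path), "stockholm")
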