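"""RNA secondary structure: dot-bracket parsing and a deterministic folder.

The folder is a stacking-aware Nussinov-style dynamic program (pair scores
GC=3, AU=2, GU=1, +1 per stacked pair) with deterministic tie-breaking.
It stands in for an external thermodynamic folder so the pipeline runs
without external binaries; externally predicted dot-bracket structures are
accepted everywhere a structure is needed.
"""
from __future__ import annotations

from dataclasses import dataclass

MIN_LOOP = 3

PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
STACK_BONUS = 1


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_SCORES


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing set of base pairs (i, j), i < j, 0-based."""

    pairs: frozenset[tuple[int, int]]
    length: int

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of bounds")
            if j - i < MIN_LOOP + 1:
                raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_LOOP}")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for b in range(a + 1, len(ordered)):
                k, l = ordered[b]
                if k > j:
                    break
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


class DotBracketError(ValueError):
    def __init__(self, message: str, index: int):
        super().__init__(f"{message} at index {index}")
        self.index = index


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a pair set.

    Unbalanced brackets raise :class:`DotBracketError` naming the first
    offending index (first unmatched '(' or the offending ')').
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(text):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise DotBracketError("unmatched ')'", idx)
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise DotBracketError(f"invalid character {ch!r}", idx)
    if stack:
        raise DotBracketError("unclosed '('", stack[0])
    return SecondaryStructure(frozenset(pairs), len(text))


def render_dotbracket(struct: SecondaryStructure) -> str:
    chars = ["."] * struct.length
    for i, j in struct.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def score_structure(seq: str, pairs: frozenset[tuple[int, int]] | set[tuple[int, int]]) -> int:
    """Score a pair set: base-pair scores plus a bonus per stacked pair."""
    total = 0
    pset = set(pairs)
    for i, j in pairs:
        total += PAIR_SCORES[(seq[i], seq[j])]
        if (i + 1, j - 1) in pset:
            total += STACK_BONUS
    return total


def fold(seq, min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Fold a sequence by maximizing the stacking-aware pair score.

    Two DP tables: W[i][j] = best score on [i, j]; V[i][j] = best score on
    [i, j] given (i, j) paired (V carries the +1 stacking bonus when the
    enclosed optimum pairs (i+1, j-1)).  Ties break toward the pairing with
    smaller i, then smaller j, making the output deterministic.
    """
    s = seq.residues if hasattr(seq, "residues") else str(seq)
    n = len(s)
    if n < min_loop + 2:
        raise ValueError(f"sequence of length {n} too short to fold (need >= {min_loop + 2})")

    NEG = float("-inf")
    W = [[0] * n for _ in range(n)]
    V = [[NEG] * n for _ in range(n)]

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if can_pair(s[i], s[j]):
                best = W[i + 1][j - 1] if j - 1 >= i + 1 else 0
                if j - 1 - (i + 1) >= min_loop + 1 and V[i + 1][j - 1] != NEG:
                    best = max(best, V[i + 1][j - 1] + STACK_BONUS)
                V[i][j] = PAIR_SCORES[(s[i], s[j])] + best
            # W recurrence: leave i unpaired, or pair i with some k
            best_w = W[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if V[i][k] != NEG:
                    rest = W[k + 1][j] if k + 1 <= j else 0
                    cand = V[i][k] + rest
                    if cand > best_w:
                        best_w = cand
            W[i][j] = best_w

    pairs: set[tuple[int, int]] = set()

    def trace_w(i: int, j: int) -> None:
        while i < j:
            if W[i][j] == W[i + 1][j]:
                # prefer pairing i if it achieves the same score, smallest k first
                paired = False
                for k in range(i + min_loop + 1, j + 1):
                    if V[i][k] != NEG:
                        rest = W[k + 1][j] if k + 1 <= j else 0
                        if V[i][k] + rest == W[i][j]:
                            trace_v(i, k)
                            i = k + 1
                            paired = True
                            break
                if not paired:
                    i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if V[i][k] != NEG:
                    rest = W[k + 1][j] if k + 1 <= j else 0
                    if V[i][k] + rest == W[i][j]:
                        trace_v(i, k)
                        i = k + 1
                        break

    def trace_v(i: int, j: int) -> None:
        pairs.add((i, j))
        inner_i, inner_j = i + 1, j - 1
        if inner_j <= inner_i:
            return
        base = V[i][j] - PAIR_SCORES[(s[i], s[j])]
        if (
            inner_j - inner_i >= min_loop + 1
            and V[inner_i][inner_j] != NEG
            and base == V[inner_i][inner_j] + STACK_BONUS
        ):
            trace_v(inner_i, inner_j)
        else:
            trace_w(inner_i, inner_j)

    trace_w(0, n - 1)
    return SecondaryStructure(frozenset(pairs), n)
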