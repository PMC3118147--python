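"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, literal
rule counting, full-matrix recursion — and shares no code path with the
package implementation it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

PAIR_SCORES = {"GC": 3, "CG": 3, "AU": 2, "UA": 2, "GU": 1, "UG": 1}


# ---------------------------------------------------------------------------
# folding


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every non-crossing pair set over seq (canonical pairs only)."""
    n = len(seq)

    def helices(lo: int, hi: int):
        # all structures on [lo, hi)
        if hi - lo < min_loop + 2:
            yield frozenset()
            return
        # position lo unpaired
        for rest in helices(lo + 1, hi):
            yield rest
        for j in range(lo + min_loop + 1, hi):
            if seq[lo] + seq[j] in PAIR_SCORES:
                for inner in helices(lo + 1, j):
                    for outer in helices(j + 1, hi):
                        yield frozenset({(lo, j)}) | inner | outer

    yield from helices(0, n)


def score_pairs(seq: str, pairs) -> int:
    total = 0
    ps = set(pairs)
    for i, j in pairs:
        total += PAIR_SCORES[seq[i] + seq[j]]
        if (i + 1, j - 1) in ps:
            total += 1
    return total


def best_fold_score(seq: str, min_loop: int = 3) -> int:
    return max(score_pairs(seq, p) for p in enumerate_structures(seq, min_loop))


# ---------------------------------------------------------------------------
# edit distance and window search


def lev(a: str, b: str) -> int:
    d = {(0, 0): 0}
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            if i == 0 and j == 0:
                continue
            cands = []
            if i > 0:
                cands.append(d[i - 1, j] + 1)
            if j > 0:
                cands.append(d[i, j - 1] + 1)
            if i > 0 and j > 0:
                match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
                cands.append(d[i - 1, j - 1] + (0 if match else 1))
            d[i, j] = min(cands)
    return d[len(a), len(b)]


def all_windows(target: str, query: str, max_edits: int):
    """Every (start, end, distance) substring window within max_edits."""
    out = {}
    m = len(query)
    for s in range(len(target)):
        for e in range(s + max(1, m - max_edits), min(len(target), s + m + max_edits) + 1):
            d = lev(target[s:e], query)
            if d <= max_edits:
                key = (s, e)
                if key not in out or d < out[key]:
                    out[key] = d
    return [(s, e, d) for (s, e), d in out.items()]


# ---------------------------------------------------------------------------
# miRcheck rule counting (literal, structure-based)


def mircheck_counts(partner: dict[int, int], loop_span, length: int, mir):
    """Measure the seven rules directly from the pairing table.

    Returns None when the miR has no paired base or spans the loop (rule-1
    hard failure).
    """
    m0, m1 = mir
    loop_lo, loop_hi = loop_span
    paired = [i for i in range(m0, m1) if i in partner]
    if not paired:
        return None
    partners = sorted(partner[i] for i in paired)
    span_mir = (paired[0], paired[-1] + 1)
    span_star = (partners[0], partners[-1] + 1)

    def arm(iv):
        if iv[1] <= loop_lo:
            return "5p"
        if iv[0] >= loop_hi:
            return "3p"
        return "loop"

    if arm((m0, m1)) == "loop":
        return None
    arms_ok = (
        arm(span_mir) != "loop" and arm(span_star) != "loop" and arm(span_mir) != arm(span_star)
    )

    # runs of unpaired positions within miR
    runs = []
    i = m0
    while i < m1:
        if i not in partner:
            j = i
            while j < m1 and j not in partner:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    unpaired = sum(b - a for a, b in runs)
    longest = max((b - a for a, b in runs), default=0)

    asym = 0
    for a, b in runs:
        left = next((k for k in range(a - 1, -1, -1) if k in partner), None)
        right = next((k for k in range(b, length) if k in partner), None)
        if left is None or right is None:
            continue
        gap = abs(partner[left] - partner[right]) - 1
        asym += max(0, (b - a) - gap)

    # star interval exactly as the implementation defines it (documented
    # convention): partner span widened by unpaired miR ends, shifted +2
    u5 = paired[0] - m0
    u3 = (m1 - 1) - paired[-1]
    lo = partners[0] - u3 + 2
    hi = partners[-1] + 1 + u5 + 2
    lo, hi = max(lo, 0), min(hi, length)
    star_len = hi - lo
    len_diff = abs((m1 - m0) - star_len)
    if arm((m0, m1)) == "3p":
        dist = m0 - hi
    else:
        dist = lo - m1
    return {
        "arms_ok": arms_ok,
        "unpaired": unpaired,
        "n_runs": len(runs),
        "len_diff": len_diff,
        "asym": asym,
        "longest": longest,
        "dist": dist,
    }


def mircheck_decisions(counts) -> dict[int, bool]:
    if counts is None:
        return {k: False for k in range(1, 8)}
    return {
        1: counts["arms_ok"],
        2: counts["unpaired"] <= 6,
        3: counts["n_runs"] <= 3,
        4: counts["len_diff"] <= 3,
        5: counts["asym"] <= 3,
        6: counts["longest"] <= 3,
        7: 5 <= counts["dist"] <= 300,
    }


# ---------------------------------------------------------------------------
# consensus pair DP


def best_noncrossing_support(candidates: dict[tuple[int, int], float],
                             n_cols: int, min_loop: int = 3) -> float:
    """Exhaustive maximum total support over non-crossing candidate subsets."""
    items = [p for p in candidates if p[1] - p[0] > min_loop]
    best = 0.0
    for r in range(len(items) + 1):
        for combo in itertools.combinations(items, r):
            used = set()
            ok = True
            for i, j in combo:
                if i in used or j in used:
                    ok = False
                    break
                used.add(i)
                used.add(j)
            if not ok:
                continue
            for (i, j), (k, l) in itertools.combinations(combo, 2):
                if i < k < j < l or k < i < l < j:
                    ok = False
                    break
            if ok:
                best = max(best, sum(candidates[p] for p in combo))
    return best


# ---------------------------------------------------------------------------
# likelihood by exhaustive state summation


def brute_loglik(rows, partition, tree, model) -> float:
    from phasemir.phylo.models import reversible_eigen, transition_matrices

    rates = model.gamma_rates()
    K = model.n_rate_categories
    pi4 = np.asarray(model.base_freqs)
    pi16 = np.asarray(model.doublet_freqs)
    code = {"A": 0, "C": 1, "G": 2, "U": 3}
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    lengths = np.array([max(n.length, 0.0) for n in nodes])
    tips = sorted(rows)
    total = 0.0
    specs = [
        (4, pi4, model.gtr_matrix(),
         [[code.get(rows[t][j], 4) for t in tips] for j in partition.unpaired]),
        (16, pi16, model.doublet_matrix(),
         [[(code[rows[t][i]] * 4 + code[rows[t][j]]
            if rows[t][i] in code and rows[t][j] in code else 16)
           for t in tips] for (i, j) in partition.pairs]),
    ]
    for nstates, pi, Q, cols in specs:
        eig = reversible_eigen(Q, pi)
        P = transition_matrices(*eig, lengths, rates)
        internal = [i for i, n in enumerate(nodes) if not n.is_leaf]
        tipidx = {t: i for i, t in enumerate(tips)}
        leafrow = {i: tipidx[n.name] for i, n in enumerate(nodes) if n.is_leaf}
        for col in cols:
            site = 0.0
            for c in range(K):
                for assign in itertools.product(range(nstates), repeat=len(internal)):
                    amap = dict(zip(internal, assign))
                    p = pi[amap[idx[id(tree.root)]]]
                    for n in nodes:
                        if n is tree.root:
                            continue
                        i = idx[id(n)]
                        if n.is_leaf:
                            st = col[leafrow[i]]
                            if st >= nstates:  # gap: sum over states = row sum
                                continue
                        else:
                            st = amap[i]
                        p *= P[i, c, amap[idx[id(n.parent)]], st]
                    site += p
            total += math.log(site / K)
    return total


# ---------------------------------------------------------------------------
# reconciliation by exhaustive event-placement search


def brute_reconcile(gene_tree, species_tree, tip_map):
    """Minimal duplication + loss counts over all valid reconciliation maps."""
    sp_nodes = list(species_tree.postorder())
    parent = {}
    depth = {}

    def walk(n, d):
        depth[id(n)] = d
        for c in n.children:
            parent[id(c)] = n
            walk(c, d + 1)

    walk(species_tree.root, 0)

    def ancestors(n):
        out = [n]
        while id(n) in parent:
            n = parent[id(n)]
            out.append(n)
        return out

    def lca(a, b):
        seen = {id(x) for x in ancestors(a)}
        for x in ancestors(b):
            if id(x) in seen:
                return x
        raise AssertionError

    def dist(anc, desc):
        d = 0
        while desc is not anc:
            desc = parent[id(desc)]
            d += 1
        return d

    sp_by_name = {n.name: n for n in sp_nodes if n.is_leaf}
    gnodes = list(gene_tree.postorder())
    internal = [n for n in gnodes if not n.is_leaf]
    fixed = {id(n): sp_by_name[tip_map[n.name]] for n in gnodes if n.is_leaf}

    choices = []
    lca_of = {}
    for n in internal:
        # valid images: ancestors of the LCA of the children's minimal maps
        def min_map(x):
            if x.is_leaf:
                return fixed[id(x)]
            return lca_of[id(x)]

        m = min_map(n.children[0])
        for c in n.children[1:]:
            m = lca(m, min_map(c))
        lca_of[id(n)] = m
        choices.append(ancestors(m))

    best = None
    for assign in itertools.product(*choices):
        amap = dict(fixed)
        amap.update({id(n): s for n, s in zip(internal, assign)})
        valid = True
        dups = losses = 0
        for n in internal:
            mu = amap[id(n)]
            kids = [amap[id(c)] for c in n.children]
            for mc in kids:
                anc = {id(x) for x in ancestors(mc)}
                if id(mu) not in anc:
                    valid = False
            if not valid:
                break
            # speciation iff children map strictly below through distinct arms
            arms = set()
            spec_ok = True
            for mc in kids:
                if mc is mu:
                    spec_ok = False
                    break
                walker = mc
                while parent[id(walker)] is not mu:
                    walker = parent[id(walker)]
                arms.add(id(walker))
            is_dup = not (spec_ok and len(arms) == len(kids))
            dups += is_dup
            for mc in kids:
                k = dist(mu, mc)
                losses += k if is_dup else k - 1
        if valid and (best is None or dups + losses < best[0] + best[1]):
            best = (dups, losses)
    return best
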