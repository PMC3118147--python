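"""Synthetic-data generators with machine-readable ground truth.

Every generator is deterministic given its seed (or Generator) and returns
the quantities a test needs to verify the analysis that consumes its
output: planted hairpin geometry and structure, planted partition read
proportions, planted cleavage hot-spots, the simulating tree/model/structure
for alignments, and the full duplication/loss event log for gene families.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PartitionScheme, build_partitions, classify_from_flags
from .hairpin import Hairpin, Interval, locate_star
from .pare import PareLibrary
from .quant import SmallRNALibrary, assign_partition, QuantParams, LEAK
from .sequences import RnaSequence, reverse_complement
from .structure import SecondaryStructure
from .phylo.models import SubstitutionModel, reversible_eigen, transition_matrices
from .phylo.trees import Node, Tree

NUCS = np.array(list("ACGU"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCS[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# hairpins


@dataclass(frozen=True)
class HairpinSpec:
    """Planted type-1 anatomy: sp1 | miR* | sp2 | ACR5 | sp3 | ACR3 | sp4 | miR | sp5.

    Defaults give D = 66 (> 60, type 1) and pass every miRcheck rule.
    Violation switches plant specific duplex irregularities:

    - ``sym_loops``: (miR offset, length) interior loops unpaired on both
      sides (raises the unpaired count without asymmetry);
    - ``mir_bulges``: miR-side-only bulges (asymmetric; star partners of the
      flanking pairs are adjacent);
    - ``star_bulges``: extra unpaired star nucleotides (lengthens miR*);
    - ``short_d``: omit the ACR duplex and elongation (D <= 60, type 2).
    """

    sp1: int = 12
    sp2: int = 8
    loop: int = 10
    sp4: int = 8
    sp5: int = 12
    mir_len: int = 21
    acr_len: int = 21
    mir_on_five_prime: bool = False
    mir_seq: str | None = None
    acr3_seq: str | None = None
    sym_loops: tuple[tuple[int, int], ...] = ()
    mir_bulges: tuple[tuple[int, int], ...] = ()
    star_bulges: tuple[tuple[int, int], ...] = ()
    short_d: bool = False
    seed: int = 0


@dataclass
class PlantedHairpin:
    hairpin: Hairpin
    mir: Interval
    star: Interval            # locate_star ground truth is the raw duplex span
    scheme: PartitionScheme | None
    acr5: Interval | None
    acr3: Interval | None
    D: int
    type_label: int


def _plant_duplex(spec: HairpinSpec):
    """Relative pairing of the miR against its star region.

    Returns (star_region_len, rel_pairs) with rel_pairs of (mir offset,
    star offset from the loop-proximal star end).
    """
    sym = {off: ln for off, ln in spec.sym_loops}
    mbul = {off: ln for off, ln in spec.mir_bulges}
    sbul = {off: ln for off, ln in spec.star_bulges}
    in_sym = set()
    for off, ln in spec.sym_loops:
        in_sym.update(range(off, off + ln))
    in_mbul = set()
    for off, ln in spec.mir_bulges:
        in_mbul.update(range(off, off + ln))
    pairs = []
    k = 0
    for i in range(spec.mir_len):
        if i in sbul:
            k += sbul[i]
        if i in in_sym:
            k += 1
            continue
        if i in in_mbul:
            continue
        pairs.append((i, k))
        k += 1
    return k, pairs


def gen_hairpin(spec: HairpinSpec = HairpinSpec()) -> PlantedHairpin:
    """Build a stem-loop with planted duplexes and exact ground truth."""
    rng = _rng(spec.seed)
    mir = spec.mir_seq or _random_seq(rng, spec.mir_len)
    acr3 = spec.acr3_seq or _random_seq(rng, spec.acr_len)
    acr5 = reverse_complement(acr3)

    star_len, rel_pairs = _plant_duplex(spec)
    # star region sequence: paired slots complement the miR, unpaired slots
    # copy the miR base (same-base never pairs)
    comp = dict(zip("ACGU", "UGCA"))
    star_local = ["A"] * star_len
    for i, k in rel_pairs:
        star_local[k] = comp[mir[i]]
    taken = {k for _, k in rel_pairs}
    for k in range(star_len):
        if k not in taken:
            star_local[k] = _random_seq(rng, 1)

    if spec.short_d:
        segs = [
            ("sp1", _random_seq(rng, spec.sp1)),
            ("star", "".join(reversed(star_local))),
            ("loop", _random_seq(rng, spec.loop)),
            ("mir", mir),
            ("sp5", _random_seq(rng, spec.sp5)),
        ]
    else:
        segs = [
            ("sp1", _random_seq(rng, spec.sp1)),
            ("star", "".join(reversed(star_local))),
            ("sp2", _random_seq(rng, spec.sp2)),
            ("acr5", acr5),
            ("loop", _random_seq(rng, spec.loop)),
            ("acr3", acr3),
            ("sp4", _random_seq(rng, spec.sp4)),
            ("mir", mir),
            ("sp5", _random_seq(rng, spec.sp5)),
        ]
    offs: dict[str, Interval] = {}
    pos = 0
    parts = []
    for name, s in segs:
        offs[name] = (pos, pos + len(s))
        parts.append(s)
        pos += len(s)
    seq_text = "".join(parts)

    s0, s1 = offs["star"]
    m0, m1 = offs["mir"]
    pairs: set[tuple[int, int]] = set()
    for i, k in rel_pairs:
        pairs.add((s1 - 1 - k, m0 + i))
    if not spec.short_d:
        a5, a5e = offs["acr5"]
        a3, a3e = offs["acr3"]
        for i in range(spec.acr_len):
            pairs.add((a5 + i, a3e - 1 - i))

    seq = RnaSequence(f"synthetic_hairpin_{spec.seed}", seq_text)
    if spec.mir_on_five_prime:
        # mirror the whole construct
        seq = RnaSequence(seq.id, reverse_complement(seq_text))
        L = len(seq_text)
        pairs = {(L - 1 - j, L - 1 - i) for i, j in pairs}
        flip = lambda iv: (L - iv[1], L - iv[0])
        offs = {k: flip(v) for k, v in offs.items()}
        m0, m1 = offs["mir"]

    struct = SecondaryStructure(frozenset(pairs), len(seq))
    h = Hairpin.from_structure(seq, struct)
    mir_iv = offs["mir"]
    star_iv = locate_star(h, mir_iv)
    from .scan import loop_gap

    D = loop_gap(h, mir_iv, star_iv)
    if spec.short_d:
        return PlantedHairpin(h, mir_iv, star_iv, None, None, None, D, 2)
    try:
        scheme = build_partitions(h, mir_iv, offs["acr5"], offs["acr3"])
    except ValueError:
        # planted duplex irregularities can push miR* outside the conserved
        # length band; such fixtures carry no partition scheme
        scheme = None
    label = classify_from_flags(seq.id, D, True, True).type_label
    return PlantedHairpin(h, mir_iv, star_iv, scheme, offs["acr5"], offs["acr3"], D, label)


# ---------------------------------------------------------------------------
# small-RNA libraries


@dataclass(frozen=True)
class LibrarySpec:
    """Per-partition read proportions (incl. 'leak'), depth and read lengths.

    Defaults emulate the canonical phased profile: the miR dominates, the
    other duplex strands are minor, space partitions near-silent.
    """

    proportions: tuple[tuple[str, float], ...] = (
        ("miR", 0.70), ("miR*", 0.08), ("ACR5", 0.05), ("ACR3", 0.12), (LEAK, 0.05),
    )
    depth: int = 100_000
    read_lengths: tuple[int, ...] = (20, 21, 22)
    length_probs: tuple[float, ...] = (0.15, 0.7, 0.15)
    seed: int = 0

    def __post_init__(self):
        total = sum(p for _, p in self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _feasible_starts(part: Interval, L: int, seq_len: int,
                     frac: float = 0.8) -> tuple[int, int]:
    """Start range giving >= frac overlap of an L-nt read with the partition."""
    ps, pe = part
    t = int(np.ceil(frac * L - 1e-9))
    lo = max(0, ps - (L - t))
    hi = min(seq_len - L, pe - t)
    return lo, hi


def gen_library(planted: PlantedHairpin, spec: LibrarySpec = LibrarySpec(),
                sample_id: str = "synthetic") -> tuple[SmallRNALibrary, dict[str, float]]:
    """Sample reads per partition at the planted proportions.

    Reads for a named partition are placed to overlap it by >= 80%; leak
    reads straddle a partition boundary below the threshold on both sides.
    Returns the collapsed library plus the realized per-partition counts
    (the exact ground truth for the quantifier).
    """
    rng = _rng(spec.seed)
    scheme = planted.scheme
    if scheme is None:
        raise ValueError("library generation needs a partitioned (type-1) hairpin")
    seq = planted.hairpin.seq.residues
    names = [n for n, _ in spec.proportions]
    probs = np.array([p for _, p in spec.proportions])
    draws = rng.multinomial(spec.depth, probs)
    realized: dict[str, float] = {}
    counts: dict[str, float] = {}
    qp = QuantParams()
    boundaries = np.array([scheme.intervals[n][1] for n in scheme.order[:-1]])
    lens = np.asarray(spec.read_lengths)
    for name, n_reads in zip(names, draws):
        if n_reads == 0:
            realized[name] = 0.0
            continue
        L = rng.choice(lens, size=n_reads, p=np.asarray(spec.length_probs))
        if name == LEAK:
            # centre reads on random internal boundaries: ~half on each side
            b = rng.choice(boundaries, size=n_reads)
            s = np.clip(b - L // 2, 0, len(seq) - L)
            keep = np.array(
                [assign_partition((si, si + li), scheme, qp) == LEAK
                 for si, li in zip(s.tolist(), L.tolist())]
            )
            s, L = s[keep], L[keep]
        else:
            s = np.empty(n_reads, dtype=np.int64)
            keep = np.ones(n_reads, dtype=bool)
            for lv in np.unique(L):
                mask = L == lv
                lo, hi = _feasible_starts(scheme.intervals[name], int(lv), len(seq))
                if hi < lo:
                    keep &= ~mask
                    continue
                s[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
            s, L = s[keep], L[keep]
        realized[name] = float(len(s))
        uniq, cnt = np.unique(np.stack([s, L], axis=1), axis=0, return_counts=True)
        for (si, li), c in zip(uniq.tolist(), cnt.tolist()):
            read = seq[si:si + li]
            counts[read] = counts.get(read, 0.0) + float(c)
    lib = SmallRNALibrary.from_pairs(sample_id, sorted(counts.items()),
                                     total_reads=sum(counts.values()))
    return lib, realized


def gen_shared_paralog(planted: PlantedHairpin, seed: int = 0) -> RnaSequence:
    """A paralog precursor sharing exactly the miR partition sequence."""
    rng = _rng(seed)
    scheme = planted.scheme
    m0, m1 = scheme.intervals["miR"]
    block = planted.hairpin.seq.residues[m0:m1]
    return RnaSequence(
        planted.hairpin.seq.id + "_paralog",
        _random_seq(rng, 40) + block + _random_seq(rng, 40),
    )


# ---------------------------------------------------------------------------
# PARE libraries


def gen_pare(target: RnaSequence, hotspots: dict[int, float], depth: int,
             seed: int = 0, tag_len: int = 20,
             sample_id: str = "pare") -> tuple[PareLibrary, np.ndarray]:
    """Sample degradome tags with 5' ends at the given hot-spot distribution.

    Returns the collapsed library and the realized per-position tag counts
    (the ground-truth raw profile).
    """
    rng = _rng(seed)
    positions = np.array(sorted(hotspots))
    if positions.size == 0:
        raise ValueError("need at least one hot-spot")
    if positions.max() + tag_len > len(target):
        raise ValueError("hot-spot too close to the 3' end for the tag length")
    probs = np.array([hotspots[p] for p in positions], dtype=float)
    probs = probs / probs.sum()
    draws = rng.multinomial(depth, probs)
    truth = np.zeros(len(target))
    counts: dict[str, float] = {}
    for pos, k in zip(positions, draws):
        if k == 0:
            continue
        tag = target.residues[pos:pos + tag_len]
        counts[tag] = counts.get(tag, 0.0) + float(k)
        truth[pos] += k
    lib = PareLibrary.from_pairs(sample_id, sorted(counts.items()),
                                 total_reads=float(depth))
    return lib, truth


# ---------------------------------------------------------------------------
# alignment evolution


def paired_doublet_freqs(strength: float = 0.97) -> tuple[float, ...]:
    """Doublet frequencies concentrated on the canonical pairs — the
    stationary distribution of a stem column under compensatory selection."""
    canonical = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}  # AU UA CG GC GU UG
    freqs = np.full(16, (1 - strength) / 10)
    for a, b in canonical:
        freqs[a * 4 + b] = strength / 6
    return tuple(freqs / freqs.sum())


@dataclass(frozen=True)
class EvolSpec:
    """Alignment simulation: tree, model, column count, planted pairs.

    ``root_pairs_canonical`` draws the ancestral state of each planted
    doublet from the stationary distribution conditioned on a canonical
    pairing — the planted structure is defined to exist in the ancestor;
    an ancestrally unpaired column would not carry the planted helix.
    """

    tree: Tree
    model: SubstitutionModel
    n_cols: int
    pairs: tuple[tuple[int, int], ...] = ()
    seed: int = 0
    root_pairs_canonical: bool = False


def _sample_markov(rng, P_rows: np.ndarray) -> np.ndarray:
    """Sample one categorical draw per row of a stochastic matrix slice."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def evolve(spec: EvolSpec) -> dict[str, str]:
    """Simulate an alignment: 4-state CTMC on unpaired columns, 16-state on
    planted pairs, discrete-gamma site rates, exact matrix exponentials."""
    rng = _rng(spec.seed)
    model = spec.model
    rates = model.gamma_rates()
    pi4 = np.asarray(model.base_freqs)
    pi16 = np.asarray(model.doublet_freqs)
    e4 = reversible_eigen(model.gtr_matrix(), pi4)
    e16 = reversible_eigen(model.doublet_matrix(), pi16)

    paired_cols = {c for p in spec.pairs for c in p}
    unpaired_cols = [j for j in range(spec.n_cols) if j not in paired_cols]
    n_un, n_pr = len(unpaired_cols), len(spec.pairs)

    nodes = list(spec.tree.postorder())
    order = list(reversed(nodes))  # root first
    lengths = np.array([max(n.length, 0.0) for n in nodes])
    idx = {id(n): i for i, n in enumerate(nodes)}

    canonical16 = np.array([a * 4 + b for a, b in
                            [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]])

    def simulate(n_sites, pi, eig, nstates):
        if n_sites == 0:
            return {}
        cats = rng.integers(0, model.n_rate_categories, n_sites)
        P = transition_matrices(*eig, lengths, rates)  # (node, cat, S, S)
        states: dict[int, np.ndarray] = {}
        root_i = idx[id(spec.tree.root)]
        root_pi = np.asarray(pi, dtype=float)
        if nstates == 16 and spec.root_pairs_canonical:
            mask = np.zeros(16)
            mask[canonical16] = 1.0
            root_pi = root_pi * mask
            root_pi = root_pi / root_pi.sum()
        states[root_i] = rng.choice(nstates, size=n_sites, p=root_pi)
        for n in order:
            if n is spec.tree.root:
                continue
            i = idx[id(n)]
            parent_states = states[idx[id(n.parent)]]
            child = np.empty(n_sites, dtype=np.int64)
            for c in range(model.n_rate_categories):
                mask = cats == c
                if not mask.any():
                    continue
                rows = P[i, c][parent_states[mask]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                child[mask] = _sample_markov(rng, rows)
            states[i] = child
        return states

    st4 = simulate(n_un, pi4, e4, 4)
    st16 = simulate(n_pr, pi16, e16, 16)

    rows: dict[str, str] = {}
    for n in nodes:
        if not n.is_leaf:
            continue
        i = idx[id(n)]
        chars = [""] * spec.n_cols
        if n_un:
            for k, j in enumerate(unpaired_cols):
                chars[j] = "ACGU"[st4[i][k]]
        for k, (a, b) in enumerate(spec.pairs):
            code = st16[i][k]
            chars[a] = "ACGU"[code // 4]
            chars[b] = "ACGU"[code % 4]
        rows[n.name] = "".join(chars)
    return rows


# ---------------------------------------------------------------------------
# round-trip validation studies
#
# These bundle a generator with the analysis that should invert it; the test
# suite and the reproduction script both run them at their study sizes.


def consensus_recovery_trial(seed: int, n_rows: int = 30, n_cols: int = 150,
                             n_helix: int = 40) -> tuple[int, int, int]:
    """Evolve an alignment with a planted helix under compensatory selection
    and re-detect it.  Returns (recovered pairs, planted pairs, crossing
    pairs in the detected set)."""
    from .consensus import StructuralAlignment, detect_pairs
    from .phylo.trees import random_unrooted_topology

    rng = _rng(seed)
    tree = random_unrooted_topology(
        [f"t{i}" for i in range(n_rows)], rng, lambda: float(rng.exponential(0.1))
    )
    pairs = tuple((i, n_cols - 1 - i) for i in range(n_helix))
    model = SubstitutionModel(doublet_freqs=paired_doublet_freqs())
    rows = evolve(EvolSpec(tree, model, n_cols, pairs, seed=int(rng.integers(1 << 30)),
                           root_pairs_canonical=True))
    aln = StructuralAlignment(tuple(sorted(rows)), tuple(rows[k] for k in sorted(rows)))
    got = [(c.i, c.j) for c in detect_pairs(aln)]
    crossing = sum(
        1
        for a in range(len(got))
        for b in range(a + 1, len(got))
        if got[a][0] < got[b][0] < got[a][1] < got[b][1]
        or got[b][0] < got[a][0] < got[b][1] < got[a][1]
    )
    return len(set(got) & set(pairs)), len(pairs), crossing


def mcmc_recovery_trial(seed: int, n_taxa: int = 6, n_cols: int = 2000,
                        n_helix: int = 200, generations: int = 50_000,
                        n_runs: int = 2) -> tuple[bool, float]:
    """Simulate data on a known topology and test whether the majority-rule
    consensus of the posterior sample recovers it.  Returns (recovered,
    ASDSF between the independent runs)."""
    from .phylo.likelihood import SitePartition
    from .phylo.mcmc import McmcConfig, majority_consensus, mcmc
    from .phylo.trees import random_unrooted_topology

    rng = _rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    true_tree = random_unrooted_topology(
        taxa, rng, lambda: float(rng.uniform(0.05, 0.3))
    )
    pairs = tuple((i, 2 * n_helix - 1 - i) for i in range(n_helix))
    model = SubstitutionModel(
        gtr_exchangeabilities=(1.0, 2.0, 1.0, 1.0, 4.0, 1.5),
        base_freqs=(0.3, 0.2, 0.25, 0.25),
        doublet_freqs=paired_doublet_freqs(0.95),
        gamma_shape=0.5,
    )
    rows = evolve(EvolSpec(true_tree, model, n_cols, pairs,
                           seed=int(rng.integers(1 << 30))))
    part = SitePartition.from_structure(n_cols, pairs)
    res = mcmc(rows, part, model,
               McmcConfig(n_generations=generations, n_runs=n_runs,
                          seed=int(rng.integers(1 << 30))))
    cons = majority_consensus(res.pooled(), taxa)
    return cons.splits() == true_tree.splits(), res.asdsf


# ---------------------------------------------------------------------------
# gene families by duplication and loss


@dataclass(frozen=True)
class FamilySpec:
    species_tree: Tree
    dup_rate: float = 0.3
    loss_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class FamilyTruth:
    gene_tree: Tree
    tip_map: dict[str, str]
    n_duplications: int
    n_losses: int
    seed_used: int


def gen_family(spec: FamilySpec, max_attempts: int = 100) -> FamilyTruth:
    """Birth-death of gene lineages along the species tree.

    One ancestral gene enters at the species root; along each species branch
    every lineage independently duplicates (rate ``dup_rate``) or dies (rate
    ``loss_rate``); at species nodes surviving lineages speciate.  The event
    log gives the true duplication and loss counts; the returned gene tree
    is pruned to surviving tips (unary nodes suppressed).  Retries with
    advanced seeds when everything goes extinct.
    """
    for attempt in range(max_attempts):
        seed = spec.seed + attempt
        rng = _rng(seed)
        events = {"dup": 0, "loss": 0}
        counter = [0]

        def evolve_branch(lineage: Node, length: float) -> list[Node]:
            """Lineages surviving to the branch end, as children of `lineage`."""
            total = spec.dup_rate + spec.loss_rate
            t = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t >= length:
                return [lineage]
            if rng.random() < spec.dup_rate / total:
                events["dup"] += 1
                left, right = Node(), Node()
                lineage.add(left)
                lineage.add(right)
                return evolve_branch(left, length - t) + evolve_branch(right, length - t)
            events["loss"] += 1
            return []

        def descend(sp_node: Node, lineage: Node) -> None:
            if sp_node.is_leaf:
                counter[0] += 1
                lineage.name = f"{sp_node.name}_g{counter[0]}"
                tip_map[lineage.name] = sp_node.name
                return
            for child in sp_node.children:
                entry = Node()
                lineage.add(entry)
                for survivor in evolve_branch(entry, child.length or 1.0):
                    descend(child, survivor)

        tip_map: dict[str, str] = {}
        root = Node()
        descend(spec.species_tree.root, root)

        pruned = _prune_extinct(root)
        if pruned is not None and len(Tree(pruned).leaves()) >= 2:
            return FamilyTruth(Tree(pruned), tip_map, events["dup"], events["loss"], seed)
    raise RuntimeError(f"all lineages lost in {max_attempts} attempts")


def _prune_extinct(node: Node) -> Node | None:
    """Drop extinct subtrees and suppress unary nodes."""
    if node.is_leaf:
        return node if node.name else None
    kept = [p for p in (map(_prune_extinct, list(node.children))) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    out = Node(node.name, node.length)
    for k in kept:
        k.parent = None
        out.add(k)
    return out
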