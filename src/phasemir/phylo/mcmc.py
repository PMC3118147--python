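"""Desk-scale Bayesian tree inference for the partitioned GTR+doublet model.

Metropolis-Hastings over topology (nearest-neighbour interchange), branch
lengths (multiplier), gamma shape (multiplier), and base/doublet stationary
frequencies (Dirichlet), with independent seeded runs, pooled post-burn-in
samples, logged acceptance rates and the average standard deviation of
split frequencies (ASDSF) between runs as the convergence report.

Priors: uniform over topologies, iid Exponential(mean 0.1) branch lengths,
Exponential(mean 1) gamma shape, flat Dirichlet on frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .likelihood import PartitionedLikelihood, SitePartition
from .models import SubstitutionModel, reversible_eigen, transition_matrices
from .trees import Node, Tree, nni, random_unrooted_topology

BRANCH_PRIOR_RATE = 10.0
ALPHA_PRIOR_RATE = 1.0


@dataclass(frozen=True)
class McmcConfig:
    n_generations: int
    sample_interval: int = 100
    n_runs: int = 2
    burn_in: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_generations <= 0 or self.sample_interval <= 0 or self.n_runs <= 0:
            raise ValueError("generations, interval and runs must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")


@dataclass
class TreeSample:
    splits: frozenset
    newick: str
    loglik: float
    alpha: float


@dataclass
class McmcResult:
    runs: list[list[TreeSample]]          # post-burn-in samples per run
    acceptance: dict[str, float]
    asdsf: float
    config: McmcConfig

    def pooled(self) -> list[TreeSample]:
        return [s for run in self.runs for s in run]


def _log_dirichlet(x: np.ndarray, conc: np.ndarray) -> float:
    return float(
        gammaln(conc.sum()) - gammaln(conc).sum() + ((conc - 1) * np.log(x)).sum()
    )


class _Chain:
    """One MCMC run over (topology, branch lengths, alpha, frequencies)."""

    def __init__(self, engine: PartitionedLikelihood | None, model: SubstitutionModel,
                 rng: np.random.Generator, taxa: list[str]):
        self.engine = engine
        self.rng = rng
        self.exch = np.asarray(model.gtr_exchangeabilities, dtype=float)
        self.ncat = model.n_rate_categories
        self.tree = random_unrooted_topology(
            taxa, rng, lambda: float(rng.exponential(1.0 / BRANCH_PRIOR_RATE))
        )
        self.alpha = model.gamma_shape
        self.pi4 = np.asarray(model.base_freqs, dtype=float)
        self.pi16 = np.asarray(model.doublet_freqs, dtype=float)
        self.tip_index = (
            engine.tip_index if engine is not None else {t: i for i, t in enumerate(taxa)}
        )
        self._refresh_model()
        self._sync_flat()
        self.logp = self._posterior_current()

    def _sync_flat(self):
        from .likelihood import flatten_tree

        nodes, children, lengths, tip_rows = flatten_tree(self.tree, self.tip_index)
        self._nodes = nodes
        self._children = children
        self._lengths = lengths
        self._tip_rows = tip_rows
        self._blen_sum = float(lengths.sum()) - max(self.tree.root.length, 0.0)

    # -- cached model pieces --------------------------------------------
    def _refresh_model(self):
        from .models import discrete_gamma, doublet_rate_matrix, gtr_rate_matrix

        self.rates = discrete_gamma(self.alpha, self.ncat)
        self.e4 = reversible_eigen(gtr_rate_matrix(self.exch, self.pi4), self.pi4)
        self.e16 = reversible_eigen(doublet_rate_matrix(self.exch, self.pi16), self.pi16)
        self._pcache: dict[float, tuple] = {}

    def _loglik_arrays(self, children, lengths, tip_rows) -> float:
        if self.engine is None:
            return 0.0
        eng = self.engine
        P4, P16 = self._transition_for(lengths)
        ll = eng._prune(children, lengths, tip_rows, P4, 4, eng.w4, self.pi4, self.ncat)
        if eng.w16.size:
            ll += eng._prune(children, lengths, tip_rows, P16, 16, eng.w16,
                             self.pi16, self.ncat)
        return ll

    def _transition_for(self, lengths: np.ndarray):
        """Per-node P matrices assembled from a per-branch-length cache.

        Topology moves leave branch lengths unchanged, so nearly all lookups
        hit; the cache is dropped whenever rates or frequencies move.
        """
        if len(self._pcache) > 4096:
            self._pcache = {}
        cache = self._pcache
        missing = [l for l in lengths if l not in cache]
        if missing:
            uniq = sorted(set(missing))
            P4 = transition_matrices(*self.e4, np.array(uniq), self.rates)
            P16 = (
                transition_matrices(*self.e16, np.array(uniq), self.rates)
                if self.engine is not None and self.engine.w16.size
                else np.zeros((len(uniq), self.ncat, 16, 16))
            )
            for i, l in enumerate(uniq):
                cache[l] = (P4[i], P16[i])
        P4 = np.stack([cache[l][0] for l in lengths])
        P16 = np.stack([cache[l][1] for l in lengths])
        return P4, P16

    def _log_prior(self) -> float:
        n_branches = len(self._nodes) - 1
        lp = n_branches * np.log(BRANCH_PRIOR_RATE) - BRANCH_PRIOR_RATE * self._blen_sum
        lp += np.log(ALPHA_PRIOR_RATE) - ALPHA_PRIOR_RATE * self.alpha
        return float(lp)

    def _posterior_current(self) -> float:
        return (
            self._loglik_arrays(self._children, self._lengths, self._tip_rows)
            + self._log_prior()
        )

    # -- moves -----------------------------------------------------------
    def step(self) -> str:
        u = self.rng.random()
        if u < 0.35:
            return self._move_nni()
        if u < 0.80:
            return self._move_branch()
        if u < 0.90:
            return self._move_alpha()
        return self._move_freqs()

    def _accept(self, new_logp: float, log_hastings: float) -> bool:
        return np.log(self.rng.random() + 1e-300) < (new_logp - self.logp + log_hastings)

    def _move_nni(self) -> str:
        undo = nni(self.tree, self.rng)
        if undo is None:
            return "nni:reject"
        from .likelihood import flatten_tree

        _, children, lengths, tip_rows = flatten_tree(self.tree, self.tip_index)
        logp = self._loglik_arrays(children, lengths, tip_rows) + self._log_prior()
        if self._accept(logp, 0.0):
            self.logp = logp
            self._sync_flat()
            return "nni:accept"
        undo()
        return "nni:reject"

    def _move_branch(self) -> str:
        i = int(self.rng.integers(len(self._nodes) - 1))  # root is last in postorder
        node = self._nodes[i]
        old = node.length
        m = float(np.exp(1.0 * (self.rng.random() - 0.5)))
        new = old * m
        node.length = new
        self._lengths[i] = new
        self._blen_sum += new - old
        logp = self._posterior_current()
        if self._accept(logp, np.log(m)):
            self.logp = logp
            return "branch:accept"
        node.length = old
        self._lengths[i] = old
        self._blen_sum += old - new
        return "branch:reject"

    def _move_alpha(self) -> str:
        old_alpha, old_rates = self.alpha, self.rates
        m = float(np.exp(0.7 * (self.rng.random() - 0.5)))
        self.alpha = old_alpha * m
        from .models import discrete_gamma

        self.rates = discrete_gamma(self.alpha, self.ncat)
        old_cache, self._pcache = self._pcache, {}
        logp = self._posterior_current()
        if self._accept(logp, np.log(m)):
            self.logp = logp
            return "alpha:accept"
        self.alpha, self.rates = old_alpha, old_rates
        self._pcache = old_cache
        return "alpha:reject"

    def _move_freqs(self) -> str:
        which = "pi4" if self.rng.random() < 0.5 else "pi16"
        cur = getattr(self, which)
        conc = 300.0 * cur
        prop = self.rng.dirichlet(np.maximum(conc, 1e-2))
        prop = np.maximum(prop, 1e-6)
        prop /= prop.sum()
        log_h = _log_dirichlet(cur, 300.0 * prop) - _log_dirichlet(prop, conc)
        old = cur.copy()
        old_cache = self._pcache
        setattr(self, which, prop)
        try:
            self._refresh_model()
        except (ValueError, np.linalg.LinAlgError):
            setattr(self, which, old)
            self._refresh_model()
            self._pcache = old_cache
            return "freq:reject"
        logp = self._posterior_current()
        if self._accept(logp, log_h):
            self.logp = logp
            return "freq:accept"
        setattr(self, which, old)
        self._refresh_model()
        self._pcache = old_cache
        return "freq:reject"


def mcmc(
    rows: dict[str, str] | None,
    partition: SitePartition | None,
    model: SubstitutionModel,
    config: McmcConfig,
    taxa: list[str] | None = None,
) -> McmcResult:
    """Run ``config.n_runs`` independent seeded chains and pool samples.

    ``rows=None`` runs prior-only sampling over the given ``taxa`` (used to
    validate that the chain targets the uniform topology prior).
    """
    if rows is not None:
        engine = PartitionedLikelihood(rows, partition)
        taxa = engine.tips
    else:
        engine = None
        if not taxa:
            raise ValueError("taxa required for prior-only sampling")
    if len(taxa) < 4:
        raise ValueError("need >= 4 taxa")

    runs: list[list[TreeSample]] = []
    accept_counts: dict[str, int] = {}
    move_counts: dict[str, int] = {}
    for r in range(config.n_runs):
        rng = np.random.default_rng((config.seed, r))
        chain = _Chain(engine, model, rng, list(taxa))
        samples: list[TreeSample] = []
        for gen in range(1, config.n_generations + 1):
            outcome = chain.step()
            move, _, result = outcome.partition(":")
            move_counts[move] = move_counts.get(move, 0) + 1
            if result == "accept":
                accept_counts[move] = accept_counts.get(move, 0) + 1
            if gen % config.sample_interval == 0:
                samples.append(
                    TreeSample(chain.tree.splits(), chain.tree.newick(),
                               chain.logp, chain.alpha)
                )
        cut = int(len(samples) * config.burn_in)
        runs.append(samples[cut:])

    acceptance = {
        m: accept_counts.get(m, 0) / c for m, c in sorted(move_counts.items())
    }
    return McmcResult(runs, acceptance, _asdsf(runs), config)


def _asdsf(runs: list[list[TreeSample]]) -> float:
    """Average standard deviation of split frequencies across runs."""
    if len(runs) < 2 or any(not r for r in runs):
        return float("nan")
    all_splits = set()
    for run in runs:
        for s in run:
            all_splits.update(s.splits)
    if not all_splits:
        return 0.0
    sds = []
    for split in all_splits:
        freqs = [sum(split in s.splits for s in run) / len(run) for run in runs]
        sds.append(float(np.std(freqs)))
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# consensus and duplicate handling


def majority_consensus(samples: list[TreeSample] | list[frozenset], taxa: list[str],
                       threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: splits with frequency strictly above the
    threshold, annotated with their posterior probabilities."""
    if not samples:
        raise ValueError("no samples")
    split_sets = [s.splits if isinstance(s, TreeSample) else s for s in samples]
    counts: dict[frozenset, int] = {}
    for ss in split_sets:
        for split in ss:
            counts[split] = counts.get(split, 0) + 1
    n = len(split_sets)
    majority = {s: c / n for s, c in counts.items() if c / n > threshold}

    taxa = sorted(taxa)
    # laminar family (majority splits are mutually compatible): nest by size
    ordered = sorted(majority, key=len, reverse=True)
    root = Node()
    node_for: dict[frozenset, Node] = {}
    parent_of: dict[frozenset, Node] = {}
    for s in ordered:
        best = None
        for t in ordered:
            if t is not s and s < t and (best is None or len(t) < len(best)):
                best = t
        parent = node_for[best] if best is not None else root
        node = Node()
        node.support = majority[s]
        node.length = 1.0
        parent.add(node)
        node_for[s] = node
    # attach leaves to the smallest containing split (or root)
    for name in taxa:
        best = None
        for s in ordered:
            if name in s and (best is None or len(s) < len(best)):
                best = s
        holder = node_for[best] if best is not None else root
        holder.add(Node(name, 1.0))
    return Tree(root)


def dedup_reinsert(rows: dict[str, str]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Collapse identical alignment rows to one representative.

    Returns (reduced rows, representative -> all original ids including the
    representative itself); use :func:`reinsert_duplicates` on the inferred
    tree afterwards.
    """
    by_seq: dict[str, list[str]] = {}
    for rid in sorted(rows):
        by_seq.setdefault(rows[rid], []).append(rid)
    reduced = {ids[0]: seq for seq, ids in by_seq.items()}
    mapping = {ids[0]: ids for ids in by_seq.values() if len(ids) > 1}
    return reduced, mapping


def reinsert_duplicates(tree: Tree, mapping: dict[str, list[str]],
                        branch_length: float = 0.001, support: float = 100.0) -> Tree:
    """Expand each representative tip into a node holding the original
    redundant taxa, with posterior 100 and branch lengths 0.001."""
    out = tree.copy()
    for leaf in out.leaves():
        if leaf.name in mapping:
            originals = mapping[leaf.name]
            leaf.name = None
            leaf.support = support
            for orig in originals:
                leaf.add(Node(orig, branch_length))
    return out
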