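"""Felsenstein pruning for the partitioned GTR + doublet model.

Unpaired alignment columns are 4-state characters; each consensus base-pair
column pair forms one 16-state doublet character.  Site patterns are
compressed, gaps are missing data (all-ones partial likelihoods), and every
site likelihood is averaged over the discrete-gamma categories.  Per-node
rescaling keeps partials in range.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    NUC,
    SubstitutionModel,
    reversible_eigen,
    transition_matrices,
)
from .trees import Tree

GAP4 = 4
GAP16 = 16
_NUC_CODE = {c: i for i, c in enumerate(NUC)}


@dataclass(frozen=True)
class SitePartition:
    """Column layout: unpaired column indices plus doublet column pairs."""

    unpaired: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        used = list(self.unpaired)
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i},{j}) not ordered")
            used.extend((i, j))
        if len(used) != len(set(used)):
            raise ValueError("partition assigns a column twice")
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k > j:
                    break
                if i < k < j < l:
                    raise ValueError(f"crossing doublet pairs ({i},{j}), ({k},{l})")

    @classmethod
    def from_structure(cls, n_cols: int, pairs) -> "SitePartition":
        paired = {i for p in pairs for i in p}
        unpaired = tuple(j for j in range(n_cols) if j not in paired)
        return cls(unpaired, tuple(tuple(p) for p in pairs))


def _encode_partition(rows: dict[str, str], tips: list[str], partition: SitePartition):
    """State codes per tip for both partitions, pattern-compressed.

    Returns (codes4, weights4, codes16, weights16); codes are arrays of
    shape (ntip, npattern) with GAP codes for missing data.
    """
    def code4(c: str) -> int:
        return _NUC_CODE.get(c, GAP4)

    n = len(tips)
    cols4 = np.array(
        [[code4(rows[t][j]) for t in tips] for j in partition.unpaired], dtype=np.int64
    ).reshape(len(partition.unpaired), n)
    cols16 = np.zeros((len(partition.pairs), n), dtype=np.int64)
    for pi, (i, j) in enumerate(partition.pairs):
        for ti, t in enumerate(tips):
            a, b = code4(rows[t][i]), code4(rows[t][j])
            cols16[pi, ti] = a * 4 + b if (a != GAP4 and b != GAP4) else GAP16

    def compress(cols: np.ndarray):
        if cols.shape[0] == 0:
            return np.zeros((n, 0), dtype=np.int64), np.zeros(0)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq.T.copy(), counts.astype(float)

    codes4, w4 = compress(cols4)
    codes16, w16 = compress(cols16)
    return codes4, w4, codes16, w16


def flatten_tree(tree: Tree, tip_index: dict[str, int]):
    """Postorder arrays: (nodes, children indices, branch lengths, tip rows)."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = [[index[id(c)] for c in n.children] for n in nodes]
    lengths = np.array([max(n.length, 0.0) for n in nodes])
    tip_rows = [tip_index.get(n.name, -1) if n.is_leaf else -1 for n in nodes]
    for n, r in zip(nodes, tip_rows):
        if n.is_leaf and r == -1:
            raise ValueError(f"tip {n.name!r} absent from alignment")
    return nodes, children, lengths, tip_rows


def _tip_partials(codes: np.ndarray, nstates: int) -> np.ndarray:
    """(ntip, nstates, npattern) one-hot partials; gaps are all-ones."""
    ntip, npat = codes.shape
    out = np.zeros((ntip, nstates, npat))
    for s in range(nstates):
        out[:, s, :] = (codes == s) | (codes == nstates)
    return out


class PartitionedLikelihood:
    """Reusable pruning engine bound to one alignment and site partition."""

    def __init__(self, rows: dict[str, str], partition: SitePartition):
        self.tips = sorted(rows)
        self.partition = partition
        c4, w4, c16, w16 = _encode_partition(rows, self.tips, partition)
        self.w4, self.w16 = w4, w16
        self.tp4 = _tip_partials(c4, 4)
        self.tp16 = _tip_partials(c16, 16)
        self.tip_index = {t: i for i, t in enumerate(self.tips)}
        self._tiles: dict[tuple[int, int], np.ndarray] = {}

    def _tile(self, nstates: int, ncat: int) -> np.ndarray:
        """Tip partials tiled per category, contiguous for fast matmul."""
        key = (nstates, ncat)
        if key not in self._tiles:
            tp = self.tp4 if nstates == 4 else self.tp16
            ntip, _, npat = tp.shape
            self._tiles[key] = np.ascontiguousarray(
                np.broadcast_to(tp[:, None], (ntip, ncat, nstates, npat))
            )
        return self._tiles[key]

    def _buffers(self, nstates: int, ncat: int, children) -> dict[int, np.ndarray]:
        """Reusable partial-likelihood buffers for the internal nodes."""
        npat = (self.tp4 if nstates == 4 else self.tp16).shape[2]
        key = (nstates, ncat)
        cache = getattr(self, "_bufcache", None)
        if cache is None:
            cache = self._bufcache = {}
        store = cache.setdefault(key, {})
        for idx, kids in enumerate(children):
            if kids and idx not in store:
                store[idx] = np.empty((ncat, nstates, npat))
        return store

    def _scratch(self, nstates: int, ncat: int) -> np.ndarray:
        npat = (self.tp4 if nstates == 4 else self.tp16).shape[2]
        key = ("scratch", nstates, ncat)
        cache = getattr(self, "_scratchcache", None)
        if cache is None:
            cache = self._scratchcache = {}
        if key not in cache:
            cache[key] = np.empty((ncat, nstates, npat))
        return cache[key]

    # -- tree flattening -------------------------------------------------
    def _flatten(self, tree: Tree):
        return flatten_tree(tree, self.tip_index)

    def _prune(self, children, lengths, tip_rows, P, nstates, weights, pi, ncat):
        """Log-likelihood of one partition given per-edge P matrices.

        Per-node rescaling is applied only on large trees; shallow trees
        stay comfortably inside double range without it.
        """
        if weights.size == 0:
            return 0.0
        tiles = self._tile(nstates, ncat)
        npat = tiles.shape[3]
        nn = len(children)
        rescale = nn > 24
        bufs = self._buffers(nstates, ncat, children)
        partials: list[np.ndarray | None] = [None] * nn
        logscale = np.zeros(npat) if rescale else None
        scratch = self._scratch(nstates, ncat)
        for idx in range(nn):
            kids = children[idx]
            if not kids:
                continue
            acc = bufs[idx]
            first = True
            for k in kids:
                child = tiles[tip_rows[k]] if tip_rows[k] >= 0 else partials[k]
                if first:
                    np.matmul(P[k], child, out=acc)
                    first = False
                else:
                    np.matmul(P[k], child, out=scratch)
                    acc *= scratch
            if rescale:
                mx = acc.max(axis=(0, 1))
                mx[mx <= 0] = 1.0
                acc /= mx
                logscale += np.log(mx)
            partials[idx] = acc
        root = partials[nn - 1]
        site_l = (pi @ root.sum(axis=0)) / ncat
        np.maximum(site_l, 1e-300, out=site_l)
        ll = np.log(site_l)
        if rescale:
            ll += logscale
        return float(weights @ ll)

    def loglik(self, tree: Tree, model: SubstitutionModel) -> float:
        rates = model.gamma_rates()
        pi4 = np.asarray(model.base_freqs)
        pi16 = np.asarray(model.doublet_freqs)
        e4 = reversible_eigen(model.gtr_matrix(), pi4)
        e16 = reversible_eigen(model.doublet_matrix(), pi16)
        _, children, lengths, tip_rows = self._flatten(tree)
        P4 = transition_matrices(*e4, lengths, rates)
        P16 = transition_matrices(*e16, lengths, rates)
        ncat = model.n_rate_categories
        ll4 = self._prune(children, lengths, tip_rows, P4, 4, self.w4, pi4, ncat)
        ll16 = self._prune(children, lengths, tip_rows, P16, 16, self.w16, pi16, ncat)
        return ll4 + ll16


def loglik(rows: dict[str, str], partition: SitePartition, tree: Tree,
           model: SubstitutionModel) -> float:
    """One-shot partitioned log-likelihood (see :class:`PartitionedLikelihood`)."""
    return PartitionedLikelihood(rows, partition).loglik(tree, model)
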