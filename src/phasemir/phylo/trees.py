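"""Light phylogenetic tree structure with Newick bridging via dendropy.

Unrooted topologies are held as rooted trees with a trifurcating root (the
standard representation for reversible-model inference); rooted binary trees
serve reconciliation and consensus output.
"""
from __future__ import annotations

from typing import Callable, Iterator

import dendropy
import numpy as np


class Node:
    __slots__ = ("children", "parent", "length", "name", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.length = length
        self.name = name
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        self.parent.children.remove(self)
        self.parent = None
        return self

    def __repr__(self):
        return f"<Node {self.name or '*'} len={self.length:.4g}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Child endpoints of internal edges (both endpoints internal)."""
        return [
            n
            for n in self.postorder()
            if n.parent is not None and not n.is_leaf and n.parent.children
        ]

    # -- copying ---------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(clone(c))
            return m

        return Tree(clone(self.root))

    # -- splits ----------------------------------------------------------
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the side not holding the
        lexicographically smallest taxon (canonical orientation)."""
        names = sorted(self.leaf_names())
        ref = names[0]
        all_set = frozenset(names)
        out = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n.parent is not None:
                side = below[id(n)]
                if ref in side:
                    side = all_set - side
                if 2 <= len(side) <= len(names) - 2:
                    out.add(side)
        return frozenset(out)

    def topology_key(self) -> frozenset[frozenset[str]]:
        return self.splits()

    # -- Newick ----------------------------------------------------------
    def newick(self, support: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if support and n.support is not None:
                label = f"{n.support:g}"
            elif n.name:
                label = n.name
            return f"({inner}){label}:{n.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = self.root.name or ""
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        def conv(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else (dn.label or None)
            n = Node(name, dn.edge.length or 0.0)
            for c in dn.child_nodes():
                n.add(conv(c))
            return n

        return cls(conv(dt.seed_node))

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick(), schema="newick", taxon_namespace=taxon_namespace
        )


def random_unrooted_topology(names: list[str], rng: np.random.Generator,
                             branch_sampler: Callable[[], float] | None = None) -> Tree:
    """Uniform random unrooted binary topology (trifurcating root)."""
    if len(names) < 3:
        raise ValueError("need >= 3 taxa")
    draw = branch_sampler or (lambda: float(rng.exponential(0.1)))
    # sequential random addition: uniform over unrooted topologies
    names = list(names)
    root = Node()
    for nm in names[:3]:
        root.add(Node(nm, draw()))
    tree = Tree(root)
    edges: list[Node] = list(root.children)
    for nm in names[3:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node(None, draw())
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        leaf = mid.add(Node(nm, draw()))
        edges.append(mid)
        edges.append(leaf)
    return tree


def nni(tree: Tree, rng: np.random.Generator):
    """In-place nearest-neighbour interchange on a random internal edge.

    Swaps a random child of the edge's lower node with a random sibling
    subtree.  Returns an undo callable (the move is an involution), or
    None when the tree has no internal edge.
    """
    candidates = tree.internal_edges()
    if not candidates:
        return None
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent
    w = v.children[int(rng.integers(len(v.children)))]
    sibs = [c for c in u.children if c is not v]
    s = sibs[int(rng.integers(len(sibs)))]
    iw = v.children.index(w)
    is_ = u.children.index(s)

    def swap():
        v.children[iw], u.children[is_] = u.children[is_], v.children[iw]
        v.children[iw].parent = v
        u.children[is_].parent = u

    swap()
    return swap
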