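"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node maps to the last common ancestor (in the species tree)
of the species carrying its descendant genes.  A node is a duplication iff
it maps to the same species node as one of its children (a duplication
increases the paralog count within one clade); losses are the ancestral
genes implied absent along the species-tree path between a node's mapping
and its children's mappings.  The LCA map minimizes both event counts.
"""
from __future__ import annotations

from dataclasses import dataclass

from .trees import Node, Tree


def read_tip_map(path) -> dict[str, str]:
    """Two-column TSV: gene tip label -> species tip label."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, species = line.split("\t")[:2]
            out[gene] = species
    return out


@dataclass
class ReconciliationResult:
    mapping: dict[int, Node]          # id(gene node) -> species node
    duplications: list[Node]          # gene nodes that are duplications
    losses: list[tuple[Node, Node]]   # (gene child edge, species node lost under)
    n_duplications: int
    n_losses: int


def _species_index(species_tree: Tree):
    depth: dict[int, int] = {}
    parent: dict[int, Node | None] = {}

    def walk(n: Node, d: int):
        depth[id(n)] = d
        for c in n.children:
            parent[id(c)] = n
            walk(c, d + 1)

    parent[id(species_tree.root)] = None
    walk(species_tree.root, 0)
    return depth, parent


def _lca(a: Node, b: Node, depth, parent) -> Node:
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        else:
            a = parent[id(a)]
    return a


def reconcile(gene_tree: Tree, species_tree: Tree,
              tip_map: dict[str, str]) -> ReconciliationResult:
    """Reconcile a rooted gene tree against a rooted species tree.

    ``tip_map`` sends gene tip labels to species tip labels; every gene tip
    must be mapped.
    """
    species_by_name = {n.name: n for n in species_tree.postorder() if n.is_leaf}
    depth, parent = _species_index(species_tree)

    mapping: dict[int, Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            if node.name not in tip_map:
                raise ValueError(f"gene tip {node.name!r} has no species mapping")
            sp = tip_map[node.name]
            if sp not in species_by_name:
                raise ValueError(f"species {sp!r} absent from species tree")
            mapping[id(node)] = species_by_name[sp]
        else:
            m = mapping[id(node.children[0])]
            for c in node.children[1:]:
                m = _lca(m, mapping[id(c)], depth, parent)
            mapping[id(node)] = m

    duplications: list[Node] = []
    losses: list[tuple[Node, Node]] = []
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        mu = mapping[id(node)]
        is_dup = any(mapping[id(c)] is mu for c in node.children)
        if is_dup:
            duplications.append(node)
        for c in node.children:
            mc = mapping[id(c)]
            k = depth[id(mc)] - depth[id(mu)]  # species edges traversed
            implied = k if is_dup else k - 1
            # record which species nodes lost a gene copy along the path
            walker = mc
            path = []
            while walker is not mu:
                path.append(walker)
                walker = parent[id(walker)]
            for sp in path[1:] if not is_dup else path:
                # a loss in each species branched off the path
                losses.append((c, sp))
            assert implied == max(len(path) - (0 if is_dup else 1), 0)
    return ReconciliationResult(
        mapping, duplications, losses, len(duplications), len(losses)
    )
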