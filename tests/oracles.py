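"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the code paths they validate: tree metrics go
through networkx shortest paths, rootings are enumerated by physically
rerooting dendropy clones, parsimony is an exhaustive minimum over all
ancestral labelings, and graph components use a tiny union-find.
"""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np


def random_tree(n_tips: int, seed: int, min_len=0.05, max_len=1.0) -> dendropy.Tree:
    """Random rooted bifurcating tree with uniform branch lengths."""
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = ns.new_taxon(f"t{i + 1:02d}")
        nd.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = dendropy.Node()
        p.edge.length = float(rng.uniform(min_len, max_len))
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = nodes[0]
    for ch in list(root.child_nodes()):
        root.remove_child(ch)
        tree.seed_node.add_child(ch)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def tree_graph(tree: dendropy.Tree) -> nx.Graph:
    g = nx.Graph()
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            g.add_edge(id(nd), id(ch), weight=float(ch.edge.length or 0.0))
    return g


def brute_force_midpoint_radius(tree: dendropy.Tree, grid: float = 1e-4) -> float:
    """Min over all edge points (discretized) of the max point-to-tip distance."""
    g = tree_graph(tree)
    leaves = list(tree.leaf_node_iter())
    dist = {
        id(l): nx.single_source_dijkstra_path_length(g, id(l)) for l in leaves
    }
    best = np.inf
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            L = float(ch.edge.length or 0.0)
            # leaves on the child side reach an edge point through ch
            child_leaves = {id(l) for l in ch.leaf_iter()}
            a = max(dist[il][id(ch)] for il in child_leaves)
            others = [id(l) for l in leaves if id(l) not in child_leaves]
            b = max(dist[il][id(nd)] for il in others) if others else -np.inf
            x = np.arange(0.0, L + grid, grid)
            best = min(best, float(np.max(
                np.stack([a + x, b + (L - x)]), axis=0).min()))
    return best


def max_root_tip_distance(tree: dendropy.Tree) -> float:
    return max(l.distance_from_root() for l in tree.leaf_node_iter())


def canonical_bipartition(tree: dendropy.Tree, side: frozenset) -> frozenset:
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_tips)
    return side if ref not in side else all_tips - side


def all_edges_by_bipartition(tree: dendropy.Tree) -> dict[frozenset, object]:
    """Map canonical bipartition -> one representative dendropy edge."""
    out = {}
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if not side or side == all_tips:
            continue
        out.setdefault(canonical_bipartition(tree, side), nd.edge)
    return out


def monophyletic_by_scan(tree: dendropy.Tree, tipset: set[str]) -> bool:
    """Independent monophyly check: some node's leaf set equals tipset."""
    for nd in tree.preorder_node_iter():
        if {l.taxon.label for l in nd.leaf_iter()} == tipset:
            return True
    return False


def reroot_and_test_roots(tree: dendropy.Tree, tipset: set[str]) -> set[frozenset]:
    """All edges whose rooting makes tipset monophyletic, by rerooting."""
    valid = set()
    for bipart in all_edges_by_bipartition(tree):
        clone = tree.clone(depth=1)
        edge = all_edges_by_bipartition(clone)[bipart]
        L = float(edge.length or 0.0)
        clone.reroot_at_edge(edge, length1=L / 2, length2=L / 2,
                             update_bipartitions=True)
        if monophyletic_by_scan(clone, tipset):
            valid.add(bipart)
    return valid


def greedy_clade_cover(tree: dendropy.Tree, tipset: set[str]) -> int:
    """Minimal cover of tipset by clades, greedy on the laminar clade family."""
    clades = []
    for nd in tree.preorder_node_iter():
        leafset = frozenset(l.taxon.label for l in nd.leaf_iter())
        if leafset <= tipset:
            clades.append(leafset)
    uncovered = set(tipset)
    count = 0
    while uncovered:
        tip = min(uncovered)
        best = max((c for c in clades if tip in c), key=len)
        uncovered -= best
        count += 1
    return count


def exhaustive_parsimony(tree: dendropy.Tree, character: dict[str, int]) -> int:
    """Minimum state changes over all ancestral labelings (exponential)."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = np.inf
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = {id(nd): s for nd, s in zip(internals, states)}
        for l in tree.leaf_node_iter():
            assign[id(l)] = character[l.taxon.label]
        changes = 0
        for nd in tree.preorder_node_iter():
            for ch in nd.child_nodes():
                changes += assign[id(nd)] != assign[id(ch)]
        best = min(best, changes)
    return int(best)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(nodes, edges) -> list[frozenset]:
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict = {}
    for n in nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]
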