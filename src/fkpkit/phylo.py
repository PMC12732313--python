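"""Tree operations for the single-fusion-event hypothesis.

Built on :mod:`dendropy` trees.  Provides midpoint rooting, monophyly
testing, enumeration of root positions compatible with monophyly of a
tip set, minimal clade cover (how many clades a tip set splinters into
under a given rooting), and small-parsimony counts of fusion gain/loss
events for a binary tip character.

Root positions are modelled as points on edges (an edge is bisected by
the new root), matching midpoint-rooting semantics.  Polytomies and
zero-length branches are accepted throughout; the parsimony count uses
unit-cost dynamic programming, which is exact on multifurcating trees.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Literal

import dendropy

log = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "write_newick",
    "tip_labels",
    "midpoint_root",
    "is_monophyletic",
    "monophyly_roots",
    "min_clade_cover",
    "fitch_fusion_events",
]


class NewickError(ValueError):
    pass


def read_newick(path=None, data: str | None = None) -> dendropy.Tree:
    """Read a Newick tree from a path or literal string.

    Raises :class:`NewickError` on malformed input or duplicate tips.
    """
    kwargs = {"path": path} if data is None else {"data": data}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            **kwargs,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"failed to parse newick: {exc}") from exc
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _check_tipset(tree: dendropy.Tree, tipset: Iterable[str]) -> set[str]:
    tips = set(tipset)
    if not tips:
        raise ValueError("tipset must be nonempty")
    unknown = tips - set(tip_labels(tree))
    if unknown:
        raise KeyError(f"unknown tip(s): {sorted(unknown)}")
    return tips


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------

def _leaf_paths(tree: dendropy.Tree):
    """Map each node to (parent, edge length); error on missing lengths."""
    parent: dict = {}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise ValueError("midpoint rooting requires branch lengths on all edges")
            parent[ch] = (nd, float(ch.edge.length))
    return parent


def _path_between(parent, a, b):
    """Node sequence from tip ``a`` to tip ``b`` with cumulative distances."""
    anc_a = {}
    node, dist = a, 0.0
    while True:
        anc_a[node] = dist
        if node not in parent:
            break
        p, length = parent[node]
        dist += length
        node = p
    # climb from b until meeting an ancestor of a (the LCA on the path)
    node, dist_b = b, 0.0
    chain_b = [(b, 0.0)]
    while node not in anc_a:
        p, length = parent[node]
        dist_b += length
        node = p
        chain_b.append((node, dist_b))
    lca, b_to_lca = node, dist_b
    path = []
    node, dist_a = a, 0.0
    while node is not lca:
        path.append((node, dist_a))
        p, length = parent[node]
        dist_a += length
        node = p
    path.append((lca, dist_a))
    for nd, d_from_b in reversed(chain_b[:-1]):
        path.append((nd, dist_a + (b_to_lca - d_from_b)))
    return path


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    Equivalently minimizes the maximum root-to-tip distance.  Ties between
    equally long paths are broken by the lexicographically smallest
    (sorted) tip-label pair.  The input is not modified.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two tips")
    parent = _leaf_paths(tree)

    # pairwise tip distances via root-path dictionaries
    depth = {}
    for leaf in leaves:
        d, node = 0.0, leaf
        chain = {}
        while node in parent:
            chain[node] = d
            p, length = parent[node]
            d += length
            node = p
        chain[node] = d
        depth[leaf] = chain

    best = None  # (dist, (labA, labB), leafA, leafB)
    for i, la in enumerate(leaves):
        for lb in leaves[i + 1 :]:
            chain_a = depth[la]
            # find LCA: first ancestor of b present in chain_a
            node, db = lb, 0.0
            while node not in chain_a:
                p, length = parent[node]
                db += length
                node = p
            dist = chain_a[node] + db
            key = (la.taxon.label, lb.taxon.label)
            if best is None or dist > best[0] + 1e-12 or (
                abs(dist - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (dist, key, la, lb)

    total, _, la, lb = best
    half = total / 2.0
    path = _path_between(parent, la, lb)
    # locate the edge (between consecutive path nodes) containing `half`
    for (n0, d0), (n1, d1) in zip(path, path[1:]):
        if d1 >= half - 1e-12:
            # root sits on the edge between n0 and n1 at distance half-d0 from n0
            if n1 in parent and parent[n1][0] is n0:
                child, down = n1, d1 - half  # root -> child length
            else:
                child, down = n0, half - d0
            edge = child.edge
            up = float(edge.length) - down
            tree.reroot_at_edge(
                edge, length1=max(up, 0.0), length2=max(down, 0.0),
                update_bipartitions=True,
            )
            tree.is_rooted = True
            return tree
    raise AssertionError("midpoint not located on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def _mrca(tree: dendropy.Tree, tips: set[str]):
    """Most recent common ancestor of the labelled tips (seed as root)."""
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    paths = []
    for lab in tips:
        node, chain = leaves[lab], []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths.append(list(reversed(chain)))
    mrca = None
    for level in zip(*paths):
        if all(nd is level[0] for nd in level):
            mrca = level[0]
        else:
            break
    return mrca


def is_monophyletic(tree: dendropy.Tree, tipset: Iterable[str]) -> bool:
    """True iff the tip descendants of MRCA(tipset) equal tipset exactly."""
    tips = _check_tipset(tree, tipset)
    mrca = _mrca(tree, tips)
    under = {l.taxon.label for l in mrca.leaf_iter()}
    return under == tips


def _edge_bipartitions(tree: dendropy.Tree):
    """Yield (edge, frozenset of tip labels on the head-node side).

    Trivial 'edges' above the seed node are skipped; for a degree-2 seed
    the two incident child edges represent the same unrooted edge and are
    deduplicated.
    """
    all_tips = frozenset(tip_labels(tree))
    seen: set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if not side or side == all_tips:
            continue
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        if canon in seen:
            continue
        seen.add(canon)
        yield nd.edge, side


def edge_bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical bipartitions (side not containing the smallest tip label)."""
    all_tips = frozenset(tip_labels(tree))
    ref = min(all_tips)
    out = set()
    for _, side in _edge_bipartitions(tree):
        out.add(side if ref not in side else all_tips - side)
    return out


def monophyly_roots(tree: dendropy.Tree, tipset: Iterable[str]) -> set[frozenset]:
    """Edges that, used as root positions, make ``tipset`` monophyletic.

    The tree is treated as unrooted.  Edges are identified by their
    canonical bipartition: the frozenset of tip labels on the side *not*
    containing the lexicographically smallest tip of the whole tree.

    A tip set is monophyletic under a rooting iff some edge ``f``
    bipartitions the tips into exactly (tipset | complement) and the root
    lies on ``f`` itself or anywhere in the complement component.
    """
    tips = _check_tipset(tree, tipset)
    all_tips = frozenset(tip_labels(tree))
    ref = min(all_tips)
    if tips == all_tips:
        warnings.warn("tipset covers all tips; every rooting is compatible")
        return edge_bipartition_set(tree)

    comp = all_tips - tips
    valid: set[frozenset] = set()
    split_edge_node = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if side == tips or side == comp:
            split_edge_node = nd
            split_side = side
            break
    if split_edge_node is None:
        return valid  # no edge separates tipset from the rest

    def canon(side: frozenset) -> frozenset:
        return side if ref not in side else all_tips - side

    valid.add(canon(split_side))
    if split_side == tips:
        # complement component: everything outside the subtree of split node
        inside = set(split_edge_node.preorder_iter())
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None or nd in inside:
                continue
            side = frozenset(l.taxon.label for l in nd.leaf_iter())
            if side and side != all_tips:
                valid.add(canon(side))
    else:
        # complement hangs below the split edge: valid roots inside it
        for nd in split_edge_node.preorder_iter():
            if nd is split_edge_node or nd.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in nd.leaf_iter())
            if side and side != all_tips:
                valid.add(canon(side))
    return valid


def min_clade_cover(tree: dendropy.Tree, tipset: Iterable[str]) -> int:
    """Number of maximal clades with tip sets inside ``tipset`` covering it.

    Equals 1 iff the tip set is monophyletic in the rooted tree.
    """
    tips = _check_tipset(tree, tipset)
    count = 0

    def pure(nd) -> bool:
        # postorder flag: all descendant tips in tipset
        if nd.is_leaf():
            return nd.taxon.label in tips
        return all(flags[id(ch)] for ch in nd.child_nodes())

    flags: dict[int, bool] = {}
    for nd in tree.postorder_node_iter():
        flags[id(nd)] = pure(nd)
    for nd in tree.preorder_node_iter():
        if flags[id(nd)] and (
            nd.parent_node is None or not flags[id(nd.parent_node)]
        ):
            count += 1
    return count


# ---------------------------------------------------------------------------
# parsimony on the binary fusion character
# ---------------------------------------------------------------------------

def _validate_character(tree: dendropy.Tree, character: dict[str, int]) -> None:
    tips = set(tip_labels(tree))
    missing = tips - set(character)
    if missing:
        raise ValueError(f"character does not cover tip(s): {sorted(missing)[:5]}")
    bad = {s for s in character.values() if s not in (0, 1)}
    if bad:
        raise ValueError(f"non-binary states: {sorted(bad)}")


def fitch_fusion_events(
    tree: dendropy.Tree,
    character: dict[str, int],
    mode: Literal["unordered", "dollo"] = "unordered",
) -> int:
    """Minimum number of fusion-state changes on a rooted tree.

    ``unordered``: small-parsimony minimum over all ancestral labelings
    (unit-cost dynamic programming; exact on polytomies).  ``dollo``:
    minimum events allowing at most one 0->1 gain — the gain is placed on
    the branch above the MRCA of the fused tips and each maximal
    fully-unfused clade inside that subtree counts as one loss.
    """
    _validate_character(tree, character)
    if mode == "unordered":
        INF = float("inf")
        cost: dict[int, list[float]] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                s = character[nd.taxon.label]
                cost[id(nd)] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
            else:
                c = [0.0, 0.0]
                for ch in nd.child_nodes():
                    cc = cost[id(ch)]
                    for s in (0, 1):
                        c[s] += min(cc[s], cc[1 - s] + 1.0)
                cost[id(nd)] = c
        return int(min(cost[id(tree.seed_node)]))
    if mode == "dollo":
        fused = sorted(l for l, s in character.items() if s == 1)
        if not fused:
            return 0
        mrca = _mrca(tree, set(fused))
        unfused_under = [
            l.taxon.label for l in mrca.leaf_iter() if character[l.taxon.label] == 0
        ]
        losses = (
            min_clade_cover_subtree(mrca, set(unfused_under)) if unfused_under else 0
        )
        return 1 + losses
    raise ValueError(f"unknown mode {mode!r}")


def min_clade_cover_subtree(root_node, tips: set[str]) -> int:
    """Maximal all-in-``tips`` clades under ``root_node`` (helper for Dollo)."""
    flags: dict[int, bool] = {}
    count = 0
    for nd in root_node.postorder_iter():
        if nd.is_leaf():
            flags[id(nd)] = nd.taxon.label in tips
        else:
            flags[id(nd)] = all(flags[id(ch)] for ch in nd.child_nodes())
    for nd in root_node.preorder_iter():
        if flags[id(nd)] and (nd is root_node or not flags[id(nd.parent_node)]):
            count += 1
    return count
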