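"""Tree I/O, midpoint rooting, monophyly, clade cover and fusion parsimony.

Brute-force oracles (reroot-and-test, exhaustive ancestral labelings,
discretized midpoint search) live in oracles.py.
"""

import numpy as np
import pytest

from fkpkit.phylo import (
    NewickError,
    edge_bipartition_set,
    fitch_fusion_events,
    is_monophyletic,
    midpoint_root,
    min_clade_cover,
    monophyly_roots,
    read_newick,
    tip_labels,
    write_newick,
)
from oracles import (
    brute_force_midpoint_radius,
    exhaustive_parsimony,
    greedy_clade_cover,
    max_root_tip_distance,
    random_tree,
    reroot_and_test_roots,
)

QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        t = read_newick(data="((A:1,B:2):0.5,C:3);")
        assert sorted(tip_labels(t)) == ["A", "B", "C"]
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        again = read_newick(p)
        assert write_newick(again) == write_newick(t)

    def test_absent_lengths_stay_absent(self):
        t = read_newick(data="(A,B);")
        for leaf in t.leaf_node_iter():
            assert leaf.edge.length is None

    def test_malformed_input(self):
        with pytest.raises(NewickError):
            read_newick(data="((A,B);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick(data="((A:1,A:1):1,B:1);")


class TestMidpointRoot:
    def test_two_tips(self):
        t = read_newick(data="(A:1,B:3);")
        rooted = midpoint_root(t)
        dists = {l.taxon.label: l.distance_from_root()
                 for l in rooted.leaf_node_iter()}
        assert dists["A"] == pytest.approx(2.0)
        assert dists["B"] == pytest.approx(2.0)

    def test_balanced_quartet_centers_internal_edge(self):
        rooted = midpoint_root(read_newick(data=QUARTET))
        assert max_root_tip_distance(rooted) == pytest.approx(2.0)

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            midpoint_root(read_newick(data="(A,B,C);"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_radius(self, seed):
        t = random_tree(20, seed)
        rooted = midpoint_root(t)
        achieved = max_root_tip_distance(rooted)
        oracle = brute_force_midpoint_radius(t, grid=1e-4)
        assert achieved == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", range(3))
    def test_preserves_tip_to_tip_metric(self, seed):
        t = random_tree(10, seed + 50)
        before = {
            frozenset((a.label, b.label)): d
            for a, b, d in _pairwise_distances(t)
        }
        rooted = midpoint_root(t)
        after = {
            frozenset((a.label, b.label)): d
            for a, b, d in _pairwise_distances(rooted)
        }
        for key, d in before.items():
            assert after[key] == pytest.approx(d, abs=1e-9)


def _pairwise_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            yield a, b, pdm.distance(a, b)


class TestMonophyly:
    def test_true_clade(self):
        t = read_newick(data="((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B"})

    def test_split_pair(self):
        t = read_newick(data="((A,B),(C,D));")
        assert not is_monophyletic(t, {"A", "C"})

    def test_all_tips_trivially_monophyletic(self):
        t = read_newick(data="((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B", "C", "D"})

    def test_unknown_tip_rejected(self):
        t = read_newick(data="((A,B),(C,D));")
        with pytest.raises(KeyError):
            is_monophyletic(t, {"A", "Z"})


class TestMonophylyRoots:
    def test_quartet_three_of_five_edges(self):
        t = read_newick(data=QUARTET)
        roots = monophyly_roots(t, {"A", "B"})
        assert len(roots) == 3
        assert len(edge_bipartition_set(t)) == 5

    def test_singleton_all_edges(self):
        t = read_newick(data=QUARTET)
        roots = monophyly_roots(t, {"A"})
        assert roots == edge_bipartition_set(t)

    def test_all_tips_warns_and_returns_all(self):
        t = read_newick(data=QUARTET)
        with pytest.warns(UserWarning):
            roots = monophyly_roots(t, {"A", "B", "C", "D"})
        assert roots == edge_bipartition_set(t)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reroot_and_test_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(int(rng.integers(4, 11)), seed + 100)
        labels = tip_labels(t)
        k = int(rng.integers(1, len(labels)))
        tipset = set(rng.choice(labels, size=k, replace=False))
        assert monophyly_roots(t, tipset) == reroot_and_test_roots(t, tipset)


class TestMinCladeCover:
    def test_clade_is_one(self):
        t = read_newick(data="((A,B),(C,D));")
        assert min_clade_cover(t, {"A", "B"}) == 1

    def test_split_pair_is_two(self):
        t = read_newick(data="((A,B),(C,D));")
        assert min_clade_cover(t, {"A", "C"}) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_greedy_cover_oracle(self, seed):
        rng = np.random.default_rng(seed + 7)
        t = random_tree(int(rng.integers(4, 11)), seed + 200)
        labels = tip_labels(t)
        k = int(rng.integers(1, len(labels) + 1))
        tipset = set(rng.choice(labels, size=k, replace=False))
        assert min_clade_cover(t, tipset) == greedy_clade_cover(t, tipset)

    @pytest.mark.parametrize("seed", range(8))
    def test_cover_one_iff_monophyletic(self, seed):
        rng = np.random.default_rng(seed + 13)
        t = random_tree(8, seed + 300)
        labels = tip_labels(t)
        k = int(rng.integers(1, 9))
        tipset = set(rng.choice(labels, size=k, replace=False))
        assert (min_clade_cover(t, tipset) == 1) == is_monophyletic(t, tipset)


class TestFitch:
    def test_uniform_character_no_changes(self):
        t = read_newick(data=QUARTET)
        assert fitch_fusion_events(t, {l: 1 for l in "ABCD"}) == 0

    def test_alternating_quartet(self):
        t = read_newick(data=QUARTET)
        char = {"A": 1, "B": 0, "C": 1, "D": 0}
        assert fitch_fusion_events(t, char) == 2

    def test_non_binary_state_rejected(self):
        t = read_newick(data=QUARTET)
        with pytest.raises(ValueError, match="binary"):
            fitch_fusion_events(t, {"A": 2, "B": 0, "C": 0, "D": 0})

    def test_incomplete_character_rejected(self):
        t = read_newick(data=QUARTET)
        with pytest.raises(ValueError, match="cover"):
            fitch_fusion_events(t, {"A": 1})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(8, seed + 400)
        char = {l: int(rng.integers(0, 2)) for l in tip_labels(t)}
        assert fitch_fusion_events(t, char) == exhaustive_parsimony(t, char)

    def test_polytomy_accepted(self):
        t = read_newick(data="(A,B,C,(D,E));")
        char = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 1}
        assert fitch_fusion_events(t, char) == exhaustive_parsimony(t, char)

    def test_dollo_counts_gain_plus_losses(self):
        # gain above (A,B,C,D) ancestor, loss on B and C's clade
        t = read_newick(data="(((A,(B,C)),D),E);")
        char = {"A": 1, "B": 0, "C": 0, "D": 1, "E": 0}
        assert fitch_fusion_events(t, char, mode="dollo") == 2  # 1 gain + 1 loss

    def test_dollo_no_fused_tips(self):
        t = read_newick(data=QUARTET)
        assert fitch_fusion_events(t, {l: 0 for l in "ABCD"}, mode="dollo") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_parsimony_score_root_invariant(self, seed):
        from oracles import all_edges_by_bipartition

        t = random_tree(7, seed + 500)
        rng = np.random.default_rng(seed)
        char = {l: int(rng.integers(0, 2)) for l in tip_labels(t)}
        base = fitch_fusion_events(t, char)
        for bipart in all_edges_by_bipartition(t):
            clone = t.clone(depth=1)
            edge = all_edges_by_bipartition(clone)[bipart]
            L = float(edge.length or 0.0)
            clone.reroot_at_edge(edge, length1=L / 2, length2=L / 2,
                                 update_bipartitions=True)
            assert abs(fitch_fusion_events(clone, char) - base) <= 1
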