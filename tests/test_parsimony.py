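"""Parsimony scoring, MPR enumeration, synapomorphy calling, tree search."""

import itertools

import numpy as np
import pytest

from appfam.oracles import (brute_force_mprs, brute_force_parsimony,
                            brute_force_synapomorphies)
from appfam.parsimony import (CharacterColumn, MprSizeError, SynapoEntry,
                              bootstrap_support, consensus,
                              detect_synapomorphies, enumerate_mprs,
                              fitch_score, heuristic_search)
from appfam.simulate import SimulationConfig, simulate_family
from appfam.trees import Node, PhyloTree, read_newick_string, \
    robinson_foulds
from appfam.types import AlignedMatrix

from conftest import random_binary_tree, random_matrix


def all_unrooted_topologies(labels):
    """Every unrooted binary topology, as trees rooted on the first tip's
    edge (3 for 4 taxa, 15 for 5 taxa).

    The first tip is a fixed handle under the root, so each remaining
    rooted edge corresponds to exactly one unrooted edge; inserting the
    next taxon into every such edge enumerates topologies without
    duplicates.
    """
    first, rest = labels[0], labels[1:]
    base = Node()
    base.add_child(Node(label=first))
    base.add_child(Node(label=rest[0]))
    trees = [base]
    for lab in rest[1:]:
        grown = []
        for t in trees:
            n_edges = len([n for n in PhyloTree(t).postorder()
                           if n is not t and n.label != first])
            for i in range(n_edges):
                tree2 = PhyloTree(t).copy()
                edges2 = [n for n in tree2.postorder()
                          if n is not tree2.root and n.label != first]
                target = edges2[i]
                parent = target.parent
                joint = Node()
                parent.children[parent.children.index(target)] = joint
                joint.parent = parent
                joint.add_child(target)
                joint.add_child(Node(label=lab))
                grown.append(tree2.root)
        trees = grown
    return [PhyloTree(r) for r in trees]


class TestFitchScore:
    def test_identical_rows_score_zero(self, quartet_tree):
        m = AlignedMatrix(["1", "2", "3", "4"], ["MKV"] * 4)
        assert fitch_score(quartet_tree, m) == 0

    def test_single_informative_column(self, quartet_tree, quartet_matrix):
        assert fitch_score(quartet_tree, quartet_matrix) == 1

    def test_missing_tip_row_raises(self, quartet_tree):
        m = AlignedMatrix(["1", "2", "3"], ["A", "A", "T"])
        with pytest.raises(KeyError, match="tip"):
            fitch_score(quartet_tree, m)

    def test_gaps_and_x_are_missing_data(self):
        t = read_newick_string("((a,b),(c,d));")
        m = AlignedMatrix(list("abcd"), ["A", "A", "-", "X"])
        assert fitch_score(t, m) == 0

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            m = random_matrix(rng, n, int(rng.integers(3, 12)))
            assert fitch_score(tree, m) == brute_force_parsimony(tree, m)

    def test_polytomies_scored_exactly(self):
        rng = np.random.default_rng(22)
        t = read_newick_string("((a,b,c),(d,e),f);")
        t.assign_ids()
        for _ in range(15):
            m = random_matrix(rng, 6, 8)
            m.row_ids = list("abcdef")
            m._index = {r: i for i, r in enumerate(m.row_ids)}
            assert fitch_score(t, m) == brute_force_parsimony(t, m)

    def test_best_tree_over_all_five_taxon_topologies(self):
        rng = np.random.default_rng(23)
        m = random_matrix(rng, 5, 10, p_gap=0.0)
        m.row_ids = [f"t{i}" for i in range(5)]
        m._index = {r: i for i, r in enumerate(m.row_ids)}
        topos = all_unrooted_topologies(m.row_ids)
        assert len(topos) == 15
        fitch_best = min(fitch_score(t, m) for t in topos)
        brute_best = min(brute_force_parsimony(t, m) for t in topos)
        assert fitch_best == brute_best


class TestEnumerateMprs:
    def test_constant_column_single_mpr(self, quartet_tree):
        col = CharacterColumn(0, {"1": "A", "2": "A", "3": "A", "4": "A"})
        mprs = enumerate_mprs(quartet_tree, col)
        assert len(mprs) == 1
        assert set(mprs[0].values()) == {"A"}

    def test_quartet_count_matches_brute_force(self, quartet_tree,
                                               quartet_matrix):
        col = CharacterColumn.from_matrix(quartet_matrix, 0)
        mine = enumerate_mprs(quartet_tree, col)
        ref = brute_force_mprs(quartet_tree, col)
        as_sets = lambda labs: {frozenset(l.items()) for l in labs}
        assert as_sets(mine) == as_sets(ref)

    def test_cherry_has_two_reconstructions(self):
        t = read_newick_string("(a,b);")
        t.assign_ids()
        col = CharacterColumn(0, {"a": "A", "b": "T"})
        mprs = enumerate_mprs(t, col)
        assert {m[t.root.id] for m in mprs} == {"A", "T"}

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            m = random_matrix(rng, n, 1)
            col = CharacterColumn.from_matrix(m, 0)
            as_sets = lambda labs: {frozenset(l.items()) for l in labs}
            assert as_sets(enumerate_mprs(tree, col)) == \
                as_sets(brute_force_mprs(tree, col))

    def test_large_tree_guard(self):
        rng = np.random.default_rng(1)
        tree = random_binary_tree(rng, [f"t{i}" for i in range(25)])
        col = CharacterColumn(0, {f"t{i}": "A" for i in range(25)})
        with pytest.raises(MprSizeError):
            enumerate_mprs(tree, col)


class TestDetectSynapomorphies:
    def test_requires_rooted_tree(self, quartet_matrix):
        t = read_newick_string("((1,2),(3,4));")
        t.rooted = False
        with pytest.raises(ValueError, match="root"):
            detect_synapomorphies(t, quartet_matrix)

    def test_planted_substitution_found_at_planted_node(self,
                                                        small_bundle):
        tree = small_bundle.tree
        table = detect_synapomorphies(tree, small_bundle.alignment)
        keys = {(e.node_id, e.column, e.derived) for e in table.entries}
        for s in small_bundle.synapomorphies:
            assert (s.node_id, s.column, s.derived) in keys

    def test_cherry_with_outgroup_yields_autapomorphy_only(self):
        t = read_newick_string("((a,b),c);")
        t.assign_ids()
        m = AlignedMatrix(list("abc"), ["A", "T", "A"])
        table = detect_synapomorphies(t, m)
        assert table.entries == []
        assert table.autapomorphy_count == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            tree = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            m = random_matrix(rng, n, 10)
            table = detect_synapomorphies(tree, m)
            mine = {(e.node_id, e.column, e.derived)
                    for e in table.entries}
            assert mine == brute_force_synapomorphies(tree, m)

    def test_invariant_under_tip_order_permutation(self, small_bundle):
        tree = small_bundle.tree
        m = small_bundle.alignment
        perm = list(reversed(m.row_ids))
        m2 = m.subset(perm)
        t1 = detect_synapomorphies(tree, m)
        t2 = detect_synapomorphies(tree, m2)
        key = lambda t: {(e.node_id, e.column, e.ancestral, e.derived)
                         for e in t.entries}
        assert key(t1) == key(t2)

    def test_total_bounded_by_parsimony_length(self, small_bundle):
        tree = small_bundle.tree
        table = detect_synapomorphies(tree, small_bundle.alignment)
        assert table.total <= fitch_score(tree, small_bundle.alignment)

    def test_tsv_round_trip(self, small_bundle, tmp_path):
        table = detect_synapomorphies(small_bundle.tree,
                                      small_bundle.alignment)
        p = tmp_path / "syn.tsv"
        table.write_tsv(p)
        lines = p.read_text().strip().split("\n")
        assert lines[0].startswith("node_id")
        assert len(lines) == table.total + 1


class TestHeuristicSearch:
    def test_four_taxa_finds_exhaustive_optimum(self):
        rng = np.random.default_rng(51)
        for _ in range(5):
            m = random_matrix(rng, 4, 12, p_gap=0.0)
            m.row_ids = list("abcd")
            m._index = {r: i for i, r in enumerate(m.row_ids)}
            topos = all_unrooted_topologies(m.row_ids)
            best = min(fitch_score(t, m) for t in topos)
            res = heuristic_search(m, n_starts=3, seed=1)
            assert res.score == best

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(52)
        m = random_matrix(rng, 8, 40)
        a = heuristic_search(m, n_starts=2, seed=9)
        b = heuristic_search(m, n_starts=2, seed=9)
        assert a.score == b.score
        assert [t.to_newick() for t in a.trees] == \
            [t.to_newick() for t in b.trees]

    def test_recovers_true_tree_under_low_homoplasy(self):
        # equal branch lengths so every internal edge carries signal
        # (~10 expected changes per edge at 0.3 subs/site over the tree)
        from appfam.simulate import evolve_family, simulate_tree
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            tree = simulate_tree(10, seed=100 + seed)
            n_edges = sum(1 for n in tree.postorder()
                          if n is not tree.root)
            for n in tree.postorder():
                if n is not tree.root:
                    n.length = 1.0 / n_edges
            cfg = SimulationConfig(
                n_clades=1, tips_per_clade=10, sequence_length=600,
                rate=0.3, seed=100 + seed, clade_names=("t",),
                add_outgroup=False)
            bundle = evolve_family(tree, cfg)
            res = heuristic_search(bundle.alignment, n_starts=3, seed=seed)
            rf = min(robinson_foulds(bundle.tree, t) for t in res.trees)
            hits += rf == 0
        assert hits >= 0.9 * n_seeds


class TestConsensus:
    def test_single_tree_is_its_own_consensus(self):
        t = read_newick_string("((a,b),(c,d));")
        c = consensus([t])
        assert c.splits() == t.splits()

    def test_shared_clade_survives_with_polytomy(self):
        t1 = read_newick_string("(((A,B),C),(D,E));")
        t2 = read_newick_string("(((A,B),D),(C,E));")
        c = consensus([t1, t2], rule="majority", cutoff=0.5)
        assert c.splits() == {frozenset("CDE")}  # {A,B} as unrooted split

    def test_two_thirds_majority_retained(self):
        t1 = read_newick_string("(((A,B),C),(D,E));")
        t2 = read_newick_string("(((A,B),D),(C,E));")
        c = consensus([t1, t1, t2], rule="majority", cutoff=0.5)
        assert frozenset("DE") in c.splits()

    def test_strict_keeps_only_universal_clades(self):
        t1 = read_newick_string("(((A,B),C),(D,E));")
        t2 = read_newick_string("(((A,B),D),(C,E));")
        c = consensus([t1, t2], rule="strict")
        assert c.splits() == {frozenset("CDE")}

    def test_mismatched_tip_sets_rejected(self):
        t1 = read_newick_string("((a,b),c);")
        t2 = read_newick_string("((a,b),d);")
        with pytest.raises(ValueError, match="tip sets"):
            consensus([t1, t2])


class TestBootstrap:
    def _signal_matrix(self):
        # one orthogonal character block per cherry: the true topology
        # ((t0,t1),(t2,t3),(t4,t5)) is the unique optimum
        blocks = [frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})]
        rows = []
        for taxon in range(6):
            row = ""
            for block in blocks:
                row += ("W" if taxon in block else "A") * 5
            rows.append(row + "A" * 5)
        return AlignedMatrix([f"t{i}" for i in range(6)], rows)

    def test_single_replicate_supports_are_binary(self):
        cons, freqs = bootstrap_support(self._signal_matrix(), n_reps=1,
                                        seed=3)
        assert set(freqs.values()) <= {0.0, 100.0}

    def test_deterministic_for_fixed_seed(self):
        m = self._signal_matrix()
        _, f1 = bootstrap_support(m, n_reps=5, seed=4)
        _, f2 = bootstrap_support(m, n_reps=5, seed=4)
        assert f1 == f2

    def test_clean_signal_gives_full_support(self):
        cons, freqs = bootstrap_support(self._signal_matrix(), n_reps=10,
                                        seed=5)
        cherries = [frozenset({"t0", "t1"}), frozenset({"t2", "t3"}),
                    frozenset({"t4", "t5"})]
        all_tips = frozenset(f"t{i}" for i in range(6))
        anchor = min(all_tips)
        for cherry in cherries:
            side = all_tips - cherry if anchor in cherry else cherry
            assert freqs.get(side, 0.0) == 100.0
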