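import numpy as np
import pytest

import dendropy
from dendropy.calculate import treecompare

from conftest import (
    brute_force_length,
    generic_matrix,
    random_matrix,
    random_topology,
)
from karyophylo import (
    Phylotree,
    bootstrap,
    exhaustive_search,
    fitch_length,
    fitch_steps_per_char,
    heuristic_search,
    majority_rule,
    n_unrooted_topologies,
    robinson_foulds,
    root_on_outgroup,
    strict_consensus,
    tbr_neighbors,
    tree_statistics,
)

TAXA4 = ("A", "B", "C", "D")


class TestFitch:
    def test_quartet_lengths(self, quartet_matrix):
        good = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        bad1 = Phylotree.from_newick("((A,C),(B,D));", taxa=TAXA4)
        bad2 = Phylotree.from_newick("((A,D),(B,C));", taxa=TAXA4)
        assert fitch_length(good, quartet_matrix) == 1
        assert fitch_length(bad1, quartet_matrix) == 2
        assert fitch_length(bad2, quartet_matrix) == 2

    def test_constant_matrix_scores_zero(self):
        m = generic_matrix(np.zeros((4, 5)), taxa=TAXA4)
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        assert fitch_length(t, m) == 0

    def test_missing_states_are_free(self):
        m = generic_matrix([[1], [-1], [0], [-1]], taxa=TAXA4)
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        assert fitch_length(t, m) == 1

    def test_rooting_invariance(self, quartet_matrix):
        unrooted = Phylotree.from_newick("(A,B,(C,D));", taxa=TAXA4)
        rooted = root_on_outgroup(unrooted, ["C", "D"])
        assert fitch_length(unrooted, quartet_matrix) == \
            fitch_length(rooted, quartet_matrix)

    def test_leaf_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, 12)
        t = random_topology(rng, m.taxa)
        base = fitch_length(t, m)
        perm = list(rng.permutation(6))
        relabelled = Phylotree(tuple(m.taxa[i] for i in perm),
                               {u: list(v) for u, v in t.adj.items()})
        m2 = generic_matrix(m.states[perm], taxa=relabelled.taxa)
        assert fitch_length(relabelled, m2) == base

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        m = random_matrix(rng, n, 6, missing_frac=0.15)
        t = random_topology(rng, m.taxa)
        assert fitch_length(t, m) == brute_force_length(t, m)

    def test_per_character_steps_sum_to_length(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 7, 20, missing_frac=0.1)
        t = random_topology(rng, m.taxa)
        steps = fitch_steps_per_char(t, m)
        assert int(steps.sum()) == fitch_length(t, m)

    def test_polytomy_scoring(self, quartet_matrix):
        # a hard polytomy cannot group A+B: both 1-leaves change state
        star = Phylotree.from_newick("(A,B,C,D);", taxa=TAXA4)
        assert fitch_length(star, quartet_matrix) == 2
        resolved = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        assert fitch_length(resolved, quartet_matrix) == 1


class TestExhaustive:
    def test_topology_counts(self):
        assert n_unrooted_topologies(4) == 3
        assert n_unrooted_topologies(8) == 10395

    def test_four_taxa_evaluates_three(self, quartet_matrix):
        res = exhaustive_search(quartet_matrix)
        assert res.search_log["topologies_evaluated"] == 3
        assert res.length == 1
        assert res.n_trees == 1

    def test_refuses_oversized_problems(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 11, 5)
        with pytest.raises(ValueError, match="heuristic"):
            exhaustive_search(m)

    def test_eight_taxa_topology_count(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 8, 10)
        res = exhaustive_search(m)
        assert res.search_log["topologies_evaluated"] == 10395


class TestTBR:
    def test_quartet_neighbors(self):
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        nb = tbr_neighbors(t)
        assert len(nb) == 2
        assert t.topology_key() not in {x.topology_key() for x in nb}

    def test_five_taxa_against_fragment_oracle(self):
        """A topology is one TBR move away iff bisecting one edge in each
        tree can produce the identical pair of fragments."""
        taxa = ("A", "B", "C", "D", "E")
        m = generic_matrix(np.zeros((5, 1)), taxa=taxa)
        all_trees = exhaustive_search(m).mp_trees  # all 15 topologies tie
        base = all_trees[0]

        def fragment_keys(tree):
            n = tree.nleaves
            full = (1 << n) - 1
            out = set()
            for (u, v) in tree.edges():
                side = tree._leafmask_side(v, u)

                def induced(mask):
                    leaves = [i for i in range(n) if mask >> i & 1]
                    sub = set()
                    for s in tree.splits():
                        r = s & mask
                        if 2 <= bin(r).count("1") <= len(leaves) - 2:
                            if r >> leaves[0] & 1:
                                r = mask ^ r
                            sub.add(r)
                    return frozenset(sub)

                out.add(frozenset([(side, induced(side)),
                                   (full ^ side, induced(full ^ side))]))
            return out

        base_frag = fragment_keys(base)
        oracle = {t.topology_key() for t in all_trees
                  if t.topology_key() != base.topology_key()
                  and fragment_keys(t) & base_frag}
        impl = {t.topology_key() for t in tbr_neighbors(base)}
        assert impl == oracle

    def test_input_never_in_neighborhood(self):
        rng = np.random.default_rng(9)
        t = random_topology(rng, [f"t{i}" for i in range(7)])
        assert t.topology_key() not in {x.topology_key()
                                        for x in tbr_neighbors(t)}


class TestHeuristic:
    def test_matches_exhaustive_on_small_problems(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            m = random_matrix(rng, 7, int(rng.integers(15, 30)))
            ex = exhaustive_search(m)
            he = heuristic_search(m, n_addition_replicates=10, seed=seed)
            assert he.length == ex.length
            assert he.topology_keys() == ex.topology_keys()

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(77)
        m = random_matrix(rng, 8, 25)
        a = heuristic_search(m, n_addition_replicates=1, seed=123)
        b = heuristic_search(m, n_addition_replicates=1, seed=123)
        assert a.length == b.length
        assert [t.to_newick() for t in a.mp_trees] == \
            [t.to_newick() for t in b.mp_trees]

    def test_needs_four_taxa(self):
        m = generic_matrix([[0], [1], [1]], taxa=["A", "B", "C"])
        with pytest.raises(ValueError):
            heuristic_search(m, seed=0)


class TestStatistics:
    def test_ci_hi_complement(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = random_matrix(rng, 6, 15)
            res = exhaustive_search(m)
            assert res.ci + res.hi == pytest.approx(1.0, abs=0)

    def test_single_character_two_steps(self):
        # one variable character forced onto a conflicting tree: CI = 1/2
        m = generic_matrix([[1], [0], [1], [0]], taxa=TAXA4)
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        stats = tree_statistics(t, m)
        assert stats["length"] == 2
        assert stats["ci"] == pytest.approx(0.5)

    def test_homoplasy_free_matrix(self):
        m = generic_matrix([[1, 0], [1, 0], [0, 1], [0, 1]], taxa=TAXA4)
        res = exhaustive_search(m)
        assert res.ci == 1.0 and res.hi == 0.0

    def test_zero_length_ci_convention(self):
        m = generic_matrix(np.ones((4, 3)), taxa=TAXA4)
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        stats = tree_statistics(t, m)
        assert stats["ci"] == 1.0 and stats["ri"] is None

    def test_dropping_character_never_lengthens(self):
        rng = np.random.default_rng(31)
        m = random_matrix(rng, 6, 12)
        base = exhaustive_search(m).length
        for c in m.characters:
            assert exhaustive_search(m.drop_character(c.id)).length <= base


class TestConsensusAndRF:
    def test_singleton_consensus(self):
        t = Phylotree.from_newick("((A,B),(C,D),E);",
                                  taxa=("A", "B", "C", "D", "E"))
        assert strict_consensus([t]).splits() == t.splits()

    def test_disjoint_trees_give_star(self):
        taxa = ("A", "B", "C", "D", "E")
        t1 = Phylotree.from_newick("((A,B),C,(D,E));", taxa=taxa)
        t2 = Phylotree.from_newick("((A,D),C,(B,E));", taxa=taxa)
        assert strict_consensus([t1, t2]).splits() == frozenset()

    def test_majority_threshold(self):
        taxa = ("A", "B", "C", "D", "E")
        t1 = Phylotree.from_newick("((A,B),C,(D,E));", taxa=taxa)
        t2 = Phylotree.from_newick("((A,B),E,(C,D));", taxa=taxa)
        t3 = Phylotree.from_newick("((A,D),C,(B,E));", taxa=taxa)
        maj = majority_rule([t1, t2, t3], threshold=0.5)
        names = {frozenset(taxa[i] for i in range(5) if m >> i & 1)
                 for m in maj.splits()}
        assert frozenset({"A", "B"}) in names or \
            frozenset({"C", "D", "E"}) in names
        with pytest.raises(ValueError):
            majority_rule([t1, t2], threshold=0.3)

    def test_rf_basics(self):
        good = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        alt = Phylotree.from_newick("((A,C),(B,D));", taxa=TAXA4)
        assert robinson_foulds(good, good.copy()) == 0
        assert robinson_foulds(good, alt) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_rf_matches_dendropy(self, seed):
        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(8))
        a = random_topology(rng, taxa)
        b = random_topology(rng, taxa)
        ns = dendropy.TaxonNamespace(list(taxa))
        da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                               taxon_namespace=ns)
        db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                               taxon_namespace=ns)
        da.encode_bipartitions()
        db.encode_bipartitions()
        assert robinson_foulds(a, b) == \
            treecompare.symmetric_difference(da, db)

    def test_strict_consensus_matches_dendropy(self):
        rng = np.random.default_rng(4)
        taxa = tuple(f"t{i}" for i in range(7))
        trees = [random_topology(rng, taxa) for _ in range(4)]
        mine = strict_consensus(trees)
        ns = dendropy.TaxonNamespace(list(taxa))
        dlist = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=ns) for t in trees],
            taxon_namespace=ns)
        dcons = dlist.consensus(min_freq=1.0)
        ref = Phylotree.from_dendropy(dcons, taxa=taxa)
        assert mine.splits() == ref.splits()


class TestRooting:
    def test_quartet_outgroup(self):
        t = Phylotree.from_newick("((A,B),(G,T));", taxa=("A", "B", "G", "T"))
        rooted = root_on_outgroup(t, ["G", "T"])
        assert rooted.root_mask is not None

    def test_single_leaf_outgroup(self):
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        rooted = root_on_outgroup(t, ["D"])
        full = (1 << 4) - 1
        mask = rooted.root_mask
        assert mask in (1 << 3, full ^ (1 << 3))

    def test_non_monophyletic_outgroup_warns(self):
        t = Phylotree.from_newick("((A,C),(B,D));", taxa=TAXA4)
        with pytest.warns(UserWarning, match="monophyletic"):
            root_on_outgroup(t, ["A", "B"])

    def test_outgroup_must_be_proper_subset(self):
        t = Phylotree.from_newick("((A,B),(C,D));", taxa=TAXA4)
        with pytest.raises(ValueError):
            root_on_outgroup(t, list(TAXA4))


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 5, 12)
        b = bootstrap(m, replicates=1, seed=4,
                      search={"method": "exhaustive"})
        assert set(b.split_support.values()) <= {0.0, 100.0}

    def test_bitwise_reproducibility(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 6, 15)
        a = bootstrap(m, replicates=50, seed=99)
        b = bootstrap(m, replicates=50, seed=99)
        assert a.split_support == b.split_support
        assert a.consensus.to_newick() == b.consensus.to_newick()

    def test_unanimous_signal_support_matches_binomial(self):
        # 5 of 10 characters mark the same split, the rest are autapomorphies:
        # a replicate recovers the split iff it draws >= 1 informative column,
        # with probability 1 - (1/2)^10 = 0.9990
        grid = np.zeros((6, 10), dtype=np.int8)
        grid[:2, :5] = 1          # split {t0,t1} on 5 columns
        for j in range(5, 10):
            grid[j - 4, j] = 1    # autapomorphies for t1..t5
        m = generic_matrix(grid)
        b = bootstrap(m, replicates=1000, seed=17,
                      search={"method": "exhaustive"})
        expected = 100 * (1 - 0.5 ** 10)
        assert b.support(["t0", "t1"]) >= 99.0
        assert b.support(["t0", "t1"]) == pytest.approx(expected, abs=0.5)

    def test_degenerate_matrix_flagged(self):
        grid = np.zeros((4, 3), dtype=np.int8)
        grid[0, 0] = 1  # single autapomorphy: nothing informative
        m = generic_matrix(grid)
        b = bootstrap(m, replicates=5, seed=1,
                      search={"method": "exhaustive"})
        assert b.degenerate
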