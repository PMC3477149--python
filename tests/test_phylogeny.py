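import numpy as np
import pytest

from gametolog import SimConfig, simulate_gametologs
from gametolog.phylogeny import (DistanceMatrix, PhylogenyError,
                                 bootstrap_nj, classify_informative_sites,
                                 is_monophyletic, nj_tree, ps_distance_matrix,
                                 terminal_branch_ratio)
from oracles import random_additive_tree


def _tree_from_matrix(names, D):
    return nj_tree(DistanceMatrix(names=list(names), d=np.asarray(D)))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        t = _tree_from_matrix("abc", [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        assert t.terminal_branch_length("a") == pytest.approx(0.1)
        assert t.terminal_branch_length("b") == pytest.approx(0.3)
        assert t.terminal_branch_length("c") == pytest.approx(0.5)

    def test_four_taxon_additive_roundtrip(self):
        # tree ((a:1,b:2):0.5,(c:3,d:4)): additive distances recovered exactly
        D = [[0, 3, 4.5, 5.5],
             [3, 0, 5.5, 6.5],
             [4.5, 5.5, 0, 7],
             [5.5, 6.5, 7, 0]]
        t = _tree_from_matrix("abcd", D)
        assert t.bipartitions() == {frozenset({"c", "d"})}
        for pair, d in [("ab", 3), ("ad", 5.5), ("cd", 7)]:
            assert t.path_length(*pair) == pytest.approx(d)

    def test_equal_distances_resolve_deterministically(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = _tree_from_matrix("abcd", D)
        t2 = _tree_from_matrix("abcd", D)
        assert t1.to_newick() == t2.to_newick()
        # tie-break joins the lexicographically smallest index pair first
        assert frozenset({"c", "d"}) in t1.bipartitions() or \
            frozenset({"a", "b"}) in t1.bipartitions()

    def test_undefined_distance_reported(self):
        D = [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]
        with pytest.raises(PhylogenyError, match="a.*b"):
            _tree_from_matrix("abc", D)

    def test_random_additive_trees_recovered_exactly(self, rng):
        # oracle property: NJ is exact on additive matrices
        for _ in range(30):
            n = int(rng.integers(4, 9))
            names, D, true_splits = random_additive_tree(n, rng)
            t = _tree_from_matrix(names, D)
            assert t.bipartitions() == true_splits
            for i in range(n):
                for j in range(i + 1, n):
                    assert t.path_length(names[i], names[j]) == pytest.approx(
                        D[i, j], abs=1e-9)

    def test_agrees_with_dendropy_on_ps_matrix(self):
        # independent NJ implementation recovers the same topology
        dendropy = pytest.importorskip("dendropy")
        aln, _ = simulate_gametologs(SimConfig(n_codons=800, seed=4))
        dm = ps_distance_matrix(aln)
        ours = nj_tree(dm)

        csv = "," + ",".join(dm.names) + "\n"
        for i, n in enumerate(dm.names):
            csv += n + "," + ",".join(f"{x:.10f}" for x in dm.d[i]) + "\n"
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        ref = pdm.nj_tree()
        taxa = frozenset(dm.names)
        refleaf = min(dm.names)
        ref_splits = set()
        for node in ref.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if refleaf in leaves:
                leaves = taxa - leaves
            if 1 < len(leaves) < len(taxa) - 1:
                ref_splits.add(leaves)
        assert ours.bipartitions() == ref_splits


class TestBootstrap:
    def test_unambiguous_clade_gets_full_support(self, write_fasta):
        from gametolog.alignment_io import read_alignment
        base = "GCT" * 60
        div = "GCA" * 60
        path = write_fasta([("a", base), ("b", base), ("c", div), ("d", div)])
        aln = read_alignment(path)
        t = bootstrap_nj(aln, reps=100, seed=1)
        (split,) = t.bipartitions()
        assert t.supports[split] == 100.0

    def test_seed_determinism_and_order_invariance(self):
        aln, _ = simulate_gametologs(SimConfig(n_codons=600, seed=9))
        t1 = bootstrap_nj(aln, reps=50, seed=5)
        t2 = bootstrap_nj(aln, reps=50, seed=5)
        assert t1.supports == t2.supports
        # shuffle taxon order: same supports for the same named splits
        perm = [3, 1, 4, 0, 2]
        from gametolog.alignment_io import CodonAlignment
        shuffled = CodonAlignment(ids=[aln.ids[i] for i in perm],
                                  taxa=[aln.taxa[i] for i in perm],
                                  rows=[aln.rows[i] for i in perm])
        t3 = bootstrap_nj(shuffled, reps=50, seed=5)
        assert set(t3.supports) == set(t1.supports)

    def test_simulated_gametologs_cluster_by_chromosome(self):
        # recombination arrest long before speciation: X and Y clusters
        cfg = SimConfig(n_codons=2000, T_split=2e7, T_arrest=1.8e8, seed=13)
        aln, _ = simulate_gametologs(cfg)
        t = bootstrap_nj(aln, reps=100, seed=3)
        assert is_monophyletic(t, ["EX", "MX"], "OUT")
        assert is_monophyletic(t, ["EY", "MY"], "OUT")
        x_split = frozenset({"EY", "MY", "OUT"})  # complement side of {EX,MX}
        assert t.supports[x_split] >= 95.0


@pytest.fixture(scope="module")
def tree():
    # arrest long before speciation: clean X and Y clusters
    aln, _ = simulate_gametologs(
        SimConfig(n_codons=2000, T_split=5e7, T_arrest=1.8e8, seed=2))
    return nj_tree(ps_distance_matrix(aln))


class TestMonophyly:

    def test_trivial_subsets(self, tree):
        assert is_monophyletic(tree, tree.leaves, "OUT")
        assert is_monophyletic(tree, ["EX"], "OUT")

    def test_conversion_free_topology(self, tree):
        assert is_monophyletic(tree, ["EX", "MX"], "OUT")
        assert is_monophyletic(tree, ["EY", "MY"], "OUT")
        assert not is_monophyletic(tree, ["EX", "MY"], "OUT")

    def test_missing_taxon_is_error(self, tree):
        with pytest.raises(PhylogenyError):
            is_monophyletic(tree, ["EX", "nope"], "OUT")
        with pytest.raises(PhylogenyError):
            is_monophyletic(tree, ["EX"], "nope")


class TestTerminalBranchRatio:
    def test_short_y_branch_signature(self):
        # a converted Y copy sits roughly one-sixth as deep as its ortholog
        # (terminal branches b = 2.75, c = 16.25, a = 5)
        t = _tree_from_matrix("abc", [[0, 7.75, 21.25],
                                      [7.75, 0, 19.0],
                                      [21.25, 19.0, 0]])
        assert terminal_branch_ratio(t, "b", "c") == pytest.approx(2.75 / 16.25, rel=1e-6)
        assert 2.75 / 16.25 == pytest.approx(0.169, abs=5e-4)

    def test_constructed_ratio(self):
        # terminal branches a = 1, b = 2, c = 4
        t = _tree_from_matrix("abc", [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        assert terminal_branch_ratio(t, "a", "c") == pytest.approx(0.25)
        with pytest.raises(PhylogenyError):
            zero = _tree_from_matrix("abc", [[0, 1, 1], [1, 0, 2], [1, 2, 0]])
            terminal_branch_ratio(zero, "b", "a")


class TestInformativeSites:
    def _site(self, ex, ey, mx, my, col=0):
        return (col, (ex, ey, mx, my))

    def test_definitional_classes(self):
        c = classify_informative_sites([self._site("A", "G", "A", "G")])
        assert (c.nA, c.nB, c.nC) == (1, 0, 0)
        c = classify_informative_sites([self._site("A", "A", "G", "G")])
        assert (c.nA, c.nB, c.nC) == (0, 1, 0)
        c = classify_informative_sites([self._site("A", "G", "G", "A")])
        assert (c.nA, c.nB, c.nC) == (0, 0, 1)

    def test_uninformative_sites_skipped(self):
        sites = [self._site("A", "G", "G", "G"),      # singleton
                 self._site("A", "A", "A", "A"),      # constant
                 self._site("A", "C", "G", "T")]      # all distinct
        c = classify_informative_sites(sites)
        assert c.n_informative == 0 and c.n_skipped == 3

    def test_partition_is_exhaustive(self, rng):
        sites = [(i, tuple("ACGT"[b] for b in rng.integers(0, 4, 4)))
                 for i in range(500)]
        c = classify_informative_sites(sites)
        assert c.n_informative + c.n_skipped == 500
        assert sorted(c.positions["A"] + c.positions["B"] + c.positions["C"]) \
            == sorted(set(c.positions["A"] + c.positions["B"] + c.positions["C"]))
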