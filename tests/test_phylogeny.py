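"""Concatenation, distance models, neighbor joining, and bootstrap supports."""

import math

import numpy as np
import pytest

from obgenome.phylogeny import (DistanceMatrix, DistanceModel, GeneAlignment,
                                SaturatedDistanceError, Superalignment,
                                bootstrap_support, concatenate, distance_matrix,
                                model_distance, nj_tree, p_distance,
                                robinson_foulds)

from .oracles import (best_topology_exhaustive, random_additive_tree,
                      tree_split_lengths)


class TestConcatenate:
    def test_two_alignments(self):
        a = GeneAlignment("g1", ["x", "y"], ["A" * 10, "C" * 10])
        b = GeneAlignment("g2", ["x", "y"], ["G" * 20, "T" * 20])
        sup = concatenate([a, b])
        assert sup.length == 30
        assert sup.partitions == {"g1": (1, 10), "g2": (11, 30)}
        assert sup.rows[0] == "A" * 10 + "G" * 20

    def test_single_alignment_identity(self):
        a = GeneAlignment("g", ["x", "y"], ["AC", "GT"])
        sup = concatenate([a])
        assert sup.rows == a.rows and sup.partitions == {"g": (1, 2)}

    def test_row_order_follows_first_alignment(self):
        a = GeneAlignment("g1", ["x", "y"], ["AA", "CC"])
        b = GeneAlignment("g2", ["y", "x"], ["TT", "GG"])
        sup = concatenate([a, b])
        assert sup.rows == ["AAGG", "CCTT"]

    def test_taxon_mismatch_names_offenders(self):
        a = GeneAlignment("g1", ["x", "y"], ["AA", "CC"])
        b = GeneAlignment("g2", ["x", "z"], ["TT", "GG"])
        with pytest.raises(ValueError, match="z"):
            concatenate([a, b])

    def test_simulated_genes_sum_lengths(self):
        from obgenome.simulate import evolve_gene_alignments

        lengths = list(np.random.default_rng(0).integers(50, 150, size=38))
        alns = evolve_gene_alignments("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
                                      [int(x) for x in lengths], seed=2)
        sup = concatenate(alns)
        assert sup.length == sum(lengths) and len(sup.partitions) == 38


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("ACDE", "ACDE") == 0.0

    def test_pairwise_deletion_hand_count(self):
        assert p_distance("AC-T", "AG-T") == pytest.approx(1 / 3)

    def test_gap_in_either_row_drops_column_for_the_pair(self):
        assert p_distance("A-CT", "AG-T") == pytest.approx(0.0)

    def test_no_comparable_columns_error(self):
        with pytest.raises(ValueError):
            p_distance("--", "AA")

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_per_column_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alpha = np.array(list("ACDE-"))
        n = 50
        a = "".join(alpha[rng.integers(0, 5, n)])
        b = "".join(alpha[rng.integers(0, 5, n)])
        comparable = [(x, y) for x, y in zip(a, b) if "-" not in (x, y)]
        if not comparable:
            return
        expect = sum(x != y for x, y in comparable) / len(comparable)
        assert p_distance(a, b) == pytest.approx(expect)


class TestModelDistance:
    @pytest.mark.parametrize("model", [DistanceModel("p"), DistanceModel("poisson"),
                                       DistanceModel("gamma", 1.0),
                                       DistanceModel("jc20")])
    def test_zero_p_is_zero(self, model):
        assert model_distance(0.0, model) == 0.0

    def test_poisson_closed_form(self):
        assert model_distance(1 - math.exp(-1), DistanceModel("poisson")) == \
            pytest.approx(1.0, abs=1e-12)

    def test_gamma_closed_form(self):
        assert model_distance(0.5, DistanceModel("gamma", 1.0)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_p(self):
        ps = np.linspace(0.0, 0.9, 30)
        for model in (DistanceModel("p"), DistanceModel("poisson"),
                      DistanceModel("gamma", 0.7), DistanceModel("jc20")):
            ds = [model_distance(p, model) for p in ps]
            assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_gamma_converges_to_poisson(self):
        for p in (0.1, 0.5, 0.8):
            g = model_distance(p, DistanceModel("gamma", 1e6))
            assert g == pytest.approx(model_distance(p, DistanceModel("poisson")),
                                      rel=1e-4)

    def test_saturation_errors(self):
        with pytest.raises(SaturatedDistanceError):
            model_distance(1.0, DistanceModel("poisson"))
        with pytest.raises(SaturatedDistanceError):
            model_distance(1.0, DistanceModel("gamma", 1.0))

    def test_gamma_requires_shape(self):
        with pytest.raises(ValueError):
            DistanceModel("gamma")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {c.name: ln for c, ln in tree.root.children}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_four_taxon_additive_matrix_exact(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:1))
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        taxa = ["A", "B", "C", "D"]
        # four-point condition: the two largest of the three pair sums are equal
        sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]])
        assert sums[1] == sums[2]
        tree = nj_tree(DistanceMatrix(taxa, d))
        got = tree_split_lengths(tree, taxa)
        assert got[frozenset({"C", "D"})] == pytest.approx(1.0)  # internal edge
        assert got[frozenset({"B", "C", "D"})] == pytest.approx(1.0)  # pendant A
        assert got[frozenset({"B"})] == pytest.approx(2.0)
        assert got[frozenset({"C"})] == pytest.approx(3.0)
        assert got[frozenset({"D"})] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (6, 1), (6, 2), (7, 3),
                                             (8, 4), (8, 5)])
    def test_additive_matrices_recovered_exactly(self, n_taxa, seed):
        """NJ on additive matrices equals the generating tree (topology and
        branch lengths)."""
        taxa = [chr(ord("A") + i) for i in range(n_taxa)]
        d, true_splits, by_split = random_additive_tree(
            taxa, np.random.default_rng(seed))
        tree = nj_tree(DistanceMatrix(taxa, d))
        got = tree_split_lengths(tree, taxa)
        assert set(tree.bipartitions()) == true_splits
        for split, ln in by_split.items():
            assert got[split] == pytest.approx(ln, abs=1e-9)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 10), (6, 11)])
    def test_matches_exhaustive_topology_search(self, n_taxa, seed):
        """On additive matrices NJ agrees with brute-force search over every
        unrooted topology scored by least-squares fit."""
        taxa = [chr(ord("A") + i) for i in range(n_taxa)]
        d, _, _ = random_additive_tree(taxa, np.random.default_rng(seed))
        best_splits, _ = best_topology_exhaustive(taxa, d)
        tree = nj_tree(DistanceMatrix(taxa, d))
        assert set(tree.bipartitions()) == best_splits

    def test_agrees_with_scikit_bio_on_generic_matrix(self):
        """Independent-library cross-check on a non-additive matrix."""
        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        n = 7
        taxa = [chr(ord("A") + i) for i in range(n)]
        m = rng.uniform(0.2, 1.5, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mine = nj_tree(DistanceMatrix(taxa, m)).to_newick()
        theirs = str(skbio_nj(SkbioDM(m, ids=taxa)))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def _cherry_alignment(d: float, n_sites: int, seed: int) -> Superalignment:
    from obgenome.simulate import evolve_alignment

    aln = evolve_alignment(f"(A:{d / 2},B:{d / 2});", n_sites, seed=seed)
    return Superalignment(aln.taxa, aln.rows, {"g": (1, n_sites)})


class TestEstimatorConsistency:
    def test_jc20_inverts_the_simulator_exactly(self):
        """Distance 1.0 between two leaves is recovered by the 20-state
        equal-rates inversion within 3 SE at 10,000 sites."""
        sup = _cherry_alignment(1.0, 10_000, seed=21)
        d = distance_matrix(sup, DistanceModel("jc20")).matrix[0, 1]
        p = distance_matrix(sup, DistanceModel("p")).matrix[0, 1]
        se_p = math.sqrt(p * (1 - p) / 10_000)
        dddp = 1.0 / (1.0 - 20 * p / 19)  # delta-method derivative
        assert abs(d - 1.0) <= 3 * se_p * abs(dddp)

    def test_poisson_unbiased_at_moderate_divergence(self):
        """At d = 0.3 the Poisson correction (large-alphabet limit) is
        unbiased within 3 SE of the sampling noise."""
        sup = _cherry_alignment(0.3, 10_000, seed=22)
        d = distance_matrix(sup, DistanceModel("poisson")).matrix[0, 1]
        p = distance_matrix(sup, DistanceModel("p")).matrix[0, 1]
        se = math.sqrt(p * (1 - p) / 10_000) / (1 - p)
        assert abs(d - 0.3) <= 3 * se


TEN_TAXON_TREE = ("(((A:0.08,B:0.06):0.05,(C:0.09,(D:0.07,E:0.11):0.04):0.06):0.2,"
                  "((F:0.09,(G:0.05,H:0.12):0.07):0.05,(I:0.06,J:0.08):0.06):0.2);")


def _ten_taxon_superalignment(seed: int = 5) -> Superalignment:
    from obgenome.simulate import evolve_gene_alignments

    lengths = np.random.default_rng(1).integers(80, 200, size=38)
    lengths = (lengths * 5000 / lengths.sum()).astype(int).tolist()
    lengths[-1] += 5000 - sum(lengths)
    return concatenate(evolve_gene_alignments(TEN_TAXON_TREE, lengths, seed=seed))


class TestRecoveryAndBootstrap:
    def test_simulated_ten_taxon_topology_recovered(self):
        import dendropy

        sup = _ten_taxon_superalignment()
        tree = nj_tree(distance_matrix(sup, DistanceModel("jc20")))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=TEN_TAXON_TREE, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_strong_deep_split_has_high_support(self):
        sup = _ten_taxon_superalignment()
        tree = bootstrap_support(sup, DistanceModel("jc20"), n_reps=100, seed=9)
        bps = tree.bipartitions()
        deep = bps.get(frozenset("ABCDE")) or bps.get(frozenset("FGHIJ"))
        assert deep is not None and deep.support >= 99.0
        for node in bps.values():
            assert 0.0 <= node.support <= 100.0

    def test_zero_reps_leaves_point_estimate_unsupported(self):
        sup = _ten_taxon_superalignment()
        tree = bootstrap_support(sup, DistanceModel("jc20"), n_reps=0, seed=1)
        assert all(n.support is None for n in tree.bipartitions().values())

    def test_same_seed_reproduces_supports(self):
        sup = _ten_taxon_superalignment()
        t1 = bootstrap_support(sup, DistanceModel("jc20"), n_reps=30, seed=4)
        t2 = bootstrap_support(sup, DistanceModel("jc20"), n_reps=30, seed=4)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_robinson_foulds_zero_on_self(self):
        sup = _ten_taxon_superalignment()
        tree = nj_tree(distance_matrix(sup, DistanceModel("jc20")))
        assert robinson_foulds(tree, tree) == 0
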