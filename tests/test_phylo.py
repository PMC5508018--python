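import numpy as np
import pytest

import oracles
from mlsakit import diversity, phylo
from mlsakit.errors import (
    InsufficientDataError,
    InvalidParameterError,
    SaturationError,
)
from mlsakit.phylo import DistanceMatrix
from mlsakit.seqio import GeneAlignment, SimilarityMatrix

from conftest import random_alignment


def ids_matrix(vals, metric="identity"):
    n = len(vals)
    return SimilarityMatrix(tuple(f"s{i}" for i in range(n)),
                            np.asarray(vals, float), metric)


class TestToDistance:
    def test_closed_forms(self):
        m = ids_matrix([[100.0, 90.0], [90.0, 100.0]])
        d_none = phylo.to_distance(m, "none")
        assert d_none.values[0, 1] == pytest.approx(0.10)
        d_jc = phylo.to_distance(m, "jukes-cantor")
        assert d_jc.values[0, 1] == pytest.approx(0.1073, abs=5e-5)
        assert d_none.values[0, 0] == 0.0

    def test_saturated_similarity_rejected(self):
        m = ids_matrix([[100.0, 20.0], [20.0, 100.0]])
        with pytest.raises(SaturationError):
            phylo.to_distance(m, "jukes-cantor")

    def test_non_identity_metric_rejected(self):
        m = ids_matrix([[100.0, 60.0], [60.0, 100.0]], metric="dDDH")
        with pytest.raises(InvalidParameterError):
            phylo.to_distance(m)


class TestNeighborJoining:
    def test_three_point_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                     float))
        tree = phylo.nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        # path lengths of ((A:1,B:2):1,(C:1,D:1))
        ids = ("A", "B", "C", "D")
        d = np.array([
            [0, 3, 3, 3],
            [3, 0, 4, 4],
            [3, 4, 0, 2],
            [3, 4, 2, 0],
        ], float)
        tree = phylo.nj_tree(DistanceMatrix(ids, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        fitted = tree.path_lengths()
        np.testing.assert_allclose(
            fitted.values, d[np.ix_([0, 1, 2, 3], [0, 1, 2, 3])], atol=1e-9
        )

    def test_ultrametric_two_groups(self):
        ids = ("A", "B", "C", "D")
        d = np.array([
            [0, 1, 4, 4],
            [1, 0, 4, 4],
            [4, 4, 0, 1],
            [4, 4, 1, 0],
        ], float)
        tree = phylo.nj_tree(DistanceMatrix(ids, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 3.0], [3.0, 0]]))
        tree = phylo.nj_tree(dm)
        assert sum(c.length for c in tree.root.children) == pytest.approx(3.0)

    def test_single_taxon_rejected(self):
        with pytest.raises(InsufficientDataError):
            phylo.nj_tree(DistanceMatrix(("A",), np.zeros((1, 1))))

    def test_deterministic_on_ties(self):
        d = np.array([
            [0, 2, 2, 2],
            [2, 0, 2, 2],
            [2, 2, 0, 2],
            [2, 2, 2, 0],
        ], float)
        t1 = phylo.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        t2 = phylo.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        assert t1.to_newick() == t2.to_newick()

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrices_fit_exactly(self, n_taxa):
        """NJ on an additive matrix reproduces the generating path-length
        matrix to numerical precision."""
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dist, _ = oracles.random_additive_matrix(n_taxa, rng)
            ids = tuple(f"T{i}" for i in range(n_taxa))
            tree = phylo.nj_tree(DistanceMatrix(ids, dist))
            fitted = tree.path_lengths()
            order = [fitted.ids.index(s) for s in ids]
            np.testing.assert_allclose(
                fitted.values[np.ix_(order, order)], dist, atol=1e-9
            )

    def test_matches_scikit_bio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        dist, true_bp = oracles.random_additive_matrix(6, rng)
        ids = [f"T{i}" for i in range(6)]
        ours = phylo.nj_tree(DistanceMatrix(tuple(ids), dist))
        ref = skbio.tree.nj(skbio.DistanceMatrix(dist, ids))
        ref_bp = set()
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= 4:
                side = side if "T0" not in side else \
                    frozenset(ids) - side
                ref_bp.add(side)
        ours_named = {
            frozenset(bp) for bp in ours.bipartitions()
        }
        assert ours_named == ref_bp
        assert {frozenset(f"T{i}" for i in bp) for bp in true_bp} == \
            ours_named


class TestBootstrap:
    def _two_group_loci(self):
        # two 3-strain groups differing at 50 of 300 columns
        rng = np.random.default_rng(5)
        base = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 300))
        other = bytearray(base)
        for pos in rng.choice(300, size=50, replace=False):
            other[pos] = {65: 67, 67: 71, 71: 84, 84: 65}[other[pos]]
        def mutate(seq, k, seed):
            r = np.random.default_rng(seed)
            b = bytearray(seq)
            for pos in r.choice(300, size=k, replace=False):
                b[pos] = {65: 71, 67: 84, 71: 65, 84: 67}[b[pos]]
            return bytes(b).decode()
        seqs = {}
        for i in range(3):
            seqs[f"a{i}"] = mutate(base, 3, 10 + i)
        for i in range(3):
            seqs[f"b{i}"] = mutate(bytes(other), 3, 20 + i)
        return [GeneAlignment("g1", seqs)]

    def test_strong_signal_full_support(self):
        tree = phylo.bootstrap_supports(self._two_group_loci(), n_reps=100,
                                        seed=3)
        central = frozenset({"b0", "b1", "b2"})
        supports = {
            frozenset(n.leaf_names()): n.support
            for n in tree.root.walk()
            if n is not tree.root and not n.is_leaf
        }
        matching = [s for bp, s in supports.items()
                    if bp == central or bp == frozenset({"a0", "a1", "a2"})]
        assert matching and all(s == 100 for s in matching)

    def test_single_replicate_supports_binary(self):
        tree = phylo.bootstrap_supports(self._two_group_loci(), n_reps=1,
                                        seed=0)
        sup = [n.support for n in tree.root.walk()
               if n.support is not None]
        assert sup and set(sup) <= {0, 100}

    def test_deterministic_given_seed(self):
        t1 = phylo.bootstrap_supports(self._two_group_loci(), n_reps=25,
                                      seed=9)
        t2 = phylo.bootstrap_supports(self._two_group_loci(), n_reps=25,
                                      seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_zero_replicates_rejected(self):
        with pytest.raises(InvalidParameterError):
            phylo.bootstrap_supports(self._two_group_loci(), n_reps=0)

    def test_signal_free_alignment_reports_no_support(self):
        seqs = {f"s{i}": "ACGT" * 25 for i in range(5)}
        tree = phylo.bootstrap_supports([GeneAlignment("flat", seqs)],
                                        n_reps=20, seed=1)
        internal = [n for n in tree.root.walk()
                    if n is not tree.root and not n.is_leaf]
        assert all(n.support is None for n in internal)


class TestCladesAtThreshold:
    def block(self):
        v = np.full((4, 4), 90.0)
        v[:2, :2] = 98.0
        v[2:, 2:] = 98.0
        np.fill_diagonal(v, 100.0)
        return ids_matrix(v)

    def test_two_blocks(self):
        part = phylo.clades_at_threshold(self.block(), 97.3)
        assert sorted(sorted(c) for c in part.clusters) == \
            [["s0", "s1"], ["s2", "s3"]]

    def test_tiny_threshold_single_cluster(self):
        part = phylo.clades_at_threshold(self.block(), 0.01)
        assert len(part.clusters) == 1

    def test_threshold_bounds(self):
        with pytest.raises(InvalidParameterError):
            phylo.clades_at_threshold(self.block(), 100.1)
        part = phylo.clades_at_threshold(self.block(), 100.0)
        assert len(part.clusters) == 4

    def test_monotone_in_threshold(self, rng):
        aln = random_alignment("x", 8, 100, rng)
        m = diversity.pairwise_identity(aln)
        prev = None
        for thr in (50.0, 70.0, 80.0, 90.0, 99.0):
            part = phylo.clades_at_threshold(m, thr)
            if prev is not None:
                # raising the threshold never merges clusters
                assert len(part.clusters) >= len(prev.clusters)
                for cluster in part.clusters:
                    assert any(cluster <= old for old in prev.clusters)
            prev = part
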