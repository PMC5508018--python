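import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from mlsakit import diversity, mlsa
from mlsakit._genetic_code import SENSE_CODONS
from mlsakit.errors import (
    FrameError,
    InsufficientDataError,
    UndefinedSimilarityError,
)
from mlsakit.phylo import Node, PhyloTree
from mlsakit.seqio import GeneAlignment
from mlsakit.synthetic_data import LocusParams, evolve_locus

from conftest import random_alignment


def aln(*seqs, locus="gyrB"):
    return GeneAlignment(locus, {f"s{i + 1}": s for i, s in enumerate(seqs)})


class TestAlleles:
    @pytest.mark.parametrize(
        "seqs,expected_n,expected_map",
        [
            (["AAA", "AAA", "AAT"], 2, {"s1": 1, "s2": 1, "s3": 2}),
            (["AAA", "AAC", "AAG", "AAT", "ACA"], 5, None),
            (["acgt", "ACGT"], 1, {"s1": 1, "s2": 1}),
        ],
    )
    def test_examples(self, seqs, expected_n, expected_map):
        n, allele_of = diversity.count_alleles(aln(*seqs))
        assert n == expected_n
        if expected_map is not None:
            assert allele_of == expected_map


class TestParsimonyInformative:
    def test_hand_tally(self):
        # col1 {A:2,T:2} informative; col2 constant; col3 singleton T->A
        pi, pct = diversity.parsimony_informative(
            aln("AAT", "AAT", "TAT", "TAA")
        )
        assert pi == 1
        assert pct == 33.3

    def test_all_identical(self):
        pi, pct = diversity.parsimony_informative(aln("ACG", "ACG", "ACG",
                                                      "ACG"))
        assert (pi, pct) == (0, 0.0)

    def test_gap_excluded_from_states(self):
        # column A,A,T,-: T is a singleton once the gap is dropped
        pi, _ = diversity.parsimony_informative(aln("A", "A", "T", "-"))
        assert pi == 0

    def test_single_sequence_rejected(self):
        with pytest.raises(InsufficientDataError):
            diversity.parsimony_informative(aln("ACGT"))

    def test_invariant_under_row_and_column_permutation(self, rng):
        base = random_alignment("x", 8, 60, rng)
        pi0, pct0 = diversity.parsimony_informative(base)
        ids = list(base.sequences)
        for _ in range(5):
            row_perm = rng.permutation(len(ids))
            col_perm = rng.permutation(base.n_columns)
            shuffled = GeneAlignment("x", {
                ids[i]: "".join(base.sequences[ids[i]][c] for c in col_perm)
                for i in row_perm
            })
            assert diversity.parsimony_informative(shuffled) == (pi0, pct0)


class TestMeanGC:
    @pytest.mark.parametrize(
        "seqs,expected",
        [(["GCGC"], 100.0), (["ATAT"], 0.0), (["ATGC", "AT-C"], 41.7)],
    )
    def test_examples(self, seqs, expected):
        assert diversity.mean_gc(aln(*seqs)) == expected


class TestPairwiseIdentity:
    def test_identical(self):
        m = diversity.pairwise_identity(aln("ACGTACGTAC", "ACGTACGTAC"))
        assert m.values[0, 1] == 100.0

    def test_one_mismatch_in_ten(self):
        m = diversity.pairwise_identity(aln("ACGTACGTAC", "ACGTACGTAT"))
        assert m.values[0, 1] == 90.0

    def test_pairwise_deletion_skips_gap_columns(self):
        m = diversity.pairwise_identity(aln("AC-T", "ACGT"))
        assert m.values[0, 1] == 100.0

    def test_no_comparable_columns(self):
        with pytest.raises(UndefinedSimilarityError):
            diversity.pairwise_identity(aln("A-", "-A"))

    def test_symmetry(self, rng):
        m = diversity.pairwise_identity(random_alignment("x", 6, 40, rng))
        np.testing.assert_allclose(m.values, m.values.T)


class TestSimilaritySummary:
    def test_examples(self):
        m = diversity.pairwise_identity(aln("ACGTACGTAC", "ACGTACGTAT"))
        assert diversity.similarity_summary(m) == (90.0, 90.0, 90.0)

    def test_three_values(self, rng):
        from mlsakit.seqio import SimilarityMatrix

        vals = np.array([
            [100.0, 90.0, 95.0],
            [90.0, 100.0, 100.0],
            [95.0, 100.0, 100.0],
        ])
        m = SimilarityMatrix(("a", "b", "c"), vals, "identity")
        assert diversity.similarity_summary(m) == (90.0, 100.0, 95.0)

    def test_single_strain_rejected(self):
        from mlsakit.seqio import SimilarityMatrix

        m = SimilarityMatrix(("a",), np.array([[100.0]]), "identity")
        with pytest.raises(InsufficientDataError):
            diversity.similarity_summary(m)


class TestNeiGojobori:
    def test_identical_sequences_undefined_ratio(self):
        r = diversity.nei_gojobori_kaks(aln("GTTGCA", "GTTGCA"))
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_hand_worked_synonymous_pair(self):
        # GTT/GTA: Val/Val; per-seq S=2, N=4; one synonymous difference
        r = diversity.nei_gojobori_kaks(aln("GTTGCA", "GTAGCA"))
        assert r.ka == 0.0
        assert r.ks == pytest.approx(-0.75 * np.log(1 - 2 / 3), rel=1e-9)
        assert r.ks == pytest.approx(0.8239, abs=1e-4)
        assert r.ratio == 0.0

    def test_nonsynonymous_only_ratio_undefined(self):
        # AAA (Lys) -> GAA (Glu): nonsynonymous, no synonymous signal
        r = diversity.nei_gojobori_kaks(aln("AAAGCT", "GAAGCT"))
        assert r.ka > 0.0 and r.ks == 0.0 and r.ratio is None

    def test_frame_errors(self):
        with pytest.raises(FrameError):
            diversity.nei_gojobori_kaks(aln("ACGTA", "ACGTA"))
        with pytest.raises(FrameError, match="stop"):
            diversity.nei_gojobori_kaks(aln("TAAGCT", "TAAGCT"))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        seq1, seq2 = _mutated_pair(np.random.default_rng(seed), 30)
        got = diversity.nei_gojobori_kaks(aln(seq1, seq2))
        dn, ds = oracles.ng_pairwise(seq1, seq2)
        assert got.ka == pytest.approx(dn, abs=1e-12)
        assert got.ks == pytest.approx(ds, abs=1e-12)


def _mutated_pair(rng, n_codons):
    """Random sense-codon sequence plus a lightly mutated copy (keeps the
    pair far from saturation so Ka/Ks stays defined)."""
    codons1, codons2 = [], []
    for _ in range(n_codons):
        c1 = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        c2 = c1
        if rng.random() < 0.3:
            for _ in range(20):
                pos = rng.integers(3)
                alt = "ACGT"[rng.integers(4)]
                cand = c2[:pos] + alt + c2[pos + 1:]
                if cand not in ("TAA", "TAG", "TGA") and cand != c2:
                    c2 = cand
                    break
        codons1.append(c1)
        codons2.append(c2)
    return "".join(codons1), "".join(codons2)


class TestLocusStats:
    def test_composition_gapless(self, rng):
        a = random_alignment("gyrB", 6, 60, rng)
        st_ = diversity.locus_stats(a, coding=False)
        assert st_.length_min == st_.length_max == 60
        assert st_.pi_pct == diversity.pi_percent(st_.pi_count, 60)
        assert st_.kaks_ratio is None and st_.ka is None

    def test_noncoding_locus_omits_kaks(self, genus_scale_bundle):
        st_ = diversity.locus_stats(genus_scale_bundle.alignments["16S"],
                                    coding=False)
        assert st_.ka is None and st_.ks is None and st_.kaks_ratio is None

    def test_purifying_simulation_stays_below_half(self):
        tree = PhyloTree(Node(children=[
            Node(name="a", length=0.05), Node(name="b", length=0.05),
            Node(name="c", length=0.08),
        ]))
        params = LocusParams("sim", 300, omega=0.1, kappa=2.0)
        for rep in range(10):
            a = evolve_locus(tree, params, seed=100 + rep)
            r = diversity.nei_gojobori_kaks(a)
            assert r.ratio is not None and r.ratio < 0.5


class TestConcatenationIdentity:
    def test_weighted_mean_of_per_locus_identities(self, rng):
        """On gapless data, concatenated identity equals the
        column-weighted mean of per-locus identities exactly."""
        loci = [random_alignment(f"g{k}", 4, 30 + 10 * k, rng)
                for k in range(3)]
        whole = diversity.pairwise_identity(
            mlsa.concatenate(loci), "complete-deletion"
        )
        lens = np.array([a.n_columns for a in loci], float)
        per = np.stack([
            diversity.pairwise_identity(a, "complete-deletion").values
            for a in loci
        ])
        expected = np.tensordot(lens / lens.sum(), per, axes=1)
        np.fill_diagonal(expected, 100.0)
        np.testing.assert_allclose(whole.values, expected, atol=1e-9)
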