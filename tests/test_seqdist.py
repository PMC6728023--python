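import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import brute_force_nw
from metadendro.io_formats import Alphabet, SequenceRecord
from metadendro.seqdist import (
    GapPenalty,
    common_markers,
    distance_matrix_gene,
    load_matrix,
    max_score,
    nw_score,
    organism_pair_distance,
    p_distance,
)

NUC = load_matrix("NUC")
B62 = load_matrix("BLOSUM62")
GAP = GapPenalty()


def nrec(seq, org="x", marker="RIBO", copy=1):
    return SequenceRecord(org, marker, seq, copy, Alphabet.NUCLEOTIDE)


def arec(seq, org="x", marker="EC:1.1.1.1", copy=1):
    return SequenceRecord(org, marker, seq, copy, Alphabet.AMINO_ACID)


class TestSubstitutionMatrices:
    def test_nuc_scheme(self):
        assert NUC.score("A", "A") == 5
        assert NUC.score("A", "C") == -4

    def test_blosum_symmetric_with_self_scores(self):
        for x in "ACDEFGHIKLMNPQRSTVWY":
            for y in "ACDEFGHIKLMNPQRSTVWY":
                assert B62.score(x, y) == B62.score(y, x)
            assert B62.score(x, x) > 0

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="not scored"):
            NUC.score("A", "J")

    def test_unknown_matrix_name(self):
        with pytest.raises(ValueError, match="unknown substitution matrix"):
            load_matrix("BLOSUM55")


class TestNwScore:
    def test_identical_sequences_all_matches(self):
        a = nrec("ACGT")
        assert nw_score(a, a, NUC) == 20.0

    def test_matches_exhaustive_enumeration_on_example(self):
        a, b = nrec("ACGT"), nrec("AGT")
        expected = brute_force_nw("ACGT", "AGT", NUC.score, 10.0, 0.5)
        assert expected == 4.5  # 3 matches (15) minus one gap of length 1 (10.5)
        assert nw_score(a, b, NUC) == expected

    def test_matches_enumeration_on_random_short_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            la, lb = rng.integers(1, 7, size=2)
            sa = "".join(rng.choice(list("AC"), size=la))
            sb = "".join(rng.choice(list("AC"), size=lb))
            expected = brute_force_nw(sa, sb, NUC.score, 10.0, 0.5)
            assert nw_score(nrec(sa), nrec(sb), NUC) == pytest.approx(expected)

    def test_agrees_with_reference_aligner(self):
        # independent cross-check against biopython's global affine aligner
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.5
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            la, lb = rng.integers(5, 40, size=2)
            sa = "".join(rng.choice(aas, size=la))
            sb = "".join(rng.choice(aas, size=lb))
            assert nw_score(arec(sa), arec(sb), B62) == pytest.approx(aligner.score(sa, sb))

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            nw_score(nrec("ACGT"), arec("MKV"), NUC)


class TestPDistance:
    def test_zero_for_identical(self):
        a = nrec("ACGTACGT")
        assert p_distance(a, a, NUC) == 0.0

    def test_max_score_is_min_of_self_scores(self):
        assert max_score(nrec("ACGT"), nrec("AGT"), NUC) == 15.0
        assert max_score(nrec("AAAA"), nrec("AAAA"), NUC) == 20.0

    def test_can_exceed_one_for_all_mismatch(self):
        # all-mismatch alignment is optimal: any gap pair costs 21 > 9 saved
        assert p_distance(nrec("AAAA"), nrec("CCCC"), NUC) == pytest.approx(1.8)

    def test_derived_from_oracle_for_unequal_lengths(self):
        s = brute_force_nw("ACGT", "AGT", NUC.score, 10.0, 0.5)
        assert p_distance(nrec("ACGT"), nrec("AGT"), NUC) == pytest.approx(1 - s / 15.0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_self_distance_always_zero(self, seq):
        a = nrec(seq)
        assert p_distance(a, a, NUC) == 0.0

    def test_monotone_in_mismatches(self):
        base = "ACGTACGTACGT"
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        prev = -1.0
        for k in range(len(base) + 1):
            mutated = "".join(flip[c] if i < k else c for i, c in enumerate(base))
            p = p_distance(nrec(base), nrec(mutated), NUC)
            assert p >= prev
            prev = p


class TestOrganismPairDistance:
    def test_singletons_equal_p_distance(self):
        a, b = nrec("ACGTACGT"), nrec("ACGGACGT")
        assert organism_pair_distance([a], [b], NUC) == p_distance(a, b, NUC)

    def test_best_match_picks_identical_copy(self):
        s = nrec("ACGTACGT")
        t = nrec("TTTTTTTTTTTT")
        assert organism_pair_distance([s], [s, t], NUC) == 0.0

    def test_matches_brute_force_minima(self, rng):
        seqsA = [nrec("".join(rng.choice(list("ACGT"), size=10)), copy=i + 1) for i in range(2)]
        seqsB = [nrec("".join(rng.choice(list("ACGT"), size=10)), org="y", copy=i + 1) for i in range(3)]
        expected = np.mean(
            [min(p_distance(x, y, NUC) for y in seqsB) for x in seqsA]
        )
        assert organism_pair_distance(seqsA, seqsB, NUC) == pytest.approx(expected)

    def test_symmetric_under_argument_order(self, rng):
        seqsA = [nrec("".join(rng.choice(list("ACGT"), size=12)), copy=i + 1) for i in range(2)]
        seqsB = [nrec("".join(rng.choice(list("ACGT"), size=12)), org="y", copy=i + 1) for i in range(3)]
        assert organism_pair_distance(seqsA, seqsB, NUC) == pytest.approx(
            organism_pair_distance(seqsB, seqsA, NUC)
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            organism_pair_distance([], [nrec("ACGT")], NUC)


class TestGeneMatrices:
    def test_common_markers_excludes_ribo(self, small_bundle):
        ds = small_bundle.dataset
        orgs = small_bundle.organisms
        common = common_markers(orgs, ds)
        assert "RIBO" not in common
        assert "EC:1.1.1.1" in common  # family 1 is universal by construction
        # independent recomputation via raw intersection
        expected = set.intersection(
            *[{m for m in ds.markers_of(o) if m != "RIBO"} for o in orgs]
        )
        assert common == expected

    def test_identical_organisms_give_zero_matrix(self, small_bundle):
        from metadendro.io_formats import Dataset

        ds = Dataset()
        for org in ("aaa", "bbb", "ccc"):
            ds.add_record(nrec("ACGTACGT", org=org))
            ds.add_record(arec("MKVLL", org=org, marker="EC:1.1.1.1"))
        for method in ("DRIBO", "DENZS"):
            D = distance_matrix_gene(["aaa", "bbb", "ccc"], ds, method)
            assert np.array_equal(D.values, np.zeros((3, 3)))

    def test_d1enz_equals_denzs_with_single_common_ec(self):
        from metadendro.io_formats import Dataset

        ds = Dataset()
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for org in ("aaa", "bbb", "ccc"):
            ds.add_record(arec("".join(rng.choice(aas, size=20)), org=org, marker="EC:1.1.1.1"))
        d1 = distance_matrix_gene(["aaa", "bbb", "ccc"], ds, "D1ENZ", rng=np.random.default_rng(0))
        de = distance_matrix_gene(["aaa", "bbb", "ccc"], ds, "DENZS")
        assert np.array_equal(d1.values, de.values)

    def test_denzs_is_mean_of_per_ec_matrices(self):
        from metadendro.io_formats import Dataset

        rng = np.random.default_rng(4)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        markers = ("EC:1.1.1.1", "EC:2.2.2.2")
        ds_both = Dataset()
        singles = {mk: Dataset() for mk in markers}
        for org in ("aaa", "bbb", "ccc", "ddd"):
            for mk in markers:
                rec = arec("".join(rng.choice(aas, size=25)), org=org, marker=mk)
                ds_both.add_record(rec)
                singles[mk].add_record(rec)
        orgs = ["aaa", "bbb", "ccc", "ddd"]
        combined = distance_matrix_gene(orgs, ds_both, "DENZS")
        per_ec = [distance_matrix_gene(orgs, singles[mk], "DENZS").values for mk in markers]
        assert np.allclose(combined.values, np.mean(per_ec, axis=0))

    def test_matrices_symmetric_zero_diagonal(self, small_bundle):
        rng = np.random.default_rng(0)
        for method in ("DRIBO", "DENZS", "D1ENZ"):
            D = distance_matrix_gene(
                small_bundle.organisms, small_bundle.dataset, method, rng=rng
            )
            assert np.array_equal(D.values, D.values.T)
            assert np.all(np.diag(D.values) == 0)

    def test_missing_ribo_error_names_organism(self):
        from metadendro.io_formats import Dataset

        ds = Dataset()
        ds.add_record(nrec("ACGT", org="aaa"))
        ds.add_record(nrec("ACGT", org="bbb"))
        ds.add_record(arec("MKV", org="ccc"))
        with pytest.raises(ValueError, match="ccc"):
            distance_matrix_gene(["aaa", "bbb", "ccc"], ds, "DRIBO")
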