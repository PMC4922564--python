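import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import gotoh_global, smith_waterman_local
from isofam._tables import AMINO_ACIDS
from isofam.evidence import (EvidenceError, EvidenceMatrix,
                             active_site_blosum62, active_site_identity,
                             global_alignment_score, local_alignment_score,
                             matrix_correlation, normalize_matrix,
                             scalar_difference_matrix,
                             sequence_derived_properties,
                             shared_annotation_matrix, vector_distance_matrix)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestAlignmentScores:
    def test_global_identity_no_gaps(self):
        # BLOSUM62 diagonal: K=5, A=4, W=11
        assert global_alignment_score("KAW", "KAW") == 20

    def test_self_score_is_sum_of_diagonal(self):
        seq = "MKVLWAYF"
        expected = sum(float(BLOSUM62[c, c]) for c in seq)
        assert global_alignment_score(seq, seq) == expected

    def test_local_block_match(self):
        assert local_alignment_score("KAW", "GKAWG") == 20

    def test_local_floor_zero(self):
        # no positive-scoring residue pair between these
        assert local_alignment_score("W", "P") == 0.0

    def test_symmetry(self):
        a, b = "MKVLW", "MKIW"
        assert global_alignment_score(a, b) == global_alignment_score(b, a)

    def test_empty_sequence_errors(self):
        with pytest.raises(EvidenceError, match="empty"):
            global_alignment_score("", "KAW")

    def test_unknown_residue_errors_by_default(self):
        with pytest.raises(EvidenceError, match="unknown residue"):
            global_alignment_score("KAZ", "KAW")

    def test_unknown_residue_as_x_scores_zero(self):
        # B replaced by X scoring 0: K/K + 0 + W/W
        assert global_alignment_score("KZW", "KAW", on_unknown="x") == 16

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(42)
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(50):
            la, lb = rng.integers(1, 31, size=2)
            a = "".join(rng.choice(letters, la))
            b = "".join(rng.choice(letters, lb))
            assert global_alignment_score(a, b) == pytest.approx(
                gotoh_global(a, b, BLOSUM62), abs=1e-9)
            assert local_alignment_score(a, b) == pytest.approx(
                smith_waterman_local(a, b, BLOSUM62), abs=1e-9)


class TestActiveSiteComparisons:
    @pytest.mark.parametrize("a, b, expected", [
        ("KGDIF", "KGDIF", 100.0),
        ("KGDI-", "KGDIF", 100.0),   # gap column excluded entirely
        ("KC", "RC", 50.0),
    ])
    def test_identity(self, a, b, expected):
        assert active_site_identity(a, b) == expected

    @pytest.mark.parametrize("a, b, expected", [
        ("KC", "KC", 14.0),   # K/K=5 + C/C=9
        ("KC", "RC", 11.0),   # K/R=2 + C/C=9
    ])
    def test_blosum_score(self, a, b, expected):
        assert active_site_blosum62(a, b) == expected

    def test_all_gap_columns_warn_and_score_zero(self):
        with pytest.warns(UserWarning, match="no comparable"):
            assert active_site_blosum62("--", "AA") == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(EvidenceError, match="widths"):
            active_site_identity("KC", "KCD")

    def test_symmetry(self):
        assert active_site_identity("KCD-", "RCDA") == \
            active_site_identity("RCDA", "KCD-")
        assert active_site_blosum62("KCDI", "RCDL") == \
            active_site_blosum62("RCDL", "KCDI")


class TestPropertyMatrices:
    def test_scalar_differences(self):
        m = scalar_difference_matrix({"a": 10, "b": 10, "c": 30},
                                     ["a", "b", "c"], "difMolWeight")
        iu = np.triu_indices(3, 1)
        assert sorted(m.values[iu]) == [0, 20, 20]
        assert m.orientation == "distance"

    def test_scalar_missing_value_masks_pairs(self):
        m = scalar_difference_matrix({"a": 1.0, "c": 2.0},
                                     ["a", "b", "c"], "difGRAVY")
        assert m.missing[0, 1] and m.missing[1, 2] and not m.missing[0, 2]

    @pytest.mark.parametrize("metric, expected", [
        ("euclidean", 5.0), ("squared-euclidean", 25.0)])
    def test_vector_distances(self, metric, expected):
        m = vector_distance_matrix({"a": [0, 0], "b": [3, 4]},
                                   ["a", "b"], "csmDist", metric=metric)
        assert m.values[0, 1] == expected

    def test_vector_length_mismatch_errors(self):
        with pytest.raises(EvidenceError, match="differing lengths"):
            vector_distance_matrix({"a": [0], "b": [1, 2]}, ["a", "b"], "x")

    def test_shared_annotations(self):
        m = shared_annotation_matrix(
            {"a": {"x", "y", "z"}, "b": {"y", "z", "w"}, "c": set()},
            ["a", "b", "c"], "interpro")
        assert m.values[0, 1] == 2 and m.values[0, 2] == 0
        assert m.values[0, 0] == 3  # |A n A| = |A|


class TestSequenceDerivedProperties:
    def test_class_percentages(self):
        rec = sequence_derived_properties("AAAA")
        assert rec["aliphatic"] == 100.0 and rec["aromatic"] == 0.0

    def test_glycine_molecular_weight(self):
        # residue mass of G (57.05) + one water (18.02), average masses
        rec = sequence_derived_properties("G")
        assert rec["molWeight"] == pytest.approx(75.07, abs=0.05)

    def test_gravy_is_mean_hydropathy(self):
        from Bio.SeqUtils.ProtParamData import kd

        rec = sequence_derived_properties("AILV")
        assert rec["gravy"] == pytest.approx(
            np.mean([kd[c] for c in "AILV"]), abs=1e-9)

    def test_composition_is_dayhoff_normalized(self):
        from isofam._tables import DAYHOFF_FREQ_PERCENT

        rec = sequence_derived_properties("AC")
        comp = dict(zip(AMINO_ACIDS, rec["composition"]))
        assert comp["A"] == pytest.approx(50.0 / DAYHOFF_FREQ_PERCENT["A"])
        assert comp["W"] == 0.0


class TestNormalization:
    def _matrix(self, tri, orientation="similarity", missing=None):
        n = 3
        values = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        values[iu] = tri
        values = values + values.T
        return EvidenceMatrix(name="x", ids=["a", "b", "c"], values=values,
                              orientation=orientation, missing=missing)

    def test_distance_like_is_reversed(self):
        m = normalize_matrix(self._matrix([0, 2, 4], orientation="distance"))
        iu = np.triu_indices(3, 1)
        assert sorted(m.values[iu]) == [0.0, 0.5, 1.0]
        assert m.values[0, 1] == 1.0  # raw distance 0 -> max similarity
        assert m.orientation == "similarity" and m.normalized

    def test_negative_values_map_to_symmetric_interval(self):
        m = normalize_matrix(self._matrix([-3, -1, 1]))
        iu = np.triu_indices(3, 1)
        assert sorted(m.values[iu]) == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        m = normalize_matrix(self._matrix([1, 5, 9], orientation="distance"))
        again = normalize_matrix(m)
        np.testing.assert_allclose(again.values, m.values)

    def test_constant_matrix_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            m = normalize_matrix(self._matrix([2, 2, 2]))
        assert (m.values == 0).all()

    def test_missing_entries_become_minimum_similarity(self):
        missing = np.zeros((3, 3), dtype=bool)
        missing[0, 1] = missing[1, 0] = True
        m = normalize_matrix(self._matrix([99.0, 2, 4], missing=missing))
        assert m.values[0, 1] == 0.0  # imputed, not taken from raw 99
        assert m.values[1, 2] == 1.0

    def test_diagonal_set_to_max_similarity(self):
        m = normalize_matrix(self._matrix([1, 2, 3], orientation="distance"))
        assert (np.diag(m.values) == 1.0).all()


class TestMatrixCorrelation:
    def _pair(self, tri_a, tri_b):
        def make(tri):
            values = np.zeros((3, 3))
            iu = np.triu_indices(3, 1)
            values[iu] = tri
            return EvidenceMatrix(name="m", ids=["a", "b", "c"],
                                  values=values + values.T)
        return make(tri_a), make(tri_b)

    def test_self_correlation_is_one(self):
        a, _ = self._pair([1, 2, 3], [1, 2, 3])
        assert matrix_correlation(a, a) == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self):
        a, b = self._pair([1, 2, 3], [-1, -2, -3])
        assert matrix_correlation(a, b) == pytest.approx(-1.0)

    def test_constant_matrix_errors(self):
        a, b = self._pair([1, 2, 3], [5, 5, 5])
        with pytest.raises(EvidenceError, match="variance"):
            matrix_correlation(a, b)
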