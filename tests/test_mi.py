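import math

import numpy as np
import pytest

from conftest import brute_force_partial_mi
from isofam._tables import AMINO_ACIDS
from isofam.mi import (MIError, cluster_profile_matrix, overall_mi, pmi,
                       position_cluster_mi, rank_discriminative_residues,
                       residue_cluster_mi)
from isofam.pockets import ActiveSiteAlignment
from isofam.spectral import ClusterAssignment


def _msa_from_columns(*columns):
    """Build an alignment from per-position residue strings (one char/protein)."""
    n = len(columns[0])
    return ActiveSiteAlignment(rows={
        f"p{i}": "".join(col[i] for col in columns) for i in range(n)})


def _labels(groups):
    labels = {}
    for c, members in enumerate(groups, start=1):
        for pid in members:
            labels[pid] = c
    return ClusterAssignment(labels=labels, k=len(groups))


FOUR = _labels([("p0", "p1"), ("p2", "p3")])


class TestPMI:
    def test_independence_gives_zero(self):
        assert pmi(0.25, 0.5, 0.5) == 0.0

    def test_positive_association(self):
        assert pmi(0.5, 0.5, 0.5) == pytest.approx(math.log(2))

    def test_negative_association(self):
        assert pmi(0.1, 0.5, 0.5) < 0

    def test_zero_joint_gives_neg_inf(self):
        assert pmi(0.0, 0.5, 0.5) == -math.inf

    def test_invalid_probability_errors(self):
        with pytest.raises(MIError):
            pmi(1.5, 0.5, 0.5)
        with pytest.raises(MIError, match="positive"):
            pmi(0.1, 0.0, 0.5)


class TestResidueClusterMI:
    def test_exclusive_residue(self):
        msa = _msa_from_columns("AACC")
        assert residue_cluster_mi(msa, FOUR, 0, 1, "A") == pytest.approx(
            math.log(2))

    def test_cluster_independent_residue_scores_zero(self):
        msa = _msa_from_columns("ACAC")
        assert residue_cluster_mi(msa, FOUR, 0, 1, "A") == 0.0

    def test_shared_residue_hand_value(self):
        # column A,A,A,C: MI(c1,A) = 1*ln(4/3) + 0.5*ln(2/3)
        msa = _msa_from_columns("AAAC")
        expected = math.log(4 / 3) + 0.5 * math.log(2 / 3)
        assert residue_cluster_mi(msa, FOUR, 0, 1, "A") == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.0850, abs=1e-4)

    def test_cluster_gapped_at_position_scores_zero(self):
        msa = _msa_from_columns("--CC")
        assert residue_cluster_mi(msa, FOUR, 0, 1, "C") == 0.0

    def test_agrees_with_probability_table_oracle(self):
        rng = np.random.default_rng(7)
        alphabet = np.array(list(AMINO_ACIDS[:4] + "-"))
        for _ in range(100):
            n = int(rng.integers(4, 13))
            width = int(rng.integers(1, 4))
            rows = ["".join(rng.choice(alphabet, width)) for _ in range(n)]
            msa = ActiveSiteAlignment(rows={f"p{i}": rows[i] for i in range(n)})
            k = int(rng.integers(2, 4))
            raw = rng.integers(0, k, size=n)
            raw[:k] = np.arange(k)  # ensure non-empty clusters
            labels = ClusterAssignment(
                labels={f"p{i}": int(raw[i]) + 1 for i in range(n)}, k=k)
            p = int(rng.integers(0, width))
            c = int(rng.integers(1, k + 1))
            r = str(rng.choice(list(AMINO_ACIDS[:4])))
            assert residue_cluster_mi(msa, labels, p, c, r) == pytest.approx(
                brute_force_partial_mi(msa, labels, p, c, r), abs=1e-9)

    def test_opposite_sign_property(self):
        # whenever both PMIs are finite they have opposite signs
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = 12
            col = rng.choice(list("ACDE"), n)
            raw = rng.integers(0, 2, size=n)
            raw[:2] = [0, 1]
            rows = [(int(raw[i]) + 1, col[i]) for i in range(n)]
            total = n
            for c in (1, 2):
                for r in set(col):
                    n_c = sum(1 for cc, _ in rows if cc == c)
                    n_r = sum(1 for _, rr in rows if rr == r)
                    c_in = sum(1 for cc, rr in rows if cc == c and rr == r)
                    c_out = n_r - c_in
                    if c_in == 0 or c_out == 0 or n_c in (0, total):
                        continue
                    pmi_in = math.log((c_in / total) / ((n_c / total) * (n_r / total)))
                    pmi_out = math.log(
                        (c_out / total) / (((total - n_c) / total) * (n_r / total)))
                    if pmi_in != 0:
                        assert pmi_in * pmi_out < 0 or pmi_out == 0


class TestPositionClusterMI:
    def test_single_exclusive_residue(self):
        msa = _msa_from_columns("AACC")
        assert position_cluster_mi(msa, FOUR, 0, 1) == pytest.approx(math.log(2))

    def test_mixed_cluster_frequency_weighting(self):
        # column A,A,A,C cluster c2: f_C = 0.5, MI(c2,C) = 0.5*ln2
        msa = _msa_from_columns("AAAC")
        assert position_cluster_mi(msa, FOUR, 0, 2) == pytest.approx(
            0.5 * (0.5 * math.log(2)), abs=1e-12)

    def test_uniform_column_scores_zero(self):
        msa = _msa_from_columns("AAAA")
        assert position_cluster_mi(msa, FOUR, 0, 1) == 0.0

    def test_outer_weighting_can_be_disabled(self):
        msa = _msa_from_columns("AAAC")
        weighted = position_cluster_mi(msa, FOUR, 0, 2)
        unweighted = position_cluster_mi(msa, FOUR, 0, 2,
                                         weight_by_frequency=False)
        assert unweighted == pytest.approx(2 * weighted)


class TestOverallMI:
    def test_single_position_two_clusters(self, four_protein_msa,
                                          two_cluster_labels):
        report = overall_mi(four_protein_msa, two_cluster_labels)
        assert report.overall == pytest.approx(math.log(2))
        assert report.unnormalized_sum == pytest.approx(2 * math.log(2))

    @pytest.mark.parametrize("c", [2, 3, 5])
    @pytest.mark.parametrize("p", [1, 10])
    def test_closed_form_ln_c(self, c, p):
        # C equal-size clusters, every position has a cluster-exclusive residue
        size = 3
        residues = AMINO_ACIDS[:c]
        cols = ["".join(residues[j] * size for j in range(c))] * p
        msa = _msa_from_columns(*cols)
        labels = _labels([tuple(f"p{j * size + i}" for i in range(size))
                          for j in range(c)])
        report = overall_mi(msa, labels)
        assert report.overall == pytest.approx(math.log(c), abs=1e-12)

    def test_identical_column_contributes_zero(self):
        msa = _msa_from_columns("AACC", "GGGG")
        report = overall_mi(msa, FOUR)
        assert report.per_position_cluster[(1, 1)] == 0.0
        assert report.overall == pytest.approx(math.log(2) / 2)

    def test_invariant_under_relabeling_and_reordering(self):
        msa = _msa_from_columns("AACC", "AGCG", "DDDE")
        swapped = _labels([("p2", "p3"), ("p0", "p1")])
        assert overall_mi(msa, FOUR).overall == pytest.approx(
            overall_mi(msa, swapped).overall)

    def test_zero_when_frequencies_identical_across_clusters(self):
        msa = _msa_from_columns("ACAC", "GWGW")
        assert overall_mi(msa, FOUR).overall == 0.0

    def test_all_partial_terms_nonnegative(self):
        rng = np.random.default_rng(5)
        col = "".join(rng.choice(list("ACD-"), 12))
        msa = _msa_from_columns(col)
        labels = _labels([tuple(f"p{i}" for i in range(6)),
                          tuple(f"p{i}" for i in range(6, 12))])
        report = overall_mi(msa, labels)
        assert report.overall >= 0
        assert all(v >= 0 for v, _ in report.per_residue.values())

    def test_alignment_must_cover_labeled_proteins(self, two_cluster_labels):
        msa = ActiveSiteAlignment(rows={"p1": "A"})
        with pytest.raises(MIError, match="lacks rows"):
            overall_mi(msa, two_cluster_labels)


class TestSDPRanking:
    def test_planted_sdp_ranks_first(self):
        # position 0 separates clusters perfectly; others are uniform
        msa = _msa_from_columns("AACC", "GGGG", "WWWW")
        report = overall_mi(msa, FOUR)
        ranked_1 = rank_discriminative_residues(report, 1)
        ranked_2 = rank_discriminative_residues(report, 2)
        assert ranked_1[0][0].startswith("A1")
        assert ranked_2[0][0].startswith("C1")

    def test_uniform_alignment_gives_empty_ranking(self):
        msa = _msa_from_columns("AAAA", "CCCC")
        report = overall_mi(msa, FOUR)
        assert rank_discriminative_residues(report, 1) == []

    def test_structure_number_rendering(self):
        msa = _msa_from_columns("AACC")
        report = overall_mi(msa, FOUR)
        ranked = rank_discriminative_residues(report, 1,
                                              position_labels={0: 523})
        assert ranked[0][0] == "A1_523"

    def test_ties_break_by_position_then_residue(self):
        msa = _msa_from_columns("AACC", "AACC")
        report = overall_mi(msa, FOUR)
        labels_only = [label for label, _ in
                       rank_discriminative_residues(report, 1)]
        assert labels_only == ["A1", "A2"]


class TestClusterProfiles:
    def test_identical_rows_give_one_hot(self):
        msa = _msa_from_columns("AACC", "KKRR")
        profiles = cluster_profile_matrix(msa, FOUR)
        assert profiles[1][0, AMINO_ACIDS.index("A")] == 1.0
        assert profiles[2][1, AMINO_ACIDS.index("R")] == 1.0

    def test_columns_sum_to_one(self):
        msa = _msa_from_columns("AAC-", "K-RR")
        profiles = cluster_profile_matrix(msa, FOUR)
        for mat in profiles.values():
            np.testing.assert_allclose(mat.sum(axis=1), 1.0)

    def test_split_frequencies(self):
        msa = _msa_from_columns("AACC", "KRWW")
        profiles = cluster_profile_matrix(msa, FOUR)
        assert profiles[1][1, AMINO_ACIDS.index("K")] == 0.5
        assert profiles[1][1, AMINO_ACIDS.index("R")] == 0.5
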