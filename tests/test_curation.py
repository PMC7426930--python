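from __future__ import annotations

import numpy as np
import pytest

from seqcurate import (
    DistanceMatrix,
    Thresholds,
    build_conflict_report,
    flag_intrageneric,
    flag_intraspecific,
)
from tests._oracles import single_linkage_oracle


def matrix_from(d_rows, species, labels=None):
    """Build a DistanceMatrix straight from a nested list (None = missing)."""
    n = len(d_rows)
    labels = labels or [f"SP_x_A{i}" for i in range(n)]
    d = np.full((n, n), np.nan)
    sites = np.full((n, n), 500, dtype=int)
    for i in range(n):
        for j in range(n):
            if d_rows[i][j] is not None:
                d[i, j] = d_rows[i][j]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, species=list(species), d=d,
                          n_sites=sites, min_overlap=0)


def uniform_matrix(n, value, species="Genx alpha"):
    rows = [[value] * n for _ in range(n)]
    return matrix_from(rows, [species] * n)


class TestThresholds:
    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            Thresholds(bad)

    def test_default_is_three_percent(self):
        assert Thresholds().t == 0.03


class TestFlagIntraspecific:
    def test_all_tight_no_flags(self):
        m = uniform_matrix(5, 0.01)
        flags, notes = flag_intraspecific(m, 0.03)
        assert flags == [] and notes == []

    def test_single_outlier_flagged_with_evidence(self):
        # 4 tight conspecifics plus one at 9% from everything
        rows = [[0.01] * 4 + [0.09] for _ in range(4)]
        rows.append([0.09] * 4 + [0.0])
        m = matrix_from(rows, ["Genx alpha"] * 5)
        flags, _ = flag_intraspecific(m, 0.03)
        assert [f.accession for f in flags] == ["A4"]
        assert flags[0].d == pytest.approx(0.09)
        assert flags[0].category == "intraspecific_divergent"
        assert flags[0].threshold == 0.03

    def test_minority_cluster_flagged(self):
        # clusters {0..5} and {6,7} separated by 8%
        n = 8
        rows = [[None] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                same = (i < 6) == (j < 6)
                rows[i][j] = 0.01 if same else 0.08
        m = matrix_from(rows, ["Genx alpha"] * n)
        flags, _ = flag_intraspecific(m, 0.03)
        assert sorted(f.accession for f in flags) == ["A6", "A7"]
        # matches the naive agglomeration oracle
        clusters = single_linkage_oracle(
            [[rows[i][j] for j in range(n)] for i in range(n)], 0.03
        )
        minority = min(clusters, key=len)
        assert {int(f.accession[1]) for f in flags} == set(minority)

    def test_single_sequence_unassessable(self):
        m = uniform_matrix(1, 0.0)
        flags, notes = flag_intraspecific(m, 0.03)
        assert flags == []
        assert notes == [("A0", "unassessable_single")]

    def test_undefined_distances_neither_accept_nor_flag(self):
        rows = [
            [0.0, 0.01, None],
            [0.01, 0.0, None],
            [None, None, 0.0],
        ]
        m = matrix_from(rows, ["Genx alpha"] * 3)
        flags, notes = flag_intraspecific(m, 0.03)
        assert flags == []
        assert ("A2", "insufficient_overlap") in notes

    def test_equal_size_cluster_tiebreak_deterministic(self):
        rows = [[None] * 4 for _ in range(4)]
        for i in range(4):
            for j in range(4):
                same = (i < 2) == (j < 2)
                rows[i][j] = 0.005 if same else 0.09
        m = matrix_from(rows, ["Genx alpha"] * 4)
        flags, _ = flag_intraspecific(m, 0.03)
        # keep the cluster holding the lexicographically smallest label (A0)
        assert sorted(f.accession for f in flags) == ["A2", "A3"]

    def test_mixed_species_rejected(self):
        m = matrix_from([[0.0, 0.01], [0.01, 0.0]], ["Genx alpha", "Genx beta"])
        with pytest.raises(ValueError):
            flag_intraspecific(m, 0.03)


class TestFlagIntrageneric:
    def two_species_matrix(self, cross, labels=None):
        rows = [
            [0.0, 0.01, cross, cross],
            [0.01, 0.0, cross, cross],
            [cross, cross, 0.0, 0.01],
            [cross, cross, 0.01, 0.0],
        ]
        return matrix_from(
            rows, ["Genx alpha"] * 2 + ["Genx beta"] * 2, labels=labels
        )

    def test_distinct_species_above_threshold_no_flags(self):
        assert flag_intrageneric(self.two_species_matrix(0.08), 0.03) == []

    def test_planted_similar_pair_both_flagged(self):
        rows = [
            [0.0, 0.01, 0.08, 0.08],
            [0.01, 0.0, 0.08, 0.08],
            [0.08, 0.08, 0.0, 0.005],
            [0.08, 0.08, 0.005, 0.0],
        ]
        # row 3 belongs to beta but sits 0.5% from alpha's row 2... make it so
        m = matrix_from(rows, ["Genx alpha"] * 3 + ["Genx beta"])
        flags = flag_intrageneric(m, 0.03)
        assert sorted(f.accession for f in flags) == ["A2", "A3"]
        for f in flags:
            assert f.d == pytest.approx(0.005)
            assert f.category == "intrageneric_similar"

    def test_zero_threshold_flags_only_identical(self):
        rows = [
            [0.0, 0.0, 0.1],
            [0.0, 0.0, 0.1],
            [0.1, 0.1, 0.0],
        ]
        m = matrix_from(rows, ["Genx alpha", "Genx beta", "Genx gamma"])
        flags = flag_intrageneric(m, 0.0)
        assert sorted(f.accession for f in flags) == ["A0", "A1"]

    def test_single_species_genus_empty(self):
        m = uniform_matrix(3, 0.01)
        assert flag_intrageneric(m, 0.03) == []


class TestThresholdBoundary:
    """Inequality directions: intraspecific accepts <= t, intrageneric flags <= t."""

    def test_intraspecific_exactly_t_accepted(self):
        t = 3 / 100
        m = uniform_matrix(3, 3 / 100)
        flags, _ = flag_intraspecific(m, t)
        assert flags == []

    def test_intraspecific_just_above_t_flagged(self):
        t = 3 / 100
        m = uniform_matrix(3, 4 / 100)
        flags, _ = flag_intraspecific(m, t)
        assert len(flags) > 0

    def test_intrageneric_exactly_t_flagged(self):
        t = 3 / 100
        m = matrix_from(
            [[0.0, 3 / 100], [3 / 100, 0.0]], ["Genx alpha", "Genx beta"]
        )
        assert len(flag_intrageneric(m, t)) == 2

    def test_intrageneric_just_above_t_accepted(self):
        t = 3 / 100
        m = matrix_from(
            [[0.0, 4 / 100], [4 / 100, 0.0]], ["Genx alpha", "Genx beta"]
        )
        assert flag_intrageneric(m, t) == []


class TestMonotonicity:
    def test_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            vals = rng.random((n, n)) * 0.1
            d = (vals + vals.T) / 2
            rows = [[float(d[i, j]) for j in range(n)] for i in range(n)]
            m_intra = matrix_from(rows, ["Genx alpha"] * n)
            species = ["Genx alpha" if i % 2 else "Genx beta" for i in range(n)]
            m_inter = matrix_from(rows, species)
            t1, t2 = sorted(rng.random(2) * 0.1)
            f1, _ = flag_intraspecific(m_intra, t1)
            f2, _ = flag_intraspecific(m_intra, t2)
            assert len(f2) <= len(f1)
            g1 = {f.accession for f in flag_intrageneric(m_inter, t1)}
            g2 = {f.accession for f in flag_intrageneric(m_inter, t2)}
            assert g1 <= g2


class TestConflictReport:
    def test_empty(self):
        report = build_conflict_report([])
        assert len(report.table) == 0
        assert report.curated_subset(["A", "B"]) == ["A", "B"]

    def test_counts_and_exclusion(self):
        m = uniform_matrix(3, 0.09)
        flags, _ = flag_intraspecific(m, 0.03)
        report = build_conflict_report(
            flags,
            mapping_failures=[("M1", "mapping_failure")],
            non_binomials=[("U1", "Genx sp.")],
            duplicates=[("NC_000001", "duplicate_of:A0")],
        )
        assert report.category_counts["count"].sum() == len(report.table)
        curated = report.curated_subset([f.accession for f in flags] + ["KEEP1"])
        assert curated == ["KEEP1"]
        # no sequence is both accepted and flagged by the divergence rules
        assert not (set(curated) & report.flagged_accessions)

    def test_annotate_policy_keeps_everything(self):
        m = uniform_matrix(3, 0.09)
        flags, _ = flag_intraspecific(m, 0.03)
        report = build_conflict_report(flags, policy="annotate")
        accs = [f.accession for f in flags]
        assert report.curated_subset(accs) == accs

    def test_report_columns(self):
        report = build_conflict_report([])
        assert list(report.table.columns) == [
            "accession", "species", "category", "partner", "d_percent",
            "n_sites", "threshold_percent", "verdict", "rationale", "reference",
        ]

    def test_bad_policy_rejected(self):
        with pytest.raises(ValueError):
            build_conflict_report([], policy="discard")
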