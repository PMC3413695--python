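import numpy as np
import pytest
from scipy import stats

from brushdx.cohort import default_cohort_spec, generate_cohort
from brushdx.io_tables import Group
from brushdx.qpcr import (
    compute_ddct,
    compute_delta_ct,
    group_comparison,
    group_t_test,
    spearman_matrix,
)
from conftest import make_record


def matrix_from_columns(mal, ben, marker="M1"):
    """Build a one-marker DeltaCtMatrix from explicit per-group ΔCt lists."""
    records = []
    for i, v in enumerate(mal):
        records.append(make_record(f"M{i}", "malignant", "missing",
                                   {"GAPDH": 18.0, marker: 18.0 + v}))
    for i, v in enumerate(ben):
        records.append(make_record(f"B{i}", "benign", "missing",
                                   {"GAPDH": 18.0, marker: 18.0 + v}))
    return compute_delta_ct(records)


class TestDeltaCt:
    def test_direct_subtraction(self, toy_matrix):
        i = toy_matrix.patient_ids.index("P1")
        j = toy_matrix.marker_index("IGF2BP3")
        assert toy_matrix.dct[i, j] == pytest.approx(27.8 - 18.2)

    def test_identical_target_and_reference(self):
        m = compute_delta_ct([make_record("P", "benign", "missing",
                                          {"GAPDH": 20.0, "X": 20.0})])
        assert m.dct[0, 0] == 0.0

    def test_censored_target_propagates(self):
        m = compute_delta_ct([make_record("P", "benign", "missing",
                                          {"GAPDH": 20.0, "X": (40.0, True)})])
        assert m.dct[0, 0] == 20.0
        assert m.censored[0, 0]

    def test_missing_target_propagates(self):
        m = compute_delta_ct([make_record("P", "benign", "missing",
                                          {"GAPDH": 20.0, "X": None})])
        assert np.isnan(m.dct[0, 0])

    def test_unusable_reference_rejects_record(self):
        recs = [
            make_record("P1", "benign", "missing", {"GAPDH": None, "X": 25.0}),
            make_record("P2", "benign", "missing", {"GAPDH": (40.0, True), "X": 25.0}),
            make_record("P3", "benign", "missing", {"GAPDH": 18.0, "X": 25.0}),
        ]
        m = compute_delta_ct(recs)
        assert m.patient_ids == ["P3"]
        reasons = dict(m.rejected)
        assert "missing" in reasons["P1"] and "censored" in reasons["P2"]

    def test_invariant_under_per_patient_ct_shift(self, toy_records):
        base = compute_delta_ct(toy_records)
        shifted = [
            make_record(rec.patient_id, rec.group, rec.cytology,
                        {g: v.value + 0.5 * k for g, v in rec.ct.items()})
            for k, rec in enumerate(toy_records)
        ]
        m2 = compute_delta_ct(shifted)
        np.testing.assert_allclose(m2.dct, base.dct, atol=1e-12)


class TestDdct:
    @pytest.mark.parametrize("diff, approx_fold", [(3.5, 11.3), (1.3, 2.46)])
    def test_median_difference_gives_fold_change(self, diff, approx_fold):
        m = matrix_from_columns([9.0, 10.0, 11.0], [9.0 + diff, 10.0 + diff, 11.0 + diff])
        ddct, fold = compute_ddct(m, "M1")
        assert ddct == pytest.approx(diff)
        assert fold == 2.0 ** ddct
        assert fold == pytest.approx(approx_fold, abs=0.05)

    def test_identical_medians(self):
        m = matrix_from_columns([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert compute_ddct(m, "M1") == (0.0, 1.0)

    def test_label_swap_reciprocity(self, rng):
        mal = rng.normal(9, 2, 15).tolist()
        ben = rng.normal(12, 2, 11).tolist()
        d1, f1 = compute_ddct(matrix_from_columns(mal, ben), "M1")
        d2, f2 = compute_ddct(matrix_from_columns(ben, mal), "M1")
        assert d2 == pytest.approx(-d1)
        assert f2 == pytest.approx(1.0 / f1)

    def test_even_n_midpoint_median(self):
        m = matrix_from_columns([1.0, 3.0], [5.0, 9.0])
        ddct, _ = compute_ddct(m, "M1")
        assert ddct == pytest.approx(7.0 - 2.0)

    def test_empty_group_raises(self):
        m = matrix_from_columns([1.0, 2.0], [])
        with pytest.raises(ValueError, match="benign"):
            compute_ddct(m, "M1")


class TestGroupTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        m = matrix_from_columns([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t, p = group_t_test(m, "M1")
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_welch(self, rng):
        mal = rng.normal(9.58, 2.87, 72)
        ben = rng.normal(13.08, 2.38, 47)
        t, p = group_t_test(matrix_from_columns(mal.tolist(), ben.tolist()), "M1")
        se = np.sqrt(mal.var(ddof=1) / 72 + ben.var(ddof=1) / 47)
        assert t == pytest.approx((mal.mean() - ben.mean()) / se)
        assert 0 <= p <= 1

    def test_reported_moments_give_significant_difference(self):
        """Two groups at the study's IGF2BP3 moments separate at p < 1e-4
        in at least 99% of seeded replicates."""
        hits = 0
        n_rep = 1000
        rng = np.random.default_rng(42)
        for _ in range(n_rep):
            mal = rng.normal(9.58, 2.87, 72)
            ben = rng.normal(13.08, 2.38, 47)
            p = stats.ttest_ind(mal, ben, equal_var=False).pvalue
            hits += p < 1e-4
        assert hits / n_rep >= 0.99

    def test_welch_close_to_pooled_on_equal_variances(self, rng):
        """At the cohort sizes used, Welch and pooled p-values agree within
        0.01 on average over replicates of equal-variance data (single
        replicates can diverge slightly more when p sits mid-range)."""
        diffs = []
        for _ in range(200):
            mal = rng.normal(10, 2, 72)
            ben = rng.normal(11, 2, 47)
            p_welch = stats.ttest_ind(mal, ben, equal_var=False).pvalue
            p_pooled = stats.ttest_ind(mal, ben, equal_var=True).pvalue
            diffs.append(abs(p_welch - p_pooled))
        assert np.mean(diffs) < 0.01
        assert np.median(diffs) < 0.01

    def test_censored_values_excluded_from_moments(self):
        recs = [
            make_record("M1", "malignant", "missing", {"GAPDH": 18.0, "X": 25.0}),
            make_record("M2", "malignant", "missing", {"GAPDH": 18.0, "X": 26.0}),
            make_record("M3", "malignant", "missing", {"GAPDH": 18.0, "X": (40.0, True)}),
            make_record("B1", "benign", "missing", {"GAPDH": 18.0, "X": 27.0}),
            make_record("B2", "benign", "missing", {"GAPDH": 18.0, "X": 28.0}),
        ]
        m = compute_delta_ct(recs)
        comp = group_comparison(m)
        assert comp.loc["X", "mean_malignant"] == pytest.approx(7.5)  # censored out
        assert comp.loc["X", "median_malignant"] == pytest.approx(8.0)  # censored in

    def test_insufficient_n_names_group(self):
        m = matrix_from_columns([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="malignant"):
            group_t_test(m, "M1")


class TestSpearman:
    def test_monotone_pairs(self):
        mal = [(1.0, 2.0), (2.0, 4.0), (3.0, 9.0), (4.0, 16.0)]
        recs = [make_record(f"M{i}", "malignant", "missing",
                            {"GAPDH": 18.0, "A": 18 + a, "B": 18 + b})
                for i, (a, b) in enumerate(mal)]
        m = compute_delta_ct(recs)
        corr = spearman_matrix(m, Group.MALIGNANT)
        assert corr.rho.loc["A", "B"] == pytest.approx(1.0)

    def test_anti_monotone_pair(self):
        recs = [make_record(f"M{i}", "malignant", "missing",
                            {"GAPDH": 18.0, "A": 18.0 + i, "B": 22.0 - i})
                for i in range(5)]
        corr = spearman_matrix(compute_delta_ct(recs), Group.MALIGNANT)
        assert corr.rho.loc["A", "B"] == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(8, 2, 30)
        b = 0.5 * a + rng.normal(0, 1, 30)
        recs1, recs2 = [], []
        for i in range(30):
            recs1.append(make_record(f"M{i}", "malignant", "missing",
                                     {"GAPDH": 10.0, "A": 10 + a[i], "B": 10 + b[i]}))
            # exp/5 and cube are strictly increasing maps into (0, 40)
            recs2.append(make_record(f"M{i}", "malignant", "missing",
                                     {"GAPDH": 10.0, "A": 10 + np.exp(a[i] / 5),
                                      "B": 10 + (b[i] / 4) ** 3}))
        r1 = spearman_matrix(compute_delta_ct(recs1), Group.MALIGNANT)
        r2 = spearman_matrix(compute_delta_ct(recs2), Group.MALIGNANT)
        assert r1.rho.loc["A", "B"] == pytest.approx(r2.rho.loc["A", "B"], abs=1e-12)

    def test_constant_column_reported_undefined(self):
        recs = [make_record(f"M{i}", "malignant", "missing",
                            {"GAPDH": 18.0, "A": 20.0, "B": 18.0 + i})
                for i in range(5)]
        corr = spearman_matrix(compute_delta_ct(recs), Group.MALIGNANT)
        assert np.isnan(corr.rho.loc["A", "B"])
        assert ("A", "B", "constant marker column") in corr.undefined

    def test_symmetry_and_unit_diagonal(self, default_matrix):
        corr = spearman_matrix(default_matrix, Group.MALIGNANT)
        r = corr.rho.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.nanmax(np.abs(r)) <= 1.0

    def test_generator_hits_target_correlation(self):
        """Synthetic malignant cohorts reproduce the HOXB7–IGF2BP3 target
        rank correlation 0.602 within ±0.15 in at least 95% of replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            records = generate_cohort(default_cohort_spec(seed=seed))
            m = compute_delta_ct(records)
            corr = spearman_matrix(m, Group.MALIGNANT)
            hits += abs(corr.rho.loc["HOXB7", "IGF2BP3"] - 0.602) <= 0.15
        assert hits / n_rep >= 0.95

    def test_small_group_raises(self, toy_matrix):
        with pytest.raises(ValueError, match="n < 3"):
            spearman_matrix(toy_matrix, Group.BENIGN)
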