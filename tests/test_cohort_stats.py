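"""Cohort statistics: patient clustering, asymmetry, ICC, Spearman,
t-test, log-vs-linear R², STIR frequency."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myofat import (
    asymmetry_summary,
    cluster_patients,
    icc_agreement,
    linear_vs_log_r2,
    make_cohort_scores,
    spearman_bonferroni,
    stir_frequency,
    two_sample_t,
)
from myofat.cohort_stats import icc_consistency, side_mean_features
from myofat.errors import DegenerateInputError, InvalidParameterError
from myofat.phantom import THIGH_ARCHETYPES, THIGH_MUSCLES


class TestClusterPatients:
    def test_recovers_archetypes(self):
        table = make_cohort_scores((50, 50, 50), THIGH_ARCHETYPES,
                                   score_noise_sd=0.4, seed=2)
        res = cluster_patients(table, region="thigh", k=3, n_restarts=20, seed=0)
        ars = pytest.importorskip("sklearn.metrics").adjusted_rand_score
        assert ars(table["true_cluster"], res.assignments) >= 0.9

    def test_zero_noise_perfect_recovery(self):
        table = make_cohort_scores((1, 1, 1), THIGH_ARCHETYPES,
                                   score_noise_sd=0.0, seed=0)
        res = cluster_patients(table, k=3, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.assignments)) == 3

    def test_k1_center_is_grand_mean(self):
        table = make_cohort_scores((4, 4, 4), THIGH_ARCHETYPES,
                                   score_noise_sd=0.3, seed=1)
        res = cluster_patients(table, k=1, seed=0)
        X = side_mean_features(table, "thigh").to_numpy()
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0))

    def test_k_exceeding_patients_rejected(self):
        table = make_cohort_scores((1, 1, 1), THIGH_ARCHETYPES,
                                   score_noise_sd=0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            cluster_patients(table, k=5, seed=0)

    def test_matches_exhaustive_partition_minimum(self):
        # <= 8 patients, k = 3: enumerate every assignment into <= 3 groups
        table = make_cohort_scores((3, 3, 2), THIGH_ARCHETYPES,
                                   score_noise_sd=0.6, seed=4)
        X = side_mean_features(table, "thigh").to_numpy()
        best = np.inf
        for assign in itertools.product(range(3), repeat=len(X)):
            a = np.array(assign)
            inertia = 0.0
            for g in range(3):
                pts = X[a == g]
                if len(pts):
                    inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
            best = min(best, inertia)
        res = cluster_patients(table, k=3, n_restarts=20, seed=0)
        assert res.inertia == pytest.approx(best, rel=1e-9)

    def test_labels_ordered_by_severity(self):
        table = make_cohort_scores((10, 10, 10), THIGH_ARCHETYPES,
                                   score_noise_sd=0.2, seed=3)
        res = cluster_patients(table, k=3, seed=0)
        means = [res.centers[c].mean() for c in range(3)]
        assert means == sorted(means)  # cluster 1 = mildest


class TestAsymmetry:
    def _table(self, rows):
        cols = {}
        for m in THIGH_MUSCLES:
            cols[f"{m}_L"] = [r.get(m, (2, 2))[0] for r in rows]
            cols[f"{m}_R"] = [r.get(m, (2, 2))[1] for r in rows]
        return pd.DataFrame(cols)

    def test_one_grade_difference_is_asymmetric(self):
        t = self._table([{"VM": (3, 2)}])
        s = asymmetry_summary(t)
        assert s["per_muscle_percent"]["VM"] == 100.0

    def test_equal_grades_symmetric(self):
        t = self._table([{"VM": (2, 2)}])
        assert asymmetry_summary(t)["per_muscle_percent"]["VM"] == 0.0

    def test_cohort_frequency(self):
        rows = [{"RF": (3, 2)}] * 9 + [{}]  # 9 of 10 patients asymmetric
        s = asymmetry_summary(self._table(rows))
        assert s["percent_patients_thigh"] == pytest.approx(90.0)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        r = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5])[:, None], (1, 2))
        icc, (cv_mean, cv_sd) = icc_agreement(r)
        assert icc == pytest.approx(1.0)
        assert cv_mean == 0.0 and cv_sd == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_anova_mean_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        subj = rng.normal(10, 3, size=6)
        r = subj[:, None] + rng.normal(0, 1, size=(6, 2))
        icc, _ = icc_agreement(r)
        # independent oracle: two-way ANOVA via statsmodels OLS
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        n, k = r.shape
        df = pd.DataFrame(
            {"y": r.ravel(),
             "subject": np.repeat(np.arange(n), k).astype(str),
             "rater": np.tile(np.arange(k), n).astype(str)}
        )
        tab = anova_lm(smf.ols("y ~ C(subject) + C(rater)", data=df).fit(), typ=2)
        msr = tab.loc["C(subject)", "sum_sq"] / (n - 1)
        msc = tab.loc["C(rater)", "sum_sq"] / (k - 1)
        mse = tab.loc["Residual", "sum_sq"] / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        r = rng.normal(5, 2, size=(8, 3))
        icc, _ = icc_agreement(r)
        n, k = r.shape
        df = pd.DataFrame(
            {"y": r.ravel(),
             "targets": np.repeat(np.arange(n), k),
             "raters": np.tile(np.arange(k), n)}
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="y")
        icc2 = ref.set_index("Type").loc["ICC(A,1)", "ICC"]  # two-way random, absolute
        assert icc == pytest.approx(icc2, abs=1e-8)

    def test_constant_offset_absolute_below_consistency(self):
        rng = np.random.default_rng(0)
        col = rng.normal(10, 3, size=8)
        r = np.column_stack([col, col + 2.0])
        icc_abs, _ = icc_agreement(r)
        icc_con = icc_consistency(r)
        assert icc_abs < icc_con

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc_agreement(np.full((4, 2), 3.0))


class TestSpearman:
    def test_monotone_relation_gives_rho_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0])
        rho, p, _ = spearman_bonferroni(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 4.0])
        rho, p, _ = spearman_bonferroni(x, y)
        # oracle: all 720 orderings through scipy's spearman rho
        rhos = []
        for perm in itertools.permutations(y):
            rhos.append(stats.spearmanr(x, np.array(perm)).statistic)
        rhos = np.array(rhos)
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=2.0, size=20)
        _, p, p_adj = spearman_bonferroni(x, y, m_tests=10)
        assert p_adj == pytest.approx(min(1.0, 10 * p))
        assert p <= p_adj <= 1.0

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, p1, _ = spearman_bonferroni(x, y)
        rho2, p2, _ = spearman_bonferroni(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_bonferroni(np.ones(6), np.arange(6.0))


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = two_sample_t(x, x.copy())
        assert t == 0.0 and p == pytest.approx(1.0)
        assert df == 6

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        t1, _, p1 = two_sample_t(x, y)
        t2, _, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_pooled(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        t, df, p = two_sample_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t(np.full(5, 2.0), np.full(4, 2.0))


class TestLinearVsLog:
    def test_exact_log_linear_data(self):
        score = np.linspace(1, 4, 30)
        frac = np.exp(-4 + 1.1 * score)
        r2_lin, r2_log = linear_vs_log_r2(score, frac)
        assert r2_log == pytest.approx(1.0)
        assert r2_log > r2_lin

    def test_exact_linear_data(self):
        score = np.linspace(1, 4, 30)
        r2_lin, _ = linear_vs_log_r2(score, 0.05 + 0.1 * score)
        assert r2_lin == pytest.approx(1.0)

    def test_zero_fractions_offset_with_warning(self):
        score = np.array([1.0, 2.0, 3.0, 4.0])
        frac = np.array([0.0, 0.1, 0.2, 0.4])
        with pytest.warns(UserWarning, match="offset"):
            r2_lin, r2_log = linear_vs_log_r2(score, frac)
        assert 0 <= r2_log <= 1


class TestStir:
    def test_all_zero(self):
        t = make_cohort_scores((2, 2, 2), stir_rate=0.0, seed=0)
        assert stir_frequency(t) == (0.0, 0.0)

    def test_direct_count(self):
        # 35 patients x 32 entries = 1120; flag 35 entries in 10 patients
        t = make_cohort_scores((16, 10, 9), stir_rate=0.0, seed=0)
        stir_cols = [c for c in t.columns if c.startswith("stir_")]
        flat = [(i, c) for c in stir_cols[:4] for i in range(10)]
        for i, c in flat[:35]:
            t.loc[i, c] = 1
        pct_m, pct_p = stir_frequency(t)
        assert pct_m == pytest.approx(100 * 35 / 1120)
        assert pct_p == pytest.approx(100 * 10 / 35)

    def test_single_patient_single_flag(self):
        t = make_cohort_scores((1,), {1: {m: 2.0 for m in THIGH_MUSCLES}},
                               stir_rate=0.0, seed=0)
        t.loc[0, "stir_VM_L"] = 1
        pct_m, pct_p = stir_frequency(t)
        assert pct_m == pytest.approx(100 / 20)
        assert pct_p == 100.0
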