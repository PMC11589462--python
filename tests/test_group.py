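import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from olfbold.group_analysis import (
    adjusted_group_test,
    bh_fdr,
    cohens_d,
    direction_matrix,
    regress_on_upsit,
    relative_change,
    summarize_cohort,
)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "pd_mean, hc_mean, expected",
        [(28, 32, -12.5), (5.0, 5.0, 0.0), (0.97, 0.50, 94.0)],
    )
    def test_values(self, pd_mean, hc_mean, expected):
        assert relative_change(pd_mean, hc_mean) == pytest.approx(expected)

    def test_zero_reference_is_missing(self):
        assert np.isnan(relative_change(3.0, 0.0))


def glm_oracle(y, X):
    """Normal-equation solve with classical t-test p-values."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    t = beta / se
    p = 2 * sp_stats.t.sf(np.abs(t), df)
    return beta, p


class TestAdjustedGroupTest:
    def _six_subject_example(self):
        values = np.array([3.1, 2.7, 3.9, 1.2, 1.5, 0.8])
        groups = np.array(["PD"] * 3 + ["HC"] * 3)
        cov = pd.DataFrame(
            {"age": [65, 62, 70, 44, 48, 41], "roi_volume": [100, 95, 104, 99, 102, 97.0]}
        )
        return values, groups, cov

    def test_matches_normal_equation_oracle(self):
        values, groups, cov = self._six_subject_example()
        coef, p = adjusted_group_test(values, groups, cov)
        X = np.column_stack(
            [np.ones(6), (groups == "PD").astype(float), cov.age, cov.roi_volume]
        )
        beta, pvals = glm_oracle(values, X)
        assert coef == pytest.approx(beta[1], rel=1e-10)
        assert p == pytest.approx(pvals[1], rel=1e-10)

    def test_confound_fully_absorbed(self, rng):
        age = np.concatenate([rng.normal(65, 5, 20), rng.normal(45, 5, 20)])
        groups = np.array(["PD"] * 20 + ["HC"] * 20)
        values = 2.0 * age
        cov = pd.DataFrame({"age": age, "roi_volume": rng.normal(100, 5, 40)})
        coef, _ = adjusted_group_test(values, groups, cov)
        assert abs(coef) < 1e-8

    def test_reduces_to_t_test_with_constant_covariates(self, rng):
        x = rng.normal(1.0, 0.5, 12)
        y = rng.normal(0.5, 0.5, 14)
        values = np.concatenate([x, y])
        groups = np.array(["PD"] * 12 + ["HC"] * 14)
        cov = pd.DataFrame({"age": np.full(26, 50.0), "roi_volume": np.full(26, 100.0)})
        _, p = adjusted_group_test(values, groups, cov)
        t_ref = sp_stats.ttest_ind(x, y)
        assert p == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_collinear_covariate_named(self, rng):
        age = rng.normal(60, 5, 20)
        values = rng.normal(size=20)
        groups = np.array(["PD"] * 10 + ["HC"] * 10)
        cov = pd.DataFrame({"age": age, "roi_volume": 2 * age + 1})
        with pytest.raises(ValueError, match="roi_volume|age"):
            adjusted_group_test(values, groups, cov)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            adjusted_group_test(
                np.ones(4), np.array(["PD", "PD", "HC", "HC"]),
                pd.DataFrame({"age": [1, 2, 3, 4.0]}),
            )

    def test_null_p_values_uniform(self, rng):
        """Identical group distributions: p-values uniform on [0, 1]."""
        pvals = []
        for _ in range(300):
            values = rng.normal(size=200)
            groups = np.array(["PD"] * 100 + ["HC"] * 100)
            cov = pd.DataFrame({"age": rng.normal(50, 8, 200),
                                "roi_volume": rng.normal(100, 10, 200)})
            pvals.append(adjusted_group_test(values, groups, cov)[1])
        ks = sp_stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCohensD:
    def test_identical_means_give_zero(self):
        assert cohens_d([1.0, 2, 3], [2.0, 1, 3]) == pytest.approx(0.0)

    def test_eight_value_example_matches_pooled_formula(self):
        x = np.array([2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 1.5, 2.5, 3.0])
        d = cohens_d(x, y)
        sp = np.sqrt((3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6)
        assert d == pytest.approx(abs(x.mean() - y.mean()) / sp, rel=1e-12)

    def test_zero_pooled_sd_is_missing(self):
        assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))

    def test_reported_as_magnitude(self):
        assert cohens_d([0.0, 0.1], [5.0, 5.1]) > 0


class TestRegressOnUpsit:
    def test_perfect_relationship(self, rng):
        upsit = rng.normal(25, 5, 30)
        cov = pd.DataFrame({"age": rng.normal(50, 8, 30)})
        r, p = regress_on_upsit(upsit.copy(), upsit, cov)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_covariate_removes_contamination(self, rng):
        age = rng.normal(50, 8, 40)
        upsit = rng.normal(25, 5, 40)
        values = upsit + 3.0 * age
        cov = pd.DataFrame({"age": age})
        r, _ = regress_on_upsit(values, upsit, cov)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_zero_order_mode(self, rng):
        age = rng.normal(50, 8, 40)
        upsit = rng.normal(25, 5, 40)
        values = upsit + 3.0 * age
        r_partial, _ = regress_on_upsit(values, upsit, pd.DataFrame({"age": age}))
        r_zero, _ = regress_on_upsit(values, upsit, pd.DataFrame({"age": age}),
                                     partial=False)
        assert r_partial > r_zero

    def test_constant_input_missing(self):
        r, p = regress_on_upsit(np.ones(10), np.arange(10.0), None)
        assert np.isnan(r) and np.isnan(p)

    def test_null_r_small(self, rng):
        rs = [
            regress_on_upsit(rng.normal(size=200), rng.normal(size=200),
                             pd.DataFrame({"age": rng.normal(size=200)}))[0]
            for _ in range(50)
        ]
        assert abs(np.mean(rs)) < 0.05


def bh_oracle(pvals, alpha):
    """Exhaustive step-up evaluation."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            kmax = k
    flags = np.zeros(m, bool)
    flags[order[:kmax]] = True
    return flags


class TestBhFdr:
    def test_all_small_all_flagged(self):
        assert bh_fdr([0.001] * 11, 0.05).all()

    def test_all_one_none_flagged(self):
        assert not bh_fdr([1.0] * 11, 0.05).any()

    def test_mixed_vector_matches_oracle(self):
        p = [0.01, 0.02, 0.03, 0.5] + [0.9] * 7
        assert np.array_equal(bh_fdr(p, 0.05), bh_oracle(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5], 0.05)

    def test_oracle_equivalence_on_grid(self):
        grid = [0.01, 0.05, 0.2, 1.0]
        for length in (1, 2, 3, 4):
            for combo in itertools.product(grid, repeat=length):
                assert np.array_equal(
                    bh_fdr(list(combo), 0.05), bh_oracle(list(combo), 0.05)
                ), combo


def _toy_cohort(rng, effect=1.0):
    rois = ["olfactory_bulb", "piriform_cortex", "amygdala"]
    subjects = []
    for g, n in (("PD", 8), ("HC", 8)):
        for i in range(n):
            subjects.append(
                {
                    "subject_id": f"{g.lower()}{i}",
                    "group": g,
                    "age": rng.normal(65 if g == "PD" else 45, 5),
                    "upsit": rng.normal(20 if g == "PD" else 31, 2),
                    **{f"roi_vol_{r}": rng.normal(100, 5) for r in rois},
                }
            )
    subjects = pd.DataFrame(subjects)
    rows = []
    for _, s in subjects.iterrows():
        for r in rois:
            base = 10.0 if s.group == "HC" else 10.0 - effect
            rows.append(
                {"subject_id": s.subject_id, "roi": r,
                 "n_active": rng.normal(base, 0.5),
                 "dss_individual": rng.normal(base / 10, 0.1)}
            )
    return pd.DataFrame(rows), subjects


class TestSummarizeCohort:
    def test_table_structure_and_relative_change(self, rng):
        metrics, subjects = _toy_cohort(rng, effect=3.0)
        tables = summarize_cohort(metrics, subjects)
        assert set(tables) == {"n_active", "dss_individual"}
        t = tables["n_active"]
        assert len(t) == 3
        for col in ("mean_pd", "se_pd", "mean_hc", "se_hc", "relative_change",
                    "p_group", "cohens_d", "r_upsit", "p_upsit", "fdr_significant"):
            assert col in t.columns
        row = t.iloc[0]
        assert row.relative_change == pytest.approx(
            100 * (row.mean_pd - row.mean_hc) / row.mean_hc
        )
        # standard error convention: sd / sqrt(n)
        sub = metrics[(metrics.roi == row.roi)].merge(subjects, on="subject_id")
        pd_vals = sub.loc[sub.group == "PD", "n_active"]
        assert row.se_pd == pytest.approx(pd_vals.std(ddof=1) / np.sqrt(len(pd_vals)))

    def test_strong_effect_flagged_weak_not(self, rng):
        metrics, subjects = _toy_cohort(rng, effect=3.0)
        tables = summarize_cohort(metrics, subjects)
        assert tables["n_active"]["fdr_significant"].all()

    def test_too_few_finite_subjects_rejected(self, rng):
        metrics, subjects = _toy_cohort(rng)
        metrics.loc[
            (metrics.roi == "amygdala")
            & metrics.subject_id.str.startswith("pd"), "dss_individual",
        ] = np.nan
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize_cohort(metrics, subjects)

    def test_direction_matrix(self, rng):
        metrics, subjects = _toy_cohort(rng, effect=3.0)
        tables = summarize_cohort(metrics, subjects)
        dm = direction_matrix(tables)
        assert set(dm["n_active"]) == {"down"}   # patients below controls
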