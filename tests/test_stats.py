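import numpy as np
import pytest
from scipy import stats as sps

import connlife as cl
from oracles import ols_normal_equations
from conftest import make_cohort


class TestRollingCorrelation:
    def test_window_count_over_lifespan(self):
        ages = np.linspace(18.5, 88.9, 400)
        rng = np.random.default_rng(0)
        df = cl.rolling_correlation(ages, rng.standard_normal(400),
                                    rng.standard_normal(400), width=10,
                                    step=1, n_boot=49, seed=0)
        assert len(df) == 62  # starts 18..79 inclusive
        assert df["age_start"].iloc[0] == 18
        assert df["age_start"].iloc[-1] == 79

    def test_linear_window_gives_unit_correlation(self):
        ages = np.linspace(20, 35, 120)
        metric = 2.0 * ages + 1.0
        fi = metric.copy()
        df = cl.rolling_correlation(ages, metric, fi, n_boot=60, seed=1)
        assert np.allclose(df["r"].dropna(), 1.0)
        last = df.dropna().iloc[0]
        assert last["ci_high"] - last["ci_low"] < 1e-6

    def test_sparse_window_reports_null(self):
        ages = np.array([20.0, 20.5, 40.0, 40.5, 41.0, 41.5])
        m = np.arange(6.0)
        df = cl.rolling_correlation(ages, m, m[::-1], width=10, n_boot=30,
                                    seed=2)
        first = df.iloc[0]
        assert first["n"] == 2 and np.isnan(first["r"])

    def test_interior_subject_covered_width_over_step_times(self):
        ages = np.full(5, 50.3)
        ages = np.concatenate([ages, [18.0, 90.0]])
        m = np.arange(7.0)
        df = cl.rolling_correlation(ages, m, m * 2, width=10, step=1,
                                    n_boot=30, seed=3)
        covered = ((df["age_start"] <= 50.3)
                   & (50.3 < df["age_start"] + 10)).sum()
        assert covered == 10

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            cl.rolling_correlation([1, 2, 3], [1, 2, 3], [1, 2, 3], width=0)


class TestBCaInterval:
    def test_constant_sample_collapses(self):
        lo, hi = cl.bca_interval(np.full(20, 3.3), np.mean, n_boot=100,
                                 seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_symmetric_case_matches_percentile(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        lo, hi = cl.bca_interval(x, np.mean, n_boot=2000, seed=2)
        boots = np.array([np.mean(x[rng.integers(0, 200, 200)])
                          for _ in range(2000)])
        plo, phi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(plo, abs=0.05)
        assert hi == pytest.approx(phi, abs=0.05)

    def test_matches_scipy_bca_cross_check(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=80)  # skewed: z0 and a matter
        lo, hi = cl.bca_interval(x, np.mean, n_boot=4000, seed=4)
        res = sps.bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                            random_state=np.random.default_rng(5))
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.05)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.05)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            cl.bca_interval(np.array([1.0, 2.0]), np.mean)


class TestTTests:
    def test_identical_paired_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = cl.t_tests(a, a, paired=True)
        assert (t, df, p) == (0.0, 3, 1.0)

    def test_paired_matches_hand_formula(self):
        a = np.array([12.1, 14.2, 11.8, 15.0, 13.3])
        b = np.array([11.0, 13.5, 12.2, 14.1, 12.6])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * sps.t.sf(abs(t_hand), 4)
        t, df, p = cl.t_tests(a, b, paired=True)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == 4
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_pooled_df_is_classical(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(14) + 1
        _, df, _ = cl.t_tests(a, b, pooled=True)
        assert df == 22
        _, df_welch, _ = cl.t_tests(a, b)
        assert df_welch != 22

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        sims = 1000
        for _ in range(sims):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            _, _, p = cl.t_tests(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / sims <= 0.07

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            cl.t_tests([1.0], [2.0], paired=True)


class TestOLSModels:
    def _metrics_frame(self, n=60, seed=0, le=None):
        rng = np.random.default_rng(seed)
        ages = np.linspace(25, 75, n)
        cohort = make_cohort(list(ages),
                             fis=list(30 - 0.1 * ages),
                             sexes=["F", "M"] * (n // 2))
        import pandas as pd
        df = pd.DataFrame({
            "id": cohort.ids,
            "small_worldness": rng.random(n) + 1,
            "sc_total": rng.random(n) * 10,
            "mean_sc_distance": rng.random(n) * 50 + 20,
        })
        df["le_a"] = le if le is not None else rng.random(n)
        df["le_b"] = df["le_a"]
        return df, cohort

    def test_noiseless_recovery_exact(self):
        df, cohort = self._metrics_frame()
        ages = cohort.table["age"].to_numpy()
        df["le_a"] = 2.0 * ages + 0.0 * (cohort.table["sex"] == "M") + 1.0
        df["le_b"] = df["le_a"]
        fit = cl.fit_local_efficiency_models(df, cohort, model_id=1,
                                             group="all")
        assert fit.term("Age")["estimate"] == pytest.approx(2.0, abs=1e-8)
        assert fit.term("Sex (male)")["estimate"] == pytest.approx(0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        df, cohort = self._metrics_frame(seed=1)
        rng = np.random.default_rng(2)
        df["le_a"] = (0.01 * cohort.table["age"].to_numpy()
                      + 0.3 * df["small_worldness"]
                      + 0.05 * df["sc_total"]
                      + 0.02 * rng.standard_normal(len(df)))
        df["le_b"] = df["le_a"]
        fit = cl.fit_local_efficiency_models(df, cohort, model_id=3,
                                             group="all")
        design = df[["small_worldness", "sc_total", "mean_sc_distance"]].copy()
        design.insert(0, "sex", (cohort.table["sex"] == "M").astype(float).to_numpy())
        design.insert(0, "age", cohort.table["age"].to_numpy())
        beta = ols_normal_equations(design.to_numpy(), df["le_a"].to_numpy())
        np.testing.assert_allclose(fit.table["estimate"].to_numpy(), beta,
                                   atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        df, cohort = self._metrics_frame(seed=3)
        fit = cl.fit_local_efficiency_models(df, cohort, model_id=1,
                                             group="all")
        # recompute residuals from the reported coefficients
        d = cl.stats.local_efficiency_design(df, cohort)
        X = np.column_stack([np.ones(len(d)), d["age"], d["sex_male"],
                             d["small_worldness"], d["sc_total"]])
        resid = d["le_mean"].to_numpy() - X @ fit.table["estimate"].to_numpy()
        assert np.abs(X.T @ resid).max() < 1e-6

    def test_collinear_design_rejected(self):
        df, cohort = self._metrics_frame(seed=4)
        df["sc_total"] = 2.0 * df["small_worldness"]
        with pytest.raises(ValueError, match="collinear"):
            cl.fit_local_efficiency_models(df, cohort, model_id=1,
                                           group="all")

    def test_planted_coefficient_recovered_with_ci(self):
        rng = np.random.default_rng(6)
        n = 350
        df, cohort = self._metrics_frame(n=n, seed=6)
        df["le_a"] = (3.0 * df["small_worldness"]
                      + 0.3 * rng.standard_normal(n))
        df["le_b"] = df["le_a"]
        fit = cl.fit_local_efficiency_models(df, cohort, model_id=1,
                                             group="all")
        row = fit.term("Small-worldness")
        assert row["ci_low"] > 0
        assert row["estimate"] == pytest.approx(3.0, abs=0.5)


class TestGroupComparison:
    def _fit_like(self, lo, hi, term="Age"):
        import pandas as pd
        table = pd.DataFrame({
            "term": [term], "estimate": [(lo + hi) / 2],
            "ci_low": [lo], "ci_high": [hi], "se": [1.0], "t": [1.0],
            "p": [0.5]})
        return cl.RegressionFit(table=table, r_squared=0.5, n=10,
                                dependent="y")

    def test_disjoint_intervals_differ(self):
        v = cl.compare_group_estimates(self._fit_like(1, 2),
                                       self._fit_like(3, 4), "Age")
        assert v["verdict"] == "different"

    def test_overlapping_intervals_do_not(self):
        v = cl.compare_group_estimates(self._fit_like(1, 3),
                                       self._fit_like(2, 4), "Age")
        assert v["verdict"] == "not different"

    def test_missing_term_errors(self):
        with pytest.raises(KeyError):
            cl.compare_group_estimates(self._fit_like(1, 2),
                                       self._fit_like(3, 4), "SC total")
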