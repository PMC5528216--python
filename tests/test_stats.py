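"""Screens, comparisons, logistic regression and the model battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adipo.errors import ComputationError, SeparationError, ValidationError
from adipo.stats import (
    MODEL_PREDICTORS,
    LogisticFit,
    backward_lr_selection,
    fit_logistic,
    hosmer_lemeshow,
    independent_t_test,
    iqr_outliers,
    levene_test,
    nagelkerke_r2,
    pearson,
    run_paper_models,
    vif,
)
from adipo.stats import test_normality as shapiro_wilk


class TestScreens:
    def test_shapiro_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_shapiro_detects_lognormal(self, rng):
        _, p = shapiro_wilk(np.exp(rng.normal(0, 1, 500)))
        assert p < 0.05

    def test_shapiro_type_one_rate_near_nominal(self, rng):
        rejections = sum(
            shapiro_wilk(rng.normal(0, 1, 50))[1] < 0.05 for _ in range(300)
        )
        assert 0.01 < rejections / 300 < 0.10

    def test_levene_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = levene_test(g, g)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_levene_power_at_variance_ratio_nine(self, rng):
        rejected = sum(
            levene_test(rng.normal(0, 1, 200), rng.normal(0, 3, 200))[1] < 0.05
            for _ in range(30)
        )
        assert rejected >= 29

    def test_levene_type_one_near_nominal(self, rng):
        rejections = sum(
            levene_test(rng.normal(0, 1, 100), rng.normal(0, 1, 100))[1] < 0.05
            for _ in range(200)
        )
        assert 0.01 < rejections / 200 < 0.11

    def test_iqr_outlier_fixture(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 100.0]
        flags = iqr_outliers(values, k=2.2)
        assert flags.tolist() == [False] * 7 + [True]

    def test_iqr_degenerate_cases(self):
        assert not iqr_outliers([5.0] * 10).any()
        assert not iqr_outliers([1.0, 2.0, 3.0, 4.0, 100.0], k=np.inf).any()
        with pytest.warns(UserWarning):
            flags = iqr_outliers([1.0, 2.0, 900.0])
        assert not flags.any()

    def test_vif_orthogonal_and_collinear(self, rng):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = vif(np.column_stack([x1, x2]))
        np.testing.assert_allclose(out, [1.0, 1.0], atol=1e-10)
        dup = np.column_stack([x1, x1])
        assert np.isinf(vif(dup)).all()

    def test_vif_closed_form_at_rho_08(self, rng):
        cov = [[1.0, 0.8], [0.8, 1.0]]
        X = rng.multivariate_normal([0, 0], cov, size=50_000)
        out = vif(X)
        np.testing.assert_allclose(out, 1.0 / (1.0 - 0.64), rtol=0.05)


class TestComparisons:
    def test_t_identical_groups(self):
        t, df, p = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_t_detects_five_sd_shift(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        _, _, p = independent_t_test(a, b)
        assert p < 1e-3

    def test_log10_transform_identity(self, rng):
        a = np.abs(rng.normal(10, 1, 40)) + 1
        b = 10.0 * a
        t_ours, _, p_ours = independent_t_test(a, b, log10_first=True)
        t_ref, p_ref = sps.ttest_ind(np.log10(a), np.log10(b))
        assert t_ours == pytest.approx(float(t_ref))
        assert p_ours == pytest.approx(float(p_ref))
        assert np.mean(np.log10(b)) - np.mean(np.log10(a)) == pytest.approx(1.0)

    def test_t_zero_pooled_variance(self):
        with pytest.raises(ComputationError):
            independent_t_test([1.0, 1.0], [1.0, 1.0])

    def test_pearson_affine_and_sign(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 3)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)
        with pytest.raises(ComputationError):
            pearson(x, np.ones_like(x))

    def test_pearson_drops_incomplete_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, 6.0, 8.0, 1.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(1.0)


def _grid_mle(X, y, rounds=8, pts=21, span=4.0):
    """Brute-force likelihood maximization on a shrinking parameter grid."""
    Xd = np.column_stack([np.ones(len(y)), X])
    d = Xd.shape[1]
    center = np.zeros(d)
    half = np.full(d, span)
    for _ in range(rounds):
        axes = [np.linspace(c - h, c + h, pts) for c, h in zip(center, half)]
        mesh = np.meshgrid(*axes, indexing="ij")
        B = np.stack([m.ravel() for m in mesh])
        eta = Xd @ B
        ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        center = B[:, np.argmax(ll)]
        half = half * (2.0 / (pts - 1)) * 2.0
    return center


@pytest.fixture()
def twelve_points():
    X = np.array(
        [
            [0.2, 1.0], [0.5, 0.0], [0.9, 1.0], [1.4, 0.0],
            [1.8, 1.0], [2.1, 0.0], [2.5, 1.0], [2.9, 0.0],
            [3.2, 1.0], [3.6, 0.0], [3.9, 1.0], [4.2, 0.0],
        ]
    )
    y = np.array([0, 0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1], dtype=float)
    return X, y


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = fit_logistic(None, y)
        assert fit.coef[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_by_two_table_log_odds_ratio(self):
        # cells: x=0 -> 8/32 events, x=1 -> 24/16 events
        x = np.repeat([0.0, 1.0], 40)
        y = np.concatenate([np.ones(8), np.zeros(32), np.ones(24), np.zeros(16)])
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        lor = np.log((24 * 32) / (16 * 8))
        assert fit.coef[1] == pytest.approx(lor, abs=1e-6)
        assert fit.odds_ratio[0] == pytest.approx(np.exp(lor), rel=1e-6)

    def test_matches_grid_search_oracle(self, twelve_points):
        X, y = twelve_points
        fit = fit_logistic(pd.DataFrame(X, columns=["x1", "x2"]), y)
        oracle = _grid_mle(X, y)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-3)

    def test_odds_ratio_is_exp_of_coefficient(self, twelve_points):
        X, y = twelve_points
        fit = fit_logistic(pd.DataFrame(X, columns=["x1", "x2"]), y)
        np.testing.assert_array_equal(fit.odds_ratio, np.exp(fit.coef[1:]))
        assert (fit.ci_low < fit.odds_ratio).all()
        assert (fit.odds_ratio < fit.ci_high).all()

    def test_complete_separation_reported(self):
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_parameter_recovery_within_3_se(self):
        true_b = np.array([-2.0, 0.12])
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(20.0, 8.0, 5000)
            p = 1.0 / (1.0 + np.exp(-(true_b[0] + true_b[1] * x)))
            y = (rng.uniform(size=5000) < p).astype(float)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            if np.all(np.abs(fit.coef - true_b) <= 3 * fit.se):
                hits += 1
        assert hits >= 9

    def test_nagelkerke_null_and_limits(self):
        y = np.array([0.0, 1.0] * 20)
        null = fit_logistic(None, y)
        assert nagelkerke_r2(null, null, len(y)) == 0.0
        near_perfect = LogisticFit(
            predictors=["x"], coef=np.zeros(2), se=np.ones(2),
            wald_p=np.ones(2), llf=-1e-9, n=len(y), converged=True,
        )
        assert nagelkerke_r2(near_perfect, null, len(y)) == pytest.approx(1.0)
        worse = LogisticFit(
            predictors=["x"], coef=np.zeros(2), se=np.ones(2),
            wald_p=np.ones(2), llf=null.llf - 1.0, n=len(y), converged=True,
        )
        with pytest.raises(ComputationError):
            nagelkerke_r2(worse, null, len(y))


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.uniform(size=500) < p).astype(float)
        _, df, _ = hosmer_lemeshow(y, p, groups=10)
        assert df == 8

    def test_perfect_calibration_zero_statistic(self):
        # each bin holds one success and one failure at p = 0.5: O = E
        p = np.full(200, 0.5)
        y = np.tile([0.0, 1.0], 100)
        chi2, _, pval = hosmer_lemeshow(y, p, groups=10)
        assert chi2 == pytest.approx(0.0)
        assert pval == pytest.approx(1.0)

    def test_rejection_rate_near_alpha_when_well_specified(self):
        rejections = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 1000)
            p = 1.0 / (1.0 + np.exp(-(0.3 + 0.8 * x)))
            y = (rng.uniform(size=1000) < p).astype(float)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            phat = 1.0 / (1.0 + np.exp(-(fit.coef[0] + fit.coef[1] * x)))
            _, _, pval = hosmer_lemeshow(y, phat, groups=10)
            rejections += pval < 0.05
        assert 0.005 <= rejections / reps <= 0.13


class TestSelectionAndBattery:
    def test_strong_predictors_all_retained(self):
        rng = np.random.default_rng(3)
        n = 500
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-(0.2 + 1.2 * x1 - 1.0 * x2)))
        y = (rng.uniform(size=n) < p).astype(float)
        fit, trace = backward_lr_selection(
            pd.DataFrame({"x1": x1, "x2": x2}), y, p_out=0.10
        )
        assert fit.predictors == ["x1", "x2"]
        assert trace.steps[-1].removed is None

    def test_noise_predictor_removed(self):
        rng = np.random.default_rng(4)
        n = 500
        x1, noise = rng.normal(0, 1, n), rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-(0.2 + 1.2 * x1)))
        y = (rng.uniform(size=n) < p).astype(float)
        fit, trace = backward_lr_selection(
            pd.DataFrame({"x1": x1, "noise": noise}), y, p_out=0.10
        )
        assert fit.predictors == ["x1"]
        assert trace.steps[0].removed == "noise"
        # the trace strictly shrinks
        sizes = [len(s.retained) for s in trace.steps]
        assert sizes == sorted(sizes, reverse=True)

    def test_battery_with_ai_as_only_informative_predictor(self):
        from adipo.synthetic import CohortTableSpec, MetricSpec, generate_cohort_table

        spec = CohortTableSpec(
            n_early=250, n_late=250,
            area=MetricSpec(700.0, 180.0, 700.0, 180.0, lower=1.0),
            ai=MetricSpec(np.log10(1.30), 0.05, np.log10(1.55), 0.05,
                          log10_scale=True, lower=1.0),
            lipid=MetricSpec(40.0, 12.0, 40.0, 12.0, lower=1.0, upper=100.0),
            corr=np.eye(3),
            seed=6,
        )
        df = generate_cohort_table(spec)
        res = run_paper_models(df)
        for name in ("A", "B", "D"):
            assert res[name].fit.predictors == ["ai"], name
        assert (
            res["F"].diagnostics.nagelkerke_r2 > res["E"].diagnostics.nagelkerke_r2
        )

    def test_subset_sizes_follow_missingness(self, study_table):
        res = run_paper_models(study_table)
        assert {k: v.n for k, v in res.items()} == {
            "A": 77, "B": 139, "C": 77, "D": 83, "E": 77, "F": 77, "G": 77
        }

    def test_deviance_nesting_on_complete_cases(self, study_table):
        sub = study_table.dropna(
            subset=["adipocyte_area_um2", "ai", "lipid_percent"]
        )
        y = (sub["cohort"] == "late").astype(float).to_numpy()
        cols = ["adipocyte_area_um2", "ai", "lipid_percent"]
        dev = {}
        from itertools import combinations

        for k in range(0, 4):
            for combo in combinations(cols, k):
                X = sub[list(combo)] if combo else None
                dev[combo] = fit_logistic(X, y).deviance
        for combo, d in dev.items():
            if not combo:
                continue
            for smaller in combinations(combo, len(combo) - 1):
                assert d <= dev[smaller] + 1e-8

    def test_empty_table_skips_all_models(self):
        df = pd.DataFrame(
            columns=["sample_id", "cohort", "adipocyte_area_um2", "ai", "lipid_percent"]
        )
        res = run_paper_models(df)
        assert all(r.skipped for r in res.values())
        assert set(res) == set(MODEL_PREDICTORS)
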