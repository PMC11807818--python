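"""Cox fits, trend test, restricted cubic splines, PH diagnostics and AFT."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy.optimize import minimize_scalar

from diisurv.cohort import assign_quartiles
from diisurv.errors import (
    InsufficientEventsError,
    InvalidInputError,
    NoEventsError,
    NonIdentifiableError,
)
from diisurv.survival import (
    build_design,
    fit_aft,
    fit_cox,
    rcs_basis,
    rcs_knots,
    rcs_nonlinearity,
    schoenfeld_ph_test,
    trend_test,
)
from tests.conftest import make_survival_frame


def efron_pl(beta, t, e, x):
    """Hand-written Efron-tie partial likelihood (independent oracle)."""
    ll = 0.0
    for tk in np.unique(t[e == 1]):
        D = (t == tk) & (e == 1)
        R = t >= tk
        d = D.sum()
        ll += beta * x[D].sum()
        rs = np.exp(beta * x[R]).sum()
        ds = np.exp(beta * x[D]).sum()
        for l in range(d):
            ll -= np.log(rs - l / d * ds)
    return ll


def grid_oracle(t, e, x, lo=-3.0, hi=3.0):
    grid = np.linspace(lo, hi, 1201)
    vals = [efron_pl(b, t, e, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    r = minimize_scalar(lambda b: -efron_pl(b, t, e, x),
                        bounds=(b0 - 0.02, b0 + 0.02), method="bounded",
                        options={"xatol": 1e-9})
    return float(r.x)


def _as_cohort(t, e, x):
    return pd.DataFrame({"dii": x, "follow_up_weeks": t,
                         "event": np.where(e == 1, "cld", "censored")})


class TestCoxOracle:
    def test_four_subject_worked_example(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(_as_cohort(t, e, x), mode="continuous", tier=1,
                      compute_trend=False)
        oracle = grid_oracle(t, e, x)
        assert np.log(fit.continuous_hr.hr) == pytest.approx(oracle, abs=1e-4)

    def test_random_small_datasets(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 15:
            n = int(rng.integers(4, 9))
            x = rng.standard_normal(n).round(2)
            t = rng.exponential(1.0, n).round(3) + 0.001
            e = rng.integers(0, 2, n)
            if e.sum() < 2:
                continue
            try:
                fit = fit_cox(_as_cohort(t, e, x), mode="continuous", tier=1,
                              compute_trend=False)
            except Exception:
                continue
            b = np.log(fit.continuous_hr.hr)
            if abs(b) > 2.5:
                continue
            assert b == pytest.approx(grid_oracle(t, e, x), abs=1e-4)
            checked += 1

    def test_two_group_rate_ratio_two(self):
        rng = np.random.default_rng(3)
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        df = make_survival_frame(rng, n, beta=np.log(2.0), rate=2e-3,
                                 exposure=x)
        fit = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        assert 1.9 <= fit.continuous_hr.hr <= 2.1

    def test_null_covariate_recovers_unity(self):
        rng = np.random.default_rng(4)
        df = make_survival_frame(rng, 20_000, beta=0.0, rate=2e-3)
        fit = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        assert 0.97 <= fit.continuous_hr.hr <= 1.03

    def test_no_events_raises(self):
        df = _as_cohort(np.array([1.0, 2.0]), np.array([0, 0]),
                        np.array([0.5, -0.5]))
        with pytest.raises(NoEventsError):
            fit_cox(df, mode="continuous", tier=1, compute_trend=False)

    def test_constant_covariate_named(self, cohort):
        bad = cohort.copy()
        bad["sex"] = "female"
        with pytest.raises(NonIdentifiableError, match="sex"):
            fit_cox(bad, mode="continuous", tier=3, compute_trend=False)

    def test_quartile_fit_shapes(self, cohort):
        fit = fit_cox(cohort, mode="quartile", tier=2)
        assert set(fit.quartile_hr) == {"Q2", "Q3", "Q4"}
        for e in fit.quartile_hr.values():
            assert e.ci_low <= e.hr <= e.ci_high
            assert 0 <= e.p <= 1
        assert fit.trend_p is not None and 0 <= fit.trend_p <= 1


class TestTrend:
    def test_strong_effect_gives_tiny_p(self):
        rng = np.random.default_rng(5)
        df = make_survival_frame(rng, 20_000, beta=0.2, rate=2e-3)
        df["dii_quartile"] = assign_quartiles(df["dii"]).to_numpy()
        p = trend_test(df, "dii", tier=1)
        assert p < 1e-3

    def test_sign_agreement_with_continuous_fit(self):
        rng = np.random.default_rng(6)
        df = make_survival_frame(rng, 10_000, beta=0.15, rate=2e-3)
        df["dii_quartile"] = assign_quartiles(df["dii"]).to_numpy()
        cont = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        # refit trend model to inspect the coefficient sign
        med = df.groupby("dii_quartile", observed=False)["dii"].median()
        tdf = df.assign(dii=df["dii_quartile"].map(med).astype(float))
        tfit = fit_cox(tdf, mode="continuous", tier=1, compute_trend=False)
        assert np.sign(np.log(tfit.continuous_hr.hr)) \
            == np.sign(np.log(cont.continuous_hr.hr))

    def test_degenerate_exposure_rejected(self):
        df = _as_cohort(np.linspace(1, 9, 9), np.ones(9, int), np.zeros(9))
        with pytest.warns(UserWarning):
            df["dii_quartile"] = assign_quartiles(df["dii"]).to_numpy()
        with pytest.raises(InvalidInputError):
            trend_test(df, "dii", tier=1)


class TestSplines:
    def test_basis_linear_at_or_below_first_knot(self):
        knots = np.array([1.0, 2.0, 3.0, 5.0])
        x = np.linspace(-2, 1.0, 50)
        B = rcs_basis(x, knots)
        np.testing.assert_array_equal(B[:, 1:], 0.0)
        np.testing.assert_allclose(B[:, 0], x)

    def test_basis_linear_beyond_last_knot(self):
        # second derivative vanishes outside the boundary knots
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.linspace(3.5, 6.0, 40)
        B = rcs_basis(x, knots)
        for j in range(B.shape[1]):
            d2 = np.diff(B[:, j], 2)
            np.testing.assert_allclose(d2, 0.0, atol=1e-9)

    def test_knot_quantiles(self):
        x = np.linspace(0, 1, 10_001)
        k = rcs_knots(x, 4)
        np.testing.assert_allclose(k, [0.05, 0.35, 0.65, 0.95], atol=1e-3)
        with pytest.raises(InvalidInputError):
            rcs_knots(np.ones(100), 4)

    def test_quadratic_hazard_detected(self):
        rng = np.random.default_rng(7)
        df = make_survival_frame(rng, 10_000, beta=0.3, quad=0.25, rate=1e-3)
        sp = rcs_nonlinearity(df, tier=1)
        assert sp.nonlinear_p < 0.05
        assert sp.overall_p < sp.nonlinear_p or sp.overall_p < 0.05

    def test_linear_hazard_not_flagged(self):
        rng = np.random.default_rng(8)
        df = make_survival_frame(rng, 10_000, beta=0.3, rate=1e-3)
        sp = rcs_nonlinearity(df, tier=1)
        assert sp.nonlinear_p > 0.01
        assert sp.overall_p < 1e-6   # the linear association is real
        assert len(sp.knots) == 4 and np.all(np.diff(sp.knots) > 0)


class TestSchoenfeld:
    def test_per_covariate_matches_lifelines(self):
        rng = np.random.default_rng(9)
        n = 800
        x1 = rng.standard_normal(n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        T = rng.exponential(1 / np.exp(0.5 * x1 + 0.3 * x2))
        C = rng.exponential(2.0, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "_T": np.minimum(T, C),
                           "_E": (T <= C).astype(int)})
        cph = CoxPHFitter().fit(df, "_T", "_E")
        cph._train_df = df
        mine = schoenfeld_ph_test(cph, time_transform="km")
        ref = proportional_hazard_test(cph, df, time_transform="km")
        for nm, p in zip(ref.name, ref.p_value):
            assert mine.per_covariate[nm] == pytest.approx(p, abs=1e-10)

    def test_single_covariate_global_equals_per_covariate(self):
        rng = np.random.default_rng(10)
        df = make_survival_frame(rng, 2_000, beta=0.3, rate=2e-3)
        fit = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        res = schoenfeld_ph_test(fit)
        assert res.global_p == pytest.approx(res.per_covariate["dii"], abs=1e-10)

    def test_time_varying_effect_detected(self):
        rng = np.random.default_rng(11)
        n = 5_000
        x = rng.standard_normal(n)
        lam1 = 0.002 * np.exp(0.5 * x)
        lam2 = 0.002 * np.exp(-0.5 * x)
        E1 = rng.exponential(1 / lam1)
        T = np.where(E1 < 150.0, E1, 150.0 + rng.exponential(1 / lam2))
        df = _as_cohort(np.minimum(T, 300.0),
                        (T <= 300.0).astype(int), x)
        fit = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        assert schoenfeld_ph_test(fit).global_p < 0.05

    def test_too_few_events(self):
        df = _as_cohort(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]),
                        np.array([0.3, -0.2, 0.1]))
        fit = fit_cox(df, mode="continuous", tier=1, compute_trend=False)
        with pytest.raises(InsufficientEventsError):
            schoenfeld_ph_test(fit)


class TestAFT:
    def test_weibull_acceleration_factor_recovery(self):
        rng = np.random.default_rng(12)
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        shape = 1.3
        scale0 = 400.0
        # AFT: T = T0 * exp(log(0.8) * x) -> acceleration factor 0.8
        T = scale0 * np.exp(np.log(0.8) * x) * \
            rng.weibull(shape, n)
        t = np.minimum(T, 600.0)
        df = _as_cohort(t, (T <= 600.0).astype(int), x)
        fit = fit_aft(df, mode="continuous", tier=1)
        assert 0.78 <= fit.time_ratios["dii"].hr <= 0.82

    def test_null_covariate_time_ratio_near_one(self):
        rng = np.random.default_rng(13)
        df = make_survival_frame(rng, 10_000, beta=0.0, rate=2e-3)
        fit = fit_aft(df, mode="continuous", tier=1)
        e = fit.time_ratios["dii"]
        assert 0.95 <= e.hr <= 1.05
        assert e.ci_low <= 1.0 <= e.ci_high

    def test_exponential_data_gives_unit_weibull_shape(self):
        rng = np.random.default_rng(14)
        df = make_survival_frame(rng, 10_000, beta=0.3, rate=2e-3)
        fit = fit_aft(df, mode="continuous", tier=1)
        rho = float(np.exp(fit.fitter.summary.loc[("rho_", "Intercept"), "coef"]))
        assert 0.95 <= rho <= 1.05


class TestDesign:
    def test_unknown_level_rejected(self, cohort):
        bad = cohort.copy()
        bad.loc[bad.index[0], "sex"] = "unknown"
        with pytest.raises(InvalidInputError, match="sex"):
            build_design(bad, ["sex"])

    def test_tier3_design_reference_levels(self, cohort):
        X = build_design(cohort, ["sex", "bp_category"],
                         cohort[["dii"]])
        assert "sex_male" in X.columns and "sex_female" not in X.columns
        for c in ["bp_category_elevated", "bp_category_stage1",
                  "bp_category_stage2"]:
            assert c in X.columns
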