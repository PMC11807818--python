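"""Exposure-outcome survival inference.

Cox proportional-hazards fits (quartile and continuous exposure, three
adjustment tiers), the quartile-median trend test, restricted-cubic-spline
nonlinearity assessment, Schoenfeld-residual proportional-hazards
diagnostics with a Weibull AFT fallback, Fine-Gray competing-risk models and
post-diagnosis progression analysis.

Adjustment tiers: tier 1 is unadjusted; tier 2 adds age, sex, ethnicity,
education and the Townsend deprivation index; tier 3 further adds alcohol,
smoking, BMI, physical activity, blood-pressure category and diabetes.
Follow-up is measured in weeks throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, WeibullAFTFitter
from lifelines.statistics import proportional_hazard_test
from scipy.stats import chi2, norm

from .cohort import assign_quartiles
from .errors import (
    FittingError,
    InsufficientEventsError,
    InvalidInputError,
    NoEventsError,
    NonIdentifiableError,
)
from .finegray import FineGrayFit, fine_gray_fit

__all__ = [
    "TIER2_COVARIATES",
    "TIER3_COVARIATES",
    "HREstimate",
    "SurvivalFit",
    "CompetingRiskFit",
    "SplineFit",
    "PHTestResult",
    "AFTFit",
    "build_design",
    "fit_cox",
    "trend_test",
    "rcs_basis",
    "rcs_knots",
    "rcs_nonlinearity",
    "schoenfeld_ph_test",
    "fit_aft",
    "fit_fine_gray",
    "progression_analysis",
]

TIER2_COVARIATES = ["age", "sex", "ethnicity", "education", "tdi"]
TIER3_COVARIATES = TIER2_COVARIATES + [
    "alcohol", "smoking", "bmi", "physical_activity", "bp_category", "diabetes",
]

# canonical category orders; the first level is the reference
_CATEGORY_ORDERS = {
    "sex": ["female", "male"],
    "ethnicity": ["white", "others"],
    "education": ["high", "median", "low"],
    "alcohol": ["rare", "previous", "current"],
    "smoking": ["rare", "previous", "current"],
    "physical_activity": ["reach", "no-reach"],
    "bp_category": ["normal", "elevated", "stage1", "stage2"],
    "diabetes": ["no", "yes"],
    "age_group": ["younger", "older"],
    "tdi_group": ["low", "high"],
}

_CONTINUOUS = {"age", "tdi", "bmi"}


def tier_covariates(tier: int) -> list[str]:
    if tier == 1:
        return []
    if tier == 2:
        return list(TIER2_COVARIATES)
    if tier == 3:
        return list(TIER3_COVARIATES)
    raise InvalidInputError(f"tier must be 1, 2 or 3, got {tier}")


def _encode(cohort: pd.DataFrame, col: str) -> pd.DataFrame:
    """Dummy-code a covariate against its canonical reference level."""
    if col in _CONTINUOUS:
        return cohort[[col]].astype(float)
    order = _CATEGORY_ORDERS.get(col)
    cat = pd.Categorical(cohort[col], categories=order) if order else \
        pd.Categorical(cohort[col])
    if pd.isna(cat).any():
        bad = sorted(set(cohort[col]) - set(cat.categories))
        raise InvalidInputError(f"unknown levels {bad} in covariate '{col}'")
    dummies = pd.get_dummies(pd.Series(cat, index=cohort.index),
                             prefix=col, drop_first=True, dtype=float)
    return dummies


def build_design(
    cohort: pd.DataFrame,
    covariates: list[str],
    exposure_cols: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exposure columns followed by dummy-coded adjustment covariates.

    Raises :class:`NonIdentifiableError` naming any constant column.
    """
    parts = []
    if exposure_cols is not None:
        parts.append(exposure_cols.astype(float))
    for c in covariates:
        if c not in cohort.columns:
            raise InvalidInputError(f"covariate '{c}' not in cohort")
        parts.append(_encode(cohort, c))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise NonIdentifiableError(f"covariate column '{c}' is constant")
    return X


@dataclass
class HREstimate:
    """A hazard-ratio (or sHR / time-ratio) point estimate with Wald CI."""

    hr: float
    ci_low: float
    ci_high: float
    p: float

    def as_tuple(self):
        return (self.hr, self.ci_low, self.ci_high, self.p)


@dataclass
class SurvivalFit:
    """Cox model results for one exposure/outcome/tier combination."""

    model_tier: int
    exposure: str
    outcome: str
    mode: str                                 # "quartile" or "continuous"
    quartile_hr: dict = field(default_factory=dict)   # Q2..Q4 -> HREstimate
    continuous_hr: HREstimate | None = None
    trend_p: float | None = None
    n: int = 0
    n_events: int = 0
    ph_test: "PHTestResult | None" = None
    fitter: object = field(default=None, repr=False)


@dataclass
class CompetingRiskFit:
    """Fine-Gray results; same shape as :class:`SurvivalFit`."""

    model_tier: int
    exposure: str
    primary_event: str
    competing_events: tuple
    mode: str
    quartile_shr: dict = field(default_factory=dict)
    continuous_shr: HREstimate | None = None
    n: int = 0
    n_events: int = 0
    fit: FineGrayFit | None = field(default=None, repr=False)


@dataclass
class SplineFit:
    """Restricted-cubic-spline Cox fit with nonlinearity Wald tests."""

    knots: np.ndarray
    coefs: np.ndarray
    overall_p: float
    nonlinear_p: float
    fitter: object = field(default=None, repr=False)


@dataclass
class PHTestResult:
    """Grambsch-Therneau proportional-hazards test."""

    per_covariate: dict
    global_p: float
    time_transform: str


@dataclass
class AFTFit:
    """Weibull accelerated-failure-time fit (time-ratio scale)."""

    model_tier: int
    exposure: str
    time_ratios: dict          # column -> HREstimate (acceleration factors)
    fitter: object = field(default=None, repr=False)


def _check_events(ind: np.ndarray, what: str = "events") -> int:
    n_ev = int(ind.sum())
    if n_ev == 0:
        raise NoEventsError(f"no {what} in the data")
    return n_ev


def _cox_frame(
    cohort: pd.DataFrame,
    X: pd.DataFrame,
    outcome: str,
    duration_col: str,
    event_col: str,
) -> tuple[pd.DataFrame, int]:
    ind = (cohort[event_col] == outcome).to_numpy()
    n_ev = _check_events(ind, f"'{outcome}' events")
    df = X.copy()
    df["_T"] = cohort[duration_col].astype(float).to_numpy()
    df["_E"] = ind.astype(int)
    return df, n_ev


def _fit_cph(df: pd.DataFrame, ties: str = "efron") -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_T", event_col="_E",
                    fit_options={"step_size": 0.95, "precision": 1e-9})
        except Exception as exc:
            raise FittingError(f"Cox fit failed: {exc}") from exc
    cph._train_df = df  # retained for residual-based diagnostics
    return cph


def _hr_from_summary(summ: pd.Series) -> HREstimate:
    return HREstimate(
        hr=float(np.exp(summ["coef"])),
        ci_low=float(np.exp(summ["coef lower 95%"])),
        ci_high=float(np.exp(summ["coef upper 95%"])),
        p=float(summ["p"]),
    )


def _quartile_dummies(labels: pd.Series) -> pd.DataFrame:
    lab = pd.Categorical(labels, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True)
    return pd.get_dummies(pd.Series(lab, index=labels.index), prefix="quartile",
                          drop_first=True, dtype=float)


def fit_cox(
    cohort: pd.DataFrame,
    exposure: str = "dii",
    mode: str = "continuous",
    tier: int = 3,
    outcome: str = "cld",
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
    ties: str = "efron",
    compute_trend: bool = True,
    quartile_col: str | None = None,
) -> SurvivalFit:
    """Cox PH fit of an exposure on an outcome at a given adjustment tier.

    ``mode='quartile'`` enters the exposure as Q2-Q4 indicators against Q1
    and (by default) also runs the quartile-median trend test;
    ``mode='continuous'`` enters it per unit.  Ties are handled by the Efron
    approximation (lifelines' default); ``ties='breslow'`` is unsupported by
    the backend and kept only to document the choice.
    """
    if mode not in ("quartile", "continuous"):
        raise InvalidInputError(f"mode must be 'quartile' or 'continuous', got {mode}")
    covs = tier_covariates(tier)
    if mode == "continuous":
        expo = cohort[[exposure]].astype(float)
    else:
        qcol = quartile_col or f"{exposure}_quartile"
        labels = cohort[qcol] if qcol in cohort.columns else assign_quartiles(cohort[exposure])
        expo = _quartile_dummies(labels)
    X = build_design(cohort, covs, expo)
    df, n_ev = _cox_frame(cohort, X, outcome, duration_col, event_col)
    cph = _fit_cph(df, ties)

    fit = SurvivalFit(model_tier=tier, exposure=exposure, outcome=outcome,
                      mode=mode, n=len(df), n_events=n_ev, fitter=cph)
    if mode == "continuous":
        fit.continuous_hr = _hr_from_summary(cph.summary.loc[exposure])
    else:
        for q in ("Q2", "Q3", "Q4"):
            fit.quartile_hr[q] = _hr_from_summary(cph.summary.loc[f"quartile_{q}"])
        if compute_trend:
            qcol2 = quartile_col or f"{exposure}_quartile"
            labels = cohort[qcol2] if qcol2 in cohort.columns else \
                assign_quartiles(cohort[exposure])
            fit.trend_p = trend_test(cohort, exposure, labels=labels, tier=tier,
                                     outcome=outcome, duration_col=duration_col,
                                     event_col=event_col)
    return fit


def trend_test(
    cohort: pd.DataFrame,
    exposure: str,
    labels: pd.Series | None = None,
    tier: int = 3,
    outcome: str = "cld",
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
) -> float:
    """P for trend: quartile medians of the exposure entered as continuous.

    Each participant's quartile label is replaced by the within-quartile
    median exposure, the Cox model refit, and the Wald p-value for that term
    returned.  The quartile medians must be strictly increasing.
    """
    if labels is None:
        qcol = f"{exposure}_quartile"
        if qcol not in cohort.columns:
            raise InvalidInputError(f"no quartile labels: column '{qcol}' absent")
        labels = cohort[qcol]
    if pd.isna(labels).any():
        raise InvalidInputError("quartile labels contain missing values")
    med = cohort[exposure].astype(float).groupby(np.asarray(labels)).median()
    med = med.reindex(["Q1", "Q2", "Q3", "Q4"]).dropna()
    if len(med) < 2:
        raise InvalidInputError("degenerate exposure: a single quartile present")
    if not np.all(np.diff(med.to_numpy()) > 0):
        raise InvalidInputError(
            f"quartile medians are not strictly increasing: {med.to_dict()}"
        )
    trend_var = pd.DataFrame(
        {"quartile_median": pd.Series(np.asarray(labels), index=cohort.index).map(med).astype(float)}
    )
    X = build_design(cohort, tier_covariates(tier), trend_var)
    df, _ = _cox_frame(cohort, X, outcome, duration_col, event_col)
    cph = _fit_cph(df)
    return float(cph.summary.loc["quartile_median", "p"])


def rcs_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knot placement at Harrell's recommended quantiles (3-5 knots)."""
    quantiles = {
        3: [10, 50, 90],
        4: [5, 35, 65, 95],
        5: [5, 27.5, 50, 72.5, 95],
    }
    if n_knots not in quantiles:
        raise InvalidInputError(f"n_knots must be 3, 4 or 5, got {n_knots}")
    k = np.percentile(np.asarray(x, dtype=float), quantiles[n_knots])
    if not np.all(np.diff(k) > 0):
        raise InvalidInputError("exposure has too few distinct values for the knots")
    return k


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear tails, k-1 columns.

    Column 0 is x itself; columns 1..k-2 are the restricted cubic terms,
    scaled by (k_last - k_first)^2 so coefficients stay comparable.  At or
    below the first knot every nonlinear column is exactly zero.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if len(k) < 3 or not np.all(np.diff(k) > 0):
        raise InvalidInputError("need >= 3 strictly increasing knots")
    t1, tl, tl1 = k[0], k[-1], k[-2]
    scale = (tl - t1) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for tj in k[:-2]:
        term = (
            cube(x - tj)
            - cube(x - tl1) * (tl - tj) / (tl - tl1)
            + cube(x - tl) * (tl1 - tj) / (tl - tl1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def _wald_p(params: np.ndarray, cov: np.ndarray, idx: list[int]) -> float:
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular covariance in Wald test: {exc}") from exc
    return float(chi2.sf(stat, df=len(idx)))


def rcs_nonlinearity(
    cohort: pd.DataFrame,
    exposure: str = "dii",
    tier: int = 3,
    n_knots: int = 4,
    outcome: str = "cld",
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
) -> SplineFit:
    """Dose-response nonlinearity via a restricted-cubic-spline Cox fit.

    ``overall_p`` is the Wald test of all spline terms (any association);
    ``nonlinear_p`` tests only the k-2 nonlinear terms (departure from
    linearity).
    """
    x = cohort[exposure].astype(float).to_numpy()
    knots = rcs_knots(x, n_knots)
    basis = rcs_basis(x, knots)
    names = [f"rcs_{exposure}_{j}" for j in range(basis.shape[1])]
    expo = pd.DataFrame(basis, columns=names, index=cohort.index)
    X = build_design(cohort, tier_covariates(tier), expo)
    df, _ = _cox_frame(cohort, X, outcome, duration_col, event_col)
    cph = _fit_cph(df)
    params = cph.params_.to_numpy()
    cov = cph.variance_matrix_.to_numpy()
    all_idx = [list(cph.params_.index).index(nm) for nm in names]
    nl_idx = all_idx[1:]
    return SplineFit(
        knots=knots,
        coefs=params[all_idx],
        overall_p=_wald_p(params, cov, all_idx),
        nonlinear_p=_wald_p(params, cov, nl_idx),
        fitter=cph,
    )


def schoenfeld_ph_test(
    fit: SurvivalFit | CoxPHFitter,
    cohort: pd.DataFrame | None = None,
    time_transform: str = "km",
) -> PHTestResult:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Correlates scaled Schoenfeld residuals with a transform of event time
    (default: the Kaplan-Meier transform 1 - S(t)); returns a chi-square
    p-value per covariate and the global joint test.
    """
    cph = fit.fitter if isinstance(fit, SurvivalFit) else fit
    if cph is None:
        raise InvalidInputError("fit carries no underlying Cox fitter")
    events = cph.event_observed
    d = float(events.sum())
    if d < 2:
        raise InsufficientEventsError("need >= 2 events for the PH test")
    durations, weights = cph.durations, cph.weights
    if time_transform == "km":
        kmf = KaplanMeierFitter().fit(durations, events, weights=weights)
        g_all = (1 - kmf.survival_function_.loc[durations, "KM_estimate"]).to_numpy()
    elif time_transform == "rank":
        g_all = np.cumsum(np.asarray(events, dtype=float))
    elif time_transform == "identity":
        g_all = np.asarray(durations, dtype=float)
    elif time_transform == "log":
        g_all = np.log(np.asarray(durations, dtype=float))
    else:
        raise InvalidInputError(f"unknown time transform '{time_transform}'")
    g = g_all[np.asarray(events, dtype=bool)]
    gc = g - g.mean()
    ssg = float((gc ** 2).sum())

    train = cohort if cohort is not None else getattr(cph, "_train_df", None)
    if train is None:
        raise InvalidInputError("training data required for Schoenfeld residuals")
    resid = cph.compute_residuals(train, kind="scaled_schoenfeld")
    sr = resid[cph.params_.index].to_numpy(dtype=float)
    se2 = (cph.standard_errors_ ** 2).to_numpy()
    q = gc @ sr                                    # = d * V u
    per_stat = q ** 2 / (d * se2 * ssg)
    per_p = chi2.sf(per_stat, df=1)
    V = cph.variance_matrix_.to_numpy()
    u = np.linalg.solve(V, q) / d
    global_stat = float(d * u @ V @ u / ssg)
    global_p = float(chi2.sf(global_stat, df=len(u)))
    return PHTestResult(
        per_covariate={nm: float(p) for nm, p in zip(cph.params_.index, per_p)},
        global_p=global_p,
        time_transform=time_transform,
    )


def fit_aft(
    cohort: pd.DataFrame,
    exposure: str = "dii",
    mode: str = "continuous",
    tier: int = 3,
    outcome: str = "cld",
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
    distribution: str = "weibull",
) -> AFTFit:
    """Weibull accelerated-failure-time fit (fallback when PH fails).

    Reported quantities are time ratios exp(coef): values below 1 mean the
    covariate shortens time to event.  Log-normal and log-logistic
    alternatives are available via ``distribution``.
    """
    from lifelines import LogLogisticAFTFitter, LogNormalAFTFitter

    fitters = {
        "weibull": WeibullAFTFitter,
        "lognormal": LogNormalAFTFitter,
        "loglogistic": LogLogisticAFTFitter,
    }
    if distribution not in fitters:
        raise InvalidInputError(f"unknown AFT distribution '{distribution}'")
    if mode == "continuous":
        expo = cohort[[exposure]].astype(float)
    else:
        qcol = f"{exposure}_quartile"
        labels = cohort[qcol] if qcol in cohort.columns else assign_quartiles(cohort[exposure])
        expo = _quartile_dummies(labels)
    X = build_design(cohort, tier_covariates(tier), expo)
    df, _ = _cox_frame(cohort, X, outcome, duration_col, event_col)
    aft = fitters[distribution]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            aft.fit(df, duration_col="_T", event_col="_E")
        except Exception as exc:
            raise FittingError(f"AFT fit failed to converge: {exc}") from exc
    summ = aft.summary
    primary = summ.index.get_level_values(0)[0]
    ratios = {}
    for col in X.columns:
        row = summ.loc[(primary, col)]
        ratios[col] = HREstimate(
            hr=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p=float(row["p"]),
        )
    return AFTFit(model_tier=tier, exposure=exposure, time_ratios=ratios, fitter=aft)


def fit_fine_gray(
    cohort: pd.DataFrame,
    primary_event: str = "cld",
    competing_events: tuple = ("cirrhosis", "liver_cancer", "death"),
    exposure: str = "dii",
    mode: str = "continuous",
    tier: int = 3,
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
) -> CompetingRiskFit:
    """Fine-Gray subdistribution-hazard fit with robust CIs.

    Event labels outside the primary/competing sets count as censored.
    """
    ev = cohort[event_col]
    code = np.where(ev == primary_event, 1, np.where(ev.isin(competing_events), 2, 0))
    n_primary = _check_events(code == 1, f"primary '{primary_event}' events")
    if (code != 2).sum() == 0 or n_primary == 0:
        raise NoEventsError("all events are competing events")
    if mode == "continuous":
        expo = cohort[[exposure]].astype(float)
    else:
        qcol = f"{exposure}_quartile"
        labels = cohort[qcol] if qcol in cohort.columns else assign_quartiles(cohort[exposure])
        expo = _quartile_dummies(labels)
    X = build_design(cohort, tier_covariates(tier), expo)
    fgfit = fine_gray_fit(cohort[duration_col].astype(float).to_numpy(), code, X)
    summ = fgfit.summary()

    out = CompetingRiskFit(
        model_tier=tier, exposure=exposure, primary_event=primary_event,
        competing_events=tuple(competing_events), mode=mode, n=len(cohort),
        n_events=n_primary, fit=fgfit,
    )

    def est(nm):
        r = summ.loc[nm]
        return HREstimate(hr=float(r["sHR"]), ci_low=float(r["ci_low"]),
                          ci_high=float(r["ci_high"]), p=float(r["p"]))

    if mode == "continuous":
        out.continuous_shr = est(exposure)
    else:
        for q in ("Q2", "Q3", "Q4"):
            out.quartile_shr[q] = est(f"quartile_{q}")
    return out


def progression_analysis(
    cld_cases: pd.DataFrame,
    outcome: str = "cirrhosis",
    exposure: str = "dii",
    mode: str = "continuous",
    tier: int = 3,
    duration_col: str = "prog_time_weeks",
    event_col: str = "prog_event",
) -> SurvivalFit:
    """Progression among incident cases: time origin reset to diagnosis.

    ``cld_cases`` must contain only participants with an incident primary
    event, with post-diagnosis follow-up in ``duration_col`` and the
    progression outcome label in ``event_col``.
    """
    if len(cld_cases) == 0:
        raise NoEventsError("empty case set for progression analysis")
    return fit_cox(cld_cases, exposure=exposure, mode=mode, tier=tier,
                   outcome=outcome, duration_col=duration_col,
                   event_col=event_col)
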