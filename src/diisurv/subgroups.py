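"""Stratified analyses, interaction tests, sensitivity subsets and
DII-biomarker correlations.

Subgroup fits re-run the adjusted Cox model within each stratum of a
categorical covariate (dropping only the stratifier itself from the
adjustment set); heterogeneity is assessed by a Wald test of
exposure x stratum product terms in the pooled model, with the exposure
entered continuously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr, spearmanr

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NoEventsError,
)
from .survival import (
    HREstimate,
    _cox_frame,
    _fit_cph,
    _hr_from_summary,
    build_design,
    tier_covariates,
)

__all__ = [
    "SubgroupResult",
    "StratumEstimate",
    "subgroup_analysis",
    "typical_diet_subset",
    "biomarker_correlation",
]

# stratifier label -> adjustment covariate it replaces
_STRATIFIER_SOURCE = {"age_group": "age", "tdi_group": "tdi"}


@dataclass
class StratumEstimate:
    stratum: str
    estimate: HREstimate | None
    n: int
    n_events: int
    skipped: bool = False


@dataclass
class SubgroupResult:
    stratifier: str
    exposure: str
    strata: list = field(default_factory=list)
    interaction_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            est = s.estimate
            rows.append({
                "stratifier": self.stratifier,
                "stratum": s.stratum,
                "hr": est.hr if est else np.nan,
                "ci_low": est.ci_low if est else np.nan,
                "ci_high": est.ci_high if est else np.nan,
                "p": est.p if est else np.nan,
                "n": s.n,
                "n_events": s.n_events,
                "interaction_p": self.interaction_p,
            })
        return pd.DataFrame(rows)


def subgroup_analysis(
    cohort: pd.DataFrame,
    stratifier: str,
    exposure: str = "dii",
    tier: int = 3,
    outcome: str = "cld",
    duration_col: str = "follow_up_weeks",
    event_col: str = "event",
) -> SubgroupResult:
    """Per-stratum adjusted HRs plus an interaction p-value.

    Strata with zero events are flagged and skipped with a warning rather
    than aborting the whole analysis.
    """
    if stratifier not in cohort.columns:
        raise InvalidInputError(f"stratifier '{stratifier}' not in cohort")
    covs = [c for c in tier_covariates(tier)
            if c != stratifier and c != _STRATIFIER_SOURCE.get(stratifier)]
    result = SubgroupResult(stratifier=stratifier, exposure=exposure)

    levels = pd.unique(cohort[stratifier])
    for lev in levels:
        sub = cohort[cohort[stratifier] == lev]
        n_ev = int((sub[event_col] == outcome).sum())
        if n_ev == 0:
            warnings.warn(f"stratum {stratifier}={lev!r} has no events; skipped",
                          stacklevel=2)
            result.strata.append(StratumEstimate(str(lev), None, len(sub), 0, True))
            continue
        expo = sub[[exposure]].astype(float)
        X = build_design(sub, covs, expo)
        df, _ = _cox_frame(sub, X, outcome, duration_col, event_col)
        cph = _fit_cph(df)
        result.strata.append(
            StratumEstimate(str(lev), _hr_from_summary(cph.summary.loc[exposure]),
                            len(sub), n_ev)
        )

    # pooled model with exposure x stratum product terms (Wald heterogeneity test)
    strat_dummies = pd.get_dummies(cohort[stratifier], prefix=stratifier,
                                   drop_first=True, dtype=float)
    inter = strat_dummies.mul(cohort[exposure].astype(float), axis=0)
    inter.columns = [f"{exposure}_x_{c}" for c in strat_dummies.columns]
    pooled_covs = [c for c in tier_covariates(tier)
                   if c != _STRATIFIER_SOURCE.get(stratifier)]
    if stratifier not in pooled_covs:
        pooled_covs.append(stratifier)
    expo_cols = pd.concat([cohort[[exposure]].astype(float), inter], axis=1)
    Xp = build_design(cohort, pooled_covs, expo_cols)
    dfp, _ = _cox_frame(cohort, Xp, outcome, duration_col, event_col)
    cph_p = _fit_cph(dfp)
    names = list(cph_p.params_.index)
    idx = [names.index(c) for c in inter.columns]
    b = cph_p.params_.to_numpy()[idx]
    V = cph_p.variance_matrix_.to_numpy()[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    result.interaction_p = float(chi2.sf(stat, df=len(idx)))
    return result


def typical_diet_subset(cohort: pd.DataFrame, typical_flag: str = "typical_diet") -> pd.DataFrame:
    """Restrict to participants whose reported diet was typical of their
    habitual intake, guarding against dietary change over follow-up."""
    if typical_flag not in cohort.columns:
        raise InvalidInputError(f"flag column '{typical_flag}' absent from cohort")
    return cohort[cohort[typical_flag].astype(bool)].copy()


def biomarker_correlation(
    dii,
    biomarkers: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate the DII with inflammatory biomarkers (WBC, neutrophils, CRP).

    Returns one row per biomarker column with the coefficient, p-value,
    number of complete pairs, and the method used.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidInputError(f"method must be 'pearson' or 'spearman', got {method}")
    fn = pearsonr if method == "pearson" else spearmanr
    x = pd.Series(np.asarray(dii, dtype=float)).reset_index(drop=True)
    rows = []
    for col in biomarkers.columns:
        if col == "participant_id":
            continue
        y = pd.Series(biomarkers[col].to_numpy(dtype=float))
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"fewer than 3 complete pairs for biomarker '{col}'"
            )
        r, p = fn(x[ok], y[ok])
        rows.append({"biomarker": col, "r": float(r), "p": float(p),
                     "n": int(ok.sum()), "method": method})
    return pd.DataFrame(rows)
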