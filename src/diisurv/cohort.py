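"""Cohort construction: exclusions, 1-year landmark, covariate reclassification
and exposure-quartile assignment.

Produces the analysis-ready table consumed by the survival models.  Exclusion
reasons are logged one per dropped participant with first-match precedence
missing-data -> prior-disease -> landmark; the landmark drops anyone whose
event (or censoring) falls inside the first year of follow-up, reducing
reverse causation from latent disease present at entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dietary_scoring import (
    DIIReferenceTable,
    density_reference_from_cohort,
    score_intakes,
)
from .diet_quality import HEIStandards, MEDSConfig, compute_hei2020, compute_meds
from .errors import InvalidInputError

__all__ = [
    "LANDMARK_WEEKS",
    "AGE_MEDIAN_YEARS",
    "TDI_MEDIAN",
    "classify_bp",
    "reclassify_education",
    "dichotomize",
    "assign_quartiles",
    "apply_exclusions",
    "build_cohort",
    "ExclusionLog",
]

#: One year expressed in weeks (365.25 days).
LANDMARK_WEEKS = 365.25 / 7.0
#: Cohort median age used for the older/younger split.
AGE_MEDIAN_YEARS = 58.0
#: Cohort median Townsend deprivation index used for the high/low split.
TDI_MEDIAN = -2.3

EVENT_LABELS = ("cld", "cirrhosis", "liver_cancer", "death", "censored")

# UK Biobank education coding -> three tiers. -3 is the prefer-not-to-answer
# sentinel, grouped with the low tier.
_EDUCATION_MAP = {1: "high", 2: "median", 5: "median", 6: "median",
                  3: "low", 4: "low", 7: "low", -3: "low"}


def classify_bp(systolic: float, diastolic: float) -> str:
    """Four-category blood pressure per standard clinical guidelines.

    normal: SP<120 and DP<80; elevated: 120<=SP<=129 and DP<80;
    stage1: 130<=SP<=139 or 80<=DP<=89 (not meeting stage2);
    stage2: SP>=140 or DP>=90.
    """
    if not (systolic > 0 and diastolic > 0):
        raise InvalidInputError(
            f"blood pressures must be positive, got SP={systolic}, DP={diastolic}"
        )
    if systolic >= 140 or diastolic >= 90:
        return "stage2"
    if 130 <= systolic or 80 <= diastolic:
        return "stage1"
    if 120 <= systolic:
        return "elevated"
    return "normal"


def classify_bp_series(systolic, diastolic) -> pd.Series:
    """Vectorised :func:`classify_bp`."""
    sp = np.asarray(systolic, dtype=float)
    dp = np.asarray(diastolic, dtype=float)
    if not ((sp > 0).all() and (dp > 0).all()):
        raise InvalidInputError("blood pressures must be positive")
    out = np.where(
        (sp >= 140) | (dp >= 90), "stage2",
        np.where((sp >= 130) | (dp >= 80), "stage1",
                 np.where(sp >= 120, "elevated", "normal")),
    )
    return pd.Series(out)


def reclassify_education(code: int) -> str:
    """Collapse the 7-level qualification coding into high/median/low tiers.

    1 (degree) -> high; 2, 5, 6 (A-levels, HND/HNC, professional) -> median;
    3, 4, 7 (O-levels/CSE/none) and the prefer-not-to-answer sentinel (-3)
    -> low.
    """
    try:
        code = int(code)
    except (TypeError, ValueError):
        raise InvalidInputError(f"education code must be an integer, got {code!r}")
    if code not in _EDUCATION_MAP:
        raise InvalidInputError(f"unknown education code {code}")
    return _EDUCATION_MAP[code]


def dichotomize(
    values,
    cutoff: float,
    below_label: str,
    at_or_above_label: str,
    boundary: str = "upper",
) -> pd.Series:
    """Median-split a numeric vector into two labelled groups.

    ``boundary='upper'`` sends values equal to the cutoff to the upper group
    (the convention used for age: 58 -> older); ``boundary='lower'`` sends
    them to the lower group (TDI: -2.3 -> low).  A degenerate input where
    every value lands in one group emits a warning.
    """
    x = np.asarray(values, dtype=float)
    if boundary == "upper":
        upper = x >= cutoff
    elif boundary == "lower":
        upper = x > cutoff
    else:
        raise InvalidInputError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    out = np.where(upper, at_or_above_label, below_label)
    if len(x) and (upper.all() or (~upper).all()):
        warnings.warn("dichotomize produced a single group", stacklevel=2)
    return pd.Series(out)


def dichotomize_age(age, cutoff: float = AGE_MEDIAN_YEARS) -> pd.Series:
    return dichotomize(age, cutoff, "younger", "older", boundary="upper")


def dichotomize_tdi(tdi, cutoff: float = TDI_MEDIAN) -> pd.Series:
    return dichotomize(tdi, cutoff, "low", "high", boundary="lower")


def assign_quartiles(scores) -> pd.Series:
    """Rank-based partition into Q1-Q4, ascending in score.

    With ``n = 4q + r`` the first ``r`` groups receive the extra member
    (so 121,329 observations split 30,333/30,332/30,332/30,332).  Tied scores
    share the quartile of the first occurrence of their value; a fully tied
    vector collapses to Q1 with a warning.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 4:
        raise InvalidInputError(f"need at least 4 observations for quartiles, got {n}")
    q, r = divmod(n, 4)
    sizes = [q + 1] * r + [q] * (4 - r)
    bounds = np.cumsum(sizes)
    order = np.argsort(x, kind="mergesort")
    pos_label = np.searchsorted(bounds, np.arange(n), side="right")  # 0..3 by rank
    label_by_pos = np.empty(n, dtype=int)
    # ties share the label of the first (lowest-rank) member of their value block
    sorted_vals = x[order]
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = sorted_vals[1:] != sorted_vals[:-1]
    first_idx = np.maximum.accumulate(np.where(new_block, np.arange(n), 0))
    label_by_pos[order] = pos_label[first_idx]
    if n and (x == x[0]).all():
        warnings.warn("all scores identical; every observation assigned to Q1",
                      stacklevel=2)
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])[label_by_pos]
    s = pd.Series(pd.Categorical(labels, categories=["Q1", "Q2", "Q3", "Q4"],
                                 ordered=True))
    if hasattr(scores, "index"):
        s.index = scores.index
    return s


@dataclass
class ExclusionLog:
    """One reason per dropped participant, in precedence order."""

    entries: list[dict] = field(default_factory=list)

    def add(self, participant_id, reason: str) -> None:
        self.entries.append({"participant_id": participant_id, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["participant_id", "reason"])

    def counts(self) -> dict:
        return self.to_frame()["reason"].value_counts().to_dict() if self.entries else {}

    def __len__(self) -> int:
        return len(self.entries)


_REQUIRED_COVARIATES = [
    "age", "sex", "ethnicity", "education_code", "tdi", "bmi", "smoking",
    "alcohol", "physical_activity", "systolic", "diastolic", "diabetes",
]


def _check_unique(df: pd.DataFrame, name: str) -> None:
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise InvalidInputError(f"duplicate participant_id {dup!r} in {name} table")


def apply_exclusions(
    intakes: pd.DataFrame,
    covariates: pd.DataFrame,
    followup: pd.DataFrame,
    reference: DIIReferenceTable | None = None,
    landmark_weeks: float = LANDMARK_WEEKS,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Merge the raw tables and drop ineligible participants.

    Reasons, first match wins: ``missing-data`` (any required nutrient,
    covariate or follow-up field absent), ``prior-disease`` (history of
    chronic liver disease or malignancy at entry), ``landmark`` (event or
    censoring within the first year).  Returns the retained merged table and
    the log; retained + excluded = input.
    """
    reference = reference or DIIReferenceTable.default()
    for df, name in ((intakes, "intakes"), (covariates, "covariates"),
                     (followup, "followup")):
        if "participant_id" not in df.columns:
            raise InvalidInputError(f"{name} table lacks participant_id")
        _check_unique(df, name)

    merged = intakes.merge(covariates, on="participant_id", how="inner").merge(
        followup, on="participant_id", how="inner"
    )
    log = ExclusionLog()
    if merged.empty:
        return merged, log

    nutrient_cols = [c for c in reference.parameters] + ["total_energy_kcal"]
    missing_cols = [c for c in nutrient_cols + _REQUIRED_COVARIATES
                    + ["follow_up_weeks", "event"] if c in merged.columns]
    absent = [c for c in nutrient_cols + ["follow_up_weeks", "event"]
              if c not in merged.columns]
    if absent:
        raise InvalidInputError(f"merged table missing required columns: {absent}")

    miss = merged[missing_cols].isna().any(axis=1)
    prior_cols = [c for c in ("prior_cld", "prior_malignancy") if c in merged.columns]
    prior = merged[prior_cols].fillna(False).astype(bool).any(axis=1) if prior_cols \
        else pd.Series(False, index=merged.index)
    landmark = merged["follow_up_weeks"] < landmark_weeks

    reason = np.select(
        [miss.to_numpy(), prior.to_numpy(), landmark.to_numpy()],
        ["missing-data", "prior-disease", "landmark"],
        default="",
    )
    for pid, why in zip(merged["participant_id"], reason):
        if why:
            log.add(pid, why)
    retained = merged.loc[reason == ""].reset_index(drop=True)
    return retained, log


def build_cohort(
    intakes: pd.DataFrame,
    covariates: pd.DataFrame,
    followup: pd.DataFrame,
    reference: DIIReferenceTable | None = None,
    density_reference: DIIReferenceTable | None = None,
    hei_standards: HEIStandards | None = None,
    meds_config: MEDSConfig | None = None,
    landmark_weeks: float = LANDMARK_WEEKS,
    age_cutoff: float = AGE_MEDIAN_YEARS,
    tdi_cutoff: float = TDI_MEDIAN,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full construction: exclusions -> scores -> reclassification -> quartiles.

    Returns the analysis table (one row per retained participant with dii,
    edii, hei2020, meds, dii_quartile, classified covariates, follow-up and
    event) plus the exclusion log.  The eDII reference defaults to a
    cohort-derived density table when none is supplied.
    """
    reference = reference or DIIReferenceTable.default()
    cohort, log = apply_exclusions(intakes, covariates, followup, reference,
                                   landmark_weeks)
    if cohort.empty:
        return cohort, log

    cohort = cohort.copy()
    cohort["dii"] = score_intakes(cohort, reference)["dii"].to_numpy()
    if density_reference is None:
        density_reference = density_reference_from_cohort(cohort, reference)
    cohort["edii"] = score_intakes(cohort, density_reference, density=True)["edii"].to_numpy()

    try:
        cohort["hei2020"] = compute_hei2020(cohort, hei_standards)["hei2020"].to_numpy()
    except Exception:
        cohort["hei2020"] = np.nan  # food-group columns are optional inputs
    try:
        cohort["meds"] = compute_meds(cohort, meds_config,
                                      sex=cohort.get("sex"))["meds"].to_numpy()
    except Exception:
        cohort["meds"] = np.nan

    cohort["age_group"] = dichotomize_age(cohort["age"], age_cutoff).to_numpy()
    cohort["tdi_group"] = dichotomize_tdi(cohort["tdi"], tdi_cutoff).to_numpy()
    cohort["education"] = cohort["education_code"].map(reclassify_education)
    cohort["bp_category"] = classify_bp_series(cohort["systolic"],
                                               cohort["diastolic"]).to_numpy()
    cohort["dii_quartile"] = assign_quartiles(cohort["dii"]).to_numpy()
    return cohort, log
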