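"""Dietary Inflammatory Index (DII) and energy-adjusted DII (eDII) scoring.

The DII summarises the inflammatory potential of a diet as a weighted sum over
dietary parameters.  For each parameter, an individual's mean daily intake is
standardised against a global reference mean and standard deviation
(``z = (intake - mean) / sd``), mapped onto a centred percentile in (-1, 1),
multiplied by the parameter's literature-derived inflammatory effect weight
(negative = anti-inflammatory, positive = pro-inflammatory), and the component
scores are summed.  The eDII applies the identical machinery to nutrient
densities per 1,000 kcal of total energy, which removes the influence of total
consumption volume.

The centred-percentile transform is ``2 * Phi(z) - 1`` with ``Phi`` the
standard normal CDF (the established DII convention); an empirical rank-based
alternative is available for cohort-level scoring.

The shipped 29-parameter reference table carries literature-derived global
means, SDs and weights and is a placeholder for a study-specific table: any
table with the same four columns can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidInputError, InvalidReferenceError, MissingDataError

__all__ = [
    "DIIReferenceTable",
    "DIIResult",
    "compute_z",
    "z_to_centered_percentile",
    "compute_dii",
    "compute_edii",
    "score_intakes",
    "density_reference_from_cohort",
    "default_reference",
]


@dataclass(frozen=True)
class DIIReferenceTable:
    """Per-parameter global mean, SD and inflammatory effect weight.

    Parameters are unique; every SD is strictly positive.  ``per_1000_kcal``
    marks a table expressed on the nutrient-density scale used by the eDII.
    """

    table: pd.DataFrame
    per_1000_kcal: bool = False

    def __post_init__(self) -> None:
        required = {"parameter", "global_mean", "global_sd", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidReferenceError(f"reference table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise InvalidReferenceError("reference table is empty")
        if self.table["parameter"].duplicated().any():
            dups = self.table.loc[self.table["parameter"].duplicated(), "parameter"].tolist()
            raise InvalidReferenceError(f"duplicate parameters in reference table: {dups}")
        if not (self.table["global_sd"] > 0).all():
            bad = self.table.loc[~(self.table["global_sd"] > 0), "parameter"].tolist()
            raise InvalidReferenceError(f"non-positive global SD for: {bad}")

    @property
    def parameters(self) -> list[str]:
        return self.table["parameter"].tolist()

    @property
    def max_abs_score(self) -> float:
        """Upper bound on |DII|: sum of absolute weights."""
        return float(self.table["weight"].abs().sum())

    @classmethod
    def from_csv(cls, path, per_1000_kcal: bool = False) -> "DIIReferenceTable":
        return cls(pd.read_csv(path), per_1000_kcal=per_1000_kcal)

    @classmethod
    def default(cls) -> "DIIReferenceTable":
        """The shipped 29-parameter literature-derived reference table."""
        with resources.files("diisurv.data").joinpath("dii_reference.csv").open() as fh:
            return cls(pd.read_csv(fh))


def default_reference() -> DIIReferenceTable:
    return DIIReferenceTable.default()


@dataclass
class DIIResult:
    """Per-participant DII with intermediates retained for audit."""

    participant_id: object
    z_scores: dict = field(default_factory=dict)
    centered_percentiles: dict = field(default_factory=dict)
    component_scores: dict = field(default_factory=dict)
    dii_total: float = 0.0
    edii_total: float | None = None


def compute_z(intake: float, global_mean: float, global_sd: float) -> float:
    """Standardise an intake against the global reference: (x - mu) / sigma."""
    if not global_sd > 0:
        raise InvalidReferenceError(f"global_sd must be positive, got {global_sd}")
    return (intake - global_mean) / global_sd


# strict open-interval bound: 2*Phi(z)-1 saturates to +/-1 in floating point
# for |z| > ~8, so percentiles are clipped just inside the interval
_PCT_BOUND = 1.0 - 1e-12


def z_to_centered_percentile(z: float) -> float:
    """Map a z-score to a centred percentile in (-1, 1) via 2*Phi(z) - 1."""
    if not np.all(np.isfinite(z)):
        raise InvalidInputError(f"z must be finite, got {z}")
    p = 2.0 * norm.cdf(z) - 1.0
    return float(np.clip(p, -_PCT_BOUND, _PCT_BOUND)) if np.isscalar(p) else \
        np.clip(p, -_PCT_BOUND, _PCT_BOUND)


def _score_mapping(intakes: Mapping[str, float], ref: DIIReferenceTable) -> DIIResult:
    res = DIIResult(participant_id=None)
    total = 0.0
    for row in ref.table.itertuples(index=False):
        p = row.parameter
        if p not in intakes:
            raise MissingDataError(f"intake record is missing parameter '{p}'")
        z = compute_z(float(intakes[p]), row.global_mean, row.global_sd)
        pct = z_to_centered_percentile(z)
        comp = pct * row.weight
        res.z_scores[p] = z
        res.centered_percentiles[p] = pct
        res.component_scores[p] = comp
        total += comp
    res.dii_total = total
    return res


def compute_dii(record: Mapping, ref: DIIReferenceTable) -> DIIResult:
    """Score one participant's absolute intakes against ``ref``.

    ``record`` maps parameter names to mean daily intakes and may carry
    ``participant_id``; every parameter in ``ref`` must be present.
    """
    res = _score_mapping(record, ref)
    res.participant_id = record.get("participant_id") if hasattr(record, "get") else None
    return res


def compute_edii(
    record: Mapping,
    density_ref: DIIReferenceTable,
    total_energy_kcal: float | None = None,
) -> DIIResult:
    """Score one participant on the nutrient-density (per 1,000 kcal) scale.

    Intakes are converted to densities ``intake * 1000 / energy`` and scored
    against a reference expressed on the same scale.
    """
    if total_energy_kcal is None and hasattr(record, "get"):
        total_energy_kcal = record.get("total_energy_kcal")
    if total_energy_kcal is None or not total_energy_kcal > 0:
        raise InvalidInputError(
            f"total_energy_kcal must be positive, got {total_energy_kcal}"
        )
    densities = {
        p: float(record[p]) * 1000.0 / total_energy_kcal
        for p in density_ref.parameters
        if p in record
    }
    res = _score_mapping(densities, density_ref)
    res.participant_id = record.get("participant_id") if hasattr(record, "get") else None
    res.edii_total = res.dii_total
    return res


def _validate_frame(intakes: pd.DataFrame, ref: DIIReferenceTable) -> None:
    missing = [p for p in ref.parameters if p not in intakes.columns]
    if missing:
        raise MissingDataError(f"intake table missing parameters: {missing}")


def score_intakes(
    intakes: pd.DataFrame,
    ref: DIIReferenceTable,
    density: bool = False,
    energy_col: str = "total_energy_kcal",
    percentile: str = "normal",
    components: bool = False,
) -> pd.DataFrame:
    """Vectorised cohort scoring.

    Parameters
    ----------
    intakes
        One row per participant; columns are parameter names (plus
        ``energy_col`` when ``density=True``).
    ref
        Reference table on the matching scale (absolute for DII, per
        1,000 kcal for the eDII).
    density
        Convert intakes to densities per 1,000 kcal before scoring (eDII).
    percentile
        ``"normal"`` for 2*Phi(z)-1, ``"empirical"`` for within-cohort rank
        percentiles rescaled to (-1, 1).
    components
        Also return per-parameter component scores as extra columns.

    Returns
    -------
    DataFrame indexed like ``intakes`` with a ``dii`` column (named ``edii``
    when ``density=True``).
    """
    _validate_frame(intakes, ref)
    if percentile not in ("normal", "empirical"):
        raise InvalidInputError(f"unknown percentile mode '{percentile}'")
    X = intakes[ref.parameters].to_numpy(dtype=float)
    if density:
        if energy_col not in intakes.columns:
            raise MissingDataError(f"intake table missing '{energy_col}'")
        energy = intakes[energy_col].to_numpy(dtype=float)
        if not (energy > 0).all():
            raise InvalidInputError("total energy must be positive for all rows")
        X = X * (1000.0 / energy)[:, None]
    mu = ref.table["global_mean"].to_numpy()
    sd = ref.table["global_sd"].to_numpy()
    w = ref.table["weight"].to_numpy()
    Z = (X - mu) / sd
    if percentile == "normal":
        P = np.clip(2.0 * norm.cdf(Z) - 1.0, -_PCT_BOUND, _PCT_BOUND)
    else:
        # mid-rank percentile within the scored cohort, rescaled to (-1, 1)
        n = Z.shape[0]
        ranks = pd.DataFrame(Z).rank(method="average").to_numpy()
        P = 2.0 * (ranks - 0.5) / n - 1.0
    comp = P * w
    total = comp.sum(axis=1)
    name = "edii" if density else "dii"
    out = pd.DataFrame({name: total}, index=intakes.index)
    if "participant_id" in intakes.columns:
        out.insert(0, "participant_id", intakes["participant_id"].to_numpy())
    if components:
        for j, p in enumerate(ref.parameters):
            out[f"component_{p}"] = comp[:, j]
    return out


def density_reference_from_cohort(
    intakes: pd.DataFrame,
    ref: DIIReferenceTable,
    energy_col: str = "total_energy_kcal",
) -> DIIReferenceTable:
    """Derive a per-1,000 kcal reference from the cohort itself.

    Fallback for when no external density reference is available: density
    means and SDs are taken from the scored cohort while the inflammatory
    weights are carried over unchanged from ``ref``.  Parameters whose
    density is (near-)constant across the cohort are dropped: in particular
    total energy itself, which the density method turns into the constant
    1,000 kcal per 1,000 kcal, so it cannot contribute to an
    energy-adjusted score.
    """
    _validate_frame(intakes, ref)
    if energy_col not in intakes.columns:
        raise MissingDataError(f"intake table missing '{energy_col}'")
    energy = intakes[energy_col].to_numpy(dtype=float)
    if not (energy > 0).all():
        raise InvalidInputError("total energy must be positive for all rows")
    X = intakes[ref.parameters].to_numpy(dtype=float) * (1000.0 / energy)[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-8 * np.maximum(np.abs(mu), 1.0)
    if not keep.any():
        raise InvalidReferenceError("every density is constant across the cohort")
    tab = pd.DataFrame(
        {
            "parameter": np.asarray(ref.parameters)[keep],
            "global_mean": mu[keep],
            "global_sd": sd[keep],
            "weight": ref.table["weight"].to_numpy()[keep],
        }
    )
    return DIIReferenceTable(tab, per_1000_kcal=True)
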