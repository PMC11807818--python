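"""Diet-quality indices: Healthy Eating Index 2020 and Mediterranean Diet Score.

HEI-2020 scores 13 components (9 adequacy, 4 moderation) on nutrient/food-group
densities per 1,000 kcal, a fatty-acid ratio, or percent of energy, by linear
interpolation between a score-0 and a maximum-score standard, clamped to
[0, max_points]; the 13 maxima sum to 100.  Being density-based, the total is
invariant to proportional rescaling of all intakes and energy.

MEDS awards one point per component: beneficial components at or above the
(optionally sex-specific) cohort median, detrimental components below it, and
alcohol inside a configurable moderate range (default 5-25 g/day), for a total
in [0, 9].

Both standards tables are shipped as editable CSVs; any table with the same
columns can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError, InvalidInputError, MissingDataError

__all__ = ["HEIStandards", "MEDSConfig", "compute_hei2020", "compute_meds"]

_HEI_UNITS = {"density", "ratio", "pct_energy"}


@dataclass(frozen=True)
class HEIStandards:
    """13-component HEI-2020 standards table.

    Columns: component, max_points (5 or 10, summing to 100), direction
    (adequacy | moderation), unit (density | ratio | pct_energy),
    score0_standard, scoremax_standard, kcal_per_g (pct_energy rows only).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"component", "max_points", "direction", "unit",
               "score0_standard", "scoremax_standard"}
        missing = req - set(self.table.columns)
        if missing:
            raise InvalidConfigurationError(f"HEI standards missing columns: {sorted(missing)}")
        if (self.table["score0_standard"] == self.table["scoremax_standard"]).any():
            raise InvalidConfigurationError("score0 and scoremax standards must differ")
        bad = set(self.table["unit"]) - _HEI_UNITS
        if bad:
            raise InvalidConfigurationError(f"unknown HEI units: {sorted(bad)}")

    @property
    def total_points(self) -> float:
        return float(self.table["max_points"].sum())

    @classmethod
    def from_csv(cls, path) -> "HEIStandards":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "HEIStandards":
        with resources.files("diisurv.data").joinpath("hei2020_standards.csv").open() as fh:
            return cls(pd.read_csv(fh))


@dataclass(frozen=True)
class MEDSConfig:
    """9-component MEDS configuration.

    ``table`` columns: component, direction (beneficial | detrimental | range).
    ``alcohol_range`` is the moderate-consumption window in g/day scored 1.
    ``sex_specific`` computes medians within sex when a sex column is present.
    """

    table: pd.DataFrame
    alcohol_range: tuple[float, float] = (5.0, 25.0)
    sex_specific: bool = True

    def __post_init__(self) -> None:
        req = {"component", "direction"}
        if req - set(self.table.columns):
            raise InvalidConfigurationError("MEDS config needs component and direction columns")
        bad = set(self.table["direction"]) - {"beneficial", "detrimental", "range"}
        if bad:
            raise InvalidConfigurationError(f"unknown MEDS directions: {sorted(bad)}")
        if not self.alcohol_range[0] < self.alcohol_range[1]:
            raise InvalidConfigurationError("alcohol_range must be (low, high) with low < high")

    @classmethod
    def from_csv(cls, path, **kw) -> "MEDSConfig":
        return cls(pd.read_csv(path), **kw)

    @classmethod
    def default(cls, **kw) -> "MEDSConfig":
        with resources.files("diisurv.data").joinpath("meds_components.csv").open() as fh:
            return cls(pd.read_csv(fh), **kw)


def _hei_component_values(
    df: pd.DataFrame, row, energy: np.ndarray
) -> np.ndarray:
    """Raw scoring variable for one HEI component (density / ratio / %energy)."""
    comp = row.component
    if row.unit == "ratio":
        # (MUFA + PUFA) / SFA from nutrient columns, or a precomputed column
        if comp in df.columns:
            return df[comp].to_numpy(dtype=float)
        for cols in (("mufa_g", "pufa_g", "saturated_fat_g"),):
            if all(c in df.columns for c in cols):
                sfa = df[cols[2]].to_numpy(dtype=float)
                if not (sfa > 0).all():
                    raise InvalidInputError("saturated fat must be positive for the fatty-acid ratio")
                return (df[cols[0]].to_numpy(float) + df[cols[1]].to_numpy(float)) / sfa
        raise MissingDataError(f"missing food group '{comp}' (or mufa_g/pufa_g/saturated_fat_g)")
    if comp not in df.columns:
        raise MissingDataError(f"missing food group '{comp}'")
    x = df[comp].to_numpy(dtype=float)
    if row.unit == "density":
        return x * 1000.0 / energy
    # pct_energy
    return x * float(row.kcal_per_g) * 100.0 / energy


def compute_hei2020(
    intakes: pd.DataFrame,
    standards: HEIStandards | None = None,
    energy_col: str = "total_energy_kcal",
    components: bool = False,
) -> pd.DataFrame:
    """Score each row of ``intakes`` on the HEI-2020 scale [0, 100].

    Each component's scoring variable is linearly interpolated between its
    score-0 and maximum-score standards and clamped; moderation components
    have score0 > scoremax so the same interpolation scores them in reverse.
    """
    standards = standards or HEIStandards.default()
    if energy_col not in intakes.columns:
        raise MissingDataError(f"intake table missing '{energy_col}'")
    energy = intakes[energy_col].to_numpy(dtype=float)
    if not (energy > 0).all():
        raise InvalidInputError("total energy must be positive for all rows")
    per_comp = {}
    for row in standards.table.itertuples(index=False):
        v = _hei_component_values(intakes, row, energy)
        frac = (v - row.score0_standard) / (row.scoremax_standard - row.score0_standard)
        per_comp[row.component] = row.max_points * np.clip(frac, 0.0, 1.0)
    total = np.sum(list(per_comp.values()), axis=0)
    out = pd.DataFrame({"hei2020": total}, index=intakes.index)
    if "participant_id" in intakes.columns:
        out.insert(0, "participant_id", intakes["participant_id"].to_numpy())
    if components:
        for c, s in per_comp.items():
            out[f"hei_{c}"] = s
    return out


def compute_meds(
    intakes: pd.DataFrame,
    config: MEDSConfig | None = None,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Score each row on the 9-point Mediterranean diet scale.

    Cohort medians are the cutoffs (sex-specific when configured and ``sex``
    is supplied); requires at least two participants.
    """
    config = config or MEDSConfig.default()
    if len(intakes) < 2:
        raise InvalidConfigurationError(
            "cohort-median MEDS cutoffs need at least 2 participants"
        )
    comps = config.table
    missing = [c for c in comps["component"] if c not in intakes.columns]
    if missing:
        raise MissingDataError(f"intake table missing MEDS components: {missing}")

    if config.sex_specific and sex is not None:
        groups = pd.Series(np.asarray(sex), index=intakes.index)
    else:
        groups = pd.Series("all", index=intakes.index)

    score = np.zeros(len(intakes), dtype=int)
    lo, hi = config.alcohol_range
    for row in comps.itertuples(index=False):
        x = intakes[row.component].astype(float)
        if row.direction == "range":
            score += ((x >= lo) & (x <= hi)).to_numpy().astype(int)
            continue
        med = x.groupby(groups).transform("median")
        if row.direction == "beneficial":
            score += (x >= med).to_numpy().astype(int)
        else:
            score += (x < med).to_numpy().astype(int)
    out = pd.DataFrame({"meds": score}, index=intakes.index)
    if "participant_id" in intakes.columns:
        out.insert(0, "participant_id", intakes["participant_id"].to_numpy())
    return out
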