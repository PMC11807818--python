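"""End-to-end orchestration: simulate/load -> score -> build -> fit -> report.

Writes diffable CSV/JSON outputs mirroring the shapes of the study's main
tables: quartile + continuous + trend associations per exposure and model
tier, progression analyses among incident cases, forest-plot-ready subgroup
estimates, and a machine-readable run manifest (package version, seed,
canonical config hash) so every reported number can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_cohort
from .errors import DiisurvError, InvalidConfigurationError
from .simulate import SimulationConfig, generate_cohort, generate_progression
from .subgroups import biomarker_correlation, subgroup_analysis
from .survival import (
    fit_cox,
    fit_fine_gray,
    progression_analysis,
    rcs_nonlinearity,
    schoenfeld_ph_test,
)

__all__ = ["RunConfig", "run_pipeline", "config_hash"]

_DEFAULT_EXPOSURES = ["dii"]
_DEFAULT_SUBGROUPS = ["sex", "age_group", "tdi_group", "smoking", "diabetes"]


class RunConfig(dict):
    """Plain-dict run configuration with validation and canonical hashing."""

    DEFAULTS = {
        "seed": 0,
        "n": 20_000,
        "tiers": [1, 2, 3],
        "exposures": _DEFAULT_EXPOSURES,
        "outcome": "cld",
        "competing_events": ["cirrhosis", "liver_cancer", "death"],
        "subgroups": _DEFAULT_SUBGROUPS,
        "progression_outcomes": ["cirrhosis", "liver_cancer"],
        "out_dir": "results",
    }

    @classmethod
    def with_defaults(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = cls(cls.DEFAULTS)
        cfg.update(overrides or {})
        if not cfg["exposures"]:
            raise InvalidConfigurationError("at least one exposure is required")
        if not cfg["outcome"]:
            raise InvalidConfigurationError("an outcome is required")
        return cfg


def config_hash(config: dict) -> str:
    """SHA-256 over the canonicalised (sorted-key JSON) configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _fit_rows(cohort, exposure, tier, outcome):
    quart = fit_cox(cohort, exposure=exposure, mode="quartile", tier=tier,
                    outcome=outcome)
    cont = fit_cox(cohort, exposure=exposure, mode="continuous", tier=tier,
                   outcome=outcome)
    row = {"exposure": exposure, "model": tier, "Q1": "1 (reference)"}
    for q in ("Q2", "Q3", "Q4"):
        e = quart.quartile_hr[q]
        row[q] = f"{e.hr:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f}) {e.p:.3g}"
    e = cont.continuous_hr
    row["continuous"] = f"{e.hr:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f}) {e.p:.3g}"
    row["p_trend"] = f"{quart.trend_p:.3g}"
    row["n_events"] = quart.n_events
    return row, quart, cont


def run_pipeline(config: dict | None = None, log=print) -> dict:
    """Execute the full analysis and write its outputs.

    Stages: simulate (seeded) -> score + build cohort -> Cox and Fine-Gray
    fits per tier -> spline nonlinearity + PH diagnostics -> progression ->
    subgroups -> biomarker correlations.  A stage failure aborts the run,
    removes partial outputs, and re-raises with the stage name.
    """
    cfg = RunConfig.with_defaults(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "init"

    def _write_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)
        return path

    def _write_json(obj, name: str):
        path = out_dir / name
        path.write_text(json.dumps(obj, indent=2, default=str))
        written.append(path)
        return path

    try:
        stage = "simulate"
        sim_cfg = SimulationConfig(n=int(cfg["n"]), seed=int(cfg["seed"]))
        tables = generate_cohort(sim_cfg)

        stage = "build-cohort"
        cohort, excl = build_cohort(tables["intakes"], tables["covariates"],
                                    tables["followup"])
        for exposure in cfg["exposures"]:
            if exposure != "dii":
                qcol = f"{exposure}_quartile"
                from .cohort import assign_quartiles
                cohort[qcol] = assign_quartiles(cohort[exposure]).to_numpy()

        stage = "fit-survival"
        assoc_rows = []
        ph_info = {}
        for exposure in cfg["exposures"]:
            for tier in cfg["tiers"]:
                row, quart, cont = _fit_rows(cohort, exposure, tier,
                                             cfg["outcome"])
                row["model_type"] = "cox"
                assoc_rows.append(row)
                if tier == max(cfg["tiers"]):
                    ph = schoenfeld_ph_test(cont)
                    ph_info[exposure] = {"global_p": ph.global_p,
                                         "per_covariate": ph.per_covariate}
                fg_q = fit_fine_gray(cohort, cfg["outcome"],
                                     tuple(cfg["competing_events"]),
                                     exposure, "quartile", tier)
                fg_c = fit_fine_gray(cohort, cfg["outcome"],
                                     tuple(cfg["competing_events"]),
                                     exposure, "continuous", tier)
                frow = {"exposure": exposure, "model": tier,
                        "model_type": "fine-gray", "Q1": "1 (reference)"}
                for q in ("Q2", "Q3", "Q4"):
                    e = fg_q.quartile_shr[q]
                    frow[q] = f"{e.hr:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f}) {e.p:.3g}"
                e = fg_c.continuous_shr
                frow["continuous"] = f"{e.hr:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f}) {e.p:.3g}"
                frow["p_trend"] = "/"
                frow["n_events"] = fg_q.n_events
                assoc_rows.append(frow)
        _write_csv(pd.DataFrame(assoc_rows), "associations.csv")

        stage = "splines"
        spline_info = {}
        for exposure in cfg["exposures"]:
            sp = rcs_nonlinearity(cohort, exposure=exposure,
                                  tier=max(cfg["tiers"]), outcome=cfg["outcome"])
            spline_info[exposure] = {"knots": list(np.round(sp.knots, 4)),
                                     "overall_p": sp.overall_p,
                                     "nonlinear_p": sp.nonlinear_p}

        stage = "progression"
        cases = cohort[cohort["event"] == cfg["outcome"]].copy()
        prog = generate_progression(cases, sim_cfg)
        cases = cases.merge(prog, on="participant_id")
        prog_rows = []
        for exposure in cfg["exposures"]:
            for out_ev in cfg["progression_outcomes"]:
                try:
                    pfit = progression_analysis(cases, outcome=out_ev,
                                                exposure=exposure,
                                                tier=max(cfg["tiers"]))
                    e = pfit.continuous_hr
                    prog_rows.append({
                        "exposure": exposure, "outcome": out_ev,
                        "hr": round(e.hr, 4), "ci_low": round(e.ci_low, 4),
                        "ci_high": round(e.ci_high, 4), "p": e.p,
                        "n_cases": len(cases), "n_events": pfit.n_events,
                    })
                except DiisurvError as exc:
                    prog_rows.append({"exposure": exposure, "outcome": out_ev,
                                      "hr": None, "note": str(exc)})
        _write_csv(pd.DataFrame(prog_rows), "progression.csv")

        stage = "subgroups"
        forest = []
        for strat in cfg["subgroups"]:
            res = subgroup_analysis(cohort, strat, exposure=cfg["exposures"][0],
                                    tier=max(cfg["tiers"]), outcome=cfg["outcome"])
            forest.append(res.to_frame())
        _write_csv(pd.concat(forest, ignore_index=True), "forest.csv")

        stage = "biomarkers"
        bio = tables["biomarkers"].merge(cohort[["participant_id", "dii"]],
                                         on="participant_id")
        corr = biomarker_correlation(bio["dii"],
                                     bio.drop(columns=["participant_id", "dii"]))
        _write_csv(corr, "biomarker_correlations.csv")

        stage = "manifest"
        manifest = {
            "package": "diisurv",
            "version": __version__,
            "python": sys.version.split()[0],
            "seed": int(cfg["seed"]),
            "config": dict(cfg),
            "config_hash": config_hash(dict(cfg)),
            "n_input": int(cfg["n"]),
            "n_analysis": int(len(cohort)),
            "n_excluded": len(excl),
            "exclusion_reasons": excl.counts(),
            "ph_test": ph_info,
            "splines": spline_info,
        }
        _write_json(manifest, "manifest.json")
        _write_json(excl.counts(), "exclusion_log.json")
        log(f"pipeline complete: {len(written)} files in {out_dir}")
        return manifest
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        log(f"pipeline failed during stage '{stage}'; partial outputs removed")
        raise
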