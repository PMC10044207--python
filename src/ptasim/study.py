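"""Configuration-driven study runner and tabular result export.

Runs the baseline plus a scenario battery, each as an
intermittent-infusion arm and a continuous-infusion counterpart, and
writes plain-text result tables: per-repetition PTAs, a summary (mean PTA
and success flag per scenario/arm), the scenario-vs-baseline ratio
comparisons (forest-plot data), and a JSON metadata record with the seed
and every resolved default.

A single global seed spawns an independent, deterministic random
substream per (scenario, arm), keyed by position in the battery, so
adding a scenario does not perturb the others' results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    ScenarioConfig,
    default_cohort_spec,
    default_model,
    default_regimen,
    default_target,
    fig1_scenarios,
    resolve_scenario,
)
from .pdmetrics import PDTarget
from .poppk import CovariateModel, PKModelSpec
from .profiles import Regimen
from .pta import PTAResult, ScenarioComparison, SimSettings, compare_scenarios, run_pta

__all__ = ["StudyConfig", "run_study", "export_forest", "load_study_config"]

log = logging.getLogger("ptasim")


@dataclass(frozen=True)
class StudyConfig:
    """Full study specification: model, regimen, target, settings, battery."""

    model: PKModelSpec = field(default_factory=default_model)
    regimen: Regimen = field(default_factory=default_regimen)
    target: PDTarget = field(default_factory=default_target)
    settings: SimSettings = field(default_factory=SimSettings)
    cohort_spec: CohortSpec = field(default_factory=default_cohort_spec)
    scenarios: tuple = ()  # empty -> the default battery
    baseline_label: str = "baseline"

    def resolved_scenarios(self) -> list[ScenarioConfig]:
        scenarios = list(self.scenarios) if self.scenarios else fig1_scenarios()
        labels = [s.label for s in scenarios]
        if self.baseline_label not in labels:
            raise ValueError(f"baseline scenario {self.baseline_label!r} not in battery")
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        return scenarios


def _scenario_seed(seed: int, scenario_index: int, arm_index: int) -> int:
    """Deterministic per-(scenario, arm) substream seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(scenario_index, arm_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_study(
    config: StudyConfig,
    out_dir,
    seed: Optional[int] = None,
) -> dict:
    """Execute the study and write result tables under ``out_dir``.

    Returns the in-memory tables: ``per_rep``, ``summary``, ``comparisons``
    DataFrames plus the ``metadata`` dict.  Idempotent for a fixed seed.
    """
    scenarios = config.resolved_scenarios()  # validates before any simulation
    seed = config.settings.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    arms = ("intermittent", "continuous")
    results: dict[tuple[str, str], PTAResult] = {}
    resolved_meta: dict[str, dict] = {}
    for i, scenario in enumerate(scenarios):
        for a, arm in enumerate(arms):
            scen = scenario if arm == "intermittent" else _with_mode(scenario, "continuous")
            model, regimen, target, settings, cohort = resolve_scenario(
                scen,
                model=config.model,
                regimen=config.regimen,
                target=config.target,
                settings=config.settings,
                cohort_spec=config.cohort_spec,
            )
            settings = settings.with_overrides(seed=_scenario_seed(seed, i, a))
            log.info("scenario %s / %s: dt=%g phase=%s fu=%g", scenario.label, arm,
                     settings.dt, settings.phase, model.fu)
            results[(scenario.label, arm)] = run_pta(
                model, cohort, regimen, target, settings, label=f"{scenario.label}/{arm}"
            )
            resolved_meta[f"{scenario.label}/{arm}"] = {
                "n_compartments": model.n_compartments,
                "V": model.V, "Q": model.Q, "Vp": model.Vp,
                "fu": model.fu,
                "omega2_CL": model.omega2_CL,
                "ruv_prop_sd": model.ruv_prop_sd if settings.ruv_enabled else 0.0,
                "phase": settings.phase,
                "dt": settings.dt,
                "sCr": cohort[0].sCr,
                "required_fraction": target.required_fraction,
                "mic": target.mic,
                "regimen_mode": regimen.mode,
                "seed": settings.seed,
            }

    per_rep = pd.DataFrame(
        [
            {"scenario": label, "arm": arm, "rep": j, "pta": p}
            for (label, arm), res in results.items()
            for j, p in enumerate(res.pta_per_rep)
        ]
    )
    summary = pd.DataFrame(
        [
            {
                "scenario": label,
                "arm": arm,
                "mean_pta": res.mean_pta,
                "success": res.success,
            }
            for (label, arm), res in results.items()
        ]
    )

    comparisons: list[ScenarioComparison] = []
    comp_rows = []
    for scenario in scenarios:
        if scenario.label == config.baseline_label:
            continue
        for arm in arms:
            comp = compare_scenarios(
                results[(scenario.label, arm)],
                results[(config.baseline_label, arm)],
                label=f"{scenario.label}/{arm}",
            )
            comparisons.append(comp)
            lo, hi = comp.ci90
            comp_rows.append(
                {
                    "label": scenario.label,
                    "arm": arm,
                    "mean_ratio": comp.mean_ratio,
                    "ci90_low": lo,
                    "ci90_high": hi,
                    "n_dropped": comp.n_dropped,
                }
            )
    comparison_table = pd.DataFrame(comp_rows)

    metadata = {
        "package": "ptasim",
        "version": __version__,
        "seed": seed,
        "n_patients": config.settings.n_patients,
        "n_reps": config.settings.n_reps,
        "success_threshold": config.settings.success_threshold,
        "baseline_phase": config.settings.phase,
        "percentile_convention": "linear interpolation between order statistics",
        "scenarios": resolved_meta,
    }

    per_rep.to_csv(out / "pta_per_rep.tsv", sep="\t", index=False)
    summary.to_csv(out / "pta_summary.tsv", sep="\t", index=False)
    comparison_table.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2)

    return {
        "per_rep": per_rep,
        "summary": summary,
        "comparisons": comparison_table,
        "comparison_objects": comparisons,
        "results": results,
        "metadata": metadata,
    }


def _with_mode(scenario: ScenarioConfig, mode: str) -> ScenarioConfig:
    return ScenarioConfig(
        label=scenario.label,
        n_compartments=scenario.n_compartments,
        cv_CL=scenario.cv_CL,
        ruv_enabled=scenario.ruv_enabled,
        phase=scenario.phase,
        dt=scenario.dt,
        sCr_factor=scenario.sCr_factor,
        required_fraction=scenario.required_fraction,
        fu=scenario.fu,
        mode=mode,
    )


def export_forest(comparisons: Sequence[ScenarioComparison]) -> pd.DataFrame:
    """Forest-plot data: label, mean ratio, empiric 90% CI, dropped reps."""
    if len(comparisons) == 0:
        raise ValueError("no comparisons to export")
    rows = []
    for comp in comparisons:
        lo, hi = comp.ci90
        rows.append(
            {
                "label": comp.label,
                "mean_ratio": comp.mean_ratio,
                "ci90_low": lo,
                "ci90_high": hi,
                "n_dropped": comp.n_dropped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config loading (YAML, key names mirror the dataclass fields)
# ---------------------------------------------------------------------------

def _model_from_dict(d: dict) -> PKModelSpec:
    d = dict(d)
    cov = d.pop("covariate_model", None)
    if cov is not None:
        d["covariate_model"] = CovariateModel(**cov)
    if "cv_CL" in d:  # convenience: accept a CV instead of omega2
        from .poppk import cv_to_variance

        d["omega2_CL"] = cv_to_variance(d.pop("cv_CL"))
    return PKModelSpec(**d)


def load_study_config(path) -> StudyConfig:
    """Read a StudyConfig from a YAML file; missing sections use defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "model" in raw:
        kwargs["model"] = _model_from_dict(raw["model"])
    if "regimen" in raw:
        kwargs["regimen"] = Regimen(**raw["regimen"])
    if "target" in raw:
        kwargs["target"] = PDTarget(**raw["target"])
    if "settings" in raw:
        kwargs["settings"] = SimSettings(**raw["settings"])
    if "cohort" in raw:
        kwargs["cohort_spec"] = CohortSpec(**raw["cohort"])
    if "scenarios" in raw:
        kwargs["scenarios"] = tuple(ScenarioConfig(**s) for s in raw["scenarios"])
    if "baseline_label" in raw:
        kwargs["baseline_label"] = raw["baseline_label"]
    return StudyConfig(**kwargs)
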