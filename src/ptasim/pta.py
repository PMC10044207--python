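"""Monte Carlo probability-of-target-attainment engine.

A PTA run draws a cohort of individual PK parameter sets from the
population model, simulates each patient's concentration profile under a
dosing regimen, and scores the fraction of patients meeting the PD target
— once per repetition.  The mean PTA over repetitions is the headline
statistic; the per-repetition values support the scenario-vs-reference
ratio with empiric percentile confidence intervals, and a MIC sweep with
common random numbers feeds the cumulative fraction of response (CFR)
against a MIC distribution.

The whole repetition x patient x grid-point tensor is evaluated with the
closed forms in one vectorised pass, so paper-scale runs (200 repetitions
of 50 patients) take well under a second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pdmetrics import PDTarget
from .poppk import Patient, PKModelSpec, typical_clearance
from .profiles import (
    Regimen,
    _disposition_terms,
    _multidose_conc,
    _steady_state_closed_form,
    _step_response,
    time_grid,
)

__all__ = [
    "SimSettings",
    "PTAResult",
    "MICDistribution",
    "ScenarioComparison",
    "run_pta",
    "pta_mic_sweep",
    "cfr",
    "compare_scenarios",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSettings:
    """Monte Carlo settings: cohort size, repetitions, grid and phase."""

    n_patients: int = 50
    n_reps: int = 200
    dt: float = 0.2  # h
    seed: int = 0
    ruv_enabled: bool = False
    phase: str = "first_dose"  # first_dose | steady_state
    success_threshold: float = 90.0  # % mean PTA counted as success

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_reps < 1:
            raise ValueError("n_patients and n_reps must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0 < self.success_threshold <= 100:
            raise ValueError("success_threshold must be in (0, 100]")
        if self.phase not in ("first_dose", "steady_state"):
            raise ValueError("phase must be 'first_dose' or 'steady_state'")

    def with_overrides(self, **kwargs) -> "SimSettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PTAResult:
    """Per-repetition PTA values and their summary."""

    pta_per_rep: np.ndarray  # %, one entry per repetition
    success_threshold: float
    scenario_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pta_per_rep, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("pta_per_rep must be a non-empty 1-D array")
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError("PTA values must lie in [0, 100]")
        object.__setattr__(self, "pta_per_rep", arr)

    @property
    def mean_pta(self) -> float:
        return float(np.mean(self.pta_per_rep))

    @property
    def success(self) -> bool:
        return self.mean_pta >= self.success_threshold


@dataclass(frozen=True)
class MICDistribution:
    """Discrete MIC frequency distribution on a two-fold dilution grid."""

    mics: tuple  # mg/L, ascending
    freqs: tuple  # fractions summing to 1

    def __post_init__(self) -> None:
        mics = tuple(float(m) for m in self.mics)
        freqs = tuple(float(f) for f in self.freqs)
        if len(mics) != len(freqs) or len(mics) == 0:
            raise ValueError("mics and freqs must be non-empty and of equal length")
        if any(m2 <= m1 for m1, m2 in zip(mics, mics[1:])):
            raise ValueError("mics must be strictly ascending")
        if any(f < 0 for f in freqs):
            raise ValueError("freqs must be >= 0")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("freqs must sum to 1")
        object.__setattr__(self, "mics", mics)
        object.__setattr__(self, "freqs", freqs)

    def quantile(self, q: float) -> float:
        """Smallest MIC whose cumulative frequency reaches q (0 < q <= 1)."""
        cdf = 0.0
        for m, f in zip(self.mics, self.freqs):
            cdf += f
            if cdf >= q - 1e-12:
                return m
        return self.mics[-1]

    @property
    def mic50(self) -> float:
        return self.quantile(0.5)

    @property
    def mic90(self) -> float:
        return self.quantile(0.9)

    def to_table(self, path) -> None:
        """Write as two-column tab-separated text (mic, frequency)."""
        pd.DataFrame({"mic": self.mics, "frequency": self.freqs}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_table(cls, path) -> "MICDistribution":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(mics=tuple(df.iloc[:, 0]), freqs=tuple(df.iloc[:, 1]))


@dataclass(frozen=True)
class ScenarioComparison:
    """Per-repetition PTA ratios of a scenario against a reference."""

    ratios_per_rep: np.ndarray
    n_dropped: int  # repetitions with zero reference PTA
    label: str = ""

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios_per_rep))

    @property
    def ci90(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.ratios_per_rep, [5.0, 95.0])
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Vectorised simulation core
# ---------------------------------------------------------------------------

def _draw_parameter_matrix(
    spec: PKModelSpec,
    cohort: Sequence[Patient],
    n_reps: int,
    rng: np.random.Generator,
):
    """(n_reps, n_patients) clearance and volume matrices from the population model."""
    tvcl = np.array([typical_clearance(spec.covariate_model, spec.tvCL, p) for p in cohort])
    shape = (n_reps, len(cohort))
    if spec.omega2_CL > 0:
        eta_cl = rng.normal(0.0, math.sqrt(spec.omega2_CL), size=shape)
    else:
        eta_cl = np.zeros(shape)
    if spec.omega2_V > 0:
        eta_v = rng.normal(0.0, math.sqrt(spec.omega2_V), size=shape)
    else:
        eta_v = np.zeros(shape)
    CL = tvcl[None, :] * np.exp(eta_cl)
    V = spec.V * np.exp(eta_v)
    return CL, V


def _conc_tensor(spec, CL, V, regimen: Regimen, settings: SimSettings, times: np.ndarray):
    """(n_reps, n_patients, n_times) total concentrations for the drawn parameters."""
    CL3 = CL[..., None]
    V3 = np.asarray(V)[..., None]
    if spec.n_compartments == 2:
        terms = _disposition_terms(CL3, V3, spec.Q, spec.Vp)
    else:
        terms = _disposition_terms(CL3, V3)
    if regimen.mode == "continuous":
        R0 = regimen.daily_dose / 24.0
        if settings.phase == "steady_state":
            total = np.broadcast_to(R0 / CL3, CL3.shape[:-1] + times.shape).copy()
        else:
            total = _step_response(terms, R0, times[None, None, :])
    else:
        if settings.phase == "steady_state":
            total = _steady_state_closed_form(terms, regimen, times[None, None, :])
        else:
            total = _multidose_conc(terms, regimen, times[None, None, :])
    return np.broadcast_to(total, CL.shape + times.shape)


def _simulate_free_conc(
    spec: PKModelSpec,
    cohort: Sequence[Patient],
    regimen: Regimen,
    settings: SimSettings,
):
    """Free-concentration tensor (n_reps, n_patients, n_times) plus the grid."""
    if regimen.mode == "continuous":
        t_end = 24.0
    else:
        t_end = regimen.interval
    times = time_grid(0.0, t_end, settings.dt)
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    CL, V = _draw_parameter_matrix(spec, cohort, settings.n_reps, rng)
    total = _conc_tensor(spec, CL, V, regimen, settings, times)
    if settings.ruv_enabled and spec.ruv_prop_sd > 0:
        eps = rng.normal(0.0, spec.ruv_prop_sd, size=total.shape)
        total = np.maximum(total * (1.0 + eps), 0.0)
    return spec.fu * total, times


def _met_matrix(free, times, target: PDTarget, mic: Optional[float] = None):
    """Boolean (n_reps, n_patients): does each simulated patient meet the target?"""
    eff_mic = target.mic_multiplier * (mic if mic is not None else target.mic)
    if target.metric == "fT_above_MIC":
        ft = 100.0 * np.mean(free > eff_mic, axis=-1)
        return ft >= target.required_fraction
    if target.metric == "fAUC_MIC":
        ratio = np.trapezoid(free, times, axis=-1) / eff_mic
        return ratio >= target.required_ratio
    if target.metric == "Cmax_MIC":
        return np.max(free, axis=-1) / eff_mic >= target.required_ratio
    # trough_threshold on the free scale; total-scale targets are routed
    # through run_pta, which rescales the tensor by 1/fu first
    if not times[0] <= target.at_time <= times[-1] + (times[1] - times[0] if len(times) > 1 else 0):
        raise ValueError(f"at_time={target.at_time} outside the simulated window")
    idx = int(np.argmin(np.abs(times - target.at_time)))
    return free[..., idx] >= target.threshold


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def run_pta(
    spec: PKModelSpec,
    cohort: Sequence[Patient],
    regimen: Regimen,
    target: PDTarget,
    settings: SimSettings,
    label: str = "",
) -> PTAResult:
    """Monte Carlo PTA: per-repetition percent of patients meeting the target.

    Each repetition redraws the cohort's individual parameters (and any
    residual error); PTA_j = 100 x (patients meeting target) / n_patients.
    Bit-reproducible for a fixed seed and configuration.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if target.metric == "trough_threshold" and regimen.mode == "intermittent":
        if target.at_time is not None and target.at_time > regimen.interval:
            raise ValueError("trough at_time lies outside the dosing interval")
    free, times = _simulate_free_conc(spec, cohort, regimen, settings)
    if target.metric == "trough_threshold" and target.scale == "total":
        met = _trough_met_total(free / spec.fu, times, target)
    else:
        met = _met_matrix(free, times, target)
    pta = 100.0 * np.mean(met, axis=1)
    return PTAResult(pta_per_rep=pta, success_threshold=settings.success_threshold, scenario_label=label)


def _trough_met_total(total, times, target: PDTarget):
    idx = int(np.argmin(np.abs(times - target.at_time)))
    return total[..., idx] >= target.threshold


def pta_mic_sweep(
    spec: PKModelSpec,
    cohort: Sequence[Patient],
    regimen: Regimen,
    target: PDTarget,
    settings: SimSettings,
    mics: Sequence[float],
) -> dict[float, PTAResult]:
    """PTA at each MIC with common random numbers across the sweep.

    The same drawn profiles are scored against every MIC, so PTA is
    non-increasing in MIC by construction.
    """
    mics = [float(m) for m in mics]
    if len(mics) == 0:
        raise ValueError("mic list is empty")
    if any(m <= 0 for m in mics) or any(b <= a for a, b in zip(mics, mics[1:])):
        raise ValueError("mics must be positive and strictly ascending")
    free, times = _simulate_free_conc(spec, cohort, regimen, settings)
    out: dict[float, PTAResult] = {}
    for mic in mics:
        met = _met_matrix(free, times, target, mic=mic)
        pta = 100.0 * np.mean(met, axis=1)
        out[mic] = PTAResult(
            pta_per_rep=pta,
            success_threshold=settings.success_threshold,
            scenario_label=f"MIC={mic:g}",
        )
    return out


def cfr(pta_by_mic: dict, dist: MICDistribution) -> float:
    """Cumulative fraction of response: frequency-weighted mean PTA (%).

    Every MIC in the distribution must be present in the sweep results.
    """
    total = 0.0
    for mic, freq in zip(dist.mics, dist.freqs):
        if mic not in pta_by_mic:
            raise ValueError(f"no PTA available for MIC {mic:g} mg/L")
        value = pta_by_mic[mic]
        pta = value.mean_pta if isinstance(value, PTAResult) else float(value)
        total += pta * freq
    return total


def compare_scenarios(
    scenario: PTAResult,
    reference: PTAResult,
    label: str = "",
) -> ScenarioComparison:
    """Per-repetition PTA ratio of scenario over reference, with empiric 90% CI.

    Ratios are paired by repetition index; repetitions with a zero
    reference PTA are dropped and counted in ``n_dropped``.
    """
    s = scenario.pta_per_rep
    r = reference.pta_per_rep
    if len(s) != len(r):
        raise ValueError("scenario and reference must have the same number of repetitions")
    keep = r > 0
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped == len(r):
        raise ValueError("reference PTA is zero in every repetition; ratios undefined")
    ratios = s[keep] / r[keep]
    return ScenarioComparison(
        ratios_per_rep=ratios,
        n_dropped=n_dropped,
        label=label or scenario.scenario_label,
    )
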