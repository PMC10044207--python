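"""Synthetic virtual cohorts, MIC distributions and the scenario battery.

No raw patient data ships with this package: cohorts are generated from a
small covariate specification (fixed typical values or log-normally
dispersed serum creatinine), and susceptibility data are represented as
two-fold-dilution MIC distributions constructed to match prescribed
MIC50/MIC90 quantiles.

The scenario battery enumerates single-factor deviations from a baseline
simulation configuration — compartment count, between-subject variability,
residual error, first dose vs steady state, sampling interval, renal
function, PD-target stringency, protein binding — each of which can be run
as an intermittent-infusion arm and a continuous-infusion counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .poppk import CovariateModel, Patient, PKModelSpec, cv_to_variance
from .profiles import Regimen
from .pdmetrics import PDTarget
from .pta import MICDistribution, SimSettings

__all__ = [
    "CohortSpec",
    "ScenarioConfig",
    "generate_cohort",
    "generate_mic_distribution",
    "fig1_scenarios",
    "default_model",
    "default_regimen",
    "default_continuous_regimen",
    "default_target",
    "default_cohort_spec",
]

# Baseline study conditions: a published cefepime population model anchored at
# tvCL 13.6 L/h for sCr 0.47 mg/dL with a power covariate model (exponent 0.51
# calibrated so sCr 0.7 -> 11.1 L/h), 22.8% CV clearance BSV, fu 0.8 fixed.
# The central volume and residual-error SD are not part of the printed model;
# the defaults below are realistic cefepime values (see docs/methods.md).
BASELINE_TVCL = 13.6  # L/h
BASELINE_SCR_REF = 0.47  # mg/dL
BASELINE_EXPONENT = 0.51
BASELINE_CV_CL = 0.228
BASELINE_FU = 0.8
DEFAULT_V = 18.0  # L
DEFAULT_RUV_SD = 0.2
TWO_CMT_V = 12.0  # L central
TWO_CMT_VP = 6.0  # L peripheral
TWO_CMT_Q = 10.0  # L/h
BASELINE_MIC = 8.0  # mg/L, susceptibility breakpoint
CONTINUOUS_DAILY_DOSE = 6000.0  # mg/day


def default_model(**overrides) -> PKModelSpec:
    """Baseline one-compartment population model."""
    spec = PKModelSpec(
        tvCL=BASELINE_TVCL,
        V=DEFAULT_V,
        n_compartments=1,
        fu=BASELINE_FU,
        omega2_CL=cv_to_variance(BASELINE_CV_CL),
        ruv_prop_sd=DEFAULT_RUV_SD,
        covariate_model=CovariateModel(
            kind="power_sCr",
            reference_value=BASELINE_SCR_REF,
            exponent=BASELINE_EXPONENT,
        ),
    )
    return spec.with_overrides(**overrides) if overrides else spec


def default_regimen() -> Regimen:
    """2000 mg q8 h infused over 30 min."""
    return Regimen(mode="intermittent", dose=2000.0, interval=8.0, infusion_duration=0.5)


def default_continuous_regimen() -> Regimen:
    """Continuous infusion matching a 6000 mg total daily dose."""
    return Regimen(mode="continuous", daily_dose=CONTINUOUS_DAILY_DOSE)


def default_target(**overrides) -> PDTarget:
    """fT 60% > MIC 8 mg/L."""
    kwargs = dict(metric="fT_above_MIC", required_fraction=60.0, mic=BASELINE_MIC)
    kwargs.update(overrides)
    return PDTarget(**kwargs)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Covariate generator for a virtual cohort.

    ``fixed`` mode gives every patient the typical covariates; ``lognormal``
    mode draws serum creatinine from a log-normal with the given median and
    CV (age/weight/sex stay at their typical values).
    """

    n: int = 50
    sCr_mode: Literal["fixed", "lognormal"] = "fixed"
    sCr: float = BASELINE_SCR_REF  # fixed value, or median in lognormal mode
    sCr_cv: float = 0.3
    age: float = 49.0  # years; with weight 72 kg these give CrCl ~130 mL/min at sCr 0.7
    weight: float = 72.0  # kg
    sex: Literal["male", "female"] = "male"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.sCr > 0:
            raise ValueError("sCr must be > 0")
        if self.sCr_cv < 0:
            raise ValueError("sCr_cv must be >= 0")


def default_cohort_spec(**overrides) -> CohortSpec:
    return CohortSpec(**overrides)


def generate_cohort(spec: CohortSpec) -> list[Patient]:
    """Generate a virtual cohort; deterministic for a fixed seed."""
    if spec.sCr_mode == "fixed":
        scr = np.full(spec.n, spec.sCr)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        sigma = math.sqrt(math.log1p(spec.sCr_cv**2))
        scr = spec.sCr * np.exp(rng.normal(0.0, sigma, size=spec.n))
    return [
        Patient(id=f"pt{i:05d}", sCr=float(s), age=spec.age, weight=spec.weight, sex=spec.sex)
        for i, s in enumerate(scr)
    ]


# ---------------------------------------------------------------------------
# MIC distributions
# ---------------------------------------------------------------------------

def _is_twofold(value: float) -> bool:
    return abs(math.log2(value) - round(math.log2(value))) < 1e-9


def generate_mic_distribution(
    target_mic50: float,
    target_mic90: float,
    dilution_range: tuple[float, float] = (0.25, 1024.0),
) -> MICDistribution:
    """Two-fold-dilution MIC distribution with prescribed MIC50 and MIC90.

    The returned distribution places 30% of isolates below the MIC50,
    reaches a cumulative frequency of 60% at the MIC50 and 95% at the
    MIC90, with the remainder spread over neighbouring dilutions — so the
    empirical 50th/90th percentiles (smallest MIC at which the CDF reaches
    the quantile) equal the targets exactly.
    """
    lo, hi = dilution_range
    for name, v in (("target_mic50", target_mic50), ("target_mic90", target_mic90)):
        if not v > 0 or not _is_twofold(v):
            raise ValueError(f"{name}={v} is not on the two-fold dilution grid")
    if target_mic50 > target_mic90:
        raise ValueError("target_mic50 must be <= target_mic90")
    if not (lo <= target_mic50 and target_mic90 <= hi):
        raise ValueError("targets fall outside the dilution range")

    k_lo, k_hi = round(math.log2(lo)), round(math.log2(hi))
    grid = [2.0**k for k in range(k_lo, k_hi + 1)]
    below = [m for m in grid if m < target_mic50]
    between = [m for m in grid if target_mic50 < m < target_mic90]
    above = [m for m in grid if m > target_mic90]

    mics: list[float] = []
    freqs: list[float] = []
    cdf = 0.0
    if below:
        share = 0.3 / len(below)
        for m in below:
            mics.append(m)
            freqs.append(share)
        cdf = 0.3
    if target_mic50 == target_mic90:
        mics.append(target_mic50)
        freqs.append(1.0 - cdf)
        return MICDistribution(mics=tuple(mics), freqs=tuple(freqs))
    # CDF just below mic50 is <= 0.3 < 0.5; reach 0.6 at mic50
    mics.append(target_mic50)
    freqs.append(0.6 - cdf)
    cdf = 0.6
    if between:
        share = 0.25 / len(between)  # CDF just below mic90 becomes 0.85 < 0.9
        for m in between:
            mics.append(m)
            freqs.append(share)
        cdf = 0.85
    if above:
        mics.append(target_mic90)
        freqs.append(0.95 - cdf)
        share = 0.05 / len(above)
        for m in above:
            mics.append(m)
            freqs.append(share)
    else:
        mics.append(target_mic90)
        freqs.append(1.0 - cdf)
    return MICDistribution(mics=tuple(mics), freqs=tuple(freqs))


# ---------------------------------------------------------------------------
# Scenario battery
# ---------------------------------------------------------------------------

_OVERRIDE_FIELDS = (
    "n_compartments",
    "cv_CL",
    "ruv_enabled",
    "phase",
    "dt",
    "sCr_factor",
    "required_fraction",
    "fu",
    "mode",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: a label plus overrides of the baseline.

    A baseline config has no overrides; each battery variant overrides
    exactly one field.
    """

    label: str
    n_compartments: Optional[int] = None
    cv_CL: Optional[float] = None
    ruv_enabled: Optional[bool] = None
    phase: Optional[str] = None
    dt: Optional[float] = None
    sCr_factor: Optional[float] = None
    required_fraction: Optional[float] = None
    fu: Optional[float] = None
    mode: Optional[str] = None

    def overridden_fields(self) -> tuple[str, ...]:
        return tuple(f for f in _OVERRIDE_FIELDS if getattr(self, f) is not None)

    @property
    def is_baseline(self) -> bool:
        return not self.overridden_fields()


def fig1_scenarios(baseline: Optional[ScenarioConfig] = None) -> list[ScenarioConfig]:
    """The single-factor scenario battery around the baseline.

    Baseline: one compartment, 2000 mg q8 h over 0.5 h, fu 0.8,
    fT 60% > MIC 8 mg/L, dt 0.2 h, sCr 0.47 mg/dL, 22.8% CV, no residual
    error, first dose.  Returns the baseline followed by the 12 variants;
    each variant differs from the baseline in exactly one field.  Every
    scenario can additionally be run as a continuous-infusion counterpart
    (6000 mg/day) by the study runner.
    """
    if baseline is None:
        baseline = ScenarioConfig(label="baseline")
    if not baseline.is_baseline:
        raise ValueError("baseline scenario must carry no overrides")
    variants = [
        ScenarioConfig(label="two_compartment", n_compartments=2),
        ScenarioConfig(label="bsv_cv_50", cv_CL=0.5),
        ScenarioConfig(label="with_ruv", ruv_enabled=True),
        ScenarioConfig(label="steady_state", phase="steady_state"),
        ScenarioConfig(label="dt_0.05h", dt=0.05),
        ScenarioConfig(label="dt_1h", dt=1.0),
        ScenarioConfig(label="sCr_halved", sCr_factor=0.5),
        ScenarioConfig(label="sCr_doubled", sCr_factor=2.0),
        ScenarioConfig(label="ft_40", required_fraction=40.0),
        ScenarioConfig(label="ft_80", required_fraction=80.0),
        ScenarioConfig(label="fu_0.6", fu=0.6),
        ScenarioConfig(label="fu_1.0", fu=1.0),
    ]
    return [baseline] + variants


def resolve_scenario(
    scenario: ScenarioConfig,
    model: Optional[PKModelSpec] = None,
    regimen: Optional[Regimen] = None,
    target: Optional[PDTarget] = None,
    settings: Optional[SimSettings] = None,
    cohort_spec: Optional[CohortSpec] = None,
):
    """Apply a scenario's overrides to the baseline study configuration.

    Returns (model, regimen, target, settings, cohort) ready for run_pta.
    """
    model = model if model is not None else default_model()
    regimen = regimen if regimen is not None else default_regimen()
    target = target if target is not None else default_target()
    settings = settings if settings is not None else SimSettings()
    cohort_spec = cohort_spec if cohort_spec is not None else default_cohort_spec()

    model_kw: dict = {}
    if scenario.n_compartments is not None:
        if scenario.n_compartments == 2:
            model_kw.update(n_compartments=2, V=TWO_CMT_V, Q=TWO_CMT_Q, Vp=TWO_CMT_VP)
        else:
            model_kw.update(n_compartments=1, Q=None, Vp=None)
    if scenario.cv_CL is not None:
        model_kw["omega2_CL"] = cv_to_variance(scenario.cv_CL)
    if scenario.fu is not None:
        model_kw["fu"] = scenario.fu
    if model_kw:
        model = model.with_overrides(**model_kw)

    settings_kw: dict = {}
    if scenario.ruv_enabled is not None:
        settings_kw["ruv_enabled"] = scenario.ruv_enabled
    if scenario.phase is not None:
        settings_kw["phase"] = scenario.phase
    if scenario.dt is not None:
        settings_kw["dt"] = scenario.dt
    if settings_kw:
        settings = settings.with_overrides(**settings_kw)

    if scenario.required_fraction is not None:
        target = PDTarget(
            metric=target.metric,
            required_fraction=scenario.required_fraction,
            mic=target.mic,
            mic_multiplier=target.mic_multiplier,
            phase=target.phase,
        )

    if scenario.sCr_factor is not None:
        cohort_spec = CohortSpec(
            n=cohort_spec.n,
            sCr_mode=cohort_spec.sCr_mode,
            sCr=cohort_spec.sCr * scenario.sCr_factor,
            sCr_cv=cohort_spec.sCr_cv,
            age=cohort_spec.age,
            weight=cohort_spec.weight,
            sex=cohort_spec.sex,
            seed=cohort_spec.seed,
        )

    if scenario.mode == "continuous":
        regimen = default_continuous_regimen()

    cohort = generate_cohort(
        CohortSpec(
            n=settings.n_patients,
            sCr_mode=cohort_spec.sCr_mode,
            sCr=cohort_spec.sCr,
            sCr_cv=cohort_spec.sCr_cv,
            age=cohort_spec.age,
            weight=cohort_spec.weight,
            sex=cohort_spec.sex,
            seed=cohort_spec.seed,
        )
    )
    return model, regimen, target, settings, cohort
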