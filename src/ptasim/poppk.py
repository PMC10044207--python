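"""Population-pharmacokinetic model specification and individual-parameter sampling.

A population PK model describes the typical (median) pharmacokinetic
parameters of a patient population together with their between-subject
variability (BSV).  For renally cleared beta-lactams such as cefepime the
dominant covariate is renal function, entering the model either as serum
creatinine (sCr, mg/dL) through a power law, or as creatinine clearance
(CrCl, mL/min) through a linear equation.  Individual clearances are
realised from the typical value by a log-normal random effect,
``CL_i = tvCL(covariates) * exp(eta)`` with ``eta ~ N(0, omega^2)``.

Clearance variability is conventionally reported as a coefficient of
variation (CV); the exact log-normal correspondence ``omega^2 = ln(1 + CV^2)``
is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "CovariateModel",
    "PKModelSpec",
    "Patient",
    "IndividualParameters",
    "typical_clearance",
    "cockcroft_gault",
    "cv_to_variance",
    "draw_individual",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateModel:
    """Covariate model linking renal function to typical clearance.

    kind
        ``"power_sCr"``  : tvCL = tvCL_ref * (reference_value / sCr) ** exponent
        ``"linear_CrCl"``: tvCL = slope * CrCl + intercept
        ``"none"``       : tvCL = tvCL_ref (no covariate scaling)
    reference_value
        Covariate value at which ``tvCL_ref`` applies (mg/dL for power_sCr).
    exponent
        Power-law exponent (dimensionless, power_sCr only).
    slope, intercept
        Linear model coefficients: (L/h)/(mL/min) and L/h.
    """

    kind: Literal["power_sCr", "linear_CrCl", "none"] = "none"
    reference_value: float = 1.0
    exponent: float = 0.0
    slope: float = 0.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("power_sCr", "linear_CrCl", "none"):
            raise ValueError(f"unknown covariate model kind: {self.kind!r}")
        if self.kind == "power_sCr" and not self.reference_value > 0:
            raise ValueError("reference_value must be > 0 for a power_sCr model")
        for name in ("exponent", "slope", "intercept"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")


@dataclass(frozen=True)
class PKModelSpec:
    """Population PK model: structural model, typical values and variability.

    tvCL is the typical clearance (L/h) at the covariate reference;
    V the central volume (L); Q/Vp intercompartmental clearance and
    peripheral volume for the two-compartment model; fu the fraction
    unbound; omega2_* log-scale BSV variances; ruv_prop_sd the SD of the
    proportional residual error on simulated observations.
    """

    tvCL: float
    V: float
    n_compartments: int = 1
    Q: Optional[float] = None
    Vp: Optional[float] = None
    fu: float = 1.0
    omega2_CL: float = 0.0
    omega2_V: float = 0.0
    ruv_prop_sd: float = 0.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if not self.tvCL > 0:
            raise ValueError("tvCL must be > 0")
        if not self.V > 0:
            raise ValueError("V must be > 0")
        if self.n_compartments == 2:
            if self.Q is None or self.Vp is None:
                raise ValueError("Q and Vp are required for a two-compartment model")
            if not (self.Q > 0 and self.Vp > 0):
                raise ValueError("Q and Vp must be > 0")
        elif self.Q is not None or self.Vp is not None:
            raise ValueError("Q/Vp only apply to a two-compartment model")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")
        for name in ("omega2_CL", "omega2_V", "ruv_prop_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_overrides(self, **kwargs) -> "PKModelSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Patient:
    """Virtual patient covariates."""

    id: str
    sCr: float  # mg/dL
    age: float = 49.0  # years
    weight: float = 72.0  # kg
    sex: Literal["male", "female"] = "male"
    CrCl: Optional[float] = None  # mL/min; derived via Cockcroft-Gault if None

    def __post_init__(self) -> None:
        if not self.sCr > 0:
            raise ValueError("sCr must be > 0")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")
        if not 0 < self.age < 130:
            raise ValueError("age must be in (0, 130)")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def creatinine_clearance(self) -> float:
        """CrCl in mL/min, Cockcroft-Gault-derived when not given explicitly."""
        if self.CrCl is not None:
            return self.CrCl
        return cockcroft_gault(self.age, self.weight, self.sex, self.sCr)


@dataclass(frozen=True)
class IndividualParameters:
    """One realisation of the population model for a single virtual patient."""

    CL_i: float  # L/h
    V_i: float  # L
    fu: float = 1.0
    Q_i: Optional[float] = None
    Vp_i: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.CL_i > 0 and self.V_i > 0):
            raise ValueError("CL_i and V_i must be > 0")
        if (self.Q_i is None) != (self.Vp_i is None):
            raise ValueError("Q_i and Vp_i must be given together")
        if self.Q_i is not None and not (self.Q_i > 0 and self.Vp_i > 0):
            raise ValueError("Q_i and Vp_i must be > 0")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL_i / V_i (1/h)."""
        return self.CL_i / self.V_i


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def typical_clearance(cov_model: CovariateModel, tvCL_ref: float, patient: Patient) -> float:
    """Typical clearance (L/h) for a patient under a covariate model.

    power_sCr scales the reference clearance by ``(sCr_ref / sCr) ** exponent``,
    so clearance falls as serum creatinine rises; linear_CrCl evaluates
    ``slope * CrCl + intercept``.
    """
    if cov_model.kind == "none":
        return tvCL_ref
    if cov_model.kind == "power_sCr":
        if patient.sCr is None:
            raise ValueError("covariate model requires sCr but patient has none")
        if not patient.sCr > 0:
            raise ValueError("sCr must be > 0")
        return tvCL_ref * (cov_model.reference_value / patient.sCr) ** cov_model.exponent
    # linear_CrCl
    crcl = patient.creatinine_clearance
    if crcl is None:
        raise ValueError("covariate model requires CrCl but patient has none")
    cl = cov_model.slope * crcl + cov_model.intercept
    if not cl > 0:
        raise ValueError(f"linear covariate model produced non-positive clearance {cl}")
    return cl


def cockcroft_gault(age: float, weight: float, sex: str, sCr: float) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min).

    ``((140 - age) * weight) / (72 * sCr)``, multiplied by 0.85 for females.
    """
    if sCr <= 0:
        raise ValueError("sCr must be > 0")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    crcl = ((140.0 - age) * weight) / (72.0 * sCr)
    if sex == "female":
        crcl *= 0.85
    return max(crcl, 0.0)


def cv_to_variance(cv: float) -> float:
    """Log-scale variance omega^2 = ln(1 + cv^2) of a log-normal with the given CV."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return math.log1p(cv * cv)


def draw_individual(
    spec: PKModelSpec,
    patient: Patient,
    rng: np.random.Generator,
) -> IndividualParameters:
    """Sample one individual's PK parameters from the population model.

    Clearance and (optionally) central volume receive independent
    log-normal random effects; Q and Vp carry no BSV and are copied from
    the specification.
    """
    tvcl = typical_clearance(spec.covariate_model, spec.tvCL, patient)
    eta_cl = rng.normal(0.0, math.sqrt(spec.omega2_CL)) if spec.omega2_CL > 0 else 0.0
    eta_v = rng.normal(0.0, math.sqrt(spec.omega2_V)) if spec.omega2_V > 0 else 0.0
    return IndividualParameters(
        CL_i=tvcl * math.exp(eta_cl),
        V_i=spec.V * math.exp(eta_v),
        fu=spec.fu,
        Q_i=spec.Q,
        Vp_i=spec.Vp,
    )
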