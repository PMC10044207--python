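"""Pharmacodynamic target metrics evaluated on concentration profiles.

Beta-lactam efficacy tracks the fraction of the dosing window during which
the free drug concentration exceeds the MIC (fT%>MIC); fAUC:MIC and
Cmax:MIC are the indices used for concentration-driven antibiotic classes.
The grid-based fT%>MIC estimator counts grid points — deliberately, since
its dependence on the sampling interval is itself of interest — while
``ft_above_mic_exact_1cmt`` provides the continuous-time value from the
logarithmic crossing times of the one-compartment closed form.

Convention: strict ``>`` for MIC exceedance (the index is written
``fT > MIC``); ``>=`` for toxicity threshold exceedance at a time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .poppk import IndividualParameters
from .profiles import ConcentrationProfile, Regimen

__all__ = [
    "PDTarget",
    "ft_above_mic",
    "ft_above_mic_exact_1cmt",
    "fauc_over_mic",
    "cmax_over_mic",
    "conc_exceeds_at",
    "target_met",
]


@dataclass(frozen=True)
class PDTarget:
    """A pharmacodynamic target: metric, threshold and evaluation phase.

    For ``fT_above_MIC`` the target is met when the percent of the window
    with free drug above ``mic_multiplier * mic`` reaches
    ``required_fraction``.  For the ratio indices the target is met when
    the ratio reaches ``required_ratio``.  ``trough_threshold`` tests
    (total or free) concentration >= ``threshold`` at ``at_time``.
    """

    metric: Literal["fT_above_MIC", "fAUC_MIC", "Cmax_MIC", "trough_threshold"] = "fT_above_MIC"
    required_fraction: float = 60.0  # % of window (fT metric)
    mic: float = 8.0  # mg/L
    mic_multiplier: float = 1.0
    required_ratio: Optional[float] = None  # fAUC_MIC / Cmax_MIC metrics
    threshold: Optional[float] = None  # mg/L (trough metric)
    at_time: Optional[float] = None  # h (trough metric)
    scale: Literal["total", "free"] = "free"
    phase: Literal["first_dose", "steady_state"] = "first_dose"

    def __post_init__(self) -> None:
        if not 0 < self.required_fraction <= 100:
            raise ValueError("required_fraction must be in (0, 100]")
        if not self.mic > 0:
            raise ValueError("mic must be > 0")
        if not self.mic_multiplier >= 1:
            raise ValueError("mic_multiplier must be >= 1")
        if self.metric in ("fAUC_MIC", "Cmax_MIC") and self.required_ratio is None:
            raise ValueError(f"{self.metric} target needs required_ratio")
        if self.metric == "trough_threshold" and (self.threshold is None or self.at_time is None):
            raise ValueError("trough_threshold target needs threshold and at_time")

    @property
    def effective_mic(self) -> float:
        """Single effective threshold mic_multiplier * mic (mg/L)."""
        return self.mic_multiplier * self.mic


# ---------------------------------------------------------------------------
# Grid-based metrics
# ---------------------------------------------------------------------------

def ft_above_mic(profile: ConcentrationProfile, mic: float) -> float:
    """Percent of grid points with free concentration strictly above mic.

    The denominator is the number of grid points in the (half-open)
    window, so coarse sampling quantises the result in steps of
    ``100 / n_points``.
    """
    n = len(profile.times)
    if n == 0:
        raise ValueError("empty profile")
    return 100.0 * float(np.count_nonzero(profile.free_conc > mic)) / n


def fauc_over_mic(profile: ConcentrationProfile, mic: float) -> float:
    """Trapezoidal free-drug AUC over the window divided by mic (dimensionless)."""
    if len(profile.times) == 0:
        raise ValueError("empty profile")
    if len(profile.times) == 1:
        raise ValueError("need at least two grid points for an AUC")
    return float(np.trapezoid(profile.free_conc, profile.times)) / mic


def cmax_over_mic(profile: ConcentrationProfile, mic: float) -> float:
    """Maximum free concentration on the grid divided by mic."""
    if len(profile.times) == 0:
        raise ValueError("empty profile")
    return float(np.max(profile.free_conc)) / mic


def conc_exceeds_at(
    profile: ConcentrationProfile,
    t: float,
    threshold: float,
    scale: Literal["total", "free"] = "total",
) -> bool:
    """True iff concentration at the grid point nearest t is >= threshold."""
    lo, hi = profile.window
    if not lo <= t < hi + profile.dt:  # allow the interval-end trough lookup
        raise ValueError(f"t={t} outside profile window [{lo}, {hi})")
    idx = int(np.argmin(np.abs(profile.times - t)))
    conc = profile.total_conc if scale == "total" else profile.free_conc
    return bool(conc[idx] >= threshold)


# ---------------------------------------------------------------------------
# Analytic (continuous-time) fT%>MIC for the one-compartment model
# ---------------------------------------------------------------------------

def _time_above_monotone(c_start, c_end, t_start, t_end, solve, m):
    """Time above m on one monotone segment; `solve` inverts c(t) = m."""
    if c_start < c_end:  # rising
        if m >= c_end:
            return 0.0
        t_cross = t_start if m < c_start else solve(m)
        return t_end - t_cross
    # falling
    if m >= c_start:
        return 0.0
    t_cross = t_end if m < c_end else solve(m)
    return t_cross - t_start


def ft_above_mic_exact_1cmt(
    params: IndividualParameters,
    regimen: Regimen,
    fu: float,
    mic: float,
    window: Optional[tuple[float, float]] = None,
    phase: Literal["first_dose", "steady_state"] = "first_dose",
) -> float:
    """Exact continuous-time fT%>MIC for a one-compartment model.

    Solves the rising- and falling-segment crossing times in closed form
    (logarithms of the mono-exponential pieces) and divides the time above
    ``mic`` by the window length.  First-dose windows must lie within the
    first dosing interval, where a single administration contributes.
    """
    if params.Q_i is not None:
        raise ValueError("no closed crossing form for two compartments; use a fine grid")
    ke = params.ke
    m = mic / fu  # total-scale threshold

    if regimen.mode == "continuous":
        R0 = regimen.daily_dose / 24.0
        css = R0 / params.CL_i
        if window is None:
            window = (0.0, 24.0)
        t0, t1 = window
        if not t1 > t0:
            raise ValueError("window is empty")
        if phase == "steady_state":
            return 100.0 if css > m else 0.0
        if css <= m:
            return 0.0
        t_cross = -math.log(1.0 - m / css) / ke
        above = max(0.0, t1 - max(t_cross, t0))
        return 100.0 * above / (t1 - t0)

    tau = regimen.interval
    Tinf = regimen.infusion_duration
    R0 = regimen.dose / Tinf
    a = R0 / params.CL_i  # plateau of an unending infusion
    if window is None:
        window = (0.0, tau)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= tau + 1e-12):
        raise ValueError("window must lie within one dosing interval [0, tau]")

    if phase == "first_dose":
        if regimen.loading_dose is not None:
            raise ValueError("loading-dose schedules are not supported by the analytic form")
        cmax = a * -math.expm1(-ke * Tinf)
        above = 0.0
        # rising segment [0, Tinf]: c(t) = a (1 - e^{-ke t})
        seg_end = min(Tinf, t1)
        if seg_end > t0:
            above += _time_above_monotone(
                a * -math.expm1(-ke * max(t0, 0.0)),
                a * -math.expm1(-ke * seg_end),
                max(t0, 0.0),
                seg_end,
                lambda mm: -math.log(1.0 - mm / a) / ke,
                m,
            )
        # falling segment [Tinf, t1]: c(t) = cmax e^{-ke (t - Tinf)}
        if t1 > Tinf:
            s0 = max(t0, Tinf)
            above += _time_above_monotone(
                cmax * math.exp(-ke * (s0 - Tinf)),
                cmax * math.exp(-ke * (t1 - Tinf)),
                s0,
                t1,
                lambda mm: Tinf + math.log(cmax / mm) / ke,
                m,
            )
        return 100.0 * above / (t1 - t0)

    # steady state: in-infusion c(t) = a + (K - a) e^{-ke t}; post-infusion D e^{-ke t}
    r = math.exp(-ke * tau)
    K = a * math.expm1(ke * Tinf) * r / (1.0 - r)  # concentration at t = 0+
    D = a * math.expm1(ke * Tinf) / (1.0 - r)  # post-infusion coefficient
    above = 0.0
    seg_end = min(Tinf, t1)
    if seg_end > t0:
        def c_in(t: float) -> float:
            return a + (K - a) * math.exp(-ke * t)

        above += _time_above_monotone(
            c_in(max(t0, 0.0)),
            c_in(seg_end),
            max(t0, 0.0),
            seg_end,
            lambda mm: -math.log((mm - a) / (K - a)) / ke,
            m,
        )
    if t1 > Tinf:
        s0 = max(t0, Tinf)
        above += _time_above_monotone(
            D * math.exp(-ke * s0),
            D * math.exp(-ke * t1),
            s0,
            t1,
            lambda mm: math.log(D / mm) / ke,
            m,
        )
    return 100.0 * above / (t1 - t0)


# ---------------------------------------------------------------------------
# Target evaluation
# ---------------------------------------------------------------------------

def target_met(profile: ConcentrationProfile, target: PDTarget) -> bool:
    """Whether a profile meets the PD target (success uses >= throughout)."""
    if target.metric == "fT_above_MIC":
        return ft_above_mic(profile, target.effective_mic) >= target.required_fraction
    if target.metric == "fAUC_MIC":
        return fauc_over_mic(profile, target.effective_mic) >= target.required_ratio
    if target.metric == "Cmax_MIC":
        return cmax_over_mic(profile, target.effective_mic) >= target.required_ratio
    return conc_exceeds_at(profile, target.at_time, target.threshold, target.scale)
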