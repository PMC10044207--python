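"""Closed-form infusion profiles against a numerical ODE oracle, steady state,
superposition and discretisation behaviour."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ptasim import (
    IndividualParameters,
    ProfileSettings,
    Regimen,
    conc_1cmt_infusion,
    conc_2cmt_infusion,
    continuous_infusion_profile,
    simulate_profile,
    steady_state_conc,
    time_grid,
)


def ode_profile(params, regimen, times, n_doses=None):
    """Numerical-integration oracle for intermittent IV infusion.

    Integrates the compartmental mass-balance ODEs with the infusion as an
    explicit time-dependent input; independent of the closed forms under test.
    """
    CL, V = params.CL_i, params.V_i
    two_cmt = params.Q_i is not None
    tau, Tinf, R0 = regimen.interval, regimen.infusion_duration, regimen.infusion_rate
    t_max = float(np.max(times))
    if n_doses is None:
        n_doses = int(np.floor(t_max / tau)) + 1

    def rate_in(t):
        for k in range(n_doses):
            if k * tau <= t < k * tau + Tinf:
                return R0
        return 0.0

    if two_cmt:
        Q, Vp = params.Q_i, params.Vp_i

        def rhs(t, y):
            a_c, a_p = y
            return [
                rate_in(t) - (CL / V) * a_c - (Q / V) * a_c + (Q / Vp) * a_p,
                (Q / V) * a_c - (Q / Vp) * a_p,
            ]

        y0 = [0.0, 0.0]
    else:

        def rhs(t, y):
            return [rate_in(t) - (CL / V) * y[0]]

        y0 = [0.0]

    # break integration at dose start/stop discontinuities for accuracy
    breaks = sorted({0.0, t_max} | {k * tau for k in range(n_doses)} | {k * tau + Tinf for k in range(n_doses)})
    breaks = [b for b in breaks if 0.0 <= b <= t_max]
    lookup = {round(breaks[0], 9): y0[0]}
    y = y0
    for lo, hi in zip(breaks, breaks[1:]):
        # always evaluate the segment end so the carried state is the state at hi
        t_eval = sorted({t for t in times if lo < t <= hi} | {hi})
        out = solve_ivp(rhs, (lo, hi), y, t_eval=t_eval, rtol=1e-10, atol=1e-12)
        for t, c in zip(out.t, out.y[0]):
            lookup[round(t, 9)] = c
        y = out.y[:, -1]
    return np.array([lookup[round(t, 9)] for t in times]) / V


class TestOneCompartment:
    def test_hand_checked_values(self, worked_params, q8h_regimen):
        assert conc_1cmt_infusion(worked_params, q8h_regimen, 0.0) == 0.0
        assert conc_1cmt_infusion(worked_params, q8h_regimen, 0.5) == pytest.approx(88.48, abs=0.01)
        assert conc_1cmt_infusion(worked_params, q8h_regimen, 2.0) == pytest.approx(41.80, abs=0.01)

    def test_negative_time_rejected(self, worked_params, q8h_regimen):
        with pytest.raises(ValueError):
            conc_1cmt_infusion(worked_params, q8h_regimen, -0.1)

    def test_matches_ode_oracle_across_random_parameters(self, q8h_regimen, rng):
        times = np.linspace(0.1, 23.9, 48)  # spans three dosing intervals
        for _ in range(5):
            params = IndividualParameters(
                CL_i=rng.uniform(3, 25), V_i=rng.uniform(10, 40), fu=0.8
            )
            closed = conc_1cmt_infusion(params, q8h_regimen, times)
            ode = ode_profile(params, q8h_regimen, times)
            np.testing.assert_allclose(closed, ode, rtol=1e-3, atol=1e-8)

    def test_superposition_linearity(self, worked_params):
        t = np.linspace(0, 7.9, 30)
        single = Regimen(mode="intermittent", dose=1000, interval=8, infusion_duration=0.5)
        double = Regimen(mode="intermittent", dose=2000, interval=8, infusion_duration=0.5)
        np.testing.assert_allclose(
            conc_1cmt_infusion(worked_params, double, t),
            2.0 * conc_1cmt_infusion(worked_params, single, t),
            rtol=1e-12,
        )

    def test_loading_dose_adds_first_administration(self, worked_params):
        reg = Regimen(mode="intermittent", dose=1000, interval=8, infusion_duration=0.5,
                      loading_dose=2000)
        # at t = 2 h only the loading dose has been given
        expected = conc_1cmt_infusion(
            worked_params,
            Regimen(mode="intermittent", dose=2000, interval=8, infusion_duration=0.5),
            2.0,
        )
        assert conc_1cmt_infusion(worked_params, reg, 2.0) == pytest.approx(expected)


class TestTwoCompartment:
    PARAMS = IndividualParameters(CL_i=10.0, V_i=12.0, fu=0.8, Q_i=8.0, Vp_i=10.0)

    def test_zero_at_time_zero(self, q8h_regimen):
        assert conc_2cmt_infusion(self.PARAMS, q8h_regimen, 0.0) == 0.0

    def test_reduces_to_one_compartment_as_q_vanishes(self, worked_params, q8h_regimen):
        degenerate = IndividualParameters(CL_i=10.0, V_i=20.0, fu=0.8, Q_i=1e-9, Vp_i=10.0)
        t = time_grid(0.1, 8.0, 0.25)
        c2 = conc_2cmt_infusion(degenerate, q8h_regimen, t)
        c1 = conc_1cmt_infusion(worked_params, q8h_regimen, t)
        np.testing.assert_allclose(c2, c1, rtol=1e-3)

    def test_matches_ode_oracle(self, q8h_regimen):
        times = time_grid(0.125, 8.0, 0.125)[:64]
        closed = conc_2cmt_infusion(self.PARAMS, q8h_regimen, times)
        ode = ode_profile(self.PARAMS, q8h_regimen, times)
        np.testing.assert_allclose(closed, ode, rtol=1e-3)

    def test_missing_peripheral_parameters_rejected(self, worked_params, q8h_regimen):
        with pytest.raises(ValueError, match="Q_i and Vp_i"):
            conc_2cmt_infusion(worked_params, q8h_regimen, 1.0)


class TestSteadyState:
    def test_trough_accumulation_worked_example(self, worked_params, q8h_regimen):
        trough1 = conc_1cmt_infusion(worked_params, q8h_regimen, 8.0)
        assert trough1 == pytest.approx(2.081, abs=0.005)
        trough_ss = steady_state_conc(worked_params, q8h_regimen, 8.0)
        assert trough_ss == pytest.approx(2.120, abs=0.005)
        assert trough_ss == pytest.approx(trough1 / (1 - np.exp(-0.5 * 8)), abs=1e-9)

    @pytest.mark.parametrize("params", [
        IndividualParameters(CL_i=10.0, V_i=20.0, fu=0.8),
        IndividualParameters(CL_i=10.0, V_i=12.0, fu=0.8, Q_i=8.0, Vp_i=10.0),
    ])
    def test_closed_form_equals_truncated_superposition(self, params, q8h_regimen):
        t = time_grid(0.0, 8.0, 0.2)
        closed = steady_state_conc(params, q8h_regimen, t)
        summed = steady_state_conc(params, q8h_regimen, t, method="superposition")
        np.testing.assert_allclose(closed, summed, atol=1e-6)

    def test_steady_state_dominates_first_dose_pointwise(self, worked_params, q8h_regimen):
        t = time_grid(0.0, 8.0, 0.2)
        ss = steady_state_conc(worked_params, q8h_regimen, t)
        fd = conc_1cmt_infusion(worked_params, q8h_regimen, t)
        assert np.all(ss >= fd)

    def test_no_accumulation_limit(self, worked_params):
        # ke*tau = 50: accumulation is negligible and steady state equals a single dose
        reg = Regimen(mode="intermittent", dose=2000, interval=100.0, infusion_duration=0.5)
        t = time_grid(0.0, 8.0, 0.5)
        np.testing.assert_allclose(
            steady_state_conc(worked_params, reg, t),
            conc_1cmt_infusion(worked_params, reg, t),
            atol=1e-6,
        )

    def test_continuous_regimen_rejected(self, worked_params):
        with pytest.raises(ValueError):
            steady_state_conc(worked_params, Regimen(mode="continuous", daily_dose=6000), 1.0)


class TestContinuousInfusion:
    def test_css_worked_example(self):
        params = IndividualParameters(CL_i=13.6, V_i=18.0, fu=0.8)
        prof = continuous_infusion_profile(params, 6000.0)
        assert prof.total_conc[0] == pytest.approx(18.38, abs=0.01)
        assert prof.free_conc[0] == pytest.approx(14.71, abs=0.01)

    def test_css_vanishes_at_extreme_clearance(self):
        params = IndividualParameters(CL_i=1e9, V_i=18.0, fu=0.8)
        prof = continuous_infusion_profile(params, 6000.0)
        assert np.max(prof.total_conc) < 1e-6

    def test_first_dose_starts_at_zero_and_rises_to_css(self):
        params = IndividualParameters(CL_i=13.6, V_i=18.0, fu=0.8)
        prof = continuous_infusion_profile(params, 6000.0, window=(0, 48), dt=0.5,
                                           phase="first_dose")
        assert prof.total_conc[0] == 0.0
        assert np.all(np.diff(prof.total_conc) > 0)
        assert prof.total_conc[-1] == pytest.approx(250 / 13.6, rel=1e-6)


class TestSimulateProfile:
    def test_grid_has_exactly_40_points(self, worked_params, q8h_regimen):
        prof = simulate_profile(worked_params, q8h_regimen, ProfileSettings(dt=0.2))
        assert len(prof.times) == 40
        assert prof.times[0] == 0.0 and prof.times[-1] == pytest.approx(7.8)

    def test_noise_free_identity(self, worked_params, q8h_regimen):
        prof = simulate_profile(worked_params, q8h_regimen, ProfileSettings(dt=0.2))
        direct = conc_1cmt_infusion(worked_params, q8h_regimen, prof.times)
        np.testing.assert_array_equal(prof.total_conc, direct)
        np.testing.assert_allclose(prof.free_conc, 0.8 * direct, rtol=1e-12)

    def test_proportional_error_is_unbiased(self, worked_params, q8h_regimen):
        # 250 replicate profiles x 40 points = 10,000 noisy observations;
        # the mean observed/noiseless ratio must sit within 1% of 1
        gen = np.random.default_rng(77)
        noiseless = simulate_profile(worked_params, q8h_regimen, ProfileSettings(dt=0.2))
        ratios = []
        for _ in range(250):
            prof = simulate_profile(
                worked_params, q8h_regimen,
                ProfileSettings(dt=0.2, ruv_enabled=True, ruv_prop_sd=0.2, rng=gen),
            )
            ratios.append(prof.total_conc[1:] / noiseless.total_conc[1:])  # skip C(0)=0
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)

    def test_ruv_needs_rng(self, worked_params, q8h_regimen):
        with pytest.raises(ValueError, match="rng"):
            simulate_profile(worked_params, q8h_regimen,
                             ProfileSettings(ruv_enabled=True, ruv_prop_sd=0.2))

    def test_invalid_grid_rejected(self, worked_params, q8h_regimen):
        with pytest.raises(ValueError):
            simulate_profile(worked_params, q8h_regimen, ProfileSettings(dt=0.0))
        with pytest.raises(ValueError):
            simulate_profile(worked_params, q8h_regimen,
                             ProfileSettings(t_start=8.0, t_end=8.0))

    def test_profile_round_trips_through_table(self, worked_params, q8h_regimen, tmp_path):
        import pandas as pd

        prof = simulate_profile(worked_params, q8h_regimen, ProfileSettings(dt=0.2))
        path = tmp_path / "profile.tsv"
        prof.to_frame().to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["total_mg_L"], prof.total_conc)
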