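"""Step-response closed forms, descriptors and trajectory fitting."""

import math

import numpy as np
import pytest

from metadyn.dynamics import (
    ModelParams,
    damping_coefficient,
    fit_metabolite,
    mean_fitting_error,
    settling_time,
    step_response,
)

from conftest import STUDY_GRID, ode_step_response, random_params


class TestClosedForm:
    def test_zero_at_step_time_and_final_value(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = random_params(rng)
            M = rng.uniform(0.5, 15.0)
            assert step_response(p, M, 0.0) == pytest.approx(0.0, abs=1e-12)
            assert step_response(p, M, 1e6) == pytest.approx(p.K * M, rel=1e-6, abs=1e-9)

    def test_matches_ode_oracle_both_branches(self):
        rng = np.random.default_rng(2)
        times = np.array([0.0, 5.0, 15.0, 30.0, 60.0, 120.0])
        for _ in range(200):
            p = random_params(rng)
            M = rng.uniform(0.5, 15.0)
            closed = step_response(p, M, times)
            ode = ode_step_response(p, M, times)
            scale = max(abs(p.K * M), float(np.max(np.abs(ode))))
            assert np.max(np.abs(closed - ode)) / scale < 1e-6

    def test_specific_overdamped_values_match_ode(self):
        p = ModelParams.overdamped(1.0, 5.0, 30.0, 10.0)
        t = np.array([5.0, 30.0, 120.0])
        np.testing.assert_allclose(
            step_response(p, 6.0, t), ode_step_response(p, 6.0, t), rtol=1e-6
        )

    def test_pole_zero_cancellation_gives_first_order(self):
        # tau_a = tau1 cancels the slow pole: K*M*(1 - exp(-t/tau2))
        p = ModelParams.overdamped(0.7, 30.0, 30.0, 8.0)
        t = np.linspace(0.0, 120.0, 25)
        expect = 0.7 * 4.0 * (1.0 - np.exp(-t / 8.0))
        np.testing.assert_allclose(step_response(p, 4.0, t), expect, rtol=1e-9, atol=1e-12)

    def test_repeated_root_confluent_limit(self):
        p = ModelParams.overdamped(1.2, 3.0, 10.0, 10.0)
        t = np.linspace(0.0, 100.0, 21)
        np.testing.assert_allclose(
            step_response(p, 1.0, t), ode_step_response(p, 1.0, t), rtol=1e-6, atol=1e-9
        )

    def test_branches_agree_at_critical_damping(self):
        tau = 12.0
        po = ModelParams.overdamped(1.0, 3.0, tau, tau)
        pu = ModelParams.underdamped(1.0, 3.0, tau, 1.0 - 1e-9)
        t = np.linspace(0.0, 150.0, 40)
        np.testing.assert_allclose(step_response(po, 2.0, t), step_response(pu, 2.0, t), atol=2e-6)

    def test_pre_step_times_stay_at_zero_deviation(self):
        p = ModelParams.overdamped(1.0, 0.0, 20.0, 5.0)
        assert step_response(p, 10.0, np.array([-10.0, -1.0]))[0] == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ModelParams.overdamped(1.0, 0.0, -5.0, 2.0)
        with pytest.raises(ValueError, match="zeta"):
            ModelParams.underdamped(1.0, 0.0, 5.0, 1.2)
        with pytest.raises(ValueError, match="scenario"):
            ModelParams("critically", 1.0, 0.0)

    def test_tau_ordering_convention(self):
        p = ModelParams.overdamped(1.0, 0.0, 3.0, 9.0)
        assert (p.tau1, p.tau2) == (9.0, 3.0)


class TestDescriptors:
    def test_damping_overdamped_formula(self):
        assert damping_coefficient(ModelParams.overdamped(1, 0, 4.0, 1.0)) == pytest.approx(1.25)
        assert damping_coefficient(ModelParams.overdamped(1, 0, 7.0, 7.0)) == pytest.approx(1.0)

    def test_damping_underdamped_is_stored_zeta(self):
        assert damping_coefficient(ModelParams.underdamped(1, 0, 5.0, 0.4)) == 0.4

    def test_overdamped_damping_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t1 = rng.uniform(1, 50)
            t2 = rng.uniform(1, 50)
            assert damping_coefficient(ModelParams.overdamped(1, 0, t1, t2)) >= 1.0

    def test_settling_time_first_order_closed_form(self):
        # pole-zero cancellation leaves K*M*(1-exp(-t/tau2)); with y0 = 0 the
        # band crossing is at tau2 * ln(1/0.05)
        tau2 = 7.0
        p = ModelParams.overdamped(1.0, 30.0, 30.0, tau2)
        assert settling_time(p, 1.0, y0=0.0) == pytest.approx(tau2 * math.log(20.0), rel=1e-6)

    def test_settling_time_flat_response_is_zero(self):
        p = ModelParams.overdamped(0.0, 1.0, 20.0, 5.0)
        assert settling_time(p, 10.0, y0=3.0) == 0.0

    def test_settling_time_underdamped_last_band_exit(self):
        p = ModelParams.underdamped(1.0, 0.0, 20.0, 0.3)
        ts = settling_time(p, 1.0, y0=0.0)
        # dense-grid oracle on the closed form
        tt = np.linspace(0.0, 2000.0, 400_001)
        y = step_response(p, 1.0, tt)
        outside = np.abs(y - 1.0) > 0.05
        t_oracle = tt[np.max(np.nonzero(outside)[0])]
        assert ts == pytest.approx(t_oracle, abs=tt[1] - tt[0])
        # first band entry is strictly earlier than the settling time
        first_inside = tt[np.min(np.nonzero(~outside[1:])[0]) + 1]
        assert first_inside < ts

    def test_settling_time_monotone_in_tau(self):
        prev = 0.0
        for tau in (5.0, 10.0, 20.0, 40.0):
            p = ModelParams.underdamped(1.0, 0.2 * tau, tau, 0.6)
            t = settling_time(p, 1.0, y0=0.0)
            assert t >= prev
            prev = t

    def test_settling_time_undefined_for_nonpositive_final(self):
        with pytest.raises(ValueError):
            settling_time(ModelParams.overdamped(-1.0, 0.0, 20.0, 5.0), 10.0, y0=2.0)


class TestFitError:
    def test_perfect_fit_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mean_fitting_error(y, y) == 0.0

    def test_constant_offset_calibration(self):
        obs = np.array([10.0, 12.0, 8.0, 10.0])
        fit = obs + 0.05 * obs.mean()
        assert mean_fitting_error(fit, obs) == pytest.approx(5.0)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            mean_fitting_error(np.array([1.0, 1.0]), np.array([1.0, -3.0]))


class TestFitting:
    @pytest.mark.parametrize(
        "true",
        [
            ModelParams.overdamped(0.5, 2.0, 20.0, 5.0),
            ModelParams.overdamped(-0.3, 0.0, 30.0, 10.0),
            ModelParams.overdamped(1.0, -3.0, 15.0, 6.0),
            ModelParams.underdamped(0.8, 1.0, 10.0, 0.5),
            ModelParams.underdamped(-0.5, 0.0, 8.0, 0.7),
        ],
        ids=["over", "over-neg-K", "inverse-response", "under", "under-neg-K"],
    )
    def test_zero_noise_roundtrip(self, true):
        M, y0 = 12.5, 10.0
        y = y0 + step_response(true, M, STUDY_GRID)
        fr = fit_metabolite(STUDY_GRID, y, None, M=M, seed=5)
        assert fr.accepted and fr.scenario == true.scenario
        assert fr.mean_fit_error < 1e-6
        got = fr.params
        for name in ("K", "tau_a", "tau1", "tau2", "tau", "zeta"):
            t, g = getattr(true, name), getattr(got, name)
            if t is None or t == 0.0:
                continue
            assert g == pytest.approx(t, rel=1e-3), name

    def test_flat_profile_fits_near_zero_gain(self):
        rng = np.random.default_rng(0)
        y = 10.0 * rng.lognormal(0.0, 0.005, STUDY_GRID.size)
        fr = fit_metabolite(STUDY_GRID, y, None, M=12.5, seed=1)
        assert abs(fr.params.K * 12.5) <= 0.1 * 10.0  # |K*M| under the noise floor

    def test_scenario_identified_with_noise(self):
        rng = np.random.default_rng(11)
        M, y0 = 12.5, 10.0
        hits = 0
        cases = []
        for zeta in (0.5, 1.5):
            for _ in range(10):
                if zeta < 1:
                    p = ModelParams.underdamped(0.6, 0.0, 12.0, zeta)
                else:
                    # zeta = 1.5 realized as real poles with tau1/tau2 = (z+sqrt(z^2-1))^2
                    r = (1.5 + math.sqrt(1.25)) ** 2
                    p = ModelParams.overdamped(0.6, 0.0, 12.0 * math.sqrt(r), 12.0 / math.sqrt(r))
                cases.append(p)
        for i, p in enumerate(cases):
            true = y0 + step_response(p, M, STUDY_GRID)
            reps = true[None, :] * rng.lognormal(0.0, 0.05, (3, STUDY_GRID.size))
            fr = fit_metabolite(STUDY_GRID, reps.mean(0), reps.std(0, ddof=1), M=M, seed=i)
            hits += fr.scenario == p.scenario
        assert hits >= 16  # 80% of 20 noisy designs

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6"):
            fit_metabolite(np.array([-10.0, 0, 5, 10]), np.ones(4), None, M=1.0)

    def test_missing_prestep_rejected(self):
        t = np.array([0.0, 5, 10, 15, 30, 60, 120])
        with pytest.raises(ValueError, match="pre-step"):
            fit_metabolite(t, np.ones(7), None, M=1.0)
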