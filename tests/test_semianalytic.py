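import math

import numpy as np
import pytest

from ringosc import closedform
from ringosc.experiments import random_params
from ringosc.model import OscillatorParams
from ringosc.semianalytic import (
    IntegralConstants,
    amplitude,
    constants_from_cycle,
    constants_residual,
    cycle_times,
    peaks,
    period,
    solve,
    solve_constants,
    troughs,
)
from ringosc.simulate import simulate


def saturating_constants(p: OscillatorParams) -> IntegralConstants:
    """The closed-form limit used as the solver's first iterate."""
    C1, C2 = -p.ceiling, p.ceiling.copy()
    return IntegralConstants(
        C1=C1, C2=C2,
        gamma=(p.K - p.ceiling) / C1, delta=p.K / C2,
        residual_norm=math.nan,
    )


class TestConstantsResidual:
    def test_zero_at_simulator_derived_constants(self, ring3):
        res = simulate(ring3, tol=1e-12)
        C = constants_from_cycle(ring3, res.cycle)
        r = constants_residual(ring3, C.C1, C.C2)
        assert np.max(np.abs(r)) < 1e-9

    def test_saturating_guess_nearly_closes_long_loops(self, uniform_ring):
        p = uniform_ring(15)
        C = saturating_constants(p)
        r15 = np.max(np.abs(constants_residual(p, C.C1, C.C2)))
        p3 = uniform_ring(3)
        C3 = saturating_constants(p3)
        r3 = np.max(np.abs(constants_residual(p3, C3.C1, C3.C2)))
        assert r15 < 1e-3
        assert r15 < r3

    def test_perturbed_constants_do_not_close(self, ring3):
        C = solve_constants(ring3)
        r = constants_residual(ring3, C.C1 * 1.1, C.C2 * 1.1)
        assert np.max(np.abs(r)) > 1e-3

    def test_domain_error_for_wrong_sign_constants(self, ring3):
        from ringosc.semianalytic import DomainError

        with pytest.raises(DomainError):
            constants_residual(ring3, np.full(3, 0.5), np.full(3, 1.0))


class TestSolveConstants:
    def test_matches_simulator_constants(self, ring3):
        C = solve_constants(ring3)
        sim = constants_from_cycle(ring3, simulate(ring3, tol=1e-12).cycle)
        np.testing.assert_allclose(C.C1, sim.C1, rtol=1e-9)
        np.testing.assert_allclose(C.C2, sim.C2, rtol=1e-9)
        assert C.residual_norm <= 1e-12

    def test_signs_and_ratio_ranges(self, ring3):
        C = solve_constants(ring3)
        assert np.all(C.C1 < 0) and np.all(C.C2 > 0)
        assert np.all((0 < C.gamma) & (C.gamma < 1))
        assert np.all((0 < C.delta) & (C.delta < 1))

    def test_small_threshold_converges(self, uniform_ring):
        p = uniform_ring(3, rho=0.05)
        C = solve_constants(p)
        sim = constants_from_cycle(p, simulate(p, tol=1e-12).cycle)
        np.testing.assert_allclose(C.C1, sim.C1, rtol=1e-8)
        assert np.all((0 < C.gamma) & (C.gamma < 1))
        assert np.all((0 < C.delta) & (C.delta < 1))

    def test_non_oscillatory_rejected(self):
        p = OscillatorParams(alpha=[1, 1], beta=[1, 1], K=[0.5, 0.5])
        with pytest.raises(ValueError, match="oscillate"):
            solve_constants(p)


class TestPeriodAndAmplitude:
    def test_period_matches_simulator(self, ring3):
        sol = solve(ring3)
        res = simulate(ring3)
        assert sol.period == pytest.approx(res.cycle.period, rel=1e-9)

    def test_period_equals_sum_of_cycle_times(self, ring3):
        C = solve_constants(ring3)
        times = cycle_times(ring3, C)
        assert period(ring3, C) == pytest.approx(times.total, rel=1e-14)

    def test_seven_loop_close_to_closed_form(self, uniform_ring):
        # measured exact gap at n=7 is 1.2%, shrinking fast with n
        p = uniform_ring(7)
        sol = solve(p)
        assert sol.period == pytest.approx(7 * math.log(4), rel=0.02)

    def test_amplitude_matches_simulator(self, ring3):
        sol = solve(ring3)
        res = simulate(ring3)
        np.testing.assert_allclose(sol.amplitude, res.cycle.amplitude, rtol=1e-9)

    def test_amplitude_approaches_ceiling_from_below(self, uniform_ring):
        eps9 = solve(uniform_ring(9)).amplitude
        eps3 = solve(uniform_ring(3)).amplitude
        assert np.all(eps9 < 1.0)
        assert np.all(eps9 > eps3.max())

    def test_amplitude_formula_specialisation_n3(self):
        # eps_1 = C_11 (gamma_1 gamma_2^{a1/a2} gamma_3^{a1/a3} - 1)
        p = random_params(3, seed=5)
        C = solve_constants(p)
        a = p.alpha
        expected = C.C1[0] * (
            C.gamma[0]
            * C.gamma[1] ** (a[0] / a[1])
            * C.gamma[2] ** (a[0] / a[2])
            - 1.0
        )
        assert amplitude(p, C)[0] == pytest.approx(expected, rel=1e-12)

    def test_peaks_troughs_match_simulator(self, ring3):
        C = solve_constants(ring3)
        res = simulate(ring3, tol=1e-12)
        np.testing.assert_allclose(peaks(ring3, C), res.cycle.peaks, rtol=1e-9)
        np.testing.assert_allclose(troughs(ring3, C), res.cycle.troughs, rtol=1e-9)


class TestCycleTimes:
    def test_interval_times_match_event_log(self, ring3):
        C = solve_constants(ring3)
        times = cycle_times(ring3, C)
        res = simulate(ring3, tol=1e-12)
        n = ring3.n
        tail = res.events[-2 * n - 1:]
        durations = {  # duration of interval ending at each crossing
            (ev.species, ev.direction): ev.time - prev.time
            for prev, ev in zip(tail, tail[1:])
        }
        for i in range(n):
            assert durations[(i + 1, 1)] == pytest.approx(
                times.tau_rise[i], rel=1e-9)
            assert durations[(i + 1, -1)] == pytest.approx(
                times.tau_fall[i], rel=1e-9)

    def test_uniform_symmetry(self, uniform_ring):
        times = cycle_times(uniform_ring(5), solve_constants(uniform_ring(5)))
        np.testing.assert_allclose(times.tau_rise, times.tau_rise[0], rtol=1e-12)
        np.testing.assert_allclose(times.tau_fall, times.tau_fall[0], rtol=1e-12)

    def test_saturating_limit_at_half_rho(self, uniform_ring):
        # gamma = delta = 0.5 exactly in the saturating limit at rho = 0.5
        p = uniform_ring(4)
        times = cycle_times(p, saturating_constants(p))
        np.testing.assert_allclose(times.tau_rise, math.log(2), rtol=1e-14)
        np.testing.assert_allclose(times.tau_fall, math.log(2), rtol=1e-14)


class TestSimulatorEquivalence:
    """Seeded random draws: the two exact tiers must agree to 1e-8."""

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_random_draws(self, n):
        rng = np.random.default_rng(900 + n)
        devs_tau, devs_eps = [], []
        for _ in range(40):
            p = random_params(n, rng)
            sol = solve(p)
            res = simulate(p)
            assert res.converged
            devs_tau.append(abs(sol.period - res.cycle.period) / sol.period)
            devs_eps.append(
                np.max(np.abs(sol.amplitude - res.cycle.amplitude)
                       / sol.amplitude)
            )
        assert np.median(devs_tau) < 1e-8
        assert np.median(devs_eps) < 1e-8

    def test_full_gap_shrinks_with_loop_length(self):
        medians = []
        for n in (3, 5, 7):
            rng = np.random.default_rng(40 + n)
            gaps = [
                abs(closedform.period_full(p) - solve(p).period) / solve(p).period
                for p in (random_params(n, rng) for _ in range(40))
            ]
            medians.append(np.median(gaps))
        assert medians[0] > medians[1] > medians[2]
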