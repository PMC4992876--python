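import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fmisopk import (
    InputFunction,
    KineticParams,
    frame_average_signal,
    macro_influx_rate,
    roi_signal,
    solve_two_tissue,
)
from fmisopk.errors import ExtrapolationError, InvalidSpecError, UndefinedMacroError
from fmisopk.kinetics import FrameAveragedModel


def ode_oracle(params, cp, eval_times, max_step=5.0):
    """Independent stiff-ODE integration of the compartment system."""
    t, c = cp.sample_times, cp.plasma_concentration
    alpha = (params.k2 + params.k3) / 60.0
    k3, k4, K1 = params.k3 / 60.0, params.k4 / 60.0, params.K1 / 60.0

    def rhs(tt, y):
        cpv = np.interp(tt, t, c)
        return [K1 * cpv - alpha * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

    sol = solve_ivp(rhs, [0.0, float(np.max(eval_times))], [0.0, 0.0],
                    t_eval=eval_times, rtol=1e-10, atol=1e-12,
                    max_step=max_step, method="LSODA")
    return sol.y[0], sol.y[1]


class TestMacroInfluxRate:
    def test_no_trapping_gives_zero(self):
        assert macro_influx_rate(KineticParams(K1=0.1, k2=0.05, k3=0.0)) == 0.0

    def test_undefined_when_both_rates_zero(self):
        with pytest.raises(UndefinedMacroError):
            macro_influx_rate(KineticParams(K1=0.1, k2=0.0, k3=0.0))

    def test_formula(self):
        p = KineticParams(K1=0.1095, k2=0.0602, k3=0.0109)
        assert macro_influx_rate(p) == pytest.approx(0.1095 * 0.0109 / 0.0711)


class TestKineticParamsValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidSpecError):
            KineticParams(K1=0.1, k2=0.1, k3=0.1, w_p=0.5, w_d=0.5, w_a=0.5)

    def test_rates_nonnegative(self):
        with pytest.raises(InvalidSpecError):
            KineticParams(K1=-0.1, k2=0.1, k3=0.1)


class TestSolveTwoTissue:
    def test_zero_input_gives_zero_curves(self, schedule):
        cp0 = InputFunction(np.arange(0.0, 7201.0, 10.0), np.zeros(721))
        cur = solve_two_tissue(KineticParams(K1=0.1, k2=0.05, k3=0.01),
                               cp0, schedule.frame_end)
        assert np.all(cur.C_d == 0) and np.all(cur.C_a == 0)

    def test_zero_delivery_gives_zero_curves(self, cp, schedule):
        cur = solve_two_tissue(KineticParams(K1=0.0, k2=0.05, k3=0.01),
                               cp, schedule.frame_end)
        assert np.all(cur.C_d == 0) and np.all(cur.C_a == 0)

    def test_constant_input_closed_form(self):
        """For constant C_p = c and k4 = 0: C_d = (K1 c / alpha)(1 - e^{-alpha t})."""
        c = 500.0
        cp_const = InputFunction(np.array([0.0, 7200.0]), np.array([c, c]))
        p = KineticParams(K1=0.06, k2=0.03, k3=0.012)
        times = np.array([60.0, 600.0, 3600.0, 7200.0])
        cur = solve_two_tissue(p, cp_const, times)
        alpha = (p.k2 + p.k3) / 60.0
        expected = (p.K1 / 60.0) * c / alpha * (1.0 - np.exp(-alpha * times))
        np.testing.assert_allclose(cur.C_d, expected, rtol=1e-9)
        # C_a = k3 * int C_d, evaluated analytically
        expected_ca = (p.k3 / 60.0) * (p.K1 / 60.0) * c / alpha * (
            times - (1.0 - np.exp(-alpha * times)) / alpha)
        np.testing.assert_allclose(cur.C_a, expected_ca, rtol=1e-9)

    @pytest.mark.parametrize("preset_k4", [("MDA-1h", 0.0), ("U87MG-1h", 0.0),
                                           ("MDA-1h", 0.01), ("U87MG-6h", 0.003)])
    def test_agrees_with_numeric_ode_oracle(self, cp, schedule, preset_k4):
        """Closed-form convolution within 0.1% of stiff numerical integration."""
        from fmisopk import preset_params
        name, k4 = preset_k4
        base = preset_params(name)
        p = KineticParams(K1=base.K1, k2=base.k2, k3=base.k3, k4=k4,
                          w_p=base.w_p, w_d=base.w_d, w_a=base.w_a)
        times = schedule.frame_end
        cur = solve_two_tissue(p, cp, times)
        cd, ca = ode_oracle(p, cp, times)
        assert np.max(np.abs(cur.C_d - cd)) <= 1e-3 * np.max(cd)
        assert np.max(np.abs(cur.C_a - ca)) <= 1e-3 * np.max(ca)

    def test_superposition_in_input(self, cp, schedule, mda_params):
        doubled = InputFunction(cp.sample_times, 2.0 * cp.plasma_concentration)
        a = solve_two_tissue(mda_params, cp, schedule.frame_end)
        b = solve_two_tissue(mda_params, doubled, schedule.frame_end)
        np.testing.assert_allclose(b.C_d, 2.0 * a.C_d, rtol=1e-10)
        np.testing.assert_allclose(b.C_a, 2.0 * a.C_a, rtol=1e-10)

    def test_trapped_pool_monotone_when_irreversible(self, cp, mda_params):
        times = np.linspace(0.0, 7200.0, 500)
        cur = solve_two_tissue(mda_params, cp, times)
        assert np.all(np.diff(cur.C_a) >= -1e-12)

    def test_reversible_converges_to_irreversible_as_k4_vanishes(self, cp, schedule,
                                                                 mda_params):
        times = schedule.frame_end
        ref = solve_two_tissue(mda_params, cp, times)
        gaps = []
        for k4 in (1e-3, 1e-4, 1e-5):
            p = KineticParams(K1=mda_params.K1, k2=mda_params.k2, k3=mda_params.k3,
                              k4=k4, w_p=mda_params.w_p, w_d=mda_params.w_d,
                              w_a=mda_params.w_a)
            cur = solve_two_tissue(p, cp, times)
            gaps.append(max(np.max(np.abs(cur.C_d - ref.C_d)),
                            np.max(np.abs(cur.C_a - ref.C_a))))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] <= 1e-3 * np.max(ref.C_a)

    def test_eval_beyond_input_support_raises(self, cp, mda_params):
        with pytest.raises(ExtrapolationError):
            solve_two_tissue(mda_params, cp, np.array([8000.0]))


class TestRoiSignal:
    def test_pure_blood_voxel_returns_input(self, cp, schedule):
        p = KineticParams(K1=0.1, k2=0.05, k3=0.01, w_p=1.0, w_d=0.0, w_a=0.0)
        cur = solve_two_tissue(p, cp, schedule.frame_end)
        np.testing.assert_allclose(roi_signal(p, cp, cur), cp(schedule.frame_end))

    def test_weighted_sum_arithmetic(self):
        from fmisopk.kinetics import CompartmentCurves
        p = KineticParams(K1=0.1, k2=0.05, k3=0.01, w_p=0.1, w_d=0.45, w_a=0.45)
        cp10 = InputFunction(np.array([0.0, 100.0]), np.array([10.0, 10.0]))
        cur = CompartmentCurves(np.array([50.0]), np.array([2.0]), np.array([4.0]))
        assert roi_signal(p, cp10, cur)[0] == pytest.approx(3.7)

    def test_convexity_when_all_pools_equal(self):
        from fmisopk.kinetics import CompartmentCurves
        p = KineticParams(K1=0.1, k2=0.05, k3=0.01, w_p=0.2, w_d=0.3, w_a=0.5)
        c = 7.5
        cpc = InputFunction(np.array([0.0, 100.0]), np.array([c, c]))
        cur = CompartmentCurves(np.array([40.0]), np.array([c]), np.array([c]))
        assert roi_signal(p, cpc, cur)[0] == pytest.approx(c)


class TestFrameAverageSignal:
    def test_constant_signal_averages_to_itself(self, schedule):
        c = 123.0
        cpc = InputFunction(np.array([0.0, 7200.0]), np.array([c, c]))
        p = KineticParams(K1=0.0, k2=0.0, k3=0.0, w_p=1.0, w_d=0.0, w_a=0.0)
        tac = frame_average_signal(p, cpc, schedule)
        np.testing.assert_allclose(tac.values, c, rtol=1e-12)

    def test_linear_signal_averages_to_midpoint_value(self, schedule):
        a = 0.05
        t = np.array([0.0, 7200.0])
        cplin = InputFunction(t, a * t)
        p = KineticParams(K1=0.0, k2=0.0, k3=0.0, w_p=1.0, w_d=0.0, w_a=0.0)
        tac = frame_average_signal(p, cplin, schedule)
        np.testing.assert_allclose(tac.values, a * schedule.midpoints(), rtol=1e-12)

    def test_matches_fine_grid_quadrature(self, cp, schedule, mda_params):
        """Frame averages within 0.1% of trapezoid quadrature at 0.25 s."""
        tac = frame_average_signal(mda_params, cp, schedule)
        fine = FrameAveragedModel(cp, None,
                                  extra_times=np.arange(0.0, 7200.25, 0.25))
        cur = fine.curves(mda_params)
        sig = (mda_params.w_p * np.interp(fine.grid, cp.sample_times,
                                          cp.plasma_concentration)
               + mda_params.w_d * cur.C_d + mda_params.w_a * cur.C_a)
        i0 = np.searchsorted(fine.grid, schedule.frame_start)
        i1 = np.searchsorted(fine.grid, schedule.frame_end)
        quad = np.array([
            np.trapezoid(sig[a:b + 1], fine.grid[a:b + 1]) / (fine.grid[b] - fine.grid[a])
            for a, b in zip(i0, i1)])
        np.testing.assert_allclose(tac.values, quad, rtol=1e-3)
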