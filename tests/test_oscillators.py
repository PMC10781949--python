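"""Phase dynamics, order parameter, frequency sampling, threshold recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from msgfield import (
    CouplingConfig,
    FrequencyModel,
    PhaseState,
    analytic_R_inf,
    estimate_critical_coupling,
    integrate,
    order_parameter,
    phase_derivative,
    sample_frequencies,
    steady_state_R,
)
from msgfield.oscillators import TWO_PI


def _loop_derivative(theta, omega, G, h):
    """Independent double-loop evaluation of the coupled phase equation."""
    n = len(theta)
    out = np.empty(n)
    for j in range(n):
        acc = 0.0
        for k in range(n):
            gjk = G if np.isscalar(G) else G[j, k]
            acc += gjk * h(theta[j] - theta[k])
        out[j] = omega[j] + acc / n
    return out


class TestSampleFrequencies:
    def test_zero_scale_degenerates_to_constant(self):
        om = sample_frequencies(50, FrequencyModel(omega0=2.5, gamma=0.0), seed=3)
        assert np.all(om == 2.5)

    def test_seed_determinism(self):
        m = FrequencyModel(omega0=1.0, gamma=0.7)
        assert np.array_equal(sample_frequencies(100, m, seed=42), sample_frequencies(100, m, seed=42))

    def test_large_sample_matches_cauchy_law(self):
        om = sample_frequencies(10000, FrequencyModel(omega0=3.0, gamma=1.0), seed=0)
        assert abs(np.median(om) - 3.0) < 0.1
        ks = stats.kstest(om, stats.cauchy(loc=3.0, scale=1.0).cdf)
        # 1% critical value for the KS statistic, large-n approximation
        assert ks.statistic < 1.628 / math.sqrt(10000)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            FrequencyModel(omega0=0.0, gamma=-0.1)


class TestPhaseDerivative:
    def test_equal_phases_leave_only_natural_frequencies(self, rng):
        omega = rng.normal(size=8)
        state = PhaseState(theta=np.full(8, 1.2), omega=omega)
        assert np.allclose(phase_derivative(state, CouplingConfig(coupling=2.0)), omega)

    def test_two_oscillator_hand_value(self):
        state = PhaseState(theta=np.array([0.0, np.pi / 2]), omega=np.array([1.0, 1.0]))
        d = phase_derivative(state, CouplingConfig(coupling=1.0))
        assert d == pytest.approx([1.5, 0.5])

    @pytest.mark.parametrize("matrix_coupling", [False, True])
    def test_matches_double_loop_oracle(self, rng, matrix_coupling):
        for _ in range(100):
            n = rng.integers(2, 51)
            theta = rng.uniform(0, TWO_PI, n)
            omega = rng.normal(size=n)
            if matrix_coupling:
                G = rng.uniform(0, 2, size=(n, n))
                np.fill_diagonal(G, 0.0)
            else:
                G = float(rng.uniform(0, 3))
            d = phase_derivative(PhaseState(theta=theta, omega=omega), CouplingConfig(coupling=G))
            oracle = _loop_derivative(theta, omega, G, lambda x: -math.sin(x))
            assert np.allclose(d, oracle, atol=1e-12)

    def test_nonfinite_phases_rejected(self):
        state = PhaseState(theta=np.array([0.0, 1.0]), omega=np.zeros(2))
        state.theta[0] = np.nan
        with pytest.raises(ValueError):
            phase_derivative(state, CouplingConfig())

    def test_generic_coupling_function_falls_back_to_pairwise(self, rng):
        from msgfield.oscillators import register_coupling_function

        register_coupling_function("test_h", lambda x: np.sin(x) ** 3)
        n = 7
        theta = rng.uniform(0, TWO_PI, n)
        omega = rng.normal(size=n)
        d = phase_derivative(PhaseState(theta=theta, omega=omega), CouplingConfig(coupling=1.5, h_name="test_h"))
        oracle = _loop_derivative(theta, omega, 1.5, lambda x: math.sin(x) ** 3)
        assert np.allclose(d, oracle, atol=1e-12)


class TestOrderParameter:
    def test_identical_phases_fully_coherent(self):
        r, _ = order_parameter(np.full(10, 0.7))
        assert r == pytest.approx(1.0)

    def test_symmetric_four_point_configuration_cancels(self):
        r, _ = order_parameter([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_quarter_turn_pair(self):
        r, theta = order_parameter([0.0, np.pi / 2])
        assert r == pytest.approx(math.sqrt(2) / 2, abs=1e-12)
        assert theta == pytest.approx(np.pi / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_parameter([])

    def test_global_phase_shift_invariance(self, rng):
        for _ in range(10):
            theta = rng.uniform(0, TWO_PI, 30)
            shift = rng.uniform(0, TWO_PI)
            r0, _ = order_parameter(theta)
            r1, _ = order_parameter(np.mod(theta + shift, TWO_PI))
            assert r1 == pytest.approx(r0, abs=1e-12)
            assert 0.0 <= r0 <= 1.0


class TestIntegrate:
    def test_zero_coupling_is_exactly_linear_drift(self, rng):
        n = 10
        theta0 = rng.uniform(0, TWO_PI, n)
        omega = rng.normal(size=n)
        traj = integrate(
            PhaseState(theta=theta0.copy(), omega=omega),
            CouplingConfig(coupling=0.0, dt=0.01, method="euler"),
            horizon=5.0,
        )
        for i, t in enumerate(traj.times):
            expected = np.mod(theta0 + omega * t, TWO_PI)
            diff = np.mod(traj.theta_matrix[i] - expected + np.pi, TWO_PI) - np.pi
            assert np.allclose(diff, 0.0, atol=1e-9)

    def test_identical_oscillators_synchronize(self, rng):
        n = 100
        state = PhaseState(theta=rng.uniform(0, TWO_PI, n), omega=np.full(n, 2.0))
        traj = integrate(state, CouplingConfig(coupling=1.0), horizon=30.0, store_phases=False)
        assert traj.R[-1] >= 0.99

    def test_step_halving_converges(self, rng):
        n = 10
        theta0 = rng.uniform(0, TWO_PI, n)
        omega = rng.normal(size=n)
        finals = []
        for dt in (0.02, 0.01):
            traj = integrate(
                PhaseState(theta=theta0.copy(), omega=omega.copy()),
                CouplingConfig(coupling=1.0, dt=dt),
                horizon=10.0,
            )
            finals.append(traj.theta_matrix[-1])
        diff = np.mod(finals[0] - finals[1] + np.pi, TWO_PI) - np.pi
        assert np.max(np.abs(diff)) < 1e-4

    def test_R_stays_in_unit_interval_and_sigma_nonnegative(self, rng):
        n = 20
        G = rng.uniform(0, 1, size=(n, n))
        traj = integrate(
            PhaseState(theta=rng.uniform(0, TWO_PI, n), omega=rng.normal(size=n)),
            CouplingConfig(coupling=G),
            horizon=5.0,
        )
        assert np.all((traj.R >= 0) & (traj.R <= 1))
        assert np.all(traj.sigma >= 0)

    def test_horizon_shorter_than_dt_rejected(self):
        state = PhaseState(theta=np.zeros(2), omega=np.zeros(2))
        with pytest.raises(ValueError):
            integrate(state, CouplingConfig(dt=0.1), horizon=0.01)


class TestSteadyStateR:
    def test_constant_series(self):
        from msgfield.oscillators import SimTrajectory

        traj = SimTrajectory(
            times=np.arange(6.0), R=np.full(6, 0.4), Theta=np.zeros(6), sigma=np.zeros(6)
        )
        assert steady_state_R(traj, 0.3) == pytest.approx(0.4)

    def test_burn_in_window(self):
        from msgfield.oscillators import SimTrajectory

        r = np.array([0.0, 0.0, 0.5, 0.7, 0.7, 0.7])
        traj = SimTrajectory(times=np.arange(6.0), R=r, Theta=np.zeros(6), sigma=np.zeros(6))
        assert steady_state_R(traj, 0.5) == pytest.approx(0.7)
        assert steady_state_R(traj, 0.0) == pytest.approx(r.mean())

    def test_bad_burn_in_rejected(self):
        from msgfield.oscillators import SimTrajectory

        traj = SimTrajectory(times=np.arange(2.0), R=np.zeros(2), Theta=np.zeros(2), sigma=np.zeros(2))
        with pytest.raises(ValueError):
            steady_state_R(traj, 1.0)


class TestAnalyticRInf:
    @pytest.mark.parametrize(
        "G, gamma, expected",
        [
            (2.0, 1.0, 0.0),  # boundary G = 2 gamma
            (1.0, 1.0, 0.0),  # below threshold
            (0.5, 0.0, 1.0),  # zero spread
            (4.0, 1.0, math.sqrt(0.5)),
            (3.0, 1.0, math.sqrt(1.0 - 2.0 / 3.0)),
        ],
    )
    def test_branch_rule(self, G, gamma, expected):
        assert analytic_R_inf(G, gamma) == pytest.approx(expected, abs=1e-15)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            analytic_R_inf(-1.0, 0.5)


class TestEstimateCriticalCoupling:
    def test_exact_line_recovers_two_gamma_exactly(self):
        gamma = 0.8
        grid = [2.5, 3.0, 4.0, 5.0, 6.0, 8.0]
        analytic = [analytic_R_inf(g, gamma) for g in grid]
        est = estimate_critical_coupling(
            FrequencyModel(gamma=gamma), n=10, G_grid=grid, steady_R_values=analytic
        )
        assert est.G_c == pytest.approx(2.0 * gamma, abs=1e-10)
        assert est.intercept == pytest.approx(1.0, abs=1e-10)

    def test_too_few_supercritical_points_rejected(self):
        gamma = 1.0
        grid = [0.5, 1.0, 1.5, 2.0]
        analytic = [analytic_R_inf(g, gamma) for g in grid]
        with pytest.raises(ValueError, match="grid points"):
            estimate_critical_coupling(
                FrequencyModel(gamma=gamma), n=10, G_grid=grid, steady_R_values=analytic
            )

    def test_small_simulation_recovers_threshold_scaling(self):
        # gamma = 0.5 => G_c ~ 1; modest N keeps this a fast smoke test
        est = estimate_critical_coupling(
            FrequencyModel(gamma=0.5), n=400, G_grid=[1.25, 1.5, 2.0, 2.5, 3.0, 4.0], horizon=100.0, seed=5
        )
        assert est.G_c == pytest.approx(1.0, abs=0.2)
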