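"""Message-coupled phase oscillators.

Each cell (or subsystem) is reduced to a limit-cycle oscillator with
phase theta_j and natural frequency omega_j; messages couple them:

    dtheta_j/dt = omega_j + (1/N) sum_k G_jk h(theta_j - theta_k),

with h an odd, 2*pi-periodic coupling function, by default the
attractive Kuramoto coupling h(x) = -sin(x).  G_jk is either a scalar
binding strength G_E (global, all-to-all coupling) or the aggregate
matrix of a message :class:`~msgfield.messages.ForceField`.

For natural frequencies drawn from a Cauchy (Lorentzian) distribution
with centre omega0 and scale gamma, the mean-field stationary order
parameter is

    R_inf = sqrt(1 - 2*gamma/G_E)   for G_E > 2*gamma,   else 0,

so synchronization appears at the critical coupling G_c = 2*gamma.
The module simulates the finite-N dynamics, measures R(t), and recovers
G_c from simulated steady states by regressing R^2 on 1/G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TWO_PI",
    "FrequencyModel",
    "PhaseState",
    "CouplingConfig",
    "SimTrajectory",
    "CriticalCouplingEstimate",
    "register_coupling_function",
    "sample_frequencies",
    "phase_derivative",
    "integrate",
    "order_parameter",
    "steady_state_R",
    "analytic_R_inf",
    "estimate_critical_coupling",
]

TWO_PI = 2.0 * math.pi


# --- coupling functions ------------------------------------------------------

#: Registered coupling functions h(x).  ``sine_like`` marks h(x) = -sin(x),
#: for which the pairwise sum collapses to vectorized trigonometric identities.
_COUPLING_FUNCTIONS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], bool]] = {}


def register_coupling_function(name: str, fn: Callable[[np.ndarray], np.ndarray], *, sine_like: bool = False) -> None:
    """Register an odd 2*pi-periodic coupling function under ``name``."""
    _COUPLING_FUNCTIONS[name] = (fn, sine_like)


register_coupling_function("attractive_sine", lambda x: -np.sin(x), sine_like=True)
register_coupling_function("repulsive_sine", lambda x: np.sin(x))


# --- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyModel:
    """Cauchy (Lorentzian) natural-frequency distribution.

    f(omega) = (1/pi) * gamma / ((omega - omega0)^2 + gamma^2)

    ``omega0`` is the centre (radians per unit time) and ``gamma >= 0``
    the scale; gamma = 0 degenerates to identical frequencies.
    """

    omega0: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


@dataclass
class PhaseState:
    """Phases (wrapped to [0, 2*pi)) and natural frequencies of N oscillators."""

    theta: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.mod(np.asarray(self.theta, dtype=float), TWO_PI)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape != self.omega.shape or self.theta.ndim != 1:
            raise ValueError("theta and omega must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class CouplingConfig:
    """How oscillators are coupled and integrated.

    ``coupling`` is either a scalar global strength G_E >= 0 or an N x N
    force matrix (its diagonal is zeroed: no self-coupling).  ``h_name``
    selects a registered coupling function.  ``dt`` is the fixed
    integrator step; ``method`` is "rk4" (default) or "euler".
    """

    coupling: float | np.ndarray = 1.0
    h_name: str = "attractive_sine"
    dt: float = 0.01
    method: str = "rk4"
    flows: np.ndarray | None = None  # optional pairwise flow matrix for entropy accounting

    def __post_init__(self) -> None:
        if np.isscalar(self.coupling):
            if self.coupling < 0:
                raise ValueError(f"scalar coupling must be >= 0, got {self.coupling}")
        else:
            g = np.array(self.coupling, dtype=float)
            if g.ndim != 2 or g.shape[0] != g.shape[1]:
                raise ValueError(f"coupling matrix must be square, got shape {g.shape}")
            np.fill_diagonal(g, 0.0)
            self.coupling = g
        if self.h_name not in _COUPLING_FUNCTIONS:
            raise ValueError(f"unknown coupling function {self.h_name!r}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.method not in ("rk4", "euler"):
            raise ValueError(f"method must be 'rk4' or 'euler', got {self.method!r}")

    @property
    def h(self) -> Callable[[np.ndarray], np.ndarray]:
        return _COUPLING_FUNCTIONS[self.h_name][0]

    @property
    def _sine_like(self) -> bool:
        return _COUPLING_FUNCTIONS[self.h_name][1]


@dataclass
class SimTrajectory:
    """Recorded simulation output: order parameter, mean phase, entropy."""

    times: np.ndarray
    R: np.ndarray
    Theta: np.ndarray
    sigma: np.ndarray
    theta_matrix: np.ndarray | None = None  # time x N, present if phases were stored

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.R) == len(self.Theta) == len(self.sigma)):
            raise ValueError("times, R, Theta, sigma must have equal length")
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-12):
            raise ValueError("order parameter R must lie in [0, 1]")
        if self.theta_matrix is not None and self.theta_matrix.shape[0] != len(self.times):
            raise ValueError("theta_matrix rows must match times")


# --- operations --------------------------------------------------------------


def sample_frequencies(n: int, model: FrequencyModel, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. Cauchy natural frequencies via the inverse CDF.

    omega = omega0 + gamma * tan(pi * (u - 1/2)), u ~ Uniform(0, 1).
    Inverse-CDF sampling keeps draws reproducible across platforms for a
    given seed.  gamma = 0 returns a constant vector.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    return model.omega0 + model.gamma * np.tan(math.pi * (u - 0.5))


def _derivative(theta: np.ndarray, omega: np.ndarray, config: CouplingConfig) -> np.ndarray:
    """dtheta/dt for the phase-reduced coupled system (no validation)."""
    n = theta.size
    if config._sine_like:
        # (1/N) sum_k G_jk * sin(theta_k - theta_j)
        #   = (cos(theta_j) * (G s)_j - sin(theta_j) * (G c)_j) / N
        c = np.cos(theta)
        s = np.sin(theta)
        if np.isscalar(config.coupling):
            gs = config.coupling * s.sum()
            gc = config.coupling * c.sum()
            return omega + (c * gs - s * gc) / n
        g = config.coupling
        return omega + (c * (g @ s) - s * (g @ c)) / n
    diff = theta[:, None] - theta[None, :]
    h = config.h(diff)
    if np.isscalar(config.coupling):
        np.fill_diagonal(h, 0.0)  # h odd => h(0)=0; enforce for arbitrary h
        return omega + config.coupling * h.sum(axis=1) / n
    return omega + (config.coupling * h).sum(axis=1) / n


def phase_derivative(state: PhaseState, config: CouplingConfig) -> np.ndarray:
    """dtheta_j/dt = omega_j + (1/N) sum_k G_jk h(theta_j - theta_k)."""
    if not np.all(np.isfinite(state.theta)):
        raise ValueError("phases must be finite")
    if not np.isscalar(config.coupling) and np.asarray(config.coupling).shape != (len(state), len(state)):
        raise ValueError(
            f"coupling matrix shape {np.asarray(config.coupling).shape} "
            f"does not match N={len(state)}"
        )
    return _derivative(state.theta, state.omega, config)


def order_parameter(theta: Sequence[float]) -> tuple[float, float]:
    """Order parameter (R, Theta): R e^{i Theta} = (1/N) sum_j e^{i theta_j}."""
    th = np.asarray(theta, dtype=float)
    if th.size == 0:
        raise ValueError("order_parameter of an empty phase vector")
    z_re = np.cos(th).mean()
    z_im = np.sin(th).mean()
    return math.hypot(z_re, z_im), math.atan2(z_im, z_re)


def _sigma_per_step(config: CouplingConfig, n: int) -> float:
    """Entropy generated per unit time by steady message flows over the coupling.

    Uses sigma = sum_jk G_jk J_jk with G the coupling matrix (a scalar G_E is
    an all-to-all matrix without the diagonal) and J the configured flow
    matrix, defaulting to unit flow on every coupled pair.
    """
    if np.isscalar(config.coupling):
        if config.flows is None:
            return float(config.coupling * n * (n - 1))
        j = np.array(config.flows, dtype=float)
        np.fill_diagonal(j, 0.0)
        return float(config.coupling * j.sum())
    g = config.coupling
    j = (g > 0).astype(float) if config.flows is None else np.asarray(config.flows, dtype=float)
    return float((g * j).sum())


def integrate(
    initial: PhaseState,
    config: CouplingConfig,
    horizon: float,
    seed: int | None = None,
    record_every: int = 1,
    store_phases: bool = True,
) -> SimTrajectory:
    """Fixed-step integration of the coupled phase equations.

    RK4 by default (Euler selectable); phases are wrapped to [0, 2*pi)
    every step; R(t) and Theta(t) are recorded every ``record_every``
    steps (plus t = 0 and the final step).  The dynamics are
    deterministic; ``seed`` is accepted for interface symmetry and
    recorded nowhere here.
    """
    if horizon < config.dt:
        raise ValueError(f"horizon {horizon} must be >= dt {config.dt}")
    if not np.all(np.isfinite(initial.theta)) or not np.all(np.isfinite(initial.omega)):
        raise ValueError("initial state must be finite")
    n_steps = int(round(horizon / config.dt))
    theta = initial.theta.copy()
    omega = initial.omega
    dt = config.dt
    sigma0 = _sigma_per_step(config, len(initial))

    times, Rs, Thetas, thetas = [], [], [], []

    def record(step: int) -> None:
        r, big_theta = order_parameter(theta)
        times.append(step * dt)
        Rs.append(r)
        Thetas.append(big_theta)
        if store_phases:
            thetas.append(theta.copy())

    record(0)
    for step in range(1, n_steps + 1):
        if config.method == "euler":
            theta = theta + dt * _derivative(theta, omega, config)
        else:
            k1 = _derivative(theta, omega, config)
            k2 = _derivative(theta + 0.5 * dt * k1, omega, config)
            k3 = _derivative(theta + 0.5 * dt * k2, omega, config)
            k4 = _derivative(theta + dt * k3, omega, config)
            theta = theta + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        theta = np.mod(theta, TWO_PI)
        if step % record_every == 0 or step == n_steps:
            if not np.all(np.isfinite(theta)):
                raise RuntimeError(f"integration diverged to a non-finite state at t={step * dt:g}")
            record(step)

    return SimTrajectory(
        times=np.array(times),
        R=np.array(Rs),
        Theta=np.array(Thetas),
        sigma=np.full(len(times), sigma0),
        theta_matrix=np.array(thetas) if store_phases else None,
    )


def steady_state_R(traj: SimTrajectory, burn_in_fraction: float = 0.5) -> float:
    """Time-averaged R(t) over the post-burn-in window."""
    if not 0 <= burn_in_fraction < 1:
        raise ValueError(f"burn_in_fraction must be in [0, 1), got {burn_in_fraction}")
    start = int(len(traj.R) * burn_in_fraction)
    window = traj.R[start:]
    if window.size == 0:
        raise ValueError("burn-in leaves an empty averaging window")
    return float(window.mean())


def analytic_R_inf(G_E: float, gamma: float) -> float:
    """Mean-field stationary order parameter for Cauchy frequencies.

    sqrt(1 - 2*gamma/G_E) when G_E > 2*gamma, else 0 (incoherence).
    """
    if G_E < 0 or gamma < 0:
        raise ValueError("G_E and gamma must be >= 0")
    if G_E > 2.0 * gamma:
        return math.sqrt(1.0 - 2.0 * gamma / G_E)
    return 0.0


class CriticalCouplingEstimate(NamedTuple):
    G_c: float
    intercept: float  # diagnostic; ~1 when the mean-field line holds
    couplings: tuple[float, ...]
    steady_R: tuple[float, ...]


def estimate_critical_coupling(
    model: FrequencyModel,
    n: int,
    G_grid: Sequence[float],
    horizon: float = 200.0,
    seed: int = 0,
    dt: float = 0.01,
    burn_in_fraction: float = 0.5,
    r_min: float = 0.3,
    steady_R_values: Sequence[float] | None = None,
) -> CriticalCouplingEstimate:
    """Estimate the critical coupling G_c from steady states on a grid.

    The mean-field law R^2 = 1 - 2*gamma/G is linear in 1/G with slope
    -2*gamma = -G_c, so the estimator simulates steady_state_R at each
    grid coupling (one shared frequency sample and initial condition),
    regresses mean R^2 on 1/G over points with mean R > ``r_min``, and
    returns the negated slope.  ``steady_R_values`` substitutes known
    steady-state values (e.g. the analytic law) for the simulations.
    """
    grid = np.asarray(sorted(G_grid), dtype=float)
    if steady_R_values is None:
        if n < 2:
            raise ValueError("need at least 2 oscillators")
        rng = np.random.default_rng(seed)
        omega = sample_frequencies(n, model, rng)
        theta0 = rng.uniform(0.0, TWO_PI, size=n)
        r_bar = []
        for g in grid:
            traj = integrate(
                PhaseState(theta=theta0.copy(), omega=omega.copy()),
                CouplingConfig(coupling=float(g), dt=dt),
                horizon,
                store_phases=False,
            )
            r_bar.append(steady_state_R(traj, burn_in_fraction))
        r_bar = np.array(r_bar)
    else:
        r_bar = np.asarray(steady_R_values, dtype=float)
        if r_bar.shape != grid.shape:
            raise ValueError("steady_R_values must match the grid length")
    mask = r_bar > r_min
    if mask.sum() < 2:
        raise ValueError(
            f"only {int(mask.sum())} grid points have steady R > {r_min}; need >= 2 to regress"
        )
    fit = stats.linregress(1.0 / grid[mask], r_bar[mask] ** 2)
    return CriticalCouplingEstimate(
        G_c=float(-fit.slope),
        intercept=float(fit.intercept),
        couplings=tuple(grid),
        steady_R=tuple(r_bar),
    )
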