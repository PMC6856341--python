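"""Ground-truth generators for verifying the decompositions.

Four families of fixtures with known spectral content:

* a planar double pendulum (small-amplitude motion has two analytic
  normal-mode frequencies and no redundancy),
* gait-like limit-cycle signals — d zero-mean angle channels that are
  sums of K harmonics of a fundamental near normal walking cadence with
  per-channel complex coefficients and additive measurement noise,
* a Van der Pol oscillator (the classical eigenfunction-describable
  limit cycle), and
* explicit linear systems y_{t+1} = A·y_t for eigenvalue oracles.

Integrators are fixed-step RK4 so that a given configuration and seed
reproduce bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import AngleSeries

__all__ = [
    "PendulumParams",
    "GaitGeneratorConfig",
    "simulate_double_pendulum",
    "analytic_pendulum_frequencies",
    "pendulum_energy",
    "generate_harmonic_gait",
    "default_gait_coefficients",
    "noise_sd_for_snr",
    "simulate_linear_system",
    "simulate_van_der_pol",
]

_INTERNAL_DT = 1e-3  # RK4 step (s); output is decimated to the requested dt


@dataclass(frozen=True)
class PendulumParams:
    """Planar double pendulum: point masses on massless rods.

    Both angles are measured from the downward vertical.  ``damping``
    adds a linear torque −damping·θ̇ per joint (0 = conservative).
    """

    m1: float = 1.0
    m2: float = 1.0
    l1: float = 1.0
    l2: float = 1.0
    g: float = 9.81
    damping: float = 0.0
    theta1_0: float = 0.01
    theta2_0: float = 0.0
    omega1_0: float = 0.0
    omega2_0: float = 0.0

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.l1, self.l2, self.g) <= 0:
            raise ValueError("masses, lengths and g must be positive")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")


@dataclass(frozen=True)
class GaitGeneratorConfig:
    """Harmonic limit-cycle generator emulating segmental angle data.

    Channel i at frame t is Σ_k Re[c_{i,k}·e^{i2πk·f₀·tΔt}] plus white
    Gaussian noise of standard deviation ``noise_sd``; the deterministic
    part has zero temporal mean by construction (no DC coefficient).
    """

    fundamental: float = 0.8  # Hz, normal walking cadence
    harmonics: int = 5
    coefficients: np.ndarray | None = None  # d × K complex
    noise_sd: float = 0.0  # rad
    dt: float = 0.01  # s (100 Hz sampling)
    duration: float = 30.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fundamental <= 0 or self.harmonics < 1:
            raise ValueError("need fundamental > 0 and harmonics ≥ 1")
        if self.dt <= 0 or self.duration < 2 * self.dt:
            raise ValueError("need dt > 0 and duration of at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.harmonics * self.fundamental >= 0.5 / self.dt:
            raise ValueError(
                f"highest harmonic {self.harmonics * self.fundamental:g} Hz "
                f"violates the Nyquist limit {0.5 / self.dt:g} Hz"
            )
        coeff = self.coefficients
        if coeff is None:
            coeff = default_gait_coefficients(harmonics=self.harmonics)
        coeff = np.atleast_2d(np.asarray(coeff, dtype=complex))
        if coeff.shape[1] != self.harmonics:
            raise ValueError("coefficients must have K columns")
        object.__setattr__(self, "coefficients", coeff)


def default_gait_coefficients(d: int = 3, harmonics: int = 5) -> np.ndarray:
    """Fixed per-channel complex harmonic coefficients (d × K).

    Magnitudes mimic segmental elevation angles: the distal channel
    (foot-like) carries the largest weight and amplitudes decay with
    harmonic order roughly as observed in walking spectra.  Phases are a
    fixed, arbitrary but incommensurate pattern so the channels are not
    trivially collinear.
    """
    base = np.array([0.25, 0.35, 0.50])  # thigh/shank/foot-like, rad
    decay = np.array([1.0, 0.45, 0.25, 0.12, 0.08])
    if d > base.size:
        base = np.resize(base, d)
    if harmonics > decay.size:
        decay = np.resize(decay, harmonics)
    i = np.arange(d)[:, None]
    k = np.arange(1, harmonics + 1)[None, :]
    phases = 2.0 * np.pi * ((0.37 * i + 0.61 * k + 0.13 * i * k) % 1.0)
    return base[:d, None] * decay[None, :harmonics] * np.exp(1j * phases)


def noise_sd_for_snr(coefficients: np.ndarray, snr_db: float) -> float:
    """Noise standard deviation giving the requested per-channel SNR.

    Signal RMS per channel is sqrt(Σ_k |c_{i,k}|²/2); the channel-mean
    RMS is divided by 10^(snr_db/20).
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=complex))
    rms = np.sqrt(np.sum(np.abs(coefficients) ** 2, axis=1) / 2.0)
    return float(np.mean(rms) / 10.0 ** (snr_db / 20.0))


def generate_harmonic_gait(config: GaitGeneratorConfig) -> AngleSeries:
    """Seeded d-channel sum-of-harmonics limit-cycle signal."""
    n_frames = int(round(config.duration / config.dt)) + 1
    t = np.arange(n_frames) * config.dt
    k = np.arange(1, config.harmonics + 1)
    carriers = np.exp(
        1j * 2.0 * np.pi * config.fundamental * k[:, None] * t[None, :]
    )  # K × frames
    clean = np.real(config.coefficients @ carriers)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        clean = clean + rng.normal(0.0, config.noise_sd, clean.shape)
    return AngleSeries(clean, config.dt)


# -- double pendulum ----------------------------------------------------


def _pendulum_rhs(state: np.ndarray, p: PendulumParams) -> np.ndarray:
    th1, th2, w1, w2 = state
    delta = th1 - th2
    cd, sd = np.cos(delta), np.sin(delta)
    # mass matrix of the angular accelerations
    a11 = (p.m1 + p.m2) * p.l1
    a12 = p.m2 * p.l2 * cd
    a21 = p.l1 * cd
    a22 = p.l2
    b1 = -p.m2 * p.l2 * w2**2 * sd - (p.m1 + p.m2) * p.g * np.sin(th1)
    b2 = p.l1 * w1**2 * sd - p.g * np.sin(th2)
    if p.damping > 0:
        b1 -= p.damping * w1
        b2 -= p.damping * w2
    det = a11 * a22 - a12 * a21
    acc1 = (a22 * b1 - a12 * b2) / det
    acc2 = (a11 * b2 - a21 * b1) / det
    return np.array([w1, w2, acc1, acc2])


def pendulum_energy(
    theta1, theta2, omega1, omega2, p: PendulumParams
) -> np.ndarray:
    """Total mechanical energy (kinetic + potential), J."""
    t1 = 0.5 * (p.m1 + p.m2) * p.l1**2 * np.asarray(omega1) ** 2
    t2 = 0.5 * p.m2 * p.l2**2 * np.asarray(omega2) ** 2
    t12 = (
        p.m2
        * p.l1
        * p.l2
        * np.asarray(omega1)
        * np.asarray(omega2)
        * np.cos(np.asarray(theta1) - np.asarray(theta2))
    )
    v = -(p.m1 + p.m2) * p.g * p.l1 * np.cos(theta1) - p.m2 * p.g * p.l2 * np.cos(
        theta2
    )
    return t1 + t2 + t12 + v


def simulate_double_pendulum(
    params: PendulumParams, duration: float, dt: float
) -> AngleSeries:
    """Fixed-step RK4 integration of the double pendulum.

    Integrates at an internal 1 ms step (or finer if ``dt`` is smaller)
    and decimates to the requested sampling interval.  For undamped
    runs the energy drift is checked against the oscillation energy
    scale; drift above 1% aborts with advice to reduce the step.
    """
    if duration < 2 * dt:
        raise ValueError("duration must span at least 2 output frames")
    sub = max(1, int(round(dt / _INTERNAL_DT)))
    h = dt / sub
    n_out = int(round(duration / dt)) + 1
    state = np.array(
        [params.theta1_0, params.theta2_0, params.omega1_0, params.omega2_0]
    )
    out = np.empty((2, n_out))
    out[:, 0] = state[:2]
    e0 = pendulum_energy(*state, params)
    e_rest = -(params.m1 + params.m2) * params.g * params.l1 - (
        params.m2 * params.g * params.l2
    )
    e_scale = max(e0 - e_rest, np.finfo(float).tiny)
    for i in range(1, n_out):
        for _ in range(sub):
            state = _rk4_step(_pendulum_rhs, state, h, params)
        out[:, i] = state[:2]
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(
                "double-pendulum integration diverged; use a smaller dt"
            )
    if params.damping == 0:
        drift = abs(pendulum_energy(*state, params) - e0) / e_scale
        if drift > 0.01:
            raise FloatingPointError(
                f"energy drift {drift:.2%} exceeds 1%; use a smaller dt"
            )
    return AngleSeries(out, dt, labels=("theta1", "theta2"))


def analytic_pendulum_frequencies(params: PendulumParams):
    """Small-angle normal-mode frequencies (Hz) of the undamped pendulum.

    Solves the generalized eigenproblem K·v = ω²·M·v of the linearised
    (hanging-equilibrium) mass and stiffness matrices.  For m1 = m2 and
    l1 = l2 = l this reduces to ω± = sqrt((2 ∓ √2)·g/l).
    """
    if params.damping != 0:
        raise ValueError("analytic frequencies require an undamped pendulum")
    p = params
    M = np.array(
        [
            [(p.m1 + p.m2) * p.l1**2, p.m2 * p.l1 * p.l2],
            [p.m2 * p.l1 * p.l2, p.m2 * p.l2**2],
        ]
    )
    K = np.diag([(p.m1 + p.m2) * p.g * p.l1, p.m2 * p.g * p.l2])
    w2 = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(M, K))))
    return tuple(np.sqrt(w2) / (2.0 * np.pi))


# -- other fixtures -----------------------------------------------------


def simulate_linear_system(
    A: np.ndarray, x0: np.ndarray, steps: int, dt: float = 1.0
) -> AngleSeries:
    """Trajectory y_t = A^t·x0 for t = 0..steps."""
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] != x0.size:
        raise ValueError("A must be square and match x0")
    out = np.empty((x0.size, steps + 1))
    out[:, 0] = x0
    x = x0
    for t in range(1, steps + 1):
        x = A @ x
        out[:, t] = x
    return AngleSeries(out, dt)


def simulate_van_der_pol(
    mu: float, dt: float, duration: float, init=(1.0, 0.0)
) -> AngleSeries:
    """RK4 integration of x″ − μ(1 − x²)x′ + x = 0; returns (x, x′)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if duration < 2 * dt:
        raise ValueError("duration must span at least 2 output frames")

    def rhs(state, _):
        x, v = state
        return np.array([v, mu * (1.0 - x**2) * v - x])

    sub = max(1, int(round(dt / _INTERNAL_DT)))
    h = dt / sub
    n_out = int(round(duration / dt)) + 1
    state = np.asarray(init, dtype=float)
    out = np.empty((2, n_out))
    out[:, 0] = state
    for i in range(1, n_out):
        for _ in range(sub):
            state = _rk4_step(rhs, state, h, None)
        if not np.all(np.isfinite(state)) or np.abs(state).max() > 1e6:
            raise FloatingPointError(
                "Van der Pol integration unstable; use a smaller dt"
            )
        out[:, i] = state
    return AngleSeries(out, dt, labels=("x", "xdot"))


def _rk4_step(rhs, state, h, args):
    k1 = rhs(state, args)
    k2 = rhs(state + 0.5 * h * k1, args)
    k3 = rhs(state + 0.5 * h * k2, args)
    k4 = rhs(state + h * k3, args)
    return state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
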