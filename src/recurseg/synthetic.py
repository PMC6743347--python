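"""Ground-truthed synthetic generators for metastable switching dynamics.

Two families:

* ``generate_switching_ensemble`` — a surrogate for module-averaged,
  unit-normalized BOLD ensembles: every subject's trajectory dwells near a
  shared set of unit centers (geometric dwell lengths), with great-circle
  transients between consecutive centers and isotropic noise.  Exact
  per-sample labels are returned, so segmentation accuracy can be scored.

* three minimal dynamical systems, each realizing a canonical mechanism for
  switching between two metastable states: a planar slow-fast system with a
  hysteresis loop over two attracting branches, a pair of coupled forced
  double-well oscillators with intermingled basins of attraction, and a
  four-dimensional flow on the unit 3-sphere with a robust heteroclinic
  cycle between the poles (0,0,0,+-1), optionally driven by noise in the
  last coordinate.

All integrators are fixed-step (classical 4th-order Runge-Kutta for the
deterministic part, Euler-Maruyama for the Brownian term) so that runs are
bit-reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .recurrence import Trajectory

_CENTER_TRIES = 5000


# ---------------------------------------------------------------------------
# switching-ensemble surrogate


@dataclass(frozen=True)
class SwitchingConfig:
    """Metastable-switching surrogate of a module-averaged BOLD recording.

    Defaults emulate the shape of the motivating recordings: T = 1200
    samples of M = 40 module averages with a handful of metastable states,
    mean dwell of 40 samples, short transients, and moderate isotropic
    noise on the unit hypersphere.
    """

    n_modules: int = 40
    n_states: int = 3
    n_times: int = 1200
    mean_dwell: int = 40
    transient_len: int = 5
    noise_sigma: float = 0.05
    transient_jitter: float = 2.0
    min_center_angle: float = np.pi / 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ParameterError("n_states must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.n_times < self.n_states * (self.mean_dwell + self.transient_len):
            raise ParameterError(
                "n_times too small for the requested dwell/transient structure"
            )


def _draw_separated_centers(
    rng: np.random.Generator, n_states: int, n_modules: int, min_angle: float
) -> np.ndarray:
    """Unit centers with pairwise angle >= min_angle.

    Rejection sampling, falling back to pairwise repulsion on the sphere for
    separations a random draw is unlikely to hit (e.g. near-antipodal
    pairs).  Raises if the packing is infeasible for (n_states, M).
    """
    min_cos = np.cos(min_angle)
    c = None
    for _ in range(200):
        draw = rng.standard_normal((n_states, n_modules))
        draw /= np.linalg.norm(draw, axis=1, keepdims=True)
        gram = draw @ draw.T
        worst = gram[np.triu_indices(n_states, k=1)].max() if n_states > 1 else -1.0
        if n_states == 1 or worst <= min_cos:
            return draw
        if c is None or worst < c[1]:
            c = (draw, worst)
    centers = c[0]
    for _ in range(_CENTER_TRIES):
        gram = centers @ centers.T
        np.fill_diagonal(gram, -1.0)
        if gram.max() <= min_cos:
            return centers
        # push each center away from its most-aligned neighbour
        nearest = np.argmax(gram, axis=1)
        step = centers - 0.1 * centers[nearest]
        centers = step / np.linalg.norm(step, axis=1, keepdims=True)
    raise ParameterError(
        f"cannot pack {n_states} centers at pairwise angle >= {min_angle:.3f} rad "
        f"in {n_modules} dimensions"
    )


def _slerp(c1: np.ndarray, c2: np.ndarray, n_interior: int) -> np.ndarray:
    """Interior points of the great-circle arc from c1 to c2."""
    if n_interior == 0:
        return np.empty((0, c1.size))
    cosang = float(np.clip(np.dot(c1, c2), -1.0, 1.0))
    omega = np.arccos(cosang)
    u = np.arange(1, n_interior + 1) / (n_interior + 1)
    if omega < 1e-12:
        return np.tile(c1, (n_interior, 1))
    return (
        np.sin((1 - u)[:, None] * omega) * c1 + np.sin(u[:, None] * omega) * c2
    ) / np.sin(omega)


def generate_switching_ensemble(
    cfg: SwitchingConfig, n_subjects: int = 1
) -> tuple[list[Trajectory], list[np.ndarray], np.ndarray]:
    """Draw an ensemble of metastable switching trajectories with ground truth.

    All subjects share the same centers; each subject gets its own epoch
    order (no immediate repeats) and noise realization.  Returns the
    trajectories, the exact per-sample labels (0 during transients,
    ``1..n_states`` during dwells), and the shared centers.

    Dwell samples scatter around their center with isotropic noise of
    standard deviation ``noise_sigma`` per module.  Transient samples sit on
    the great-circle arc between the centers with ``transient_jitter`` times
    that dispersion: transition paths are traversed loosely rather than
    stereotypically, so repeated transitions do not build up spurious
    recurrences along the arc.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    centers = _draw_separated_centers(
        rng, cfg.n_states, cfg.n_modules, cfg.min_center_angle
    )
    trajectories: list[Trajectory] = []
    labels: list[np.ndarray] = []
    for _ in range(n_subjects):
        rows: list[np.ndarray] = []
        labs: list[int] = []
        state = int(rng.integers(cfg.n_states))
        while len(labs) < cfg.n_times:
            dwell = int(rng.geometric(1.0 / cfg.mean_dwell)) if cfg.mean_dwell > 1 else 1
            rows.append(np.tile(centers[state], (dwell, 1)))
            labs.extend([state + 1] * dwell)
            if cfg.n_states > 1:
                nxt = int(rng.integers(cfg.n_states - 1))
                nxt = nxt if nxt < state else nxt + 1
            else:
                nxt = state
            arc = _slerp(centers[state], centers[nxt], cfg.transient_len)
            if arc.size:
                rows.append(arc)
                labs.extend([0] * arc.shape[0])
            state = nxt
        values = np.vstack(rows)[: cfg.n_times]
        lab = np.asarray(labs[: cfg.n_times], dtype=np.int64)
        if cfg.noise_sigma > 0:
            scale = np.where(lab > 0, 1.0, cfg.transient_jitter)
            values = values + (
                cfg.noise_sigma * scale[:, None] * rng.standard_normal(values.shape)
            )
        values /= np.linalg.norm(values, axis=1, keepdims=True)
        trajectories.append(Trajectory(values))
        labels.append(lab)
    return trajectories, labels, centers


# ---------------------------------------------------------------------------
# fixed-step integration


def rk4_integrate(f, x0: np.ndarray, t_end: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step 4th-order Runge-Kutta for ``x' = f(t, x)``."""
    if dt <= 0 or t_end <= 0:
        raise ParameterError("dt and t_end must be positive")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, len(x0)))
    x = np.asarray(x0, dtype=float).copy()
    states[0] = x
    for k in range(n):
        t = times[k]
        k1 = f(t, x)
        k2 = f(t + dt / 2, x + dt / 2 * k1)
        k3 = f(t + dt / 2, x + dt / 2 * k2)
        k4 = f(t + dt, x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise InputError(f"integration blew up at t = {times[k + 1]:.6g}")
        states[k + 1] = x
    return times, states


# ---------------------------------------------------------------------------
# slow-fast hysteresis model


@dataclass(frozen=True)
class SlowFastConfig:
    """Planar slow-fast system whose fast nullcline is two near-horizontal
    attracting branches crossed by a transversal line.

    The fast variable ``x2`` relaxes onto one of the branches near ``b`` or
    ``c``; the slow variable ``x1`` drifts (rate ``eps_timescale``) until
    the transversal line ``x2 = alpha*x1 + beta`` crosses the occupied
    branch at a transcritical point, after which the state jumps to the
    other branch — a hysteresis loop producing two metastable activity
    levels.  ``branch_tilt`` gives the branches a small negative slope; it
    keeps the tracking error of the occupied branch sign-definite so the
    transcritical passage resolves deterministically.  ``angle_drift``
    optionally modulates the transversal line's slope slowly in time
    (default off).
    """

    a: float = 0.3
    b: float = -1.0
    c: float = 1.0
    alpha: float = -2.0
    beta: float = -0.5
    eps_timescale: float = 0.004
    initial_state: tuple[float, float] = (0.0, 1.0)
    t_end: float = 3000.0
    dt: float = 0.05
    branch_tilt: float = -0.05
    angle_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_timescale <= 0 or self.dt <= 0:
            raise ParameterError("eps_timescale and dt must be positive")


def slowfast_rhs(t: float, x: np.ndarray, cfg: SlowFastConfig) -> np.ndarray:
    x1, x2 = x
    alpha = cfg.alpha + cfg.angle_drift * np.sin(cfg.eps_timescale * t)
    line = alpha * x1 + cfg.beta
    lo = cfg.b + cfg.branch_tilt * x1
    hi = cfg.c + cfg.branch_tilt * x1
    return np.array(
        [
            cfg.eps_timescale * (cfg.a - x2),
            -(x2 - lo) * (x2 - hi) * (x2 - line),
        ]
    )


def simulate_slowfast(cfg: SlowFastConfig, freeze_slow: bool = False) -> Trajectory:
    """Integrate the slow-fast system; ``freeze_slow`` sets the slow rate to 0
    (the fast-subsystem limit, in which no switching occurs)."""
    def f(t, x):
        dx = slowfast_rhs(t, x, cfg)
        if freeze_slow:
            dx[0] = 0.0
        return dx

    times, states = rk4_integrate(f, np.asarray(cfg.initial_state), cfg.t_end, cfg.dt)
    return Trajectory(states, sample_interval=cfg.dt)


# ---------------------------------------------------------------------------
# intermingled-basins model


@dataclass(frozen=True)
class RiddledConfig:
    """Two coupled, damped double-well oscillators with sinusoidal forcing.

    Each oscillator has the bistable potential ``V(x) = -x^2/2 + x^4/4``;
    ``alpha`` couples the positions diffusively, ``p`` and ``q`` damp the
    first and second oscillator, and ``A sin(mu t)`` forces both.  At the
    printed parameters the forcing drives chaotic cross-well motion whose
    basins are finely intermingled, so the pair switches irregularly
    between the two well states; with ``A = 0`` the system started at an
    attractor stays there.
    """

    A: float = 1.011
    mu: float = 0.632
    alpha: float = -4.0
    p: float = 0.1
    q: float = 0.005
    initial_state: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 0.0)
    t_end: float = 240.0
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")


def riddled_rhs(t: float, s: np.ndarray, cfg: RiddledConfig) -> np.ndarray:
    x1, v1, x2, v2 = s
    forcing = cfg.A * np.sin(cfg.mu * t)
    return np.array(
        [
            v1,
            -cfg.p * v1 + x1 - x1**3 + cfg.alpha * (x1 - x2) + forcing,
            v2,
            -cfg.q * v2 + x2 - x2**3 - cfg.alpha * (x1 - x2) + forcing,
        ]
    )


def riddled_equilibrium(cfg: RiddledConfig, sign: int = 1) -> np.ndarray:
    """A stable rest state of the unforced system (both oscillators in the
    same well): ``x1 = x2 = +-1``, velocities zero."""
    w = float(np.sign(sign))
    return np.array([w, 0.0, w, 0.0])


def simulate_riddled(cfg: RiddledConfig, observables: str = "positions") -> Trajectory:
    """Integrate the forced pair; return positions (default) or the full state."""
    if observables not in ("positions", "full"):
        raise ParameterError(f"unknown observables {observables!r}")
    times, states = rk4_integrate(
        lambda t, s: riddled_rhs(t, s, cfg), np.asarray(cfg.initial_state), cfg.t_end, cfg.dt
    )
    values = states if observables == "full" else states[:, [0, 2]]
    return Trajectory(values, sample_interval=cfg.dt)


# ---------------------------------------------------------------------------
# heteroclinic-cycle model


@dataclass(frozen=True)
class HeteroclinicConfig:
    """Four-dimensional flow on the unit 3-sphere with a robust heteroclinic
    cycle between the saddles (0,0,0,+1) and (0,0,0,-1).

    The connections lie in the invariant planes spanned by ``(x1, x4)``
    (pole-to-pole via ``x1 > 0``) and ``(x2, x4)`` (return path); ``x3`` is
    transversally contracting.  With ``alpha2 < 0`` the contraction rate
    ``alpha1 - alpha2*x4`` at each saddle exceeds the expansion rate
    ``alpha1 + alpha2*x4``, so the noise-free cycle is attracting and
    successive passage times grow monotonically.  Noise enters the last
    equation only, with a time-growing amplitude
    ``sigma(t) = min(noise_a * exp(noise_b * t), sigma_cap)`` that
    counteracts the slow-down; after each Euler-Maruyama kick the state is
    projected back onto the sphere.
    """

    alpha1: float = 1.0
    alpha2: float = -0.1
    noise_a: float = 5e-5
    noise_b: float = 0.33
    sigma_cap: float = 0.01
    gamma: float = 1.0
    initial_state: tuple[float, float, float, float] = (
        1e-2,
        1e-2,
        0.0,
        np.sqrt(1.0 - 2e-4),
    )
    t_end: float = 200.0
    dt: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if abs(np.linalg.norm(np.asarray(self.initial_state)) - 1.0) > 1e-9:
            raise ParameterError("initial state must lie on the unit 3-sphere")


def heteroclinic_drift(x: np.ndarray, cfg: HeteroclinicConfig) -> np.ndarray:
    """Deterministic vector field; exactly tangent to the unit sphere."""
    x1, x2, x3, x4 = x
    a_rate = cfg.alpha1 + cfg.alpha2 * x4
    b_rate = cfg.alpha1 - cfg.alpha2 * x4
    h = np.array(
        [
            a_rate * x1 * x4,
            -b_rate * x2 * x4,
            -cfg.gamma * x3,
            -a_rate * x1**2 + b_rate * x2**2,
        ]
    )
    return h - np.dot(x, h) * x


def simulate_heteroclinic(cfg: HeteroclinicConfig) -> Trajectory:
    """Integrate the sphere flow; RK4 drift plus (optional) Euler-Maruyama noise.

    With ``noise_a = 0`` the run is deterministic and conserves the unit
    norm to integrator precision.
    """
    n = int(round(cfg.t_end / cfg.dt))
    states = np.empty((n + 1, 4))
    x = np.asarray(cfg.initial_state, dtype=float).copy()
    states[0] = x
    dt = cfg.dt
    noisy = cfg.noise_a > 0
    rng = np.random.default_rng(cfg.seed) if noisy else None
    kicks = rng.standard_normal(n) if noisy else None
    for k in range(n):
        k1 = heteroclinic_drift(x, cfg)
        k2 = heteroclinic_drift(x + dt / 2 * k1, cfg)
        k3 = heteroclinic_drift(x + dt / 2 * k2, cfg)
        k4 = heteroclinic_drift(x + dt * k3, cfg)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if noisy:
            sigma = min(cfg.noise_a * np.exp(cfg.noise_b * k * dt), cfg.sigma_cap)
            x[3] += sigma * np.sqrt(dt) * kicks[k]
            x /= np.linalg.norm(x)
        if not np.all(np.isfinite(x)):
            raise InputError(f"integration blew up at t = {(k + 1) * dt:.6g}")
        states[k + 1] = x
    return Trajectory(states, sample_interval=cfg.dt)


def passage_intervals(series: np.ndarray, dt: float) -> np.ndarray:
    """Intervals between successive zero crossings of a scalar series."""
    sign = np.sign(series)
    idx = np.nonzero(np.abs(np.diff(sign)) > 1)[0]
    return np.diff(idx) * dt


# ---------------------------------------------------------------------------
# embedding and resampling helpers


def embed_trajectory(
    low: Trajectory, m_target: int, seed: int | None = None, noise_sigma: float = 0.0
) -> Trajectory:
    """Lift a low-dimensional trajectory into M modules via a seeded random
    column-orthonormal map (plus optional isotropic noise).

    Orthonormality preserves pairwise inner products, so the recurrence
    structure of the source survives the embedding.
    """
    d = low.n_modules
    if m_target < d:
        raise ParameterError(f"m_target ({m_target}) must be >= source dim ({d})")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((m_target, d)))
    values = low.values @ q.T
    if noise_sigma > 0:
        values = values + noise_sigma * rng.standard_normal(values.shape)
    return Trajectory(values, low.sample_interval)


def downsample_trajectory(traj: Trajectory, max_samples: int) -> Trajectory:
    """Stride-subsample a densely integrated trajectory to at most
    ``max_samples`` time points (keeps the first sample)."""
    if max_samples < 2:
        raise ParameterError("max_samples must be >= 2")
    stride = max(1, int(np.ceil(traj.n_times / max_samples)))
    values = traj.values[::stride]
    si = traj.sample_interval * stride if traj.sample_interval else None
    return Trajectory(values, sample_interval=si)
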