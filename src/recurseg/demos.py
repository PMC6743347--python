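"""Canonical end-to-end demonstrations on the synthetic generators.

Each demo runs one simulator under its reference conditions, observes the
trajectory the way the pipeline expects its inputs — module-averaged,
unit-normalized time series — and segments it at the Markov-optimal ball
size.  Observation means: the densely integrated orbit is subsampled to a
recording-length series (a few to a few tens of samples per expected
dwell), lifted into M = 40 modules through a seeded column-orthonormal map,
and given isotropic measurement noise of 0.05 per module.

The demos require a metastable class to hold at least 10% of the samples
(``min_dwell = T // 10``).  The looser library default (``min_dwell = 2``)
admits any class that recurs at all, which on cyclically switching
dynamics also picks up the recurrences of the connecting paths themselves;
a macroscopic-dwell threshold separates the metastable activity levels
from those path recurrences.
"""

from __future__ import annotations

import numpy as np

from .markov import UtilityCurve
from .pipeline import PipelineConfig, SubjectResult, run_subject_pipeline
from .recurrence import Trajectory
from .synthetic import (
    HeteroclinicConfig,
    RiddledConfig,
    SlowFastConfig,
    downsample_trajectory,
    embed_trajectory,
    simulate_heteroclinic,
    simulate_riddled,
    simulate_slowfast,
)

N_MODULES = 40
OBS_NOISE = 0.05


def observe(traj: Trajectory, max_samples: int, seed: int) -> Trajectory:
    """Subsample, embed into module space, and add measurement noise."""
    ds = downsample_trajectory(traj, max_samples)
    return embed_trajectory(ds, N_MODULES, seed=seed, noise_sigma=OBS_NOISE)


def _segment(observed: Trajectory) -> SubjectResult:
    cfg = PipelineConfig(
        normalization="unit", min_dwell=max(2, observed.n_times // 10)
    )
    return run_subject_pipeline(observed, cfg)


def demo_slowfast(seed: int = 0) -> SubjectResult:
    """Hysteresis-loop slow-fast system: ~9 relaxation switches over
    t = 3000, sampled to 1000 points (tens of samples per branch dwell)."""
    traj = simulate_slowfast(SlowFastConfig())
    return _segment(observe(traj, 1000, seed))


def demo_riddled(seed: int = 0) -> SubjectResult:
    """Forced coupled double-well pair: irregular cross-well switching over
    t = 240, sampled to 1200 points (~25 samples per dwell)."""
    traj = simulate_riddled(RiddledConfig())
    return _segment(observe(traj, 1200, seed))


def demo_heteroclinic(seed: int = 0) -> SubjectResult:
    """Noise-driven heteroclinic cycle on the 3-sphere: pole-to-pole
    switching over t = 100, sampled to 120 points (~10 per dwell)."""
    traj = simulate_heteroclinic(HeteroclinicConfig(t_end=100.0, seed=seed))
    return _segment(observe(traj, 120, seed + 1))


def heteroclinic_pole_equilibria(atol: float = 1e-12) -> int:
    """Number of sphere poles (0,0,0,+-1) at which the noise-free drift
    vanishes identically."""
    from .synthetic import heteroclinic_drift

    cfg = HeteroclinicConfig(noise_a=0.0)
    count = 0
    for sign in (1.0, -1.0):
        pole = np.array([0.0, 0.0, 0.0, sign])
        if np.abs(heteroclinic_drift(pole, cfg)).max() <= atol:
            count += 1
    return count
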