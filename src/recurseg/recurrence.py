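"""Recurrence plots and recurrence-grammar segmentation.

The segmentation idea: a trajectory on the unit hypersphere revisits
neighbourhoods of phase space while it dwells in a metastable state.  A
recurrence plot marks all pairs of time points closer than a ball size
``epsilon`` under the cosine distance.  Interpreting each recurrence as a
rewriting rule that replaces a larger time index by a smaller recurrent one
and iterating those rules to a fixed point labels every time point with the
minimal time index of its recurrence class.  Classes visited only once are
transients (label 0); the remaining classes are the metastable states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, DimensionError, InputError, ParameterError

logger = logging.getLogger(__name__)

_UNIT_ATOL = 1e-6


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered sequence of M-dimensional state vectors.

    Rows of ``values`` are time points, columns are modules (observables).
    """

    values: np.ndarray
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DimensionError(f"trajectory must be 2-D, got shape {values.shape}")
        if values.shape[0] < 2:
            raise InputError("trajectory needs at least 2 time points")
        if values.shape[1] < 1:
            raise DimensionError("trajectory needs at least 1 module")
        if not np.all(np.isfinite(values)):
            raise InputError("trajectory contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_modules(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NormalizedTrajectory(Trajectory):
    """A trajectory whose rows all lie on the unit hypersphere."""

    def __post_init__(self) -> None:
        super().__post_init__()
        norms = np.linalg.norm(self.values, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            worst = int(np.argmax(np.abs(norms - 1.0)))
            raise ContractViolationError(
                f"row {worst} has norm {norms[worst]:.12g}, expected 1"
            )


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary time-by-time matrix of ``epsilon``-recurrences."""

    matrix: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"recurrence plot must be square, got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_times(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SymbolicSequence:
    """Per-time-point integer labels; 0 marks transients.

    Before transient relabeling every positive symbol is the minimal 1-based
    time index of its recurrence class, hence ``symbols[t-1] <= t``.
    """

    symbols: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        if s.ndim != 1 or s.size == 0:
            raise InputError("symbolic sequence must be a non-empty 1-D array")
        if np.any(s < 0):
            raise InputError("symbols must be nonnegative")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return self.symbols.size

    @property
    def alphabet(self) -> set[int]:
        """Distinct positive symbols present."""
        return {int(k) for k in np.unique(self.symbols) if k > 0}


@dataclass(frozen=True)
class MetastablePartition:
    """Time-index classes of metastable states plus the transient set.

    ``classes[k]`` holds the 1-based time indices labeled ``k``; together
    with ``transient_times`` the classes partition ``{1..T}``.
    """

    classes: dict[int, np.ndarray]
    transient_times: np.ndarray
    clouds: dict[int, np.ndarray] = field(default_factory=dict)


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine distance ``1 - x.y`` between two unit vectors; ranges over [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
    for name, v in (("x", x), ("y", y)):
        if abs(np.linalg.norm(v) - 1.0) > _UNIT_ATOL:
            raise ContractViolationError(f"{name} is not unit-normalized")
    return float(1.0 - np.dot(x, y))


def pairwise_cosine_distances(traj: NormalizedTrajectory) -> np.ndarray:
    """T-by-T matrix of cosine distances ``1 - X X^T``, clipped to [0, 2]."""
    gram = traj.values @ traj.values.T
    d = 1.0 - gram
    np.clip(d, 0.0, 2.0, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def normalize_trajectory(raw: Trajectory, mode: str = "zscore_unit") -> NormalizedTrajectory:
    """Project each time point onto the unit hypersphere.

    Parameters
    ----------
    raw
        The input trajectory.
    mode
        ``"unit"`` divides each row by its Euclidean norm. ``"zscore_unit"``
        first z-scores each module (column) over time — removing amplitude
        offsets so cosine distance compares activation patterns — then
        row-normalizes.  Zero-variance columns are left centered only.
    """
    if mode not in ("unit", "zscore_unit"):
        raise ParameterError(f"unknown normalization mode {mode!r}")
    values = raw.values.copy()
    if mode == "zscore_unit":
        mean = values.mean(axis=0)
        std = values.std(axis=0, ddof=0)
        zero_var = std == 0.0
        if np.any(zero_var):
            logger.warning(
                "%d zero-variance column(s) left centered only", int(zero_var.sum())
            )
            std = np.where(zero_var, 1.0, std)
        values = (values - mean) / std
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0.0):
        t = int(np.argmin(norms)) + 1
        raise InputError(f"zero-norm state at time index {t}; cannot normalize")
    return NormalizedTrajectory(values / norms[:, None], raw.sample_interval)


def recurrence_plot(traj: NormalizedTrajectory, epsilon: float) -> RecurrencePlot:
    """Threshold the pairwise cosine distances at ``epsilon`` (strict)."""
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    d = pairwise_cosine_distances(traj)
    return RecurrencePlot(d < epsilon, float(epsilon))


def _grammar_fixed_point(adjacency: np.ndarray) -> np.ndarray:
    """Iterate the recurrence-grammar rewriting rules to their fixed point.

    ``adjacency`` is a symmetric boolean matrix with a True diagonal.  Each
    recurrent pair ``i > j`` contributes the rule ``i -> j``; recurrent
    triples ``i > j > k`` additionally contribute ``j -> k``, so one sweep
    replaces every symbol by the smallest symbol in its closed recurrence
    neighbourhood.  Because a symbol is always the time index of a vertex in
    the same recurrence class, sweeps can be interleaved with rule chaining
    (``i -> j`` and ``j -> k`` compose to ``i -> k``), which accelerates
    convergence without changing the fixed point: every symbol ends up as
    the minimal time index of its connected component.
    """
    n = adjacency.shape[0]
    symbols = np.arange(1, n + 1, dtype=np.int64)
    big = np.int64(n + 1)
    for _ in range(n):
        # one synchronous sweep of the rule set
        cand = np.where(adjacency, symbols[None, :], big).min(axis=1)
        # chain rules transitively (pointer jumping) until stable
        while True:
            jumped = np.minimum(cand, cand[cand - 1])
            if np.array_equal(jumped, cand):
                break
            cand = jumped
        if np.array_equal(cand, symbols):
            break
        symbols = cand
    return symbols


def recurrence_grammar_segment(rp: RecurrencePlot) -> SymbolicSequence:
    """Rewrite the sequence of time indices 1..T through the recurrence grammar.

    At the fixed point every symbol equals the minimal time index of its
    connected component in the recurrence graph (off-diagonal 1-entries).
    """
    adj = rp.matrix | rp.matrix.T
    np.fill_diagonal(adj, True)
    return SymbolicSequence(_grammar_fixed_point(adj))


def relabel_transients(s: SymbolicSequence, min_dwell: int = 2) -> tuple[SymbolicSequence, int]:
    """Mark symbol classes occurring fewer than ``min_dwell`` times as transient.

    Returns the relabeled sequence and ``n``, the number of Markov states:
    the surviving metastable classes plus one distinguished transient.
    """
    if min_dwell < 1:
        raise ParameterError(f"min_dwell must be >= 1, got {min_dwell}")
    symbols = s.symbols.copy()
    labels, counts = np.unique(symbols, return_counts=True)
    keep = {int(k) for k, c in zip(labels, counts) if k > 0 and c >= min_dwell}
    mask = ~np.isin(symbols, sorted(keep))
    symbols[mask] = 0
    return SymbolicSequence(symbols), len(keep) + 1


def extract_states(
    traj: NormalizedTrajectory, s: SymbolicSequence
) -> MetastablePartition:
    """Group trajectory rows into metastable state clouds by shared symbol.

    Classes are mutually disjoint and, together with the transient set,
    cover all time points.
    """
    if len(s) != traj.n_times:
        raise DimensionError(
            f"sequence length {len(s)} != trajectory length {traj.n_times}"
        )
    times = np.arange(1, len(s) + 1, dtype=np.int64)
    classes: dict[int, np.ndarray] = {}
    clouds: dict[int, np.ndarray] = {}
    for k in sorted(s.alphabet):
        sel = s.symbols == k
        classes[k] = times[sel]
        clouds[k] = traj.values[sel]
    return MetastablePartition(
        classes=classes,
        transient_times=times[s.symbols == 0],
        clouds=clouds,
    )
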