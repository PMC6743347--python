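"""End-to-end orchestration: subject segmentation, module-count sweeps,
ensemble clustering and parcellation projection.

The per-subject path is: normalize onto the unit hypersphere, sweep the
recurrence ball size over a grid, keep the Markov-utility maximizer, and
report the optimal segmentation.  The ensemble path pools the metastable
state clouds of all subjects, clusters them by thresholded Hausdorff
distance, rewrites each subject's symbolic sequence with ensemble cluster
ids, and (optionally) projects one representative per cluster into region
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .hausdorff import (
    EnsembleClustering,
    HausdorffMatrix,
    StateCloud,
    build_distance_matrix,
    cluster_states,
    coverage_report,
    relabel_ensemble_sequences,
    theta_search,
)
from .io import read_trajectory
from .markov import UtilityCurve, optimize_epsilon, segment_at_epsilon
from .projection import MixingMatrix, ProjectionProfile, project_state, representative_state
from .recurrence import (
    MetastablePartition,
    NormalizedTrajectory,
    SymbolicSequence,
    Trajectory,
    extract_states,
    normalize_trajectory,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every free parameter of the analysis, recorded in reports.

    ``normalization`` defaults to per-module z-scoring followed by unit
    normalization; ``epsilon_grid`` of None selects the automatic
    percentile grid; ``theta`` is the Hausdorff clustering threshold.
    """

    normalization: str = "zscore_unit"
    epsilon_grid: tuple[float, ...] | None = None
    n_grid: int = 50
    min_dwell: int = 2
    theta: float = 0.8
    theta_grid: tuple[float, ...] | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "epsilon_grid": list(self.epsilon_grid) if self.epsilon_grid else "auto",
            "n_grid": self.n_grid,
            "min_dwell": self.min_dwell,
            "theta": self.theta,
            "theta_grid": list(self.theta_grid) if self.theta_grid else None,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SubjectResult:
    """Optimal segmentation of one subject."""

    subject_id: str
    normalized: NormalizedTrajectory
    sequence: SymbolicSequence
    curve: UtilityCurve
    partition: MetastablePartition
    report: dict


@dataclass(frozen=True)
class EnsembleResult:
    """Pooled clustering of an ensemble plus derived artifacts."""

    clustering: EnsembleClustering
    raster: dict[str, np.ndarray]
    coverage: pd.DataFrame
    profiles: dict[int, ProjectionProfile] = field(default_factory=dict)
    representatives: dict[int, np.ndarray] = field(default_factory=dict)
    theta_table: pd.DataFrame | None = None
    distances: "HausdorffMatrix | None" = None

    def distance_frame(self) -> pd.DataFrame:
        """Pooled Hausdorff distances with (subject, symbol) headers."""
        labels = [f"{s}:{k}" for s, k in self.distances.index]
        return pd.DataFrame(self.distances.dist, index=labels, columns=labels)


def run_subject_pipeline(
    traj: Trajectory | str | Path,
    cfg: PipelineConfig = PipelineConfig(),
    subject_id: str = "subject",
) -> SubjectResult:
    """Segment one subject's trajectory at the Markov-optimal ball size."""
    if not isinstance(traj, Trajectory):
        traj = read_trajectory(traj)
    normalized = normalize_trajectory(traj, mode=cfg.normalization)
    grid = np.asarray(cfg.epsilon_grid, dtype=float) if cfg.epsilon_grid else None
    curve = optimize_epsilon(
        normalized, grid=grid, min_dwell=cfg.min_dwell, n_grid=cfg.n_grid
    )
    sequence, n = segment_at_epsilon(
        normalized, curve.best_epsilon, min_dwell=cfg.min_dwell
    )
    partition = extract_states(normalized, sequence)
    dwell_counts = {int(k): int(v.size) for k, v in partition.classes.items()}
    report = {
        "subject_id": subject_id,
        "n_times": normalized.n_times,
        "n_modules": normalized.n_modules,
        "best_epsilon": curve.best_epsilon,
        "n_states": n,
        "complexity": n - 1,
        "utility_max": float(curve.utilities[curve.best_index]),
        "dwell_counts": dwell_counts,
        "n_transient": int(partition.transient_times.size),
        "config": cfg.as_dict(),
    }
    return SubjectResult(subject_id, normalized, sequence, curve, partition, report)


def _sweep_inventory(
    ensemble: str | Path | dict[int, list], module_counts: list[int]
) -> dict[int, list]:
    """Resolve the per-module-count trajectory inventory from a mapping or a
    directory tree ``<root>/M<count>/*.tsv``."""
    if isinstance(ensemble, dict):
        missing = [m for m in module_counts if not ensemble.get(m)]
        if missing:
            raise InputError(f"no trajectories for module counts: {missing}")
        return {m: list(ensemble[m]) for m in module_counts}
    root = Path(ensemble)
    inventory: dict[int, list] = {}
    missing = []
    for m in module_counts:
        files = sorted((root / f"M{m}").glob("*.tsv"))
        if not files:
            missing.append(m)
        inventory[m] = list(files)
    if missing:
        raise InputError(f"no trajectories under {root} for module counts: {missing}")
    return inventory


def complexity_sweep(
    ensemble: str | Path | dict[int, list],
    module_counts: list[int],
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Mean and standard deviation of per-subject complexity per module count.

    ``ensemble`` is either a mapping ``{module_count: [trajectories]}`` or a
    directory with one subdirectory ``M<count>`` of per-subject TSVs per
    count.  The standard deviation uses the population convention (a single
    subject reports 0).
    """
    inventory = _sweep_inventory(ensemble, module_counts)
    rows = []
    for m in module_counts:
        complexities = [
            run_subject_pipeline(t, cfg, subject_id=f"M{m}_s{i}").report["complexity"]
            for i, t in enumerate(inventory[m])
        ]
        arr = np.asarray(complexities, dtype=float)
        rows.append(
            {
                "n_modules": m,
                "mean_complexity": float(arr.mean()),
                "sd_complexity": float(arr.std(ddof=0)),
                "complexities": ",".join(str(int(c)) for c in complexities),
            }
        )
    return pd.DataFrame(
        rows, columns=["n_modules", "mean_complexity", "sd_complexity", "complexities"]
    )


def pool_state_clouds(results: dict[str, SubjectResult]) -> list[StateCloud]:
    """Pool every subject's metastable state clouds (transients excluded),
    ordered by subject id then symbol."""
    clouds = []
    for subject_id in results:
        partition = results[subject_id].partition
        for symbol in sorted(partition.clouds):
            clouds.append(
                StateCloud(partition.clouds[symbol], subject_id, int(symbol))
            )
    return clouds


def run_ensemble_pipeline(
    results: dict[str, SubjectResult],
    cfg: PipelineConfig = PipelineConfig(),
    mixing: MixingMatrix | None = None,
) -> EnsembleResult:
    """Cluster pooled metastable states across subjects at threshold theta.

    Produces the subjects-by-time cluster-label raster, the per-cluster
    subject coverage table, and — when a mixing matrix is supplied — a
    region-space projection of each cluster's max-infinity-norm
    representative.  If ``cfg.theta_grid`` is set, a theta search table is
    attached as well.
    """
    if len(results) < 2:
        raise InputError("ensemble clustering needs at least 2 subjects")
    clouds = pool_state_clouds(results)
    if not clouds:
        raise InputError("no metastable states in the ensemble")
    distances = build_distance_matrix(clouds)
    clustering = cluster_states(distances, cfg.theta)
    subjects = list(results)
    coverage = coverage_report(clustering, subjects)
    sequences = {s: results[s].sequence for s in subjects}
    relabeled = relabel_ensemble_sequences(sequences, clustering)
    raster = {s: relabeled[s].symbols for s in subjects}
    theta_table = None
    if cfg.theta_grid:
        theta_table = theta_search(
            distances, subjects, np.asarray(cfg.theta_grid, dtype=float)
        )
    # cluster representatives: max-infinity-norm member over the pooled cloud
    representatives: dict[int, np.ndarray] = {}
    profiles: dict[int, ProjectionProfile] = {}
    members: dict[int, list[np.ndarray]] = {}
    for cloud in clouds:
        cid = clustering.labels[(cloud.subject_id, cloud.symbol)]
        members.setdefault(cid, []).append(cloud.points)
    for cid in sorted(members):
        merged = StateCloud(np.vstack(members[cid]), subject_id=f"cluster{cid}", symbol=cid)
        rep = representative_state(merged)
        representatives[cid] = rep.vector
        if mixing is not None:
            profiles[cid] = project_state(rep, mixing)
    return EnsembleResult(
        clustering=clustering,
        raster=raster,
        coverage=coverage,
        profiles=profiles,
        representatives=representatives,
        theta_table=theta_table,
        distances=distances,
    )


def recovery_score(
    predicted: SymbolicSequence | np.ndarray, truth: np.ndarray
) -> float:
    """Adjusted Rand index between a segmentation and ground-truth labels,
    restricted to samples that are non-transient in the ground truth."""
    from sklearn.metrics import adjusted_rand_score

    pred = predicted.symbols if isinstance(predicted, SymbolicSequence) else np.asarray(predicted)
    truth = np.asarray(truth)
    if pred.size != truth.size:
        raise ParameterError("prediction and truth must have equal length")
    mask = truth > 0
    if not np.any(mask):
        raise InputError("ground truth has no metastable samples")
    return float(adjusted_rand_score(truth[mask], pred[mask]))
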