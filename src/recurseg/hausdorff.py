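"""Ensemble clustering of metastable state clouds via Hausdorff distances.

Trajectories from different subjects live on the same unit hypersphere, so
their metastable state clouds can be compared directly.  All clouds are
pooled, pairwise Hausdorff distances (max-min cosine distances) are
computed, the distance matrix is thresholded at theta, and the recurrence
grammar is re-applied to the resulting binary matrix.  Each cluster is
labeled by the minimal pooled index of its members, mirroring the
within-subject segmentation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, InputError, ParameterError
from .recurrence import RecurrencePlot, SymbolicSequence, recurrence_grammar_segment


@dataclass(frozen=True)
class StateCloud:
    """All state vectors of one metastable state of one subject.

    ``points`` keeps trajectory (time) order so downstream tie-breaks on the
    earliest time index are well defined.
    """

    points: np.ndarray
    subject_id: str
    symbol: int

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            raise InputError(f"empty state cloud ({self.subject_id}, {self.symbol})")
        norms = np.linalg.norm(pts, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InputError(
                f"cloud ({self.subject_id}, {self.symbol}) has non-unit points"
            )
        object.__setattr__(self, "points", pts)

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class HausdorffMatrix:
    """Pairwise Hausdorff distances over pooled state clouds."""

    dist: np.ndarray
    index: list[tuple[str, int]]

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.index):
            raise DimensionError("distance matrix / index size mismatch")
        object.__setattr__(self, "dist", d)


@dataclass(frozen=True)
class EnsembleClustering:
    """Cluster assignment of pooled clouds at threshold theta.

    Cluster ids are minimal 1-based pooled indices (grammar convention).
    """

    labels: dict[tuple[str, int], int]
    theta: float
    n_clusters: int


def _directed_max_min(d: np.ndarray, axis: int) -> float:
    return float(d.min(axis=axis).max())


def hausdorff_distance(A: StateCloud, B: StateCloud) -> float:
    """Hausdorff distance between two clouds under the cosine distance.

    The larger of the two directed distances max_{x in A} min_{y in B}
    d_cos(x, y) and its mirror image; zero exactly when the point sets
    coincide.
    """
    if A.dim != B.dim:
        raise DimensionError(f"cloud dimension mismatch: {A.dim} vs {B.dim}")
    d = 1.0 - A.points @ B.points.T
    np.clip(d, 0.0, 2.0, out=d)
    return max(_directed_max_min(d, 1), _directed_max_min(d, 0))


def build_distance_matrix(clouds: list[StateCloud]) -> HausdorffMatrix:
    """All pairwise Hausdorff distances; each pair computed once (symmetry)."""
    if not clouds:
        raise InputError("need at least one state cloud")
    dims = {c.dim for c in clouds}
    if len(dims) > 1:
        raise DimensionError(f"clouds have mixed dimensions: {sorted(dims)}")
    p = len(clouds)
    dist = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            dist[i, j] = dist[j, i] = hausdorff_distance(clouds[i], clouds[j])
    return HausdorffMatrix(dist, [(c.subject_id, c.symbol) for c in clouds])


def cluster_states(D: HausdorffMatrix, theta: float) -> EnsembleClustering:
    """Threshold the distance matrix at theta and re-apply the recurrence grammar.

    ``Q[i, j] = 1`` iff ``D[i, j] < theta`` (strict); connected clouds merge
    into one cluster labeled by the minimal pooled index.
    """
    if theta <= 0:
        raise ParameterError(f"theta must be positive, got {theta}")
    q = D.dist < theta
    np.fill_diagonal(q, True)
    symbols = recurrence_grammar_segment(RecurrencePlot(q, theta)).symbols
    labels = {key: int(sym) for key, sym in zip(D.index, symbols)}
    return EnsembleClustering(labels, float(theta), int(np.unique(symbols).size))


def coverage_report(
    clustering: EnsembleClustering, subjects: list[str]
) -> pd.DataFrame:
    """Per-cluster subject counts and the full-coverage flag.

    A clustering fully covers the ensemble when every subject contributes at
    least one cloud to every cluster.  Returned frame: one row per cluster
    with columns ``cluster``, ``n_subjects``, ``subjects``; the flag is
    stored under ``frame.attrs["full_coverage"]`` along with a per-subject
    cluster count table in ``frame.attrs["clusters_per_subject"]``.
    """
    members: dict[int, set[str]] = {}
    per_subject: dict[str, set[int]] = {s: set() for s in subjects}
    for (subj, _sym), cid in clustering.labels.items():
        members.setdefault(cid, set()).add(subj)
        per_subject.setdefault(subj, set()).add(cid)
    rows = [
        {"cluster": cid, "n_subjects": len(subjs), "subjects": ",".join(sorted(subjs))}
        for cid, subjs in sorted(members.items())
    ]
    frame = pd.DataFrame(rows, columns=["cluster", "n_subjects", "subjects"])
    full = all(set(members) <= per_subject.get(s, set()) for s in subjects) and bool(members)
    frame.attrs["full_coverage"] = full
    frame.attrs["clusters_per_subject"] = {
        s: len(cids) for s, cids in per_subject.items()
    }
    return frame


def relabel_ensemble_sequences(
    seqs: dict[str, SymbolicSequence], clustering: EnsembleClustering
) -> dict[str, SymbolicSequence]:
    """Rewrite each subject's positive symbols as ensemble cluster ids.

    Transient labels (0) are preserved.  Raises if a subject's symbol is
    missing from the clustering.
    """
    out: dict[str, SymbolicSequence] = {}
    for subj, seq in seqs.items():
        symbols = seq.symbols.copy()
        for k in seq.alphabet:
            key = (subj, k)
            if key not in clustering.labels:
                raise InputError(f"no cluster for subject {subj!r}, symbol {k}")
            symbols[seq.symbols == k] = clustering.labels[key]
        out[subj] = SymbolicSequence(symbols)
    return out


def theta_search(
    D: HausdorffMatrix,
    subjects: list[str],
    theta_grid: np.ndarray,
) -> pd.DataFrame:
    """Report cluster counts and coverage over a theta grid.

    Operationalizes the minimal-covering-set criterion: among thresholds
    achieving full coverage, smaller cluster counts are preferable; the grid
    row order preserves the caller's thetas.
    """
    rows = []
    for theta in np.asarray(theta_grid, dtype=float):
        clustering = cluster_states(D, float(theta))
        cov = coverage_report(clustering, subjects)
        rows.append(
            {
                "theta": float(theta),
                "n_clusters": clustering.n_clusters,
                "full_coverage": bool(cov.attrs["full_coverage"]),
            }
        )
    return pd.DataFrame(rows, columns=["theta", "n_clusters", "full_coverage"])
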