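"""Projection of metastable states onto anatomical / functional parcellations.

Each metastable state is a cloud of unit vectors in module space.  A single
representative — the member maximizing the infinity norm, which gives the
sharpest module contrast — is projected into region space (e.g. 45 AAL
regions or a set of resting-state networks) through a K-by-M mixing matrix
``y = W x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, InputError, ParameterError
from .hausdorff import StateCloud


@dataclass(frozen=True)
class MixingMatrix:
    """Linear map from module space (M) to labeled region space (K)."""

    weights: np.ndarray
    region_labels: list[str]
    space: str = "custom"

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if w.shape[0] != len(self.region_labels):
            raise DimensionError(
                f"{w.shape[0]} rows but {len(self.region_labels)} region labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise InputError("region labels must be unique")
        if not np.all(np.isfinite(w)):
            raise InputError("mixing matrix has non-finite entries")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_modules(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class RepresentativeState:
    """The max-infinity-norm member of a state cloud."""

    vector: np.ndarray
    source: tuple[str | int, int]
    max_abs: float


@dataclass(frozen=True)
class ProjectionProfile:
    """Region-space image of a representative state; entries may be negative."""

    values: np.ndarray
    region_labels: list[str]
    signed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != len(self.region_labels):
            raise DimensionError("profile length != number of region labels")
        object.__setattr__(self, "values", v)


def representative_state(cloud: StateCloud) -> RepresentativeState:
    """Pick the cloud member with maximal infinity norm (earliest wins ties)."""
    norms = np.abs(cloud.points).max(axis=1)
    best = int(np.argmax(norms))  # argmax takes the first (earliest) maximizer
    return RepresentativeState(
        vector=cloud.points[best].copy(),
        source=(cloud.subject_id, cloud.symbol),
        max_abs=float(norms[best]),
    )


def project_state(x: RepresentativeState | np.ndarray, mix: MixingMatrix) -> ProjectionProfile:
    """Project a module-space vector into region space: ``y = W x``."""
    vec = x.vector if isinstance(x, RepresentativeState) else np.asarray(x, dtype=float)
    if vec.shape != (mix.n_modules,):
        raise DimensionError(
            f"vector length {vec.shape} incompatible with mixing matrix "
            f"({mix.n_regions}x{mix.n_modules})"
        )
    return ProjectionProfile(mix.weights @ vec, mix.region_labels)


def rank_regions(profile: ProjectionProfile, top: int) -> list[str]:
    """Region labels sorted by descending absolute projection strength.

    Ties are broken by label order, making the ranking deterministic.
    """
    if top < 1 or top > len(profile.region_labels):
        raise ParameterError(f"top must be in [1, {len(profile.region_labels)}]")
    order = sorted(
        range(len(profile.region_labels)),
        key=lambda i: (-abs(profile.values[i]), profile.region_labels[i]),
    )
    return [profile.region_labels[i] for i in order[:top]]


def read_mixing_matrix(path: str | Path, space: str = "custom") -> MixingMatrix:
    """Read a mixing matrix TSV (region labels as row index, modules as columns).

    If the header row is longer than the column count implied by a K-by-M
    orientation — i.e. the file stores modules as rows — the matrix is
    auto-transposed so that regions index the rows.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    weights = frame.to_numpy(dtype=float)
    labels = [str(x) for x in frame.index]
    cols = [str(c) for c in frame.columns]
    if all(c.lower().startswith("region") for c in cols) and not all(
        r.lower().startswith("region") for r in labels
    ):
        weights = weights.T
        labels = cols
    return MixingMatrix(weights, labels, space)


def write_profile(profile: ProjectionProfile, path: str | Path) -> None:
    """Write a two-column TSV (region, value)."""
    pd.DataFrame(
        {"region": profile.region_labels, "value": profile.values}
    ).to_csv(path, sep="\t", index=False)


def synthetic_mixing_matrix(
    n_modules: int,
    n_regions: int = 45,
    seed: int | None = None,
    space: str = "AAL",
) -> MixingMatrix:
    """Random nonnegative block-structured mixing matrix with labeled rows.

    A stand-in for atlas-derived module-to-region overlap matrices: each
    region loads mostly on a contiguous block of modules with a small
    uniform background.
    """
    if n_modules < 1 or n_regions < 1:
        raise ParameterError("n_modules and n_regions must be positive")
    rng = np.random.default_rng(seed)
    weights = 0.05 * rng.random((n_regions, n_modules))
    block = max(1, n_modules // n_regions)
    for k in range(n_regions):
        start = (k * block) % n_modules
        stop = min(start + block, n_modules)
        weights[k, start:stop] += rng.random(stop - start) + 0.5
    labels = [f"{space}_region_{k + 1:02d}" for k in range(n_regions)]
    return MixingMatrix(weights, labels, space)
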