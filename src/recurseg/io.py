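"""Plain-text readers and writers for the pipeline's tabular artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .markov import UtilityCurve
from .recurrence import SymbolicSequence, Trajectory


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a tab-separated trajectory (header row of module names, one row
    per time point)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot parse {path}: {exc}") from exc
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = next(
            i for i in range(len(frame)) if not pd.api.types.is_numeric_dtype(frame.iloc[i])
            or frame.iloc[i].isna().any()
        )
        raise InputError(f"{path}: non-numeric value near line {bad + 2}")
    if np.isnan(values).any():
        line = int(np.argwhere(np.isnan(values))[0, 0]) + 2
        raise InputError(f"{path}: missing value near line {line}")
    return Trajectory(values.astype(float))


def write_trajectory(traj: Trajectory, path: str | Path, prefix: str = "module") -> None:
    cols = [f"{prefix}_{i + 1}" for i in range(traj.n_modules)]
    pd.DataFrame(traj.values, columns=cols).to_csv(path, sep="\t", index=False)


def write_symbolic_sequence(seq: SymbolicSequence, path: str | Path) -> None:
    """Two-column TSV (time_index, symbol); time indices are 1-based."""
    pd.DataFrame(
        {"time_index": np.arange(1, len(seq) + 1), "symbol": seq.symbols}
    ).to_csv(path, sep="\t", index=False)


def read_symbolic_sequence(path: str | Path) -> SymbolicSequence:
    frame = pd.read_csv(path, sep="\t")
    if "symbol" not in frame.columns:
        raise InputError(f"{path}: expected a 'symbol' column")
    return SymbolicSequence(frame["symbol"].to_numpy(dtype=np.int64))


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"time_index": np.arange(1, len(labels) + 1), "label": labels}
    ).to_csv(path, sep="\t", index=False)


def write_utility_curve(curve: UtilityCurve, path: str | Path) -> None:
    """Three-column TSV (epsilon, utility, complexity)."""
    pd.DataFrame(
        {
            "epsilon": curve.epsilons,
            "utility": curve.utilities,
            "complexity": curve.complexities,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_raster(rasters: dict[str, np.ndarray], path: str | Path) -> None:
    """Subjects-by-time TSV of ensemble cluster labels."""
    frame = pd.DataFrame.from_dict(rasters, orient="index")
    frame.index.name = "subject"
    frame.columns = [f"t{j + 1}" for j in range(frame.shape[1])]
    frame.to_csv(path, sep="\t")
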