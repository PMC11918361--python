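"""Readers and writers for slice movies, neuron tables, configs and run logs.

Time series live on disk as a stacked text format (one whitespace
matrix per frame, frames separated by blank lines, a small ``#``
header) so that fixtures stay diffable; multi-page grayscale TIFF
stacks are also accepted.  Neuron tables are plain CSV with a fixed
header.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InsufficientDataError, MaskError
from .types import (
    MIN_FRAMES,
    NEURON_COLUMNS,
    RunConfig,
    SliceTimeSeriesGrid,
    SnapshotNeuronTable,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_neuron_table",
    "write_neuron_table",
    "read_mask",
    "write_mask",
    "load_config",
    "save_config",
    "config_hash",
    "write_run_log",
]


# ---------------------------------------------------------------------------
# slice time series


def _parse_frame_stack(path: Path) -> tuple[np.ndarray, dict]:
    header: dict = {}
    frames: list[np.ndarray] = []
    block: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
                continue
            if not line:
                if block:
                    frames.append(np.array(block, dtype=float))
                    block = []
                continue
            block.append([float(x) for x in line.split()])
    if block:
        frames.append(np.array(block, dtype=float))
    if not frames:
        raise FormatError(f"no frames found in {path}")
    shape0 = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape0:
            raise FormatError(
                f"ragged frames: frame 0 is {shape0}, frame {i} is {f.shape}"
            )
    return np.stack(frames, axis=-1), header


def read_timeseries(
    path: str | Path,
    mask_path: str | Path | None = None,
    mask_floor: float = 0.0,
    frame_interval_h: float | None = None,
    orientation_label: str | None = None,
) -> SliceTimeSeriesGrid:
    """Read a slice movie from a frame-stack text file or a TIFF stack.

    If no mask file is supplied, a pixel counts as in-tissue when its
    mean intensity exceeds ``mask_floor``.  Fewer than 48 frames or
    frames of unequal shape are rejected; an all-below-floor stack
    yields an empty-mask error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict = {}
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        stack = np.asarray(tifffile.imread(path), dtype=float)
        if stack.ndim != 3:
            raise FormatError(f"expected a multi-page grayscale stack in {path}")
        intensity = np.moveaxis(stack, 0, -1)  # pages are frames
    else:
        intensity, header = _parse_frame_stack(path)
    if intensity.shape[-1] < MIN_FRAMES:
        raise InsufficientDataError(
            f"{path}: {intensity.shape[-1]} frames < required {MIN_FRAMES}"
        )
    if mask_path is not None:
        mask = read_mask(mask_path)
    else:
        mask = intensity.mean(axis=-1) > mask_floor
        if not mask.any():
            raise MaskError(
                f"{path}: inferred mask is empty (no pixel mean above "
                f"{mask_floor})"
            )
    interval = (
        frame_interval_h
        if frame_interval_h is not None
        else float(header.get("interval_h", 1.0))
    )
    orientation = (
        orientation_label
        if orientation_label is not None
        else header.get("orientation", "coronal")
    )
    return SliceTimeSeriesGrid(
        intensity=intensity,
        mask=mask,
        frame_interval_h=interval,
        orientation_label=orientation,
    )


def write_timeseries(grid: SliceTimeSeriesGrid, path: str | Path) -> Path:
    """Write a grid as frame-stack text (inverse of :func:`read_timeseries`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# rows={grid.n_rows} cols={grid.n_cols} frames={grid.n_frames} "
            f"interval_h={grid.frame_interval_h!r} "
            f"orientation={grid.orientation_label}\n"
        )
        for t in range(grid.n_frames):
            for r in range(grid.n_rows):
                fh.write(" ".join(repr(float(v)) for v in grid.intensity[r, :, t]))
                fh.write("\n")
            fh.write("\n")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path)
    return np.atleast_2d(arr).astype(bool)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")
    return path


# ---------------------------------------------------------------------------
# snapshot neuron tables


def read_neuron_table(path: str | Path) -> SnapshotNeuronTable:
    """Read a neuron table CSV (columns by header name, order-free)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return SnapshotNeuronTable(df)


def write_neuron_table(table: SnapshotNeuronTable, path: str | Path) -> Path:
    """Write a table as CSV with the fixed canonical header.

    Floats are written with shortest round-tripping repr, so
    ``read_neuron_table`` is an exact inverse.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write(",".join(NEURON_COLUMNS) + "\n")
    for row in table.data.itertuples(index=False):
        buf.write(
            f"{int(row.neuron_id)},{float(row.x_um)!r},{float(row.y_um)!r},"
            f"{float(row.z_um)!r},{float(row.intensity)!r}\n"
        )
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# config and run log


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return path


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full parameter set, echoed in every run log."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_log(
    path: str | Path,
    stage: str,
    cfg: RunConfig,
    outputs: list[str | Path],
) -> Path:
    """Write a plain-text log: stage, seed, config hash/values, outputs.

    Deliberately timestamp-free so identical (config, seed) reruns
    produce byte-identical logs.
    """
    path = Path(path)
    lines = [
        f"stage: {stage}",
        f"seed: {cfg.seed}",
        f"config_hash: {config_hash(cfg)}",
        "config:",
    ]
    for k, v in sorted(cfg.to_dict().items()):
        lines.append(f"  {k}: {v}")
    lines.append("outputs:")
    for o in outputs:
        lines.append(f"  - {o}")
    path.write_text("\n".join(lines) + "\n")
    return path
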