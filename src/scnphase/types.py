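"""Core domain containers for slice movies and snapshot neuron tables.

Axis convention for snapshot data: ``x`` runs medial–lateral, ``y``
rostral–caudal, ``z`` dorsal–ventral, all in micrometres.  Virtual slab
definitions depend on this: a coronal slab restricts ``y``, a sagittal
slab restricts ``x`` and a horizontal slab restricts ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, MaskError

ORIENTATIONS = ("coronal", "horizontal", "sagittal")

#: minimum number of hourly frames needed for the 48-point Fourier analysis
MIN_FRAMES = 48

NEURON_COLUMNS = ("neuron_id", "x_um", "y_um", "z_um", "intensity")


@dataclass
class SliceTimeSeriesGrid:
    """A masked pixel grid of hourly bioluminescence frames.

    Parameters
    ----------
    intensity
        Array of shape ``(n_rows, n_cols, n_frames)``, arbitrary
        brightness units.
    mask
        Boolean in-tissue mask of shape ``(n_rows, n_cols)``.
    frame_interval_h
        Hours between successive frames (1 for the hourly movies the
        analysis assumes).
    orientation_label
        One of ``coronal``, ``horizontal``, ``sagittal``.
    """

    intensity: np.ndarray
    mask: np.ndarray
    frame_interval_h: float = 1.0
    orientation_label: str = "coronal"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.ndim != 3:
            raise FormatError(
                f"intensity must be 3-D (rows, cols, frames); got shape "
                f"{self.intensity.shape}"
            )
        if self.mask.shape != self.intensity.shape[:2]:
            raise MaskError(
                f"mask shape {self.mask.shape} does not match grid "
                f"{self.intensity.shape[:2]}"
            )
        if self.n_frames < MIN_FRAMES:
            raise InsufficientDataError(
                f"need at least {MIN_FRAMES} frames, got {self.n_frames}"
            )
        if not self.mask.any():
            raise MaskError("tissue mask has no in-tissue pixel")
        if not np.isfinite(self.intensity).all():
            raise FormatError("intensity contains non-finite values")
        if self.orientation_label not in ORIENTATIONS:
            raise FormatError(
                f"orientation_label must be one of {ORIENTATIONS}; got "
                f"{self.orientation_label!r}"
            )

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[2]

    @property
    def times_h(self) -> np.ndarray:
        """Frame times in hours, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_h

    def masked_series(self) -> np.ndarray:
        """Time series of the masked pixels, shape ``(n_masked, n_frames)``."""
        return self.intensity[self.mask]

    def mean_series(self) -> np.ndarray:
        """Tissue-mean brightness over time (the reference oscillation)."""
        return self.masked_series().mean(axis=0)


@dataclass
class SnapshotNeuronTable:
    """Neurons detected in a cleared whole-SCN volume at one time point.

    Wraps a dataframe with columns ``neuron_id, x_um, y_um, z_um,
    intensity``; the intensity is the single per-neuron scalar (median
    spot brightness) exported by the detection step.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in NEURON_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column {missing[0]}")
        df = df.loc[:, list(NEURON_COLUMNS)].reset_index(drop=True)
        df["neuron_id"] = df["neuron_id"].astype(int)
        for c in NEURON_COLUMNS[1:]:
            df[c] = df[c].astype(float)
        if df["neuron_id"].duplicated().any():
            dup = int(df.loc[df["neuron_id"].duplicated(), "neuron_id"].iloc[0])
            raise FormatError(f"duplicate neuron_id {dup}")
        coords = df[["x_um", "y_um", "z_um"]].to_numpy()
        if not np.isfinite(coords).all():
            raise FormatError("non-finite coordinate")
        inten = df["intensity"].to_numpy()
        if not np.isfinite(inten).all() or (inten < 0).any():
            raise FormatError("intensities must be finite and nonnegative")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnapshotNeuronTable):
            return NotImplemented
        return self.data.equals(other.data)

    @property
    def positions(self) -> np.ndarray:
        """Positions as an ``(N, 3)`` array of (x, y, z) in micrometres."""
        return self.data[["x_um", "y_um", "z_um"]].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.data["intensity"].to_numpy()

    @property
    def neuron_id(self) -> np.ndarray:
        return self.data["neuron_id"].to_numpy()


@dataclass
class RunConfig:
    """All tunable stage parameters plus the global seed.

    Defaults reproduce the canonical analysis settings: 400 intensity
    bins with a 10% symmetric trim, order-parameter target 0.8, 20 μm
    connection radius, 100 μm slab width, Kuramoto step 30 s over 24 h.
    """

    seed: int = 0
    # delta-model preprocessing
    n_bins: int = 400
    trim_frac: float = 0.10
    # calibration
    order_target: float = 0.8
    # connectivity / slicing
    connection_radius_um: float = 20.0
    slab_width_um: float = 100.0
    # sweep grids
    q_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1)
    k_grid: tuple = (0.0, 0.5, 1.0, 2.0)
    # integrator
    dt_h: float = 30.0 / 3600.0
    duration_h: float = 24.0
    # clustering
    n_clusters: int = 5

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["q_grid"] = list(self.q_grid)
        d["k_grid"] = list(self.k_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        for g in ("q_grid", "k_grid"):
            if g in known:
                known[g] = tuple(float(v) for v in known[g])
        return cls(**known)
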