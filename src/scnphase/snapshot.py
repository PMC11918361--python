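"""Snapshot analysis: phase estimates, distribution statistics, anisotropy.

Applies the calibrated one-parameter model φ_i = α·m_i to a neuron
table, summarises the resulting phase distribution with moment-based
skewness and excess kurtosis (both invariant to the choice of α), and
quantifies spatial anisotropy of short-range connectivity through the
spherical-coordinate histogram of nearest-neighbour directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ConfigError, InsufficientDataError
from .model import HOURS_TO_RAD, CalibratedScale
from .types import SnapshotNeuronTable

__all__ = [
    "PhaseEstimateSet",
    "DirectionHistogram",
    "estimate_snapshot_phases",
    "phase_distribution_stats",
    "connection_directions",
    "direction_histogram",
]


@dataclass
class PhaseEstimateSet:
    """Per-neuron estimated phases (hours, mean ≈ 0) for one snapshot."""

    neuron_id: np.ndarray
    phase_h: np.ndarray
    alpha_rad_per_unit: float
    source_n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_id, "phase_hours": self.phase_h})


def estimate_snapshot_phases(
    table: SnapshotNeuronTable, scale: CalibratedScale
) -> PhaseEstimateSet:
    """Apply φ_i = α·(I_i − mean I) and convert to hours.

    The scale must have been calibrated on this table's intensities;
    a size or mean mismatch raises.  Estimates falling outside
    (−12, 12] h indicate miscalibration and trigger a warning (they
    are reported unclipped).
    """
    I = table.intensity
    if scale.n != I.size or not np.isclose(
        scale.intensity_mean, I.mean(), rtol=1e-9, atol=1e-6
    ):
        raise ConfigError(
            "calibrated scale does not match this table's intensities"
        )
    m = I - I.mean()
    phase_h = scale.alpha_rad_per_unit * m / HOURS_TO_RAD
    n_out = int(np.sum((phase_h <= -12.0) | (phase_h > 12.0)))
    if n_out:
        warnings.warn(
            f"{n_out} estimated phases fall outside (−12, 12] h: "
            "model extrapolation / possible miscalibration",
            stacklevel=2,
        )
    return PhaseEstimateSet(
        neuron_id=table.neuron_id.copy(),
        phase_h=phase_h,
        alpha_rad_per_unit=scale.alpha_rad_per_unit,
        source_n=I.size,
    )


def phase_distribution_stats(phases) -> dict:
    """Mean, sd, skewness and excess kurtosis of a phase collection.

    Moment-based sample statistics; excess kurtosis is kurtosis − 3,
    so a Gaussian scores 0 and leptokurtic distributions score > 0.
    Zero-variance input flags skewness/kurtosis as NaN.
    """
    x = np.asarray(phases, dtype=float).ravel()
    if x.size < 4:
        raise InsufficientDataError("need at least 4 phases for moments")
    sd = float(x.std(ddof=1))
    if x.std() == 0:
        return {
            "mean": float(x.mean()),
            "sd": 0.0,
            "skewness": float("nan"),
            "excess_kurtosis": float("nan"),
        }
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "skewness": float(stats.skew(x)),
        "excess_kurtosis": float(stats.kurtosis(x, fisher=True)),
    }


def connection_directions(
    table: SnapshotNeuronTable, radius_um: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit direction vectors of all neuron pairs within the radius.

    For every ordered pair (i, j) with 0 < ‖r_i − r_j‖ ≤ radius the
    direction v_ij = (r_i − r_j)/‖r_i − r_j‖ is emitted, so the
    multiset is antipodally symmetric.  Returns ``(v, theta, phi)``
    with the spherical convention
    v = (cos θ sin φ, sin θ sin φ, cos φ): θ ∈ (−π, π] azimuth in the
    x–y plane, φ ∈ [0, π] polar angle from +z.  Coincident neurons are
    skipped with a warning.
    """
    if len(table) < 2:
        raise InsufficientDataError("need at least 2 neurons")
    if radius_um <= 0:
        raise ConfigError("radius must be positive")
    pos = table.positions
    pairs = cKDTree(pos).query_pairs(r=radius_um, output_type="ndarray")
    if pairs.size:
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        norm = np.linalg.norm(d, axis=1)
        zero = norm == 0
        if zero.any():
            warnings.warn(
                f"skipping {int(zero.sum())} coincident neuron pair(s)",
                stacklevel=2,
            )
            d, norm = d[~zero], norm[~zero]
        v_half = d / norm[:, None]
        v = np.concatenate([v_half, -v_half], axis=0)
    else:
        v = np.empty((0, 3))
    phi = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    theta = np.arctan2(v[:, 1], v[:, 0])
    return v, theta, phi


@dataclass
class DirectionHistogram:
    """2-D histogram of connection directions in (θ, φ) coordinates."""

    counts: np.ndarray  # (n_theta, n_phi)
    fractions: np.ndarray
    theta_edges: np.ndarray
    phi_edges: np.ndarray
    solid_angle_corrected: bool = False

    @property
    def n_directions(self) -> int:
        return int(self.counts.sum())


def direction_histogram(
    theta: np.ndarray,
    phi: np.ndarray,
    bins: int = 35,
    solid_angle_corrected: bool = False,
) -> DirectionHistogram:
    """Bin spherical angles into a ``bins × bins`` grid.

    The default bins raw angles equal-width in θ ∈ (−π, π] and
    φ ∈ [0, π]; note an isotropic direction field is then sin φ-shaped,
    not flat.  With ``solid_angle_corrected`` the grid is equal-area in
    (θ, cos φ) instead, so isotropy maps to a flat histogram.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    if theta.size == 0:
        raise InsufficientDataError("no directions to histogram")
    theta_edges = np.linspace(-np.pi, np.pi, bins + 1)
    if solid_angle_corrected:
        cos_edges = np.linspace(1.0, -1.0, bins + 1)
        phi_edges = np.arccos(cos_edges)
    else:
        phi_edges = np.linspace(0.0, np.pi, bins + 1)
    counts, _, _ = np.histogram2d(theta, phi, bins=[theta_edges, phi_edges])
    counts = counts.astype(int)
    return DirectionHistogram(
        counts=counts,
        fractions=counts / counts.sum(),
        theta_edges=theta_edges,
        phi_edges=phi_edges,
        solid_angle_corrected=solid_angle_corrected,
    )
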