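"""The ΔI–Δϕ linear phase model, hourly scan, order parameter, calibration.

At a single movie frame the z-scored brightness differences between
intensity bins are regressed on the corresponding phase differences,

    ΔI = slope · Δϕ + c + ε,

with Δϕ in hours.  Because every ordered pair of distinct bins enters
the pair set, the design is antisymmetric and the intercept c is zero
up to numerical tolerance.  Scanning the 24 hours from the trough
locates the frame where brightness is most nearly linear in phase (the
descending mean-crossing of the cosine).

For snapshot data the model collapses to φ_i = α·m_i with m_i the
mean-centred intensities; α is fixed by requiring the Kuramoto order
parameter of the resulting phases (in radians) to equal a target level
of synchrony, 0.8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError, InsufficientDataError
from .fourier import CircadianField, trough_index
from .types import SliceTimeSeriesGrid

__all__ = [
    "BinnedPairSet",
    "DeltaRegressionModel",
    "CalibratedScale",
    "preprocess_bins",
    "all_pairs_deltas",
    "fit_delta_model",
    "scan_hours",
    "order_parameter",
    "calibrate_alpha",
]

HOURS_TO_RAD = 2 * np.pi / 24.0


@dataclass
class BinnedPairSet:
    """Ordered bin-pair differences (ΔI, Δϕ) for one movie frame.

    Antisymmetric by construction: for every pair (ΔI, Δϕ) the pair
    (−ΔI, −Δϕ) is present.
    """

    bin_centers: np.ndarray  # occupied bins only
    bin_mean_phase_h: np.ndarray
    bin_counts: np.ndarray
    delta_intensity: np.ndarray
    delta_phase_h: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def preprocess_bins(
    frame: np.ndarray,
    phases_h: np.ndarray,
    n_bins: int = 400,
    trim_frac: float = 0.10,
) -> BinnedPairSet:
    """Z-score, trim, bin one frame's intensities and pair up the bins.

    Steps: (1) z-score the intensities across all supplied pixels;
    (2) drop the ``trim_frac`` highest and lowest intensities
    (``round(trim_frac·n)`` from each side); (3) sort survivors into
    ``n_bins`` equal-width bins over the trimmed range, dropping empty
    bins; (4) ΔI = difference of bin centers, Δϕ = difference of per-bin
    arithmetic-mean phases, for every ordered pair of distinct bins.
    """
    I = np.asarray(frame, dtype=float).ravel()
    ph = np.asarray(phases_h, dtype=float).ravel()
    if I.shape != ph.shape:
        raise ConfigError("frame and phases must cover the same pixels")
    keep = np.isfinite(ph)
    I, ph = I[keep], ph[keep]
    n = I.size
    if n < 2 * max(1, int(round(trim_frac * n))) + 2:
        raise InsufficientDataError("too few pixels to trim and bin")
    sd = I.std()
    if sd == 0:
        raise ConfigError("constant frame: intensities cannot be binned")
    z = (I - I.mean()) / sd

    k = int(round(trim_frac * n))
    order = np.argsort(z, kind="stable")
    kept = order[k : n - k] if k > 0 else order
    z, ph = z[kept], ph[kept]

    lo, hi = z.min(), z.max()
    if hi <= lo:
        raise ConfigError("degenerate binning: trimmed intensities constant")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = np.flatnonzero(counts)
    if occupied.size < 2:
        raise InsufficientDataError(
            f"only {occupied.size} occupied bins; use a smaller bin count"
        )
    sums = np.bincount(idx, weights=ph, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])[occupied]
    mean_phase = sums[occupied] / counts[occupied]

    i, j = np.meshgrid(
        np.arange(occupied.size), np.arange(occupied.size), indexing="ij"
    )
    off = i != j
    return BinnedPairSet(
        bin_centers=centers,
        bin_mean_phase_h=mean_phase,
        bin_counts=counts[occupied],
        delta_intensity=(centers[i] - centers[j])[off],
        delta_phase_h=(mean_phase[i] - mean_phase[j])[off],
    )


def all_pairs_deltas(
    frame: np.ndarray, phases_h: np.ndarray, max_pixels: int | None = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unbinned all-pixel-pairs (ΔI, Δϕ) variant, for comparison only.

    Z-scores intensities and emits ordered pairs of distinct pixels
    (subsampled to ``max_pixels`` pixels for tractability).
    """
    I = np.asarray(frame, dtype=float).ravel()
    ph = np.asarray(phases_h, dtype=float).ravel()
    keep = np.isfinite(ph)
    I, ph = I[keep], ph[keep]
    if max_pixels is not None and I.size > max_pixels:
        sel = np.random.default_rng(seed).choice(I.size, max_pixels, replace=False)
        I, ph = I[sel], ph[sel]
    z = (I - I.mean()) / I.std()
    i, j = np.meshgrid(np.arange(z.size), np.arange(z.size), indexing="ij")
    off = i != j
    return (z[i] - z[j])[off], (ph[i] - ph[j])[off]


@dataclass
class DeltaRegressionModel:
    """OLS fit of ΔI on Δϕ at one time point.

    ``slope_fit`` is in z-scored-intensity units per hour;
    ``resid_se_hours`` re-expresses the residual scatter in hours by
    dividing through the slope magnitude.
    """

    t_from_trough_h: float
    slope_fit: float
    intercept: float
    r_squared: float
    slope_se: float
    p_value: float
    slope_ci95: tuple[float, float]
    resid_se: float
    resid_se_hours: float
    ok: bool = True
    note: str = ""

    @classmethod
    def failed(cls, t: float, note: str) -> "DeltaRegressionModel":
        nan = float("nan")
        return cls(t, nan, nan, nan, nan, nan, (nan, nan), nan, nan, False, note)


def fit_delta_model(
    pairs: BinnedPairSet, t_from_trough_h: float = 0.0
) -> DeltaRegressionModel:
    """Ordinary least squares of ΔI on Δϕ over the bin-pair set."""
    import statsmodels.api as sm

    dphi = pairs.delta_phase_h
    dI = pairs.delta_intensity
    if np.unique(dphi).size < 2:
        raise ConfigError("rank-deficient design: fewer than 2 distinct Δϕ")
    X = sm.add_constant(dphi)
    res = sm.OLS(dI, X).fit()
    ci = res.conf_int(alpha=0.05)
    resid_se = float(np.sqrt(res.mse_resid))
    slope = float(res.params[1])
    return DeltaRegressionModel(
        t_from_trough_h=t_from_trough_h,
        slope_fit=slope,
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        resid_se=resid_se,
        resid_se_hours=resid_se / abs(slope) if slope != 0 else float("inf"),
    )


def scan_hours(
    grid: SliceTimeSeriesGrid,
    field: CircadianField,
    n_bins: int = 400,
    trim_frac: float = 0.10,
) -> list[DeltaRegressionModel]:
    """Fit the ΔI–Δϕ model at each of the 24 hours following the trough.

    Hour t uses frame ``trough + t`` (wrapped back one cycle if it
    would leave the first 48 frames).  Per-hour failures yield flagged
    entries rather than aborting the scan.
    """
    t0 = trough_index(grid)
    mask = field.mask & field.defined
    phases = field.phase_h[mask]
    out: list[DeltaRegressionModel] = []
    for t in range(24):
        fi = t0 + t
        if fi > 47:
            fi -= 24
        try:
            pairs = preprocess_bins(
                grid.intensity[mask, fi], phases, n_bins=n_bins, trim_frac=trim_frac
            )
            out.append(fit_delta_model(pairs, t_from_trough_h=float(t)))
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            out.append(DeltaRegressionModel.failed(float(t), str(exc)))
    return out


def order_parameter(phases, units: str = "radians") -> float:
    """Modulus of the mean unit phasor: 1 = full synchrony, 0 = scattered."""
    ph = np.asarray(phases, dtype=float).ravel()
    if ph.size == 0:
        raise ConfigError("order parameter of an empty phase collection")
    if units == "hours":
        ph = ph * HOURS_TO_RAD
    elif units != "radians":
        raise ConfigError(f"unknown units {units!r}")
    return float(np.abs(np.exp(1j * ph).mean()))


@dataclass
class CalibratedScale:
    """Result of the order-parameter calibration of φ_i = α·m_i.

    ``alpha_rad_per_unit`` maps mean-centred intensity to radians;
    ``alpha_h_per_unit`` is the same in hours.  ``intensity_mean`` and
    ``n`` identify the intensity set the scale was tuned on.
    """

    alpha_rad_per_unit: float
    target: float
    achieved: float
    intensity_mean: float
    n: int

    @property
    def alpha_h_per_unit(self) -> float:
        return self.alpha_rad_per_unit / HOURS_TO_RAD


def calibrate_alpha(
    intensities,
    target: float = 0.8,
    tol: float = 1e-9,
) -> CalibratedScale:
    """Tune α > 0 so the order parameter of {α·m_i} equals the target.

    ``m_i`` are the intensities mean-centred (done here).  O(α) starts
    at 1 for α = 0 and initially decreases; the smallest positive root
    on that first monotone branch is returned via bracketing plus
    Brent's method.  If O turns back upward before reaching the target
    (e.g. two-point intensity sets with a high target), calibration
    fails rather than jumping branches.
    """
    from scipy.optimize import brentq

    if not 0.0 < target < 1.0:
        raise ConfigError("calibration target must lie strictly in (0, 1)")
    I = np.asarray(intensities, dtype=float).ravel()
    if I.size < 2 or np.ptp(I) == 0:
        raise CalibrationError(
            "cannot calibrate: intensities carry no dispersion (O ≡ 1)"
        )
    m = I - I.mean()
    scale = m.std()

    def O(alpha: float) -> float:
        return order_parameter(alpha * m, units="radians")

    # expand α geometrically; stop at first crossing of the target or
    # when O turns upward (end of the first decreasing branch)
    a_prev, o_prev = 0.0, 1.0
    a = 0.01 / scale
    bracket = None
    for _ in range(200):
        o = O(a)
        if o <= target:
            bracket = (a_prev, a)
            break
        if o > o_prev + 1e-12:
            raise CalibrationError(
                f"order parameter turns upward at O={o_prev:.4f} before "
                f"reaching target {target}"
            )
        a_prev, o_prev = a, o
        a *= 1.5
    if bracket is None:
        raise CalibrationError("no α found with O(α·m) at the target level")
    lo, hi = bracket
    if lo == 0.0:
        lo = 1e-12 / scale
    root = brentq(lambda x: O(x) - target, lo, hi, xtol=tol / scale)
    achieved = O(root)
    if abs(achieved - target) > 1e-6:
        raise CalibrationError(
            f"calibration did not converge: achieved {achieved}, target {target}"
        )
    return CalibratedScale(
        alpha_rad_per_unit=float(root),
        target=float(target),
        achieved=float(achieved),
        intensity_mean=float(I.mean()),
        n=int(I.size),
    )
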