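"""Fourier analysis of slice movies: circadian amplitude, phase and power.

The circadian component of a 48-frame hourly series is DFT bin k = 2
of a 48-point transform.  The phase convention is fixed by the
reconstruction contract: the 24-h component of pixel p reads

    mean_p + A_p * cos(2π (t − h_p) / 24),

with h in hours.  Raw phases are then normalised so that h = 0 is the
phase of the tissue-mean oscillation, wrapping every pixel into
(−12, 12] — at most 12 h advanced or delayed relative to the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InsufficientDataError, MaskError
from .types import MIN_FRAMES, SliceTimeSeriesGrid

__all__ = [
    "CircadianField",
    "ClusterPartition",
    "circadian_component",
    "normalize_phases",
    "series_circadian_phase_h",
    "power_spectrum",
    "circadian_power_fraction",
    "cluster_pixels",
    "phase_histogram",
    "trough_index",
    "wrap_hours",
]

#: number of frames used by the 48-point transform
N_FFT = 48
#: DFT bin holding the 24-h period at hourly sampling of 48 frames
CIRCADIAN_BIN = 2


def wrap_hours(h: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase hours into the half-open interval (−12, 12]."""
    wrapped = -((-np.asarray(h) + 12.0) % 24.0 - 12.0)
    return wrapped if np.ndim(h) else float(wrapped)


def _cosine_pair(series: np.ndarray, k: int = CIRCADIAN_BIN) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine coefficients (a, b) of bin ``k`` over the first 48 frames.

    Defined so the component reconstructs as a·cos(2πkt/48) + b·sin(2πkt/48).
    ``series`` has time on the last axis.
    """
    x = np.asarray(series, dtype=float)[..., :N_FFT]
    X = np.fft.rfft(x, axis=-1)[..., k]
    a = 2.0 * X.real / N_FFT
    b = -2.0 * X.imag / N_FFT
    return a, b


@dataclass
class CircadianField:
    """Per-pixel 24-h Fourier component of a slice movie.

    ``a``/``b`` are cosine/sine coefficients; ``amplitude`` is
    ``hypot(a, b)``; ``phase_h`` the reconstruction phase in hours
    (NaN where the amplitude vanishes, flagged in ``defined``);
    ``power_fraction`` the 24-h bin's share of the non-DC power.
    """

    a: np.ndarray
    b: np.ndarray
    amplitude: np.ndarray
    phase_h: np.ndarray
    power_fraction: np.ndarray
    mask: np.ndarray
    defined: np.ndarray
    normalized: bool = False

    def masked_phases(self) -> np.ndarray:
        """Phases (hours) of the masked, defined pixels."""
        return self.phase_h[self.mask & self.defined]

    def to_records(self):
        """Rows (row, col, a, b, A, phase_hours, power_fraction) for export."""
        import pandas as pd

        rr, cc = np.nonzero(self.mask)
        return pd.DataFrame(
            {
                "row": rr,
                "col": cc,
                "a": self.a[rr, cc],
                "b": self.b[rr, cc],
                "amplitude": self.amplitude[rr, cc],
                "phase_hours": self.phase_h[rr, cc],
                "power_fraction": self.power_fraction[rr, cc],
            }
        )


def circadian_component(grid: SliceTimeSeriesGrid) -> CircadianField:
    """Extract the 24-h Fourier component of every masked pixel.

    Uses exactly frames 0..47.  Zero-amplitude (constant) pixels get
    NaN phase and ``defined=False`` rather than raising.  Phases here
    are raw — relative to t = 0 — and become tissue-referenced only
    after :func:`normalize_phases`.
    """
    if grid.n_frames < MIN_FRAMES:
        raise InsufficientDataError("need 48 hourly frames")
    series = grid.intensity
    a, b = _cosine_pair(series)
    amplitude = np.hypot(a, b)
    defined = amplitude > 0
    phase_h = np.full(amplitude.shape, np.nan)
    with np.errstate(invalid="ignore"):
        # atan2, not arctan(b/a): the full-quadrant angle is needed for
        # shifts beyond a quarter cycle
        phase_h[defined] = np.arctan2(b[defined], a[defined]) * 24.0 / (2 * np.pi)
    phase_h[defined] = wrap_hours(phase_h[defined])

    X = np.fft.rfft(series[..., :N_FFT], axis=-1)
    p = np.abs(X) ** 2
    p[..., 1:-1] *= 2.0  # one-sided power, Nyquist unpaired
    total = p[..., 1:].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, p[..., CIRCADIAN_BIN] / total, np.nan)
    return CircadianField(
        a=a,
        b=b,
        amplitude=amplitude,
        phase_h=phase_h,
        power_fraction=frac,
        mask=grid.mask.copy(),
        defined=defined & grid.mask,
    )


def series_circadian_phase_h(series: np.ndarray) -> float:
    """Phase (hours, raw) of the 24-h component of one series."""
    a, b = _cosine_pair(series)
    if np.hypot(a, b) == 0:
        raise MaskError("reference series has zero circadian amplitude")
    return float(wrap_hours(np.arctan2(b, a) * 24.0 / (2 * np.pi)))


def normalize_phases(
    field: CircadianField, reference: np.ndarray | None = None
) -> CircadianField:
    """Re-reference phases so h = 0 is the tissue-mean oscillation.

    ``h_p ← wrap(h_p − h_ref)`` into (−12, 12].  By DFT linearity the
    24-h pair of the tissue-mean series equals the masked mean of the
    per-pixel pairs, so with ``reference=None`` the reference phase is
    derived from the field itself; passing the mean series explicitly
    gives the same result on a raw field.  The Fourier pairs are
    rotated along with the phases, which makes the operation
    idempotent.  Errors if the reference has no circadian amplitude.
    """
    if reference is not None:
        h_ref = series_circadian_phase_h(reference)
    else:
        c_mean = np.mean(
            field.a[field.mask] + 1j * field.b[field.mask]
        )
        if np.abs(c_mean) == 0:
            raise MaskError("tissue-mean oscillation has zero amplitude")
        h_ref = float(np.angle(c_mean) * 24.0 / (2 * np.pi))
    rot = np.exp(-1j * 2 * np.pi * h_ref / 24.0)
    c = (field.a + 1j * field.b) * rot
    out = CircadianField(
        a=c.real,
        b=c.imag,
        amplitude=field.amplitude.copy(),
        phase_h=field.phase_h.copy(),
        power_fraction=field.power_fraction.copy(),
        mask=field.mask.copy(),
        defined=field.defined.copy(),
        normalized=True,
    )
    sel = out.defined
    out.phase_h[sel] = wrap_hours(out.phase_h[sel] - h_ref)
    return out


def analyze_timeseries(grid: SliceTimeSeriesGrid) -> CircadianField:
    """Convenience: circadian component normalised to the tissue mean."""
    return normalize_phases(circadian_component(grid), grid.mean_series())


def power_spectrum(series: np.ndarray) -> list[tuple[float, float]]:
    """One-sided power per nonzero-frequency bin as (period h, power).

    DC is excluded; interior bins carry the factor 2 so the listed
    powers sum to the non-DC signal energy (Parseval).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < N_FFT:
        raise InsufficientDataError("need a single series of ≥ 48 samples")
    X = np.fft.rfft(x[:N_FFT])
    p = np.abs(X) ** 2
    p[1:-1] *= 2.0
    out = []
    for k in range(1, len(p)):
        out.append((N_FFT / k, float(p[k])))
    return out


def circadian_power_fraction(series: np.ndarray) -> float:
    """Share of non-DC power in the 24-h bin; NaN for a constant series."""
    spec = power_spectrum(series)
    total = sum(p for _, p in spec)
    if total == 0:
        return float("nan")
    return spec[CIRCADIAN_BIN - 1][1] / total


@dataclass
class ClusterPartition:
    """Pixel clustering, labels 1..k ordered by cluster-mean peak time."""

    labels: np.ndarray  # grid of int, 0 outside mask
    k: int
    peak_times_h: np.ndarray  # per label, nondecreasing

    def label_map(self) -> np.ndarray:
        return self.labels


def cluster_pixels(
    grid: SliceTimeSeriesGrid, k: int = 5, seed: int = 0
) -> ClusterPartition:
    """K-means on per-pixel z-scored series, labels ordered by peak latency.

    Label 1 is the cluster whose mean circadian oscillation peaks
    earliest.  Pixels with a constant series are z-scored to zero.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ConfigError("need k >= 2 clusters")
    series = grid.masked_series()
    if len(series) < k:
        raise ConfigError(f"k={k} exceeds the {len(series)} masked pixels")
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (series - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(z)

    # peak time of each cluster's mean series: t = h (mod 24) of its
    # circadian reconstruction
    peaks = np.empty(k)
    for lbl in range(k):
        mean_series = series[raw == lbl].mean(axis=0)
        a, b = _cosine_pair(mean_series)
        h = np.arctan2(b, a) * 24.0 / (2 * np.pi)
        peaks[lbl] = h % 24.0
    order = np.argsort(peaks, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)

    labels = np.zeros(grid.mask.shape, dtype=int)
    labels[grid.mask] = relabel[raw]
    return ClusterPartition(labels=labels, k=k, peak_times_h=np.sort(peaks))


def phase_histogram(
    field: CircadianField, bin_width_h: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of normalised phases over (−12, 12].

    Returns ``(counts, edges)``; counts sum to the number of masked,
    defined pixels.
    """
    n_bins = int(round(24.0 / bin_width_h))
    edges = np.linspace(-12.0, 12.0, n_bins + 1)
    ph = field.masked_phases()
    # np.histogram closes the left edge; nudge exact −12 values (which
    # wrap_hours never produces anyway) and count 12 in the top bin
    counts, _ = np.histogram(ph, bins=edges)
    return counts, edges


def trough_index(grid: SliceTimeSeriesGrid) -> int:
    """Frame index (0..23) of the trough of the tissue-mean oscillation.

    CT0000 is defined as the trough of expression; we take the argmin
    over one cycle of the circadian reconstruction of the tissue-mean
    series.
    """
    mean_series = grid.mean_series()
    a, b = _cosine_pair(mean_series)
    if np.hypot(a, b) == 0:
        raise MaskError("tissue-mean series has no circadian component")
    h = np.arctan2(b, a) * 24.0 / (2 * np.pi)
    t = np.arange(24)
    recon = np.hypot(a, b) * np.cos(2 * np.pi * (t - h) / 24.0)
    return int(np.argmin(recon))
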