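import warnings

import numpy as np
import pandas as pd
import pytest

from scnphase.errors import ConfigError
from scnphase.model import HOURS_TO_RAD, CalibratedScale, calibrate_alpha, order_parameter
from scnphase.snapshot import (
    connection_directions,
    direction_histogram,
    estimate_snapshot_phases,
    phase_distribution_stats,
)
from scnphase.synthetic import SnapshotSynthConfig, synth_snapshot
from scnphase.types import SnapshotNeuronTable


def make_table(positions, intensity=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SnapshotNeuronTable(
        pd.DataFrame(
            {
                "neuron_id": np.arange(n),
                "x_um": positions[:, 0],
                "y_um": positions[:, 1],
                "z_um": positions[:, 2],
                "intensity": np.ones(n) if intensity is None else intensity,
            }
        )
    )


class TestPhaseEstimation:
    def test_mean_intensity_neuron_has_zero_phase(self):
        I = np.array([10.0, 20.0, 30.0, 20.0])
        table = make_table(np.zeros((4, 3)), I)
        scale = CalibratedScale(
            alpha_rad_per_unit=0.1, target=0.8, achieved=0.8,
            intensity_mean=I.mean(), n=4,
        )
        est = estimate_snapshot_phases(table, scale)
        assert est.phase_h[1] == pytest.approx(0.0)
        assert est.phase_h[3] == pytest.approx(0.0)

    def test_direct_product(self):
        """α = 0.5 h/unit and centered intensity 2 give phase 1 h."""
        I = np.array([4.0, 6.0, 8.0])  # mean 6, centered {−2, 0, 2}
        table = make_table(np.zeros((3, 3)), I)
        scale = CalibratedScale(
            alpha_rad_per_unit=0.5 * HOURS_TO_RAD, target=0.8, achieved=0.8,
            intensity_mean=6.0, n=3,
        )
        est = estimate_snapshot_phases(table, scale)
        np.testing.assert_allclose(est.phase_h, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_order_parameter_equals_target(self, default_snapshot):
        table, _ = default_snapshot
        scale = calibrate_alpha(table.intensity, target=0.8)
        est = estimate_snapshot_phases(table, scale)
        assert order_parameter(est.phase_h, units="hours") == pytest.approx(
            0.8, abs=1e-6
        )
        assert abs(est.phase_h.mean()) < 1e-9

    def test_scale_table_mismatch(self, default_snapshot):
        table, _ = default_snapshot
        scale = CalibratedScale(
            alpha_rad_per_unit=0.1, target=0.8, achieved=0.8,
            intensity_mean=0.0, n=17,
        )
        with pytest.raises(ConfigError):
            estimate_snapshot_phases(table, scale)

    def test_shift_invariance_and_recalibration_equivariance(
        self, default_snapshot
    ):
        """Adding a constant to all intensities leaves phases unchanged;
        scaling intensities is absorbed by recalibration."""
        table, _ = default_snapshot
        base = estimate_snapshot_phases(
            table, calibrate_alpha(table.intensity)
        )

        def with_intensity(I):
            df = table.data.copy()
            df["intensity"] = I
            t = SnapshotNeuronTable(df)
            return estimate_snapshot_phases(t, calibrate_alpha(t.intensity))

        shifted = with_intensity(table.intensity + 500.0)
        np.testing.assert_allclose(shifted.phase_h, base.phase_h, atol=1e-7)
        scaled = with_intensity(table.intensity * 3.0)
        np.testing.assert_allclose(scaled.phase_h, base.phase_h, rtol=1e-6,
                                   atol=1e-7)

    def test_extrapolation_warning(self):
        I = np.array([0.0, 100.0, 200.0, 300.0])
        table = make_table(np.zeros((4, 3)), I)
        scale = CalibratedScale(
            alpha_rad_per_unit=0.5, target=0.8, achieved=0.8,
            intensity_mean=I.mean(), n=4,
        )
        with pytest.warns(UserWarning, match="outside"):
            est = estimate_snapshot_phases(table, scale)
        # unclipped: diagnostic of miscalibration
        assert np.abs(est.phase_h).max() > 12.0


class TestDistributionStats:
    def test_symmetric_two_point(self):
        s = phase_distribution_stats([-1.0, 1.0, -1.0, 1.0])
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert s["mean"] == pytest.approx(0.0)

    def test_exponential_moments(self):
        """Exponential: skewness 2, excess kurtosis 6 (known moments)."""
        rng = np.random.default_rng(8)
        x = rng.exponential(1.0, 100_000)
        s = phase_distribution_stats(x)
        assert s["skewness"] == pytest.approx(2.0, abs=0.1)
        assert s["excess_kurtosis"] == pytest.approx(6.0, abs=0.6)

    def test_synthetic_phases_right_skewed_leptokurtic(self, default_snapshot):
        """The skew-normal phase code yields the rightward skew and
        positive excess kurtosis seen in whole-SCN phase distributions."""
        table, _ = default_snapshot
        scale = calibrate_alpha(table.intensity)
        est = estimate_snapshot_phases(table, scale)
        s = phase_distribution_stats(est.phase_h)
        assert s["skewness"] > 0.0
        assert s["excess_kurtosis"] > 0.0

    def test_stats_invariant_to_alpha(self, default_snapshot):
        """Skewness/kurtosis are scale-free: the choice of α (via the
        calibration target) does not move them."""
        table, _ = default_snapshot
        s1 = phase_distribution_stats(
            estimate_snapshot_phases(
                table, calibrate_alpha(table.intensity, target=0.8)
            ).phase_h
        )
        s2 = phase_distribution_stats(
            estimate_snapshot_phases(
                table, calibrate_alpha(table.intensity, target=0.9)
            ).phase_h
        )
        assert s1["skewness"] == pytest.approx(s2["skewness"], rel=1e-6)
        assert s1["excess_kurtosis"] == pytest.approx(
            s2["excess_kurtosis"], rel=1e-6
        )
        assert s1["sd"] != pytest.approx(s2["sd"], rel=1e-3)

    def test_zero_variance_flagged(self):
        s = phase_distribution_stats([2.0, 2.0, 2.0, 2.0])
        assert np.isnan(s["skewness"]) and np.isnan(s["excess_kurtosis"])


class TestConnectionDirections:
    def test_pair_along_y_axis(self):
        """Two neurons 10 μm apart along +y: polar angle π/2 and
        azimuth ±π/2 (the antipodal partner)."""
        table = make_table([[0.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        v, theta, phi = connection_directions(table, radius_um=20.0)
        assert v.shape == (2, 3)
        np.testing.assert_allclose(phi, np.pi / 2, atol=1e-12)
        assert sorted(theta) == pytest.approx([-np.pi / 2, np.pi / 2])

    def test_radius_threshold(self):
        table = make_table([[0.0, 0.0, 0.0], [25.0, 0.0, 0.0]])
        v, theta, phi = connection_directions(table, radius_um=20.0)
        assert v.shape == (0, 3)

    def test_antipodal_closure(self, small_snapshot):
        table, _ = small_snapshot
        v, _, _ = connection_directions(table, radius_um=25.0)
        assert len(v) % 2 == 0
        order = np.lexsort(v.T)
        order_neg = np.lexsort((-v).T)
        np.testing.assert_allclose(v[order], -v[order_neg], atol=1e-12)

    def test_coincident_neurons_skipped(self):
        table = make_table([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="coincident"):
            v, _, _ = connection_directions(table, radius_um=20.0)
        assert len(v) == 4  # two neuron pairs survive, both directions


class TestDirectionHistogram:
    def test_single_direction_single_bin(self):
        hist = direction_histogram(
            np.full(50, 0.3), np.full(50, 1.2), bins=35
        )
        assert hist.counts.max() == 50
        assert (hist.counts > 0).sum() == 1
        assert hist.fractions.sum() == pytest.approx(1.0)

    def test_fraction_normalisation(self, small_snapshot):
        table, _ = small_snapshot
        _, theta, phi = connection_directions(table, radius_um=25.0)
        hist = direction_histogram(theta, phi, bins=35)
        assert hist.counts.sum() == len(theta)
        assert hist.fractions.sum() == pytest.approx(1.0)

    def test_antipodal_bin_symmetry(self):
        """With an even bin count the map (θ, φ) → (θ ± π, π − φ) is
        bin-exact, so an antipodally closed input gives a symmetric
        histogram."""
        rng = np.random.default_rng(5)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v = np.concatenate([v, -v])
        theta = np.arctan2(v[:, 1], v[:, 0])
        phi = np.arccos(np.clip(v[:, 2], -1, 1))
        hist = direction_histogram(theta, phi, bins=36)
        c = hist.counts
        mapped = np.roll(c[:, ::-1], 18, axis=0)
        np.testing.assert_array_equal(c, mapped)

    def test_isotropic_occupancy_follows_sine(self):
        """Isotropic directions are sin φ-weighted in raw (θ, φ) bins
        but flat after the solid-angle correction."""
        rng = np.random.default_rng(6)
        v = rng.normal(size=(200_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        theta = np.arctan2(v[:, 1], v[:, 0])
        phi = np.arccos(np.clip(v[:, 2], -1, 1))
        raw = direction_histogram(theta, phi, bins=35)
        marg = raw.counts.sum(axis=0).astype(float)
        edges = raw.phi_edges
        expected = np.diff(-np.cos(edges)) / 2.0  # ∫ sinφ dφ per bin
        np.testing.assert_allclose(
            marg / marg.sum(), expected, rtol=0.12
        )
        corr = direction_histogram(theta, phi, bins=35, solid_angle_corrected=True)
        marg_c = corr.counts.sum(axis=0).astype(float)
        np.testing.assert_allclose(
            marg_c / marg_c.sum(), np.full(35, 1 / 35), rtol=0.1
        )

    def test_laminated_cloud_detectable_anisotropy(self):
        """Fraction of directions near the equator (|φ − π/2| < π/7)
        exceeds the isotropic expectation on laminated clouds."""
        table, _ = synth_snapshot(
            SnapshotSynthConfig(n_neurons=2500, laminar_spacing_um=12.0, seed=9)
        )
        _, _, phi = connection_directions(table, radius_um=20.0)
        band = np.pi / 7
        frac = np.mean(np.abs(phi - np.pi / 2) < band)
        iso_expected = np.sin(band)  # ∫ band sinφ dφ / 2 = sin(π/7)
        assert frac > iso_expected
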