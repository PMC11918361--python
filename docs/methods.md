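# Methods

This note records the modelling conventions, parameter defaults and
numerical choices behind `scnphase`, and what the synthetic data do and do
not establish.

## Signal model and Fourier conventions

A pixel's bioluminescence over the first 48 hourly frames is treated as

    I(t) = A·cos(2π(t − h)/24) + C + ε(t),

optionally damped by a slow multiplicative envelope on the oscillatory term
(luciferin depletion / dye bleaching). The circadian component is bin k = 2
of the 48-point DFT. We store the cosine/sine pair `(a, b)` defined by the
reconstruction `a·cos(2πt/24) + b·sin(2πt/24)`, giving `A = √(a²+b²)` and
`h = atan2(b, a)·24/2π`. `atan2` (full quadrant) is essential: a plain
`arctan(b/a)` is ambiguous for shifts beyond a quarter cycle, and only the
atan2 convention reproduces shifted-cosine fixtures at all lags (pinned by
tests).

**Phase reference.** Phases are re-referenced so `h = 0` is the tissue-mean
oscillation, wrapped into `(−12, 12]`. Because the DFT is linear, the mean
series' Fourier pair equals the mean of the per-pixel pairs, so
normalisation can be computed from the field itself; the Fourier pairs are
rotated together with the phases, which makes the operation exactly
idempotent. Circadian time zero is the trough of the tissue-mean circadian
reconstruction (argmin over one 24-h cycle).

**Power.** One-sided powers (interior bins doubled) over non-DC bins; the
circadian power fraction is the k = 2 share. A constant series has no
defined phase or fraction and is flagged, not raised.

## The ΔI–Δϕ model

At one frame: z-score intensities over in-tissue pixels, drop the
`round(0.1·n)` lowest and highest, sort survivors into 400 equal-*width*
bins over the trimmed range (empty bins dropped), and emit every ordered
pair of distinct bins with ΔI the difference of bin centers and Δϕ the
difference of per-bin arithmetic-mean phases. "Equally sized" is read as
equal-width; arithmetic (not circular) means are valid because the phase
distribution is tight. The ordered-pair construction makes the design
antisymmetric, which forces the OLS intercept to zero — a deliberate
structural property, tested to numerical tolerance. The regression is
unweighted by bin occupancy (an occupancy-weighted fit would change little
given near-uniform bins and is not offered as a default). An unbinned
all-pixel-pairs variant exists for comparison only.

Two statistical caveats are intrinsic to this design and documented here
because they bound what the reported uncertainties mean:

- the ~160k ordered bin pairs are strongly dependent (each bin enters ~800
  pairs, both directions), so the OLS slope standard error is far smaller
  than the replicate-to-replicate scatter of the slope; treat it as a
  curvature summary, not a sampling error;
- binning on a noisy intensity selects noise into the bins and inflates the
  slope by a factor ≈ 1 + 1/GNR², where GNR is the gain-to-noise ratio of
  the intensity→phase code (≲2% at GNR ≥ 7).

**Hourly scan.** One model per hour t = 0..23 after the trough (frame
`trough + t`, wrapped back one cycle if beyond frame 47); per-hour failures
are flagged entries. On synthetic movies the fit is excellent at the two
mean crossings of the cosine (~6 h and ~18 h after the trough) and
collapses at the peak, where curvature, not slope, dominates. Which of the
two crossings wins is not determined by a symmetric cosine model: with a
decaying envelope and constant-variance noise the earlier (ascending)
crossing has slightly better signal-to-noise and usually edges out the
descending one. A preference for the descending crossing, as seen in real
recordings, requires waveform asymmetry that a four-parameter sinusoid does
not contain.

## Order parameter and calibration

`O({ϕⱼ}) = |N⁻¹ Σ e^{iϕⱼ}|`, 1 at full synchrony, ~0 for uniformly
scattered phases. The snapshot model `ϕᵢ = α·mᵢ` (mᵢ mean-centred
intensity, radians) is calibrated by solving `O(α·m) = target` for the
smallest positive α. `O(0) = 1` and the first branch is decreasing; the
solver expands a bracket geometrically and refines by Brent's method
(achieved-vs-target tolerance 10⁻⁶). If O turns upward before reaching the
target (possible for highly discrete intensity sets), calibration errors
rather than jumping to a later branch — the smallest dispersion consistent
with the data is the only defensible choice. Calibration is exactly
equivariant: scaling intensities by c scales α by 1/c.

The default target is 0.8; the observed per-slice synchrony levels average
≈0.836, and a 0.84 target is one configuration flag away (`order_target`).
Skewness and excess kurtosis of the estimated phases are invariant to the
target; mean and SD are not.

## Synthetic data

**Slice movies** (default 60×60 grid, elliptical mask, 48 hourly frames):
per-pixel amplitudes Normal(1000, CV 0.2) clipped away from zero, shared
baseline 2000, phase field = left-right gradient (span 2 h) + skew-normal
jitter (scale 1 h, shape 3, right-skewed), re-centred to mean zero; trough
of the tissue mean anchored at t = 0; envelope `exp(−t/τ)` with τ = 96 h on
the oscillatory term only (decay is qualitative in real recordings; 96 h
keeps two days of usable signal); additive Gaussian noise with sd = 10% of
the mean amplitude, constant in time (camera-like). The phase distribution
is unimodal and tight (sd < 1.5 h), as in slice recordings.

**Snapshot clouds** (default N = 3000): positions uniform in an ellipsoid
with semi-axes (147, 255, 82) μm along (medial-lateral, rostral-caudal,
dorsal-ventral). These semi-axes are not anatomy: they are chosen so that
100 μm central slabs retain ≈50/29/80% (sagittal/coronal/horizontal) of
neurons — the closed-form marginal `∝ 1 − (u/L)²` integrated over
`|u| ≤ 50` — matching the observed removal pattern. True phases are
skew-normal (scale 1.5 h, shape 3, mean-centred); intensity = 100·ϕ + 5000
+ Normal(0, 20) clipped at zero, i.e. a gain-to-noise ratio of 5 so the
linear code is recoverable (estimated-vs-true phase correlation > 0.95).
An optional laminar spacing snaps z to evenly spaced layers, concentrating
nearest-neighbour directions at polar angle π/2 for anisotropy tests.

What the generators deliberately do **not** emulate: bilateral two-lobe
geometry, core/shell regional structure, spatially structured snapshot
phases (real SCNs carry phase waves; synthetic intensities are spatially
i.i.d.), and non-sinusoidal PER2 waveforms. Consequences: spatial-cluster
analyses on synthetic movies recover construction, not biology; and
slab-level phase statistics of synthetic clouds fluctuate by sampling alone
(see "Deviation statistic" below).

## Connectivity and dynamics

Adjacency: all neuron pairs within 20 μm (Euclidean, KD-tree) plus each
unordered pair independently with probability q (a draw landing on an
existing edge is a no-op); undirected, no self-edges. Random edges are
sampled once per (q, seed) on the intact node set; virtual slices take the
induced subgraph — slicing removes edges, it never resamples them, which is
the physical reading of cutting tissue.

Kuramoto dynamics with identical intrinsic frequency ω = 2π/24 h⁻¹ are
integrated in unwrapped phase by classical fixed-step RK4 at dt = 30 s over
24 h, with hourly checkpoints. The two-oscillator gap obeys
`tan(δ/2) = tan(δ₀/2)e^(−2Kt)`; RK4 tracks this closed form to <10⁻⁶ rad
over the full day (integrator oracle), and halving dt moves final phases by
<10⁻⁸ rad. Wrapping is applied only inside deviation and order-parameter
computations, never to the state (avoids branch artifacts).

**Virtual slices**: 100 μm slab centred on the mean of the slicing
coordinate — coronal on y (rostral-caudal), sagittal on x (medial-lateral),
horizontal on z (dorsal-ventral) — boundary inclusive.

**Deviation statistic**: mean over slab neurons of the absolute
principal-value difference between sliced and intact phases at the 24 h
checkpoint (∈ [0, π] rad; ×24/2π for hours). Hourly checkpoints are kept
for visualisation but the statistic uses only 24 h. A structural property
worth knowing: with identical frequencies the coupling conserves Σθᵢ, so at
strong coupling each network relaxes toward the mean of its initial phases
and the statistic approaches |slab-mean − global-mean| of the initial
phases. On spatially i.i.d. synthetic phases that difference is sampling
noise scaling as σ_ϕ·√(1/n_slab − 1/N) — larger for slabs that keep fewer
neurons, hence coronal > sagittal > horizontal *in expectation*, with
realisation-to-realisation inversions. Deterministic orderings require
spatially structured initial phases.

**Sweep**: default q log-spaced 10⁻⁴..10⁻¹ (the wider of the two published
ranges; the narrower 0..0.01 range is one config away), K linear 0..2; per
(q, K) one intact and three slab simulations share the same edge
realisation and initial phases; winners are argmax orientations with exact
ties flagged (K = 0 yields all ties and exactly zero deviations).

## Problem sizes and determinism

Default test-suite scales: 60×60 movies, N = 3000 clouds, a 4×4 (q, K)
sweep grid — sizes at which every analysis runs on one desktop CPU core in
minutes while keeping the slab populations large enough for stable
retention fractions. All stochastic steps take explicit seeds
(`numpy.random.default_rng`); sweeps derive per-q child seeds from a
`SeedSequence`, so identical (config, seed) reruns are bit-reproducible,
and the CLI writes timestamp-free run logs (seed, config hash, outputs) to
make that verifiable.

## Known limitations

- The slope SE of the ΔI–Δϕ fit is not a sampling SE (pair dependence; see
  above).
- Estimated snapshot phases can exceed ±12 h for heavy-tailed intensity
  sets; they are warned about and left unclipped as a miscalibration
  diagnostic.
- The direction histogram's raw (θ, φ) binning is not solid-angle uniform;
  an isotropic cloud looks sin φ-shaped. The equal-area variant
  (`solid_angle_corrected=True`) is provided for that comparison.
- Heterogeneous intrinsic frequencies, biophysical TTFL models and
  GPU-scale sweeps are out of scope.
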