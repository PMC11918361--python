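# scnphase

Estimating circadian phase across the suprachiasmatic nucleus (SCN) from a
single snapshot of PER2 expression, and simulating how tissue slicing damages
the oscillatory network.

The SCN — the ~20,000-neuron master circadian clock of the mammalian
hypothalamus — oscillates with a stable spatial phase pattern. Time-series
recordings (PER2::LUC bioluminescence movies of cultured slices) reveal that
pattern directly, but slicing severs connectivity; whole-tissue cleared
volumes (iDISCO + light sheet) preserve connectivity but yield only a single
time point per animal. `scnphase` implements the bridge between the two:

1. **Phase from time series.** For each pixel of a ≥48-frame hourly movie,
   the 24-h Fourier component gives amplitude `A = √(a²+b²)` and phase
   `h = atan2(b, a)·24/2π`, normalised so `h = 0` is the tissue-mean
   oscillation and `h ∈ (−12, 12]`.
2. **A one-parameter brightness→phase model.** At a single frame, z-scored
   intensities are trimmed (top/bottom 10%), sorted into 400 equal-width
   bins, and all ordered bin pairs are regressed as `ΔI = slope·Δϕ + c + ε`.
   Scanning the 24 hours after the expression trough shows the relation is
   most linear at the mean crossings of the cosine and collapses at the
   peak. The snapshot model is then `ϕᵢ = α·mᵢ` with `mᵢ` mean-centred
   intensity.
3. **Calibration by synchrony.** `α` is tuned so the Kuramoto order
   parameter `O = |N⁻¹ Σ e^{iϕⱼ}|` of the estimated phases equals a target
   level (0.8 by default, the synchrony observed in slice recordings at the
   same circadian time).
4. **Virtual slicing + Kuramoto simulation.** On the estimated phases and
   3-D neuron positions, `θ̇ᵢ = ω + K Σⱼ Aᵢⱼ sin(θⱼ − θᵢ)` is integrated by
   classical RK4 (30 s step, 24 h), on the intact cloud and on 100 μm
   coronal/sagittal/horizontal slabs (induced subgraphs). The *deviation
   statistic* — the mean absolute principal-value phase difference at 24 h
   over the slab's neurons — quantifies the damage done by each slicing
   orientation across a (q, K) grid of long-range connection probability
   and coupling strength.

Because the original imaging data are not deposited, a first-class synthetic
module (`scnphase.synthetic`) generates slice movies and ellipsoidal neuron
clouds with known ground-truth phases, sized so that 100 μm central slabs
remove ≈71% (coronal), ≈50% (sagittal) and ≈20% (horizontal) of neurons.

## Worked example

```sh
scnphase synth-snapshot --seed 1 --n-neurons 3000 --out demo
scnphase calibrate demo/neurons.csv --out demo
scnphase estimate-phase demo/neurons.csv --out demo
```

prints

```
wrote demo/neurons.csv (3000 neurons)
alpha=0.00670988 rad/unit (achieved O=0.80000000)
mean=2.43e-14 sd=2.577 skewness=0.6688 excess_kurtosis=0.4544
```

i.e. the calibration finds the scale `α ≈ 6.7×10⁻³` radians per intensity
unit that makes the 3,000 estimated phases exactly as synchronised as the
target (order parameter 0.8); the resulting phase distribution has mean 0 by
construction, a spread of ≈2.6 h, and is right-skewed and leptokurtic — the
shape whole-SCN phase distributions show. The same phases then seed a
slicing simulation:

```sh
scnphase sweep demo/neurons.csv --seed 0 --q-grid 1e-4 --k-grid 1 --out demo
```

which prints the winning (most-damaged) orientation for that cell of the
(q, K) grid —

```
     q   K  winner
0.0001 1.0 coronal
```

— and writes `demo/sweep.csv` with the deviation statistic of each
orientation (coronal slabs typically deviate most, horizontal least).

The library API mirrors the CLI: see `scnphase.synthetic`,
`scnphase.fourier`, `scnphase.model`, `scnphase.snapshot`,
`scnphase.kuramoto`. `docs/methods.md` documents the model conventions,
parameter defaults and known limitations.

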