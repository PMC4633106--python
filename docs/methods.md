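# Methods

This document records the model, the parameter values with units, how
the synthetic-data generator relates to the real measurement, and the
numerical and statistical choices made in the implementation.

## 1. Local-coupling model of thin-filament activation

Actin thin filaments are regulated by tropomyosin/troponin (Tm/Tn),
which in the absence of calcium and bound myosin suppresses myosin
attachment. A bound myosin head holds tropomyosin aside over a finite
span of filament, lowering the activation energy for further binding
nearby. The model reduces this to two parameters:

- `epsilon` ∈ (0, 1]: the factor by which Tm/Tn reduces the attachment
  rate on fully blocked actin. It is the only calcium-dependent
  parameter: 0.4 at pCa 5, 0.06 at pCa 6, 0.02 at pCa 7.
- `C` (positive integer): the coupling range expressed in binding
  sites, `C = L_C / dL` where `L_C` is the critical length over which a
  bound head deforms tropomyosin and `dL` is the site spacing. With
  `L_C = 385 nm` (35 sites on the original 11 nm myosin lattice) and
  `dL = 5.5 nm`, `C = 70`.

If the nearest bound neighbours of a site are `i` sites to the left and
`j` to the right, the attachment rate is the piecewise law

```
k(i,j) = epsilon            * k0   if i >= C and j >= C
         epsilon^(i/C)      * k0   if i <  C and j >= C
         epsilon^(j/C)      * k0   if i >= C and j <  C
         epsilon^((i+j-C)/C)* k0   if i <  C, j < C, i + j > C
         k0                        if i + j <= C
```

implemented both literally (`coupling.attachment_rate`) and in the
equivalent closed form `k0 * epsilon ** (max(min(i,C) + min(j,C) - C, 0)/C)`
used for whole-lattice vectorization (`coupling.attachment_rates`);
their equality is tested on random lattices. An end of the filament
with no bound neighbour is treated as that neighbour being infinitely
far away (`NO_NEIGHBOR = inf`). The corresponding activation energy
penalty is `dE(L) = -(min(L, C)/C) * ln(epsilon)`: linear in the
distance `L` to the nearest bound head, saturating at `-ln(epsilon)`
(5.8 kT at the lower plausibility bound `epsilon = 0.003`).

## 2. Kinetic scheme and parameters

Each site is a three-state cycle:

```
EMPTY --k(i,j)--> AMD --k_D--> AM --k_T*[ATP]--> EMPTY
```

| Parameter | Value | Units | Meaning |
|---|---|---|---|
| `k_b0` | 0.00055 | nM⁻¹ s⁻¹ | per-site attachment constant; `k0 = k_b0 [Myo]` |
| `k_D` | 350 | s⁻¹ | ADP release |
| `k_T` | 2 | µM⁻¹ s⁻¹ | ATP-induced detachment |
| `C` | 70 | sites | coupling range at 5.5 nm spacing |
| `epsilon` | 0.4 / 0.06 / 0.02 | – | pCa 5 / 6 / 7 |
| `dL` | 5.5 | nm | site spacing |
| `t_equil` | 35 | s | discarded equilibration |

`k_b0` derives from the measured per-length attachment constant
0.2 nM⁻¹ µm⁻¹ s⁻¹: times 5.5 nm of filament per site, divided by 2
because each site models one of the two sides of the filament
(`simulate.per_site_k_b0_from_per_um`). A 3 µm filament has
`ceil(3000 / 5.5) = 546` sites per side (ceiling rounding reproduces
546 exactly).

## 3. Stochastic simulation

`simulate.gillespie_run` is an exact direct-method Gillespie
simulation: all `k(i,j)` are recomputed after every event (no
approximation; the vectorized neighbour scan makes this O(N) per
event, ~45 µs/event on one CPU for N = 546). The two filament sides
are statistically independent and get independent child seeds.
Recording starts after the 35 s equilibration; frames are the
*fraction of the frame time each site was occupied* (AMD or AM), so a
head bound 1/10th of a frame produces a spot 1/10th as bright
(`simulate.sample_frames`).

## 4. Fluorescence rendering — generator realism

`render.render_movie` mimics the measurement chain of single-molecule
TIRF imaging of GFP-S1 on surface-anchored filaments:

| Parameter | Value | Units |
|---|---|---|
| emission rate `e` | 450 | intensity units / s |
| single-GFP frame intensity `I1 = e/f` | 45 (10 Hz), ≈118.4 (3.8 Hz) | units |
| PSF sigma | 160 nm = 2 px | 80 nm pixels |
| `sigma_F` | 0.22 | scaled units, per fluorophore per frame |
| `sigma_N` | 0.21–0.36 (per condition) | scaled units, per pixel per frame |

Each bound fluorophore contributes a Gaussian of *peak amplitude*
`(e/f) * (w + eta_F)` where `w` is its bound fraction of the frame and
`eta_F ~ N(0, sigma_F)` models GFP intensity variability; background
noise `N(0, sigma_N * e/f)` is added to every pixel. Negative pixel
values are kept (as in background-subtracted camera data). The image
is the 3 µm filament (38 pixels) plus a 5-pixel margin on each side
(48 pixels). "Scaled intensity" is `I * f / e`, making a single GFP
equal 1 at any frame rate. Kymographs are the movie transposed to
pixels × frames.

Deliberate simplifications: no photobleaching, no diffusing spots, no
camera shot noise or EM gain statistics (all noise is the calibrated
Gaussian `sigma_N`), no filament drift, and the PSF is a 1-D Gaussian
along the filament axis (the experimental analysis also collapses to a
line profile).

## 5. Spot analysis

`spots.fit_frame` fits a sum of Gaussians of *fixed* sigma (2 px) to
each frame: candidate peaks are local maxima of the PSF-smoothed
profile; least-squares refinement (scipy, bounded: amplitudes ≥ 0,
centres inside the profile); spots fitted below the detection
threshold are pruned and the rest refitted. Default threshold:
`2.5 * sigma_N * e/f`.

One deviation from the naive reading of the procedure: the local-maxima
threshold is applied to the *smoothed* profile, where a true spot of
amplitude `A` is attenuated to `A/sqrt(2)` (matched filter with sigma
equal to the PSF). The seed threshold is therefore
`min_amplitude / sqrt(2)`. With the literal threshold, single-GFP spots
at the higher noise levels are systematically missed while the final
acceptance is still `min_amplitude`, which would bias the amplitude
histograms; with a laxer seed threshold, noise-only movies grow false
positives. The matched-filter correction (≈4.7 smoothed-noise SDs)
detects single GFPs at every packaged condition and yields zero spots
in myosin-free movies.

Amplitude histograms use bin *centres* on integer multiples of the bin
width (default 0.25 in scaled units), so the bin containing a single
GFP is (0.875, 1.125]. Per-frame RMS fit residuals estimate the
background noise when spots are absent or well fitted.

## 6. Exact oracle

`oracle.build_generator` enumerates all `3^N` joint states of an
N-site lattice (N ≤ 10; the dense generator at N = 10 is ~28 GB sparse
equivalent — the guard keeps memory bounded) with an *independent*
re-implementation of the rate law (explicit neighbour scans, explicit
piecewise branches). The stationary law is the null space of the
generator (scipy.linalg.null_space) with irreducibility and positivity
checks. `oracle.empirical_state_distribution` replays an event trace
into a time-weighted joint-state distribution; agreement with the
master equation is measured in total variation. The oracle validates
the simulator engine at fast-mixing rates (so that ~10⁶ events sample
the state space densely within the CI budget); engine correctness does
not depend on the rate scale, which only sets how often each event
type occurs.

## 7. Summaries and epsilon estimation

`summary.mean_fluorescence` is the grand mean of a scaled kymograph
minus a baseline: the average over pixels of each pixel's minimum over
frames, applied as a single scalar. A
per-pixel baseline is available behind a flag but is not the default.
Because the minimum of noise is negative, the summary is slightly
positive even for noise-only movies — this offset is common to target
and trial simulations in the estimator and cancels there.

`summary.superlinearity` computes second differences of mean
fluorescence vs [Myo] on the (non-uniform) concentration grid
{1, 5, 10, 15} nM; all positive = superlinear, the signature of local
coupling. `summary.estimate_epsilon` bisects on `log(epsilon)` within
(0.003, 1) against a replicate-averaged mean-fluorescence target,
using *common random numbers* (the same replicate seed sequences at
every trial epsilon) so the objective is monotone despite Monte-Carlo
noise; targets outside the achievable range return the nearer bound
with `at_boundary=True`.

## 8. Seeding and reproducibility

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn`: master → replicates → (simulation,
rendering) → (side A, side B). Pipeline manifests record the master
seed and the scheme; reruns are bit-identical (tested byte-for-byte).
CSV readers use pandas' `float_precision="round_trip"` so written
traces reload exactly.

## 9. Reduced problem sizes

The packaged presets are the nine full experimental conditions (500 or
1000 frames). The test and acceptance suites run the same generator at
reduced frame counts (150–1000 frames) and, for the epsilon-recovery
experiment, replicate counts chosen so that the replicate-limited
scatter places the ±50% band at roughly four standard errors
(24 replicates × 1000 frames for epsilon = 0.02, where mean
fluorescence is least sensitive to epsilon; 8 × 300 elsewhere). These
are scale choices of this package's CI, not claims about the full
conditions, which run unchanged via `thinfil reproduce-paper`.

## 10. Limitations

- Mean fluorescence (with the scalar-minimum baseline) is a relatively
  weak statistic for epsilon at strong blocking (pCa 7): recovery
  tolerance there is Monte-Carlo-limited, not bias-limited.
- The CTMC oracle is exact but limited to N ≤ 10 sites; full-lattice
  validation is statistical (closed-form limits at epsilon = 1,
  stationarity checks).
- No photophysics (bleaching/blinking) or spatial drift; histogram
  tails from overlapping spots are reproduced only insofar as the 1-D
  fixed-sigma fitting pipeline reproduces them.
- `C` is held fixed at 70; only epsilon varies with calcium.
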