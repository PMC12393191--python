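# Methods

## The sequence being simulated

`esmgre` models a multislice, bipolar multi-echo gradient-echo (mGRE)
acquisition extended with *echo shifting*: after `p` prompt echoes, a pair
of unbalanced gradients with area ratio −1 : 2 (−A′ followed by +2A′)
dephases the freshly excited spins and rephases them one sub-TR interval
(TR / number of slices) later, where the remaining `q` echoes are read out.
Long echo times — needed to characterise slow-relaxing water pools such as
CSF, whose T2* is an order of magnitude longer than brain tissue's — are
thereby reached without lengthening TR: while slice *n*'s late echoes form,
slice *n + 1* has already been excited and contributes its own prompt
echoes, and its spins are dephased by −A′ during the shifted readout.

The phase bookkeeping implemented in `sequence.py` is exact by
construction:

* freshly excited spins see the second half of the slice-select lobe
  (area A_r) cancelled by the rephaser, a readout pre-dephaser of half a
  lobe area, and bipolar lobes whose centres are zero crossings — so their
  net zeroth moment vanishes at every prompt echo centre;
* across one full sub-TR a *passing* spin packet accumulates exactly +A′
  (select + rephase + duplicated refocus cancel; −A′ + 2A′ = +A′), so the
  −A′ lobe of the next interval nulls it precisely during the shifted
  readout slots, and the packet is spoiled by one further A′ per interval
  afterwards;
* the duplicated readout dephaser at the end of each interval restores the
  readout moment to zero — with opposite polarity to the original
  pre-dephaser when the total number of readout lobes is even — which is
  what lets the previous slice's spins refocus on the readout axis too.

`zeroth_moment` verifies these statements numerically on the sampled
waveform rather than symbolically; the test suite checks them for
K ∈ {4, 8, 10, 12, 16}.

## Gradient design conventions

Hardware details are not part of a protocol sheet, so the waveform builder
fixes documented conventions (all overridable per `ProtocolConfig`):

| quantity | default | reason |
| --- | --- | --- |
| gradient raster | 0.01 ms | lobe boundaries and areas are rounded to it |
| slew rate | 180 mT/m/ms | typical 3 T whole-body gradient set |
| generic lobe amplitude cap | 40 mT/m | ditto |
| echo-shift lobe plateau | 18 mT/m | moderate amplitude limits eddy currents; reproduces the printed shifted-echo timing (below) |
| RF duration / time-bandwidth | 2.0 ms / 2.5 | short low-TBW excitation typical of short-TR GRE |

The echo-shift gradient area is `K ×` the slice-rephase area
A_r = G_ss (τ_RF/2 + ramp/2), with G_ss derived from the RF bandwidth and
slice thickness.  The RF TBW and the shift-lobe amplitude were fixed by
reverse-engineering the published protocol sheet for the 64-echo, K = 10,
2 mm-slice acquisition: with TBW 2.5 and an 18 mT/m plateau the builder
reproduces the printed echo times (last prompt echo 66.21 vs 66.18 ms,
first shifted echo 206.84 vs 206.88 ms, last shifted echo 237.71 vs
237.72 ms; residuals are raster/rounding effects) and yields a
shifted-echo b-value of ≈ 196 s/mm², squarely between the two figures that
the same session reports in different places (≈ 180 and ≈ 250 s/mm²).  A
TBW-4 excitation would put b near 470 s/mm², outside that bracket, which
is why the lower default was adopted.  The toolkit always reports its own
computed b rather than either printed figure.

Echo times follow slot arithmetic: every navigator occupies exactly one
echo spacing in the train (its phase rewind/wind blips are absorbed into
the adjacent ramps), a reading supported by the printed values
(TE₄₃ ≈ TE₁ + 43·ΔTE and TE₆₄ − TE₄₄ ≈ 21·ΔTE with one navigator among the
21 shifted echoes).  The sub-TR used in timing is rounded to the raster.

## b-values

b(TE_n) = γ² ∫₀^TE_n m(t)² dt with m the zeroth gradient moment summed
over the read and slice axes (phase-encode lobes excluded, as the b
calculation for such sequences prescribes).  The waveform is piecewise
linear on a half-raster grid; each sample cell's contribution to ∫m² is
integrated in closed form (m is quadratic inside a cell), with one-sided
edge amplitudes recovered from quarter-point samples so that zero-ramp
(discontinuous) test waveforms are handled exactly.  The integrator
reproduces the Stejskal–Tanner closed form for rectangular pulsed-gradient
pairs to machine precision; the test and acceptance suites require
< 0.1 %.

## Phantom and forward model

The digital phantom is a row of axis-aligned rectangular blocks (GM, WM,
putamen, globus pallidus, CSF) on an empty background, sized to the
protocol matrix.  Default tissue values are literature-typical 3 T numbers
(T1/T2* in ms, D in μm²/ms): GM 1300/55/0.8, WM 850/50/0.7,
Put 1100/40/0.7, GP 1000/30/0.7, CSF 4300/1800/3.0, all overridable; no
test depends on these specific values.

The voxel signal is the spoiled-GRE steady state with off-resonance phase
and diffusion attenuation,

    s(TE_n) = M0 sin α (1−E1)/(1−cos α·E1) · e^{−TE_n/T2*}
              · e^{i(φ0 + 2π Δf TE_n)} · e^{−b(TE_n) D} + ε(0, σ²),

E1 = e^{−TR/T1}, with independent Gaussian noise on both complex channels.
Because the multislice scheme uses one RF pulse per slice per effective
TR, no extra saturation terms appear.  Noise levels are specified as an
SNR knob relative to the white-matter signal at TE₁ (default SNR 50).
The simulation is 2D and single-slice; inter-slice effects enter only
through the timing/spoiling analysis above, which is exact for the
global-gradient geometry.

## K-space corruption and navigator correction

Shot-to-shot resonance-frequency offsets Δf₀(p) (sinusoid + drift +
optional jitter per phase-encode line, spatially uniform) multiply line
*p* of echo *n* by e^{i2πΔf₀(p)TE_n} and ghost the images along the phase
encode.  Navigators are phase-encode-free readouts (the k_y = 0 line)
acquired mid-way through the prompt and the shifted block.

Correction happens in hybrid (x, k_y) space.  Step 1 takes the phase of
nav1 on line p relative to line 1 — computed as the argument of the
conjugate product, which avoids unwrapping for offsets below π — and
multiplies every echo and navigator by e^{−iφ_p(x)·TE_n/TE_nav1}.  Step 2
repeats this with the (already corrected) shifted-block navigator and
touches only the shifted echoes, scaled by TE_n/TE_nav2.  Both steps also
align the estimating navigator itself, which makes each step idempotent.
For noiseless, model-consistent corruption the two steps restore the
reference images to floating-point accuracy; the residual is a per-echo
global phase, invisible in magnitude.  When a noise σ is supplied, phase
estimates at readout positions whose navigator SNR is below the mean are
replaced by the median phase of the above-mean positions (the low-SNR
fallback); "below average" is taken over readout positions.

Limits: offsets whose accumulated phase at the navigator TE exceeds ±π
wrap and are only partially corrected; spatially varying fields are out of
scope (the correction targets the global field term, as the two-step
scheme assumes).  The simulation is single-coil; multi-coil combination is
an orthogonal published step and is not modelled.

## Voxelwise fitting

The magnitude fit model is s(TE_n) = M0 e^{−TE_n/T2*} e^{−b_n D}
e^{(−1)^n δ}, with the (−1)^n sign taken from each echo's bipolar readout
polarity and steady-state factors folded into M0.  In simulations δ is
excluded by default (the generator is ideal); the δ machinery is exercised
separately.

* **Noise handling.** Magnitude data is Rician; the default objective is
  the Rician log-likelihood with σ held fixed at the background estimate
  (σ from four 20 × 20 background corner ROIs, Rayleigh mean relation
  σ = mean/√(π/2); a second-moment variant is available).  A Gaussian
  least-squares objective is available for comparison and noiseless work.
  The exponentially scaled Bessel I₀ keeps the likelihood stable.
* **Optimiser.** Parameters (log M0, R2* = 1/T2*, D) with bounds
  T2* ∈ [1, 5000] ms, D ∈ [0, 10] μm²/ms.  Initialisation: weighted
  log-linear regression on the prompt echoes for (M0, R2*), the
  shifted-block log offset for D.  A vectorised Levenberg–Marquardt (and,
  for Rician, a damped Newton ascent with the exact likelihood gradient)
  runs over all voxels simultaneously; when a step would cross a bound the
  parameter is pinned and the step re-solved in the free subspace, which
  is what keeps boundary voxels (D = 0 tissue) converging in a handful of
  iterations.  Convergence: relative parameter change < 10⁻⁶ or an
  objective plateau, 200 iterations cap.  A per-voxel scipy reference path
  (`fit_voxel`) with a 3-point multi-start on T2* serves as the slow gold
  standard and is cross-checked against a refined brute-force likelihood
  lattice in the tests.
* **δ correction.** Iteratively: fit without δ, synthesise δ-free signals,
  pick the δ minimising the acquired-vs-synthesised squared discrepancy
  (bounded scalar solve; per-voxel Newton variant available), demodulate,
  refit; stop at |Δδ| < 10⁻⁴ or 10 iterations.  δ is a single global
  scalar by default, estimated on high-SNR voxels.
* **Model comparison.** cAIC = −2 log L + 2k + 2k(k+1)/(n−k−1) per voxel
  for the fits with (k = 3) and without (k = 2) the diffusion term;
  undefined when n − k − 1 ≤ 0.  In the phantom the diffusion model wins
  essentially everywhere in CSF (large b·D) and nowhere in tissue, whose
  shifted echoes are noise-dominated.

Expected behaviour reproduced by the tests: omitting the diffusion term
biases T2* *low* on diffusing spins, increasingly so with K; Gaussian
fitting biases T2* *high* relative to Rician fitting when the echo-train
tail drops below SNR ≈ 2.

## Simulation study grid

The study crosses echo counts {24, 32, 64} × K ∈ {4, 8, 10, 12, 16} ×
shifted fractions {0, 1/6, 1/3, 1/2, 2/3, 5/6} with 10 noise replicates
per cell (seeds base + 1000·cell + replicate, so any cell reruns
bit-identically).  Per cell the slice count is maximised subject to the
readout block fitting the sub-TR, as scanner protocols are configured;
infeasible cells are recorded as skipped rather than silently dropped.
The experiment matrix is 64 × 64 rather than full scanner resolution —
the comparison rests on the statistics of voxelwise fits, not on
resolution — which keeps the full grid at roughly four to five minutes on
one CPU.  Tissue regions are summarised by mean ± std; CSF-type regions
by median (Q1, Q3) after closed-interval filters 80 ≤ T2* ≤ 2000 ms and
2 ≤ D ≤ 5 μm²/ms, and region pairs can be compared with the asymptotic
two-sample Kolmogorov–Smirnov test.

The K-trend report checks two monotone signatures at 64 echoes: the CSF
shifted-echo signal decreases with K (larger diffusion weighting), and the
standard deviation of fitted D does not increase with K (stronger encoding
is more precise).

## What the generator does and does not emulate

The synthetic data carries the properties the method manipulates — decay,
steady state, diffusion attenuation by the shift gradients, bipolar
modulation, global field fluctuation, Rician magnitude statistics — so
passing tests validate the timing algebra, the correction and the
estimators.  It does **not** contain flow/IVIM effects (deliberately
excluded from both generator and fit model), susceptibility-induced
mesoscopic dephasing, multi-compartment decay, spatially varying
fluctuation fields, coil sensitivities, motion, or scanner nonidealities
(eddy currents, gradient delays); agreement on the phantom therefore says
nothing about those confounds in real data.

## Known limitations

* Per-voxel T2* precision collapses for very long T2* relative to the
  sampled TE range: the Cramér–Rao bound for the 64-echo/K = 10 train at
  SNR 50 grows from ~2 % at T2* ≈ 50 ms to ~30 % at T2* = 2000 ms, and
  the estimator is near-efficient — wide CSF interquartile ranges are a
  property of the design, not a fitting defect.
* The navigator correction assumes |phase| < π per comparison at the
  navigator TE; larger drifts would need unwrapping across lines.
* δ is treated as spatially global by default; a per-voxel option exists
  but is noisier.
* The b-value and moment analysis treat gradients as ideal trapezoids on
  the raster; no eddy-current or concomitant-field terms.
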