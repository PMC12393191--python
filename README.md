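# esmgre — echo-shifted multi-echo GRE simulation and T2*/D fitting

Quantifying T2* in slow-relaxing water pools such as cerebrospinal fluid
(CSF) needs echo times an order of magnitude longer than brain tissue
requires, which normally forces a long TR and a long scan.  An
*echo-shifted* multi-echo gradient-echo sequence avoids that: after `p`
prompt echoes, a pair of unbalanced gradients with areas −A′ and +2A′
(A′ = K × slice-rephase area) defers the remaining `q` echoes into the next
sub-TR interval (TR / number of slices) of the multislice loop, so both the
early and the late part of the decay are sampled without extending TR.  The
same gradients diffusion-weight the shifted echoes with a b-value set by K,
so CSF diffusivity comes for free.

`esmgre` is an in-silico toolkit for this sequence, aimed at sequence
developers and quantitative-MRI methodologists.  It provides:

* **Sequence timing and gradients** — echo-train layout with navigator
  slots, trapezoidal waveforms on a 10 µs raster, zeroth-moment/spoiling
  analysis, and per-echo b-values
  `b(TE_n) = γ² ∫₀^TEn (∫₀ᵗ G dt′)² dt` (phase-encode lobes excluded).
* **Digital phantom and forward model** — rectangular GM/WM/putamen/
  globus-pallidus/CSF blocks evaluated through the spoiled-GRE steady
  state `M0 sin α (1−E1)/(1−cos α E1) e^{−TE/T2*} e^{i(φ0+2πΔf TE)}
  e^{−bD} + ε(0, σ²)`.
* **K-space corruption and navigator correction** — per-line resonance
  offsets Δf₀(p) ghost the images; the two-step correction removes
  per-line phases estimated from a prompt-block and a shifted-block
  navigator, scaled by TE_n/TE_nav, in hybrid (x, k_y) space.
* **Voxelwise fitting** — magnitude model
  `s(TE_n) = M0 e^{−TE_n/T2*} e^{−b(TE_n)D} e^{(−1)^n δ}` fitted by
  Rician maximum likelihood (σ from background corners) or Gaussian least
  squares, with iterative bipolar-modulation (δ) correction and per-voxel
  cAIC comparison of the fits with and without the diffusion term.
* **Simulation studies** — the echo-count × K × shifted-count grid with
  seeded replicates, ROI summaries (mean ± std, or median/quartiles with
  inclusion filters for CSF-type regions) and K-trend reports.

## Worked example

Simulate the bundled 64-echo / K = 10 protocol over the block phantom,
corrupt it with a 5 Hz breathing-like field fluctuation, correct it with
the navigators, and fit parameter maps:

```python
import numpy as np
from esmgre import (get_preset, design_sequence, build_figure2_phantom,
                    acquire_kspace, FluctuationModel, NoiseSpec,
                    reconstruct_magnitude, fit_map, caic_compare)
from esmgre.kspace import correct
from esmgre.phantom import sigma_for_snr

cfg = get_preset("sim_64x64_k10")   # 64 echoes, 21 shifted, K = 10, TR 1.2 s
train, wf = design_sequence(cfg)
print(f"TE1={train.te[0]:.2f} ms, TE43={train.te[42]:.2f} ms, "
      f"TE44={train.te[43]:.2f} ms, TE64={train.te[63]:.2f} ms")
print(f"shifted-echo b = {train.b[train.is_shifted].mean():.1f} s/mm^2")

phantom = build_figure2_phantom(cfg)
sigma = sigma_for_snr(phantom, train, cfg, snr=50.0)
ks = acquire_kspace(phantom, train, cfg,
                    fluctuation=FluctuationModel(amplitude=5.0, period=24.0),
                    noise=NoiseSpec(sigma=sigma, seed=7))
fixed, report = correct(ks, sigma=sigma, support=phantom.support)
print(f"ghost energy {report.ghost_energy_before:.4f} -> "
      f"{report.ghost_energy_after:.4f}")

images = reconstruct_magnitude(fixed)
fits = fit_map(images, train, sigma=sigma, mask=phantom.support)
cmp_ = caic_compare(fits["with_diffusion"], fits["without_diffusion"])
csf = phantom.labels == 5
print(f"CSF: T2* = {np.nanmedian(fits['with_diffusion'].t2star[csf]):.0f} ms, "
      f"D = {np.nanmedian(fits['with_diffusion'].d[csf]):.2f} um^2/ms, "
      f"diffusion model preferred in {100*cmp_['prefer_diffusion'][csf].mean():.0f}% of voxels")
```

Output:

```
TE1=3.00 ms, TE43=66.21 ms, TE44=226.41 ms, TE64=257.28 ms
shifted-echo b = 221.3 s/mm^2
ghost energy 0.0352 -> 0.0037
CSF: T2* = 1891 ms, D = 3.04 um^2/ms, diffusion model preferred in 100% of voxels
```

The prompt block (3–66 ms) samples the tissue decay and the shifted block
(226–257 ms, one sub-TR of this 8-slice, TR = 1.2 s protocol later) the
CSF decay; with the in vivo preset (`table1_invivo`, TR 3 s, 23 slices)
the builder instead reproduces that protocol sheet's printed echo times —
66.21 / 206.84 / 237.71 ms against printed 66.18 / 206.88 / 237.72 ms —
and a shifted-echo b of ≈ 196 s/mm² for K = 10.  The navigator correction
removes the phase-encode ghosts (tenfold ghost-energy drop at this noise
level; exact removal in the noiseless limit), after which the voxelwise
Rician fit recovers the phantom's CSF diffusivity (3.0 μm²/ms ground
truth) and its long T2* with the wide per-voxel spread that the
Cramér–Rao bound dictates at this TE range.

The same pipeline is scriptable from the shell:

```bash
esmgre simulate --preset sim_64x64_k10 --out sim --snr 50 --seed 1
esmgre correct  --kspace sim/kspace.h5 --out corr
esmgre fit      --images corr/echo_images_corrected.nii.gz \
                --train sim/echo_train.json --out maps --model both
esmgre grid     --out study --replicates 10
```

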