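# Methods

## Model and assumptions

The observed image is `Y = X + N`, where `X` is the latent clean image and
`N` is additive white Gaussian noise with unknown standard deviation σ,
independent of `X`, identically distributed per pixel, signal-independent
and unclipped. The estimator targets a single global σ in the intensity
units of the input; it does not model Poisson (signal-dependent) noise,
spatially varying noise, or quantization/clipping effects.

The central assumption is that the image contains *latent-flat* patches:
`d × d` windows whose clean content is constant. For such a window the
unbiased sample variance over its `w = d²` pixels satisfies
`(w−1) s² / σ² ~ χ²(w−1)` exactly, which is what makes pooled chi-square
inference possible.

## Procedure

1. **Decomposition.** All stride-1 windows, `S = (P−d+1)(Q−d+1)` of them.
   A stride of 1 maximizes the flat-patch yield at negligible cost, because
   per-patch quantities are computed with shared full-image passes (see
   *Numerics*).
2. **Texture intensity.** `ε = Σ |G_h| + Σ |G_v|` over the valid correlation
   region of the patch, with a zero-sum kernel pair (`hv = hhᵀ`). Absolute
   values make ε non-negative and monotone in structure strength; a signed
   sum would cancel on noise and carry no selection power. The default
   kernel is the 1×2 first difference `[−1, 1]`: the simplest zero-sum pair,
   and the method is self-consistent for any choice because the threshold
   calibration uses the same kernels. A Sobel pair is available
   (`GradientKernels.sobel()`); it produces larger ε values and a
   correspondingly larger calibrated threshold.
3. **Threshold calibration.** `ε_δ(σ)` is the maximum ε over `n = 100 000`
   i.i.d. pure-noise patches at level σ. Because ε is positively homogeneous
   in the pixel values, the patches are drawn once at unit variance and the
   statistic is scaled by σ; with a fixed seed this is exactly equivalent to
   redrawing at every σ and makes recalibration inside the iteration free
   and bit-reproducible. The maximum over draws grows slowly with `n` and is
   itself noisy; a quantile alternative (`calib_quantile=0.999`, say) is
   available for users who prefer a stable statistic, but the default
   follows the max convention.
4. **Selection.** Patches with `ε ≤ ε_δ` (inclusive tie) are flat. If fewer
   than `c_min = 10` pass — possible on richly textured images — the `c_min`
   smallest-ε patches are used instead, with a warning: a variance pool
   needs a minimum membership to mean anything.
5. **Bootstrap σ₀.** Before any threshold exists, the `q0 = 5%` smallest-ε
   patches are pooled. Conditioning on a small gradient intensity also
   selects noise realizations with below-average sample variance (on flat
   noisy images the shrinkage is roughly 0.6× on the variance, i.e. ~20% low
   on σ), so the pooled value is divided by a Monte-Carlo shrinkage factor:
   the mean variance of the lowest-`q0` fraction of *unit-noise* patches,
   computed from the same draw protocol and seed as the calibration (cached,
   deterministic). After correction σ₀ lands within ~1% on flat images,
   which keeps the first calibrated threshold in a regime where essentially
   all latent-flat patches are recovered.
6. **Pooling.** `σ² = Σ_l (w−1) σ_l² / Q_χ²(T; C(w−1))` with
   `T = 1 − e⁻⁶ ≈ 0.9975212`. The quantile exceeds the degrees of freedom
   slightly, so the estimate is conservatively biased low by
   `≈ z_T √(2/df)/2` relative — about 0.07% on σ for a 512×512 flat image —
   and the bias vanishes as `C(w−1) → ∞`. A literal variant that pools raw
   variances against `Q_χ²(T; C)` is kept behind
   `df_convention="patch_count"`; it divides by roughly `C` instead of
   `C(w−1)` and is *not* a consistent estimator of σ — it exists for
   comparison only, and flat-image recovery pins the pooled convention as
   the default.
7. **Iteration.** Alternate calibration at σ_t with reselection and
   re-pooling; stop when `Φ = (σ_{t+1}² − σ_t²)² / (σ_t²)² ≤ γ = 10⁻³`, when
   the selected set repeats (a fixed point by construction), or after
   `max_iter = 10` iterations (non-convergence returns the last iterate with
   `converged=False` and a warning). `Φ` with a zero previous iterate is
   defined as 0 if the new iterate is also 0 (converged) and +∞ otherwise.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `d` | 6 | px | smallest window with a usable variance (w=36); larger d finds fewer flat patches |
| `confidence` T | 1 − e⁻⁶ | — | near-certain upper quantile; makes σ̂ a slight under- rather than over-estimate, which downstream denoisers tolerate better |
| `gamma` γ | 10⁻³ | — | ≈3% relative change of σ², inside the estimator's noise floor |
| `max_iter` | 10 | — | the loop converges in 1–3 iterations in practice |
| `calib_samples` | 100 000 | patches | max statistic stabilizes to ~1% across seeds at this size |
| `q0` | 0.05 | — | bootstrap pool large enough to be stable, small enough to stay flat-dominated |
| `c_min` | 10 | patches | floor below which the chi-square pool is meaningless |

σ is reported in the input's intensity units; inputs are never rescaled.

## Synthetic data

The generator produces the study conditions: flat images at gray levels
64/128/192, AWGN corruption (unclipped, float, deterministic per seed),
ramps, checkerboards (default 16 px tiles, so tile interiors are genuinely
flat), a half-flat/half-checkerboard composite (default 4 px tiles, below
the patch size, so every patch on the textured half straddles an edge —
used for selection-purity studies), and an angiogram-like vessel tree
(smooth random curvilinear bright structures with a Gaussian cross-profile
cut off at 2.5 half-widths on an exactly flat background).

What passing tests on these phantoms do **not** show: real radiographs have
signal-dependent noise components, anatomical backgrounds that are textured
at every scale, and 8-bit clipping; the phantoms isolate the AWGN model the
estimator is built for. Clipping can be enabled (`clip_to_8bit`) to study
its effect but is excluded from the standard experiments, since the
degradation model is unclipped Gaussian.

Experiment sizes are 512×512 images with 20 repetitions per noise level
(100 repetitions for the iteration-stability study), chosen as the package's
standard desk-scale protocol; image size and repetition counts are plain
parameters for anyone who wants the full 1024×1024 / 100-rep protocol.

## Numerics

- All arithmetic in float64; integer inputs are promoted, never clipped.
- Per-patch quantities are computed via shared full-image passes: the valid
  correlation of every patch equals a window of the full-image valid
  correlation, so the texture map is a box sum over |G|; patch means and
  variances come from windowed sums of the image and its square (tiny
  negative variances from cancellation are clamped to 0).
- Valid-region correlation only — padding would fabricate gradients at
  patch borders.
- Selection uses an inclusive comparison (`ε ≤ ε_δ`); immaterial at floating
  point but pinned for reproducibility.
- Ties in the bootstrap/fallback smallest-ε orderings are broken by patch
  index (stable sort).
- The chi-square quantile is `scipy.stats.chi2.ppf`; the test suite
  cross-checks it against an independent bisection inversion of the
  regularized incomplete gamma function to 1e-8 relative at df up to 1e5.
- Exact symmetries (tested): adding a constant to an integer-valued image
  leaves the texture map bit-identical; doubling the image doubles ε, ε_δ
  (same seed) and σ_end bit-exactly; reruns with the same seed are
  bit-identical.

## Known limitations

- A single global σ: no per-region noise maps.
- Images with no truly flat content (dense texture everywhere) push the
  selector into its `c_min` fallback and the estimate inherits whatever
  structure leaks into those patches — the result is then an upper-biased σ.
- The max-based threshold grows (slowly) with `calib_samples`; the two are
  a matched pair and should be changed together (or switch to the quantile
  variant).
- Overlapping patches make pooled variances statistically dependent; the
  pooled chi-square count treats them as independent. This affects the
  (unused) finite-sample distribution, not the near-unbiasedness of the
  estimate, which the recovery experiments measure directly.
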