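# Methods

## The problem

Low-dose CT perfusion imaging trades radiation exposure for noise: reducing
tube current raises the per-pixel noise floor, and in renal perfusion series
that noise propagates directly into the time–density curves and the
perfusion parameters derived from them. `dyashrink` implements an
edge-preserving wavelet denoiser for such images, the two classical
baselines it is customarily compared against, the MSE/SNR fidelity metrics
used to rank them, and a synthetic phantom generator so the whole pipeline
is testable without scanner data.

## The transform

The denoiser operates in an **undecimated dyadic wavelet domain**: every
subband keeps the full image size and deeper scales use the same filters
with `2**(j-1) - 1` zeros inserted between taps (the à trous scheme). Unlike
the decimated orthogonal transform, this representation is
translation-invariant — denoising a shifted image gives the shifted result —
which removes the pseudo-Gibbs artifacts decimated shrinkage produces near
edges.

Each scale carries exactly **two directional detail planes**, horizontal
(d=1) and vertical (d=2). One ladder step, acting on the running
approximation `S`:

    A      = h_j *rows S        W_j^1 = g_j *rows S
    S_j    = h_j *cols A        W_j^2 = g_j *cols A

with `h` the smoothing filter and `g = δ − h` its complementary high-pass.
Because the high-pass is the complement of the low-pass, the ladder
telescopes, `S_{j-1} = W_j^1 + W_j^2 + S_j`, so synthesis is plane-wise
summation and reconstruction is exact to machine precision for any boundary
rule (measured ~1e-15 max abs error; the test tolerance is 1e-8). The price
of this construction is a mild asymmetry: the vertical channel is formed
from the row-smoothed approximation, so the two channels see noise through
slightly different equivalent filters (handled explicitly below).

The default `h` is the cubic-B-spline kernel `[1,4,6,4,1]/16` — smooth,
short, and the standard à trous choice for medical images; a two-tap
Haar-type pair is available. The method is filter-agnostic. Boundary
handling is symmetric (mirror) reflection by default, which avoids edge
artifacts on anatomy; a periodic mode exists and is what makes the
translation-invariance property exact.

## Noise model and its propagation

Noise is modeled as i.i.d. additive Gaussian with unknown standard
deviation σ. σ is estimated robustly from the finest-scale detail
coefficients by the MAD rule `σ̂ = median(|w|) / 0.6745` — the finest band
is noise-dominated, and the median ignores the sparse large coefficients
contributed by edges. Both directional planes are pooled, each first
normalized by its own equivalent-filter gain: the two scale-1 channels have
gains `‖g‖` and `‖g‖·‖h‖` (differing by ~2x), so unnormalized pooling
would estimate neither the pixel-domain σ nor either channel's coefficient
σ. `estimate_sigma` is the bare MAD rule; `estimate_image_sigma` applies
the gain correction and is what the pipeline uses. On pure N(0, 15²) fields
at 256×256 the estimator recovers σ within ~0.5%.

The coefficient-domain noise variance at scale j is obtained by propagating
σ² through the filter cascade: the equivalent filter of a detail channel is
the convolution of the zero-inserted low-pass filters of scales 1..j−1 with
the zero-inserted high-pass of scale j (separably, row × column), and the
variance is σ² times its tap energy. `propagate_noise_variance` returns the
per-direction value on request and the direction mean by default; the mean
equals the variance of the pooled scale-j coefficient sample, which is what
the Monte-Carlo validation measures (agreement within ~1–2% at 512×512).

## Threshold

Each directional subband gets an adaptive threshold

    λ_{j,d} = (σ_{j,d}² / σ_x) · sqrt(ln(L_j) / J),
    σ_x = sqrt(max(β_{j,d} − σ_{j,d}², ε))

where `β_{j,d}` is the sample variance of the subband's (noisy)
coefficients, `L_j` the subband coefficient count (the full image size —
the transform is undecimated), `J` the decomposition depth, and ε = 1e-12 a
floor against division blow-up. The first factor is the BayesShrink
noise-to-signal ratio: subbands with no signal content beyond noise get an
effectively infinite threshold and are zeroed, signal-rich subbands are
barely touched. The second factor grows with subband size and decays with
depth, so shallow decompositions threshold more aggressively per scale.
Natural log; λ = 0 when σ² = 0 or L = 1, which makes denoising the exact
identity on noiseless input.

Two alternative groupings are provided for comparison
(`threshold_rule=`): `"noisy-variance"` divides by `sqrt(β)` instead of the
signal spread, and `"variance-ratio"` divides by β itself. The latter is
dimensionless (variance over variance) and therefore produces thresholds of
order 1 regardless of the intensity scale — at σ = 15 on a [0,255] image
its thresholds sit ~7x below the coefficient noise floor and it removes
almost nothing. The BayesShrink-style default is the only one of the three
whose threshold is in coefficient units, and the only one that reproduces
the expected three-way method ordering; that is why it is the default.

## Shrinkage

Coefficients are not thresholded in isolation: wavelet coefficients of real
edges are spatially clustered, so each coefficient `x` is judged together
with `M`, the maximum absolute coefficient in the m×m window centered on it
(default m = 3, boundary following the transform's mode):

- `|x| ≥ λ` — keep unchanged;
- `|x| < λ` and `M ≥ λ` — shrink to `x · (1 − (λ−|x|)/(M−|x|))`, the
  factor clamped to [0,1]: a small coefficient next to a strong one is
  probably part of an edge and is partially retained;
- otherwise — zero: the whole neighborhood is below threshold.

Comparisons use `|x|` and the sign is preserved; the degenerate case
`M = |x| < λ` (vanishing denominator) falls to the zero branch. The rule is
a contraction (`|out| ≤ |x|`) and the three branches partition every
subband — the diagnostics report the per-subband branch counts. The coarse
approximation `S_J` is never thresholded.

Default depth is J = 3, suitable for 128–256 px images; all parameters are
exposed on `IWTDenoiser`, `denoise_iwt`, and the CLI.

## Baselines

- **MFD** — mean filter, default 3×3: the weakest standard linear smoother.
- **OWD** — decimated orthogonal wavelet shrinkage: db4, depth 3, soft
  thresholding at the universal threshold `σ·sqrt(2 ln MN)`, with σ from
  the same MAD estimator applied to the finest horizontal+vertical detail
  subbands. This is deliberately the textbook configuration: universal
  thresholding oversmooths and the decimated transform shift-varies, which
  is exactly the behavior the adaptive undecimated method improves on.

On 20-replicate comparisons (128×128 phantom, σ = 15) the mean MSE ordering
is stable at IWT < MFD < OWD (≈46 / ≈125 / ≈175) with the SNR ordering
reversed, across every master seed tried.

## Metrics and TDC

MSE is the mean squared per-pixel difference; SNR is
`10·log10(Σf² / Σ(f−f̂)²)` in dB. Both are computed on the native intensity
scale (they are scale-dependent). Identical images raise an explicit
undefined-SNR error rather than returning a sentinel. `extract_tdc` reduces
a frame sequence to the ROI-mean time series — the time–density curve used
in perfusion analysis. Perfusion-parameter maps (BF/BV/MTT) are out of
scope: they require a deconvolution model this package does not implement.

## The phantom

`make_phantom` composes a soft-tissue background with a large parenchyma
ellipse, a bright cortical rim, a darker hilum, and optional random
lesion-like ellipses — piecewise-constant regions separated by sharp edges,
which is the regime wavelet shrinkage addresses and what the fidelity
properties are asserted on. It emulates the *statistics* of a kidney CT
slice (edges + flat regions + a bright cortex ROI), not anatomy: no partial
volume, no beam hardening, no streak artifacts, no spatially correlated
noise. Passing tests therefore demonstrate correctness of the algorithms
under the stated noise model, not clinical performance.

Noise is additive Gaussian (default σ = 15 on a [0,255] range — visually
plausible low-dose noise); a Poisson–Gaussian option maps the maximum
intensity to `dose_scale` expected photon counts for signal-dependent
noise. `make_perfusion_series` drives the cortical rim with a gamma-variate
first-pass enhancement curve (default peak 60 intensity units at t = 20 s,
shape α = 3) over 15 frames at 4-s spacing — a one-minute low-dose renal
protocol — and returns the injected noiseless curve and the cortex ROI so
extraction can be checked against ground truth exactly (frames are not
clipped, keeping the round trip exact).

All generators are bit-reproducible given their seeds; the comparison
runner expands one master seed into per-replicate seeds via
`numpy.random.SeedSequence`.

## Numerical choices and edge cases

- All arithmetic in float64; integer images are converted on read and
  clipped/quantized back to their recorded source range only on write.
  Comparison metrics are computed pre-quantization.
- Perfect reconstruction holds by construction (telescoping ladder), not by
  approximate filter design; the 1e-8 test tolerance is slack.
- A constant (or otherwise >50%-flat) image yields a zero MAD estimate,
  zero thresholds, and exact identity denoising.
- `β ≤ σ_j²` (no detectable signal in a subband) drives the threshold to
  ~σ_j²/√ε — effectively zeroing the subband, which is the intended limit.
- Problem sizes in the test suite (64–512 px, 20 replicates) keep the whole
  suite in seconds while leaving every statistical margin wide (the
  ordering margins are ~2x, the estimator tolerances ~20x the observed
  error).

## Known limitations

- The noise model is stationary; real low-dose CT noise is
  signal-dependent and spatially correlated by reconstruction. The
  Poisson–Gaussian option covers the first effect only.
- The two-direction transform has no diagonal channel; purely diagonal
  texture is split between the two channels less sparsely than a
  three-subband transform would represent it.
- σ estimation assumes the finest band is majority-noise; images that are
  >50% fine texture would bias it upward.
- DICOM support is read-only and single-frame.
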