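# dyashrink

Edge-preserving denoising of low-dose CT images in an **undecimated dyadic
wavelet domain**, with the classical baselines it is compared against and
the synthetic phantoms needed to test everything without scanner data.

Low-dose CT perfusion imaging (e.g. renal perfusion series) pays for its
reduced radiation with a high noise floor. `dyashrink` removes that noise
while preserving anatomy edges by combining three ingredients:

1. **À trous dyadic transform** — every scale keeps the full image size
   (no downsampling), so the transform is translation-invariant and free of
   the pseudo-Gibbs artifacts of decimated wavelet shrinkage. Each scale j
   carries two directional detail planes `W_j^1` (horizontal), `W_j^2`
   (vertical) and a coarse approximation `S_J`; reconstruction is exact.
2. **Adaptive per-subband threshold** — the noise level σ is estimated
   robustly from the finest detail band, `σ̂ = median(|w|)/0.6745`,
   propagated to each scale through the filter cascade
   (`σ_j² = σ²·‖F_j‖²`), and turned into a BayesShrink-style threshold
   `λ_j = (σ_j²/σ_x)·sqrt(ln(L_j)/J)` where `σ_x` is the estimated signal
   spread of the subband.
3. **Neighborhood-window shrinkage** — each coefficient is judged together
   with the maximum absolute coefficient `M` in the 3×3 window around it:
   kept if `|x| ≥ λ`, partially retained as `x·(1−(λ−|x|)/(M−|x|))` if a
   neighbor exceeds λ (edges are clustered), zeroed otherwise.

Also included: the mean-filter (`mfd`) and orthogonal-wavelet (`owd`,
db4/soft/universal-threshold) baseline denoisers, MSE and
`SNR = 10·log10(Σf²/Σ(f−f̂)²)` metrics, ROI time–density-curve extraction
for perfusion series, kidney-like ellipse phantoms with Gaussian or
Poisson–Gaussian noise, and a CLI. Denoisers are scikit-learn-style
transformers (`IWTDenoiser`, `MeanFilterDenoiser`,
`OrthogonalWaveletDenoiser`) with thin functional wrappers.

## Worked example

```python
import numpy as np
from dyashrink import (PhantomSpec, NoiseSpec, make_phantom, add_noise,
                       denoise_iwt, denoise_mean_filter, denoise_owd, mse, snr)

clean = make_phantom(PhantomSpec(128, 128, seed=0))          # kidney-like slice, [0, 255]
noisy = add_noise(clean, NoiseSpec("gaussian", sigma=15.0, seed=1))

denoised, diag = denoise_iwt(noisy)                          # J=3, 3x3 window
print(f"estimated sigma : {diag.noise_model.sigma:.3f}")
for name, img in [("noisy", noisy), ("iwt", denoised),
                  ("mfd", denoise_mean_filter(noisy, 3)), ("owd", denoise_owd(noisy))]:
    print(f"{name:>5}: MSE {mse(clean, img):8.2f}   SNR {snr(clean, img):6.2f} dB")
```

prints

```
estimated sigma : 15.990
noisy: MSE   222.73   SNR  16.71 dB
  iwt: MSE    47.56   SNR  23.41 dB
  mfd: MSE   136.75   SNR  18.83 dB
  owd: MSE   184.15   SNR  17.53 dB
```

The MAD estimator recovers the injected σ = 15 to within ~7% on a single
image, the adaptive denoiser cuts the mean squared error by ~4.7x (+6.7 dB),
and the method ordering — adaptive dyadic < mean filter < orthogonal
shrinkage in MSE, reversed in SNR — matches what the underlying method was
designed to show. `diag` also carries the per-subband thresholds and
keep/shrink/zero branch counts, serializable as JSON.

## Command line

```bash
dyashrink simulate --height 128 --width 128 --sigma 15 --seed 3 -o sim/     # phantom + sidecar
dyashrink denoise -i sim/phantom_noisy.tif -o denoised.tif --method iwt --diagnostics diag.json
dyashrink compare --replicates 20 --sigma 15 --methods iwt,mfd,owd --seed 1 -o report.json
dyashrink simulate --series --frames 15 --interval 4.0 -o series/           # perfusion series
```

`compare` writes a JSON report (configuration echo, per-replicate MSE/SNR
rows, per-method aggregates) plus a CSV table. PNG, TIFF (8/16-bit) and
single-frame DICOM (read, with rescale slope/intercept) are supported.

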