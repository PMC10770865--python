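# flimphasor

A toolkit for denoising and segmenting frequency-domain fluorescence
lifetime imaging (FD-FLIM) measurements in phasor space.

FLIM maps the excited-state decay time τ of fluorophores per pixel —
a contrast mechanism that is independent of excitation power and dye
concentration. Fast frequency-domain instruments read out, per pixel, four
intermediate-frequency mixer voltages V_IF(φ) at φ ∈ {0, ½π, π, 1½π} and
form the complex FLIM measurement from complementary-phase differences:

    S = V_IF(0) − V_IF(π),      G = V_IF(½π) − V_IF(1½π),
    τ = S / (ω·G),              ω = 2π·f_mod   (f_mod = 80 MHz by default)

Each pixel also maps to a phasor, g = m·cos φ, s = m·sin φ, where φ and m
are the phase shift and modulation degree of the emission; mono-exponential
decays lie on the universal semicircle s² + (g − ½)² = ¼. For time-domain
(TCSPC) data the same coordinates come from the normalized cosine/sine
transforms of the decay histogram I(t).

At low photon counts G and S are dominated by photon shot noise: each
mixer channel is Poisson-distributed (plus Gaussian read noise), so their
differences follow a Skellam distribution — mean λ₁ − λ₂, variance
λ₁ + λ₂ — which approaches a Gaussian for bright signals. This mixed
Poisson-Gaussian structure is exactly what general-purpose residual
denoising CNNs are trained against, which is why denoising the G and S
planes (rather than the lifetime image itself) works so well.

The package provides:

- **simulator** — multi-fluorophore scenes (disks/ellipses/textured
  lifetime fields, mono- or bi-exponential), their noiseless four-phase
  homodyne readout, mixed Poisson-Gaussian noise, TCSPC decay stacks, and
  supervised / Noise2Noise / averaged training-pair generation;
- **phasor** — G/S extraction, lifetime maps with validity masks, time-
  and frequency-domain phasor clouds, calibration, 2-D phasor histograms;
- **denoise** — iterative median filtering and a compact DnCNN-style
  residual CNN (numpy, deterministic) with exact min–max pre/post scaling;
- **segment** — K-means clustering of the phasor cloud (Lloyd +
  k-means++ restarts, canonical labels) mapped back to pixel label images;
- **metrics_render** — PSNR/SSIM on 8-bit min–max normalized lifetime
  images, HSV composite-lifetime renders, Gaussian fits to lifetime
  histograms;
- **pipeline / CLI** — the full before/after workflow behind
  `flimphasor simulate | run | train | evaluate`.

## Worked example

Run the full pipeline on a synthetic three-fluorophore field modeled on a
fixed BPAE cell sample (mitochondria 1.5–2 ns, nuclei 2–2.8 ns, F-actin
> 2.8 ns), with median×3 denoising and K = 3 phasor clustering:

```sh
flimphasor run --scene-name bpae --out out/bpae --k 3 --seed 2
```

prints

```
wrote 16 files to out/bpae
    noisy: PSNR 6.54 dB  SSIM 0.031
 denoised: PSNR 13.61 dB  SSIM 0.174  (gain +7.06 dB)
```

The two lines compare each branch's lifetime image against the scene's
ground-truth lifetime map after both are clipped to the display range and
min–max normalized to 8 bits: denoising the G/S planes raised lifetime
PSNR by ~7 dB here. `out/bpae` contains, for both branches, the G/S and
lifetime TIFFs, phasor histograms, K-means label images, cluster overlays
and HSV composite-lifetime PNGs (brightness = intensity, hue = lifetime
from blue at 0 ns to red at 3 ns), plus `metrics.csv` and a `manifest.txt`
listing every file written.

The same workflow is available as a library:

```python
import flimphasor as fp

cfg = fp.RunConfig(kmeans_k=3, seed=2)
result = fp.run_pipeline(cfg, scene_spec=fp.bpae_like_spec(), out_dir="out/bpae")
print(result.metrics)
```

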