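# Methods

## Forward model

The simulator emulates a four-phase homodyne FD-FLIM readout. A pixel
containing a mono-exponential fluorophore with lifetime τ and modulated
amplitude A contributes

    V_IF(θ) = B + A·m·sin(θ + φ),   m = 1/√(1 + (ωτ)²),  φ = arctan(ωτ),

sampled at θ ∈ {0, ½π, π, 1½π}, with ω = 2π·f_mod and f_mod defaulting to
80 MHz (a typical Ti:sapphire repetition rate). The mixer phase origin is
not fixed by the measurement convention itself; the sine convention was
chosen because it makes the complementary-phase differences satisfy
S/G = tan φ = ωτ exactly, so the ratio lifetime τ = S/(ωG) is exact for
mono-exponential pixels — a property the test suite asserts to 1e-9
relative error. Bi-exponential pixels sum component signals weighted by
fractional amplitude; for them the ratio readout reports the apparent
(phase) lifetime and truth comparison is done in phasor space.

The DC offset B defaults to 5× the largest modulated amplitude so that
every phase sample is a valid (non-negative) Poisson rate — physical PMT
signals are non-negative.

## Noise model

Each phase channel independently receives photon shot noise and read
noise: v → gain·Poisson(v/gain) + N(0, σ²). Because the channels are
independent Poisson variables, the differences G and S are
Skellam-distributed (mean λ₁ − λ₂, variance λ₁ + λ₂), approaching a
Gaussian at high rates. The acceptance harness verifies both moments at
λ₁ = 100, λ₂ = 60 over 10⁶ pixels.

Default synthetic study conditions, chosen once as a realistic low-power
two-photon FD-FLIM photon budget: modulated amplitude 100
photon-equivalents per pixel, photon gain 1, read σ = 2. The standard
evaluation scene is a 256×256 two-fluorophore field (3 ns background, 1 ns
disks) at these settings; its per-pixel lifetime SNR is roughly 2–5,
i.e. visibly noisy but not hopeless, matching the in vivo regimes the
method targets.

## Phasor coordinates and calibration

Time-domain phasors integrate I(t)·cos ωt and I(t)·sin ωt with a
bin-centre rectangle rule (error O(Δt²); at the 1 ps test resolution the
deviation from the closed form is below 1e-7). Frequency-domain phasors
use φ = arctan2(s, g). The instrument scale of G/S is arbitrary, so
absolute placement of (g, s) requires a reference: given a calibration
measurement of known τ_ref, the cloud is multiplied by the single complex
factor that moves the reference's mean phasor onto the closed-form point —
standard phasor-FLIM practice. Without a reference, only the phase is
physically meaningful, and each pixel is placed at the semicircle point
with its measured phase (m := |cos φ|). This keeps noiseless
mono-exponential data exactly on the universal semicircle and preserves
the phase spread of noisy clouds; it discards modulation-based
information, which an uncalibrated two-channel readout cannot recover
anyway. Pixels pushed left of the semicircle by noise (g < 0) are kept
but flagged.

Lifetime maps carry validity masks instead of raising on degenerate
pixels: |G| below 1e-12 of the plane maximum, or intensity below the
configured fraction of the maximum, marks a pixel invalid (NaN sentinel);
masked pixels are excluded from every statistic, cloud and fit.

The phasor histogram bins the window [0, 1] × [0, 0.6], which covers the
universal semicircle with headroom; out-of-window entries are clipped
into edge bins and counted separately, so the histogram total always
equals the cloud size.

## Denoisers

**Iterative median.** 3×3 window, edge-replicating, three passes by
default — further passes cost time without measurable benefit on either
synthetic or reported real data. Each pass is asserted against a
brute-force sorted-window oracle in the tests.

**Residual CNN.** A compact DnCNN-style network: 3×3 convolutions with
edge-replication padding, ReLU activations, and a final layer predicting
the noise residual that is subtracted from the input. It is implemented
directly on numpy (im2col convolutions, hand-derived backprop, Adam,
MSE loss), which makes training and inference bit-deterministic for a
given seed. Defaults — depth 5, width 16, 40×40 patches, 200 patches,
15 epochs, batch 16, lr 1e-3 — are sized so training completes in about
a minute on one CPU core while still clearing the +2 dB synthetic
acceptance floor; all are configurable upward. One model serves both the
G and S planes. Supervised training pairs noisy draws with noiseless (or
averaged) targets; Noise2Noise pairs two independent noisy draws of the
same field of view — useful when ground truth is unobtainable, as in
vivo.

**Scaling.** CNN inference operates on [0, 1] min–max scaled planes; the
wrapper scales each plane with its own retained (lo, hi) and inverts the
map exactly afterwards (round-trip error ≤ 1e-12). G and S are scaled
independently because the lifetime ratio is sensitive to any affine
mismatch between the planes. Training patches share one (lo, hi) between
input and target (the joint range) so the learned residual lives in the
same normalized units.

## Segmentation

K-means runs on the per-pixel (g, s) coordinates — not the binned
histogram — preserving the 1:1 back-mapping from cluster entries to
pixels. Lloyd's algorithm with 10 restarts (alternating k-means++ and
plain random initialization; the random restarts escape the local
optimum k-means++ repeatedly lands in when one far point dominates the
d² draw), 300 iterations max. Inertia is asserted non-increasing on
every run. Labels are renumbered by ascending centroid g (ties by s), so
results are restart-order independent; label 0 is reserved for
background/invalid pixels in label images. Accuracy against ground truth
is permutation-matched via the Hungarian algorithm on the contingency
table. K is user-specified (K = 3 suits three-stain fixed samples, K = 2
two-population fields); no automatic K selection is applied silently.

## Metrics and rendering

PSNR uses the reference's peak: 10·log₁₀(max(Y)²/MSE), with an +inf
sentinel at zero MSE so identity comparisons are representable. SSIM uses
8×8 uniform sliding windows at valid positions with C1 = (0.01·255)²,
C2 = (0.03·255)²; for volumes, plane scores are averaged. Both metrics
are only ever computed on lifetime images min–max normalized to 8 bits —
the pipeline enforces this protocol — after clipping to the configured
display range. The clip is essential on synthetic data: τ = S/(ωG) is
unbounded as G → 0, and a handful of outlier pixels would otherwise own
the whole 8-bit range, leaving the metric comparing nothing but
outliers. Real lifetime images are implicitly range-limited the same way
by their display scale bars. The evaluation scene uses a (0, 4) ns
display range (both fluorophores plus headroom); renders default to
(0, 3) ns.

Composite renders map intensity to HSV value and lifetime to hue, blue
(τ_min) to red (τ_max); invalid pixels are black unless explicitly
flagged red. Lifetime histograms are summarized by a least-squares sum of
Gaussians fitted to the binned counts (matching how such fits are drawn
over histograms), with initial means at evenly spaced percentiles;
weights are component areas normalized to 1 and components are reported
in ascending mean order.

## Problem sizes and determinism

The standard evaluation uses the 256×256 scene over five noise seeds;
the CNN is trained once on a held-out BPAE-like scene. The full
acceptance run takes a few minutes on a single core. Every stochastic
step (scene textures, noise, training order, K-means restarts) draws
from a seeded generator; two pipeline runs with one seed write
byte-identical outputs, including the CNN branch.

## What the synthetic generator does and does not show

The generator reproduces the statistical structure that matters for
denoising — piecewise-smooth G/S fields, Poisson/Skellam shot noise,
Gaussian read noise, textured lifetime ranges per fluorophore — but not
optical blur, instrument response convolution, afterpulsing,
photobleaching, autofluorescence mixtures, or the spatial morphology of
real tissue. Passing the synthetic acceptance floor therefore
demonstrates that the implementation is correct and that the method
behaves as designed under its stated noise model; it does not certify
performance on any particular real acquisition, which depends on
calibration quality and on how closely the real noise matches the model.

## Known limitations

- Uncalibrated FD phasor clouds collapse onto the semicircle arc (phase
  only); multi-exponential modulation information needs a calibration
  reference.
- The CNN is deliberately small; heavy noise regimes or fine texture may
  favor a deeper model (configurable, at CPU training cost).
- Volumes are processed plane-by-plane; no 3-D context is used.
- Time-lapse or multi-channel data must be pre-split into XYZ volumes.
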