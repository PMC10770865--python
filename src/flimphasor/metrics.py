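"""Image-quality metrics and lifetime rendering.

PSNR and SSIM follow the usual definitions: PSNR(X, Y) =
10*log10(max(Y)^2 / MSE(X, Y)) with the reference Y supplying the peak
(the measure is therefore reference-asymmetric), and SSIM with an 8x8
uniform sliding window and stabilizing constants C1 = (0.01*255)^2,
C2 = (0.03*255)^2, averaged over all (valid) windows.  Both are meant to
be computed on lifetime images scaled to 8 bits with min-max
normalization, which makes max(Y) = 255 by construction.

Rendering: composite lifetime images combine intensity (brightness) and
lifetime (hue, blue = short to red = long) in HSV space.  Lifetime
histograms can be summarized by a least-squares sum-of-Gaussians fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

from .phasor import LifetimeImage

__all__ = [
    "CompositeImage",
    "GaussianMixFit",
    "FitError",
    "psnr",
    "ssim",
    "minmax_8bit",
    "composite_hsv",
    "fit_lifetime_gaussians",
]

_C1 = (0.01 * 255.0) ** 2
_C2 = (0.03 * 255.0) ** 2
_SSIM_WIN = 8


class FitError(RuntimeError):
    """Raised when a histogram fit fails to converge."""


@dataclass
class CompositeImage:
    """HSV-composited lifetime render (RGB channels in [0, 1])."""

    rgb: np.ndarray
    tau_range_ns: tuple[float, float]
    hue_convention: str = "blue(short) -> red(long)"

    def __post_init__(self) -> None:
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb channels must lie in [0, 1]")


@dataclass
class GaussianMixFit:
    """Sum-of-Gaussians fit to a lifetime histogram (ascending means)."""

    n_components: int
    means_ns: np.ndarray
    sigmas_ns: np.ndarray
    weights: np.ndarray
    r_squared: float

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be >= 0 and sum to 1")
        if np.any(self.sigmas_ns <= 0):
            raise ValueError("sigmas must be > 0")


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio of x against reference y, in dB.

    Returns ``inf`` when the images are identical (zero MSE).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(np.max(y))
    return 10.0 * np.log10(peak * peak / mse)


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Structural similarity of two images pre-normalized to 8-bit range.

    8x8 uniform sliding windows (valid positions only), C1 = (0.01*255)^2,
    C2 = (0.03*255)^2; symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.ndim == 3:  # volumes: mean of per-plane scores
        return float(np.mean([ssim(xp, yp) for xp, yp in zip(x, y)]))
    if min(x.shape) < _SSIM_WIN:
        raise ValueError(f"image smaller than the {_SSIM_WIN}x{_SSIM_WIN} window")
    wx = sliding_window_view(x, (_SSIM_WIN, _SSIM_WIN))
    wy = sliding_window_view(y, (_SSIM_WIN, _SSIM_WIN))
    mx = wx.mean(axis=(2, 3))
    my = wy.mean(axis=(2, 3))
    vx = (wx * wx).mean(axis=(2, 3)) - mx * mx
    vy = (wy * wy).mean(axis=(2, 3)) - my * my
    cxy = (wx * wy).mean(axis=(2, 3)) - mx * my
    num = (2 * mx * my + _C1) * (2 * cxy + _C2)
    den = (mx * mx + my * my + _C1) * (vx + vy + _C2)
    return float(np.mean(num / den))


def minmax_8bit(image: np.ndarray) -> np.ndarray:
    """Min-max normalize an image onto integer [0, 255] (round half-up)."""
    image = np.asarray(image, dtype=float)
    lo = image.min()
    hi = image.max()
    if hi == lo:
        raise ValueError("constant image cannot be min-max normalized")
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def composite_hsv(
    intensity: np.ndarray,
    tau: LifetimeImage,
    tau_range_ns: tuple[float, float] = (0.0, 3.0),
    flag_invalid: bool = False,
) -> CompositeImage:
    """HSV composite: brightness = intensity, hue = lifetime (blue -> red).

    The value channel is min-max-normalized intensity; hue maps tau
    clipped to ``tau_range_ns`` linearly from blue (short) to red (long);
    saturation is 1 at valid pixels.  Invalid pixels render black, or at
    full-red hue when ``flag_invalid`` is set.
    """
    lo, hi = tau_range_ns
    if not hi > lo:
        raise ValueError("degenerate tau range")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != tau.tau_ns.shape:
        raise ValueError("shape mismatch")
    rng = intensity.max() - intensity.min()
    value = (intensity - intensity.min()) / rng if rng > 0 else np.zeros_like(intensity)
    frac = np.zeros_like(value)
    np.clip((tau.tau_ns - lo) / (hi - lo), 0.0, 1.0, out=frac, where=tau.valid)
    # hue wheel: 2/3 (blue) at tau_min down to 0 (red) at tau_max
    hue = (2.0 / 3.0) * (1.0 - frac)
    sat = np.ones_like(value)
    if flag_invalid:
        hue[~tau.valid] = 0.0
    else:
        value = np.where(tau.valid, value, 0.0)
    rgb = hsv_to_rgb(np.stack([hue, sat, value], axis=-1))
    return CompositeImage(rgb=rgb, tau_range_ns=(float(lo), float(hi)))


def _gauss_sum(x, *params):
    n = len(params) // 3
    out = np.zeros_like(x)
    for i in range(n):
        a, mu, sig = params[3 * i : 3 * i + 3]
        out = out + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_lifetime_gaussians(
    tau: LifetimeImage,
    n_components: int = 2,
    bins: int = 100,
    seed: int = 0,
) -> GaussianMixFit:
    """Least-squares fit of a sum of Gaussians to the lifetime histogram.

    Initial means sit at evenly spaced percentiles of the valid lifetimes;
    the fit is on the binned histogram (curve fit, not pixel-level EM).
    Components are reported in ascending mean order with weights
    proportional to component area.  Raises :class:`FitError` on
    non-convergence.
    """
    vals = tau.tau_ns[tau.valid]
    if len(vals) < 10 * n_components:
        raise ValueError("need at least 10 valid pixels per component")
    counts, edges = np.histogram(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    span = edges[-1] - edges[0]
    qs = np.linspace(0, 100, n_components + 2)[1:-1]
    mu0 = np.percentile(vals, qs)
    sig0 = max(span / (4.0 * n_components), 1e-6)
    a0 = counts.max() / n_components if counts.max() > 0 else 1.0
    p0 = []
    for mu in mu0:
        p0 += [a0, mu, sig0]
    lower = [0.0, edges[0] - span, 1e-9] * n_components
    upper = [np.inf, edges[-1] + span, 10 * span + 1e-6] * n_components
    try:
        popt, _ = curve_fit(
            _gauss_sum,
            centers,
            counts.astype(float),
            p0=p0,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amps = popt[0::3]
    mus = popt[1::3]
    sigs = np.abs(popt[2::3])
    areas = amps * sigs * np.sqrt(2 * np.pi)
    total = areas.sum()
    weights = areas / total if total > 0 else np.full(n_components, 1.0 / n_components)
    order = np.argsort(mus)
    fitted = _gauss_sum(centers, *popt)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GaussianMixFit(
        n_components=n_components,
        means_ns=mus[order],
        sigmas_ns=sigs[order],
        weights=weights[order],
        r_squared=r2,
    )
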