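"""Denoising of the G and S measurement planes.

Two denoisers are provided, matching common FD-FLIM practice:

* iterative 2-D median filtering (edge-replicating, typically three
  passes — further passes add nothing but runtime), and
* a compact residual CNN in the DnCNN style: a stack of 3x3 convolutions
  with ReLU whose final layer predicts the noise residual, subtracted from
  the input.  It can be trained supervised (noisy -> clean/averaged
  targets) or Noise2Noise (two independent noisy draws of one FOV).

Both operate on single 2-D planes.  CNN inference runs on [0, 1]-scaled
planes; :func:`denoise_gs` wraps each plane in an exactly invertible
min-max scale/unscale pair so the full dynamic range is presented to the
model and the signed G/S units are restored afterwards.

The CNN is implemented directly on numpy (im2col convolutions, Adam,
mean-squared-error loss) and is fully deterministic for a given seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .phasor import FlimMeasurement

__all__ = [
    "DenoiserModel",
    "ScaleParams",
    "median_denoise",
    "range_scale",
    "range_unscale",
    "train_denoiser",
    "apply_denoiser",
    "denoise_gs",
    "median_model",
    "save_model",
    "load_model",
]


@dataclass
class ScaleParams:
    """Min/max of a plane before [0, 1] scaling (needed to invert it)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("hi must be >= lo")


@dataclass
class DenoiserModel:
    """A parameterized denoiser: median settings or trained CNN weights."""

    kind: str
    median_kernel: int = 3
    median_iterations: int = 3
    cnn_depth: int = 5
    cnn_width: int = 16
    weights: list | None = None
    train_seed: int = 0
    training_mode: str = "supervised"

    def __post_init__(self) -> None:
        if self.kind not in ("median", "cnn"):
            raise ValueError("kind must be 'median' or 'cnn'")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if self.kind == "cnn" and self.cnn_depth < 3:
            raise ValueError("cnn_depth must be >= 3")


def median_model(kernel: int = 3, iterations: int = 3) -> DenoiserModel:
    """Convenience constructor for an iterative median-filter model."""
    return DenoiserModel(kind="median", median_kernel=kernel, median_iterations=iterations)


def median_denoise(image: np.ndarray, kernel: int = 3, iterations: int = 1) -> np.ndarray:
    """Apply ``iterations`` sequential passes of the 2-D median filter.

    Edge handling is replication padding; ``iterations=0`` is the identity.
    """
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel must be odd")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = np.asarray(image, dtype=float)
    for _ in range(iterations):
        out = ndimage.median_filter(out, size=kernel, mode="nearest")
    return out


def range_scale(image: np.ndarray) -> tuple[np.ndarray, ScaleParams]:
    """Min-max scale a plane onto [0, 1], returning the inverse parameters."""
    image = np.asarray(image, dtype=float)
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        raise ValueError("constant image has a degenerate range")
    return (image - lo) / (hi - lo), ScaleParams(lo=lo, hi=hi)


def range_unscale(scaled: np.ndarray, params: ScaleParams) -> np.ndarray:
    """Invert :func:`range_scale`: scaled * (hi - lo) + lo."""
    return np.asarray(scaled, dtype=float) * (params.hi - params.lo) + params.lo


# ---------------------------------------------------------------------------
# numpy residual CNN


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*9) patches with edge padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * 9)


def _conv_forward(x, W, b):
    cols = _im2col(x)
    y = cols @ W + b  # (N, H, W, Cout)
    return y.transpose(0, 3, 1, 2), cols


def _conv_backward(d_out, cols, W, x_shape):
    n, c, h, w = x_shape
    cout = W.shape[1]
    d = d_out.transpose(0, 2, 3, 1)  # (N, H, W, Cout)
    dW = cols.reshape(-1, W.shape[0]).T @ d.reshape(-1, cout)
    db = d.sum(axis=(0, 1, 2))
    dcols = (d @ W.T).reshape(n, h, w, c, 3, 3)
    # scatter back onto the padded grid, then fold pad rows/cols onto edges
    dxp = np.zeros((n, c, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    dx = dxp[:, :, 1:-1, 1:-1].copy()
    dx[:, :, 0, :] += dxp[:, :, 0, 1:-1]
    dx[:, :, -1, :] += dxp[:, :, -1, 1:-1]
    dx[:, :, :, 0] += dxp[:, :, 1:-1, 0]
    dx[:, :, :, -1] += dxp[:, :, 1:-1, -1]
    dx[:, :, 0, 0] += dxp[:, :, 0, 0]
    dx[:, :, 0, -1] += dxp[:, :, 0, -1]
    dx[:, :, -1, 0] += dxp[:, :, -1, 0]
    dx[:, :, -1, -1] += dxp[:, :, -1, -1]
    return dx, dW, db


def _init_weights(depth: int, width: int, rng: np.random.Generator) -> list:
    """He-normal initialization for [1 -> width -> ... -> width -> 1]."""
    chans = [1] + [width] * (depth - 1) + [1]
    weights = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        fan_in = cin * 9
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        weights.append([W, np.zeros(cout)])
    return weights


def _forward(x: np.ndarray, weights: list, keep_cache: bool = False):
    """Residual forward pass: returns (output, cache). Output = x - residual."""
    a = x
    cache = []
    for li, (W, b) in enumerate(weights):
        z, cols = _conv_forward(a, W, b)
        last = li == len(weights) - 1
        nxt = z if last else np.maximum(z, 0.0)
        if keep_cache:
            cache.append((a.shape, cols, None if last else (z > 0)))
        a = nxt
    return x - a, cache


def _train_step(x, target, weights, lr_state):
    """One Adam step on MSE(output, target); returns the loss."""
    out, cache = _forward(x, weights, keep_cache=True)
    n_elem = out.size
    diff = out - target
    loss = float(np.mean(diff**2))
    # d loss / d residual = -d loss / d out
    d = -(2.0 / n_elem) * diff
    grads = [None] * len(weights)
    for li in range(len(weights) - 1, -1, -1):
        x_shape, cols, relu_mask = cache[li]
        if relu_mask is not None:
            d = d * relu_mask
        d, dW, db = _conv_backward(d, cols, weights[li][0], x_shape)
        grads[li] = (dW, db)
    # Adam update
    t, ms, vs, lr = lr_state["t"] + 1, lr_state["m"], lr_state["v"], lr_state["lr"]
    b1, b2, eps = 0.9, 0.999, 1e-8
    for li, (dW, db) in enumerate(grads):
        for pi, g in enumerate((dW, db)):
            ms[li][pi] = b1 * ms[li][pi] + (1 - b1) * g
            vs[li][pi] = b2 * vs[li][pi] + (1 - b2) * g * g
            mhat = ms[li][pi] / (1 - b1**t)
            vhat = vs[li][pi] / (1 - b2**t)
            weights[li][pi] -= lr * mhat / (np.sqrt(vhat) + eps)
    lr_state["t"] = t
    return loss


def train_denoiser(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    mode: str = "supervised",
    depth: int = 5,
    width: int = 16,
    epochs: int = 15,
    seed: int = 0,
    batch_size: int = 16,
    lr: float = 1e-3,
) -> DenoiserModel:
    """Train the residual CNN on (input, target) plane pairs.

    All planes must already be scaled to [0, 1] (values outside a small
    tolerance are an error) and share one shape.  ``mode`` records whether
    targets are clean/averaged (supervised) or independent noisy draws
    (noise2noise); the optimization itself is identical.  Deterministic for
    a given seed.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if mode not in ("supervised", "noise2noise"):
        raise ValueError(f"unknown training mode {mode!r}")
    xs = np.stack([np.asarray(p[0], dtype=float) for p in pairs])[:, None]
    ys = np.stack([np.asarray(p[1], dtype=float) for p in pairs])[:, None]
    for name, arr in (("input", xs), ("target", ys)):
        if arr.min() < -0.05 or arr.max() > 1.05:
            raise ValueError(f"{name} planes must be scaled to [0, 1]")
    rng = np.random.default_rng(seed)
    weights = _init_weights(depth, width, rng)
    lr_state = {
        "t": 0,
        "lr": lr,
        "m": [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights],
        "v": [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights],
    }
    n = len(xs)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            _train_step(xs[idx], ys[idx], weights, lr_state)
    return DenoiserModel(
        kind="cnn",
        cnn_depth=depth,
        cnn_width=width,
        weights=weights,
        train_seed=seed,
        training_mode=mode,
    )


def apply_denoiser(image: np.ndarray, model: DenoiserModel) -> np.ndarray:
    """Run a denoiser on a single 2-D plane.

    Median models dispatch to :func:`median_denoise`.  CNN models expect a
    [0, 1]-scaled plane and return input minus the predicted residual;
    being fully convolutional they accept any plane size.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("apply_denoiser operates on single 2-D planes")
    if model.kind == "median":
        return median_denoise(image, model.median_kernel, model.median_iterations)
    if model.weights is None:
        raise ValueError("cnn model has no trained weights")
    out, _ = _forward(image[None, None], model.weights)
    return out[0, 0]


def denoise_gs(meas: FlimMeasurement, model: DenoiserModel) -> FlimMeasurement:
    """Denoise the G and S planes of a measurement independently.

    Each plane runs through range_scale -> apply_denoiser -> range_unscale
    with its own ScaleParams; intensity passes through unchanged.  3-D
    stacks are processed plane by plane.
    """

    def one_plane(plane: np.ndarray) -> np.ndarray:
        if model.kind == "median":
            # median commutes with affine maps; skip degenerate-range errors
            return apply_denoiser(plane, model)
        scaled, params = range_scale(plane)
        return range_unscale(apply_denoiser(scaled, model), params)

    def process(arr: np.ndarray) -> np.ndarray:
        if arr.ndim == 2:
            return one_plane(arr)
        return np.stack([one_plane(p) for p in arr])

    return FlimMeasurement(
        g=process(meas.g),
        s=process(meas.s),
        intensity=meas.intensity.copy(),
        f_mod_hz=meas.f_mod_hz,
    )


def save_model(model: DenoiserModel, path: str | os.PathLike) -> None:
    """Save a model as an .npz weight blob plus a YAML sidecar."""
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path += ".npz"
    meta = {
        "kind": model.kind,
        "median_kernel": model.median_kernel,
        "median_iterations": model.median_iterations,
        "cnn_depth": model.cnn_depth,
        "cnn_width": model.cnn_width,
        "train_seed": model.train_seed,
        "training_mode": model.training_mode,
    }
    arrays = {}
    if model.weights is not None:
        for li, (W, b) in enumerate(model.weights):
            arrays[f"W{li}"] = W
            arrays[f"b{li}"] = b
    np.savez(path, **arrays)
    with open(path[:-4] + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_model(path: str | os.PathLike) -> DenoiserModel:
    """Load a model saved by :func:`save_model`."""
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path[:-4] + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    data = np.load(path)
    weights = None
    n_layers = sum(1 for k in data.files if k.startswith("W"))
    if n_layers:
        weights = [[data[f"W{li}"], data[f"b{li}"]] for li in range(n_layers)]
    return DenoiserModel(weights=weights, **meta)
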