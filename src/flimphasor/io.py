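"""Image-stack and run-configuration I/O.

All measured data travels as multi-page grayscale TIFF (one page per Z
plane); rendered RGB output is PNG.  Axis order is fixed as (Z, Y, X) with
0-based pixel coordinates; the Z axis is omitted for single planes.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for malformed or invariant-violating run configuration."""


@dataclass
class ImageStack:
    """A 2-D plane or 3-D volume of real-valued pixels.

    Attributes
    ----------
    pixels : ndarray
        2-D ``(Y, X)`` or 3-D ``(Z, Y, X)`` array of finite reals.
    axes : tuple of str
        Ordered axis labels, always ending in ``("Y", "X")``.
    pixel_size_um, plane_depth_um : float, optional
        Physical pixel width and Z step in micrometres.
    """

    pixels: np.ndarray
    axes: tuple[str, ...] = ("Y", "X")
    pixel_size_um: float | None = None
    plane_depth_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixels, got {self.pixels.ndim}-D")
        self.axes = tuple(self.axes)
        expected = ("Y", "X") if self.pixels.ndim == 2 else ("Z", "Y", "X")
        if self.axes != expected:
            raise ValueError(f"axes {self.axes} do not match shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if min(self.pixels.shape) < 1:
            raise ValueError("all axis lengths must be >= 1")

    @property
    def n_planes(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def planes(self):
        """Iterate over 2-D Z planes (a single plane for 2-D stacks)."""
        if self.pixels.ndim == 2:
            yield self.pixels
        else:
            yield from self.pixels


# Defaults: 80 MHz modulation (the instant-FLIM laser repetition rate),
# median x3 denoising, K=3 clusters, 0-3 ns display range.
_CONFIG_DEFAULTS = dict(
    f_mod_hz=8.0e7,
    denoiser="median",
    median_iterations=3,
    kmeans_k=3,
    seed=0,
    tau_display_range_ns=(0.0, 3.0),
    intensity_threshold=0.05,
)

_DENOISERS = ("median", "cnn", "none")


@dataclass
class RunConfig:
    """Pipeline run settings (flat key-value config file on disk)."""

    f_mod_hz: float = _CONFIG_DEFAULTS["f_mod_hz"]
    denoiser: str = "median"
    median_iterations: int = 3
    kmeans_k: int = 3
    seed: int = 0
    tau_display_range_ns: tuple[float, float] = (0.0, 3.0)
    intensity_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.f_mod_hz > 0:
            raise ConfigError("f_mod_hz must be > 0")
        if self.denoiser not in _DENOISERS:
            raise ConfigError(f"denoiser must be one of {_DENOISERS}")
        if self.median_iterations < 0:
            raise ConfigError("median_iterations must be >= 0")
        if self.kmeans_k < 1:
            raise ConfigError("kmeans_k must be >= 1")
        if not (0 <= self.intensity_threshold < 1):
            raise ConfigError("intensity_threshold must be in [0, 1)")
        lo, hi = self.tau_display_range_ns
        if not hi > lo:
            raise ConfigError("tau_display_range_ns must be an increasing pair")
        self.tau_display_range_ns = (float(lo), float(hi))


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    The Z length equals the page count; the Z axis is omitted for a single
    page.  Sample values are preserved exactly for lossless inputs.
    """
    arr = tifffile.imread(os.fspath(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim == 2:
        return ImageStack(arr, axes=("Y", "X"))
    if arr.ndim == 3:
        return ImageStack(arr, axes=("Z", "Y", "X"))
    raise ValueError(f"unsupported TIFF dimensionality: {arr.shape}")


def write_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write a stack as a multi-page float32 TIFF (one page per Z plane)."""
    path = os.fspath(path)
    data = stack.pixels.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a flat YAML key-value file into a :class:`RunConfig`.

    Unspecified keys take their documented defaults; unknown keys are hard
    errors (silent typos in denoiser settings would corrupt comparisons).
    """
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "tau_display_range_ns" in raw:
        raw["tau_display_range_ns"] = tuple(raw["tau_display_range_ns"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
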