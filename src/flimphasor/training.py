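"""Patch extraction and end-to-end CNN training from simulated scenes.

Training data are 2-D patches cut from the G and S planes of simulated
noisy/target measurement pairs.  Each patch pair is min-max scaled to
[0, 1] with parameters shared between input and target (the joint range),
so the residual the network learns is expressed in the same normalized
units the inference wrapper (:func:`flimphasor.denoise.denoise_gs`)
presents at run time.
"""

from __future__ import annotations

import numpy as np

from .denoise import DenoiserModel, train_denoiser
from .phasor import FlimMeasurement
from .simulate import NoiseParams, generate_scene, make_pair_set

__all__ = ["extract_patch_pairs", "train_cnn_on_scene"]


def extract_patch_pairs(
    pairs: list[tuple[FlimMeasurement, FlimMeasurement]],
    n_patches: int,
    patch_size: int = 40,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut [0, 1]-scaled patch pairs from the G and S planes of pair sets.

    Patch locations are drawn uniformly (seeded); the G and S planes of
    each measurement pair are sampled alternately so one model sees both
    axes.  Constant-range patches are skipped.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    planes = []
    for noisy, target in pairs:
        planes.append((np.atleast_2d(noisy.g), np.atleast_2d(target.g)))
        planes.append((np.atleast_2d(noisy.s), np.atleast_2d(target.s)))
    attempts = 0
    while len(out) < n_patches and attempts < 50 * n_patches:
        attempts += 1
        x_full, y_full = planes[rng.integers(len(planes))]
        if x_full.ndim == 3:  # volume: pick a plane
            z = rng.integers(x_full.shape[0])
            x_full, y_full = x_full[z], y_full[z]
        h, w = x_full.shape
        if h < patch_size or w < patch_size:
            raise ValueError("plane smaller than patch_size")
        i = rng.integers(h - patch_size + 1)
        j = rng.integers(w - patch_size + 1)
        xp = x_full[i : i + patch_size, j : j + patch_size]
        yp = y_full[i : i + patch_size, j : j + patch_size]
        lo = min(xp.min(), yp.min())
        hi = max(xp.max(), yp.max())
        if hi == lo:
            continue
        out.append(((xp - lo) / (hi - lo), (yp - lo) / (hi - lo)))
    if len(out) < n_patches:
        raise ValueError("could not extract enough non-degenerate patches")
    return out


def train_cnn_on_scene(
    scene_spec: dict,
    mode: str = "supervised",
    noise: NoiseParams | None = None,
    f_mod_hz: float = 8.0e7,
    n_pairs: int = 4,
    n_patches: int = 200,
    patch_size: int = 40,
    depth: int = 5,
    width: int = 16,
    epochs: int = 15,
    seed: int = 0,
) -> DenoiserModel:
    """Simulate a scene, build patch pairs, and train the residual CNN.

    ``mode`` selects supervised (noiseless targets) or noise2noise
    (independent noisy targets) pairing.  Fully deterministic given
    ``seed``.
    """
    if noise is None:
        noise = NoiseParams(seed=seed)
    scene = generate_scene(scene_spec, seed=seed)
    pairs = make_pair_set(
        scene, noise, n_pairs=n_pairs, f_mod_hz=f_mod_hz, mode=mode, seed=seed
    )
    patches = extract_patch_pairs(pairs, n_patches, patch_size, seed=seed)
    return train_denoiser(
        patches, mode=mode, depth=depth, width=width, epochs=epochs, seed=seed
    )
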