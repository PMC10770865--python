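"""Standard synthetic evaluation protocol for denoiser/segmentation claims.

The evaluation scene is a 256x256 two-fluorophore field (3 ns background
with 1 ns disks, both at the default 100-photon modulated amplitude) read
out at 80 MHz under the default mixed Poisson-Gaussian noise.  Denoising
quality is the PSNR of the lifetime image against the ground-truth
lifetime map, both clipped to the scene's (0, 4) ns display range and
min-max normalized to 8 bits; segmentation quality is K=2 phasor K-means
accuracy against the truth labels.  The CNN used here is trained on a
BPAE-like scene, held out from the evaluation scene.
"""

from __future__ import annotations

import numpy as np

from .denoise import DenoiserModel, denoise_gs
from .phasor import LifetimeImage, compute_gs, lifetime_from_gs, phasor_fd
from .pipeline import _metric_pair
from .segment import kmeans_phasor, labels_to_image, segmentation_accuracy
from .simulate import (
    NoiseParams,
    add_mpg_noise,
    bpae_like_spec,
    generate_scene,
    simulate_fd_phases,
    two_fluorophore_spec,
)
from .training import train_cnn_on_scene

__all__ = [
    "EVAL_CLIP_NS",
    "EVAL_F_MOD_HZ",
    "evaluation_scene",
    "train_default_cnn",
    "denoising_psnr_gain",
    "segmentation_accuracy_pair",
]

#: Display range (ns) used for the evaluation scene's metric protocol.
EVAL_CLIP_NS = (0.0, 4.0)
EVAL_F_MOD_HZ = 8.0e7


def evaluation_scene(shape: tuple[int, int] = (256, 256)):
    """The two-fluorophore evaluation scene and its noiseless phase stack."""
    scene = generate_scene(two_fluorophore_spec(shape=shape), seed=0)
    phases = simulate_fd_phases(scene, EVAL_F_MOD_HZ)
    reference = LifetimeImage(
        tau_ns=np.where(scene.label > 0, scene.tau_ns, np.nan),
        valid=scene.label > 0,
    )
    return scene, phases, reference


def train_default_cnn(seed: int = 123) -> DenoiserModel:
    """Train the default residual CNN on a held-out BPAE-like scene."""
    return train_cnn_on_scene(bpae_like_spec(), seed=seed)


def _noisy_measurement(phases, seed: int):
    return compute_gs(add_mpg_noise(phases, NoiseParams(seed=seed)))


def denoising_psnr_gain(
    model: DenoiserModel, seeds, scene_shape: tuple[int, int] = (256, 256)
) -> list[tuple[float, float]]:
    """(noisy PSNR, denoised PSNR) per noise seed on the evaluation scene."""
    _, phases, reference = evaluation_scene(scene_shape)
    out = []
    for seed in seeds:
        meas = _noisy_measurement(phases, seed)
        den = denoise_gs(meas, model)
        p_noisy, _ = _metric_pair(lifetime_from_gs(meas), reference, EVAL_CLIP_NS)
        p_den, _ = _metric_pair(lifetime_from_gs(den), reference, EVAL_CLIP_NS)
        out.append((p_noisy, p_den))
    return out


def segmentation_accuracy_pair(
    model: DenoiserModel, seed: int, scene_shape: tuple[int, int] = (256, 256)
) -> tuple[float, float]:
    """(noisy, denoised) K=2 segmentation accuracy for one noise seed."""
    scene, phases, _ = evaluation_scene(scene_shape)
    meas = _noisy_measurement(phases, seed)
    den = denoise_gs(meas, model)
    accs = []
    for m in (meas, den):
        cloud = phasor_fd(m)
        seg = kmeans_phasor(cloud, 2, seed=seed)
        labels = labels_to_image(seg, cloud, m.g.shape)
        accs.append(segmentation_accuracy(labels, scene.label))
    return accs[0], accs[1]
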