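"""Synthetic FD-FLIM scene and measurement generator.

Emulates the four-phase homodyne readout of an instant-FLIM instrument:
each pixel's fluorophore contributes a modulated signal

    V_IF(theta) = B + A * m * sin(theta + phi),

with m = 1/sqrt(1 + (w*tau)^2), phi = arctan(w*tau), w = 2*pi*f_mod, read
at theta in {0, pi/2, pi, 3*pi/2}.  With this mixer convention the
complementary-phase differences give S/G = tan(phi) = w*tau, so the
noiseless pipeline recovers mono-exponential lifetimes exactly.

Noise is mixed Poisson-Gaussian: photon shot noise on each phase channel
independently (which makes the G and S differences Skellam-distributed)
plus additive Gaussian read noise.  A TCSPC decay simulator is included
for time-domain phasor testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasor import FlimMeasurement, compute_gs

__all__ = [
    "SceneTruth",
    "PhaseStack",
    "NoiseParams",
    "TcspcStack",
    "PHASE_ANGLES",
    "generate_scene",
    "simulate_fd_phases",
    "add_mpg_noise",
    "simulate_tcspc",
    "make_pair_set",
    "scene_apparent_tau",
    "two_fluorophore_spec",
    "bpae_like_spec",
    "plant_like_spec",
    "DEFAULT_AMPLITUDE",
    "DEFAULT_NOISE",
]

#: Mixer phase angles, fixed order.
PHASE_ANGLES = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)

#: Default modulated amplitude (photon-equivalents) for synthetic scenes —
#: a realistic per-pixel photon budget for two-photon FD-FLIM at low power.
DEFAULT_AMPLITUDE = 100.0


@dataclass
class SceneTruth:
    """Ground-truth lifetime/amplitude/label maps of a synthetic scene.

    ``tau_ns`` holds the mono-exponential lifetime per pixel.  Bi-exponential
    regions are described in ``components`` (label -> [(tau_ns, fraction)]);
    for those pixels ``tau_ns`` stores the first component and truth
    comparison is done in phasor space (see :func:`scene_apparent_tau`).
    """

    tau_ns: np.ndarray
    amplitude: np.ndarray
    label: np.ndarray
    components: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_ns = np.asarray(self.tau_ns, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if not (self.tau_ns.shape == self.amplitude.shape == self.label.shape):
            raise ValueError("tau_ns, amplitude and label must share one shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be >= 0")
        fg = self.label > 0
        if np.any(self.tau_ns[fg] <= 0):
            raise ValueError("tau_ns must be > 0 wherever label > 0")
        for lab, comps in self.components.items():
            tot = sum(f for _, f in comps)
            if not np.isclose(tot, 1.0):
                raise ValueError(f"fractions of label {lab} sum to {tot}, not 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tau_ns.shape


@dataclass
class PhaseStack:
    """The four V_IF(phase) mixer images (leading axis of length 4)."""

    v_if: np.ndarray
    f_mod_hz: float

    def __post_init__(self) -> None:
        self.v_if = np.asarray(self.v_if, dtype=float)
        if self.v_if.shape[0] != 4:
            raise ValueError("v_if must have a leading axis of length 4")
        if not self.f_mod_hz > 0:
            raise ValueError("f_mod_hz must be > 0")

    @property
    def image_shape(self) -> tuple[int, ...]:
        return self.v_if.shape[1:]


@dataclass
class NoiseParams:
    """Mixed Poisson-Gaussian noise settings.

    ``photon_gain`` converts volts to detected photons for the Poisson
    channel; ``read_sigma`` is the additive Gaussian read-noise s.d. in the
    same units as the phase images.
    """

    photon_gain: float = 1.0
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.photon_gain > 0:
            raise ValueError("photon_gain must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


#: Default noise conditions for synthetic evaluations.
DEFAULT_NOISE = NoiseParams(photon_gain=1.0, read_sigma=2.0, seed=0)


@dataclass
class TcspcStack:
    """Per-pixel TCSPC decay histograms (last axis = time bins)."""

    counts: np.ndarray
    bin_width_ns: float
    n_bins: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[-1] != self.n_bins:
            raise ValueError("last axis of counts must equal n_bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


# ---------------------------------------------------------------------------
# scene generation


def _region_mask(kind: str, region: dict, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    if kind == "full":
        return np.ones(shape, dtype=bool)
    if kind == "disk":
        cy, cx = region["center"]
        r = float(region["radius"])
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    if kind == "ellipse":
        cy, cx = region["center"]
        ry, rx = region["axes"]
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if kind == "rect":
        y0, x0 = region["corner"]
        h, w = region["size"]
        return (yy >= y0) & (yy < y0 + h) & (xx >= x0) & (xx < x0 + w)
    raise ValueError(f"unknown region kind {kind!r}")


def generate_scene(spec: dict, seed: int = 0) -> SceneTruth:
    """Build a :class:`SceneTruth` from a declarative scene description.

    ``spec`` is ``{"shape": (Y, X) or (Z, Y, X), "regions": [...]}``.  Each
    region is a dict with ``kind`` (full/disk/ellipse/rect plus geometry
    keys), ``amplitude``, and either ``tau_ns`` (scalar, or a ``(lo, hi)``
    pair drawn as a per-pixel texture field) or ``components``
    ``[(tau_ns, fraction), ...]`` for bi-exponential pixels.  Regions are
    painted in order; overlaps are resolved last-wins.  Deterministic for a
    given (spec, seed): geometry never depends on the seed, only texture
    draws do.
    """
    if not spec.get("regions"):
        raise ValueError("scene spec has no regions")
    shape = tuple(spec["shape"])
    plane_shape = shape[-2:]
    n_planes = shape[0] if len(shape) == 3 else 1
    rng = np.random.default_rng(seed)

    tau = np.zeros(shape)
    amp = np.zeros(shape)
    lab = np.zeros(shape, dtype=int)
    components: dict[int, list[tuple[float, float]]] = {}

    for i, region in enumerate(spec["regions"]):
        label = int(region.get("label", i + 1))
        mask2d = _region_mask(region.get("kind", "full"), region, plane_shape)
        mask = np.broadcast_to(mask2d, shape) if len(shape) == 3 else mask2d
        amplitude = float(region.get("amplitude", DEFAULT_AMPLITUDE))
        if "components" in region:
            comps = [(float(t), float(f)) for t, f in region["components"]]
            if any(t <= 0 for t, _ in comps):
                raise ValueError("component lifetimes must be > 0")
            components[label] = comps
            tau_vals = comps[0][0]
        else:
            t = region["tau_ns"]
            if np.ndim(t) == 0:
                if t <= 0:
                    raise ValueError("region tau_ns must be > 0")
                tau_vals = float(t)
            else:
                lo, hi = float(t[0]), float(t[1])
                if lo <= 0 or hi < lo:
                    raise ValueError("texture tau range must be 0 < lo <= hi")
                tau_vals = rng.uniform(lo, hi, size=int(mask.sum()))
        if np.ndim(tau_vals) == 0:
            tau[mask] = tau_vals
        else:
            tau[mask] = tau_vals
        amp[mask] = amplitude
        lab[mask] = label
    # drop components of labels fully painted over
    components = {k: v for k, v in components.items() if np.any(lab == k)}
    del n_planes
    return SceneTruth(tau_ns=tau, amplitude=amp, label=lab, components=components)


def two_fluorophore_spec(
    shape: tuple[int, int] = (256, 256),
    tau_a_ns: float = 3.0,
    tau_b_ns: float = 1.0,
    amplitude: float = DEFAULT_AMPLITUDE,
    n_disks: int = 6,
) -> dict:
    """Two-fluorophore test scene: a tau_a field with tau_b disks.

    Every pixel is fluorescent (labels 1 and 2), so segmentation accuracy
    is measurable over the full frame.  Disk placement is a fixed lattice —
    geometry is part of the scene description, not a random draw.
    """
    h, w = shape
    regions: list[dict] = [
        {"kind": "full", "tau_ns": tau_a_ns, "amplitude": amplitude, "label": 1}
    ]
    side = int(np.ceil(np.sqrt(n_disks)))
    r = min(h, w) / (4 * side)
    k = 0
    for i in range(side):
        for j in range(side):
            if k >= n_disks:
                break
            cy = (i + 0.5) * h / side
            cx = (j + 0.5) * w / side
            regions.append(
                {
                    "kind": "disk",
                    "center": (cy, cx),
                    "radius": r * (1.0 + 0.5 * ((i + j) % 2)),
                    "tau_ns": tau_b_ns,
                    "amplitude": amplitude,
                    "label": 2,
                }
            )
            k += 1
    return {"shape": shape, "regions": regions}


def bpae_like_spec(shape: tuple[int, int] = (256, 256), amplitude: float = DEFAULT_AMPLITUDE) -> dict:
    """Synthetic stand-in for a fixed BPAE cell field.

    Three labelled structures with the lifetime ranges reported for the
    real stains: mitochondria 1.5-2 ns, nuclei 2-2.8 ns, F-actin > 2.8 ns.
    Lifetimes inside each structure are textured (uniform in range).
    """
    h, w = shape
    regions: list[dict] = [
        # F-actin background mesh: whole frame, tau > 2.8 ns
        {"kind": "full", "tau_ns": (2.8, 3.4), "amplitude": 0.6 * amplitude, "label": 3},
    ]
    # mitochondria: small ellipses scattered on a lattice
    for i in range(4):
        for j in range(4):
            cy = (i + 0.5) * h / 4 + (7 if (i + j) % 2 else -5)
            cx = (j + 0.5) * w / 4 + (-6 if j % 2 else 8)
            regions.append(
                {
                    "kind": "ellipse",
                    "center": (cy, cx),
                    "axes": (h / 28, w / 14),
                    "tau_ns": (1.5, 2.0),
                    "amplitude": amplitude,
                    "label": 1,
                }
            )
    # two nuclei: large disks, tau 2-2.8 ns
    for cy, cx in ((0.32 * h, 0.30 * w), (0.68 * h, 0.72 * w)):
        regions.append(
            {
                "kind": "disk",
                "center": (cy, cx),
                "radius": min(h, w) / 7,
                "tau_ns": (2.0, 2.8),
                "amplitude": 0.9 * amplitude,
                "label": 2,
            }
        )
    return {"shape": shape, "regions": regions}


def plant_like_spec(shape: tuple[int, int] = (256, 256), amplitude: float = DEFAULT_AMPLITUDE) -> dict:
    """Synthetic leaf mesophyll: chlorophyll ~0.6 ns, cytosol ~0.9 ns."""
    h, w = shape
    regions: list[dict] = [
        {"kind": "full", "tau_ns": (0.75, 1.0), "amplitude": 0.8 * amplitude, "label": 2}
    ]
    for i in range(3):
        for j in range(3):
            regions.append(
                {
                    "kind": "disk",
                    "center": ((i + 0.5) * h / 3, (j + 0.5) * w / 3),
                    "radius": min(h, w) / 9,
                    "tau_ns": (0.45, 0.75),
                    "amplitude": amplitude,
                    "label": 1,
                }
            )
    return {"shape": shape, "regions": regions}


# ---------------------------------------------------------------------------
# forward models


def _scene_complex_signal(scene: SceneTruth, omega: float) -> np.ndarray:
    """Per-pixel complex modulated signal A*m*exp(i*phi) (volts)."""
    z = np.zeros(scene.shape, dtype=complex)
    mono = scene.label > 0
    for lab, comps in scene.components.items():
        mono &= scene.label != lab
    wt = omega * scene.tau_ns * 1e-9
    m = 1.0 / np.sqrt(1.0 + wt * wt)
    phi = np.arctan(wt)
    z[mono] = (scene.amplitude * m * np.exp(1j * phi))[mono]
    for lab, comps in scene.components.items():
        sel = scene.label == lab
        zc = 0.0
        for tau_ns, frac in comps:
            wtc = omega * tau_ns * 1e-9
            mc = 1.0 / np.sqrt(1.0 + wtc * wtc)
            zc = zc + frac * mc * np.exp(1j * np.arctan(wtc))
        z[sel] = scene.amplitude[sel] * zc
    return z


def scene_apparent_tau(scene: SceneTruth, f_mod_hz: float) -> np.ndarray:
    """Phase-apparent lifetime map (ns): tan(phi)/omega of the summed signal.

    Equals ``tau_ns`` exactly for mono-exponential pixels; for mixtures it
    is the single lifetime the phase readout reports.
    """
    omega = 2.0 * np.pi * f_mod_hz
    z = _scene_complex_signal(scene, omega)
    tau = np.zeros(scene.shape)
    fg = scene.label > 0
    tau[fg] = np.tan(np.angle(z[fg])) / omega * 1e9
    return tau


def simulate_fd_phases(
    scene: SceneTruth, f_mod_hz: float = 8.0e7, dc_offset: float | None = None
) -> PhaseStack:
    """Noiseless four-phase homodyne readout of a scene.

    Default DC offset is 5x the largest modulated amplitude, guaranteeing
    non-negative Poisson rates after noise is added (physical PMT signals
    are non-negative).
    """
    if not f_mod_hz > 0:
        raise ValueError("f_mod_hz must be > 0")
    omega = 2.0 * np.pi * f_mod_hz
    z = _scene_complex_signal(scene, omega)
    if dc_offset is None:
        dc_offset = 5.0 * float(np.max(np.abs(z))) if np.any(np.abs(z) > 0) else 1.0
    # V(theta) = B + Im(z * exp(i*theta)) = B + A*m*sin(theta + phi)
    v = np.stack(
        [dc_offset + (z * np.exp(1j * theta)).imag for theta in PHASE_ANGLES]
    )
    return PhaseStack(v_if=v, f_mod_hz=f_mod_hz)


def add_mpg_noise(phases: PhaseStack, noise: NoiseParams) -> PhaseStack:
    """Apply mixed Poisson-Gaussian noise to each phase channel.

    Each sample v becomes ``gain * Poisson(v / gain) + N(0, sigma^2)``,
    drawn independently per channel (which is what makes the G and S
    differences Skellam-distributed).  Deterministic given ``noise.seed``.
    """
    rates = phases.v_if / noise.photon_gain
    if np.any(rates < 0):
        raise ValueError("negative expected photon count; raise dc_offset")
    rng = np.random.default_rng(noise.seed)
    v = noise.photon_gain * rng.poisson(rates).astype(float)
    if noise.read_sigma > 0:
        v += rng.normal(0.0, noise.read_sigma, size=v.shape)
    return PhaseStack(v_if=v, f_mod_hz=phases.f_mod_hz)


def simulate_tcspc(
    scene: SceneTruth,
    bin_width_ns: float,
    n_bins: int,
    photons_per_pixel: float | None = None,
    seed: int = 0,
) -> TcspcStack:
    """Per-pixel TCSPC decay histograms for a scene.

    Noiseless mode (``photons_per_pixel`` None or inf): counts proportional
    to exp(-t/tau) at bin centres, scaled by pixel amplitude.  Noisy mode:
    independent Poisson draws per bin with the pixel's expected total.
    The time span must cover at least 5x the longest simulated lifetime.
    """
    fg = scene.label > 0
    max_tau = float(scene.tau_ns[fg].max()) if np.any(fg) else 0.0
    for comps in scene.components.values():
        max_tau = max(max_tau, max(t for t, _ in comps))
    if n_bins * bin_width_ns < 5.0 * max_tau:
        raise ValueError("bin span must cover >= 5x the longest lifetime")
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    shape = scene.shape
    expected = np.zeros(shape + (n_bins,))
    mono = fg.copy()
    for lab in scene.components:
        mono &= scene.label != lab
    if np.any(mono):
        decays = np.exp(-t[None, :] / scene.tau_ns[mono][:, None])
        expected[mono] = scene.amplitude[mono][:, None] * decays
    for lab, comps in scene.components.items():
        sel = scene.label == lab
        mix = sum(f * np.exp(-t / tau) for tau, f in comps)
        expected[sel] = scene.amplitude[sel][:, None] * mix[None, :]
    if photons_per_pixel is None or np.isinf(photons_per_pixel):
        return TcspcStack(counts=expected, bin_width_ns=bin_width_ns, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    totals = expected.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        rates = np.where(totals > 0, expected / totals * photons_per_pixel, 0.0)
    counts = rng.poisson(rates).astype(float)
    return TcspcStack(counts=counts, bin_width_ns=bin_width_ns, n_bins=n_bins)


# ---------------------------------------------------------------------------
# training pairs


def make_pair_set(
    scene: SceneTruth,
    noise: NoiseParams,
    n_pairs: int,
    f_mod_hz: float = 8.0e7,
    mode: str = "supervised",
    seed: int = 0,
    n_average: int = 5,
) -> list[tuple[FlimMeasurement, FlimMeasurement]]:
    """Build denoiser training pairs from a scene.

    ``supervised``: each noisy draw paired with the noiseless G/S.
    ``noise2noise``: two independent noisy draws of the same field of view.
    ``averaged``: noisy draw paired with the mean of ``n_average``
    independent draws (mirrors repeated-acquisition averaging of one FOV).
    Deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if mode not in ("supervised", "noise2noise", "averaged"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("noise2noise", "averaged") and n_average < 2:
        raise ValueError("averaged/noise2noise modes need n_average >= 2")
    clean_phases = simulate_fd_phases(scene, f_mod_hz)
    clean = compute_gs(clean_phases)
    ss = np.random.SeedSequence(seed)
    pairs: list[tuple[FlimMeasurement, FlimMeasurement]] = []

    def draw(child_seed: int) -> FlimMeasurement:
        params = NoiseParams(noise.photon_gain, noise.read_sigma, seed=child_seed)
        return compute_gs(add_mpg_noise(clean_phases, params))

    for child in ss.spawn(n_pairs):
        seeds = child.generate_state(1 + n_average) % (2**31)
        noisy = draw(int(seeds[0]))
        if mode == "supervised":
            target = clean
        elif mode == "noise2noise":
            target = draw(int(seeds[1]))
        else:
            draws = [draw(int(s)) for s in seeds[1 : 1 + n_average]]
            target = FlimMeasurement(
                g=np.mean([d.g for d in draws], axis=0),
                s=np.mean([d.s for d in draws], axis=0),
                intensity=np.mean([d.intensity for d in draws], axis=0),
                f_mod_hz=f_mod_hz,
            )
        pairs.append((noisy, target))
    return pairs
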