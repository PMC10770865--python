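"""Phasor analysis for frequency- and time-domain FLIM.

The frequency-domain measurement delivers two signed planes formed from
complementary mixer-phase differences,

    S = V_IF(0) - V_IF(pi),    G = V_IF(pi/2) - V_IF(3*pi/2),

and the (uncalibrated) lifetime tau = S / (omega * G) with
omega = 2*pi*f_mod.  A pixel's phasor is g = m cos(phi), s = m sin(phi)
where phi and m are the phase shift and modulation degree of the emission;
mono-exponential decays live on the universal semicircle
s^2 + (g - 1/2)^2 = 1/4.  Time-domain (TCSPC) decays map to the same plane
through the normalized cosine/sine transforms of I(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlimMeasurement",
    "LifetimeImage",
    "PhasorCloud",
    "PhasorHistogram",
    "compute_gs",
    "lifetime_from_gs",
    "mono_exp_phasor",
    "phasor_td",
    "phasor_fd",
    "phasor_histogram",
]


@dataclass
class FlimMeasurement:
    """Signed real/imaginary FLIM planes plus intensity and f_mod."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    f_mod_hz: float

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.g.shape == self.s.shape == self.intensity.shape):
            raise ValueError("g, s and intensity must share one shape")
        if not self.f_mod_hz > 0:
            raise ValueError("f_mod_hz must be > 0")

    @property
    def omega(self) -> float:
        """Angular modulation frequency 2*pi*f_mod (rad/s)."""
        return 2.0 * np.pi * self.f_mod_hz


@dataclass
class LifetimeImage:
    """Per-pixel lifetime in ns with a validity mask.

    Invalid pixels carry NaN and are excluded from all statistics.
    """

    tau_ns: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.tau_ns = np.asarray(self.tau_ns, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.tau_ns.shape != self.valid.shape:
            raise ValueError("tau_ns and valid must share one shape")
        if not np.all(np.isfinite(self.tau_ns[self.valid])):
            raise ValueError("tau_ns must be finite wherever valid")

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """The lifetime map with invalid pixels replaced by ``fill``."""
        out = np.where(self.valid, self.tau_ns, fill)
        return out


@dataclass
class PhasorCloud:
    """Per-pixel (g, s) phasor coordinates with pixel back-mapping.

    ``pixel_index`` has one row per entry, giving the (z, y, x) — or (y, x)
    for single planes — pixel of that entry.  ``flagged`` marks entries with
    negative g (left of the semicircle; noise can push pixels there).
    """

    g_coord: np.ndarray
    s_coord: np.ndarray
    m: np.ndarray
    phi: np.ndarray
    pixel_index: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.g_coord)
        for name in ("s_coord", "m", "phi", "flagged"):
            if len(getattr(self, name)) != n:
                raise ValueError("cloud arrays must have equal length")
        if self.pixel_index.shape[0] != n:
            raise ValueError("pixel_index must have one row per entry")

    def __len__(self) -> int:
        return len(self.g_coord)


@dataclass
class PhasorHistogram:
    """2-D binned phasor density over the (g, s) window.

    sum(counts) equals the number of cloud entries binned; ``clipped``
    counts how many entries fell outside the window and were accumulated
    in edge bins.
    """

    counts: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray
    clipped: int = 0


def compute_gs(phases) -> FlimMeasurement:
    """Form S, G and intensity from the four mixer-phase images.

    s = V_IF(0) - V_IF(pi); g = V_IF(pi/2) - V_IF(3*pi/2); intensity is the
    mean of the four phase images (the DC estimate).
    """
    v = np.asarray(phases.v_if, dtype=float)
    s = v[0] - v[2]
    g = v[1] - v[3]
    intensity = v.mean(axis=0)
    return FlimMeasurement(g=g, s=s, intensity=intensity, f_mod_hz=phases.f_mod_hz)


def lifetime_from_gs(meas: FlimMeasurement, intensity_threshold: float = 0.0) -> LifetimeImage:
    """Per-pixel lifetime tau = s / (omega * g) in ns.

    Pixels with |g| below 1e-12 of the plane maximum, or with intensity
    below ``intensity_threshold`` times the intensity maximum, are marked
    invalid (never raised as exceptions).
    """
    omega = meas.omega
    g_eps = 1e-12 * np.max(np.abs(meas.g)) if meas.g.size else 0.0
    valid = np.abs(meas.g) > g_eps
    if intensity_threshold > 0 and meas.intensity.size:
        valid &= meas.intensity >= intensity_threshold * np.max(meas.intensity)
    tau_s = np.full(meas.g.shape, np.nan)
    np.divide(meas.s, omega * meas.g, out=tau_s, where=valid)
    return LifetimeImage(tau_ns=tau_s * 1e9, valid=valid)


def mono_exp_phasor(tau_ns, f_mod_hz: float):
    """Closed-form phasor of a mono-exponential decay.

    g = 1 / (1 + (omega*tau)^2),  s = omega*tau / (1 + (omega*tau)^2);
    tau = 0 maps to (1, 0) and tau -> inf to (0, 0).  Accepts scalars or
    arrays.
    """
    tau_ns = np.asarray(tau_ns, dtype=float)
    if np.any(tau_ns < 0):
        raise ValueError("tau_ns must be >= 0")
    wt = 2.0 * np.pi * f_mod_hz * tau_ns * 1e-9
    with np.errstate(over="ignore"):
        denom = 1.0 + wt * wt
    g = np.where(np.isinf(denom), 0.0, 1.0 / denom)
    s = np.where(np.isinf(denom), 0.0, wt / denom)
    if g.ndim == 0:
        return float(g), float(s)
    return g, s


def _cloud_from_complex(z: np.ndarray, index: np.ndarray) -> PhasorCloud:
    g = z.real
    s = z.imag
    phi = np.arctan2(s, g)
    m = np.abs(z)
    return PhasorCloud(
        g_coord=g, s_coord=s, m=m, phi=phi, pixel_index=index, flagged=g < 0
    )


def phasor_td(decays, f_mod_hz: float) -> PhasorCloud:
    """Phasor of TCSPC decays via bin-centre rectangle-rule integration.

    g_i = int I(t) cos(wt) dt / int I(t) dt and the sine analogue for s_i,
    with w = 2*pi*f_mod.  Zero-count pixels are excluded from the cloud.
    """
    counts = np.asarray(decays.counts, dtype=float)
    n_bins = counts.shape[-1]
    dt_s = decays.bin_width_ns * 1e-9
    t = (np.arange(n_bins) + 0.5) * dt_s
    w = 2.0 * np.pi * f_mod_hz
    total = counts.sum(axis=-1)
    if not np.any(total > 0):
        raise ValueError("all-zero decay stack")
    keep = total > 0
    flat = counts[keep]
    tot = total[keep]
    g = flat @ np.cos(w * t) / tot
    s = flat @ np.sin(w * t) / tot
    index = np.argwhere(keep)
    return _cloud_from_complex(g + 1j * s, index)


def phasor_fd(
    meas: FlimMeasurement,
    intensity_threshold: float = 0.0,
    calibration: tuple[float, FlimMeasurement] | None = None,
) -> PhasorCloud:
    """Phasor cloud of an FD measurement (Eq. g = m cos phi, s = m sin phi).

    The raw instrument scale of G/S is arbitrary, so absolute placement
    needs a reference.  With ``calibration = (tau_ref_ns, ref_meas)`` the
    cloud is rescaled by the single complex factor that moves the
    reference's mean phasor onto ``mono_exp_phasor(tau_ref_ns)``, the
    standard FD-FLIM calibration.  Without calibration only the phase is
    physically meaningful: each pixel is placed at the universal-semicircle
    point with its measured phase (m := |cos phi|), which puts noiseless
    mono-exponential data exactly on the semicircle.
    """
    g_eps = 1e-12 * np.max(np.abs(meas.g)) if meas.g.size else 0.0
    mod = np.hypot(meas.g, meas.s)
    valid = mod > g_eps
    if intensity_threshold > 0 and meas.intensity.size:
        valid &= meas.intensity >= intensity_threshold * np.max(meas.intensity)
    index = np.argwhere(valid)
    z_raw = meas.g[valid] + 1j * meas.s[valid]
    if calibration is not None:
        tau_ref_ns, ref = calibration
        ref_mod = np.hypot(ref.g, ref.s)
        ref_keep = ref_mod > 1e-12 * np.max(ref_mod) if ref_mod.size else ref_mod > 0
        z_ref = np.mean(ref.g[ref_keep] + 1j * ref.s[ref_keep]) if np.any(ref_keep) else 0.0
        if np.abs(z_ref) == 0:
            raise ValueError("calibration reference has zero modulation")
        g_true, s_true = mono_exp_phasor(tau_ref_ns, meas.f_mod_hz)
        z = z_raw * ((g_true + 1j * s_true) / z_ref)
    else:
        phi = np.angle(z_raw)
        m = np.abs(np.cos(phi))
        z = m * np.exp(1j * phi)
    return _cloud_from_complex(z, index)


# Default phasor window: the universal semicircle spans g in [0, 1] and
# s in [0, 1/2]; 0.6 leaves visual headroom above the apex.
PHASOR_WINDOW = ((0.0, 1.0), (0.0, 0.6))


def phasor_histogram(cloud: PhasorCloud, n_bins: int = 128) -> PhasorHistogram:
    """Bin a phasor cloud on the default [0,1]x[0,0.6] (g, s) window.

    Out-of-window entries are clipped into the nearest edge bin and
    reported in the ``clipped`` total, so sum(counts) == len(cloud).
    """
    if len(cloud) == 0:
        raise ValueError("empty phasor cloud")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    (g_lo, g_hi), (s_lo, s_hi) = PHASOR_WINDOW
    g = np.asarray(cloud.g_coord, dtype=float)
    s = np.asarray(cloud.s_coord, dtype=float)
    outside = (g < g_lo) | (g > g_hi) | (s < s_lo) | (s > s_hi)
    gc = np.clip(g, g_lo, g_hi)
    sc = np.clip(s, s_lo, s_hi)
    counts, g_edges, s_edges = np.histogram2d(
        gc, sc, bins=n_bins, range=PHASOR_WINDOW
    )
    return PhasorHistogram(
        counts=counts, g_edges=g_edges, s_edges=s_edges, clipped=int(outside.sum())
    )
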