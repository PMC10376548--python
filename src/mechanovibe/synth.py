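"""Synthetic fixtures with known ground truth for every input modality.

Three generators emulate the measured inputs of a rhythmic-vibration
experiment:

* :func:`make_filament_image` — fluorescence-like images of straight
  filaments (anti-aliased bars, Gaussian PSF blur, additive Gaussian or
  Poisson noise) with a ground-truth table of each filament's length, width
  and angle;
* :func:`make_accel_trace` — three-axis accelerometer traces: the z axis
  carries a schedule-gated sine carrier with optional odd harmonics plus
  noise, x and y carry noise only;
* :func:`make_particle_video` — tracer-particle frame sequences advected in
  an analytic steady two-vortex flow derived from the stream function
  psi(x, y) = Psi sin(2 pi x / W) sin(pi y / H), which has zero normal flow
  at the walls and splits the near-wall flow direction between the left and
  right halves of the chamber.

All generators are deterministic under a fixed seed, and the ground truth
they return is sufficient to score any downstream recovery without hidden
state.  The flow model is the simplest field with the right vortex
topology; it makes no claim of physical fidelity to acoustic streaming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .accel import AccelTrace
from .actin import CalibratedImage
from .ptv import ParticleTracks
from .schedule import PulseSchedule, render_signal

__all__ = [
    "FilamentSceneSpec",
    "FlowSceneSpec",
    "make_filament_image",
    "make_accel_trace",
    "make_particle_video",
    "two_vortex_velocity",
]


@dataclass(frozen=True)
class FilamentSceneSpec:
    """Scene description for a synthetic filament image.

    ``filaments`` lists (center_xy_px, angle_deg, length_um, width_um,
    intensity) tuples; angle follows the analyzer convention (degrees from
    the image x-axis, y up).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.04
    filaments: tuple[tuple[tuple[float, float], float, float, float, float], ...] = ()
    background_level: float = 10.0
    noise_sd: float = 2.0
    psf_sigma_px: float = 1.0
    seed: int = 0
    noise_model: str = "gaussian"  # or "poisson"

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise_sd and psf_sigma_px must be non-negative")
        h, w = self.image_shape
        for (cx, cy), ang, length_um, width_um, _ in self.filaments:
            half = length_um / self.pixel_size_um / 2.0
            th = np.radians(ang)
            for s in (-1.0, 1.0):
                x = cx + s * half * np.cos(th)
                y = cy + s * half * np.sin(th)
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(
                        f"filament at {(cx, cy)} extends outside the image"
                    )


def random_filament_scene(
    n_filaments: int = 20,
    image_shape: tuple[int, int] = (384, 384),
    pixel_size_um: float = 0.04,
    length_range_um: tuple[float, float] = (1.5, 3.5),
    width_range_um: tuple[float, float] = (0.12, 0.24),
    intensity: float = 200.0,
    background_level: float = 10.0,
    noise_sd: float = 2.0,
    psf_sigma_px: float = 1.0,
    seed: int = 0,
) -> FilamentSceneSpec:
    """Draw a random non-degenerate scene of straight filaments."""
    rng = np.random.default_rng(seed)
    h, w = image_shape
    fils = []
    tries = 0
    while len(fils) < n_filaments and tries < n_filaments * 200:
        tries += 1
        length = float(rng.uniform(*length_range_um))
        width = float(rng.uniform(*width_range_um))
        ang = float(rng.uniform(-89.0, 89.0))
        half_px = length / pixel_size_um / 2.0
        margin = half_px + 6
        if 2 * margin >= min(h, w):
            raise ValueError("filament length too large for the image")
        cx = float(rng.uniform(margin, w - margin))
        cy = float(rng.uniform(margin, h - margin))
        th = np.radians(ang)
        p0 = np.array([cx - half_px * np.cos(th), cy - half_px * np.sin(th)])
        p1 = np.array([cx + half_px * np.cos(th), cy + half_px * np.sin(th)])
        # keep filaments well separated so recovery is attributable
        ok = True
        for (ocx, ocy), oang, olen, _, _ in fils:
            if np.hypot(cx - ocx, cy - ocy) < (half_px + olen / pixel_size_um / 2 + 12):
                ok = False
                break
        if ok:
            fils.append(((cx, cy), ang, length, width, intensity))
    if len(fils) < n_filaments:
        raise ValueError("could not place the requested number of filaments")
    return FilamentSceneSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        filaments=tuple(fils),
        background_level=background_level,
        noise_sd=noise_sd,
        psf_sigma_px=psf_sigma_px,
        seed=seed,
    )


def make_filament_image(
    spec: FilamentSceneSpec,
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render a filament scene; returns the image and its ground-truth table.

    Bars are rendered with anti-aliased edges (sub-pixel coverage from the
    distance to the bar's center segment), blurred with an isotropic
    Gaussian PSF and corrupted with noise.  Ground-truth columns:
    filament_id, length_um, width_um, angle_deg, cx_px, cy_px.
    """
    h, w = spec.image_shape
    img = np.full((h, w), float(spec.background_level))
    yy, xx = np.mgrid[0:h, 0:w]
    # image y axis points down; scene angles are y-up
    truth = []
    for k, ((cx, cy), ang, length_um, width_um, intensity) in enumerate(
        spec.filaments
    ):
        half = length_um / spec.pixel_size_um / 2.0
        half_w = width_um / spec.pixel_size_um / 2.0
        th = np.radians(ang)
        ux, uy = np.cos(th), np.sin(th)
        # pixel coords y-up: y_up = (h - 1) - row
        py = (h - 1) - yy
        dx = xx - cx
        dy = py - cy
        t = np.clip(dx * ux + dy * uy, -half, half)
        ddx = dx - t * ux
        ddy = dy - t * uy
        dist = np.hypot(ddx, ddy)
        coverage = np.clip(half_w + 0.5 - dist, 0.0, 1.0)
        img += intensity * coverage
        truth.append(
            {
                "filament_id": k,
                "length_um": length_um,
                "width_um": width_um,
                "angle_deg": ang,
                "cx_px": cx,
                "cy_px": cy,
            }
        )
    if spec.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_px)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "poisson":
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    elif spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    image = CalibratedImage(img, spec.pixel_size_um)
    return image, pd.DataFrame(truth)


def make_accel_trace(
    schedule: PulseSchedule,
    amplitude_g: float = 2.39,
    harmonics: tuple[tuple[int, float], ...] = (),
    noise_sd: float = 0.0,
    sample_rate: float = 3200.0,
    carrier_hz: float = 51.0,
    seed: int = 0,
) -> AccelTrace:
    """Emulate a three-axis accelerometer trace of a gated-sine vibration.

    z = gated sine of ``amplitude_g`` at ``carrier_hz`` plus optional odd
    harmonic components ((order, relative amplitude) pairs) plus Gaussian
    noise; x and y carry noise only.  The default amplitude 2.39 g gives a
    continuous-vibration RMS of 2.39/sqrt(2) = 1.69 g.
    """
    if amplitude_g <= 0:
        raise ValueError("amplitude_g must be positive")
    base = render_signal(schedule, carrier_hz=carrier_hz, sample_rate=sample_rate)
    z = amplitude_g * base.samples.copy()
    gate = base.samples != 0
    n = len(z)
    t = np.arange(n) / sample_rate
    for order, rel in harmonics:
        harm = np.sin(2 * np.pi * carrier_hz * order * t)
        z += amplitude_g * rel * np.where(gate, harm, 0.0)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        z = z + rng.normal(0, noise_sd, n)
        ax = rng.normal(0, noise_sd, n)
        ay = rng.normal(0, noise_sd, n)
    else:
        ax = np.zeros(n)
        ay = np.zeros(n)
    return AccelTrace(sample_rate, t, ax, ay, z)


@dataclass(frozen=True)
class FlowSceneSpec:
    """Scene description for a two-vortex tracer-particle video."""

    domain: tuple[float, float] = (0.01, 0.01)  # (W, H) m, chamber cross-section
    stream_amplitude: float = 1e-6  # Psi, m^2/s
    n_particles: int = 100
    frame_rate: float = 25.0
    n_frames: int = 50
    image_shape: tuple[int, int] = (128, 128)
    spot_sigma_px: float = 1.2
    spot_intensity: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.n_frames < 1 or self.n_particles < 1:
            raise ValueError("invalid flow scene parameters")


def two_vortex_velocity(
    x: np.ndarray, y: np.ndarray, spec: FlowSceneSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic velocity of the two-vortex stream function at (x, y) [m].

    u = d(psi)/dy, v = -d(psi)/dx with
    psi = Psi sin(2 pi x / W) sin(pi y / H).
    """
    W, H = spec.domain
    P = spec.stream_amplitude
    u = P * (np.pi / H) * np.sin(2 * np.pi * x / W) * np.cos(np.pi * y / H)
    v = -P * (2 * np.pi / W) * np.cos(2 * np.pi * x / W) * np.sin(np.pi * y / H)
    return u, v


def make_particle_video(
    spec: FlowSceneSpec,
    gate_schedule: PulseSchedule | None = None,
) -> tuple[np.ndarray, ParticleTracks, dict]:
    """Advect tracer particles in the two-vortex flow and render frames.

    Particles are advected with classical 4th-order Runge–Kutta steps at the
    frame interval and reflected at the walls (particle count is conserved).
    With ``gate_schedule`` given, the flow is switched off during the
    schedule's "off" segments (pulsed-vibration streaming stops between
    pulses), so particle motion follows the pulse pattern.  Returns
    ``(frames, ground_truth_tracks, meta)`` where frames is a
    (n_frames, h, w) float stack of Gaussian spots, the tracks carry the
    exact particle positions in meters, and meta holds the pixel size and
    an ``analytic_velocity(x, y)`` callable for oracle comparisons.
    """
    W, H = spec.domain
    h, w = spec.image_shape
    px_m = W / w  # pixel size, m (assumes square pixels; H/h must match)
    rng = np.random.default_rng(spec.seed)
    pos = np.column_stack(
        (rng.uniform(0.02 * W, 0.98 * W, spec.n_particles),
         rng.uniform(0.02 * H, 0.98 * H, spec.n_particles))
    )
    dt = 1.0 / spec.frame_rate

    def vel(p: np.ndarray) -> np.ndarray:
        u, v = two_vortex_velocity(p[:, 0], p[:, 1], spec)
        return np.column_stack((u, v))

    def reflect(p: np.ndarray) -> np.ndarray:
        p = p.copy()
        for dim, lim in ((0, W), (1, H)):
            p[:, dim] = np.abs(p[:, dim])
            over = p[:, dim] > lim
            p[over, dim] = 2 * lim - p[over, dim]
            p[:, dim] = np.clip(p[:, dim], 0, lim)
        return p

    frames = np.zeros((spec.n_frames, h, w))
    tracks: dict[int, list[tuple[int, float, float]]] = {
        i: [] for i in range(spec.n_particles)
    }

    def render(frame: np.ndarray, p: np.ndarray) -> None:
        sig = spec.spot_sigma_px
        half = max(2, int(np.ceil(4 * sig)))
        for x_m, y_m in p:
            cx = x_m / px_m - 0.5  # pixel centers at half-integers
            cy_up = y_m / px_m - 0.5
            r0 = (h - 1) - cy_up  # row coordinate (y down)
            c0 = cx
            rmin = max(0, int(np.floor(r0)) - half)
            rmax = min(h, int(np.ceil(r0)) + half + 1)
            cmin = max(0, int(np.floor(c0)) - half)
            cmax = min(w, int(np.ceil(c0)) + half + 1)
            if rmin >= rmax or cmin >= cmax:
                continue
            rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
            frame[rmin:rmax, cmin:cmax] += spec.spot_intensity * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2)
            )

    for fi in range(spec.n_frames):
        render(frames[fi], pos)
        for i, (x_m, y_m) in enumerate(pos):
            tracks[i].append((fi, float(x_m), float(y_m)))
        if fi == spec.n_frames - 1:
            break
        if gate_schedule is not None and gate_schedule.state_at(fi * dt) == "off":
            continue
        k1 = vel(pos)
        k2 = vel(reflect(pos + 0.5 * dt * k1))
        k3 = vel(reflect(pos + 0.5 * dt * k2))
        k4 = vel(reflect(pos + dt * k3))
        pos = reflect(pos + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))

    gt = ParticleTracks(
        frame_rate=spec.frame_rate, pixel_size_um=px_m * 1e6, tracks=tracks
    )
    meta = {
        "pixel_size_um": px_m * 1e6,
        "analytic_velocity": lambda x, y: two_vortex_velocity(x, y, spec),
        "spec": spec,
    }
    return frames, gt, meta
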