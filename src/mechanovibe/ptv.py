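"""Particle tracking velocimetry and boundary shear stress.

Tracer particles (bright spots on a dark background) are detected per frame
with sub-pixel intensity-weighted centroids, linked across frames by greedy
nearest-neighbour matching, and converted to gridded mean-velocity fields by
finite differences.  Near the bottom wall, the no-slip condition lets the
wall shear stress experienced by adherent cells be approximated from the
first reliably measured velocity above the surface:

    tau(x) = mu * u(x, y0) / y0

where ``mu`` is the dynamic viscosity, ``u`` the horizontal velocity and
``y0`` the center height of the lowest grid row with enough track samples.
tau is signed: it follows the local flow direction.

Coordinates: origin at the bottom-left of the imaged plane, y increasing
upward, pixel centers at half-integer pixel coordinates.  With a camera
frame rate far below the vibration carrier (stroboscopic sampling), the
velocities recovered here are mean drift velocities of the streaming flow,
not the oscillatory motion itself.

The module also provides motiongrams: per-frame absolute difference images
collapsed along one spatial axis and stacked over time, plus the quantity of
motion (QoM), the per-frame sum of supra-threshold differences normalized by
pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ParticleTracks",
    "VelocityField",
    "ShearStressProfile",
    "detect_particles",
    "link_tracks",
    "velocity_field",
    "boundary_shear",
    "motiongram",
]


@dataclass(frozen=True)
class ParticleTracks:
    """Linked particle trajectories in physical units.

    ``tracks`` maps track_id -> list of (frame_index, x_m, y_m); within a
    track frame indices are strictly increasing.
    """

    frame_rate: float
    pixel_size_um: float
    tracks: dict[int, list[tuple[int, float, float]]]

    def __post_init__(self) -> None:
        for tid, pts in self.tracks.items():
            frames = [p[0] for p in pts]
            if any(b <= a for a, b in zip(frames, frames[1:])):
                raise ValueError(f"track {tid}: frame indices not increasing")

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class VelocityField:
    """Gridded mean velocities; cells without samples are NaN, not zero."""

    grid_x: np.ndarray  # cell-center x, m
    grid_y: np.ndarray  # cell-center y, m
    u: np.ndarray  # (ny, nx) m/s, NaN where empty
    v: np.ndarray
    counts: np.ndarray  # samples per cell


@dataclass(frozen=True)
class ShearStressProfile:
    """Signed boundary shear stress tau(x) = mu*u(x, y0)/y0 at height y0."""

    mu: float  # Pa s
    y0: float  # m
    x: np.ndarray  # m
    tau: np.ndarray  # Pa, NaN where u undefined

    @property
    def abs_tau(self) -> np.ndarray:
        """|tau| over cells where it is defined (for distribution plots)."""
        t = self.tau[np.isfinite(self.tau)]
        return np.abs(t)


def detect_particles(
    frame: np.ndarray,
    min_area: int = 2,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Sub-pixel centroids of bright connected components.

    Returns an (n, 2) array of (x, y) centroids in pixel units, origin at the
    bottom-left, pixel centers at half-integers.  ``threshold`` is either a
    numeric intensity cutoff or ``"otsu"``.  Components with area below
    ``min_area`` are discarded.  Two overlapping particles merged into one
    component yield a single centroid (known limitation of blob detection).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2D grayscale")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(img) == 0:
            return np.empty((0, 2))
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    if not mask.any():
        return np.empty((0, 2))
    lab = label(mask)
    h = img.shape[0]
    cents = []
    for rp in regionprops(lab, intensity_image=img):
        if rp.area < min_area:
            continue
        r, c = rp.centroid_weighted
        cents.append((c + 0.5, h - r - 0.5))
    return np.array(cents) if cents else np.empty((0, 2))


def link_tracks(
    frames_centroids: list[np.ndarray],
    max_disp: float = 10.0,
    frame_rate: float = 25.0,
    pixel_size_um: float = 1.0,
) -> ParticleTracks:
    """Greedy nearest-neighbour linking of per-frame centroid lists.

    Candidate links between consecutive frames are taken in ascending
    distance; each centroid is used at most once per frame pair (injective
    matching) and links longer than ``max_disp`` pixels are rejected.
    Unmatched centroids start new tracks.  Positions are converted to meters
    with ``pixel_size_um``.
    """
    if len(frames_centroids) < 2:
        raise ValueError("need at least two frames to link")
    scale = pixel_size_um * 1e-6
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    next_id = 0
    # active[i] = track id of centroid i in the previous frame
    prev = np.asarray(frames_centroids[0], dtype=float).reshape(-1, 2)
    active = []
    for p in prev:
        tracks[next_id] = [(0, p[0] * scale, p[1] * scale)]
        active.append(next_id)
        next_id += 1
    for fi in range(1, len(frames_centroids)):
        cur = np.asarray(frames_centroids[fi], dtype=float).reshape(-1, 2)
        assigned_prev: set[int] = set()
        assigned_cur: set[int] = set()
        new_active = [-1] * len(cur)
        if len(prev) and len(cur):
            d = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
            order = np.argsort(d, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, d.shape)
                if d[i, j] > max_disp:
                    break
                if i in assigned_prev or j in assigned_cur:
                    continue
                assigned_prev.add(int(i))
                assigned_cur.add(int(j))
                tid = active[i]
                tracks[tid].append((fi, cur[j, 0] * scale, cur[j, 1] * scale))
                new_active[j] = tid
        for j in range(len(cur)):
            if new_active[j] == -1:
                tracks[next_id] = [(fi, cur[j, 0] * scale, cur[j, 1] * scale)]
                new_active[j] = next_id
                next_id += 1
        prev, active = cur, new_active
    return ParticleTracks(frame_rate, pixel_size_um, tracks)


def velocity_field(
    tracks: ParticleTracks,
    grid_shape: tuple[int, int],
    domain: tuple[float, float, float, float] | None = None,
) -> VelocityField:
    """Bin per-track finite-difference velocities onto a grid and average.

    Velocities are Δposition × frame_rate between consecutive track points
    (divided by the frame gap when frames were skipped), located at the step
    midpoint.  ``grid_shape`` is (ny, nx); ``domain`` is
    ``(x_min, x_max, y_min, y_max)`` in meters, inferred from the data when
    omitted.  Cells with no samples hold NaN.
    """
    ny, nx = grid_shape
    pts = []
    for path in tracks.tracks.values():
        for (f0, x0, y0), (f1, x1, y1) in zip(path, path[1:]):
            dt = (f1 - f0) / tracks.frame_rate
            pts.append(((x0 + x1) / 2, (y0 + y1) / 2, (x1 - x0) / dt, (y1 - y0) / dt))
    if not pts:
        raise ValueError("no track steps to grid (need tracks with >= 2 points)")
    arr = np.array(pts)
    if domain is None:
        domain = (
            arr[:, 0].min(),
            arr[:, 0].max() * (1 + 1e-9) + 1e-12,
            arr[:, 1].min(),
            arr[:, 1].max() * (1 + 1e-9) + 1e-12,
        )
    x0, x1, y0, y1 = domain
    ix = np.clip(((arr[:, 0] - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((arr[:, 1] - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
    counts = np.zeros((ny, nx), dtype=int)
    usum = np.zeros((ny, nx))
    vsum = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1)
    np.add.at(usum, (iy, ix), arr[:, 2])
    np.add.at(vsum, (iy, ix), arr[:, 3])
    with np.errstate(invalid="ignore"):
        u = np.where(counts > 0, usum / np.maximum(counts, 1), np.nan)
        v = np.where(counts > 0, vsum / np.maximum(counts, 1), np.nan)
    gx = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    gy = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    return VelocityField(gx, gy, u, v, counts)


def boundary_shear(
    field: VelocityField, mu: float, min_count: int = 5
) -> ShearStressProfile:
    """Shear stress profile at the lowest reliably measured grid row.

    ``y0`` is the center height of the lowest grid row containing at least
    one cell with ``min_count`` or more velocity samples; cells below
    ``min_count`` in that row are NaN in the profile.  tau is signed with
    the direction of the horizontal flow.
    """
    if mu <= 0:
        raise ValueError("dynamic viscosity mu must be positive")
    rows = np.flatnonzero((field.counts >= min_count).any(axis=1))
    if rows.size == 0:
        raise ValueError(
            f"no grid row has a cell with >= {min_count} samples; "
            "cannot estimate boundary shear"
        )
    r = int(rows[0])
    y0 = float(field.grid_y[r])
    if y0 <= 0:
        raise ValueError("lowest measured row is at or below the wall (y0 <= 0)")
    u_row = np.where(field.counts[r] >= min_count, field.u[r], np.nan)
    tau = mu * u_row / y0
    return ShearStressProfile(mu=mu, y0=y0, x=field.grid_x.copy(), tau=tau)


def motiongram(
    frames: np.ndarray | list[np.ndarray],
    axis: str = "x",
    noise_floor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Motiongram and quantity of motion from a frame sequence.

    Each consecutive frame pair is differenced; absolute differences at or
    below ``noise_floor`` are zeroed.  The motiongram collapses each
    difference image along the chosen axis (``"x"`` averages over columns,
    leaving a (n_frames-1, height) matrix; ``"y"`` averages over rows) and
    stacks the result over time.  QoM is the per-frame sum of
    supra-threshold absolute difference divided by the pixel count; it is
    zero exactly when consecutive frames agree to within the noise floor.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need >= 2 frames of identical shape")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    diff = np.abs(np.diff(stack, axis=0))
    diff[diff <= noise_floor] = 0.0
    collapse_axis = 2 if axis == "x" else 1
    mg = diff.mean(axis=collapse_axis)
    npix = stack.shape[1] * stack.shape[2]
    qom = diff.reshape(diff.shape[0], -1).sum(axis=1) / npix
    return mg, qom
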