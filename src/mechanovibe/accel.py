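"""Accelerometer trace characterization.

Operates on three-axis acceleration recordings (units of g, nominally
3200 Hz) of a vertically vibrated cell-culture plate, and reduces a trace to
the standard vibration parameter set: fundamental frequency, acceleration
peak and RMS, crest factor (peak/RMS — how "peaky" or intermittent the
signal is), RMS velocity and displacement obtained by spectral integration,
total vibration and silence times, and amplitude distributions.

Velocity and displacement are integrated in the frequency domain: the
acceleration spectrum is divided by iω once (velocity) or twice
(displacement), the DC bin and all bins below a high-pass cutoff are zeroed
to suppress drift, and the result is inverse-transformed.  Accelerations in
g are converted to SI with g = 9.81 m/s².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

G_TO_MS2 = 9.81

__all__ = [
    "AccelTrace",
    "VibrationSummary",
    "Spectrum",
    "load_accel_csv",
    "axis_rms",
    "characterize",
    "spectrum",
    "fundamental",
    "integrate_spectral",
    "segment_activity",
    "amplitude_distribution",
]


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled three-axis acceleration in g."""

    sample_rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("axis arrays must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.sample_rate

    def is_uniform(self, rtol: float = 1e-3) -> bool:
        """True if sampling intervals match 1/sample_rate within rtol."""
        if len(self.t) < 2:
            return True
        dt = np.diff(self.t)
        return bool(np.all(np.abs(dt * self.sample_rate - 1.0) < rtol))


@dataclass(frozen=True)
class VibrationSummary:
    """The per-condition vibration parameter set."""

    fundamental_hz: float
    peak_g: float
    rms_g: float
    crest_factor: float
    rms_velocity_ms: float
    rms_displacement_m: float
    vibration_time_s: float
    silence_time_s: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Measured fundamental frequency (Hz)": self.fundamental_hz,
            "Total vibration time (s)": self.vibration_time_s,
            "Total silence (intervals) time (s)": self.silence_time_s,
            "Acceleration peak (g)": self.peak_g,
            "Acceleration RMS (g)": self.rms_g,
            "Crest factor": self.crest_factor,
            "Velocity RMS (m/s)": self.rms_velocity_ms,
            "Displacement RMS (m)": self.rms_displacement_m,
        }


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum of a real signal."""

    freqs: np.ndarray
    magnitude: np.ndarray


class AccelParseError(ValueError):
    """Raised when an accelerometer CSV cannot be parsed."""


def load_accel_csv(path: str | Path, sample_rate: float = 3200.0) -> AccelTrace:
    """Load a 3- or 4-column CSV (optional leading time column, units g).

    A header row is detected and skipped automatically.  With three columns
    the time base is synthesized from ``sample_rate``.  Malformed numeric
    fields raise :class:`AccelParseError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(v) for v in first.strip().split(",") if v != ""]
    except ValueError:
        skip = 1  # header row
    df = pd.read_csv(path, header=None, skiprows=skip, comment="#")
    if df.shape[1] not in (3, 4):
        raise AccelParseError(
            f"{path}: expected 3 or 4 columns, found {df.shape[1]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1 + skip
        raise AccelParseError(f"{path}: non-numeric value on line {line}")
    arr = numeric.to_numpy(dtype=float)
    if arr.shape[1] == 4:
        t, ax, ay, az = arr.T
    else:
        ax, ay, az = arr.T
        t = np.arange(len(ax)) / sample_rate
    return AccelTrace(sample_rate, t, ax, ay, az)


def axis_rms(trace: AccelTrace) -> tuple[float, float, float]:
    """Per-axis RMS after removing each axis's static-gravity mean."""
    if len(trace.t) == 0:
        raise ValueError("empty trace")
    out = []
    for a in (trace.ax, trace.ay, trace.az):
        out.append(float(np.sqrt(np.mean((a - a.mean()) ** 2))))
    return tuple(out)  # type: ignore[return-value]


def spectrum(signal: np.ndarray, sample_rate: float) -> Spectrum:
    """One-sided amplitude spectrum of the mean-removed signal.

    Scaled so a pure sine of amplitude A appears with magnitude A at its
    frequency bin (for bin-centered frequencies).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short for a spectrum")
    x = x - x.mean()
    mag = np.abs(np.fft.rfft(x)) * 2.0 / x.size
    mag[0] /= 2.0
    if x.size % 2 == 0:
        mag[-1] /= 2.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    return Spectrum(freqs, mag)


def fundamental(
    spec: Spectrum, search_band: tuple[float, float] = (20.0, 200.0)
) -> float:
    """Fundamental frequency: arg-max bin within the search band, refined by
    parabolic interpolation on the magnitude."""
    lo, hi = search_band
    sel = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if sel.size == 0:
        raise ValueError(f"empty search band {search_band}")
    mags = spec.magnitude[sel]
    if np.all(mags <= 0):
        raise ValueError("no spectral peak found in band")
    k = sel[int(np.argmax(mags))]
    f = spec.freqs[k]
    if 0 < k < len(spec.freqs) - 1:
        a, b, c = spec.magnitude[k - 1 : k + 2]
        denom = a - 2 * b + c
        if denom != 0:
            delta = 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            f = f + delta * (spec.freqs[1] - spec.freqs[0])
    return float(f)


def integrate_spectral(
    signal_g: np.ndarray,
    sample_rate: float,
    order: int = 1,
    highpass_hz: float = 5.0,
) -> np.ndarray:
    """Integrate acceleration (g) once (→ m/s) or twice (→ m) spectrally.

    Divides the rFFT by (iω)**order, zeros the DC bin and all bins below
    ``highpass_hz`` to suppress drift, and inverse-transforms.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    a = np.asarray(signal_g, dtype=float) * G_TO_MS2
    a = a - a.mean()
    n = a.size
    spec_c = np.fft.rfft(a)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    omega = 2.0 * np.pi * freqs
    keep = freqs >= highpass_hz
    out = np.zeros_like(spec_c)
    out[keep] = spec_c[keep] / (1j * omega[keep]) ** order
    return np.fft.irfft(out, n=n)


def segment_activity(
    signal: np.ndarray,
    sample_rate: float,
    threshold_g: float | None = None,
    min_gap_ms: float = 50.0,
    carrier_hz: float = 50.0,
) -> tuple[float, float, list[tuple[float, float, str]]]:
    """Segment a trace into vibration and silence periods.

    A moving-RMS envelope (window = one carrier period) is thresholded at
    ``threshold_g`` (default: 10% of the trace peak) to detect active runs;
    runs and gaps shorter than ``min_gap_ms`` are merged into their
    neighbours.  Each detected boundary is then refined by intersecting the
    two asymptotes of the cumulative signal energy around it — flat in the
    silence, linear inside the pulse — which locates the gate edge to a
    fraction of a carrier period regardless of the envelope smoothing
    window.  Returns ``(vibration_time_s, silence_time_s, segments)`` with
    segments as ``(start_s, end_s, "on"|"off")``; on + off time equals the
    trace duration exactly.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    duration = n / sample_rate
    if n == 0:
        return 0.0, 0.0, []
    x = x - x.mean()
    win = max(1, int(round(sample_rate / carrier_hz)))
    kernel = np.ones(win) / win
    ms_env = np.convolve(x**2, kernel, mode="same")  # mean-square envelope
    env = np.sqrt(np.maximum(ms_env, 0.0))
    if threshold_g is None:
        peak = float(np.max(np.abs(x)))
        threshold_g = 0.1 * peak if peak > 0 else np.inf
    active = env > threshold_g

    if not active.any():
        return 0.0, duration, [(0.0, duration, "off")]

    # merge runs shorter than min_gap_ms (off-gaps first, then on-blips)
    min_run = max(1, int(round(min_gap_ms / 1000.0 * sample_rate)))
    for target in (False, True):
        edges = np.flatnonzero(np.diff(active.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [n]))
        for s, e in zip(starts, ends):
            if active[s] == target and (e - s) < min_run and s > 0 and e < n:
                active[s:e] = not target

    # refined boundaries: intersect the flat (silence) and linear (pulse)
    # asymptotes of the cumulative signal energy around each coarse edge
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [n]))
    on_runs = [(s, e) for s, e in zip(starts, ends) if active[s]]
    energy = np.concatenate(([0.0], np.cumsum(x**2)))  # energy[i] = sum x[:i]^2
    # boxcar over one carrier period cancels the sin(2*omega*t) energy
    # ripple, leaving the cumulative energy exactly linear inside a pulse
    # and exactly flat in a silence (away from the edges)
    energy_s = np.convolve(energy, kernel, mode="same")

    def _refine(coarse: int, kind: str) -> float:
        """Refined edge position (samples) for an 'onset' or 'offset' edge."""
        sgn = 1 if kind == "onset" else -1
        flat = coarse - sgn * win
        ramp_a = coarse + sgn * 2 * win
        ramp_b = coarse + sgn * 3 * win
        pts = (flat, ramp_a, ramp_b)
        if min(pts) < win or max(pts) > n - win:
            return float(coarse)
        level = float(energy_s[flat])
        slope = (energy_s[ramp_b] - energy_s[ramp_a]) / (ramp_b - ramp_a)
        if slope <= 0:
            return float(coarse)
        pos = ramp_a + (level - energy_s[ramp_a]) / slope
        return float(np.clip(pos, coarse - 2 * win, coarse + 2 * win))

    refined: list[tuple[float, float]] = []
    for s, e in on_runs:
        lo = _refine(s, "onset") if s > 0 else 0.0
        hi = _refine(e, "offset") if e < n else float(n)
        if hi > lo:
            refined.append((max(lo, 0.0), min(hi, float(n))))

    # assemble segments, merging overlaps
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(refined):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))

    segments: list[tuple[float, float, str]] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            segments.append((cursor / sample_rate, lo / sample_rate, "off"))
        segments.append((lo / sample_rate, hi / sample_rate, "on"))
        cursor = hi
    if cursor < n:
        segments.append((cursor / sample_rate, duration, "off"))

    vib = sum(e - s for s, e, st in segments if st == "on")
    sil = duration - vib
    return float(vib), float(sil), segments


def characterize(
    signal: np.ndarray,
    sample_rate: float,
    search_band: tuple[float, float] = (20.0, 200.0),
    highpass_hz: float = 5.0,
    threshold_g: float | None = None,
    carrier_hz: float | None = None,
) -> VibrationSummary:
    """Full single-axis characterization (the per-condition parameter table).

    Peak is the maximum of |a| after mean removal; RMS is over the full
    trace (silences included); crest factor is peak/RMS.  Velocity and
    displacement RMS come from spectral integration with the given high-pass
    cutoff.  Vibration/silence times come from :func:`segment_activity`.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        raise ValueError("crest factor undefined for an all-zero signal")
    peak = float(np.max(np.abs(x)))
    spec = spectrum(x, sample_rate)
    f0 = fundamental(spec, search_band)
    vel = integrate_spectral(x, sample_rate, order=1, highpass_hz=highpass_hz)
    disp = integrate_spectral(x, sample_rate, order=2, highpass_hz=highpass_hz)
    vib, sil, _ = segment_activity(
        x, sample_rate, threshold_g=threshold_g, carrier_hz=carrier_hz or f0
    )
    return VibrationSummary(
        fundamental_hz=f0,
        peak_g=peak,
        rms_g=rms,
        crest_factor=peak / rms,
        rms_velocity_ms=float(np.sqrt(np.mean(vel**2))),
        rms_displacement_m=float(np.sqrt(np.mean(disp**2))),
        vibration_time_s=vib,
        silence_time_s=sil,
    )


def amplitude_distribution(
    signal: np.ndarray, bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram |a| by category plus a signed histogram.

    Values beyond the last edge are counted in the outermost bin so that the
    absolute-value counts always sum to the sample count.  Returns
    ``(abs_counts, signed_counts)``; the signed histogram uses edges mirrored
    about zero.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be ascending with length >= 2")
    x = np.asarray(signal, dtype=float)
    absx = np.clip(np.abs(x), edges[0], np.nextafter(edges[-1], -np.inf))
    abs_counts, _ = np.histogram(absx, bins=edges)
    signed_edges = np.concatenate((-edges[::-1], edges[1:]))
    xs = np.clip(
        x,
        signed_edges[0],
        np.nextafter(signed_edges[-1], -np.inf),
    )
    signed_counts, _ = np.histogram(xs, bins=signed_edges)
    return abs_counts, signed_counts
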