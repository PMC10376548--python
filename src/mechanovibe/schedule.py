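"""Pulse-schedule generation and randomness assessment.

A vibration session is described by a :class:`PulseSchedule`: an ordered list
of alternating on/off segments whose millisecond durations sum exactly to the
session length.  Three modes are supported:

* **CV** (Continuous Vibration) — a single "on" segment spanning the session;
* **RP** (Regular Pulse) — fixed pulse duration and interval (e.g. 1000 ms on,
  1000 ms off);
* **VP** (Variable Pulse) — pulse durations and intervals drawn uniformly as
  integers from ``[lower_ms, upper_ms)``, reproducible from a seed.

Schedules can be rendered into a gated sine carrier
(:func:`render_signal`) for downstream acceleration emulation and WAV export.

The randomness of the integer sequences driving VP is assessed with the
Wald–Wolfowitz runs test, Shannon entropy of the empirical value
distribution (natural log, so the maximum is ``ln n``), and the normalized
sample autocorrelation with a ±z(α)/√n confidence band.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from scipy.io import wavfile

__all__ = [
    "PulseSchedule",
    "GatedSineSignal",
    "RandomnessReport",
    "generate_cv_schedule",
    "generate_rp_schedule",
    "generate_vp_schedule",
    "render_signal",
    "runs_test",
    "sequence_entropy",
    "autocorrelation",
    "randomness_report",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_signal_wav",
]

Mode = Literal["CV", "RP", "VP"]


@dataclass(frozen=True)
class PulseSchedule:
    """Alternating on/off segments defining one vibration session.

    ``segments`` is an ordered list of ``(state, duration_ms)`` with state
    ``"on"`` or ``"off"``; durations are positive integers and sum to
    ``session_length_s * 1000`` exactly (the final segment is clipped at the
    session boundary).
    """

    mode: Mode
    segments: tuple[tuple[str, int], ...]
    session_length_s: float
    seed: int | None = None
    limits_ms: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for state, dur in self.segments:
            if state not in ("on", "off"):
                raise ValueError(f"invalid segment state {state!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        total = sum(d for _, d in self.segments)
        if abs(total - self.session_length_s * 1000.0) > 0.5:
            raise ValueError(
                f"segment durations sum to {total} ms, expected "
                f"{self.session_length_s * 1000:.0f} ms"
            )

    @property
    def total_on_s(self) -> float:
        """Accumulated pulse (vibration) time in seconds."""
        return sum(d for s, d in self.segments if s == "on") / 1000.0

    @property
    def total_off_s(self) -> float:
        """Accumulated interval (silence) time in seconds."""
        return sum(d for s, d in self.segments if s == "off") / 1000.0

    @property
    def onsets_ms(self) -> np.ndarray:
        """Cumulative onset time of each segment in ms."""
        durs = np.array([d for _, d in self.segments], dtype=np.int64)
        return np.concatenate(([0], np.cumsum(durs)[:-1]))

    def durations(self, state: str) -> np.ndarray:
        """All segment durations (ms) of the given state, in order."""
        return np.array([d for s, d in self.segments if s == state], dtype=np.int64)

    def state_at(self, t_s: float) -> str:
        """Segment state ("on"/"off") at time t_s; "off" beyond the session."""
        ms = t_s * 1000.0
        if ms < 0 or ms >= self.session_length_s * 1000.0:
            return "off"
        onsets = self.onsets_ms
        idx = int(np.searchsorted(onsets, ms, side="right")) - 1
        return self.segments[idx][0]


@dataclass(frozen=True)
class GatedSineSignal:
    """A sine carrier gated by a pulse schedule, dimensionless in [-1, 1]."""

    samples: np.ndarray
    sample_rate: float
    carrier_hz: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class RandomnessReport:
    """Randomness diagnostics for an integer/numeric sequence."""

    n: int
    runs_test_p: float
    entropy: float
    entropy_max: float
    autocorr: np.ndarray = field(repr=False)
    ci_halfwidth: float = 0.0
    alpha: float = 0.05


def _build_alternating(
    session_ms: int, durations_iter, mode: Mode, seed: int | None = None,
    limits_ms: tuple[int, int] | None = None,
) -> PulseSchedule:
    """Assemble alternating on/off segments, clipping the last at session end."""
    segments: list[tuple[str, int]] = []
    elapsed = 0
    state = "on"
    for dur in durations_iter:
        dur = int(dur)
        if elapsed + dur >= session_ms:
            clipped = session_ms - elapsed
            if clipped > 0:
                segments.append((state, clipped))
            elapsed = session_ms
            break
        segments.append((state, dur))
        elapsed += dur
        state = "off" if state == "on" else "on"
    return PulseSchedule(
        mode=mode,
        segments=tuple(segments),
        session_length_s=session_ms / 1000.0,
        seed=seed,
        limits_ms=limits_ms,
    )


def generate_cv_schedule(session_s: float) -> PulseSchedule:
    """Continuous Vibration: one uninterrupted "on" segment."""
    if session_s <= 0:
        raise ValueError("session_s must be positive")
    session_ms = int(round(session_s * 1000))
    return PulseSchedule("CV", (("on", session_ms),), session_ms / 1000.0)


def generate_rp_schedule(
    session_s: float, pulse_ms: int, interval_ms: int
) -> PulseSchedule:
    """Regular Pulse: fixed pulse duration and interval, starting with a pulse.

    Parameters
    ----------
    session_s : total session length in seconds.
    pulse_ms : "on" duration of every pulse, ms.
    interval_ms : "off" duration between pulses, ms.
    """
    if session_s <= 0 or pulse_ms <= 0 or interval_ms <= 0:
        raise ValueError("session and durations must be positive")
    session_ms = int(round(session_s * 1000))

    def durations():
        while True:
            yield pulse_ms
            yield interval_ms

    return _build_alternating(session_ms, durations(), "RP")


def generate_vp_schedule(
    session_s: float, lower_ms: int, upper_ms: int, seed: int
) -> PulseSchedule:
    """Variable Pulse: on/off durations drawn uniformly from [lower, upper) ms.

    Each duration is ``lower_ms`` plus an integer drawn uniformly from
    ``[0, upper_ms - lower_ms)``.  The same seed reproduces the same schedule
    byte-for-byte; the final segment is clipped at the session boundary.
    """
    if session_s <= 0:
        raise ValueError("session_s must be positive")
    if not (0 < lower_ms < upper_ms):
        raise ValueError("require 0 < lower_ms < upper_ms")
    session_ms = int(round(session_s * 1000))
    rng = np.random.default_rng(seed)
    span = upper_ms - lower_ms

    def durations():
        while True:
            yield lower_ms + int(rng.integers(0, span))

    return _build_alternating(
        session_ms, durations(), "VP", seed=seed, limits_ms=(lower_ms, upper_ms)
    )


def render_signal(
    schedule: PulseSchedule,
    carrier_hz: float = 50.0,
    sample_rate: float = 8000.0,
    continuous_phase: bool = False,
) -> GatedSineSignal:
    """Render a schedule as a unit-amplitude gated sine.

    The sine phase resets to zero at each pulse onset by default, producing a
    hard on/off envelope; pass ``continuous_phase=True`` to keep a free-running
    carrier gated by the schedule instead.
    """
    if sample_rate <= 2 * carrier_hz:
        raise ValueError(
            f"sample_rate {sample_rate} must exceed twice the carrier "
            f"({2 * carrier_hz} Hz)"
        )
    n_total = int(round(schedule.session_length_s * sample_rate))
    out = np.zeros(n_total)
    onsets = schedule.onsets_ms
    for (state, dur), onset in zip(schedule.segments, onsets):
        if state != "on":
            continue
        i0 = int(round(onset / 1000.0 * sample_rate))
        i1 = min(int(round((onset + dur) / 1000.0 * sample_rate)), n_total)
        if i1 <= i0:
            continue
        if continuous_phase:
            t = np.arange(i0, i1) / sample_rate
        else:
            t = np.arange(i1 - i0) / sample_rate
        out[i0:i1] = np.sin(2 * np.pi * carrier_hz * t)
    return GatedSineSignal(out, sample_rate, carrier_hz)


# --------------------------------------------------------------------------
# randomness assessment


def runs_test(sequence: Sequence[float]) -> float:
    """Two-sided Wald–Wolfowitz runs test p-value about the median.

    The sequence is dichotomized about its median; values equal to the median
    are dropped.  Uses the normal approximation to the run-count distribution,
    appropriate for n ≥ 20.  p < 0.05 indicates the sequence is unlikely to
    have been produced randomly.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size == 0 or np.all(x == x[0]):
        raise ValueError("runs test undefined: all values identical")
    med = np.median(x)
    signs = np.sign(x - med)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        raise ValueError("runs test undefined: one-sided after dichotomization")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def sequence_entropy(sequence: Sequence[float]) -> tuple[float, float]:
    """Shannon entropy (nats) of the empirical distribution of distinct values.

    Returns ``(entropy, entropy_max)`` with ``entropy_max = ln(n)``, the value
    attained when every element of the sequence is distinct.  The closer the
    entropy is to the maximum, the more random the sequence.
    """
    x = np.asarray(sequence)
    if x.size == 0:
        raise ValueError("empty sequence")
    _, counts = np.unique(x, return_counts=True)
    h = float(sps.entropy(counts))  # natural log
    return h, float(np.log(x.size))


def autocorrelation(
    sequence: Sequence[float], max_lag: int
) -> tuple[np.ndarray, float]:
    """Normalized sample autocorrelation r(k) for k = 0..max_lag.

    Returns ``(r, ci_halfwidth)`` where the confidence half-width is
    ``1.96/sqrt(n)`` (α = 0.05); coefficients inside ±that band are not
    significantly correlated.
    """
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the sequence length")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        raise ValueError("autocorrelation undefined for zero-variance sequence")
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = np.dot(xc[: n - k], xc[k:]) / denom
    return r, 1.959963984540054 / np.sqrt(n)


def randomness_report(
    sequence: Sequence[float], max_lag: int | None = None, alpha: float = 0.05
) -> RandomnessReport:
    """Full randomness diagnostics for one sequence."""
    x = np.asarray(sequence, dtype=float)
    if max_lag is None:
        max_lag = x.size - 1
    h, hmax = sequence_entropy(x)
    r, ci = autocorrelation(x, max_lag)
    return RandomnessReport(
        n=x.size,
        runs_test_p=runs_test(x),
        entropy=h,
        entropy_max=hmax,
        autocorr=r,
        ci_halfwidth=ci,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# export / import


def write_schedule_csv(schedule: PulseSchedule, path: str | Path) -> None:
    """Write segments as CSV (state,onset_ms,duration_ms) + JSON sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", "onset_ms", "duration_ms"])
        for (state, dur), onset in zip(schedule.segments, schedule.onsets_ms):
            w.writerow([state, int(onset), int(dur)])
    sidecar = {
        "mode": schedule.mode,
        "session_length_s": schedule.session_length_s,
        "seed": schedule.seed,
        "limits_ms": list(schedule.limits_ms) if schedule.limits_ms else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_schedule_csv(path: str | Path) -> PulseSchedule:
    """Read a schedule written by :func:`write_schedule_csv`."""
    path = Path(path)
    segments = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            segments.append((row["state"], int(row["duration_ms"])))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    session_s = meta.get(
        "session_length_s", sum(d for _, d in segments) / 1000.0
    )
    limits = meta.get("limits_ms")
    return PulseSchedule(
        mode=meta.get("mode", "RP"),
        segments=tuple(segments),
        session_length_s=session_s,
        seed=meta.get("seed"),
        limits_ms=tuple(limits) if limits else None,
    )


def write_signal_wav(
    signal: GatedSineSignal, path: str | Path, dtype: str = "float32"
) -> None:
    """Export a rendered signal as WAV (PCM 16-bit or float32)."""
    if dtype == "float32":
        data = signal.samples.astype(np.float32)
    elif dtype == "int16":
        data = np.round(np.clip(signal.samples, -1, 1) * 32767).astype(np.int16)
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
    wavfile.write(str(path), int(signal.sample_rate), data)
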