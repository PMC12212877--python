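"""Saccade detection and eye-movement kinematics on uniformly sampled gaze traces.

Gaze is represented as horizontal/vertical position in degrees of visual
angle on a uniform millisecond time grid (coil-style 1 kHz sampling by
default).  Saccades are detected as maximal runs of supra-threshold radial
speed, merged across short gaps and filtered by duration — the standard
velocity-threshold approach for coil data.  The exact criteria are
configurable through :class:`DetectionParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeTrace",
    "SaccadeEvent",
    "DetectionParams",
    "radial_speed",
    "detect_saccades",
    "accept_landing",
    "validate_update_timing",
    "first_catchup_latency",
    "simulated_translation_profile",
]

#: Landing-acceptance radius around the target center, degrees (strict "<").
LANDING_RADIUS_DEG = 2.0

#: Amplitude (deg) separating microsaccades from saccades in reports.
MICROSACCADE_AMPLITUDE_DEG = 1.0


@dataclass(frozen=True)
class EyeTrace:
    """Uniformly sampled two-channel gaze position.

    Parameters
    ----------
    t : array of float
        Sample times in ms, strictly increasing and uniform.
    x, y : array of float
        Horizontal / vertical gaze position in degrees of visual angle.
    sampling_rate : float
        Samples per second (Hz).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise ValueError("t, x, y must be 1-D arrays")
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("EyeTrace needs at least 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise ValueError("t must be uniformly sampled")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("x and y must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def __eq__(self, other) -> bool:  # array-valued fields need explicit eq
        if not isinstance(other, EyeTrace):
            return NotImplemented
        return (
            self.sampling_rate == other.sampling_rate
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade, parameterized from the speed trace."""

    onset: float  # ms
    peak_velocity_time: float  # ms
    end: float  # ms
    amplitude: float  # deg, radial displacement onset -> end
    peak_speed: float  # deg/s
    landing: tuple[float, float]  # deg, mean gaze shortly after the end

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak_velocity_time <= self.end):
            raise ValueError("require onset <= peak_velocity_time <= end")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class DetectionParams:
    """Velocity-threshold saccade-detection criteria.

    Defaults are standard practice for 1 kHz coil traces: radial-speed
    threshold 20 deg/s, minimum duration 8 ms, events separated by less
    than 20 ms merged, velocity from a 5-point central difference after a
    +/-5 ms moving average.
    """

    speed_threshold: float = 20.0  # deg/s
    min_duration: float = 8.0  # ms
    min_intersaccadic_interval: float = 20.0  # ms
    smoothing_halfwidth: float = 5.0  # ms

    def __post_init__(self) -> None:
        for name in (
            "speed_threshold",
            "min_duration",
            "min_intersaccadic_interval",
            "smoothing_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _moving_average(v: np.ndarray, halfwidth_samples: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    if halfwidth_samples <= 0:
        return v.astype(float, copy=True)
    k = halfwidth_samples
    padded = np.pad(v, k, mode="edge")
    kernel = np.full(2 * k + 1, 1.0 / (2 * k + 1))
    return np.convolve(padded, kernel, mode="valid")


def _central_diff5(v: np.ndarray, dt_s: float) -> np.ndarray:
    """5-point central difference with replicated edges; units per second."""
    p = np.pad(v, 2, mode="edge")
    d = (-p[4:] + 8.0 * p[3:-1] - 8.0 * p[1:-3] + p[:-4]) / (12.0 * dt_s)
    return d


def radial_speed(
    trace: EyeTrace, smoothing_halfwidth: float = 5.0
) -> np.ndarray:
    """Radial eye speed in deg/s, same length as the trace.

    Positions are smoothed with a centered moving average of half-width
    ``smoothing_halfwidth`` ms, differentiated with a 5-point central
    difference (edge values replicated), and combined as
    sqrt(vx**2 + vy**2).
    """
    if len(trace.t) < 5:
        raise ValueError("trace shorter than the differentiation stencil")
    dt_s = trace.dt_ms / 1000.0
    k = int(round(smoothing_halfwidth / trace.dt_ms))
    xs = _moving_average(trace.x, k)
    ys = _moving_average(trace.y, k)
    vx = _central_diff5(xs, dt_s)
    vy = _central_diff5(ys, dt_s)
    return np.hypot(vx, vy)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def _landing_position(trace: EyeTrace, end_idx: int, window_ms: float = 10.0) -> tuple[float, float]:
    # Mean gaze over the 10 ms following the saccade end; reduces
    # sensitivity to post-saccadic drift when judging where gaze "landed".
    n = int(round(window_ms / trace.dt_ms))
    lo = min(end_idx + 1, len(trace.t) - 1)
    hi = min(end_idx + 1 + n, len(trace.t))
    if hi <= lo:
        lo, hi = end_idx, end_idx + 1
    return float(np.mean(trace.x[lo:hi])), float(np.mean(trace.y[lo:hi]))


def detect_saccades(
    trace: EyeTrace, params: DetectionParams | None = None
) -> list[SaccadeEvent]:
    """Detect saccades as supra-threshold radial-speed runs.

    Runs with speed >= ``speed_threshold`` are merged when separated by
    gaps shorter than ``min_intersaccadic_interval`` and kept when their
    duration is at least ``min_duration``.  Edge samples affected by the
    smoothing/differentiation stencils are excluded from detection.
    Returns events sorted by onset; the list may be empty.
    """
    params = params or DetectionParams()
    speed = radial_speed(trace, params.smoothing_halfwidth)
    dt = trace.dt_ms
    edge = int(round(params.smoothing_halfwidth / dt)) + 2
    mask = speed >= params.speed_threshold
    if edge > 0:
        mask[:edge] = False
        mask[len(mask) - edge:] = False

    runs = _runs_above(mask)
    # merge runs separated by less than the inter-saccadic interval
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) * dt < params.min_intersaccadic_interval:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    events: list[SaccadeEvent] = []
    for start, stop in merged:
        if trace.t[stop] - trace.t[start] < params.min_duration:
            continue
        seg = speed[start : stop + 1]
        pk = start + int(np.argmax(seg))
        amp = math.hypot(
            trace.x[stop] - trace.x[start], trace.y[stop] - trace.y[start]
        )
        events.append(
            SaccadeEvent(
                onset=float(trace.t[start]),
                peak_velocity_time=float(trace.t[pk]),
                end=float(trace.t[stop]),
                amplitude=float(amp),
                peak_speed=float(speed[pk]),
                landing=_landing_position(trace, stop),
            )
        )
    return events


def accept_landing(
    saccade: SaccadeEvent,
    target_center: tuple[float, float],
    radius: float = LANDING_RADIUS_DEG,
) -> bool:
    """True iff the landing position is strictly within ``radius`` deg of the target."""
    d = math.hypot(
        saccade.landing[0] - target_center[0],
        saccade.landing[1] - target_center[1],
    )
    return d < radius


def validate_update_timing(
    saccade: SaccadeEvent,
    update_completion: float,
    trace: EyeTrace,
    smoothing_halfwidth: float = 5.0,
) -> dict:
    """Check that a display update completed intra-saccadically.

    Returns ``intra_saccadic`` (onset <= update_completion <= end) and the
    radial eye speed linearly interpolated at the update-completion time.
    """
    if not (trace.t[0] <= update_completion <= trace.t[-1]):
        raise ValueError(
            f"update_completion {update_completion} ms outside trace support "
            f"[{trace.t[0]}, {trace.t[-1]}] ms"
        )
    speed = radial_speed(trace, smoothing_halfwidth)
    s = float(np.interp(update_completion, trace.t, speed))
    intra = bool(saccade.onset <= update_completion <= saccade.end)
    return {"intra_saccadic": intra, "speed_at_update_end": s}


def first_catchup_latency(
    trace: EyeTrace,
    primary: SaccadeEvent,
    params: DetectionParams | None = None,
) -> float | None:
    """Latency (ms) of the first saccade after the primary one, or None.

    Latency is the onset of the earliest detected saccade with onset
    strictly after the primary saccade's end, expressed relative to that
    end.
    """
    for ev in detect_saccades(trace, params):
        if ev.onset > primary.end:
            return ev.onset - primary.end
    return None


def simulated_translation_profile(
    frame_rate: float, frame_displacements: list[float] | np.ndarray
) -> dict:
    """Kinematics of a frame-by-frame stimulus translation.

    A simulated saccade moves the stimulus toward the fovea in discrete
    display frames; e.g. per-frame displacements of (2.5, 4, 1.5) deg at
    85 Hz produce an accelerating-decelerating profile with a peak speed
    of 340 deg/s.  Returns cumulative positions per frame, the peak speed
    in deg/s, and the frame duration in ms.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    d = np.asarray(frame_displacements, dtype=float)
    if d.size == 0:
        raise ValueError("frame_displacements must be non-empty")
    if np.any(d < 0):
        raise ValueError("frame displacements must be non-negative")
    return {
        "positions": np.cumsum(d),
        "peak_speed": float(d.max() * frame_rate),
        "frame_duration_ms": 1000.0 / frame_rate,
    }
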