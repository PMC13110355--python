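"""Eye-trace signal processing: velocity, saccades, desaccading, pursuit summaries.

Conventions: positions in degrees of visual angle, screen-centered, x
positive rightward and y positive upward; time in ms at a uniform sampling
rate (1000 Hz default); velocities in deg/s.  Analysis windows are
half-open ``[start, end)`` in ms with 0 = target motion onset.

Velocity is obtained by central differences after zero-phase (forward-
backward) low-pass Butterworth filtering of position; the velocity trace is
filtered again.  Saccades are detected with velocity + acceleration
thresholds (EyeLink-style cognitive defaults: 30 deg/s and 8000 deg/s^2)
and excised from velocity traces by linear interpolation before pursuit
velocity is averaged 250-500 ms after target onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = ["EyeTrace", "VelocityTrace", "SaccadeEvent", "FilterSpec",
           "DETECTION_FILTER",
           "differentiate_and_filter", "detect_saccades", "desaccade",
           "mean_pursuit_velocity", "oculometric_decision",
           "saccade_endpoint", "running_average"]


@dataclass(frozen=True)
class EyeTrace:
    """Timestamped 2-D gaze position at a fixed sampling rate."""

    t: np.ndarray          # ms, uniform, strictly increasing
    x: np.ndarray          # deg
    y: np.ndarray          # deg
    markers: dict = field(default_factory=dict)   # event name -> time (ms)

    def __post_init__(self):
        t = np.asarray(self.t, float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, float))
        object.__setattr__(self, "y", np.asarray(self.y, float))
        if t.size != self.x.size or t.size != self.y.size:
            raise ValueError("t, x, y must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(np.median(np.diff(self.t)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.t)
        return bool(d.size == 0 or np.allclose(d, d[0], rtol=rtol))


@dataclass(frozen=True)
class VelocityTrace:
    t: np.ndarray
    v: np.ndarray                       # deg/s, horizontal component
    interpolated_mask: np.ndarray       # True where samples were replaced
    markers: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float            # ms
    offset: float           # ms
    amplitude: float        # deg
    peak_velocity: float    # deg/s
    landing: tuple[float, float]   # (x, y) deg

    def __post_init__(self):
        if self.onset >= self.offset:
            raise ValueError("saccade onset must precede offset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass settings (order, cutoff Hz)."""

    order: int = 2
    pos_cutoff_hz: float = 30.0
    vel_cutoff_hz: float = 40.0


#: lighter filtering for saccade detection: the 30/40 Hz pursuit-analysis
#: filters smear saccadic accelerations below the detection threshold, so
#: events are located on a 60/80 Hz velocity trace (as tracker parsers do on
#: raw data) and then excised from the analysis trace.
DETECTION_FILTER = FilterSpec(order=2, pos_cutoff_hz=60.0, vel_cutoff_hz=80.0)


from functools import lru_cache


@lru_cache(maxsize=64)
def _butter_sos(order: int, cutoff_hz: float, fs_hz: float):
    return signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")


def _lowpass(x: np.ndarray, cutoff_hz: float, fs_hz: float, order: int) -> np.ndarray:
    return signal.sosfiltfilt(_butter_sos(order, float(cutoff_hz), float(fs_hz)), x)


def differentiate_and_filter(trace: EyeTrace,
                             filter_spec: FilterSpec = FilterSpec(),
                             axis: str = "x",
                             max_gap_ms: float = 50.0) -> VelocityTrace:
    """Central-difference velocity after zero-phase Butterworth filtering.

    Position is low-pass filtered, differentiated (central differences,
    one-sided at the edges), and the velocity is filtered again.  NaN gaps
    up to ``max_gap_ms`` are linearly bridged and flagged in the mask;
    longer gaps raise with their spans listed.
    """
    if not trace.is_uniform():
        raise ValueError("trace must be uniformly sampled")
    pos = trace.x if axis == "x" else trace.y
    dt_s = trace.dt / 1000.0
    fs = 1.0 / dt_s
    if trace.t.size < 3 * (filter_spec.order * 3 + 1):
        raise ValueError("trace shorter than filter warm-up")
    mask = np.isnan(pos)
    if mask.any():
        spans = _nan_spans(trace.t, mask)
        too_long = [s for s in spans if s[1] - s[0] > max_gap_ms]
        if too_long:
            raise ValueError(f"NaN gaps longer than {max_gap_ms} ms: {too_long}")
        pos = pos.copy()
        idx = np.arange(pos.size)
        pos[mask] = np.interp(idx[mask], idx[~mask], pos[~mask])
    pos_f = _lowpass(pos, filter_spec.pos_cutoff_hz, fs, filter_spec.order)
    v = np.gradient(pos_f, dt_s)
    v = _lowpass(v, filter_spec.vel_cutoff_hz, fs, filter_spec.order)
    return VelocityTrace(t=trace.t, v=v, interpolated_mask=mask,
                         markers=dict(trace.markers))


def _nan_spans(t: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    spans = []
    in_gap = False
    for i, m in enumerate(mask):
        if m and not in_gap:
            start, in_gap = t[i], True
        elif not m and in_gap:
            spans.append((float(start), float(t[i - 1])))
            in_gap = False
    if in_gap:
        spans.append((float(start), float(t[-1])))
    return spans


def detect_saccades(vel: VelocityTrace,
                    velocity_threshold: float = 30.0,
                    acceleration_threshold: float = 8000.0,
                    merge_ms: float = 20.0,
                    trace: EyeTrace | None = None) -> list[SaccadeEvent]:
    """Velocity+acceleration threshold saccade detection.

    A sample is saccadic when |v| > ``velocity_threshold`` (deg/s) AND the
    event contains samples with |a| > ``acceleration_threshold`` (deg/s^2);
    onset/offset are the velocity-threshold re-crossings.  Events closer
    than ``merge_ms`` are merged.  Landing positions are read from
    ``trace`` when given, else NaN.
    """
    v = np.asarray(vel.v, float)
    if v.size == 0:
        return []
    dt_s = float(np.median(np.diff(vel.t))) / 1000.0
    acc = np.gradient(v, dt_s)
    fast = np.abs(v) > velocity_threshold
    if not fast.any():
        return []
    runs = _runs(fast)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and (vel.t[a] - vel.t[merged[-1][1]]) < merge_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = []
    for a, b in merged:
        if np.max(np.abs(acc[a:b + 1])) < acceleration_threshold:
            continue
        amp = np.nan
        landing = (np.nan, np.nan)
        if trace is not None:
            amp = float(np.hypot(trace.x[b] - trace.x[a], trace.y[b] - trace.y[a]))
            landing = (float(trace.x[b]), float(trace.y[b]))
        events.append(SaccadeEvent(
            onset=float(vel.t[a]), offset=float(vel.t[b]),
            amplitude=0.0 if np.isnan(amp) else amp,
            peak_velocity=float(np.max(np.abs(v[a:b + 1]))),
            landing=landing))
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    ends = np.concatenate((idx[splits], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def desaccade(vel: VelocityTrace, events: list[SaccadeEvent],
              pad: float = 10.0) -> VelocityTrace:
    """Replace saccadic samples (padded by ``pad`` ms) by linear interpolation.

    Overlapping padded spans are merged into a single interpolation span.
    Spans touching the trace boundary hold the boundary value.  Samples
    outside padded spans are never changed.
    """
    if not events:
        return vel
    t = vel.t
    v = vel.v.copy()
    mask = vel.interpolated_mask.copy()
    cut = np.zeros(t.size, dtype=bool)
    for ev in events:
        cut |= (t >= ev.onset - pad) & (t <= ev.offset + pad)
    for a, b in _runs(cut):
        left = v[a - 1] if a > 0 else v[min(b + 1, v.size - 1)]
        right = v[b + 1] if b < v.size - 1 else v[max(a - 1, 0)]
        v[a:b + 1] = np.interp(t[a:b + 1],
                               [t[a] - (t[1] - t[0]), t[b] + (t[1] - t[0])],
                               [left, right])
        mask[a:b + 1] = True
    return replace(vel, v=v, interpolated_mask=mask)


def mean_pursuit_velocity(vel: VelocityTrace,
                          window: tuple[float, float] = (250.0, 500.0),
                          onset_marker: str = "target_onset",
                          quality_max_interp: float = 0.5) -> tuple[float, bool]:
    """Mean desaccaded horizontal velocity in ``[onset+start, onset+end)``.

    Returns ``(velocity, low_quality)``; the flag is set when more than
    ``quality_max_interp`` of the window samples were interpolated.
    """
    if onset_marker not in vel.markers:
        raise ValueError(f"missing marker {onset_marker!r}")
    onset = vel.markers[onset_marker]
    sel = (vel.t >= onset + window[0]) & (vel.t < onset + window[1])
    if not sel.any():
        raise ValueError("analysis window outside trace")
    frac_interp = float(vel.interpolated_mask[sel].mean())
    return float(vel.v[sel].mean()), frac_interp > quality_max_interp


def oculometric_decision(v_standard: float, v_comparison: float,
                         rng: np.random.Generator | None = None) -> bool:
    """True iff the comparison was pursued faster than the standard.

    Exact ties (measure-zero with real data) are broken by a seeded fair
    coin when ``rng`` is given, else by NumPy's default generator.
    """
    if not (np.isfinite(v_standard) and np.isfinite(v_comparison)):
        raise ValueError("velocities must be finite")
    if v_comparison == v_standard:
        rng = rng or np.random.default_rng()
        return bool(rng.integers(2))
    return bool(v_comparison > v_standard)


def saccade_endpoint(trace: EyeTrace, events: list[SaccadeEvent],
                     midline_x: float = 0.0) -> tuple[float, float] | None:
    """Landing position of the first saccade crossing the vertical midline.

    The vertical component is reported relative to the horizontal midline
    (targets sit at +-3 deg).  Returns None (trial invalid) when no saccade
    lands beyond ``midline_x``.
    """
    for ev in sorted(events, key=lambda e: e.onset):
        lx, ly = ev.landing
        if np.isfinite(lx) and lx > midline_x:
            return (float(lx), float(ly))
    return None


def running_average(series: np.ndarray, window_sd: float) -> np.ndarray:
    """Sliding-Gaussian-window running average with edge renormalization."""
    if window_sd < 0:
        raise ValueError("window_sd must be >= 0")
    series = np.asarray(series, float)
    if window_sd == 0 or series.size < 2:
        return series.copy()
    half = int(np.ceil(4 * window_sd))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / window_sd) ** 2)
    num = np.convolve(series, k, mode="same")
    den = np.convolve(np.ones_like(series), k, mode="same")
    return num / den
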