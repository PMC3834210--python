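"""Gait-event detection and reach-timing measures.

Foot events are found as sign changes of a marker's vertical velocity:
an upward zero crossing of a *toe* marker's velocity is a toe lift-off
(RTL/LTL), a downward crossing of a *heel* marker's velocity is a heel
strike (RHS/LHS).  The velocity is obtained from position by central
differences and optionally low-pass filtered (zero phase) before the
crossing search; crossing times are refined to sub-sample precision by
linear interpolation between the bracketing samples.

Timing measures follow the standard gait definitions: a gait cycle is the
interval between two successive lifts of the same toe; the stance phase
runs from a foot strike to the next same-foot lift and is expressed as a
percentage of the enclosing cycle.  Reaching is timed from the distance
of the hand to the world origin, which peaks at target contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "FootEvent",
    "EventTimeline",
    "ReachTiming",
    "detect_foot_events",
    "gait_cycle_durations",
    "stance_fractions",
    "reach_timing",
]

EVENT_TYPES = ("RTL", "RHS", "LTL", "LHS")


@dataclass(frozen=True)
class FootEvent:
    time: float  # seconds
    type: str  # one of RTL, RHS, LTL, LHS

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class EventTimeline:
    """Ordered foot-event sequence, possibly merged across channels."""

    events: list[FootEvent]
    source_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def merged_with(self, other: "EventTimeline") -> "EventTimeline":
        return EventTimeline(
            events=self.events + other.events,
            source_channels=self.source_channels + other.source_channels,
        )

    def times_of(self, event_type: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.type == event_type])

    def to_dict(self) -> dict:
        return {
            "events": [{"time": e.time, "type": e.type} for e in self.events],
            "source_channels": self.source_channels,
        }


@dataclass
class ReachTiming:
    """Timing of one reach relative to the gait events around it.

    reach_time : peak-hand-distance time, seconds.
    reach_duration : interval between the distance peaks bracketing the
        reach peak, seconds (> 0).
    couplings : signed intervals (seconds) from ``reach_time`` to each of
        the next four foot events, ascending.
    """

    reach_time: float
    reach_duration: float
    couplings: list[float]

    def __post_init__(self) -> None:
        if self.reach_duration <= 0:
            raise ValueError("reach_duration must be > 0")
        if sorted(self.couplings) != list(self.couplings):
            raise ValueError("couplings must be ascending")


def _zero_crossing_times(velocity: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample zero-crossing times and directions (+1 up, -1 down)."""
    v0, v1 = velocity[:-1], velocity[1:]
    idx = np.flatnonzero(np.signbit(v0) != np.signbit(v1))
    idx = idx[(v0[idx] != 0) | (v1[idx] != 0)]
    frac = v0[idx] / (v0[idx] - v1[idx])
    times = (idx + frac) / rate
    direction = np.where(v1[idx] > v0[idx], 1, -1)
    return times, direction


def detect_foot_events(
    series: np.ndarray,
    rate: float,
    *,
    foot: str = "R",
    marker: str = "toe",
    is_velocity: bool = False,
    smooth_cutoff: float | None = 10.0,
    refractory: float = 0.2,
    keep: str = "auto",
    channel_label: str | None = None,
) -> EventTimeline:
    """Detect foot events from a vertical marker trajectory (or velocity).

    Parameters
    ----------
    series : 1-D array
        Vertical position (default) or vertical velocity
        (``is_velocity=True``) of one toe or heel marker.
    rate : float
        Sampling rate in Hz.
    foot, marker : str
        ``foot`` is 'R' or 'L'; ``marker`` is 'toe' or 'heel' and sets
        which crossing direction is a typed event (toe: upward -> lift;
        heel: downward -> strike).
    smooth_cutoff : float or None
        Zero-phase Butterworth low-pass cutoff (Hz) applied to the
        velocity before the crossing search; None disables smoothing.
    refractory : float
        Minimum inter-event interval (s); later crossings inside the
        window are discarded as noise-induced double crossings.
    keep : {'auto', 'all'}
        'auto' keeps only the crossing direction meaningful for the marker
        kind; 'all' types every crossing by its direction (up -> lift,
        down -> strike), useful for diagnostics.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 10:
        raise ValueError("series must have at least 10 samples")
    if foot not in ("R", "L"):
        raise ValueError("foot must be 'R' or 'L'")
    if marker not in ("toe", "heel"):
        raise ValueError("marker must be 'toe' or 'heel'")
    velocity = series if is_velocity else np.gradient(series) * rate
    if smooth_cutoff is not None and smooth_cutoff < rate / 2:
        b, a = butter(2, smooth_cutoff / (rate / 2))
        velocity = filtfilt(b, a, velocity)
    times, direction = _zero_crossing_times(velocity, rate)
    if keep == "auto":
        wanted = 1 if marker == "toe" else -1
        mask = direction == wanted
        times, direction = times[mask], direction[mask]
    events = []
    last = -np.inf
    for t, d in zip(times, direction):
        if t - last < refractory:
            continue
        kind = "TL" if d > 0 else "HS"
        events.append(FootEvent(time=float(t), type=f"{foot}{kind}"))
        last = t
    if not events:
        warnings.warn("no velocity sign changes found; empty timeline", stacklevel=2)
    label = channel_label or f"{foot}_{marker}"
    return EventTimeline(events=events, source_channels=[label])


def _foot_times(timeline: EventTimeline, foot: str) -> tuple[np.ndarray, np.ndarray]:
    lifts = timeline.times_of(f"{foot}TL")
    strikes = timeline.times_of(f"{foot}HS")
    return lifts, strikes


def gait_cycle_durations(timeline: EventTimeline, foot: str = "R") -> np.ndarray:
    """Durations between successive same-foot toe lifts, seconds."""
    lifts, _ = _foot_times(timeline, foot)
    if len(lifts) < 2:
        raise ValueError(f"need at least 2 {foot}TL events, got {len(lifts)}")
    return np.diff(lifts)


def stance_fractions(timeline: EventTimeline, foot: str = "R") -> np.ndarray:
    """Stance (strike to next same-foot lift) as % of the enclosing gait cycle.

    For each strike the enclosing cycle runs from the same-foot lift
    preceding the strike to the lift following it.  Strikes without both
    bracketing lifts are skipped with a warning.
    """
    lifts, strikes = _foot_times(timeline, foot)
    out = []
    skipped = 0
    for s in strikes:
        before = lifts[lifts < s]
        after = lifts[lifts > s]
        if len(before) == 0 or len(after) == 0:
            skipped += 1
            continue
        cycle = after[0] - before[-1]
        out.append(100.0 * (after[0] - s) / cycle)
    if skipped:
        warnings.warn(f"skipped {skipped} unpaired strike(s) for foot {foot}", stacklevel=2)
    return np.asarray(out)


def reach_timing(hand_distance: np.ndarray, rate: float, timeline: EventTimeline) -> ReachTiming:
    """Time the reach from the hand-distance series and couple it to foot events.

    The reach time is the (parabolically refined) global maximum of the
    distance series, which must be an interior local maximum; the reach
    duration is the interval between the local distance peaks bracketing
    it; the couplings are the signed intervals to the next four foot
    events (an event coincident with the reach counts with interval 0).
    """
    x = np.asarray(hand_distance, dtype=float)
    peaks, _ = find_peaks(x)
    if len(peaks) == 0:
        raise ValueError("hand-distance series has no interior local maximum")
    top = peaks[np.argmax(x[peaks])]
    if np.argmax(x) in (0, len(x) - 1):
        raise ValueError("global hand-distance maximum at the series boundary; invalid trial")
    # parabolic sub-sample refinement of the peak
    y0, y1, y2 = x[top - 1], x[top], x[top + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
    reach_time = (top + offset) / rate
    before = peaks[peaks < top]
    after = peaks[peaks > top]
    if len(before) == 0 or len(after) == 0:
        raise ValueError("reach peak is not bracketed by neighbouring distance peaks")
    reach_duration = (after[0] - before[-1]) / rate
    upcoming = [e.time - reach_time for e in timeline.events if e.time >= reach_time - 1e-9]
    if len(upcoming) < 4:
        raise ValueError(f"need 4 foot events after the reach, found {len(upcoming)}")
    return ReachTiming(
        reach_time=float(reach_time),
        reach_duration=float(reach_duration),
        couplings=[float(c) for c in upcoming[:4]],
    )
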