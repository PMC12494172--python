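"""Gaze-stream processing: I-VT fixation classification, AOI assignment,
and windowed fixation summaries for a food Pavlovian conditioning task.

The task presents four fractal conditioned stimuli (CS) paired with candy
rewards of value 2, 1, 0 and 0 (the last with a buzzer). Gaze is recorded
at 50 Hz with a head-mounted eye tracker; scene coordinates are expressed
directly in visual degrees. Fixations are classified with a
velocity-threshold (I-VT) filter and assigned to one of three areas of
interest: the CS image, the reward-delivery location (UCS), or background
(BG). The behavioral readout per trial is the gaze index
``p(CS) - p(UCS)`` over valid fixation time in the late window of CS
presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GazeStream",
    "FixationEvent",
    "AOIRect",
    "AOILayout",
    "TrialRecord",
    "TrialFixationSummary",
    "classify_fixations",
    "gaze_sample_quality",
    "assign_aoi",
    "window_summary",
    "summarize_trials",
    "apply_exclusions",
    "DEFAULT_VELOCITY_THRESHOLD",
    "DEFAULT_MIN_FIXATION_MS",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_QC_THRESHOLD",
    "DEFAULT_KEEP_PER_CS_TYPE",
]

#: I-VT angular velocity threshold separating fixations from saccades (deg/s).
DEFAULT_VELOCITY_THRESHOLD = 30.0
#: Minimum duration for a valid fixation (ms).
DEFAULT_MIN_FIXATION_MS = 50.0
#: Analysis window: last portion of the 3 s CS presentation (ms).
DEFAULT_WINDOW_MS = 1500.0
#: Participant-level minimum percentage of valid gaze samples.
DEFAULT_QC_THRESHOLD = 80.0
#: Experimental trials retained per CS type (the trailing 4 of 16 are dropped).
DEFAULT_KEEP_PER_CS_TYPE = 12


@dataclass
class GazeStream:
    """Timestamped gaze samples in scene coordinates (visual degrees).

    ``t`` is in milliseconds and must be strictly increasing; the nominal
    inter-sample interval is 20 ms (50 Hz). ``valid`` flags samples the
    tracker identified as genuine eye positions.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("gaze stream arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FixationEvent:
    """A classified fixation: start/end timestamps (ms) and centroid (deg)."""

    start: float
    end: float
    cx: float
    cy: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AOIRect:
    """Axis-aligned rectangle in scene degrees; closed boundaries."""

    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def mirrored(self) -> "AOIRect":
        """Reflection about the vertical scene midline (x -> -x)."""
        return AOIRect(-self.x1, -self.x0, self.y0, self.y1)

    def overlaps(self, other: "AOIRect") -> bool:
        return not (
            self.x1 < other.x0
            or other.x1 < self.x0
            or self.y1 < other.y0
            or other.y1 < self.y0
        )


@dataclass(frozen=True)
class AOILayout:
    """CS and UCS rectangles for the reference (CS-left) orientation.

    Everything outside both rectangles is background (BG). The layout is
    mirrored about the vertical midline when a trial runs in the CS-right
    orientation.
    """

    cs: AOIRect
    ucs: AOIRect

    def __post_init__(self) -> None:
        if self.cs.overlaps(self.ucs):
            raise ValueError("CS and UCS AOI rectangles must be disjoint")

    def oriented(self, orientation: str) -> "AOILayout":
        if orientation == "CS-left":
            return self
        if orientation == "CS-right":
            return AOILayout(cs=self.cs.mirrored(), ucs=self.ucs.mirrored())
        raise ValueError(f"unknown orientation: {orientation!r}")


# Default scene geometry: CS image left of center, candy dispenser right,
# symmetric about the midline so the orientation switch is an exact mirror.
DEFAULT_LAYOUT = AOILayout(
    cs=AOIRect(-14.0, -4.0, -5.0, 5.0),
    ucs=AOIRect(4.0, 14.0, -5.0, 5.0),
)


@dataclass(frozen=True)
class TrialRecord:
    """One task trial: CS identity/value, timing (ms), orientation."""

    index: int  # 1-based within shaping / experimental sequence
    cs_type: int  # 1..4
    cs_value: float  # 2, 1, 0, 0
    cs_onset: float
    cs_offset: float
    orientation: str  # "CS-left" | "CS-right"
    shaping: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("CS-left", "CS-right"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class TrialFixationSummary:
    """Percent of valid fixation time per AOI in the late-CS window."""

    trial: TrialRecord
    pct_cs: float
    pct_ucs: float
    pct_bg: float
    valid_fix_time: float  # ms of fixation overlap with the window

    @property
    def gaze_index(self) -> float:
        """(pct_cs - pct_ucs)/100; NaN when no fixation time in window."""
        if self.valid_fix_time <= 0:
            return float("nan")
        return (self.pct_cs - self.pct_ucs) / 100.0


def classify_fixations(
    stream: GazeStream,
    velocity_threshold: float = DEFAULT_VELOCITY_THRESHOLD,
    min_duration: float = DEFAULT_MIN_FIXATION_MS,
    max_gap_ms: float = 0.0,
    merge_max_ms: float = 0.0,
    merge_max_deg: float = 0.0,
) -> list[FixationEvent]:
    """Classify gaze samples into fixations with an I-VT filter.

    Point-to-point angular velocity between consecutive valid samples is
    compared against ``velocity_threshold`` (deg/s). Maximal runs of valid
    samples whose internal velocities all stay strictly below the threshold
    and that span at least ``min_duration`` ms become fixations with the
    (time-weighted) mean position as centroid. Invalid samples terminate a
    run unless the gap is at most ``max_gap_ms`` (gap fill-in, off by
    default). Adjacent fixations closer than ``merge_max_ms`` in time and
    ``merge_max_deg`` in space are merged when both are positive (off by
    default).
    """
    if velocity_threshold <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    if len(stream) == 0:
        raise ValueError("empty gaze stream")

    idx = np.flatnonzero(stream.valid)
    if len(idx) < 2:
        return []

    t = stream.t[idx]
    x = stream.x[idx]
    y = stream.y[idx]
    dt = np.diff(t)  # ms
    dist = np.hypot(np.diff(x), np.diff(y))  # deg
    vel = dist / (dt / 1000.0)  # deg/s

    # A transition between consecutive valid samples continues a fixation run
    # when it is slow AND the samples are consecutive in the raw stream
    # (or the raw gap is within the fill-in allowance).
    raw_gap = np.diff(stream.t[idx]) if max_gap_ms > 0 else dt
    contiguous = np.diff(idx) == 1
    if max_gap_ms > 0:
        contiguous = contiguous | (raw_gap <= max_gap_ms)
    link = (vel < velocity_threshold) & contiguous

    events: list[FixationEvent] = []
    start = 0
    for i in range(len(link) + 1):
        if i == len(link) or not link[i]:
            stop = i  # run covers valid samples start..stop inclusive
            if stop > start:
                dur = t[stop] - t[start]
                if dur >= min_duration:
                    sl = slice(start, stop + 1)
                    events.append(
                        FixationEvent(
                            start=float(t[start]),
                            end=float(t[stop]),
                            cx=float(np.mean(x[sl])),
                            cy=float(np.mean(y[sl])),
                        )
                    )
            start = i + 1

    if merge_max_ms > 0 and merge_max_deg > 0 and len(events) > 1:
        merged = [events[0]]
        for ev in events[1:]:
            prev = merged[-1]
            if (
                ev.start - prev.end <= merge_max_ms
                and np.hypot(ev.cx - prev.cx, ev.cy - prev.cy) <= merge_max_deg
            ):
                w1, w2 = prev.duration, ev.duration
                tot = w1 + w2 if (w1 + w2) > 0 else 1.0
                merged[-1] = FixationEvent(
                    start=prev.start,
                    end=ev.end,
                    cx=(prev.cx * w1 + ev.cx * w2) / tot,
                    cy=(prev.cy * w1 + ev.cy * w2) / tot,
                )
            else:
                merged.append(ev)
        events = merged

    return events


def gaze_sample_quality(stream: GazeStream) -> float:
    """Percentage of valid samples over the recording span."""
    if len(stream) == 0:
        raise ValueError("empty gaze stream")
    return 100.0 * float(np.count_nonzero(stream.valid)) / len(stream)


def assign_aoi(fixation: FixationEvent, layout: AOILayout, orientation: str) -> str:
    """AOI role ("CS", "UCS" or "BG") of a fixation centroid.

    The layout is defined for the CS-left orientation and mirrored about
    the vertical midline for CS-right trials.
    """
    lay = layout.oriented(orientation)
    if lay.cs.contains(fixation.cx, fixation.cy):
        return "CS"
    if lay.ucs.contains(fixation.cx, fixation.cy):
        return "UCS"
    return "BG"


def window_summary(
    trial: TrialRecord,
    fixations: Sequence[FixationEvent],
    layout: AOILayout,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> TrialFixationSummary:
    """Percent fixation per AOI in the last ``window_ms`` of CS presentation.

    Each fixation contributes its temporal overlap with
    ``[cs_offset - window_ms, cs_offset]`` to the AOI containing its
    centroid (pro-rated for fixations straddling the window boundary).
    Percents are shares of the total overlapped fixation time; the gaze
    index is defined only when that total is positive.
    """
    w0 = trial.cs_offset - window_ms
    w1 = trial.cs_offset
    time_in = {"CS": 0.0, "UCS": 0.0, "BG": 0.0}
    for fx in fixations:
        overlap = min(fx.end, w1) - max(fx.start, w0)
        if overlap > 0:
            time_in[assign_aoi(fx, layout, trial.orientation)] += overlap
    total = sum(time_in.values())
    if total > 0:
        pct = {k: 100.0 * v / total for k, v in time_in.items()}
    else:
        pct = {k: float("nan") for k in time_in}
    return TrialFixationSummary(
        trial=trial,
        pct_cs=pct["CS"],
        pct_ucs=pct["UCS"],
        pct_bg=pct["BG"],
        valid_fix_time=total,
    )


def summarize_trials(
    trials: Iterable[TrialRecord],
    fixations: Sequence[FixationEvent],
    layout: AOILayout,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> list[TrialFixationSummary]:
    """Window summaries for every experimental (non-shaping) trial."""
    return [
        window_summary(tr, fixations, layout, window_ms)
        for tr in trials
        if not tr.shaping
    ]


def apply_exclusions(
    summaries: Sequence[TrialFixationSummary],
    keep_per_cs_type: int = DEFAULT_KEEP_PER_CS_TYPE,
) -> list[TrialFixationSummary]:
    """Drop shaping trials and the trailing trials of each CS type.

    The last presentations of each CS suffer degraded tracking quality
    (fatigue, head movement), so only the first ``keep_per_cs_type``
    experimental trials per CS type are retained — 12 of 16 by default,
    leaving 48 trials.
    """
    out: list[TrialFixationSummary] = []
    by_type: dict[int, int] = {}
    n_exp: dict[int, int] = {}
    for s in summaries:
        if s.trial.shaping:
            continue
        n_exp[s.trial.cs_type] = n_exp.get(s.trial.cs_type, 0) + 1
    short = {k for k, v in n_exp.items() if v < keep_per_cs_type}
    if short:
        warnings.warn(
            f"CS types {sorted(short)} have fewer than {keep_per_cs_type} "
            "experimental trials; keeping all",
            stacklevel=2,
        )
    for s in sorted((s for s in summaries if not s.trial.shaping), key=lambda s: s.trial.index):
        k = s.trial.cs_type
        by_type[k] = by_type.get(k, 0) + 1
        if by_type[k] <= keep_per_cs_type:
            out.append(s)
    return out
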