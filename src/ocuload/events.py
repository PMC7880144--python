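"""Velocity-threshold (I-VT) fixation/saccade classification, saccadic
intrusion detection, and event-rate utilities.

I-VT compares the instantaneous angular gaze speed against a fixed
threshold (30 deg/s by default): below-threshold runs become fixation
candidates, above-threshold runs become saccades.  Speed is estimated by a
central difference over a short sample window (3 samples by default)
because two-point differencing of 100 Hz gaze data amplifies tracker noise.

A saccadic intrusion is an involuntary horizontal excursion away from the
fixated position followed by a return: the gaze x-coordinate departs from
its pre-excursion reference by more than ``min_deviation`` (0.4 deg) and
comes back within ``return_tolerance`` of the reference after 60-870 ms.
The reference is the mean gaze over the 100 ms preceding onset; the
departure threshold applies to x only (intrusions are horizontal), while
the return must be to the same position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .io import GazeRecording

__all__ = [
    "OcularEvent",
    "IVTParams",
    "SIParams",
    "gaze_velocity",
    "ivt_classify",
    "detect_intrusions",
    "event_rate",
    "windowed_counts",
    "events_to_frame",
]

EventKind = Literal["fixation", "saccade", "intrusion"]


@dataclass
class OcularEvent:
    """A classified ocular event: fixation, saccade, or saccadic intrusion.

    Geometry fields are populated where meaningful: centroid for fixations,
    amplitude for saccades/intrusions, peak velocity for saccades.
    """

    kind: EventKind
    t_start: float
    t_end: float
    centroid_x: float = np.nan
    centroid_y: float = np.nan
    amplitude: float = np.nan
    peak_velocity: float = np.nan

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValidationError("event must have t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class IVTParams:
    """I-VT filter parameters (angular threshold in deg/s, durations in s)."""

    velocity_threshold: float = 30.0
    min_fixation_duration: float = 0.060
    max_gap_fill: float = 0.075
    velocity_window: int = 3

    def __post_init__(self) -> None:
        if not self.velocity_threshold > 0:
            raise ValidationError("velocity_threshold must be positive")
        if self.min_fixation_duration < 0 or self.max_gap_fill < 0:
            raise ValidationError("durations must be non-negative")
        if self.velocity_window < 2:
            raise ValidationError("velocity_window must span at least 2 samples")


@dataclass(frozen=True)
class SIParams:
    """Saccadic-intrusion detector parameters (times in s, angles in deg)."""

    min_return: float = 0.060
    max_return: float = 0.870
    min_deviation: float = 0.4
    return_tolerance: float = 0.4
    reference_window: float = 0.100
    max_deviation: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.min_return < self.max_return:
            raise ValidationError("need 0 < min_return < max_return")
        if not self.min_deviation > 0:
            raise ValidationError("min_deviation must be positive")
        if not self.return_tolerance > 0:
            raise ValidationError("return_tolerance must be positive")
        if not self.max_deviation > self.min_deviation:
            raise ValidationError("max_deviation must exceed min_deviation")


def gaze_velocity(recording: GazeRecording, window: int = 3) -> np.ndarray:
    """Per-sample angular speed (deg/s) by central difference.

    The speed at sample ``i`` is the 2-D angular displacement between
    samples ``i-h`` and ``i+h`` (``h = window // 2``) divided by the elapsed
    time; at the record edges the window is clipped (one-sided difference).
    Samples that are invalid, or whose difference window touches an invalid
    sample, get NaN.
    """
    t, x, y = recording.t, recording.x, recording.y
    n = len(t)
    if int(np.sum(recording.valid)) < 2:
        raise InsufficientDataError("need at least 2 valid samples for velocity")
    h = max(window // 2, 1)
    idx = np.arange(n)
    j0 = np.clip(idx - h, 0, n - 1)
    j1 = np.clip(idx + h, 0, n - 1)
    dt = t[j1] - t[j0]
    dx = x[j1] - x[j0]
    dy = y[j1] - y[j0]
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.hypot(dx, dy) / dt
    speed[dt <= 0] = np.nan
    # endpoints or the sample itself invalid -> speed undefined there
    bad = ~recording.valid | np.isnan(x)
    speed[bad | bad[j0] | bad[j1]] = np.nan
    return speed


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Contiguous runs of identical labels as (start, stop_exclusive, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def ivt_classify(recording: GazeRecording, params: IVTParams = IVTParams()) -> list[OcularEvent]:
    """Classify a recording into fixations and saccades with the I-VT filter.

    Below-threshold runs lasting at least ``min_fixation_duration`` become
    fixations (centroid = mean valid position); above-threshold runs become
    saccades whose amplitude is the angular distance between the bounding
    fixation centroids (run endpoints at the record edges).  Invalid
    stretches shorter than ``max_gap_fill`` flanked by the same class are
    absorbed into it.  Events never overlap in time.
    """
    t, x, y = recording.t, recording.x, recording.y
    n = len(t)
    if n == 0 or not recording.valid.any():
        warnings.warn("all samples invalid; no events classified")
        return []
    speed = gaze_velocity(recording, params.velocity_window)

    labels = np.where(np.isnan(speed), "G", np.where(speed < params.velocity_threshold, "F", "S"))
    # absorb short gaps flanked by one class
    runs = _runs(labels)
    for k, (i0, i1, lab) in enumerate(runs):
        if lab != "G" or k == 0 or k == len(runs) - 1:
            continue
        prev_lab, next_lab = runs[k - 1][2], runs[k + 1][2]
        gap = t[i1 - 1] - t[i0]
        if prev_lab == next_lab and prev_lab != "G" and gap <= params.max_gap_fill:
            labels[i0:i1] = prev_lab
    runs = _runs(labels)

    def _end_time(i1: int) -> float:
        return t[i1] if i1 < n else float(t[-1] + 1.0 / recording.nominal_rate)

    # first pass: fixation events (needed for saccade amplitudes)
    fixations: dict[int, OcularEvent] = {}
    for k, (i0, i1, lab) in enumerate(runs):
        if lab != "F":
            continue
        t0, t1 = t[i0], _end_time(i1)
        if t1 - t0 < params.min_fixation_duration:
            continue
        cx = float(np.nanmean(x[i0:i1]))
        cy = float(np.nanmean(y[i0:i1]))
        fixations[k] = OcularEvent("fixation", float(t0), float(t1), centroid_x=cx, centroid_y=cy)

    events: list[OcularEvent] = []
    for k, (i0, i1, lab) in enumerate(runs):
        if lab == "F":
            if k in fixations:
                events.append(fixations[k])
            continue
        if lab != "S":
            continue
        before = fixations.get(k - 1)
        after = fixations.get(k + 1)
        x0, y0 = (before.centroid_x, before.centroid_y) if before else (x[i0], y[i0])
        x1, y1 = (after.centroid_x, after.centroid_y) if after else (x[i1 - 1], y[i1 - 1])
        amp = float(np.hypot(x1 - x0, y1 - y0))
        events.append(
            OcularEvent(
                "saccade",
                float(t[i0]),
                float(_end_time(i1)),
                amplitude=amp,
                peak_velocity=float(np.nanmax(speed[i0:i1])),
            )
        )
    return events


def detect_intrusions(
    recording: GazeRecording, params: SIParams = SIParams()
) -> list[OcularEvent]:
    """Detect saccadic intrusions on the horizontal gaze channel.

    An intrusion starts when x departs from its pre-excursion reference
    (mean gaze over the preceding ``reference_window``) by more than
    ``min_deviation`` and ends at the first sample where the gaze is back
    within ``return_tolerance`` of the reference position (both
    coordinates), provided that return happens after ``min_return`` and no
    later than ``max_return``.  The departure criterion is horizontal-only
    — intrusions are conjugate horizontal movements — but the return is a
    return to the same position, which is what separates an intrusion from
    a pair of ordinary saccades that happen to revisit the same x.
    Excursions larger than ``max_deviation`` in x are rejected as
    deliberate gaze shifts (intrusions are only a few times larger than
    microsaccades).  Candidates are resolved greedily by onset so
    detections never overlap.
    """
    t, x, y = recording.t, recording.x, recording.y
    n = len(t)
    if n == 0:
        return []
    # trailing mean gaze over the reference window, excluding the current sample
    win = max(int(round(params.reference_window * recording.nominal_rate)), 1)
    ref_x = pd.Series(x).shift(1).rolling(win, min_periods=1).mean().to_numpy()
    ref_y = pd.Series(y).shift(1).rolling(win, min_periods=1).mean().to_numpy()

    dev = np.abs(x - ref_x)
    events: list[OcularEvent] = []
    i = 1
    while i < n:
        if not (dev[i] > params.min_deviation) or (dev[i - 1] > params.min_deviation):
            i += 1
            continue
        r = ref_x[i]
        ry = ref_y[i]
        if np.isnan(r):
            i += 1
            continue
        onset = t[i]
        matched = False
        for j in range(i + 1, n):
            dt = t[j] - onset
            if dt > params.max_return:
                break
            if np.isnan(x[j]):
                continue
            returned_y = np.isnan(ry) or np.isnan(y[j]) or abs(y[j] - ry) <= params.return_tolerance
            if abs(x[j] - r) <= params.return_tolerance and returned_y:
                if dt < params.min_return:
                    break  # returned too fast: ordinary jitter, not an intrusion
                amp = float(np.nanmax(np.abs(x[i:j + 1] - r)))
                if amp > params.max_deviation:
                    break  # too large: a deliberate gaze shift, not an intrusion
                events.append(
                    OcularEvent("intrusion", float(onset), float(t[j]), amplitude=amp)
                )
                i = j + 1
                matched = True
                break
        if not matched:
            i += 1
    return events


def event_rate(
    events: Iterable[OcularEvent],
    kind: EventKind,
    duration: float,
    t_start: float = 0.0,
    per: str = "second",
) -> float:
    """Rate of events of one kind whose onset falls in
    ``[t_start, t_start + duration)``, per second or per minute."""
    if not duration > 0:
        raise ValidationError("duration must be positive")
    count = sum(
        1
        for e in events
        if e.kind == kind and t_start <= e.t_start < t_start + duration
    )
    rate = count / duration
    if per == "minute":
        return rate * 60.0
    if per != "second":
        raise ValidationError(f"unknown rate unit {per!r}")
    return rate


def windowed_counts(
    events: Iterable[OcularEvent],
    window: float,
    span: float,
    kind: EventKind | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Event counts (by onset) in consecutive half-open windows of ``window``
    seconds covering ``[t0, t0 + span)``; a trailing partial window is
    flagged ``complete=False``."""
    if not window > 0:
        raise ValidationError("window must be positive")
    n_win = int(np.ceil(span / window))
    counts = np.zeros(n_win, int)
    for e in events:
        if kind is not None and e.kind != kind:
            continue
        k = int(np.floor((e.t_start - t0) / window))
        if 0 <= k < n_win and e.t_start < t0 + span:
            counts[k] += 1
    starts = t0 + window * np.arange(n_win)
    complete = starts + window <= t0 + span + 1e-12
    return pd.DataFrame({"window_start": starts, "count": counts, "complete": complete})


def events_to_frame(events: Sequence[OcularEvent]) -> pd.DataFrame:
    """Events as a DataFrame (the CSV interchange layout)."""
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "centroid_x": e.centroid_x,
                "centroid_y": e.centroid_y,
                "amplitude": e.amplitude,
                "peak_velocity": e.peak_velocity,
            }
            for e in events
        ],
        columns=["kind", "t_start", "t_end", "centroid_x", "centroid_y", "amplitude", "peak_velocity"],
    )


def frame_to_events(frame: pd.DataFrame) -> list[OcularEvent]:
    return [
        OcularEvent(
            str(r.kind),
            float(r.t_start),
            float(r.t_end),
            centroid_x=float(r.centroid_x),
            centroid_y=float(r.centroid_y),
            amplitude=float(r.amplitude),
            peak_velocity=float(r.peak_velocity),
        )
        for r in frame.itertuples()
    ]
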