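"""Sum-of-sines boundary-avoidance tracking task: target signal, boundary
schedule, and pilot-inceptor-workload / performance metrics.

The tracking target moves in pitch as the sum of five sinusoids at
incommensurate frequencies (so the motion is hard to anticipate).  Error
boundaries start at +/-5 deg around the target and shrink by 20% after
every 60 s, which progressively raises the pilot's control gain and hence
workload.  Inceptor workload is quantified by the duty cycle (percentage of
time with significant stick movement) and aggressiveness (RMS stick speed,
deg/s); task performance by the pitch tracking error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .events import OcularEvent

__all__ = [
    "SOSSpec",
    "BoundarySchedule",
    "TrackingTrace",
    "ErrorSummary",
    "sos_signal",
    "boundary_at",
    "stick_rate",
    "duty_cycle",
    "aggressiveness",
    "tracking_error",
    "per_boundary_metrics",
]

#: Default five-component spec: incommensurate frequencies spanning
#: 0.05-0.6 Hz with amplitudes decreasing toward higher frequency.  These
#: defaults are package choices, fully configurable.
DEFAULT_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (1.5, 0.054, 0.0),
    (1.2, 0.117, 1.1),
    (1.0, 0.205, 2.3),
    (0.7, 0.331, 0.7),
    (0.4, 0.563, 1.9),
)


@dataclass(frozen=True)
class SOSSpec:
    """Sum-of-sines target: (amplitude deg, frequency Hz, phase rad) terms."""

    components: tuple[tuple[float, float, float], ...] = DEFAULT_COMPONENTS

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValidationError("SOSSpec needs at least one component")
        freqs = [f for _, f, _ in self.components]
        amps = [a for a, _, _ in self.components]
        if any(f <= 0 for f in freqs) or len(set(freqs)) != len(freqs):
            raise ValidationError("frequencies must be positive and distinct")
        if any(a <= 0 for a in amps):
            raise ValidationError("amplitudes must be positive")

    @property
    def rms(self) -> float:
        """RMS of the signal over an infinitely long window (closed form)."""
        return float(np.sqrt(sum(a * a / 2 for a, _, _ in self.components)))


def sos_signal(spec: SOSSpec, t: np.ndarray | Sequence[float]) -> np.ndarray:
    """Evaluate the sum-of-sines target pitch (degrees) on a time grid."""
    t = np.asarray(t, float)
    if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
        raise ValidationError("time grid must be 1-D and increasing")
    out = np.zeros_like(t)
    for a, f, ph in spec.components:
        out += a * np.sin(2 * np.pi * f * t + ph)
    return out


@dataclass(frozen=True)
class BoundarySchedule:
    """Boundary half-width schedule: hold for ``step_interval`` seconds then
    shrink by ``shrink_fraction`` (5 deg, 20%, 60 s by default)."""

    initial_half_width: float = 5.0
    shrink_fraction: float = 0.2
    step_interval: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.shrink_fraction < 1:
            raise ValidationError("shrink_fraction must lie in (0, 1)")
        if not self.step_interval > 0:
            raise ValidationError("step_interval must be positive")
        if not self.initial_half_width > 0:
            raise ValidationError("initial_half_width must be positive")


def boundary_at(
    schedule: BoundarySchedule, t: float | np.ndarray
) -> float | np.ndarray:
    """Boundary half-width at time ``t``:
    ``initial * (1 - shrink)**floor(t / step_interval)``."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    steps = np.floor(t / schedule.step_interval)
    hw = schedule.initial_half_width * (1.0 - schedule.shrink_fraction) ** steps
    return float(hw) if hw.ndim == 0 else hw


@dataclass
class TrackingTrace:
    """Time-aligned tracking-task channels (all in degrees)."""

    t: np.ndarray
    target_pitch: np.ndarray
    own_pitch: np.ndarray
    stick: np.ndarray
    boundary_half_width: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.t, self.target_pitch, self.own_pitch, self.stick, self.boundary_half_width]
        for i, a in enumerate(arrays):
            arrays[i] = np.asarray(a, float)
        self.t, self.target_pitch, self.own_pitch, self.stick, self.boundary_half_width = arrays
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValidationError("trace channels must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "target_pitch": self.target_pitch,
                "own_pitch": self.own_pitch,
                "stick": self.stick,
                "boundary_half_width": self.boundary_half_width,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackingTrace":
        f = pd.read_csv(path)
        return cls(
            f["t"].to_numpy(),
            f["target_pitch"].to_numpy(),
            f["own_pitch"].to_numpy(),
            f["stick"].to_numpy(),
            f["boundary_half_width"].to_numpy(),
        )


def stick_rate(stick: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Stick deflection rate (deg/s) by central difference (one-sided at the
    edges) — the same estimator used for gaze velocity."""
    stick = np.asarray(stick, float)
    t = np.asarray(t, float)
    if len(stick) < 2:
        raise ValidationError("need at least 2 samples for a rate")
    return np.gradient(stick, t)


def duty_cycle(
    stick: np.ndarray, t: np.ndarray, movement_threshold: float = 1.0
) -> float:
    """Percentage of time with significant stick movement: the fraction of
    samples whose absolute stick rate exceeds ``movement_threshold`` deg/s,
    times 100."""
    rate = np.abs(stick_rate(stick, t))
    return float(np.mean(rate > movement_threshold) * 100.0)


def aggressiveness(stick: np.ndarray, t: np.ndarray) -> float:
    """RMS stick movement speed in deg/s."""
    rate = stick_rate(stick, t)
    return float(np.sqrt(np.mean(rate**2)))


@dataclass
class ErrorSummary:
    """Tracking-error series and summary statistics."""

    error: np.ndarray
    mean_abs: float
    rms: float
    n_hits: int
    hit_fraction: float


def tracking_error(trace: TrackingTrace) -> ErrorSummary:
    """Pitch tracking error ``own - target`` with boundary-hit accounting.

    A boundary hit is a contiguous excursion with ``|error| >=
    boundary_half_width``; ``n_hits`` counts excursions, ``hit_fraction``
    the fraction of samples inside one.
    """
    err = trace.own_pitch - trace.target_pitch
    inside = np.abs(err) >= trace.boundary_half_width
    # count rising edges of the hit mask
    n_hits = int(np.sum(np.diff(np.concatenate(([False], inside)).astype(int)) == 1))
    return ErrorSummary(
        error=err,
        mean_abs=float(np.mean(np.abs(err))),
        rms=float(np.sqrt(np.mean(err**2))),
        n_hits=n_hits,
        hit_fraction=float(np.mean(inside)),
    )


def per_boundary_metrics(
    trace: TrackingTrace,
    events: Iterable[OcularEvent],
    schedule: BoundarySchedule,
    movement_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-boundary-step metric table.

    The trace is cut at the schedule's step boundaries (anchored at t = 0);
    each row reports the step's half-width, fixation and saccade counts
    (events attributed by onset), stick duty cycle and aggressiveness, and
    the median absolute tracking error.  A trailing partial step is kept
    and flagged ``complete=False`` so counts conserve against whole-trace
    totals.
    """
    t = trace.t
    span = t[-1] - t[0]
    if span < schedule.step_interval:
        warnings.warn("trace shorter than one boundary step; empty metric table")
        return pd.DataFrame(
            columns=["step", "t_start", "t_end", "boundary_half_width",
                     "n_fixations", "n_saccades", "duty_cycle_pct",
                     "aggressiveness", "median_abs_error", "complete"]
        )
    events = list(events)
    t_last = t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0)
    n_steps = int(np.ceil(t_last / schedule.step_interval))
    rows = []
    err = trace.own_pitch - trace.target_pitch
    for k in range(n_steps):
        a = k * schedule.step_interval
        b = (k + 1) * schedule.step_interval
        mask = (t >= a) & (t < b)
        if mask.sum() < 2:
            continue
        rows.append(
            {
                "step": k,
                "t_start": a,
                "t_end": b,
                "boundary_half_width": boundary_at(schedule, a),
                "n_fixations": sum(
                    1 for e in events if e.kind == "fixation" and a <= e.t_start < b
                ),
                "n_saccades": sum(
                    1 for e in events if e.kind == "saccade" and a <= e.t_start < b
                ),
                "duty_cycle_pct": duty_cycle(trace.stick[mask], t[mask], movement_threshold),
                "aggressiveness": aggressiveness(trace.stick[mask], t[mask]),
                "median_abs_error": float(np.median(np.abs(err[mask]))),
                "complete": bool(t_last >= b - 1e-9),
            }
        )
    return pd.DataFrame(rows)
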