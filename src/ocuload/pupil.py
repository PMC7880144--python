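"""Pupil-diameter preprocessing and the Measure of Pupillary Cognition (MPC).

MPC is a spectral workload index: the pupil-diameter signal is cut into
fixed-length buffers (1 s by default), each buffer is mean-removed and
discrete-Fourier-transformed, and the single-sided magnitudes of all bins
whose centre frequency lies in the 1-5 Hz band (inclusive) are summed.
With 1 s buffers at 100 Hz those are exactly the 1, 2, 3, 4 and 5 Hz bins.

Magnitude convention: single-sided magnitudes are scaled by 2/N (1/N for
the DC and Nyquist bins), so a bin-centred sinusoid of amplitude A
contributes magnitude A regardless of buffer length.  The per-buffer mean
is removed before the transform to keep DC leakage out of the 1 Hz bin;
both the mean removal and the (rectangular by default) window are
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError

__all__ = [
    "PupilSeries",
    "MPCSeries",
    "ConditionSummary",
    "preprocess_pupil",
    "mpc",
    "mpc_condition_summary",
    "pupil_sd",
]

PUPIL_RANGE_MM = (0.0, 12.0)


@dataclass
class PupilSeries:
    """Timestamped pupil-diameter signal for one eye (mm; NaN = missing)."""

    t: np.ndarray
    diameter: np.ndarray
    eye: str = "left"
    rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.diameter = np.asarray(self.diameter, float)
        if self.t.shape != self.diameter.shape:
            raise ValidationError("t and diameter must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        present = self.diameter[np.isfinite(self.diameter)]
        if present.size and (present.min() <= PUPIL_RANGE_MM[0] or present.max() >= PUPIL_RANGE_MM[1]):
            raise ValidationError("pupil diameters must lie in (0, 12) mm")
        if self.rate is None:
            if len(self.t) < 2:
                raise ValidationError("cannot infer rate from < 2 samples")
            self.rate = 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MPCSeries:
    """Per-buffer MPC values; ``valid`` is False where the buffer contained
    an uninterpolated gap."""

    buffer_start: np.ndarray
    mpc: np.ndarray
    valid: np.ndarray
    band: tuple[float, float] = (1.0, 5.0)
    buffer_length: float = 1.0

    def mean(self) -> float:
        vals = self.mpc[self.valid]
        return float(np.mean(vals)) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"buffer_start": self.buffer_start, "mpc": self.mpc, "valid": self.valid}
        )


def preprocess_pupil(
    series: PupilSeries,
    max_gap: float = 0.5,
    clip_range: tuple[float, float] | None = None,
) -> PupilSeries:
    """Linearly interpolate blink gaps shorter than ``max_gap`` seconds.

    Longer gaps (and gaps at the record edges) stay missing, so the MPC
    buffers containing them are later flagged invalid.  ``clip_range``
    optionally clips diameters to a physiological range.
    """
    t = series.t
    d = series.diameter.copy()
    isnan = np.isnan(d)
    if isnan.any() and (~isnan).any():
        # fill each interior NaN run whose bounding valid samples are close enough
        idx = np.arange(len(d))
        valid_idx = idx[~isnan]
        run_start = None
        for i in range(len(d) + 1):
            if i < len(d) and isnan[i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                lo, hi = run_start - 1, i
                if lo >= 0 and hi < len(d) and t[hi] - t[lo] <= max_gap:
                    d[run_start:i] = np.interp(t[run_start:i], [t[lo], t[hi]], [d[lo], d[hi]])
                run_start = None
    if clip_range is not None:
        d = np.clip(d, *clip_range)
    return PupilSeries(t, d, eye=series.eye, rate=series.rate)


def _single_sided_magnitude(segment: np.ndarray, window: str) -> np.ndarray:
    n = len(segment)
    if window == "hann":
        w = np.hanning(n)
        seg = segment * w * (n / w.sum())  # preserve amplitude of slow components
    elif window == "rect":
        seg = segment
    else:
        raise ConfigurationError(f"unknown window {window!r}")
    spec = np.abs(np.fft.rfft(seg)) / n
    mags = spec.copy()
    mags[1:] *= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0  # Nyquist bin is not duplicated
    return mags


def mpc(
    series: PupilSeries,
    band: tuple[float, float] = (1.0, 5.0),
    buffer: float | None = 1.0,
    remove_mean: bool = True,
    window: str = "rect",
) -> MPCSeries | float:
    """Measure of Pupillary Cognition: summed in-band single-sided FFT
    magnitudes per buffer.

    With ``buffer=None`` the whole series is transformed at once and a
    scalar is returned.  A buffer containing missing samples yields NaN and
    is flagged invalid.  Band limits are inclusive on both ends.
    """
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ConfigurationError("band must satisfy 0 < f_lo < f_hi")
    rate = float(series.rate)
    if rate < 2 * f_hi:
        raise ConfigurationError(
            f"sampling rate {rate} Hz below Nyquist requirement {2 * f_hi} Hz"
        )

    def _one(segment: np.ndarray) -> float:
        seg = segment - segment.mean() if remove_mean else segment
        mags = _single_sided_magnitude(seg, window)
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / rate)
        eps = 1e-9
        in_band = (freqs >= f_lo - eps) & (freqs <= f_hi + eps)
        return float(mags[in_band].sum())

    d = series.diameter
    if buffer is None:
        if np.isnan(d).any():
            raise ValidationError("full-signal MPC requires a gap-free series")
        return _one(d)

    n_buf = int(round(buffer * rate))
    if n_buf < 2:
        raise ConfigurationError("buffer too short for the sampling rate")
    n_full = len(d) // n_buf
    starts, values, valid = [], [], []
    for k in range(n_full):
        seg = d[k * n_buf : (k + 1) * n_buf]
        starts.append(float(series.t[k * n_buf]))
        if np.isnan(seg).any():
            values.append(np.nan)
            valid.append(False)
        else:
            values.append(_one(seg))
            valid.append(True)
    return MPCSeries(
        np.array(starts), np.array(values), np.array(valid, bool),
        band=(f_lo, f_hi), buffer_length=buffer,
    )


@dataclass
class ConditionSummary:
    """Mean MPC per condition plus ordering flags against a reference
    (highest-workload) condition."""

    means: dict[str, float]
    reference: str
    exceeds: dict[str, bool]


def mpc_condition_summary(
    mpc_by_condition: Mapping[str, MPCSeries], reference: str | None = None
) -> ConditionSummary:
    """Per-condition mean MPC and ``reference > other`` ordering flags.

    ``reference`` defaults to the last condition in mapping order (e.g. C3
    for conditions C1, C2, C3).  A condition with no valid buffer gets a
    NaN mean and a warning.
    """
    labels = list(mpc_by_condition)
    if not labels:
        raise ValidationError("no conditions supplied")
    if reference is None:
        reference = labels[-1]
    if reference not in mpc_by_condition:
        raise ValidationError(f"reference condition {reference!r} not present")
    means: dict[str, float] = {}
    for label, series in mpc_by_condition.items():
        m = series.mean()
        if np.isnan(m):
            warnings.warn(f"condition {label!r} has no valid MPC buffer")
        means[label] = m
    ref_mean = means[reference]
    exceeds = {
        label: bool(ref_mean > means[label])
        for label in labels
        if label != reference
    }
    return ConditionSummary(means=means, reference=reference, exceeds=exceeds)


def pupil_sd(series: PupilSeries) -> float:
    """Sample standard deviation (mm) of the valid pupil samples."""
    vals = series.diameter[np.isfinite(series.diameter)]
    if vals.size < 2:
        raise InsufficientDataError("need at least 2 valid samples for pupil SD")
    return float(np.std(vals, ddof=1))
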