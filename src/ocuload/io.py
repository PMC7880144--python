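"""Gaze data model, tabular readers/writers, pixel/degree conversion and
phase slicing.

The canonical in-memory gaze unit is degrees of visual angle: every angular
threshold used downstream (0.4 deg intrusion deviation, 30 deg/s velocity
threshold) is angular, so pixel-native exports are converted on load using
the scene-camera geometry.  The pixel<->degree mapping is linear
(constant pixels-per-degree = resolution / field-of-view); no tangent
correction is applied, which is a small-angle approximation adequate for
wide-FOV wearable trackers.

Time is in seconds with t = 0 at the first sample.  Phase intervals are
half-open ``[start, end)`` so that a partition of the time axis assigns
every sample to exactly one phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, EmptyInputError, ValidationError

__all__ = [
    "CameraGeometry",
    "GazeRecording",
    "PhaseTable",
    "PhaseSegment",
    "degrees_to_pixels",
    "pixels_to_degrees",
    "read_gaze_table",
    "write_gaze_table",
    "read_phase_table",
    "write_phase_table",
    "slice_by_phase",
]

#: columns of the canonical sample frame
SAMPLE_COLUMNS = ["t", "x", "y", "pupil_left", "pupil_right", "valid"]

PUPIL_RANGE_MM = (0.0, 12.0)


@dataclass(frozen=True)
class CameraGeometry:
    """Scene-camera geometry used to convert pixel gaze to visual angle.

    Defaults correspond to a wearable tracker with a 1920x1080 scene camera
    covering a 160-degree horizontal field of view.
    """

    horizontal_fov: float = 160.0
    horizontal_resolution: float = 1920.0
    vertical_fov: float = 90.0
    vertical_resolution: float = 1080.0

    def __post_init__(self) -> None:
        for name in (
            "horizontal_fov",
            "horizontal_resolution",
            "vertical_fov",
            "vertical_resolution",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"CameraGeometry.{name} must be positive")

    def pixels_per_degree(self, axis: str = "horizontal") -> float:
        if axis == "horizontal":
            return self.horizontal_resolution / self.horizontal_fov
        if axis == "vertical":
            return self.vertical_resolution / self.vertical_fov
        raise ConfigurationError(f"unknown axis {axis!r}")


def degrees_to_pixels(
    angle: float | np.ndarray, camera: CameraGeometry, axis: str = "horizontal"
) -> float | np.ndarray:
    """Convert visual angle (degrees) to scene-camera pixels on one axis."""
    return np.multiply(angle, camera.pixels_per_degree(axis))


def pixels_to_degrees(
    offset: float | np.ndarray, camera: CameraGeometry, axis: str = "horizontal"
) -> float | np.ndarray:
    """Convert a pixel offset to visual angle; exact inverse of
    :func:`degrees_to_pixels`."""
    return np.divide(offset, camera.pixels_per_degree(axis))


@dataclass
class GazeRecording:
    """Timestamped gaze samples with optional pupil diameters.

    ``samples`` holds columns ``t`` (s, strictly increasing, 0 at start),
    ``x``/``y`` (degrees of visual angle, NaN when invalid), ``pupil_left``/
    ``pupil_right`` (mm, NaN when missing) and boolean ``valid``.
    """

    samples: pd.DataFrame
    nominal_rate: float
    native_units: str = "degrees"
    camera: CameraGeometry | None = None
    parse_report: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample frame missing columns {missing}")
        t = self.samples["t"].to_numpy(float)
        if len(t) and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise ValidationError("timestamps must be finite and non-negative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be positive")
        if self.native_units not in ("pixels", "degrees"):
            raise ValidationError(f"unknown native_units {self.native_units!r}")
        if self.native_units == "pixels" and self.camera is None:
            raise ValidationError("pixel-native recordings require a CameraGeometry")
        pupils = self.samples[["pupil_left", "pupil_right"]].to_numpy(float)
        present = pupils[np.isfinite(pupils)]
        if present.size and (
            present.min() <= PUPIL_RANGE_MM[0] or present.max() >= PUPIL_RANGE_MM[1]
        ):
            raise ValidationError("pupil diameters must lie in (0, 12) mm")

    # -- convenience accessors -------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.samples["t"].to_numpy(float)

    @property
    def x(self) -> np.ndarray:
        return self.samples["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.samples["y"].to_numpy(float)

    @property
    def valid(self) -> np.ndarray:
        return self.samples["valid"].to_numpy(bool)

    @property
    def duration(self) -> float:
        t = self.t
        if len(t) < 2:
            return 0.0
        return float(t[-1] - t[0] + 1.0 / self.nominal_rate)

    def __len__(self) -> int:
        return len(self.samples)

    @classmethod
    def from_arrays(
        cls,
        t: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        pupil_left: Sequence[float] | None = None,
        pupil_right: Sequence[float] | None = None,
        valid: Sequence[bool] | None = None,
        nominal_rate: float | None = None,
        camera: CameraGeometry | None = None,
    ) -> "GazeRecording":
        t = np.asarray(t, float)
        n = len(t)
        nan = np.full(n, np.nan)
        frame = pd.DataFrame(
            {
                "t": t,
                "x": np.asarray(x, float),
                "y": np.asarray(y, float),
                "pupil_left": nan if pupil_left is None else np.asarray(pupil_left, float),
                "pupil_right": nan if pupil_right is None else np.asarray(pupil_right, float),
                "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
            }
        )
        if nominal_rate is None:
            nominal_rate = infer_rate(t)
        return cls(frame, nominal_rate=nominal_rate, camera=camera)


def infer_rate(t: np.ndarray) -> float:
    """Nominal sampling rate as the reciprocal of the median inter-sample
    interval."""
    t = np.asarray(t, float)
    if len(t) < 2:
        raise ValidationError("cannot infer sampling rate from < 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValidationError("non-increasing timestamps")
    return 1.0 / dt


# ---------------------------------------------------------------------------
# dialect-driven tabular reader / writer
# ---------------------------------------------------------------------------

DEFAULT_DIALECT: dict = {
    "columns": {"time": "t", "x": "x", "y": "y"},
    "units": "degrees",
    "time_unit": "s",
    "delimiter": ",",
}

_OPTIONAL_COLUMNS = ("pupil_left", "pupil_right", "validity")
_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


def load_dialect(source: str | Path | Mapping) -> dict:
    """Load a column-mapping dialect from a mapping or a YAML/JSON file."""
    if isinstance(source, Mapping):
        dialect = dict(source)
    else:
        text = Path(source).read_text()
        dialect = (
            json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
        )
    cols = dialect.get("columns", {})
    for required in ("time", "x", "y"):
        if required not in cols:
            raise ConfigurationError(f"dialect missing required column mapping {required!r}")
    dialect.setdefault("units", "degrees")
    dialect.setdefault("time_unit", "s")
    dialect.setdefault("delimiter", ",")
    if dialect["units"] not in ("pixels", "degrees"):
        raise ConfigurationError(f"dialect units must be pixels or degrees")
    if dialect["time_unit"] not in _TIME_SCALE:
        raise ConfigurationError(f"unknown time_unit {dialect['time_unit']!r}")
    return dialect


def read_gaze_table(
    path: str | Path,
    dialect: str | Path | Mapping | None = None,
    camera: CameraGeometry | None = None,
    nominal_rate: float | None = None,
) -> GazeRecording:
    """Read a delimited gaze export into a :class:`GazeRecording`.

    The dialect maps file columns onto the canonical fields and declares the
    native units; pixel-native files are converted to degrees using
    ``camera`` (or a camera block inside the dialect).  Rows whose time cell
    fails numeric parse are dropped (counted in ``parse_report``); rows with
    unparsable x/y are kept but marked invalid.  Duplicate timestamps are
    collapsed keeping the first occurrence.
    """
    dialect = load_dialect(DEFAULT_DIALECT if dialect is None else dialect)
    cols = dialect["columns"]
    if camera is None and "camera" in dialect:
        camera = CameraGeometry(**dialect["camera"])

    raw = pd.read_csv(path, sep=dialect["delimiter"], dtype=str, skipinitialspace=True)
    for key in ("time", "x", "y"):
        if cols[key] not in raw.columns:
            raise ConfigurationError(
                f"required column {cols[key]!r} (for {key!r}) not found in {path}"
            )
    n_rows = len(raw)
    if n_rows == 0:
        raise EmptyInputError(f"{path} contains no data rows")

    t = pd.to_numeric(raw[cols["time"]], errors="coerce") * _TIME_SCALE[dialect["time_unit"]]
    x = pd.to_numeric(raw[cols["x"]], errors="coerce")
    y = pd.to_numeric(raw[cols["y"]], errors="coerce")

    def _optional(key: str) -> pd.Series:
        name = cols.get(key)
        if name is None or name not in raw.columns:
            return pd.Series(np.nan, index=raw.index)
        return pd.to_numeric(raw[name], errors="coerce")

    pl, pr = _optional("pupil_left"), _optional("pupil_right")
    validity = cols.get("validity")
    declared_valid = (
        pd.Series(True, index=raw.index)
        if validity is None or validity not in raw.columns
        else pd.to_numeric(raw[validity], errors="coerce").fillna(0).astype(bool)
    )

    keep = t.notna()
    n_bad_time = int((~keep).sum())
    if n_bad_time:
        warnings.warn(f"{n_bad_time} rows with unparsable timestamps skipped")
    frame = pd.DataFrame(
        {"t": t, "x": x, "y": y, "pupil_left": pl, "pupil_right": pr,
         "valid": declared_valid & x.notna() & y.notna()}
    )[keep]
    frame = frame.sort_values("t", kind="stable")
    dup = frame["t"].duplicated(keep="first")
    n_dup = int(dup.sum())
    frame = frame[~dup].reset_index(drop=True)
    if len(frame) == 0:
        raise EmptyInputError(f"{path} contains no parsable rows")

    frame.loc[~frame["valid"], ["x", "y"]] = np.nan
    # out-of-range pupils treated as missing rather than rejecting the file
    for c in ("pupil_left", "pupil_right"):
        bad = (frame[c] <= PUPIL_RANGE_MM[0]) | (frame[c] >= PUPIL_RANGE_MM[1])
        frame.loc[bad, c] = np.nan
    frame["t"] = frame["t"] - frame["t"].iloc[0]

    native_units = dialect["units"]
    if native_units == "pixels":
        if camera is None:
            raise ConfigurationError("pixel-unit dialect requires camera geometry")
        frame["x"] = pixels_to_degrees(frame["x"].to_numpy(), camera, "horizontal")
        frame["y"] = pixels_to_degrees(frame["y"].to_numpy(), camera, "vertical")

    if nominal_rate is None:
        nominal_rate = dialect.get("nominal_rate") or infer_rate(frame["t"].to_numpy())
    rec = GazeRecording(
        frame, nominal_rate=float(nominal_rate), native_units=native_units, camera=camera
    )
    rec.parse_report = {
        "rows": n_rows,
        "parsed": len(frame),
        "invalid": int((~frame["valid"]).sum()),
        "skipped_bad_time": n_bad_time,
        "deduplicated": n_dup,
    }
    return rec


def write_gaze_table(recording: GazeRecording, path: str | Path) -> None:
    """Write the canonical sample frame as CSV (degrees, seconds)."""
    recording.samples.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# phase tables and slicing
# ---------------------------------------------------------------------------


@dataclass
class PhaseTable:
    """Labeled, non-overlapping half-open time intervals ``[start, end)``."""

    intervals: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, a, b in self.intervals:
            if not a < b:
                raise ValidationError(f"phase {label!r}: start {a} must precede end {b}")
        ordered = sorted(self.intervals, key=lambda iv: iv[1])
        for (la, _, ea), (lb, sb, _) in zip(ordered, ordered[1:]):
            if sb < ea - 1e-12:
                raise ValidationError(f"phases {la!r} and {lb!r} overlap")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def span(self) -> tuple[float, float]:
        return (
            min(s for _, s, _ in self.intervals),
            max(e for _, _, e in self.intervals),
        )

    @classmethod
    def windows(cls, span: float, window: float, label: str = "w") -> "PhaseTable":
        """Regular half-open windows covering ``[0, span)``."""
        edges = np.arange(0.0, span, window)
        return cls(
            [(f"{label}{i}", float(a), float(min(a + window, span)))
             for i, a in enumerate(edges)]
        )


def read_phase_table(path: str | Path) -> PhaseTable:
    frame = pd.read_csv(path)
    for c in ("label", "start_s", "end_s"):
        if c not in frame.columns:
            raise ConfigurationError(f"phase table missing column {c!r}")
    return PhaseTable(
        [(str(r.label), float(r.start_s), float(r.end_s)) for r in frame.itertuples()]
    )


def write_phase_table(table: PhaseTable, path: str | Path) -> None:
    pd.DataFrame(table.intervals, columns=["label", "start_s", "end_s"]).to_csv(
        path, index=False
    )


@dataclass
class PhaseSegment:
    """One phase-slice of a recording; ``duration`` is the phase-interval
    length (for rate normalisation), not the sample span."""

    label: str
    recording: GazeRecording
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def slice_by_phase(recording: GazeRecording, phases: PhaseTable) -> list[PhaseSegment]:
    """Split a recording into labeled phase segments.

    Each segment holds the samples with ``t`` in ``[t_start, t_end)``.  A
    phase may overhang the recording span by at most one sample period.
    """
    t = recording.t
    if len(t) == 0:
        raise EmptyInputError("empty recording")
    tol = 1.0 / recording.nominal_rate
    lo, hi = t[0], t[-1] + tol
    segments: list[PhaseSegment] = []
    for label, a, b in phases:
        if a < lo - tol or b > hi + tol:
            raise ValidationError(
                f"phase {label!r} [{a}, {b}) outside recording span [{lo}, {hi}]"
            )
        mask = (t >= a) & (t < b)
        sub = recording.samples[mask].reset_index(drop=True)
        seg = GazeRecording(
            sub,
            nominal_rate=recording.nominal_rate,
            native_units=recording.native_units,
            camera=recording.camera,
        )
        segments.append(PhaseSegment(label, seg, a, b))
    return segments
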