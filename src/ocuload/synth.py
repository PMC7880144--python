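"""Synthetic gaze, pupil, tracking-task and flight-profile generators with
exported ground truth.

The generators emulate the statistical structure of simulator and in-flight
recordings so every pipeline stage can be validated against known truth:

* gaze is an alternating fixation/saccade process whose realized fixation
  rate matches the workload profile in expectation, with optional square
  saccadic-intrusion excursions on the x channel and Gaussian position
  noise;
* the pupil signal is a baseline plus slow drift plus an in-band (1-5 Hz)
  component realized as random-phase sinusoids on exactly the MPC bin
  frequencies, plus white noise and optional blink gaps;
* the tracking pilot is a proportional-derivative pursuit of the
  sum-of-sines target whose gain (and stick remnant) rises as the
  boundaries shrink;
* the flight generator couples the instantaneous fixation-rate parameter
  to the magnitude of the rate of descent during dives (raised-cosine
  descend-and-recover altitude profile).

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DivergenceError, ValidationError
from .events import OcularEvent
from .io import GazeRecording, PhaseTable
from .pupil import PupilSeries
from .task import BoundarySchedule, SOSSpec, TrackingTrace, sos_signal, boundary_at

__all__ = [
    "WorkloadProfile",
    "GroundTruth",
    "PilotGain",
    "FlightData",
    "simulate_gaze",
    "simulate_pupil",
    "simulate_pilot_tracking",
    "simulate_flight",
]

#: fixed saccade flight time (s); amplitude-dependent durations are not
#: modelled because the detectors only need super-threshold velocity
SACCADE_DURATION = 0.030
#: shortest fixation the generator will emit (s)
MIN_FIXATION = 0.100
#: rise/fall time of an injected intrusion excursion (s)
INTRUSION_RISE = 0.020


@dataclass
class WorkloadProfile:
    """Per-interval generator parameters encoding a workload level.

    ``fixation_rate`` is in fixations/s, ``saccade_amplitude_mean`` in
    degrees, ``intrusion_rate`` in intrusions/s, ``pupil_band_power`` the
    per-bin amplitude (mm) of the 1-5 Hz pupil component,
    ``pupil_baseline`` in mm, ``stick_activity`` a dimensionless scale for
    stick remnant.
    """

    label: str = "C1"
    duration_s: float = 60.0
    fixation_rate: float = 2.0
    saccade_amplitude_mean: float = 5.0
    intrusion_rate: float = 0.0
    pupil_band_power: float = 0.02
    pupil_baseline: float = 4.0
    stick_activity: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        for name in ("fixation_rate", "intrusion_rate", "pupil_band_power"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 1.0 < self.pupil_baseline < 9.0:
            raise ValidationError("pupil_baseline must lie in (1, 9) mm")


@dataclass
class GroundTruth:
    """True events and parameters behind a synthetic recording."""

    events: list[OcularEvent]
    profiles: list[WorkloadProfile]
    seed: int
    extras: dict = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)


def _check_feasible(profile: WorkloadProfile) -> None:
    if profile.fixation_rate * MIN_FIXATION > 1.0:
        raise ValidationError(
            f"profile {profile.label!r}: fixation_rate {profile.fixation_rate}/s "
            f"infeasible with minimum fixation duration {MIN_FIXATION}s"
        )


def _gaze_path(
    segments: Sequence[tuple[str, float, float, float, float]],
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[OcularEvent]]:
    """Alternating fixation/saccade path over concatenated segments.

    ``segments`` rows are (label, duration, fixation_rate,
    saccade_amplitude_mean, intrusion_rate).  Returns (t, x, y, events).
    """
    total = sum(s[1] for s in segments)
    n = int(round(total * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    y = np.zeros(n)
    events: list[OcularEvent] = []

    pos = np.array([0.0, 0.0])
    cursor = 0.0
    seg_idx = 0
    seg_end = segments[0][1]

    def current_segment(time: float):
        nonlocal seg_idx, seg_end
        while seg_idx < len(segments) - 1 and time >= seg_end - 1e-12:
            seg_idx += 1
            seg_end += segments[seg_idx][1]
        return segments[seg_idx]

    while cursor < total - 1.0 / rate:
        _, _, fix_rate, sacc_amp, intr_rate = current_segment(cursor)
        mean_cycle = 1.0 / fix_rate if fix_rate > 0 else total
        mean_fix = max(mean_cycle - SACCADE_DURATION, MIN_FIXATION)
        fix_dur = max(float(rng.gamma(2.0, mean_fix / 2.0)), MIN_FIXATION)
        fix_end = min(cursor + fix_dur, total)

        i0 = int(np.ceil(cursor * rate - 1e-9))
        i1 = int(np.ceil(fix_end * rate - 1e-9))
        x[i0:i1] = pos[0]
        y[i0:i1] = pos[1]
        events.append(
            OcularEvent(
                "fixation", cursor, max(fix_end, cursor + 1.0 / rate),
                centroid_x=pos[0], centroid_y=pos[1],
            )
        )

        # inject intrusions that fit wholly inside this fixation
        if intr_rate > 0 and fix_end - cursor > 0.9:
            n_int = rng.poisson(intr_rate * (fix_end - cursor))
            onset_lo, onset_hi = cursor + 0.15, fix_end - 0.8
            proposals = sorted(rng.uniform(onset_lo, max(onset_lo, onset_hi), n_int)) if onset_hi > onset_lo else []
            last_end = cursor
            for onset in proposals:
                dur = float(rng.uniform(0.20, 0.60))
                amp = float(rng.uniform(0.8, 1.5)) * (1 if rng.random() < 0.5 else -1)
                if onset < last_end + 0.1 or onset + dur > fix_end - 0.1:
                    continue
                j0 = int(np.ceil(onset * rate))
                j1 = int(np.ceil((onset + dur) * rate))
                tt = t[j0:j1]
                shape = np.clip(
                    np.minimum((tt - onset) / INTRUSION_RISE, (onset + dur - tt) / INTRUSION_RISE),
                    0.0, 1.0,
                )
                x[j0:j1] += amp * shape
                events.append(OcularEvent("intrusion", onset, onset + dur, amplitude=abs(amp)))
                last_end = onset + dur

        cursor = fix_end
        if cursor >= total - SACCADE_DURATION - 1.0 / rate:
            break

        # saccade to a new position (lognormal amplitude, center-biased direction)
        sigma = 0.4
        mu = np.log(max(sacc_amp, 1.6)) - sigma**2 / 2
        amp = float(np.clip(rng.lognormal(mu, sigma), 1.5, 20.0))
        if np.hypot(*pos) > 12.0:
            theta = float(np.arctan2(-pos[1], -pos[0]) + rng.normal(0, 0.5))
        else:
            theta = float(rng.uniform(0, 2 * np.pi))
        new_pos = pos + amp * np.array([np.cos(theta), np.sin(theta)])
        new_pos = np.clip(new_pos, -18.0, 18.0)

        sac_end = cursor + SACCADE_DURATION
        i0 = int(np.ceil(cursor * rate - 1e-9))
        i1 = int(np.ceil(sac_end * rate - 1e-9))
        if i1 > i0:
            u = (t[i0:i1] - cursor) / SACCADE_DURATION
            ease = (1 - np.cos(np.pi * np.clip(u, 0, 1))) / 2
            x[i0:i1] = pos[0] + (new_pos[0] - pos[0]) * ease
            y[i0:i1] = pos[1] + (new_pos[1] - pos[1]) * ease
        events.append(
            OcularEvent(
                "saccade", cursor, sac_end,
                amplitude=float(np.hypot(*(new_pos - pos))),
            )
        )
        pos = new_pos
        cursor = sac_end

    return t, x, y, events


def simulate_gaze(
    profiles: Sequence[WorkloadProfile] | WorkloadProfile,
    rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate a gaze recording as an alternating fixation/saccade process.

    Fixation durations are gamma-distributed (shape 2) with mean chosen so
    the realized fixation rate matches each profile's ``fixation_rate`` in
    expectation; saccadic intrusions are injected as square x-excursions
    (> 0.4 deg, returning within 60-870 ms) at ``intrusion_rate``.
    """
    if isinstance(profiles, WorkloadProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if rate < 50:
        raise ValidationError("gaze rate must be at least 50 Hz")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    for p in profiles:
        _check_feasible(p)
    rng = np.random.default_rng(seed)
    segments = [
        (p.label, p.duration_s, p.fixation_rate, p.saccade_amplitude_mean, p.intrusion_rate)
        for p in profiles
    ]
    t, x, y, events = _gaze_path(segments, rate, rng)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, len(t))
        y = y + rng.normal(0, noise_sd, len(t))
    rec = GazeRecording.from_arrays(t, x, y, nominal_rate=rate)
    return rec, GroundTruth(events=events, profiles=profiles, seed=seed)


def simulate_pupil(
    profiles: Sequence[WorkloadProfile] | WorkloadProfile,
    rate: float = 100.0,
    blink_rate: float = 0.0,
    noise_sd: float = 0.005,
    drift_amplitude: float = 0.15,
    seed: int = 0,
) -> tuple[PupilSeries, GroundTruth]:
    """Simulate a pupil-diameter signal.

    diameter = baseline + slow drift + in-band component + white noise.
    The in-band component is a sum of random-phase sinusoids at exactly
    1, 2, 3, 4 and 5 Hz, each of amplitude ``pupil_band_power``, so the
    expected MPC per 1 s buffer is 5x the band-power parameter.  Blink
    gaps of 100-300 ms (NaN) occur at ``blink_rate`` per minute.
    """
    if isinstance(profiles, WorkloadProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if rate < 10.0:
        raise ValidationError("pupil rate must be at least 10 Hz (2 x 5 Hz band top)")
    rng = np.random.default_rng(seed)
    total = sum(p.duration_s for p in profiles)
    n = int(round(total * rate))
    t = np.arange(n) / rate
    d = np.empty(n)
    drift_phase = rng.uniform(0, 2 * np.pi)
    cursor = 0.0
    for p in profiles:
        mask = (t >= cursor - 1e-12) & (t < cursor + p.duration_s - 1e-12)
        tt = t[mask]
        seg = np.full(mask.sum(), p.pupil_baseline)
        seg += drift_amplitude * np.sin(2 * np.pi * 0.02 * tt + drift_phase)
        for k in range(1, 6):
            seg += p.pupil_band_power * np.sin(2 * np.pi * k * tt + rng.uniform(0, 2 * np.pi))
        seg += rng.normal(0, noise_sd, len(tt)) if noise_sd > 0 else 0.0
        d[mask] = seg
        cursor += p.duration_s
    d = np.clip(d, 0.5, 11.5)

    blinks: list[tuple[float, float]] = []
    if blink_rate > 0:
        n_blinks = rng.poisson(blink_rate / 60.0 * total)
        for onset in np.sort(rng.uniform(0, total, n_blinks)):
            dur = float(rng.uniform(0.1, 0.3))
            d[(t >= onset) & (t < onset + dur)] = np.nan
            blinks.append((float(onset), float(onset) + dur))

    series = PupilSeries(t, d, rate=rate)
    truth = GroundTruth(
        events=[], profiles=profiles, seed=seed,
        extras={"blinks": blinks, "band_power": [p.pupil_band_power for p in profiles]},
    )
    return series, truth


@dataclass(frozen=True)
class PilotGain:
    """Proportional-derivative pilot model parameters.

    Per boundary step k the proportional gain and the stick remnant (white
    noise added to the stick output, emulating neuromuscular noise that
    rises with pilot gain) are scaled by ``(1 + growth * k)``.  The
    derivative gain is not stepped: the discrete derivative term feeds the
    previous own-pitch increment back with gain ``plant_gain * kd``, so
    stepping it up would destabilise the loop rather than model a more
    aggressive pilot.
    """

    kp: float = 2.0
    kd: float = 0.4
    growth: float = 0.5
    plant_gain: float = 1.0
    remnant_sd: float = 0.15


def simulate_pilot_tracking(
    sos: SOSSpec = SOSSpec(),
    schedule: BoundarySchedule = BoundarySchedule(),
    gain: PilotGain = PilotGain(),
    n_steps: int = 3,
    rate: float = 100.0,
    seed: int = 0,
) -> TrackingTrace:
    """Simulate a pilot tracking the sum-of-sines target within shrinking
    boundaries.

    The own-aircraft pitch rate equals ``plant_gain * stick``; the stick is
    a PD law on the tracking error plus remnant noise, with gains stepped
    up at each boundary shrink (rising pilot gain as the task tightens).
    """
    duration = n_steps * schedule.step_interval
    n = int(round(duration * rate))
    dt = 1.0 / rate
    t = np.arange(n) * dt
    target = sos_signal(sos, t)
    rng = np.random.default_rng(seed)
    remnant = rng.normal(0, 1.0, n) if gain.remnant_sd > 0 else np.zeros(n)

    own = np.zeros(n)
    stick = np.zeros(n)
    e_prev = 0.0
    for i in range(n):
        k = int(t[i] // schedule.step_interval)
        scale = 1.0 + gain.growth * k
        e = target[i] - own[i]
        de = (e - e_prev) / dt if i > 0 else 0.0
        stick[i] = scale * gain.kp * e + gain.kd * de + gain.remnant_sd * scale * remnant[i]
        e_prev = e
        if i + 1 < n:
            own[i + 1] = own[i] + dt * gain.plant_gain * stick[i]
            if not np.isfinite(own[i + 1]) or abs(own[i + 1]) > 1e4:
                raise DivergenceError(
                    f"tracking loop diverged at t={t[i]:.2f}s "
                    f"(kp={gain.kp}, kd={gain.kd}, plant_gain={gain.plant_gain})"
                )
    hw = boundary_at(schedule, t)
    return TrackingTrace(t, target, own, stick, hw)


@dataclass
class FlightData:
    """Outputs of the flight-profile generator."""

    gaze: GazeRecording
    pupil: PupilSeries
    altitude_t: np.ndarray
    altitude: np.ndarray
    truth: GroundTruth


def simulate_flight(
    phases: PhaseTable,
    profiles: Mapping[str, WorkloadProfile],
    dives: Sequence[tuple[float, float, float]] = (),
    base_altitude: float = 20000.0,
    coupling: float = 0.0,
    rate: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> FlightData:
    """Simulate a flight: phase-wise gaze and pupil plus an altitude trace.

    ``dives`` rows are (start_s, depth_ft, duration_s); each dive follows a
    raised-cosine descend-and-recover altitude profile.  With ``coupling``
    (fixations/s per ft/s) non-zero, the instantaneous fixation-rate
    parameter is ``phase rate + coupling * |rate of descent|``, re-evaluated
    every second — the mechanism behind the inverted-U co-variation of
    fixation rate and vertical speed during a dive.
    """
    span_lo, span_hi = phases.span
    total = span_hi - span_lo
    if span_lo != 0:
        raise ValidationError("phase table must start at t=0")
    for label, _, _ in phases:
        if label not in profiles:
            raise ValidationError(f"no WorkloadProfile for phase {label!r}")

    dives = sorted(dives)
    for (s1, _, d1), (s2, _, _) in zip(dives, dives[1:]):
        if s2 < s1 + d1:
            raise ValidationError("dives must not overlap")
    for s, depth, d in dives:
        if s < 0 or s + d > total:
            raise ValidationError("dive outside flight span")
        if depth <= 0 or d <= 0:
            raise ValidationError("dive depth and duration must be positive")

    alt_rate = 10.0
    t_alt = np.arange(int(round(total * alt_rate))) / alt_rate
    alt = np.full_like(t_alt, base_altitude)
    for s, depth, d in dives:
        u = (t_alt - s) / d
        m = (u >= 0) & (u <= 1)
        alt[m] -= depth / 2.0 * (1 - np.cos(2 * np.pi * u[m]))
    rod = np.gradient(alt, t_alt)

    def phase_of(time: float) -> str:
        for label, a, b in phases:
            if a <= time < b:
                return label
        return phases.intervals[-1][0]

    # per-second gaze segments with dive-coupled fixation rate
    ss = np.random.SeedSequence(seed)
    rng_gaze, rng_noise, seed_pupil = ss.spawn(3)
    segments = []
    true_rates = []
    for k in range(int(np.ceil(total))):
        a, b = float(k), min(float(k + 1), total)
        label = phase_of(a + (b - a) / 2)
        p = profiles[label]
        m = (t_alt >= a) & (t_alt < b)
        extra = coupling * float(np.mean(np.abs(rod[m]))) if m.any() else 0.0
        fr = min(p.fixation_rate + extra, 0.9 / MIN_FIXATION)
        segments.append((label, b - a, fr, p.saccade_amplitude_mean, p.intrusion_rate))
        true_rates.append(fr)

    t, x, y, events = _gaze_path(segments, rate, np.random.default_rng(rng_gaze))
    if noise_sd > 0:
        noise = np.random.default_rng(rng_noise)
        x = x + noise.normal(0, noise_sd, len(t))
        y = y + noise.normal(0, noise_sd, len(t))
    gaze = GazeRecording.from_arrays(t, x, y, nominal_rate=rate)

    phase_profiles = [
        WorkloadProfile(
            label=label, duration_s=b - a,
            fixation_rate=profiles[label].fixation_rate,
            saccade_amplitude_mean=profiles[label].saccade_amplitude_mean,
            intrusion_rate=profiles[label].intrusion_rate,
            pupil_band_power=profiles[label].pupil_band_power,
            pupil_baseline=profiles[label].pupil_baseline,
        )
        for label, a, b in phases
    ]
    pupil, _ = simulate_pupil(phase_profiles, rate=rate, seed=seed_pupil.generate_state(1)[0] % (2**31))

    truth = GroundTruth(
        events=events,
        profiles=phase_profiles,
        seed=seed,
        extras={
            "coupling": coupling,
            "per_second_fixation_rate": np.array(true_rates),
            "dives": list(dives),
        },
    )
    return FlightData(gaze=gaze, pupil=pupil, altitude_t=t_alt, altitude=alt, truth=truth)
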