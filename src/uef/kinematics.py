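"""Elbow-flexion cycle segmentation and the eight UEF outcome parameters.

The UEF test summarises a 20-s maximal-pace elbow flexion/extension trial
with eight parameters, each a frailty marker:

================== ==========================================================
speed              mean per-cycle angular-velocity range (max minus min), deg/s
flexibility        mean per-cycle elbow flexion range, deg
power              mean per-cycle product of angular-acceleration range and
                   angular-velocity range, deg^2/s^3
rise_time          mean time to peak angular velocity within a cycle, s
moment             mean per-cycle peak elbow moment, Nm: forearm+hand moment
                   of inertia times peak unsigned angular acceleration
speed_variability  coefficient of variation of per-cycle velocity ranges, %
speed_reduction    percent change of the mean per-cycle velocity range from
                   the first 5 s to the last 5 s (negative = slowing), %
flexion_number     number of flexion/extension cycles in 20 s
================== ==========================================================

Cycle boundaries are positive-going zero crossings of a low-pass-filtered
copy of the elbow velocity; all per-cycle quantities are computed from the
unfiltered series.  Elbow angle is obtained by trapezoidal integration with a
per-cycle linear detrend, which bounds gyroscope drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .trace import MotionTrace

DEG_TO_RAD = math.pi / 180.0

#: Time window (s) over which speed_reduction compares early vs late cycles.
REDUCTION_WINDOW_S = 5.0


@dataclass(frozen=True)
class InertiaModel:
    """Anthropometric model of the forearm+hand segment.

    Winter-style defaults: segment mass fraction of body mass, segment length
    fraction of stature, radius of gyration as a fraction of segment length.
    """

    segment_mass_fraction: float = 0.022
    segment_length_fraction: float = 0.254
    gyration_radius_fraction: float = 0.827

    def __post_init__(self) -> None:
        for name in (
            "segment_mass_fraction",
            "segment_length_fraction",
            "gyration_radius_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


DEFAULT_INERTIA = InertiaModel()


@dataclass
class AngularVelocitySeries:
    """Elbow angular velocity (forearm minus upper arm), deg/s, flexion positive."""

    sampling_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate


@dataclass
class FlexionCycle:
    """Per-cycle quantities over the half-open sample interval [start, end)."""

    start_index: int
    end_index: int
    velocity_range: float
    angle_range: float
    acceleration_range: float
    rise_time: float
    peak_acceleration: float
    peak_moment: float | None = None

    @property
    def midpoint_index(self) -> float:
        return 0.5 * (self.start_index + self.end_index)


@dataclass
class UEFParameters:
    """The eight UEF outcomes for one subject.  Missing values are NaN."""

    speed: float
    flexibility: float
    power: float
    rise_time: float
    moment: float
    speed_variability: float
    speed_reduction: float
    flexion_number: int

    def as_dict(self) -> dict[str, float]:
        return {
            "speed": self.speed,
            "flexibility": self.flexibility,
            "power": self.power,
            "rise_time": self.rise_time,
            "moment": self.moment,
            "speed_variability": self.speed_variability,
            "speed_reduction": self.speed_reduction,
            "flexion_number": self.flexion_number,
        }


def elbow_velocity(trace: MotionTrace, rest_window_s: float = 0.0) -> AngularVelocitySeries:
    """Elbow angular velocity: forearm minus upper-arm channel, bias-removed.

    Each channel's constant bias is estimated as its mean over an initial
    rest window of ``rest_window_s`` seconds and subtracted.  The default of
    0 s skips bias removal (the standard trial starts moving immediately);
    pass a positive window when the recording includes a rest lead-in.
    """
    if rest_window_s < 0:
        raise ValueError("rest_window_s must be >= 0")
    fore = trace.forearm_velocity
    upper = trace.upperarm_velocity
    if rest_window_s > 0:
        n_rest = int(round(rest_window_s * trace.sampling_rate))
        n_rest = min(max(n_rest, 1), fore.size)
        fore = fore - fore[:n_rest].mean()
        upper = upper - upper[:n_rest].mean()
    return AngularVelocitySeries(trace.sampling_rate, fore - upper)


def segment_cycles(
    series: AngularVelocitySeries,
    lowpass_hz: float = 3.0,
    min_cycle_s: float = 0.25,
    range_floor_frac: float = 0.10,
    min_range_dps: float = 20.0,
) -> list[FlexionCycle]:
    """Segment flexion/extension cycles from an elbow angular-velocity series.

    Candidate boundaries are positive-going zero crossings of a 4th-order
    Butterworth low-pass-filtered copy (default cutoff 3 Hz).  Boundaries
    closer than ``min_cycle_s`` are merged; candidate cycles whose unfiltered
    velocity range falls below ``max(min_range_dps, range_floor_frac *
    median range)`` are discarded, which maps an all-noise series to zero
    cycles rather than an exception.  A partial segment at either edge is
    kept as a cycle when it spans at least half the median cycle duration
    (symmetric under time reversal), so a noise-free train at frequency f
    yields round(duration * f) cycles.

    Per-cycle quantities are computed from the unfiltered series; the elbow
    angle is the cumulative trapezoid of velocity, linearly detrended within
    the cycle.
    """
    fs = series.sampling_rate
    x = series.values
    if series.duration_s < 1.0:
        raise ValueError("series must be at least 1 s long")
    nyq = fs / 2.0
    cutoff = min(lowpass_hz, 0.9 * nyq)
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    filt = signal.sosfiltfilt(sos, x)

    crossing = np.flatnonzero((filt[:-1] <= 0.0) & (filt[1:] > 0.0))
    if crossing.size == 0:
        return []
    # merge boundaries closer than the minimum cycle duration
    min_gap = int(round(min_cycle_s * fs))
    kept = [int(crossing[0])]
    for c in crossing[1:]:
        if c - kept[-1] >= min_gap:
            kept.append(int(c))

    bounds = [(kept[i], kept[i + 1]) for i in range(len(kept) - 1)]
    if bounds:
        med_dur = float(np.median([e - s for s, e in bounds]))
        # partial cycles at either edge count when they span at least half a
        # typical cycle (keeps the count symmetric under time reversal)
        tail = x.size - kept[-1]
        if tail >= 0.5 * med_dur and tail >= min_gap:
            bounds.append((kept[-1], x.size))
        head = kept[0]
        if head >= 0.5 * med_dur and head >= min_gap:
            bounds.insert(0, (0, kept[0]))
    elif x.size - kept[0] >= min_gap:
        # single crossing: the remainder is the only candidate cycle
        bounds.append((kept[0], x.size))
    if not bounds:
        return []

    ranges = np.array([x[s:e].max() - x[s:e].min() for s, e in bounds])
    floor = max(min_range_dps, range_floor_frac * float(np.median(ranges)))
    dt = 1.0 / fs
    cycles: list[FlexionCycle] = []
    for (s, e), vrange in zip(bounds, ranges):
        if vrange < floor:
            continue
        seg = x[s:e]
        accel = np.gradient(seg, dt)
        ang = cumulative_trapezoid(seg, dx=dt, initial=0.0)
        ang = ang - np.linspace(ang[0], ang[-1], ang.size)  # per-cycle drift detrend
        cycles.append(
            FlexionCycle(
                start_index=s,
                end_index=e,
                velocity_range=float(vrange),
                angle_range=float(ang.max() - ang.min()),
                acceleration_range=float(accel.max() - accel.min()),
                rise_time=float(np.argmax(seg) * dt),
                peak_acceleration=float(np.abs(accel).max()),
            )
        )
    return cycles


def estimate_inertia(
    mass_kg: float, height_cm: float, model: InertiaModel = DEFAULT_INERTIA
) -> float:
    """Forearm+hand moment of inertia about the elbow, kg m^2.

    I = (m * mass_fraction) * (h * length_fraction * gyration_fraction)^2
    with h the stature in metres.
    """
    if mass_kg <= 0 or height_cm <= 0:
        raise ValueError("mass and height must be positive")
    segment_mass = mass_kg * model.segment_mass_fraction
    gyration_m = (height_cm / 100.0) * model.segment_length_fraction * model.gyration_radius_fraction
    return segment_mass * gyration_m**2


def compute_uef_parameters(
    series: AngularVelocitySeries,
    cycles: list[FlexionCycle],
    mass_kg: float | None = None,
    height_cm: float | None = None,
    inertia_model: InertiaModel = DEFAULT_INERTIA,
) -> UEFParameters:
    """Aggregate per-cycle quantities into the eight UEF parameters.

    speed / flexibility / power / rise_time / moment are means of per-cycle
    values; speed_variability is the CV (in %) of per-cycle velocity ranges;
    speed_reduction compares the mean velocity range of cycles whose midpoint
    falls in the first 5 s with those in the last 5 s.  With fewer than two
    cycles the variability and reduction are NaN (flagged missing) but the
    remaining parameters are still computed; moment requires mass and height.
    """
    n = len(cycles)
    if n == 0:
        return UEFParameters(*([float("nan")] * 7), flexion_number=0)

    vranges = np.array([c.velocity_range for c in cycles])
    speed = float(vranges.mean())
    flexibility = float(np.mean([c.angle_range for c in cycles]))
    power = float(np.mean([c.acceleration_range * c.velocity_range for c in cycles]))
    rise_time = float(np.mean([c.rise_time for c in cycles]))

    moment = float("nan")
    if mass_kg is not None and height_cm is not None:
        inertia = estimate_inertia(mass_kg, height_cm, inertia_model)
        for c in cycles:
            c.peak_moment = inertia * c.peak_acceleration * DEG_TO_RAD
        moment = float(np.mean([c.peak_moment for c in cycles]))

    variability = float("nan")
    reduction = float("nan")
    if n >= 2:
        mean_r = vranges.mean()
        if mean_r > 0:
            variability = float(100.0 * vranges.std(ddof=1) / mean_r)
        mid_t = np.array([c.midpoint_index for c in cycles]) / series.sampling_rate
        duration = series.duration_s
        first = vranges[mid_t < REDUCTION_WINDOW_S]
        last = vranges[mid_t >= duration - REDUCTION_WINDOW_S]
        if first.size and last.size and first.mean() > 0:
            reduction = float(100.0 * (last.mean() - first.mean()) / first.mean())

    return UEFParameters(
        speed=speed,
        flexibility=flexibility,
        power=power,
        rise_time=rise_time,
        moment=moment,
        speed_variability=variability,
        speed_reduction=reduction,
        flexion_number=n,
    )


def extract_parameters(
    trace: MotionTrace,
    mass_kg: float | None = None,
    height_cm: float | None = None,
    rest_window_s: float = 0.0,
    lowpass_hz: float = 3.0,
    min_cycle_s: float = 0.25,
    range_floor_frac: float = 0.10,
    min_range_dps: float = 20.0,
    inertia_model: InertiaModel = DEFAULT_INERTIA,
) -> UEFParameters:
    """Convenience pipeline: trace -> elbow velocity -> cycles -> parameters."""
    series = elbow_velocity(trace, rest_window_s=rest_window_s)
    cycles = segment_cycles(
        series,
        lowpass_hz=lowpass_hz,
        min_cycle_s=min_cycle_s,
        range_floor_frac=range_floor_frac,
        min_range_dps=min_range_dps,
    )
    return compute_uef_parameters(
        series, cycles, mass_kg=mass_kg, height_cm=height_cm, inertia_model=inertia_model
    )
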