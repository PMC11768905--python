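"""Gait event detection, stride segmentation and temporal parameters.

Events are detected on the foot-mounted sensor only: the foot-off (FO,
toes leave the ground) coincides with the maximum angular velocity about
the pitch axis of the foot gyroscope, and the foot-strike (FS, initial
contact) with the maxima of the pitch-axis linear acceleration. A stride
is anchored FO→next FO, with the swing phase [FO, FS) first and the
stance phase [FS, next FO) second; the conventional FS→FS anchoring is
available as a configuration switch.

Trial-level rules mirror overground-walkway practice: the first and last
stride of each side are discarded (acceleration/deceleration phases) and
a trial is valid only if at least four strides per side remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "EventType",
    "GaitEvent",
    "Stride",
    "TemporalParams",
    "DetectionParams",
    "TrialValidity",
    "AgreementReport",
    "detect_peak_events",
    "detect_foot_off",
    "detect_foot_strike",
    "segment_strides",
    "apply_trial_rules",
    "temporal_params",
    "event_agreement",
]


class EventType(str, Enum):
    foot_strike = "foot_strike"
    foot_off = "foot_off"


@dataclass(frozen=True)
class GaitEvent:
    type: EventType
    side: str            # "L" or "R"
    time: float          # seconds from trial start
    source: str = "detected"   # detected | reference | ground_truth


@dataclass(frozen=True)
class Stride:
    """One gait cycle of one limb, anchored foot-off → next foot-off."""

    side: str
    index: int
    fo_start: float
    fs: float
    fo_end: float

    def __post_init__(self):
        if not self.fo_start < self.fs < self.fo_end:
            raise InputError(
                f"stride must satisfy fo_start < fs < fo_end, got "
                f"({self.fo_start}, {self.fs}, {self.fo_end})"
            )

    @property
    def duration(self) -> float:
        return self.fo_end - self.fo_start

    @property
    def swing_duration(self) -> float:
        return self.fs - self.fo_start

    @property
    def stance_duration(self) -> float:
        return self.fo_end - self.fs

    @property
    def swing_fraction(self) -> float:
        return self.swing_duration / self.duration


@dataclass
class TemporalParams:
    """Temporal spatiotemporal gait parameters (no position data required)."""

    cycle_time: float            # mean stride duration, s
    step_time: float | None      # mean alternating-side FS interval, s
    cadence: float | None        # steps/min = 60 / step_time
    swing_pct: float             # mean swing fraction × 100
    stance_pct: float            # 100 − swing_pct
    n_strides: dict[str, int] = field(default_factory=dict)


@dataclass
class DetectionParams:
    """Peak-picking guards for event detection.

    ``min_separation`` (s) defaults to half the dominant period estimated
    by autocorrelation (fallback: 0.5 s); ``prominence_factor`` scales the
    robust signal spread (95th percentile − median) into a prominence
    threshold. Both guards reject noise-born maxima; the underlying rule
    is simply "the maxima of the channel".
    """

    min_separation: float | None = None
    prominence_factor: float = 0.3
    fallback_period: float = 1.0


def estimate_dominant_period(x: np.ndarray, sample_rate: float,
                             min_lag_s: float = 0.3) -> float | None:
    """Dominant period (s) via the first autocorrelation peak beyond min_lag."""
    x = np.asarray(x, float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    ac = sps.correlate(x, x, mode="full")[len(x) - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lag0 = int(round(min_lag_s * sample_rate))
    if lag0 >= len(ac) - 2:
        return None
    peaks, props = sps.find_peaks(ac[lag0:], height=0.1)
    if len(peaks) == 0:
        return None
    return (lag0 + peaks[0]) / sample_rate


def detect_peak_events(x: np.ndarray, sample_rate: float,
                       params: DetectionParams | None = None) -> np.ndarray:
    """Times of dominant local maxima of a 1-D channel.

    Returns a strictly increasing array of event times (s). A constant or
    near-constant channel yields an empty array.
    """
    params = params or DetectionParams()
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise InputError("expected a 1-D channel")
    spread = np.percentile(x, 95) - np.median(x)
    if spread <= 0:
        return np.array([])
    prominence = params.prominence_factor * spread
    if params.min_separation is not None:
        sep = params.min_separation
    else:
        period = estimate_dominant_period(x, sample_rate) or params.fallback_period
        sep = 0.5 * period
    distance = max(1, int(round(sep * sample_rate)))
    # peaks must be prominent AND stand above the channel's upper spread;
    # prominence alone admits noise peaks flanked by deep noise dips
    idx, _ = sps.find_peaks(x, prominence=prominence,
                            height=np.median(x) + prominence, distance=distance)
    return idx / sample_rate


def detect_foot_off(gyro_pitch: np.ndarray, sample_rate: float,
                    params: DetectionParams | None = None) -> np.ndarray:
    """Foot-off times from the foot gyroscope pitch channel (preprocessed)."""
    return detect_peak_events(gyro_pitch, sample_rate, params)


def detect_foot_strike(accel_pitch: np.ndarray, sample_rate: float,
                       params: DetectionParams | None = None) -> np.ndarray:
    """Foot-strike times from the foot accelerometer pitch channel (preprocessed)."""
    return detect_peak_events(accel_pitch, sample_rate, params)


def segment_strides(fo_times, fs_times, side: str,
                    anchor: str = "foot_off") -> list[Stride]:
    """Pair event trains into strides.

    With the default ``foot_off`` anchor, each FO is paired with the first
    subsequent FS and the next FO (swing then stance). A FO with no FS
    before the next FO is dropped with a warning; unpaired leading FS and
    the trailing FO are discarded. The ``foot_strike`` anchor builds
    FS→FS cycles (stance then swing) symmetrically.
    """
    fo = np.asarray(sorted(fo_times), float)
    fs = np.asarray(sorted(fs_times), float)
    if anchor == "foot_strike":
        # FS→FS cycle: internal event is the FO that follows the anchoring FS
        strides = []
        k = 0
        for i in range(len(fs) - 1):
            inner = fo[(fo > fs[i]) & (fo < fs[i + 1])]
            if len(inner) == 0:
                logger.warning("side %s: foot-strike at %.3f s has no foot-off "
                               "before the next foot-strike; dropped", side, fs[i])
                continue
            strides.append(Stride(side, k, fs[i], inner[0], fs[i + 1]))
            k += 1
        return strides
    if anchor != "foot_off":
        raise InputError(f"unknown stride anchor {anchor!r}")
    strides = []
    k = 0
    for i in range(len(fo) - 1):
        inner = fs[(fs > fo[i]) & (fs < fo[i + 1])]
        if len(inner) == 0:
            logger.warning("side %s: foot-off at %.3f s has no foot-strike "
                           "before the next foot-off; dropped", side, fo[i])
            continue
        strides.append(Stride(side, k, fo[i], inner[0], fo[i + 1]))
        k += 1
    return strides


@dataclass
class TrialValidity:
    valid: bool
    strides: dict[str, list[Stride]]
    reason: str = ""


def apply_trial_rules(strides_by_side: dict[str, list[Stride]],
                      min_strides: int = 4) -> TrialValidity:
    """Trim warm-up/slow-down strides and check the validity rule.

    The first and last stride of each side are removed; if fewer than
    ``min_strides`` remain on any side the trial is flagged invalid
    (status, not exception).
    """
    trimmed: dict[str, list[Stride]] = {}
    for side, strides in strides_by_side.items():
        kept = strides[1:-1] if len(strides) > 2 else []
        trimmed[side] = [Stride(s.side, i, s.fo_start, s.fs, s.fo_end)
                         for i, s in enumerate(kept)]
    short = {side: len(s) for side, s in trimmed.items() if len(s) < min_strides}
    if short:
        reason = "; ".join(f"side {side}: {n} strides after trimming "
                           f"(minimum {min_strides})" for side, n in short.items())
        return TrialValidity(False, trimmed, reason)
    return TrialValidity(True, trimmed)


def temporal_params(strides_by_side: dict[str, list[Stride]]) -> TemporalParams:
    """Temporal parameters from segmented strides.

    cycle_time is the mean stride duration over both sides; step_time the
    mean interval between successive foot-strikes of alternating sides
    (undefined, hence None, if only one side has strides).
    """
    all_strides = [s for strides in strides_by_side.values() for s in strides]
    if not all_strides:
        raise InputError("no strides")
    cycle_time = float(np.mean([s.duration for s in all_strides]))
    swing_pct = float(np.mean([s.swing_fraction for s in all_strides]) * 100.0)
    sides_with = [side for side, s in strides_by_side.items() if s]
    step_time = None
    if len(sides_with) >= 2:
        fs_events = sorted((s.fs, s.side) for s in all_strides)
        steps = [t2 - t1 for (t1, s1), (t2, s2) in zip(fs_events, fs_events[1:])
                 if s1 != s2]
        if steps:
            step_time = float(np.mean(steps))
    cadence = 60.0 / step_time if step_time else None
    return TemporalParams(
        cycle_time=cycle_time,
        step_time=step_time,
        cadence=cadence,
        swing_pct=swing_pct,
        stance_pct=100.0 - swing_pct,
        n_strides={side: len(s) for side, s in strides_by_side.items()},
    )


@dataclass
class AgreementReport:
    """Timing agreement between detected and reference events of one type/side."""

    mean_pct: float          # mean |Δt| as % of cycle time
    max_pct: float           # max |Δt| as % of cycle time
    mean_abs_s: float
    n_matched: int
    n_missed: int            # reference events with no detected match
    n_spurious: int          # detected events with no reference match
    cycle_time: float

    @property
    def recall(self) -> float:
        total = self.n_matched + self.n_missed
        return self.n_matched / total if total else float("nan")


def event_agreement(detected, reference, max_lag_cycles: float = 0.25) -> AgreementReport:
    """Score detected event times against a reference train.

    Events are matched greedily one-to-one by smallest |Δt|, capped at
    ``max_lag_cycles`` of the median reference cycle (the inter-event
    interval), which prevents cross-stride matches. Differences are
    normalised by the median cycle time and reported in percent.
    """
    det = np.asarray(sorted(detected), float)
    ref = np.asarray(sorted(reference), float)
    if len(ref) == 0:
        raise InputError("reference event list is empty")
    if len(ref) >= 2:
        cycle = float(np.median(np.diff(ref)))
    else:
        cycle = float("nan")
    max_lag = max_lag_cycles * cycle if np.isfinite(cycle) else np.inf

    pairs = sorted(
        (abs(d - r), i, j)
        for i, d in enumerate(det) for j, r in enumerate(ref)
        if abs(d - r) <= max_lag
    )
    used_d: set[int] = set()
    used_r: set[int] = set()
    deltas = []
    for dt, i, j in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        deltas.append(dt)
    deltas = np.array(deltas)
    mean_abs = float(deltas.mean()) if len(deltas) else float("nan")
    max_abs = float(deltas.max()) if len(deltas) else float("nan")
    return AgreementReport(
        mean_pct=100.0 * mean_abs / cycle,
        max_pct=100.0 * max_abs / cycle,
        mean_abs_s=mean_abs,
        n_matched=len(deltas),
        n_missed=len(ref) - len(used_r),
        n_spurious=len(det) - len(used_d),
        cycle_time=cycle,
    )
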