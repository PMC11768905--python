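"""Movement-smoothness metrics: SPARC, Peaks Metric, and LDLJ.

All three metrics operate on a 1-D movement-intensity profile v(t) over a
window [t1, t2] — here an axis component or the triaxial resultant of a
gyroscope (default) or accelerometer stream, over the complete trial or a
stride/swing/stance window.

SPARC is the negative arc length of the normalised Fourier magnitude
spectrum V̂(ω) = |V(ω)|/|V(0)| over [0, ω_c]:

    λ_S = − ∫₀^ωc √( (1/ω_c)² + (dV̂/dω)² ) dω

A smoother profile has a more compact spectrum, hence a shorter arc and a
value closer to 0. The cutoff ω_c is either adaptive (the highest
frequency at which V̂ still exceeds an amplitude threshold, bounded by
2π·fc_max) as in the original metric definition, or fixed at 2π·fc_max.
The bound defaults to 10 Hz, twice the ~2 strides/s fundamental of
healthy adult walking.

The Peaks Metric is −(number of interior local maxima of v): each
superimposed submovement adds a peak. LDLJ is the negative log of the
duration- and amplitude-normalised integrated squared jerk of the
profile; all three decrease (grow more negative) as movement
intermittency increases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, ParameterError
from .events import Stride
from .io import IMUTrial, Location, Modality

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityProfile",
    "SparcParams",
    "SmoothnessRecord",
    "sparc",
    "peaks_metric",
    "ldlj",
    "smoothness_table",
    "records_to_dataframe",
]

#: spectral metrics need a minimal support (second differences + spectrum)
MIN_WINDOW = 8

COMPONENTS = ("yaw", "pitch", "roll", "magnitude")
SCOPES = ("complete", "stride", "swing", "stance")
METRICS = ("SPARC", "PM", "LDLJ")


@dataclass
class VelocityProfile:
    """A 1-D profile v(t) over [t1, t2] with its provenance."""

    v: np.ndarray
    sample_rate: float
    t1: float = 0.0
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v = np.asarray(self.v, float)
        if self.v.ndim != 1 or len(self.v) < 2:
            raise InputError("profile must be 1-D with at least 2 samples")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")

    @property
    def t2(self) -> float:
        return self.t1 + (len(self.v) - 1) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.t2 - self.t1


@dataclass
class SparcParams:
    fc_max: float = 10.0         # Hz; upper bound on the cutoff
    amp_threshold: float = 0.05  # V̂ level defining the adaptive cutoff
    zero_pad_factor: int = 4     # spectrum grid density multiplier
    fixed_cutoff: bool = False   # force ω_c = 2π·fc_max

    def __post_init__(self):
        if self.fc_max <= 0 or self.amp_threshold <= 0 or self.zero_pad_factor < 1:
            raise ParameterError("invalid SPARC parameters")


@dataclass
class SmoothnessRecord:
    metric: str
    value: float
    subject: str = ""
    trial: str = ""
    location: str = ""
    segment: str = ""
    modality: str = ""
    component: str = ""
    scope: str = ""
    side: str = ""
    stride_index: int | None = None


def _spectrum(v: np.ndarray, sample_rate: float, zero_pad_factor: int):
    n = len(v)
    nfft = zero_pad_factor * (1 << (n - 1).bit_length())
    mag = np.abs(np.fft.rfft(v, nfft))
    freq = np.fft.rfftfreq(nfft, 1.0 / sample_rate)
    return freq, mag


def sparc(p: VelocityProfile, params: SparcParams | None = None) -> float:
    """Spectral arc length of the profile's normalised magnitude spectrum.

    Always ≤ 0 (the straight-line chord alone contributes −1 after
    normalisation); invariant to amplitude scaling. With a fixed cutoff the
    spectrum is linearly interpolated at exactly fc_max so the arc length
    covers [0, ω_c] independent of the FFT grid.
    """
    params = params or SparcParams()
    v = p.v
    if len(v) < MIN_WINDOW:
        raise InputError(f"profile too short for SPARC (need >= {MIN_WINDOW} samples)")
    if params.fc_max >= p.sample_rate / 2:
        raise ParameterError("fc_max must be below Nyquist")
    freq, mag = _spectrum(v, p.sample_rate, params.zero_pad_factor)
    if mag[0] == 0:
        raise DomainError("V(0) = 0: profile has zero mean, SPARC undefined")
    vhat = mag / mag[0]

    sel = freq <= params.fc_max
    if params.fixed_cutoff:
        f_sel = freq[sel]
        v_sel = vhat[sel]
        if f_sel[-1] < params.fc_max and sel.sum() < len(freq):
            v_at_fc = np.interp(params.fc_max, freq, vhat)
            f_sel = np.append(f_sel, params.fc_max)
            v_sel = np.append(v_sel, v_at_fc)
        fc = params.fc_max
    else:
        idx = np.flatnonzero(vhat[sel] >= params.amp_threshold)
        j = max(int(idx[-1]), 1) if len(idx) else 1
        f_sel = freq[: j + 1]
        v_sel = vhat[: j + 1]
        fc = f_sel[-1]
    # piecewise-linear arc length of (ω/ω_c, V̂)
    arc = np.sum(np.sqrt((np.diff(f_sel) / fc) ** 2 + np.diff(v_sel) ** 2))
    return -float(arc)


def peaks_metric(p: VelocityProfile) -> int:
    """Negative count of interior local maxima of the profile.

    A strict maximum requires v[i−1] < v[i] > v[i+1]; a flat run strictly
    above both neighbours counts as one maximum.
    """
    v = p.v
    if len(v) < 3:
        raise InputError("profile too short for the Peaks Metric (need >= 3 samples)")
    # collapse equal-value runs so plateaus count once
    keep = np.concatenate([[True], np.diff(v) != 0])
    w = v[keep]
    if len(w) < 3:
        return 0
    count = int(np.sum((w[1:-1] > w[:-2]) & (w[1:-1] > w[2:])))
    return -count


def ldlj(p: VelocityProfile) -> float:
    """Log dimensionless jerk of the profile.

        λ_L = − ln( (t2−t1)³ / v_peak² · ∫ |d²v/dt²|² dt ),  v_peak = max |v|

    Dimensionless by construction: invariant to amplitude scaling and to
    time rescaling. The second derivative is taken by central second
    differences and the integral by the trapezoid rule over the interior
    samples.
    """
    v = p.v
    if len(v) < MIN_WINDOW:
        raise InputError(f"profile too short for LDLJ (need >= {MIN_WINDOW} samples)")
    vpeak_sq = float(np.max(v**2))
    if vpeak_sq == 0:
        raise DomainError("all-zero profile: LDLJ undefined")
    h = 1.0 / p.sample_rate
    d2 = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / h**2
    integral = float(np.trapezoid(d2**2, dx=h))
    if integral == 0:
        raise DomainError("profile has zero jerk everywhere: LDLJ undefined")
    T = p.duration
    return -math.log(T**3 * integral / vpeak_sq)


_METRIC_FUNCS = {
    "SPARC": lambda p, params: sparc(p, params),
    "PM": lambda p, params: float(peaks_metric(p)),
    "LDLJ": lambda p, params: ldlj(p),
}


def _window_slice(x: np.ndarray, sample_rate: float, t_a: float, t_b: float) -> tuple[np.ndarray, int]:
    i0 = int(round(t_a * sample_rate))
    i1 = int(round(t_b * sample_rate))
    i0 = max(i0, 0)
    i1 = min(i1, len(x) - 1)
    return x[i0:i1 + 1], i0


def smoothness_table(trial: IMUTrial, strides_by_side: dict[str, list[Stride]],
                     metrics: Sequence[str] = METRICS,
                     components: Sequence[str] = COMPONENTS,
                     scopes: Sequence[str] = SCOPES,
                     locations: Iterable[Location] | None = None,
                     sparc_params: SparcParams | None = None,
                     profile_source: str = "gyro",
                     sparc_abs: bool = True,
                     min_window: int = MIN_WINDOW) -> list[SmoothnessRecord]:
    """Compute every requested metric over every scope window of a trial.

    One record per (location × component × scope × stride × metric);
    complete-scope records are computed once per location/component.
    Strides are foot-derived; lateral sensors use the strides of their own
    side and the hip sensor receives both sides' segmentations. The
    profile is a gyroscope channel by default (angular speed as v(t));
    ``profile_source="accel"`` switches to the accelerometer. SPARC is
    evaluated on |v| (it expects a speed profile); PM and LDLJ on the
    signed channel. Windows shorter than ``min_window`` samples are
    skipped with a warning.
    """
    sparc_params = sparc_params or SparcParams()
    if profile_source not in ("gyro", "accel"):
        raise ParameterError("profile_source must be 'gyro' or 'accel'")
    locations = list(locations) if locations is not None else trial.locations
    records: list[SmoothnessRecord] = []

    def eval_window(x, scope, loc, comp, side, idx):
        for metric in metrics:
            v = np.abs(x) if (metric == "SPARC" and sparc_abs) else x
            profile = VelocityProfile(v, trial.sample_rate,
                                      source={"location": loc.value, "component": comp,
                                              "scope": scope, "side": side})
            try:
                value = _METRIC_FUNCS[metric](profile, sparc_params)
            except (DomainError, InputError) as exc:
                logger.warning("%s skipped (%s/%s/%s stride %s): %s",
                               metric, loc.value, comp, scope, idx, exc)
                continue
            records.append(SmoothnessRecord(
                metric=metric, value=value, subject=trial.subject_id,
                trial=trial.trial_id, location=loc.value, segment=loc.segment,
                modality=profile_source, component=comp, scope=scope,
                side=side, stride_index=idx))

    for loc in locations:
        loc = Location(loc)
        sig = trial.gyro(loc) if profile_source == "gyro" else trial.accel(loc)
        sides = [loc.side] if loc.side else list(strides_by_side)
        for comp in components:
            full = sig.channel(comp)
            if "complete" in scopes:
                eval_window(full, "complete", loc, comp, loc.side or "both", None)
            for side in sides:
                for stride in strides_by_side.get(side, []):
                    windows = {
                        "stride": (stride.fo_start, stride.fo_end),
                        "swing": (stride.fo_start, stride.fs),
                        "stance": (stride.fs, stride.fo_end),
                    }
                    for scope in scopes:
                        if scope == "complete":
                            continue
                        a, b = windows[scope]
                        x, _ = _window_slice(full, trial.sample_rate, a, b)
                        if len(x) < min_window:
                            logger.warning("window %s [%0.2f, %0.2f] too short; skipped",
                                           scope, a, b)
                            continue
                        eval_window(x, scope, loc, comp, side, stride.index)
    return records


def records_to_dataframe(records: Iterable[SmoothnessRecord]) -> pd.DataFrame:
    """Tidy table: one row per smoothness value with full provenance."""
    rows = [vars(r).copy() for r in records]
    df = pd.DataFrame(rows, columns=["subject", "trial", "location", "segment",
                                     "modality", "component", "scope", "side",
                                     "stride_index", "metric", "value"])
    return df
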