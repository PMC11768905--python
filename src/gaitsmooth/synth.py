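"""Synthetic IMU gait trials with known ground-truth events.

The generator emulates the signal morphology a foot-mounted IMU shows in
level overground walking: the gyroscope pitch channel carries one dominant
peak per stride at foot-off, and the accelerometer pitch channel one
impact-like peak per stride at foot-strike, superimposed on a low-amplitude
stride-periodic oscillation. Left and right feet are offset by half a
stride period. Defaults follow the healthy-adult cohort values this
toolkit targets: a 1.10 s gait cycle with 38.4 % of the cycle in swing.

Roughness is controllable through ``n_submovements``: extra Gaussian
bumps superimposed per gait phase, modelling the submovement-superposition
account of non-smooth movement. Non-foot sensors (shank, thigh, hip) are
attenuated, phase-shifted copies of the foot signals — sufficient for
sensor-location comparisons, with no claim of biomechanical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .events import EventType, GaitEvent
from .io import IMUTrial, Location, Modality, TriaxialSignal

__all__ = ["SyntheticGaitSpec", "GroundTruth", "generate_trial",
           "generate_cohort", "add_submovements"]

# channel amplitudes in physical units (foot sensor, healthy overground gait)
GYRO_PEAK = 300.0    # °/s, foot pitch angular velocity at foot-off
ACCEL_PEAK = 25.0    # m/s², foot pitch acceleration impact at foot-strike
BASELINE_FRACTION = 0.12     # stride-periodic oscillation under the event peaks
SEGMENT_ATTENUATION = {"foot": 1.0, "shank": 0.6, "thigh": 0.4, "hip": 0.25}
SEGMENT_SHIFT_FRACTION = 0.05  # of the stride period, per proximal step


@dataclass
class SyntheticGaitSpec:
    """Generator parameters; defaults are the study conditions of the toolkit."""

    n_strides: int = 6                 # strides per side
    stride_period: float = 1.10        # s (healthy-adult cycle time)
    swing_fraction: float = 0.384      # fraction of cycle in swing
    cadence_jitter: float = 0.02       # relative SD of per-stride period
    noise_sd: float = 0.05             # additive noise SD, fraction of channel peak
    n_submovements: int = 0            # extra bumps per gait phase (roughness)
    submovement_amplitude: float = 0.2  # fraction of channel peak
    impact_sharpness: float = 0.03     # s, FS impact peak width (Gaussian sigma)
    sample_rate: float = 100.0         # Hz
    seed: int = 0

    def __post_init__(self):
        if self.n_strides < 1:
            raise ParameterError("n_strides must be >= 1")
        if not 0 < self.swing_fraction < 1:
            raise ParameterError("swing_fraction must lie in (0, 1)")
        if self.stride_period <= 0 or self.impact_sharpness <= 0 or self.sample_rate <= 0:
            raise ParameterError("durations and sample_rate must be > 0")
        if self.noise_sd < 0 or self.cadence_jitter < 0:
            raise ParameterError("noise_sd and cadence_jitter must be >= 0")
        if self.n_submovements < 0:
            raise ParameterError("n_submovements must be >= 0")


@dataclass
class GroundTruth:
    """True event times and phase durations from the generator."""

    events: list[GaitEvent] = field(default_factory=list)
    swing_durations: dict[str, np.ndarray] = field(default_factory=dict)
    stance_durations: dict[str, np.ndarray] = field(default_factory=dict)

    def times(self, side: str, type: EventType | str) -> np.ndarray:
        type = EventType(type)
        return np.array([e.time for e in self.events
                         if e.side == side and e.type == type])


def add_submovements(profile: np.ndarray, n: int, amplitude_fraction: float = 0.2,
                     seed: int | None = None, rng: np.random.Generator | None = None,
                     sigma_fraction: float = 0.02) -> np.ndarray:
    """Superimpose ``n`` Gaussian submovement bumps on a 1-D profile.

    Bump width is ``sigma_fraction`` of the profile length (at least two
    samples) and bump centres are drawn uniformly inside the profile with a
    pairwise separation of at least 3σ, so each bump contributes a distinct
    local maximum. ``n = 0`` returns the input unchanged.
    """
    profile = np.asarray(profile, float)
    if n == 0:
        return profile.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(profile)
    sigma = max(2.0, sigma_fraction * L)
    lo, hi = 3.0 * sigma, L - 1 - 3.0 * sigma
    if hi <= lo:
        raise ParameterError(f"profile of {L} samples too short for {n} submovements")
    amp = amplitude_fraction * (np.max(np.abs(profile)) or 1.0)
    # rejection-sample centres with >= 3 sigma pairwise separation
    centres: list[float] = []
    for _ in range(10_000):
        c = rng.uniform(lo, hi)
        if all(abs(c - o) >= 3.0 * sigma for o in centres):
            centres.append(c)
            if len(centres) == n:
                break
    else:
        raise ParameterError(f"could not place {n} separated submovements in {L} samples")
    i = np.arange(L)
    bumps = sum(amp * np.exp(-0.5 * ((i - c) / sigma) ** 2) for c in centres)
    return profile + bumps


def _stride_phase(t: np.ndarray, fo_times: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Continuous stride phase: 0 at each foot-off, increasing by 1 per stride.

    Extrapolates with the first/last period outside the event span.
    """
    knots_t = np.concatenate([fo_times, [fo_times[-1] + periods[-1]]])
    knots_p = np.arange(len(knots_t), dtype=float)
    phase = np.interp(t, knots_t, knots_p)
    before = t < knots_t[0]
    after = t > knots_t[-1]
    phase[before] = (t[before] - knots_t[0]) / periods[0]
    phase[after] = knots_p[-1] + (t[after] - knots_t[-1]) / periods[-1]
    return phase


def _pulse_channel(t: np.ndarray, event_times: np.ndarray, widths: np.ndarray,
                   phase: np.ndarray, phase_offset: float, peak: float,
                   envelope: np.ndarray | float = 1.0,
                   baseline_fraction: float = BASELINE_FRACTION) -> np.ndarray:
    """One dominant Gaussian peak per event over a phase-locked oscillation.

    The baseline cosine attains its per-stride maximum at ``phase_offset``
    (the event's position in the stride), so it reinforces the event peak
    instead of creating competing maxima. ``envelope`` tapers the baseline
    to zero during the standstill lead-in/lead-out.
    """
    ch = envelope * baseline_fraction * peak * np.cos(2 * np.pi * (phase - phase_offset))
    for et, w in zip(event_times, widths):
        ch = ch + peak * np.exp(-0.5 * ((t - et) / w) ** 2)
    return ch


def _band_limited_noise(rng: np.random.Generator, n: int, sd: float,
                        sample_rate: float, bandwidth: float = 15.0) -> np.ndarray:
    """White Gaussian noise low-passed at the sensor's effective bandwidth."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n) * sd
    if bandwidth < sample_rate / 2:
        sos = sps.butter(4, bandwidth, btype="low", fs=sample_rate, output="sos")
        w = sps.sosfiltfilt(sos, w)
    return w


def generate_trial(spec: SyntheticGaitSpec,
                   subject_id: str = "SYN", trial_id: str = "T00"
                   ) -> tuple[IMUTrial, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    Deterministic given ``spec.seed``. Per-stride periods are the nominal
    stride period multiplied by a mean-one lognormal jitter factor; the
    right foot is offset by half a nominal stride period.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strides
    # standstill padding; 0.8 of a period keeps the jitter-free event
    # schedule on the sample grid (no half-sample peak ties)
    pad = 0.8 * spec.stride_period

    # per-side event schedule
    fo: dict[str, np.ndarray] = {}
    fs: dict[str, np.ndarray] = {}
    periods: dict[str, np.ndarray] = {}
    for side, offset in (("L", 0.0), ("R", 0.5 * spec.stride_period)):
        if spec.cadence_jitter > 0:
            jit = rng.lognormal(mean=-0.5 * spec.cadence_jitter**2,
                                sigma=spec.cadence_jitter, size=n)
        else:
            jit = np.ones(n)
        p = spec.stride_period * jit
        starts = pad + offset + np.concatenate([[0.0], np.cumsum(p[:-1])])
        fo[side] = starts
        fs[side] = starts + spec.swing_fraction * p
        periods[side] = p

    duration = max(fo[s][-1] + periods[s][-1] for s in ("L", "R")) + pad
    t = np.arange(int(round(duration * spec.sample_rate)) + 1) / spec.sample_rate

    truth = GroundTruth()
    for side in ("L", "R"):
        for i in range(n):
            truth.events.append(GaitEvent(EventType.foot_off, side, float(fo[side][i]),
                                          source="ground_truth"))
            truth.events.append(GaitEvent(EventType.foot_strike, side, float(fs[side][i]),
                                          source="ground_truth"))
        truth.swing_durations[side] = fs[side] - fo[side]
        truth.stance_durations[side] = periods[side] - truth.swing_durations[side]
    truth.events.sort(key=lambda e: e.time)

    def foot_channels(side: str) -> dict[str, np.ndarray]:
        phase = _stride_phase(t, fo[side], periods[side])
        swing_w = 0.25 * truth.swing_durations[side]
        imp_w = np.full(n, spec.impact_sharpness)
        # standstill taper: oscillation fades in before the first event and
        # out after the last, so no spurious maxima appear in the padding
        walk_a, walk_b = fo[side][0], fo[side][-1] + periods[side][-1]
        ramp = 0.6 * pad
        env = (np.clip((t - (walk_a - ramp)) / ramp, 0, 1)
               * np.clip(((walk_b + ramp) - t) / ramp, 0, 1))
        gy = _pulse_channel(t, fo[side], swing_w, phase, 0.0, GYRO_PEAK, env)
        ay = _pulse_channel(t, fs[side], imp_w, phase, spec.swing_fraction,
                            ACCEL_PEAK, env)
        if spec.n_submovements > 0:
            gy = _inject_phase_submovements(gy, side, spec, rng)
            ay = _inject_phase_submovements(ay, side, spec, rng,
                                            peak=ACCEL_PEAK)
        # secondary axes: smaller, slightly offset copies so the resultant is 3-D
        gx = 0.35 * _pulse_channel(t - 0.04, fo[side], swing_w * 1.2, phase, 0.0,
                                   GYRO_PEAK, env)
        gz = 0.25 * _pulse_channel(t + 0.04, fo[side], swing_w * 1.1, phase, 0.0,
                                   GYRO_PEAK, env)
        ax = 0.40 * _pulse_channel(t - 0.02, fs[side], imp_w * 1.5, phase,
                                   spec.swing_fraction, ACCEL_PEAK, env)
        az = 0.30 * _pulse_channel(t + 0.02, fs[side], imp_w * 1.5, phase,
                                   spec.swing_fraction, ACCEL_PEAK, env)
        return {"ax": ax, "ay": ay, "az": az, "gx": gx, "gy": gy, "gz": gz}

    def _inject_phase_submovements(ch, side, spec, rng, peak=GYRO_PEAK):
        fsr = spec.sample_rate
        out = ch.copy()
        for i in range(n):
            for a, b in ((fo[side][i], fs[side][i]),
                         (fs[side][i], fo[side][i] + periods[side][i])):
                i0, i1 = int(round(a * fsr)), int(round(b * fsr))
                i1 = min(i1, len(out) - 1)
                if i1 - i0 < 20:
                    continue
                out[i0:i1] = add_submovements(
                    out[i0:i1], spec.n_submovements,
                    amplitude_fraction=spec.submovement_amplitude, rng=rng)
        return out

    foot = {"L": foot_channels("L"), "R": foot_channels("R")}

    def attenuated(base: dict[str, np.ndarray], segment: str) -> dict[str, np.ndarray]:
        att = SEGMENT_ATTENUATION[segment]
        steps = {"foot": 0, "shank": 1, "thigh": 2, "hip": 3}[segment]
        shift = int(round(steps * SEGMENT_SHIFT_FRACTION * spec.stride_period
                          * spec.sample_rate))
        return {k: att * np.roll(v, shift) for k, v in base.items()}

    layout = {
        Location.foot_L: attenuated(foot["L"], "foot"),
        Location.foot_R: attenuated(foot["R"], "foot"),
        Location.shank_L: attenuated(foot["L"], "shank"),
        Location.shank_R: attenuated(foot["R"], "shank"),
        Location.thigh_L: attenuated(foot["L"], "thigh"),
        Location.thigh_R: attenuated(foot["R"], "thigh"),
        Location.hip: {k: 0.5 * (a + b) for (k, a), (_, b) in
                       zip(attenuated(foot["L"], "hip").items(),
                           attenuated(foot["R"], "hip").items())},
    }

    sensors = {}
    for loc, ch in layout.items():
        noisy = {}
        for name, sig in ch.items():
            peak = np.max(np.abs(sig)) or 1.0
            noisy[name] = sig + _band_limited_noise(
                rng, len(sig), spec.noise_sd * peak, spec.sample_rate)
        accel = TriaxialSignal(loc, Modality.accel, spec.sample_rate,
                               noisy["ax"], noisy["ay"], noisy["az"])
        gyro = TriaxialSignal(loc, Modality.gyro, spec.sample_rate,
                              noisy["gx"], noisy["gy"], noisy["gz"])
        sensors[loc] = (accel, gyro)

    trial = IMUTrial(subject_id, trial_id, sensors)
    return trial, truth


def generate_cohort(n_trials: int, base_spec: SyntheticGaitSpec | None = None,
                    base_seed: int = 0) -> list[tuple[IMUTrial, GroundTruth]]:
    """Generate a cohort of trials with per-trial seeds base_seed + i."""
    base_spec = base_spec or SyntheticGaitSpec()
    out = []
    for i in range(n_trials):
        spec = replace(base_spec, seed=base_seed + i)
        out.append(generate_trial(spec, subject_id=f"SYN{i:02d}", trial_id=f"T{i:02d}"))
    return out
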