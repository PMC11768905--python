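"""Reading, writing and conditioning of triaxial IMU recordings.

A trial is a set of body-worn inertial sensors (hip, thighs, shanks, feet),
each providing a triaxial accelerometer (m/s²) and gyroscope (°/s) stream.
Axis semantics follow the x=yaw, y=pitch, z=roll convention; for a
foot-mounted sensor the pitch axis is the mediolateral (flexion–extension)
axis, which carries the event-bearing signal content.

Conditioning reproduces the standard wearable-gait preprocessing chain:
resampling to a common rate (100 Hz), zero-phase fourth-order Butterworth
low-pass filtering at 5 Hz (walking fundamentals lie at 1–2 Hz), and the
triaxial resultant (Euclidean magnitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError, InputError, ParameterError

__all__ = [
    "Location",
    "Modality",
    "TriaxialSignal",
    "IMUTrial",
    "load_trial",
    "save_trial",
    "resample",
    "lowpass",
    "magnitude",
    "preprocess_trial",
]

#: columns expected in a sensor CSV, after the optional time column
CHANNEL_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")
TIME_COLUMN = "time_s"

#: maximum run of consecutive non-finite samples repaired by interpolation
MAX_NAN_RUN = 2


class Location(str, Enum):
    """Sensor placement on the biomechanical model."""

    hip = "hip"
    thigh_L = "thigh_L"
    thigh_R = "thigh_R"
    shank_L = "shank_L"
    shank_R = "shank_R"
    foot_L = "foot_L"
    foot_R = "foot_R"

    @property
    def side(self) -> str | None:
        if self.value.endswith("_L"):
            return "L"
        if self.value.endswith("_R"):
            return "R"
        return None

    @property
    def segment(self) -> str:
        """Anatomical segment without laterality (foot, shank, thigh, hip)."""
        return self.value.split("_")[0]


class Modality(str, Enum):
    accel = "accel"  # linear acceleration, m/s²
    gyro = "gyro"    # angular velocity, °/s


@dataclass
class TriaxialSignal:
    """Uniformly sampled 3-channel time series from one sensor modality.

    Timestamps are implicit: sample ``k`` is at ``k / sample_rate`` seconds.
    """

    location: Location
    modality: Modality
    sample_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.location = Location(self.location)
        self.modality = Modality(self.modality)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InputError("x, y, z channels must have identical length")
        if len(self.x) < 2:
            raise InputError("signal needs at least 2 samples")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        for name, ch in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(ch)):
                raise InputError(f"non-finite values in channel {name}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.x)) / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self.x) - 1) / self.sample_rate

    def channel(self, component: str) -> np.ndarray:
        """Return one axis by semantic name (yaw/pitch/roll) or the resultant."""
        mapping = {"yaw": self.x, "pitch": self.y, "roll": self.z, "x": self.x,
                   "y": self.y, "z": self.z}
        if component == "magnitude":
            return magnitude(self)
        try:
            return mapping[component]
        except KeyError:
            raise ParameterError(f"unknown component {component!r}") from None


@dataclass
class IMUTrial:
    """A gait trial: one (accel, gyro) signal pair per instrumented location."""

    subject_id: str
    trial_id: str
    sensors: dict[Location, tuple[TriaxialSignal, TriaxialSignal]]
    sample_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.sensors = {Location(k): v for k, v in self.sensors.items()}
        if not self.sensors:
            raise InputError("trial has no sensors")
        if self.sample_rate == 0.0:
            self.sample_rate = next(iter(self.sensors.values()))[0].sample_rate

    @property
    def locations(self) -> list[Location]:
        return list(self.sensors)

    def has_foot_sensor(self) -> bool:
        return Location.foot_L in self.sensors or Location.foot_R in self.sensors

    def accel(self, location: Location | str) -> TriaxialSignal:
        return self.sensors[Location(location)][0]

    def gyro(self, location: Location | str) -> TriaxialSignal:
        return self.sensors[Location(location)][1]


def _repair_nonfinite(values: np.ndarray, max_run: int = MAX_NAN_RUN) -> np.ndarray:
    """Linearly interpolate short non-finite runs; reject longer ones."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    # length of the longest consecutive bad run
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0])))))[::2]
    if runs.max() > max_run or bad[0] or bad[-1]:
        raise InputError(
            f"non-finite run of length {int(runs.max())} exceeds repair policy "
            f"(max {max_run} consecutive, interior only)"
        )
    idx = np.arange(len(values))
    out = values.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return out


def _load_sensor_file(path: Path, location: Location,
                      declared_rate: float | None) -> tuple[TriaxialSignal, TriaxialSignal]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if TIME_COLUMN in df.columns:
        t = df[TIME_COLUMN].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError(f"{path}: time column is not strictly increasing")
        rate = 1.0 / float(np.median(dt))
    elif declared_rate is not None:
        rate = float(declared_rate)
    else:
        raise FormatError(f"{path}: no {TIME_COLUMN} column and no declared sample_rate")
    channels = {c: _repair_nonfinite(df[c].to_numpy(dtype=float)) for c in CHANNEL_COLUMNS}
    accel = TriaxialSignal(location, Modality.accel, rate,
                           channels["ax"], channels["ay"], channels["az"])
    gyro = TriaxialSignal(location, Modality.gyro, rate,
                          channels["gx"], channels["gy"], channels["gz"])
    return accel, gyro


def load_trial(paths: Mapping[Location | str, str | Path],
               subject_id: str = "S00", trial_id: str = "T00",
               sample_rate: float | None = None) -> IMUTrial:
    """Load one trial from per-location delimited tables.

    Each file must contain the six channel columns ``ax ay az gx gy gz``
    and either a ``time_s`` column (native rate inferred from the median
    time step) or a ``sample_rate`` declared by the caller.
    """
    sensors = {}
    for loc, path in paths.items():
        loc = Location(loc)
        sensors[loc] = _load_sensor_file(Path(path), loc, sample_rate)
    rates = {round(s[0].sample_rate, 6) for s in sensors.values()}
    common = sensors[next(iter(sensors))][0].sample_rate if len(rates) == 1 else 0.0
    trial = IMUTrial(subject_id, trial_id, sensors)
    trial.sample_rate = common or trial.sample_rate
    return trial


def save_trial(trial: IMUTrial, directory: str | Path,
               float_format: str = "%.9g") -> Path:
    """Write one CSV per location plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "sample_rate": trial.sample_rate,
        "files": {},
    }
    for loc, (accel, gyro) in trial.sensors.items():
        df = pd.DataFrame({
            TIME_COLUMN: accel.times,
            "ax": accel.x, "ay": accel.y, "az": accel.z,
            "gx": gyro.x, "gy": gyro.y, "gz": gyro.z,
        })
        fname = f"{trial.trial_id}_{loc.value}.csv"
        df.to_csv(directory / fname, index=False, float_format=float_format)
        manifest["files"][loc.value] = fname
    manifest_path = directory / f"{trial.trial_id}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_manifest(manifest_path: str | Path) -> IMUTrial:
    """Load a trial from a JSON manifest written by :func:`save_trial`."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    paths = {loc: manifest_path.parent / fname for loc, fname in meta["files"].items()}
    return load_trial(paths, subject_id=meta.get("subject_id", "S00"),
                      trial_id=meta.get("trial_id", "T00"))


def resample(sig: TriaxialSignal, target_rate: float) -> TriaxialSignal:
    """Resample to ``target_rate`` with an anti-aliased polyphase FIR.

    The rational conversion ratio is approximated to within 1/1000 of the
    exact ratio; an identical rate returns a copy. Band-limited content below
    the smaller of the two Nyquist frequencies is preserved; a short edge
    transient (a few filter lengths) is inherent to FIR resampling.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be > 0")
    if len(sig) < 4:
        raise InputError("signal too short to resample (need >= 4 samples)")
    if abs(target_rate - sig.sample_rate) < 1e-9 * sig.sample_rate:
        return replace(sig, x=sig.x.copy(), y=sig.y.copy(), z=sig.z.copy())
    frac = Fraction(target_rate / sig.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = [sps.resample_poly(ch, up, down, padtype="line")
           for ch in (sig.x, sig.y, sig.z)]
    return TriaxialSignal(sig.location, sig.modality, target_rate, *out)


def lowpass(sig: TriaxialSignal, order: int = 4, fc: float = 5.0) -> TriaxialSignal:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so event timing is not shifted
    by group delay; the effective attenuation is therefore that of a filter
    of twice the nominal order.
    """
    nyq = sig.sample_rate / 2.0
    if not 0 < fc < nyq:
        raise ParameterError(f"cut-off {fc} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = sps.butter(order, fc, btype="low", fs=sig.sample_rate, output="sos")
    out = [sps.sosfiltfilt(sos, ch) for ch in (sig.x, sig.y, sig.z)]
    return TriaxialSignal(sig.location, sig.modality, sig.sample_rate, *out)


def magnitude(sig: TriaxialSignal) -> np.ndarray:
    """Triaxial resultant: elementwise sqrt(x² + y² + z²)."""
    return np.sqrt(sig.x**2 + sig.y**2 + sig.z**2)


def preprocess_trial(trial: IMUTrial, target_rate: float = 100.0,
                     filter_order: int = 4, filter_fc: float = 5.0) -> IMUTrial:
    """Resample every sensor to a common rate, then low-pass filter.

    Trials already at the target rate are filtered only.
    """
    sensors = {}
    for loc, (accel, gyro) in trial.sensors.items():
        accel = lowpass(resample(accel, target_rate), filter_order, filter_fc)
        gyro = lowpass(resample(gyro, target_rate), filter_order, filter_fc)
        n = min(len(accel), len(gyro))
        accel = replace(accel, x=accel.x[:n], y=accel.y[:n], z=accel.z[:n])
        gyro = replace(gyro, x=gyro.x[:n], y=gyro.y[:n], z=gyro.z[:n])
        sensors[loc] = (accel, gyro)
    # equalize lengths across locations (rounding in rational resampling)
    n = min(len(a) for a, _ in sensors.values())
    for loc, (a, g) in sensors.items():
        sensors[loc] = (
            replace(a, x=a.x[:n], y=a.y[:n], z=a.z[:n]),
            replace(g, x=g.x[:n], y=g.y[:n], z=g.z[:n]),
        )
    out = IMUTrial(trial.subject_id, trial.trial_id, sensors)
    out.sample_rate = target_rate
    return out
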