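"""Sensor-recording data model, CSV/JSON I/O, resampling, impact detection.

A session is a uniformly sampled multi-channel time series: a 3-axis
gyroscope (deg/s), a 3-axis accelerometer on the racket and optionally at
the wrist and elbow (g), one grip-pressure channel and two raw surface-EMG
channels (sensor units).  On disk a session is a plain CSV stream with a
``time_s`` column plus one column per channel, and a JSON sidecar carrying
player metadata (id, group, handedness, grip position, spin condition).

The processing entry points here implement the first stage of the
pipeline: resampling all recordings onto a common grid, flipping x-axis
channels for left-handed players so swing direction is comparable across
the cohort, detecting ball impacts as 20 g threshold crossings on the
racket z-axis, and cutting fixed 2 s stroke windows centred on impact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "MANDATORY_CHANNELS",
    "WRIST_CHANNELS",
    "ELBOW_CHANNELS",
    "SensorRecording",
    "StrokeWindow",
    "read_session",
    "write_session",
    "resample_uniform",
    "normalize_handedness",
    "detect_impacts",
    "extract_stroke_windows",
]

GYRO_CHANNELS = ("gyro_x", "gyro_y", "gyro_z")
RACKET_CHANNELS = ("racket_ax", "racket_ay", "racket_az")
WRIST_CHANNELS = ("wrist_ax", "wrist_ay", "wrist_az")
ELBOW_CHANNELS = ("elbow_ax", "elbow_ay", "elbow_az")
ANALOG_CHANNELS = ("grip_raw", "emg_ecr_raw", "emg_fcr_raw")

#: Channels a session cannot be loaded without.
MANDATORY_CHANNELS = GYRO_CHANNELS + RACKET_CHANNELS + ANALOG_CHANNELS

#: Column suffix per channel group used in the CSV header.
_CSV_UNITS = {name: "dps" for name in GYRO_CHANNELS}
_CSV_UNITS.update({name: "g" for name in RACKET_CHANNELS + WRIST_CHANNELS + ELBOW_CHANNELS})

ACCEL_RANGE_G = 200.0      # ADXL377 full scale
GYRO_RANGE_DPS = 4000.0    # ICM20649 full scale

_UNIFORM_TOL = 1e-6        # relative grid-spacing tolerance (1 ppm)


def _csv_column(name: str) -> str:
    unit = _CSV_UNITS.get(name)
    return f"{name}_{unit}" if unit else name


@dataclass
class SensorRecording:
    """One uniformly sampled multi-channel recording session.

    ``channels`` maps channel names (``gyro_x`` … ``emg_fcr_raw``) to
    float arrays on the common ``time`` grid.  Wrist/elbow accelerometers
    are optional; their presence is exposed via :attr:`has_wrist` /
    :attr:`has_elbow` (in the study 37 of 40 players had usable arm
    accelerometer data).
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sample_rate: float
    handedness: str = "right"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time grid must be 1-D with at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        mean_dt = dt.mean()
        if np.max(np.abs(dt - mean_dt)) > _UNIFORM_TOL * max(mean_dt, 1.0):
            raise ValueError("time grid is not uniform within tolerance")
        for name in MANDATORY_CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing mandatory channel: {name}")
        for name, series in self.channels.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"channel {name} length does not match time grid")
            self.channels[name] = arr
        for name in RACKET_CHANNELS + WRIST_CHANNELS + ELBOW_CHANNELS:
            if name in self.channels and np.any(np.abs(self.channels[name]) > ACCEL_RANGE_G * (1 + 1e-9)):
                raise ValueError(f"{name} exceeds the ±{ACCEL_RANGE_G:g} g sensor range")
        for name in GYRO_CHANNELS:
            if np.any(np.abs(self.channels[name]) > GYRO_RANGE_DPS * (1 + 1e-9)):
                raise ValueError(f"{name} exceeds the ±{GYRO_RANGE_DPS:g} dps sensor range")
        if self.handedness not in ("right", "left"):
            raise ValueError(f"unknown handedness: {self.handedness!r}")

    @property
    def has_wrist(self) -> bool:
        return all(name in self.channels for name in WRIST_CHANNELS)

    @property
    def has_elbow(self) -> bool:
        return all(name in self.channels for name in ELBOW_CHANNELS)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "SensorRecording":
        return SensorRecording(
            time=self.time.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            sample_rate=self.sample_rate,
            handedness=self.handedness,
            metadata=dict(self.metadata),
        )


@dataclass
class StrokeWindow:
    """A fixed 2 s epoch centred on one ball impact (t = 0 at impact)."""

    time: np.ndarray              # seconds relative to impact, uniform
    channels: dict[str, np.ndarray]
    sample_rate: float
    impact_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.time.size
        if self.impact_index != (n - 1) // 2 or n % 2 != 1:
            raise ValueError("impact must sit at the centre sample of an odd-length window")

    @property
    def has_wrist(self) -> bool:
        return all(name in self.channels for name in WRIST_CHANNELS)

    @property
    def has_elbow(self) -> bool:
        return all(name in self.channels for name in ELBOW_CHANNELS)


# ---------------------------------------------------------------------------
# File I/O

def write_session(rec: SensorRecording, path: str | Path) -> None:
    """Write a session as ``<path>.csv`` + ``<path>.json`` (or to *path* if
    it already ends in ``.csv``)."""
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    json_path = csv_path.with_suffix(".json")
    columns = {"time_s": rec.time}
    for name in MANDATORY_CHANNELS + WRIST_CHANNELS + ELBOW_CHANNELS:
        if name in rec.channels:
            columns[_csv_column(name)] = rec.channels[name]
    pd.DataFrame(columns).to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "sample_rate": rec.sample_rate,
        "handedness": rec.handedness,
        "metadata": rec.metadata,
        "channels": sorted(rec.channels),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))


def read_session(path: str | Path) -> SensorRecording:
    """Read a session written by :func:`write_session`.

    Raises ``ValueError`` naming the first missing mandatory channel
    column, and propagates the grid-uniformity check of
    :class:`SensorRecording`.
    """
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    json_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise ValueError("missing time_s column")
    for name in MANDATORY_CHANNELS:
        if _csv_column(name) not in df.columns:
            raise ValueError(f"missing mandatory channel column: {_csv_column(name)}")
    channels = {}
    for name in MANDATORY_CHANNELS + WRIST_CHANNELS + ELBOW_CHANNELS:
        col = _csv_column(name)
        if col in df.columns:
            channels[name] = df[col].to_numpy(dtype=float)
    sidecar = json.loads(json_path.read_text()) if json_path.exists() else {}
    time = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time).mean()
    return SensorRecording(
        time=time,
        channels=channels,
        sample_rate=float(sidecar.get("sample_rate", 1.0 / dt)),
        handedness=sidecar.get("handedness", "right"),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Processing

def resample_uniform(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Resample a recording onto a uniform grid at ``target_rate`` Hz.

    Linear interpolation; the new grid spans exactly the original
    duration with ``round(duration * target_rate) + 1`` samples, so first
    and last samples are preserved and constant/ramp channels are
    reproduced exactly.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0, t1 = float(rec.time[0]), float(rec.time[-1])
    n_out = int(round((t1 - t0) * target_rate)) + 1
    if n_out < 2:
        raise ValueError("recording too short for target rate")
    new_time = np.linspace(t0, t1, n_out)
    channels = {name: np.interp(new_time, rec.time, series) for name, series in rec.channels.items()}
    actual_rate = (n_out - 1) / (t1 - t0)
    return SensorRecording(
        time=new_time,
        channels=channels,
        sample_rate=actual_rate,
        handedness=rec.handedness,
        metadata=dict(rec.metadata),
    )


#: Channels whose x-axis is mirrored between left and right handed players.
_FLIP_CHANNELS = ("gyro_x", "racket_ax")


def normalize_handedness(rec: SensorRecording) -> SensorRecording:
    """Negate the gyroscope and racket-accelerometer x-axes of left-handed
    players so their swing matches the right-handed sign convention.

    Right-handed recordings are returned unchanged (same object); applying
    the flip twice restores the original channels.
    """
    if rec.handedness == "right":
        return rec
    out = rec.copy()
    for name in _FLIP_CHANNELS:
        out.channels[name] = -out.channels[name]
    out.metadata = {**out.metadata, "x_axis_flipped": not rec.metadata.get("x_axis_flipped", False)}
    return out


def detect_impacts(rec: SensorRecording, cfg: PipelineConfig | None = None) -> list[float]:
    """Return impact times: first samples at which the racket z-axis
    reaches the 20 g threshold.

    Successive detections closer than the refractory period are
    suppressed, and only impacts with a full ±1 s data margin inside the
    recording are returned (a stroke window must fit around them).
    """
    cfg = cfg or PipelineConfig()
    z = rec.channels["racket_az"]
    sig = np.abs(z) if cfg.use_abs_impact else z
    above = sig >= cfg.impact_threshold
    # first samples of each run above threshold
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    impacts: list[float] = []
    last = -np.inf
    for idx in onsets:
        t = float(rec.time[idx])
        if t - last < cfg.impact_refractory:
            continue
        last = t
        if t - rec.time[0] >= 1.0 and rec.time[-1] - t >= 1.0:
            impacts.append(t)
    return impacts


def extract_stroke_windows(rec: SensorRecording, impacts: list[float]) -> list[StrokeWindow]:
    """Cut one ±1 s window per impact, centred on the impact sample.

    The window holds ``2 * round(sample_rate) + 1`` samples with the
    impact at the exact centre; an impact closer than 1 s to either
    recording edge is an error.
    """
    half = int(round(rec.sample_rate))
    windows = []
    for t_imp in impacts:
        centre = int(np.argmin(np.abs(rec.time - t_imp)))
        lo, hi = centre - half, centre + half + 1
        if lo < 0 or hi > rec.time.size:
            raise ValueError(f"impact at t={t_imp:.3f}s lacks a full ±1 s margin")
        window_time = rec.time[lo:hi] - rec.time[centre]
        channels = {name: series[lo:hi].copy() for name, series in rec.channels.items()}
        windows.append(
            StrokeWindow(
                time=window_time,
                channels=channels,
                sample_rate=rec.sample_rate,
                impact_index=half,
                metadata={**rec.metadata, "impact_time": t_imp},
            )
        )
    return windows
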