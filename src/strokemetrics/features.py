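"""EMG envelopes, MVC/grip normalization and shock-transmission metrics.

EMG amplitude is extracted with the classic rectify-and-smooth chain:
zero-phase order-8 Butterworth high-pass at 10 Hz (removes movement
artefact and DC), full-wave rectification, then a zero-phase order-8
Butterworth low-pass at 10 Hz.  "Order 8" is the design order of each
pass; forward–backward application doubles the effective order and
cancels phase lag, so envelope bursts stay aligned with their sources.
Negative undershoot from the smoothing filter is clipped at zero since a
muscle-activity amplitude is physically nonnegative.

Grip pressure and the two EMG envelopes are expressed in percent of a
per-player reference measured during three 5 s seated maximal-grip
trials: the trial with the highest grip value is selected and the middle
two seconds of its grip trace and EMG envelopes are averaged.  Dynamic
values routinely exceed 100 %MVC — the isometric reference does not bound
activity during a stroke.

Impact shock is quantified on band-limited acceleration magnitudes: a
400 Hz zero-phase low-pass removes string vibration and a 15 Hz
zero-phase high-pass removes gross arm motion, leaving the 15–400 Hz
frame-shock band.  The post-impact peak of each band-limited magnitude
(racket, wrist, elbow) feeds the transmission percentage
``100 − ((A_racket − A_x) / A_racket × 100)``, which simplifies to
``100 · A_x / A_racket``: the fraction of the racket's impact shock that
reaches the body site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import FilterConfig
from .recording import StrokeWindow, WRIST_CHANNELS, ELBOW_CHANNELS
from .segmentation import PhaseBoundaries, racket_head_acceleration

__all__ = [
    "MvcReference",
    "NormalizedStroke",
    "ShockMetrics",
    "emg_envelope",
    "mvc_reference",
    "normalize_to_mvc",
    "shock_bandlimit",
    "peak_after_impact",
    "shock_transmission_pct",
    "compute_shock_metrics",
]


@dataclass(frozen=True)
class MvcReference:
    """Per-player normalization references from the maximal-grip trials."""

    grip_max: float
    ecr_mvc: float
    fcr_mvc: float
    selected_trial: int

    def __post_init__(self) -> None:
        if min(self.grip_max, self.ecr_mvc, self.fcr_mvc) <= 0:
            raise ValueError("all MVC reference values must be positive")


@dataclass
class NormalizedStroke:
    """Normalized per-stroke curves on the window time grid."""

    time: np.ndarray
    grip_pct: np.ndarray
    ecr_pct: np.ndarray
    fcr_pct: np.ndarray
    racket_head_accel: np.ndarray
    swing_path_angle: np.ndarray
    gyro_y: np.ndarray
    bounds: PhaseBoundaries | None = None
    metadata: dict | None = None


@dataclass(frozen=True)
class ShockMetrics:
    """Band-limited post-impact peaks and transmission percentages."""

    peak_racket: float
    peak_wrist: float | None
    peak_elbow: float | None
    pct_wrist: float | None
    pct_elbow: float | None
    wrist_available: bool = True
    elbow_available: bool = True


def _sos(order: int, cutoff, btype: str, fs: float):
    return sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def emg_envelope(raw: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Rectify-and-smooth EMG amplitude envelope (zero-phase, clipped at 0)."""
    cfg = cfg or FilterConfig()
    cfg.validate_rate(rate)
    raw = np.asarray(raw, dtype=float)
    min_len = 3 * 2 * (2 * cfg.emg_order + 1)   # sosfiltfilt default padding
    if raw.size < min_len:
        raise ValueError(f"series too short for order-{cfg.emg_order} zero-phase filtering")
    hp = sps.sosfiltfilt(_sos(cfg.emg_order, cfg.emg_hp_cutoff, "highpass", rate), raw)
    env = sps.sosfiltfilt(_sos(cfg.emg_order, cfg.emg_lp_cutoff, "lowpass", rate), np.abs(hp))
    return np.clip(env, 0.0, None)


def mvc_reference(trials, cfg: FilterConfig | None = None) -> MvcReference:
    """Build the normalization reference from three maximal-grip trials.

    The trial attaining the global maximum grip value is selected (first
    trial wins ties); references are means over the middle 2 s of that
    trial's grip trace and EMG envelopes.
    """
    trials = list(trials)
    if len(trials) != 3:
        raise ValueError(f"exactly three MVC trials are required, got {len(trials)}")
    for k, rec in enumerate(trials):
        if rec.duration < 5.0 - 1e-9:
            raise ValueError(f"MVC trial {k} shorter than 5 s")
    maxima = [float(np.max(rec.channels["grip_raw"])) for rec in trials]
    sel = int(np.argmax(maxima))   # np.argmax returns the first maximum
    rec = trials[sel]
    mid = (rec.time[0] + rec.time[-1]) / 2.0
    mask = (rec.time >= mid - 1.0) & (rec.time <= mid + 1.0)
    grip_ref = float(rec.channels["grip_raw"][mask].mean())
    ecr_env = emg_envelope(rec.channels["emg_ecr_raw"], rec.sample_rate, cfg)
    fcr_env = emg_envelope(rec.channels["emg_fcr_raw"], rec.sample_rate, cfg)
    ecr_ref = float(ecr_env[mask].mean())
    fcr_ref = float(fcr_env[mask].mean())
    if min(grip_ref, ecr_ref, fcr_ref) <= 0:
        raise ValueError("non-positive MVC reference value")
    return MvcReference(grip_max=grip_ref, ecr_mvc=ecr_ref, fcr_mvc=fcr_ref,
                        selected_trial=sel)


def normalize_to_mvc(window: StrokeWindow, ref: MvcReference,
                     cfg: FilterConfig | None = None,
                     bounds: PhaseBoundaries | None = None) -> NormalizedStroke:
    """Express a stroke's grip and EMG envelopes in percent of reference."""
    from .segmentation import swing_path_angle  # local import avoids cycle at module load

    grip_pct = 100.0 * window.channels["grip_raw"] / ref.grip_max
    ecr_pct = 100.0 * emg_envelope(window.channels["emg_ecr_raw"], window.sample_rate, cfg) / ref.ecr_mvc
    fcr_pct = 100.0 * emg_envelope(window.channels["emg_fcr_raw"], window.sample_rate, cfg) / ref.fcr_mvc
    return NormalizedStroke(
        time=window.time,
        grip_pct=grip_pct,
        ecr_pct=ecr_pct,
        fcr_pct=fcr_pct,
        racket_head_accel=racket_head_acceleration(window),
        swing_path_angle=swing_path_angle(window),
        gyro_y=window.channels["gyro_y"],
        bounds=bounds,
        metadata=dict(window.metadata),
    )


def shock_bandlimit(acc: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Restrict an acceleration series to the 15–400 Hz frame-shock band.

    Zero-phase low-pass at 400 Hz (string vibration) followed by a
    zero-phase high-pass at 15 Hz (arm motion), order ``shock_order`` per
    pass.
    """
    cfg = cfg or FilterConfig()
    if rate <= 800.0:
        raise ValueError("sample rate must exceed 800 Hz for the 400 Hz low-pass")
    cfg.validate_rate(rate)
    acc = np.asarray(acc, dtype=float)
    lp = sps.sosfiltfilt(_sos(cfg.shock_order, cfg.shock_lp_cutoff, "lowpass", rate), acc)
    return sps.sosfiltfilt(_sos(cfg.shock_order, cfg.shock_hp_cutoff, "highpass", rate), lp)


def peak_after_impact(series: np.ndarray, time: np.ndarray,
                      bounds: PhaseBoundaries | None = None,
                      max_lag: float = 0.5) -> float:
    """Peak |series| over t ∈ [0, min(max_lag, follow-through end)]."""
    t_end = max_lag if bounds is None else min(max_lag, bounds.t_follow_end)
    mask = (time >= 0.0) & (time <= t_end)
    if not mask.any():
        raise ValueError("empty post-impact search interval")
    return float(np.max(np.abs(np.asarray(series)[mask])))


def shock_transmission_pct(a_x: float, a_racket: float) -> float:
    """Percentage of racket impact shock transferred to a body site.

    Evaluates ``100 − ((a_racket − a_x) / a_racket × 100)``; larger means
    more impact force reaches the arm.  Undefined for a nonpositive
    racket peak.
    """
    if a_racket <= 0:
        raise ValueError("racket peak acceleration must be positive")
    if a_x < 0:
        raise ValueError("site peak acceleration must be nonnegative")
    return 100.0 - ((a_racket - a_x) / a_racket * 100.0)


def _bandlimited_magnitude(window: StrokeWindow, names, cfg: FilterConfig) -> np.ndarray:
    """Vector magnitude of per-axis band-limited acceleration channels.

    Each axis is restricted to the 15–400 Hz shock band *before* the
    Euclidean norm is taken: the filters are linear on the axis signals,
    so an attenuated copy of the racket transient stays an attenuated
    copy, whereas filtering the (rectified, hence nonlinear) magnitude
    series would fold swing and contaminant components into the peak.
    """
    bl = [shock_bandlimit(window.channels[n], window.sample_rate, cfg) for n in names]
    return np.sqrt(sum(x ** 2 for x in bl))


def compute_shock_metrics(window: StrokeWindow, bounds: PhaseBoundaries | None = None,
                          cfg: FilterConfig | None = None) -> ShockMetrics:
    """Band-limit the racket/wrist/elbow accelerations, take post-impact
    peaks of their vector magnitudes and express wrist/elbow peaks as
    transmission percentages.  Absent wrist/elbow channels yield ``None``
    fields with availability flags cleared."""
    cfg = cfg or FilterConfig()
    from .recording import RACKET_CHANNELS
    peak_racket = peak_after_impact(
        _bandlimited_magnitude(window, RACKET_CHANNELS, cfg), window.time, bounds)

    peaks: dict[str, float | None] = {"wrist": None, "elbow": None}
    for site, names, present in (("wrist", WRIST_CHANNELS, window.has_wrist),
                                 ("elbow", ELBOW_CHANNELS, window.has_elbow)):
        if present:
            mag = _bandlimited_magnitude(window, names, cfg)
            peaks[site] = peak_after_impact(mag, window.time, bounds)

    def pct(site):
        return None if peaks[site] is None else shock_transmission_pct(peaks[site], peak_racket)

    return ShockMetrics(
        peak_racket=peak_racket,
        peak_wrist=peaks["wrist"],
        peak_elbow=peaks["elbow"],
        pct_wrist=pct("wrist"),
        pct_elbow=pct("elbow"),
        wrist_available=window.has_wrist,
        elbow_available=window.has_elbow,
    )
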