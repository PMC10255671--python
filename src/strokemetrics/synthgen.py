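"""Synthetic forehand-stroke recordings with known ground truth.

Real multi-sensor tennis recordings are not publicly deposited, so every
stage of the pipeline is exercised against synthetic sessions whose phase
boundaries, impact peaks, attenuation ratios and EMG burst windows are
known by construction.  The generator emulates the qualitative structure
of racket-mounted IMU + arm accelerometer + grip/EMG recordings:

* racket acceleration follows a smooth swing profile that first exceeds
  1 g at the programmed preparation onset and falls back below 1 g at the
  follow-through end, with a > 20 g exponentially decaying impact
  transient (150 Hz carrier) on the z-axis at the programmed impact time;
* the swing-path angle (atan2 of racket x over z) ramps monotonically
  from a backswing value below −90° through −90° exactly at the
  programmed acceleration onset, up to a terminal angle at impact — the
  low-to-high "brushing" trajectory;
* wrist and elbow accelerometers carry the racket impact transient scaled
  by attenuation ratios in (0, 1), plus a < 15 Hz arm-motion component
  and a > 400 Hz string-vibration component, i.e. contaminants that the
  15–400 Hz shock band-limit removes;
* grip pressure is a smooth burst peaking near impact; the two EMG
  channels are band-limited (20–450 Hz) noise bursts confined to
  programmed windows.

Channels are clipped to the hardware ranges (±200 g accelerometers,
±4000 dps gyroscope).  All randomness is driven by explicit integer
seeds: identical seeds give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .recording import SensorRecording

__all__ = [
    "StrokeParams",
    "StrokeTruth",
    "MvcParams",
    "CohortSpec",
    "PlayerData",
    "generate_stroke",
    "generate_mvc_trials",
    "generate_cohort",
]

_NOISE_GROUPS = ("accel", "gyro", "grip", "emg")

#: Default additive measurement-noise standard deviations per channel family.
DEFAULT_NOISE_SD = {"accel": 0.02, "gyro": 2.0, "grip": 0.005, "emg": 0.02}

#: Terminal swing-path angles (degrees) reproducing the study's group/spin
#: orderings: experienced players brush far more on topspin.
DEFAULT_THETA_END = {
    ("experienced", "flat"): 4.3,
    ("experienced", "topspin"): 20.0,
    ("recreational", "flat"): 5.2,
    ("recreational", "topspin"): 6.8,
}


@dataclass(frozen=True)
class StrokeTruth:
    """Ground truth for one synthetic stroke (times relative to impact)."""

    t_prep_start: float
    t_accel_start: float
    t_impact: float
    t_follow_end: float
    attenuation_wrist: float
    attenuation_elbow: float
    emg_burst_windows: dict
    peak_impact_g: float
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 < self.t_prep_start < self.t_accel_start < 0.0 < self.t_follow_end < 1.0):
            raise ValueError("phase boundary ordering violated or outside (−1, +1) s")
        if not (0.0 < self.attenuation_elbow < self.attenuation_wrist < 1.0):
            raise ValueError("require 0 < attenuation_elbow < attenuation_wrist < 1")
        if self.peak_impact_g <= 20.0:
            raise ValueError("peak_impact_g must exceed the 20 g detection threshold")


@dataclass(frozen=True)
class StrokeParams:
    """Shape parameters for one synthetic stroke recording."""

    sample_rate: float = 8333.0
    duration: float = 3.0
    impact_time: float = 1.5           # absolute position of impact in the recording
    t_prep_start: float = -0.45        # phase boundaries relative to impact (s)
    t_accel_start: float = -0.12
    t_follow_end: float = 0.38
    peak_impact_g: float = 50.0
    impact_freq: float = 150.0         # transient carrier, inside the 15–400 Hz band
    impact_decay: float = 0.015        # e-folding time of the transient (s)
    attenuation_wrist: float = 0.2
    attenuation_elbow: float = 0.05
    swing_peak_g: float = 3.5
    theta_start: float = -150.0        # backswing swing-path angle (deg), < −90
    theta_end: float = 20.0            # terminal swing-path angle at impact (deg), > −90
    grip_amp: float = 1.0
    emg_burst_windows: tuple = (("ecr", (-0.10, 0.30)), ("fcr", (-0.30, 0.00)))
    emg_burst_amp: tuple = (1.0, 1.5)  # (ecr, fcr) burst noise SD, sensor units
    arm_motion_amp: tuple = (0.5, 0.25)   # (wrist, elbow) g, < 15 Hz component
    arm_motion_freq: float = 2.5
    string_vib_amp: tuple = (0.4, 0.15)   # (wrist, elbow) g, > 400 Hz component
    string_vib_freq: float = 800.0
    include_wrist: bool = True
    include_elbow: bool = True
    handedness: str = "right"
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        if self.sample_rate <= 1000.0:
            raise ValueError("sample_rate must exceed 1000 Hz")
        if not (0.0 < self.attenuation_elbow < self.attenuation_wrist < 1.0):
            raise ValueError("require 0 < attenuation_elbow < attenuation_wrist < 1")
        if not (-1.0 < self.t_prep_start < self.t_accel_start < 0.0 < self.t_follow_end < 1.0):
            raise ValueError("phase boundaries must satisfy prep < accel < 0 < follow within ±1 s")
        if self.peak_impact_g <= 20.0:
            raise ValueError("peak_impact_g must exceed 20 g")
        if not self.theta_start < -90.0 < self.theta_end:
            raise ValueError("swing-path ramp must straddle −90°")
        if self.impact_time - 1.0 < 0 or self.impact_time + 1.0 > self.duration:
            raise ValueError("impact must have a ±1 s margin inside the recording")

    def noiseless(self) -> "StrokeParams":
        """Copy with all additive measurement noise switched off."""
        return replace(self, noise_sd={k: 0.0 for k in DEFAULT_NOISE_SD})


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float = 20.0, hi: float = 450.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the surface-EMG band."""
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(t_rel: np.ndarray, start: float, end: float) -> np.ndarray:
    """Hann-shaped burst envelope over [start, end] seconds (else zero)."""
    env = np.zeros_like(t_rel)
    mask = (t_rel >= start) & (t_rel <= end)
    span = end - start
    if span > 0:
        env[mask] = np.sin(np.pi * (t_rel[mask] - start) / span) ** 2
    return env


def generate_stroke(params: StrokeParams | None = None, seed: int = 0
                    ) -> tuple[SensorRecording, StrokeTruth]:
    """Generate one recording containing a single forehand stroke.

    Returns the recording and the ground truth actually realised on the
    sample grid (boundary times are snapped to the nearest sample, so
    downstream recovery can be asserted to ±1 sample).
    """
    p = params or StrokeParams()
    rng = np.random.default_rng(seed)
    fs = p.sample_rate
    n = int(round(p.duration * fs)) + 1
    t = np.arange(n) / fs

    i0 = int(round(p.impact_time * fs))
    i_prep = i0 + int(round(p.t_prep_start * fs))
    i_accel = i0 + int(round(p.t_accel_start * fs))
    i_follow = i0 + int(round(p.t_follow_end * fs))
    t_rel = (np.arange(n) - i0) / fs

    # --- racket-head acceleration magnitude profile (g) -------------------
    # below 1 g outside the stroke, jumps to 1.05 g exactly at the
    # preparation-onset sample, sinusoidal hump through the swing, drops
    # back below 1 g exactly at the follow-through-end sample.
    P = np.full(n, 0.3)
    span = np.arange(i_prep, i_follow)
    s = (span - i_prep) / max(i_follow - i_prep, 1)
    P[span] = 1.05 + (p.swing_peak_g - 1.05) * np.sin(np.pi * s)

    # --- swing-path angle trajectory (degrees) ----------------------------
    # monotone ramp crossing −90° exactly at the acceleration-onset sample.
    theta = np.full(n, p.theta_start)
    d = max(int(round(min(0.1, (p.t_accel_start - p.t_prep_start) / 2) * fs)), 1)
    ramp0 = i_accel - d
    seg1 = np.arange(ramp0, i_accel + 1)
    theta[seg1] = p.theta_start + (-90.0 - p.theta_start) * (seg1 - ramp0) / d
    seg2 = np.arange(i_accel, i0 + 1)
    theta[seg2] = -90.0 + (p.theta_end + 90.0) * (seg2 - i_accel) / max(i0 - i_accel, 1)
    theta[i0:] = p.theta_end
    theta_rad = np.deg2rad(theta)

    racket_ax = P * np.sin(theta_rad)
    racket_ay = np.zeros(n)
    racket_az = P * np.cos(theta_rad)

    # --- impact transient: decaying cosine starting AT the impact sample --
    tau = (np.arange(n) - i0) / fs
    transient = np.where(
        tau >= 0,
        p.peak_impact_g * np.exp(-np.maximum(tau, 0.0) / p.impact_decay)
        * np.cos(2 * np.pi * p.impact_freq * tau),
        0.0,
    )
    racket_az = racket_az + transient

    # --- gyroscope (deg/s): plausible swing profile + impact ring ---------
    swing_env = np.zeros(n)
    swing_env[span] = np.sin(np.pi * s)
    ring = np.where(tau >= 0, 180.0 * np.exp(-np.maximum(tau, 0.0) / 0.03)
                    * np.cos(2 * np.pi * 120.0 * tau), 0.0)
    gyro_y = 450.0 * swing_env + ring
    gyro_x = 150.0 * swing_env * np.sin(2 * np.pi * 1.2 * t_rel)
    gyro_z = 300.0 * swing_env * np.clip(t_rel / 0.4, -1, 1)

    # --- grip pressure: smooth burst peaking at impact --------------------
    w = 0.5
    grip = 0.1 + p.grip_amp * np.where(np.abs(t_rel) < w,
                                       np.cos(np.pi * t_rel / (2 * w)) ** 2, 0.0)

    # --- EMG: band-limited noise bursts inside the programmed windows -----
    burst_windows = dict(p.emg_burst_windows)
    emg = {}
    for (name, (b0, b1)), amp in zip(burst_windows.items(), p.emg_burst_amp):
        carrier = _bandlimited_noise(rng, n, fs)
        emg[name] = amp * carrier * _burst_envelope(t_rel, b0, b1)

    channels = {
        "gyro_x": gyro_x, "gyro_y": gyro_y, "gyro_z": gyro_z,
        "racket_ax": racket_ax, "racket_ay": racket_ay, "racket_az": racket_az,
        "grip_raw": grip,
        "emg_ecr_raw": emg["ecr"], "emg_fcr_raw": emg["fcr"],
    }

    # --- wrist/elbow: attenuated transient + out-of-band contaminants -----
    arm = np.sin(2 * np.pi * p.arm_motion_freq * t_rel)
    vib = np.where(tau >= 0, np.exp(-np.maximum(tau, 0.0) / 0.05)
                   * np.sin(2 * np.pi * p.string_vib_freq * tau), 0.0)
    for site, ratio, present, i_site in (
        ("wrist", p.attenuation_wrist, p.include_wrist, 0),
        ("elbow", p.attenuation_elbow, p.include_elbow, 1),
    ):
        if not present:
            continue
        channels[f"{site}_ax"] = ratio * transient + p.string_vib_amp[i_site] * vib
        channels[f"{site}_ay"] = p.arm_motion_amp[i_site] * arm
        channels[f"{site}_az"] = np.zeros(n)

    # --- additive measurement noise and hardware clipping -----------------
    noise = dict(p.noise_sd)
    for name, series in channels.items():
        if name.startswith("gyro"):
            sd, rng_lim = noise.get("gyro", 0.0), 4000.0
        elif name == "grip_raw":
            sd, rng_lim = noise.get("grip", 0.0), np.inf
        elif name.startswith("emg"):
            sd, rng_lim = noise.get("emg", 0.0), np.inf
        else:
            sd, rng_lim = noise.get("accel", 0.0), 200.0
        if sd > 0:
            series = series + rng.normal(0.0, sd, n)
        channels[name] = np.clip(series, -rng_lim, rng_lim) if np.isfinite(rng_lim) else series

    if p.handedness == "left":
        # a left-handed player's mirrored swing: x-axes change sign
        channels["gyro_x"] = -channels["gyro_x"]
        channels["racket_ax"] = -channels["racket_ax"]

    rec = SensorRecording(
        time=t, channels=channels, sample_rate=fs,
        handedness=p.handedness, metadata={"synthetic": True, "seed": int(seed)},
    )
    truth = StrokeTruth(
        t_prep_start=(i_prep - i0) / fs,
        t_accel_start=(i_accel - i0) / fs,
        t_impact=0.0,
        t_follow_end=(i_follow - i0) / fs,
        attenuation_wrist=p.attenuation_wrist,
        attenuation_elbow=p.attenuation_elbow,
        emg_burst_windows=burst_windows,
        peak_impact_g=p.peak_impact_g,
        seed=int(seed),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# MVC trials

@dataclass(frozen=True)
class MvcParams:
    """Parameters for the three maximum-grip reference trials.

    Each trial is a sustained maximal grip: the grip channel holds a
    trapezoidal plateau (the middle 2 s sit entirely on the plateau) and
    the two EMG channels burst at an amplitude proportional to the
    plateau.  Exactly one trial carries the maximum plateau.
    """

    sample_rate: float = 8333.0
    trial_duration: float = 6.0
    plateau_grip: tuple = (0.85, 1.0, 0.9)
    ecr_scale: float = 2.0     # EMG burst SD per unit grip plateau
    fcr_scale: float = 1.2
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        if self.trial_duration < 5.0:
            raise ValueError("MVC trials must last at least 5 s")
        if len(self.plateau_grip) != 3:
            raise ValueError("exactly three MVC trials are required")


def generate_mvc_trials(params: MvcParams | None = None, seed: int = 0) -> list[SensorRecording]:
    """Generate the three seated maximum-grip trials for one player."""
    p = params or MvcParams()
    fs = p.sample_rate
    n = int(round(p.trial_duration * fs)) + 1
    t = np.arange(n) / fs
    mid = p.trial_duration / 2
    rise = 0.5
    plateau_lo, plateau_hi = mid - 1.5, mid + 1.5   # middle 2 s sits inside
    env = np.clip(np.minimum((t - (plateau_lo - rise)) / rise,
                             ((plateau_hi + rise) - t) / rise), 0.0, 1.0)
    trials = []
    root = np.random.default_rng(seed)
    for k, level in enumerate(p.plateau_grip):
        rng = np.random.default_rng(root.integers(2**31))
        grip = level * env
        sd = p.noise_sd.get("grip", 0.0)
        if sd > 0:
            grip = grip + rng.normal(0, sd, n)
        channels = {name: np.zeros(n) for name in
                    ("gyro_x", "gyro_y", "gyro_z", "racket_ax", "racket_ay", "racket_az")}
        channels["grip_raw"] = grip
        for ch, scale in (("emg_ecr_raw", p.ecr_scale), ("emg_fcr_raw", p.fcr_scale)):
            burst = scale * level * _bandlimited_noise(rng, n, fs) * env
            esd = p.noise_sd.get("emg", 0.0)
            if esd > 0:
                burst = burst + rng.normal(0, esd, n)
            channels[ch] = burst
        trials.append(SensorRecording(
            time=t, channels=channels, sample_rate=fs,
            metadata={"synthetic": True, "mvc_trial": k, "plateau": level},
        ))
    return trials


# ---------------------------------------------------------------------------
# Cohorts

EffectCurve = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class CohortSpec:
    """Specification for a two-group synthetic cohort.

    ``group_effect_curves`` maps a raw channel name to a callable
    ``f(t_rel) -> offset`` evaluated on times relative to each impact;
    the offset is added to that channel, for players of the second group
    only, within ±1 s of every impact.  For the EMG channels the offset is
    injected as an amplitude-modulated 80 Hz carrier scaled by π/2 so the
    downstream rectified-and-smoothed envelope rises by ≈ the requested
    offset (an additive DC offset would be removed by the 10 Hz high-pass).
    A cohort with no (or all-zero) effect curves is a null cohort: both
    groups are drawn from the same distribution.
    """

    n_players_per_group: int = 8
    n_strokes_per_player: int = 3
    group_effect_curves: Mapping[str, EffectCurve] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    sample_rate: float = 2000.0
    seed: int = 0
    groups: tuple = ("experienced", "recreational")
    spins: tuple = ("flat", "topspin")
    stroke_spacing: float = 2.2
    group_param_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    spin_param_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    left_handed_fraction: float = 0.075

    def __post_init__(self) -> None:
        if self.n_players_per_group < 2:
            raise ValueError("need at least 2 players per group")
        if self.n_strokes_per_player < 1:
            raise ValueError("need at least 1 stroke per player")
        if self.sample_rate <= 1000.0:
            raise ValueError("sample_rate must exceed 1000 Hz")


@dataclass
class PlayerData:
    """All recordings for one synthetic player."""

    player_id: str
    group: str
    grip_position: str
    handedness: str
    mvc_trials: list
    sessions: dict          # spin condition -> SensorRecording
    included: dict          # spin condition -> list[bool] inclusion flags per stroke


def _inject_effect(rec: SensorRecording, impact_times: Sequence[float],
                   curves: Mapping[str, EffectCurve]) -> None:
    """Add group-effect offsets around each impact (in place)."""
    for channel, fn in curves.items():
        if channel not in rec.channels:
            raise ValueError(f"effect curve names unknown channel: {channel}")
        series = rec.channels[channel]
        for t_imp in impact_times:
            mask = np.abs(rec.time - t_imp) <= 1.0
            t_rel = rec.time[mask] - t_imp
            offset = np.asarray(fn(t_rel), dtype=float)
            if offset.shape != t_rel.shape:
                raise ValueError(f"effect curve for {channel} returned wrong length")
            if channel.startswith("emg"):
                carrier = np.sin(2 * np.pi * 80.0 * t_rel)
                series[mask] += (np.pi / 2) * offset * carrier
            else:
                series[mask] += offset


def generate_cohort(spec: CohortSpec | None = None
                    ) -> tuple[list[PlayerData], list[StrokeTruth], list[str]]:
    """Generate a two-group cohort of players with per-spin sessions.

    Returns ``(players, truths, labels)``; ``truths`` is ordered by
    (player, spin condition, stroke) and ``labels`` gives the group of
    each player in order.  Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or CohortSpec()
    root = np.random.default_rng(spec.seed)
    players: list[PlayerData] = []
    truths: list[StrokeTruth] = []
    labels: list[str] = []
    n_strokes = spec.n_strokes_per_player
    session_len = 2.0 + (n_strokes - 1) * spec.stroke_spacing + 0.2

    idx = 0
    for g_i, group in enumerate(spec.groups):
        for _ in range(spec.n_players_per_group):
            idx += 1
            player_rng = np.random.default_rng(root.integers(2**31))
            handedness = "left" if player_rng.random() < spec.left_handed_fraction else "right"
            grip_position = ["Eastern", "semi-Western"][int(player_rng.random() < 0.45)]
            pid = f"P{idx:02d}"
            labels.append(group)

            # per-player trait variation around the cohort means
            base = {
                "attenuation_wrist": float(np.clip(player_rng.normal(0.2, 0.03), 0.08, 0.45)),
                "attenuation_elbow": float(np.clip(player_rng.normal(0.04, 0.008), 0.01, 0.07)),
                "peak_impact_g": float(player_rng.uniform(40.0, 60.0)),
                "grip_amp": float(player_rng.uniform(0.8, 1.2)),
            }
            base.update(spec.group_param_overrides.get(group, {}))

            mvc = generate_mvc_trials(
                MvcParams(sample_rate=spec.sample_rate, noise_sd=spec.noise_sd),
                seed=int(player_rng.integers(2**31)),
            )

            sessions: dict[str, SensorRecording] = {}
            included: dict[str, list[bool]] = {}
            for spin in spec.spins:
                time = np.arange(int(round(session_len * spec.sample_rate)) + 1) / spec.sample_rate
                session_channels: dict[str, np.ndarray] | None = None
                impact_times = []
                for s_i in range(n_strokes):
                    stroke_seed = int(player_rng.integers(2**31))
                    t_imp = 1.05 + s_i * spec.stroke_spacing
                    overrides = dict(base)
                    overrides.update(spec.spin_param_overrides.get(spin, {}))
                    overrides.setdefault(
                        "theta_end", DEFAULT_THETA_END.get((group, spin), 10.0))
                    sp = StrokeParams(
                        sample_rate=spec.sample_rate,
                        duration=2.1,
                        impact_time=1.05,
                        t_prep_start=float(player_rng.uniform(-0.65, -0.35)),
                        t_accel_start=float(player_rng.uniform(-0.22, -0.07)),
                        t_follow_end=float(player_rng.uniform(0.25, 0.55)),
                        handedness=handedness,
                        noise_sd=spec.noise_sd,
                        **overrides,
                    )
                    stroke_rec, truth = generate_stroke(sp, seed=stroke_seed)
                    truths.append(truth)
                    offset = int(round((t_imp - 1.05) * spec.sample_rate))
                    if session_channels is None:
                        session_channels = {
                            name: np.zeros(time.size) for name in stroke_rec.channels}
                    for name, series in stroke_rec.channels.items():
                        session_channels[name][offset:offset + series.size] += series
                    impact_times.append(t_imp)
                session = SensorRecording(
                    time=time, channels=session_channels, sample_rate=spec.sample_rate,
                    handedness=handedness,
                    metadata={"player_id": pid, "group": group, "spin": spin,
                              "grip_position": grip_position, "synthetic": True},
                )
                if g_i == 1 and spec.group_effect_curves:
                    _inject_effect(session, impact_times, spec.group_effect_curves)
                sessions[spin] = session
                included[spin] = [True] * n_strokes
            players.append(PlayerData(
                player_id=pid, group=group, grip_position=grip_position,
                handedness=handedness, mvc_trials=mvc,
                sessions=sessions, included=included,
            ))
    return players, truths, labels
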