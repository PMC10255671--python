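"""Kinematic series and stroke-phase segmentation.

A forehand stroke divides into preparation (backswing onset to the first
forward racket movement), acceleration (forward movement to ball impact),
impact (t = 0) and follow-through (impact to stroke end).  The boundaries
are read off two derived series:

* **racket-head acceleration** — the Euclidean norm of the racket
  accelerometer's three axes (g); preparation starts when it first
  exceeds 1 g before impact and follow-through ends when it first falls
  back below 1 g after impact;
* **swing-path angle** — the full-quadrant inverse tangent of the racket
  x-axis over the z-axis, in degrees; −90° corresponds to acceleration
  toward the bottom edge of the racket, i.e. the pause before the racket
  moves forward, and the acceleration phase starts at the last pre-impact
  crossing of −90°.  The two-argument arctangent is essential: the
  single-argument quotient form has open range (−90°, 90°) and can never
  attain −90°.

Each phase is additionally split into early/late halves at its temporal
midpoint for phase-resolved summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .recording import StrokeWindow

__all__ = [
    "PhaseBoundaries",
    "racket_head_acceleration",
    "swing_path_angle",
    "segment_phases",
    "split_early_late",
]


@dataclass(frozen=True)
class PhaseBoundaries:
    """Stroke-phase boundary times in seconds relative to impact."""

    t_prep_start: float
    t_accel_start: float
    t_follow_end: float
    t_impact: float = 0.0
    flags: tuple = ()

    def __post_init__(self) -> None:
        if not (-1.0 < self.t_prep_start <= self.t_accel_start < 0.0 < self.t_follow_end < 1.0):
            raise ValueError("boundaries must satisfy −1 < prep ≤ accel < 0 < follow < 1")

    @property
    def phases(self) -> dict[str, tuple[float, float]]:
        return {
            "preparation": (self.t_prep_start, self.t_accel_start),
            "acceleration": (self.t_accel_start, 0.0),
            "follow_through": (0.0, self.t_follow_end),
        }


def racket_head_acceleration(window: StrokeWindow) -> np.ndarray:
    """Pointwise vector magnitude of the racket accelerometer axes (g)."""
    return np.sqrt(window.channels["racket_ax"] ** 2
                   + window.channels["racket_ay"] ** 2
                   + window.channels["racket_az"] ** 2)


def swing_path_angle(window: StrokeWindow) -> np.ndarray:
    """Swing-path angle series in degrees, range (−180, 180].

    atan2(x, z): 0° when the acceleration points out of the string bed
    (+z), −90° toward the bottom edge (−x).  Samples where both inputs
    are zero have no defined angle; the previous value is carried
    forward (0° if the series starts undefined).
    """
    x = window.channels["racket_ax"]
    z = window.channels["racket_az"]
    angle = np.degrees(np.arctan2(x, z))
    undefined = (x == 0.0) & (z == 0.0)
    if undefined.any():
        angle = angle.copy()
        prev = 0.0
        for i in range(angle.size):
            if undefined[i]:
                angle[i] = prev
            else:
                prev = angle[i]
    # map −180 to +180 so the range is the half-open (−180, 180]
    angle[angle == -180.0] = 180.0
    return angle


def _sustained_true(mask: np.ndarray, n_sustain: int) -> np.ndarray:
    """Boolean array marking samples that start a run of >= n_sustain Trues."""
    if n_sustain <= 1:
        return mask
    # windowed AND via cumulative sum of the boolean series
    c = np.concatenate(([0], np.cumsum(mask.astype(int))))
    ok = np.zeros_like(mask)
    last = mask.size - n_sustain
    if last >= 0:
        ok[: last + 1] = (c[n_sustain:] - c[:-n_sustain]) == n_sustain
    return ok


def segment_phases(window: StrokeWindow, cfg: PipelineConfig | None = None) -> PhaseBoundaries:
    """Locate the preparation onset, acceleration onset and follow-through
    end of a stroke window (impact is t = 0 at the window centre).

    Onsets on the 1 g racket-head-acceleration threshold must be
    sustained for at least 10 ms to reject single-sample noise; the
    follow-through search starts at +0.05 s so the impact transient
    itself cannot terminate the stroke.  If no −90° swing-path crossing
    exists before impact, the time of the pre-impact minimum of the
    swing-path angle is used and the result is flagged.
    """
    cfg = cfg or PipelineConfig()
    accel = racket_head_acceleration(window)
    t = window.time
    fs = window.sample_rate
    centre = window.impact_index
    n_sustain = max(int(round(0.010 * fs)), 1)
    flags: list[str] = []

    # preparation onset: first sustained sample above threshold, scanning
    # forward from the window start (pre-impact region only)
    above = accel > cfg.phase_threshold
    onset_ok = _sustained_true(above, n_sustain)
    pre_idx = np.flatnonzero(onset_ok[:centre])
    if pre_idx.size == 0:
        raise ValueError("no preparation onset: racket-head acceleration never "
                         f"sustains > {cfg.phase_threshold:g} g before impact")
    i_prep = int(pre_idx[0])

    # follow-through end: first sustained sample below threshold after +0.05 s
    guard = centre + max(int(round(0.05 * fs)), 1)
    below = ~above
    offset_ok = _sustained_true(below, n_sustain)
    post_idx = np.flatnonzero(offset_ok[guard:])
    if post_idx.size == 0:
        raise ValueError("no follow-through end: racket-head acceleration never "
                         f"sustains < {cfg.phase_threshold:g} g after impact")
    i_follow = int(guard + post_idx[0])

    # acceleration onset: latest pre-impact upward crossing of −90°
    angle = swing_path_angle(window)
    pre = angle[: centre + 1]
    crossings = np.flatnonzero((pre[1:] >= -90.0) & (pre[:-1] < -90.0)) + 1
    if crossings.size:
        i_accel = int(crossings[-1])
    else:
        i_accel = int(np.argmin(pre))
        flags.append("accel_onset_fallback_min_angle")
    if i_accel < i_prep:
        i_accel = i_prep
        flags.append("accel_onset_clamped_to_prep")

    return PhaseBoundaries(
        t_prep_start=float(t[i_prep]),
        t_accel_start=float(t[i_accel]),
        t_follow_end=float(t[i_follow]),
        flags=tuple(flags),
    )


def split_early_late(bounds: PhaseBoundaries) -> dict[str, tuple[float, float]]:
    """Split each phase into early/late halves at its temporal midpoint.

    Returns a dict with keys like ``preparation_early``; the two halves
    partition the phase (union equals the phase, intersection empty).  A
    zero-length phase yields two empty intervals and is flagged with the
    key ``<phase>_degenerate`` mapping to the point interval.
    """
    out: dict[str, tuple[float, float]] = {}
    for name, (a, b) in bounds.phases.items():
        mid = (a + b) / 2.0
        out[f"{name}_early"] = (a, mid)
        out[f"{name}_late"] = (mid, b)
        if b <= a:
            out[f"{name}_degenerate"] = (a, b)
    return out
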