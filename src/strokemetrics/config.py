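"""Configuration objects for the forehand-stroke processing pipeline.

Three small dataclasses collect every tunable threshold in one place:

* :class:`PipelineConfig` — impact detection and stroke windowing (working
  sample rate, the 20 g impact threshold on the racket z-axis, the 1 g
  phase threshold on racket-head acceleration).
* :class:`FilterConfig` — Butterworth designs for the EMG amplitude
  envelope (order-8, 10 Hz high-pass then 10 Hz low-pass on the rectified
  signal, both zero-phase) and the 15–400 Hz shock band-limit.
* :class:`SnpmConfig` — permutation counts, significance level and seeding
  for the non-parametric 1-D SPM tests.

All three can be loaded from a single YAML document with
:func:`load_configs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "PipelineConfig",
    "FilterConfig",
    "SnpmConfig",
    "load_configs",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Impact detection and windowing parameters.

    Attributes
    ----------
    target_rate : float
        Common working sample rate in Hz; recordings are resampled to this
        grid before any analysis.
    impact_threshold : float
        Ball-impact threshold in g on the racket z-axis accelerometer
        (perpendicular to the string bed).
    impact_refractory : float
        Minimum spacing in seconds between successive detected impacts.
    phase_threshold : float
        Racket-head acceleration threshold in g marking the start of the
        preparation phase and the end of the follow-through.
    use_abs_impact : bool
        If True, threshold |z| rather than the signed z channel.  Impact
        polarity depends on sensor mounting; the default thresholds the
        signed channel.
    """

    target_rate: float = 8333.0
    impact_threshold: float = 20.0
    impact_refractory: float = 0.5
    phase_threshold: float = 1.0
    use_abs_impact: bool = False

    def __post_init__(self) -> None:
        for name in ("target_rate", "impact_threshold", "impact_refractory", "phase_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth filter parameters for EMG envelopes and shock band-limiting.

    The EMG chain is: zero-phase high-pass at ``emg_hp_cutoff``, full-wave
    rectification, zero-phase low-pass at ``emg_lp_cutoff``; ``emg_order``
    is the design order of each pass (forward–backward application doubles
    the effective order).  The shock chain is a zero-phase low-pass at
    ``shock_lp_cutoff`` (removes string vibration) followed by a zero-phase
    high-pass at ``shock_hp_cutoff`` (removes arm motion).
    """

    emg_order: int = 8
    emg_hp_cutoff: float = 10.0
    emg_lp_cutoff: float = 10.0
    shock_lp_cutoff: float = 400.0
    shock_hp_cutoff: float = 15.0
    shock_order: int = 4

    def __post_init__(self) -> None:
        for name in ("emg_hp_cutoff", "emg_lp_cutoff", "shock_lp_cutoff", "shock_hp_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.emg_order < 1 or self.shock_order < 1:
            raise ValueError("filter orders must be >= 1")

    def validate_rate(self, rate: float) -> None:
        """Raise if any cutoff reaches the Nyquist frequency of *rate*."""
        nyq = rate / 2.0
        for name in ("emg_hp_cutoff", "emg_lp_cutoff", "shock_lp_cutoff", "shock_hp_cutoff"):
            if getattr(self, name) >= nyq:
                raise ValueError(f"{name}={getattr(self, name)} Hz >= Nyquist ({nyq} Hz)")


@dataclass(frozen=True)
class SnpmConfig:
    """Permutation-test parameters for 1-D SnPM comparisons.

    ``n_permutations`` random relabelings are drawn unless the number of
    distinct relabelings is at most ``exhaustive_limit``, in which case the
    null distribution is enumerated exactly.  ``alpha`` is the two-sided
    familywise significance level applied to the max-|t| null.
    """

    alpha: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0
    exhaustive_limit: int = 10_000
    n_nodes: int = 401

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")


def load_configs(path: str | Path) -> tuple[PipelineConfig, FilterConfig, SnpmConfig]:
    """Load the three config objects from a YAML file.

    The document may contain ``pipeline``, ``filters`` and ``snpm``
    sections; missing sections or keys fall back to defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return (
        PipelineConfig(**(doc.get("pipeline") or {})),
        FilterConfig(**(doc.get("filters") or {})),
        SnpmConfig(**(doc.get("snpm") or {})),
    )


def dump_configs(pipeline: PipelineConfig, filters: FilterConfig, snpm: SnpmConfig) -> dict:
    """Serialise the three configs to a plain dict (for run logs)."""
    return {"pipeline": asdict(pipeline), "filters": asdict(filters), "snpm": asdict(snpm)}
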