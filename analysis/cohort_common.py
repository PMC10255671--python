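"""Shared cohort definition for the numbered analysis drivers.

One place defines the simulated study conditions so every driver sees the
identical cohort: two groups of 4 players, 3 strokes per spin condition,
2 kHz sampling (desk-scale), default measurement noise, and the
group/spin-specific terminal swing-path angles that emulate the study's
low-to-high brushing orderings.
"""

from strokemetrics.config import PipelineConfig, SnpmConfig
from strokemetrics.synthgen import CohortSpec, generate_cohort

COHORT_SPEC = CohortSpec(
    n_players_per_group=4,
    n_strokes_per_player=3,
    sample_rate=2000.0,
    seed=2023,
)

PIPELINE_CFG = PipelineConfig(target_rate=2000.0)
SNPM_CFG = SnpmConfig(n_permutations=1000, n_nodes=101, seed=2023)


def make_cohort():
    return generate_cohort(COHORT_SPEC)
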