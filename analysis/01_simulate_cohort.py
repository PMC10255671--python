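#!/usr/bin/env python
"""Simulate the study cohort: two groups of players, two spin conditions.

Generates a deterministic synthetic cohort (4 experienced + 4 recreational
players, 3 forehand strokes per spin condition at 2 kHz, plus three
maximal-grip reference trials per player), writes the raw sessions as
CSV/JSON under ``scratch/cohort/`` with a manifest, and records the
per-stroke ground truth (phase boundaries, programmed attenuations, impact
peaks) under ``results/01_cohort_truth.csv``.

The downstream drivers regenerate the same cohort from the seed, so they
can be run independently of the files written here.
"""

import sys
from pathlib import Path

import pandas as pd
import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
from cohort_common import COHORT_SPEC, make_cohort  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from strokemetrics.recording import write_session

    players, truths, labels = make_cohort()
    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"players": []}
    rows = []
    truth_iter = iter(truths)
    for player in players:
        entry = {"id": player.player_id, "group": player.group,
                 "grip_position": player.grip_position,
                 "handedness": player.handedness,
                 "sessions": {}, "mvc_trials": []}
        for spin, session in player.sessions.items():
            path = out / f"{player.player_id}_{spin}.csv"
            write_session(session, path)
            entry["sessions"][spin] = str(path)
            for k in range(COHORT_SPEC.n_strokes_per_player):
                truth = next(truth_iter)
                rows.append({
                    "player_id": player.player_id, "group": player.group,
                    "spin": spin, "stroke": k,
                    "t_prep_start": truth.t_prep_start,
                    "t_accel_start": truth.t_accel_start,
                    "t_follow_end": truth.t_follow_end,
                    "attenuation_wrist": truth.attenuation_wrist,
                    "attenuation_elbow": truth.attenuation_elbow,
                    "peak_impact_g": truth.peak_impact_g,
                })
        for k, trial in enumerate(player.mvc_trials):
            path = out / f"{player.player_id}_mvc{k}.csv"
            write_session(trial, path)
            entry["mvc_trials"].append(str(path))
        manifest["players"].append(entry)

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(results / "01_cohort_truth.csv", index=False,
                    float_format="%.6g")

    print(f"simulated {len(players)} players "
          f"({labels.count('experienced')} experienced, "
          f"{labels.count('recreational')} recreational), "
          f"{len(rows)} strokes at {COHORT_SPEC.sample_rate:.0f} Hz")
    print(f"sessions under {out}, ground truth in results/01_cohort_truth.csv")
    print("programmed attenuation ranges: "
          f"wrist {truth_df.attenuation_wrist.min():.3f}–"
          f"{truth_df.attenuation_wrist.max():.3f}, "
          f"elbow {truth_df.attenuation_elbow.min():.3f}–"
          f"{truth_df.attenuation_elbow.max():.3f}")


if __name__ == "__main__":
    main()
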