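"""End-to-end orchestration: ingest → segment → features → group statistics.

The pipeline consumes one recording session per player per spin condition
(flat / topspin) plus three maximal-grip reference trials per player, and
produces:

* a per-stroke feature table (phase boundaries, band-limited shock peaks
  and transmission percentages, grip/EMG peaks in percent of reference);
* a per-player summary (stroke means per spin condition);
* scalar comparison tables — paired flat-vs-topspin within each group and
  two-sample between groups at each spin level, each row naming the test
  actually used (t or Wilcoxon) and its normality decision;
* SnPM cluster tables for the curve variables (racket face-angle rate,
  racket-head acceleration, grip %, ECR %, FCR %) over the same four
  comparison families.

No multiple-comparison correction is applied across the scalar tests —
each runs at α = 0.05 — and players whose wrist/elbow accelerometers are
absent are excluded from the corresponding shock comparisons only.
Players preferring a Continental grip are ingested but excluded from
grip-position comparisons.  Everything is deterministic given the seeds
recorded in the run metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import FilterConfig, PipelineConfig, SnpmConfig, dump_configs
from .features import compute_shock_metrics, mvc_reference, normalize_to_mvc
from .recording import (SensorRecording, detect_impacts, extract_stroke_windows,
                        normalize_handedness, read_session, resample_uniform)
from .segmentation import segment_phases
from .spm import (GroupCurves, compare_scalars, decimate_to_grid,
                  player_mean_curve, snpm_paired, snpm_two_sample)
from .synthgen import PlayerData

__all__ = [
    "StudyManifest",
    "ResultsBundle",
    "run_pipeline",
    "run_cohort",
    "write_outputs",
]

CURVE_VARIABLES = ("gyro_y", "racket_head_accel", "grip_pct", "ecr_pct", "fcr_pct")

SCALAR_VARIABLES = ("peak_racket", "peak_wrist", "peak_elbow",
                    "pct_wrist", "pct_elbow",
                    "grip_at_impact_pct", "ecr_peak_pct", "fcr_peak_pct")

#: Scalar variables that require arm accelerometers.
_SHOCK_VARIABLES = {"peak_wrist", "peak_elbow", "pct_wrist", "pct_elbow"}


@dataclass
class StudyManifest:
    """Players and file paths for a file-based pipeline run."""

    players: list        # dicts: id, group, grip_position, handedness,
                         # sessions {spin: path}, mvc_trials [paths]

    def __post_init__(self) -> None:
        ids = [p["id"] for p in self.players]
        if len(set(ids)) != len(ids):
            raise ValueError("player ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(players=doc["players"])

    def load(self) -> list[PlayerData]:
        """Read every referenced session into memory."""
        from .synthgen import PlayerData  # local to avoid confusion in docs
        out = []
        for entry in self.players:
            sessions = {spin: read_session(p) for spin, p in entry["sessions"].items()}
            mvc = [read_session(p) for p in entry["mvc_trials"]]
            if len(mvc) < 3:
                raise ValueError(f"player {entry['id']} has {len(mvc)} MVC trials; 3 required")
            included = {spin: entry.get("included", {}).get(spin, [True] * 10**6)
                        for spin in sessions}
            out.append(PlayerData(
                player_id=entry["id"], group=entry["group"],
                grip_position=entry.get("grip_position", "Eastern"),
                handedness=entry.get("handedness", "right"),
                mvc_trials=mvc, sessions=sessions, included=included,
            ))
        return out


@dataclass
class ResultsBundle:
    """All tables produced by one pipeline run."""

    stroke_features: pd.DataFrame
    player_summary: pd.DataFrame
    scalar_tests: pd.DataFrame
    snpm_clusters: pd.DataFrame
    curves: dict                      # (group, spin, variable) -> GroupCurves
    run_metadata: dict


def _process_player(player: PlayerData, pipeline_cfg: PipelineConfig,
                    filter_cfg: FilterConfig, snpm_cfg: SnpmConfig):
    """Segment one player's sessions and extract per-stroke features."""
    ref = mvc_reference(player.mvc_trials, filter_cfg)
    rows = []
    curves: dict[tuple[str, str], list[np.ndarray]] = {}
    for spin, session in player.sessions.items():
        rec = session
        if abs(rec.sample_rate - pipeline_cfg.target_rate) > 1e-6 * pipeline_cfg.target_rate:
            rec = resample_uniform(rec, pipeline_cfg.target_rate)
        rec = normalize_handedness(rec)
        impacts = detect_impacts(rec, pipeline_cfg)
        windows = extract_stroke_windows(rec, impacts)
        included_flags = player.included.get(spin, [True] * len(windows))
        for k, window in enumerate(windows):
            if k < len(included_flags) and not included_flags[k]:
                continue
            bounds = segment_phases(window, pipeline_cfg)
            stroke = normalize_to_mvc(window, ref, filter_cfg, bounds)
            shock = compute_shock_metrics(window, bounds, filter_cfg)
            rows.append({
                "player_id": player.player_id,
                "group": player.group,
                "grip_position": player.grip_position,
                "spin": spin,
                "stroke_id": f"{player.player_id}_{spin}_{k:02d}",
                "impact_time": window.metadata.get("impact_time", np.nan),
                "t_prep_start": bounds.t_prep_start,
                "t_accel_start": bounds.t_accel_start,
                "t_follow_end": bounds.t_follow_end,
                "segmentation_flags": ";".join(bounds.flags),
                "peak_racket": shock.peak_racket,
                "peak_wrist": shock.peak_wrist,
                "peak_elbow": shock.peak_elbow,
                "pct_wrist": shock.pct_wrist,
                "pct_elbow": shock.pct_elbow,
                "wrist_available": shock.wrist_available,
                "elbow_available": shock.elbow_available,
                "grip_at_impact_pct": float(stroke.grip_pct[window.impact_index]),
                "ecr_peak_pct": float(stroke.ecr_pct.max()),
                "fcr_peak_pct": float(stroke.fcr_pct.max()),
            })
            curves.setdefault((spin, "strokes"), []).append(stroke)
    return rows, curves, ref


def run_cohort(players: list[PlayerData],
               pipeline_cfg: PipelineConfig | None = None,
               filter_cfg: FilterConfig | None = None,
               snpm_cfg: SnpmConfig | None = None,
               min_valid_strokes: int = 5) -> ResultsBundle:
    """Run the full analysis on in-memory player data."""
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    filter_cfg = filter_cfg or FilterConfig()
    snpm_cfg = snpm_cfg or SnpmConfig()

    all_rows = []
    player_curves: dict[tuple[str, str, str], np.ndarray] = {}
    curve_grid = None
    groups_present: list[str] = []
    spins_present: list[str] = []

    for player in players:
        rows, curves, _ = _process_player(player, pipeline_cfg, filter_cfg, snpm_cfg)
        all_rows.extend(rows)
        if player.group not in groups_present:
            groups_present.append(player.group)
        for (spin, _), strokes in curves.items():
            if spin not in spins_present:
                spins_present.append(spin)
            for var in CURVE_VARIABLES:
                mean, _sd = player_mean_curve(strokes, var)
                grid, dec = decimate_to_grid(strokes[0].time, mean, snpm_cfg.n_nodes)
                curve_grid = grid
                player_curves[(player.player_id, spin, var)] = dec

    stroke_features = pd.DataFrame(all_rows)

    # per-player summary: stroke means per spin
    if not stroke_features.empty:
        player_summary = (stroke_features
                          .groupby(["player_id", "group", "grip_position", "spin"],
                                   as_index=False)
                          .agg(n_strokes=("stroke_id", "count"),
                               **{v: (v, "mean") for v in SCALAR_VARIABLES}))
        player_summary["flagged_low_strokes"] = player_summary["n_strokes"] < min_valid_strokes
    else:
        player_summary = pd.DataFrame()

    group_of = {p.player_id: p.group for p in players}
    has_arm = {p.player_id: all(s.has_wrist and s.has_elbow for s in p.sessions.values())
               for p in players}

    # ---- scalar comparisons ---------------------------------------------
    scalar_rows = []
    if not player_summary.empty:
        pivot = player_summary.set_index(["player_id", "spin"])
        players_by_group = {g: [p.player_id for p in players if p.group == g]
                            for g in groups_present}

        def values(pids, spin, var):
            vals, kept = [], []
            for pid in pids:
                if var in _SHOCK_VARIABLES and not has_arm[pid]:
                    continue
                try:
                    v = pivot.loc[(pid, spin), var]
                except KeyError:
                    continue
                if np.isfinite(v):
                    vals.append(float(v))
                    kept.append(pid)
            return np.array(vals), kept

        seed_counter = 0
        for var in SCALAR_VARIABLES:
            # paired: flat vs topspin within each group
            if len(spins_present) >= 2:
                s1, s2 = spins_present[0], spins_present[1]
                for g in groups_present:
                    v1, ids1 = values(players_by_group[g], s1, var)
                    v2, ids2 = values(players_by_group[g], s2, var)
                    common = [pid for pid in ids1 if pid in ids2]
                    if len(common) < 2:
                        continue
                    a = np.array([v1[ids1.index(pid)] for pid in common])
                    b = np.array([v2[ids2.index(pid)] for pid in common])
                    rep = compare_scalars(a, b, paired=True, seed=snpm_cfg.seed + seed_counter)
                    seed_counter += 1
                    scalar_rows.append({
                        "variable": var, "comparison": f"{g}: {s1} vs {s2}",
                        "family": "paired", "n": len(common),
                        "mean_a": rep.mean_a, "mean_b": rep.mean_b,
                        "statistic": rep.statistic, "p_value": rep.p_value,
                        "test": rep.test_name, "normality_p": rep.normality_p,
                        "significant": rep.p_value < snpm_cfg.alpha,
                    })
            # two-sample: between groups at each spin
            if len(groups_present) >= 2:
                g1, g2 = groups_present[0], groups_present[1]
                for spin in spins_present:
                    va, _ = values(players_by_group[g1], spin, var)
                    vb, _ = values(players_by_group[g2], spin, var)
                    if len(va) < 2 or len(vb) < 2:
                        continue
                    rep = compare_scalars(va, vb, paired=False, seed=snpm_cfg.seed + seed_counter)
                    seed_counter += 1
                    scalar_rows.append({
                        "variable": var, "comparison": f"{g1} vs {g2}: {spin}",
                        "family": "two-sample", "n": f"{len(va)}/{len(vb)}",
                        "mean_a": rep.mean_a, "mean_b": rep.mean_b,
                        "statistic": rep.statistic, "p_value": rep.p_value,
                        "test": rep.test_name, "normality_p": rep.normality_p,
                        "significant": rep.p_value < snpm_cfg.alpha,
                    })
    scalar_tests = pd.DataFrame(scalar_rows)

    # ---- SnPM comparisons ------------------------------------------------
    curves_out: dict = {}
    snpm_rows = []
    if curve_grid is not None:
        def group_curves(g, spin, var):
            pids = [p.player_id for p in players if p.group == g
                    and (p.player_id, spin, var) in player_curves]
            if not pids:
                return None
            mat = np.vstack([player_curves[(pid, spin, var)] for pid in pids])
            return GroupCurves(grid=curve_grid, curves=mat, group=g, variable=var), pids

        for var in CURVE_VARIABLES:
            for g in groups_present:
                for spin in spins_present:
                    gc = group_curves(g, spin, var)
                    if gc:
                        curves_out[(g, spin, var)] = gc[0]
            # paired flat vs topspin within group
            if len(spins_present) >= 2:
                s1, s2 = spins_present[0], spins_present[1]
                for g in groups_present:
                    a, b = curves_out.get((g, s1, var)), curves_out.get((g, s2, var))
                    if a is None or b is None or a.n != b.n or a.n < 2:
                        continue
                    res = snpm_paired(a, b, snpm_cfg)
                    for (c0, c1, direction) in res.clusters:
                        snpm_rows.append({
                            "variable": var, "comparison": f"{g}: {s1} vs {s2}",
                            "family": "paired", "cluster_start_s": c0,
                            "cluster_end_s": c1,
                            "higher_mean": s1 if direction == "A>B" else s2,
                            "critical_t": res.critical_t,
                        })
            # two-sample between groups per spin
            if len(groups_present) >= 2:
                g1, g2 = groups_present[0], groups_present[1]
                for spin in spins_present:
                    a, b = curves_out.get((g1, spin, var)), curves_out.get((g2, spin, var))
                    if a is None or b is None or a.n < 2 or b.n < 2:
                        continue
                    res = snpm_two_sample(a, b, snpm_cfg)
                    for (c0, c1, direction) in res.clusters:
                        snpm_rows.append({
                            "variable": var, "comparison": f"{g1} vs {g2}: {spin}",
                            "family": "two-sample", "cluster_start_s": c0,
                            "cluster_end_s": c1,
                            "higher_mean": g1 if direction == "A>B" else g2,
                            "critical_t": res.critical_t,
                        })
    snpm_clusters = pd.DataFrame(
        snpm_rows, columns=["variable", "comparison", "family", "cluster_start_s",
                            "cluster_end_s", "higher_mean", "critical_t"])

    metadata = {
        "n_players": len(players),
        "groups": groups_present,
        "spins": spins_present,
        "configs": dump_configs(pipeline_cfg, filter_cfg, snpm_cfg),
        "n_strokes": int(len(stroke_features)),
    }
    return ResultsBundle(
        stroke_features=stroke_features,
        player_summary=player_summary,
        scalar_tests=scalar_tests,
        snpm_clusters=snpm_clusters,
        curves=curves_out,
        run_metadata=metadata,
    )


def run_pipeline(manifest: StudyManifest,
                 pipeline_cfg: PipelineConfig | None = None,
                 filter_cfg: FilterConfig | None = None,
                 snpm_cfg: SnpmConfig | None = None) -> ResultsBundle:
    """File-based entry point: load every session in the manifest and run."""
    players = manifest.load()
    groups = {p.group for p in players}
    for g in groups:
        if sum(p.group == g for p in players) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 players")
    return run_cohort(players, pipeline_cfg, filter_cfg, snpm_cfg)


def write_outputs(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write CSV tables, a JSON results document and a plain-text run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("stroke_features", bundle.stroke_features),
                     ("player_summary", bundle.player_summary),
                     ("scalar_tests", bundle.scalar_tests),
                     ("snpm_clusters", bundle.snpm_clusters)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    results_json = out / "results.json"
    results_json.write_text(json.dumps({
        "run_metadata": bundle.run_metadata,
        "scalar_tests": bundle.scalar_tests.to_dict(orient="records"),
        "snpm_clusters": bundle.snpm_clusters.to_dict(orient="records"),
    }, indent=1, default=_json_default))
    written.append(results_json)
    log = out / "run_log.txt"
    meta = bundle.run_metadata
    log.write_text(
        "strokemetrics pipeline run\n"
        f"players: {meta.get('n_players')}  groups: {meta.get('groups')}  "
        f"spins: {meta.get('spins')}\n"
        f"strokes analysed: {meta.get('n_strokes')}\n"
        f"configs: {json.dumps(meta.get('configs'), sort_keys=True)}\n"
    )
    written.append(log)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
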