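"""Pipeline orchestration.

Two entry layers:

* in-memory cohort runs (:func:`run_imaging_cohort`,
  :func:`run_presence_cohort`) that chain simulate -> render -> detect ->
  register -> track -> presence matrix for a whole group without touching
  disk; and
* the staged, artifact-writing :func:`run_pipeline` used by the CLI, where
  every stage drops CSV/JSON outputs plus a manifest and reruns with the
  same config are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as stio
from .config import RunConfig
from .detection import (
    DetectionParams,
    SpineObservation,
    detect_protrusions,
    filter_spines,
    trace_dendrite,
)
from .dynamics import PresenceMatrix, compute_metric_table
from .registration import RegistrationResult, register_to_baseline
from .stats import ALPHA, GroupSeries, grubbs_exclude, one_way_anova_tukey, pool_sham, unpaired_t
from .synthetic import (
    ImagingParams,
    SimConfig,
    SimulatedDendrite,
    observations_from_timelines,
    render_stack,
    simulate_cohort,
)
from .tracking import MatchingParams, match_spines, resolve_reappearances

STAGES = ("simulate", "detect", "track", "quantify", "behave", "stats")


class PipelineError(RuntimeError):
    pass


@dataclass
class DendriteResult:
    dendrite_id: str
    mouse_id: str
    group: str
    trace_length_um: float
    presence: PresenceMatrix
    registrations: list[RegistrationResult | None]


@dataclass
class CohortResult:
    presence: PresenceMatrix
    per_dendrite: list[DendriteResult]

    @property
    def n_dendrites(self) -> int:
        return len(self.per_dendrite)


def _dendrite_rng(seed: int, mouse_idx: int, dend_idx: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, mouse_idx, dend_idx, purpose))
    )


def _backfill_presence(
    tracks, stacks, registrations, trace0, radius_um: float = 0.35
) -> None:
    """Retrospective presence check for tracks that appear mid-series.

    Mirrors the coordinate-carrying bookkeeping of a baseline-referenced
    workflow, in reverse: before accepting a track as newly formed, earlier
    sessions are re-examined at its location; if foreground already
    protrudes there beyond the shaft rim (the spine was present but lost in
    segmentation, e.g. merged with a neighbour), presence is back-filled so
    the spine is not scored as a formation.
    """
    from scipy import ndimage as ndi

    from .detection import _foreground

    pxy = stacks[0].pixel_size_xy_um
    cache = {}

    def session_maps(i):
        if i not in cache:
            full = _foreground(stacks[i])
            fg = full.any(axis=0)
            off = (
                registrations[i].offset_xyz
                if registrations[i] is not None
                else np.zeros(3)
            )
            bb = trace0.backbone[:, :2] + off[:2]
            seeds = np.zeros(fg.shape, dtype=bool)
            idx = np.round(bb[:, ::-1] / pxy).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(fg.shape)), axis=1)
            seeds[tuple(idx[ok].T)] = True
            dist = ndi.distance_transform_edt(~seeds, sampling=(pxy, pxy))
            thickness = ndi.distance_transform_edt(fg, sampling=(pxy, pxy))
            rim = float(np.median(thickness[tuple(idx[ok].T)])) + pxy
            cache[i] = (full, dist, rim)
        return cache[i]

    rad = max(1, int(round(radius_um / pxy)))
    for t in tracks:
        c = t.cohort_index
        if c == 0:
            continue
        pos = np.asarray(t.positions[c])
        for j in range(c - 1, -1, -1):
            off = (
                registrations[j].offset_xyz
                if registrations[j] is not None
                else np.zeros(3)
            )
            pos_j = pos + off
            full, dist, rim = session_maps(j)
            iz = int(round(pos_j[2] / stacks[j].z_step_um))
            z0, z1 = max(0, iz - 1), min(full.shape[0], iz + 2)
            fg = full[z0:z1].any(axis=0)  # tip z-neighbourhood only
            iy, ix = int(round(pos_j[1] / pxy)), int(round(pos_j[0] / pxy))
            y0, y1 = max(0, iy - rad), min(fg.shape[0], iy + rad + 1)
            x0, x1 = max(0, ix - rad), min(fg.shape[1], ix + rad + 1)
            patch = fg[y0:y1, x0:x1] & (dist[y0:y1, x0:x1] > rim)
            if y0 < y1 and x0 < x1 and int(patch.sum()) >= 3:
                t.presence[j] = 1
                t.positions[j] = tuple(float(v) for v in pos)
                t.lengths[j] = t.lengths.get(c, 0.0)
            else:
                break


def process_dendrite(
    den: SimulatedDendrite,
    imaging: ImagingParams,
    detection: DetectionParams,
    matching: MatchingParams,
    rng: np.random.Generator,
    max_shift_um: float = 5.0,
) -> DendriteResult:
    """Image -> detect -> register -> track one simulated dendrite.

    The backbone is traced once on the baseline stack and carried to later
    sessions through the recovered translation, mirroring a
    baseline-referenced ROI workflow.
    """
    days = den.timelines[0].session_days if den.timelines else ()
    if not days:
        raise PipelineError(f"dendrite {den.geometry.dendrite_id} has no spines to image")
    stacks = []
    for i, day in enumerate(days):
        jitter = (0.0, 0.0, 0.0) if i == 0 else None
        stacks.append(
            render_stack(den.timelines, den.geometry, day, imaging, rng=rng, jitter_um=jitter)
        )
    trace0 = trace_dendrite(stacks[0], detection, dendrite_id=den.geometry.dendrite_id)
    registrations: list[RegistrationResult | None] = [None]
    for st in stacks[1:]:
        registrations.append(register_to_baseline(st, stacks[0], max_shift_um=max_shift_um))

    obs_by_session: list[list[SpineObservation]] = []
    for i, st in enumerate(stacks):
        tr = trace0 if i == 0 else trace0.translated(registrations[i].offset_xyz)
        cands = detect_protrusions(st, tr, detection)
        obs_by_session.append(filter_spines(cands, detection.min_length_um))

    tracks = match_spines(
        obs_by_session,
        registrations,
        matching,
        session_days=days,
        dendrite_id=den.geometry.dendrite_id,
    )
    tracks = resolve_reappearances(tracks, matching)
    _backfill_presence(tracks, stacks, registrations, trace0)
    pm = PresenceMatrix.from_tracks(
        tracks, den.geometry.mouse_id, den.geometry.group, trace0.length_um
    )
    return DendriteResult(
        den.geometry.dendrite_id,
        den.geometry.mouse_id,
        den.geometry.group,
        trace0.length_um,
        pm,
        registrations,
    )


def run_imaging_cohort(
    cfg: SimConfig,
    imaging: ImagingParams = ImagingParams(),
    detection: DetectionParams = DetectionParams(),
    matching: MatchingParams = MatchingParams(),
) -> CohortResult:
    """Full image-level pipeline over every dendrite of a group."""
    results = []
    for k, den in enumerate(simulate_cohort(cfg)):
        m = k // cfg.dendrites_per_mouse
        d = k % cfg.dendrites_per_mouse
        rng = _dendrite_rng(cfg.seed, m, d, purpose=1)
        results.append(process_dendrite(den, imaging, detection, matching, rng))
    return CohortResult(
        PresenceMatrix.concat([r.presence for r in results]), results
    )


def run_presence_cohort(
    cfg: SimConfig, matching: MatchingParams = MatchingParams()
) -> CohortResult:
    """Presence-matrix-level pipeline: ground-truth observations are fed
    straight into tracking (no imaging), then matched and merged as usual."""
    results = []
    for den in simulate_cohort(cfg):
        obs = observations_from_timelines(den)
        regs: list[RegistrationResult | None] = [None] * len(obs)
        tracks = match_spines(
            obs,
            regs,
            matching,
            session_days=den.timelines[0].session_days if den.timelines else cfg.session_days,
            dendrite_id=den.geometry.dendrite_id,
        )
        tracks = resolve_reappearances(tracks, matching)
        pm = PresenceMatrix.from_tracks(
            tracks, den.geometry.mouse_id, den.geometry.group, den.geometry.length_um
        )
        results.append(
            DendriteResult(
                den.geometry.dendrite_id,
                den.geometry.mouse_id,
                den.geometry.group,
                den.geometry.length_um,
                pm,
                regs,
            )
        )
    return CohortResult(PresenceMatrix.concat([r.presence for r in results]), results)


# ---------------------------------------------------------------------------
# staged artifact-writing pipeline (CLI backend)


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs output of stage '{stage}' ({path}); "
            f"run '{stage}' first"
        )


def _presence_csv_to_matrix(path: Path) -> PresenceMatrix:
    df = pd.read_csv(path, index_col="spine_id")
    day_cols = [c for c in df.columns if c.startswith("day_")]
    days = [int(c.split("_")[1]) for c in day_cols]
    presence = df[day_cols].copy()
    presence.columns = days
    meta = df[
        ["dendrite_id", "mouse_id", "group", "cohort_day", "reappearance_events", "segment_length_um"]
    ].copy()
    return PresenceMatrix(presence.astype(np.int8), meta)


def _presence_matrix_to_csv(pm: PresenceMatrix, path: Path) -> None:
    out = pm.meta.copy()
    for d in pm.session_days:
        out[f"day_{d}"] = pm.presence[d]
    out.index.name = "spine_id"
    out.to_csv(path, float_format="%.6f")


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (in canonical order), writing artifacts.

    simulate: ground-truth timelines (CSV) per group
    detect+track (merged here as 'detect' then 'track'): imaging pipeline ->
        observations and presence matrices
    quantify: tidy metric table (CSV) + JSON summary
    behave:   discrimination-index table from the configured interaction CSV
    stats:    group comparisons (pooling rule, Grubbs, t/ANOVA) as JSON
    """
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    if not stages:
        raise PipelineError("no recognized stages requested")
    out = _out(cfg)
    chash = cfg.config_hash()
    written: dict[str, list[str]] = {}

    if "simulate" in stages:
        files = []
        for group in cfg.groups:
            cohort = simulate_cohort(cfg.sim_config(group))
            tls = [tl for den in cohort for tl in den.timelines]
            f = out / f"timelines_{group}.csv"
            stio.timelines_to_frame(tls).to_csv(f, index=False, float_format="%.6f")
            files.append(str(f))
        stio.write_manifest(out / "manifest_simulate.json", "simulate", chash, cfg.seed, files)
        written["simulate"] = files

    if "detect" in stages or "track" in stages:
        _require(out / "manifest_simulate.json", "simulate", "detect")
        files = []
        for group in cfg.groups:
            res = run_imaging_cohort(
                cfg.sim_config(group),
                cfg.imaging_params(),
                cfg.detection_params(),
                cfg.matching_params(),
            )
            f = out / f"presence_{group}.csv"
            _presence_matrix_to_csv(res.presence, f)
            files.append(str(f))
        stio.write_manifest(out / "manifest_track.json", "track", chash, cfg.seed, files)
        written["track"] = files

    if "quantify" in stages:
        _require(out / "manifest_track.json", "track", "quantify")
        mats = [
            _presence_csv_to_matrix(out / f"presence_{group}.csv") for group in cfg.groups
        ]
        pm = PresenceMatrix.concat(mats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = compute_metric_table(pm)
        f = out / "metrics.csv"
        table.to_csv(f, index=False, float_format="%.6f")
        summary = (
            table.groupby(["group", "metric", "day"])["value"].mean().reset_index()
        )
        fj = out / "metrics_summary.json"
        fj.write_text(summary.to_json(orient="records", indent=2))
        stio.write_manifest(
            out / "manifest_quantify.json", "quantify", chash, cfg.seed, [str(f), str(fj)]
        )
        written["quantify"] = [str(f), str(fj)]

    if "behave" in stages:
        if cfg.behavior_csv is None:
            raise PipelineError("stage 'behave' needs behavior_csv in the config")
        from .behavior import score_table

        df = pd.read_csv(cfg.behavior_csv)
        scored = score_table(df)
        f = out / "discrimination_index.csv"
        scored.to_csv(f, index=False, float_format="%.6f")
        stio.write_manifest(out / "manifest_behave.json", "behave", chash, cfg.seed, [str(f)])
        written["behave"] = [str(f)]

    if "stats" in stages:
        _require(out / "manifest_quantify.json", "quantify", "stats")
        table = pd.read_csv(out / "metrics.csv")
        report = group_comparison_report(table, alpha=cfg.alpha)
        f = out / "stats_report.json"
        f.write_text(json.dumps(report, indent=2, default=float))
        stio.write_manifest(out / "manifest_stats.json", "stats", chash, cfg.seed, [str(f)])
        written["stats"] = [str(f)]

    return written


def group_comparison_report(metric_table: pd.DataFrame, alpha: float = ALPHA) -> list[dict]:
    """Per metric and day: Grubbs exclusion, sham pooling, then the group
    comparison (unpaired t for two groups, one-way ANOVA + Tukey beyond)."""
    report = []
    for (metric, day), sub in metric_table.groupby(["metric", "day"]):
        series = {}
        for group, vals in sub.groupby("group")["value"]:
            s = GroupSeries(group, vals.to_numpy())
            if s.n >= 3:
                s, log = grubbs_exclude(s, alpha)
            else:
                log = {"excluded": None, "warning": "n < 3"}
            series[group] = (s, log)
        entry: dict = {
            "metric": metric,
            "day": int(day),
            "exclusions": {g: log for g, (_, log) in series.items()},
        }
        groups = [s for s, _ in series.values()]
        if {"sham_vehicle", "sham_isrib"} <= set(series):
            dec = pool_sham(series["sham_vehicle"][0], series["sham_isrib"][0], alpha)
            entry["sham_pooling"] = {"pooled": dec.pooled, "p": dec.pvalue}
            groups = dec.series + [
                s for g, (s, _) in series.items() if g not in ("sham_vehicle", "sham_isrib")
            ]
        usable = [g for g in groups if g.n >= 2]
        if len(usable) == 2:
            res = unpaired_t(usable[0], usable[1])
            entry["test"] = {
                "name": res.test,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.pvalue,
            }
        elif len(usable) >= 3:
            res = one_way_anova_tukey(usable)
            entry["test"] = {
                "name": res.test,
                "F": res.statistic,
                "p": res.pvalue,
                "tukey": res.detail["tukey"].to_dict(orient="records"),
            }
        report.append(entry)
    return report
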