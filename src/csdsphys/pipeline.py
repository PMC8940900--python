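"""End-to-end runner: simulate -> behavior -> photometry -> ephys -> stats.

The statistics stage sees only the per-mouse metrics table assembled
from *extracted* quantities (trajectory scoring, processed photometry,
detected spikes); the generator's latent ground truth never crosses
into :func:`build_stats_panel`.  Recovery against ground truth lives in
the test suite, not here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arenas import epm_arena, oft_arena, si_arena
from .behavior import (
    classify_mouse,
    fust_preference,
    si_ratio,
    sucrose_preference,
    zone_entry_times,
    zone_occupancy,
)
from .cohort import CohortConfig, gen_cohort, mouse_seeds
from .ephys import (
    classify_putative_da,
    detect_spikes,
    firing_rate,
    per_mouse_mean,
    trough_latency_ms,
)
from .ephys_sim import gen_cell_attached
from .photometry import compartment_auc, detect_events, dff, peri_event
from .photosim import PhotometrySimParams, gen_photometry
from .stats import compare_groups, correlate
from .tracks import gen_trajectory

__all__ = ["PipelineConfig", "run_pipeline", "build_stats_panel"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    video_hz: float = 30.0
    si_phase_s: float = 150.0
    si_base_frac: float = 0.30
    epm_duration_s: float = 300.0
    oft_duration_s: float = 300.0
    neurons_per_mouse: tuple[int, int] = (3, 7)
    cell_attached_s: float = 60.0
    cell_attached_fs: float = 10_000.0
    min_dwell_s: float = 0.2
    include_photometry: bool = True
    include_oft: bool = True
    include_consumption: bool = True

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "neurons_per_mouse" in raw:
            raw["neurons_per_mouse"] = tuple(raw["neurons_per_mouse"])
        return PipelineConfig(cohort=cohort, **raw)


def _si_stage(cfg: PipelineConfig, gt: pd.DataFrame) -> pd.DataFrame:
    """Two-phase social-interaction test per mouse."""
    arena = si_arena()
    seeds_nt = mouse_seeds(cfg.cohort.seed, len(gt), "si_notarget")
    seeds_tg = mouse_seeds(cfg.cohort.seed, len(gt), "si_target")
    rows = []
    for i, row in gt.reset_index(drop=True).iterrows():
        tgt_frac = float(np.clip(cfg.si_base_frac * row.si_mean / 100.0, 0.02, 0.85))
        traj_nt = gen_trajectory(arena, {"interaction": cfg.si_base_frac},
                                 cfg.si_phase_s, cfg.video_hz, seeds_nt[i])
        traj_tg = gen_trajectory(arena, {"interaction": tgt_frac},
                                 cfg.si_phase_s, cfg.video_hz, seeds_tg[i])
        occ_nt = zone_occupancy(traj_nt, cfg.min_dwell_s)
        occ_tg = zone_occupancy(traj_tg, cfg.min_dwell_s)
        t_nt = occ_nt.time_in_zone_s["interaction"]
        t_tg = occ_tg.time_in_zone_s["interaction"]
        ratio = si_ratio(t_tg, t_nt) if t_nt > 0 else float("nan")
        rows.append({
            "mouse_id": row.mouse_id,
            "stressed": bool(row.stressed),
            "si_time_target_s": t_tg,
            "si_time_notarget_s": t_nt,
            "si_ratio": ratio,
            # locomotion reported from the no-target phase to avoid
            # social-approach bias
            "distance_cm": occ_nt.distance_cm,
            "velocity_cm_s": occ_nt.mean_velocity_cm_s,
            "group": classify_mouse(ratio, bool(row.stressed)) if np.isfinite(ratio) else None,
        })
    return pd.DataFrame(rows)


def _epm_stage(cfg: PipelineConfig, gt: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    arena = epm_arena()
    seeds = mouse_seeds(cfg.cohort.seed, len(gt), "epm")
    rows = []
    trajs = []
    for i, row in gt.reset_index(drop=True).iterrows():
        open_f = float(row.openarm_frac)
        targets = {"open": open_f, "center": 0.15, "closed": max(0.0, 1.0 - open_f - 0.15)}
        traj = gen_trajectory(arena, targets, cfg.epm_duration_s, cfg.video_hz, seeds[i])
        occ = zone_occupancy(traj, cfg.min_dwell_s)
        rows.append({
            "mouse_id": row.mouse_id,
            "epm_open_time_s": occ.time_in_zone_s["open"],
            "epm_open_pct": 100.0 * occ.time_in_zone_s["open"] / occ.duration_s,
            "epm_open_entries": occ.entries["open"],
        })
        trajs.append(traj)
    return pd.DataFrame(rows), trajs


def _oft_stage(cfg: PipelineConfig, gt: pd.DataFrame) -> pd.DataFrame:
    arena = oft_arena()
    seeds = mouse_seeds(cfg.cohort.seed, len(gt), "oft")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.cohort.seed % (2**31), 7]))
    rows = []
    for i, row in gt.reset_index(drop=True).iterrows():
        # center occupancy shares the anxiety drive of open-arm occupancy
        center_f = float(np.clip(0.04 + 0.5 * row.openarm_frac
                                 + 0.02 * rng.standard_normal(), 0.02, 0.5))
        traj = gen_trajectory(arena, {"center": center_f, "periphery": 1.0 - center_f},
                              cfg.oft_duration_s, cfg.video_hz, seeds[i])
        occ = zone_occupancy(traj, cfg.min_dwell_s)
        rows.append({
            "mouse_id": row.mouse_id,
            "oft_center_pct": 100.0 * occ.time_in_zone_s["center"] / occ.duration_s,
            "oft_center_entries": occ.entries["center"],
        })
    return pd.DataFrame(rows)


def _consumption_stage(cfg: PipelineConfig, gt: pd.DataFrame) -> pd.DataFrame:
    """Sucrose-preference and urine-sniffing records tied to the SI phenotype."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.cohort.seed % (2**31), 11]))
    rows = []
    for _, row in gt.iterrows():
        sp_true = float(np.clip(35.0 + 0.35 * row.si_mean + 4.0 * rng.standard_normal(), 15.0, 95.0))
        total_g = 6.0
        sucrose_g = total_g * sp_true / 100.0
        water_time = 40.0
        fust_true = float(np.clip(0.5 + 0.008 * row.si_mean + 0.15 * rng.standard_normal(), 0.1, 3.0))
        rows.append({
            "mouse_id": row.mouse_id,
            "sucrose_preference": sucrose_preference(sucrose_g, total_g - sucrose_g),
            "fust_preference": fust_preference(fust_true * water_time, water_time),
        })
    return pd.DataFrame(rows)


def _photometry_stage(cfg: PipelineConfig, gt: pd.DataFrame, epm_trajs: list) -> pd.DataFrame:
    seeds = mouse_seeds(cfg.cohort.seed, len(gt), "photometry")
    rows = []
    for i, row in gt.reset_index(drop=True).iterrows():
        traj = epm_trajs[i]
        params = PhotometrySimParams.for_sensor(row.sensor)
        sim = gen_photometry(
            traj,
            base_rate_per_min=row.transient_base_per_min,
            zone_gain_per_min=row.transient_openarm_gain,
            zone="open",
            params=params,
            seed=seeds[i],
        )
        series = dff(sim.recording)
        idx = np.clip(np.round(series.time_s / traj.dt_s).astype(int), 0, len(traj) - 1)
        masks = {z: np.asarray(traj.arena.in_zone(z, traj.x_cm[idx], traj.y_cm[idx]))
                 for z in traj.arena.zone_names()}
        aucs = compartment_auc(series, masks)
        events = detect_events(series)
        onsets = [(float(t), "open_entry")
                  for t in zone_entry_times(traj, "open", cfg.min_dwell_s)]
        pe = peri_event(series, onsets, mouse_id=row.mouse_id)
        rows.append({
            "mouse_id": row.mouse_id,
            "events_per_min": events.events_per_min,
            "auc_per_s_open": aucs["open"].auc_per_s,
            "auc_per_s_closed": aucs["closed"].auc_per_s,
            "summary_z_open_entry": pe["open_entry"].summary_z if "open_entry" in pe else float("nan"),
        })
    return pd.DataFrame(rows)


def _ephys_stage(cfg: PipelineConfig, gt: pd.DataFrame) -> pd.DataFrame:
    seeds = mouse_seeds(cfg.cohort.seed, len(gt), "ephys")
    neuron_rows = []
    for i, row in gt.reset_index(drop=True).iterrows():
        rng = np.random.default_rng(seeds[i])
        lo, hi = cfg.neurons_per_mouse
        n_neurons = int(rng.integers(lo, hi + 1))
        for child in seeds[i].spawn(n_neurons):
            true_rate = float(np.clip(row.firing_hz + 0.3 * rng.standard_normal(), 0.2, 14.0))
            trace, _, fs = gen_cell_attached(
                true_rate, cfg.cell_attached_s, seed=child,
                sample_rate_hz=cfg.cell_attached_fs,
            )
            spikes = detect_spikes(trace, fs)
            rate = firing_rate(spikes, cfg.cell_attached_s)
            lat = trough_latency_ms(trace, fs, spikes)
            neuron_rows.append({
                "mouse_id": row.mouse_id,
                "firing_hz": rate,
                "trough_latency_ms": lat,
                "is_putative_da": classify_putative_da(rate, lat),
            })
    neurons = pd.DataFrame(neuron_rows)
    mouse = per_mouse_mean(neurons, features=["firing_hz"])
    return mouse


def build_stats_panel(metrics: pd.DataFrame) -> dict:
    """Correlation panel and group comparisons from extracted metrics only.

    Social-interaction correlations are computed on the stressed mice
    (the SI ratio is a post-defeat phenotype); circuit-anxiety
    correlations use every mouse with a firing estimate.
    """
    forbidden = {"trait", "susceptible", "si_mean", "openarm_frac"}
    leaked = forbidden & set(metrics.columns)
    if leaked:
        raise ValueError(f"ground-truth columns leaked into the stats stage: {sorted(leaked)}")

    out: dict = {"correlations": {}, "group_comparisons": {}}

    def corr(name, df, xcol, ycol):
        sub = df[[xcol, ycol]].dropna()
        if len(sub) < 3 or sub[xcol].std() == 0 or sub[ycol].std() == 0:
            return
        res = correlate(sub[xcol], sub[ycol], xcol, ycol)
        lo, hi = res.ci95()
        out["correlations"][name] = {
            "method": res.method, "r": res.r, "p": res.p, "n": res.n,
            "ci95": [lo, hi],
        }

    stressed = metrics[metrics["stressed"]]
    if "firing_hz" in metrics:
        corr("firing_vs_si_ratio", stressed, "si_ratio", "firing_hz")
        corr("firing_vs_epm_open_pct", metrics, "epm_open_pct", "firing_hz")
    if "sucrose_preference" in metrics:
        corr("si_ratio_vs_sucrose_preference", stressed, "si_ratio", "sucrose_preference")
        corr("si_ratio_vs_fust_preference", stressed, "si_ratio", "fust_preference")
    if "oft_center_pct" in metrics:
        corr("epm_open_vs_oft_center", metrics, "epm_open_pct", "oft_center_pct")

    for feature in ("firing_hz", "epm_open_pct", "si_ratio"):
        if feature not in metrics:
            continue
        groups = {}
        for g in ("CTL", "A", "AD"):
            vals = metrics.loc[metrics["group"] == g, feature].dropna().to_numpy()
            if len(vals) >= 2:
                groups[g] = vals
        if len(groups) >= 2:
            res = compare_groups(groups)
            out["group_comparisons"][feature] = {
                "omnibus": res.omnibus,
                "statistic": res.statistic,
                "p": res.p,
                "posthoc": res.posthoc.to_dict(orient="records"),
            }
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on a freshly simulated cohort; return the report."""
    _, gt_obj = gen_cohort(cfg.cohort)
    gt = gt_obj.table
    if gt.empty:
        raise ValueError("empty cohort: nothing to analyze")

    metrics = _si_stage(cfg, gt)
    epm, epm_trajs = _epm_stage(cfg, gt)
    metrics = metrics.merge(epm, on="mouse_id")
    if cfg.include_oft:
        metrics = metrics.merge(_oft_stage(cfg, gt), on="mouse_id")
    if cfg.include_consumption:
        metrics = metrics.merge(_consumption_stage(cfg, gt), on="mouse_id")
    if cfg.include_photometry:
        metrics = metrics.merge(_photometry_stage(cfg, gt, epm_trajs), on="mouse_id")
    metrics = metrics.merge(_ephys_stage(cfg, gt), on="mouse_id", how="left")

    stats = build_stats_panel(metrics)
    report = {
        "version": __version__,
        "seed": cfg.cohort.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "cohort"},
            "cohort": dataclasses.asdict(cfg.cohort),
        },
        "n_mice": int(len(metrics)),
        "group_counts": metrics["group"].value_counts().to_dict(),
        "stats": stats,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    report["metrics"] = metrics
    return report
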