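"""Orchestration: generate → preprocess → behavior → speed code → event
profiles → cluster tests → mixed model, as one configured, seeded run.

A run is one experiment: a set of sample/test session pairs (synthetic by
default) analyzed jointly, mirroring a multi-session aggregate analysis.
Stage outputs land under the run directory as small CSV/JSON/HDF5 files, a
manifest records the configuration and seeds, and rerunning with the same
configuration reproduces all numbers exactly.
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
from scipy import stats

from cholinepipe import behavior, clusterstat, eventavg, mixedmodel, photometry, session_io, speedcode, synth

logger = logging.getLogger(__name__)

EVENT_BEHAVIORS = ("locomotion", "grooming", "rearing")
OBJECT_BEHAVIORS = ("explore_stat", "explore_nonstat")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; serialized verbatim to the run dir."""

    out_dir: str = "run"
    seed: int = 0
    n_pairs: int = 10  # sample/test session pairs
    n_mice: int = 3
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    window: float = 0.5  # s, moving-average smoothing
    target_rate: float = 30.0  # Hz, analysis clock
    speed_floor: float = 1.0  # cm/s
    n_perm_bouts: int = 1000
    n_perm_recency: int = 500
    perm_seed: int = 7
    recency_span: float = 60.0  # s tested for the session-start divergence
    recency_fit_window: float = 180.0  # s for exponential fits
    di_test_window: float = 180.0  # s (first 3 min of test)
    di_sample_window: float = 720.0  # s (first 12 min of sample)
    di_sliding_step: float = 30.0
    lmm_random: str = "intercepts"
    lmm_window: float = 180.0
    lmm_step: float = 60.0
    min_bouts_for_cluster: int = 5
    write_files: bool = True
    stages: tuple = ("generate", "preprocess", "behavior", "speedcode", "eventavg",
                     "clusterstat", "lmm")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            doc = yaml.safe_load(f)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class SessionRecord:
    """In-memory per-session artifacts accumulated across stages."""

    session: synth.SyntheticSession
    dff: photometry.DffSeries | None = None
    speed30: np.ndarray | None = None
    model: speedcode.SpeedModel | None = None
    bouts: dict = field(default_factory=dict)


def _session_plan(cfg: RunConfig) -> list[dict]:
    plan = []
    k = 0
    for pair in range(cfg.n_pairs):
        mouse = f"m{pair % cfg.n_mice}"
        oblom = pair // cfg.n_mice + 1
        for phase in ("sample", "test"):
            plan.append(
                {
                    "mouse_id": mouse,
                    "oblom_id": oblom,
                    "phase": phase,
                    "session_id": f"s{k:02d}",
                    "seed": cfg.seed * 100003 + k,
                }
            )
            k += 1
    return plan


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns all results.

    With ``write_files`` enabled, per-session artifacts and aggregate tables
    are persisted under ``cfg.out_dir`` alongside a manifest.
    """
    out = Path(cfg.out_dir)
    if cfg.write_files:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as f:
            yaml.safe_dump(cfg.to_dict(), f)

    results: dict = {"config": cfg}
    records: list[SessionRecord] = []

    if "generate" in cfg.stages:
        for spec in _session_plan(cfg):
            gen_cfg = synth.GeneratorConfig(
                seed=spec["seed"] % (2**31 - 1), phase=spec["phase"], **cfg.generator
            )
            meta = photometry.SessionMeta(
                mouse_id=spec["mouse_id"],
                phase=spec["phase"],
                oblom_id=spec["oblom_id"],
                session_id=spec["session_id"],
            )
            sess = synth.simulate_session(gen_cfg, meta=meta)
            records.append(SessionRecord(session=sess))
            if cfg.write_files:
                (out / "sessions").mkdir(exist_ok=True)
                session_io.write_session(sess, out / "sessions" / spec["session_id"])
    results["n_sessions"] = len(records)

    if "preprocess" in cfg.stages:
        for rec in records:
            rec.dff = photometry.preprocess(
                rec.session.photometry, window=cfg.window, target_rate=cfg.target_rate
            )
            rec.speed30 = rec.session.traj.speed
            if cfg.write_files:
                session_io.write_dff(
                    rec.dff, out / "sessions" / rec.session.photometry.meta.session_id / "dff.h5"
                )

    if "behavior" in cfg.stages:
        results["di"] = _stage_behavior(cfg, records, out)

    if "speedcode" in cfg.stages:
        results["speed"] = _stage_speedcode(cfg, records, out)

    if "eventavg" in cfg.stages or "clusterstat" in cfg.stages:
        results["events"] = _stage_events(cfg, records, out)

    if "lmm" in cfg.stages:
        results["lmm"] = _stage_lmm(cfg, records, out)

    results["records"] = records
    if cfg.write_files:
        manifest = {
            "seed": cfg.seed,
            "perm_seed": cfg.perm_seed,
            "n_sessions": len(records),
            "stages": list(cfg.stages),
            "schema_version": session_io.SCHEMA_VERSION,
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1)
    return results


def _stage_behavior(cfg: RunConfig, records: list[SessionRecord], out: Path) -> pd.DataFrame:
    rows = []
    for rec in records:
        meta = rec.session.photometry.meta
        etho = rec.session.etho
        duration = etho.n_frames / etho.rate
        win = cfg.di_test_window if meta.phase == "test" else cfg.di_sample_window
        win = min(win, duration)
        try:
            di = behavior.window_di(etho, 0.0, win).di
        except ValueError:
            di = np.nan
        rows.append({"session_id": meta.session_id, "phase": meta.phase, "di": di,
                     "window_s": win})
        for name in EVENT_BEHAVIORS + OBJECT_BEHAVIORS:
            rec.bouts[name] = behavior.extract_bouts(
                etho.flags[name], etho.t, behavior=name, session_id=meta.session_id
            )
    df = pd.DataFrame(rows)
    if cfg.write_files:
        df.to_csv(out / "di.csv", index=False)
        bout_rows = [
            {"session_id": b.session_id, "behavior": b.behavior, "onset_t": b.onset_t,
             "offset_t": b.offset_t, "duration": b.duration}
            for rec in records for bs in rec.bouts.values() for b in bs
        ]
        pd.DataFrame(bout_rows).to_csv(out / "bouts.csv", index=False)
    return df


def _stage_speedcode(cfg: RunConfig, records: list[SessionRecord], out: Path) -> dict:
    rows = []
    for rec in records:
        meta = rec.session.photometry.meta
        dffv = rec.dff.values
        sp = photometry.moving_average(rec.speed30, cfg.window, cfg.target_rate)
        n = min(dffv.size, sp.size)
        dffv, sp = dffv[:n], sp[:n]
        l2 = speedcode.log2_speed(sp, cfg.speed_floor)
        curve = speedcode.timescale_correlation(dffv, l2, cfg.target_rate)
        model = speedcode.fit_speed_model(dffv, l2, rate=cfg.target_rate)
        rec.model = model
        rows.append(
            {
                "session_id": meta.session_id,
                "phase": meta.phase,
                "r_speed": float(np.corrcoef(dffv, sp)[0, 1]),
                "r_log2speed": model.r,
                "slope": model.slope,
                "se_slope_eff": model.se_slope_eff,
                "best_window": curve.best_window,
            }
        )
    per_session = pd.DataFrame(rows)

    # across-session average traces for the recency decay fits
    n_fit = int(min(cfg.recency_fit_window * cfg.target_rate,
                    min(r.dff.values.size for r in records)))
    t_fit = np.arange(n_fit) / cfg.target_rate
    obs = np.mean([r.dff.values[:n_fit] for r in records], axis=0)
    pred = np.mean([r.model.predicted[:n_fit] for r in records], axis=0)
    resid = np.mean([r.model.residual[:n_fit] for r in records], axis=0)
    taus = {
        "observed": speedcode.fit_exponential_decay(obs, t_fit, cfg.recency_fit_window),
        "predicted": speedcode.fit_exponential_decay(pred, t_fit, cfg.recency_fit_window),
        "residual": speedcode.fit_exponential_decay(resid, t_fit, cfg.recency_fit_window),
    }
    result = {"per_session": per_session, "taus": taus}
    if cfg.write_files:
        per_session.to_csv(out / "speedcode.csv", index=False)
        with open(out / "recency_taus.json", "w") as f:
            json.dump({k: {"A": v.A, "tau": v.tau, "offset": v.offset} for k, v in taus.items()},
                      f, indent=1)
    return result


def pooled_event_matrices(
    records: list[SessionRecord],
    name: str,
    phase: str | None = None,
    pre: float = 5.0,
    post: float = 5.0,
    n_core: int = 100,
):
    """Observed and speed-predicted warped matrices over pooled bouts.

    Returns ``(obs, pred, dt, durations)`` or None if fewer than 2 usable bouts.
    """
    obs_rows, pred_rows, durations = [], [], []
    for rec in records:
        meta = rec.session.photometry.meta
        if phase is not None and meta.phase != phase:
            continue
        dff = rec.dff
        for bout in rec.bouts.get(name, []):
            try:
                obs_rows.append(
                    eventavg.warp_bout(dff.values, dff.t, dff.rate, bout, pre, post, n_core)
                )
            except ValueError:
                continue
            pred_rows.append(
                eventavg.warp_bout(rec.model.predicted, dff.t, dff.rate, bout, pre, post, n_core)
            )
            durations.append(bout.duration)
    if len(obs_rows) < 2:
        return None
    rate = records[0].dff.rate
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    dt = np.empty(n_pre + n_core + n_post)
    dt[:n_pre] = 1.0 / rate
    dt[n_pre : n_pre + n_core] = float(np.mean(durations)) / n_core
    dt[n_pre + n_core :] = 1.0 / rate
    return np.vstack(obs_rows), np.vstack(pred_rows), dt, durations


def _stage_events(cfg: RunConfig, records: list[SessionRecord], out: Path) -> dict:
    comparisons = [(name, None) for name in EVENT_BEHAVIORS]
    comparisons += [(name, ph) for name in OBJECT_BEHAVIORS for ph in ("sample", "test")]
    cluster_rows = []
    events: dict = {"clusters": {}, "timing": {}}
    for name, phase in comparisons:
        mats = pooled_event_matrices(records, name, phase)
        key = name if phase is None else f"{name}:{phase}"
        if mats is None or mats[0].shape[0] < cfg.min_bouts_for_cluster:
            logger.info("cluster comparison %s skipped: too few bouts", key)
            continue
        obs, pred, dt, durations = mats
        res = clusterstat.cluster_test(
            obs, pred, dt=dt, n_perm=cfg.n_perm_bouts, seed=cfg.perm_seed
        )
        events["clusters"][key] = res
        cluster_rows.append(
            {
                "comparison": key,
                "n_bouts": obs.shape[0],
                "n_clusters": len(res.clusters),
                "n_sig": len(res.sig_clusters),
                "min_p": res.min_p,
                "relative_length_pct": res.relative_length_pct,
            }
        )

    # session-start recency divergence: sessions are the paired events
    n_span = int(cfg.recency_span * cfg.target_rate)
    obs = np.vstack([r.dff.values[:n_span] for r in records])
    pred = np.vstack([r.model.predicted[:n_span] for r in records])
    res = clusterstat.cluster_test(
        obs, pred, dt=1.0 / cfg.target_rate, n_perm=cfg.n_perm_recency, seed=cfg.perm_seed
    )
    events["clusters"]["recency"] = res
    cluster_rows.append(
        {
            "comparison": "recency",
            "n_bouts": obs.shape[0],
            "n_clusters": len(res.clusters),
            "n_sig": len(res.sig_clusters),
            "min_p": res.min_p,
            "relative_length_pct": res.relative_length_pct,
        }
    )

    # locomotion rise/decay timing, paired per bout across sessions
    for side in ("onset", "offset"):
        obs_times, pred_times = [], []
        for rec in records:
            dff = rec.dff
            bouts = list(rec.bouts.get("locomotion", []))
            if not bouts:
                continue
            obs_est = eventavg.estimate_timing(dff.values, dff.t, dff.rate, bouts, side=side)
            pred_est = eventavg.estimate_timing(
                rec.model.predicted, dff.t, dff.rate, bouts, side=side
            )
            obs_times.append(obs_est.per_bout_crossing)
            pred_times.append(pred_est.per_bout_crossing)
        if obs_times:
            a = np.concatenate(obs_times)
            b = np.concatenate(pred_times)
            obs_all = eventavg.TimingEstimate(a, float(np.nanmedian(a)),
                                              float(np.nanstd(a)), int(np.isnan(a).sum()), side)
            pred_all = eventavg.TimingEstimate(b, float(np.nanmedian(b)),
                                               float(np.nanstd(b)), int(np.isnan(b).sum()), side)
            events["timing"][side] = eventavg.timing_comparison(obs_all, pred_all)

    if cfg.write_files:
        pd.DataFrame(cluster_rows).to_csv(out / "cluster_summary.csv", index=False)
        doc = {}
        for key, res in events["clusters"].items():
            doc[key] = {
                "n_perm": res.n_perm,
                "seed": res.seed,
                "relative_length_pct": res.relative_length_pct,
                "clusters": [
                    {"start_idx": c.start_idx, "end_idx": c.end_idx, "mass": c.mass,
                     "length_s": c.length_s, "p_mass": c.p_mass, "p_length": c.p_length}
                    for c in res.clusters
                ],
            }
        with open(out / "clusters.json", "w") as f:
            json.dump(doc, f, indent=1)
        timing_rows = [
            {"side": side, "median_difference": t.median_difference, "p": t.p_value,
             "n_pairs": t.n_pairs}
            for side, t in events["timing"].items()
        ]
        pd.DataFrame(timing_rows).to_csv(out / "timing.csv", index=False)
    return events


def _stage_lmm(cfg: RunConfig, records: list[SessionRecord], out: Path) -> dict:
    table = mixedmodel.assemble_frame_table(
        [
            {"dff": r.dff, "speed": r.speed30, "etho": r.session.etho,
             "meta": r.session.photometry.meta}
            for r in records
        ]
    )
    result = mixedmodel.fit_lmm(table, random_spec=cfg.lmm_random)
    contrast = mixedmodel.novelty_contrast(result)
    sliding = mixedmodel.sliding_lmm(
        table, window=cfg.lmm_window, step=cfg.lmm_step, random_spec=cfg.lmm_random
    )
    try:
        meta_fit = mixedmodel.ols_meta(sliding)
    except ValueError as exc:
        logger.info("ols_meta skipped: %s", exc)
        meta_fit = None
    if cfg.write_files:
        result.fixed.to_csv(out / "lmm.csv")
        with open(out / "contrast.json", "w") as f:
            json.dump(
                {"estimate": contrast.estimate, "F": contrast.F, "p": contrast.p,
                 "F_eff": contrast.F_eff, "p_eff": contrast.p_eff,
                 "df": [contrast.df_num, contrast.df_den]},
                f, indent=1,
            )
        sliding.to_csv(out / "sliding_coefs.csv", index=False)
        if meta_fit is not None:
            meta_fit.to_csv(out / "ols_meta.csv")
    return {"table_rows": len(table), "fit": result, "contrast": contrast,
            "sliding": sliding, "meta": meta_fit}


def summarize(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Aggregate a completed run's files into summary tables.

    Includes the per-session comparison of R(log2 speed) vs R(speed) with a
    paired t test.
    """
    run_dir = Path(run_dir)
    if not run_dir.exists():
        raise FileNotFoundError(f"run directory {run_dir} does not exist")
    needed = ["speedcode.csv", "di.csv", "cluster_summary.csv", "lmm.csv"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run {run_dir} is missing stage outputs: {missing}")
    out: dict[str, pd.DataFrame] = {}
    sc = pd.read_csv(run_dir / "speedcode.csv")
    tstat, p = stats.ttest_rel(sc["r_log2speed"], sc["r_speed"])
    speed_summary = pd.DataFrame(
        {
            "quantity": ["r_speed", "r_log2speed", "best_window_s", "slope"],
            "mean": [sc["r_speed"].mean(), sc["r_log2speed"].mean(),
                     sc["best_window"].mean(), sc["slope"].mean()],
            "sd": [sc["r_speed"].std(), sc["r_log2speed"].std(),
                   sc["best_window"].std(), sc["slope"].std()],
        }
    )
    speed_summary.attrs["paired_t"] = float(tstat)
    speed_summary.attrs["paired_p"] = float(p)
    out["speed"] = speed_summary
    out["per_session"] = sc

    di = pd.read_csv(run_dir / "di.csv")
    out["di"] = di.groupby("phase")["di"].agg(["mean", "std", "count"]).reset_index()
    out["clusters"] = pd.read_csv(run_dir / "cluster_summary.csv")
    out["lmm"] = pd.read_csv(run_dir / "lmm.csv", index_col=0)
    if (run_dir / "recency_taus.json").exists():
        with open(run_dir / "recency_taus.json") as f:
            taus = json.load(f)
        out["taus"] = pd.DataFrame(taus).T
    for name, df in out.items():
        df.to_csv(run_dir / f"summary_{name}.csv", index=False)
    return out
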