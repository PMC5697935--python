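"""End-to-end orchestration of the session analyses.

``run_all`` executes shock-trial exclusion, single-unit encoding,
VTA cell classification, population GPFA, LFP spectra / coherence /
Granger causality, and spike-field phase locking on one session directory,
writing per-stage TSV/JSON outputs plus a machine-readable ``summary.json``
that records the seed, a config hash, and the included-trial list.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells, encoding, gpfa, phaselock, spectra
from .core import (Session, TrialTable, exclude_shock_trials, read_session)
from .synth import substream

log = logging.getLogger("riskephys")


@dataclass
class RunConfig:
    """Printed analysis parameters collected in one place."""

    session: str = "."
    out: str = "out"
    epoch_window: tuple = (-1.0, 1.0)       # wPEV epoch around events
    peri_action_window: tuple = (-2.0, 2.0)  # LFP / phase-locking epoch
    gpfa_window: tuple = (-0.5, 0.5)
    gpfa_bin: float = 0.02
    gpfa_dims: int = 5
    gpfa_max_iter: int = 200
    theta_band: tuple = (5.0, 15.0)
    n_shuffles: int = 1000
    n_perm_gc: int = 200
    alpha_encoding: float = 0.01
    alpha_rayleigh: float = 0.05
    alpha_gc: float = 0.001
    plv_iters: int = 1000
    plv_resample: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_encoding, self.alpha_rayleigh, self.alpha_gc):
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha {a} outside (0, 1)")
        for w in (self.epoch_window, self.peri_action_window, self.gpfa_window):
            if w[0] >= w[1]:
                raise ValueError(f"malformed window {w}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def behavioral_summary(trials: TrialTable) -> dict:
    """Descriptive per-block RT statistics and the RT-by-lag-from-shock
    profile (how many trials after a shock the RT stays elevated)."""
    df = trials.df
    per_block = {}
    for b, sub in df.groupby("block"):
        per_block[int(b)] = {
            "n": int(len(sub)),
            "rt_mean": float(sub["rt"].mean()),
            "rt_var": float(sub["rt"].var(ddof=1)),
            "immobile_rt_mean": float(sub["immobile_rt"].mean()),
            "immobile_rt_var": float(sub["immobile_rt"].var(ddof=1)),
            "reward_rt_mean": float(sub["reward_rt"].mean()),
        }
    lag_profile = {}
    shock_idx = np.flatnonzero(df["shock_flag"].to_numpy())
    if shock_idx.size:
        last = -np.inf
        lags = np.full(len(df), np.inf)
        for i in range(len(df)):
            if df["shock_flag"].iloc[i]:
                last = i
                lags[i] = 0
            else:
                lags[i] = i - last
        for lag in range(1, 6):
            sel = lags == lag
            if np.any(sel):
                lag_profile[lag] = {"rt_mean": float(df["rt"][sel].mean()),
                                    "n": int(sel.sum())}
    return {"per_block": per_block, "rt_by_lag_from_shock": lag_profile}


def encoding_stage(session: Session, cfg: RunConfig,
                   align: str = "action") -> pd.DataFrame:
    trials = exclude_shock_trials(session.trials)
    rows = []
    for u in session.units:
        res = encoding.encode_unit(
            u, trials, align=align, window=cfg.epoch_window,
            n_shuffles=cfg.n_shuffles, alpha=cfg.alpha_encoding,
            seed=cfg.seed)
        tensor = encoding.bin_peri_event(u, trials, align,
                                         (-0.5, 0.5), bin_width=1.0)
        counts = tensor.data[0, :, 0]
        src = encoding.src_direction(counts, trials.blocks, u.unit_id)
        base = encoding.baseline_block_modulation(u, trials)
        rt_corr = encoding.rate_rt_correlation(
            counts, trials.df["rt"].to_numpy())
        rows.append({
            "unit_id": u.unit_id, "region": u.region,
            "encoder": res.encoder, "n_crossing_bins": len(res.crossing_bins),
            "max_wpev": float(np.max(res.wpev)),
            "global_band": res.global_band,
            "src": src.summary, "direction": src.sign,
            "baseline_modulated": base["modulated"],
            "baseline_p": base["p"], "baseline_direction": base["direction"],
            "rate_rt_r": rt_corr["r"], "rate_rt_p": rt_corr["p"],
        })
    return pd.DataFrame(rows)


def spectra_stage(session: Session, cfg: RunConfig) -> dict:
    """Per-block theta z-power, coherence, and GC asymmetry."""
    trials = exclude_shock_trials(session.trials)
    out = {"theta_z": {}, "coherence": {}, "gc": {}}
    band = cfg.theta_band
    for region, lfp in session.lfp.items():
        base = spectra.baseline_power(lfp, trials)
        out["theta_z"][region] = {}
        for b in np.unique(trials.blocks):
            sub = TrialTable(trials.df[trials.df["block"] == b])
            spec = spectra.multitaper_spectrogram(
                lfp, sub, "action", cfg.peri_action_window)
            sub_base = base[trials.blocks == b]
            z = spectra.normalize_spectrogram(spec, sub_base)
            pre = z.window_centers < 0
            out["theta_z"][region][int(b)] = spectra.band_mean(
                z.power[pre].mean(0), z.freqs, band)
    if {"mPFC", "VTA"} <= set(session.lfp):
        for b in np.unique(trials.blocks):
            sub = TrialTable(trials.df[trials.df["block"] == b])
            coh = spectra.msc_coherence(session.lfp["VTA"],
                                        session.lfp["mPFC"], sub, "action",
                                        cfg.peri_action_window)
            out["coherence"][int(b)] = spectra.band_mean(
                coh.power.mean(0), coh.freqs, band)
            segs_v = spectra.peri_event_segments(
                session.lfp["VTA"], sub, "action", cfg.peri_action_window)
            segs_m = spectra.peri_event_segments(
                session.lfp["mPFC"], sub, "action", cfg.peri_action_window)
            gc = spectra.granger_pair(segs_v, segs_m,
                                      fs=session.lfp["VTA"].fs)
            out["gc"][int(b)] = {
                "vta_to_mpfc": spectra.band_mean(gc.gc_xy, gc.freqs, band),
                "mpfc_to_vta": spectra.band_mean(gc.gc_yx, gc.freqs, band),
                "order": gc.var.order,
            }
    return out


def phaselock_stage(session: Session, cfg: RunConfig) -> dict:
    trials = exclude_shock_trials(session.trials)
    out = {}
    for spike_region, lfp_region in (("mPFC", "mPFC"), ("VTA", "VTA"),
                                     ("mPFC", "VTA"), ("VTA", "mPFC")):
        if lfp_region not in session.lfp:
            continue
        phase = phaselock.bandpass_phase(session.lfp[lfp_region],
                                         cfg.theta_band)
        results = []
        for u in session.units_in(spike_region):
            res = phaselock.unit_block_plv(
                u, phase, trials, window=cfg.peri_action_window,
                n_iter=cfg.plv_iters, n_resample=cfg.plv_resample,
                seed=cfg.seed)
            if res is not None:
                results.extend(res)
        key = f"{spike_region}_spikes_to_{lfp_region}_lfp"
        if results:
            comp = phaselock.blockwise_plv_comparison(results,
                                                      cfg.alpha_rayleigh)
            comp["pairwise"] = {f"{a}-{b}": v
                                for (a, b), v in comp["pairwise"].items()}
            out[key] = comp
    return out


def gpfa_stage(session: Session, cfg: RunConfig, region: str = "mPFC") -> dict:
    trials = exclude_shock_trials(session.trials)
    units = session.units_in(region)
    if len(units) < 10:
        return {"skipped": f"only {len(units)} {region} units (<10)"}
    tensor = encoding.bin_peri_event(units, trials, "action",
                                     cfg.gpfa_window, bin_width=cfg.gpfa_bin)
    Y = gpfa.tensor_to_observations(tensor)
    p = min(cfg.gpfa_dims, len(units) - 1)
    model = gpfa.gpfa_fit(Y, p, max_iter=cfg.gpfa_max_iter, seed=cfg.seed)
    model.bin_centers = tensor.bin_centers
    trajset = gpfa.orthonormalize(model, model.trajectories(Y),
                                  blocks=trials.blocks)
    corr = gpfa.trajectory_rt_correlation(trajset, trials)
    return {"p": p, "r_total": corr["r_total"], "p_total": corr["p_total"],
            "per_block": corr["per_block"],
            "final_loglik": model.loglik_history[-1],
            "converged": model.converged}


def run_all(config: RunConfig) -> dict:
    """Execute every stage on one session directory and write the report
    bundle; a stage failure aborts with the stage name while earlier
    results stay on disk."""
    t_start = time.time()
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    session = read_session(config.session)
    trials = exclude_shock_trials(session.trials)

    summary: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "session": str(config.session),
        "included_trials": trials.df["trial_id"].tolist(),
    }
    stages = []

    def run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # preserve partial results
            _write_summary(out_dir, summary)
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        stages.append({"stage": name, "seconds": round(time.time() - t0, 2)})
        log.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    summary["behavior"] = run_stage(
        "behavior", lambda: behavioral_summary(session.trials))

    enc = run_stage("encoding", lambda: encoding_stage(session, config))
    (out_dir / "encoding").mkdir(exist_ok=True)
    enc.to_csv(out_dir / "encoding" / "encoding_results.tsv", sep="\t",
               index=False)
    summary["encoding"] = {
        "prop_encoders_by_region": {
            r: float(sub["encoder"].mean())
            for r, sub in enc.groupby("region")},
        "prop_excitatory": float((enc["direction"] == "excitatory").mean()),
    }

    cls = run_stage("cell_classes", lambda: cells.classify_session(
        session, seed=config.seed))
    if cls["labels"]:
        (out_dir / "cells").mkdir(exist_ok=True)
        pd.DataFrame([
            {"unit_id": uid, "label": lab,
             "baseline_rate": session.unit(uid).baseline_rate,
             "width": session.unit(uid).waveform_width}
            for uid, lab in cls["labels"].items()
        ]).to_csv(out_dir / "cells" / "vta_classes.tsv", sep="\t", index=False)
        labels = list(cls["labels"].values())
        summary["cells"] = {
            "n_da": labels.count("putative_DA"),
            "n_nonda": labels.count("putative_nonDA")}

    summary["gpfa"] = run_stage("gpfa", lambda: gpfa_stage(session, config))
    summary["spectra"] = run_stage("spectra",
                                   lambda: spectra_stage(session, config))
    summary["phaselock"] = run_stage("phaselock",
                                     lambda: phaselock_stage(session, config))
    summary["stage_timing"] = stages
    summary["total_seconds"] = round(time.time() - t_start, 2)
    _write_summary(out_dir, summary)
    return summary


def _write_summary(out_dir: Path, summary: dict) -> None:
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
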