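"""End-to-end orchestration: simulate -> collect -> infer -> closed-loop
session -> offline judgment.

The study emulates the full experimental flow on synthetic data:

1. a collection phase stimulates every site ``n_anti`` times while the
   population fires spontaneously;
2. evoked responses are filtered (Gaussian-subtraction high-pass), Z-scored
   by the pooled pre-stimulation noise of each tetrode, and antidromic-spike
   targets are inferred with the online parameter set;
3. the closed-loop controller watches the spontaneous spike stream and fires
   collision-test stimulations triggered by spikes matching a target pattern;
4. all trials (collection + triggered) are re-filtered and judged offline
   with both protocols, irrespective of the online protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .control import SessionConfig, StimulationLog, run_collision_session
from .infer import CollisionTarget, EvokedTrialSet, infer_targets
from .judge import JudgeParams, judge_session
from .signal import gaussian_subtract_filter, robust_noise_level
from .simulate import (
    SimConfig,
    SimGroundTruth,
    StimulusEvent,
    append_stimulations,
    default_config,
    make_ground_truth,
    render_evoked_trials,
)

__all__ = ["StudyResult", "sim_config_from_run", "build_evoked_sets", "infer_all", "run_study"]


@dataclass
class StudyResult:
    """Everything a full synthetic study produced."""

    run_config: RunConfig
    sim_config: SimConfig
    truth: SimGroundTruth
    online_targets: list[CollisionTarget]
    stim_log: StimulationLog
    evoked: dict[tuple[int, int], EvokedTrialSet]
    targets: dict[str, list[CollisionTarget]]
    judgments: dict[str, pd.DataFrame]

    def projection_pairs(self, protocol: str) -> pd.DataFrame:
        """Judgment rows of true (neuron, own-target) projection pairs."""
        df = self.judgments[protocol]
        return df[df["category"] == "projection"]


def sim_config_from_run(cfg: RunConfig, seed: int) -> SimConfig:
    return default_config(
        seed=seed,
        n_tetrodes=cfg.n_tetrodes,
        n_projection=cfg.n_projection,
        n_synaptic=cfg.n_synaptic,
        n_unrelated=cfg.n_unrelated,
        session_length=cfg.session_length,
        fs=cfg.fs,
        n_anti=cfg.n_anti,
        i_same=cfg.i_same,
        i_diff=cfg.i_diff,
        duration_ms=cfg.duration_ms,
        noise_sd=cfg.noise_sd,
        t_range_ms=cfg.t_range_ms,
    )


def build_evoked_sets(
    truth: SimGroundTruth,
    stims: list[StimulusEvent] | None = None,
    rng: np.random.Generator | None = None,
    sigma: float = 0.25e-3,
    noise_level: float | None = None,
) -> dict[tuple[int, int], EvokedTrialSet]:
    """Render, filter and Z-score peri-stimulus trials per (tetrode, site).

    The noise level is the robust SD (median |x| / 0.6745) of the filtered
    pre-stimulation halves, pooled per tetrode over its 4 channels and over
    the trials of all sites. ``noise_level`` overrides the estimate (useful
    for noise-free fixtures).
    """
    cfg = truth.config
    stims = sorted(stims if stims is not None else truth.schedule, key=lambda s: s.t_stim)
    rng = rng or np.random.default_rng(truth.seed + 3)
    half = int(round(cfg.t_range_ms * cfg.fs / 1000.0))
    out: dict[tuple[int, int], EvokedTrialSet] = {}
    for tet in range(cfg.n_tetrodes):
        raw = render_evoked_trials(truth, tet, stims, rng=rng)
        filt = gaussian_subtract_filter(raw, sigma=sigma, fs=cfg.fs, axis=-1)
        if noise_level is None:
            level = robust_noise_level(filt[:, :, :half])
        else:
            level = noise_level
        z = filt / level
        for site in cfg.sites:
            idx = [i for i, s in enumerate(stims) if s.site == site]
            if not idx:
                continue
            out[(tet, site)] = EvokedTrialSet(
                tetrode_id=tet,
                site=site,
                trials=z[idx],
                fs=cfg.fs,
                t_range_ms=cfg.t_range_ms,
                stims=[stims[i] for i in idx],
                noise_level=level,
            )
    return out


def infer_all(
    evoked_sets: dict[tuple[int, int], EvokedTrialSet],
    protocol: str,
    cfg: RunConfig,
    online: bool = False,
) -> list[CollisionTarget]:
    """Infer collision targets for every tetrode-site set with one protocol."""
    targets: list[CollisionTarget] = []
    for evoked in evoked_sets.values():
        targets.extend(
            infer_targets(
                evoked,
                protocol,
                width_ms=cfg.width_ms_online if online else cfg.width_ms_offline,
                w_jitter=cfg.w_jitter_online if online else cfg.w_jitter_offline,
                theta_win=cfg.theta_win,
                alpha=cfg.alpha_ms,
                theta_aggr=cfg.theta_aggr_online if online else cfg.theta_aggr_offline,
                detect_sd=cfg.detect_sd,
            )
        )
    return targets


def _spike_stream(
    truth: SimGroundTruth, t_start_ms: float, t_end_ms: float, pattern_noise_sd: float, rng
):
    """Ground-truth spontaneous spikes as a detected-spike stream (times in
    samples, tetrode ids, rectified peak vectors)."""
    fs = truth.fs
    times, tets, zs = [], [], []
    for n in truth.neurons:
        sp = truth.spont_trains[n.id]
        sp = sp[(sp > t_start_ms) & (sp <= t_end_ms)]
        times.append(sp * fs / 1000.0)
        tets.append(np.full(len(sp), n.tetrode_id))
        z = n.amp_pattern[None, :] + rng.normal(0.0, pattern_noise_sd, size=(len(sp), 4))
        zs.append(np.minimum(z, 0.0))
    t = np.concatenate(times) if times else np.empty(0)
    order = np.argsort(t, kind="stable")
    return (
        t[order],
        np.concatenate(tets)[order] if times else np.empty(0, int),
        np.concatenate(zs)[order] if times else np.empty((0, 4)),
    )


def _annotate(df: pd.DataFrame, truth: SimGroundTruth, targets: list[CollisionTarget]) -> pd.DataFrame:
    """Attach ground-truth pair categories and true latencies."""
    by_id = {n.id: n for n in truth.neurons}
    matched_neuron = []
    for tg in targets:
        match, best = -1, 0.5
        for n in truth.neurons:
            if n.tetrode_id != tg.tetrode_id:
                continue
            for p in n.projections:
                if p.site == tg.site and abs(tg.latency_ms - p.latency) < best:
                    match, best = n.id, abs(tg.latency_ms - p.latency)
        matched_neuron.append(match)
    cats, true_lat, true_jit = [], [], []
    for r in df.itertuples():
        n = by_id[r.neuron]
        tg = targets[r.target]
        if matched_neuron[r.target] == r.neuron:
            p = next(p for p in n.projections if p.site == tg.site)
            cats.append("projection")
            true_lat.append(p.latency)
            true_jit.append(0.6745 * p.jitter_sd)
        elif any(s.site == tg.site for s in n.synaptic_inputs):
            s = next(s for s in n.synaptic_inputs if s.site == tg.site)
            cats.append("synaptic")
            true_lat.append(s.latency)
            true_jit.append(s.jitter_qd)
        else:
            cats.append("unrelated")
            true_lat.append(float("nan"))
            true_jit.append(float("nan"))
    out = df.copy()
    out["category"] = cats
    out["true_latency_ms"] = true_lat
    out["true_jitter_ms"] = true_jit
    out["matched"] = [matched_neuron[t] for t in out["target"]]
    return out


def run_study(cfg: RunConfig | None = None, seed: int | None = None) -> StudyResult:
    """Run the full synthetic study and judge it offline with both protocols."""
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    sim_cfg = sim_config_from_run(cfg, seed)
    rng = np.random.default_rng(seed + 101)

    truth = make_ground_truth(sim_cfg, seed=seed)
    collection = list(truth.schedule)

    # online stage: infer targets from the collection trials
    online_sets = build_evoked_sets(truth, collection, rng=np.random.default_rng(seed + 5))
    online_targets = infer_all(online_sets, cfg.online_protocol, cfg, online=True)

    # closed-loop stage on the remaining session
    collect_end_ms = max(s.t_stim for s in collection) * 1000.0 / sim_cfg.fs
    t_start_ms = collect_end_ms + 1000.0
    t_end_ms = sim_cfg.session_length * 1000.0 - cfg.t_range_ms - 5.0
    st, tt, zz = _spike_stream(truth, t_start_ms, t_end_ms, cfg.pattern_noise_sd, rng)
    session_cfg = SessionConfig(
        theta_trig=cfg.theta_trig,
        n_test=cfg.n_test,
        i_same=cfg.i_same,
        i_diff=cfg.i_diff,
        latency_ms=cfg.latency_ms,
        t_range_ms=cfg.t_range_ms,
        n_anti=cfg.n_anti,
        duration_ms=cfg.duration_ms,
    )
    last = {}
    for s in collection:
        last[s.site] = max(last.get(s.site, -np.inf), float(s.t_stim))
    log = run_collision_session(
        st, tt, zz, online_targets, session_cfg, sim_cfg.fs, initial_last_stim=last
    )
    truth = append_stimulations(truth, log.events, rng)

    # offline stage over all trials, both protocols
    evoked_sets = build_evoked_sets(truth, rng=np.random.default_rng(seed + 7))
    neuron_spikes = {n.id: truth.neuron_spike_times_ms(n.id) for n in truth.neurons}
    neuron_tet = {n.id: n.tetrode_id for n in truth.neurons}
    params = JudgeParams(
        r_max=cfg.r_max_ms,
        min_triggers=cfg.min_triggers,
        no_trigger_cap=cfg.no_trigger_cap,
        jitter_criterion_ms=cfg.jitter_criterion_ms,
        sigma_multiplier=cfg.sigma_multiplier,
        detect_sd=cfg.detect_sd,
    )
    targets: dict[str, list[CollisionTarget]] = {}
    judgments: dict[str, pd.DataFrame] = {}
    for protocol in ("I", "II"):
        targets[protocol] = infer_all(evoked_sets, protocol, cfg, online=False)
        df = judge_session(evoked_sets, targets[protocol], neuron_spikes, neuron_tet, params)
        if len(df):
            df = _annotate(df, truth, targets[protocol])
        else:
            for col in ("category", "true_latency_ms", "true_jitter_ms", "matched"):
                df[col] = []
        judgments[protocol] = df
    return StudyResult(
        run_config=cfg,
        sim_config=sim_cfg,
        truth=truth,
        online_targets=online_targets,
        stim_log=log,
        evoked=evoked_sets,
        targets=targets,
        judgments=judgments,
    )


def summarize_recovery(result: StudyResult) -> dict:
    """Parameter-recovery summary of a study (per protocol): fraction of true
    projection pairs judged successful, synaptic false positives with broad
    true jitter, latency recovery error, and cross-protocol latency
    agreement."""
    out: dict = {}
    proj_neurons = [n for n in result.truth.neurons if n.projections]
    matched_lat: dict[str, dict[int, float]] = {}
    for protocol in ("I", "II"):
        df = result.judgments[protocol]
        pp = result.projection_pairs(protocol)
        # one judgment per projection neuron: its highest-AUC successful
        # matched pair (the adopted one), or failure if none succeeded
        best: dict[int, pd.Series] = {}
        for _, row in pp[pp["success"]].iterrows():
            nid = int(row["neuron"])
            if nid not in best or row["auc"] > best[nid]["auc"]:
                best[nid] = row
        errs = np.array(
            [abs(r["latency_ms"] - r["true_latency_ms"]) for r in best.values()]
        )
        syn = df[(df["category"] == "synaptic") & (df["true_jitter_ms"] >= 0.5)]
        out[protocol] = {
            "n_projection": len(proj_neurons),
            "n_projection_success": len(best),
            "projection_success_rate": len(best) / max(1, len(proj_neurons)),
            "synaptic_false_positives": int(syn["success"].sum()),
            "max_latency_error_ms": float(errs.max()) if len(errs) else float("nan"),
            "median_latency_error_ms": float(np.median(errs)) if len(errs) else float("nan"),
        }
        matched_lat[protocol] = {n: float(r["latency_ms"]) for n, r in best.items()}
    common = set(matched_lat["I"]) & set(matched_lat["II"])
    diffs = [abs(matched_lat["I"][n] - matched_lat["II"][n]) for n in common]
    out["cross_protocol"] = {
        "n_common": len(common),
        "median_latency_disagreement_ms": float(np.median(diffs)) if diffs else float("nan"),
    }
    return out
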