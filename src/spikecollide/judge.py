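"""Offline judgment of collision tests.

For every pair of a spike cluster ("neuron") and an inferred antidromic-spike
group (a :class:`~spikecollide.infer.CollisionTarget`), stimulation trials of
the target's site are partitioned:

* trials with a spike of the neuron inside ``(t_min - R_max, t_min)`` are
  dropped first: a spike within the supremum of refractory periods before the
  earliest inferred antidromic timing could eliminate the evoked spike by
  refractoriness rather than collision;
* trigger trials have at least one spike in ``[t_off - L_min, t_stim]``, the
  range in which a spontaneous spike is guaranteed to collide with the
  antidromic spike on the axon (pairs with fewer than 15 trigger trials are
  excluded);
* no-trigger trials have no spike in ``[t_stim - L_max - R_max, t_stim]``
  (so collision is impossible), taken as the 10 temporally nearest trials per
  trigger trial, duplicates merged.

Elimination of the evoked spike is quantified per trial — the negative peak
amplitude inside the inferred window (protocol I) or the similarity to the
inferred center spike (protocol II) — and discrimination between trigger and
no-trigger trials is measured by the ROC area (AUC, Mann-Whitney identity).
A pair is successful when its AUC exceeds the batch median by more than five
robust standard deviations (sigma = median|AUC - median AUC| / 0.6745) AND the
jitter (quartile deviation of spline-interpolated evoked-spike latencies in
no-trigger trials) is below 0.25 ms. Among multiple successful pairs of one
neuron, only the highest-AUC pair is adopted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import rankdata

from .errors import ParameterError
from .infer import (
    CollisionTarget,
    EvokedTrialSet,
    TrialSpikes,
    detect_trial_spikes,
    quartile_deviation,
    spike_similarity,
)

__all__ = [
    "JudgeParams",
    "TestedPair",
    "PairJudgment",
    "extract_trials",
    "elimination_variable",
    "elimination_values",
    "roc_auc",
    "robust_sigma",
    "latency_and_jitter",
    "judge_pair",
    "judge_session",
]


@dataclass
class JudgeParams:
    """Offline judgment parameters with their standard defaults."""

    r_max: float = 4.0  # supremum of somatic refractory periods (ms)
    min_triggers: int = 15
    no_trigger_cap: int = 10  # nearest no-trigger trials per trigger trial
    jitter_criterion_ms: float = 0.25
    sigma_multiplier: float = 5.0
    detect_sd: float = 5.0
    min_evoked: int = 4
    oversample: int = 20


@dataclass
class TestedPair:
    """Trial partition of one neuron x target collision test."""

    trigger_trials: np.ndarray
    no_trigger_trials: np.ndarray
    excluded_refractory: int
    r_max: float = 4.0

    def __post_init__(self) -> None:
        tr = set(self.trigger_trials.tolist())
        if tr & set(self.no_trigger_trials.tolist()):
            raise ParameterError("trigger and no-trigger sets must be disjoint")

    @property
    def n_trigger(self) -> int:
        return len(self.trigger_trials)

    @property
    def n_no_trigger(self) -> int:
        return len(self.no_trigger_trials)


@dataclass
class PairJudgment:
    """Judgment of one neuron x target pair."""

    neuron: int
    target_index: int
    auc: float
    sigma_context: float
    jitter_qd: float
    latency_median: float
    n_trigger: int
    n_no_trigger: int
    success: bool
    adopted: bool = False


def extract_trials(
    spike_times_ms: np.ndarray,
    stims_ms: np.ndarray,
    target: CollisionTarget,
    r_max: float = 4.0,
    min_triggers: int = 15,
    no_trigger_cap: int = 10,
) -> TestedPair | None:
    """Partition stimulation trials into trigger and no-trigger sets.

    ``spike_times_ms`` are the neuron's sorted spike times, ``stims_ms`` the
    onsets of the target site's stimulations (both session ms). Returns
    ``None`` when fewer than ``min_triggers`` trigger trials survive (the
    pair is excluded, not an error).
    """
    sp = np.asarray(spike_times_ms, dtype=float)
    ts = np.asarray(stims_ms, dtype=float)
    t_min, t_max, d_i = target.t_min, target.t_max, target.d_i

    def count_between(lo: np.ndarray, hi: np.ndarray, lo_side: str, hi_side: str) -> np.ndarray:
        return np.searchsorted(sp, hi, side=hi_side) - np.searchsorted(sp, lo, side=lo_side)

    # (1) refractory-confound exclusion: any spike in (t_min - R_max, t_min)
    refr = count_between(ts + t_min - r_max, ts + t_min, "right", "left") > 0
    # (2) trigger range [t_off - L_min, t_stim] = [2 d_i - t_min, 0] rel. onset
    trig = count_between(ts + 2 * d_i - t_min, ts, "left", "right") > 0
    # (4) no-trigger range [t_stim - L_max - R_max, t_stim]
    quiet = count_between(ts - (t_max + r_max), ts, "left", "right") == 0

    kept = ~refr
    trigger_idx = np.flatnonzero(kept & trig)
    if len(trigger_idx) < min_triggers:
        return None
    cand = np.flatnonzero(kept & quiet)
    chosen: set[int] = set()
    for i in trigger_idx:
        order = np.argsort(np.abs(ts[cand] - ts[i]), kind="stable")[:no_trigger_cap]
        chosen.update(cand[order].tolist())
    return TestedPair(
        trigger_trials=trigger_idx,
        no_trigger_trials=np.array(sorted(chosen), dtype=int),
        excluded_refractory=int(refr.sum()),
        r_max=r_max,
    )


def _window_bounds(evoked: EvokedTrialSet, target: CollisionTarget) -> tuple[int, int, int]:
    """Sample bounds and channel of a protocol-I target's amplitude window.

    Falls back to the representative-timing range when the target carries no
    stored window (e.g. hand-built targets)."""
    win = target.window
    if win is not None:
        return evoked.sample_of(win.start_ms), evoked.sample_of(win.end_ms), win.channel
    a = evoked.sample_of(target.t_min - 0.2)
    b = evoked.sample_of(target.t_max + 0.2) + 1
    return a, b, int(np.argmin(target.u))


def _window_values(evoked: EvokedTrialSet, target: CollisionTarget) -> np.ndarray:
    a, b, ch = _window_bounds(evoked, target)
    seg = evoked.trials[:, ch, a:b]
    return np.maximum(0.0, -seg.min(axis=1))


def _similarity_values(
    evoked: EvokedTrialSet, target: CollisionTarget, spikes: TrialSpikes
) -> np.ndarray:
    cst = target.center
    if cst is None:
        raise ParameterError("protocol-II target lacks its center spike")
    out = np.zeros(evoked.n_trials)
    if spikes.n == 0:
        return out
    nz = np.linalg.norm(spikes.z, axis=1)
    nc = np.linalg.norm(cst.center_z)
    cos = (spikes.z @ cst.center_z) / (nz * nc)
    wt = math.sin(math.pi / 18.0) ** 2 / target.alpha**2
    s = np.exp(cos**2 - 1.0 - wt * (spikes.t_ms - cst.center_t_ms) ** 2)
    np.maximum.at(out, spikes.trial, s)
    return out


def elimination_values(
    evoked: EvokedTrialSet, target: CollisionTarget, spikes: TrialSpikes | None = None
) -> np.ndarray:
    """Per-trial elimination variable for all trials of the evoked set."""
    if target.protocol == "I":
        return _window_values(evoked, target)
    if spikes is None:
        spikes = detect_trial_spikes(evoked)
    return _similarity_values(evoked, target, spikes)


def elimination_variable(
    trial_trace: np.ndarray,
    target: CollisionTarget,
    evoked: EvokedTrialSet,
    spikes: TrialSpikes | None = None,
    trial_index: int = 0,
) -> float:
    """Elimination variable of a single trial (see :func:`elimination_values`)."""
    return float(elimination_values(evoked, target, spikes)[trial_index])


def roc_auc(no_trigger_values, trigger_values) -> float:
    """ROC area between the two value sets, by the Mann-Whitney identity:
    AUC = P(no-trigger > trigger) + P(tie)/2. Elimination in trigger trials
    therefore drives AUC above 0.5."""
    x = np.asarray(no_trigger_values, dtype=float)
    y = np.asarray(trigger_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("roc_auc requires two non-empty sets")
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def robust_sigma(auc_values) -> float:
    """Robust SD: median absolute deviation about the median / 0.6745."""
    a = np.asarray(auc_values, dtype=float)
    if a.size < 2:
        raise ParameterError("robust_sigma requires at least two values")
    return float(np.median(np.abs(a - np.median(a))) / 0.6745)


def _spline_peak_time(trace: np.ndarray, peak: int, dt_ms: float, oversample: int) -> float:
    """Sub-sample trough time (ms, relative to sample 0 of the trace)."""
    lo = max(0, peak - 4)
    hi = min(len(trace), peak + 5)
    xs = np.arange(lo, hi, dtype=float)
    cs = CubicSpline(xs, trace[lo:hi])
    grid = np.linspace(max(lo, peak - 1.5), min(hi - 1, peak + 1.5), 6 * oversample + 1)
    return float(grid[np.argmin(cs(grid))] * dt_ms)


def evoked_latencies(
    evoked: EvokedTrialSet,
    target: CollisionTarget,
    spikes: TrialSpikes | None = None,
    detect_sd: float = 5.0,
    oversample: int = 20,
) -> np.ndarray:
    """Spline-interpolated evoked-spike latency per trial (NaN when the trial
    has no evoked spike for this target).

    Protocol I takes the peak within the inferred window (required to reach
    ``detect_sd``); protocol II the detected spike most similar to the center.
    The peak channel's waveform is interpolated by a cubic spline with
    ``oversample``-fold refinement; latency is the interpolated trough time.
    """
    half = evoked.half
    dt = evoked.dt_ms
    lat = np.full(evoked.n_trials, np.nan)
    if target.protocol == "I":
        a, b, ch = _window_bounds(evoked, target)
        seg = evoked.trials[:, ch, a:b]
        k = np.argmin(seg, axis=1)
        ok = seg[np.arange(len(k)), k] <= -detect_sd
        for i in np.flatnonzero(ok):
            peak = a + int(k[i])
            t = _spline_peak_time(evoked.trials[i, ch], peak, dt, oversample)
            lat[i] = t - half * dt
    else:
        if spikes is None:
            spikes = detect_trial_spikes(evoked, detect_sd=detect_sd)
        if spikes.n == 0:
            return lat
        cst = target.center
        sim = np.array(
            [
                spike_similarity(z, t, cst.center_z, cst.center_t_ms, target.alpha)
                for z, t in zip(spikes.z, spikes.t_ms)
            ]
        )
        for j, sl in enumerate(spikes.trial_slices()):
            if sl.start == sl.stop:
                continue
            best = sl.start + int(np.argmax(sim[sl]))
            ch = int(np.argmin(spikes.z[best]))
            peak = half + int(round(spikes.t_ms[best] / dt))
            t = _spline_peak_time(evoked.trials[j, ch], peak, dt, oversample)
            lat[j] = t - half * dt
    return lat


def latency_and_jitter(
    evoked: EvokedTrialSet,
    no_trigger_trials: np.ndarray,
    target: CollisionTarget,
    spikes: TrialSpikes | None = None,
    detect_sd: float = 5.0,
    min_evoked: int = 4,
    oversample: int = 20,
    latencies: np.ndarray | None = None,
) -> tuple[float, float]:
    """Median latency and jitter (quartile deviation) of the evoked spikes in
    the given no-trigger trials. Raises when fewer than ``min_evoked`` trials
    contain an evoked spike."""
    if latencies is None:
        latencies = evoked_latencies(
            evoked, target, spikes=spikes, detect_sd=detect_sd, oversample=oversample
        )
    vals = latencies[np.asarray(no_trigger_trials, dtype=int)]
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_evoked:
        raise ParameterError(
            f"only {len(vals)} no-trigger trials with an evoked spike (need {min_evoked})"
        )
    return float(np.median(vals)), quartile_deviation(vals)


def judge_pair(
    auc: float,
    jitter_qd: float,
    batch_aucs,
    jitter_criterion_ms: float = 0.25,
    sigma_multiplier: float = 5.0,
) -> tuple[bool, float]:
    """Success criterion of one pair given the batch AUC distribution.

    The AUC outlier criterion is a deviation above the batch median greater
    than ``sigma_multiplier`` robust SDs (the batch is dominated by unmatched
    pairs whose AUC scatters around chance level).
    Returns ``(success, sigma)``.
    """
    sigma = robust_sigma(batch_aucs)
    med = float(np.median(np.asarray(batch_aucs, dtype=float)))
    success = (
        np.isfinite(jitter_qd)
        and jitter_qd < jitter_criterion_ms
        and (auc - med) > sigma_multiplier * sigma
    )
    return bool(success), sigma


def judge_session(
    evoked_sets: dict[tuple[int, int], EvokedTrialSet],
    targets: list[CollisionTarget],
    neuron_spikes_ms: dict[int, np.ndarray],
    neuron_tetrode: dict[int, int],
    params: JudgeParams | None = None,
) -> pd.DataFrame:
    """Judge every same-tetrode neuron x target pair of an analysis run.

    Returns one row per pair that passed trial extraction, with columns
    ``protocol, tetrode, site, target, neuron, n_trigger, n_no_trigger,
    n_excluded_refractory, auc, sigma, jitter_ms, latency_ms, success,
    adopted``. The robust-sigma batch is the whole run.
    """
    params = params or JudgeParams()
    rows: list[dict] = []
    for (tet, site), evoked in evoked_sets.items():
        site_targets = [(j, t) for j, t in enumerate(targets) if t.tetrode_id == tet and t.site == site]
        if not site_targets:
            continue
        stims_ms = np.array([s.t_stim_ms(evoked.fs) for s in evoked.stims])
        spikes = detect_trial_spikes(evoked, detect_sd=params.detect_sd)
        neurons = [n for n, t in neuron_tetrode.items() if t == tet]
        for j, tg in site_targets:
            values = elimination_values(evoked, tg, spikes)
            lats = evoked_latencies(
                evoked, tg, spikes=spikes, detect_sd=params.detect_sd, oversample=params.oversample
            )
            for nid in neurons:
                pair = extract_trials(
                    neuron_spikes_ms[nid],
                    stims_ms,
                    tg,
                    r_max=params.r_max,
                    min_triggers=params.min_triggers,
                    no_trigger_cap=params.no_trigger_cap,
                )
                if pair is None or pair.n_no_trigger == 0:
                    continue
                auc = roc_auc(values[pair.no_trigger_trials], values[pair.trigger_trials])
                try:
                    lat, jit = latency_and_jitter(
                        evoked,
                        pair.no_trigger_trials,
                        tg,
                        min_evoked=params.min_evoked,
                        latencies=lats,
                    )
                except ParameterError:
                    lat, jit = float("nan"), float("nan")
                rows.append(
                    {
                        "protocol": tg.protocol,
                        "tetrode": tet,
                        "site": site,
                        "target": j,
                        "neuron": nid,
                        "n_trigger": pair.n_trigger,
                        "n_no_trigger": pair.n_no_trigger,
                        "n_excluded_refractory": pair.excluded_refractory,
                        "auc": auc,
                        "jitter_ms": jit,
                        "latency_ms": lat,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "protocol",
            "tetrode",
            "site",
            "target",
            "neuron",
            "n_trigger",
            "n_no_trigger",
            "n_excluded_refractory",
            "auc",
            "jitter_ms",
            "latency_ms",
        ],
    )
    if df.empty:
        df["sigma"] = []
        df["success"] = []
        df["adopted"] = []
        return df
    sigma = robust_sigma(df["auc"]) if len(df) >= 2 else float("nan")
    med = float(df["auc"].median())
    df["sigma"] = sigma
    df["success"] = (
        (df["auc"] - med > params.sigma_multiplier * sigma)
        & (df["jitter_ms"] < params.jitter_criterion_ms)
        & df["jitter_ms"].notna()
    )
    df["adopted"] = False
    for nid, grp in df[df["success"]].groupby("neuron"):
        df.loc[grp["auc"].idxmax(), "adopted"] = True
    return df
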