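"""Antidromic-spike inference and collision-target construction.

Given Z-scored evoked responses of one tetrode aligned to the stimulation
onsets of one site, two protocols infer groups of putative antidromic spikes
(stable-latency, stable-pattern evoked spikes of a single unit):

Protocol I (window search)
    A fixed-width temporal window slides over post-stimulus time on each of
    the four channels. Per window and trial the most negative peak is taken;
    the window is scored by the first quartile of the peak magnitudes (the
    value exceeded by 75% of trials, so stable spiking scores high). The best
    window is refined iteratively: keep the 75% largest peaks, measure the
    quartile deviation (QD) of their timings, reset the window to
    median +- W_jitter * QD, and repeat until the bounds stop moving.

Protocol II (center-spike search)
    Spikes are detected in every trial (negative peaks below ``detect_sd``).
    Each detected spike is scored by the first quartile of its similarity to
    the most similar spike of every trial, with

        S_kl = exp[ cos^2(theta_kl) - 1 - sin^2(pi/18)/alpha^2 * (t_k-t_l)^2 ]

    where theta_kl is the angle between the two rectified 4-channel peak
    patterns. The highest-quartile spike is adopted as an aggregation center;
    its 75% most similar per-trial spikes become representatives and leave
    the candidate pool, and the search iterates.

Both protocols end in :func:`build_target`, which produces the quantities the
collision test needs: the median peak pattern u, the median waveform, and the
representative-timing bounds t_min/t_max with the latency bounds
L_min = t_min - t_off and L_max = t_max - t_stim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .simulate import StimulusEvent

__all__ = [
    "EvokedTrialSet",
    "TrialSpikes",
    "AntidromicWindow",
    "CenterSpikeTarget",
    "CollisionTarget",
    "amplitude_quartile",
    "quartile_deviation",
    "spike_similarity",
    "detect_trial_spikes",
    "window_search",
    "center_spike_search",
    "build_target",
]

#: timing weight of the similarity kernel: Delta t = alpha matches an angle
#: difference of pi/18 between peak patterns
_KERNEL_TIMING_WEIGHT = math.sin(math.pi / 18.0) ** 2


@dataclass
class EvokedTrialSet:
    """Aligned, Z-scored evoked responses of one tetrode for one site.

    ``trials`` has shape ``(n_trials, 4, 2*half+1)`` spanning
    ``[-t_range, +t_range]`` ms around each stimulation onset (onset at the
    center sample).
    """

    tetrode_id: int
    site: int
    trials: np.ndarray
    fs: float
    t_range_ms: float = 30.0
    stims: list[StimulusEvent] = field(default_factory=list)
    noise_level: float = 1.0

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3 or self.trials.shape[1] != 4:
            raise ShapeError("trials must be (n_trials, 4, n_samples)")
        if self.t_range_ms <= 0:
            raise ParameterError("t_range_ms must be positive")
        if self.stims and len(self.stims) != self.n_trials:
            raise ShapeError("stimulus metadata does not match the trial count")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def half(self) -> int:
        return (self.trials.shape[2] - 1) // 2

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        """Light-pulse duration D_i of this site's stimulations."""
        return self.stims[0].duration_ms if self.stims else 1.0

    def sample_of(self, t_ms: float) -> int:
        return self.half + int(round(t_ms / self.dt_ms))

    def time_of(self, sample: int | np.ndarray):
        return (np.asarray(sample) - self.half) * self.dt_ms


@dataclass
class TrialSpikes:
    """Spikes detected in post-stimulus evoked responses (all trials pooled),
    sorted by (trial, time)."""

    trial: np.ndarray  # (m,) trial index
    t_ms: np.ndarray  # (m,) time after stimulation onset
    z: np.ndarray  # (m, 4) rectified peak vectors
    n_trials: int

    @property
    def n(self) -> int:
        return len(self.t_ms)

    def trial_slices(self) -> list[slice]:
        bounds = np.searchsorted(self.trial, np.arange(self.n_trials + 1))
        return [slice(bounds[j], bounds[j + 1]) for j in range(self.n_trials)]


@dataclass
class AntidromicWindow:
    """A converged protocol-I window with its representative peaks."""

    channel: int
    start_ms: float  # post-stimulus, half-open [start, end)
    end_ms: float
    amplitude_quartile: float
    rep_trials: np.ndarray
    rep_times_ms: np.ndarray
    rep_amps: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ParameterError("window start must precede its end")


@dataclass
class CenterSpikeTarget:
    """A protocol-II aggregation center with its representative spikes."""

    center_trial: int
    center_t_ms: float
    center_z: np.ndarray
    similarity_quartile: float
    alpha: float
    rep_trials: np.ndarray
    rep_times_ms: np.ndarray
    rep_z: np.ndarray
    rep_similarity: np.ndarray

    def __post_init__(self) -> None:
        # the kernel is positive, but trials without any detected spike
        # contribute similarity 0, so offline (unthresholded) quartiles may
        # reach 0 exactly
        if not 0.0 <= self.similarity_quartile <= 1.0:
            raise ParameterError("similarity quartile must lie in [0, 1]")
        if len(set(self.rep_trials.tolist())) != len(self.rep_trials):
            raise ParameterError("representatives must come from distinct trials")


@dataclass
class CollisionTarget:
    """Everything the online trigger and offline judgment need to know about
    one inferred antidromic-spike group."""

    tetrode_id: int
    site: int
    protocol: str  # 'I' | 'II'
    u: np.ndarray  # median 4-channel peak pattern
    median_waveform: np.ndarray  # (4, n_samples), aligned to the peak
    waveform_peak_idx: int
    t_min: float  # earliest representative timing (ms post onset)
    t_max: float  # latest representative timing (ms post onset)
    d_i: float  # light-pulse duration (ms)
    rep_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    window: AntidromicWindow | None = None
    center: CenterSpikeTarget | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ParameterError("t_min must not exceed t_max")

    @property
    def L_min(self) -> float:
        """Lower latency bound: t_min - t_off."""
        return self.t_min - self.d_i

    @property
    def L_max(self) -> float:
        """Upper latency bound: t_max - t_stim."""
        return self.t_max

    @property
    def latency_ms(self) -> float:
        """Median representative timing."""
        return float(np.median(self.rep_times_ms)) if len(self.rep_times_ms) else 0.5 * (self.t_min + self.t_max)


def amplitude_quartile(values) -> float:
    """First quartile "75% from the largest": the level that 75% of the
    entries reach or exceed (25th percentile, linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("amplitude_quartile of an empty set")
    return float(np.percentile(values, 25))


def quartile_deviation(values) -> float:
    """Half the interquartile range, same interpolation convention."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("quartile_deviation of an empty set")
    q1, q3 = np.percentile(values, [25, 75])
    return float((q3 - q1) / 2.0)


def spike_similarity(z_k, t_k: float, z_l, t_l: float, alpha: float) -> float:
    """Similarity of two rectified evoked spikes in pattern-angle and timing.

    Equals 1 for identical spikes and decreases monotonically with the
    pattern-angle difference and with |t_k - t_l|; a timing difference of
    ``alpha`` weighs like a pattern-angle difference of pi/18.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    z_k = np.asarray(z_k, dtype=float)
    z_l = np.asarray(z_l, dtype=float)
    kk = float(z_k @ z_k)
    ll = float(z_l @ z_l)
    if kk == 0 or ll == 0:
        raise ParameterError("similarity of a zero peak vector is undefined")
    cos2 = min(1.0, float(z_k @ z_l) ** 2 / (kk * ll))
    return math.exp(cos2 - 1.0 - _KERNEL_TIMING_WEIGHT / alpha**2 * (t_k - t_l) ** 2)


def detect_trial_spikes(evoked: EvokedTrialSet, detect_sd: float = 5.0) -> TrialSpikes:
    """Threshold detection of negative peaks below ``detect_sd`` in the
    post-stimulus range (0, T_range] of every trial.

    Within each maximal supra-threshold run (union over channels) one spike is
    emitted at the sample maximizing the rectified squared amplitude.
    """
    if detect_sd <= 0:
        raise ParameterError("detect_sd must be positive")
    X = evoked.trials
    half = evoked.half
    post = X[:, :, half + 1 :]
    rect = np.minimum(post, 0.0)
    a = np.einsum("icj,icj->ij", rect, rect)
    on = (post < -detect_sd).any(axis=1)
    trials: list[int] = []
    times: list[float] = []
    vecs: list[np.ndarray] = []
    dt = evoked.dt_ms
    for i in range(X.shape[0]):
        oi = on[i]
        if not oi.any():
            continue
        idx = np.flatnonzero(np.diff(np.concatenate(([False], oi, [False])).astype(np.int8)))
        for s, e in zip(idx[::2], idx[1::2]):
            k = s + int(np.argmax(a[i, s:e]))
            trials.append(i)
            times.append((k + 1) * dt)
            vecs.append(rect[i, :, k])
    if trials:
        return TrialSpikes(
            trial=np.asarray(trials),
            t_ms=np.asarray(times),
            z=np.asarray(vecs),
            n_trials=X.shape[0],
        )
    return TrialSpikes(
        trial=np.empty(0, int), t_ms=np.empty(0), z=np.empty((0, 4)), n_trials=X.shape[0]
    )


def _window_peaks(X: np.ndarray, half: int, a: int, b: int, dt: float):
    """Per-trial most-negative peak in samples [half+a, half+b): (amps, times_ms)."""
    seg = X[:, half + a : half + b]
    k = np.argmin(seg, axis=1)
    vals = seg[np.arange(seg.shape[0]), k]
    return np.maximum(0.0, -vals), (k + a) * dt


def window_search(
    evoked: EvokedTrialSet,
    width_ms: float = 1.0,
    w_jitter: float = 4.0,
    theta_win: float = 5.0,
    max_iter: int = 20,
) -> list[AntidromicWindow]:
    """Protocol I: slide, score, adopt and refine amplitude windows.

    Returns converged windows in adoption order (highest amplitude quartile
    first). Candidate windows below ``theta_win`` are excluded; adopted
    windows exclude all time-overlapping windows on every channel;
    non-converging refinements are rejected.
    """
    if width_ms <= 0 or w_jitter <= 0:
        raise ParameterError("width_ms and w_jitter must be positive")
    fs = evoked.fs
    dt = evoked.dt_ms
    half = evoked.half
    n_post = int(round(evoked.t_range_ms / dt))
    w = max(2, int(round(width_ms / dt)))
    n_pos = n_post - w + 1
    if n_pos <= 0:
        raise ParameterError("window wider than the post-stimulus range")
    # starts (in samples after onset): 1 .. n_post - w + 1
    starts = np.arange(1, n_post - w + 2)
    q = np.empty((len(starts), 4))
    for c in range(4):
        sw = np.lib.stride_tricks.sliding_window_view(
            evoked.trials[:, c, half + 1 : half + 1 + n_post], w, axis=1
        )
        amp = np.maximum(0.0, -sw.min(axis=2))
        q[:, c] = np.percentile(amp, 25, axis=0)
    candidates = q >= theta_win

    adopted: list[AntidromicWindow] = []
    while candidates.any():
        flat = np.where(candidates, q, -np.inf)
        pos, ch = np.unravel_index(int(np.argmax(flat)), flat.shape)
        candidates[pos, ch] = False
        X = evoked.trials[:, ch, :]
        a, b = int(starts[pos]), int(starts[pos]) + w
        ok = False
        for _ in range(max_iter):
            amps, times = _window_peaks(X, half, a, b, dt)
            k_rep = math.ceil(0.75 * len(amps))
            order = np.lexsort((times, -amps))[:k_rep]
            med = float(np.median(times[order]))
            qd = quartile_deviation(times[order])
            na = int(round((med - w_jitter * qd) / dt))
            nb = int(round((med + w_jitter * qd) / dt)) + 1
            m = int(round(med / dt))
            na = min(na, m - 1)
            nb = max(nb, m + 2)
            na = max(1, na)
            nb = min(n_post + 1, nb)
            if na >= nb:
                break
            if na == a and nb == b:
                ok = True
                break
            a, b = na, nb
        if not ok:
            continue
        # a refined window drifting into an already-adopted range is rejected,
        # keeping adopted windows non-overlapping on every channel
        if any(a * dt < win.end_ms and b * dt > win.start_ms for win in adopted):
            continue
        amps, times = _window_peaks(X, half, a, b, dt)
        k_rep = math.ceil(0.75 * len(amps))
        order = np.lexsort((times, -amps))[:k_rep]
        win = AntidromicWindow(
            channel=int(ch),
            start_ms=a * dt,
            end_ms=b * dt,
            amplitude_quartile=amplitude_quartile(amps),
            rep_trials=np.sort(order),
            rep_times_ms=times[np.sort(order)],
            rep_amps=amps[np.sort(order)],
        )
        adopted.append(win)
        # exclude overlapping windows on all channels
        overlap = (starts < b) & (starts + w > a)
        candidates[overlap, :] = False
    return adopted


def _similarity_blocks(
    spikes: TrialSpikes, alpha: float, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial best similarity B and its argument A for candidate rows."""
    norms = np.linalg.norm(spikes.z, axis=1)
    U = spikes.z / norms[:, None]
    slices = spikes.trial_slices()
    wt = _KERNEL_TIMING_WEIGHT / alpha**2
    B = np.zeros((len(rows), spikes.n_trials))
    A = np.full((len(rows), spikes.n_trials), -1, dtype=int)
    chunk = max(1, int(2e7) // max(1, spikes.n))
    for c0 in range(0, len(rows), chunk):
        sel = rows[c0 : c0 + chunk]
        cos = U[sel] @ U.T
        S = np.exp(cos**2 - 1.0 - wt * (spikes.t_ms[sel, None] - spikes.t_ms[None, :]) ** 2)
        for j, sl in enumerate(slices):
            if sl.start == sl.stop:
                continue
            sub = S[:, sl]
            am = np.argmax(sub, axis=1)
            B[c0 : c0 + len(sel), j] = sub[np.arange(len(sel)), am]
            A[c0 : c0 + len(sel), j] = sl.start + am
    return B, A


def center_spike_search(
    evoked: EvokedTrialSet,
    alpha: float = 1.0,
    theta_aggr: float | None = None,
    detect_sd: float = 5.0,
    max_targets: int | None = None,
    spikes: TrialSpikes | None = None,
) -> list[CenterSpikeTarget]:
    """Protocol II: find aggregation centers of evoked spikes.

    With ``theta_aggr=None`` (offline mode) no candidate is excluded by its
    similarity quartile, so low-aggregation centers are returned as well (they
    serve as controls downstream). Trials without any detected spike
    contribute similarity 0 to every candidate's distribution.
    """
    if spikes is None:
        spikes = detect_trial_spikes(evoked, detect_sd=detect_sd)
    if spikes.n == 0:
        return []
    rows = np.arange(spikes.n)
    B, A = _similarity_blocks(spikes, alpha, rows)
    q = np.percentile(B, 25, axis=1)
    candidate = np.ones(spikes.n, dtype=bool)
    if theta_aggr is not None:
        candidate &= q >= theta_aggr
    has_spike = np.array([sl.start != sl.stop for sl in spikes.trial_slices()])
    n_contrib = int(has_spike.sum())
    k_rep = math.ceil(0.75 * n_contrib)
    out: list[CenterSpikeTarget] = []
    while candidate.any():
        idx = np.flatnonzero(candidate)
        k = idx[np.lexsort((spikes.t_ms[idx], -q[idx]))[0]]
        sims = B[k, has_spike]
        args = A[k, has_spike]
        order = np.argsort(-sims, kind="stable")[:k_rep]
        reps = args[order]
        out.append(
            CenterSpikeTarget(
                center_trial=int(spikes.trial[k]),
                center_t_ms=float(spikes.t_ms[k]),
                center_z=spikes.z[k].copy(),
                similarity_quartile=float(q[k]),
                alpha=alpha,
                rep_trials=spikes.trial[reps],
                rep_times_ms=spikes.t_ms[reps],
                rep_z=spikes.z[reps],
                rep_similarity=sims[order],
            )
        )
        candidate[reps] = False
        candidate[k] = False
        if max_targets is not None and len(out) >= max_targets:
            break
    return out


def build_target(
    evoked: EvokedTrialSet,
    rep_trials: np.ndarray,
    rep_times_ms: np.ndarray,
    protocol: str,
    window: AntidromicWindow | None = None,
    center: CenterSpikeTarget | None = None,
    alpha: float = 1.0,
    waveform_pre_ms: float = 1.0,
    waveform_post_ms: float = 1.5,
) -> CollisionTarget:
    """Summarize a representative spike set into a collision target.

    ``u`` is the component-wise median of the rectified 4-channel vectors at
    the representative peaks; the median waveform is aligned at the peak
    sample; ``t_min``/``t_max`` bound the representative timings.
    """
    rep_trials = np.asarray(rep_trials, dtype=int)
    rep_times_ms = np.asarray(rep_times_ms, dtype=float)
    if rep_trials.size == 0:
        raise ParameterError("cannot build a target from an empty representative set")
    if protocol not in ("I", "II"):
        raise ParameterError(f"unknown protocol {protocol!r}")
    half = evoked.half
    dt = evoked.dt_ms
    idx = half + np.round(rep_times_ms / dt).astype(int)
    vecs = np.minimum(evoked.trials[rep_trials, :, idx], 0.0)  # (k, 4)
    u = np.median(vecs, axis=0)
    pre_n = int(round(waveform_pre_ms / dt))
    post_n = int(round(waveform_post_ms / dt))
    n_t = evoked.trials.shape[2]
    snippets = np.zeros((len(rep_trials), 4, pre_n + post_n + 1))
    for i, (tr, k) in enumerate(zip(rep_trials, idx)):
        lo, hi = k - pre_n, k + post_n + 1
        s_lo, s_hi = max(0, lo), min(n_t, hi)
        snippets[i, :, s_lo - lo : s_lo - lo + (s_hi - s_lo)] = evoked.trials[tr, :, s_lo:s_hi]
    return CollisionTarget(
        tetrode_id=evoked.tetrode_id,
        site=evoked.site,
        protocol=protocol,
        u=u,
        median_waveform=np.median(snippets, axis=0),
        waveform_peak_idx=pre_n,
        t_min=float(rep_times_ms.min()),
        t_max=float(rep_times_ms.max()),
        d_i=evoked.duration_ms,
        rep_times_ms=rep_times_ms.copy(),
        window=window,
        center=center,
        alpha=alpha,
    )


def infer_targets(
    evoked: EvokedTrialSet,
    protocol: str,
    width_ms: float = 1.0,
    w_jitter: float = 4.0,
    theta_win: float = 5.0,
    alpha: float = 1.0,
    theta_aggr: float | None = None,
    detect_sd: float = 5.0,
    max_targets: int | None = None,
) -> list[CollisionTarget]:
    """Run one protocol end to end on one tetrode-site trial set."""
    targets: list[CollisionTarget] = []
    if protocol == "I":
        for win in window_search(
            evoked, width_ms=width_ms, w_jitter=w_jitter, theta_win=theta_win, max_iter=20
        )[: max_targets if max_targets else None]:
            targets.append(
                build_target(
                    evoked, win.rep_trials, win.rep_times_ms, "I", window=win, alpha=alpha
                )
            )
    elif protocol == "II":
        for cst in center_spike_search(
            evoked, alpha=alpha, theta_aggr=theta_aggr, detect_sd=detect_sd, max_targets=max_targets
        ):
            targets.append(
                build_target(
                    evoked, cst.rep_trials, cst.rep_times_ms, "II", center=cst, alpha=alpha
                )
            )
    else:
        raise ParameterError(f"unknown protocol {protocol!r}")
    return targets
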