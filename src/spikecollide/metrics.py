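"""Spike-property metrics for characterizing identified projections.

Covers the waveform and firing statistics used to compare successfully
identified projection neurons with the remaining units: trough-to-peak
duration (projection neurons are wide, fast-spiking interneurons narrow, with
a boundary near 0.5 ms), ongoing rate outside stimulation windows, waveform
stability and peak-pattern bias of evoked spikes, trigger-vs-evoked waveform
similarity, and the ROC sweep of the waveform window width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy import stats

from .errors import ParameterError, ShapeError
from .judge import roc_auc
from .signal import DEFAULT_FS

__all__ = [
    "WaveformWindow",
    "NeuronProfile",
    "trough_to_peak",
    "ongoing_rate",
    "waveform_stability",
    "peak_pattern_bias",
    "waveform_similarity",
    "width_sweep_auc",
]


@dataclass(frozen=True)
class WaveformWindow:
    """Peak-centered waveform window (ms before/after the largest peak)."""

    pre_ms: float = 0.25
    post_ms: float = 0.5
    n_channels: int = 4

    def __post_init__(self) -> None:
        if self.pre_ms < 0 or self.post_ms < 0 or self.pre_ms + self.post_ms <= 0:
            raise ParameterError("window must have non-negative, non-empty extent")

    def slice_at(self, peak_idx: int, fs: float = DEFAULT_FS) -> slice:
        pre = int(round(self.pre_ms * fs / 1000.0))
        post = int(round(self.post_ms * fs / 1000.0))
        return slice(peak_idx - pre, peak_idx + post + 1)


@dataclass
class NeuronProfile:
    """Summary spike properties of one unit."""

    neuron: int
    trough_to_peak_ms: float
    ongoing_rate_hz: float
    group: str = "other"  # 'success' | 'other'

    def __post_init__(self) -> None:
        if self.trough_to_peak_ms <= 0:
            raise ParameterError("trough_to_peak_ms must be positive")
        if self.ongoing_rate_hz < 0:
            raise ParameterError("ongoing_rate_hz must be non-negative")


def trough_to_peak(waveform: np.ndarray, fs: float = DEFAULT_FS, oversample: int = 20) -> float:
    """Sub-sample duration from the waveform trough to the subsequent peak.

    The (unfiltered) single-channel waveform is spline-interpolated; the
    trough is the interpolated global minimum and the peak the interpolated
    maximum after it. A trace without a post-trough maximum is an error.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or len(w) < 5:
        raise ShapeError("waveform must be a 1-D trace of at least 5 samples")
    i_tr = int(np.argmin(w))
    if i_tr >= len(w) - 2:
        raise ParameterError("no post-trough maximum inside the window")
    i_pk = i_tr + int(np.argmax(w[i_tr:]))
    if i_pk == i_tr:
        raise ParameterError("no post-trough maximum inside the window")
    cs = CubicSpline(np.arange(len(w), dtype=float), w)
    dt = 1000.0 / fs

    def refine(i: int, minimize: bool) -> float:
        lo, hi = max(0, i - 1), min(len(w) - 1, i + 1)
        grid = np.linspace(lo, hi, 2 * oversample + 1)
        v = cs(grid)
        return float(grid[np.argmin(v) if minimize else np.argmax(v)])

    return (refine(i_pk, False) - refine(i_tr, True)) * dt


def ongoing_rate(
    spike_times: np.ndarray,
    stim_times: np.ndarray,
    exclusion_ms: float = 30.0,
) -> float:
    """Spontaneous rate between the first and last stimulation, excluding the
    ``exclusion_ms`` period following each stimulation. Times in seconds."""
    sp = np.sort(np.asarray(spike_times, dtype=float))
    st = np.sort(np.asarray(stim_times, dtype=float))
    if len(st) < 2:
        raise ParameterError("at least two stimulations are needed to bound the range")
    lo, hi = st[0], st[-1]
    excl = exclusion_ms / 1000.0
    # merged exclusion zones (t, t+excl], clipped to the analysis range
    zones = []
    for t in st:
        a, b = max(lo, t), min(hi, t + excl)
        if b <= a:
            continue
        if zones and a <= zones[-1][1]:
            zones[-1] = (zones[-1][0], max(zones[-1][1], b))
        else:
            zones.append((a, b))
    retained = (hi - lo) - sum(b - a for a, b in zones)
    if retained <= 0:
        raise ParameterError("exclusion zones cover the whole analysis range")
    inside = (sp >= lo) & (sp <= hi)
    count = int(inside.sum())
    for a, b in zones:
        count -= int(((sp > a) & (sp <= b)).sum())
    return count / retained


def _concat_window(w: np.ndarray, peak_idx: int, window: WaveformWindow, fs: float) -> np.ndarray:
    sl = window.slice_at(peak_idx, fs)
    if sl.start < 0 or sl.stop > w.shape[-1]:
        raise ShapeError("waveform window extends beyond the trace")
    return w[..., sl].reshape(-1)


def waveform_stability(
    trial_waveforms: np.ndarray,
    window: WaveformWindow | None = None,
    peak_idx: int | None = None,
    fs: float = DEFAULT_FS,
) -> float:
    """Median Pearson correlation between each trial's 4-channel waveform and
    the median waveform, over the peak-centered window."""
    window = window or WaveformWindow()
    W = np.asarray(trial_waveforms, dtype=float)
    if W.ndim != 3 or W.shape[1] != 4:
        raise ShapeError("trial_waveforms must be (n_trials, 4, n_samples)")
    if W.shape[0] < 3:
        raise ParameterError("waveform stability needs at least 3 trials")
    med = np.median(W, axis=0)
    if peak_idx is None:
        peak_idx = int(np.unravel_index(np.argmin(med), med.shape)[1])
    ref = _concat_window(med, peak_idx, window, fs)
    if np.ptp(ref) == 0:
        raise ParameterError("constant median waveform: correlation undefined")
    rs = []
    for i in range(W.shape[0]):
        x = _concat_window(W[i], peak_idx, window, fs)
        if np.ptp(x) == 0:
            raise ParameterError("constant trial waveform: correlation undefined")
        rs.append(float(np.corrcoef(x, ref)[0, 1]))
    return float(np.median(rs))


def peak_pattern_bias(median_peaks: np.ndarray) -> float:
    """Coefficient of variation of the four median peak magnitudes
    (population SD over mean)."""
    m = np.abs(np.asarray(median_peaks, dtype=float))
    if m.shape != (4,):
        raise ShapeError("median_peaks must be a 4-vector")
    mean = m.mean()
    if mean == 0:
        raise ParameterError("all-zero peak pattern: CV undefined")
    return float(m.std() / mean)


def waveform_similarity(
    w1: np.ndarray,
    w2: np.ndarray,
    window: WaveformWindow | None = None,
    peak_idx1: int | None = None,
    peak_idx2: int | None = None,
    fs: float = DEFAULT_FS,
) -> tuple[float, float]:
    """Similarity of two peak-aligned 4-channel median waveforms.

    Returns ``(pattern_cos, waveform_r)``: the direction cosine of the two
    4-vectors of per-channel peak amplitudes, and the Pearson correlation of
    the concatenated windowed waveforms (16 samples x 4 channels at the
    default window and 20 kHz).
    """
    window = window or WaveformWindow()
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.ndim != 2 or w1.shape[0] != 4 or w2.ndim != 2 or w2.shape[0] != 4:
        raise ShapeError("waveforms must be (4, n_samples)")
    if peak_idx1 is None:
        peak_idx1 = int(np.unravel_index(np.argmin(w1), w1.shape)[1])
    if peak_idx2 is None:
        peak_idx2 = int(np.unravel_index(np.argmin(w2), w2.shape)[1])
    sl1 = window.slice_at(peak_idx1, fs)
    sl2 = window.slice_at(peak_idx2, fs)
    p1 = w1[:, sl1].min(axis=1)
    p2 = w2[:, sl2].min(axis=1)
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("zero peak pattern: direction cosine undefined")
    pattern_cos = float(p1 @ p2 / (n1 * n2))
    x1 = _concat_window(w1, peak_idx1, window, fs)
    x2 = _concat_window(w2, peak_idx2, window, fs)
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ParameterError("constant waveform: correlation undefined")
    waveform_r = float(np.corrcoef(x1, x2)[0, 1])
    return pattern_cos, waveform_r


def width_sweep_auc(
    success_pairs: list[tuple[np.ndarray, np.ndarray]],
    other_pairs: list[tuple[np.ndarray, np.ndarray]],
    max_width_samples: int = 10,
    fs: float = DEFAULT_FS,
) -> tuple[np.ndarray, tuple[int, int]]:
    """ROC discriminability of success vs other pairs from the evoked-trigger
    waveform correlation, swept over pre/post window widths of 0..10 samples
    (0-0.5 ms at 20 kHz).

    Each pair is ``(evoked_waveform, trigger_waveform)``, both ``(4, n)`` and
    peak-aligned. Returns the (11 x 11) AUC grid indexed ``[pre, post]`` and
    its argmax.
    """
    if not success_pairs or not other_pairs:
        raise ParameterError("both pair classes must be non-empty")
    dt_ms = 1000.0 / fs
    n = max_width_samples
    grid = np.empty((n + 1, n + 1))

    def corr_values(pairs, window):
        vals = []
        for w1, w2 in pairs:
            _, r = waveform_similarity(w1, w2, window=window, fs=fs)
            vals.append(r)
        return np.asarray(vals)

    del dt_ms
    for pre in range(n + 1):
        for post in range(n + 1):
            # pre = post = 0 degenerates to the correlation of the two
            # 4-vectors of peak amplitudes (one sample per channel)
            window = _IntWindow(pre, post)
            s_vals = corr_values(success_pairs, window)
            o_vals = corr_values(other_pairs, window)
            grid[pre, post] = roc_auc(s_vals, o_vals)
    best = np.unravel_index(int(np.argmax(grid)), grid.shape)
    return grid, (int(best[0]), int(best[1]))


class _IntWindow(WaveformWindow):
    """Waveform window specified directly in samples (for the width sweep)."""

    def __init__(self, pre_samples: int, post_samples: int):
        object.__setattr__(self, "pre_ms", float(pre_samples))
        object.__setattr__(self, "post_ms", float(post_samples))
        object.__setattr__(self, "n_channels", 4)
        self._pre = pre_samples
        self._post = post_samples

    def slice_at(self, peak_idx: int, fs: float = DEFAULT_FS) -> slice:
        return slice(peak_idx - self._pre, peak_idx + self._post + 1)


def group_test(values_a, values_b, kind: str = "ranksum"):
    """Thin pass-through to standard group-level tests (rank-sum, signed-rank,
    chi-square); provided for convenience, not independently validated."""
    if kind == "ranksum":
        return stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    if kind == "signed_rank":
        return stats.wilcoxon(values_a, values_b)
    if kind == "chi2":
        return stats.chi2_contingency(np.asarray([values_a, values_b]))
    raise ParameterError(f"unknown test kind {kind!r}")
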