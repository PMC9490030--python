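"""Filtering, spike detection and evoked-trace normalization.

Extracellular spikes appear as sharp negative deflections. Online-style
processing uses a causal one-sided exponential high-pass per channel,

    z_c(t) = x_c(t) - y_c(t),      y_c(t+1) = y_c(t) + G_y * z_c(t),

and compares, per tetrode, the squared amplitude of the rectified 4-channel
vector against a running variance estimate,

    zhat_c(t) = min(z_c(t), 0),    a(t) = sum_c zhat_c(t)^2,
    v(t+1)    = v(t) + G_v * (a(t) - v(t)),
    spike on  iff  a(t) > theta_sp^2 * v(t).

Within each maximal run of consecutive "spike on" samples exactly one spike
is emitted at the sample maximizing a(t) (earliest sample on ties).

Offline/semi-offline processing uses a zero-phase high-pass that subtracts a
Gaussian-smoothed copy of the signal (sigma = 0.25 ms by default), and evoked
traces are normalized into Z-scores by the pooled pre-stimulation noise level
of the tetrode.

Time convention: internal times are 0-based sample indices; interfaces report
milliseconds, with sub-sample fractions where values are interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import lfilter

from .errors import DivisionGuardError, ParameterError, ShapeError

__all__ = [
    "RecordingSegment",
    "FilterState",
    "DetectedSpike",
    "gain_from_timescale",
    "online_highpass",
    "gaussian_subtract_filter",
    "detect_spikes",
    "detect_spikes_recording",
    "normalize_evoked",
]

DEFAULT_FS = 20_000.0
#: averaging scales of the online filters (seconds)
DEFAULT_TAU_Y = 0.25e-3
DEFAULT_TAU_V = 1.0
DEFAULT_THETA_SP = 4.0


@dataclass
class RecordingSegment:
    """A multichannel recording block.

    Parameters
    ----------
    samples
        ``(n_samples, n_channels)`` amplitude matrix, arbitrary units.
    fs
        Sampling rate in samples/s.
    tetrodes
        List of tetrode groups; each group names exactly 4 channel indices.
        A channel may appear in at most one group.
    t0
        Session time of the first sample, in samples.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    tetrodes: list[tuple[int, int, int, int]] = field(default_factory=list)
    t0: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ShapeError("samples must be a 2-D (time x channel) matrix")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        seen: set[int] = set()
        n_ch = self.samples.shape[1]
        norm = []
        for group in self.tetrodes:
            group = tuple(int(c) for c in group)
            if len(group) != 4:
                raise ShapeError(f"tetrode {group} does not have exactly 4 channels")
            for c in group:
                if c in seen:
                    raise ShapeError(f"channel {c} appears in more than one tetrode")
                if not 0 <= c < n_ch:
                    raise ShapeError(f"channel {c} outside the sample matrix")
                seen.add(c)
            norm.append(group)
        self.tetrodes = norm

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def tetrode_samples(self, tetrode_id: int) -> np.ndarray:
        """Return the ``(n_samples, 4)`` sub-matrix of one tetrode."""
        return self.samples[:, list(self.tetrodes[tetrode_id])]


@dataclass
class FilterState:
    """Running state of the causal filters for one tetrode.

    ``y`` is the per-channel local average, ``v`` the per-tetrode running
    variance estimate of the rectified squared amplitude.
    """

    y: np.ndarray
    v: float
    gain_y: float
    gain_v: float

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if not 0.0 < self.gain_y <= 1.0:
            raise ParameterError("gain_y must lie in (0, 1]")
        if not 0.0 < self.gain_v <= 1.0:
            raise ParameterError("gain_v must lie in (0, 1]")
        if self.v < 0:
            raise ParameterError("v must be non-negative")


@dataclass(frozen=True)
class DetectedSpike:
    """One detected spike: time, rectified peak vector, squared amplitude."""

    t: int
    z_hat: np.ndarray
    a: float
    tetrode_id: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.z_hat, dtype=float)
        object.__setattr__(self, "z_hat", z)
        if z.shape != (4,):
            raise ShapeError("z_hat must be a 4-vector")
        if np.any(z > 0):
            raise ParameterError("z_hat components must be rectified (<= 0)")
        if not np.isclose(self.a, float(z @ z), rtol=1e-9, atol=1e-12):
            raise ParameterError("a must equal |z_hat|^2")


def gain_from_timescale(tau: float, fs: float = DEFAULT_FS) -> float:
    """Convert an averaging timescale to a one-sided exponential filter gain.

    ``gain = 1 / (tau * fs)``, clamped to at most 1. The defaults of the
    online filters are 0.25 ms (-> 0.2 at 20 kHz) for the signal average and
    1 s (-> 5e-5) for the variance average.
    """
    if tau <= 0 or fs <= 0:
        raise ParameterError("tau and fs must be positive")
    return min(1.0, 1.0 / (tau * fs))


def online_highpass(x: np.ndarray, state: FilterState) -> np.ndarray:
    """Causal single-pass high-pass: subtract the running local average.

    ``x`` is ``(n_samples,)`` or ``(n_samples, n_channels)``; the state's
    ``y`` must match the channel count. The state is advanced in place and the
    filtered stream (same shape as ``x``) is returned.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if state.y.shape != (x.shape[1],):
        raise ShapeError("state.y does not match the channel count")
    g = state.gain_y
    # y(t) = (1-G) y(t-1) + G x(t-1); realized as an order-1 IIR with a
    # one-sample delayed numerator so y(0) equals the stored state.
    y, zf = lfilter([0.0, g], [1.0, -(1.0 - g)], x, axis=0, zi=state.y[None, :])
    state.y = zf[0]
    z = x - y
    return z[:, 0] if squeeze else z


def gaussian_subtract_filter(
    x: np.ndarray, sigma: float = 0.25e-3, fs: float = DEFAULT_FS, axis: int = -1
) -> np.ndarray:
    """Zero-phase high-pass: subtract the Gaussian-smoothed signal.

    The kernel (sigma in seconds, default 0.25 ms) is truncated at +-4 sigma,
    renormalized to unit sum, and applied with reflected boundaries, so a
    constant input maps exactly to zero.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    x = np.asarray(x, dtype=float)
    s = sigma * fs
    radius = int(np.ceil(4.0 * s))
    lags = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (lags / s) ** 2)
    kernel /= kernel.sum()
    if x.shape[axis] <= radius:
        raise ParameterError("stream shorter than the truncated kernel support")
    smooth = ndimage.convolve1d(x, kernel, axis=axis, mode="reflect")
    return x - smooth


def detect_spikes(
    z: np.ndarray,
    state: FilterState,
    theta_sp: float = DEFAULT_THETA_SP,
    t0: int = 0,
    tetrode_id: int = 0,
) -> list[DetectedSpike]:
    """Detect spikes in a filtered 4-channel tetrode stream.

    Rectifies the stream, tracks the running variance ``v`` of the squared
    amplitude, and emits one spike per maximal supra-threshold run, at the
    sample maximizing ``a(t)`` (the earliest such sample on ties). The state's
    ``v`` is advanced in place. ``t0`` offsets reported spike times into
    session time.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != 4:
        raise ShapeError("z must be (n_samples, 4)")
    if theta_sp <= 0:
        raise ParameterError("theta_sp must be positive")
    z_hat = np.minimum(z, 0.0)
    a = np.einsum("ij,ij->i", z_hat, z_hat)
    gv = state.gain_v
    # v(t) = (1-Gv) v(t-1) + Gv a(t-1), seeded with the stored state.
    v, zf = lfilter([0.0, gv], [1.0, -(1.0 - gv)], a, zi=[state.v])
    state.v = float(zf[0])
    on = a > theta_sp**2 * v
    if not on.any():
        return []
    edges = np.flatnonzero(np.diff(on.astype(np.int8)))
    starts = list(np.flatnonzero(on[1:] & ~on[:-1]) + 1)
    if on[0]:
        starts.insert(0, 0)
    ends = list(np.flatnonzero(on[:-1] & ~on[1:]) + 1)
    if on[-1]:
        ends.append(len(on))
    del edges
    spikes = []
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(a[s:e]))
        spikes.append(
            DetectedSpike(t=t0 + k, z_hat=z_hat[k].copy(), a=float(a[k]), tetrode_id=tetrode_id)
        )
    return spikes


def detect_spikes_recording(
    segment: RecordingSegment,
    theta_sp: float = DEFAULT_THETA_SP,
    tau_y: float = DEFAULT_TAU_Y,
    tau_v: float = DEFAULT_TAU_V,
    warmup: float = 1.0,
) -> dict[int, list[DetectedSpike]]:
    """Run the online filter + detector over every tetrode of a recording.

    The local average is seeded with the first sample, the variance estimate
    with the mean squared rectified amplitude of the first ``warmup`` seconds,
    and detections within the warm-up period are discarded.
    """
    gy = gain_from_timescale(tau_y, segment.fs)
    gv = gain_from_timescale(tau_v, segment.fs)
    n_warm = min(int(round(warmup * segment.fs)), segment.n_samples)
    out: dict[int, list[DetectedSpike]] = {}
    for tid in range(len(segment.tetrodes)):
        x = segment.tetrode_samples(tid).astype(float)
        state = FilterState(y=x[0].copy(), v=0.0, gain_y=gy, gain_v=gv)
        z = online_highpass(x, state)
        z_hat = np.minimum(z[:n_warm], 0.0)
        a_warm = np.einsum("ij,ij->i", z_hat, z_hat)
        state.v = float(a_warm.mean()) if n_warm else 0.0
        spikes = detect_spikes(z, state, theta_sp=theta_sp, t0=segment.t0, tetrode_id=tid)
        out[tid] = [sp for sp in spikes if sp.t - segment.t0 >= n_warm]
    return out


def normalize_evoked(
    trials: np.ndarray, prestim: np.ndarray
) -> tuple[np.ndarray, float]:
    """Z-score aligned evoked traces by the pooled pre-stimulation noise.

    One noise level is estimated per tetrode, pooled over the 4 channels and
    over all trials (of all stimulation sites): the robust Gaussian SD
    ``median(|x|) / 0.6745`` of the filtered pre-stimulation segments. The
    median-based estimate equals the SD for pure Gaussian noise but is barely
    inflated by the spikes riding on the pre-stimulation baseline. Returns
    the normalized traces and the noise level.
    """
    trials = np.asarray(trials, dtype=float)
    prestim = np.asarray(prestim, dtype=float)
    if prestim.size == 0:
        raise ParameterError("at least one pre-stimulation segment is required")
    noise = robust_noise_level(prestim)
    if noise == 0.0:
        raise DivisionGuardError("pre-stimulation noise level is exactly zero")
    return trials / noise, noise


def robust_noise_level(x: np.ndarray) -> float:
    """Robust Gaussian noise SD of a (possibly spike-contaminated) signal:
    ``median(|x|) / 0.6745``."""
    return float(np.median(np.abs(np.asarray(x, dtype=float))) / 0.6745)
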