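"""Closed-loop collision-test controller emulation.

The online controller watches the detected-spike stream of every tetrode.
For each spike it evaluates the squared direction cosine to every collision
target of the same tetrode,

    D = (z_hat . u / |u|)^2 / a_k ,

and, if D exceeds theta_trig^2 for a target whose stimulation site respects
the minimum inter-stimulation intervals (I_same between same-site pulses,
I_diff between any two pulses), fires that site's stimulation with a fixed
emulated closed-loop latency (3.2 ms worst case by default). A target is
retired after N_test stimulations. When one spike matches several eligible
targets, only the highest-D target fires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from .infer import CollisionTarget
from .signal import DetectedSpike
from .simulate import StimulusEvent

__all__ = [
    "SessionConfig",
    "TriggerDecision",
    "StimulationLog",
    "trigger_similarity",
    "evaluate_trigger",
    "run_collision_session",
]


@dataclass
class SessionConfig:
    """Closed-loop session parameters (defaults are the standard values)."""

    theta_trig: float = 0.99
    n_test: int = 200
    i_same: float = 1.0  # s
    i_diff: float = 0.5  # s
    latency_ms: float = 3.2  # emulated spike-to-TTL-onset latency
    latency_budget_ms: float = 3.2
    t_range_ms: float = 30.0
    n_anti: int = 100
    duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_trig < 1.0:
            raise ParameterError("theta_trig must lie in (0, 1)")
        for name in ("n_test", "i_same", "i_diff", "t_range_ms", "n_anti", "duration_ms"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.latency_ms < 0 or self.latency_ms > self.latency_budget_ms:
            raise ParameterError("latency_ms must lie in [0, latency_budget_ms]")


@dataclass(frozen=True)
class TriggerDecision:
    """Evaluation of one spike against one target."""

    spike_t: float  # sample
    target_index: int
    D: float
    fired: bool
    onset: float | None = None  # scheduled stimulation onset (sample)
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0 + 1e-12:
            raise ParameterError("D must lie in [0, 1]")


@dataclass
class StimulationLog:
    """Outcome of a closed-loop session."""

    events: list[StimulusEvent]
    decisions: list[TriggerDecision]
    counts: np.ndarray  # per-target stimulation counts
    fs: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": ev.site,
                "t_stim": ev.t_stim,
                "t_off_ms": ev.t_off_ms(self.fs),
                "triggered_by": ev.triggered_by,
                "target": d.target_index,
                "D": d.D,
            }
            for ev, d in zip(self.events, self.decisions)
        ]
        return pd.DataFrame(
            rows, columns=["site", "t_stim", "t_off_ms", "triggered_by", "target", "D"]
        )


def trigger_similarity(z_hat, a_k: float, u) -> float:
    """Squared direction cosine between a spike's rectified peak vector and a
    target peak pattern: D = (z_hat . u)^2 / (|u|^2 a_k), in [0, 1] and
    invariant to positive rescaling of either vector."""
    z_hat = np.asarray(z_hat, dtype=float)
    u = np.asarray(u, dtype=float)
    if z_hat.shape != u.shape:
        raise ShapeError("z_hat and u must have the same shape")
    uu = float(u @ u)
    if a_k <= 0 or uu == 0:
        raise ParameterError("similarity of a zero vector is undefined")
    return float(z_hat @ u) ** 2 / (uu * a_k)


def evaluate_trigger(
    spike: DetectedSpike, target: CollisionTarget, target_index: int, cfg: SessionConfig, fs: float
) -> TriggerDecision:
    """Score one spike against one target (no interval bookkeeping)."""
    d = trigger_similarity(spike.z_hat, spike.a, target.u)
    fired = d > cfg.theta_trig**2
    onset = spike.t + cfg.latency_ms * fs / 1000.0 if fired else None
    return TriggerDecision(
        spike_t=float(spike.t),
        target_index=target_index,
        D=min(d, 1.0),
        fired=fired,
        onset=onset,
        latency_ms=cfg.latency_ms if fired else None,
    )


def run_collision_session(
    spike_times: np.ndarray,
    spike_tetrodes: np.ndarray,
    spike_z: np.ndarray,
    targets: list[CollisionTarget],
    cfg: SessionConfig,
    fs: float,
    initial_last_stim: dict[int, float] | None = None,
) -> StimulationLog:
    """Emulate a closed-loop collision-test session over a spike stream.

    Parameters
    ----------
    spike_times, spike_tetrodes, spike_z
        Time-ordered detected spikes: times in samples, tetrode ids, and
        rectified 4-channel peak vectors ``(n, 4)``.
    targets
        Collision targets (typically from the online inference step).
    initial_last_stim
        Optional per-site time (samples) of the last earlier stimulation, so
        the interval constraints also hold across a phase boundary.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    spike_tetrodes = np.asarray(spike_tetrodes, dtype=int)
    spike_z = np.asarray(spike_z, dtype=float)
    if spike_z.ndim != 2 or spike_z.shape[1] != 4:
        raise ShapeError("spike_z must be (n, 4)")
    if np.any(np.diff(spike_times) < 0):
        raise ParameterError("spike stream must be time-ordered")

    by_tet: dict[int, list[int]] = {}
    for j, tg in enumerate(targets):
        by_tet.setdefault(tg.tetrode_id, []).append(j)
    u_unit = np.array(
        [tg.u / np.linalg.norm(tg.u) if np.linalg.norm(tg.u) else tg.u for tg in targets]
    )
    sites = np.array([tg.site for tg in targets])
    all_sites = sorted(set(sites.tolist()))
    last = {s: -math.inf for s in all_sites}
    if initial_last_stim:
        last.update(initial_last_stim)

    lat = cfg.latency_ms * fs / 1000.0
    same = cfg.i_same * fs
    diff = cfg.i_diff * fs
    theta2 = cfg.theta_trig**2
    counts = np.zeros(len(targets), dtype=int)
    events: list[StimulusEvent] = []
    decisions: list[TriggerDecision] = []
    active = np.ones(len(targets), dtype=bool)

    for t, tet, z in zip(spike_times, spike_tetrodes, spike_z):
        idx = by_tet.get(int(tet))
        if not idx or not active.any():
            continue
        onset = t + lat
        eligible_sites = {
            s
            for s in all_sites
            if onset - last[s] >= same and all(onset - last[o] >= diff for o in all_sites if o != s)
        }
        if not eligible_sites:
            continue
        cand = [j for j in idx if active[j] and sites[j] in eligible_sites]
        if not cand:
            continue
        a = float(z @ z)
        if a <= 0:
            continue
        dvals = (u_unit[cand] @ z) ** 2 / a
        best = int(np.argmax(dvals))
        if dvals[best] <= theta2:
            continue
        j = cand[best]
        site = int(sites[j])
        events.append(
            StimulusEvent(
                site=site,
                # floor keeps the onset within the latency budget even for
                # sub-sample trigger times
                t_stim=int(math.floor(onset)),
                duration_ms=cfg.duration_ms,
                triggered_by=float(t),
            )
        )
        decisions.append(
            TriggerDecision(
                spike_t=float(t),
                target_index=j,
                D=min(float(dvals[best]), 1.0),
                fired=True,
                onset=float(onset),
                latency_ms=cfg.latency_ms,
            )
        )
        last[site] = onset
        counts[j] += 1
        if counts[j] >= cfg.n_test:
            active[j] = False
    return StimulationLog(events=events, decisions=decisions, counts=counts, fs=fs)
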