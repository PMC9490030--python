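"""Ground-truth simulator of collision-test sessions.

Generates labeled multichannel tetrode recordings: spontaneous spike trains,
optogenetic stimulation schedules, antidromically and synaptically evoked
spikes, and the axonal collision / refractory elimination physics.

Physics
-------
An antidromic spike evoked by a stimulation at ``t_stim`` initiates at the
stimulation site after the evoking delay ``d`` and arrives at the recorded
soma after the conduction time ``C`` (plus trial-to-trial jitter applied to
the arrival only; ``d`` and ``C`` are axonal properties and fixed per
projection):

* refractory elimination (antidromic AND synaptic spikes): a somatic spike at
  ``t_spon`` in ``[t_A - R, t_A)`` leaves the soma refractory at the arrival
  time ``t_A``.
* collision elimination (antidromic only): a spontaneous spike travelling
  down the axon annihilates the antidromic spike if it has not yet cleared
  the stimulation site, i.e. ``t_spon + C + R' >= t_stim + d`` with
  ``t_spon <= t_A``, where ``R'`` is the axonal refractory period.

When both rules fire, the reported cause is ``collision``.

Times inside this module are session milliseconds (float); stimulation onsets
are also carried as sample indices for the recording interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SchedulingError, ShapeError
from .signal import DEFAULT_FS, RecordingSegment

__all__ = [
    "SpikeTemplate",
    "Projection",
    "SynapticInput",
    "SimNeuron",
    "StimulusEvent",
    "SimGroundTruth",
    "SimConfig",
    "EvokedOutcome",
    "schedule_stimulations",
    "evoked_spike_outcome",
    "make_ground_truth",
    "ground_truth_from_trains",
    "append_stimulations",
    "render_recording",
    "render_evoked_trials",
    "study_population",
    "default_config",
]


@dataclass(frozen=True)
class SpikeTemplate:
    """Analytic biphasic extracellular waveform: negative trough, later
    positive peak.

    Difference of two Gaussians, normalized to trough depth -1 at offset 0.
    Defaults give a wide, projection-like shape (0.7 ms trough to peak); the
    narrow fast-spiking-like variant uses 0.3 ms. The analytic form allows
    rendering events at sub-sample times.
    """

    trough_to_peak_ms: float = 0.7
    trough_sigma_ms: float | None = None
    peak_sigma_ms: float | None = None
    peak_ratio: float = 0.35

    def __post_init__(self) -> None:
        if self.trough_to_peak_ms <= 0:
            raise ParameterError("trough_to_peak_ms must be positive")
        if self.trough_sigma_ms is None:
            object.__setattr__(self, "trough_sigma_ms", self.trough_to_peak_ms / 4.0)
        if self.peak_sigma_ms is None:
            object.__setattr__(self, "peak_sigma_ms", 2.0 * self.trough_sigma_ms)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Waveform value at offsets ``t_ms`` (ms) from the trough."""
        t = np.asarray(t_ms, dtype=float)
        st, sp = self.trough_sigma_ms, self.peak_sigma_ms
        ttp, r = self.trough_to_peak_ms, self.peak_ratio
        raw = -np.exp(-0.5 * (t / st) ** 2) + r * np.exp(-0.5 * ((t - ttp) / sp) ** 2)
        depth = 1.0 - r * math.exp(-0.5 * (ttp / sp) ** 2)
        return raw / depth

    @property
    def support_ms(self) -> tuple[float, float]:
        return (-4.0 * self.trough_sigma_ms, self.trough_to_peak_ms + 4.0 * self.peak_sigma_ms)

    def sample(self, fs: float = DEFAULT_FS, pre_ms: float | None = None, post_ms: float | None = None) -> np.ndarray:
        """Sample the template on the grid, trough on a sample."""
        lo, hi = self.support_ms
        pre = lo if pre_ms is None else -pre_ms
        post = hi if post_ms is None else post_ms
        n0 = int(math.floor(pre * fs / 1000.0))
        n1 = int(math.ceil(post * fs / 1000.0))
        return self.evaluate(np.arange(n0, n1 + 1) * 1000.0 / fs)


@dataclass(frozen=True)
class Projection:
    """Axonal projection of a neuron to a stimulation site."""

    site: int
    d: float  # evoking delay at the stimulation site (ms)
    C: float  # conduction time through the axon (ms)
    jitter_sd: float = 0.05  # antidromic arrival jitter SD (ms)
    r_prime: float = 1.0  # axonal refractory period (ms)

    def __post_init__(self) -> None:
        if self.d <= 0 or self.C <= 0:
            raise ParameterError("d and C must be positive")
        if self.jitter_sd < 0 or self.r_prime < 0:
            raise ParameterError("jitter_sd and r_prime must be non-negative")

    @property
    def latency(self) -> float:
        """Stimulation-to-soma latency L = d + C (ms)."""
        return self.d + self.C


@dataclass(frozen=True)
class SynapticInput:
    """Polysynaptic drive from a stimulation site onto a neuron."""

    site: int
    latency: float  # ms
    jitter_qd: float = 1.0  # quartile deviation of the evoked latency (ms)
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.latency <= 0:
            raise ParameterError("latency must be positive")
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError("probability must lie in [0, 1]")


@dataclass
class SimNeuron:
    """A simulated unit with its projection geometry and waveform."""

    id: int
    tetrode_id: int
    amp_pattern: np.ndarray  # 4-vector of non-positive peak amplitudes (noise-SD units)
    template: SpikeTemplate = field(default_factory=SpikeTemplate)
    rate: float = 10.0  # spontaneous Poisson rate (Hz)
    r: float = 2.8  # somatic refractory period (ms)
    projections: list[Projection] = field(default_factory=list)
    synaptic_inputs: list[SynapticInput] = field(default_factory=list)
    evoked_scale: float = 1.2  # evoked / spontaneous amplitude ratio
    label: str = "unrelated"

    def __post_init__(self) -> None:
        self.amp_pattern = np.asarray(self.amp_pattern, dtype=float)
        if self.amp_pattern.shape != (4,):
            raise ShapeError("amp_pattern must be a 4-vector")
        if np.any(self.amp_pattern > 0):
            raise ParameterError("amp_pattern components must be non-positive")
        if self.rate < 0:
            raise ParameterError("rate must be non-negative")
        if self.r <= 0:
            raise ParameterError("refractory period r must be positive")
        if self.evoked_scale < 1.0:
            raise ParameterError("evoked_scale must be >= 1")


@dataclass
class StimulusEvent:
    """One optogenetic stimulation: site, onset and light-pulse duration."""

    site: int
    t_stim: int  # onset, sample index
    duration_ms: float = 1.0
    triggered_by: float | None = None  # trigger spike time (sample), if closed-loop

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ParameterError("duration must be positive (t_off > t_stim)")

    def t_stim_ms(self, fs: float) -> float:
        return self.t_stim * 1000.0 / fs

    def t_off_ms(self, fs: float) -> float:
        return self.t_stim_ms(fs) + self.duration_ms


@dataclass(frozen=True)
class EvokedOutcome:
    present: bool
    cause: str  # 'none' | 'collision' | 'refractory'


@dataclass
class SimConfig:
    """Full description of a simulated session."""

    neurons: list[SimNeuron]
    sites: list[int]
    n_tetrodes: int
    session_length: float = 600.0  # seconds
    fs: float = DEFAULT_FS
    n_anti: int = 100
    i_same: float = 1.0  # s
    i_diff: float = 0.5  # s
    duration_ms: float = 1.0  # light pulse duration D_i (all sites)
    noise_sd: float = 1.0
    t_range_ms: float = 30.0
    collection_start: float = 1.0  # s

    def validate(self) -> None:
        if self.n_tetrodes <= 0:
            raise ParameterError("config field n_tetrodes must be positive")
        if not self.sites:
            raise ParameterError("config field sites must be non-empty")
        if self.session_length <= 0:
            raise ParameterError("config field session_length must be positive")
        if self.n_anti <= 0:
            raise ParameterError("config field n_anti must be positive")
        if self.noise_sd < 0:
            raise ParameterError("config field noise_sd must be non-negative")
        for n in self.neurons:
            if not 0 <= n.tetrode_id < self.n_tetrodes:
                raise ParameterError(f"config field neurons: tetrode_id {n.tetrode_id} out of range")
            for p in n.projections:
                if p.site not in self.sites:
                    raise ParameterError(f"config field neurons: projection site {p.site} unknown")


@dataclass
class SimGroundTruth:
    """Labeled events of a simulated session.

    ``events`` columns: neuron, t_ms (session ms), kind
    ('spontaneous'|'antidromic'|'synaptic'), eliminated (bool), cause
    ('none'|'collision'|'refractory'), stim_index (-1 for spontaneous).
    """

    config: SimConfig
    neurons: list[SimNeuron]
    events: pd.DataFrame
    schedule: list[StimulusEvent]
    spont_trains: dict[int, np.ndarray]  # neuron id -> sorted spike times (ms)
    seed: int

    @property
    def fs(self) -> float:
        return self.config.fs

    def neuron_spike_times_ms(self, neuron_id: int) -> np.ndarray:
        """All observable spikes of a unit: spontaneous plus surviving evoked.

        This is what an (idealized) spike-sorting cluster for the unit would
        contain, and is the judgment module's per-neuron input.
        """
        ev = self.events
        sel = (ev["neuron"] == neuron_id) & ~ev["eliminated"]
        return np.sort(ev.loc[sel, "t_ms"].to_numpy())


def schedule_stimulations(
    sites: list[int],
    i_same: float = 1.0,
    i_diff: float = 0.5,
    n_anti: int = 100,
    session_length: float = 600.0,
    seed: int | np.random.Generator = 0,
    fs: float = DEFAULT_FS,
    duration_ms: float = 1.0,
    start: float = 1.0,
) -> list[StimulusEvent]:
    """Serial site rotation with randomized timing.

    Every same-site gap is at least ``i_same`` seconds, every gap at least
    ``i_diff`` seconds, and each site receives exactly ``n_anti`` events.
    Raises :class:`SchedulingError` if the events do not fit in
    ``session_length`` seconds.
    """
    if not sites:
        raise ParameterError("at least one stimulation site is required")
    if i_same <= 0 or i_diff <= 0:
        raise ParameterError("intervals must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    last_any = start - i_diff
    last_site = {s: -math.inf for s in sites}
    events: list[StimulusEvent] = []
    for _ in range(n_anti):
        for s in sites:
            t = max(last_any + i_diff, last_site[s] + i_same) + rng.uniform(0.0, 0.25)
            if t > session_length - 0.05:
                raise SchedulingError(
                    f"cannot fit {n_anti} stimulations per site into {session_length} s"
                )
            events.append(
                StimulusEvent(site=s, t_stim=int(round(t * fs)), duration_ms=duration_ms)
            )
            last_any = t
            last_site[s] = t
    return events


def evoked_spike_outcome(
    projection,
    t_stim: float,
    t_off: float,
    spont_times: np.ndarray,
    kind: str = "antidromic",
    arrival: float | None = None,
) -> EvokedOutcome:
    """Decide whether one evoked spike survives, and why not otherwise.

    ``projection`` is a mapping or object with fields ``d``, ``C``, ``R`` and
    ``R_prime`` (all ms); ``spont_times`` the neuron's sorted spontaneous
    spike times (ms). ``arrival`` overrides the nominal soma arrival
    ``t_stim + d + C`` (e.g. to add jitter). Collision takes precedence over
    refractory elimination when both rules fire.
    """
    if kind not in ("antidromic", "synaptic"):
        raise ParameterError(f"unknown evoked kind {kind!r}")
    if isinstance(projection, dict):
        d, C, R, r_prime = (projection[k] for k in ("d", "C", "R", "R_prime"))
    else:
        d, C = projection.d, projection.C
        R = getattr(projection, "R", None) or getattr(projection, "r")
        r_prime = getattr(projection, "R_prime", None) or getattr(projection, "r_prime")
    sp = np.asarray(spont_times, dtype=float)
    t_a = t_stim + d + C if arrival is None else arrival

    collided = False
    if kind == "antidromic":
        lo = t_stim + d - C - r_prime
        i0 = np.searchsorted(sp, lo, side="left")
        i1 = np.searchsorted(sp, t_a, side="right")
        collided = i1 > i0
    i0 = np.searchsorted(sp, t_a - R, side="left")
    i1 = np.searchsorted(sp, t_a, side="left")
    refractory = i1 > i0
    if collided:
        return EvokedOutcome(False, "collision")
    if refractory:
        return EvokedOutcome(False, "refractory")
    return EvokedOutcome(True, "none")


def _spontaneous_train(rate: float, r_ms: float, t_end_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson train with dead-time thinning: ISI = r + Exp(1/rate)."""
    if rate <= 0:
        return np.empty(0)
    mean_isi = 1000.0 / rate
    n_guess = int(t_end_ms / (mean_isi + r_ms) * 1.3) + 20
    times = np.cumsum(r_ms + rng.exponential(mean_isi, size=n_guess))
    while times.size and times[-1] < t_end_ms:
        extra = times[-1] + np.cumsum(r_ms + rng.exponential(mean_isi, size=n_guess))
        times = np.concatenate([times, extra])
    return times[times < t_end_ms]


def _evoked_events_for_neuron(
    neuron: SimNeuron,
    schedule: list[StimulusEvent],
    stim_offset: int,
    spont: np.ndarray,
    fs: float,
    rng: np.random.Generator,
) -> list[tuple]:
    """Rows (neuron, t_ms, kind, eliminated, cause, stim_index)."""
    rows: list[tuple] = []
    for proj in neuron.projections:
        for j, st in enumerate(schedule):
            if st.site != proj.site:
                continue
            ts = st.t_stim_ms(fs)
            arrival = ts + proj.d + proj.C + rng.normal(0.0, proj.jitter_sd)
            out = evoked_spike_outcome(
                {"d": proj.d, "C": proj.C, "R": neuron.r, "R_prime": proj.r_prime},
                ts,
                st.t_off_ms(fs),
                spont,
                kind="antidromic",
                arrival=arrival,
            )
            rows.append(
                (neuron.id, arrival, "antidromic", not out.present, out.cause, stim_offset + j)
            )
    for syn in neuron.synaptic_inputs:
        for j, st in enumerate(schedule):
            if st.site != syn.site:
                continue
            if rng.uniform() >= syn.probability:
                continue
            ts = st.t_stim_ms(fs)
            arrival = ts + syn.latency + rng.normal(0.0, syn.jitter_qd / 0.6745)
            out = evoked_spike_outcome(
                {"d": syn.latency, "C": 0.0, "R": neuron.r, "R_prime": 0.0},
                ts,
                st.t_off_ms(fs),
                spont,
                kind="synaptic",
                arrival=arrival,
            )
            rows.append(
                (neuron.id, arrival, "synaptic", not out.present, out.cause, stim_offset + j)
            )
    return rows


_EVENT_COLUMNS = ["neuron", "t_ms", "kind", "eliminated", "cause", "stim_index"]


def _event_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df = df.astype(
        {"neuron": int, "t_ms": float, "kind": str, "eliminated": bool, "cause": str, "stim_index": int}
    )
    return df.sort_values("t_ms", kind="stable").reset_index(drop=True)


def make_ground_truth(
    config: SimConfig, seed: int, schedule: list[StimulusEvent] | None = None
) -> SimGroundTruth:
    """Simulate a full labeled session (reproducible for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = schedule_stimulations(
            config.sites,
            i_same=config.i_same,
            i_diff=config.i_diff,
            n_anti=config.n_anti,
            session_length=config.session_length,
            seed=rng,
            fs=config.fs,
            duration_ms=config.duration_ms,
            start=config.collection_start,
        )
    t_end_ms = config.session_length * 1000.0
    rows: list[tuple] = []
    spont_trains: dict[int, np.ndarray] = {}
    for neuron in config.neurons:
        spont = _spontaneous_train(neuron.rate, neuron.r, t_end_ms, rng)
        spont_trains[neuron.id] = spont
        rows.extend((neuron.id, t, "spontaneous", False, "none", -1) for t in spont)
        rows.extend(
            _evoked_events_for_neuron(neuron, schedule, 0, spont, config.fs, rng)
        )
    return SimGroundTruth(
        config=config,
        neurons=list(config.neurons),
        events=_event_frame(rows),
        schedule=list(schedule),
        spont_trains=spont_trains,
        seed=seed,
    )


def ground_truth_from_trains(
    config: SimConfig,
    trains: dict[int, np.ndarray],
    seed: int = 0,
    schedule: list[StimulusEvent] | None = None,
) -> SimGroundTruth:
    """Build a labeled session from hand-crafted spontaneous trains.

    Useful for deterministic fixtures: evoked outcomes are evaluated against
    the given trains (sorted ms) instead of sampled Poisson activity.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = schedule_stimulations(
            config.sites,
            i_same=config.i_same,
            i_diff=config.i_diff,
            n_anti=config.n_anti,
            session_length=config.session_length,
            seed=rng,
            fs=config.fs,
            duration_ms=config.duration_ms,
            start=config.collection_start,
        )
    rows: list[tuple] = []
    spont_trains: dict[int, np.ndarray] = {}
    for neuron in config.neurons:
        spont = np.sort(np.asarray(trains.get(neuron.id, np.empty(0)), dtype=float))
        spont_trains[neuron.id] = spont
        rows.extend((neuron.id, t, "spontaneous", False, "none", -1) for t in spont)
        rows.extend(_evoked_events_for_neuron(neuron, schedule, 0, spont, config.fs, rng))
    return SimGroundTruth(
        config=config,
        neurons=list(config.neurons),
        events=_event_frame(rows),
        schedule=list(schedule),
        spont_trains=spont_trains,
        seed=seed,
    )


def append_stimulations(
    truth: SimGroundTruth, new_stims: list[StimulusEvent], rng: np.random.Generator
) -> SimGroundTruth:
    """Extend a session with additional (e.g. closed-loop) stimulations.

    Evoked outcomes for the new stimulations are evaluated against the
    existing spontaneous trains; the combined schedule is kept sorted.
    """
    offset = len(truth.schedule)
    rows: list[tuple] = []
    for neuron in truth.neurons:
        rows.extend(
            _evoked_events_for_neuron(
                neuron, new_stims, offset, truth.spont_trains[neuron.id], truth.fs, rng
            )
        )
    events = _event_frame(
        list(truth.events.itertuples(index=False, name=None)) + rows
    )
    return SimGroundTruth(
        config=truth.config,
        neurons=truth.neurons,
        events=events,
        schedule=truth.schedule + list(new_stims),
        spont_trains=truth.spont_trains,
        seed=truth.seed,
    )


def _tetrode_event_arrays(truth: SimGroundTruth):
    """Per-tetrode sorted (times_ms, amp (n,4)) for non-eliminated events."""
    by_id = {n.id: n for n in truth.neurons}
    ev = truth.events
    live = ev[~ev["eliminated"]]
    out = {}
    for tid in range(truth.config.n_tetrodes):
        ids = [n.id for n in truth.neurons if n.tetrode_id == tid]
        sub = live[live["neuron"].isin(ids)]
        t = sub["t_ms"].to_numpy()
        amps = np.empty((len(sub), 4))
        templates = []
        for i, (nid, kind) in enumerate(zip(sub["neuron"], sub["kind"])):
            n = by_id[nid]
            scale = 1.0 if kind == "spontaneous" else n.evoked_scale
            amps[i] = n.amp_pattern * scale
            templates.append(n.template)
        order = np.argsort(t, kind="stable")
        out[tid] = (t[order], amps[order], [templates[i] for i in order])
    return out


def _add_event(buf: np.ndarray, t_ms: float, amps: np.ndarray, template: SpikeTemplate, fs: float, t0_ms: float = 0.0) -> None:
    """Add one analytic waveform into ``buf`` (n_samples, 4).

    ``amps`` are the (non-positive) trough values per channel; the template's
    trough is normalized to -1, so the channel waveform is ``|amp| * w``.
    """
    lo, hi = template.support_ms
    rel = t_ms - t0_ms
    i0 = max(0, int(math.ceil((rel + lo) * fs / 1000.0)))
    i1 = min(buf.shape[0] - 1, int(math.floor((rel + hi) * fs / 1000.0)))
    if i1 < i0:
        return
    offs = np.arange(i0, i1 + 1) * 1000.0 / fs - rel
    buf[i0 : i1 + 1] += np.outer(template.evaluate(offs), np.abs(amps))


def render_recording(
    truth: SimGroundTruth,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> RecordingSegment:
    """Render the whole session as a continuous recording.

    Additive model: Gaussian noise plus each non-eliminated event's template
    scaled by the neuron's amplitude pattern (times ``evoked_scale`` for
    evoked kinds). Eliminated events render nothing.
    """
    cfg = truth.config
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    fs = cfg.fs
    n_samples = int(round(cfg.session_length * fs))
    n_ch = 4 * cfg.n_tetrodes
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    samples = (
        rng.normal(0.0, sd, size=(n_samples, n_ch)) if sd > 0 else np.zeros((n_samples, n_ch))
    )
    per_tet = _tetrode_event_arrays(truth)
    for tid, (times, amps, templates) in per_tet.items():
        view = samples[:, 4 * tid : 4 * tid + 4]
        for t, a, tpl in zip(times, amps, templates):
            _add_event(view, t, a, tpl, fs)
    tetrodes = [tuple(range(4 * t, 4 * t + 4)) for t in range(cfg.n_tetrodes)]
    return RecordingSegment(samples=samples, fs=fs, tetrodes=tetrodes, t0=0)


def render_evoked_trials(
    truth: SimGroundTruth,
    tetrode_id: int,
    stims: list[StimulusEvent],
    t_range_ms: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render raw peri-stimulus windows ``(n_trials, 4, 2*T+1)`` for one
    tetrode, spanning ``[-t_range, +t_range]`` around each onset.

    Only the window contents are synthesized (fresh noise per trial), which
    makes long sessions tractable; stimulations are far enough apart that
    windows never overlap in the default configuration.
    """
    cfg = truth.config
    fs = cfg.fs
    tr = cfg.t_range_ms if t_range_ms is None else t_range_ms
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    rng = rng or np.random.default_rng(truth.seed + 2)
    half = int(round(tr * fs / 1000.0))
    n_t = 2 * half + 1
    times, amps, templates = _tetrode_event_arrays(truth)[tetrode_id]
    margin = max((tpl.support_ms[1] - tpl.support_ms[0]) for tpl in templates) if templates else 2.0
    out = (
        rng.normal(0.0, sd, size=(len(stims), 4, n_t))
        if sd > 0
        else np.zeros((len(stims), 4, n_t))
    )
    for i, st in enumerate(stims):
        ts = st.t_stim_ms(fs)
        lo = np.searchsorted(times, ts - tr - margin)
        hi = np.searchsorted(times, ts + tr + margin)
        buf = np.zeros((n_t, 4))
        for j in range(lo, hi):
            _add_event(buf, times[j], amps[j], templates[j], fs, t0_ms=ts - half * 1000.0 / fs)
        out[i] += buf.T
    return out


def _amp_pattern(rng: np.random.Generator, lo: float = 15.0, hi: float = 40.0) -> np.ndarray:
    """Biased 4-channel peak pattern with the dominant trough in [lo, hi]
    noise-SD units.

    Extracellular amplitude falls off steeply with distance from each
    electrode tip, so a single unit's tetrode pattern is strongly biased
    toward its nearest channels; a Dirichlet draw with concentration < 1
    reproduces that bias (nearly flat patterns would make distinct units
    almost collinear in pattern space, which real tetrodes do not show).
    """
    dominant = rng.uniform(lo, hi)
    w = rng.dirichlet(np.full(4, 0.5))
    w /= w.max()
    return -dominant * w


def study_population(
    rng: np.random.Generator,
    sites: list[int],
    n_tetrodes: int = 2,
    n_projection: int = 20,
    n_synaptic: int = 6,
    n_unrelated: int = 6,
    latency_range: tuple[float, float] = (5.0, 15.0),
    proj_jitter_sd: float = 0.05,
    syn_jitter_qd_min: float = 1.0,
    evoking_delay: float = 0.7,
    r_soma: float = 2.8,
    r_axon: float = 1.0,
) -> list[SimNeuron]:
    """Build the standard mixed population: projection neurons with tight
    antidromic latencies, synaptic responders with broad evoked jitter, and
    unrelated units (a quarter of them narrow, fast-spiking-like).

    Projection latencies are spread evenly over ``latency_range`` and
    interleaved across (tetrode, site) combinations so that same-combination
    latencies stay well separated.
    """
    wide = SpikeTemplate(trough_to_peak_ms=0.7)
    narrow = SpikeTemplate(trough_to_peak_ms=0.3)
    neurons: list[SimNeuron] = []
    nid = 0
    lats = np.linspace(latency_range[0], latency_range[1], n_projection)
    for i in range(n_projection):
        tet = i % n_tetrodes
        site = sites[(i // n_tetrodes) % len(sites)]
        neurons.append(
            SimNeuron(
                id=nid,
                tetrode_id=tet,
                amp_pattern=_amp_pattern(rng),
                template=wide,
                # modest rates keep chance collision elimination of a
                # projection's own antidromic spikes well below 25% of trials
                rate=rng.uniform(2.5, 5.0),
                r=r_soma,
                projections=[
                    Projection(
                        site=site,
                        d=evoking_delay,
                        C=float(lats[i]) - evoking_delay,
                        jitter_sd=proj_jitter_sd,
                        r_prime=r_axon,
                    )
                ],
                label="projection",
            )
        )
        nid += 1
    for i in range(n_synaptic):
        tet = i % n_tetrodes
        site = sites[(i // n_tetrodes) % len(sites)]
        neurons.append(
            SimNeuron(
                id=nid,
                tetrode_id=tet,
                amp_pattern=_amp_pattern(rng),
                template=wide,
                rate=rng.uniform(4.0, 8.0),
                r=r_soma,
                synaptic_inputs=[
                    SynapticInput(
                        site=site,
                        latency=float(rng.uniform(6.0, 14.0)),
                        jitter_qd=syn_jitter_qd_min + 0.4 * (i % 4),
                        probability=0.65,
                    )
                ],
                label="synaptic",
            )
        )
        nid += 1
    for i in range(n_unrelated):
        fast = i % 3 == 2
        neurons.append(
            SimNeuron(
                id=nid,
                tetrode_id=i % n_tetrodes,
                amp_pattern=_amp_pattern(rng),
                template=narrow if fast else wide,
                rate=rng.uniform(8.0, 16.0) if fast else rng.uniform(4.0, 10.0),
                r=r_soma,
                label="fast_spiking" if fast else "unrelated",
            )
        )
        nid += 1
    return neurons


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default synthetic study: 2 tetrodes, 3 sites, 100 stimulations per
    site plus a closed-loop test phase; 20 projection neurons (latencies
    5-15 ms, jitter SD 0.05 ms) yielding 20 true pairs, 6 synaptic responders
    (jitter QD >= 1 ms, ~20 responder pairs) and 6 unrelated units (60
    unrelated pairs)."""
    rng = np.random.default_rng(seed)
    sites = [0, 1, 2]
    pop_keys = {
        k: overrides.pop(k)
        for k in list(overrides)
        if k in ("n_projection", "n_synaptic", "n_unrelated", "proj_jitter_sd", "syn_jitter_qd_min")
    }
    n_tetrodes = overrides.pop("n_tetrodes", 2)
    neurons = study_population(rng, sites, n_tetrodes=n_tetrodes, **pop_keys)
    cfg = SimConfig(neurons=neurons, sites=sites, n_tetrodes=n_tetrodes, **overrides)
    cfg.validate()
    return cfg
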