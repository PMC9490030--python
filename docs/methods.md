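# Methods

This note documents the models, parameters and numerical choices behind
`spikecollide`, in the spirit of a methods section: what each stage assumes,
which knobs matter, what the simulator does and does not emulate, and where
the design was genuinely open.

## Signal model and online detection

Extracellular spikes are sharp negative deflections riding on slow field
potentials. The online path uses a causal one-sided exponential high-pass per
channel,

    z_c(t) = x_c(t) − y_c(t),   y_c(t+1) = y_c(t) + G_y · z_c(t),

with `G_y = 1/(τ_y · fs)` (default τ_y = 0.25 ms → G_y = 0.2 at 20 kHz).
Detection is per tetrode: channels are rectified (`ẑ_c = min(z_c, 0)`), the
squared amplitude `a(t) = Σ_c ẑ_c²(t)` is compared against a running variance
estimate `v(t+1) = v(t) + G_v (a(t) − v(t))` (τ_v = 1 s → G_v = 5×10⁻⁵), and
`a(t) > θ_sp² v(t)` (θ_sp = 4 SD) switches "spike on". One spike is emitted
per maximal supra-threshold run, at the sample maximizing `a(t)` (earliest on
ties, for determinism). Warm-up: `y` is seeded with the first sample and `v`
with the mean rectified squared amplitude of the first second; detections in
that second are discarded. The recursions are exact order-1 IIR filters and
are evaluated as such (single pass, no look-ahead).

The causal filter distorts waveforms slightly (the rectified trough can shift
by 1–2 samples, and a large positive after-lobe produces a small negative
rebound that can re-cross threshold for very large spikes). Offline and
semi-offline analyses therefore use a zero-phase high-pass that subtracts a
Gaussian-smoothed copy of the signal (σ = 0.25 ms, kernel truncated at ±4σ
and renormalized to unit sum, reflected boundaries — a constant input maps
exactly to zero).

Evoked responses are Z-scored by one noise level per tetrode, pooled over the
4 channels and the pre-stimulation halves of all trials of all sites. The
estimator is the robust Gaussian SD `median(|x|)/0.6745`: it equals the SD on
pure noise but, unlike a pooled RMS, is only marginally inflated by the
spikes that ride on every real pre-stimulation baseline (a pooled RMS grows
with background rate and would compress all Z amplitudes).

## Antidromic-spike inference

Both protocols operate on Z-scored trials of one (tetrode, site) pair aligned
to stimulation onset, searching `(0, T_range]` (T_range = 30 ms); spikes
during the light pulse are eligible because optogenetic stimulation has no
electrical artifact.

**Protocol I (window search).** A window of fixed width (2 ms online, 1 ms
offline) slides in 1-sample steps over each channel. Per window and trial the
most negative peak is taken; the window score is the first quartile of the
peak magnitudes — the value that 75% of trials reach, so a stable responder
scores near its amplitude while windows with inconsistent spiking collapse
toward the noise floor. Windows scoring below θ_win = 5 (Z units, mirroring
protocol II's detection threshold; the online candidate threshold is not
otherwise constrained) are excluded. The best window is refined iteratively:
keep the 75% largest peaks, take the quartile deviation (QD) of their
timings, reset the window to median ± W_jitter·QD (W_jitter = 5 online, 4
offline), and repeat until the integer window bounds stop changing (cap 20
iterations; non-converging candidates are rejected; a refined window that
drifts into an already-adopted range is rejected, keeping adopted windows
disjoint). A degenerate QD of 0 is floored at a one-sample half-width.
After adoption, all window positions overlapping the adopted range are
removed on every channel and the search repeats.

**Protocol II (center-spike search).** Spikes are detected in every trial
(negative peaks below 5 SD; one spike per supra-threshold run, channels
pooled). Similarity between spikes k and l combines pattern angle and timing:

    S_kl = exp[ cos²θ_kl − 1 − sin²(π/18)/α² · (t_k − t_l)² ],

with α = 1 ms offline (a 1 ms timing offset weighs like a π/18 pattern
rotation). Each detected spike is scored by the first quartile of its
best-match similarity per trial (a spike represents its own trial with
S = 1; trials without any detected spike contribute 0). Candidates below
θ_aggr are excluded online (θ_aggr = 0.98); offline the candidate set is
left unrestricted so that low-aggregation centers survive as control pairs
for the judgment batch. The top-quartile spike becomes a center; its
`ceil(0.75 × contributing trials)` most similar per-trial spikes become
representatives, leave the candidate pool, and the search iterates.

Both protocols end in a collision target: the component-wise median peak
pattern `u`, the median waveform aligned at the peak, and the representative
timing bounds `t_min`/`t_max`, from which the latency bounds
`L_min = t_min − t_off` and `L_max = t_max − t_stim` follow.

Quartiles and QDs use linear interpolation between order statistics
(`numpy.percentile`'s default), fixed once for amplitude quartiles,
similarity quartiles and jitter.

## Closed-loop controller

Each detected spike is scored against every same-tetrode target by the
squared direction cosine `D = (ẑ_k·u/|u|)² / a_k`. Among targets whose sites
satisfy both interval constraints at the scheduled onset (≥ I_same = 1 s
since the same site, ≥ I_diff = 0.5 s since any site), the highest-D target
fires if `D > θ_trig²` (θ_trig = 0.99); the arbitration rule for multiple
matches is a package choice. The emulated loop latency is fixed at the 3.2 ms
worst case (configurable down to 0); onsets are floored to the sample grid so
the budget is never exceeded. A target retires after N_test = 200 tests.

## Offline judgment

For each (neuron, target) pair on the same tetrode, the target site's trials
are partitioned:

1. trials with a spike in `(t_min − R_max, t_min)` are dropped (R_max = 4 ms,
   the supremum of somatic refractory periods): such a spike could eliminate
   the evoked spike by refractoriness, mimicking collision. The upper end is
   exclusive so the evoked spike itself never triggers exclusion.
2. trigger trials: ≥ 1 spike in `[t_off − L_min, t_stim]`, where collision is
   guaranteed; pairs with < 15 trigger trials are excluded.
3. no-trigger trials: no spike in `[t_stim − L_max − R_max, t_stim]`, taken
   as the 10 temporally nearest per trigger trial with duplicates merged.

Elimination per trial is the window's peak magnitude (protocol I) or the
maximum similarity to the center spike (protocol II; 0 when nothing is
detected). The ROC area between no-trigger and trigger values uses the
Mann–Whitney identity with midrank ties, so elimination drives AUC toward 1.
Latency per no-trigger trial is the cubic-spline-interpolated trough time of
the evoked spike's peak channel (20× oversampling around the discrete peak);
jitter is the QD of those latencies (≥ 4 evoked trials required).

A pair succeeds when `AUC − median(batch AUCs) > 5σ` with
`σ = median|AUC − median|/0.6745`, and jitter < 0.25 ms. The criterion is
centered on the batch median because the batch is dominated by unmatched
pairs whose AUCs scatter around chance; centering on 0 or 0.5 would make the
rule depend on an arbitrary origin (the choice is ours; the batch is one
analysis run). Among multiple successful pairs of one neuron only the
highest-AUC pair is adopted.

Note that a spontaneous spike shortly *after* the stimulus (earlier than
`t_min − R_max`) can still collide on the axon; the pre-stimulus ranges
cannot exclude such trials, which appear as occasional high elimination
values among no-trigger trials. This is inherent to the design, not an
implementation artifact.

## Simulator

Each unit has a biphasic analytic template (difference of Gaussians,
trough normalized to −1; trough-to-peak 0.7 ms for wide/projection-like
units, 0.3 ms for fast-spiking-like ones, matching the bimodal duration
boundary at 0.5 ms), a 4-channel amplitude pattern (trough depths in
noise-SD units, dominant channel 15–40, biased across channels by a
Dirichlet(0.5) draw — extracellular amplitude falls steeply with distance
from each electrode tip, so single-unit patterns are strongly biased), a
dead-time Poisson spontaneous train (ISI = R + Exp(1/rate), R = 2.8 ms from
juxtacellular estimates), and optionally projections
(`d` = 0.7 ms < D_i so spikes initiate before light offset, `C = L − d`,
arrival jitter SD 0.05 ms applied to the arrival only, axonal refractory
R′ = 1 ms) or synaptic inputs (latency, jitter QD, probability 0.65).

Evoked outcomes follow the axonal physics exactly: refractory elimination
(both kinds) when a somatic spike lies in `[t_A − R, t_A)`; collision
elimination (antidromic only) when a spontaneous spike satisfies
`t_spon + C + R′ ≥ t_stim + d` with `t_spon ≤ t_A`; collision takes
precedence when both hold (for antidromic spikes the refractory interval is
contained in the collision interval, so pure-refractory causes arise only
for synaptic spikes). Evoked amplitudes are scaled by `evoked_scale = 1.2`
(antidromic spikes are reported larger than spontaneous ones; the ratio is a
free parameter). Rendering is additive: Gaussian noise plus each surviving
event's template, evaluated analytically at sub-sample event times (needed
for sub-sample latency and jitter checks); eliminated events render nothing.
Peristimulus windows can be rendered without synthesizing the whole session,
which keeps long sessions tractable.

The default study emulates the standard session: 2 tetrodes, 3 sites,
N_anti = 100 collection stimulations per site, then a closed-loop test phase
to the end of an 850 s session (~1300 triggered tests). The population is 20
projection neurons (latencies evenly spread over 5–15 ms and interleaved
across tetrode-site combinations; rates 2.5–5 Hz so that chance collision
elimination stays well below the 25% the amplitude quartile tolerates), 6
synaptic responders (jitter QD 1.0–2.2 ms) and 6 unrelated units (a third of
them fast-spiking-like), i.e. 16 units per tetrode — 20 true projection
pairs, ~20 responder pairs and ~60 unrelated pairs for the judgment batch.
The controller consumes the ground-truth spontaneous spike stream with
pattern noise (SD 0.5) rather than re-detecting from a rendered continuous
signal, which decouples the controller contract checks from detector
artifacts; detection itself is validated separately against rendered
recordings.

What the simulator does **not** emulate: electrode drift, bursting and
amplitude adaptation, spike-sorting errors (cluster labels are exact),
overlapping-spike waveform distortion beyond linear summation, correlated
or non-Gaussian noise, ChR2 kinetics beyond the fixed evoking delay, and
frequency-following stimulation. Passing tests therefore demonstrate the
correctness of the computational pipeline under its stated assumptions, not
robustness to sorting errors or non-stationary recordings.

## Known limitations and expected failure modes

* Projections with `L < loop latency + 2·D_i` (≈ 5.2 ms at defaults) cannot
  accumulate trigger trials: closed-loop triggers fire 3.2 ms before the
  stimulus, outside the trigger range `[t_off − L_min, t_stim]`, and the
  pair is excluded. The shortest-latency unit of the default study (5.0 ms)
  fails for exactly this reason — the known short-latency limitation of
  collision testing with a fixed loop delay.
* Protocol II's representative sets can absorb background spikes whose
  patterns mimic the center when the timing weight is mild (α = 1 ms),
  biasing `t_min`/`t_max` outward; this is conservative (it narrows the
  trigger range and can only lose pairs, never create false positives).
* The 5σ rule needs a batch with many unmatched control pairs; on tiny
  sessions (one or two units) it cannot fire and the raw AUC/jitter evidence
  should be read directly.

## Problem sizes used in the test suite

Unit tests run on single-tetrode sessions of 20–540 s with up to 420
stimulations; the acceptance study uses the full default session above
(850 s, ~1700 stimulations total) and completes in about a minute, so the
whole suite runs in a few minutes on one CPU.
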