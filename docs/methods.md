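# Methods

## Signal model and conventions

A trial is a 70-ms extracellular voltage trace (mV) sampled at 100 kHz,
with sample 0 at stimulus onset.  Indexing is 0-based,
`time_ms = index * 1000 / sampling_rate`, and every window is half-open
`[start, end)`.  The 70-ms length is deliberate: the baseline-activity
window is literally "the last 10 ms (60–70 ms)", which the generator keeps
spike-free by construction.

## Preprocessing

Traces are low-pass filtered with a digital 2nd-order Butterworth at
5 kHz (scipy `butter`/`sosfilt`, bilinear design) before any detection.

*Causal single pass, not zero-phase.*  A forward–backward pass squares the
magnitude response, i.e. doubles the effective filter order relative to the
stated 2nd-order response.  The causal pass's constant low-frequency group
delay, √2/(2π·fc) ≈ 0.045 ms at these settings, shifts thalamic and
cortical spikes equally, so it cancels exactly in TS relay latencies and
adds only a common ~0.045-ms offset to ES latencies — negligible against
the 0.5-ms equivalence bound.  `FilterSpec.zero_phase` switches to
`sosfiltfilt` for users who prefer zero lag over the nominal order.

*Digital vs analog magnitude.*  At the cutoff the gain is exactly 1/√2 (the
bilinear design prewarps there); away from it the response follows the
digital closed form `1/sqrt(1 + (tan(pi f/fs)/tan(pi fc/fs))^4)`, slightly
below the analog `1/sqrt(1 + (f/fc)^4)` (0.231 vs 0.243 at 10 kHz).  Tests
assert the digital form, since that is what any digital Butterworth
implementation produces.

*Baseline SD divisor.*  Population (n) vs sample (n−1) is a genuine
convention choice; the default is n−1 (`ddof=1`), exposed as a parameter so
thresholds are reproducible from a config alone.  Over the 1000-sample
baseline window the difference is 0.05%.

## Spike detection

Threshold = multiplier × baseline SD of the same trace (10× for cortex,
6× for thalamus).  Candidate windows (0.7 ms cortex / 0.5 ms thalamus)
are scanned exhaustively at single-sample steps over
`[exclusion, duration − window]`; amplitudes are measured within the
window relative to its own trough (pre-trough max − trough, post-trough
max − trough), matching the descending/ascending geometry of a biphasic
AP; "larger than the threshold" is strict `>`.  Among overlapping
qualifying windows the one with the largest descending + ascending sum is
kept, greedily, ties to the earlier start — each biphasic deflection
yields one event.  The trough is the event's canonical time; all latencies
are therefore trough-to-trough and internally consistent.

*Degenerate baselines.*  On an exactly silent baseline the relative
threshold is 0 and strict `>` would fire on the filter's numerical residue
(~1e-10 mV) and on sub-microvolt waveform structure.  `DetectionParams`
therefore carries a minimal-deflection floor, default 1e-6 mV (1 nV) — far
below any physical extracellular signal, so it is inert on real or noisy
synthetic data.  For strictly noiseless experiments the floor is the only
amplitude scale in the problem and should be set to a physically meaningful
value (the recovery tests use 0.05 mV, 10% of the template trough);
otherwise the detector will faithfully report every tiny flank of the
spike's own overshoot as a qualifying deflection.

*False positives.*  At the 10× cortical threshold, pure-noise traces
essentially never qualify (≤ 1 event per 1000 traces).  The laxer 6×
thalamic threshold admits a few-percent per-trace false-positive rate on
pure band-limited noise (measured ~3%, bounded at 5% in the tests); in
practice thalamic detection rides on spikes several times that amplitude.

## Latency analysis

One record per detected cortical spike.  TS reference: the first thalamic
spike of the same trial (trials with no detected thalamic spike are
skipped and logged; a trial with no thalamic *trace* at all is a
structural error).  ES reference: stimulus onset, t = 0.  Negative TS
latencies are kept and flagged, not dropped.

Outlier exclusion per subject × mode: quartiles by linear interpolation
between order statistics (the common default; `np.quantile`), values
*strictly* beyond `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR` excluded, so fence-exact
values and zero-IQR groups are kept in full.  Summaries report quartiles
and means of kept values plus the per-subject |mean TS − mean ES|.

## Waveform similarity

Selection uses the detected windows verbatim (0.7-ms cortical signals):
the highest-correlated cross-trace pair (s1, s2) first, then, among the
remaining spikes from unused traces, the best correlate of s1 and of s2.
If one spike is the best companion for both anchors, it goes to the anchor
with the higher correlation and the other anchor takes its next best; all
four spikes come from four different traces.  Correlation ties (within
1e-12) resolve by the canonical (trial, trough-time) order, so selection
is deterministic even for identical waveforms.

Averaging is hierarchical: stage 1 aligns and averages (s1, s3), stage 2
(s2, s4), stage 3 the two stage outputs — each anchor is paired with the
spike selected *for* it, maximizing within-pair similarity before any
averaging (`AlignmentParams.pairing="sequential"` switches to
(s1, s2)/(s3, s4)).  Alignment searches all 0.5-ms segments with centers
within ±0.05 ms of each spike's trough at single-sample (0.01-ms) steps,
shifts the second trace so the most correlated segments coincide exactly,
truncates to the common support, and averages point-wise.  Correlation
ties break by the smallest deviation from the peak-to-peak shift, then the
earliest centers.  The output peak is recomputed as the minimum near the
aligned center (a global argmin could land on unrelated trace content,
e.g. an ES artifact).

The final score applies the same search with 1-ms segments to the TS and
ES averages; the maximizing Pearson r is the similarity.  Note the search
*maximizes* r: anti-correlated inputs yield the least-negative alignment,
not −1, unless the center search is degenerate.

## Synthetic data generator

The generator emulates what the analysis assumes about the recordings:

| parameter | default | meaning |
|---|---|---|
| `trace_duration_ms` / `sampling_rate` | 70 / 100 kHz | trial length, rate |
| `template_amplitude_mv`, `template_width_ms` | 0.5, 0.3 | AP trough depth; half-support |
| `noise_sd_mv` | 0.02 | additive white Gaussian noise |
| `thalamic_latency_mean_ms/_sd_ms` | 8.0 / 0.5 | TS thalamic first-spike latency L |
| `relay_delay_mean_ms/_sd_ms` | 4.5 / 0.3 | relay delay D, shared by TS and ES |
| `artifact_amplitude_mv/_decay_ms` | 2.0 / 1.0 | ES exponential artifact at t = 0 |
| `min_spike_time_ms` | 5.3 | placement-validity lower bound |
| `extra_spike_rate` | 0 | spontaneous cortical spikes per trial |

The AP template is a biphasic descending-then-ascending waveform (raised
cosine down to the trough, cubic recovery with a ~15% overshoot) rescaled
so the sampled minimum equals −amplitude exactly; support is 2 × width.
TS trials place a thalamic trough at L and a cortical trough at L + D; ES
trials place a cortical trough at D′ drawn from the same relay law and add
the artifact (which motivates the detector's 5-ms exclusion window); no ES
thalamic trace exists, since the thalamic electrode delivers the stimulus.

*The validity window and mode exchangeability.*  Spike times are redrawn
(cap 5000) until they land in `(min_spike_time_ms, duration − 2 ms)`.  The
lower bound defaults to the detection exclusion (5 ms) plus the template
half-support, because a spike the analysis can never see is not a usable
trial.  Critically, the bound is applied to the relay delay in *both*
modes — not just to the ES spike time, where it coincides with the spike
time.  Truncating only ES would make the two modes' latency populations
differ by construction (~0.6 ms for the defaults) and would manufacture a
latency "difference" where the data-generating process has none; applying
the same truncation keeps TS and ES ground-truth latencies exchangeable,
which is the null the equivalence analysis probes.  With the default
Normal(4.5, 0.3) law this truncation is severe (it keeps the upper ~0.4%
tail, hence the large retry cap), so the realized latencies concentrate
near 5.3–5.6 ms; tests of the *untruncated* parent law set
`min_spike_time_ms` low explicitly.

*What the generator does not emulate:* bursting or multi-unit activity,
latency–amplitude correlations, 1/f or line noise, electrode drift, spike
shape variability within a mode, and any dependence of responses on
stimulus strength.  Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the assumed statistical structure, not
robustness to every pathology of real recordings.

## Problem sizes and numerical choices

Default synthetic studies use 20–30 trials per mode and single subjects;
the similarity study is evaluated over 10 seeded datasets and the latency
study over 10 (bounds: every-seed r > 0.9; ≥ 9/10 seeds |Δmean| < 0.5 ms).
Parameter-recovery checks use 200 trials.  Correlation ties use a 1e-12
tolerance; trace files store ≥ 6 significant digits, so round-trips are
exact to ~1e-7 relative.  Stimulus bookkeeping converts V across kΩ
directly to mA and rounds to two decimals for reporting.

## Known limitations

- The final r is computed between averages of only 4 spikes per mode; with
  noisy or scarce spikes the selection step's correlations are themselves
  noisy, and the score inherits that variance.
- The causal filter biases ES (but not TS) latencies by the group delay;
  use `zero_phase` if absolute ES latencies matter more than the nominal
  filter order.
- Outlier fences are recomputed per group; re-filtering a kept set with
  *recomputed* fences can in principle exclude further values (the
  documented behaviour asserts idempotence only against the original
  fences).
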