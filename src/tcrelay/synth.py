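"""Seeded synthetic paired thalamic/cortical trials, plus stimulus bookkeeping.

The generator emulates the statistical structure the analysis assumes:
70-ms trials sampled at 100 kHz with stimulus onset at t = 0; biphasic
action-potential templates riding on additive white Gaussian noise; for TS
trials a thalamic first-spike latency L ~ Normal and a cortical spike at
L + D with relay delay D ~ Normal; for ES trials a cortical spike at D'
drawn from the SAME relay-delay law plus a decaying-exponential stimulation
artifact starting at t = 0 (ES is delivered in the thalamus, so no thalamic
trace is recorded for ES trials).

Spike placement is constrained to a validity window
``(min_spike_time_ms, trace_duration - 2 ms)`` by redraw-with-cap.  The
lower bound (default 5.3 ms = the 5-ms artifact-exclusion window plus the
template half-support) is applied to the relay delay in BOTH modes, not
just to the ES spike time: the analysis can only ever observe latencies
beyond the exclusion window, and truncating one mode but not the other
would build a spurious TS-vs-ES latency difference into data meant to be
exchangeable between modes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import GenerationError, ParameterError
from .io import Dataset, TraceRecord, save_dataset
from .traces import Trace

#: Stimulus parameter sets available on the pulse generator.
TESTED_STRENGTHS_V = (20.0, 40.0, 60.0, 80.0, 90.0)
TESTED_DURATIONS_MS = (0.2, 0.6, 1.0, 1.4, 1.8, 2.0)
#: Measured tip impedance of the pulled theta-glass stimulating electrode.
TIP_IMPEDANCE_MEAN_KOHM = 885.0
TIP_IMPEDANCE_MIN_KOHM = 770.0


@dataclasses.dataclass
class StimulusSpec:
    """One electrical-stimulation setting."""

    pulse_strength_v: float
    pulse_duration_ms: float = TESTED_DURATIONS_MS[0]
    tip_impedance_kohm: float = TIP_IMPEDANCE_MEAN_KOHM

    def validate(self) -> None:
        if self.pulse_strength_v < 0:
            raise ParameterError("pulse strength must be >= 0 V")
        if not self.tip_impedance_kohm > 0:
            raise ParameterError("tip impedance must be positive")


def estimate_max_current(spec: StimulusSpec) -> float:
    """Ohm's-law current estimate in mA, rounded to 2 decimals.

    Volts across kiloohms gives milliamps directly: 90 V over the minimum
    770 kOhm tip impedance bounds the delivered current at 0.12 mA.
    """
    spec.validate()
    return round(spec.pulse_strength_v / spec.tip_impedance_kohm, 2)


@dataclasses.dataclass
class SynthConfig:
    """Generator settings.  Defaults are the study conditions: 70-ms trials
    at 100 kHz, 0.5-mV spike templates on 0.02-mV noise, thalamic latency
    Normal(8, 0.5) ms and relay delay Normal(4.5, 0.3) ms shared between
    modes, and a 2-mV / 1-ms exponential ES artifact."""

    n_trials_per_mode: int = 20
    trace_duration_ms: float = 70.0
    sampling_rate: float = 100000.0
    template_amplitude_mv: float = 0.5
    template_width_ms: float = 0.3
    noise_sd_mv: float = 0.02
    thalamic_latency_mean_ms: float = 8.0
    thalamic_latency_sd_ms: float = 0.5
    relay_delay_mean_ms: float = 4.5
    relay_delay_sd_ms: float = 0.3
    artifact_amplitude_mv: float = 2.0
    artifact_decay_ms: float = 1.0
    extra_spike_rate: float = 0.0
    min_spike_time_ms: float = 5.3
    max_retries: int = 5000
    subject_id: str = "s1"
    seed: int = 0
    # Optional distinct ES template (None = same waveform as TS); used to
    # probe the pipeline's discrimination between shared and differing
    # spike shapes.
    es_template_amplitude_mv: float | None = None
    es_template_width_ms: float | None = None

    def validate(self) -> None:
        if self.n_trials_per_mode < 0:
            raise ParameterError("n_trials_per_mode must be >= 0")
        for name in ("trace_duration_ms", "sampling_rate",
                     "template_amplitude_mv", "template_width_ms",
                     "artifact_decay_ms"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.noise_sd_mv < 0 or self.extra_spike_rate < 0:
            raise ParameterError("noise_sd_mv and extra_spike_rate must be >= 0")
        if self.thalamic_latency_sd_ms < 0 or self.relay_delay_sd_ms < 0:
            raise ParameterError("latency SDs must be >= 0")
        if not (self.thalamic_latency_mean_ms + self.relay_delay_mean_ms
                < self.trace_duration_ms):
            raise ParameterError(
                "thalamic latency + relay delay means must fit in the trace")
        if self.max_retries < 1:
            raise ParameterError("max_retries must be >= 1")

    @property
    def spike_window_ms(self) -> tuple[float, float]:
        """Validity window (lo, hi) for spike times and relay delays."""
        return (self.min_spike_time_ms, self.trace_duration_ms - 2.0)


@dataclasses.dataclass
class Trial:
    """One generated trial with its ground truth."""

    trial_id: str
    mode: str
    thalamic: Trace | None
    cortical: Trace
    thalamic_spike_times_ms: list[float]
    cortical_spike_times_ms: list[float]


def generate_template(amplitude: float, width: float,
                      sampling_rate: float) -> np.ndarray:
    """Biphasic AP template: descending phase to the trough, then an
    ascending overshoot decaying back to baseline.

    Total support is 2 x ``width`` ms; the sampled minimum equals exactly
    ``-amplitude`` (enforced by rescaling) and the waveform starts and ends
    at 0, so the descending amplitude is exactly ``amplitude`` and the
    ascending amplitude exceeds it (overshoot ~15% of the trough depth).
    Deterministic in its arguments.
    """
    if not (amplitude > 0 and width > 0 and sampling_rate > 0):
        raise ParameterError("amplitude, width and sampling rate must be positive")
    n = int(round(2.0 * width * sampling_rate / 1000.0))
    if n < 4:
        raise ParameterError("template support shorter than 4 samples")
    x = np.linspace(0.0, 2.0, n)
    y = np.empty(n)
    desc = x <= 1.0
    y[desc] = -0.5 * (1.0 - np.cos(np.pi * x[desc]))
    s = x[~desc] - 1.0
    y[~desc] = -(1.0 - s) ** 3 + 0.4 * np.sin(np.pi * s) ** 2 * s
    y *= amplitude / -y.min()
    return y


def _draw_valid(rng: np.random.Generator, mean: float, sd: float,
                lo: float, hi: float, max_retries: int,
                what: str) -> tuple[float, int]:
    """Normal draw rejected outside (lo, hi); errors once the cap is hit.
    Returns (value, draws used)."""
    used = 0
    while used < max_retries:
        batch = min(64, max_retries - used)
        vals = rng.normal(mean, sd, size=batch)
        used += batch
        ok = np.flatnonzero((vals > lo) & (vals < hi))
        if ok.size:
            return float(vals[ok[0]]), used
    raise GenerationError(
        f"could not draw a valid {what} in ({lo}, {hi}) ms from "
        f"Normal({mean}, {sd}) within {max_retries} attempts")


def _insert_template(samples: np.ndarray, template: np.ndarray,
                     trough_time_ms: float, sampling_rate: float) -> None:
    trough_in_template = int(np.argmin(template))
    start = int(round(trough_time_ms * sampling_rate / 1000.0)) - trough_in_template
    lo = max(0, start)
    hi = min(samples.size, start + template.size)
    samples[lo:hi] += template[lo - start:hi - start]


def generate_trial(config: SynthConfig, mode: str,
                   rng: np.random.Generator, trial_id: str = "trial") -> Trial:
    """Generate one TS trial (thalamic + cortical trace) or ES trial
    (cortical trace only), with ground-truth spike times."""
    config.validate()
    if mode not in ("TS", "ES"):
        raise ParameterError(f"mode must be TS or ES, got {mode!r}")
    lo, hi = config.spike_window_ms
    fs = config.sampling_rate
    n = int(round(config.trace_duration_ms * fs / 1000.0))
    template = generate_template(
        config.template_amplitude_mv, config.template_width_ms, fs)
    if mode == "ES" and (config.es_template_amplitude_mv is not None
                         or config.es_template_width_ms is not None):
        template = generate_template(
            config.es_template_amplitude_mv or config.template_amplitude_mv,
            config.es_template_width_ms or config.template_width_ms, fs)

    if mode == "TS":
        for _ in range(config.max_retries):
            thal_t, _ = _draw_valid(rng, config.thalamic_latency_mean_ms,
                                    config.thalamic_latency_sd_ms, lo, hi,
                                    config.max_retries, "thalamic latency")
            delay, _ = _draw_valid(rng, config.relay_delay_mean_ms,
                                   config.relay_delay_sd_ms, lo, hi,
                                   config.max_retries, "relay delay")
            if lo < thal_t + delay < hi:
                break
        else:
            raise GenerationError("could not place a valid TS spike pair")
        cort_times = [thal_t + delay]
        thal_times = [thal_t]
    else:
        delay, _ = _draw_valid(rng, config.relay_delay_mean_ms,
                               config.relay_delay_sd_ms, lo, hi,
                               config.max_retries, "relay delay")
        cort_times = [delay]
        thal_times = []

    # Optional spontaneous cortical spikes; confined below the baseline
    # window (minus a template support) so the 60-70 ms segment stays
    # spike-free by construction.
    if config.extra_spike_rate > 0:
        n_extra = int(rng.poisson(config.extra_spike_rate))
        upper = min(hi, 60.0 - 2.0 * config.template_width_ms)
        for _ in range(n_extra):
            for _ in range(config.max_retries):
                t = float(rng.uniform(lo, upper))
                if all(abs(t - t0) > 1.0 for t0 in cort_times):
                    cort_times.append(t)
                    break
            else:
                raise GenerationError("could not place a spontaneous spike")
        cort_times.sort()

    thalamic = None
    if mode == "TS":
        thal_samples = np.zeros(n)
        _insert_template(thal_samples, template, thal_times[0], fs)
        if config.noise_sd_mv > 0:
            thal_samples += rng.normal(0.0, config.noise_sd_mv, n)
        thalamic = Trace(config.subject_id, trial_id, "thalamus", mode, fs,
                         thal_samples)

    cort_samples = np.zeros(n)
    for t in cort_times:
        _insert_template(cort_samples, template, t, fs)
    if mode == "ES" and config.artifact_amplitude_mv != 0:
        t_ms = np.arange(n) * 1000.0 / fs
        cort_samples += (config.artifact_amplitude_mv
                         * np.exp(-t_ms / config.artifact_decay_ms))
    if config.noise_sd_mv > 0:
        cort_samples += rng.normal(0.0, config.noise_sd_mv, n)
    cortical = Trace(config.subject_id, trial_id, "cortex", mode, fs,
                     cort_samples)

    return Trial(trial_id=trial_id, mode=mode, thalamic=thalamic,
                 cortical=cortical, thalamic_spike_times_ms=thal_times,
                 cortical_spike_times_ms=cort_times)


def generate_trials(config: SynthConfig) -> list[Trial]:
    """All trials for one subject: n TS pairs then n ES cortical trials,
    from a single generator seeded with ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials = []
    for mode in ("TS", "ES"):
        for i in range(config.n_trials_per_mode):
            trials.append(generate_trial(config, mode, rng,
                                         trial_id=f"{mode}{i:03d}"))
    return trials


def generate_dataset(config: SynthConfig, out_dir=None) -> Dataset:
    """Generate a full dataset; optionally write traces + manifest to disk."""
    records = []
    for trial in generate_trials(config):
        if trial.thalamic is not None:
            records.append(TraceRecord(
                trace=trial.thalamic,
                ground_truth_spike_times_ms=list(trial.thalamic_spike_times_ms)))
        records.append(TraceRecord(
            trace=trial.cortical,
            ground_truth_spike_times_ms=list(trial.cortical_spike_times_ms)))
    dataset = Dataset(records)
    if out_dir is not None:
        save_dataset(dataset, out_dir)
    return dataset
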