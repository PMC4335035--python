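"""End-to-end orchestration: filter -> detect -> latencies -> similarity.

``run_pipeline`` takes a :class:`~tcrelay.io.Dataset` and a
:class:`PipelineConfig` and produces the result bundle: a per-spike
detection table, raw and outlier-filtered latency tables, a per
subject x mode latency summary with per-subject TS-vs-ES mean differences,
and one waveform-similarity report per subject.  Every housed constant
defaults to the analysis's standard value (filter order 2 / 5 kHz cutoff,
threshold multipliers 10 and 6, windows 0.7 / 0.5 ms, 5-ms exclusion,
60-70 ms baseline, 0.5 / 1.0-ms segments, 0.1-ms center search, 1.5-IQR
outlier rule).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any

import pandas as pd

from . import latency as latency_mod
from . import similarity as sim_mod
from .detect import DetectionParams, SpikeEvent, detect_spikes, params_for_site
from .errors import PipelineStageError, SelectionInfeasibleError, TcrelayError
from .io import Dataset
from .preprocess import BaselineWindow, FilterSpec, butterworth_lowpass
from .similarity import AlignmentParams, AveragedWaveform, SimilarityReport

logger = logging.getLogger("tcrelay")


@dataclasses.dataclass
class PipelineConfig:
    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    baseline: BaselineWindow = dataclasses.field(default_factory=BaselineWindow)
    cortex: DetectionParams = dataclasses.field(
        default_factory=DetectionParams.cortex)
    thalamus: DetectionParams = dataclasses.field(
        default_factory=DetectionParams.thalamus)
    alignment: AlignmentParams = dataclasses.field(default_factory=AlignmentParams)
    iqr_multiplier: float = latency_mod.IQR_MULTIPLIER

    def __post_init__(self) -> None:
        self.cortex.baseline = self.baseline
        self.thalamus.baseline = self.baseline

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        """Build from nested config keys (``filter.order`` etc.)."""
        cfg = cls()
        flt = data.get("filter", {})
        cfg.filter = FilterSpec(
            order=int(flt.get("order", cfg.filter.order)),
            cutoff_hz=float(flt.get("cutoff_hz", cfg.filter.cutoff_hz)),
            zero_phase=bool(flt.get("zero_phase", cfg.filter.zero_phase)))
        base = data.get("baseline", {})
        cfg.baseline = BaselineWindow(
            start_ms=float(base.get("start_ms", cfg.baseline.start_ms)),
            end_ms=float(base.get("end_ms", cfg.baseline.end_ms)))
        det = data.get("detect", {})
        for site in ("cortex", "thalamus"):
            params = getattr(cfg, site)
            site_cfg = det.get(site, {})
            params.window_ms = float(site_cfg.get("window_ms", params.window_ms))
            params.threshold_multiplier = float(site_cfg.get(
                "threshold_multiplier", params.threshold_multiplier))
            params.exclusion_ms = float(site_cfg.get(
                "exclusion_ms", params.exclusion_ms))
            params.baseline = cfg.baseline
        aln = data.get("align", {})
        cfg.alignment = AlignmentParams(
            pair_segment_ms=float(aln.get("pair_segment_ms", 0.5)),
            final_segment_ms=float(aln.get("final_segment_ms", 1.0)),
            center_search_ms=float(aln.get("center_search_ms", 0.1)),
            pairing=str(aln.get("pairing", "anchor")))
        cfg.iqr_multiplier = float(
            data.get("iqr", {}).get("multiplier", cfg.iqr_multiplier))
        return cfg


@dataclasses.dataclass
class PipelineResult:
    detections: pd.DataFrame
    latencies: pd.DataFrame          # raw records with a `kept` column
    latency_summary: pd.DataFrame    # per subject x mode, post-exclusion
    mode_differences: pd.DataFrame   # per subject |mean TS - mean ES|
    similarity: list[SimilarityReport]
    similarity_table: pd.DataFrame
    averaged_waveforms: dict[tuple[str, str], AveragedWaveform]
    skipped_trials: dict[tuple[str, str], list[str]]


def detection_table(events: list[SpikeEvent]) -> pd.DataFrame:
    rows = [{
        "subject": e.subject_id, "trial": e.trial_id, "site": e.site,
        "mode": e.mode, "trough_time_ms": e.trough_time_ms,
        "window_start_ms": e.window_start_ms,
        "descending_mV": e.descending_mv, "ascending_mV": e.ascending_mv,
        "threshold_mV": e.threshold_mv,
    } for e in events]
    return pd.DataFrame(rows, columns=[
        "subject", "trial", "site", "mode", "trough_time_ms",
        "window_start_ms", "descending_mV", "ascending_mV", "threshold_mV"])


def filter_dataset(dataset: Dataset, config: PipelineConfig) -> Dataset:
    """Low-pass filter every trace (stage: filter)."""
    from .io import TraceRecord
    records = [TraceRecord(
        trace=butterworth_lowpass(r.trace, config.filter),
        path=r.path,
        ground_truth_spike_times_ms=r.ground_truth_spike_times_ms)
        for r in dataset]
    logger.info("filter: %d traces low-pass filtered (order %d, %.0f Hz)",
                len(records), config.filter.order, config.filter.cutoff_hz)
    return Dataset(records)


def detect_dataset(dataset: Dataset, config: PipelineConfig
                   ) -> dict[tuple[str, str, str], list[SpikeEvent]]:
    """Detect spikes in every filtered trace, keyed by (subject, trial, site)."""
    events: dict[tuple[str, str, str], list[SpikeEvent]] = {}
    total = 0
    for rec in dataset:
        params = params_for_site(rec.trace.site, config.cortex, config.thalamus)
        evts = detect_spikes(rec.trace, params)
        events[rec.trace.key] = evts
        total += len(evts)
    logger.info("detect: %d spikes in %d traces", total, len(dataset))
    return events


def _latency_records(dataset: Dataset,
                     events: dict[tuple[str, str, str], list[SpikeEvent]],
                     ) -> tuple[list[latency_mod.LatencyRecord],
                                dict[tuple[str, str], list[str]]]:
    records: list[latency_mod.LatencyRecord] = []
    skipped: dict[tuple[str, str], list[str]] = {}
    for subject in dataset.subjects:
        for mode in ("TS", "ES"):
            trials = dataset.trials(subject, mode)
            if not trials:
                continue
            cortical = {t: events.get((subject, t, "cortex"), []) for t in trials}
            thalamic = None
            if mode == "TS":
                thalamic = {t: events[(subject, t, "thalamus")]
                            for t in trials
                            if (subject, t, "thalamus") in events}
            recs, skip = latency_mod.tc_relay_latencies(cortical, thalamic, mode)
            records.extend(recs)
            if skip:
                skipped[(subject, mode)] = skip
    return records, skipped


def _similarity_for_subject(subject: str, dataset: Dataset,
                            events: dict[tuple[str, str, str], list[SpikeEvent]],
                            config: PipelineConfig,
                            ) -> tuple[SimilarityReport,
                                       dict[str, AveragedWaveform]]:
    averages: dict[str, AveragedWaveform] = {}
    for mode in ("TS", "ES"):
        spikes = [e for key, evts in events.items() for e in evts
                  if key[0] == subject and key[2] == "cortex" and e.mode == mode]
        if len(spikes) < config.alignment.selection_count:
            raise SelectionInfeasibleError(
                f"subject {subject!r} mode {mode}: "
                f"{len(spikes)} cortical spikes detected, need "
                f"{config.alignment.selection_count}")
        selection = sim_mod.select_representative_spikes(spikes, config.alignment)
        traces, peaks, trials = [], [], []
        for spike in selection.spikes:
            rec = dataset.get(subject, spike.trial_id, "cortex")
            traces.append(rec.trace.samples)
            peaks.append(spike.trough_index)
            trials.append(spike.trial_id)
        fs = dataset.get(subject, trials[0], "cortex").trace.sampling_rate
        averages[mode] = sim_mod.hierarchical_average(
            traces, peaks, fs,
            config.alignment, subject_id=subject, mode=mode,
            spike_trials=tuple(trials))
        logger.info("similarity: subject %s mode %s selected trials %s "
                    "(pair r=%.4f)", subject, mode, trials, selection.pair_r)
    report = sim_mod.final_similarity(averages["TS"], averages["ES"],
                                      config.alignment)
    return report, averages


def run_pipeline(dataset: Dataset, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full analysis on a dataset; any stage error is re-raised as
    :class:`PipelineStageError` carrying the stage name."""
    config = config or PipelineConfig()

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except TcrelayError as exc:
            raise PipelineStageError(name, exc) from exc

    filtered = stage("filter", filter_dataset, dataset, config)
    events = stage("detect", detect_dataset, filtered, config)
    records, skipped = stage("latency", _latency_records, filtered, events)
    summary, lat_table = stage(
        "latency", latency_mod.summarize_latencies, records,
        config.iqr_multiplier)
    differences = stage("latency", latency_mod.mode_mean_differences, summary)
    logger.info("latency: %d records, %d subject x mode groups",
                len(lat_table), len(summary))

    reports: list[SimilarityReport] = []
    averaged: dict[tuple[str, str], AveragedWaveform] = {}
    for subject in filtered.subjects:
        report, averages = stage(
            "similarity", _similarity_for_subject, subject, filtered, events,
            config)
        reports.append(report)
        for mode, avg in averages.items():
            averaged[(subject, mode)] = avg
        logger.info("similarity: subject %s r=%.4f", subject, report.r)

    all_events = [e for evts in events.values() for e in evts]
    sim_table = pd.DataFrame([{
        "subject": rep.subject_id,
        "r": rep.r,
        "ts_center_offset_ms": rep.ts_center_offset_ms,
        "es_center_offset_ms": rep.es_center_offset_ms,
        "ts_stage_shifts_ms": ";".join(
            f"{s:.3f}" for s in averaged[(rep.subject_id, "TS")].stage_shifts_ms),
        "es_stage_shifts_ms": ";".join(
            f"{s:.3f}" for s in averaged[(rep.subject_id, "ES")].stage_shifts_ms),
    } for rep in reports], columns=["subject", "r", "ts_center_offset_ms",
                                    "es_center_offset_ms", "ts_stage_shifts_ms",
                                    "es_stage_shifts_ms"])
    return PipelineResult(
        detections=detection_table(all_events),
        latencies=lat_table,
        latency_summary=summary,
        mode_differences=differences,
        similarity=reports,
        similarity_table=sim_table,
        averaged_waveforms=averaged,
        skipped_trials=skipped,
    )
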