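"""Thalamocortical relay latencies, outlier exclusion and summaries.

For a TS trial the relay latency of each detected cortical spike is its
trough time minus the trough time of the FIRST thalamic spike of the same
trial; for an ES trial the stimulus is delivered in the thalamus at t = 0,
so the latency is simply the cortical spike time.  Outliers — values more
than 1.5 interquartile ranges below Q1 or above Q3 — are excluded per
subject and per mode before summarizing.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import SpikeEvent
from .errors import ParameterError, StructuralError

IQR_MULTIPLIER = 1.5


@dataclasses.dataclass
class LatencyRecord:
    subject_id: str
    mode: str
    trial_id: str
    cortical_spike_time_ms: float
    reference_time_ms: float

    @property
    def latency_ms(self) -> float:
        return self.cortical_spike_time_ms - self.reference_time_ms

    @property
    def negative(self) -> bool:
        """Cortical spike preceding its reference; kept but flagged."""
        return self.latency_ms < 0


@dataclasses.dataclass
class IqrResult:
    kept: list[float]
    excluded: list[float]
    kept_indices: list[int]
    excluded_indices: list[int]
    q1: float
    q3: float
    lower_fence: float
    upper_fence: float


def tc_relay_latencies(
    cortical_by_trial: Mapping[str, Sequence[SpikeEvent]],
    thalamic_by_trial: Mapping[str, Sequence[SpikeEvent]] | None,
    mode: str,
) -> tuple[list[LatencyRecord], list[str]]:
    """One latency record per detected cortical spike.

    Parameters
    ----------
    cortical_by_trial : mapping trial_id -> cortical SpikeEvents (time order)
    thalamic_by_trial : mapping trial_id -> thalamic SpikeEvents; required
        for TS (a trial absent from it is a structural error, distinct from
        a trial present with no detected thalamic spike, which is skipped).
    mode : "TS" or "ES"

    Returns (records, skipped_trial_ids) where skipped trials are TS trials
    with no detected thalamic spike.
    """
    records: list[LatencyRecord] = []
    skipped: list[str] = []
    for trial_id, cortical in cortical_by_trial.items():
        if mode == "ES":
            reference = 0.0
        elif mode == "TS":
            if thalamic_by_trial is None or trial_id not in thalamic_by_trial:
                raise StructuralError(
                    f"TS trial {trial_id!r}: no thalamic trace supplied")
            thalamic = thalamic_by_trial[trial_id]
            if len(thalamic) == 0:
                skipped.append(trial_id)
                continue
            reference = min(e.trough_time_ms for e in thalamic)
        else:
            raise ParameterError(f"mode must be TS or ES, got {mode!r}")
        for event in cortical:
            records.append(LatencyRecord(
                subject_id=event.subject_id,
                mode=mode,
                trial_id=trial_id,
                cortical_spike_time_ms=event.trough_time_ms,
                reference_time_ms=reference,
            ))
    return records, skipped


def iqr_filter(values: Sequence[float], multiplier: float = IQR_MULTIPLIER) -> IqrResult:
    """Exclude values more than ``multiplier`` IQRs outside [Q1, Q3].

    Quartiles use linear interpolation between order statistics.  Exclusion
    is strict ("more than"), so values exactly on a fence are kept, and with
    IQR = 0 nothing is excluded.  Order of kept values is preserved.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ParameterError("iqr_filter requires at least one value")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    iqr = q3 - q1
    lower = q1 - multiplier * iqr
    upper = q3 + multiplier * iqr
    outside = (vals < lower) | (vals > upper)
    return IqrResult(
        kept=[float(v) for v in vals[~outside]],
        excluded=[float(v) for v in vals[outside]],
        kept_indices=[int(i) for i in np.flatnonzero(~outside)],
        excluded_indices=[int(i) for i in np.flatnonzero(outside)],
        q1=float(q1), q3=float(q3),
        lower_fence=float(lower), upper_fence=float(upper),
    )


def latency_table(records: Iterable[LatencyRecord]) -> pd.DataFrame:
    """Raw per-spike latency table in a fixed column order."""
    rows = [{
        "subject": r.subject_id,
        "mode": r.mode,
        "trial": r.trial_id,
        "cortical_spike_time_ms": r.cortical_spike_time_ms,
        "reference_time_ms": r.reference_time_ms,
        "latency_ms": r.latency_ms,
        "negative": r.negative,
    } for r in records]
    return pd.DataFrame(
        rows, columns=["subject", "mode", "trial", "cortical_spike_time_ms",
                       "reference_time_ms", "latency_ms", "negative"])


def summarize_latencies(records: Iterable[LatencyRecord],
                        multiplier: float = IQR_MULTIPLIER,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject x mode summary after outlier exclusion.

    Returns ``(summary, latencies)`` where ``latencies`` is the raw table
    with a ``kept`` column and ``summary`` has one row per subject x mode
    (n_raw, n_kept, quartiles and mean of kept values).  Groups with zero
    records are impossible here (groups arise from records), but empty kept
    sets cannot occur since the filter keeps >= the inter-quartile half.
    """
    table = latency_table(records)
    table["kept"] = False
    rows = []
    for (subject, mode), group in table.groupby(["subject", "mode"], sort=True):
        res = iqr_filter(group["latency_ms"].to_numpy(), multiplier)
        idx = group.index.to_numpy()
        table.loc[idx[res.kept_indices], "kept"] = True
        kept = np.asarray(res.kept)
        rows.append({
            "subject": subject,
            "mode": mode,
            "n_raw": int(len(group)),
            "n_kept": int(kept.size),
            "q1_ms": res.q1,
            "median_ms": float(np.median(kept)),
            "q3_ms": res.q3,
            "mean_ms": float(np.mean(kept)),
            "n_excluded": len(res.excluded_indices),
            "excluded_indices": ";".join(str(i) for i in res.excluded_indices),
        })
    summary = pd.DataFrame(
        rows, columns=["subject", "mode", "n_raw", "n_kept", "q1_ms",
                       "median_ms", "q3_ms", "mean_ms", "n_excluded",
                       "excluded_indices"])
    return summary, table


def mode_mean_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """|mean TS - mean ES| latency per subject; subjects missing a mode
    (or with an empty group) emit no row."""
    rows = []
    for subject, group in summary.groupby("subject", sort=True):
        modes = group.set_index("mode")
        if "TS" in modes.index and "ES" in modes.index:
            diff = abs(float(modes.loc["TS", "mean_ms"]) -
                       float(modes.loc["ES", "mean_ms"]))
            rows.append({"subject": subject,
                         "mean_ts_ms": float(modes.loc["TS", "mean_ms"]),
                         "mean_es_ms": float(modes.loc["ES", "mean_ms"]),
                         "abs_difference_ms": diff})
    return pd.DataFrame(rows, columns=["subject", "mean_ts_ms", "mean_es_ms",
                                       "abs_difference_ms"])
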