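"""Evoked-spike detection by the dual-amplitude threshold rule.

A candidate window of fixed length (0.7 ms for cortex, 0.5 ms for thalamus)
qualifies as a spike when BOTH its descending amplitude (pre-trough maximum
minus trough) and ascending amplitude (post-trough maximum minus trough)
exceed a threshold set as a multiple of the trace's baseline activity
(10x for cortex, 6x for thalamus).  The first 5 ms of each trace are
excluded from detection because of stimulation artifacts.

Candidate windows are scanned exhaustively at single-sample steps; among
overlapping qualifying windows the one maximizing descending + ascending
amplitude is kept (greedy, ties to the earlier start), so each biphasic
deflection yields a single event.  The trough is the event's canonical time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError
from .preprocess import BaselineWindow, baseline_sd
from .traces import Trace

#: Threshold floor in mV.  With an exactly silent baseline the threshold
#: would be 0 and strict ">" would fire on the filter's numerical residue
#: (~1e-10 mV); 1 nV is far below any physical extracellular signal.
THRESHOLD_FLOOR_MV = 1e-6


@dataclasses.dataclass
class DetectionParams:
    """Site-specific detection parameters."""

    window_ms: float
    threshold_multiplier: float
    exclusion_ms: float = 5.0
    baseline: BaselineWindow = dataclasses.field(default_factory=BaselineWindow)
    sd_ddof: int = 1
    threshold_floor_mv: float = THRESHOLD_FLOOR_MV

    @classmethod
    def cortex(cls, **overrides) -> "DetectionParams":
        """Cortical defaults: 0.7-ms window, 10x baseline threshold."""
        return cls(window_ms=0.7, threshold_multiplier=10.0, **overrides)

    @classmethod
    def thalamus(cls, **overrides) -> "DetectionParams":
        """Thalamic defaults: 0.5-ms window, 6x baseline threshold."""
        return cls(window_ms=0.5, threshold_multiplier=6.0, **overrides)

    def validate(self) -> None:
        if not self.window_ms > 0:
            raise ParameterError(f"window must be positive, got {self.window_ms}")
        if not self.threshold_multiplier > 0:
            raise ParameterError(
                f"threshold multiplier must be positive, got {self.threshold_multiplier}")
        if self.exclusion_ms < 0:
            raise ParameterError(f"exclusion must be >= 0, got {self.exclusion_ms}")


@dataclasses.dataclass
class SpikeEvent:
    """One detected spike: a qualifying window with its amplitudes."""

    subject_id: str
    trial_id: str
    site: str
    mode: str
    trough_time_ms: float
    window_start_ms: float
    descending_mv: float
    ascending_mv: float
    threshold_mv: float
    trough_index: int
    window_start_index: int
    waveform: np.ndarray

    @property
    def trace_key(self) -> tuple[str, str]:
        return (self.subject_id, self.trial_id)


def window_amplitudes(waveform: np.ndarray) -> tuple[float, float, int]:
    """Descending/ascending amplitudes and trough index of one window.

    The trough is the window's global minimum (first sample on ties);
    descending = max over samples up to and including the trough, minus the
    trough; ascending = max over samples from the trough onward, minus the
    trough.  A trough at a window edge leaves that side's amplitude 0.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ParameterError("empty waveform")
    trough = int(np.argmin(w))
    descending = float(np.max(w[: trough + 1]) - w[trough])
    ascending = float(np.max(w[trough:]) - w[trough])
    return descending, ascending, trough


def detect_spikes(trace: Trace, params: DetectionParams) -> list[SpikeEvent]:
    """Detect spikes in one (filtered) trace.

    Returns non-overlapping events in time order.  The threshold is
    ``threshold_multiplier * baseline_sd(trace)`` (with a tiny numerical
    floor; see :data:`THRESHOLD_FLOOR_MV`).
    """
    params.validate()
    sd = baseline_sd(trace, params.baseline, ddof=params.sd_ddof)
    threshold = max(params.threshold_multiplier * sd, params.threshold_floor_mv)

    fs = trace.sampling_rate
    wlen = int(round(params.window_ms * fs / 1000.0))
    if wlen < 2:
        raise ParameterError("detection window shorter than 2 samples")
    n = trace.n_samples
    first_start = int(np.ceil(params.exclusion_ms * fs / 1000.0))
    if first_start + wlen > n:
        return []

    x = trace.samples
    windows = sliding_window_view(x, wlen)[first_start:]
    m = windows.shape[0]
    rows = np.arange(m)
    trough_idx = np.argmin(windows, axis=1)
    trough_val = windows[rows, trough_idx]
    fwd_max = np.maximum.accumulate(windows, axis=1)
    bwd_max = np.maximum.accumulate(windows[:, ::-1], axis=1)[:, ::-1]
    descending = fwd_max[rows, trough_idx] - trough_val
    ascending = bwd_max[rows, trough_idx] - trough_val
    qualifies = (descending > threshold) & (ascending > threshold)

    starts = np.flatnonzero(qualifies)
    if starts.size == 0:
        return []
    scores = descending[starts] + ascending[starts]
    # Greedy: best combined amplitude first; ties to the earlier start.
    order = np.lexsort((starts, -scores))
    accepted: list[int] = []
    for k in order:
        s = starts[k]
        if all(abs(s - s2) >= wlen for s2 in accepted):
            accepted.append(int(s))
    accepted.sort()

    events = []
    for s in accepted:
        abs_start = first_start + s
        t_idx = int(trough_idx[s])
        events.append(SpikeEvent(
            subject_id=trace.subject_id,
            trial_id=trace.trial_id,
            site=trace.site,
            mode=trace.mode,
            trough_time_ms=trace.index_to_ms(abs_start + t_idx),
            window_start_ms=trace.index_to_ms(abs_start),
            descending_mv=float(descending[s]),
            ascending_mv=float(ascending[s]),
            threshold_mv=float(threshold),
            trough_index=abs_start + t_idx,
            window_start_index=abs_start,
            waveform=np.array(x[abs_start:abs_start + wlen]),
        ))
    return events


def params_for_site(site: str, cortex: DetectionParams | None = None,
                    thalamus: DetectionParams | None = None) -> DetectionParams:
    """Pick the site's detection parameters (defaults when not supplied)."""
    if site == "cortex":
        return cortex or DetectionParams.cortex()
    if site == "thalamus":
        return thalamus or DetectionParams.thalamus()
    raise ParameterError(f"unknown site {site!r}")
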