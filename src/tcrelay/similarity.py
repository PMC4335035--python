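"""Spike selection, time-aligned hierarchical averaging, and the final
Pearson similarity between TS- and ES-evoked averaged cortical spikes.

Per modality, four detected cortical spikes from four different traces are
selected by their pairwise waveform correlation (evaluated on the detected
windows): the most correlated cross-trace pair (s1, s2) first, then the two
remaining spikes that best correlate with s1 and s2 respectively.  The four
spike-bearing traces are then averaged hierarchically: each pair is shifted
on the time axis so their most highly correlated 0.5-ms segments (centers
searched within 0.1 ms of the spike trough, single-sample steps) overlap
exactly, and averaged point-wise; the two pair averages are averaged the
same way.  Finally the most highly correlated 1-ms segments of the TS and
ES averaged spikes are found by the same center search, and their Pearson
r quantifies waveform similarity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .detect import SpikeEvent
from .errors import (AlignmentError, ParameterError, SelectionInfeasibleError,
                     UndefinedCorrelationError)

#: Correlations closer than this are treated as tied and resolved by the
#: documented deterministic tie-break (smallest shift, then earliest center).
_R_TIE_TOL = 1e-12


@dataclasses.dataclass
class AlignmentParams:
    """Segment lengths and search ranges for alignment and comparison.

    pair_segment_ms : segment used when aligning two traces (default 0.5)
    final_segment_ms : segment for the final TS-vs-ES comparison (default 1.0)
    center_search_ms : total width of the center search window around the
        spike peak (default 0.1, i.e. centers within +/-0.05 ms of the peak)
    selection_count : number of representative spikes per modality (4)
    pairing : "anchor" pairs each first-stage anchor with the spike selected
        for it — (s1, s3) and (s2, s4); "sequential" pairs (s1, s2) and
        (s3, s4).
    """

    pair_segment_ms: float = 0.5
    final_segment_ms: float = 1.0
    center_search_ms: float = 0.1
    selection_count: int = 4
    pairing: str = "anchor"

    def validate(self) -> None:
        if not (self.pair_segment_ms > 0 and self.final_segment_ms > 0):
            raise ParameterError("segment lengths must be positive")
        if self.center_search_ms < 0:
            raise ParameterError("center_search_ms must be >= 0")
        if self.selection_count != 4:
            raise ParameterError("selection_count is fixed at 4")
        if self.pairing not in ("anchor", "sequential"):
            raise ParameterError(f"unknown pairing {self.pairing!r}")


@dataclasses.dataclass
class SegmentMatch:
    """Result of the best-correlated-segment search."""

    center_a: int
    center_b: int
    offset_a: int       # center_a - peak_a, in samples
    offset_b: int
    r: float


@dataclasses.dataclass
class AlignedAverage:
    """Point-wise average of two traces after segment alignment."""

    samples: np.ndarray
    peak_index: int
    shift_samples: int  # shift applied to b's time axis (positive = later)
    r: float


@dataclasses.dataclass
class Selection:
    """The four representative spikes, in anchor order (s1, s2, s3, s4)."""

    spikes: tuple[SpikeEvent, SpikeEvent, SpikeEvent, SpikeEvent]
    pair_r: float
    tied: bool


@dataclasses.dataclass
class AveragedWaveform:
    subject_id: str
    mode: str
    spike_trials: tuple[str, str, str, str]
    samples: np.ndarray
    peak_index: int
    sampling_rate: float
    stage_shifts_ms: tuple[float, float, float]


@dataclasses.dataclass
class SimilarityReport:
    subject_id: str
    r: float
    ts_segment: np.ndarray
    es_segment: np.ndarray
    ts_center_offset_ms: float
    es_center_offset_ms: float


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input rather than
    silently returning 0 or NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson_r requires two equal-length 1-d sequences")
    if x.size < 2:
        raise ParameterError("pearson_r requires at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(np.dot(xd, yd) / (sx * sy))


def _normalized_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardized to zero mean / unit norm; second return flags
    constant (invalid) rows."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    return centered / safe[:, None], valid


def select_representative_spikes(spikes: list[SpikeEvent],
                                 params: AlignmentParams | None = None) -> Selection:
    """Choose 4 spikes from 4 distinct traces by waveform correlation.

    (s1, s2) is the cross-trace pair with the highest Pearson r between
    detected windows; s3 maximizes r with s1 and s4 maximizes r with s2
    among the rest, all from mutually distinct traces.  If one remaining
    spike is the best match for both anchors it goes to the anchor with the
    higher r and the other anchor takes its next best.  Ties break by the
    canonical (trial, trough time) order.
    """
    params = params or AlignmentParams()
    params.validate()
    spikes = sorted(spikes, key=lambda e: (e.trial_id, e.trough_time_ms))
    trials = [e.trace_key for e in spikes]
    if len(spikes) < params.selection_count or len(set(trials)) < params.selection_count:
        raise SelectionInfeasibleError(
            f"need {params.selection_count} spikes in {params.selection_count} "
            f"distinct traces; have {len(spikes)} spikes in "
            f"{len(set(trials))} traces")
    lengths = {e.waveform.size for e in spikes}
    if len(lengths) != 1:
        raise ParameterError("all spike waveforms must share one window length")

    W = np.stack([e.waveform for e in spikes])
    Z, valid = _normalized_rows(W)
    R = Z @ Z.T
    n = len(spikes)
    same_trial = np.array([[trials[i] == trials[j] for j in range(n)]
                           for i in range(n)])
    invalid = ~valid
    R[same_trial] = -np.inf
    R[invalid, :] = -np.inf
    R[:, invalid] = -np.inf

    # Best cross-trace pair; canonical order resolves ties.
    iu, ju = np.triu_indices(n, k=1)
    pair_r = R[iu, ju]
    if not np.isfinite(pair_r.max()):
        raise SelectionInfeasibleError("no valid cross-trace spike pair")
    best = float(pair_r.max())
    tied_pairs = np.flatnonzero(pair_r >= best - _R_TIE_TOL)
    k = int(tied_pairs[0])
    s1, s2 = int(iu[k]), int(ju[k])

    used_trials = {trials[s1], trials[s2]}
    candidates = [k for k in range(n)
                  if k not in (s1, s2) and trials[k] not in used_trials
                  and valid[k]]
    if not candidates:
        raise SelectionInfeasibleError("no candidates left for companion spikes")

    def best_for(anchor: int, pool: list[int]) -> int:
        rs = np.array([R[k, anchor] for k in pool])
        top = rs.max()
        return pool[int(np.flatnonzero(rs >= top - _R_TIE_TOL)[0])]

    c1 = best_for(s1, candidates)
    c2 = best_for(s2, candidates)
    if trials[c1] != trials[c2]:
        s3, s4 = c1, c2
    elif R[c1, s1] >= R[c2, s2]:
        s3 = c1
        rest = [k for k in candidates if trials[k] != trials[c1]]
        if not rest:
            raise SelectionInfeasibleError("no distinct trace left for s4")
        s4 = best_for(s2, rest)
    else:
        s4 = c2
        rest = [k for k in candidates if trials[k] != trials[c2]]
        if not rest:
            raise SelectionInfeasibleError("no distinct trace left for s3")
        s3 = best_for(s1, rest)

    tied = bool(tied_pairs.size > 1)
    return Selection(
        spikes=(spikes[s1], spikes[s2], spikes[s3], spikes[s4]),
        pair_r=best, tied=tied)


def best_correlated_segments(a: np.ndarray, b: np.ndarray, peak_a: int,
                             peak_b: int, sampling_rate: float,
                             segment_ms: float,
                             center_search_ms: float) -> SegmentMatch:
    """Exhaustive search for the most correlated equal-length segments.

    Candidate centers lie within +/- ``center_search_ms / 2`` of each peak at
    single-sample steps; segments are ``segment_ms`` long, centered on their
    candidate center.  Ties in r (within 1e-12) break by the smallest
    deviation of the implied shift from the peak-to-peak shift, then by the
    earliest center pair.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    seg = int(round(segment_ms * sampling_rate / 1000.0))
    if seg < 2:
        raise ParameterError("segment shorter than 2 samples")
    half = int(round(center_search_ms * sampling_rate / 1000.0 / 2.0))
    left = seg // 2

    def segments(x: np.ndarray, peak: int) -> tuple[np.ndarray, np.ndarray]:
        centers = peak + np.arange(-half, half + 1)
        if centers[0] - left < 0 or centers[-1] - left + seg > x.size:
            raise ParameterError(
                "trace too short to host a segment at every candidate center")
        rows = np.stack([x[c - left:c - left + seg] for c in centers])
        return centers, rows

    centers_a, rows_a = segments(a, peak_a)
    centers_b, rows_b = segments(b, peak_b)
    Za, valid_a = _normalized_rows(rows_a)
    Zb, valid_b = _normalized_rows(rows_b)
    R = Za @ Zb.T
    R[~valid_a, :] = -np.inf
    R[:, ~valid_b] = -np.inf
    top = R.max()
    if not np.isfinite(top):
        raise UndefinedCorrelationError("all candidate segments are constant")
    ii, jj = np.nonzero(R >= top - _R_TIE_TOL)
    # shift deviation: how far the implied b-shift strays from aligning peaks
    dev = np.abs((centers_b[jj] - peak_b) - (centers_a[ii] - peak_a))
    order = np.lexsort((centers_b[jj], centers_a[ii], dev))
    i, j = int(ii[order[0]]), int(jj[order[0]])
    return SegmentMatch(
        center_a=int(centers_a[i]), center_b=int(centers_b[j]),
        offset_a=int(centers_a[i] - peak_a), offset_b=int(centers_b[j] - peak_b),
        r=float(R[i, j]))


def align_average_pair(a: np.ndarray, peak_a: int, b: np.ndarray, peak_b: int,
                       sampling_rate: float,
                       params: AlignmentParams | None = None) -> AlignedAverage:
    """Shift b so the optimal segments coincide, then average point-wise.

    The common support is truncated to the overlap; the output peak is the
    minimum of the averaged trace near the aligned segment center.
    """
    params = params or AlignmentParams()
    params.validate()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    match = best_correlated_segments(
        a, b, peak_a, peak_b, sampling_rate,
        params.pair_segment_ms, params.center_search_ms)
    # b sample j lands at a-axis index j + delta
    delta = match.center_a - match.center_b
    start = max(0, delta)
    end = min(a.size, b.size + delta)
    seg = int(round(params.pair_segment_ms * sampling_rate / 1000.0))
    if end - start < seg:
        raise AlignmentError(
            f"alignment leaves only {end - start} samples of overlap")
    avg = 0.5 * (a[start:end] + b[start - delta:end - delta])
    # Recompute the peak locally around the aligned center: the global
    # minimum of a full-trace average could sit on unrelated content.
    c = match.center_a - start
    lo = max(0, c - seg)
    hi = min(avg.size, c + seg + 1)
    peak = lo + int(np.argmin(avg[lo:hi])) + start  # back to a's axis
    return AlignedAverage(samples=avg, peak_index=peak - start,
                          shift_samples=delta, r=match.r)


def hierarchical_average(traces: list[np.ndarray], peaks: list[int],
                         sampling_rate: float,
                         params: AlignmentParams | None = None,
                         subject_id: str = "", mode: str = "",
                         spike_trials: tuple[str, ...] = ("", "", "", ""),
                         ) -> AveragedWaveform:
    """Three-stage pairwise averaging of the four selected spikes' traces.

    ``traces``/``peaks`` are in anchor order (s1, s2, s3, s4).  With
    ``pairing="anchor"`` stage 1 averages (s1, s3) and stage 2 (s2, s4);
    with ``pairing="sequential"``, (s1, s2) and (s3, s4).  Stage 3 aligns
    and averages the two stage outputs by the same segment rule.
    """
    params = params or AlignmentParams()
    params.validate()
    if len(traces) != 4 or len(peaks) != 4:
        raise ParameterError("hierarchical_average requires exactly 4 traces")
    if params.pairing == "anchor":
        pairs = ((0, 2), (1, 3))
    else:
        pairs = ((0, 1), (2, 3))
    stage_out = []
    for stage, (i, j) in enumerate(pairs, start=1):
        try:
            stage_out.append(align_average_pair(
                traces[i], peaks[i], traces[j], peaks[j], sampling_rate, params))
        except (AlignmentError, UndefinedCorrelationError, ParameterError) as exc:
            raise AlignmentError(f"stage {stage}: {exc}") from exc
    try:
        final = align_average_pair(
            stage_out[0].samples, stage_out[0].peak_index,
            stage_out[1].samples, stage_out[1].peak_index,
            sampling_rate, params)
    except (AlignmentError, UndefinedCorrelationError, ParameterError) as exc:
        raise AlignmentError(f"stage 3: {exc}") from exc
    ms = 1000.0 / sampling_rate
    return AveragedWaveform(
        subject_id=subject_id, mode=mode, spike_trials=tuple(spike_trials),
        samples=final.samples, peak_index=final.peak_index,
        sampling_rate=sampling_rate,
        stage_shifts_ms=(stage_out[0].shift_samples * ms,
                         stage_out[1].shift_samples * ms,
                         final.shift_samples * ms))


def final_similarity(avg_ts: AveragedWaveform, avg_es: AveragedWaveform,
                     params: AlignmentParams | None = None) -> SimilarityReport:
    """Pearson r of the most correlated 1-ms segments of the two averages."""
    params = params or AlignmentParams()
    params.validate()
    if avg_ts.sampling_rate != avg_es.sampling_rate:
        raise ParameterError("averaged waveforms must share a sampling rate")
    fs = avg_ts.sampling_rate
    match = best_correlated_segments(
        avg_ts.samples, avg_es.samples, avg_ts.peak_index, avg_es.peak_index,
        fs, params.final_segment_ms, params.center_search_ms)
    seg = int(round(params.final_segment_ms * fs / 1000.0))
    left = seg // 2
    ts_seg = np.array(avg_ts.samples[match.center_a - left:
                                     match.center_a - left + seg])
    es_seg = np.array(avg_es.samples[match.center_b - left:
                                     match.center_b - left + seg])
    ms = 1000.0 / fs
    return SimilarityReport(
        subject_id=avg_ts.subject_id, r=match.r,
        ts_segment=ts_seg, es_segment=es_seg,
        ts_center_offset_ms=match.offset_a * ms,
        es_center_offset_ms=match.offset_b * ms)
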