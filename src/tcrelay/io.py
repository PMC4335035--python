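"""On-disk dialect for traces, manifests and result tables.

Traces are human-inspectable CSV: ``# key=value`` comment headers followed by
one sample per line (mV, >= 6 significant digits).  A dataset is a directory
of trace files plus a JSON manifest listing, per trace, the file path,
subject, trial, mode, site and the generator's ground-truth spike times (when
the dataset is synthetic).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Iterator

import numpy as np

from .errors import EmptyTraceError, MissingHeaderError, TraceFormatError
from .traces import Trace

_REQUIRED_HEADERS = ("subject_id", "trial_id", "site", "mode", "sampling_rate_hz")
_SAMPLE_FORMAT = "%.8g"
MANIFEST_NAME = "manifest.json"


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace in the package dialect; refuses invalid traces."""
    if trace.samples.size and not np.all(np.isfinite(trace.samples)):
        raise TraceFormatError("refusing to write trace with non-finite samples")
    path = Path(path)
    lines = [
        f"# subject_id={trace.subject_id}",
        f"# trial_id={trace.trial_id}",
        f"# site={trace.site}",
        f"# mode={trace.mode}",
        f"# sampling_rate_hz={trace.sampling_rate!r}",
        f"# filtered={'true' if trace.filtered else 'false'}",
    ]
    for key, value in sorted(trace.meta.items()):
        lines.append(f"# {key}={value}")
    lines.extend(_SAMPLE_FORMAT % v for v in trace.samples)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace file; unknown header keys land in ``Trace.meta``."""
    path = Path(path)
    headers: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                headers[key.strip()] = value.strip()
            else:
                try:
                    samples.append(float(line))
                except ValueError:
                    raise TraceFormatError(
                        f"{path}:{lineno}: non-numeric sample line {line!r}") from None
    for key in _REQUIRED_HEADERS:
        if key not in headers:
            raise MissingHeaderError(key)
    if not samples:
        raise EmptyTraceError(f"{path}: trace file contains no sample lines")
    meta = {k: v for k, v in headers.items()
            if k not in _REQUIRED_HEADERS and k != "filtered"}
    return Trace(
        subject_id=headers["subject_id"],
        trial_id=headers["trial_id"],
        site=headers["site"],
        mode=headers["mode"],
        sampling_rate=float(headers["sampling_rate_hz"]),
        samples=np.array(samples),
        filtered=headers.get("filtered", "false").lower() == "true",
        meta=meta,
    )


@dataclasses.dataclass
class TraceRecord:
    """One manifest entry: a trace plus its ground truth (if synthetic)."""

    trace: Trace
    path: str | None = None
    ground_truth_spike_times_ms: list[float] | None = None


class Dataset:
    """In-memory collection of trace records with grouped access."""

    def __init__(self, records: Iterable[TraceRecord]):
        self.records: list[TraceRecord] = list(records)
        self._by_key = {r.trace.key: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TraceRecord]:
        return iter(self.records)

    def get(self, subject_id: str, trial_id: str, site: str) -> TraceRecord | None:
        return self._by_key.get((subject_id, trial_id, site))

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.trace.subject_id, None)
        return list(seen)

    def select(self, *, subject_id: str | None = None, mode: str | None = None,
               site: str | None = None) -> list[TraceRecord]:
        out = []
        for r in self.records:
            t = r.trace
            if subject_id is not None and t.subject_id != subject_id:
                continue
            if mode is not None and t.mode != mode:
                continue
            if site is not None and t.site != site:
                continue
            out.append(r)
        return out

    def trials(self, subject_id: str, mode: str) -> list[str]:
        """Trial ids for a subject x mode, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.select(subject_id=subject_id, mode=mode):
            seen.setdefault(r.trace.trial_id, None)
        return list(seen)


def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write every trace plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[dict[str, Any]] = []
    for rec in dataset.records:
        t = rec.trace
        fname = f"{t.subject_id}_{t.trial_id}_{t.site}.csv"
        write_trace(t, out_dir / fname)
        rec.path = fname
        entry: dict[str, Any] = {
            "path": fname,
            "subject": t.subject_id,
            "trial": t.trial_id,
            "mode": t.mode,
            "site": t.site,
        }
        if rec.ground_truth_spike_times_ms is not None:
            entry["ground_truth_spike_times_ms"] = [
                float(v) for v in rec.ground_truth_spike_times_ms]
        entries.append(entry)
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps({"traces": entries}, indent=1) + "\n")
    return manifest_path


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from its manifest; trace files resolve relative to it."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise TraceFormatError(f"{manifest_path}: invalid manifest JSON: {exc}") from exc
    records = []
    for entry in manifest.get("traces", []):
        trace = read_trace(base / entry["path"])
        if (trace.subject_id, trace.trial_id, trace.site) != (
                entry["subject"], entry["trial"], entry["site"]):
            raise TraceFormatError(
                f"{entry['path']}: trace headers disagree with manifest entry")
        gt = entry.get("ground_truth_spike_times_ms")
        records.append(TraceRecord(
            trace=trace, path=entry["path"],
            ground_truth_spike_times_ms=None if gt is None else list(gt)))
    return Dataset(records)
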