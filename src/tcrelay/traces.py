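"""The Trace container and its time-axis conventions.

A :class:`Trace` holds one trial's extracellular voltage samples (mV) for one
recording site, with the metadata the downstream analysis keys on.  The time
convention throughout the package: sample 0 is stimulus onset (t = 0 ms),
indexing is 0-based, ``time_ms = index * 1000 / sampling_rate``, and windows
are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .errors import TraceValidationError

SITES = ("thalamus", "cortex")
MODES = ("TS", "ES")


@dataclasses.dataclass
class Trace:
    """One trial's voltage trace at one site.

    Parameters
    ----------
    subject_id, trial_id : str
        Labels; ``(subject_id, trial_id, site)`` identifies the trace.
    site : {"thalamus", "cortex"}
    mode : {"TS", "ES"}
        Stimulation modality: tactile (TS) or electrical microstimulation (ES).
    sampling_rate : float
        Samples per second (Hz); recordings are acquired at 100 kHz.
    samples : array-like
        Voltage in mV, one value per sample.
    filtered : bool
        Set by the preprocessing stage once the trace has been low-pass
        filtered; detection expects filtered traces.
    meta : dict
        Opaque extra metadata (unknown file-header keys are preserved here).
    """

    subject_id: str
    trial_id: str
    site: str
    mode: str
    sampling_rate: float
    samples: np.ndarray
    filtered: bool = False
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise TraceValidationError("samples must be one-dimensional")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise TraceValidationError(
                f"sampling_rate must be positive, got {self.sampling_rate!r}")
        if self.site not in SITES:
            raise TraceValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if self.mode not in MODES:
            raise TraceValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise TraceValidationError("all samples must be finite")

    # -- time axis helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def ms_to_index(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms."""
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def index_to_ms(self, index: int) -> float:
        return index * 1000.0 / self.sampling_rate

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.trial_id, self.site)

    def copy_with(self, **changes: Any) -> "Trace":
        """Return a copy with the given fields replaced (samples are copied)."""
        fields = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        fields["samples"] = np.array(fields["samples"], copy=True)
        fields["meta"] = dict(fields["meta"])
        fields.update(changes)
        return Trace(**fields)
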