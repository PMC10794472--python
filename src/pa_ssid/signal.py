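"""Core trace container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PASignal"]

#: fraction of max |y| used to detect signal onset everywhere in the package
ONSET_THRESHOLD = 0.10


@dataclass
class PASignal:
    """A uniformly sampled real-valued trace.

    Parameters
    ----------
    samples : array-like
        Amplitudes in arbitrary units, at least 4 samples, all finite.
    ts : float
        Sampling interval in seconds (> 0).
    t0 : float
        Absolute time of the first sample, in seconds.
    label : str
        Class label, or ``"unlabeled"``.
    meta : dict
        Free-form annotations (provenance, diagnostics).
    """

    samples: np.ndarray
    ts: float
    t0: float = 0.0
    label: str = "unlabeled"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 4:
            raise ValueError(f"need at least 4 samples, got {self.samples.size}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.ts > 0):
            raise ValueError(f"ts must be positive, got {self.ts}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + self.ts * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        return self.ts * self.samples.size

    def onset_index(self, threshold: float = ONSET_THRESHOLD) -> int:
        """First index where |y| reaches ``threshold`` x max |y|."""
        a = np.abs(self.samples)
        peak = a.max()
        if peak == 0:
            raise ValueError("all-zero signal has no onset")
        return int(np.argmax(a >= threshold * peak))

    def aligned(self, threshold: float = ONSET_THRESHOLD) -> "PASignal":
        """Copy of the trace starting at the detected onset (t0 adjusted)."""
        k = self.onset_index(threshold)
        return PASignal(
            samples=self.samples[k:].copy(),
            ts=self.ts,
            t0=self.t0 + k * self.ts,
            label=self.label,
            meta=dict(self.meta),
        )
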