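"""Uniformly sampled ionic-current trace container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurrentTrace"]


@dataclass
class CurrentTrace:
    """A uniformly sampled single-channel current recording.

    Parameters
    ----------
    samples
        Current values in amperes, one-dimensional, finite.
    sampling_rate
        Sampling frequency in Hz (typically 100-200 kHz for patch-clamp
        nanopore recordings).
    start_time
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate
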