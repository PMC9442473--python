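"""Binned photon-count time traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PhotonTrace"]


@dataclass
class PhotonTrace:
    """A photon-count trace from a point detector.

    Attributes
    ----------
    counts:
        Non-negative integer photon counts per detector bin.
    bin_width:
        Width of one bin, seconds.
    meta:
        Acquisition metadata or, for simulated traces, the ground truth
        used to generate them.
    """

    counts: np.ndarray
    bin_width: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (number of bins times bin width)."""
        return len(self.counts) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate, counts/s."""
        if len(self.counts) == 0:
            return 0.0
        return float(self.counts.sum()) / self.duration

    @property
    def times(self) -> np.ndarray:
        """Bin start times, seconds."""
        return np.arange(len(self.counts)) * self.bin_width

    def crop(self, start: float, stop: float) -> "PhotonTrace":
        """Return the sub-trace covering [start, stop) seconds."""
        i0 = int(round(start / self.bin_width))
        i1 = int(round(stop / self.bin_width))
        return PhotonTrace(self.counts[i0:i1].copy(), self.bin_width, dict(self.meta))

    def __len__(self) -> int:
        return len(self.counts)
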