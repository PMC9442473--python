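"""Per-centriole intensity time series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["CentrioleSeries"]


@dataclass
class CentrioleSeries:
    """Background-subtracted centriolar intensity versus time.

    Times are in minutes relative to ``anchor`` (an event name such as
    ``"NEB"`` or ``"CS"``; series fresh from acquisition or simulation
    use ``"cycle_start"`` until aligned).  Intensities are in arbitrary
    or normalized units.
    """

    times: np.ndarray
    intensities: np.ndarray
    anchor: str = "cycle_start"
    embryo_id: str = ""
    centriole_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, t0: float, anchor: str) -> "CentrioleSeries":
        """Return a copy with the time axis shifted so ``t0`` maps to 0."""
        return CentrioleSeries(
            self.times - t0,
            self.intensities.copy(),
            anchor=anchor,
            embryo_id=self.embryo_id,
            centriole_id=self.centriole_id,
            meta=dict(self.meta),
        )

    def scaled(self, factor: float) -> "CentrioleSeries":
        """Return a copy with intensities multiplied by ``factor``."""
        return CentrioleSeries(
            self.times.copy(),
            self.intensities * factor,
            anchor=self.anchor,
            embryo_id=self.embryo_id,
            centriole_id=self.centriole_id,
            meta=dict(self.meta),
        )
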