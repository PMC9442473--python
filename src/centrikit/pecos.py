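"""Peak-counting spectroscopy (PeCoS).

For proteins whose cytoplasmic signal is too dim for FCS, the number of
fluorescence bursts in a point trace serves as a concentration proxy.
One long recording (e.g. the first 9 min of S-phase) is split into
fixed-length intervals (default 60 s); each interval is smoothed with a
moving average, thresholded at ``median + k_sigma * robust sd`` of the
smoothed trace, and a peak is a maximal contiguous super-threshold run.
Recordings where a bright object (a centriole or yolk granule) drifts
into the spot produce a sustained rise in the rate and are rejected
whole.

Thresholding constants are declared package defaults, configurable per
run; peak counting is invariant to rescaling the trace because the
threshold is data-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from centrikit.trace import PhotonTrace

__all__ = ["PecosResult", "split_intervals", "count_peaks", "reject_transit"]

_MAD_TO_SD = 1.4826  # consistency factor: MAD of a Gaussian -> sd


@dataclass
class PecosResult:
    """Burst count for one interval."""

    interval_index: int
    peak_count: int
    threshold: float  # counts per (smoothed) bin
    rejected: bool = False
    reason: str = ""
    flags: list[str] = field(default_factory=list)


def split_intervals(trace: PhotonTrace, interval: float = 60.0) -> list[PhotonTrace]:
    """Split a long recording into consecutive fixed-length intervals.

    Non-overlapping, in order; a trailing remainder shorter than
    ``interval`` is discarded.  A 540-s recording at 60-s intervals
    yields 9 intervals.
    """

    if interval <= 0:
        raise ValueError("interval must be positive")
    bins_per = int(round(interval / trace.bin_width))
    if bins_per < 1:
        raise ValueError("interval shorter than one bin")
    n_int = len(trace) // bins_per
    out = []
    for i in range(n_int):
        seg = trace.counts[i * bins_per : (i + 1) * bins_per].copy()
        out.append(PhotonTrace(seg, trace.bin_width, dict(trace.meta)))
    return out


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def count_peaks(
    trace: PhotonTrace,
    smoothing: float = 1e-3,
    k_sigma: float = 4.0,
    interval_index: int = 0,
) -> PecosResult:
    """Count bursts in one interval.

    ``smoothing`` is the moving-average window in seconds (default
    1 ms); the threshold is ``median + k_sigma * 1.4826 * MAD`` of the
    smoothed interval.  Bursts closer than the smoothing window merge
    into one maximal super-threshold run and count once.
    """

    if smoothing <= 0:
        raise ValueError("smoothing window must be positive")
    window = max(1, int(round(smoothing / trace.bin_width)))
    sm = _smooth(trace.counts, window)
    flags = []
    if not np.any(trace.counts):
        return PecosResult(interval_index, 0, 0.0, flags=["low_signal"])
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    sd = _MAD_TO_SD * mad
    if sd == 0.0:
        sd = float(np.std(sm))
        flags.append("zero_mad")
    threshold = med + k_sigma * sd
    above = sm > threshold
    # maximal contiguous runs above threshold
    edges = np.diff(above.astype(np.int8))
    n_peaks = int(np.sum(edges == 1)) + int(above[0])
    return PecosResult(interval_index, n_peaks, threshold, flags=flags)


def reject_transit(
    trace: PhotonTrace,
    window: float = 0.05,
    k_sigma: float = 5.0,
    dwell: float = 0.5,
) -> bool:
    """Flag a recording in which the count rate rises for a sustained time.

    The trace is smoothed with a ``window``-second moving average; the
    recording is rejected when the smoothed rate stays above
    ``median + k_sigma * robust sd`` for longer than ``dwell`` seconds
    (a centriole or granule drifting through the spot).  Single-bin
    spikes are shorter than the dwell and pass.
    """

    if dwell <= 0 or window <= 0:
        raise ValueError("window and dwell must be positive")
    w = max(1, int(round(window / trace.bin_width)))
    sm = _smooth(trace.counts, w)
    med = float(np.median(sm))
    sd = _MAD_TO_SD * float(np.median(np.abs(sm - med)))
    if sd == 0.0:
        sd = float(np.std(sm))
        if sd == 0.0:
            return False
    above = sm > med + k_sigma * sd
    dwell_bins = max(1, int(round(dwell / trace.bin_width)))
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    longest = int(np.max(ends - starts)) if len(starts) else 0
    return longest >= dwell_bins
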