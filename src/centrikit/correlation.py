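"""Autocorrelation of photon traces.

The multi-tau estimator computes the normalized intensity
autocorrelation

    G(tau) = <delta I(t) delta I(t + tau)> / <I>^2

on a quasi-logarithmic lag grid: ``m_per_stage`` linearly spaced lags
per stage, with the trace coarsened by a factor of two between stages.
Symmetric normalization (separate left/right means for each lag) is
used to suppress finite-trace bias; by construction the first stage
equals the direct lag-domain estimator exactly.

Also here: the per-embryo segment protocol (several consecutive 10-s
recordings, an erratic-curve screen, and a minimum number of surviving
segments for the embryo to be kept) and the detector background
correction of the apparent molecule number and brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from centrikit.trace import PhotonTrace

__all__ = [
    "CorrelationCurve",
    "ScreenReport",
    "multi_tau_acf",
    "direct_acf",
    "segment_and_screen",
    "background_correct",
]


@dataclass
class CorrelationCurve:
    """A correlation curve with its acquisition statistics.

    ``lags`` are strictly increasing lag times in seconds; ``g`` the
    dimensionless correlation amplitudes; ``mean_rate`` the mean count
    rate of the underlying trace (counts/s).  ``flags`` collects
    estimator warnings (e.g. undefined normalization on an empty trace).
    """

    lags: np.ndarray
    g: np.ndarray
    mean_rate: float
    duration: float
    n_segments_kept: int = 1
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have the same length")
        if len(self.lags) > 1 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")

    @property
    def valid(self) -> bool:
        return "undefined_normalization" not in self.flags

    def restrict(self, lag_min: float, lag_max: float) -> "CorrelationCurve":
        """Return the sub-curve with ``lag_min <= lag <= lag_max``."""
        sel = (self.lags >= lag_min) & (self.lags <= lag_max)
        return CorrelationCurve(
            self.lags[sel], self.g[sel], self.mean_rate, self.duration,
            self.n_segments_kept, list(self.flags),
        )


def _sym_norm_g(counts: np.ndarray, k: int) -> float:
    """Symmetrically normalized correlation of one lag, in bin units."""
    left = counts[:-k]
    right = counts[k:]
    ml = left.mean()
    mr = right.mean()
    if ml == 0.0 or mr == 0.0:
        return np.nan
    return float(np.dot(left, right) / left.size / (ml * mr) - 1.0)


def direct_acf(trace: PhotonTrace, max_lag_bins: int) -> CorrelationCurve:
    """Direct O(n * k) estimator on a linear lag grid of 1..max_lag_bins.

    Serves as the brute-force oracle for the multi-tau estimator; both
    use identical symmetric normalization.
    """
    counts = trace.counts.astype(np.float64)
    g = np.array([_sym_norm_g(counts, k) for k in range(1, max_lag_bins + 1)])
    lags = np.arange(1, max_lag_bins + 1) * trace.bin_width
    flags = ["undefined_normalization"] if np.any(np.isnan(g)) else []
    return CorrelationCurve(lags, np.nan_to_num(g), trace.mean_rate, trace.duration, flags=flags)


def multi_tau_acf(
    trace: PhotonTrace,
    m_per_stage: int = 16,
    max_lag: Optional[float] = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon trace.

    Stage 0 evaluates lags of 1..m bins at the native bin width; each
    later stage halves the time resolution (averaging bin pairs) and
    evaluates lags of m/2+1..m coarse bins.  Stages are added while the
    coarsened trace retains at least ``2 * m_per_stage`` bins and the
    lag does not exceed ``max_lag`` (default: an eighth of the trace).
    """

    if m_per_stage < 4 or m_per_stage % 2:
        raise ValueError("m_per_stage must be an even integer >= 4")
    if len(trace) < 2 * m_per_stage:
        raise ValueError("trace too short for the requested lag grid")
    if max_lag is None:
        max_lag = trace.duration / 8.0

    counts = trace.counts.astype(np.float64)
    bw = trace.bin_width
    lags: list[float] = []
    g: list[float] = []
    flags: list[str] = []
    stage = 0
    while True:
        ks = range(1, m_per_stage + 1) if stage == 0 else range(m_per_stage // 2 + 1, m_per_stage + 1)
        scale = bw * (2 ** stage)
        done = False
        for k in ks:
            tau = k * scale
            if tau > max_lag:
                done = True
                break
            val = _sym_norm_g(counts, k)
            if np.isnan(val):
                if "undefined_normalization" not in flags:
                    flags.append("undefined_normalization")
                val = 0.0
            lags.append(tau)
            g.append(val)
        if done:
            break
        n2 = len(counts) // 2
        if n2 < 2 * m_per_stage:
            break
        counts = 0.5 * (counts[: 2 * n2 : 2] + counts[1 : 2 * n2 : 2])
        stage += 1
    return CorrelationCurve(
        np.asarray(lags), np.asarray(g), trace.mean_rate, trace.duration, flags=flags
    )


@dataclass
class ScreenReport:
    """Outcome of the segment screen for one embryo."""

    kept: list[CorrelationCurve]
    discarded: list[tuple[int, str]]  # (segment index, reason)
    embryo_kept: bool


def _erratic(curve: CorrelationCurve, tail_fraction: float) -> bool:
    """Tail-decay screen: the last decade of lags must fall below
    ``tail_fraction`` of the initial amplitude."""
    if len(curve.lags) < 8 or not curve.valid:
        return True
    amp = float(np.mean(curve.g[:5]))
    if amp <= 0.0:
        # flat/noise-only curve: nothing erratic to reject
        return False
    tail_sel = curve.lags >= curve.lags[-1] / 10.0
    tail = float(np.mean(curve.g[tail_sel]))
    return tail > tail_fraction * amp


def segment_and_screen(
    traces: Sequence[PhotonTrace],
    n_required: int = 4,
    m_per_stage: int = 16,
    rate_tolerance: float = 0.5,
    tail_fraction: float = 0.2,
    max_lag: Optional[float] = None,
) -> ScreenReport:
    """Correlate each segment of one embryo and screen out erratic ones.

    A segment is discarded when (a) its mean count rate deviates from
    the embryo median by more than ``rate_tolerance`` (fractional), or
    (b) its correlation curve fails to decay: the mean G over the
    longest decade of lags stays above ``tail_fraction`` of the initial
    amplitude.  The embryo is retained only when at least ``n_required``
    segments survive.
    """

    rates = np.array([t.mean_rate for t in traces], dtype=float)
    median_rate = float(np.median(rates)) if len(rates) else 0.0
    kept: list[CorrelationCurve] = []
    discarded: list[tuple[int, str]] = []
    for i, t in enumerate(traces):
        if median_rate > 0 and abs(t.mean_rate - median_rate) > rate_tolerance * median_rate:
            discarded.append((i, "count_rate_deviation"))
            continue
        curve = multi_tau_acf(t, m_per_stage=m_per_stage, max_lag=max_lag)
        if _erratic(curve, tail_fraction):
            discarded.append((i, "erratic_acf"))
            continue
        kept.append(curve)
    return ScreenReport(kept=kept, discarded=discarded, embryo_kept=len(kept) >= n_required)


def background_correct(n_app: float, rate: float, bg_rate: float) -> tuple[float, float]:
    """Correct apparent molecule number and brightness for background.

    An uncorrelated background at ``bg_rate`` dilutes the correlation
    amplitude by the squared signal fraction, so

        N_corr   = N_app * (1 - bg_rate / rate)^2
        CPM_corr = (rate - bg_rate) / N_corr

    Returns ``(N_corr, CPM_corr)``.
    """

    if bg_rate < 0:
        raise ValueError("background rate must be non-negative")
    if bg_rate >= rate:
        raise ValueError("background rate must be below the total count rate")
    if n_app <= 0:
        raise ValueError("apparent N must be positive")
    n_corr = n_app * (1.0 - bg_rate / rate) ** 2
    cpm_corr = (rate - bg_rate) / n_corr
    return n_corr, cpm_corr
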