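"""Kinetic models of centriolar recruitment.

Two growth models are fitted to each (per-embryo mean) intensity
series:

* linear growth + plateau: ``I(t) = b + r * min(t, t_p)`` — constant
  incorporation rate ``r`` until the breakpoint ``t_p`` (the growth
  period), then a constant plateau ``b + r * t_p`` (the centriole-size
  proxy);
* linear growth only: ``I(t) = b + r * t``.

The preferred model is the one with the lower small-sample Akaike
criterion (AICc; an extra-sum-of-squares F-test is available as an
alternative).  Oscillatory recruitment (Plk4-like) is fitted with a
Lorentzian ``I(t) = baseline + A w^2 / ((t - t0)^2 + w^2)`` whose
maximal intensity is ``baseline + A`` and full width at half maximum is
``2 w``.  Peak metrics (initial/maximal intensity, time of maximum =
onset of decline) are read from a lightly smoothed series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from centrikit.series import CentrioleSeries

__all__ = [
    "GrowthFit",
    "OscillationFit",
    "PeakMetrics",
    "fit_growth",
    "fit_lorentzian",
    "peak_metrics",
    "period_vs_sphase",
]


@dataclass
class GrowthFit:
    """Parameters of the selected growth model.

    ``plateau`` is ``b + r * t_p`` (linear+plateau only); ``aicc`` maps
    model name to its criterion value and ``chosen`` names the winner.
    """

    model: str  # "linear_plateau" or "linear_only"
    b: float
    r: float
    t_p: Optional[float]
    plateau: Optional[float]
    rss: float
    n_points: int
    aicc: dict[str, float] = field(default_factory=dict)
    warning: str = ""


@dataclass
class OscillationFit:
    amplitude: float  # maximal intensity, baseline + A
    t0: float  # peak time, min
    fwhm: float  # min
    baseline: float
    rss: float = np.nan
    flagged: str = ""


@dataclass
class PeakMetrics:
    initial: float
    maximum: float
    t_max: float  # min, relative to the series anchor
    decline_onset: Optional[float]  # = t_max; None when max is at the boundary


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _fit_linear(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line fit; returns (b, r, rss)."""
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return float(coef[0]), float(coef[1]), rss


def _plateau_rss(t: np.ndarray, y: np.ndarray, t_p: float) -> tuple[float, float, float]:
    """Conditional linear solve of (b, r) for fixed breakpoint."""
    design = np.column_stack([np.ones_like(t), np.minimum(t, t_p)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return float(coef[0]), float(coef[1]), rss


def fit_growth(
    series: CentrioleSeries,
    criterion: str = "aicc",
    f_test_alpha: float = 0.05,
) -> GrowthFit:
    """Fit both growth models and keep the preferred one.

    The breakpoint of the linear+plateau model is profiled over interior
    timepoints and refined by bounded scalar minimization (the other two
    parameters solve in closed form at each candidate).  ``criterion``
    is ``"aicc"`` (default) or ``"ftest"`` (extra-sum-of-squares F test:
    the plateau model wins when p < ``f_test_alpha``).
    """

    t = series.times
    y = series.intensities
    if len(t) < 8:
        raise ValueError("need at least 8 timepoints")
    if criterion not in ("aicc", "ftest"):
        raise ValueError("criterion must be 'aicc' or 'ftest'")

    b_lin, r_lin, rss_lin = _fit_linear(t, y)
    warning = ""
    if np.ptp(y) < 1e-12:
        return GrowthFit(
            model="linear_only", b=b_lin, r=0.0, t_p=None, plateau=None,
            rss=rss_lin, n_points=len(t),
            aicc={"linear_only": _aicc(rss_lin, len(t), 2)},
            warning="constant_series",
        )

    # profile the breakpoint over interior timepoints, then refine
    interior = t[1:-1]
    rss_grid = [(_plateau_rss(t, y, tp)[2], tp) for tp in interior]
    best_rss, best_tp = min(rss_grid)
    lo = max(t[0], best_tp - (t[1] - t[0]) * 2)
    hi = min(t[-1], best_tp + (t[1] - t[0]) * 2)
    res = optimize.minimize_scalar(
        lambda tp: _plateau_rss(t, y, tp)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    t_p = float(res.x) if res.fun <= best_rss else float(best_tp)
    b_pl, r_pl, rss_pl = _plateau_rss(t, y, t_p)

    n = len(t)
    aicc = {"linear_only": _aicc(rss_lin, n, 2), "linear_plateau": _aicc(rss_pl, n, 3)}
    if criterion == "aicc":
        choose_plateau = aicc["linear_plateau"] < aicc["linear_only"]
    else:
        if rss_pl <= 0 or n <= 3:
            choose_plateau = True
        else:
            f = (rss_lin - rss_pl) / 1 / (rss_pl / (n - 3))
            p = stats.f.sf(max(f, 0.0), 1, n - 3)
            choose_plateau = p < f_test_alpha

    if choose_plateau:
        return GrowthFit(
            model="linear_plateau", b=b_pl, r=r_pl, t_p=t_p,
            plateau=b_pl + r_pl * t_p, rss=rss_pl, n_points=n, aicc=aicc,
            warning=warning,
        )
    return GrowthFit(
        model="linear_only", b=b_lin, r=r_lin, t_p=None, plateau=None,
        rss=rss_lin, n_points=n, aicc=aicc, warning=warning,
    )


def fit_lorentzian(series: CentrioleSeries) -> OscillationFit:
    """Fit a Lorentzian pulse; amplitude is the maximal intensity.

    ``I(t) = baseline + A w^2 / ((t - t0)^2 + w^2)``; the reported
    amplitude is ``baseline + A``, the period proxy is the FWHM ``2 w``.
    A series whose maximum sits on the boundary is flagged
    non-oscillatory.
    """

    t = series.times
    y = series.intensities
    if len(t) < 8:
        raise ValueError("need at least 8 timepoints")
    imax = int(np.argmax(y))
    if imax in (0, len(t) - 1):
        return OscillationFit(np.nan, np.nan, np.nan, np.nan, flagged="no_interior_maximum")
    base0 = float(np.min(y))
    a0 = float(y[imax] - base0) or 1e-6
    t00 = float(t[imax])
    w0 = max((t[-1] - t[0]) / 6.0, 1e-3)
    model = lambda t, base, a, t0, w: base + a * w ** 2 / ((t - t0) ** 2 + w ** 2)
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(base0, a0, t00, w0),
            bounds=([-np.inf, 0.0, t[0], 1e-6], [np.inf, np.inf, t[-1], np.inf]),
            maxfev=20000,
        )
    except Exception:
        return OscillationFit(np.nan, np.nan, np.nan, np.nan, flagged="fit_failed")
    base, a, t0, w = (float(v) for v in popt)
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return OscillationFit(amplitude=base + a, t0=t0, fwhm=2.0 * w, baseline=base, rss=rss)


def peak_metrics(series: CentrioleSeries, smoothing_window: int = 3) -> PeakMetrics:
    """Initial and maximal intensity and the time recruitment turns over.

    The maximum is located on a centred moving average (default 3
    frames); the decline onset is defined as that argmax and reported as
    None (undefined-at-boundary) for monotonically rising series.
    """

    y = series.intensities
    t = series.times
    if smoothing_window < 1:
        raise ValueError("smoothing window must be >= 1")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        sm = np.convolve(y, kernel, mode="same")
        # edges of a centred moving average are biased; use raw values there
        half = smoothing_window // 2
        sm[:half] = y[:half]
        sm[-half:] = y[-half:]
    else:
        sm = y.astype(float)
    imax = int(np.argmax(sm))
    at_boundary = imax == len(t) - 1
    return PeakMetrics(
        initial=float(y[0]),
        maximum=float(sm[imax]),
        t_max=float(t[imax]),
        decline_onset=None if at_boundary else float(t[imax]),
    )


def period_vs_sphase(
    pairs: Sequence[tuple[float, float]],
) -> dict[str, float]:
    """Pearson correlation and OLS line of growth period vs S-phase length.

    ``pairs`` are per-embryo ``(growth_period, s_phase_length)`` tuples;
    returns r, the two-sided p value, and the regression slope and
    intercept of period on S-phase length.
    """

    if len(pairs) < 3:
        raise ValueError("need at least 3 embryos")
    period = np.array([p[0] for p in pairs], dtype=float)
    sphase = np.array([p[1] for p in pairs], dtype=float)
    lin = stats.linregress(sphase, period)
    return {
        "r": float(lin.rvalue),
        "p": float(lin.pvalue),
        "slope": float(lin.slope),
        "intercept": float(lin.intercept),
        "n": len(pairs),
    }
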