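"""FCS model fitting, model selection and derived quantities.

Correlation curves are fitted with the anomalous-diffusion model

    G(tau) = offset + X_T(tau) X_B(tau) (1/N)
             * sum_i f_i (1 + (tau/tau_Di)^alpha)^-1
                        (1 + (tau/tau_Di)^alpha / AR^2)^-1/2

with one or two diffusing species and up to two multiplicative dark
states,

    X_T(tau) = (1 - T + T exp(-tau/tau_T)) / (1 - T),

and analogously X_B.  The structural parameter AR (axial/lateral radius
ratio) is held fixed at 5; the triplet correlation time is bounded to
1-10 us and the blinking time to 10-300 us.  The 2 x 4 grid of
{1, 2 species} x {no dark state, triplet, blink, triplet+blink} gives
the eight candidate models; the anomalous-subdiffusion exponent alpha
is scanned on a 0.05 grid, and the model/alpha combination minimizing
the summed Bayesian information criterion over a calibration set of
curves is then applied to every measurement of the same protein.

Derived per-recording quantities: concentration C = N / (V_eff N_A),
diffusion coefficient D = omega_xy^2 / (4 tau_D) (apparent when
alpha != 1) and molecular brightness CPM = (rate - background) / N.
Outlier removal follows the ROUT scheme: a robust (Lorentzian-weighted)
fit, a robust scale from the 68.27th percentile of absolute residuals,
and a false-discovery-rate step at rate Q on the residual t statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from centrikit.correlation import CorrelationCurve, background_correct
from centrikit.volume import ObservationVolume, concentration_nM

__all__ = [
    "FcsModelSpec",
    "FcsFitResult",
    "EmbryoSummary",
    "MODEL_GRID",
    "model_g",
    "fit_curve",
    "select_model",
    "derive_quantities",
    "expected_cpm_ratio",
    "rout_filter",
    "aggregate_embryo",
]

_DARK_STATES = ("none", "triplet", "blink", "triplet_blink")

#: fitting bounds for the dark-state correlation times, seconds
TRIPLET_TAU_BOUNDS = (1e-6, 1e-5)
BLINK_TAU_BOUNDS = (1e-5, 3e-4)

#: lag fitting range, seconds (upper limit 200 ms, or 3,000 ms for
#: slow-diffusing proteins — configurable per fit)
DEFAULT_FIT_RANGE = (0.4e-9, 0.2)

_AR_DEFAULT = 5.0


@dataclass(frozen=True)
class FcsModelSpec:
    """One candidate model: species count, dark-state structure, alpha."""

    n_species: int = 1
    dark: str = "none"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_species not in (1, 2):
            raise ValueError("n_species must be 1 or 2")
        if self.dark not in _DARK_STATES:
            raise ValueError(f"dark must be one of {_DARK_STATES}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def has_triplet(self) -> bool:
        return self.dark in ("triplet", "triplet_blink")

    @property
    def has_blink(self) -> bool:
        return self.dark in ("blink", "triplet_blink")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["N", "tau_d1"]
        if self.n_species == 2:
            names += ["tau_d2", "f1"]
        if self.has_triplet:
            names += ["T", "tau_t"]
        if self.has_blink:
            names += ["B", "tau_b"]
        names.append("offset")
        return tuple(names)

    @property
    def k_free(self) -> int:
        return len(self.param_names)

    def with_alpha(self, alpha: float) -> "FcsModelSpec":
        return FcsModelSpec(self.n_species, self.dark, alpha)


#: the eight-model grid (alpha is selected separately)
MODEL_GRID: tuple[FcsModelSpec, ...] = tuple(
    FcsModelSpec(ns, dark) for ns in (1, 2) for dark in _DARK_STATES
)


def model_g(
    spec: FcsModelSpec,
    params: dict[str, float],
    lags: np.ndarray,
    ar: float = _AR_DEFAULT,
) -> np.ndarray:
    """Evaluate the model correlation function at the given lags (s)."""

    tau = np.asarray(lags, dtype=float)
    n = params["N"]
    alpha = spec.alpha
    if spec.n_species == 1:
        fracs = ((1.0, params["tau_d1"]),)
    else:
        f1 = params["f1"]
        if not 0.0 <= f1 <= 1.0:
            raise ValueError("f1 must be in [0, 1]")
        fracs = ((f1, params["tau_d1"]), (1.0 - f1, params["tau_d2"]))
    diff = np.zeros_like(tau)
    for f, tau_d in fracs:
        if tau_d <= 0:
            raise ValueError("diffusion times must be positive")
        u = (tau / tau_d) ** alpha
        diff += f / ((1.0 + u) * np.sqrt(1.0 + u / ar ** 2))
    g = diff / n
    if spec.has_triplet:
        t_frac, tau_t = params["T"], params["tau_t"]
        g *= (1.0 - t_frac + t_frac * np.exp(-tau / tau_t)) / (1.0 - t_frac)
    if spec.has_blink:
        b_frac, tau_b = params["B"], params["tau_b"]
        g *= (1.0 - b_frac + b_frac * np.exp(-tau / tau_b)) / (1.0 - b_frac)
    return g + params.get("offset", 0.0)


@dataclass
class FcsFitResult:
    """A fitted model with goodness-of-fit and derived quantities."""

    spec: FcsModelSpec
    params: dict[str, float]
    rss: float
    n_points: int
    bic: float
    mean_rate: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    derived: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


def _bic(rss: float, n: int, k: int, scale: float) -> float:
    # floor the residual scale near machine precision so that noise-free
    # comparisons between nested models are decided by the k ln(n) penalty
    floor = n * (1e-7 * max(scale, 1e-30)) ** 2
    return n * math.log(max(rss, floor) / n) + k * math.log(n)


def _initial_params(spec: FcsModelSpec, lags: np.ndarray, g: np.ndarray) -> dict[str, float]:
    amp = float(np.mean(g[: min(5, len(g))]))
    amp = amp if amp > 0 else 0.01
    n0 = 1.0 / amp
    half = amp / 2.0
    below = np.nonzero(g < half)[0]
    tau_d0 = float(lags[below[0]]) if len(below) else float(lags[len(lags) // 2])
    tau_d0 = max(tau_d0, float(lags[0]))
    p = {"N": n0, "tau_d1": tau_d0, "offset": 0.0}
    if spec.n_species == 2:
        p["tau_d2"] = tau_d0 * 10.0
        p["f1"] = 0.6
    if spec.has_triplet:
        p["T"] = 0.1
        p["tau_t"] = 3e-6
    if spec.has_blink:
        p["B"] = 0.1
        p["tau_b"] = 1e-4
    return p


def _bounds(spec: FcsModelSpec, fit_range: tuple[float, float]) -> tuple[list, list]:
    lo_tau, hi_tau = fit_range
    lower, upper = [], []
    for name in spec.param_names:
        if name == "N":
            lower.append(1e-4)
            upper.append(1e8)
        elif name in ("tau_d1", "tau_d2"):
            lower.append(lo_tau)
            upper.append(hi_tau * 10.0)
        elif name == "f1":
            lower.append(0.0)
            upper.append(1.0)
        elif name == "T":
            lower.append(0.0)
            upper.append(0.95)
        elif name == "tau_t":
            lower.append(TRIPLET_TAU_BOUNDS[0])
            upper.append(TRIPLET_TAU_BOUNDS[1])
        elif name == "B":
            lower.append(0.0)
            upper.append(0.95)
        elif name == "tau_b":
            lower.append(BLINK_TAU_BOUNDS[0])
            upper.append(BLINK_TAU_BOUNDS[1])
        elif name == "offset":
            lower.append(-0.5)
            upper.append(0.5)
    return lower, upper


def amplitude_snr(curve: CorrelationCurve) -> float:
    """Ratio of the initial correlation amplitude to the tail scatter.

    Used to recognize recordings too dim for FCS (the PeCoS regime),
    where the correlation amplitude is indistinguishable from noise.
    """
    if len(curve.g) < 12:
        return 0.0
    amp = float(np.mean(curve.g[:5]))
    tail = curve.g[curve.lags >= curve.lags[-1] / 10.0]
    noise = float(np.std(tail)) if len(tail) > 3 else float(np.std(curve.g))
    if noise <= 0:
        return np.inf if amp > 0 else 0.0
    return amp / noise


def fit_curve(
    curve: CorrelationCurve,
    spec: FcsModelSpec,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    ar: float = _AR_DEFAULT,
    weights: Optional[np.ndarray] = None,
    min_snr: float = 3.0,
) -> FcsFitResult:
    """Bounded least-squares fit of one model to one curve.

    Curves whose amplitude is below ``min_snr`` times the tail scatter
    are flagged ``amplitude_below_noise_floor`` and not fitted (the
    regime handled by peak counting instead); non-convergence is flagged
    rather than raised so callers can exclude the recording downstream.
    """

    sub = curve.restrict(*fit_range)
    if len(sub.lags) < 10:
        raise ValueError("fewer than 10 lags inside the fitting range")
    if amplitude_snr(sub) < min_snr:
        return FcsFitResult(
            spec=spec, params={}, rss=np.nan, n_points=len(sub.lags), bic=np.inf,
            mean_rate=curve.mean_rate, converged=False,
            flags=["amplitude_below_noise_floor"],
        )

    names = spec.param_names
    p0 = _initial_params(spec, sub.lags, sub.g)
    x0 = np.array([p0[n] for n in names], dtype=float)
    lower, upper = _bounds(spec, fit_range)
    x0 = np.clip(x0, lower, upper)
    w = np.ones_like(sub.g) if weights is None else np.asarray(weights, dtype=float)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(zip(names, x))
        return (model_g(spec, params, sub.lags, ar=ar) - sub.g) * w

    try:
        sol = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
        )
        converged = sol.status > 0 and np.all(np.isfinite(sol.x))
    except Exception:
        sol = None
        converged = False
    if sol is None or not converged:
        return FcsFitResult(
            spec=spec, params={}, rss=np.nan, n_points=len(sub.lags), bic=np.inf,
            mean_rate=curve.mean_rate, converged=False, flags=["fit_failed"],
        )
    params = dict(zip(names, sol.x))
    rss = float(np.sum((model_g(spec, params, sub.lags, ar=ar) - sub.g) ** 2))
    scale = float(np.max(np.abs(sub.g))) or 1.0
    bic = _bic(rss, len(sub.lags), spec.k_free, scale)
    return FcsFitResult(
        spec=spec, params=params, rss=rss, n_points=len(sub.lags), bic=bic,
        mean_rate=curve.mean_rate, converged=True,
    )


def pool_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Average correlation curves sharing one lag grid into a mean curve."""
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ValueError("curves must share a lag grid to be pooled")
    g = np.mean([c.g for c in curves], axis=0)
    return CorrelationCurve(
        lags.copy(), g,
        mean_rate=float(np.mean([c.mean_rate for c in curves])),
        duration=float(np.sum([c.duration for c in curves])),
        n_segments_kept=len(curves),
    )


def select_model(
    curves: Sequence[CorrelationCurve],
    alpha_grid_step: float = 0.05,
    alpha_range: tuple[float, float] = (0.5, 1.0),
    specs: Sequence[FcsModelSpec] = MODEL_GRID,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    ar: float = _AR_DEFAULT,
    pool: bool = True,
) -> tuple[FcsModelSpec, dict]:
    """Choose model and alpha by minimum summed BIC over calibration curves.

    With ``pool=True`` (default) the calibration curves are first
    averaged into their mean curve — fitting the segment-averaged ACF
    suppresses the per-segment noise that extra parameters would
    otherwise chase.  Every candidate (8 models x alpha grid) is fitted
    to each calibration curve; the spec minimizing the BIC total is
    returned together with the score table, and is meant to be applied
    to all measurements of the same protein.
    """

    if not curves:
        raise ValueError("at least one curve is required")
    calib: list[CorrelationCurve] = [pool_curves(curves)] if pool and len(curves) > 1 else list(curves)
    n_alpha = int(round((alpha_range[1] - alpha_range[0]) / alpha_grid_step)) + 1
    alphas = np.round(alpha_range[0] + alpha_grid_step * np.arange(n_alpha), 10)
    scores: dict[FcsModelSpec, float] = {}
    for base in specs:
        for alpha in alphas:
            cand = base.with_alpha(float(alpha))
            total = 0.0
            ok = False
            for curve in calib:
                res = fit_curve(curve, cand, fit_range=fit_range, ar=ar)
                if res.converged:
                    total += res.bic
                    ok = True
                else:
                    total += 1e9  # failed fit strongly penalized
            scores[cand] = total if ok else np.inf
    best = min(scores, key=lambda s: scores[s])
    if not np.isfinite(scores[best]):
        raise RuntimeError("all candidate fits failed")
    return best, {"scores": scores, "n_curves": len(curves)}


def derive_quantities(
    fit: FcsFitResult,
    volume: ObservationVolume,
    bg_rate: float = 0.0,
) -> dict[str, float]:
    """Concentration (nM), diffusion coefficient (um^2/s) and CPM (counts/s).

    ``D = omega_xy^2 / (4 tau_D)`` is the apparent diffusion coefficient
    when alpha != 1.  CPM uses the background-corrected N and rate.  For
    two-species fits the reported D is the fraction-weighted mean of the
    per-species values (also returned individually).  Results are stored
    in ``fit.derived`` and returned.
    """

    if not fit.converged:
        raise ValueError("cannot derive quantities from a failed fit")
    n_app = fit.params["N"]
    tau_d1 = fit.params["tau_d1"]
    if tau_d1 <= 0:
        raise ValueError("tau_D must be positive")
    if bg_rate > 0:
        n_corr, cpm = background_correct(n_app, fit.mean_rate, bg_rate)
    else:
        n_corr = n_app
        cpm = fit.mean_rate / n_app if n_app > 0 else np.nan
    conc = concentration_nM(n_corr, volume.v_eff)
    d1 = volume.omega_xy ** 2 / (4.0 * tau_d1)
    out = {"concentration": conc, "cpm": cpm, "n_corr": n_corr, "d_coef": d1, "d1": d1}
    if fit.spec.n_species == 2:
        d2 = volume.omega_xy ** 2 / (4.0 * fit.params["tau_d2"])
        f1 = fit.params["f1"]
        out["d2"] = d2
        out["d_coef"] = f1 * d1 + (1.0 - f1) * d2
    fit.derived.update(out)
    return out


def expected_cpm_ratio(n_subunits: int, p_mature: float) -> float:
    """FCS-apparent brightness ratio of an oligomer to a monomer.

    With each of ``n_subunits`` subunits independently fluorescent with
    probability ``p_mature``, the apparent molecule number comes from
    G(0) and is intensity-squared weighted, so the apparent CPM is
    E[k^2]/E[k] with k ~ Binomial(n, p): the ratio to the monomer is
    ``1 + (n - 1) p`` (a dimer with p = 0.7 is 1.7-fold brighter).
    """

    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if not 0.0 < p_mature <= 1.0:
        raise ValueError("p_mature must be in (0, 1] (0 leaves no visible particles)")
    return 1.0 + (n_subunits - 1) * p_mature


def rout_filter(values: Sequence[float], q: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier detection on scalar recordings (constant model).

    A robust location is fitted by iteratively reweighted least squares
    with Lorentzian weights; the robust scale RSDR is the 68.27th
    percentile of absolute residuals with the n/(n-K) small-sample
    correction; outliers are declared by a Benjamini-Hochberg FDR step
    at rate ``q`` (percent) on the two-tailed t statistics of the
    residuals.  Returns ``(kept_indices, flagged_indices)``.
    """

    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("at least 3 values required")
    if np.ptp(v) == 0:
        return np.arange(n), np.array([], dtype=int)

    k_free = 1
    m = float(np.median(v))
    scale = np.percentile(np.abs(v - m), 68.27) * n / (n - k_free)
    scale = scale if scale > 0 else float(np.std(v)) or 1.0
    for _ in range(100):
        r = v - m
        w = 1.0 / (1.0 + (r / scale) ** 2)
        m_new = float(np.sum(w * v) / np.sum(w))
        scale_new = np.percentile(np.abs(v - m_new), 68.27) * n / (n - k_free)
        if scale_new > 0:
            scale = scale_new
        if abs(m_new - m) < 1e-12 * max(1.0, abs(m)):
            m = m_new
            break
        m = m_new

    resid = v - m
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - k_free)
    if rsdr <= 0:
        return np.arange(n), np.array([], dtype=int)
    t = np.abs(resid) / rsdr
    pvals = 2.0 * stats.t.sf(t, df=n - k_free)
    order = np.argsort(pvals)
    q_frac = q / 100.0
    thresh = q_frac * (np.arange(1, n + 1)) / n
    passing = np.nonzero(pvals[order] <= thresh)[0]
    if len(passing) == 0:
        return np.arange(n), np.array([], dtype=int)
    cut = passing.max() + 1
    flagged = np.sort(order[:cut])
    kept = np.setdiff1d(np.arange(n), flagged)
    return kept, flagged


@dataclass
class EmbryoSummary:
    """Mean derived quantities over the kept recordings of one embryo."""

    concentration: float
    d_coef: float
    cpm: float
    n_kept: int
    timepoint: float
    kept: bool


def aggregate_embryo(
    recordings: Sequence[FcsFitResult],
    timepoint: float,
    min_kept: int = 4,
) -> EmbryoSummary:
    """Average derived quantities over one embryo's surviving recordings.

    ``recordings`` are post-outlier-removal fits from one embryo and
    timepoint; the embryo is dropped (``kept=False``) when fewer than
    ``min_kept`` remain, mirroring the at-least-4-of-6 recording rule.
    """

    good = [r for r in recordings if r.converged and r.derived]
    n = len(good)
    if n == 0:
        return EmbryoSummary(np.nan, np.nan, np.nan, 0, timepoint, False)
    mean = lambda key: float(np.mean([r.derived[key] for r in good]))
    return EmbryoSummary(
        concentration=mean("concentration"),
        d_coef=mean("d_coef"),
        cpm=mean("cpm"),
        n_kept=n,
        timepoint=timepoint,
        kept=n >= min_kept,
    )
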