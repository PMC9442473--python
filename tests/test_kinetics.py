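"""Growth-model fitting, model choice, oscillation fit, peak metrics."""

import numpy as np
import pytest

from centrikit.kinetics import (
    fit_growth,
    fit_lorentzian,
    peak_metrics,
    period_vs_sphase,
)
from centrikit.series import CentrioleSeries
from centrikit.synth import GrowthCurveConfig, simulate_growth_curves

T = np.arange(0, 13.01, 0.5)


def series(y, t=T):
    return CentrioleSeries(np.asarray(t, float), np.asarray(y, float))


def test_noise_free_plateau_recovered_exactly():
    y = 1.0 + 0.5 * np.minimum(T, 6.0)
    g = fit_growth(series(y))
    assert g.model == "linear_plateau"
    assert g.b == pytest.approx(1.0, abs=1e-6)
    assert g.r == pytest.approx(0.5, abs=1e-6)
    assert g.t_p == pytest.approx(6.0, abs=1e-6)
    assert g.plateau == pytest.approx(g.b + g.r * g.t_p, rel=1e-12)


def test_pure_line_prefers_linear_only():
    g = fit_growth(series(1.0 + 0.5 * T))
    assert g.model == "linear_only"
    assert g.t_p is None and g.plateau is None


def test_constant_series_warns_and_returns_zero_rate():
    g = fit_growth(series(np.full(T.size, 2.0)))
    assert g.model == "linear_only"
    assert g.r == pytest.approx(0.0, abs=1e-12)
    assert g.warning == "constant_series"


def test_needs_eight_timepoints():
    with pytest.raises(ValueError):
        fit_growth(series(np.arange(5.0), t=np.arange(5.0)))


def test_f_test_criterion_agrees_on_clean_plateau():
    rng = np.random.default_rng(0)
    y = 1.0 + 0.5 * np.minimum(T, 6.0) + rng.normal(0, 0.05, T.size)
    assert fit_growth(series(y), criterion="ftest").model == "linear_plateau"


def test_breakpoint_recovery_on_noisy_embryo_means():
    """At 10%-of-plateau noise per centriole, the per-embryo mean curve
    localizes the breakpoint within half a minute for >= 90% of embryos."""
    hits = 0
    n = 0
    for seed in range(5):
        cfg = GrowthCurveConfig(
            shape="linear_plateau", params={"b": 1.0, "r": 0.5, "t_p": 6.0},
            n_embryos=10, n_centrioles_per_embryo=10, noise_sd=0.4,
            centriole_to_centriole_sd=0.1, s_phase_sd=0.0, seed=seed,
        )
        coll = simulate_growth_curves(cfg)
        for e in coll.annotations:
            g = fit_growth(coll.embryo_mean(e))
            n += 1
            hits += g.t_p is not None and abs(g.t_p - 6.0) <= 0.5
    assert hits / n >= 0.9


def test_aicc_chooses_generating_model_as_noise_vanishes():
    """Selection consistency at three noise levels: the generating model
    wins more often as noise shrinks, and (near-)always at the lowest."""
    y_pl = 1.0 + 0.5 * np.minimum(T, 6.0)
    rates = []
    for noise in (0.8, 0.2, 0.02):
        correct = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            g = fit_growth(series(y_pl + rng.normal(0, noise, T.size)))
            correct += g.model == "linear_plateau"
        rates.append(correct / 20)
    assert rates[-1] >= 0.95
    assert rates[2] >= rates[0]


def test_lorentzian_exact_on_noise_free_input():
    y = 0.0 + 3.0 * 2.0 ** 2 / ((T - 6.0) ** 2 + 2.0 ** 2)
    fit = fit_lorentzian(series(y))
    assert fit.fwhm == pytest.approx(4.0, rel=1e-6)
    assert fit.amplitude == pytest.approx(3.0, rel=1e-6)
    assert fit.t0 == pytest.approx(6.0, abs=1e-6)


def test_lorentzian_flags_monotone_series():
    fit = fit_lorentzian(series(np.linspace(0, 1, T.size)))
    assert fit.flagged == "no_interior_maximum"


def test_lorentzian_peak_time_recovery_under_noise():
    truth = 0.2 + 3.0 * 2.0 ** 2 / ((T - 6.0) ** 2 + 2.0 ** 2)
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        fit = fit_lorentzian(series(truth + rng.normal(0, 0.15, T.size)))
        hits += not fit.flagged and abs(fit.t0 - 6.0) <= 0.5
    assert hits >= 18


def test_peak_metrics_of_rise_fall_series():
    cfg = GrowthCurveConfig(
        shape="rise_fall", params={"b": 0.2, "amplitude": 1.0, "peak_offset": -2.0},
        n_embryos=1, n_centrioles_per_embryo=1, noise_sd=0.0,
        centriole_to_centriole_sd=0.0, s_phase_sd=0.0, seed=0,
    )
    coll = simulate_growth_curves(cfg)
    s = coll.series[0]
    neb = coll.annotations[s.embryo_id]["NEB"]
    aligned = s.shifted(neb, anchor="NEB")
    pm = peak_metrics(aligned)
    assert pm.t_max == pytest.approx(-2.0, abs=0.5)
    assert pm.decline_onset == pm.t_max
    assert pm.maximum >= pm.initial


def test_peak_metrics_monotone_series_boundary_flag():
    pm = peak_metrics(series(np.linspace(1, 2, T.size)))
    assert pm.t_max == T[-1]
    assert pm.decline_onset is None


def test_peak_metrics_constant_series():
    pm = peak_metrics(series(np.full(T.size, 3.0)))
    assert pm.maximum == pytest.approx(pm.initial)


def test_exact_line_gives_unit_correlation():
    pairs = [(2.0 + 0.5 * s, s) for s in (10.0, 11.0, 12.0, 13.0)]
    out = period_vs_sphase(pairs)
    assert out["r"] == pytest.approx(1.0)
    assert out["slope"] == pytest.approx(0.5)


def test_correlation_invariant_to_affine_rescaling():
    rng = np.random.default_rng(5)
    s = rng.uniform(10, 16, 30)
    p = 0.4 * s + rng.normal(0, 0.3, 30)
    r1 = period_vs_sphase(list(zip(p, s)))["r"]
    r2 = period_vs_sphase(list(zip(3 * p + 1, 0.5 * s - 2)))["r"]
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_noise_dominated_pairs_give_small_correlation():
    rng = np.random.default_rng(6)
    s = rng.uniform(10, 16, 30)
    p = rng.normal(6.0, 0.5, 30)  # no dependence on S-phase
    assert abs(period_vs_sphase(list(zip(p, s)))["r"]) < 0.5


def test_inverse_rate_period_families_show_homeostasis_signature():
    """'Slow but long' vs 'fast but short' families: growth rate and
    period anti-correlate across families while the plateau stays put."""
    fits = []
    for r, t_p, seed in [(0.3, 10.0, 1), (0.5, 6.0, 2), (1.0, 3.0, 3)]:
        cfg = GrowthCurveConfig(
            shape="linear_plateau", params={"b": 1.0, "r": r, "t_p": t_p},
            n_embryos=5, n_centrioles_per_embryo=8, noise_sd=0.2,
            centriole_to_centriole_sd=0.05, s_phase_sd=0.0, seed=seed,
        )
        coll = simulate_growth_curves(cfg)
        for e in coll.annotations:
            g = fit_growth(coll.embryo_mean(e))
            if g.model == "linear_plateau":
                fits.append((g.r, g.t_p))
    rates = np.array([f[0] for f in fits])
    periods = np.array([f[1] for f in fits])
    assert np.corrcoef(rates, periods)[0, 1] < -0.5
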