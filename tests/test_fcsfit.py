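"""FCS model evaluation, fitting, BIC selection, derived quantities, ROUT."""

import numpy as np
import pytest

from centrikit.correlation import CorrelationCurve
from centrikit.fcsfit import (
    MODEL_GRID,
    FcsModelSpec,
    aggregate_embryo,
    derive_quantities,
    expected_cpm_ratio,
    fit_curve,
    model_g,
    pool_curves,
    rout_filter,
    select_model,
)
from centrikit.volume import DEFAULT_VOLUME


LAGS = np.geomspace(2e-6, 0.19, 120)


def _curve(spec, params, rate=1e5):
    return CorrelationCurve(LAGS, model_g(spec, params, LAGS), mean_rate=rate, duration=10.0)


def test_model_grid_enumerates_eight_models():
    assert len(MODEL_GRID) == 8
    assert len({(s.n_species, s.dark) for s in MODEL_GRID}) == 8


def test_zero_lag_amplitude_is_one_over_n():
    s = FcsModelSpec(1, "none", 0.8)
    g0 = model_g(s, {"N": 10, "tau_d1": 1e-3, "offset": 0.0}, np.array([1e-15]))[0]
    assert g0 == pytest.approx(0.1, rel=1e-6)


def test_value_at_tau_d_closed_form():
    s = FcsModelSpec(1, "none", 1.0)
    g = model_g(s, {"N": 10, "tau_d1": 1e-3, "offset": 0.0}, np.array([1e-3]))[0]
    assert g == pytest.approx(0.5 * (1 + 1 / 25) ** -0.5 / 10, rel=1e-12)
    assert g == pytest.approx(0.04903, abs=1e-5)


def test_triplet_amplifies_zero_lag():
    s = FcsModelSpec(1, "triplet", 1.0)
    g0 = model_g(s, {"N": 10, "tau_d1": 1e-3, "T": 0.2, "tau_t": 5e-6, "offset": 0.0},
                 np.array([1e-15]))[0]
    assert g0 == pytest.approx(1 / (10 * 0.8), rel=1e-9)


def test_matches_textbook_3d_diffusion_form():
    """alpha=1, no dark state equals the standard 3D ACF at random lags."""
    s = FcsModelSpec(1, "none", 1.0)
    rng = np.random.default_rng(0)
    taus = rng.uniform(1e-6, 0.1, 10)
    n, tau_d, ar = 7.3, 2.4e-3, 5.0
    ours = model_g(s, {"N": n, "tau_d1": tau_d, "offset": 0.0}, taus)
    textbook = 1.0 / (n * (1 + taus / tau_d) * np.sqrt(1 + taus / (ar ** 2 * tau_d)))
    assert np.allclose(ours, textbook, rtol=1e-12)


def test_fit_recovers_noise_free_parameters():
    s = FcsModelSpec(1, "none", 1.0)
    truth = {"N": 5.0, "tau_d1": 1e-3, "offset": 0.0}
    res = fit_curve(_curve(s, truth), s)
    assert res.converged
    assert res.params["N"] == pytest.approx(5.0, rel=1e-3)
    assert res.params["tau_d1"] == pytest.approx(1e-3, rel=1e-3)


def test_fit_recovers_triplet_and_blink_parameters():
    s = FcsModelSpec(1, "triplet_blink", 1.0)
    truth = {"N": 5.0, "tau_d1": 1e-3, "T": 0.2, "tau_t": 5e-6,
             "B": 0.15, "tau_b": 1e-4, "offset": 0.0}
    res = fit_curve(_curve(s, truth), s)
    assert res.params["T"] == pytest.approx(0.2, rel=0.01)
    assert res.params["tau_t"] == pytest.approx(5e-6, rel=0.02)
    assert res.params["B"] == pytest.approx(0.15, rel=0.02)


def test_bic_penalty_prefers_fewer_parameters_at_equal_rss():
    from centrikit.fcsfit import _bic

    assert _bic(1e-4, 100, 3, 1.0) < _bic(1e-4, 100, 5, 1.0)


def test_two_species_never_preferred_on_noise_free_one_species_curve():
    s1 = FcsModelSpec(1, "none", 1.0)
    curve = _curve(s1, {"N": 5.0, "tau_d1": 1e-3, "offset": 0.0})
    spec, _ = select_model([curve], alpha_range=(1.0, 1.0), pool=False)
    assert spec.n_species == 1
    assert spec.dark == "none"


def test_dim_curve_flagged_below_noise_floor():
    rng = np.random.default_rng(1)
    noise = CorrelationCurve(LAGS, rng.normal(0, 1e-3, LAGS.size), mean_rate=5e3, duration=10.0)
    res = fit_curve(noise, FcsModelSpec(1, "none", 1.0))
    assert not res.converged
    assert "amplitude_below_noise_floor" in res.flags


def test_pool_curves_averages_and_requires_common_grid():
    s = FcsModelSpec(1, "none", 1.0)
    c1 = _curve(s, {"N": 4.0, "tau_d1": 1e-3, "offset": 0.0})
    c2 = _curve(s, {"N": 8.0, "tau_d1": 1e-3, "offset": 0.0})
    pooled = pool_curves([c1, c2])
    assert pooled.g[0] == pytest.approx((c1.g[0] + c2.g[0]) / 2)
    with pytest.raises(ValueError):
        pool_curves([c1, CorrelationCurve(LAGS[:50], c2.g[:50], 1e5, 10.0)])


# -------------------------------------------------------- derived quantities


def test_concentration_single_molecule():
    s = FcsModelSpec(1, "none", 1.0)
    res = fit_curve(_curve(s, {"N": 1.0, "tau_d1": 1e-3, "offset": 0.0}), s)
    d = derive_quantities(res, DEFAULT_VOLUME)
    assert d["concentration"] == pytest.approx(6.64, abs=0.01)


def test_diffusion_coefficient_from_transit_time():
    s = FcsModelSpec(1, "none", 1.0)
    res = fit_curve(_curve(s, {"N": 5.0, "tau_d1": 4.32e-3, "offset": 0.0}), s)
    d = derive_quantities(res, DEFAULT_VOLUME)
    # omega_xy = 0.2079 um at V_eff = 0.25 fl, AR = 5 -> D = 2.50 um^2/s
    assert d["d_coef"] == pytest.approx(2.50, abs=0.01)


def test_cpm_times_n_equals_corrected_rate():
    s = FcsModelSpec(1, "none", 1.0)
    res = fit_curve(_curve(s, {"N": 5.0, "tau_d1": 1e-3, "offset": 0.0}, rate=2e5), s)
    d = derive_quantities(res, DEFAULT_VOLUME, bg_rate=3e4)
    assert d["cpm"] * d["n_corr"] == pytest.approx(2e5 - 3e4, rel=1e-12)


def test_concentration_roundtrip_machine_precision():
    from centrikit.volume import concentration_nM, molecules_per_um3

    n = 5.1234
    c = concentration_nM(n, DEFAULT_VOLUME.v_eff)
    assert molecules_per_um3(c) * DEFAULT_VOLUME.v_eff == pytest.approx(n, rel=1e-14)


# -------------------------------------------------------------- CPM ratio


def brute_force_cpm_ratio(n_subunits, p, n_draws=200_000, seed=0):
    """Enumeration-free oracle: intensity-squared-weighted brightness."""
    rng = np.random.default_rng(seed)
    k = rng.binomial(n_subunits, p, n_draws)
    return (k ** 2).mean() / k.mean()


@pytest.mark.parametrize("n_sub,p,expected", [(2, 1.0, 2.0), (2, 0.7, 1.7), (2, 1e-6, 1.0)])
def test_cpm_ratio_closed_form(n_sub, p, expected):
    assert expected_cpm_ratio(n_sub, p) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize("n_sub,p", [(2, 0.7), (3, 0.5), (4, 0.9)])
def test_cpm_ratio_matches_brute_force(n_sub, p):
    assert expected_cpm_ratio(n_sub, p) == pytest.approx(
        brute_force_cpm_ratio(n_sub, p), rel=0.01
    )


def test_cpm_ratio_rejects_zero_maturation():
    with pytest.raises(ValueError):
        expected_cpm_ratio(2, 0.0)


# ------------------------------------------------------------------- ROUT


def test_rout_flags_planted_outlier():
    kept, flagged = rout_filter([10, 11, 9, 10, 50], q=1.0)
    assert list(flagged) == [4]
    assert len(kept) == 4


def test_rout_keeps_identical_values():
    kept, flagged = rout_filter([3.0] * 6, q=1.0)
    assert len(flagged) == 0


def test_rout_needs_three_values():
    with pytest.raises(ValueError):
        rout_filter([1.0, 2.0], q=1.0)


def test_rout_false_flag_rate_on_clean_normals():
    fracs = []
    for seed in range(5):
        v = np.random.default_rng(seed).standard_normal(1000)
        _, flagged = rout_filter(v, q=1.0)
        fracs.append(len(flagged) / len(v))
    assert np.mean(fracs) <= 0.03


# -------------------------------------------------------------- aggregation


def _result(conc, d=2.5, cpm=2e4):
    res = type("R", (), {})()
    from centrikit.fcsfit import FcsFitResult

    r = FcsFitResult(spec=FcsModelSpec(1, "none", 1.0), params={"N": 5.0, "tau_d1": 1e-3},
                     rss=0.0, n_points=100, bic=0.0, mean_rate=1e5)
    r.derived = {"concentration": conc, "d_coef": d, "cpm": cpm}
    return r


def test_aggregate_means_over_recordings():
    recs = [_result(c) for c in (30.0, 32.0, 34.0, 36.0, 38.0)]
    s = aggregate_embryo(recs, timepoint=2.0)
    assert s.concentration == pytest.approx(34.0)
    assert s.n_kept == 5 and s.kept
    assert s.timepoint == 2.0


def test_embryo_dropped_when_fewer_than_four_remain():
    s = aggregate_embryo([_result(c) for c in (30.0, 31.0, 32.0)], timepoint=0.0)
    assert not s.kept


def test_identical_recordings_summary_equals_single():
    recs = [_result(33.0)] * 4
    s = aggregate_embryo(recs, timepoint=0.0)
    assert s.concentration == 33.0 and s.d_coef == 2.5 and s.cpm == 2e4
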