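"""Physics of the photon-trace simulator.

The key quantitative checks: the mean detected rate converges to the
analytic spatial average of the Gaussian detection profile, occupancy
statistics match the configured concentration, fractional Brownian
motion at alpha=1 reduces to plain diffusion, and the dark-state
telegraph chains have the right stationary statistics.
"""

import math

import numpy as np
import pytest

from centrikit.synth import (
    EmitterSpecies,
    TraceSimConfig,
    TransitEvent,
    expected_mean_rate,
    fbm_increments,
    simulate_trace,
    telegraph_states,
)
from centrikit.volume import DEFAULT_VOLUME

from conftest import make_trace_config


def test_no_emitters_no_background_gives_all_zero_counts():
    cfg = TraceSimConfig(duration=0.5, species=[], bin_width=1e-4, dt_sim=1e-4, seed=0)
    trace = simulate_trace(cfg)
    assert trace.duration == pytest.approx(0.5)
    assert not np.any(trace.counts)


def test_background_only_is_poisson_with_requested_rate():
    cfg = TraceSimConfig(duration=5.0, species=[], bin_width=1e-3, dt_sim=1e-3,
                         background_rate=2e4, seed=1)
    trace = simulate_trace(cfg)
    assert trace.mean_rate == pytest.approx(2e4, rel=0.02)


@pytest.mark.parametrize(
    "kwargs, err",
    [
        (dict(duration=1.0, bin_width=3e-5, dt_sim=2e-5), "integer multiple"),
        (dict(duration=1.0, box_factor=3.0), "box_factor"),
        (dict(duration=-1.0), "duration"),
    ],
)
def test_invalid_configs_rejected(kwargs, err):
    with pytest.raises(ValueError, match=err):
        TraceSimConfig(**kwargs)


def test_combined_dark_fraction_must_stay_below_one():
    with pytest.raises(ValueError):
        EmitterSpecies(d_coef=1.0, conc=1.0, epsilon=1e4,
                       triplet=(0.6, 5e-6), blink=(0.5, 1e-4))


def test_mean_rate_matches_analytic_within_5pct(conc_n5):
    """30-s trace at N=5: rate ~ N*eps/2^(3/2) plus background."""
    cfg = make_trace_config(conc_n5, seed=42, duration=30.0)
    trace = simulate_trace(cfg)
    expected = expected_mean_rate(cfg)
    assert expected == pytest.approx(5 * 1e5 / 2 ** 1.5, rel=0.01)
    assert trace.mean_rate == pytest.approx(expected, rel=0.05)


def test_expected_rate_scales_with_subunits_and_dark_states(conc_n5):
    base = make_trace_config(conc_n5, seed=0)
    dim = make_trace_config(conc_n5, seed=0, n_subunits=2, p_mature=0.5)
    dark = make_trace_config(conc_n5, seed=0, triplet=(0.2, 5e-6))
    assert expected_mean_rate(dim) == pytest.approx(expected_mean_rate(base), rel=1e-9)
    assert expected_mean_rate(dark) == pytest.approx(0.8 * expected_mean_rate(base), rel=1e-9)


def test_identical_seed_bit_identical_trace(conc_n5):
    a = simulate_trace(make_trace_config(conc_n5, seed=7, duration=0.5))
    b = simulate_trace(make_trace_config(conc_n5, seed=7, duration=0.5))
    c = simulate_trace(make_trace_config(conc_n5, seed=8, duration=0.5))
    assert np.array_equal(a.counts, b.counts)
    assert not np.array_equal(a.counts, c.counts)


def test_occupancy_matches_concentration(conc_n5):
    """Time-averaged molecule count in the 1/e^2 ellipsoid matches the
    analytic expectation within Poisson error."""
    cfg = make_trace_config(conc_n5, seed=3, duration=1.0, bin_width=1e-3)
    trace = simulate_trace(cfg, keep_paths=True)
    paths = trace.meta["paths"][0]  # (3, n_mol, n_steps)
    v = cfg.volume
    r2 = (paths[0] ** 2 + paths[1] ** 2) / v.omega_xy ** 2 + paths[2] ** 2 / v.omega_z ** 2
    inside = (r2 < 1.0).sum(axis=0)  # molecules inside per step
    ellipsoid_volume = 4.0 / 3.0 * math.pi * v.omega_xy ** 2 * v.omega_z
    expected = cfg.n_molecules(cfg.species[0]) / cfg.box_volume * ellipsoid_volume
    # ~1000 correlated samples of a Poisson(expected) count
    assert inside.mean() == pytest.approx(expected, rel=0.25)


def test_fbm_alpha_one_matches_brownian_increment_variance():
    rng = np.random.default_rng(0)
    inc = fbm_increments(rng, 3, 100_000, hurst=0.5, dt=1e-5, d_coef=2.5)
    assert inc.var() == pytest.approx(2 * 2.5 * 1e-5, rel=0.02)


def test_fbm_subdiffusive_msd_scaling():
    """Var[x(t)] = 2 D t^alpha for fBm with Hurst = alpha/2."""
    rng = np.random.default_rng(1)
    alpha, d_coef, dt = 0.8, 2.5, 1e-4
    inc = fbm_increments(rng, 200, 4096, hurst=alpha / 2, dt=dt, d_coef=d_coef)
    paths = np.cumsum(inc, axis=1)
    for k in (16, 256, 2048):
        msd = np.mean(paths[:, k - 1] ** 2)
        assert msd == pytest.approx(2 * d_coef * (k * dt) ** alpha, rel=0.25)


def test_telegraph_stationary_fraction_and_relaxation():
    rng = np.random.default_rng(2)
    frac, tau, dt = 0.25, 5e-6, 1e-6
    states = telegraph_states(rng, 200, 20_000, dt, frac, tau)
    bright = states.mean()
    assert bright == pytest.approx(1 - frac, abs=0.02)
    # autocorrelation of the state decays on ~tau
    s = states.astype(float) - bright
    ac = np.mean(s[:, :-5] * s[:, 5:]) / np.mean(s * s)
    assert ac == pytest.approx(math.exp(-5 * dt / tau), abs=0.1)


def test_oligomer_maturation_counts_recorded(conc_n5):
    cfg = make_trace_config(conc_n5, seed=5, duration=0.2, n_subunits=2, p_mature=0.7)
    trace = simulate_trace(cfg)
    truth = trace.meta["species"][0]
    n_mol = truth["n_molecules"]
    assert truth["n_mature_subunits"] == pytest.approx(2 * 0.7 * n_mol, rel=0.1)


def test_transit_event_elevates_rate_in_window(conc_n5):
    cfg = TraceSimConfig(
        duration=4.0, species=[], bin_width=1e-3, dt_sim=1e-3,
        background_rate=1e4, seed=9,
        transit_events=[TransitEvent(start=1.0, duration=1.0, brightness=3e5)],
    )
    trace = simulate_trace(cfg)
    t = trace.times
    inside = trace.counts[(t >= 1.2) & (t < 1.8)].mean()
    outside = trace.counts[t < 0.9].mean()
    assert inside > 3 * outside
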