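"""Shared fixtures: small, seeded simulation scenarios reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from centrikit.synth import EmitterSpecies, TraceSimConfig, simulate_trace
from centrikit.volume import DEFAULT_VOLUME


@pytest.fixture(scope="session")
def volume():
    return DEFAULT_VOLUME


@pytest.fixture(scope="session")
def conc_n5(volume):
    """Concentration putting on average 5 molecules in V_eff (~33 nM)."""
    return volume.concentration_for_occupancy(5.0)


def make_trace_config(conc, seed, duration=2.0, bin_width=2e-4, **species_kw):
    """A small free-diffusion scenario used by several modules' tests."""
    kw = dict(d_coef=2.5, conc=conc, epsilon=1e5)
    kw.update(species_kw)
    return TraceSimConfig(
        duration=duration,
        species=[EmitterSpecies(**kw)],
        volume=DEFAULT_VOLUME,
        box_factor=5.0,
        dt_sim=bin_width,
        bin_width=bin_width,
        seed=seed,
    )


@pytest.fixture(scope="session")
def diffusion_trace(conc_n5):
    """One 10-s free-diffusion trace at N=5, D=2.5 um^2/s."""
    return simulate_trace(make_trace_config(conc_n5, seed=11, duration=10.0))


@pytest.fixture(scope="session")
def short_diffusion_trace(conc_n5):
    """A 1-s trace for correlator-oracle comparisons."""
    return simulate_trace(make_trace_config(conc_n5, seed=23, duration=1.0))
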