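"""Synthetic centriole-intensity time courses with known kinetics.

Four canonical recruitment shapes are generated, mirroring the
behaviours seen for the core duplication proteins during a syncytial
nuclear cycle: linear incorporation that plateaus (Sas-6-like), pure
linear incorporation, a rise-then-fall peaking shortly before nuclear
envelope breakdown (Ana2-like), and a Lorentzian pulse (Plk4-like
oscillation).  Event annotations (centriole separation CS at cycle
start, NEB at the end of S-phase, mitosis entry) are emitted per embryo
so downstream alignment can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from centrikit.series import CentrioleSeries

__all__ = ["GrowthCurveConfig", "GrowthCurveCollection", "simulate_growth_curves"]

_SHAPES = ("linear_plateau", "linear_only", "rise_fall", "lorentzian")


@dataclass
class GrowthCurveConfig:
    """Configuration for :func:`simulate_growth_curves`.

    Shape parameters (``params``), all in minutes / signal units:

    * ``linear_plateau``: ``b`` (initial), ``r`` (rate per min), ``t_p``
      (breakpoint); plateau level is ``b + r * t_p``.
    * ``linear_only``: ``b``, ``r``.
    * ``rise_fall``: ``b``, ``amplitude``, ``peak_offset`` (minutes
      relative to NEB, negative = before NEB), ``fall_time``.
    * ``lorentzian``: ``baseline``, ``amplitude``, ``t0`` (peak time
      from cycle start), ``w`` (half-width at half-maximum).

    ``noise_sd`` is additive Gaussian noise per timepoint;
    ``centriole_to_centriole_sd`` is the s.d. of a per-centriole
    multiplicative brightness factor.  ``t_p_sphase_slope`` couples the
    per-embryo breakpoint to that embryo's S-phase length (minutes of
    breakpoint per minute of S-phase deviation), for studying the
    growth-period / S-phase relation.
    """

    shape: str
    params: dict = field(default_factory=dict)
    n_embryos: int = 10
    n_centrioles_per_embryo: int = 10
    frame_interval: float = 30.0  # seconds
    s_phase_length: float = 13.0  # minutes
    s_phase_sd: float = 0.0
    post_neb_minutes: float = 3.0
    noise_sd: float = 0.1
    centriole_to_centriole_sd: float = 0.1
    t_p_sphase_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {_SHAPES}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0 or self.centriole_to_centriole_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.s_phase_length <= 0:
            raise ValueError("s_phase_length must be positive")
        if self.shape == "linear_plateau":
            t_p = self.params.get("t_p", 0.0)
            if not 0.0 < t_p < self.s_phase_length:
                raise ValueError("breakpoint t_p must lie inside the sampled S-phase window")


@dataclass
class GrowthCurveCollection:
    """Simulated series plus per-embryo event annotations and config."""

    series: list[CentrioleSeries]
    annotations: dict[str, dict[str, float]]
    config: GrowthCurveConfig

    def embryo_mean(self, embryo_id: str) -> CentrioleSeries:
        """Mean intensity over the embryo's centrioles at each timepoint."""
        members = [s for s in self.series if s.embryo_id == embryo_id]
        if not members:
            raise KeyError(embryo_id)
        inten = np.mean([s.intensities for s in members], axis=0)
        return CentrioleSeries(
            members[0].times.copy(),
            inten,
            anchor=members[0].anchor,
            embryo_id=embryo_id,
            centriole_id="mean",
            meta=dict(members[0].meta),
        )


def _shape_values(shape: str, p: dict, t: np.ndarray, neb: float) -> np.ndarray:
    if shape == "linear_plateau":
        return p.get("b", 1.0) + p.get("r", 0.5) * np.minimum(t, p["t_p"])
    if shape == "linear_only":
        return p.get("b", 1.0) + p.get("r", 0.5) * t
    if shape == "rise_fall":
        b = p.get("b", 0.2)
        amp = p.get("amplitude", 1.0)
        t_peak = neb + p.get("peak_offset", -2.0)
        fall = p.get("fall_time", 4.0)
        rise = np.clip(t / max(t_peak, 1e-9), 0.0, 1.0)
        decay = np.clip(1.0 - (t - t_peak) / fall, 0.0, 1.0)
        return b + amp * np.where(t <= t_peak, rise, decay)
    if shape == "lorentzian":
        base = p.get("baseline", 0.2)
        amp = p.get("amplitude", 1.0)
        t0 = p.get("t0", 6.0)
        w = p.get("w", 2.0)
        return base + amp * w ** 2 / ((t - t0) ** 2 + w ** 2)
    raise ValueError(shape)


def simulate_growth_curves(
    config: GrowthCurveConfig,
    rng: Optional[np.random.Generator] = None,
) -> GrowthCurveCollection:
    """Generate noisy per-centriole recruitment curves with ground truth.

    Times are minutes from the start of the nuclear cycle (CS at t=0);
    the sampling window runs to NEB plus ``post_neb_minutes``.  Each
    series carries its true, noise-free parameters in ``meta``.
    """

    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt_min = config.frame_interval / 60.0
    series: list[CentrioleSeries] = []
    annotations: dict[str, dict[str, float]] = {}
    for e in range(config.n_embryos):
        embryo = f"embryo{e:03d}"
        s_len = config.s_phase_length + config.s_phase_sd * rng.standard_normal()
        s_len = max(s_len, 4 * dt_min)
        t = np.arange(0.0, s_len + config.post_neb_minutes + 1e-9, dt_min)
        params = dict(config.params)
        if config.shape == "linear_plateau":
            params["t_p"] = params["t_p"] + config.t_p_sphase_slope * (s_len - config.s_phase_length)
            params["t_p"] = float(np.clip(params["t_p"], dt_min, s_len - dt_min))
        truth = _shape_values(config.shape, params, t, neb=s_len)
        annotations[embryo] = {
            "cycle_start": 0.0,
            "CS": 0.0,
            "NEB": float(s_len),
            "mitosis_entry": float(s_len + config.post_neb_minutes),
            "s_phase_length": float(s_len),
        }
        for c in range(config.n_centrioles_per_embryo):
            factor = max(1.0 + config.centriole_to_centriole_sd * rng.standard_normal(), 0.05)
            noisy = truth * factor + config.noise_sd * rng.standard_normal(t.size)
            series.append(
                CentrioleSeries(
                    t,
                    noisy,
                    anchor="cycle_start",
                    embryo_id=embryo,
                    centriole_id=f"c{c:03d}",
                    meta={
                        "shape": config.shape,
                        "true_params": params,
                        "brightness_factor": factor,
                        "s_phase_length": float(s_len),
                    },
                )
            )
    return GrowthCurveCollection(series=series, annotations=annotations, config=config)
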