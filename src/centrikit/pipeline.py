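"""End-to-end pipeline driven by a YAML configuration.

Three independent stage groups can be configured:

* ``fcs`` — simulate per-embryo photon traces, correlate and screen the
  6 x 10-s segments, fit the configured (or BIC-selected) model, apply
  ROUT outlier removal to the derived per-recording quantities and
  aggregate per embryo;
* ``pecos`` — simulate one long dim-protein trace, split it into fixed
  intervals, reject transits and count peaks;
* ``imaging`` — simulate a spot movie, run the projection / bleach
  correction / background subtraction / detection / linking chain,
  extract per-centriole intensities and fit the growth kinetics.

Every run writes its tables plus one JSON manifest; rerunning with the
same config and seed reproduces all outputs bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from centrikit import fcsfit, kinetics, pecos, trackquant
from centrikit.correlation import segment_and_screen
from centrikit.io import ConfigError, RunManifest, load_config, validate_keys, write_table
from centrikit.series import CentrioleSeries
from centrikit.synth import (
    EmitterSpecies,
    SpotMovieConfig,
    TraceSimConfig,
    simulate_spot_movie,
    simulate_trace,
)
from centrikit.volume import DEFAULT_VOLUME

__all__ = ["CONFIG_SCHEMA", "run_pipeline"]

log = logging.getLogger("centrikit")

_SPECIES_SCHEMA = {
    "d_coef": None, "conc": None, "epsilon": None, "n_subunits": None,
    "p_mature": None, "alpha": None, "triplet": None, "blink": None,
}
_TRACE_SIM_SCHEMA = {
    "duration": None, "bin_width": None, "dt_sim": None, "box_factor": None,
    "background_rate": None, "species": _SPECIES_SCHEMA,
}

CONFIG_SCHEMA = {
    "seed": None,
    "out_dir": None,
    "log_level": None,
    "fcs": {
        "simulate": {**_TRACE_SIM_SCHEMA, "n_embryos": None, "traces_per_embryo": None},
        "screen": {"n_required": None, "rate_tolerance": None, "tail_fraction": None},
        "fit": {
            "n_species": None, "dark": None, "alpha": None, "select": None,
            "fit_range_max": None, "background_rate": None, "rout_q": None,
        },
    },
    "pecos": {
        "simulate": _TRACE_SIM_SCHEMA,
        "interval": None, "smoothing": None, "k_sigma": None,
    },
    "imaging": {
        "simulate": {
            "image_shape": None, "pixel_size": None, "n_pairs": None,
            "pair_separation_rate": None, "initial_separation": None,
            "spot_sigma": None, "spot_intensity": None, "axial_sigma": None,
            "bleach_rate": None, "background_level": None, "poisson_noise": None,
            "n_frames": None, "n_slices": None, "z_spacing": None, "frame_interval": None,
        },
        "track": {
            "diameter": None, "max_disp": None, "quality_threshold": None,
            "rolling_ball_radius": None,
        },
        "kinetics": {"model": None},
    },
}


def _species_from_cfg(cfg: dict) -> EmitterSpecies:
    kw = dict(cfg)
    for key in ("triplet", "blink"):
        if kw.get(key) is not None:
            kw[key] = tuple(kw[key])
    return EmitterSpecies(**kw)


def _trace_config(sim: dict, seed: int) -> TraceSimConfig:
    kw = {k: v for k, v in sim.items() if k not in ("species", "n_embryos", "traces_per_embryo")}
    species = [_species_from_cfg(sim["species"])]
    return TraceSimConfig(species=species, volume=DEFAULT_VOLUME, seed=seed, **kw)


def _run_fcs(cfg: dict, seed: int, out: Path) -> dict:
    sim = cfg["simulate"]
    n_embryos = sim.get("n_embryos", 1)
    per = sim.get("traces_per_embryo", 6)
    screen_cfg = cfg.get("screen", {})
    fit_cfg = cfg.get("fit", {})
    fit_range = (0.4e-9, fit_cfg.get("fit_range_max", 0.2))
    bg = fit_cfg.get("background_rate", 0.0)

    embryo_curves = []
    for e in range(n_embryos):
        traces = [
            simulate_trace(_trace_config(sim, seed=(seed * 100003 + e * 1009 + t) % 2**31))
            for t in range(per)
        ]
        report = segment_and_screen(traces, **screen_cfg)
        log.info("fcs embryo %d: kept %d/%d segments", e, len(report.kept), per)
        embryo_curves.append(report)

    all_kept = [c for rep in embryo_curves for c in rep.kept]
    if not all_kept:
        raise RuntimeError("no correlation curves survived the screen")
    if fit_cfg.get("select", False):
        spec, _ = fcsfit.select_model(all_kept, fit_range=fit_range)
    else:
        spec = fcsfit.FcsModelSpec(
            fit_cfg.get("n_species", 1), fit_cfg.get("dark", "none"), fit_cfg.get("alpha", 1.0)
        )

    rows = []
    fits_by_embryo: list[list[fcsfit.FcsFitResult]] = []
    for e, rep in enumerate(embryo_curves):
        fits = []
        for c in rep.kept:
            res = fcsfit.fit_curve(c, spec, fit_range=fit_range)
            if res.converged:
                fcsfit.derive_quantities(res, DEFAULT_VOLUME, bg_rate=bg)
                fits.append(res)
        fits_by_embryo.append(fits)

    # ROUT over all recordings of the protein, then per-embryo aggregation
    pooled = [f for fits in fits_by_embryo for f in fits]
    conc = [f.derived["concentration"] for f in pooled]
    if len(conc) >= 3:
        kept_idx, _ = fcsfit.rout_filter(conc, q=fit_cfg.get("rout_q", 1.0))
        kept_set = {id(pooled[i]) for i in kept_idx}
    else:
        kept_set = {id(f) for f in pooled}

    summaries = []
    for e, fits in enumerate(fits_by_embryo):
        survivors = [f for f in fits if id(f) in kept_set]
        summary = fcsfit.aggregate_embryo(survivors, timepoint=0.0)
        summaries.append(summary)
        for f in survivors:
            rows.append(
                {
                    "embryo": e, "n_fit": f.params.get("N", np.nan),
                    "tau_d_s": f.params.get("tau_d1", np.nan),
                    "concentration_nM": f.derived["concentration"],
                    "d_um2_s": f.derived["d_coef"], "cpm_cps": f.derived["cpm"],
                    "rate_cps": f.mean_rate,
                }
            )
    recordings = pd.DataFrame(rows)
    write_table(
        recordings, out / "fcs_recordings.csv",
        units={"embryo": "index", "n_fit": "molecules", "tau_d_s": "s",
               "concentration_nM": "nM", "d_um2_s": "um^2/s", "cpm_cps": "counts/s",
               "rate_cps": "counts/s"},
    )
    embryos = pd.DataFrame(
        [
            {"embryo": e, "concentration_nM": s.concentration, "d_um2_s": s.d_coef,
             "cpm_cps": s.cpm, "n_kept": s.n_kept, "kept": s.kept}
            for e, s in enumerate(summaries)
        ]
    )
    write_table(
        embryos, out / "fcs_embryos.csv",
        units={"embryo": "index", "concentration_nM": "nM", "d_um2_s": "um^2/s",
               "cpm_cps": "counts/s", "n_kept": "count", "kept": "bool"},
    )
    return {
        "model": {"n_species": spec.n_species, "dark": spec.dark, "alpha": spec.alpha},
        "n_recordings": len(recordings),
        "mean_concentration_nM": float(embryos["concentration_nM"].mean()),
        "mean_d_um2_s": float(embryos["d_um2_s"].mean()),
        "mean_cpm_cps": float(embryos["cpm_cps"].mean()),
    }


def _run_pecos(cfg: dict, seed: int, out: Path) -> dict:
    sim = cfg["simulate"]
    trace = simulate_trace(_trace_config(sim, seed=seed % 2**31))
    intervals = pecos.split_intervals(trace, cfg.get("interval", 60.0))
    rows = []
    for i, seg in enumerate(intervals):
        rejected = pecos.reject_transit(seg)
        if rejected:
            rows.append({"interval": i, "peak_count": -1, "threshold": np.nan,
                         "rejected": True})
            continue
        res = pecos.count_peaks(
            seg, smoothing=cfg.get("smoothing", 1e-3), k_sigma=cfg.get("k_sigma", 4.0),
            interval_index=i,
        )
        rows.append({"interval": i, "peak_count": res.peak_count,
                     "threshold": res.threshold, "rejected": False})
    df = pd.DataFrame(rows)
    write_table(df, out / "pecos_intervals.csv",
                units={"interval": "index", "peak_count": "count",
                       "threshold": "counts/bin", "rejected": "bool"})
    counted = df[~df["rejected"]]
    return {
        "n_intervals": len(df),
        "n_rejected": int(df["rejected"].sum()),
        "mean_peak_count": float(counted["peak_count"].mean()) if len(counted) else np.nan,
    }


def _run_imaging(cfg: dict, seed: int, out: Path) -> dict:
    sim_kw = dict(cfg["simulate"])
    if "image_shape" in sim_kw:
        sim_kw["image_shape"] = tuple(sim_kw["image_shape"])
    movie = simulate_spot_movie(SpotMovieConfig(seed=seed % 2**31, **sim_kw))
    tcfg = cfg.get("track", {})
    px = movie.pixel_size
    mip = np.stack([trackquant.max_project(s) for s in movie.frames])
    corrected, bleach_info = trackquant.bleach_correct(mip)
    processed = np.stack(
        [trackquant.rolling_ball(f, radius=tcfg.get("rolling_ball_radius", 10)) for f in corrected]
    )
    dets = [
        trackquant.detect_spots(
            f, diameter=tcfg.get("diameter", 1.1), pixel_size=px,
            quality_threshold=tcfg.get("quality_threshold"),
        )
        for f in processed
    ]
    tracks = trackquant.link_tracks(dets, max_disp=tcfg.get("max_disp", 0.5))
    complete = [t for t in tracks if t.complete]
    rows = []
    series = []
    dt_min = movie.config.frame_interval / 60.0
    for tr in complete:
        inten = trackquant.extract_intensity(processed, tr, tcfg.get("diameter", 1.1), px)
        series.append(CentrioleSeries(tr.frames * dt_min, inten, embryo_id="movie",
                                      centriole_id=f"t{tr.track_id}"))
        for i, f in enumerate(tr.frames):
            rows.append({"track": tr.track_id, "frame": int(f), "x_um": tr.x[i],
                         "y_um": tr.y[i], "intensity": inten[i]})
    write_table(pd.DataFrame(rows), out / "tracks.csv",
                units={"track": "id", "frame": "index", "x_um": "um", "y_um": "um",
                       "intensity": "AU"})
    summary: dict = {
        "n_tracks": len(tracks), "n_complete": len(complete),
        "bleach_rate_per_frame": bleach_info["b"],
    }
    model = cfg.get("kinetics", {}).get("model")
    if model and series:
        mean_series = CentrioleSeries(
            series[0].times, np.mean([s.intensities for s in series], axis=0),
            embryo_id="movie", centriole_id="mean",
        )
        if model == "growth":
            g = kinetics.fit_growth(mean_series)
            summary["growth"] = {"model": g.model, "b": g.b, "r": g.r,
                                 "t_p": g.t_p, "plateau": g.plateau}
        elif model == "lorentzian":
            l = kinetics.fit_lorentzian(mean_series)
            summary["oscillation"] = {"amplitude": l.amplitude, "t0": l.t0,
                                      "fwhm": l.fwhm, "flagged": l.flagged}
        else:
            raise ConfigError(f"unknown kinetics model {model!r}")
    return summary


def run_pipeline(
    config: dict | str | Path,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> dict:
    """Validate the configuration, run the configured stages, write outputs.

    Returns the run summary (also written to ``summary.json`` next to
    the stage tables and the manifest).  Configuration errors are
    raised before any computation; a failing stage aborts the run.
    """

    if not isinstance(config, dict):
        config = load_config(config)
    validate_keys(config, CONFIG_SCHEMA)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "centrikit_out"))
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO")).upper(), 20))

    summary: dict = {"seed": seed}
    if "fcs" in config:
        summary["fcs"] = _run_fcs(config["fcs"], seed, out)
    if "pecos" in config:
        summary["pecos"] = _run_pecos(config["pecos"], seed + 7919, out)
    if "imaging" in config:
        summary["imaging"] = _run_imaging(config["imaging"], seed + 104729, out)

    manifest = RunManifest(subcommand="pipeline", config=config, seed=seed)
    manifest.write(out / "manifest.json")
    import json

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
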