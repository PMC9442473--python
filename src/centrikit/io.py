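"""File formats, run manifests and configuration loading.

Conventions: numeric tables are UTF-8 comma-delimited with a single
header row plus a leading ``# units:`` comment line; traces and curves
are two-column delimited text with a JSON sidecar for metadata; movies
are multi-page TIFF with a JSON sidecar recording the axis order and
pixel size; configurations are YAML.  Every pipeline run emits exactly
one JSON manifest (config snapshot, seed, input checksums, package
version, timestamp) sufficient to reproduce its stochastic outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

import centrikit
from centrikit.correlation import CorrelationCurve
from centrikit.trace import PhotonTrace

__all__ = [
    "ConfigError",
    "RunManifest",
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "write_table",
    "read_table",
    "write_movie",
    "read_movie",
    "load_config",
    "validate_keys",
    "sha256_file",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k != "paths"}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace(trace: PhotonTrace, path: str | Path) -> Path:
    """Write a trace as (bin start time s, counts) text plus JSON sidecar."""
    path = Path(path)
    arr = np.column_stack([trace.times, trace.counts])
    np.savetxt(path, arr, fmt=["%.9g", "%d"], delimiter=",",
               header="time_s,counts", comments="")
    meta = {"bin_width": trace.bin_width, "duration": trace.duration,
            "mean_rate": trace.mean_rate, "meta": _jsonable(trace.meta)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> PhotonTrace:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    side = json.loads(_sidecar(path).read_text())
    return PhotonTrace(arr[:, 1].astype(np.int64), side["bin_width"], side.get("meta", {}))


def write_curve(curve: CorrelationCurve, path: str | Path) -> Path:
    """Write a correlation curve as (lag s, G) text plus JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([curve.lags, curve.g]), fmt="%.9g",
               delimiter=",", header="lag_s,g", comments="")
    meta = {"mean_rate": curve.mean_rate, "duration": curve.duration,
            "n_segments_kept": curve.n_segments_kept, "flags": curve.flags}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_curve(path: str | Path) -> CorrelationCurve:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    side = json.loads(_sidecar(path).read_text())
    return CorrelationCurve(arr[:, 0], arr[:, 1], side["mean_rate"], side["duration"],
                            side.get("n_segments_kept", 1), side.get("flags", []))


def write_table(df: pd.DataFrame, path: str | Path, units: dict[str, str]) -> Path:
    """Write a CSV table with a leading ``# units:`` declaration line."""
    path = Path(path)
    unit_line = "# units: " + ", ".join(f"{c}={units.get(c, '-')}" for c in df.columns)
    with open(path, "w") as fh:
        fh.write(unit_line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_movie(frames: np.ndarray, path: str | Path, pixel_size: float,
                frame_interval: float, extra: Optional[dict] = None) -> Path:
    """Write a (frames, slices, y, x) or (frames, y, x) stack as multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32), photometric="minisblack")
    meta = {"axes": "TZYX" if np.asarray(frames).ndim == 4 else "TYX",
            "pixel_size_um": pixel_size, "frame_interval_s": frame_interval}
    if extra:
        meta.update(_jsonable(extra))
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return frames, meta


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per pipeline run."""

    subcommand: str
    config: dict
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    package_version: str = centrikit.__version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(_jsonable(asdict(self)), indent=1))
        return path


def validate_keys(config: dict, schema: dict, path: str = "") -> None:
    """Recursively reject configuration keys absent from ``schema``.

    ``schema`` maps allowed key -> nested schema dict (or None for leaf
    values).  Raises :class:`ConfigError` naming the offending key.
    """

    for key, value in config.items():
        if key not in schema:
            where = f"{path}.{key}" if path else key
            raise ConfigError(f"unknown configuration key: {where!r}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            validate_keys(value, sub, f"{path}.{key}" if path else key)


def load_config(path: str | Path, schema: Optional[dict] = None) -> dict:
    """Load a YAML configuration, optionally validating its keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("top-level configuration must be a mapping")
    if schema is not None:
        validate_keys(cfg, schema)
    return cfg
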