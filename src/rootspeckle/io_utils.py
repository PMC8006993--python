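"""File formats, configuration and run manifests.

Traces travel as two-column CSV (``time_s`` plus the value column) with a
JSON sidecar manifest recording units, geometry and seeds; frame stacks as
multi-page TIFF, one float32 frame per page.  Reruns with identical config
and seeds reproduce trace CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, InputError
from .optics import OpticalGeometry
from .synthetic import GrowthPreset, load_presets
from .traces import ElongationTrace, FrameStack, PhaseTrace, RERTrace

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_trace_csv",
    "read_rer_trace",
    "read_trace_csv",
    "write_frame_stack",
    "read_frame_stack",
    "file_sha256",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class SimulationConfig:
    n_traces: int = 20
    duration_s: float = 150.0
    grid_shape: tuple[int, int] = (64, 64)
    speckle_size_px: float = 2.0
    noise_sd: float = 0.01
    seed: int = 0
    with_frames: bool = False


@dataclasses.dataclass
class AnalysisConfig:
    bin_rule: str = "fd"
    band_limit_hz: float = 1.5
    equal_var: bool = False
    moving_average: int = 0  # window in samples; 0 disables smoothing


@dataclasses.dataclass
class PipelineConfig:
    """Geometry, growth presets, simulation and analysis settings.

    ``load_config()`` with no file returns the packaged defaults (He-Ne
    geometry, wet/dry calibration presets); a user YAML file overrides any
    subset of keys and unknown keys are rejected.
    """

    geometry: OpticalGeometry = dataclasses.field(default_factory=OpticalGeometry)
    presets: dict[str, GrowthPreset] = dataclasses.field(default_factory=load_presets)
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "presets": {k: v.to_dict() for k, v in self.presets.items()},
            "simulation": dataclasses.asdict(self.simulation),
            "analysis": dataclasses.asdict(self.analysis),
        }


def _merge_section(cls, defaults, overrides: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")
    merged = {**{f.name: getattr(defaults, f.name) for f in dataclasses.fields(cls)}}
    merged.update(overrides)
    if "grid_shape" in merged and not isinstance(merged["grid_shape"], tuple):
        merged["grid_shape"] = tuple(merged["grid_shape"])
    return cls(**merged)


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load the pipeline configuration, merging a user YAML over defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"geometry", "presets", "simulation", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    if "geometry" in raw:
        cfg.geometry = _merge_section(
            OpticalGeometry, cfg.geometry, raw["geometry"], "geometry"
        )
    if "presets" in raw:
        for name, params in raw["presets"].items():
            params = dict(params)
            params.setdefault("label", name)
            try:
                cfg.presets[name] = GrowthPreset(**params)
            except TypeError as exc:
                raise ConfigError(f"bad preset '{name}': {exc}") from exc
    if "simulation" in raw:
        cfg.simulation = _merge_section(
            SimulationConfig, cfg.simulation, raw["simulation"], "simulation"
        )
    if "analysis" in raw:
        cfg.analysis = _merge_section(
            AnalysisConfig, cfg.analysis, raw["analysis"], "analysis"
        )
    return cfg


# ---------------------------------------------------------------------------
# trace CSV


_VALUE_COLUMNS = {
    RERTrace: ("rate", "nm s^-1 mm^-1"),
    ElongationTrace: ("x_nm", "nm"),
    PhaseTrace: ("phi_rad", "rad"),
}


def write_trace_csv(trace, path: str | Path) -> Path:
    """Write a trace as a two-column CSV; returns the path written.

    Values are serialized with ``repr`` round-trip precision so identical
    traces produce identical bytes.
    """
    path = Path(path)
    col, _unit = _VALUE_COLUMNS[type(trace)]
    values = getattr(trace, col)
    df = pd.DataFrame({"time_s": trace.times_s, col: values})
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    return path


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV, validating the layout and reporting bad cells."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise InputError(f"cannot parse CSV {path}: {exc}") from exc
    if "time_s" not in df.columns or len(df.columns) < 2:
        raise InputError(
            f"{path}: expected columns 'time_s' plus one value column, "
            f"got {list(df.columns)}"
        )
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric value at row {int(bad[0]) + 2}, column '{col}'"
            )
    return df.astype(float)


def read_rer_trace(path: str | Path, group_label: Optional[str] = None) -> RERTrace:
    """Read a rate trace CSV written by :func:`write_trace_csv`."""
    df = read_trace_csv(path)
    value_col = [c for c in df.columns if c != "time_s"][0]
    return RERTrace(
        times_s=df["time_s"].to_numpy(),
        rate=df[value_col].to_numpy(),
        group_label=group_label,
    )


# ---------------------------------------------------------------------------
# frame stacks (multi-page TIFF + JSON manifest)


def write_frame_stack(stack: FrameStack, path: str | Path) -> tuple[Path, Path]:
    """Write a frame stack as float32 multi-page TIFF plus a JSON manifest."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    manifest = {
        "n_frames": stack.n_frames,
        "frame_shape": list(stack.frame_shape),
        "dtype": "float32",
        "t0_s": float(stack.times_s[0]),
        "geometry": stack.geom.to_dict(),
    }
    mpath = path.with_suffix(".json")
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return path, mpath


def read_frame_stack(path: str | Path, manifest_path: Optional[str | Path] = None) -> FrameStack:
    """Read a multi-page TIFF stack, checking it against its manifest."""
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path else path.with_suffix(".json")
    if not manifest_path.exists():
        raise InputError(f"missing frame-stack manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        raise InputError(f"{path}: expected a multi-page 2-D stack")
    if frames.shape[0] != manifest["n_frames"]:
        raise InputError(
            f"{path}: has {frames.shape[0]} frames but manifest "
            f"{manifest_path} records {manifest['n_frames']}"
        )
    geom = OpticalGeometry(**manifest["geometry"])
    t0 = manifest.get("t0_s", 0.0)
    times = t0 + np.arange(frames.shape[0]) * geom.dt_s
    return FrameStack(frames=frames.astype(float), times_s=times, geom=geom)


# ---------------------------------------------------------------------------
# run manifests


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, outputs: list[Path], extra: Optional[dict] = None) -> Path:
    """Record a run: config snapshot plus a hash of every output file."""
    path = Path(path)
    manifest = {
        "config": config,
        "outputs": {str(p.name): file_sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
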