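"""Tidy-CSV track I/O, YAML run configuration and provenance blocks.

Track files are plain CSV with one row per frame:
matrix, sample, holder, location, sphere, repeat, time_s, displacement_m,
diameter_um. Hierarchy labels are strings; units are declared in the column
names (um converts to SI on read).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import DriveConfig, HierarchyIndex, MCMCConfig, SphereSpec, TrackSeries

__all__ = ["RunConfig", "read_tracks", "write_tracks", "read_config", "provenance_block"]

TRACK_COLUMNS = ["matrix", "sample", "holder", "location", "sphere", "repeat",
                 "time_s", "displacement_m", "diameter_um"]


@dataclass
class RunConfig:
    """Validated pipeline configuration; serialized into every provenance block."""

    seed: int = 0
    out_dir: str = "magrheo_out"
    drive: DriveConfig = field(default_factory=DriveConfig)
    fluid_viscosity_pa_s: float = 30.0
    f_volumetric_by_diameter_um: dict = field(default_factory=lambda: {30.0: 2.59e5, 100.0: 1.95e5})
    poisson_low: float = 0.37
    poisson_high: float = 0.50
    qc_min_snr: float = 3.0
    qc_min_r2: float = 0.5
    variant: str = "primary"
    response: str = "abs_shear_modulus"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    noise_parametrization: str = "shape_scale"

    def __post_init__(self) -> None:
        if self.fluid_viscosity_pa_s <= 0:
            raise ValueError("fluid viscosity must be positive")
        for d, f in self.f_volumetric_by_diameter_um.items():
            if float(d) <= 0 or float(f) <= 0:
                raise ValueError("calibration constants must be positive")
        if not 0 <= self.poisson_low <= self.poisson_high <= 0.5:
            raise ValueError("Poisson-ratio bounds must satisfy 0 <= low <= high <= 0.5")

    def to_dict(self) -> dict:
        return asdict(self)


def read_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "drive" in raw:
        raw["drive"] = DriveConfig(**raw["drive"])
    if "mcmc" in raw:
        raw["mcmc"] = MCMCConfig(**raw["mcmc"])
    if "f_volumetric_by_diameter_um" in raw:
        raw["f_volumetric_by_diameter_um"] = {float(k): float(v) for k, v
                                              in raw["f_volumetric_by_diameter_um"].items()}
    return RunConfig(**raw)


def write_tracks(tracks: list[TrackSeries], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        h = tr.hierarchy
        frames.append(pd.DataFrame({
            "matrix": h.matrix_id, "sample": h.sample_id, "holder": h.holder_id,
            "location": h.location_id, "sphere": h.sphere_id, "repeat": h.repeat_id,
            "time_s": tr.times_s, "displacement_m": tr.displacement_m,
            "diameter_um": tr.sphere.diameter_m * 1e6,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path: str | Path, drive: DriveConfig | None = None) -> list[TrackSeries]:
    """Read a tidy track CSV into typed series; header-driven, order-free.

    Rows that violate the schema (negative diameter, non-monotonic time)
    raise with the offending track identified by its hierarchy labels.
    """
    df = pd.read_csv(path, dtype={c: str for c in TRACK_COLUMNS[:6]})
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} missing columns: {sorted(missing)}")
    drive = drive or DriveConfig()
    tracks = []
    keys = TRACK_COLUMNS[:6]
    for labels, sub in df.groupby(keys, sort=True):
        sub = sub.sort_index()
        d_um = sub["diameter_um"].astype(float).iloc[0]
        if d_um <= 0:
            raise ValueError(f"track {labels}: non-positive diameter {d_um} um "
                             f"(rows {sub.index.min()}-{sub.index.max()})")
        t = sub["time_s"].astype(float).to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {labels}: time not strictly increasing "
                             f"(rows {sub.index.min()}-{sub.index.max()})")
        hier = HierarchyIndex(*labels)
        sphere = SphereSpec(sphere_id=labels[4], diameter_m=d_um * 1e-6)
        tracks.append(TrackSeries(t, sub["displacement_m"].astype(float).to_numpy(),
                                  hier, sphere, drive))
    return tracks


def provenance_block(config: RunConfig, stage: str, counts: dict | None = None) -> dict:
    """Provenance metadata written next to every stage output."""
    cfg = json.dumps(config.to_dict(), sort_keys=True, default=str)
    import magrheo

    return {
        "stage": stage,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "seed": config.seed,
        "magrheo_version": magrheo.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "counts": counts or {},
    }
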