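"""Shared domain types for the microrheometry pipeline.

Units are SI internally (meters, seconds, Pascals); phase angles cross module
boundaries in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriveConfig",
    "SphereSpec",
    "FluidProperties",
    "HierarchyIndex",
    "TrackSeries",
    "SinusoidFit",
    "MCMCConfig",
]


@dataclass(frozen=True)
class DriveConfig:
    """Sinusoidal force drive applied by the electromagnets.

    The gradient current sets the force amplitude and the offset current the
    bead magnetization; only the resulting drive frequency matters for the
    analysis, the currents are carried as provenance.
    """

    frequency_hz: float = 0.05
    i_grad_amp: float = 1.25
    i_offset: float = 0.75

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"drive frequency must be positive, got {self.frequency_hz}")
        if self.i_grad_amp < 0 or self.i_offset < 0:
            raise ValueError("drive currents must be non-negative")

    @property
    def omega(self) -> float:
        """Angular drive frequency 2*pi*f (rad/s)."""
        return 2.0 * math.pi * self.frequency_hz

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz


@dataclass(frozen=True)
class SphereSpec:
    """One measurement sphere: identity, size and coating."""

    sphere_id: str
    diameter_m: float
    is_magnetic: bool = True
    coating: str = ""

    def __post_init__(self) -> None:
        if self.diameter_m <= 0:
            raise ValueError(f"sphere diameter must be positive, got {self.diameter_m}")

    @property
    def radius_m(self) -> float:
        return self.diameter_m / 2.0

    @property
    def volume_m3(self) -> float:
        """Sphere volume pi*D^3/6."""
        return math.pi * self.diameter_m**3 / 6.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian calibration fluid (silicone oil) of known dynamic viscosity."""

    dynamic_viscosity_pa_s: float
    temperature_note: str = "room temperature"

    def __post_init__(self) -> None:
        if self.dynamic_viscosity_pa_s <= 0:
            raise ValueError("dynamic viscosity must be positive")


@dataclass(frozen=True)
class HierarchyIndex:
    """Nested experimental-design labels for one observation.

    matrix > sample > holder > location > sphere, plus the repeat index of
    the measurement. Labels are strings on purpose: positional integers drift
    silently between pipeline stages.
    """

    matrix_id: str
    sample_id: str
    holder_id: str
    location_id: str
    sphere_id: str
    repeat_id: str

    def __post_init__(self) -> None:
        for name in ("matrix_id", "sample_id", "holder_id", "location_id", "sphere_id", "repeat_id"):
            if not str(getattr(self, name)):
                raise ValueError(f"hierarchy label {name} must be non-empty")

    def key(self) -> tuple:
        """Unique observation key (matrix, sample, holder, sphere, repeat)."""
        return (self.matrix_id, self.sample_id, self.holder_id, self.sphere_id, self.repeat_id)


@dataclass
class TrackSeries:
    """One sphere's displacement relative to the reference spheres, one repeat."""

    times_s: np.ndarray
    displacement_m: np.ndarray
    hierarchy: HierarchyIndex
    sphere: SphereSpec
    drive: DriveConfig

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.displacement_m = np.asarray(self.displacement_m, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.displacement_m.shape:
            raise ValueError("times and displacement must be 1-D arrays of equal length")
        if self.times_s.size >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.times_s.size

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.n_points >= 2 else 0.0


@dataclass
class SinusoidFit:
    """Amplitude/phase estimate of a displacement track at the drive frequency.

    ``phase_deg`` follows the convention that displacement lagging the force
    drive is positive, so viscoelastic media live in [0, 90] degrees and a
    purely viscous fluid sits at 90 degrees. ``phase_defined`` is False for
    zero-variance signals where the phase is meaningless.
    """

    amplitude_m: float
    phase_deg: float
    residual_sd_m: float
    fit_r2: float
    snr: float
    phase_defined: bool = True
    drift_slope_m_per_s: float = 0.0
    offset_m: float = 0.0
    hierarchy: HierarchyIndex | None = None
    sphere: SphereSpec | None = None


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-MCMC settings shared by the calibration and heterogeneity fits.

    ``warmup`` steps are discarded, ``draws`` steps are kept (thinned by
    ``thin``); total retained draws = walkers * draws / thin. ``nwalkers``
    defaults to max(2*dim + 2, 32) when left at 0. For split diagnostics
    every walker counts as one chain; ``chains`` is the minimum number of
    walker groups and is kept for interface compatibility.
    """

    chains: int = 4
    warmup: int = 4000
    draws: int = 4000
    seed: int = 0
    nwalkers: int = 0
    thin: int = 4
    rhat_warn: float = 1.01
    rhat_fail: float = 1.05

    def __post_init__(self) -> None:
        if self.warmup < 0 or self.draws <= 0 or self.thin <= 0:
            raise ValueError("invalid MCMC sizes")
        if self.chains < 1:
            raise ValueError("need at least one chain group")
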