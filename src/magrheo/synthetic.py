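"""Synthetic-data generation with known ground truth.

Emulates what the instrument produces: sinusoidal displacement tracks of
magnetic spheres (in a calibration fluid or embedded in a matrix) and
hierarchical (|G|, phi) observation tables drawn from the same nested
random-effect chain that the heterogeneity model assumes. Every generated
dataset carries its :class:`GenerativeTruth` verbatim so recovery can be
checked against it.

Defaults mirror the study conditions: drive at f = 0.05 Hz, 30 um nominal
spheres, a 3 samples x 2 holders x (3-5 locations x 1-3 spheres) x 2 repeats
design, and calibration in a ~30 Pa s silicone oil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .types import DriveConfig, FluidProperties, HierarchyIndex, SphereSpec, TrackSeries

__all__ = [
    "Design",
    "GenerativeTruth",
    "default_truth",
    "gen_calibration_tracks",
    "gen_hierarchical_observations",
    "gen_matrix_tracks",
]

#: One full period at 0.05 Hz; the minimum identifiable window.
DEFAULT_DURATION_S = 20.0
#: Camera-style sampling rate.
DEFAULT_SAMPLE_RATE_HZ = 25.0


@dataclass(frozen=True)
class Design:
    """Per-matrix nested design sizes.

    samples x holders-per-sample x locations-per-holder x
    spheres-per-location x repeats-per-sphere.
    """

    n_samples: int = 3
    n_holders: int = 2
    n_locations: int = 4
    n_spheres_per_location: int = 2
    n_repeats: int = 2

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_holders, self.n_locations,
               self.n_spheres_per_location, self.n_repeats) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_spheres_per_holder(self) -> int:
        return self.n_locations * self.n_spheres_per_location


@dataclass
class GenerativeTruth:
    """Ground truth of one simulated hierarchical dataset (normalized scale).

    ``mu_matrix`` is the per-matrix mean of the normalized response;
    ``alpha_matrix/sample/holder`` are the scales that scatter samples,
    holders and spheres respectively; ``alpha_location`` (optional, 0 = off)
    inserts a location tier between holder and sphere. ``sigma_mu`` and
    ``sigma_sigma`` are the InverseGamma(shape, scale) noise hyperparameters;
    the realized per-sphere noise SDs are recorded in ``sigma_t`` after
    generation. ``raw_mean`` (per matrix) and the shared ``raw_sd``
    de-normalize to the measurement scale.
    """

    mu_matrix: dict[str, float]
    alpha_matrix: dict[str, float]
    alpha_sample: dict[str, float]
    alpha_holder: dict[str, float]
    sigma_sigma: dict[str, float]
    sigma_mu: float
    raw_mean: dict[str, float]
    raw_sd: float
    alpha_location: dict[str, float] = field(default_factory=dict)
    sigma_t: dict[str, list[float]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        for d in (self.alpha_matrix, self.alpha_sample, self.alpha_holder,
                  self.sigma_sigma, self.alpha_location):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"scale for {k} must be >= 0, got {v}")
        if self.sigma_mu < 0 or self.raw_sd <= 0:
            raise ValueError("noise hyperparameters must be >= 0 and raw SD positive")

    @property
    def matrices(self) -> list[str]:
        return list(self.mu_matrix)

    def to_dict(self) -> dict:
        return asdict(self)


def default_truth(matrices: tuple[str, ...] = ("agarose", "fibrin", "growdex"),
                  seed: int | None = None) -> GenerativeTruth:
    """Study-condition defaults for the hierarchical generator.

    Sphere-level scatter dominates (alpha_holder 0.8 on the normalized
    scale), with milder sample/holder design effects (0.3 / 0.2); noise is
    InverseGamma(3.0, 0.4) per sphere (mean SD 0.2). Raw means follow the
    order of magnitude of soft-hydrogel shear moduli (~100-250 Pa) with a
    shared raw SD of 50 Pa.
    """
    raw_means = {"agarose": 80.0, "fibrin": 165.0, "growdex": 230.0}
    return GenerativeTruth(
        mu_matrix={m: 0.0 for m in matrices},
        alpha_matrix={m: 0.3 for m in matrices},
        alpha_sample={m: 0.2 for m in matrices},
        alpha_holder={m: 0.8 for m in matrices},
        sigma_sigma={m: 0.4 for m in matrices},
        sigma_mu=3.0,
        raw_mean={m: raw_means.get(m, 150.0) for m in matrices},
        raw_sd=50.0,
        seed=seed,
    )


def _truncated_normal_diameters(rng: np.random.Generator, n: int,
                                mean_m: float, sd_m: float) -> np.ndarray:
    """Sphere diameters ~ Normal truncated at +/-3 SD and at zero."""
    if mean_m <= 0 or sd_m < 0:
        raise ValueError("diameter mean must be positive and SD non-negative")
    if sd_m == 0:
        return np.full(n, mean_m)
    lo = max(mean_m - 3 * sd_m, 0.0)
    hi = mean_m + 3 * sd_m
    a, b = (lo - mean_m) / sd_m, (hi - mean_m) / sd_m
    return stats.truncnorm.rvs(a, b, loc=mean_m, scale=sd_m, size=n, random_state=rng)


def _sample_times(duration_s: float, sample_rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * sample_rate_hz)) + 1
    return np.arange(n) / sample_rate_hz


def gen_calibration_tracks(
    truth_f_volumetric: float,
    fluid: FluidProperties,
    n_spheres: int = 50,
    diameter_mean_m: float = 30e-6,
    diameter_sd_m: float = 3e-6,
    drive: DriveConfig = DriveConfig(),
    noise_sd_m: float = 5e-9,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
) -> tuple[list[TrackSeries], dict]:
    """Simulate spheres oscillating in a viscous fluid under the force drive.

    In a Newtonian fluid the displacement lags the force by exactly a quarter
    period, so the noiseless track is p_hat * sin(2*pi*f*t - 90deg) with
    p_hat = F_vol * V / (3*pi*mu*D * 2*pi*f), the Stokes-drag relation
    rearranged for displacement amplitude. Additive i.i.d. Gaussian tracking
    noise of ``noise_sd_m`` is superposed. Returns the tracks plus a truth
    dict recording every per-sphere quantity.
    """
    if truth_f_volumetric <= 0:
        raise ValueError("volumetric force constant must be positive")
    if duration_s < drive.period_s:
        raise ValueError("duration must cover at least one full drive period")
    rng = np.random.default_rng(seed)
    diam = _truncated_normal_diameters(rng, n_spheres, diameter_mean_m, diameter_sd_m)
    t = _sample_times(duration_s, sample_rate_hz)
    mu = fluid.dynamic_viscosity_pa_s
    tracks: list[TrackSeries] = []
    truth = {"f_volumetric": truth_f_volumetric, "seed": seed, "spheres": []}
    for i, d in enumerate(diam):
        sphere = SphereSpec(sphere_id=f"cal{i:03d}", diameter_m=float(d))
        v_hat = truth_f_volumetric * d**2 / (18.0 * mu)  # Stokes drag inverted
        p_hat = v_hat / drive.omega
        clean = p_hat * np.sin(drive.omega * t - math.pi / 2.0)
        noisy = clean + rng.normal(0.0, noise_sd_m, size=t.size) if noise_sd_m > 0 else clean
        hier = HierarchyIndex("calibration", "s1", "h1", "l1", sphere.sphere_id, "r1")
        tracks.append(TrackSeries(t, noisy, hier, sphere, drive))
        truth["spheres"].append({"sphere_id": sphere.sphere_id, "diameter_m": float(d),
                                 "v_hat": float(v_hat), "p_hat": float(p_hat)})
    return tracks, truth


def gen_hierarchical_observations(
    design: Design,
    truth: GenerativeTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the nested random-effect chain forward into an observation table.

    For each matrix m: mu_sample = mu_matrix + alpha_matrix * z,
    mu_holder = mu_sample + alpha_sample * z, (optionally mu_location =
    mu_holder + alpha_holder * z and spheres scatter by alpha_location),
    mu_sphere = parent + scatter * z with z ~ N(0,1); per-sphere noise SD
    sigma_t ~ InverseGamma(sigma_mu, sigma_sigma_m); observations
    y ~ N(mu_sphere, sigma_t), then de-normalized with the per-matrix raw
    mean and the shared raw SD. The realized sigma_t are written back into
    ``truth.sigma_t``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth.sigma_t = {}
    for m in truth.matrices:
        a_mat = truth.alpha_matrix[m]
        a_smp = truth.alpha_sample[m]
        a_hld = truth.alpha_holder[m]
        a_loc = truth.alpha_location.get(m, 0.0)
        use_location = a_loc > 0
        sigmas: list[float] = []
        for s in range(design.n_samples):
            mu_s = truth.mu_matrix[m] + a_mat * rng.standard_normal()
            for h in range(design.n_holders):
                mu_h = mu_s + a_smp * rng.standard_normal()
                for loc in range(design.n_locations):
                    # without a location tier spheres scatter straight off the holder
                    mu_l = mu_h + a_hld * rng.standard_normal() if use_location else mu_h
                    scatter = a_loc if use_location else a_hld
                    for tt in range(design.n_spheres_per_location):
                        mu_t = mu_l + scatter * rng.standard_normal()
                        shape, scale = truth.sigma_mu, truth.sigma_sigma[m]
                        sigma_t = float(stats.invgamma.rvs(shape, scale=scale, random_state=rng)) \
                            if shape > 0 and scale > 0 else 0.0
                        sigmas.append(sigma_t)
                        for r in range(design.n_repeats):
                            y_norm = mu_t + sigma_t * rng.standard_normal() if sigma_t > 0 else mu_t
                            rows.append({
                                "matrix": m,
                                "sample": f"s{s + 1}",
                                "holder": f"h{h + 1}",
                                "location": f"l{loc + 1}",
                                "sphere": f"t{loc * design.n_spheres_per_location + tt + 1:02d}",
                                "repeat": f"r{r + 1}",
                                "y_normalized": y_norm,
                                "abs_shear_modulus_pa": truth.raw_mean[m] + truth.raw_sd * y_norm,
                            })
        truth.sigma_t[m] = sigmas
    return pd.DataFrame(rows)


def gen_matrix_tracks(
    observations: pd.DataFrame,
    f_volumetric: float,
    drive: DriveConfig = DriveConfig(),
    diameter_m: float = 30e-6,
    noise_sd_m: float = 0.0,
    drift_slope_m_per_s: float = 0.0,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
    response_col: str = "abs_shear_modulus_pa",
    phase_col: str = "phase_deg",
) -> list[TrackSeries]:
    """Invert the modulus relation into displacement tracks per observation.

    p_hat = F_vol * D^2 / (18 * |G|); each track is
    p_hat * sin(2*pi*f*t - phi) + drift * t + noise. With zero noise and
    drift, the signal + rheology round trip recovers (|G|, phi) exactly.
    A missing phase column defaults to the elastically dominated 5 degrees.
    """
    rng = np.random.default_rng(seed)
    t = _sample_times(duration_s, sample_rate_hz)
    tracks: list[TrackSeries] = []
    for _, row in observations.iterrows():
        g = float(row[response_col])
        if g <= 0:
            raise ValueError(f"|G| must be positive, got {g}")
        phi_deg = float(row[phase_col]) if phase_col in observations.columns else 5.0
        d = float(row["diameter_um"]) * 1e-6 if "diameter_um" in observations.columns else diameter_m
        p_hat = f_volumetric * d**2 / (18.0 * g)
        disp = p_hat * np.sin(drive.omega * t - math.radians(phi_deg))
        disp = disp + drift_slope_m_per_s * t
        if noise_sd_m > 0:
            disp = disp + rng.normal(0.0, noise_sd_m, size=t.size)
        hier = HierarchyIndex(str(row["matrix"]), str(row["sample"]), str(row["holder"]),
                              str(row.get("location", "l1")), str(row["sphere"]), str(row["repeat"]))
        sphere = SphereSpec(sphere_id=str(row["sphere"]), diameter_m=d)
        tracks.append(TrackSeries(t, disp, hier, sphere, drive))
    return tracks
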