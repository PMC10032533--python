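"""Stokes-drag calibration of the volumetric force constant.

Spheres oscillating in a fluid of known viscosity obey
F_vol = 18 * mu * v_hat / D^2, so the velocity amplitude is linear in the
squared sphere radius. The calibration fits that no-intercept line with a
Bayesian regression,

    v_hat ~ N(beta * r^2, sigma^2),
    beta ~ N(0, 5000),  sigma ~ InverseGamma(0.5, 1) * 1e-8,

and converts the slope draw-wise into F_vol = (9/2) * beta * mu. Goodness
of fit is a Bayesian R^2; the per-sphere phase angles double as a sanity
check (a purely viscous fluid must sit at 90 degrees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _mcmc
from .types import FluidProperties, MCMCConfig, SinusoidFit

__all__ = [
    "CalibrationFit",
    "per_sphere_force_constant",
    "fit_volumetric_force",
    "bayesian_r2",
    "phase_angle_summary",
]

#: Default prior settings (config knobs, defaults follow the model above).
BETA_PRIOR_SD = 5000.0
SIGMA_PRIOR_SHAPE = 0.5
SIGMA_PRIOR_SCALE = 1.0
SIGMA_SCALE_FACTOR = 1e-8


@dataclass
class CalibrationFit:
    """Posterior of the no-intercept calibration regression."""

    beta_draws: np.ndarray
    sigma_draws: np.ndarray
    f_volumetric_draws: np.ndarray
    bayes_r2: float
    dynamic_viscosity_pa_s: float
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    phase_samples_deg: np.ndarray | None = None

    @property
    def beta_mean(self) -> float:
        return float(np.mean(self.beta_draws))

    @property
    def beta_sd(self) -> float:
        return float(np.std(self.beta_draws, ddof=1))

    @property
    def f_volumetric_mean(self) -> float:
        return float(np.mean(self.f_volumetric_draws))

    @property
    def f_volumetric_sd(self) -> float:
        return float(np.std(self.f_volumetric_draws, ddof=1))

    def summary(self) -> dict:
        return {
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "f_volumetric_mean": self.f_volumetric_mean,
            "f_volumetric_sd": self.f_volumetric_sd,
            "bayes_r2": self.bayes_r2,
            "rhat_max": self.diagnostics.get("rhat_max"),
            "converged": self.converged,
        }

    def credible_interval(self, prob: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - prob) / 2.0
        return tuple(np.quantile(self.f_volumetric_draws, [lo, 1.0 - lo]))


def per_sphere_force_constant(r_sphere_m: float, v_hat_m_per_s: float,
                              fluid: FluidProperties) -> float:
    """Single-sphere Stokes estimate F_vol = 18 * mu * v_hat / D^2 (N/m^3)."""
    if r_sphere_m <= 0:
        raise ValueError("sphere radius must be positive")
    if v_hat_m_per_s < 0:
        raise ValueError("velocity amplitude must be non-negative")
    d = 2.0 * r_sphere_m
    return 18.0 * fluid.dynamic_viscosity_pa_s * v_hat_m_per_s / d**2


def _log_posterior_factory(r2: np.ndarray, v: np.ndarray,
                           beta_sd: float, ig_shape: float, ig_second: float,
                           scale_factor: float, ig_parametrization: str):
    """Vectorized log posterior over (beta, log sigma) rows."""
    if ig_parametrization == "shape_scale":
        ig_scale = ig_second
    elif ig_parametrization == "shape_rate":
        ig_scale = 1.0 / ig_second
    else:
        raise ValueError(f"unknown inverse-gamma parametrization {ig_parametrization!r}")
    n = v.size

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, 0]
        log_sigma = theta[:, 1]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            sigma = np.exp(log_sigma)
            lp = stats.norm.logpdf(beta, 0.0, beta_sd)
            # sigma = scale_factor * x with x ~ InvGamma; Jacobian of the log transform
            lp += stats.invgamma.logpdf(sigma / scale_factor, ig_shape, scale=ig_scale)
            lp += -np.log(scale_factor) + log_sigma
            resid = v[None, :] - beta[:, None] * r2[None, :]
            lp += (-0.5 * np.sum(resid**2, axis=1) / sigma**2 - n * log_sigma
                   - 0.5 * n * np.log(2 * np.pi))
            lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp

    return log_prob


def fit_volumetric_force(
    r_sphere_m: np.ndarray,
    v_hat_m_per_s: np.ndarray,
    fluid: FluidProperties,
    mcmc: MCMCConfig = MCMCConfig(),
    beta_prior_sd: float = BETA_PRIOR_SD,
    sigma_prior_shape: float = SIGMA_PRIOR_SHAPE,
    sigma_prior_second: float = SIGMA_PRIOR_SCALE,
    sigma_scale_factor: float = SIGMA_SCALE_FACTOR,
    ig_parametrization: str = "shape_scale",
    phase_samples_deg: np.ndarray | None = None,
) -> CalibrationFit:
    """Fit the Bayesian no-intercept calibration regression.

    ``r_sphere_m`` and ``v_hat_m_per_s`` are per-sphere radii and fitted
    velocity amplitudes in SI units; the priors are applied on those scales.
    Convergence diagnostics (split R-hat, ESS) are attached; an unconverged
    fit is returned flagged, never silently.
    """
    r = np.asarray(r_sphere_m, float)
    v = np.asarray(v_hat_m_per_s, float)
    if r.size != v.size or r.size < 2:
        raise ValueError("need matched radius/velocity arrays for at least 2 spheres")
    if np.any(r <= 0):
        raise ValueError("all radii must be positive")
    r2 = r**2

    log_prob = _log_posterior_factory(r2, v, beta_prior_sd, sigma_prior_shape,
                                      sigma_prior_second, sigma_scale_factor,
                                      ig_parametrization)
    # data-informed start: OLS slope through the origin and residual SD
    # (floored near the prior scale over n so noiseless data starts walkers
    # inside the posterior bulk rather than far up the sigma funnel)
    denom = float(np.sum(r2**2))
    beta0 = float(np.sum(v * r2) / denom) if denom > 0 else 0.0
    resid_sd = max(float(np.std(v - beta0 * r2)), sigma_scale_factor / max(v.size, 1))
    init = np.array([beta0, np.log(resid_sd)])
    # beta jitter matched to the slope uncertainty the starting sigma implies,
    # so walkers start jointly consistent even deep in the noiseless funnel
    beta_jitter = max(3.0 * resid_sd / np.sqrt(denom) if denom > 0 else 1.0,
                      abs(beta0) * 1e-6, 1e-9)
    scale = np.array([beta_jitter, 0.7])

    res = _mcmc.run_ensemble(log_prob, ndim=2, init_center=init, init_scale=scale, mcmc=mcmc)
    beta_draws = res.flat[:, 0]
    sigma_draws = np.exp(res.flat[:, 1])
    f_draws = 4.5 * beta_draws * fluid.dynamic_viscosity_pa_s

    fit = CalibrationFit(
        beta_draws=beta_draws,
        sigma_draws=sigma_draws,
        f_volumetric_draws=f_draws,
        bayes_r2=0.0,
        dynamic_viscosity_pa_s=fluid.dynamic_viscosity_pa_s,
        diagnostics=res.diagnostics,
        converged=res.converged,
        phase_samples_deg=None if phase_samples_deg is None else np.asarray(phase_samples_deg, float),
    )
    fit.bayes_r2 = bayesian_r2(fit, r, v)
    return fit


def bayesian_r2(fit: CalibrationFit, r_sphere_m: np.ndarray, v_hat_m_per_s: np.ndarray) -> float:
    """Posterior-mean Bayesian R^2: draw-wise var(fit)/(var(fit)+sigma^2).

    The predicted values beta*r^2 give the explained variance per draw; the
    modeled residual variance is sigma^2 from the same draw. Degenerate data
    with zero predictor variance yields 0 with a warning.
    """
    r2 = np.asarray(r_sphere_m, float) ** 2
    if r2.size < 2 or np.ptp(r2) == 0:
        warnings.warn("zero predictor variance: Bayesian R^2 defined as 0", stacklevel=2)
        return 0.0
    pred = fit.beta_draws[:, None] * r2[None, :]
    var_fit = np.var(pred, axis=1, ddof=1)
    var_res = fit.sigma_draws**2
    return float(np.mean(var_fit / (var_fit + var_res)))


def phase_angle_summary(fits: list[SinusoidFit] | np.ndarray) -> tuple[pd.DataFrame, dict]:
    """Per-sphere phase-angle table plus mean/median/quartile summary (degrees)."""
    if isinstance(fits, (list, tuple)) and len(fits) and isinstance(fits[0], SinusoidFit):
        rows = [{"sphere": (f.hierarchy.sphere_id if f.hierarchy else str(i)),
                 "phase_deg": f.phase_deg} for i, f in enumerate(fits)]
        table = pd.DataFrame(rows)
    else:
        table = pd.DataFrame({"phase_deg": np.asarray(fits, float)})
        table.insert(0, "sphere", [str(i) for i in range(len(table))])
    if table.empty:
        raise ValueError("need at least one fit to summarize phase angles")
    phi = table["phase_deg"].to_numpy()
    summary = {
        "mean": float(np.mean(phi)),
        "median": float(np.median(phi)),
        "q25": float(np.quantile(phi, 0.25)),
        "q75": float(np.quantile(phi, 0.75)),
        "n": int(phi.size),
    }
    return table, summary
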