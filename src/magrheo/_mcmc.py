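"""Ensemble-MCMC backbone shared by the calibration and heterogeneity fits.

Wraps :mod:`emcee`'s affine-invariant/differential-evolution ensemble sampler
with a vectorized log-posterior interface and split-walker convergence
diagnostics (R-hat / ESS via arviz, walkers treated as chains). Divergence
counts are a Hamiltonian-sampler concept and are reported as zero here; the
acceptance fraction plays the analogous health-check role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np

from .types import MCMCConfig

__all__ = ["EnsembleResult", "run_ensemble", "compute_diagnostics"]


@dataclass
class EnsembleResult:
    """Posterior draws from one ensemble run.

    ``chain`` has shape (nwalkers, ndraws, ndim) post warmup/thinning;
    ``flat`` is the (nwalkers*ndraws, ndim) view used for summaries.
    """

    chain: np.ndarray
    log_prob: np.ndarray
    acceptance_fraction: float
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def flat(self) -> np.ndarray:
        nw, nd, dim = self.chain.shape
        return self.chain.reshape(nw * nd, dim)

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]


def compute_diagnostics(chain: np.ndarray, rhat_warn: float, rhat_fail: float) -> dict:
    """Split-walker R-hat and bulk ESS, max/min over dimensions."""
    import arviz as az

    # arviz expects (chain, draw) per variable; each walker is one chain
    nw, nd, dim = chain.shape
    data = {f"p{i}": chain[:, :, i] for i in range(dim)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(data))
        ess = az.ess(az.convert_to_dataset(data))
    rhat_vals = np.array([float(rhat[f"p{i}"]) for i in range(dim)])
    ess_vals = np.array([float(ess[f"p{i}"]) for i in range(dim)])
    return {
        "rhat_max": float(np.nanmax(rhat_vals)),
        "rhat": rhat_vals,
        "ess_min": float(np.nanmin(ess_vals)),
        "ess": ess_vals,
        "n_divergent": 0,
        "rhat_warn_threshold": rhat_warn,
        "rhat_fail_threshold": rhat_fail,
    }


def run_ensemble(
    log_prob_batch,
    ndim: int,
    init_center: np.ndarray,
    init_scale: np.ndarray | float,
    mcmc: MCMCConfig,
    check_convergence: bool = True,
) -> EnsembleResult:
    """Sample a (vectorized) log posterior with a DE-move ensemble.

    ``log_prob_batch`` maps an (n, ndim) array to n log-posterior values.
    Walkers start at ``init_center`` + N(0, init_scale) jitter. The first
    ``mcmc.warmup`` steps are discarded, ``mcmc.draws`` are kept (thinned).
    Emits a warning (and flags ``converged=False``) when split-walker R-hat
    exceeds the failure threshold.
    """
    rng = np.random.default_rng(mcmc.seed)
    nwalkers = mcmc.nwalkers or max(2 * ndim + 2, 32)
    if nwalkers % 2:
        nwalkers += 1
    scale = np.broadcast_to(np.asarray(init_scale, float), (ndim,))
    p0 = init_center[None, :] + rng.normal(0.0, 1.0, size=(nwalkers, ndim)) * scale[None, :]
    lp0 = log_prob_batch(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while np.any(bad) and tries < 50:
        p0[bad] = init_center[None, :] + rng.normal(0.0, 1.0, size=(int(bad.sum()), ndim)) * 0.1 * scale[None, :]
        lp0 = log_prob_batch(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if np.any(bad):
        raise RuntimeError("could not find finite-posterior starting points for all walkers")

    # DE moves are fully vectorized; a light snooker admixture helps the
    # heavy-tailed noise hyperparameters without its python-loop cost dominating
    moves = [(emcee.moves.DEMove(), 0.95), (emcee.moves.DESnookerMove(), 0.05)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob_batch, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(mcmc.seed).get_state()
    # run warmup, then drop it from the backend so memory scales with kept draws
    state = sampler.run_mcmc(p0, max(mcmc.warmup, 1), progress=False,
                             skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.draws, progress=False, skip_initial_state_check=True)

    raw = sampler.get_chain(thin=mcmc.thin)  # (ndraws, nwalkers, ndim)
    lp = sampler.get_log_prob(thin=mcmc.thin)
    chain = np.moveaxis(raw, 0, 1)  # (nwalkers, ndraws, ndim)
    log_prob = lp.T
    acc = float(np.mean(sampler.acceptance_fraction))

    result = EnsembleResult(chain=chain, log_prob=log_prob, acceptance_fraction=acc)
    if check_convergence:
        result.diagnostics = compute_diagnostics(chain, mcmc.rhat_warn, mcmc.rhat_fail)
        if result.diagnostics["rhat_max"] >= mcmc.rhat_fail:
            result.converged = False
            warnings.warn(
                f"ensemble MCMC not converged: max R-hat "
                f"{result.diagnostics['rhat_max']:.3f} >= {mcmc.rhat_fail}",
                RuntimeWarning,
                stacklevel=2,
            )
    return result
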