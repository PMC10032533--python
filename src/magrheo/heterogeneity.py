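"""Bayesian multilevel quantification of viscoelastic heterogeneity.

The model treats each observation y (z-scored |G| or phase angle) of sphere
t, holder h, sample s in matrix m as

    mu_s   = mu_m  + alpha_m^matrix * z_s        z ~ N(0, 1)
    mu_sh  = mu_s  + alpha_m^sample * z_sh
    mu_sht = mu_sh + alpha_m^holder * z_sht
    y_shtr ~ N(mu_sht, sigma_t),   sigma_t ~ InvGamma(sigma_mu, sigma_sigma_m)

with N(0,1) priors on the matrix means, HalfNormal(0,1) priors on all scale
and noise hyperparameters, the mean-noise shape sigma_mu shared across
matrices, and the noise-spread scale sigma_sigma_m matrix-specific. The
"heterogeneity" of a matrix is the scale that scatters spheres within one
holder (``sphere_within_holder``).

Sampling strategy: all Gaussian latent effects are marginalized in closed
form — the nested structure collapses level-by-level through exact Gaussian
integrals — leaving a low-dimensional, funnel-free posterior over the
hyperparameters, which an ensemble MCMC sampler explores. Latent level
means and their non-centered z representation are recovered afterwards by
backward sampling from their exact Gaussian conditionals, so the sampled
joint posterior is identical to sampling the full non-centered model
directly.

Model variants for comparison:

- ``primary``: the three-level model above.
- ``location_level``: inserts a location tier between holder and sphere.
- ``single_level``: spheres scatter directly around the matrix mean.
- ``pooled_baseline``: one mean per matrix, per-sphere pooled noise kept.
- ``pooled_no_shared_noise``: one mean and a single noise SD per matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from . import _mcmc
from .types import MCMCConfig

__all__ = [
    "ModelSpec",
    "NormalizedData",
    "HeterogeneityDraws",
    "ElpdResult",
    "normalize",
    "build_variant",
    "fit_model",
    "heterogeneity_summary",
    "pairwise_probability",
    "elpd_loso",
    "compare_elpd",
    "diagnostics",
    "prior_predictive",
]

VARIANTS = ("primary", "location_level", "single_level", "pooled_baseline",
            "pooled_no_shared_noise")

_RESPONSE_COLUMNS = {"abs_shear_modulus": "abs_shear_modulus_pa", "phase": "phase_deg"}

# public level names -> internal scatter-target names (the scale named
# "sphere" is the one whose z's scatter spheres, i.e. Eq-16's alpha^holder)
_LEVEL_ALIASES = {
    "sphere_within_holder": "sphere",
    "sphere_within_location": "sphere",
    "sphere_within_matrix": "sphere",
    "location_within_holder": "location",
    "holder_within_sample": "holder",
    "sample_within_matrix": "sample",
}


@dataclass(frozen=True)
class ModelSpec:
    """Variant, response and sampler settings for one heterogeneity fit."""

    variant: str = "primary"
    response: str = "abs_shear_modulus"
    mcmc: MCMCConfig = MCMCConfig()
    noise_parametrization: str = "shape_scale"  # or "mean"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.response not in _RESPONSE_COLUMNS:
            raise ValueError(f"response must be one of {tuple(_RESPONSE_COLUMNS)}")
        if self.noise_parametrization not in ("shape_scale", "mean"):
            raise ValueError("noise_parametrization must be 'shape_scale' or 'mean'")


@dataclass
class NormalizedData:
    """Z-scored observations plus the constants that invert the normalization.

    Each matrix is centered by its own mean; one shared SD (computed from the
    pooled, per-matrix-centered observations) scales all matrices so that
    heterogeneity magnitudes stay comparable across matrices.
    """

    table: pd.DataFrame  # matrix, sample, holder, location, sphere, repeat, y
    raw_mean: dict[str, float]
    raw_sd: float
    response: str

    @property
    def matrices(self) -> list[str]:
        return sorted(self.table["matrix"].unique())

    def denormalize(self, y: np.ndarray, matrix: str) -> np.ndarray:
        return self.raw_mean[matrix] + self.raw_sd * np.asarray(y, float)


def normalize(observations: pd.DataFrame, response: str = "abs_shear_modulus") -> NormalizedData:
    """Center per matrix, scale by one shared SD.

    y = (raw - mean_m) / SD_shared with SD_shared the sample SD (ddof=1) of
    all centered observations pooled across matrices.
    """
    col = _RESPONSE_COLUMNS.get(response, response)
    if col not in observations.columns:
        raise ValueError(f"response column {col!r} not in observation table")
    df = observations.copy()
    if "location" not in df.columns:
        df["location"] = "l1"
    counts = df.groupby("matrix")[col].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 observations per matrix; too few in {bad}")
    raw_mean = df.groupby("matrix")[col].mean().to_dict()
    centered = df[col] - df["matrix"].map(raw_mean)
    raw_sd = float(centered.std(ddof=1))
    if raw_sd == 0 or not np.isfinite(raw_sd):
        raise ValueError("zero pooled variance: normalization undefined")
    out = df[["matrix", "sample", "holder", "location", "sphere", "repeat"]].astype(str).copy()
    out["y"] = (centered / raw_sd).to_numpy()
    return NormalizedData(table=out, raw_mean={k: float(v) for k, v in raw_mean.items()},
                          raw_sd=raw_sd, response=response)


# ---------------------------------------------------------------------------
# model structure


@dataclass
class _MatrixIndex:
    """Per-matrix sufficient statistics and grouping chain (bottom-up)."""

    name: str
    sphere_keys: list[tuple]      # (sample, holder, location, sphere)
    ybar: np.ndarray              # (T,) per-sphere repeat means
    ss: np.ndarray                # (T,) within-sphere sum of squares
    rcount: np.ndarray            # (T,) repeats per sphere
    group_maps: list[np.ndarray]  # child->group index arrays, bottom-up
    group_keys: list[list[tuple]]
    onehots: list[np.ndarray]     # (K_child, K_group) float indicators

    @property
    def n_spheres(self) -> int:
        return len(self.sphere_keys)


@dataclass
class _VariantStructure:
    """What :func:`build_variant` returns: the internal model structure."""

    variant: str
    scale_names: list[str]        # bottom-up scatter-target names; [] if pooled
    group_levels: list[list[str]]  # hierarchy columns keying each collapse target
    pooled_noise: bool            # per-sphere sigma_t with InvGamma pooling
    shared_sigma_mu: bool


def build_variant(spec: ModelSpec | str) -> _VariantStructure:
    """Map a variant name onto the level chain and noise structure it implies."""
    variant = spec.variant if isinstance(spec, ModelSpec) else spec
    if variant == "primary":
        return _VariantStructure(variant, ["sphere", "holder", "sample"],
                                 [["sample", "holder"], ["sample"]], True, True)
    if variant == "location_level":
        return _VariantStructure(variant, ["sphere", "location", "holder", "sample"],
                                 [["sample", "holder", "location"], ["sample", "holder"],
                                  ["sample"]], True, True)
    if variant == "single_level":
        return _VariantStructure(variant, ["sphere"], [], True, True)
    if variant == "pooled_baseline":
        return _VariantStructure(variant, [], [], True, True)
    if variant == "pooled_no_shared_noise":
        return _VariantStructure(variant, [], [], False, False)
    raise ValueError(f"unknown variant {variant!r}")


def _build_matrix_index(df: pd.DataFrame, structure: _VariantStructure, name: str) -> _MatrixIndex:
    sub = df[df["matrix"] == name]
    key_cols = ["sample", "holder", "location", "sphere"]
    dup = sub.duplicated(subset=key_cols + ["repeat"])
    if dup.any():
        raise ValueError(f"ill-formed hierarchy: duplicated observation keys in matrix {name}")
    grouped = sub.groupby(key_cols, sort=True)["y"]
    sphere_keys = list(grouped.groups.keys())
    ybar = grouped.mean().to_numpy()
    rcount = grouped.count().to_numpy().astype(float)
    ss = (grouped.apply(lambda v: float(np.sum((v - v.mean()) ** 2)))).to_numpy()

    group_maps, group_keys, onehots = [], [], []
    child_keys = sphere_keys
    col_index = {c: i for i, c in enumerate(key_cols)}
    for level_cols in structure.group_levels:
        idxs = [col_index[c] for c in level_cols]
        parent_of_child = [tuple(k[i] for i in idxs) for k in child_keys]
        uniq = sorted(set(parent_of_child))
        lookup = {k: j for j, k in enumerate(uniq)}
        gmap = np.array([lookup[k] for k in parent_of_child], dtype=int)
        onehot = np.zeros((len(child_keys), len(uniq)))
        onehot[np.arange(len(child_keys)), gmap] = 1.0
        group_maps.append(gmap)
        group_keys.append(uniq)
        onehots.append(onehot)
        child_keys = uniq
        col_index = {c: i for i, c in enumerate(level_cols)}
    return _MatrixIndex(name, sphere_keys, ybar, ss, rcount, group_maps, group_keys, onehots)


@dataclass
class _Layout:
    """Flat parameter-vector layout for one fit."""

    structure: _VariantStructure
    matrices: list[str]
    index: dict[str, _MatrixIndex]
    sigma_mu_pos: int | None
    blocks: dict[str, dict[str, slice | int]]
    ndim: int

    def alpha_position(self, matrix: str, scatter_name: str) -> int:
        i = self.structure.scale_names.index(scatter_name)
        return self.blocks[matrix]["alphas"].start + i


def _build_layout(data: NormalizedData, structure: _VariantStructure) -> _Layout:
    matrices = data.matrices
    index = {m: _build_matrix_index(data.table, structure, m) for m in matrices}
    pos = 0
    sigma_mu_pos = None
    if structure.shared_sigma_mu:
        sigma_mu_pos = pos
        pos += 1
    blocks: dict[str, dict] = {}
    for m in matrices:
        blk: dict = {"mu": pos}
        pos += 1
        blk["alphas"] = slice(pos, pos + len(structure.scale_names))
        pos += len(structure.scale_names)
        if structure.pooled_noise:
            blk["sigma_sigma"] = pos
            pos += 1
            blk["sigma_t"] = slice(pos, pos + index[m].n_spheres)
            pos += index[m].n_spheres
        else:
            blk["sigma"] = pos
            pos += 1
        blocks[m] = blk
    return _Layout(structure, matrices, index, sigma_mu_pos, blocks, pos)


# ---------------------------------------------------------------------------
# collapsed likelihood

_LOG_2PI = np.log(2.0 * np.pi)
_HALFNORMAL_CONST = 0.5 * np.log(2.0 / np.pi)


def _halfnormal_logpdf(x: np.ndarray) -> np.ndarray:
    return _HALFNORMAL_CONST - 0.5 * x**2


def _invgamma_logpdf(x: np.ndarray, shape: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return shape * np.log(scale) - gammaln(shape) - (shape + 1.0) * np.log(x) - scale / x


def _noise_shape_scale(sigma_mu, sigma_sigma, parametrization: str):
    """InvGamma(shape, scale) for sigma_t under either reading of the prior.

    ``shape_scale`` uses the hyperparameters literally; ``mean`` treats
    sigma_mu as the prior mean noise SD and sigma_sigma as its spread
    (shape = 2 + (mean/spread)^2 so mean and SD are finite and as stated).
    """
    if parametrization == "shape_scale":
        return sigma_mu, sigma_sigma
    shape = 2.0 + (sigma_mu / sigma_sigma) ** 2
    return shape, sigma_mu * (shape - 1.0)


def _matrix_loglik_batch(idx: _MatrixIndex, mu: np.ndarray, alphas: np.ndarray,
                         sigma_t: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood of one matrix, latent effects integrated out.

    ``mu``: (B,), ``alphas``: (B, L) bottom-up, ``sigma_t``: (B, T).
    Collapses the nested Gaussian chain exactly: each level's children enter
    as pseudo-observations with precision-weighted means, and the level mean
    integrates against its own Gaussian prior in closed form.
    """
    R = idx.rcount[None, :]
    var_t = sigma_t**2
    # repeat-level constants: product of repeat densities expressed through ybar
    logc = np.sum(-0.5 * (R - 1.0) * (_LOG_2PI + np.log(var_t))
                  - idx.ss[None, :] / (2.0 * var_t) - 0.5 * np.log(R), axis=1)
    bottom_alpha = alphas[:, 0:1] if alphas.shape[1] else np.zeros((mu.size, 1))
    v_eff = bottom_alpha**2 + var_t / R          # (B, T)
    m_eff = np.broadcast_to(idx.ybar[None, :], v_eff.shape)
    for j, onehot in enumerate(idx.onehots):
        inv_v = 1.0 / v_eff
        W = inv_v @ onehot
        S1 = (m_eff * inv_v) @ onehot
        S2 = (m_eff**2 * inv_v) @ onehot
        sumlog = np.log(2.0 * np.pi * v_eff) @ onehot
        m_g = S1 / W
        logc = logc + np.sum(-0.5 * sumlog - 0.5 * (S2 - W * m_g**2)
                             + 0.5 * (_LOG_2PI - np.log(W)), axis=1)
        v_eff = 1.0 / W + alphas[:, j + 1, None] ** 2
        m_eff = m_g
    resid = m_eff - mu[:, None]
    loglik = logc + np.sum(-0.5 * (_LOG_2PI + np.log(v_eff)) - 0.5 * resid**2 / v_eff, axis=1)
    return loglik


def _sigma_t_from_block(theta: np.ndarray, blk: dict, sigma_mu: np.ndarray,
                        noise_parametrization: str):
    """Per-sphere noise SDs and their log prior from one matrix block.

    The per-sphere parameters are sampled scale-free: sigma_t = sigma_sigma *
    x_t with x_t ~ InvGamma(shape, scale/sigma_sigma) — a non-centered
    parametrization of the noise tier that removes the funnel between the
    spread hyperparameter and the individual noise SDs.
    """
    log_ssig = theta[:, blk["sigma_sigma"]]
    sigma_sigma = np.exp(log_ssig)
    lp = _halfnormal_logpdf(sigma_sigma) + log_ssig
    log_x = theta[:, blk["sigma_t"]]
    x = np.exp(log_x)
    sigma_t = sigma_sigma[:, None] * x
    shape, scale = _noise_shape_scale(sigma_mu, sigma_sigma, noise_parametrization)
    lp += np.sum(_invgamma_logpdf(sigma_t, shape[:, None],
                                  scale[:, None]) + np.log(sigma_t), axis=1)
    return sigma_t, lp


def _log_posterior_factory(layout: _Layout, noise_parametrization: str):
    structure = layout.structure

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        B = theta.shape[0]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = np.zeros(B)
            sigma_mu = None
            if structure.shared_sigma_mu:
                log_smu = theta[:, layout.sigma_mu_pos]
                sigma_mu = np.exp(log_smu)
                lp += _halfnormal_logpdf(sigma_mu) + log_smu
            for m in layout.matrices:
                blk = layout.blocks[m]
                idx = layout.index[m]
                mu = theta[:, blk["mu"]]
                lp += -0.5 * (_LOG_2PI + mu**2)  # N(0,1) prior on the matrix mean
                log_alphas = theta[:, blk["alphas"]]
                alphas = np.exp(log_alphas)
                if alphas.shape[1]:
                    lp += np.sum(_halfnormal_logpdf(alphas) + log_alphas, axis=1)
                if structure.pooled_noise:
                    sigma_t, lp_noise = _sigma_t_from_block(theta, blk, sigma_mu,
                                                            noise_parametrization)
                    lp += lp_noise
                else:
                    log_s = theta[:, blk["sigma"]]
                    sigma = np.exp(log_s)
                    lp += _halfnormal_logpdf(sigma) + log_s
                    sigma_t = np.broadcast_to(sigma[:, None], (B, idx.n_spheres))
                lp += _matrix_loglik_batch(idx, mu, alphas, sigma_t)
            lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp

    return log_prob


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HeterogeneityDraws:
    """Posterior draws of the multilevel model plus the fit's bookkeeping."""

    spec: ModelSpec
    data: NormalizedData
    layout: _Layout
    chain: np.ndarray            # (nwalkers, ndraws, ndim), transformed scale
    log_prob: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def flat(self) -> np.ndarray:
        nw, nd, dim = self.chain.shape
        return self.chain.reshape(nw * nd, dim)

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    @property
    def matrices(self) -> list[str]:
        return self.layout.matrices

    def mu_matrix(self, matrix: str) -> np.ndarray:
        return self.flat[:, self.layout.blocks[matrix]["mu"]].copy()

    def alpha(self, matrix: str, level: str) -> np.ndarray:
        """Draws of the scale that scatters ``level``'s children; see module docs."""
        name = _LEVEL_ALIASES.get(level, level)
        if name not in self.layout.structure.scale_names:
            raise ValueError(
                f"level {level!r} not present in variant {self.spec.variant!r}")
        if matrix not in self.layout.blocks:
            raise ValueError(f"matrix {matrix!r} was not part of this fit")
        return np.exp(self.flat[:, self.layout.alpha_position(matrix, name)])

    def sigma_mu(self) -> np.ndarray:
        if self.layout.sigma_mu_pos is None:
            raise ValueError("this variant has no shared mean-noise hyperparameter")
        return np.exp(self.flat[:, self.layout.sigma_mu_pos])

    def sigma_sigma(self, matrix: str) -> np.ndarray:
        blk = self.layout.blocks[matrix]
        if "sigma_sigma" not in blk:
            raise ValueError("this variant has no per-matrix noise-spread hyperparameter")
        return np.exp(self.flat[:, blk["sigma_sigma"]])

    def sigma_t(self, matrix: str) -> np.ndarray:
        blk = self.layout.blocks[matrix]
        if "sigma_t" in blk:
            # per-sphere parameters are stored scale-free relative to sigma_sigma
            return np.exp(self.flat[:, blk["sigma_sigma"], None]) * \
                np.exp(self.flat[:, blk["sigma_t"]])
        return np.exp(self.flat[:, [blk["sigma"]]])

    def level_means(self, matrix: str, seed: int = 0) -> dict:
        """Exact conditional draws of every latent level mean (backward sampling).

        Returns a dict with per-level arrays of node means, keyed by the
        collapse-target names, plus ``sphere`` for the per-sphere means and
        ``z`` with the recovered non-centered latent variables.
        """
        return _backward_sample_level_means(self, matrix, np.random.default_rng(seed))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for m in self.matrices:
            for name in self.layout.structure.scale_names:
                a = np.exp(self.flat[:, self.layout.alpha_position(m, name)])
                rows.append({"matrix": m, "scale": name, "mean": a.mean(),
                             "sd": a.std(ddof=1),
                             "q05": np.quantile(a, 0.05), "q50": np.quantile(a, 0.50),
                             "q95": np.quantile(a, 0.95)})
        return pd.DataFrame(rows)


def _initial_point(layout: _Layout, data: NormalizedData) -> np.ndarray:
    """Moment-based starting point on the transformed scale."""
    init = np.zeros(layout.ndim)
    if layout.sigma_mu_pos is not None:
        init[layout.sigma_mu_pos] = 0.0  # sigma_mu = 1
    for m in layout.matrices:
        blk = layout.blocks[m]
        idx = layout.index[m]
        init[blk["mu"]] = float(np.mean(idx.ybar))
        scatter = max(float(np.std(idx.ybar)), 0.05)
        n_scales = blk["alphas"].stop - blk["alphas"].start
        if n_scales:
            init[blk["alphas"]] = np.log(max(scatter / np.sqrt(n_scales), 0.05))
        with np.errstate(divide="ignore"):
            rep_sd = np.sqrt(idx.ss / np.maximum(idx.rcount - 1.0, 1.0))
        pooled = float(np.sqrt(np.sum(idx.ss) / max(np.sum(idx.rcount - 1.0), 1.0)))
        pooled = max(pooled, 0.02)
        rep_sd = np.where(rep_sd > 0, rep_sd, pooled)
        if "sigma_t" in blk:
            ssig0 = max(pooled, 0.05)
            init[blk["sigma_sigma"]] = np.log(ssig0)
            init[blk["sigma_t"]] = np.log(rep_sd / ssig0)
        else:
            init[blk["sigma"]] = np.log(max(float(np.std(data.table[
                data.table["matrix"] == m]["y"])), 0.05))
    return init


def _check_design_identifiability(layout: _Layout) -> None:
    for m in layout.matrices:
        idx = layout.index[m]
        child_counts = [len(idx.sphere_keys)] + [len(k) for k in idx.group_keys]
        for j in range(len(child_counts) - 1):
            if child_counts[j] == child_counts[j + 1]:
                warnings.warn(
                    f"matrix {m!r}: one child per parent at level {j}; the "
                    f"corresponding scatter scale is prior-dominated",
                    UserWarning, stacklevel=3)


def fit_model(data: NormalizedData, spec: ModelSpec) -> HeterogeneityDraws:
    """Sample the posterior of the chosen model variant.

    Fails loudly (warning + ``converged=False``) when split R-hat exceeds the
    configured failure threshold.
    """
    structure = build_variant(spec)
    if structure.variant == "location_level":
        locs = data.table.groupby(["matrix", "sample", "holder"])["location"].nunique()
        if (locs <= 1).all():
            raise ValueError("location_level variant requires location labels that "
                             "distinguish more than one location per holder")
    layout = _build_layout(data, structure)
    if structure.scale_names:
        _check_design_identifiability(layout)
    log_prob = _log_posterior_factory(layout, spec.noise_parametrization)
    init = _initial_point(layout, data)
    res = _mcmc.run_ensemble(log_prob, ndim=layout.ndim, init_center=init,
                             init_scale=0.1, mcmc=spec.mcmc)
    return HeterogeneityDraws(spec=spec, data=data, layout=layout, chain=res.chain,
                              log_prob=res.log_prob, diagnostics=res.diagnostics,
                              converged=res.converged)


# ---------------------------------------------------------------------------
# conditional latent recovery (backward sampling)


def _upward_messages(idx: _MatrixIndex, alphas: np.ndarray, sigma_t: np.ndarray):
    """Per-draw upward pass; returns the (m, W) messages of every level."""
    R = idx.rcount[None, :]
    var_t = sigma_t**2
    bottom_alpha = alphas[:, 0:1] if alphas.shape[1] else np.zeros((sigma_t.shape[0], 1))
    v_eff = bottom_alpha**2 + var_t / R
    m_eff = np.broadcast_to(idx.ybar[None, :], v_eff.shape).copy()
    messages = []
    for j, onehot in enumerate(idx.onehots):
        inv_v = 1.0 / v_eff
        W = inv_v @ onehot
        m_g = ((m_eff * inv_v) @ onehot) / W
        messages.append({"m": m_g, "W": W})
        v_eff = 1.0 / W + alphas[:, j + 1, None] ** 2
        m_eff = m_g
    return messages, (m_eff, v_eff)


def _combine(prior_mean, prior_var_alpha, msg_m, msg_W, rng):
    """Sample N(x; msg_m, 1/msg_W) * N(x; prior_mean, alpha^2), alpha=0-safe."""
    a2 = prior_var_alpha**2
    denom = 1.0 + a2 * msg_W
    mean = (prior_mean + a2 * msg_W * msg_m) / denom
    var = a2 / denom
    return mean + np.sqrt(var) * rng.standard_normal(mean.shape)


def _backward_sample_level_means(draws: HeterogeneityDraws, matrix: str,
                                 rng: np.random.Generator) -> dict:
    layout = draws.layout
    structure = layout.structure
    idx = layout.index[matrix]
    blk = layout.blocks[matrix]
    flat = draws.flat
    mu = flat[:, blk["mu"]]
    alphas = np.exp(flat[:, blk["alphas"]]) if structure.scale_names else np.zeros((flat.shape[0], 0))
    sigma_t = draws.sigma_t(matrix)
    if sigma_t.shape[1] == 1:
        sigma_t = np.broadcast_to(sigma_t, (flat.shape[0], idx.n_spheres))
    messages, _top = _upward_messages(idx, alphas, sigma_t)

    out: dict = {"mu_matrix": mu, "z": {}}
    level_names = [structure.scale_names[j + 1] if j + 1 < len(structure.scale_names)
                   else "top" for j in range(len(messages))]
    # walk top-down: the last message level is the direct child of the matrix mean
    parent = mu[:, None]
    node_means: list[np.ndarray] = [None] * len(messages)
    for j in range(len(messages) - 1, -1, -1):
        alpha_j = alphas[:, j + 1, None]
        msg = messages[j]
        parent_vals = parent if j == len(messages) - 1 else node_means[j + 1][:, idx.group_maps[j + 1]]
        sampled = _combine(parent_vals, alpha_j, msg["m"], msg["W"], rng)
        node_means[j] = sampled
        scatter = alpha_j
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(scatter > 1e-12, (sampled - parent_vals) / scatter,
                         rng.standard_normal(sampled.shape))
        key = structure.group_levels[j][-1] if structure.group_levels else "group"
        out[f"mu_{key}"] = sampled
        out["z"][key] = z
    # sphere level
    W_t = idx.rcount[None, :] / sigma_t**2
    if messages:
        parent_t = node_means[0][:, idx.group_maps[0]]
    else:
        parent_t = mu[:, None] * np.ones((1, idx.n_spheres))
    bottom_alpha = alphas[:, 0:1] if alphas.shape[1] else np.zeros((flat.shape[0], 1))
    mu_t = _combine(parent_t, bottom_alpha, idx.ybar[None, :], W_t, rng)
    out["mu_sphere"] = mu_t
    with np.errstate(invalid="ignore", divide="ignore"):
        out["z"]["sphere"] = np.where(bottom_alpha > 1e-12,
                                      (mu_t - parent_t) / bottom_alpha,
                                      rng.standard_normal(mu_t.shape))
    return out


# ---------------------------------------------------------------------------
# summaries


def heterogeneity_summary(draws: HeterogeneityDraws, matrix: str,
                          level: str = "sphere_within_holder",
                          grid_points: int = 200) -> dict:
    """Posterior summary of one heterogeneity scale: moments, quantiles, KDE grid."""
    a = draws.alpha(matrix, level)
    qs = np.quantile(a, [0.05, 0.25, 0.50, 0.75, 0.95])
    hi = float(np.quantile(a, 0.999)) * 1.2
    grid = np.linspace(0.0, max(hi, 1e-6), grid_points)
    sd = float(np.std(a, ddof=1))
    if sd > 0:
        density = stats.gaussian_kde(a)(grid)
    else:
        density = np.zeros_like(grid)
    return {
        "matrix": matrix, "level": level,
        "mean": float(np.mean(a)), "sd": sd,
        "q05": float(qs[0]), "q25": float(qs[1]), "median": float(qs[2]),
        "q75": float(qs[3]), "q95": float(qs[4]),
        "grid": grid, "density": density,
    }


def pairwise_probability(draws: HeterogeneityDraws | np.ndarray, matrix_a,
                         matrix_b=None, level: str = "sphere_within_holder") -> float:
    """Monte-Carlo P(alpha_a > alpha_b), draws paired by iteration.

    Accepts either a fitted :class:`HeterogeneityDraws` with two matrix names
    or two raw draw arrays of equal length.
    """
    if isinstance(draws, HeterogeneityDraws):
        a = draws.alpha(matrix_a, level)
        b = draws.alpha(matrix_b, level)
    else:
        a = np.asarray(draws, float)
        b = np.asarray(matrix_a, float)
    if a.shape != b.shape:
        raise ValueError("draw arrays must be paired: mismatched draw counts")
    return float(np.mean(a > b))


def diagnostics(draws: HeterogeneityDraws | _mcmc.EnsembleResult) -> dict:
    """Convergence report: split R-hat, ESS, acceptance, pass/fail verdict."""
    d = dict(draws.diagnostics)
    d["converged"] = draws.converged
    if isinstance(draws, HeterogeneityDraws):
        d["log_prob_mean"] = float(np.mean(draws.log_prob))
    return d


# ---------------------------------------------------------------------------
# ELPD model comparison


@dataclass
class ElpdResult:
    """Leave-one-sphere-out expected log pointwise predictive density."""

    elpd: float
    se: float
    pointwise: pd.DataFrame  # matrix, sphere key, elpd contribution
    method: str
    n_spheres: int
    flags: list[str] = field(default_factory=list)
    pareto_k: np.ndarray | None = None


def _sphere_predictive_logpdf(y_star: np.ndarray, parent_mean: np.ndarray,
                              alpha: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log p(y*_1..R | parent mean) with the sphere's z and noise integrated.

    Marginally y* ~ MVN(parent_mean * 1, alpha^2 J + sigma^2 I); the
    compound-symmetric form gives a closed-form log density.
    """
    y_star = np.asarray(y_star, float)
    R = y_star.size
    ybar = float(np.mean(y_star))
    ss = float(np.sum((y_star - ybar) ** 2))
    s2 = sigma**2
    tot = s2 + R * alpha**2
    return -0.5 * (R * _LOG_2PI + (R - 1.0) * np.log(s2) + np.log(tot)
                   + ss / s2 + R * (ybar - parent_mean) ** 2 / tot)


def _held_out_parent_draws(fit: HeterogeneityDraws, matrix: str, sphere_key: tuple,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draws of (parent mean, bottom scatter scale) for a sphere's position.

    The sphere itself need not be in the fitted data: existing ancestors are
    sampled from their exact conditionals, missing ones forward from the
    deepest present ancestor down the prior chain.
    """
    layout = fit.layout
    structure = layout.structure
    idx = layout.index[matrix]
    flat = fit.flat
    n = flat.shape[0]
    mu = fit.mu_matrix(matrix)
    alphas = np.exp(flat[:, layout.blocks[matrix]["alphas"]]) \
        if structure.scale_names else np.zeros((n, 0))
    bottom_alpha = alphas[:, 0] if alphas.shape[1] else np.zeros(n)
    if not structure.group_levels:
        return mu, bottom_alpha
    cond = _backward_sample_level_means(fit, matrix, rng)
    key_cols = ["sample", "holder", "location", "sphere"]
    # find deepest existing ancestor, then forward-sample any missing tiers
    parent = mu.copy()
    missing_scales: list[int] = []
    found = False
    for j, level_cols in enumerate(structure.group_levels):
        idxs = [key_cols.index(c) for c in level_cols]
        target = tuple(sphere_key[i] for i in idxs)
        if target in idx.group_keys[j]:
            k = idx.group_keys[j].index(target)
            key = level_cols[-1]
            parent = cond[f"mu_{key}"][:, k]
            found = True
            break
        missing_scales.append(j + 1)
    if not found:
        missing_scales = list(range(len(structure.group_levels), 0, -1))
        parent = mu.copy()
        for j in sorted(missing_scales):
            a = alphas[:, j] if j < alphas.shape[1] else np.zeros(n)
            parent = parent + a * rng.standard_normal(n)
    else:
        for j in sorted(missing_scales):
            a = alphas[:, j] if j < alphas.shape[1] else np.zeros(n)
            parent = parent + a * rng.standard_normal(n)
    return parent, bottom_alpha


def _predictive_noise_draws(fit: HeterogeneityDraws, matrix: str,
                            rng: np.random.Generator) -> np.ndarray:
    """Noise SD draws for an unseen sphere: from the pooled InvGamma, or the
    single per-matrix SD when pooling is off."""
    structure = fit.layout.structure
    n = fit.flat.shape[0]
    if structure.pooled_noise:
        shape, scale = _noise_shape_scale(fit.sigma_mu(), fit.sigma_sigma(matrix),
                                          fit.spec.noise_parametrization)
        return scale / rng.gamma(shape)  # InvGamma(a, s) = s / Gamma(a, 1)
    return fit.sigma_t(matrix)[:, 0]


def elpd_loso(data: NormalizedData, spec: ModelSpec, method: str = "exact",
              seed: int = 0) -> ElpdResult:
    """Leave-one-sphere-out ELPD for one model variant.

    ``exact`` refits the model once per held-out sphere and integrates the
    held-out repeats over the refit posterior (with the sphere's latent
    effect and noise SD integrated over their priors given the draw).
    ``psis`` reuses one full-data fit with Pareto-smoothed importance
    weights grouped by sphere — the fast path; its Pareto-k diagnostics are
    attached and folds with k > 0.7 are flagged.
    """
    if method not in ("exact", "psis"):
        raise ValueError("method must be 'exact' or 'psis'")
    rng = np.random.default_rng(seed)
    df = data.table
    sphere_ids = df.groupby(["matrix", "sample", "holder", "location", "sphere"],
                            sort=True).size()
    per_matrix = sphere_ids.groupby(level=0).size()
    if (per_matrix < 2).any():
        raise ValueError("need >= 2 spheres per matrix for leave-one-sphere-out")
    keys = list(sphere_ids.index)
    rows, flags = [], []
    pareto_k = None

    if method == "psis":
        import arviz as az

        fit = fit_model(data, spec)
        if not fit.converged:
            flags.append("full-data fit unconverged")
        ks = []
        for key in keys:
            m = key[0]
            sphere_key = tuple(key[1:])
            sub = df[(df["matrix"] == m) & (df["sample"] == key[1]) & (df["holder"] == key[2])
                     & (df["location"] == key[3]) & (df["sphere"] == key[4])]
            y_star = sub["y"].to_numpy()
            parent, alpha_b = _held_out_parent_draws(fit, m, sphere_key, rng)
            t_index = fit.layout.index[m].sphere_keys.index(sphere_key)
            sig = fit.sigma_t(m)
            sig = sig[:, t_index] if sig.shape[1] > 1 else sig[:, 0]
            logq = _sphere_predictive_logpdf(y_star, parent, alpha_b, sig)
            lw, k = az.psislw(-logq)
            ks.append(float(k))
            elpd_t = logsumexp(lw + logq)
            rows.append({"matrix": m, "sphere_key": "/".join(sphere_key), "elpd": float(elpd_t)})
            if k > 0.7:
                flags.append(f"pareto k={k:.2f} for sphere {key}")
        pareto_k = np.array(ks)
    else:
        for key in keys:
            m = key[0]
            sphere_key = tuple(key[1:])
            mask = ((df["matrix"] == m) & (df["sample"] == key[1]) & (df["holder"] == key[2])
                    & (df["location"] == key[3]) & (df["sphere"] == key[4]))
            train = NormalizedData(df[~mask].reset_index(drop=True), data.raw_mean,
                                   data.raw_sd, data.response)
            y_star = df[mask]["y"].to_numpy()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = fit_model(train, spec)
            if not fit.converged:
                flags.append(f"refit unconverged for sphere {key}")
            parent, alpha_b = _held_out_parent_draws(fit, m, sphere_key, rng)
            sig = _predictive_noise_draws(fit, m, rng)
            lpd = _sphere_predictive_logpdf(y_star, parent, alpha_b, sig)
            elpd_t = logsumexp(lpd) - np.log(lpd.size)
            rows.append({"matrix": m, "sphere_key": "/".join(sphere_key), "elpd": float(elpd_t)})

    pw = pd.DataFrame(rows)
    elpd = float(pw["elpd"].sum())
    se = float(np.std(pw["elpd"], ddof=1) * np.sqrt(len(pw))) if len(pw) > 1 else float("nan")
    return ElpdResult(elpd=elpd, se=se, pointwise=pw, method=method,
                      n_spheres=len(keys), flags=flags, pareto_k=pareto_k)


def compare_elpd(a: ElpdResult, b: ElpdResult) -> dict:
    """Pairwise ELPD difference (a - b) with the SE of the paired differences."""
    if len(a.pointwise) != len(b.pointwise):
        raise ValueError("ELPD results cover different sphere sets")
    diff = a.pointwise["elpd"].to_numpy() - b.pointwise["elpd"].to_numpy()
    return {"elpd_diff": float(diff.sum()),
            "se_diff": float(np.std(diff, ddof=1) * np.sqrt(diff.size))}


# ---------------------------------------------------------------------------
# prior / fixed-parameter predictive simulation


def prior_predictive(index: pd.DataFrame, mu: float, alpha_sample: float,
                     alpha_holder: float, alpha_sphere: float,
                     sigma_t_by_sphere: dict | float, seed: int = 0) -> np.ndarray:
    """Forward-simulate normalized observations for given hyperparameters.

    ``index`` is a table of hierarchy labels (matrix/sample/holder/location/
    sphere/repeat). Effects are assigned through label-keyed dictionaries
    built from the table — an intentionally different code path from the
    nested-loop synthetic generator, so the two can cross-validate
    distributionally.
    """
    rng = np.random.default_rng(seed)
    idx = index.astype(str)
    samples = idx["sample"].unique()
    holders = idx[["sample", "holder"]].drop_duplicates()
    spheres = idx[["sample", "holder", "location", "sphere"]].drop_duplicates()
    s_eff = dict(zip(samples, mu + alpha_sample * rng.standard_normal(len(samples))))
    h_eff = {}
    for _, r in holders.iterrows():
        h_eff[(r["sample"], r["holder"])] = s_eff[r["sample"]] + \
            alpha_holder * rng.standard_normal()
    t_eff, t_sig = {}, {}
    for _, r in spheres.iterrows():
        k = (r["sample"], r["holder"], r["location"], r["sphere"])
        t_eff[k] = h_eff[(r["sample"], r["holder"])] + alpha_sphere * rng.standard_normal()
        t_sig[k] = sigma_t_by_sphere if np.isscalar(sigma_t_by_sphere) \
            else sigma_t_by_sphere[k]
    y = np.empty(len(idx))
    for i, (_, r) in enumerate(idx.iterrows()):
        k = (r["sample"], r["holder"], r["location"], r["sphere"])
        y[i] = t_eff[k] + t_sig[k] * rng.standard_normal()
    return y
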