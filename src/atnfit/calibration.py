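"""Penalized maximum-likelihood calibration of the food-web model.

The full parameter vector (growth rate(s), carrying capacity, metabolic
rates, per-link ingestion rates and half-saturation constants, optional
functional-response exponents, per-node noise scales and — under
observation noise — initial biomasses) is estimated in unconstrained
space: every positive parameter is mapped through the softplus
``log(1 + exp(x))`` and metabolic rates through ``um_lower + softplus``
so allometric lower bounds hold by construction.  The loss is the
negative log-likelihood, optionally penalized by 100 per predicted
median biomass <= 0 (soft) or set to infinity when any prediction is
non-positive (hard).  Minimization uses CMA-ES with warm restarts from
the incumbent best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .cmaes import cma_es_minimize
from .foodweb import FoodWeb, RateParameters, count_parameters
from .noise import (
    BiomassDataset,
    NoiseSpec,
    env_loglik,
    env_median_matrix,
    obs_loglik,
)

__all__ = [
    "softplus",
    "inverse_softplus",
    "allometric_lower_bound",
    "metabolic_lower_bounds",
    "ParameterTransform",
    "LossSpec",
    "FitConfig",
    "FitResult",
    "NonPositiveCounts",
    "initial_parameters",
    "count_nonpositive",
    "penalized_loss",
    "fit",
]

logger = logging.getLogger(__name__)

#: budget profiles: (offspring, max iterations per run, restarts)
BUDGETS = {"smoke": (8, 20, 2), "desk": (20, 200, 10), "paper": (200, 3000, 3000)}


def softplus(x):
    """Overflow-safe ``log(1 + exp(x))``, strictly positive and increasing."""
    return np.logaddexp(0.0, x)


def inverse_softplus(y):
    """Inverse of :func:`softplus`; defined for y > 0 only."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("inverse_softplus requires y > 0")
    # log(exp(y) - 1) = y + log(1 - exp(-y)); expm1 keeps the small-y
    # branch accurate (no cancellation), the identity keeps large y safe
    out = y + np.log(-np.expm1(-y))
    return float(out) if out.ndim == 0 else out


def allometric_lower_bound(max_weight: float, a: float = 1.0, exponent: float = -0.25) -> float:
    """Allometric metabolic-rate lower bound ``a * W**exponent`` (1/yr).

    Metabolic rate per unit biomass declines with body mass W (grams)
    with the classic quarter-power exponent; the prefactor ``a`` is a
    configurable scaling constant.
    """
    if not max_weight > 0:
        raise ValueError("max_weight must be > 0")
    return float(a * max_weight**exponent)


def metabolic_lower_bounds(
    web: FoodWeb,
    a: float = 1.0,
    exponent: float = -0.25,
    default_bound: float = 1.0,
) -> np.ndarray:
    """Per-consumer lower bounds on metabolic rates (web consumer order).

    Guilds with a known maximum body mass (the fish guilds) get the
    allometric bound; guilds of uncertain composition (zooplankton,
    benthos) fall back to ``default_bound``.
    """
    out = np.empty(len(web.consumer_indices))
    for k, i in enumerate(web.consumer_indices):
        g = web.guilds[i]
        if g.max_body_mass is not None:
            out[k] = allometric_lower_bound(g.max_body_mass, a, exponent)
        else:
            out[k] = default_bound
    return out


class ParameterTransform:
    """Bijection between the free vector in R^n and constrained parameters.

    Layout of the free vector: producer growth rates, carrying
    capacity, consumer metabolic rates (bounded below), per-link
    ingestion rates, per-link half-saturation constants, per-link FR
    exponents (when estimated), per-node noise scales, and per-node
    initial biomasses (observation layer only).
    """

    def __init__(
        self,
        web: FoodWeb,
        noise_layer: str = "environmental",
        estimate_q: bool = True,
        fixed_q: float = 0.3,
        um_lower: np.ndarray | None = None,
    ) -> None:
        self.web = web
        self.noise_layer = noise_layer
        self.estimate_q = bool(estimate_q)
        self.fixed_q = float(fixed_q)
        self.um_lower = (
            np.asarray(um_lower, dtype=float)
            if um_lower is not None
            else np.zeros(len(web.consumer_indices))
        )
        P = len(web.producer_indices)
        C = len(web.consumer_indices)
        L = web.n_links
        n = web.n_nodes
        sizes = [P, 1, C, L, L]
        names = ["r", "K", "um", "J", "B0"]
        if self.estimate_q:
            sizes.append(L)
            names.append("q")
        sizes.append(n)
        names.append("sigma")
        if noise_layer == "observation":
            sizes.append(n)
            names.append("B_init")
        self._sizes = sizes
        self._names = names
        self._offsets = np.concatenate(([0], np.cumsum(sizes)))

    @property
    def n_free(self) -> int:
        return int(self._offsets[-1])

    def _split(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: x[self._offsets[k] : self._offsets[k + 1]]
            for k, name in enumerate(self._names)
        }

    def unpack(
        self, x: np.ndarray
    ) -> tuple[RateParameters, np.ndarray, np.ndarray | None]:
        """Free vector -> (RateParameters, sigma, B_init or None)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(f"free vector must have length {self.n_free}")
        parts = self._split(x)
        q = softplus(parts["q"]) if self.estimate_q else np.full(self.web.n_links, self.fixed_q)
        params = RateParameters(
            r=softplus(parts["r"]),
            K=float(softplus(parts["K"])[0]),
            um=self.um_lower + softplus(parts["um"]),
            J=softplus(parts["J"]),
            B0=softplus(parts["B0"]),
            q=q,
            um_lower=self.um_lower.copy(),
        )
        sigma = softplus(parts["sigma"])
        B_init = softplus(parts["B_init"]) if "B_init" in parts else None
        return params, sigma, B_init

    def pack(
        self,
        params: RateParameters,
        sigma: np.ndarray,
        B_init: np.ndarray | None = None,
    ) -> np.ndarray:
        """Constrained parameters -> free vector (inverse transform)."""
        pieces = [
            inverse_softplus(params.r),
            np.atleast_1d(inverse_softplus(params.K)),
            inverse_softplus(params.um - self.um_lower),
            inverse_softplus(params.J),
            inverse_softplus(params.B0),
        ]
        if self.estimate_q:
            pieces.append(inverse_softplus(params.q))
        pieces.append(inverse_softplus(sigma))
        if "B_init" in self._names:
            if B_init is None:
                raise ValueError("observation layer requires initial biomasses")
            pieces.append(inverse_softplus(B_init))
        return np.concatenate([np.atleast_1d(p) for p in pieces])

    def free_names(self) -> list[str]:
        """One label per free coordinate, for parameter files."""
        web = self.web
        labels: list[str] = []
        for name in self._names:
            if name == "r":
                labels += [f"r[{web.node_names[i]}]" for i in web.producer_indices]
            elif name == "K":
                labels.append("K")
            elif name == "um":
                labels += [f"um[{web.node_names[i]}]" for i in web.consumer_indices]
            elif name in ("J", "B0", "q"):
                labels += [f"{name}[{c}->{r}]" for c, r in web.links]
            else:
                labels += [f"{name}[{n}]" for n in web.node_names]
        return labels


@dataclass(frozen=True)
class LossSpec:
    """Penalty applied on top of the negative log-likelihood."""

    penalty: str = "soft"  # none | soft | hard
    penalty_coefficient: float = 100.0
    include_detritus: bool = True  # count detritus cells in the penalty

    def __post_init__(self) -> None:
        if self.penalty not in ("none", "soft", "hard"):
            raise ValueError(f"unknown penalty {self.penalty!r}")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer budget and parameterization switches."""

    offspring: int = 200
    max_iterations: int = 3000
    restarts: int = 10
    seed: int = 0
    estimate_q: bool = True
    fixed_q: float = 0.3
    sigma0: float = 0.5  # initial CMA step size in free space

    @classmethod
    def from_budget(cls, budget: str, **kw) -> "FitConfig":
        offspring, max_iterations, restarts = BUDGETS[budget]
        return cls(offspring=offspring, max_iterations=max_iterations, restarts=restarts, **kw)


class NonPositiveCounts(NamedTuple):
    all_nodes: int
    excluding_detritus: int


@dataclass
class FitResult:
    """Calibration output: estimates, loss decomposition and diagnostics."""

    params: RateParameters
    sigma: np.ndarray
    B_init: np.ndarray | None
    loss: float
    loglik: float
    n_nonpositive: NonPositiveCounts
    aic: float
    n_parameters: int
    restart_trace: list[float] = field(default_factory=list)
    n_evals: int = 0


def initial_parameters(
    data: BiomassDataset,
    web: FoodWeb,
    noise: NoiseSpec,
    estimate_q: bool = True,
    fixed_q: float = 0.3,
    q_init: float = 0.2,
    um_lower: np.ndarray | None = None,
    sigma_fallback: float = 1.0,
) -> tuple[RateParameters, np.ndarray, np.ndarray | None]:
    """Data-driven starting point for the optimization.

    The carrying capacity starts at the mean total observed producer
    biomass, half-saturation constants at the mean observed biomass of
    the resource, noise scales at the sample SD of each node's series
    (SD of log-ratios for relative scaling), initial biomasses at the
    first observed year, FR exponents at a stability-range value when
    estimated, and every other parameter at one.
    """
    obs = np.where(data.observed_mask, data.B_obs, np.nan)
    prod_total = np.nansum(obs[:, web.producer_indices], axis=1)
    prod_total = prod_total[~np.isnan(prod_total)]
    K = float(np.nanmean(prod_total)) if prod_total.size else 1.0
    if not K > 0:
        K = 1.0

    node_means = np.nanmean(obs, axis=0)
    B0 = node_means[web.link_resource].copy()
    B0[~(B0 > 0)] = 1.0

    n = web.n_nodes
    sigma = np.empty(n)
    for j in range(n):
        col = obs[:, j]
        vals = col[~np.isnan(col)]
        if noise.scaling == "relative":
            ok = ~np.isnan(col[:-1]) & ~np.isnan(col[1:])
            vals = np.log(col[1:][ok] / col[:-1][ok]) if ok.sum() >= 2 else np.array([])
        if vals.size >= 2:
            sigma[j] = float(np.std(vals, ddof=1))
        else:
            logger.warning(
                "node %r has < 2 usable observations; sigma falls back to %g",
                data.nodes[j],
                sigma_fallback,
            )
            sigma[j] = sigma_fallback
    sigma[~(sigma > 0)] = sigma_fallback

    if um_lower is None:
        um_lower = metabolic_lower_bounds(web)
    um = um_lower + 1.0  # estimated offset above the bound starts at one
    q0 = q_init if estimate_q else fixed_q
    params = RateParameters(
        r=np.ones(len(web.producer_indices)),
        K=K,
        um=um,
        J=np.ones(web.n_links),
        B0=B0,
        q=np.full(web.n_links, q0),
        um_lower=np.asarray(um_lower, dtype=float),
    )
    B_init = None
    if noise.layer == "observation":
        filled = data.conditioning_states()
        B_init = filled[0].copy()
    return params, sigma, B_init


def count_nonpositive(
    median_predictions: np.ndarray,
    mask: np.ndarray,
    detritus_index: int,
    threshold: float = 0.0,
) -> NonPositiveCounts:
    """Count node-year cells with predicted median biomass <= threshold.

    Counts only masked-in cells (those aligned with likelihood factors)
    and reports both the all-node count and the count excluding
    detritus.
    """
    bad = (median_predictions <= threshold) & mask
    n_all = int(bad.sum())
    keep = np.ones(median_predictions.shape[1], dtype=bool)
    keep[detritus_index] = False
    return NonPositiveCounts(n_all, int(bad[:, keep].sum()))


def _loss_components(
    x: np.ndarray,
    data: BiomassDataset,
    web: FoodWeb,
    noise: NoiseSpec,
    transform: ParameterTransform,
) -> tuple[float, NonPositiveCounts]:
    """(log-likelihood, non-positive prediction counts) at a free vector."""
    params, sigma, B_init = transform.unpack(x)
    ns = noise.replace_sigma(sigma)
    if noise.layer == "environmental":
        ll = env_loglik(data, params, web, ns)
        med, mask = env_median_matrix(data, params, web, ns)
        counts = count_nonpositive(med, mask, web.detritus_index)
    else:
        ll, details = obs_loglik(data, params, web, ns, B_init, return_details=True)
        # simulated biomass <= 0 exactly marks removed node-years
        counts = count_nonpositive(
            details["trajectory"].B, data.observed_mask, web.detritus_index
        )
    return ll, counts


def penalized_loss(
    x: np.ndarray,
    data: BiomassDataset,
    web: FoodWeb,
    noise: NoiseSpec,
    loss_spec: LossSpec,
    transform: ParameterTransform,
) -> float:
    """Loss = -loglik, plus 100 per non-positive median (soft) or +inf (hard)."""
    try:
        ll, counts = _loss_components(x, data, web, noise, transform)
    except (ValueError, FloatingPointError) as err:  # optimizer-safe
        logger.debug("loss evaluation failed: %s", err)
        return np.inf
    if not np.isfinite(ll):
        return np.inf
    n_bad = counts.all_nodes if loss_spec.include_detritus else counts.excluding_detritus
    if loss_spec.penalty == "hard":
        return np.inf if n_bad > 0 else -ll
    if loss_spec.penalty == "soft":
        return -ll + loss_spec.penalty_coefficient * n_bad
    return -ll


def fit(
    data: BiomassDataset,
    web: FoodWeb,
    noise: NoiseSpec,
    fit_config: FitConfig,
    loss_spec: LossSpec | None = None,
    um_lower: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Calibrate the model to data with CMA-ES warm restarts.

    Each restart re-initializes the CMA covariance and step size at the
    incumbent best free vector; only the best candidate is ever kept,
    so the best loss is non-increasing across restarts.  The AIC uses
    the unpenalized log-likelihood at the optimum.
    """
    loss_spec = loss_spec or LossSpec()
    if um_lower is None:
        um_lower = metabolic_lower_bounds(web)
    transform = ParameterTransform(
        web,
        noise_layer=noise.layer,
        estimate_q=fit_config.estimate_q,
        fixed_q=fit_config.fixed_q,
        um_lower=um_lower,
    )
    if x0 is None:
        p0, s0, b0 = initial_parameters(
            data,
            web,
            noise,
            estimate_q=fit_config.estimate_q,
            fixed_q=fit_config.fixed_q,
            um_lower=um_lower,
        )
        x0 = transform.pack(p0, s0, b0)

    def objective(x: np.ndarray) -> float:
        return penalized_loss(x, data, web, noise, loss_spec, transform)

    rng = np.random.default_rng(fit_config.seed)
    best_x = np.asarray(x0, dtype=float)
    best_f = objective(best_x)
    trace: list[float] = []
    n_evals = 1
    for restart in range(fit_config.restarts):
        try:
            res = cma_es_minimize(
                objective,
                best_x,
                sigma0=fit_config.sigma0,
                popsize=fit_config.offspring,
                max_iter=fit_config.max_iterations,
                rng=rng,
            )
        except Exception as err:  # keep the incumbent, proceed
            logger.warning("restart %d failed (%s); keeping incumbent", restart, err)
            trace.append(best_f)
            continue
        n_evals += res.n_evals
        if res.fun < best_f:
            best_f = res.fun
            best_x = res.x
        trace.append(best_f)
        logger.info("restart %d: best loss %.6g", restart, best_f)

    params, sigma, B_init = transform.unpack(best_x)
    ll, counts = _loss_components(best_x, data, web, noise, transform)
    k = count_parameters(
        web,
        "environmental" if noise.layer == "environmental" else "observation",
        estimate_q=fit_config.estimate_q,
    )
    return FitResult(
        params=params,
        sigma=sigma,
        B_init=B_init,
        loss=best_f,
        loglik=ll,
        n_nonpositive=counts,
        aic=2.0 * k - 2.0 * ll,
        n_parameters=k,
        restart_trace=trace,
        n_evals=n_evals,
    )
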