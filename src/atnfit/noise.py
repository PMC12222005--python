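"""Noise models and likelihoods for calibrating the food-web dynamics.

Two opposite noise assumptions are supported:

* **Environmental noise** — stochasticity in the dynamics themselves,
  modelled by independent Wiener processes driving each node's SDE.
  The Euler–Maruyama discretization turns the intractable transition
  density into a per-node Gaussian: one year ahead of an observed state
  ``B*(t)``, node ``i`` is ``N(B*_i(t) + f_i(B*(t)) dt, scale)`` with
  ``scale = sigma_i sqrt(dt)`` (absolute) or ``sigma_i B*_i(t) sqrt(dt)``
  (relative).  Lognormal variants replace the Gaussian factor by a
  lognormal density (moment-matched by default), which confines the
  predictive mass to positive biomasses.
* **Observation noise** — a fully deterministic trajectory observed
  with independent Gaussian error per cell.

Likelihoods always condition on *recorded* biomasses (never on model
predictions), so predictive mass below zero never propagates into the
simulation.  Missing cells drop exactly their own likelihood factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .foodweb import FoodWeb, RateParameters, Trajectory, drift, simulate_deterministic

__all__ = [
    "NoiseSpec",
    "PredictiveDistribution",
    "BiomassDataset",
    "one_step_predictive",
    "one_step_predictions",
    "env_median_matrix",
    "env_loglik",
    "obs_loglik",
    "cpi",
    "median_prediction",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
#: log-density assigned to a lognormal factor whose matched mean is <= 0
#: (optimization-safe stand-in for an undefined factor)
INVALID_LOGNORMAL_LOGDENSITY = -1.0e6


@dataclass(frozen=True)
class NoiseSpec:
    """Which noise enters the model and how it scales.

    ``layer`` is ``"environmental"`` (process noise via SDE) or
    ``"observation"`` (measurement error only); ``family`` is
    ``"normal"`` or ``"lognormal"`` (lognormal only for the
    environmental layer); ``scaling`` is ``"absolute"`` (sigma in
    tonnes/km^2) or ``"relative"`` (sigma dimensionless, multiplying
    the current biomass).
    """

    layer: str
    family: str
    scaling: str
    sigma: np.ndarray  # per-node scale
    lognormal_param: str = "moment"  # "moment" or "logspace"

    def __post_init__(self) -> None:
        if self.layer not in ("environmental", "observation"):
            raise ValueError(f"unknown noise layer {self.layer!r}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.scaling not in ("absolute", "relative"):
            raise ValueError(f"unknown noise scaling {self.scaling!r}")
        if self.family == "lognormal" and self.layer != "environmental":
            raise ValueError("lognormal noise is only defined for the environmental layer")
        if self.lognormal_param not in ("moment", "logspace"):
            raise ValueError(f"unknown lognormal parameterization {self.lognormal_param!r}")
        object.__setattr__(self, "sigma", np.atleast_1d(np.asarray(self.sigma, dtype=float)))
        if np.any(self.sigma <= 0):
            raise ValueError("noise scales must be strictly positive")

    def replace_sigma(self, sigma: np.ndarray) -> "NoiseSpec":
        return NoiseSpec(self.layer, self.family, self.scaling, sigma, self.lognormal_param)


@dataclass
class PredictiveDistribution:
    """Per-node one-step-ahead distribution.

    For ``family == "normal"``, ``loc``/``scale`` are the Gaussian mean
    and standard deviation (support is the whole real line: predictive
    mass below zero is deliberately not clipped).  For
    ``family == "lognormal"``, they are the log-space location mu and
    scale parameters, and ``valid`` flags nodes whose moment-matched
    mean was positive (an invalid node carries no usable density).
    """

    family: str
    loc: np.ndarray
    scale: np.ndarray
    year: int | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loc = np.atleast_1d(np.asarray(self.loc, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if self.valid is None:
            self.valid = np.ones(self.loc.shape, dtype=bool)
        ok = self.scale[self.valid] > 0
        if not np.all(ok):
            raise ValueError("predictive scales must be strictly positive")


@dataclass
class BiomassDataset:
    """Observed biomass matrix with missingness mask and catch forcing.

    ``B_obs`` is (n_years, n_nodes) with NaN at unobserved cells;
    ``observed_mask`` marks cells that enter likelihoods (interpolated
    cells count as observed and are additionally flagged in
    ``interpolated_mask``).  ``catches`` is an equally shaped matrix of
    annual catch rates (zeros where no catch applies).
    """

    nodes: list[str]
    years: np.ndarray
    B_obs: np.ndarray
    observed_mask: np.ndarray
    catches: np.ndarray | None = None
    interpolated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.B_obs = np.asarray(self.B_obs, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        T, n = self.B_obs.shape
        if len(self.nodes) != n or self.years.shape != (T,):
            raise ValueError("dataset dimensions are inconsistent")
        if self.catches is None:
            self.catches = np.zeros_like(self.B_obs)
        self.catches = np.asarray(self.catches, dtype=float)
        if np.any(self.catches < 0):
            raise ValueError("catches must be >= 0")
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros_like(self.observed_mask)
        vals = self.B_obs[self.observed_mask]
        if vals.size and np.any(vals < 0):
            raise ValueError("observed biomasses must be >= 0")
        if vals.size and np.any(vals == 0):
            # raw zero records are legal on read; likelihoods expect them
            # replaced by 1e-8 during data preparation
            logger.warning("dataset contains zero biomass records; replace before fitting")

    @property
    def n_years(self) -> int:
        return self.B_obs.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.B_obs.shape[1]

    def conditioning_states(self) -> np.ndarray:
        """Biomass matrix with absent cells filled for drift evaluation.

        A cell masked out of the likelihood but whose recorded value is
        present (non-NaN) still conditions the drift — masking then
        removes exactly its own likelihood factors.  Genuinely absent
        entries are replaced by the node's most recent recorded value
        (carry-forward; backward fill at a leading gap).  Only the
        drift ever sees filled values — likelihood factors still
        require both endpoints of a transition to be observed.
        """
        filled = self.B_obs.copy()
        for j in range(self.n_nodes):
            col = filled[:, j]
            if np.all(np.isnan(col)):
                raise ValueError(f"node {self.nodes[j]!r} has no observations")
            idx = np.where(~np.isnan(col), np.arange(len(col)), -1)
            idx = np.maximum.accumulate(idx)
            first = np.flatnonzero(~np.isnan(col))[0]
            idx[idx < 0] = first
            filled[:, j] = col[idx]
        return filled


def _env_scales(noise: NoiseSpec, B_prev: np.ndarray, dt: float) -> np.ndarray:
    sqdt = np.sqrt(dt)
    if noise.scaling == "absolute":
        return np.broadcast_to(noise.sigma * sqdt, B_prev.shape).copy()
    return noise.sigma * B_prev * sqdt


def _lognormal_params(
    mean: np.ndarray, sd: np.ndarray, how: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-space (mu, sigma) and validity for a lognormal predictive.

    ``how == "moment"`` matches the lognormal's mean and standard
    deviation to the Euler location and the corresponding normal scale;
    ``how == "logspace"`` reuses them directly as log-space parameters.
    """
    if how == "logspace":
        valid = sd > 0
        return mean, sd, valid
    valid = mean > 0
    m = np.where(valid, mean, 1.0)
    s2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - 0.5 * s2
    return mu, np.sqrt(s2), valid


def one_step_predictive(
    B_prev: np.ndarray,
    params: RateParameters,
    web: FoodWeb,
    catch_t: np.ndarray | None,
    noise: NoiseSpec,
    dt: float = 1.0,
    year: int | None = None,
) -> PredictiveDistribution:
    """Euler–Maruyama one-year-ahead predictive from an observed state."""
    if noise.layer != "environmental":
        raise ValueError("one-step predictives are defined for the environmental layer")
    B_prev = np.asarray(B_prev, dtype=float)
    loc = B_prev + drift(B_prev, params, web, catch_t) * dt
    scale = _env_scales(noise, B_prev, dt)
    if noise.scaling == "relative" and np.any(B_prev == 0):
        raise ValueError("relative scaling is degenerate at zero biomass")
    if noise.family == "normal":
        return PredictiveDistribution("normal", loc, scale, year=year)
    mu, sig, valid = _lognormal_params(loc, scale, noise.lognormal_param)
    return PredictiveDistribution("lognormal", mu, sig, year=year, valid=valid)


def _normal_logpdf(x: np.ndarray, loc: np.ndarray, scale: np.ndarray) -> np.ndarray:
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * _LOG2PI


def _lognormal_logpdf(x: np.ndarray, mu: np.ndarray, sig: np.ndarray) -> np.ndarray:
    lx = np.log(x)
    z = (lx - mu) / sig
    return -0.5 * z * z - np.log(sig) - lx - 0.5 * _LOG2PI


def env_loglik(
    data: BiomassDataset,
    params: RateParameters,
    web: FoodWeb,
    noise: NoiseSpec,
    dt: float = 1.0,
) -> float:
    """Log-likelihood of the data under environmental noise.

    Sums log transition densities over all one-year steps, always
    predicting from recorded biomasses.  A factor enters only when the
    node is observed at both endpoints of the step; a series with no
    usable transition yields 0 (empty product) with a warning.
    """
    if noise.layer != "environmental":
        raise ValueError("env_loglik requires an environmental-layer noise spec")
    T = data.n_years
    if T < 2:
        logger.warning("env_loglik: no transitions available; empty likelihood")
        return 0.0
    filled = data.conditioning_states()
    prev = filled[:-1]  # (T-1, n)
    if noise.scaling == "relative" and np.any(prev[data.observed_mask[:-1]] == 0):
        raise ValueError("relative scaling is degenerate at zero biomass")
    f = drift(prev, params, web, data.catches[:-1])
    loc = prev + f * dt
    scale = _env_scales(noise, prev, dt)
    step_ok = np.diff(data.years) == 1
    mask = data.observed_mask[:-1] & data.observed_mask[1:] & step_ok[:, None]
    if not np.any(mask):
        logger.warning("env_loglik: no usable transitions; empty likelihood")
        return 0.0
    x = data.B_obs[1:]
    if noise.family == "normal":
        terms = _normal_logpdf(x[mask], loc[mask], scale[mask])
        return float(terms.sum())
    mu, sig, valid = _lognormal_params(loc[mask], scale[mask], noise.lognormal_param)
    terms = np.where(
        valid,
        _lognormal_logpdf(x[mask], np.where(valid, mu, 0.0), np.where(valid, sig, 1.0)),
        INVALID_LOGNORMAL_LOGDENSITY,
    )
    return float(terms.sum())


def obs_loglik(
    data: BiomassDataset,
    params: RateParameters,
    web: FoodWeb,
    noise: NoiseSpec,
    B_init: np.ndarray,
    return_details: bool = False,
):
    """Log-likelihood of the data under pure observation noise.

    Simulates the deterministic trajectory from ``B_init`` over the data
    span and sums Gaussian log-densities of the observed cells around
    the simulated biomasses.  Cells of removed node-years contribute no
    factor; their count is reported in the details (it feeds the
    non-positivity penalty during calibration).
    """
    if noise.layer != "observation":
        raise ValueError("obs_loglik requires an observation-layer noise spec")
    if B_init is None:
        raise ValueError("observation-noise likelihood needs initial biomasses")
    traj = simulate_deterministic(B_init, params, web, data.catches, data.n_years)
    alive = traj.B > 0
    alive[0] = True  # B_init is strictly positive by contract
    usable = data.observed_mask & alive
    sim = traj.B
    if noise.scaling == "absolute":
        scale = np.broadcast_to(noise.sigma, sim.shape)
    else:
        scale = noise.sigma * np.where(usable, sim, 1.0)
    terms = _normal_logpdf(data.B_obs[usable], sim[usable], scale[usable])
    ll = float(terms.sum())
    if return_details:
        n_removed = int(np.sum(data.observed_mask & ~alive))
        return ll, {"n_removed_cells": n_removed, "trajectory": traj}
    return ll


def one_step_predictions(
    data: BiomassDataset,
    params: RateParameters,
    web: FoodWeb,
    noise: NoiseSpec,
    dt: float = 1.0,
) -> tuple[list[PredictiveDistribution], np.ndarray]:
    """Per-transition predictives over the whole dataset.

    Returns one :class:`PredictiveDistribution` per target year
    ``k = 1 .. T-1`` (predicting year ``k`` from the filled state at
    ``k-1``) and the (T-1, n) factor mask marking cells that enter the
    likelihood (both endpoints observed, one-year step).
    """
    if noise.layer != "environmental":
        raise ValueError("one-step predictions are defined for the environmental layer")
    filled = data.conditioning_states()
    prev = filled[:-1]
    loc = prev + drift(prev, params, web, data.catches[:-1]) * dt
    scale = _env_scales(noise, prev, dt)
    step_ok = np.diff(data.years) == 1
    mask = data.observed_mask[:-1] & data.observed_mask[1:] & step_ok[:, None]
    preds = []
    for k in range(data.n_years - 1):
        if noise.family == "normal":
            preds.append(
                PredictiveDistribution("normal", loc[k], scale[k], year=int(data.years[k + 1]))
            )
        else:
            mu, sig, valid = _lognormal_params(loc[k], scale[k], noise.lognormal_param)
            preds.append(
                PredictiveDistribution(
                    "lognormal",
                    mu,
                    np.where(valid, sig, 1.0),
                    year=int(data.years[k + 1]),
                    valid=valid,
                )
            )
    return preds, mask


def env_median_matrix(
    data: BiomassDataset,
    params: RateParameters,
    web: FoodWeb,
    noise: NoiseSpec,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(T-1, n) matrix of predictive medians plus the factor mask.

    For the lognormal family an invalid cell (non-positive matched
    mean) carries its Euler location as a signed stand-in so that
    non-positive predictions remain countable.
    """
    preds, mask = one_step_predictions(data, params, web, noise, dt)
    filled = data.conditioning_states()
    prev = filled[:-1]
    loc = prev + drift(prev, params, web, data.catches[:-1]) * dt
    med = np.empty_like(loc)
    for k, p in enumerate(preds):
        med[k] = median_prediction(p)
        if p.family == "lognormal":
            med[k] = np.where(p.valid, med[k], loc[k])
    return med, mask


def cpi(pred: PredictiveDistribution, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tail central probability interval of a predictive distribution.

    Returns per-node (lower, upper) at the given level; for the normal
    family the lower bound may be negative.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    if pred.family == "normal":
        lo = stats.norm.ppf(a, loc=pred.loc, scale=pred.scale)
        hi = stats.norm.ppf(1 - a, loc=pred.loc, scale=pred.scale)
    else:
        lo = stats.lognorm.ppf(a, s=pred.scale, scale=np.exp(pred.loc))
        hi = stats.lognorm.ppf(1 - a, s=pred.scale, scale=np.exp(pred.loc))
    return lo, hi


def median_prediction(pred: PredictiveDistribution) -> np.ndarray:
    """Median of the predictive (equals the mean for the normal family)."""
    if pred.family == "normal":
        return pred.loc.copy()
    return np.exp(pred.loc)
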