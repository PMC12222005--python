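"""Model comparison and model–data similarity statistics.

Models are ranked by AIC (2k - 2 loglik, lower preferred).  Agreement
between predictions and data is summarized by the Bray–Curtis
dissimilarity, BC = sum |pred - obs| / sum (pred + obs) over all guilds
and years, and by the coverage of the data by the 90% central
probability interval of the predictive distributions.  Under
environmental noise, "prediction" means the median of the
one-step-ahead predictive from each recorded state; under observation
noise it is the deterministic trajectory itself.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .calibration import FitResult, NonPositiveCounts, count_nonpositive
from .foodweb import FoodWeb, simulate_deterministic
from .noise import (
    BiomassDataset,
    NoiseSpec,
    PredictiveDistribution,
    cpi,
    env_median_matrix,
    one_step_predictions,
)

__all__ = [
    "EvaluationReport",
    "aic",
    "bray_curtis",
    "cpi_coverage",
    "evaluate",
]


@dataclass
class EvaluationReport:
    """Table-row summary of one fitted model."""

    aic: float
    delta_aic: float
    bray_curtis_dissimilarity: float
    similarity: float
    cpi_coverage: float
    cpi_level: float
    n_nonpositive_all: int
    n_nonpositive_excl_detritus: int
    loglik: float
    n_parameters: int

    def to_dict(self) -> dict:
        return asdict(self)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion ``2k - 2 loglik``; lower is preferred."""
    if k < 1:
        raise ValueError("parameter count must be >= 1")
    return 2.0 * k - 2.0 * float(loglik)


def bray_curtis(
    predicted: np.ndarray,
    observed: np.ndarray,
    mask: np.ndarray | None = None,
    clamp_negative: bool = True,
) -> float:
    """Bray–Curtis dissimilarity between predictions and data.

    ``BC = sum |pred - obs| / sum (pred+ + obs)`` over masked-in cells.
    For non-negative inputs BC lies in [0, 1] and is symmetric.
    Negative predictions keep their sign in the numerator but are
    clamped to 0 in the denominator (``clamp_negative``), which keeps
    the denominator positive; a model predicting far below zero can
    then exceed 1, honestly signalling worse-than-total dissimilarity.
    The clamp can be switched off.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("prediction and observation matrices must align")
    if mask is None:
        mask = np.ones(predicted.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("Bray-Curtis undefined on an all-masked input")
    p = predicted[mask]
    o = observed[mask]
    denom_p = np.maximum(p, 0.0) if clamp_negative else p
    denom = float(np.sum(denom_p + o))
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined: non-positive denominator")
    return float(np.sum(np.abs(p - o)) / denom)


def cpi_coverage(
    observed: np.ndarray,
    predictives: list[PredictiveDistribution],
    mask: np.ndarray,
    level: float = 0.9,
) -> float:
    """Fraction of masked-in cells whose datum falls inside the level-CPI.

    ``observed`` and ``mask`` are (len(predictives), n_nodes) matrices
    aligned with the per-transition predictive list.
    """
    inside = 0
    total = 0
    for k, pred in enumerate(predictives):
        lo, hi = cpi(pred, level)
        use = mask[k] & (pred.valid if pred.valid is not None else True)
        x = observed[k]
        inside += int(np.sum((x[use] >= lo[use]) & (x[use] <= hi[use])))
        total += int(use.sum())
    if total == 0:
        return float("nan")
    return inside / total


def evaluate(
    fit: FitResult,
    data: BiomassDataset,
    web: FoodWeb,
    noise: NoiseSpec,
    reference_aic: float | None = None,
    level: float = 0.9,
) -> EvaluationReport:
    """Assemble the comparison statistics for one fitted model.

    Environmental noise: one-step-ahead predictions from the observed
    states (medians for BC, full predictives for CPI coverage).
    Observation noise: the deterministic trajectory is compared to the
    data; CPI coverage uses the observation-error distribution around
    the simulated biomasses.
    """
    ns = noise.replace_sigma(fit.sigma)
    model_aic = aic(fit.loglik, fit.n_parameters)
    if noise.layer == "environmental":
        med, mask = env_median_matrix(data, fit.params, web, ns)
        obs = data.B_obs[1:]
        bc = bray_curtis(med, obs, mask)
        preds, _ = one_step_predictions(data, fit.params, web, ns)
        cov = cpi_coverage(obs, preds, mask, level)
        counts = count_nonpositive(med, mask, web.detritus_index)
    else:
        traj = simulate_deterministic(fit.B_init, fit.params, web, data.catches, data.n_years)
        mask = data.observed_mask
        bc = bray_curtis(traj.B, data.B_obs, mask)
        if ns.scaling == "absolute":
            scale = np.broadcast_to(ns.sigma, traj.B.shape).copy()
        else:
            scale = ns.sigma * np.abs(traj.B)
        preds = [
            PredictiveDistribution(
                "normal",
                traj.B[t],
                np.where(scale[t] > 0, scale[t], 1.0),
                year=int(data.years[t]),
                valid=scale[t] > 0,
            )
            for t in range(data.n_years)
        ]
        cov = cpi_coverage(data.B_obs, preds, mask, level)
        counts = count_nonpositive(traj.B, mask, web.detritus_index)
    ref = model_aic if reference_aic is None else float(reference_aic)
    return EvaluationReport(
        aic=model_aic,
        delta_aic=model_aic - ref,
        bray_curtis_dissimilarity=bc,
        similarity=1.0 - bc,
        cpi_coverage=cov,
        cpi_level=level,
        n_nonpositive_all=counts.all_nodes,
        n_nonpositive_excl_detritus=counts.excluding_detritus,
        loglik=fit.loglik,
        n_parameters=fit.n_parameters,
    )
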