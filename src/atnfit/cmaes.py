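"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact, seeded implementation of the standard (mu/mu_w, lambda)
CMA-ES with cumulative step-size adaptation, rank-one and rank-mu
covariance updates (Hansen's tutorial formulation).  It is a
derivative-free stochastic minimizer suited to the high-dimensional,
multimodal loss surfaces of calibrated food-web models.

The objective may return ``inf`` (hard penalties): infinite candidates
simply rank last within a generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["CMAResult", "cma_es_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray  # best point found
    fun: float  # objective at the best point
    n_iter: int
    n_evals: int
    best_per_iter: list[float] = field(default_factory=list)


def cma_es_minimize(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float = 0.5,
    popsize: int | None = None,
    max_iter: int = 100,
    rng: np.random.Generator | None = None,
) -> CMAResult:
    """Minimize ``fun`` starting from ``x0`` with initial step size ``sigma0``.

    ``popsize`` is the number of offspring per generation (default
    ``4 + floor(3 ln n)``).  All strategy constants follow the standard
    defaults.  The search is fully determined by ``rng``.
    """
    rng = np.random.default_rng(rng)
    m = np.asarray(x0, dtype=float).copy()
    n = m.size
    lam = int(popsize) if popsize else 4 + int(3 * np.log(n))
    lam = max(lam, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cs = (mueff + 2.0) / (n + mueff + 5.0)
    ds = 1.0 + 2.0 * max(0.0, np.sqrt((mueff - 1.0) / (n + 1.0)) - 1.0) + cs
    cc = (4.0 + mueff / n) / (n + 4.0 + 2.0 * mueff / n)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1.0 - c1, 2.0 * (mueff - 2.0 + 1.0 / mueff) / ((n + 2.0) ** 2 + mueff))
    chiN = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n * n))

    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    Bmat = np.eye(n)
    D = np.ones(n)
    invsqrtC = np.eye(n)
    eigen_stale = 0
    eigen_every = max(1, int(lam / (10.0 * n * (c1 + cmu))) if (c1 + cmu) > 0 else 1)

    x_best = m.copy()
    f_best = float(fun(m))
    n_evals = 1
    trace: list[float] = []

    it = -1
    for it in range(max_iter):
        z = rng.standard_normal((lam, n))
        y = z @ (Bmat * D).T  # y ~ N(0, C)
        X = m + sigma * y
        f = np.array([fun(xi) for xi in X], dtype=float)
        n_evals += lam
        order = np.argsort(f, kind="stable")
        gen_best = float(f[order[0]])
        trace.append(min(gen_best, f_best))
        if gen_best < f_best:
            f_best = gen_best
            x_best = X[order[0]].copy()

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = m + sigma * y_w

        ps = (1.0 - cs) * ps + np.sqrt(cs * (2.0 - cs) * mueff) * (invsqrtC @ y_w)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1.0 - (1.0 - cs) ** (2 * (it + 1)))
            < (1.4 + 2.0 / (n + 1.0)) * chiN
        )
        pc = (1.0 - cc) * pc + hsig * np.sqrt(cc * (2.0 - cc) * mueff) * y_w

        rank_mu = (w[:, None] * y_sel).T @ y_sel
        C = (
            (1.0 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1.0 - hsig) * cc * (2.0 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chiN - 1.0))

        if not np.all(np.isfinite(C)) or not np.isfinite(sigma) or sigma > 1e8:
            break  # numerical blow-up: keep the incumbent
        eigen_stale += 1
        if eigen_stale >= eigen_every:
            eigen_stale = 0
            C = (C + C.T) / 2.0
            vals, Bmat = np.linalg.eigh(C)
            vals = np.maximum(vals, 1e-20)
            D = np.sqrt(vals)
            invsqrtC = (Bmat / D) @ Bmat.T
        if sigma * D.max() < 1e-12:
            break  # converged to numerical resolution

    return CMAResult(x=x_best, fun=f_best, n_iter=it + 1, n_evals=n_evals, best_per_iter=trace)
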