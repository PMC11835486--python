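"""A compact (mu/mu_w, lambda)-CMA-ES for low-dimensional rate fitting.

Covariance Matrix Adaptation Evolution Strategy in the standard Hansen
formulation: rank-mu weighted recombination, cumulative step-size adaptation,
and rank-one plus rank-mu covariance updates. Box bounds are handled by
projecting samples onto the box (adequate for the 3-dimensional log-rate
searches this package performs). Fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["CmaResult", "minimize_cmaes"]


@dataclass
class CmaResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    converged: bool
    trace: list[float] = field(default_factory=list)  # best f per generation


def minimize_cmaes(
    func: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    *,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    popsize: int | None = None,
    max_evals: int = 2000,
    ftol: float = 1e-12,
    xtol: float = 1e-11,
    seed: int = 0,
) -> CmaResult:
    """Minimize ``func`` starting from ``x0`` with initial step size ``sigma0``.

    Convergence is declared when the within-generation fitness spread and the
    step size both collapse (``ftol``/``xtol``); otherwise the search stops at
    ``max_evals`` and reports ``converged=False`` with the best point found.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(x0, dtype=float).copy()
    n = mean.size
    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        mean = np.clip(mean, lo, hi)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    c_sigma = (mueff + 2) / (n + mueff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mueff)
    c_mu = min(1 - c_1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)

    best_x = mean.copy()
    best_f = np.inf
    n_evals = 0
    trace: list[float] = []
    converged = False

    while n_evals < max_evals:
        # C is symmetric positive definite by construction; refresh its
        # factorization every generation (n is tiny)
        C = (C + C.T) / 2.0
        eigvals, B = np.linalg.eigh(C)
        d = np.sqrt(np.clip(eigvals, 1e-20, None))

        z = rng.standard_normal((lam, n))
        y = z @ (B * d).T
        x = mean + sigma * y
        if bounds is not None:
            x = np.clip(x, lo, hi)
            y = (x - mean) / sigma

        f = np.array([func(xi) for xi in x])
        n_evals += lam
        order = np.argsort(f)
        if f[order[0]] < best_f:
            best_f = float(f[order[0]])
            best_x = x[order[0]].copy()
        trace.append(float(f[order[0]]))

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        c_inv_half_yw = B @ ((B.T @ y_w) / d)
        p_sigma = (1 - c_sigma) * p_sigma + np.sqrt(
            c_sigma * (2 - c_sigma) * mueff
        ) * c_inv_half_yw
        norm_ps = np.linalg.norm(p_sigma)
        gen = n_evals // lam
        h_sigma = norm_ps / np.sqrt(1 - (1 - c_sigma) ** (2 * gen)) / chi_n < 1.4 + 2 / (
            n + 1
        )
        p_c = (1 - c_c) * p_c + h_sigma * np.sqrt(c_c * (2 - c_c) * mueff) * y_w

        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(w, y_sel))
        C = (
            (1 - c_1 - c_mu) * C
            + c_1 * (np.outer(p_c, p_c) + (1 - h_sigma) * c_c * (2 - c_c) * C)
            + c_mu * rank_mu
        )
        sigma *= np.exp((c_sigma / d_sigma) * (norm_ps / chi_n - 1))

        if (f.max() - f.min() < ftol and len(trace) > 5) or sigma * np.sqrt(d.max()) < xtol:
            converged = True
            break

    return CmaResult(
        x=best_x, fun=best_f, n_evaluations=n_evals, converged=converged, trace=trace
    )
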