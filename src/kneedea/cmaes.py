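"""Covariance matrix adaptation evolution strategy (CMA-ES).

A self-contained (mu/mu_w, lambda)-CMA-ES with cumulative step-size
adaptation and rank-one plus rank-mu covariance updates, following the
canonical strategy parameterization.  The pose-recovery cost landscape is
highly nonconvex (silhouette overlap has many local basins), which is why a
population-based global strategy is used rather than a gradient method.

Determinism: all sampling comes from one ``numpy.random.Generator`` seeded
by the caller, so a fixed seed reproduces the trajectory bit-for-bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class OptimizationError(RuntimeError):
    """The strategy could not proceed (e.g. all-candidate cost failures)."""


@dataclasses.dataclass
class CMAResult:
    x: np.ndarray          #: best-ever evaluated point
    cost: float            #: its cost
    evaluations: int       #: total cost-function evaluations
    generations: int
    converged: bool        #: True when stopped by stagnation (not budget)
    seed: int


def cma_es_minimize(
    cost_fn,
    x0,
    sigma0,
    popsize: int = 70,
    max_evals: int = 8000,
    seed: int = 0,
    stagnation_tol: float = 1e-12,
    stagnation_generations: int = 20,
) -> CMAResult:
    """Minimize ``cost_fn`` over R^n with CMA-ES.

    Parameters
    ----------
    cost_fn : callable mapping an (n,) vector to a finite scalar cost
        (non-finite values are treated as failures; a fully non-finite
        generation raises :class:`OptimizationError`).
    x0 : initial mean.
    sigma0 : scalar or per-parameter initial standard deviations; a vector
        sigma0 scales the coordinates so the strategy's global step size
        starts at 1 in scaled space.
    popsize : candidates per generation (lambda); must be >= 4.
    max_evals : evaluation budget.
    seed : RNG seed; identical seeds give bit-identical trajectories.
    stagnation_tol, stagnation_generations : stop when the best cost has
        improved by less than ``stagnation_tol`` (relative) over this many
        consecutive generations.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    if popsize < 4:
        raise ValueError("popsize must be >= 4")
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    scales = np.broadcast_to(np.asarray(sigma0, dtype=float), (n,)).copy()
    if np.any(scales <= 0):
        raise ValueError("sigma0 must be positive")

    rng = np.random.default_rng(seed)
    lam = int(popsize)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2.0 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1.0 / (4 * n) + 1.0 / (21 * n**2))

    # optimize in scaled coordinates: x = x0-frame, y = x / scales
    mean = x0 / scales
    sigma = 1.0
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    B = np.eye(n)
    D = np.ones(n)

    # score the start point so the result is never worse than x0
    best_x = x0.copy()
    best_cost = float(cost_fn(x0))
    if not np.isfinite(best_cost):
        best_cost = np.inf
    evals = 1
    gen = 0
    stagnant = 0
    converged = False

    while evals < max_evals:
        gen += 1
        k = min(lam, max_evals - evals)
        z = rng.standard_normal((lam, n))[:k]
        y = z @ (B * D).T            # y ~ N(0, C)
        xs = (mean + sigma * y) * scales
        costs = np.array([cost_fn(xi) for xi in xs], dtype=float)
        evals += k
        finite = np.isfinite(costs)
        if not np.any(finite):
            raise OptimizationError(
                f"all {k} candidates returned non-finite cost at generation {gen} "
                f"(mean={mean * scales}, sigma={sigma})"
            )
        costs[~finite] = np.inf

        order = np.argsort(costs, kind="stable")
        gen_best = float(costs[order[0]])
        if gen_best < best_cost - stagnation_tol * max(1.0, abs(best_cost)):
            stagnant = 0
        else:
            stagnant += 1
        if gen_best < best_cost:
            best_cost = gen_best
            best_x = xs[order[0]].copy()

        if k < lam:
            break  # budget exhausted mid-generation: selection unreliable

        sel = order[:mu]
        y_w = w @ y[sel]
        mean = mean + sigma * y_w

        # cumulative step-size adaptation
        C_inv_sqrt_y = (B / D) @ (B.T @ y_w)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * C_inv_sqrt_y
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * evals / lam)) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        # covariance update (rank-one + rank-mu)
        delta_hsig = (1 - hsig) * cc * (2 - cc)
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + delta_hsig * C)
            + cmu * (y[sel].T * w) @ y[sel]
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        C = (C + C.T) / 2.0
        D2, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(D2, 1e-20))
        if D.max() / D.min() > 1e14:
            break  # numerically exhausted

        if stagnant >= stagnation_generations:
            converged = True
            break
        if sigma * D.max() < 1e-12:
            converged = True
            break

    return CMAResult(
        x=best_x,
        cost=float(best_cost),
        evaluations=evals,
        generations=gen,
        converged=converged,
        seed=int(seed),
    )
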