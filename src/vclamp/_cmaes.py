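"""Compact covariance matrix adaptation evolution strategy (CMA-ES).

A standard (μ/μw, λ) CMA-ES with cumulative step-size adaptation and
rank-one + rank-μ covariance updates, following the widely used reference
formulation.  Written for small (n ≲ 10) smooth but expensive objectives;
candidates are kept inside box bounds by reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CMAESResult", "cmaes_minimize"]


@dataclass
class CMAESResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    message: str


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds coordinates back into [lo, hi]."""
    span = hi - lo
    y = (x - lo) % (2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def cmaes_minimize(
    fun,
    x0: np.ndarray,
    sigma0: float,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    maxiter: int = 200,
    popsize: int | None = None,
    tol_fun: float = 1e-12,
    tol_x: float = 1e-11,
    rng: np.random.Generator | None = None,
) -> CMAESResult:
    """Minimise ``fun`` from ``x0`` with initial step size ``sigma0``.

    Deterministic given ``rng``.  Returns the best point ever evaluated.
    """
    rng = rng or np.random.default_rng()
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x, best_f = mean.copy(), np.inf
    n_evals = 0
    message = "maxiter reached"
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        # sample
        evals, vals = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        sqrtC = vals @ np.diag(np.sqrt(evals)) @ vals.T
        inv_sqrtC = vals @ np.diag(1.0 / np.sqrt(evals)) @ vals.T
        z = rng.standard_normal((lam, n))
        xs = mean + sigma * z @ sqrtC.T
        if bounds is not None:
            xs = np.array([_reflect(x, lo, hi) for x in xs])
        fs = np.array([fun(x) for x in xs])
        n_evals += lam

        order = np.argsort(fs)
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()

        sel = xs[order[:mu]]
        old_mean = mean
        mean = w @ sel

        # step-size path and update
        y = (mean - old_mean) / sigma
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * inv_sqrtC @ y
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * it)) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y

        # covariance update
        artmp = (sel - old_mean) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * artmp.T @ (w[:, None] * artmp)
        )
        C = (C + C.T) / 2
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 1e6)

        f_spread = float(fs[order[mu - 1]] - fs[order[0]])
        if f_spread < tol_fun and it > 10:
            message, converged = "fun spread below tol_fun", True
            break
        if sigma * np.sqrt(float(np.max(np.diag(C)))) < tol_x:
            message, converged = "step size below tol_x", True
            break

    return CMAESResult(
        x=best_x, fun=best_f, n_evals=n_evals, n_iter=it,
        converged=converged, message=message,
    )
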