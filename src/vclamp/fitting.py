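"""Fitting the artefact model + ionic conductance to recorded currents.

Free parameters are the maximum conductance and the voltage-clamp model
parameters Rs, Cm, Voff and gleak; the machine estimates (Rs*, Cm*,
gleak*) and the compensation settings stay fixed at their amplifier
values.  Positive parameters are searched on a log scale, ``p = p0·e^s``,
referenced to p0 = 600 nS for the conductance and to the machine estimates
for Rs, Cm and gleak; Voff may be negative and is searched untransformed.

The loss is the unweighted sum of squared residuals between simulated and
observed leak-subtracted current across all sweeps.  The search runs a
multi-restart CMA-ES (derivative-free, robust to the loss landscape far
from the optimum) and refines the best candidate with a finite-difference
Gauss–Newton polish, which supplies the final digits cheaply on a smooth
noiseless objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._cmaes import cmaes_minimize
from .amplifier import AmplifierSettings, CellProperties
from .ionic import GenericINa, GenericINaParams
from .protocols import Protocol
from .simulate import IntegrationError, SolverOptions, SteadyStateError, Trace, simulate

__all__ = [
    "FitSpec",
    "FitResult",
    "transform",
    "inverse_transform",
    "objective",
    "residuals",
    "fit",
]

#: Order of the free parameters in the transformed search vector.
FREE_PARAMS = ("conductance", "Rs", "Cm", "Voff", "gleak")
_LOG_IDX = (0, 1, 2, 4)  # conductance, Rs, Cm, gleak are log-transformed
_VOFF_IDX = 3

#: Penalty objective value for candidate parameters where the coupled
#: system cannot be simulated (e.g. unstable compensation feedback).
PENALTY = 1e12


def transform(p: float, p0: float) -> float:
    """Natural parameter → search coordinate, s = ln(p/p0)."""
    if not (p > 0 and p0 > 0):
        raise ValueError("log-transformed parameters require p > 0 and p0 > 0")
    return float(np.log(p / p0))


def inverse_transform(s: float, p0: float) -> float:
    """Search coordinate → natural parameter, p = p0·e^s."""
    if not p0 > 0:
        raise ValueError("reference value p0 must be > 0")
    return float(p0 * np.exp(s))


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``p0_conductance`` is in μS (default 0.6 μS = 600 nS); the references
    for Rs, Cm and gleak are the machine estimates carried by the amplifier
    settings.  ``s_bounds`` bound each log coordinate (±2 ≈ p0/7.4 …
    7.4·p0); ``voff_bounds`` are in mV.
    """

    p0_conductance: float = 0.6
    restarts: int = 40
    s_bounds: tuple[float, float] = (-2.0, 2.0)
    voff_bounds: tuple[float, float] = (-20.0, 20.0)
    sigma0: float = 0.5
    maxiter: int = 60
    popsize: int | None = None
    polish: bool = True
    solver: SolverOptions = field(
        default_factory=lambda: SolverOptions(rtol=1e-6, atol=1e-9)
    )

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not self.p0_conductance > 0:
            raise ValueError("p0_conductance must be > 0")


@dataclass
class FitResult:
    """Best-of-restarts fit with per-restart diagnostics."""

    params: dict[str, float]
    objective: float
    x: np.ndarray
    restarts: list[dict]
    polished: bool
    n_evals: int

    @property
    def conductance(self) -> float:
        return self.params["conductance"]


def _references(spec: FitSpec, settings: AmplifierSettings) -> np.ndarray:
    """Reference values p0 per free parameter (Voff slot unused)."""
    if not settings.gleak_est > 0:
        raise ValueError(
            "fitting gleak requires a positive machine estimate gleak_est "
            "as its reference value"
        )
    return np.array(
        [spec.p0_conductance, settings.Rs_est, settings.Cm_est, np.nan,
         settings.gleak_est]
    )


def x_to_params(x: np.ndarray, p0: np.ndarray) -> dict[str, float]:
    out = {}
    for i, name in enumerate(FREE_PARAMS):
        if i == _VOFF_IDX:
            out[name] = float(x[i])
        else:
            out[name] = inverse_transform(x[i], p0[i])
    return out


def params_to_x(params: dict[str, float], p0: np.ndarray) -> np.ndarray:
    x = np.empty(len(FREE_PARAMS))
    for i, name in enumerate(FREE_PARAMS):
        x[i] = params[name] if i == _VOFF_IDX else transform(params[name], p0[i])
    return x


def residuals(
    params: dict[str, float],
    data: Sequence[Trace],
    protocols: Sequence[Protocol],
    settings: AmplifierSettings,
    model_params: GenericINaParams,
    cell_template: CellProperties | None = None,
    solver: SolverOptions | None = None,
) -> np.ndarray:
    """Concatenated (simulated − observed) Ipost over all sweeps.

    The simulation is sampled on its own grid and interpolated onto each
    sweep's time stamps.  Raises the underlying simulation error; callers
    that need a penalty value use :func:`objective`.
    """
    if len(data) != len(protocols):
        raise ValueError("need one data trace per protocol")
    tmpl = cell_template or CellProperties()
    cell = CellProperties(
        Rs=params["Rs"],
        Cm=params["Cm"],
        Cp=tmpl.Cp,
        gleak=params["gleak"],
        Eleak=tmpl.Eleak,
        Voff=params["Voff"],
    )
    model = GenericINa(model_params.with_conductance(params["conductance"]))
    opts = solver or SolverOptions(rtol=1e-6, atol=1e-9)
    res = []
    for trace, prot in zip(data, protocols):
        dt = float(np.median(np.diff(trace.t)))
        opts_i = replace(opts, dt_out=dt)
        sim = simulate(settings, cell, model, prot, options=opts_i)
        sim_on_data = np.interp(trace.t, sim.t, sim.Ipost)
        res.append(sim_on_data - trace.Ipost)
    return np.concatenate(res)


def objective(
    params: dict[str, float],
    data: Sequence[Trace],
    protocols: Sequence[Protocol],
    settings: AmplifierSettings,
    model_params: GenericINaParams,
    cell_template: CellProperties | None = None,
    solver: SolverOptions | None = None,
) -> float:
    """Sum of squared residuals; large finite penalty if simulation fails."""
    try:
        r = residuals(
            params, data, protocols, settings, model_params, cell_template,
            solver,
        )
    except (IntegrationError, SteadyStateError, ValueError):
        return PENALTY
    with np.errstate(over="ignore"):
        sse = float(r @ r)
    return sse if np.isfinite(sse) else PENALTY


def fit(
    data: Sequence[Trace],
    protocols: Sequence[Protocol],
    settings: AmplifierSettings,
    fit_spec: FitSpec | None = None,
    model_params: GenericINaParams | None = None,
    cell_template: CellProperties | None = None,
    seed: int = 0,
) -> FitResult:
    """Best-of-restarts fit of (conductance, Rs, Cm, Voff, gleak).

    Each restart runs CMA-ES from a uniform random start in the
    transformed box; the overall best candidate is then polished by
    damped Gauss–Newton on the residual vector.  Deterministic given
    ``seed``; restart seed sequences are nested, so increasing
    ``restarts`` only appends starts.
    """
    spec = fit_spec or FitSpec()
    mp = model_params or GenericINaParams()
    if len(data) == 0:
        raise ValueError("no data sweeps")
    p0 = _references(spec, settings)

    lo = np.array([spec.s_bounds[0]] * 5, dtype=float)
    hi = np.array([spec.s_bounds[1]] * 5, dtype=float)
    lo[_VOFF_IDX], hi[_VOFF_IDX] = spec.voff_bounds

    def f(x: np.ndarray) -> float:
        return objective(
            x_to_params(x, p0), data, protocols, settings, mp, cell_template,
            spec.solver,
        )

    seeds = np.random.SeedSequence(seed).spawn(spec.restarts)
    table: list[dict] = []
    best_x, best_f = None, np.inf
    n_evals = 0
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x0 = lo + (hi - lo) * rng.uniform(size=5)
        out = cmaes_minimize(
            f,
            x0,
            spec.sigma0,
            bounds=(lo, hi),
            maxiter=spec.maxiter,
            popsize=spec.popsize,
            rng=rng,
        )
        n_evals += out.n_evals
        table.append(
            {
                "restart": k,
                "start": x0.copy(),
                "value": out.fun,
                "n_evals": out.n_evals,
                "converged": out.converged,
            }
        )
        if out.fun < best_f:
            best_f, best_x = out.fun, out.x.copy()

    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError(
            f"all {spec.restarts} restarts failed; per-restart values: "
            f"{[t['value'] for t in table]}"
        )

    polished = False
    if spec.polish and best_f < PENALTY:
        def r(x: np.ndarray) -> np.ndarray:
            try:
                return residuals(
                    x_to_params(x, p0), data, protocols, settings, mp,
                    cell_template, spec.solver,
                )
            except (IntegrationError, SteadyStateError, ValueError):
                return np.full(1, np.sqrt(PENALTY))

        ls = least_squares(
            r, best_x, bounds=(lo, hi), diff_step=1e-4, xtol=1e-12,
            ftol=1e-12, gtol=1e-12,
        )
        n_evals += ls.nfev * (len(best_x) + 1)
        if ls.cost * 2 < best_f:
            best_x, best_f = ls.x, float(ls.cost * 2)
            polished = True

    return FitResult(
        params=x_to_params(best_x, p0),
        objective=float(best_f),
        x=np.asarray(best_x),
        restarts=table,
        polished=polished,
        n_evals=n_evals,
    )
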