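"""The coupled cell–amplifier ODE system and its integration.

The *voltage-clamp model* couples the membrane voltage Vm, the pipette
voltage Vp, the clamp voltage Vclamp and the supercharging estimate Vest
with first-order amplifier filters, series-resistance compensation
(``alpha_R``), supercharging/prediction (``alpha_P``), capacitance
compensation and a residual voltage offset.  The recorded current Iout is
the τz-filtered input current; leak subtraction (using the *machine
estimates* of the leak) is a pure post-processing step.

State ordering everywhere: ``[Vm, Vp, Vclamp, Vest, Iout, *ionic_states]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels
from .amplifier import PF_TO_NF, AmplifierSettings, CellProperties
from .ionic import GenericINa, IonicModel, ModelCell
from .protocols import Protocol

__all__ = [
    "ArtefactState",
    "Trace",
    "SolverOptions",
    "artefact_rhs",
    "simulate",
    "simulate_ideal",
    "leak_subtract",
    "steady_state_init",
    "SteadyStateError",
    "IntegrationError",
]


class SteadyStateError(RuntimeError):
    """Steady-state initialisation failed to reach the residual tolerance."""


class IntegrationError(RuntimeError):
    """The stiff integrator failed; the message names the failing time."""


@dataclass
class ArtefactState:
    """Full state of the coupled system at one instant."""

    Vm: float
    Vp: float
    Vclamp: float
    Vest: float
    Iout: float
    ionic_states: np.ndarray
    residual_norm: float | None = None

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.Vm, self.Vp, self.Vclamp, self.Vest, self.Iout], self.ionic_states]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ArtefactState":
        return cls(
            Vm=float(y[0]),
            Vp=float(y[1]),
            Vclamp=float(y[2]),
            Vest=float(y[3]),
            Iout=float(y[4]),
            ionic_states=np.array(y[5:], dtype=float),
        )


@dataclass
class Trace:
    """Sampled time series of a (real or ideal) voltage-clamp simulation.

    All arrays share the same length; ``t`` is strictly increasing and
    covers the protocol duration.  Currents are in nA (inward negative),
    voltages in mV, time in ms.  ``ionic_states`` (n_samples × n_states)
    is kept for convenience but is not part of the CSV representation.
    """

    t: np.ndarray
    Vcmd: np.ndarray
    Vm: np.ndarray
    Vp: np.ndarray
    Vclamp: np.ndarray
    Vest: np.ndarray
    Iion: np.ndarray
    Iout: np.ndarray
    Ipost: np.ndarray
    ionic_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("Vcmd", "Vm", "Vp", "Vclamp", "Vest", "Iion", "Iout", "Ipost"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")


@dataclass(frozen=True)
class SolverOptions:
    """Integrator and output-sampling settings.

    The μs amplifier constants alongside ms gating make the system stiff;
    the default is an implicit BDF solver at tight tolerances.  Long
    holding segments are decimated to at most ``max_points_per_segment``
    output samples so multi-second holds do not dominate memory; the
    integration accuracy is unaffected.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.01  # ms
    max_points_per_segment: int = 20_000


def _pack_params(
    settings: AmplifierSettings, cell: CellProperties, vcmd: float
) -> np.ndarray:
    head = np.empty(_kernels.N_HEAD)
    head[0] = cell.Rs
    head[1] = cell.Cm * PF_TO_NF
    head[2] = cell.Cp * PF_TO_NF
    head[3] = cell.gleak
    head[4] = cell.Eleak
    head[5] = cell.Voff
    head[6] = settings.Rs_est
    head[7] = settings.Cm_est * PF_TO_NF
    head[8] = settings.Cp_est * PF_TO_NF
    head[9] = settings.alpha_R
    head[10] = settings.alpha_P
    head[11] = settings.tau_sum
    head[12] = settings.tau_clamp
    head[13] = settings.tau_z
    head[14] = vcmd
    return head


def _model_tail(model: IonicModel) -> np.ndarray | None:
    """Kernel parameter tail for models with a compiled RHS."""
    if isinstance(model, ModelCell):
        p = model.params
        return np.array([p.Rk, p.Ck * PF_TO_NF, p.Rm])
    if isinstance(model, GenericINa):
        p = model.params
        return np.array(
            [
                p.g_max,
                p.E_Na,
                p.v_half_m, p.k_m, p.tau_m_min, p.tau_m_amp, p.v_tau_m, p.s_tau_m,
                p.v_half_h, p.k_h, p.tau_h_min, p.tau_h_amp, p.v_tau_h, p.s_tau_h,
                p.v_half_j, p.k_j, p.tau_j_min, p.tau_j_amp, p.v_tau_j, p.s_tau_j,
            ]
        )
    return None


def _kernel_for(model: IonicModel):
    if isinstance(model, ModelCell):
        return _kernels.model_cell_rhs
    if isinstance(model, GenericINa):
        return _kernels.generic_ina_rhs
    return None


@dataclass
class RhsInfo:
    """Algebraic observables of one RHS evaluation."""

    Iion: float
    Ileak: float
    Iin: float
    Vcmd_prime: float
    dIout: float


def artefact_rhs(
    y: np.ndarray,
    t: float,
    settings: AmplifierSettings,
    cell: CellProperties,
    model: IonicModel,
    vcmd: float,
) -> tuple[np.ndarray, RhsInfo]:
    """Time derivatives of the coupled system, plus observables.

    Reference (pure Python) implementation; works with any
    :class:`~vclamp.ionic.IonicModel`.  The simulator uses compiled
    equivalents for the built-in models but this function defines the
    contract and serves as the fallback for third-party models.
    """
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t}")
    cm = cell.Cm * PF_TO_NF
    cp = cell.Cp * PF_TO_NF
    cm_e = settings.Cm_est * PF_TO_NF
    cp_e = settings.Cp_est * PF_TO_NF

    vm, vp, vclamp, vest, iout = y[:5]
    states = y[5:]

    iion = model.current(t, vm, states)
    ileak = cell.gleak * (vm - cell.Eleak)

    d_vm = (vp + cell.Voff - vm) / (cell.Rs * cm) - (iion + ileak) / cm
    d_vp = (vclamp - vp) / settings.tau_clamp
    d_vest = (vcmd - vest) / ((1.0 - settings.alpha_P) * settings.Rs_est * cm_e)
    vcmd_prime = vcmd + settings.Rs_est * (
        settings.alpha_R * iout + settings.alpha_P * cm_e * d_vest
    )
    d_vclamp = (vcmd_prime - vclamp) / settings.tau_sum
    i_in = iion + ileak + cp * d_vp - cp_e * d_vclamp + cm * d_vm - cm_e * d_vest
    d_iout = (i_in - iout) / settings.tau_z
    d_states = model.rhs(t, vm, states, dVm_dt=d_vm)

    dy = np.concatenate([[d_vm, d_vp, d_vclamp, d_vest, d_iout], d_states])
    return dy, RhsInfo(iion, ileak, i_in, vcmd_prime, d_iout)


def steady_state_init(
    settings: AmplifierSettings,
    cell: CellProperties,
    model: IonicModel,
    V_hold: float,
    tol: float = 1e-8,
) -> ArtefactState:
    """Equilibrium of the coupled system at a constant command ``V_hold``.

    At steady state all filters are settled: Vest = Vcmd, Vclamp = Vp =
    Vcmd′, Iout = Iin = Iion + Ileak, and the ionic states sit at their
    voltage-dependent steady states.  That reduces the problem to a scalar
    root-find in Vm.

    The raw RHS norm at the returned state is stored on the result
    (``residual_norm``).  Convergence is checked on the time-constant
    scaled residual (each derivative multiplied by its state's relaxation
    constant, i.e. the equilibrium displacement in mV or nA), which stays
    meaningful for very small Rs where the raw dVm/dt is ill-conditioned
    in double precision.
    """

    def residual(vm: float) -> float:
        states = model.steady_states(vm)
        iion = model.current(0.0, vm, states)
        ileak = cell.gleak * (vm - cell.Eleak)
        itot = iion + ileak
        vp = V_hold + settings.Rs_est * settings.alpha_R * itot
        return (vp + cell.Voff - vm) / cell.Rs - itot

    lo, hi = -350.0, 300.0
    if residual(lo) * residual(hi) > 0:  # widen if models push currents far
        lo, hi = -1500.0, 1500.0
    try:
        vm = brentq(residual, lo, hi, xtol=1e-13, rtol=1e-15, maxiter=200)
    except ValueError as exc:
        raise SteadyStateError(
            f"no equilibrium Vm bracket for V_hold={V_hold}: {exc}"
        ) from exc

    states = model.steady_states(vm)
    iion = model.current(0.0, vm, states)
    itot = iion + cell.gleak * (vm - cell.Eleak)
    vcmd_prime = V_hold + settings.Rs_est * settings.alpha_R * itot
    state = ArtefactState(
        Vm=float(vm),
        Vp=float(vcmd_prime),
        Vclamp=float(vcmd_prime),
        Vest=float(V_hold),
        Iout=float(itot),
        ionic_states=np.asarray(states, dtype=float),
    )
    dy, _ = artefact_rhs(state.to_vector(), 0.0, settings, cell, model, V_hold)
    state.residual_norm = float(np.linalg.norm(dy))
    taus = np.ones_like(dy)
    taus[0] = cell.Rs * cell.Cm * PF_TO_NF
    taus[1] = settings.tau_clamp
    taus[2] = settings.tau_sum
    taus[3] = (1.0 - settings.alpha_P) * settings.Rs_est * settings.Cm_est * PF_TO_NF
    taus[4] = settings.tau_z
    res_scaled = float(np.linalg.norm(dy * taus))
    if res_scaled > tol:
        raise SteadyStateError(
            f"steady-state scaled residual {res_scaled:.3e} exceeds tolerance "
            f"{tol:.1e} at V_hold={V_hold} (raw RHS norm {state.residual_norm:.3e})"
        )
    return state


def _segment_samples(t0: float, dur: float, opts: SolverOptions) -> np.ndarray:
    """Left-closed sample grid for one segment (excludes the segment end)."""
    dt = opts.dt_out
    n = int(np.ceil(dur / dt - 1e-9))
    if n > opts.max_points_per_segment:
        dt = dur / opts.max_points_per_segment
        n = opts.max_points_per_segment
    return t0 + dt * np.arange(n)


def simulate(
    settings: AmplifierSettings,
    cell: CellProperties,
    model: IonicModel,
    protocol: Protocol,
    dt_out: float | None = None,
    options: SolverOptions | None = None,
    y0: np.ndarray | None = None,
) -> Trace:
    """Integrate the voltage-clamp model over a step protocol.

    Starts from the steady state at the protocol's holding (first) level,
    honours command discontinuities by restarting the integrator at each
    segment boundary (the command is never smoothed), and samples the
    output at ``dt_out``.  The returned trace includes the leak-subtracted
    current ``Ipost`` computed with the machine leak estimates.
    """
    opts = options or SolverOptions()
    if dt_out is not None:
        if not dt_out > 0:
            raise ValueError("dt_out must be > 0")
        opts = SolverOptions(
            rtol=opts.rtol,
            atol=opts.atol,
            dt_out=dt_out,
            max_points_per_segment=opts.max_points_per_segment,
        )

    if y0 is None:
        y = steady_state_init(settings, cell, model, protocol.holding).to_vector()
    else:
        y = np.asarray(y0, dtype=float).copy()

    kernel = _kernel_for(model)
    tail = _model_tail(model)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    vcmds: list[np.ndarray] = []
    t0 = 0.0
    n_seg = len(protocol.segments)
    for i, (level, dur) in enumerate(protocol.segments):
        t1 = t0 + dur
        t_samp = _segment_samples(t0, dur, opts)
        # Integrate in segment-local time: the system is autonomous within
        # a segment, and the solver's minimum step scales with |t|, which
        # would needlessly fail on fast transients after multi-second holds.
        t_eval = np.append(t_samp - t0, dur)  # endpoint for continuity

        if kernel is not None:
            p = np.concatenate([_pack_params(settings, cell, level), tail])
            fun = _make_kernel_fun(kernel, p)
        else:
            def fun(t, yv, _level=level):
                dy, _ = artefact_rhs(yv, t, settings, cell, model, _level)
                return dy

        try:
            with np.errstate(invalid="ignore", over="ignore"):
                sol = solve_ivp(
                    fun,
                    (0.0, dur),
                    y,
                    method="BDF",
                    t_eval=t_eval,
                    rtol=opts.rtol,
                    atol=opts.atol,
                )
        except (ValueError, FloatingPointError) as exc:
            raise IntegrationError(
                f"integrator failed in segment {i} (t in [{t0:.6g}, {t1:.6g}] ms); "
                "the coupled system may be unstable at these compensation "
                f"settings: {exc}"
            ) from exc
        if not sol.success:
            t_fail = (sol.t[-1] if len(sol.t) else 0.0) + t0
            raise IntegrationError(
                f"integrator failed in segment {i} near t={t_fail:.6g} ms: "
                f"{sol.message}"
            )
        y = sol.y[:, -1].copy()
        keep = len(t_samp) if i < n_seg - 1 else len(t_eval)
        ts.append(sol.t[:keep] + t0)
        ys.append(sol.y[:, :keep])
        vcmds.append(np.full(keep, level))
        t0 = t1

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    vcmd = np.concatenate(vcmds)
    # final sample sits at the protocol end; it belongs to the last segment.

    states = Y[5:, :].T
    iion = _current_vec(model, t, Y[0], states)
    trace = Trace(
        t=t,
        Vcmd=vcmd,
        Vm=Y[0],
        Vp=Y[1],
        Vclamp=Y[2],
        Vest=Y[3],
        Iion=iion,
        Iout=Y[4],
        Ipost=Y[4].copy(),
        ionic_states=states,
    )
    return leak_subtract(trace, settings)


def _make_kernel_fun(kernel, p):
    def fun(t, y):
        return kernel(t, y, p)

    return fun


def _current_vec(model: IonicModel, t, vm, states) -> np.ndarray:
    if isinstance(model, GenericINa):
        pr = model.params
        return (
            pr.g_max
            * states[:, 0] ** 3
            * states[:, 1]
            * states[:, 2]
            * (vm - pr.E_Na)
        )
    if isinstance(model, ModelCell):
        return states[:, 0] + vm / model.params.Rm
    return np.array(
        [model.current(ti, vi, si) for ti, vi, si in zip(t, vm, states)]
    )


def simulate_ideal(
    model: IonicModel,
    protocol: Protocol,
    dt_out: float = 0.01,
    options: SolverOptions | None = None,
) -> Trace:
    """Artefact-free reference: the ionic model alone with Vm ≡ Vcmd.

    The command steps instantaneously, so models may define a state jump at
    discontinuities (the model cell's Ik branch receives ΔV/Rk).  Uses the
    model's closed-form constant-voltage solution when available, falling
    back to numerical integration otherwise.  In the returned trace
    Iout ≡ Ipost ≡ Iion.
    """
    opts = options or SolverOptions(dt_out=dt_out)
    if dt_out is not None:
        opts = SolverOptions(
            rtol=opts.rtol,
            atol=opts.atol,
            dt_out=dt_out,
            max_points_per_segment=opts.max_points_per_segment,
        )

    states = np.asarray(model.steady_states(protocol.holding), dtype=float)
    v_prev = protocol.holding

    ts, vms, iions, st_list = [], [], [], []
    t0 = 0.0
    n_seg = len(protocol.segments)
    for i, (level, dur) in enumerate(protocol.segments):
        states = np.asarray(model.jump(states, v_prev, level), dtype=float)
        t1 = t0 + dur
        t_samp = _segment_samples(t0, dur, opts)
        t_eval = np.append(t_samp, t1)
        t_loc = t_eval - t0

        closed = model.analytic_step(states, level, t_loc)
        if closed is not None:
            seg_states, seg_iion = closed
        else:
            sol = solve_ivp(
                lambda t, s: model.rhs(t, level, s),
                (0.0, dur),
                states,
                method="BDF",
                t_eval=t_loc,
                rtol=opts.rtol,
                atol=opts.atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"ideal-clamp integration failed in segment {i} near "
                    f"t={t0 + sol.t[-1]:.6g} ms: {sol.message}"
                )
            seg_states = sol.y.T
            seg_iion = np.array(
                [model.current(tl, level, s) for tl, s in zip(t_loc, seg_states)]
            )

        states = np.asarray(seg_states[-1], dtype=float)
        keep = len(t_samp) if i < n_seg - 1 else len(t_eval)
        ts.append(t_eval[:keep])
        vms.append(np.full(keep, level))
        iions.append(np.asarray(seg_iion)[:keep])
        st_list.append(np.asarray(seg_states)[:keep])
        v_prev = level
        t0 = t1

    t = np.concatenate(ts)
    vm = np.concatenate(vms)
    iion = np.concatenate(iions)
    return Trace(
        t=t,
        Vcmd=vm.copy(),
        Vm=vm,
        Vp=vm.copy(),
        Vclamp=vm.copy(),
        Vest=vm.copy(),
        Iion=iion,
        Iout=iion.copy(),
        Ipost=iion.copy(),
        ionic_states=np.concatenate(st_list) if model.n_states else None,
    )


def leak_subtract(trace: Trace, settings: AmplifierSettings) -> Trace:
    """Fill ``Ipost = Iout − gleak*·(Vcmd − Eleak*)``, pointwise.

    Pure arithmetic on the recorded current using the *machine estimates*
    of the leak parameters; returns the same trace with Ipost replaced.
    """
    trace.Ipost = trace.Iout - settings.gleak_est * (trace.Vcmd - settings.Eleak_est)
    return trace
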