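"""Independent matrix-exponential oracle for the model-cell system.

With the electrical model cell attached, the complete amplifier + cell
system is affine within each constant-command segment:

    dx/dt = A x + B u + c,   x = [Vm, Vp, Vclamp, Vest, Iout, Ik]

This module assembles (A, B, c) from its own transcription of the circuit
equations — written independently of the package's RHS code — and
propagates the exact solution with matrix exponentials over each protocol
segment.  It is the closed-form reference the simulated traces must match.
"""

import numpy as np
from scipy.linalg import expm

N = 6  # Vm, Vp, Vclamp, Vest, Iout, Ik


def _affine_rhs(settings, cell, mc, x, u):
    """One evaluation of the affine system; coefficients extracted below."""
    rs, cm, cp = cell.Rs, cell.Cm * 1e-3, cell.Cp * 1e-3
    rs_e, cm_e, cp_e = settings.Rs_est, settings.Cm_est * 1e-3, settings.Cp_est * 1e-3
    a_r, a_p = settings.alpha_R, settings.alpha_P
    rk, ck, rm = mc.Rk, mc.Ck * 1e-3, mc.Rm

    vm, vp, vclamp, vest, iout, ik = x
    iion = ik + vm / rm
    ileak = cell.gleak * (vm - cell.Eleak)
    d_vm = (vp + cell.Voff - vm) / (rs * cm) - (iion + ileak) / cm
    d_vp = (vclamp - vp) / settings.tau_clamp
    d_vest = (u - vest) / ((1.0 - a_p) * rs_e * cm_e)
    vcmd_prime = u + rs_e * (a_r * iout + a_p * cm_e * d_vest)
    d_vclamp = (vcmd_prime - vclamp) / settings.tau_sum
    i_in = iion + ileak + cp * d_vp - cp_e * d_vclamp + cm * d_vm - cm_e * d_vest
    d_iout = (i_in - iout) / settings.tau_z
    d_ik = (ck * d_vm - ik) / (rk * ck)
    return np.array([d_vm, d_vp, d_vclamp, d_vest, d_iout, d_ik])


def assemble(settings, cell, mc):
    """(A, B, c) such that dx/dt = A x + B u + c."""
    zero = np.zeros(N)
    c = _affine_rhs(settings, cell, mc, zero, 0.0)
    B = _affine_rhs(settings, cell, mc, zero, 1.0) - c
    A = np.column_stack(
        [_affine_rhs(settings, cell, mc, np.eye(N)[j], 0.0) - c for j in range(N)]
    )
    return A, B, c


def equilibrium(settings, cell, mc, u):
    """Steady state: solve A x = −(B u + c)."""
    A, B, c = assemble(settings, cell, mc)
    return np.linalg.solve(A, -(B * u + c))


def simulate_lti(settings, cell, mc, protocol, dt_out):
    """Exact piecewise solution sampled at dt_out (left-closed segments).

    Returns (t, X) with X of shape (n_samples, 6), including the final
    protocol endpoint, matching the package simulator's sampling.
    """
    A, B, c = assemble(settings, cell, mc)
    x = equilibrium(settings, cell, mc, protocol.holding)

    ts, xs = [], []
    t0 = 0.0
    n_seg = len(protocol.segments)
    for i, (level, dur) in enumerate(protocol.segments):
        forcing = B * level + c
        M = np.zeros((N + 1, N + 1))
        M[:N, :N] = A
        M[:N, N] = forcing
        n = int(np.ceil(dur / dt_out - 1e-9))
        E = expm(M * dt_out)
        aug = np.append(x, 1.0)
        for k in range(n):
            ts.append(t0 + k * dt_out)
            xs.append(aug[:N].copy())
            aug = E @ aug
        # exact segment endpoint (the grid may not land on it)
        aug_end = expm(M * dur) @ np.append(x, 1.0)
        x = aug_end[:N]
        t0 += dur
        if i == n_seg - 1:
            ts.append(t0)
            xs.append(x.copy())
    return np.array(ts), np.array(xs)
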