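"""Numba-compiled right-hand sides for the coupled amplifier + cell system.

The artefact model couples four amplifier voltages with μs-scale filter
constants to ms-scale ionic gating, so the ODE system is stiff and is
integrated with an implicit solver whose cost is dominated by RHS
evaluations; compiling the RHS keeps population-scale studies (thousands of
simulations) tractable.

Parameter packing (shared head, per-model tail):

====  =======================================
p[0]  Rs (MΩ)          p[8]   Cp_est (nF)
p[1]  Cm (nF)          p[9]   alpha_R
p[2]  Cp (nF)          p[10]  alpha_P
p[3]  gleak (μS)       p[11]  tau_sum (ms)
p[4]  Eleak (mV)       p[12]  tau_clamp (ms)
p[5]  Voff (mV)        p[13]  tau_z (ms)
p[6]  Rs_est (MΩ)      p[14]  Vcmd (mV)
p[7]  Cm_est (nF)
====  =======================================

State ordering: ``y = [Vm, Vp, Vclamp, Vest, Iout, *ionic_states]``.
"""

import numba as nb
import numpy as np

N_HEAD = 15

# state indices
IV_M, IV_P, IV_CLAMP, IV_EST, II_OUT = 0, 1, 2, 3, 4
N_AMP = 5


@nb.njit(cache=True, fastmath=False)
def _amplifier_core(y, p, iion, ileak):
    """Derivatives of the five amplifier/cell states given Iion and Ileak.

    Returns (dVm, dVp, dVclamp, dVest, dIout).
    """
    rs, cm, cp = p[0], p[1], p[2]
    rs_e, cm_e, cp_e = p[6], p[7], p[8]
    a_r, a_p = p[9], p[10]
    tau_sum, tau_clamp, tau_z = p[11], p[12], p[13]
    vcmd = p[14]

    vm, vp, vclamp, vest, iout = y[0], y[1], y[2], y[3], y[4]

    d_vm = (vp + p[5] - vm) / (rs * cm) - (iion + ileak) / cm
    d_vp = (vclamp - vp) / tau_clamp
    d_vest = (vcmd - vest) / ((1.0 - a_p) * rs_e * cm_e)
    vcmd_prime = vcmd + rs_e * (a_r * iout + a_p * cm_e * d_vest)
    d_vclamp = (vcmd_prime - vclamp) / tau_sum
    i_in = iion + ileak + cp * d_vp - cp_e * d_vclamp + cm * d_vm - cm_e * d_vest
    d_iout = (i_in - iout) / tau_z
    return d_vm, d_vp, d_vclamp, d_vest, d_iout


@nb.njit(cache=True, fastmath=False)
def model_cell_rhs(t, y, p):
    """Coupled RHS with the electrical model cell.

    Model tail: p[15] = Rk (MΩ), p[16] = Ck (nF), p[17] = Rm (MΩ).
    Ionic state: y[5] = Ik (nA).
    """
    rk, ck, rm = p[15], p[16], p[17]
    ik = y[5]
    iion = ik + y[0] / rm
    ileak = p[3] * (y[0] - p[4])
    d_vm, d_vp, d_vclamp, d_vest, d_iout = _amplifier_core(y, p, iion, ileak)
    d_ik = (ck * d_vm - ik) / (rk * ck)
    out = np.empty(6)
    out[0], out[1], out[2], out[3], out[4], out[5] = (
        d_vm,
        d_vp,
        d_vclamp,
        d_vest,
        d_iout,
        d_ik,
    )
    return out


@nb.njit(cache=True, fastmath=False)
def generic_ina_rhs(t, y, p):
    """Coupled RHS with the generic HH fast sodium current.

    Model tail (20 values from p[15]): p[15]=g_max, p[16]=E_Na, then
    (v_half, k, tau_min, tau_amp, v_tau, s_tau) per gate — m at p[17..22],
    h at p[23..28], j at p[29..34].  Ionic states: y[5]=m, y[6]=h, y[7]=j.
    """
    g_max, e_na = p[15], p[16]
    vm = y[0]
    m, h, j = y[5], y[6], y[7]
    iion = g_max * m * m * m * h * j * (vm - e_na)
    ileak = p[3] * (vm - p[4])
    d_vm, d_vp, d_vclamp, d_vest, d_iout = _amplifier_core(y, p, iion, ileak)

    out = np.empty(8)
    out[0], out[1], out[2], out[3], out[4] = d_vm, d_vp, d_vclamp, d_vest, d_iout
    for g in range(3):
        o = 17 + 6 * g
        v_half, k = p[o], p[o + 1]
        t_min, t_amp, v_tau, s_tau = p[o + 2], p[o + 3], p[o + 4], p[o + 5]
        inf = 1.0 / (1.0 + np.exp(-(vm - v_half) / k))
        x = (vm - v_tau) / s_tau
        tau = t_min + t_amp / (np.exp(x) + np.exp(-x))
        out[5 + g] = (inf - y[5 + g]) / tau
    return out
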