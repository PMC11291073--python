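"""Tests of the coupled amplifier + cell ODE system.

The electrical model cell keeps the whole system affine within each
protocol segment, so an independently assembled matrix-exponential
solution (tests/oracle.py) serves as the exact reference.
"""

import numpy as np
import pytest

from oracle import assemble, equilibrium, simulate_lti

from vclamp.amplifier import AmplifierSettings, CellProperties
from vclamp.ionic import GenericINa, ModelCell
from vclamp.protocols import Protocol, build_step_protocol
from vclamp.simulate import (
    SolverOptions,
    SteadyStateError,
    Trace,
    artefact_rhs,
    leak_subtract,
    simulate,
    simulate_ideal,
    steady_state_init,
)


class TestArtefactRhs:
    def test_no_compensation_reduces_command(self, model_cell_setup, rng):
        """With αR = αP = 0 the effective command is Vcmd itself and Vest
        relaxes with Rs*·Cm*."""
        settings, cell, mc = model_cell_setup
        y = rng.normal(size=6) * 20
        vcmd = 37.0
        dy, info = artefact_rhs(y, 0.0, settings, cell, mc, vcmd)
        assert info.Vcmd_prime == pytest.approx(vcmd)
        tau_est = settings.Rs_est * settings.Cm_est * 1e-3
        assert dy[3] == pytest.approx((vcmd - y[3]) / tau_est)

    def test_supercharging_term_vanishes_at_fixed_point(self, rng):
        """When Vest = Vcmd the supercharging drive is zero regardless of αP."""
        settings = AmplifierSettings(
            alpha_R=0.0, alpha_P=0.8, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
        )
        cell = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0)
        y = rng.normal(size=6) * 10
        vcmd = -30.0
        y[3] = vcmd  # Vest at the fixed point
        dy, info = artefact_rhs(y, 0.0, settings, cell, ModelCell(), vcmd)
        assert dy[3] == 0.0
        assert info.Vcmd_prime == pytest.approx(vcmd)

    def test_matches_hand_assembled_affine_system(self, model_cell_setup, rng):
        """RHS at random states equals A·x + B·u + c from the independent
        assembly, to machine precision, across compensation levels."""
        _, cell, mc = model_cell_setup
        for a_r, a_p in [(0, 0), (0.4, 0.0), (0.0, 0.6), (0.8, 0.8), (0.95, 0.95)]:
            settings = AmplifierSettings(
                alpha_R=a_r, alpha_P=a_p, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
            )
            A, B, c = assemble(settings, cell, mc.params)
            for _ in range(5):
                y = rng.normal(size=6) * 30
                u = rng.normal() * 80
                dy, _ = artefact_rhs(y, 0.0, settings, cell, mc, u)
                np.testing.assert_allclose(
                    dy, A @ y + B * u + c, rtol=1e-12, atol=1e-12
                )

    def test_alpha_p_of_one_rejected(self):
        with pytest.raises(ValueError):
            AmplifierSettings(alpha_P=1.0)


class TestSteadyStateInit:
    def test_all_zero_at_zero_hold(self, model_cell_setup):
        settings, cell, mc = model_cell_setup
        st = steady_state_init(settings, cell, mc, 0.0)
        assert st.to_vector() == pytest.approx(np.zeros(6), abs=1e-12)

    def test_matches_linear_equilibrium(self, model_cell_setup):
        """Equilibrium at −80 mV equals the closed-form solve of the affine
        system."""
        _, cell, mc = model_cell_setup
        settings = AmplifierSettings(
            alpha_R=0.8, alpha_P=0.8, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
        )
        cell = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0, gleak=0.002, Voff=1.0)
        st = steady_state_init(settings, cell, mc, -80.0)
        x_ref = equilibrium(settings, cell, mc.params, -80.0)
        np.testing.assert_allclose(st.to_vector(), x_ref, rtol=1e-9, atol=1e-9)

    def test_residual_norm_below_tolerance(self, model_cell_setup, ina_model):
        settings, cell, _ = model_cell_setup
        for model in (ModelCell(), ina_model):
            st = steady_state_init(settings, cell, model, -80.0)
            assert st.residual_norm is not None and st.residual_norm < 1e-8

    def test_offset_shifts_vm_by_seal_divider(self):
        """For a passive cell, Vm shifts by Voff·Rseal/(Rs + Rseal)."""
        passive = GenericINa(GenericINa().params.with_conductance(0.0))
        settings = AmplifierSettings(Rs_est=10.0, Cm_est=15.0)
        voff = 7.0
        for gleak in (0.001, 0.01, 0.1):
            base = CellProperties(Rs=10.0, Cm=15.0, gleak=gleak)
            offset = CellProperties(Rs=10.0, Cm=15.0, gleak=gleak, Voff=voff)
            vm0 = steady_state_init(settings, base, passive, -80.0).Vm
            vm1 = steady_state_init(settings, offset, passive, -80.0).Vm
            rseal = 1.0 / gleak
            expected = voff * rseal / (base.Rs + rseal)
            assert vm1 - vm0 == pytest.approx(expected, rel=1e-9)


class TestLinearOracleEquivalence:
    #: relative tolerance on each signal, scaled by its oracle amplitude
    RTOL = 1e-6

    @pytest.mark.parametrize("alpha", [0.0, 0.4, 0.8, 0.95])
    def test_trace_matches_matrix_exponential(
        self, model_cell_setup, big_step_protocol, alpha
    ):
        settings, cell, mc = model_cell_setup
        settings = settings.with_compensation(alpha, alpha)
        tr = simulate(settings, cell, mc, big_step_protocol, dt_out=0.05)
        t_ref, X = simulate_lti(settings, cell, mc.params, big_step_protocol, 0.05)
        np.testing.assert_allclose(tr.t, t_ref, atol=1e-12)
        for idx, name in [(0, "Vm"), (4, "Iout")]:
            ref = X[:, idx]
            scale = np.max(np.abs(ref))
            got = getattr(tr, name)
            assert np.max(np.abs(got - ref)) < self.RTOL * scale, name

    def test_high_compensation_shows_overshoot(self, model_cell_setup,
                                               big_step_protocol):
        """At αR = αP = 0.8 the output current rings: it crosses its final
        level during the step transient."""
        settings, cell, mc = model_cell_setup
        tr = simulate(
            settings.with_compensation(0.8, 0.8), cell, mc, big_step_protocol,
            dt_out=0.01,
        )
        step = (tr.t >= 20.0) & (tr.t < 40.0)
        i_late = tr.Iout[step][-1]
        assert np.min(tr.Iout[step]) < i_late < np.max(tr.Iout[step])


class TestSimulate:
    def test_relaxes_to_ohmic_level_after_transient(
        self, model_cell_setup, big_step_protocol
    ):
        """Uncompensated step −80 → 50 mV: Iout settles to Vm/Rm + leak."""
        settings, cell, mc = model_cell_setup
        tr = simulate(settings, cell, mc, big_step_protocol, dt_out=0.05)
        end_of_step = np.searchsorted(tr.t, 40.0) - 1
        x_eq = equilibrium(settings, cell, mc.params, 50.0)
        assert tr.Iout[end_of_step] == pytest.approx(x_eq[4], rel=1e-5)

    def test_ideal_clamp_limit_tracks_ionic_current(self):
        """With artefacts zeroed (Cp = gleak = Voff = 0) the recorded
        current converges to the ideal-clamp ionic current as Rs → 0.

        The comparison window starts 3 ms (three Ik relaxation constants)
        after the step edge: the charging spike and the small instrument
        lag (τsum, τz) are slew-limited by the amplifier, independent of
        Rs, and dominate earlier times; the Rs-artefact error they mask
        scales linearly with Rs and is what this property bounds.
        """
        mc = ModelCell()
        prot = Protocol(((-80.0, 5.0), (50.0, 15.0)))
        ideal = simulate_ideal(mc, prot, dt_out=0.01)
        mask = ideal.t >= 8.0
        errs = []
        for rs in (1.0, 0.1, 0.01, 0.001):
            settings = AmplifierSettings(Rs_est=rs, Cm_est=22.0)
            cell = CellProperties(Rs=rs, Cm=22.0)
            tr = simulate(settings, cell, mc, prot, dt_out=0.01)
            errs.append(np.max(np.abs(tr.Iout[mask] - ideal.Iout[mask])))
        peak = np.max(np.abs(ideal.Iout))
        assert all(e1 > e2 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < 0.01 * peak

    def test_integrator_failure_names_the_segment(self, big_step_protocol):
        """Uncompensated pipette capacitance at high αR destabilises the
        loop; the error message locates the failure."""
        from vclamp.simulate import IntegrationError

        settings = AmplifierSettings(
            alpha_R=0.9, alpha_P=0.0, Rs_est=30.0, Cm_est=22.0, Cp_est=0.0
        )
        cell = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0)
        with pytest.raises(IntegrationError, match="segment"):
            simulate(settings, cell, ModelCell(), big_step_protocol)


class TestSupercharging:
    def test_vest_relaxation_time_constant(self):
        """Vest → Vcmd exponentially with τ = (1 − αP)·Rs*·Cm* (log-linear
        fit to 0.1%)."""
        for a_p in (0.0, 0.4, 0.8):
            settings = AmplifierSettings(
                alpha_R=0.0, alpha_P=a_p, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
            )
            cell = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0)
            prot = Protocol(((-80.0, 5.0), (50.0, 5.0)))
            tr = simulate(settings, cell, ModelCell(), prot, dt_out=0.002)
            tau_expected = (1 - a_p) * settings.Rs_est * settings.Cm_est * 1e-3
            mask = (tr.t >= 5.0) & (tr.t < 5.0 + 3 * tau_expected)
            resid = np.abs(tr.Vest[mask] - 50.0)
            slope = np.polyfit(tr.t[mask], np.log(resid), 1)[0]
            assert -1 / slope == pytest.approx(tau_expected, rel=1e-3)

    def test_alpha_p_zero_reduces_to_no_supercharging_model(
        self, model_cell_setup, big_step_protocol
    ):
        """With αP = 0 the model reduces to the earlier no-supercharging
        formulation: no command overshoot, and the membrane-capacitance
        compensation estimate relaxing with Rs*·Cm*.

        The reduced system is written out independently below; trajectory
        identity is checked to integrator tolerance.
        """
        from scipy.integrate import solve_ivp

        settings, cell, mc = model_cell_setup
        settings = settings.with_compensation(0.6, 0.0)
        tr = simulate(settings, cell, mc, big_step_protocol, dt_out=0.05)

        rs, cm, cp = cell.Rs, cell.Cm * 1e-3, cell.Cp * 1e-3
        rs_e, cm_e = settings.Rs_est, settings.Cm_est * 1e-3
        cp_e = settings.Cp_est * 1e-3
        rk, ck, rm = mc.params.Rk, mc.params.Ck * 1e-3, mc.params.Rm

        def reduced(t, y, u):
            vm, vp, vclamp, vest, iout, ik = y
            iion = ik + vm / rm
            d_vm = (vp - vm) / (rs * cm) - iion / cm
            d_vp = (vclamp - vp) / settings.tau_clamp
            d_vest = (u - vest) / (rs_e * cm_e)  # plain Cm-compensation estimate
            d_vclamp = (u + rs_e * settings.alpha_R * iout - vclamp) / settings.tau_sum
            i_in = (
                iion + cp * d_vp - cp_e * d_vclamp + cm * d_vm - cm_e * d_vest
            )
            d_iout = (i_in - iout) / settings.tau_z
            d_ik = (ck * d_vm - ik) / (rk * ck)
            return [d_vm, d_vp, d_vclamp, d_vest, d_iout, d_ik]

        y = np.array([tr.Vm[0], tr.Vp[0], tr.Vclamp[0], tr.Vest[0],
                      tr.Iout[0], 0.0])
        t0 = 0.0
        ref_t, ref_iout, ref_vm = [], [], []
        for level, dur in big_step_protocol.segments:
            t_eval = np.arange(t0, t0 + dur, 0.05)
            sol = solve_ivp(
                reduced, (t0, t0 + dur), y, args=(level,), method="BDF",
                t_eval=np.append(t_eval, t0 + dur), rtol=1e-10, atol=1e-12,
            )
            y = sol.y[:, -1]
            ref_t.append(sol.t[:-1])
            ref_vm.append(sol.y[0, :-1])
            ref_iout.append(sol.y[4, :-1])
            t0 += dur
        ref_t = np.concatenate(ref_t)
        n = len(ref_t)
        np.testing.assert_allclose(tr.t[:n], ref_t, atol=1e-12)
        scale = np.max(np.abs(np.concatenate(ref_iout)))
        assert np.max(np.abs(tr.Iout[:n] - np.concatenate(ref_iout))) < 1e-5 * scale
        assert np.max(np.abs(tr.Vm[:n] - np.concatenate(ref_vm))) < 1e-5 * 130


class TestLeakSubtract:
    def test_zero_estimate_is_identity(self, model_cell_setup):
        t = np.linspace(0, 1, 11)
        tr = Trace(
            t=t, Vcmd=np.full(11, 50.0), Vm=t, Vp=t, Vclamp=t, Vest=t,
            Iion=t, Iout=np.full(11, 2.0), Ipost=np.zeros(11),
        )
        out = leak_subtract(tr, AmplifierSettings(gleak_est=0.0))
        np.testing.assert_array_equal(out.Ipost, out.Iout)

    def test_pointwise_arithmetic(self):
        t = np.linspace(0, 1, 5)
        tr = Trace(
            t=t, Vcmd=np.full(5, 50.0), Vm=t, Vp=t, Vclamp=t, Vest=t,
            Iion=t, Iout=np.full(5, 2.0), Ipost=np.zeros(5),
        )
        out = leak_subtract(tr, AmplifierSettings(gleak_est=0.01, Eleak_est=0.0))
        np.testing.assert_allclose(out.Ipost, 1.5)

    def test_perfect_estimates_recover_iion_at_steady_state(self):
        """With gleak* = gleak, Eleak* = Eleak and negligible Rs, the
        steady-state Ipost equals the ionic current."""
        settings = AmplifierSettings(
            Rs_est=1e-4, Cm_est=22.0, gleak_est=0.02, Eleak_est=-10.0
        )
        cell = CellProperties(Rs=1e-4, Cm=22.0, gleak=0.02, Eleak=-10.0)
        prot = Protocol(((-80.0, 5.0), (50.0, 20.0)))
        tr = simulate(settings, cell, ModelCell(), prot, dt_out=0.05)
        end = -1
        iion_expected = 50.0 / ModelCell().params.Rm
        assert tr.Ipost[end] == pytest.approx(iion_expected, rel=1e-4)


class TestSimulateIdeal:
    def test_model_cell_instant_ohmic_jump(self):
        """Under ideal clamp Im jumps instantly to V/Rm at the step."""
        prot = Protocol(((0.0, 5.0), (30.0, 5.0)))
        tr = simulate_ideal(ModelCell(), prot, dt_out=0.01)
        k = np.searchsorted(tr.t, 5.0)
        rm, rk = ModelCell().params.Rm, ModelCell().params.Rk
        assert tr.Iion[k] == pytest.approx(30.0 / rm + 30.0 / rk, rel=1e-9)

    def test_ik_relaxes_with_1ms_constant_when_held(self):
        prot = Protocol(((-80.0, 5.0), (50.0, 20.0)))
        tr = simulate_ideal(ModelCell(), prot, dt_out=0.01)
        mask = (tr.t >= 5.0) & (tr.t <= 10.0)
        ik = tr.Iion[mask] - 50.0 / ModelCell().params.Rm
        slope = np.polyfit(tr.t[mask], np.log(np.abs(ik)), 1)[0]
        assert -1 / slope == pytest.approx(1.0, rel=1e-9)

    def test_subthreshold_ina_peak_below_one_percent(self, ina_model):
        prot = Protocol(((-100.0, 5.0), (-55.0, 20.0)))
        tr = simulate_ideal(ina_model, prot, dt_out=0.01)
        bound = ina_model.params.g_max * abs(-55.0 - ina_model.params.E_Na)
        assert np.max(np.abs(tr.Iion)) < 0.01 * bound


class TestTraceInvariants:
    def test_time_strictly_increasing_and_full_cover(
        self, model_cell_setup, big_step_protocol
    ):
        settings, cell, mc = model_cell_setup
        tr = simulate(settings, cell, mc, big_step_protocol, dt_out=0.05)
        assert np.all(np.diff(tr.t) > 0)
        assert tr.t[0] == 0.0
        assert tr.t[-1] == pytest.approx(big_step_protocol.total_duration)

    def test_mismatched_lengths_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            Trace(
                t=t, Vcmd=t, Vm=t, Vp=t, Vclamp=t, Vest=t,
                Iion=t, Iout=t[:-1], Ipost=t,
            )
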