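"""Amplifier settings and true cell/pipette properties.

Unit system used throughout the package: mV, ms, MΩ, pF, nA, μS.  These are
self-consistent up to the capacitance scale: mV/MΩ = nA and μS·mV = nA, but
MΩ·pF = μs.  Internally the simulator therefore converts capacitances from
pF to nF (MΩ·nF = ms, nF·mV/ms = nA), so every equation can be written
without unit factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["AmplifierSettings", "CellProperties", "PF_TO_NF"]

#: pF → nF, the only unit conversion the simulator needs.
PF_TO_NF = 1e-3

#: Hard cap on the supercharging level: the estimated-membrane-voltage time
#: constant is (1 − αP)·Rs*·Cm*, which vanishes as αP → 1.
ALPHA_P_MAX = 0.999


@dataclass(frozen=True)
class AmplifierSettings:
    """Machine-side knobs and machine estimates of the cell parameters.

    Parameters
    ----------
    alpha_R
        Series-resistance compensation level, fraction in [0, 1).  The
        amplifier adds ``Rs* · alpha_R · Iout`` to the command voltage to
        offset the voltage drop across the access resistance.
    alpha_P
        Supercharging ("prediction") level, fraction in [0, 1).  Drives a
        transient command overshoot that charges the membrane capacitance
        with effective time constant ``(1 − alpha_P)·Rs*·Cm*``.
    Rs_est, Cm_est, Cp_est
        Machine estimates of series resistance (MΩ), membrane capacitance
        (pF) and parasitic/pipette capacitance (pF) used by the
        compensation circuitry.
    gleak_est, Eleak_est
        Leak conductance (μS) and reversal (mV) estimates used only by the
        post-processing leak subtraction.
    tau_sum, tau_clamp, tau_z
        First-order time constants (ms) of the summing amplifier, the
        voltage clamp, and the measurement transconductor (τz = Rf·Cf, set
        by the amplifier filtering).  All are O(1) μs on real hardware.
    """

    alpha_R: float = 0.0
    alpha_P: float = 0.0
    Rs_est: float = 10.0
    Cm_est: float = 15.0
    Cp_est: float = 0.0
    gleak_est: float = 0.0
    Eleak_est: float = 0.0
    tau_sum: float = 2e-3
    tau_clamp: float = 0.8e-3
    tau_z: float = 7.5e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_R < 1.0):
            raise ValueError(f"alpha_R must be in [0, 1), got {self.alpha_R}")
        if not (0.0 <= self.alpha_P <= ALPHA_P_MAX):
            raise ValueError(
                f"alpha_P must be in [0, {ALPHA_P_MAX}], got {self.alpha_P}"
            )
        for name in ("Rs_est", "Cm_est", "tau_sum", "tau_clamp", "tau_z"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.Cp_est < 0 or self.gleak_est < 0:
            raise ValueError("Cp_est and gleak_est must be >= 0")

    def with_compensation(self, alpha_R: float, alpha_P: float) -> "AmplifierSettings":
        """Copy of the settings at different compensation levels."""
        return replace(self, alpha_R=alpha_R, alpha_P=alpha_P)


@dataclass(frozen=True)
class CellProperties:
    """True physical parameters of the patched cell and pipette.

    ``Voff`` is the residual lumped voltage offset (electrode offsets,
    junction potentials, ...) remaining after amplifier offset
    compensation; only this residual enters the model equations.
    ``gleak`` is the seal leak conductance (Rseal = 1/gleak when > 0).
    """

    Rs: float = 10.0
    Cm: float = 15.0
    Cp: float = 0.0
    gleak: float = 0.0
    Eleak: float = 0.0
    Voff: float = 0.0

    def __post_init__(self) -> None:
        if not self.Rs > 0:
            raise ValueError(f"Rs must be > 0, got {self.Rs}")
        if not self.Cm > 0:
            raise ValueError(f"Cm must be > 0, got {self.Cm}")
        if self.Cp < 0 or self.gleak < 0:
            raise ValueError("Cp and gleak must be >= 0")

    @property
    def Rseal(self) -> float:
        """Seal resistance in MΩ (inf for a perfect seal)."""
        return float("inf") if self.gleak == 0 else 1.0 / self.gleak
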