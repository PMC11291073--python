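"""Pluggable ionic-current models.

Two concrete models ship with the package:

* :class:`ModelCell` — the electrical "model cell", a soldered RC network
  standing in for a biological cell.  Its current splits into a dynamic
  branch ``Ik`` (series Rk–Ck, driven by dVm/dt) and an ohmic branch
  ``Im = Vm/Rm``.  Because it is linear, the full amplifier + cell system
  admits a matrix-exponential closed form, which makes it the transparent
  validation target for the artefact model.
* :class:`GenericINa` — a Hodgkin–Huxley style fast sodium current
  ``I = g_max · m³·h·j · (Vm − E_Na)`` with sigmoidal steady states and
  bell-shaped voltage-dependent time constants.  It is a generic stand-in
  with steep activation (the property that produces loss-of-clamp positive
  feedback near threshold); parameters are configurable.

Third-party currents plug in by subclassing :class:`IonicModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IonicModel",
    "ModelCell",
    "ModelCellParams",
    "GenericINa",
    "GenericINaParams",
    "density_to_conductance",
]


class IonicModel:
    """Interface for ionic-current models coupled to the artefact model.

    Subclasses define ``n_states`` ionic state variables and must implement
    :meth:`current`, :meth:`rhs` and :meth:`steady_states`.  ``rhs`` and
    ``current`` must be deterministic functions of their arguments, and
    ``steady_states(V)`` must satisfy ``rhs(t, V, steady_states(V)) == 0``.

    Models whose current depends on dVm/dt (like the model cell) use the
    ``dVm_dt`` argument; it is supplied analytically by the coupled system,
    never by numerical differentiation.
    """

    n_states: int = 0

    def current(self, t: float, Vm: float, states: np.ndarray) -> float:
        """Ionic current Iion in nA (inward negative)."""
        raise NotImplementedError

    def rhs(
        self, t: float, Vm: float, states: np.ndarray, dVm_dt: float = 0.0
    ) -> np.ndarray:
        """Time derivatives of the ionic states (per ms)."""
        raise NotImplementedError

    def steady_states(self, Vm: float) -> np.ndarray:
        """Ionic states with zero derivative at fixed ``Vm``."""
        raise NotImplementedError

    def jump(self, states: np.ndarray, v_old: float, v_new: float) -> np.ndarray:
        """State update for an instantaneous Vm discontinuity.

        Only relevant under ideal clamp, where the command (and hence Vm)
        steps instantaneously.  Default: states are continuous.
        """
        return states

    def analytic_step(
        self, states0: np.ndarray, Vm: float, t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """Closed-form (states(t), Iion(t)) at constant ``Vm``, if available.

        ``t`` is measured from the start of the constant-voltage segment.
        Return ``None`` when no closed form exists; the ideal-clamp
        simulator then falls back to numerical integration.
        """
        return None


@dataclass(frozen=True)
class ModelCellParams:
    """Component values of the electrical model cell.

    The product Rk·Ck = 1 ms fixes the time scale of the dynamic branch;
    the values below drive O(10) nA through the network for a ~130 mV step,
    mimicking fast-sodium current magnitudes.
    """

    Rk: float = 100.0  # MΩ
    Ck: float = 10.0  # pF
    Rm: float = 10.0  # MΩ

    def __post_init__(self) -> None:
        if min(self.Rk, self.Ck, self.Rm) <= 0:
            raise ValueError("model-cell components must be positive")

    @property
    def tau_k(self) -> float:
        """Rk·Ck in ms (MΩ·pF = μs)."""
        return self.Rk * self.Ck * 1e-3


class ModelCell(IonicModel):
    """Electrical model cell: Iion = Ik + Vm/Rm with a first-order Ik branch.

    State vector: ``[Ik]`` (nA).  The branch obeys
    ``dIk/dt = (Ck·dVm/dt − Ik) / (Rk·Ck)``, i.e. Ik relaxes with time
    constant Rk·Ck (1 ms by default) and is charged by membrane-voltage
    slew.
    """

    n_states = 1

    def __init__(self, params: ModelCellParams | None = None):
        self.params = params or ModelCellParams()

    def current(self, t, Vm, states):
        return states[0] + Vm / self.params.Rm

    def rhs(self, t, Vm, states, dVm_dt=0.0):
        p = self.params
        # Ck dVm/dt in nA needs Ck in nF (pF·mV/ms = pA).
        return np.array([(p.Ck * 1e-3 * dVm_dt - states[0]) / p.tau_k])

    def steady_states(self, Vm):
        return np.zeros(1)

    def jump(self, states, v_old, v_new):
        # An instantaneous Vm step dumps (ΔV·Ck)/(Rk·Ck) = ΔV/Rk into Ik.
        return states + (v_new - v_old) / self.params.Rk

    def analytic_step(self, states0, Vm, t):
        p = self.params
        ik = states0[0] * np.exp(-np.asarray(t) / p.tau_k)
        return ik[:, None], ik + Vm / p.Rm


@dataclass(frozen=True)
class GenericINaParams:
    """Parameters of the generic fast sodium current.

    Steady states are sigmoids ``x∞(V) = 1/(1 + exp(−(V − v_half)/k))``
    (k < 0 for inactivation) and time constants are bell curves
    ``τx(V) = τ_min + τ_amp / (exp((V − v_τ)/s_τ) + exp(−(V − v_τ)/s_τ))``.

    Defaults place the activation threshold near −40 mV, make activation
    steep (m∞ e-fold per ~6 mV, so m³ e-fold per ~2 mV), and put the
    ideal-clamp I-V peak near −10 mV, typical of cardiac NaV1.5 at
    physiological temperature.  ``g_max`` defaults to 0.6 μS (600 nS), a
    typical whole-cell maximum conductance for heterologously expressed
    NaV1.5.
    """

    g_max: float = 0.6  # μS
    E_Na: float = 70.0  # mV
    # activation gate m (τm ~0.05–0.17 ms: fast activation at 37 °C)
    v_half_m: float = -34.0
    k_m: float = 6.0
    tau_m_min: float = 0.1  # ms
    tau_m_amp: float = 0.3
    v_tau_m: float = -45.0
    s_tau_m: float = 12.0
    # fast inactivation gate h (τh ~0.4 ms depolarised, ~3 ms at rest)
    v_half_h: float = -70.0
    k_h: float = -6.0
    tau_h_min: float = 0.5
    tau_h_amp: float = 6.0
    v_tau_h: float = -75.0
    s_tau_h: float = 12.0
    # slow inactivation gate j (an order slower than h)
    v_half_j: float = -70.0
    k_j: float = -6.0
    tau_j_min: float = 2.5
    tau_j_amp: float = 20.0
    v_tau_j: float = -75.0
    s_tau_j: float = 15.0

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.k_m <= 0:
            raise ValueError("activation steepness k_m must be > 0")
        for name in ("tau_m_min", "tau_h_min", "tau_j_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def with_conductance(self, g_max: float) -> "GenericINaParams":
        from dataclasses import replace

        return replace(self, g_max=g_max)


def _sigmoid(v, v_half, k):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


def _bell(v, t_min, t_amp, v_tau, s_tau):
    x = (v - v_tau) / s_tau
    return t_min + t_amp / (np.exp(x) + np.exp(-x))


class GenericINa(IonicModel):
    """HH-style fast sodium current, I = g_max·m³·h·j·(Vm − E_Na).

    State vector: ``[m, h, j]``, all dimensionless gates in [0, 1].
    """

    n_states = 3

    def __init__(self, params: GenericINaParams | None = None):
        self.params = params or GenericINaParams()

    def current(self, t, Vm, states):
        m, h, j = states[0], states[1], states[2]
        return self.params.g_max * m**3 * h * j * (Vm - self.params.E_Na)

    def infs_taus(self, Vm):
        """(x∞, τx) for the three gates at voltage ``Vm``."""
        p = self.params
        infs = np.array(
            [
                _sigmoid(Vm, p.v_half_m, p.k_m),
                _sigmoid(Vm, p.v_half_h, p.k_h),
                _sigmoid(Vm, p.v_half_j, p.k_j),
            ]
        )
        taus = np.array(
            [
                _bell(Vm, p.tau_m_min, p.tau_m_amp, p.v_tau_m, p.s_tau_m),
                _bell(Vm, p.tau_h_min, p.tau_h_amp, p.v_tau_h, p.s_tau_h),
                _bell(Vm, p.tau_j_min, p.tau_j_amp, p.v_tau_j, p.s_tau_j),
            ]
        )
        return infs, taus

    def rhs(self, t, Vm, states, dVm_dt=0.0):
        infs, taus = self.infs_taus(Vm)
        return (infs - states) / taus

    def steady_states(self, Vm):
        infs, _ = self.infs_taus(Vm)
        return infs

    def analytic_step(self, states0, Vm, t):
        # Gates relax mono-exponentially at constant voltage.
        infs, taus = self.infs_taus(Vm)
        t = np.asarray(t, dtype=float)
        states = infs + (np.asarray(states0) - infs) * np.exp(
            -t[:, None] / taus
        )
        iion = (
            self.params.g_max
            * states[:, 0] ** 3
            * states[:, 1]
            * states[:, 2]
            * (Vm - self.params.E_Na)
        )
        return states, iion


def ideal_peak_per_conductance(
    params: GenericINaParams,
    hold: float = -100.0,
    v_start: float = -90.0,
    v_end: float = 50.0,
    v_inc: float = 10.0,
    step_ms: float = 20.0,
    dt: float = 0.002,
) -> float:
    """Max |peak ideal-clamp current| per μS of conductance over a step family.

    Used to calibrate conductance from a requested current density.  Uses
    the closed-form gate relaxation, so it is cheap and exact.
    """
    model = GenericINa(params.with_conductance(1.0))
    t = np.arange(0.0, step_ms + dt / 2, dt)
    peak = 0.0
    n = int(round((v_end - v_start) / v_inc)) + 1
    for v in v_start + v_inc * np.arange(n):
        s0 = model.steady_states(hold)
        _, iion = model.analytic_step(s0, float(v), t)
        peak = max(peak, float(np.max(np.abs(iion))))
    return peak


def density_to_conductance(
    density: float, Cm: float, params: GenericINaParams | None = None, **sweep_kwargs
) -> float:
    """Conductance (μS) giving a requested peak current density (A/F).

    The conductance is scaled so that the maximum |peak| ideal-clamp
    current over a standard I-V step family, per unit membrane capacitance,
    equals ``density``.  1 A/F × 1 pF = 1 pA, so the target peak current is
    ``density · Cm · 1e-3`` nA.  Linear in both arguments: doubling Cm
    doubles the conductance at fixed density.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if not Cm > 0:
        raise ValueError("Cm must be > 0")
    params = params or GenericINaParams()
    per_g = ideal_peak_per_conductance(params, **sweep_kwargs)
    target_peak_nA = density * Cm * 1e-3
    return target_peak_nA / per_g
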