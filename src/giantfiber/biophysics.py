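"""Single-compartment Hodgkin-Huxley dynamics for the Giant Fiber model.

Each compartment carries a membrane potential ``v`` (mV) and three gating
variables ``n`` (K+ activation), ``m`` (Na+ activation) and ``h`` (Na+
inactivation), all relaxing first-order toward voltage-dependent steady
states:

    dx/dt = (x_inf(v) - x) / tau_x(v)

with Boltzmann steady states ``x_inf(v) = 1 / (1 + exp((v_half - v)/slope))``
and Gaussian-bump time constants
``tau_x(v) = tau_base + tau_amp * exp(-((tau_center - v)/tau_width)**2)``.

Voltages are in mV, time in ms; currents and conductances are in consistent
"model units" (the membrane equation divides current by ``c_m``, so only
ratios matter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

__all__ = [
    "GatingKinetics",
    "MembraneParams",
    "CompartmentState",
    "N_KINETICS",
    "M_KINETICS",
    "H_KINETICS",
    "gating_steady_state",
    "gating_time_constant",
    "gating_derivative",
    "ionic_currents",
    "membrane_derivative",
    "resting_state",
]


@dataclass(frozen=True)
class GatingKinetics:
    """Voltage dependence of one gating variable.

    Parameters
    ----------
    v_half, slope : float
        Boltzmann half-activation voltage (mV) and slope factor (mV, signed;
        negative slope gives an inactivating gate).
    tau_base, tau_amp : float
        Floor (ms) and amplitude (ms) of the Gaussian time-constant curve.
    tau_center, tau_width : float
        Voltage (mV) of the time-constant peak and its width (mV).
    """

    v_half: float
    slope: float
    tau_base: float
    tau_amp: float
    tau_center: float
    tau_width: float

    def __post_init__(self) -> None:
        if self.tau_base <= 0:
            raise ValueError(f"tau_base must be > 0, got {self.tau_base}")
        if self.tau_amp < 0:
            raise ValueError(f"tau_amp must be >= 0, got {self.tau_amp}")
        if self.tau_width == 0:
            raise ValueError("tau_width must be nonzero")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


# Gating kinetics of the Giant Fiber compartment model.
N_KINETICS = GatingKinetics(v_half=-53.0, slope=15.0,
                            tau_base=1.1, tau_amp=4.7,
                            tau_center=-79.0, tau_width=50.0)
M_KINETICS = GatingKinetics(v_half=-40.0, slope=15.0,
                            tau_base=0.04, tau_amp=0.46,
                            tau_center=-38.0, tau_width=30.0)
H_KINETICS = GatingKinetics(v_half=-62.0, slope=-7.0,
                            tau_base=1.2, tau_amp=7.4,
                            tau_center=-67.0, tau_width=20.0)


@dataclass(frozen=True)
class MembraneParams:
    """Passive and active membrane parameters of one compartment.

    Maximal conductances use the canonical HH current forms
    ``I_Na = g_na * m**3 * h * (v - e_na)``, ``I_K = g_k * n**4 * (v - e_k)``
    and ``I_L = g_leak * (v - e_leak)``. Defaults for ``c_m`` and the maximal
    conductances come from the package calibration (see circuit.calibrate);
    reversal potentials are fixed at the model's published values.
    """

    c_m: float = 1.0
    g_na: float = 50.0
    g_k: float = 20.0
    g_leak: float = 2.0
    e_na: float = 65.0
    e_k: float = -74.0
    e_leak: float = -85.0
    kin_n: GatingKinetics = field(default=N_KINETICS)
    kin_m: GatingKinetics = field(default=M_KINETICS)
    kin_h: GatingKinetics = field(default=H_KINETICS)

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError(f"c_m must be > 0, got {self.c_m}")
        for name in ("g_na", "g_k", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "MembraneParams":
        return replace(self, **kwargs)


@dataclass
class CompartmentState:
    """Dynamic state of one compartment: voltage plus gating fractions."""

    v: float
    n: float
    m: float
    h: float


def gating_steady_state(v: float, kin: GatingKinetics) -> float:
    """Boltzmann steady state ``x_inf(v)``, in (0, 1) for finite ``v``."""
    return 1.0 / (1.0 + math.exp((kin.v_half - v) / kin.slope))


def gating_time_constant(v: float, kin: GatingKinetics) -> float:
    """Gaussian-bump time constant ``tau_x(v)`` in ms; strictly positive."""
    z = (kin.tau_center - v) / kin.tau_width
    return kin.tau_base + kin.tau_amp * math.exp(-z * z)


def gating_derivative(x: float, v: float, kin: GatingKinetics) -> float:
    """First-order relaxation rate ``(x_inf(v) - x) / tau_x(v)`` per ms."""
    return (gating_steady_state(v, kin) - x) / gating_time_constant(v, kin)


def ionic_currents(state: CompartmentState,
                   params: MembraneParams) -> tuple[float, float, float]:
    """Sodium, potassium and leak currents (outward positive).

    Each current vanishes at its reversal potential.
    """
    v = state.v
    i_na = params.g_na * state.m ** 3 * state.h * (v - params.e_na)
    i_k = params.g_k * state.n ** 4 * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    return i_na, i_k, i_leak


def membrane_derivative(state: CompartmentState, params: MembraneParams,
                        i_syn: float = 0.0, i_stim: float = 0.0) -> float:
    """Membrane equation: ``c_m dv/dt = -(I_Na + I_K + I_L + I_syn) + I_stim``.

    ``i_syn`` follows the same outward-positive convention as the ionic
    currents; ``i_stim`` is an injected (depolarizing-positive) current.
    """
    i_na, i_k, i_leak = ionic_currents(state, params)
    return (-(i_na + i_k + i_leak + i_syn) + i_stim) / params.c_m


def _steady_current(v: float, params: MembraneParams) -> float:
    """Total ionic current with gating clamped at its steady state."""
    state = CompartmentState(
        v=v,
        n=gating_steady_state(v, params.kin_n),
        m=gating_steady_state(v, params.kin_m),
        h=gating_steady_state(v, params.kin_h),
    )
    return sum(ionic_currents(state, params))


def resting_state(params: MembraneParams,
                  v_lo: float = -95.0, v_hi: float = -55.0) -> CompartmentState:
    """Resting fixed point of an isolated compartment.

    Solves the steady-state current balance for the resting voltage (bracketed
    between ``v_lo`` and ``v_hi``) and sets the gating variables to their
    steady states there. Used to initialize simulations so latency
    measurements are free of onset transients.
    """
    v0 = brentq(_steady_current, v_lo, v_hi, args=(params,), xtol=1e-10)
    return CompartmentState(
        v=v0,
        n=gating_steady_state(v0, params.kin_n),
        m=gating_steady_state(v0, params.kin_m),
        h=gating_steady_state(v0, params.kin_h),
    )
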