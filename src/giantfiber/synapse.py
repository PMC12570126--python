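"""The mixed electrochemical Giant Fiber -> TTMn synapse.

Two transmission components connect the presynaptic terminal compartment to
the postsynaptic (motoneuron) compartment:

* a chemical component with a gating fraction ``s`` (open-channel fraction)
  driven by presynaptic voltage,

      ds/dt = (1 + tanh(v_pre / 4)) / 2 * (1 - s) / tau_rise - s / tau_decay
      I_chem = g_syn * s * (v_post - v_syn)

* an electrical (gap-junction) component whose conductance is read off the
  fraction ``p`` of terminal volume occupied by gap-junction protein through
  a sigmoid, with two overrides: zero occupancy gives zero conductance, and
  occupancy above the saturation threshold pins the conductance at its
  maximum,

      g_gap(p) = l_min + (l_max - l_min) / (1 + exp(-k_sig * (p - x0)))
      I_gap = g_gap * (v_post - v_pre)   (postsynaptic side; presynaptic
                                          side receives the negative)

Currents are outward-positive, matching the membrane equation in
:mod:`giantfiber.biophysics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ChemSynapseParams",
    "ChemGateState",
    "GapMapParams",
    "chem_gate_drive",
    "chem_gate_derivative",
    "chem_current",
    "occupancy_to_conductance",
    "gap_current",
]


@dataclass(frozen=True)
class ChemSynapseParams:
    """Chemical-component parameters.

    ``g_syn`` is the maximal synaptic conductance (model units), ``v_syn``
    the reversal potential (0 mV: excitatory), and ``tau_rise``/``tau_decay``
    the activation/deactivation time constants (ms).
    """

    g_syn: float = 0.1
    v_syn: float = 0.0
    tau_rise: float = 0.1
    tau_decay: float = 3.0

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError(f"g_syn must be >= 0, got {self.g_syn}")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("tau_rise and tau_decay must be > 0")

    def with_(self, **kwargs) -> "ChemSynapseParams":
        return replace(self, **kwargs)


@dataclass
class ChemGateState:
    """Fraction of open synaptic channels, in [0, 1]."""

    s: float = 0.0


@dataclass(frozen=True)
class GapMapParams:
    """Sigmoid map from gap-junction occupancy (% terminal volume) to
    coupling conductance.

    ``l_min``/``l_max`` bound the conductance, ``k_sig`` sets the steepness
    (per %-occupancy), ``x0`` the midpoint (%), and ``p_sat`` the occupancy
    above which the conductance saturates at ``l_max``. Defaults come from
    the package calibration (see circuit.calibrate).
    """

    l_min: float = 0.01
    l_max: float = 2.0
    k_sig: float = 1.25
    x0: float = 6.2
    p_sat: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.l_min <= self.l_max):
            raise ValueError("need 0 <= l_min <= l_max")
        if self.k_sig <= 0:
            raise ValueError(f"k_sig must be > 0, got {self.k_sig}")
        if not (0 < self.x0 < self.p_sat):
            raise ValueError("need 0 < x0 < p_sat")

    def with_(self, **kwargs) -> "GapMapParams":
        return replace(self, **kwargs)


def chem_gate_drive(v_pre: float) -> float:
    """Presynaptic drive ``(1 + tanh(v_pre / 4)) / 2``, in (0, 1)."""
    return (1.0 + math.tanh(v_pre / 4.0)) / 2.0


def chem_gate_derivative(s: float, v_pre: float,
                         params: ChemSynapseParams) -> float:
    """Rate of change of the open-channel fraction, per ms.

    At the boundaries the derivative points inward (``>= -s/tau_decay`` at
    ``s=1`` is negative; at ``s=0`` it is nonnegative), so trajectories
    started in [0, 1] stay there.
    """
    drive = chem_gate_drive(v_pre)
    return drive * (1.0 - s) / params.tau_rise - s / params.tau_decay


def chem_current(s: float, v_post: float, params: ChemSynapseParams) -> float:
    """Chemical synaptic current ``g_syn * s * (v_post - v_syn)``.

    Outward-positive: negative (depolarizing) when the postsynaptic
    compartment sits below the 0 mV reversal.
    """
    return params.g_syn * s * (v_post - params.v_syn)


def occupancy_to_conductance(p: float, params: GapMapParams) -> float:
    """Gap-junction conductance from % of terminal volume occupied.

    Zero occupancy maps to exactly zero (no channels, no coupling);
    occupancy above ``p_sat`` maps to exactly ``l_max``; in between the
    sigmoid interpolates from ``l_min`` to ``l_max``. At exactly
    ``p == p_sat`` the sigmoid value is used (the saturation override is a
    strict inequality).
    """
    if p < 0:
        raise ValueError(f"occupancy must be >= 0, got {p}")
    if p == 0:
        return 0.0
    if p > params.p_sat:
        return params.l_max
    return params.l_min + (params.l_max - params.l_min) / (
        1.0 + math.exp(-params.k_sig * (p - params.x0)))


def gap_current(v_pre: float, v_post: float, g_gap: float,
                rectify: bool = False) -> float:
    """Gap-junction current applied to the postsynaptic compartment.

    Ohmic by default: ``g_gap * (v_post - v_pre)`` (outward-positive; the
    presynaptic compartment receives the negative of this, so the pair
    conserves charge). With ``rectify=True`` the junction only conducts when
    the presynaptic side is depolarized relative to the postsynaptic side,
    mimicking the rectifying behaviour of the heterotypic innexin channel;
    the published model equation is the ohmic form, so this is off by
    default.
    """
    if g_gap < 0:
        raise ValueError(f"g_gap must be >= 0, got {g_gap}")
    if rectify and v_pre <= v_post:
        return 0.0
    return g_gap * (v_post - v_pre)
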