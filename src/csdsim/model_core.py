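"""Membrane biophysics of the two-neuron CSD-ignition motif.

The circuit couples a fast-spiking GABAergic interneuron (Wang-Buzsaki
kinetics, instantaneous Na+ activation) to a regular-spiking pyramidal
neuron (Traub-Miles kinetics, full activation gate).  On top of the
transient Na+ current each neuron can carry a non-inactivating persistent
Na+ current whose maximal conductance is a stated *fraction* of the
transient maximum; raising that fraction in the interneuron is the
model's proxy for NaV1.1 gain of function (familial hemiplegic migraine
type 3 mutations, or the toxin Hm1a).

Conventions: voltages in mV, conductances in mS/cm^2, current densities
in uA/cm^2, time in ms.  Outward current is positive and the membrane
equation is ``C dV/dt = -sum(I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GateSpec",
    "NeuronParams",
    "SynapseParams",
    "ionic_current",
    "persistent_sodium_current",
    "nap_activation",
    "drive_current",
    "fs_gate_specs",
    "rs_gate_specs",
    "wb_m_inf",
    "wb_h_rates",
    "wb_n_rates",
    "tm_m_rates",
    "tm_h_rates",
    "tm_n_rates",
]


# ---------------------------------------------------------------------------
# rate functions
#
# Fast-spiking interneuron: Wang-Buzsaki (phi = 5 folded into h and n rates);
# Na+ activation is treated as instantaneous (m = m_inf), the standard
# reduction for this model.  Regular-spiking pyramidal neuron: Traub-Miles
# rates as used throughout the ion-concentration modelling lineage.
# ---------------------------------------------------------------------------

def _vtrap(x: np.ndarray | float, y: float) -> np.ndarray | float:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-9, y, x / (1.0 - np.exp(-np.where(np.abs(x) < 1e-9, 1.0, x) / y)))
    return out if out.ndim else float(out)


def wb_m_inf(v):
    am = 0.1 * _vtrap(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


def wb_h_rates(v):
    ah = 0.35 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-0.1 * (v + 28.0)))
    return ah, bh


def wb_n_rates(v):
    an = 0.5 * 0.1 * _vtrap(v + 34.0, 10.0)
    bn = 0.625 * np.exp(-(v + 44.0) / 80.0)
    return an, bn


def tm_m_rates(v):
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    return am, bm


def tm_h_rates(v):
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    return ah, bh


def tm_n_rates(v):
    an = 0.032 * _vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return an, bn


def _inf_tau(rates: Callable):
    def inf(v):
        a, b = rates(v)
        return a / (a + b)

    def tau(v):
        a, b = rates(v)
        return 1.0 / (a + b)

    return inf, tau


@dataclass(frozen=True)
class GateSpec:
    """A Hodgkin-Huxley gating variable.

    ``steady_state`` maps voltage (mV) to the gate's equilibrium value in
    [0, 1]; ``time_constant`` maps voltage to the relaxation time in ms
    (strictly positive); the gate enters the conductance raised to
    ``exponent``.
    """

    name: str
    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float]
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be a positive integer")


def fs_gate_specs() -> tuple[GateSpec, ...]:
    """Gates of the fast-spiking interneuron (m instantaneous)."""
    m_inf = wb_m_inf
    h_inf, h_tau = _inf_tau(wb_h_rates)
    n_inf, n_tau = _inf_tau(wb_n_rates)
    return (
        GateSpec("m", m_inf, lambda v: 1e-3, exponent=3),
        GateSpec("h", h_inf, h_tau, exponent=1),
        GateSpec("n", n_inf, n_tau, exponent=4),
    )


def rs_gate_specs() -> tuple[GateSpec, ...]:
    """Gates of the regular-spiking pyramidal neuron."""
    m_inf, m_tau = _inf_tau(tm_m_rates)
    h_inf, h_tau = _inf_tau(tm_h_rates)
    n_inf, n_tau = _inf_tau(tm_n_rates)
    return (
        GateSpec("m", m_inf, m_tau, exponent=3),
        GateSpec("h", h_inf, h_tau, exponent=1),
        GateSpec("n", n_inf, n_tau, exponent=4),
    )


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron constants.

    ``persistent_fraction`` scales the non-inactivating Na+ conductance as
    a fraction of ``gNa_max``; ``drive_conductance`` is the constant
    glutamatergic input conductance (gD), reversing at ``drive_reversal``.
    Leak conductances set to ``None`` are fitted at build time so the
    configured resting state is an exact fixed point.
    """

    name: str
    membrane_capacitance: float = 1.0        # uF/cm^2
    gNa_max: float = 35.0                    # mS/cm^2
    gK_max: float = 20.0                     # mS/cm^2
    gNa_leak: float | None = None            # mS/cm^2, None -> fitted
    gK_leak: float | None = None             # mS/cm^2, None -> fitted
    gCl_leak: float = 0.05                   # mS/cm^2
    persistent_fraction: float = 0.0         # fraction of gNa_max
    drive_conductance: float = 0.0           # mS/cm^2
    drive_reversal: float = 0.0              # mV, glutamatergic
    resting_potential: float = -65.0         # mV, leak-fit anchor
    gate_specs: tuple[GateSpec, ...] = field(default_factory=fs_gate_specs)

    def __post_init__(self) -> None:
        for g in (self.gNa_max, self.gK_max, self.gCl_leak, self.drive_conductance):
            if g is not None and g < 0:
                raise ValueError("conductances must be non-negative")
        if not 0.0 <= self.persistent_fraction <= 0.2:
            raise ValueError("persistent_fraction outside [0, 0.2]")


@dataclass(frozen=True)
class SynapseParams:
    """GABA-A synapse from the interneuron onto the pyramidal neuron.

    The reversal potential is the postsynaptic chloride Nernst potential,
    evaluated at every instant from the tracked concentrations.  Gating:
    ``ds/dt = alpha * F(V_pre) * (1 - s) - s / tau_decay`` with a steep
    release sigmoid F centred at ``release_threshold`` so transmitter is
    driven by presynaptic spikes, not by sub-spike plateaus.
    """

    g_max: float = 0.45                      # mS/cm^2
    alpha: float = 2.0                       # 1/ms, rise rate
    tau_decay: float = 9.0                   # ms
    release_threshold: float = 0.0           # mV
    release_slope: float = 2.0               # mV

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("synaptic conductance must be non-negative")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def ionic_current(v, gate_values, exponents, g_max, reversal):
    """Hodgkin-Huxley current density g_max * prod(gate**exp) * (V - E).

    Positive = outward.  ``gate_values``/``exponents`` are parallel
    sequences; gate values must lie in [0, 1].
    """
    gate_values = np.atleast_1d(np.asarray(gate_values, dtype=float))
    exponents = np.atleast_1d(np.asarray(exponents))
    if np.any(gate_values < 0) or np.any(gate_values > 1):
        raise ValueError("gate values must lie in [0, 1]")
    open_frac = np.prod(gate_values ** exponents)
    return g_max * open_frac * (v - reversal)


def nap_activation(v, v_half: float = -29.0, slope: float = 7.0):
    """Steady-state activation of the persistent Na+ conductance.

    A first-order non-inactivating sigmoid: negligible at rest, engaging
    in the perithreshold/plateau range, so that raising the persistent
    fraction both speeds repetitive firing and destabilizes the neuron
    toward depolarization block.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / slope))


def persistent_sodium_current(v, params: NeuronParams, e_na,
                              v_half: float = -29.0, slope: float = 7.0):
    """Non-inactivating Na+ current with conductance
    ``persistent_fraction * gNa_max``.  Identically zero at fraction 0;
    inward (negative) for V < ENa."""
    g = params.persistent_fraction * params.gNa_max
    return g * nap_activation(v, v_half, slope) * (np.asarray(v, dtype=float) - e_na)


def drive_current(v, g_drive, drive_reversal=0.0):
    """Constant glutamatergic drive conductance: gD * (V - E_drive)."""
    if g_drive < 0:
        raise ValueError("drive conductance must be non-negative")
    return g_drive * (np.asarray(v, dtype=float) - drive_reversal)
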