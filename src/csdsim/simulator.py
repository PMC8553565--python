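"""Assembly and integration of the coupled two-neuron / ion-state system.

The full state vector (18 entries) is::

    0  V_I    membrane potential, interneuron (mV)
    1  h_I    Na+ inactivation, interneuron
    2  n_I    K+ activation, interneuron
    3  V_P    membrane potential, pyramidal (mV)
    4  h_P    Na+ inactivation, pyramidal
    5  n_P    K+ activation, pyramidal
    6  s      GABA-A gating (interneuron -> pyramidal)
    7..9     Na_in, K_in, Cl_in interneuron (mM)
    10..12   Na_in, K_in, Cl_in pyramidal (mM)
    13..15   Na_out, K_out, Cl_out shared ECS (mM)
    16  G     glial K+ buffer load (mM, ECS-referenced)
    17  m_P   Na+ activation, pyramidal

The interneuron uses the instantaneous-m reduction of its fast-spiking
kinetics; the pyramidal neuron integrates its activation gate, which
matters for spike initiation during slow potassium-driven depolarization.
Leak conductances are fitted once, at the physiological reference
persistent fraction, so the configured resting state is an exact fixed
point of the zero-drive system; scenarios then vary the persistent
fraction and drives without refitting.

Integration is stiff-aware adaptive (LSODA) with rtol 1e-6 / atol 1e-8
and dense output on a uniform grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from numba import njit
from scipy.integrate import solve_ivp

from . import model_core as mc
from .ion_dynamics import HomeostasisParams, IonState, rt_over_f

__all__ = [
    "CircuitParams",
    "Scenario",
    "SimulationTrace",
    "SCENARIOS",
    "load_default_circuit",
    "build_system",
    "simulate",
    "run_figure5_suite",
]

N_STATE = 18

STATE_COLUMNS = (
    "v_i", "h_i", "n_i", "v_p", "h_p", "n_p", "s",
    "na_in_i", "k_in_i", "cl_in_i", "na_in_p", "k_in_p", "cl_in_p",
    "na_out", "k_out", "cl_out", "glia_buffer", "m_p",
)


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

@njit(cache=True)
def _wb_minf(v):
    x = v + 35.0
    am = 0.1 * (x / (1.0 - np.exp(-x / 10.0))) if abs(x) > 1e-9 else 1.0
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


@njit(cache=True)
def _wb_h(v):
    ah = 0.35 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-0.1 * (v + 28.0)))
    return ah, bh


@njit(cache=True)
def _wb_n(v):
    x = v + 34.0
    an = 0.05 * (x / (1.0 - np.exp(-x / 10.0))) if abs(x) > 1e-9 else 0.5
    bn = 0.625 * np.exp(-(v + 44.0) / 80.0)
    return an, bn


@njit(cache=True)
def _tm_m(v):
    x = v + 54.0
    am = 0.32 * (x / (1.0 - np.exp(-x / 4.0))) if abs(x) > 1e-9 else 1.28
    y = -(v + 27.0)
    bm = 0.28 * (y / (1.0 - np.exp(-y / 5.0))) if abs(y) > 1e-9 else 1.4
    return am, bm


@njit(cache=True)
def _tm_h(v):
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    return ah, bh


@njit(cache=True)
def _tm_n(v):
    x = v + 52.0
    an = 0.032 * (x / (1.0 - np.exp(-x / 5.0))) if abs(x) > 1e-9 else 0.16
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return an, bn


@njit(cache=True)
def _pump(na_in, k_out, pmax, km_na, km_k):
    f_na = (na_in / (na_in + km_na)) ** 3
    f_k = (k_out / (k_out + km_k)) ** 2
    return pmax * f_na * f_k


# packed parameter vector layout
(P_GNA_I, P_GK_I, P_GNAL_I, P_GKL_I, P_GCLL_I, P_PFRAC_I, P_GD_I,
 P_GNA_P, P_GK_P, P_GNAL_P, P_GKL_P, P_GCLL_P, P_PFRAC_P, P_GD_P,
 P_EDRIVE, P_PMAX_I, P_PMAX_P, P_KMNA, P_KMK_I, P_KMK_P,
 P_NAP_V, P_NAP_K, P_GLIA_RATE, P_GLIA_CAP, P_GLIA_W,
 P_EPS_K, P_EPS_NA, P_KBATH, P_NABATH,
 P_GAM_I, P_GAM_P, P_BET_I, P_BET_P,
 P_GGABA, P_ALPHA_S, P_TAU_S, P_REL_THR, P_REL_SLOPE,
 P_RTF, P_CM_I, P_CM_P) = range(41)


@njit(cache=True)
def _rhs(t, y, p):
    v_i, h_i, n_i = y[0], y[1], y[2]
    v_p, h_p, n_p = y[3], y[4], y[5]
    s = y[6]
    na_i, k_i, cl_i = y[7], y[8], y[9]
    na_p, k_p, cl_p = y[10], y[11], y[12]
    na_o, k_o, cl_o = y[13], y[14], y[15]
    glia = y[16]
    m_p = y[17]

    rtf = p[P_RTF]
    e_na_i = rtf * np.log(na_o / na_i)
    e_k_i = rtf * np.log(k_o / k_i)
    e_cl_i = -rtf * np.log(cl_o / cl_i)
    e_na_p = rtf * np.log(na_o / na_p)
    e_k_p = rtf * np.log(k_o / k_p)
    e_cl_p = -rtf * np.log(cl_o / cl_p)

    # interneuron currents
    m_i = _wb_minf(v_i)
    ah, bh = _wb_h(v_i)
    an, bn = _wb_n(v_i)
    nap_i = 1.0 / (1.0 + np.exp(-(v_i + p[P_NAP_V]) / p[P_NAP_K]))
    i_nat_i = p[P_GNA_I] * m_i ** 3 * h_i * (v_i - e_na_i)
    i_nap_i = p[P_PFRAC_I] * p[P_GNA_I] * nap_i * (v_i - e_na_i)
    i_k_i = p[P_GK_I] * n_i ** 4 * (v_i - e_k_i)
    i_nal_i = p[P_GNAL_I] * (v_i - e_na_i)
    i_kl_i = p[P_GKL_I] * (v_i - e_k_i)
    i_cl_i = p[P_GCLL_I] * (v_i - e_cl_i)
    i_d_i = p[P_GD_I] * (v_i - p[P_EDRIVE])
    ip_i = _pump(na_i, k_o, p[P_PMAX_I], p[P_KMNA], p[P_KMK_I])

    # pyramidal currents
    amp, bmp = _tm_m(v_p)
    ahp, bhp = _tm_h(v_p)
    anp, bnp = _tm_n(v_p)
    nap_p = 1.0 / (1.0 + np.exp(-(v_p + p[P_NAP_V]) / p[P_NAP_K]))
    i_nat_p = p[P_GNA_P] * m_p ** 3 * h_p * (v_p - e_na_p)
    i_nap_p = p[P_PFRAC_P] * p[P_GNA_P] * nap_p * (v_p - e_na_p)
    i_k_p = p[P_GK_P] * n_p ** 4 * (v_p - e_k_p)
    i_nal_p = p[P_GNAL_P] * (v_p - e_na_p)
    i_kl_p = p[P_GKL_P] * (v_p - e_k_p)
    i_cl_p = p[P_GCLL_P] * (v_p - e_cl_p)
    i_d_p = p[P_GD_P] * (v_p - p[P_EDRIVE])
    ip_p = _pump(na_p, k_o, p[P_PMAX_P], p[P_KMNA], p[P_KMK_P])
    i_gaba = p[P_GGABA] * s * (v_p - e_cl_p)

    out = np.empty(N_STATE)
    out[0] = -(i_nat_i + i_nap_i + i_k_i + i_nal_i + i_kl_i + i_cl_i
               + i_d_i + ip_i) / p[P_CM_I]
    out[3] = -(i_nat_p + i_nap_p + i_k_p + i_nal_p + i_kl_p + i_cl_p
               + i_d_p + ip_p + i_gaba) / p[P_CM_P]
    out[1] = ah * (1.0 - h_i) - bh * h_i
    out[2] = an * (1.0 - n_i) - bn * n_i
    out[4] = ahp * (1.0 - h_p) - bhp * h_p
    out[5] = anp * (1.0 - n_p) - bnp * n_p
    out[17] = amp * (1.0 - m_p) - bmp * m_p

    f_pre = 1.0 / (1.0 + np.exp(-(v_i - p[P_REL_THR]) / p[P_REL_SLOPE]))
    out[6] = p[P_ALPHA_S] * f_pre * (1.0 - s) - s / p[P_TAU_S]

    # per-ion totals (outward positive), pump folded in by stoichiometry
    na_tot_i = i_nat_i + i_nap_i + i_nal_i + i_d_i + 3.0 * ip_i
    k_tot_i = i_k_i + i_kl_i - 2.0 * ip_i
    na_tot_p = i_nat_p + i_nap_p + i_nal_p + i_d_p + 3.0 * ip_p
    k_tot_p = i_k_p + i_kl_p - 2.0 * ip_p
    cl_tot_p = i_cl_p + i_gaba

    gi, gp = p[P_GAM_I], p[P_GAM_P]
    bi, bp = p[P_BET_I], p[P_BET_P]
    out[7] = -gi * na_tot_i
    out[8] = -gi * k_tot_i
    out[9] = gi * i_cl_i
    out[10] = -gp * na_tot_p
    out[11] = -gp * k_tot_p
    out[12] = gp * cl_tot_p

    occ = glia / p[P_GLIA_CAP]
    if occ < 0.0:
        occ = 0.0
    elif occ > 1.0:
        occ = 1.0
    excess = k_o - p[P_KBATH]
    sig = 1.0 / (1.0 + np.exp(-excess / p[P_GLIA_W]))
    dglia = p[P_GLIA_RATE] * excess * ((1.0 - occ) * sig + occ * (1.0 - sig))

    out[13] = gi * bi * na_tot_i + gp * bp * na_tot_p \
        + p[P_EPS_NA] * (p[P_NABATH] - na_o)
    out[14] = gi * bi * k_tot_i + gp * bp * k_tot_p \
        - dglia + p[P_EPS_K] * (p[P_KBATH] - k_o)
    out[15] = -(gi * bi * i_cl_i + gp * bp * cl_tot_p)
    out[16] = dglia
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CircuitParams:
    """Everything needed to assemble the coupled system."""

    interneuron: mc.NeuronParams
    pyramidal: mc.NeuronParams
    synapse: mc.SynapseParams
    homeostasis: HomeostasisParams
    nap_v_half: float = -29.0
    nap_slope: float = 7.0
    na_in0: float = 18.0
    k_in0: float = 140.0
    na_out0: float = 144.0
    cl_out0: float = 130.0


def load_default_circuit(overrides: Mapping[str, float] | None = None) -> CircuitParams:
    """Build the packaged default circuit.

    ``overrides`` maps dotted parameter paths (e.g. ``"synapse.g_max"``,
    ``"homeostasis.pump_max_i"``, ``"interneuron.gK_max"``) to values.
    """
    text = resources.files("csdsim").joinpath("params/default.yaml").read_text()
    cfg = yaml.safe_load(text)
    if overrides:
        for key, value in overrides.items():
            section, _, name = key.partition(".")
            if not name or section not in cfg or name not in cfg[section]:
                raise KeyError(f"unknown parameter override {key!r}")
            cfg[section][name] = value

    inter = mc.NeuronParams(
        name="interneuron",
        gate_specs=mc.fs_gate_specs(),
        **cfg["interneuron"],
    )
    pyr = mc.NeuronParams(
        name="pyramidal",
        gate_specs=mc.rs_gate_specs(),
        **cfg["pyramidal"],
    )
    syn = mc.SynapseParams(**cfg["synapse"])
    homeo = HomeostasisParams(pump_max_p=0.0, **cfg["homeostasis"])
    init = cfg["initial_concentrations"]
    return CircuitParams(
        interneuron=inter, pyramidal=pyr, synapse=syn, homeostasis=homeo,
        nap_v_half=cfg["persistent_na"]["v_half"],
        nap_slope=cfg["persistent_na"]["slope"],
        na_in0=init["na_in"], k_in0=init["k_in"],
        na_out0=init["na_out"], cl_out0=init["cl_out"],
    )


@dataclass(frozen=True)
class Scenario:
    """A named simulation condition (drives, persistent fraction, length)."""

    name: str
    persistent_fraction: float = 0.01
    gD_i: float = 0.0             # mS/cm^2, drive onto the interneuron
    gD_e: float = 0.0             # mS/cm^2, drive onto the pyramidal neuron
    duration: float = 30.0        # s
    drive_onset: float = 0.0      # s (step drive after pre-relaxation)
    sample_dt: float = 0.25       # ms, output grid
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.gD_i < 0 or self.gD_e < 0:
            raise ValueError("drive conductances must be non-negative")


#: The named conditions of the modelling figure: physiological persistent
#: current (1 %) under interneuron drive, the pathological 6 % condition,
#: the minimal-drive condition at 0 %, and rest.
SCENARIOS: dict[str, Scenario] = {
    "rest": Scenario("rest", persistent_fraction=0.01, gD_i=0.0, gD_e=0.0, duration=60.0),
    "fig5b": Scenario("fig5b", persistent_fraction=0.01, gD_i=0.1, gD_e=0.0, duration=30.0),
    "fig5c": Scenario("fig5c", persistent_fraction=0.06, gD_i=0.1, gD_e=0.0, duration=30.0),
    "fig5e": Scenario("fig5e", persistent_fraction=0.0, gD_i=0.349, gD_e=0.0, duration=30.0),
}


# ---------------------------------------------------------------------------
# build + integrate
# ---------------------------------------------------------------------------

class InitializationError(RuntimeError):
    """Raised when no resting fixed point is found within tolerance."""


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid time in seconds."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def _fit_and_pack(circuit: CircuitParams) -> tuple[np.ndarray, np.ndarray]:
    """Fit leak conductances / pyramidal pump scale at the reference
    condition and return (packed params, resting state)."""
    h = circuit.homeostasis
    rtf = rt_over_f(h.temperature)
    na0, k0 = circuit.na_in0, circuit.k_in0
    nao0, clo0 = circuit.na_out0, circuit.cl_out0
    ko0 = h.k_bath
    e_na = rtf * math.log(nao0 / na0)
    e_k = rtf * math.log(ko0 / k0)

    def nap_act(v):
        return 1.0 / (1.0 + math.exp(-(v - circuit.nap_v_half) / circuit.nap_slope))

    # interneuron: pump scale given, Na/K leaks fitted
    inter = circuit.interneuron
    v0i = inter.resting_potential
    m0 = float(mc.wb_m_inf(v0i))
    ah, bh = mc.wb_h_rates(v0i)
    h0i = ah / (ah + bh)
    an, bn = mc.wb_n_rates(v0i)
    n0i = an / (an + bn)
    ip_i = h.pump_max_i * (na0 / (na0 + h.km_na)) ** 3 * (ko0 / (ko0 + h.km_k_i)) ** 2
    i_nat = inter.gNa_max * m0 ** 3 * h0i * (v0i - e_na)
    i_nap = inter.persistent_fraction * inter.gNa_max * nap_act(v0i) * (v0i - e_na)
    gnal_i = inter.gNa_leak
    if gnal_i is None:
        gnal_i = -(i_nat + i_nap + 3.0 * ip_i) / (v0i - e_na)
    i_kg = inter.gK_max * n0i ** 4 * (v0i - e_k)
    gkl_i = inter.gK_leak
    if gkl_i is None:
        gkl_i = (2.0 * ip_i - i_kg) / (v0i - e_k)
    cl_in_i = clo0 * math.exp(v0i / rtf)

    # pyramidal: Na leak fixed, pump scale derived from the rest balance
    pyr = circuit.pyramidal
    v0p = pyr.resting_potential
    amp, bmp = mc.tm_m_rates(v0p)
    m0p = amp / (amp + bmp)
    ahp, bhp = mc.tm_h_rates(v0p)
    h0p = ahp / (ahp + bhp)
    anp, bnp = mc.tm_n_rates(v0p)
    n0p = anp / (anp + bnp)
    gnal_p = pyr.gNa_leak if pyr.gNa_leak is not None else 0.0175
    i_nat_p = pyr.gNa_max * m0p ** 3 * h0p * (v0p - e_na)
    i_nap_p = pyr.persistent_fraction * pyr.gNa_max * nap_act(v0p) * (v0p - e_na)
    ip_p = -(i_nat_p + i_nap_p + gnal_p * (v0p - e_na)) / 3.0
    if ip_p <= 0:
        raise InitializationError("pyramidal rest balance gives non-positive pump rate")
    pmax_p = ip_p / ((na0 / (na0 + h.km_na)) ** 3 * (ko0 / (ko0 + h.km_k_p)) ** 2)
    i_kg_p = pyr.gK_max * n0p ** 4 * (v0p - e_k)
    gkl_p = pyr.gK_leak
    if gkl_p is None:
        gkl_p = (2.0 * ip_p - i_kg_p) / (v0p - e_k)
    cl_in_p = clo0 * math.exp(v0p / rtf)

    if min(gnal_i, gkl_i, gkl_p) < 0:
        raise InitializationError("leak fit produced a negative conductance")

    syn = circuit.synapse
    p = np.zeros(41)
    p[P_GNA_I], p[P_GK_I] = inter.gNa_max, inter.gK_max
    p[P_GNAL_I], p[P_GKL_I], p[P_GCLL_I] = gnal_i, gkl_i, inter.gCl_leak
    p[P_PFRAC_I], p[P_GD_I] = inter.persistent_fraction, inter.drive_conductance
    p[P_GNA_P], p[P_GK_P] = pyr.gNa_max, pyr.gK_max
    p[P_GNAL_P], p[P_GKL_P], p[P_GCLL_P] = gnal_p, gkl_p, pyr.gCl_leak
    p[P_PFRAC_P], p[P_GD_P] = pyr.persistent_fraction, pyr.drive_conductance
    p[P_EDRIVE] = inter.drive_reversal
    p[P_PMAX_I], p[P_PMAX_P] = h.pump_max_i, pmax_p
    p[P_KMNA], p[P_KMK_I], p[P_KMK_P] = h.km_na, h.km_k_i, h.km_k_p
    p[P_NAP_V], p[P_NAP_K] = -circuit.nap_v_half, circuit.nap_slope
    p[P_GLIA_RATE], p[P_GLIA_CAP], p[P_GLIA_W] = h.glia_rate, h.glia_capacity, h.glia_switch_width
    p[P_EPS_K], p[P_EPS_NA] = h.bath_rate_k, h.bath_rate_na
    p[P_KBATH], p[P_NABATH] = h.k_bath, h.na_bath
    p[P_GAM_I], p[P_GAM_P] = h.gamma_i, h.gamma_p
    p[P_BET_I], p[P_BET_P] = h.beta_i, h.beta_p
    p[P_GGABA], p[P_ALPHA_S], p[P_TAU_S] = syn.g_max, syn.alpha, syn.tau_decay
    p[P_REL_THR], p[P_REL_SLOPE] = syn.release_threshold, syn.release_slope
    p[P_RTF] = rtf
    p[P_CM_I], p[P_CM_P] = inter.membrane_capacitance, pyr.membrane_capacitance

    y0 = np.array([
        v0i, h0i, n0i, v0p, h0p, n0p, 0.0,
        na0, k0, cl_in_i, na0, k0, cl_in_p,
        nao0, ko0, clo0, 0.0, m0p,
    ])
    return p, y0


def build_system(circuit: CircuitParams | None = None, tol: float = 1e-3):
    """Return ``(rhs, y0, packed_params)`` for the zero-drive circuit.

    ``rhs(t, y)`` is the full deterministic right-hand side (time in ms);
    ``y0`` is the resting fixed point.  Raises
    :class:`InitializationError` if the residual derivative at the fitted
    resting state exceeds ``tol``.
    """
    if circuit is None:
        circuit = load_default_circuit()
    p, y0 = _fit_and_pack(circuit)
    resid = np.abs(_rhs(0.0, y0, p))
    if resid.max() > tol:
        raise InitializationError(
            f"no resting fixed point: max |dy/dt| = {resid.max():.3g}")

    def rhs(t, y):
        return _rhs(t, y, p)

    return rhs, y0, p


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Uniformly sampled solution of one scenario.

    ``time`` is in seconds; state columns follow ``STATE_COLUMNS``.
    """

    time: np.ndarray
    states: np.ndarray            # (n_samples, 18)
    scenario: Scenario
    params: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trace contains non-finite values")

    def __getitem__(self, column: str) -> np.ndarray:
        return self.states[:, STATE_COLUMNS.index(column)]

    @property
    def v_interneuron(self) -> np.ndarray:
        return self["v_i"]

    @property
    def v_pyramidal(self) -> np.ndarray:
        return self["v_p"]

    @property
    def k_out(self) -> np.ndarray:
        return self["k_out"]

    def ion_state(self, index: int) -> IonState:
        row = self.states[index]
        return IonState(*row[7:17])

    def currents(self) -> dict[str, np.ndarray]:
        """Per-current densities (uA/cm^2) recomputed from the state."""
        p = self.params
        rtf = p[P_RTF]
        v_i, v_p = self["v_i"], self["v_p"]
        e_na_i = rtf * np.log(self["na_out"] / self["na_in_i"])
        e_k_i = rtf * np.log(self["k_out"] / self["k_in_i"])
        e_na_p = rtf * np.log(self["na_out"] / self["na_in_p"])
        e_k_p = rtf * np.log(self["k_out"] / self["k_in_p"])
        e_cl_p = -rtf * np.log(self["cl_out"] / self["cl_in_p"])
        m_i = mc.wb_m_inf(v_i)
        nap = lambda v: 1.0 / (1.0 + np.exp(-(v + p[P_NAP_V]) / p[P_NAP_K]))
        return {
            "i_na_t_i": p[P_GNA_I] * m_i ** 3 * self["h_i"] * (v_i - e_na_i),
            "i_na_p_i": p[P_PFRAC_I] * p[P_GNA_I] * nap(v_i) * (v_i - e_na_i),
            "i_k_i": p[P_GK_I] * self["n_i"] ** 4 * (v_i - e_k_i),
            "i_drive_i": p[P_GD_I] * (v_i - p[P_EDRIVE]),
            "i_pump_i": _pump_np(self["na_in_i"], self["k_out"], p[P_PMAX_I], p[P_KMNA], p[P_KMK_I]),
            "i_na_t_p": p[P_GNA_P] * self["m_p"] ** 3 * self["h_p"] * (v_p - e_na_p),
            "i_k_p": p[P_GK_P] * self["n_p"] ** 4 * (v_p - e_k_p),
            "i_gaba": p[P_GGABA] * self["s"] * (v_p - e_cl_p),
            "i_pump_p": _pump_np(self["na_in_p"], self["k_out"], p[P_PMAX_P], p[P_KMNA], p[P_KMK_P]),
        }

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        df.insert(0, "time_s", self.time)
        return df

    def save(self, path: str) -> None:
        """Write the trace to CSV (.csv) or HDF5 (.h5/.hdf5)."""
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            import h5py
            with h5py.File(path, "w") as f:
                f.create_dataset("time_s", data=self.time)
                g = f.create_group("state")
                for j, col in enumerate(STATE_COLUMNS):
                    g.create_dataset(col, data=self.states[:, j])
                f.attrs["scenario"] = self.scenario.name
        else:
            self.to_frame().to_csv(path, index=False)


def _pump_np(na_in, k_out, pmax, km_na, km_k):
    f_na = (na_in / (na_in + km_na)) ** 3
    f_k = (k_out / (k_out + km_k)) ** 2
    return pmax * f_na * f_k


def simulate(scenario: Scenario | str,
             circuit: CircuitParams | None = None,
             rtol: float = 1e-6, atol: float = 1e-8,
             max_step: float = 50.0) -> SimulationTrace:
    """Integrate a scenario from the resting state.

    The drive steps on at t = drive_onset (default 0, the state having
    been initialized at the zero-drive fixed point).  Deterministic for
    fixed inputs and solver settings.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if circuit is None:
        circuit = load_default_circuit(scenario.overrides or None)
    elif scenario.overrides:
        raise ValueError("pass overrides either in the scenario or a prebuilt circuit, not both")

    _, y0, p = build_system(circuit)
    p = p.copy()
    p[P_PFRAC_I] = scenario.persistent_fraction
    p[P_GD_I] = scenario.gD_i
    p[P_GD_P] = scenario.gD_e

    t_end = scenario.duration * 1000.0
    t_eval = np.arange(0.0, t_end + scenario.sample_dt / 2, scenario.sample_dt)
    sol = solve_ivp(_rhs, (0.0, t_end), y0, args=(p,), method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval, max_step=max_step)
    if not sol.success:
        last = sol.t[-1] / 1000.0 if sol.t.size else 0.0
        raise IntegrationError(f"integrator failed: {sol.message}", last)
    return SimulationTrace(time=sol.t / 1000.0, states=sol.y.T,
                           scenario=scenario, params=p)


def run_figure5_suite(fractions=(0.0, 0.01, 0.02, 0.04, 0.06),
                      latency_drive: float = 0.349,
                      fi_drives=(0.05, 0.1, 0.2, 0.3),
                      bracket=(0.0, 0.6), tol: float = 0.005,
                      window: float = 30.0,
                      circuit: CircuitParams | None = None):
    """Minimal blocking drive, block latency at the reference drive, and
    the isolated-interneuron f-I curve, per persistent fraction.

    Returns a pandas DataFrame with one row per (fraction, quantity).
    """
    import pandas as pd

    from .analysis import (block_latency, interneuron_fI,
                           minimal_blocking_drive)

    from .analysis import BracketError

    rows = []
    for frac in fractions:
        try:
            mind = minimal_blocking_drive(frac, bracket=bracket, tol=tol,
                                          window=window, circuit=circuit)
        except BracketError:
            mind = float("nan")   # threshold outside the requested bracket
        rows.append({"persistent_fraction": frac,
                     "quantity": "minimal_blocking_drive", "value": mind})
        lat = block_latency(frac, latency_drive, window=window, circuit=circuit)
        rows.append({"persistent_fraction": frac,
                     "quantity": "block_latency", "value": lat})
        for drive, freq in interneuron_fI(frac, fi_drives, circuit=circuit):
            rows.append({"persistent_fraction": frac,
                         "quantity": f"fI@{drive}", "value": freq})
    return pd.DataFrame(rows)
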