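"""Ion-concentration dynamics shared by the two neurons.

Each neuron has its own intracellular Na+/K+/Cl- pools; both face one
common extracellular compartment (a single [K+]out per simulation, as in
the source model's traces).  Transmembrane currents convert to
concentration fluxes through gamma = A/(F*V_in) (mM/ms per uA/cm^2); the
extracellular pool sees the same flux scaled by the intracellular-to-
extracellular volume ratio beta.  Homeostasis comprises a 3Na+:2K+
ATPase with saturating Michaelis-Menten-style dependence on Na_in and
K_out, a capacity-limited glial K+ buffer, and first-order exchange of
K+ (and Na+) with the perfusing bath.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "IonState",
    "HomeostasisParams",
    "nernst_potential",
    "pump_current",
    "pump_flux",
    "glial_and_bath_K_flux",
    "concentration_rhs",
]

FARADAY = 96485.332          # C/mol
GAS_CONSTANT = 8.314462      # J/(mol K)


def rt_over_f(temperature: float) -> float:
    """RT/F in mV."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY


def nernst_potential(valence: int, c_in, c_out, temperature: float = 310.0):
    """Nernst reversal potential (RT/zF) ln(C_out/C_in) in mV.

    Raises
    ------
    ValueError
        If any concentration is non-positive (invalid ion state).
    """
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if np.any(c_in <= 0) or np.any(c_out <= 0):
        raise ValueError("ion concentrations must be positive")
    return rt_over_f(temperature) / valence * np.log(c_out / c_in)


@dataclass(frozen=True)
class IonState:
    """Concentrations (mM) for both neurons plus the shared ECS, and the
    glial buffer load (mM, referenced to extracellular volume)."""

    na_in_i: float
    k_in_i: float
    cl_in_i: float
    na_in_p: float
    k_in_p: float
    cl_in_p: float
    na_out: float
    k_out: float
    cl_out: float
    glia_buffer: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([
            self.na_in_i, self.k_in_i, self.cl_in_i,
            self.na_in_p, self.k_in_p, self.cl_in_p,
            self.na_out, self.k_out, self.cl_out, self.glia_buffer,
        ])

    def validate(self) -> None:
        arr = self.as_array()[:9]
        if np.any(arr <= 0):
            raise ValueError("all ion concentrations must be positive")


@dataclass(frozen=True)
class HomeostasisParams:
    """Pump, glia, bath and flux-conversion constants.

    ``pump_max`` values are current densities (uA/cm^2) at saturation;
    the pump rate is ``pump_max * (Na_in/(Na_in+km_na))^3 *
    (K_out/(K_out+km_k))^2`` and carries one net positive charge
    outward per cycle (3 Na+ out : 2 K+ in).  ``gamma`` converts uA/cm^2
    to mM/ms for a neuron's intracellular pool (A/(F*V), here for a
    ~7 um soma); ``beta`` is that pool's volume relative to the shared
    ECS.  The glial buffer takes up excess K+ at ``glia_rate`` per mM
    above bath while free capacity remains and releases it below bath;
    bath exchange is first-order toward ``k_bath`` / ``na_bath``.
    """

    pump_max_i: float = 29.5      # uA/cm^2
    pump_max_p: float = 5.2       # uA/cm^2 (re-derived by the leak fit)
    km_na: float = 8.0            # mM
    km_k_i: float = 6.0           # mM
    km_k_p: float = 2.0           # mM
    glia_rate: float = 1.0e-3     # 1/ms per mM excess
    glia_capacity: float = 220.0  # mM (ECS-referenced)
    glia_switch_width: float = 0.5  # mM, uptake/release blending
    k_bath: float = 3.5           # mM
    na_bath: float = 144.0        # mM
    bath_rate_k: float = 2.0e-5   # 1/ms
    bath_rate_na: float = 2.0e-4  # 1/ms
    temperature: float = 310.0    # K
    gamma_i: float = 4.45e-5      # mM/ms per uA/cm^2
    gamma_p: float = 4.45e-5
    beta_i: float = 8.0           # V_in / V_ecs
    beta_p: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.pump_max_i, self.pump_max_p, self.glia_rate,
                  self.bath_rate_k, self.bath_rate_na):
            if r < 0:
                raise ValueError("homeostasis rates must be non-negative")
        if self.k_bath <= 0:
            raise ValueError("bath K+ must be positive")


def pump_current(na_in, k_out, pump_max, km_na=8.0, km_k=6.0):
    """Na+/K+-ATPase cycle rate expressed as net outward current density
    (uA/cm^2): one positive charge out per cycle."""
    na_in = np.asarray(na_in, dtype=float)
    k_out = np.asarray(k_out, dtype=float)
    f_na = (na_in / (na_in + km_na)) ** 3
    f_k = (k_out / (k_out + km_k)) ** 2
    return pump_max * f_na * f_k


def pump_flux(na_in, k_out, pump_max, km_na=8.0, km_k=6.0):
    """Per-ion pump fluxes as equivalent current densities:
    (Na+ extruded, K+ imported) = (3, 2) x cycle rate.  Both returned
    positive; the caller applies signs per compartment."""
    ip = pump_current(na_in, k_out, pump_max, km_na, km_k)
    return 3.0 * ip, 2.0 * ip


def glial_and_bath_K_flux(k_out, glia_buffer, params: HomeostasisParams):
    """K+ clearance terms for the shared ECS (mM/ms).

    Returns ``(dk_out, dglia)``: the contribution to d[K+]out/dt and the
    glial-buffer loading rate.  The buffer takes up K+ in proportion to
    the excess above bath while free capacity remains, and releases its
    load when [K+]out falls below bath; at [K+]out = bath with an empty
    buffer both terms vanish.  Bath exchange is first-order.
    """
    k_out = np.asarray(k_out, dtype=float)
    occ = np.clip(np.asarray(glia_buffer, dtype=float) / params.glia_capacity, 0.0, 1.0)
    excess = k_out - params.k_bath
    sig = 1.0 / (1.0 + np.exp(-excess / params.glia_switch_width))
    dglia = params.glia_rate * excess * ((1.0 - occ) * sig + occ * (1.0 - sig))
    dbath = params.bath_rate_k * (params.k_bath - k_out)
    return dbath - dglia, dglia


def concentration_rhs(state: IonState,
                      currents_i: dict[str, float],
                      currents_p: dict[str, float],
                      params: HomeostasisParams,
                      include_homeostasis: bool = True) -> np.ndarray:
    """Time derivatives of the full ion state (mM/ms).

    ``currents_i`` / ``currents_p`` carry the per-ion membrane current
    densities of each neuron (uA/cm^2, outward positive) under keys
    ``"na"``, ``"k"``, ``"cl"`` — the pump already folded in by the
    caller, or supplied separately under ``"pump"`` (cycle rate) when
    ``include_homeostasis`` is true.  Each transmembrane flux changes the
    intracellular pool and the shared ECS with opposite sign, scaled by
    gamma and beta; an outward cation current lowers the inside and
    raises the outside, an outward Cl- current moves Cl- inward.
    """
    out = np.zeros(10)
    ip_i = currents_i.get("pump", 0.0) if include_homeostasis else 0.0
    ip_p = currents_p.get("pump", 0.0) if include_homeostasis else 0.0

    na_i = currents_i.get("na", 0.0) + 3.0 * ip_i
    k_i = currents_i.get("k", 0.0) - 2.0 * ip_i
    cl_i = currents_i.get("cl", 0.0)
    na_p = currents_p.get("na", 0.0) + 3.0 * ip_p
    k_p = currents_p.get("k", 0.0) - 2.0 * ip_p
    cl_p = currents_p.get("cl", 0.0)

    gi, gp = params.gamma_i, params.gamma_p
    bi, bp = params.beta_i, params.beta_p

    out[0] = -gi * na_i                       # Na_in interneuron
    out[1] = -gi * k_i
    out[2] = gi * cl_i                        # outward current -> Cl- enters
    out[3] = -gp * na_p
    out[4] = -gp * k_p
    out[5] = gp * cl_p
    out[6] = gi * bi * na_i + gp * bp * na_p  # Na_out
    out[7] = gi * bi * k_i + gp * bp * k_p
    out[8] = -(gi * bi * cl_i + gp * bp * cl_p)

    if include_homeostasis:
        dk_clear, dglia = glial_and_bath_K_flux(state.k_out, state.glia_buffer, params)
        out[7] += dk_clear
        out[9] = dglia
        out[6] += params.bath_rate_na * (params.na_bath - state.na_out)
    return out
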