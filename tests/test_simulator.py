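import numpy as np
import pytest

from csdsim import model_core as mc
from csdsim.ion_dynamics import (HomeostasisParams, IonState,
                                 concentration_rhs, nernst_potential,
                                 pump_current)
from csdsim.simulator import (SCENARIOS, Scenario, build_system,
                              load_default_circuit, simulate, _rhs)
from csdsim import analysis as ana


class TestBuildSystem:
    def test_resting_state_is_fixed_point(self):
        rhs, y0, _ = build_system()
        assert np.abs(rhs(0.0, y0)).max() < 1e-9

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            load_default_circuit({"synapse.not_a_param": 1.0})

    def test_rhs_matches_component_sum(self):
        """The assembled right-hand side equals the hand-built sum of the
        membrane-current and concentration-flux operations."""
        circuit = load_default_circuit()
        rhs, y0, p = build_system(circuit)
        rng = np.random.default_rng(7)
        y = y0.copy()
        y[0] += 12.0        # depolarize the interneuron
        y[3] += 5.0
        y[6] = 0.4          # synapse partly open
        y[7:17] *= 1.0 + 0.05 * rng.standard_normal(10).clip(-1, 1) * 0.5
        y[16] = 30.0
        got = rhs(0.0, y)

        h = circuit.homeostasis
        rtf = 1000.0 * 8.314462 * h.temperature / 96485.332
        v_i, h_i, n_i, v_p, h_p, n_p, s = y[:7]
        m_p = y[17]
        ion = IonState(*y[7:17])
        e_na_i = nernst_potential(1, ion.na_in_i, ion.na_out, h.temperature)
        e_k_i = nernst_potential(1, ion.k_in_i, ion.k_out, h.temperature)
        e_cl_i = nernst_potential(-1, ion.cl_in_i, ion.cl_out, h.temperature)
        e_na_p = nernst_potential(1, ion.na_in_p, ion.na_out, h.temperature)
        e_k_p = nernst_potential(1, ion.k_in_p, ion.k_out, h.temperature)
        e_cl_p = nernst_potential(-1, ion.cl_in_p, ion.cl_out, h.temperature)

        # interneuron membrane currents from model_core primitives
        gna_i, gk_i = p[0], p[1]
        gnal_i, gkl_i, gcll_i = p[2], p[3], p[4]
        inter = mc.NeuronParams(name="i", gNa_max=gna_i,
                                persistent_fraction=p[5])
        m_i = mc.wb_m_inf(v_i)
        i_na_i = (mc.ionic_current(v_i, [m_i, h_i], [3, 1], gna_i, e_na_i)
                  + mc.persistent_sodium_current(v_i, inter, e_na_i)
                  + mc.ionic_current(v_i, [1.0], [1], gnal_i, e_na_i)
                  + mc.drive_current(v_i, p[6], p[14]) + 3.0 * pump_current(
                      ion.na_in_i, ion.k_out, p[15], p[17], p[18]))
        i_k_i = (mc.ionic_current(v_i, [n_i], [4], gk_i, e_k_i)
                 + mc.ionic_current(v_i, [1.0], [1], gkl_i, e_k_i)
                 - 2.0 * pump_current(ion.na_in_i, ion.k_out, p[15], p[17], p[18]))
        i_cl_i = mc.ionic_current(v_i, [1.0], [1], gcll_i, e_cl_i)

        gna_p, gk_p = p[7], p[8]
        gnal_p, gkl_p, gcll_p = p[9], p[10], p[11]
        pyr = mc.NeuronParams(name="p", gNa_max=gna_p, persistent_fraction=p[12])
        i_gaba = p[33] * s * (v_p - e_cl_p)
        i_na_p = (mc.ionic_current(v_p, [m_p, h_p], [3, 1], gna_p, e_na_p)
                  + mc.persistent_sodium_current(v_p, pyr, e_na_p)
                  + mc.ionic_current(v_p, [1.0], [1], gnal_p, e_na_p)
                  + mc.drive_current(v_p, p[13], p[14]) + 3.0 * pump_current(
                      ion.na_in_p, ion.k_out, p[16], p[17], p[19]))
        i_k_p = (mc.ionic_current(v_p, [n_p], [4], gk_p, e_k_p)
                 + mc.ionic_current(v_p, [1.0], [1], gkl_p, e_k_p)
                 - 2.0 * pump_current(ion.na_in_p, ion.k_out, p[16], p[17], p[19]))
        i_cl_p = mc.ionic_current(v_p, [1.0], [1], gcll_p, e_cl_p)

        dv_i = -(i_na_i + i_k_i + i_cl_i)
        dv_p = -(i_na_p + i_k_p + i_cl_p + i_gaba)
        assert got[0] == pytest.approx(dv_i, rel=1e-10)
        assert got[3] == pytest.approx(dv_p, rel=1e-10)

        conc = concentration_rhs(
            ion,
            {"na": i_na_i, "k": i_k_i, "cl": i_cl_i},
            {"na": i_na_p, "k": i_k_p, "cl": i_cl_p + i_gaba},
            h)
        np.testing.assert_allclose(got[7:17], conc, rtol=1e-9, atol=1e-16)

    def test_electroneutral_bookkeeping(self):
        """Charge carried by the concentration derivatives of each
        intracellular pool equals -gamma times the total membrane current
        (i.e. +gamma * C dV/dt)."""
        _, y0, p = build_system()
        y = y0.copy()
        y[0] += 20.0
        y[3] += 8.0
        y[6] = 0.3
        d = _rhs(0.0, y, p)
        h = load_default_circuit().homeostasis
        # interneuron: z_Na dNa + z_K dK + z_Cl dCl
        charge_i = d[7] + d[8] - d[9]
        assert charge_i == pytest.approx(h.gamma_i * d[0], rel=1e-9)
        charge_p = d[10] + d[11] - d[12]
        assert charge_p == pytest.approx(h.gamma_p * d[3], rel=1e-9)


class TestSimulate:
    def test_resting_scenario_stays_at_rest(self):
        trace = simulate(SCENARIOS["rest"])
        assert trace.time[-1] == pytest.approx(60.0, abs=1e-3)
        assert np.abs(trace.v_interneuron - trace.v_interneuron[0]).max() < 1.0
        assert np.abs(trace.v_pyramidal - trace.v_pyramidal[0]).max() < 1.0
        for col in ("na_in_i", "k_in_i", "na_out", "k_out", "cl_in_p"):
            x = trace[col]
            assert np.abs(x - x[0]).max() < 0.1

    def test_deterministic_bitwise(self):
        sc = Scenario("det", persistent_fraction=0.06, gD_i=0.1, duration=2.0)
        a = simulate(sc)
        b = simulate(sc)
        assert np.array_equal(a.states, b.states)

    def test_trace_invariants(self, fig5c_trace):
        assert np.all(np.diff(fig5c_trace.time) > 0)
        assert np.all(np.isfinite(fig5c_trace.states))

    def test_decoupled_pyramidal_stays_at_rest(self):
        """With the synapse and the interneuron's extracellular flux
        zeroed, interneuron firing cannot move the pyramidal neuron."""
        sc = Scenario("decoupled", persistent_fraction=0.01, gD_i=0.3,
                      duration=3.0,
                      overrides={"synapse.g_max": 0.0,
                                 "homeostasis.beta_i": 0.0})
        trace = simulate(sc)
        spikes_i = ana.detect_spikes(trace.time, trace.v_interneuron)
        assert spikes_i.size > 100           # interneuron driven hard
        assert np.abs(trace.v_pyramidal - trace.v_pyramidal[0]).max() < 0.5

    def test_closed_system_conservation(self):
        """With bath exchange off, the volume-weighted total amount of
        each species (glial buffer included for K+) is conserved."""
        sc = Scenario("closed", persistent_fraction=0.06, gD_i=0.1,
                      duration=10.0,
                      overrides={"homeostasis.bath_rate_k": 0.0,
                                 "homeostasis.bath_rate_na": 0.0})
        trace = simulate(sc)
        h = load_default_circuit().homeostasis
        bi, bp = h.beta_i, h.beta_p
        na = bi * trace["na_in_i"] + bp * trace["na_in_p"] + trace["na_out"]
        k = (bi * trace["k_in_i"] + bp * trace["k_in_p"] + trace["k_out"]
             + trace["glia_buffer"])
        cl = bi * trace["cl_in_i"] + bp * trace["cl_in_p"] + trace["cl_out"]
        for total in (na, k, cl):
            drift = np.abs(total - total[0]).max() / total[0]
            assert drift < 1e-6

    def test_solver_tolerance_robustness(self):
        """Refining the integration tolerances tenfold moves the reported
        [K+]out maximum by < 1 % and the block latency by < 2 %."""
        sc = Scenario("tolcheck", persistent_fraction=0.06, gD_i=0.1,
                      duration=8.0)
        coarse = simulate(sc)
        fine = simulate(sc, rtol=1e-7, atol=1e-9)
        k1, k2 = coarse.k_out.max(), fine.k_out.max()
        assert abs(k1 - k2) / k2 < 0.01
        b1 = ana.cascade_onset(coarse).onset
        b2 = ana.cascade_onset(fine).onset
        assert abs(b1 - b2) / b2 < 0.02

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", duration=-1.0)
        with pytest.raises(ValueError):
            Scenario("bad", gD_i=-0.1)

    def test_csv_roundtrip(self, tmp_path, fig5c_trace):
        import pandas as pd
        path = tmp_path / "trace.csv"
        fig5c_trace.save(str(path))
        df = pd.read_csv(path)
        assert df.shape[0] == fig5c_trace.time.size
        assert "k_out" in df.columns
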