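# Default circuit constants for the two-neuron CSD-ignition model.
# Units: mV, ms, mS/cm^2, uA/cm^2, mM unless noted.

interneuron:
  membrane_capacitance: 1.0     # uF/cm^2
  gNa_max: 35.0                 # transient Na+ (fast-spiking kinetics)
  gK_max: 20.0                  # delayed rectifier
  gCl_leak: 0.05
  persistent_fraction: 0.01     # physiological reference (leak fit anchor)
  resting_potential: -65.0      # leak-fit anchor
  drive_reversal: 0.0           # glutamatergic

pyramidal:
  membrane_capacitance: 1.0
  gNa_max: 100.0                # transient Na+ (regular-spiking kinetics)
  gK_max: 20.0
  gNa_leak: 0.0175              # fixed; pump scale derived from rest balance
  gCl_leak: 0.05
  persistent_fraction: 0.0
  resting_potential: -68.0
  drive_reversal: 0.0

persistent_na:
  v_half: -29.0                 # mV, activation midpoint
  slope: 7.0                    # mV

synapse:                        # GABA-A, interneuron -> pyramidal
  g_max: 0.45
  alpha: 2.0                    # 1/ms
  tau_decay: 9.0                # ms
  release_threshold: 0.0        # mV (spike-gated release)
  release_slope: 2.0            # mV

homeostasis:
  pump_max_i: 29.5              # uA/cm^2 at saturation
  km_na: 8.0                    # mM, pump Na_in half constant
  km_k_i: 6.0                   # mM, pump K_out half constant (interneuron)
  km_k_p: 2.0                   # mM, pump K_out half constant (pyramidal)
  glia_rate: 1.0e-3             # 1/ms per mM excess K_out
  glia_capacity: 220.0          # mM, ECS-referenced
  glia_switch_width: 0.5        # mM
  k_bath: 3.5                   # mM, slice perfusate
  na_bath: 144.0                # mM
  bath_rate_k: 2.0e-5           # 1/ms
  bath_rate_na: 2.0e-4          # 1/ms
  temperature: 310.0            # K
  gamma_i: 4.45e-5              # (mM/ms)/(uA/cm^2), A/(F*V) for ~7 um soma
  gamma_p: 4.45e-5
  beta_i: 8.0                   # intracellular : ECS volume ratio
  beta_p: 1.0

initial_concentrations:
  na_in: 18.0                   # mM, both neurons
  k_in: 140.0
  na_out: 144.0
  cl_out: 130.0
  # cl_in per neuron from E_Cl = resting potential
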