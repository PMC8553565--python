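# csdsim

Cortical spreading depolarization (CSD) — the slowly propagating wave of
near-complete depolarization underlying migraine aura — can be ignited in
neocortex by *hyperactivity of GABAergic interneurons*: sustained
high-frequency firing builds up extracellular potassium faster than pumps,
glia and perfusion can clear it, recruits the surrounding pyramidal cells,
and tips the tissue into depolarization block. Gain of function of NaV1.1
(the Na⁺ channel dominant in interneurons; mutated in familial hemiplegic
migraine type 3, pharmacologically enhanced by the spider toxin Hm1a)
promotes this failure mode by increasing the interneuron's persistent Na⁺
current.

`csdsim` is a self-contained Python implementation of that mechanism for
computational neuroscientists and migraine researchers:

* a **two-neuron conductance-based model** — a fast-spiking interneuron
  (Wang–Buzsáki kinetics) coupled to a regular-spiking pyramidal neuron
  (Traub–Miles kinetics) through a GABA‑A synapse and a shared
  extracellular compartment, with complete Na⁺/K⁺/Cl⁻ concentration
  dynamics, a 3Na⁺:2K⁺ ATPase, capacity-limited glial K⁺ buffering and
  bath exchange;
* **detectors** for spikes, firing rates, depolarization-block onset (the
  operational CSD-ignition marker), [K⁺]out phase maxima, minimal-drive
  bisection and interneuron f–I curves;
* **exact small-sample contingency statistics** (Fisher 2×2 and the
  Freeman–Halton r×2 generalization, implemented from first principles in
  log space) together with the printed success/failure tables of the
  slice/in-vivo CSD-induction experiments, packaged as fixtures;
* **synthetic-data generators** (Bernoulli outcome tables, spike/plateau
  traces with ground truth) so every stage is testable without external
  data.

## Model

Each neuron obeys `C dV/dt = −ΣI` (outward positive) with

```
I_Na  = g_Na m³h (V − E_Na)            transient Na⁺
I_NaP = φ g_Na a∞(V) (V − E_Na)        persistent Na⁺, a∞ = 1/(1+e^−(V+29)/7)
I_K   = g_K n⁴ (V − E_K)               delayed rectifier
I_L   = g_L,X (V − E_X)                per-ion leaks (Na⁺, K⁺, Cl⁻)
I_D   = g_D (V − 0)                    constant glutamatergic drive
I_pump= I_max (Na_i/(Na_i+K_Na))³ (K_o/(K_o+K_K))²   (3Na⁺:2K⁺, net +1 out)
```

and every reversal potential is a live Nernst potential of the tracked
concentrations — including the GABA‑A reversal, which follows the
pyramidal neuron's Cl⁻ gradient. The persistent fraction φ of the
*interneuron* is the experiment's control parameter: 1 % is the
physiological reference, 6 % models FHM3/Hm1a.

With drive g_D,i = 0.1 mS/cm² onto the interneuron only, φ = 1 % yields
sustained ~200 Hz interneuron firing and a bounded [K⁺]out excursion
(≈10.5 mM); raising φ to 6 % makes the same drive ignite CSD: [K⁺]out
climbs to ≈13 mM during the initial discharge, both neurons fall into
depolarization block, and [K⁺]out runs away past 60 mM. With φ = 0 the
minimal igniting drive is ≈0.35 mS/cm².

## Worked example

```python
from csdsim import SCENARIOS, simulate, analyze_trace

trace = simulate(SCENARIOS["fig5c"])      # 6 % persistent fraction, gD_i = 0.1
report = analyze_trace(trace)
print(report["cascade_onset"])
print(report["k_out_max_pre_ignition"], report["k_out_max_post_pyramidal_block"])
```

prints

```
BlockEvent(onset=0.7435, offset=None, neuron='interneuron', latency_from_drive=0.7435)
13.113043430441177 69.28856749373432
```

— the interneuron blocks 0.74 s after drive onset, [K⁺]out peaks at
13.1 mM during the pre-ignition discharge and exceeds 69 mM once the
pyramidal neuron has blocked. The same run from a shell:

```bash
csdsim run --scenario fig5c --out trace.csv
csdsim analyze trace.csv
```

Exact statistics on a printed slice table (5/10 successes in vivo vs 0/13
controls):

```bash
$ csdstats fisher 5/10 0/13
{ "table": "ContingencyTable(group0: 5/10, group1: 0/13)",
  "p_two_sided": 0.007489078427293497 }
```

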