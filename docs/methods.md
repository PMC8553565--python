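# Methods

## Model structure

The circuit is the minimal motif for interneuron-driven CSD ignition: one
fast-spiking GABAergic interneuron and one regular-spiking pyramidal
neuron, each a single Hodgkin–Huxley compartment, sharing a single
extracellular space (ECS). There is one chemical synapse (GABA‑A,
interneuron → pyramidal) and one diffuse coupling (every transmembrane
current moves ions between a neuron's intracellular pool and the shared
ECS). The model is point-like: it addresses *initiation* only, not
spatial propagation.

State (18 variables): two membrane potentials; gating variables h, n per
neuron plus the pyramidal activation gate m (the interneuron uses the
standard instantaneous-m reduction of the Wang–Buzsáki model); the GABA
gating variable s; Na⁺/K⁺/Cl⁻ in each neuron and in the ECS; and the
glial K⁺ buffer load. All reversal potentials are Nernst potentials of
the instantaneous concentrations at 310 K; the GABA‑A reversal is the
pyramidal Cl⁻ Nernst potential, so chloride loading weakens inhibition
dynamically.

Kinetics: Wang–Buzsáki rates (φ = 5 folded in) for the interneuron;
Traub–Miles rates for the pyramidal neuron. The pyramidal m gate is
integrated rather than slaved to m∞ because potassium-driven
depolarization is slow (seconds): with an instantaneous gate the cell
slides through threshold without firing, whereas the full gate lets it
spike and then fail, which is the observed ignition sequence.

### Persistent Na⁺ current

Each neuron can carry a non-inactivating Na⁺ conductance equal to
`persistent_fraction × gNa_max` with first-order activation
`a∞(V) = 1/(1+exp(−(V+29)/7))`. An earlier variant tied the persistent
activation to the transient channel's m∞³; with fast-spiking kinetics
that is ~10⁻⁴ at interspike voltages, so the fraction had no effect on
firing rate and no 0 %-vs-6 % ignition asymmetry existed. The dedicated
sigmoid — negligible at rest, a few percent activated at interspike
voltages, strongly engaged on plateaus — is the standard persistent-Na⁺
form in this modelling lineage and produces both signatures: the f–I
curve rises with the fraction at every drive, and a depolarized cell
with a high fraction regenerates into block. The fraction itself remains
defined exactly as "percent of maximal Na⁺ conductance".

### Homeostasis

* **Pump**: `I_pump = I_max · (Na_i/(Na_i+8))³ · (K_o/(K_o+K_K))²`
  (µA/cm², one net charge out per cycle; 3Na⁺:2K⁺ stoichiometry in the
  concentration equations). The interneuron's K half-constant is 6 mM,
  the pyramidal neuron's 2 mM. This asymmetry is load-bearing: for a
  leak-balanced neuron the outward pump-current increase and the E_K
  depolarization produced by a rise in [K⁺]out cancel almost exactly
  when K_K ≈ 6 mM. With the saturating (2 mM) form the pyramidal neuron
  is genuinely recruited by rising [K⁺]out, which is the ignition relay;
  with the steeper (6 mM) form the interneuron gains a self-stabilizing
  brake that lets it sustain ~200 Hz firing for tens of seconds — the
  phenotype the physiological condition requires.
* **Glia**: a capacity-limited buffer (220 mM, ECS-referenced) that takes
  up K⁺ in proportion to the excess over bath while free capacity
  remains, and releases below bath. It shapes the initial [K⁺]out hump
  and sets the slow creep toward ignition near threshold.
* **Bath**: first-order exchange of ECS K⁺ (τ = 50 s) and Na⁺ (τ = 5 s)
  with the perfusate (3.5 / 144 mM). Na⁺ exchange is what allows
  minutes-long high-frequency firing: without it the interneuron's spike
  Na⁺ load collapses E_Na and the cell dies spuriously.
* **Flux conversion**: γ = 4.45×10⁻⁵ mM·cm²/(ms·µA) (a ~7 µm soma);
  intracellular:ECS volume ratios β_I = 8, β_P = 1. β asymmetry encodes
  that the interneuron's firing dominates the local K⁺ source in this
  motif. Volumes are fixed (no osmotic swelling).

### Resting state by construction

Given the resting potentials (−65 / −68 mV) and resting concentrations
(Na_i 18, K_i 140, Na_o 144, Cl_o 130 mM, [K⁺]out = bath = 3.5 mM), the
per-ion balance equations are solved for the Na⁺/K⁺ leak conductances
(interneuron, at its physiological 1 % persistent fraction) and for the
pyramidal pump scale (its Na⁺ leak fixed at the classical 0.0175
mS/cm²); Cl_in is set so E_Cl equals the resting potential. The rest
state is therefore an exact fixed point (residual ~10⁻¹⁴), and the
60-second resting-stability property holds to integrator precision.
Because the fit is anchored at 1 %, the 0 % condition rests slightly
hyperpolarized and the 6 % condition slightly depolarized — which is the
point: persistent current is excitatory.

### Synapse

GABA‑A: `g·s·(V_P − E_Cl,P)` with `ds/dt = α·F(V_pre)(1−s) − s/τ`,
α = 2 ms⁻¹, τ = 9 ms, and a steep release sigmoid centred at 0 mV.
Centring release at spike height (not at −20 mV) matters: during the
interneuron's depolarization-block plateau (~−20 mV) there are no spikes
and release must stop, otherwise the pyramidal neuron stays clamped and
ignition stalls for tens of seconds.

## Scenarios and calibration

Named scenarios: `rest` (no drive, 60 s), `fig5b` (1 %, g_D,i = 0.1
mS/cm², 30 s), `fig5c` (6 %, same drive, 30 s), `fig5e` (0 %, g_D,i =
0.349 mS/cm², 30 s). Drives are step-on at t = 0 from the resting fixed
point; latencies are measured from drive onset. The published rate
constants of the reference model live in a supplement that is not
packaged here, so the constants above were calibrated once against the
reported behaviours: bounded ~10.5 mM [K⁺]out at 1 %, ignition with a
~13 mM pre-ignition peak and >60 mM runaway at 6 %, a minimal igniting
drive of ≈0.35 mS/cm² at 0 %, latency decreasing and f–I uniformly
increasing with the fraction. All constants are in
`src/csdsim/params/default.yaml` and overridable per scenario.

Known deviation: in this calibration the 1 % pyramidal neuron engages
late (~15 s, ~30 Hz, bounded, never blocking) rather than transiently
during the early hump. The engagement window is a narrow bistable band
between the hump maximum and the late steady [K⁺]out; placing it exactly
as reported would require the unpublished constants.

## Detectors

Spikes: upward 0 mV crossings with a 2 ms refractory. Depolarization
block: V above −35 mV for ≥2 s with no spikes (the −35 mV default, not
−30, because the pyramidal plateau crosses −30 mV late during ignition
and would date block onset seconds after firing has failed; detection is
stable to ±2 mV). CSD-ignition (cascade) onset is the *earliest* block
onset of the two neurons — the beginning of the regenerative [K⁺]out
surge; the pre-ignition [K⁺]out maximum is taken before that onset, the
post-block maximum after the pyramidal onset. Minimal blocking drive:
bisection (default tolerance 0.001 mS/cm², window 30 s) on "pyramidal
block within the window". The f–I curve is measured on the isolated
interneuron with ion concentrations clamped at rest, isolating the
direct effect of the persistent conductance; with concentrations free
the high-fraction cell blocks within a second and the "frequency"
measures block latency instead.

## Numerics

LSODA with rtol 10⁻⁶ / atol 10⁻⁸, max step 50 ms, output sampled at
0.25 ms (sufficient for 0 mV spike crossings; a 10× tolerance refinement
moves the [K⁺]out maximum by <1 % and block latency by <2 %). The
right-hand side is numba-compiled; a 30 s scenario integrates in a few
seconds on one CPU. Runs are bitwise deterministic for fixed inputs and
solver settings. Scenario durations of 30 s and the 30 s bisection
window are the packaged problem sizes; the suite grid is
{0, 1, 2, 4, 6} % × bisection + latency + four f–I drives.

## Exact statistics

Fisher's 2×2 test conditions on both margins and sums hypergeometric
probabilities of all tables no more probable than the observed one
(two-sided probability-ordering rule, the convention of mainstream
implementations; one-sided variants exposed). The Freeman–Halton r×2
generalization enumerates all success columns compatible with the
margins; probabilities are accumulated as log-binomials via `lgamma`, so
p-values at the 10⁻¹⁴ scale are exact to double precision. Ties are
included in the rejection set with a 10⁻⁷ relative tolerance. The
enumeration refuses (raises) rather than approximates beyond a table
budget. Printed tables from the source experiments ship as a JSON
fixture keyed by figure panel; two carry flags — one whose printed
adjusted p depends on an unstated Bonferroni comparison count, and one
whose legend is internally inconsistent — and are excluded from
headline checks.

## Synthetic data

Outcome tables are independent binomials per group. Voltage traces place
stereotyped 2 ms triangular spikes by a refractory renewal process whose
mean rate equals the schedule (so detector tests have exact ground
truth), with an optional plateau after a block onset and optional
Gaussian noise. These emulate the *statistical* structure the detectors
and tests assume — not real electrophysiology: no channel noise, no
waveform variability, no drift. Passing detector tests therefore
demonstrate correctness of the algorithms on clean signals, and the
threshold-stability tests cover modest departures; performance on noisy
experimental recordings is not claimed. All generators take explicit
integer seeds; identical seed and spec give bitwise-identical output.

## Limitations

Single-compartment neurons; one ECS shared by exactly two cells; no
Ca²⁺, no oxygen/metabolic coupling, no osmotic swelling, no spatial
propagation. The calibration reproduces the reported ignition
phenomenology, not the unpublished parameter set; quantities reported by
the acceptance script are model outputs of this calibration.
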