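# Methods

## The model

`dipolelfp` implements a biophysical observation model for the local field
potential (LFP) of a spiking cortical network.  The generator of the field is
the cortical pyramidal neuron, reduced to three lumped compartments: the
apical dendritic tree (excitatory AMPA synapses), the soma/perisomatic basal
dendritic tree (inhibitory GABA synapses) and the axon hillock, where a leaky
integrate-and-fire (LIF) mechanism converts the membrane potential into
spikes.  The compartments are coupled by longitudinal cytoplasm resistances
`R_A`, `R_B` and — crucially — by extracellular return paths `R_C`, `R_D`.
Excitatory and inhibitory postsynaptic potentials act as electromotive forces
`E^E`, `E^I` in the resulting equivalent circuit; the dendritic dipole current
`I_D` that loops through extracellular space generates the single-cell
dendritic field potential (DFP)

    V_i = R_D · I_D,i .

Kirchhoff analysis of the circuit yields simultaneously

* the **membrane law** `τ dU/dt + U = Σ w^E E^E − Σ w^I E^I` — an ordinary
  LIF network equation with static threshold θ = 18 mV, reset E = 11 mV and
  refractory periods 2 ms (pyramidal) / 1 ms (interneurons), and
* the **observation equation**
  `V = Σ w̃^E E^E + Σ w̃^I E^I + ξ·U`,
  in which *both* synapse types enter with positive weight: inhibition lowers
  U but, by shunting the dendritic loop current, *raises* the dipole field.

Population LFP proxies: `L3 = Σ_i V_i`, `L4 = L3/K` (dipole measures), and
for comparison the ad hoc moduli measures `L1 = Σ_i (Σ|I^E| + Σ|I^I|)`,
`L2 = L1/K`, plus the population-mean membrane potential.

## Unit system and parameter derivation

All quantities live in a coherent {mV, ms, GΩ, nS, pA, pF} system, so GΩ·nS
products are dimensionless and GΩ·pF = ms; no hidden conversion factors exist
anywhere in the dynamics.  The only conversion constant is in
`volume_resistance` (Ω·cm with μm geometry → 10⁴ Ω).

Resistances come from `R = ρℓ/A` with ρ(membrane, cytoplasm, extracellular) =
(5·10⁷, 200, 333) Ω·cm, dendritic half-length 10 μm, dendritic radius 7 μm
(cytoplasm cross-section πa², extracellular cross-section `(12√3 − 3π)a²`
from hexagonal dense packing of parallel trunks), hillock cylinder 20 μm ×
0.5 μm.  Defaults give `R_A = R_B ≈ 1.30·10⁻⁴ GΩ`, `R_C = R_D ≈ 5.98·10⁻⁵ GΩ`,
`R_M ≈ 0.0796 GΩ`.

The phenomenological efficacy table (GABA/recurrent-AMPA/thalamic-AMPA on
interneurons and pyramidal cells: 2.7, 0.7, 0.95 / 1.7, 0.42, 0.55 mV, with
voltage unit v = 1 mV) is aligned to the circuit:

* weights `w = J/v`; passive coupling factor `r = w^I/ḡ_GABA = 1.7 GΩ`;
* per-synapse couplings `α = w^E/r` → 0.25 nS (cortical), 0.32 nS (thalamic);
* total excitatory conductance from the self-consistency relation
  `g_E = Σα / (1 − (R_A+R_D)Σα)` over the effective excitatory in-degree;
* membrane capacitance `C ≈ 11.22 pF` solved from the time-constant relation
  (linear in C) at the target τ = 20 ms; the forward evaluation reproduces
  the target to 10⁻¹⁰ relative by construction;
* DFP weights `w̃^E = R_D w^E (1/r − β/τ)`, `w̃^I = R_D w^I β/τ`,
  `ξ = R_D (β/τ − γ)`.

### The overdetermination of r, and the sign of ξ

The circuit algebra defines r through `R_M`, `g_I` and γ, while the efficacy
alignment fixes r = 1.7 GΩ from the synaptic table.  With realistic geometry
these disagree by ~460× (`r_circuit_diagnostic` reports ≈ 3.7·10⁻³ GΩ).  The
aligned value is authoritative for dynamics and observation — that is the
only way to reproduce the phenomenological network exactly — and the
discrepancy is surfaced, not hidden.  A direct consequence: γ ≈ 458 nS
dominates β/τ ≈ 0.049 nS, so ξ ≈ −0.027 is *negative* and the dipole DFP is
dominated by `−|ξ|·U`.  Single-synaptic-volley sign structure still holds
(w̃^E, w̃^I > 0: both synapse types raise V at fixed U), but the total
population signal L4 is essentially an inverted, scaled copy of the mean
membrane potential.  We report the raw signal and never clamp its polarity.

### Effective synapse counts

`g_E`/`g_I` need synapse counts the circuit model does not itself fix.  We use
the expected in-degrees of the reference network: `p = P·K = 800` recurrent
plus `n_thal = 800` thalamic fibres for g_E, and `q = P·L = 200` for g_I.  The
thalamic fibre count affects only the alignment; the simulated drive is one
aggregated Poisson line per neuron.

### Membrane resistance geometry

`R = ρℓ/A` applied to the hillock membrane needs a conduction length the
geometry tables do not state.  Default: radial conduction through a thin
shell — lateral cylinder surface `2π a_h ℓ_h` as area, a configurable
`membrane_thickness_um` (default 0.01 μm) as length.  The alternative reading
(hillock length as ℓ) is available via `r_m_length="hillock_length"`.

## Synaptic kinetics

Each channel is the linear cascade `τ_d I' = −I + x`, `τ_r x' = −x + F` with
rise/decay times (GABA 0.25/5 ms, AMPA on interneurons 0.2/1 ms, AMPA on
pyramidal cells 0.4/2 ms) and transmission latency τ_L = 1 ms.  Its impulse
response is the unit-normalised difference of exponentials
`s(t) = (e^(−t/τ_d) − e^(−t/τ_r))/(τ_d − τ_r)` — zero at the origin,
non-negative, integrating to one; these three constraints determine the form
uniquely.  All drive scaling sits in the forcing weight `τ_m·J` per spike, so
the aggregated channel variable I equals `w·E` identically and the membrane
law can be integrated directly in drive units (mV).  Because the cascade is
linear with constant coefficients it is integrated *exactly*: free decay is a
closed-form 2×2 matrix exponential per step, a spike is an instantaneous jump
`x += τ_m J/τ_r`.  A brute-force convolution oracle (`psc_oracle`) provides
the independent reference in tests; agreement is at float round-off
(≤ 10⁻⁸ relative required, ~10⁻¹⁵ observed).

The DFP's synaptic terms are obtained by rescaling the channel drives with
`w̃/w` rather than integrating a literal second cascade with rescaled
forcing; for linear kinetics the two are identical (asserted in tests).

## Network integration

* Grid dt = 0.1 ms (10 kHz; spectra to 5 kHz).  The latency must be an
  integer multiple of dt (validated); spike delivery uses a ring buffer of
  `τ_L/dt + 1` slots, so every event arrives after exactly τ_L.
* Membrane update is exact exponential integration with the drive held
  constant across a step; threshold test is end-of-step `U ≥ θ` with positive
  increment (no within-step interpolation — events are grid-aligned, dt ≪ τ).
* During refractoriness U is clamped at the reset potential and integration
  restarts afterwards; recorded inter-spike intervals therefore always exceed
  τ_rp (hard test assertion).
* Initial conditions: U(0) = reset, synaptic states zero; optional uniform
  jitter in [reset, θ) shortens transients.
* Interneurons obey the same membrane law with τ_m = 10 ms (the value of the
  phenomenological source network; this circuit derivation itself fixes only
  the pyramidal 20 ms) and contribute no DFP — the observation model is a
  pyramidal-cell property.
* RNG: one master seed spawns separate streams (connectivity, OU, thalamic
  Poisson per population, init jitter); all draws are array-shaped, so
  results are independent of any neuron iteration order and bitwise
  reproducible.
* LFP measures are accumulated online each step, so full-scale runs need no
  per-neuron trace storage; `record_traces=True` keeps the (T, K) pyramidal
  state arrays for desk-scale analysis.

The thalamic drive is the exact OU transition
`n' = n e^(−dt/τ_n) + σ_n √(1 − e^(−2dt/τ_n)) z` (τ_n = 16 ms,
σ_n = 0.4 spikes/ms), rectified around the constant signal c₀
(`λ = [c₀ + n]_+`, presets 1.2 / 1.6 / 2.4 spikes/ms within the stated
1.2–2.6 operating range), feeding per-neuron Poisson *counts* per bin (not
Bernoulli thinning, so λ·dt need not be small).  The rate is shared across
neurons; realisations are independent by default, with a `shared_train`
switch.

## What the synthetic world does and does not establish

All inputs are generated in-package under the stated reference conditions; no
recorded data enter anywhere.  Green tests therefore establish internal
correctness (exact algebraic identities, oracle agreement, stated qualitative
orderings), not agreement with experimental LFPs.  Desk-scale fixtures
(scale 0.1: 400 + 100 neurons) keep every other parameter at its reference
value, so they probe the same dynamical regime with 10× fewer synapses per
cell — absolute rates differ from full scale, while orderings (drive-response
monotonicity, amplitude and spectral-slope relations) are preserved and are
what the tests assert, by majority over five seeds.

One finite-size effect matters for spectra: the dipole average L4 (≈ ξ·mean U)
carries a spike/reset shot-noise floor whose power scales as 1/K.  At desk
scale it dominates L4 and mean-U spectra above ≈ 1 kHz, masking the
synaptic/membrane roll-off; at K = 4000 the L4-steeper-than-L2 ordering holds
over the whole 100 Hz–Nyquist range.  The default high-frequency slope band
is therefore 100–1000 Hz (`ObservationParams.slope_f_max_hz`).

## Numerical choices

* Tolerances: exact identities (capacitance round trip, alignment identity,
  mesh-current node law) at 10⁻¹⁰ relative; oracle comparisons at 10⁻⁸
  relative sup-norm; kernel normalisation at 10⁻⁶ by quadrature.
* The mesh-current reconstruction uses `dU/dt` from the right-hand side of
  the membrane law, never finite differences.
* `I_B` is returned as `I_D − I_IF` (the node law); an independent
  inhibitory-branch evaluation would inherit the r overdetermination above.
* Spectra: Welch averaged modified periodograms, Hann window, 256 ms segments
  (shortened to half the trace for short runs), 50 % overlap, linear
  detrending.
* Degenerate inputs: τ_r = τ_d kernels, non-positive geometry, infeasible
  alignment (`1 − (R_A+R_D)Σα ≤ 0`), latency off the grid and reset ≥ θ all
  raise typed errors before integration starts.

## Known limitations

* Point-like circuit per neuron: no spatial electrode geometry, lead fields,
  layered polarity reversals or cable-equation morphology.
* Current-based (linear) synapses only: no conductance-based or NMDA
  channels, no plasticity.
* The aligned parameter set is internally inconsistent with the circuit's own
  r (documented above); the package makes the inconsistency measurable rather
  than resolving it.
* LFP amplitudes are model-scale quantities; the dipole average is of order
  0.1–1 mV but its negative polarity (ξ < 0) is a direct consequence of the
  aligned parameters.
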