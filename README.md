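# dipolelfp

A biophysical observation model for the local field potential (LFP) of leaky
integrate-and-fire (LIF) networks, built on a reduced three-compartment
pyramidal neuron.

## The problem

Point-neuron network simulations have no extracellular space, so their "LFP"
is usually an ad hoc proxy — most commonly the sum of the absolute values of
the synaptic currents onto pyramidal cells.  Physically, however, the LFP is
generated by *dipole currents*: excitatory synapses on the apical dendrite act
as current sinks, inhibitory synapses near the soma as sources, and the loop
current `I_D` through the resistive extracellular medium produces the
single-cell dendritic field potential (DFP)

```
V_i = R_D · I_D,i .
```

`dipolelfp` derives this observation model from an equivalent circuit —
apical dendrite, perisomatic basal dendrite and axon hillock coupled by
cytoplasm resistances `R_A, R_B` and extracellular resistances `R_C, R_D` —
and shows that the *same* circuit yields an ordinary LIF membrane law

```
τ dU/dt + U = Σ_j w^E_j E^E_j − Σ_k w^I_k E^I_k ,
```

plus a linear observation equation in which both synapse types *raise* the
field,

```
V = Σ_j w̃^E_j E^E_j + Σ_k w̃^I_k E^I_k + ξ·U ,
```

with electrotonic coefficients (α, β, γ, r, τ, w, w̃, ξ) computed from cell
geometry, medium resistivities and a phenomenological synaptic-efficacy
table.  The package is for computational neuroscientists who want
biophysically grounded LFP proxies from large spiking-network simulations
without multicompartment cable models.

It provides:

* `electrotonics` — the full coefficient derivation and its consistency
  diagnostics;
* `synapse_kinetics` — exact event-driven integration of the second-order
  (difference-of-exponentials) postsynaptic current cascades;
* `thalamic_input` — Ornstein–Uhlenbeck-modulated inhomogeneous Poisson
  external drive, the network's only noise source;
* `network_sim` — the sparse 4000-pyramidal + 1000-interneuron LIF network
  (Erdős–Rényi, P = 0.2; θ = 18 mV, reset 11 mV, τ_L = 1 ms, dt = 0.1 ms);
* `observables` — per-neuron dipole DFP and moduli DFP, the population LFP
  measures L1–L4, mesh currents and Welch spectra;
* `config`/`scenarios` — YAML-configurable, seeded, self-describing runs with
  presets for the three reference drive rates (1.2 / 1.6 / 2.4 spikes/ms).

## Worked example

```python
from dipolelfp import derive_parameters, coefficients_report

circ, coef = derive_parameters()
rep = coefficients_report(circ, coef)
print(rep["r_GOhm"], rep["alpha_cortical_nS"], rep["alpha_thalamic_nS"],
      rep["C_pF"], rep["tau_ms"], rep["xi"])
```

prints

```
1.7 0.24705882352941178 0.3235294117647059 11.218752045396796 20.0 -0.02737015443928294
```

i.e. the inhibitory weight over the 1 nS unitary GABA conductance fixes the
passive coupling factor r = 1.7 GΩ; one cortical/thalamic AMPA synapse couples
with α ≈ 0.25 / 0.32 nS; C ≈ 11.22 pF realises the 20 ms membrane time
constant (recovered exactly on forward evaluation); and the membrane-feedback
weight ξ of the DFP is small and negative for realistic geometry.

Running a desk-scale network (`python examples/proxy_comparison.py`):

```
scale-0.1 network, 500 ms, c0 = 1.6 spikes/ms:
  pyramidal rate 7.88 Hz, interneuron rate 13.38 Hz

measure     mean (mV)   std (mV)  HF slope
L1         12601.6031  7649.3281     -2.92
L2            31.5040    19.1233     -2.92
L3           -80.7011     7.1867     -3.32
L4            -0.2018     0.0180     -3.32
mean_U        12.1239     1.0824     -3.36
```

The moduli measures L1/L2 (sum/average of |synaptic currents|) overestimate
the field amplitude by orders of magnitude relative to the dipole measures
L3/L4, and their spectrum decays more slowly at high frequency; the dipole
average L4 is of millivolt order and rolls off like the mean membrane
potential.

Other examples (each runs in seconds unless noted):

* `examples/derive_parameters.py` — the full coefficient report with
  diagnostics;
* `examples/synaptic_kernels.py` — kernel shapes, peak times and the
  event-driven-vs-convolution-oracle check;
* `examples/thalamic_drive.py` — OU rate statistics and Poisson spike counts;
* `examples/proxy_comparison.py` — the L1–L4 comparison above;
* `examples/full_scale_run.py` — the full 4000+1000-neuron, 2 s protocol at
  all three drive rates with overview panels (a few minutes; writes under
  `scratch/`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-derives, from the reference geometry/resistivity/efficacy tables alone,
the headline alignment quantities: the passive coupling factor r (GΩ), the
per-synapse couplings α of the recurrent-cortical and external-thalamic AMPA
classes (nS, two decimals), and the membrane time constant (ms) recovered by
forward evaluation after solving for the capacitance.  Results are written as
JSON keyed by target id.
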