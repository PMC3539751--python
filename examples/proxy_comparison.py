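"""Compare the four LFP proxies on a desk-scale network run.

L1/L2 sum/average the moduli of synaptic currents (the ad hoc comparison
model); L3/L4 sum/average the dipole DFP of the equivalent circuit.  The
moduli measures overestimate amplitude and decay more slowly at high
frequency than the mean membrane potential; the dipole average tracks it.
"""

import dipolelfp as d

cfg = d.make_fixture_network(scale=0.1, seed=0)  # 400 + 100 neurons
cfg.network.duration_ms = 500.0
result = d.run_scenario(cfg)
obs = cfg.observation

n_pyr = (result.spike_pop == d.PYRAMIDAL).sum()
n_int = (result.spike_pop == d.INTERNEURON).sum()
print(f"scale-0.1 network, 500 ms, c0 = {cfg.thalamic.c0} spikes/ms:")
print(f"  pyramidal rate {n_pyr / cfg.network.n_pyramidal / 0.5:.2f} Hz, "
      f"interneuron rate {n_int / cfg.network.n_interneurons / 0.5:.2f} Hz")

print(f"\n{'measure':8s} {'mean (mV)':>12s} {'std (mV)':>10s} {'HF slope':>9s}")
for name, trace in result.lfp.as_columns().items():
    f, p = d.power_spectrum(trace, result.lfp.fs_khz, segment_ms=250.0)
    slope = d.spectral_slope(f, p, obs.slope_f_min_hz, obs.slope_f_max_hz)
    print(f"{name:8s} {trace.mean():12.4f} {trace.std():10.4f} {slope:9.2f}")

print("\nThe moduli average L2 fluctuates an order of magnitude harder than the")
print("dipole average L4, and its 100-1000 Hz log-log slope is shallower; L4's")
print("slope matches the mean membrane potential, whose low-pass behaviour it")
print("inherits through the xi*U term.")
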