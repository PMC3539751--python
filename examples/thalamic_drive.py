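"""The two-level thalamic noise: OU-modulated rectified rate into Poisson spikes."""

import numpy as np

from dipolelfp import NoiseParams, generate_rate_trace, thalamic_spikes

p = NoiseParams(c0=1.6)  # baseline 1.6 spikes/ms, tau_n = 16 ms, sigma_n = 0.4
rng = np.random.default_rng(0)
trace = generate_rate_trace(10_000.0, 0.1, p, rng)

print(f"OU state over 10 s: mean {trace.n.mean():+.4f}, std {trace.n.std():.4f} "
      f"(stationary std is sigma_n = {p.sigma_n})")
print(f"rectified rate: min {trace.lam.min():.3f}, mean {trace.lam.mean():.3f}, "
      f"max {trace.lam.max():.3f} spikes/ms (never negative)")

counts = np.array([thalamic_spikes(lam, 0.1, 1, rng)[0] for lam in trace.lam[:50_000]])
print(f"Poisson spikes of one neuron over 5 s: {counts.sum()} events, "
      f"empirical rate {counts.sum() / 5000:.3f} spikes/ms vs "
      f"rate-trace mean {trace.lam[:50_000].mean():.3f}")
print("The rate signal is shared by all neurons; spike realisations are independent.")
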