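"""Two-level thalamic noise: OU-modulated inhomogeneous Poisson spike input.

The only noise source of the network is its external (thalamic) drive.  A
global rate signal is built from an Ornstein-Uhlenbeck process n(t),

    tau_n dn/dt = -n + sigma_n * sqrt(2 tau_n) * eta(t),

superimposed on a constant signal c0 and rectified,
lambda(t) = [c0 + n(t)]_+, so rates never go negative.  The same lambda(t) is
shared by every neuron; each neuron then receives an independent Poisson spike
count per time bin with mean lambda*dt (a configuration switch makes the spike
realisation itself shared).

The OU transition is exact for any dt:
n' = n e^(-dt/tau_n) + sigma_n sqrt(1 - e^(-2 dt/tau_n)) z, z ~ N(0, 1),
so the stationary law (mean 0, std sigma_n) holds at every step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

C0_RANGE = (1.2, 2.6)  # spikes/ms, stated operating range for the constant signal


@dataclass(frozen=True)
class NoiseParams:
    """OU time constant (ms), stationary std and baseline rate (spikes/ms)."""

    tau_n_ms: float = 16.0
    sigma_n: float = 0.4
    c0: float = 1.6
    shared_train: bool = False

    def __post_init__(self) -> None:
        if not self.tau_n_ms > 0:
            raise ValueError("tau_n must be strictly positive")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")

    def validate_preset_range(self) -> None:
        lo, hi = C0_RANGE
        if not lo <= self.c0 <= hi:
            raise ValueError(
                f"c0 = {self.c0} spikes/ms outside the preset operating range [{lo}, {hi}]"
            )


@dataclass
class RateTrace:
    """Time grid (ms), OU state n(t) and rectified rate lambda(t) (spikes/ms)."""

    t_ms: np.ndarray
    n: np.ndarray
    lam: np.ndarray


def ou_step(n: float, dt_ms: float, p: NoiseParams, rng: np.random.Generator) -> float:
    """One exact OU transition over dt."""
    if not dt_ms > 0:
        raise ValueError("dt must be strictly positive")
    decay = np.exp(-dt_ms / p.tau_n_ms)
    noise_std = p.sigma_n * np.sqrt(1.0 - decay * decay)
    return n * decay + noise_std * rng.standard_normal()


def ou_trace(n_steps: int, dt_ms: float, p: NoiseParams, rng: np.random.Generator,
             n0: float = 0.0) -> np.ndarray:
    """Exact OU sample path of length n_steps (excluding n0), vectorised.

    The exact transition is an AR(1) recursion n_{k+1} = a n_k + b z_k, run
    through a linear filter for speed; identical in law (and, given the same
    normal draws, in value) to iterating :func:`ou_step`.
    """
    a = np.exp(-dt_ms / p.tau_n_ms)
    b = p.sigma_n * np.sqrt(1.0 - a * a)
    z = rng.standard_normal(n_steps)
    drive = b * z
    drive[0] += a * n0
    return lfilter([1.0], [1.0, -a], drive)


def rectified_rate(n, c0: float):
    """Threshold-linear rate lambda = [c0 + n]_+ (spikes/ms)."""
    return np.maximum(c0 + np.asarray(n, dtype=float), 0.0)


def generate_rate_trace(duration_ms: float, dt_ms: float, p: NoiseParams,
                        rng: np.random.Generator) -> RateTrace:
    """OU state and rectified rate on a regular grid covering (0, duration]."""
    n_steps = int(round(duration_ms / dt_ms))
    t = dt_ms * np.arange(1, n_steps + 1)
    n = ou_trace(n_steps, dt_ms, p, rng)
    return RateTrace(t_ms=t, n=n, lam=rectified_rate(n, p.c0))


def thalamic_spikes(lam: float, dt_ms: float, n_neurons: int,
                    rng: np.random.Generator, shared: bool = False) -> np.ndarray:
    """Per-neuron Poisson spike counts for one bin with common mean lam*dt.

    Counts (not Bernoulli thinning), so several events per bin are possible at
    high rates.  With ``shared=True`` a single realisation is broadcast to all
    neurons; by default realisations are independent across neurons.
    """
    if lam < 0:
        raise ValueError("rate must be non-negative")
    if not dt_ms > 0:
        raise ValueError("dt must be strictly positive")
    if shared:
        return np.full(n_neurons, rng.poisson(lam * dt_ms))
    return rng.poisson(lam * dt_ms, size=n_neurons)
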