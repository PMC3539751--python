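"""Second-order postsynaptic current kinetics and their exact integration.

Each synaptic channel (GABA, recurrent AMPA, thalamic AMPA) is a linear
two-variable cascade

    tau_d dI/dt = -I + x
    tau_r dx/dt = -x + F(t)

driven by delta forcing F = tau_m * J * delta(t - t_spike - tau_L) per
presynaptic spike.  The impulse response (Green's function) of the cascade is
the unit-normalised difference of exponentials

    s(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r),  t >= 0,

so a single spike from rest produces I(t) = tau_m * J * s(t), which integrates
to tau_m * J.  Because the cascade is linear with constant coefficients it is
integrated *exactly*: free decay over a step is a closed-form 2x2 matrix
exponential and each spike is an instantaneous jump of x by tau_m*J/tau_r.

States are kept as arrays (one element per neuron) so a whole population's
channel advances in a few vector operations per time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KineticsParams:
    """Rise/decay times (ms), latency (ms), efficacy J (mV) and target membrane tau_m (ms)."""

    tau_r_ms: float
    tau_d_ms: float
    j_mv: float
    tau_m_ms: float
    tau_l_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_r_ms:
            raise ValueError("tau_r must be strictly positive")
        if self.tau_r_ms == self.tau_d_ms:
            raise ValueError(
                "degenerate kernel: tau_r == tau_d (distinct roots are assumed)"
            )
        if not self.tau_r_ms < self.tau_d_ms:
            raise ValueError("require tau_r < tau_d")
        if self.tau_l_ms < 0:
            raise ValueError("latency must be non-negative")
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m must be strictly positive")

    @property
    def jump(self) -> float:
        """x-increment per presynaptic spike, tau_m * J / tau_r (mV)."""
        return self.tau_m_ms * self.j_mv / self.tau_r_ms


@dataclass
class SynapticChannelState:
    """Aggregated cascade state of one channel across a population.

    ``I`` is the postsynaptic drive (mV, equal to w * E for the aligned
    weights), ``x`` the auxiliary variable.  Both decay to zero in the absence
    of spikes and stay non-negative for non-negative efficacies.
    """

    I: np.ndarray
    x: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SynapticChannelState":
        return cls(I=np.zeros(n), x=np.zeros(n))

    def copy(self) -> "SynapticChannelState":
        return SynapticChannelState(I=self.I.copy(), x=self.x.copy())


def greens_function(t, k: KineticsParams):
    """Unit-normalised impulse response s(t) of the cascade (1/ms).

    Zero for t < 0 (causality) and at t = 0; non-negative; integrates to one.
    Drive scaling (tau_m * J) is applied by the caller.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0.0,
        (np.exp(-t / k.tau_d_ms) - np.exp(-t / k.tau_r_ms)) / (k.tau_d_ms - k.tau_r_ms),
        0.0,
    )
    return out if out.ndim else float(out)


def greens_peak_time(k: KineticsParams) -> float:
    """Analytic argmax of the kernel, t* = tau_d tau_r / (tau_d - tau_r) * ln(tau_d/tau_r)."""
    return (
        k.tau_d_ms * k.tau_r_ms / (k.tau_d_ms - k.tau_r_ms) * np.log(k.tau_d_ms / k.tau_r_ms)
    )


def decay_propagator(dt_ms: float, k: KineticsParams) -> tuple[float, float, float]:
    """Closed-form free-decay propagator over dt: (e_d, e_r, c).

    The exact update is I <- e_d * I + c * x; x <- e_r * x, with
    c = tau_r/(tau_r - tau_d) * (e_r - e_d) >= 0.
    """
    if not dt_ms > 0:
        raise ValueError("dt must be strictly positive")
    e_d = np.exp(-dt_ms / k.tau_d_ms)
    e_r = np.exp(-dt_ms / k.tau_r_ms)
    c = k.tau_r_ms / (k.tau_r_ms - k.tau_d_ms) * (e_r - e_d)
    return e_d, e_r, c


def decay_step(state: SynapticChannelState, dt_ms: float, k: KineticsParams) -> SynapticChannelState:
    """Advance the unforced cascade exactly by dt (matrix exponential, in place)."""
    e_d, e_r, c = decay_propagator(dt_ms, k)
    state.I *= e_d
    state.I += c * state.x
    state.x *= e_r
    return state


def apply_spikes(state: SynapticChannelState, n_spikes, k: KineticsParams) -> SynapticChannelState:
    """Apply delta forcing: x jumps by n_spikes * tau_m*J/tau_r; I is continuous."""
    n = np.asarray(n_spikes)
    if np.any(n < 0):
        raise ValueError("spike counts must be non-negative")
    state.x += n * k.jump
    return state


def psc_oracle(spike_times_ms, t_grid_ms, k: KineticsParams) -> np.ndarray:
    """Direct-superposition reference trace: sum_nu tau_m*J*s(t - t_nu - tau_L).

    Brute-force convolution used as the independent oracle for the
    event-driven exact integrator; O(spikes * grid) and not meant for
    production runs.
    """
    t = np.asarray(t_grid_ms, dtype=float)
    out = np.zeros_like(t)
    scale = k.tau_m_ms * k.j_mv
    for t_nu in spike_times_ms:
        out += scale * greens_function(t - t_nu - k.tau_l_ms, k)
    return out


# Default kinetics per channel and target population (rise/decay in ms).
# tau_m is the target population's membrane time constant; J the efficacy.
def default_kinetics(tau_m_exc_ms: float = 20.0, tau_m_inh_ms: float = 10.0,
                     tau_l_ms: float = 1.0) -> dict[str, dict[str, KineticsParams]]:
    """Reference kinetics table: channels x target populations.

    GABA 0.25/5 ms, AMPA on interneurons 0.2/1 ms, AMPA on pyramidal neurons
    0.4/2 ms; thalamic AMPA shares the AMPA kinetics of its target population.
    """
    return {
        "pyramidal": {
            "ampa_rec": KineticsParams(0.4, 2.0, 0.42, tau_m_exc_ms, tau_l_ms),
            "ampa_thal": KineticsParams(0.4, 2.0, 0.55, tau_m_exc_ms, tau_l_ms),
            "gaba": KineticsParams(0.25, 5.0, 1.7, tau_m_exc_ms, tau_l_ms),
        },
        "interneuron": {
            "ampa_rec": KineticsParams(0.2, 1.0, 0.7, tau_m_inh_ms, tau_l_ms),
            "ampa_thal": KineticsParams(0.2, 1.0, 0.95, tau_m_inh_ms, tau_l_ms),
            "gaba": KineticsParams(0.25, 5.0, 2.7, tau_m_inh_ms, tau_l_ms),
        },
    }
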