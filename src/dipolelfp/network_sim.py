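"""Sparse two-population LIF network with exact synaptic integration.

The network is an Erdos-Renyi directed graph over K pyramidal neurons and L
interneurons (default 4000/1000, connection probability 0.2).  Every neuron
obeys the membrane law

    tau dU/dt + U = I_ampa_rec + I_ampa_thal - I_gaba

with channel drives produced by the exact second-order kinetics of
:mod:`dipolelfp.synapse_kinetics`.  A neuron crossing the static threshold
theta from below emits a spike, is reset, and stays clamped at the reset
potential for its population's refractory period; spikes are delivered to the
targets' channels after the synaptic latency tau_L.  The only stochastic
drive is the thalamic OU-modulated Poisson input of
:mod:`dipolelfp.thalamic_input`.

Integration is grid-based (default dt = 0.1 ms, i.e. 10 kHz sampling): the
channel cascades advance by their closed-form propagator and the membrane by
exact exponential integration with the drive held constant across a step.
Runs are bitwise reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import observables
from .electrotonics import (
    CircuitParameters,
    DerivedCoefficients,
    derive_parameters,
)
from .synapse_kinetics import (
    KineticsParams,
    SynapticChannelState,
    decay_propagator,
    default_kinetics,
)
from .thalamic_input import NoiseParams, RateTrace, generate_rate_trace

PYRAMIDAL, INTERNEURON = 0, 1


class NumericalFault(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class NetworkConfig:
    """Network sizes, LIF parameters and integration grid."""

    n_pyramidal: int = 4000
    n_interneurons: int = 1000
    connection_prob: float = 0.2
    theta_mv: float = 18.0
    reset_mv: float = 11.0
    tau_rp_exc_ms: float = 2.0
    tau_rp_inh_ms: float = 1.0
    tau_m_exc_ms: float = 20.0
    tau_m_inh_ms: float = 10.0
    tau_l_ms: float = 1.0
    dt_ms: float = 0.1
    duration_ms: float = 2000.0
    seed: int = 0
    init_jitter: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_pyramidal < 0 or self.n_interneurons < 0:
            raise ValueError("population sizes must be non-negative")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValueError("connection probability must lie in [0, 1]")
        if not self.reset_mv < self.theta_mv:
            raise ValueError("reset potential must lie below threshold")
        if not self.dt_ms > 0:
            raise ValueError("dt must be strictly positive")
        if self.duration_ms < 0:
            raise ValueError("duration must be non-negative")
        ratio = self.tau_l_ms / self.dt_ms
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"latency tau_L = {self.tau_l_ms} ms must be a positive integer "
                f"multiple of dt = {self.dt_ms} ms"
            )

    @property
    def n_total(self) -> int:
        return self.n_pyramidal + self.n_interneurons

    @property
    def latency_steps(self) -> int:
        return int(round(self.tau_l_ms / self.dt_ms))


@dataclass
class Connectivity:
    """Directed adjacency as per-source target-index arrays over all K+L neurons."""

    targets: list
    n_pyramidal: int
    n_interneurons: int

    @property
    def n_total(self) -> int:
        return self.n_pyramidal + self.n_interneurons

    def out_degrees(self) -> np.ndarray:
        return np.array([t.size for t in self.targets])

    def in_degrees(self) -> np.ndarray:
        counts = np.zeros(self.n_total, dtype=np.int64)
        for t in self.targets:
            counts[t] += 1
        return counts


def build_connectivity(cfg: NetworkConfig, rng: np.random.Generator) -> Connectivity:
    """Erdos-Renyi directed graph: each ordered pair (i != j) connected with prob P."""
    n = cfg.n_total
    targets = []
    for i in range(n):
        hit = np.nonzero(rng.random(n) < cfg.connection_prob)[0]
        hit = hit[hit != i]
        targets.append(hit.astype(np.int32))
    return Connectivity(targets=targets, n_pyramidal=cfg.n_pyramidal,
                        n_interneurons=cfg.n_interneurons)


def lif_step(U, drive, refractory_until, t_ms, dt_ms, tau_m_ms, theta_mv,
             reset_mv, tau_rp_ms):
    """One exact-exponential LIF step for a population (vectorised, in place).

    Non-refractory neurons follow U <- drive + (U - drive) e^(-dt/tau); a
    neuron whose end-of-step potential reaches theta with positive increment
    spikes at t + dt, is reset and frozen for tau_rp.  Returns the spiking
    mask.
    """
    clamped = t_ms < refractory_until - 1e-9
    decay = np.exp(-dt_ms / tau_m_ms)
    U_new = drive + (U - drive) * decay
    U_new[clamped] = reset_mv
    spiked = (~clamped) & (U_new >= theta_mv) & (U_new > U)
    U[:] = U_new
    U[spiked] = reset_mv
    refractory_until[spiked] = t_ms + dt_ms + tau_rp_ms
    if not np.all(np.isfinite(U)):
        bad = np.nonzero(~np.isfinite(U))[0]
        raise NumericalFault(
            f"non-finite membrane potential at t = {t_ms + dt_ms:.3f} ms, "
            f"neurons {bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    return spiked


@dataclass
class SimulationResult:
    """Spike records, LFP traces, thalamic rate and (optionally) full state traces."""

    t_ms: np.ndarray
    spike_times_ms: np.ndarray
    spike_ids: np.ndarray
    spike_pop: np.ndarray  # 0 = pyramidal, 1 = interneuron
    lfp: observables.LFPTraces
    thalamic_rate: RateTrace
    mean_U_interneuron: np.ndarray
    config: NetworkConfig
    noise: NoiseParams
    circuit: CircuitParameters
    coefficients: DerivedCoefficients
    seed: int
    traces: Optional[dict] = None

    def spikes_of(self, population: int) -> np.ndarray:
        return self.spike_times_ms[self.spike_pop == population]


def _empty_result(cfg, noise, circ, coef) -> SimulationResult:
    z = np.zeros(0)
    lfp = observables.LFPTraces(t_ms=z, L1=z, L2=z, L3=z, L4=z, mean_U=z,
                                fs_khz=1.0 / cfg.dt_ms)
    rate = RateTrace(t_ms=z, n=z, lam=z)
    return SimulationResult(
        t_ms=z, spike_times_ms=z, spike_ids=np.zeros(0, dtype=np.int64),
        spike_pop=np.zeros(0, dtype=np.int8), lfp=lfp, thalamic_rate=rate,
        mean_U_interneuron=z, config=cfg, noise=noise, circuit=circ,
        coefficients=coef, seed=cfg.seed, traces=None,
    )


def run_simulation(
    cfg: NetworkConfig,
    noise: NoiseParams | None = None,
    circ: CircuitParameters | None = None,
    coef: DerivedCoefficients | None = None,
    kinetics: dict | None = None,
    record_traces: bool = False,
    connectivity: Connectivity | None = None,
) -> SimulationResult:
    """Integrate the network and compute LFP measures online.

    Parameters derived from the default geometry/efficacy tables are used
    unless ``circ``/``coef`` are given.  With ``record_traces=True`` the
    per-pyramidal-neuron membrane potential and channel drives are kept as
    (T, K) arrays under ``result.traces`` (memory-heavy; intended for
    desk-scale runs).  LFP measures are always accumulated online, so
    full-scale runs need no per-neuron storage.
    """
    noise = noise or NoiseParams()
    if circ is None or coef is None:
        circ, coef = derive_parameters()
    if kinetics is None:
        kinetics = default_kinetics(cfg.tau_m_exc_ms, cfg.tau_m_inh_ms, cfg.tau_l_ms)
    for pop in kinetics.values():
        for k in pop.values():
            if abs(k.tau_l_ms - cfg.tau_l_ms) > 1e-12:
                raise ValueError("kinetics latency differs from network tau_L")

    K, L, N = cfg.n_pyramidal, cfg.n_interneurons, cfg.n_total
    dt = cfg.dt_ms
    n_steps = int(round(cfg.duration_ms / dt))

    ss = np.random.SeedSequence(cfg.seed)
    rng_conn, rng_ou, rng_thal_p, rng_thal_i, rng_init = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    if connectivity is None:
        connectivity = build_connectivity(cfg, rng_conn)

    if n_steps == 0:
        return _empty_result(cfg, noise, circ, coef)

    rate = generate_rate_trace(n_steps * dt, dt, noise, rng_ou)

    kp, ki = kinetics["pyramidal"], kinetics["interneuron"]
    st_p = {c: SynapticChannelState.zeros(K) for c in ("ampa_rec", "ampa_thal", "gaba")}
    st_i = {c: SynapticChannelState.zeros(L) for c in ("ampa_rec", "ampa_thal", "gaba")}
    prop_p = {c: decay_propagator(dt, kp[c]) for c in st_p}
    prop_i = {c: decay_propagator(dt, ki[c]) for c in st_i}

    U_p = np.full(K, cfg.reset_mv)
    U_i = np.full(L, cfg.reset_mv)
    if cfg.init_jitter:
        U_p += (cfg.theta_mv - cfg.reset_mv) * rng_init.random(K)
        U_i += (cfg.theta_mv - cfg.reset_mv) * rng_init.random(L)
    refr_p = np.full(K, -np.inf)
    refr_i = np.full(L, -np.inf)

    n_slots = cfg.latency_steps + 1
    q_exc = np.zeros((n_slots, N))
    q_inh = np.zeros((n_slots, N))
    q_thal = np.zeros((n_slots, N))

    L1 = np.empty(n_steps)
    L3 = np.empty(n_steps)
    mean_U = np.empty(n_steps)
    mean_U_int = np.empty(n_steps)
    spike_t, spike_id, spike_pop = [], [], []
    if record_traces:
        tr = {name: np.empty((n_steps, K)) for name in
              ("U", "I_ampa_rec", "I_ampa_thal", "I_gaba")}
    else:
        tr = None

    for s in range(n_steps):
        t = s * dt
        slot = s % n_slots

        # deliver events due now, then free the slot for this step's pushes
        st_p["ampa_rec"].x += q_exc[slot, :K] * kp["ampa_rec"].jump
        st_i["ampa_rec"].x += q_exc[slot, K:] * ki["ampa_rec"].jump
        st_p["gaba"].x += q_inh[slot, :K] * kp["gaba"].jump
        st_i["gaba"].x += q_inh[slot, K:] * ki["gaba"].jump
        st_p["ampa_thal"].x += q_thal[slot, :K] * kp["ampa_thal"].jump
        st_i["ampa_thal"].x += q_thal[slot, K:] * ki["ampa_thal"].jump
        q_exc[slot] = 0.0
        q_inh[slot] = 0.0
        q_thal[slot] = 0.0

        # thalamic Poisson counts for this bin, delivered after tau_L
        lam_dt = rate.lam[s] * dt
        if noise.shared_train:
            q_thal[slot, :K] += rng_thal_p.poisson(lam_dt)
            q_thal[slot, K:] += rng_thal_i.poisson(lam_dt)
        else:
            q_thal[slot, :K] += rng_thal_p.poisson(lam_dt, size=K)
            q_thal[slot, K:] += rng_thal_i.poisson(lam_dt, size=L)

        # drive held constant over the step (start-of-step channel values)
        drive_p = st_p["ampa_rec"].I + st_p["ampa_thal"].I - st_p["gaba"].I
        drive_i = st_i["ampa_rec"].I + st_i["ampa_thal"].I - st_i["gaba"].I

        for c, state in st_p.items():
            e_d, e_r, cc = prop_p[c]
            state.I *= e_d
            state.I += cc * state.x
            state.x *= e_r
        for c, state in st_i.items():
            e_d, e_r, cc = prop_i[c]
            state.I *= e_d
            state.I += cc * state.x
            state.x *= e_r

        spiked_p = lif_step(U_p, drive_p, refr_p, t, dt, cfg.tau_m_exc_ms,
                            cfg.theta_mv, cfg.reset_mv, cfg.tau_rp_exc_ms)
        spiked_i = lif_step(U_i, drive_i, refr_i, t, dt, cfg.tau_m_inh_ms,
                            cfg.theta_mv, cfg.reset_mv, cfg.tau_rp_inh_ms)

        if spiked_p.any():
            srcs = np.nonzero(spiked_p)[0]
            tgt = np.concatenate([connectivity.targets[i] for i in srcs])
            if tgt.size:
                q_exc[slot] += np.bincount(tgt, minlength=N)
            spike_t.append(np.full(srcs.size, t + dt))
            spike_id.append(srcs)
            spike_pop.append(np.zeros(srcs.size, dtype=np.int8))
        if spiked_i.any():
            srcs = np.nonzero(spiked_i)[0]
            tgt = np.concatenate([connectivity.targets[K + i] for i in srcs])
            if tgt.size:
                q_inh[slot] += np.bincount(tgt, minlength=N)
            spike_t.append(np.full(srcs.size, t + dt))
            spike_id.append(K + srcs)
            spike_pop.append(np.ones(srcs.size, dtype=np.int8))

        # end-of-step observables
        V_dip = observables.dfp(U_p, st_p["ampa_rec"].I, st_p["ampa_thal"].I,
                                st_p["gaba"].I, coef)
        V_mplb = observables.mplb_dfp(
            (st_p["ampa_rec"].I, st_p["ampa_thal"].I), st_p["gaba"].I)
        L1[s] = V_mplb.sum()
        L3[s] = V_dip.sum()
        mean_U[s] = U_p.mean()
        mean_U_int[s] = U_i.mean() if L else 0.0
        if tr is not None:
            tr["U"][s] = U_p
            tr["I_ampa_rec"][s] = st_p["ampa_rec"].I
            tr["I_ampa_thal"][s] = st_p["ampa_thal"].I
            tr["I_gaba"][s] = st_p["gaba"].I

    t_grid = dt * np.arange(1, n_steps + 1)
    lfp = observables.LFPTraces(
        t_ms=t_grid, L1=L1, L2=L1 / max(K, 1), L3=L3, L4=L3 / max(K, 1),
        mean_U=mean_U, fs_khz=1.0 / dt,
    )
    if spike_t:
        times = np.concatenate(spike_t)
        ids = np.concatenate(spike_id)
        pops = np.concatenate(spike_pop)
    else:
        times = np.zeros(0)
        ids = np.zeros(0, dtype=np.int64)
        pops = np.zeros(0, dtype=np.int8)
    return SimulationResult(
        t_ms=t_grid, spike_times_ms=times, spike_ids=ids, spike_pop=pops,
        lfp=lfp, thalamic_rate=rate, mean_U_interneuron=mean_U_int,
        config=cfg, noise=noise, circuit=circ, coefficients=coef,
        seed=cfg.seed, traces=tr,
    )


def instantaneous_rate(spike_times_ms, n_neurons: int, duration_ms: float,
                       bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Population rate trace: spikes per bin / (bin * population size), spikes/ms.

    Returns (bin centres in ms, rate).
    """
    if not bin_ms > 0:
        raise ValueError("bin width must be strictly positive")
    edges = np.arange(0.0, duration_ms + bin_ms * 0.5, bin_ms)
    counts, _ = np.histogram(spike_times_ms, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, counts / (bin_ms * max(n_neurons, 1))


def isi_minima(result: SimulationResult) -> dict[int, float]:
    """Smallest inter-spike interval per population (inf if fewer than 2 spikes)."""
    out = {}
    for pop in (PYRAMIDAL, INTERNEURON):
        mask = result.spike_pop == pop
        ids = result.spike_ids[mask]
        times = result.spike_times_ms[mask]
        best = np.inf
        for i in np.unique(ids):
            t = np.sort(times[ids == i])
            if t.size > 1:
                best = min(best, np.diff(t).min())
        out[pop] = best
    return out
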