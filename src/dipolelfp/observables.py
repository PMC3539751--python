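"""Observation models: dipole DFP, moduli-of-currents DFP, LFP measures, spectra.

Two single-cell field proxies are computed from the same network state:

* the dipole dendritic field potential (DFP) of the equivalent circuit,
  ``V = R_D * I_D`` — the potential drop the dendritic dipole current causes
  across the extracellular resistance.  In terms of the aggregated channel
  drives (I = w * E for aligned weights) it reads
  ``V = (wt_E/w_E) I_ampa + (wt_I/w_I) I_gaba + xi * U``; note both synapse
  types enter with positive weight even though they pull the membrane
  potential in opposite directions;
* the moduli proxy ``V_mplb = sum |I_exc| + sum |I_gaba|``, the ad hoc sum of
  absolute synaptic currents used as the comparison model.

Four population LFP measures follow: L1 = sum of moduli DFPs, L2 = L1/K,
L3 = sum of dipole DFPs, L4 = L3/K, plus the population-mean membrane
potential.  Spectra are averaged modified periodograms (Welch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .electrotonics import CircuitParameters, DerivedCoefficients


@dataclass
class MeshCurrents:
    """Dendritic (I_D), basal (I_B) and integrate-and-fire (I_IF) mesh currents in pA.

    Satisfies the node law I_IF = I_D - I_B pointwise by construction.
    """

    I_D: np.ndarray
    I_B: np.ndarray
    I_IF: np.ndarray


@dataclass
class LFPTraces:
    """Population LFP measures on a common time grid.

    L1/L2 (sum/average of moduli DFPs) are non-negative; L3/L4 (sum/average of
    dipole DFPs) are signed.  ``fs_khz`` is the sampling rate in kHz
    (samples per ms).
    """

    t_ms: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    L3: np.ndarray
    L4: np.ndarray
    mean_U: np.ndarray
    fs_khz: float

    def as_columns(self) -> dict[str, np.ndarray]:
        return {"L1": self.L1, "L2": self.L2, "L3": self.L3, "L4": self.L4,
                "mean_U": self.mean_U}


def _ratios(coef: DerivedCoefficients) -> tuple[float, float, float, float]:
    w_e_c = coef.r_gohm * coef.alpha_cortical_ns
    w_e_t = coef.r_gohm * coef.alpha_thalamic_ns
    if w_e_c == 0 or w_e_t == 0 or coef.w_inh == 0:
        raise ValueError("zero synaptic weight: DFP rescaling undefined")
    if coef.wt_exc_cortical is None or coef.wt_inh is None or coef.xi is None:
        raise ValueError("DFP weights not derived yet")
    return (
        coef.wt_exc_cortical / w_e_c,
        coef.wt_exc_thalamic / w_e_t,
        coef.wt_inh / coef.w_inh,
        coef.xi,
    )


def dfp(U, I_ampa_rec, I_ampa_thal, I_gaba, coef: DerivedCoefficients):
    """Dipole DFP per pyramidal neuron (mV) from aggregated channel drives.

    Exact rescaling of the linear kinetics: each channel drive I = w * E is
    multiplied by wt/w, plus the xi * U feedback term.  Linear in all inputs.
    """
    rc, rt, ri, xi = _ratios(coef)
    return (
        rc * np.asarray(I_ampa_rec)
        + rt * np.asarray(I_ampa_thal)
        + ri * np.asarray(I_gaba)
        + xi * np.asarray(U)
    )


def mplb_dfp(I_exc_channels, I_gaba, include_thalamic: bool = True):
    """Moduli DFP: sum of absolute excitatory and inhibitory channel drives.

    ``I_exc_channels`` is a sequence of excitatory channel arrays
    (recurrent AMPA first, thalamic AMPA second).  Aggregated channel drives
    are sign-definite for non-negative efficacies, so per-channel moduli equal
    moduli of per-synapse sums.
    """
    channels = list(I_exc_channels)
    if not include_thalamic and len(channels) > 1:
        channels = channels[:1]
    out = np.abs(np.asarray(I_gaba, dtype=float)).copy()
    for ch in channels:
        out += np.abs(np.asarray(ch, dtype=float))
    return out


def du_dt_from_state(U, I_ampa_rec, I_ampa_thal, I_gaba, tau_ms: float):
    """Membrane-potential derivative reconstructed from the dynamical law.

    dU/dt = (sum w_E E - sum w_I E_I - U)/tau = (I_exc - I_gaba - U)/tau,
    avoiding finite-differencing noise.
    """
    return (np.asarray(I_ampa_rec) + np.asarray(I_ampa_thal) - np.asarray(I_gaba)
            - np.asarray(U)) / tau_ms


def mesh_currents(U, I_ampa_rec, I_ampa_thal, I_gaba,
                  coef: DerivedCoefficients, circ: CircuitParameters,
                  dU_dt=None) -> MeshCurrents:
    """Mesh currents (pA) of the equivalent circuit from the network state.

    I_D = sum(alpha * E) - beta dU/dt - gamma U, with
    sum(alpha * E) = (I_ampa_rec + I_ampa_thal)/r for aligned weights
    (alpha = w/r); I_IF = C dU/dt + U/R_M; I_B = I_D - I_IF.  If ``dU_dt`` is
    not supplied it is reconstructed from the dynamical law.
    """
    if coef.beta_pf is None or coef.gamma_ns is None or coef.tau_ms is None:
        raise ValueError("coefficients incomplete: run the derivation pipeline first")
    if circ.C_pf is None:
        raise ValueError("capacitance not set")
    U = np.asarray(U, dtype=float)
    if dU_dt is None:
        dU_dt = du_dt_from_state(U, I_ampa_rec, I_ampa_thal, I_gaba, coef.tau_ms)
    alpha_E = (np.asarray(I_ampa_rec) + np.asarray(I_ampa_thal)) / coef.r_gohm
    I_D = alpha_E - coef.beta_pf * dU_dt - coef.gamma_ns * U
    I_IF = circ.C_pf * dU_dt + U / circ.R_M_gohm
    I_B = I_D - I_IF
    return MeshCurrents(I_D=I_D, I_B=I_B, I_IF=I_IF)


def dfp_from_mesh(mesh: MeshCurrents, circ: CircuitParameters) -> np.ndarray:
    """DFP via the circuit route, V = R_D * I_D (mV).

    Algebraically identical to :func:`dfp`; kept as an independent code path
    so the two implementations cross-check each other.
    """
    return circ.R_D_gohm * mesh.I_D


def lfp_measures(V_dipole, V_mplb, U, K: int, dt_ms: float,
                 t_ms=None) -> LFPTraces:
    """Population LFP measures from per-neuron traces of shape (T, K).

    L1 = sum_i V_mplb_i, L2 = L1/K, L3 = sum_i V_i, L4 = L3/K,
    mean_U = (1/K) sum_i U_i.
    """
    V_dipole = np.asarray(V_dipole)
    V_mplb = np.asarray(V_mplb)
    U = np.asarray(U)
    if not (V_dipole.shape == V_mplb.shape == U.shape):
        raise ValueError(
            f"trace grids differ: {V_dipole.shape}, {V_mplb.shape}, {U.shape}"
        )
    if V_dipole.ndim != 2 or V_dipole.shape[1] != K:
        raise ValueError(f"expected traces of shape (T, K={K}), got {V_dipole.shape}")
    L1 = V_mplb.sum(axis=1)
    L3 = V_dipole.sum(axis=1)
    if t_ms is None:
        t_ms = dt_ms * np.arange(1, V_dipole.shape[0] + 1)
    return LFPTraces(
        t_ms=np.asarray(t_ms), L1=L1, L2=L1 / K, L3=L3, L4=L3 / K,
        mean_U=U.mean(axis=1), fs_khz=1.0 / dt_ms,
    )


def power_spectrum(trace, fs_khz: float, segment_ms: float = 256.0,
                   overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of a population trace.

    Hann window, ``segment_ms`` segments with fractional ``overlap``, linear
    detrending.  Returns (frequency in Hz, PSD per Hz).  Frequencies run up to
    the Nyquist rate (5 kHz at dt = 0.1 ms).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(segment_ms * fs_khz))
    if trace.size < nperseg:
        raise ValueError(
            f"trace of {trace.size} samples shorter than one {nperseg}-sample segment"
        )
    fs_hz = fs_khz * 1000.0
    freq, psd = signal.welch(
        trace, fs=fs_hz, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend="linear",
    )
    return freq, psd


def spectral_slope(freq_hz, psd, f_min_hz: float = 100.0,
                   f_max_hz: float | None = None) -> float:
    """Log-log slope of the PSD over [f_min, f_max] by least squares."""
    freq_hz = np.asarray(freq_hz)
    psd = np.asarray(psd)
    if f_max_hz is None:
        f_max_hz = freq_hz.max()
    mask = (freq_hz >= f_min_hz) & (freq_hz <= f_max_hz) & (psd > 0)
    if mask.sum() < 3:
        raise ValueError("too few spectral points in the requested band")
    slope, _ = np.polyfit(np.log10(freq_hz[mask]), np.log10(psd[mask]), 1)
    return float(slope)
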