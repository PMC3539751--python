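"""Schema-validated run configuration.

A run is fully described by nested blocks — geometry, resistivities,
efficacies, kinetics, network, thalamic, alignment, observation — each backed
by a dataclass whose defaults are the reference parameter set (Erdos-Renyi
4000+1000 network, 18/11 mV threshold/reset, Table-style efficacies and
rise/decay times, OU-Poisson thalamic drive).  All physical quantities carry
unit suffixes in their key names (``tau_n_ms``, ``r_GOhm`` in reports, ...)
to prevent silent unit errors.  Unknown keys are rejected; an empty file
yields the full default configuration.  The YAML format is the single
supported config dialect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .electrotonics import (
    CircuitParameters,
    DerivedCoefficients,
    EfficacyTable,
    Geometry,
    Resistivities,
    derive_parameters,
)
from .network_sim import NetworkConfig
from .synapse_kinetics import KineticsParams
from .thalamic_input import NoiseParams


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class SynapticTimes:
    """Rise and decay times (ms) per channel; latency lives on the network block."""

    gaba_tau_r_ms: float = 0.25
    gaba_tau_d_ms: float = 5.0
    ampa_on_int_tau_r_ms: float = 0.2
    ampa_on_int_tau_d_ms: float = 1.0
    ampa_on_pyr_tau_r_ms: float = 0.4
    ampa_on_pyr_tau_d_ms: float = 2.0


@dataclass(frozen=True)
class AlignmentParams:
    """Knobs of the electrotonic alignment.

    ``n_thalamic_fibres`` only enters the effective excitatory synapse count
    p_eff = P*K + n_thalamic_fibres used for the total conductance g_E; the
    simulated thalamic drive itself is one aggregated input line per neuron.
    """

    tau_target_ms: float = 20.0
    n_thalamic_fibres: int = 800
    r_m_length: str = "membrane_thickness"


@dataclass(frozen=True)
class ObservationParams:
    """Spectral-analysis parameters.

    The high-frequency slope band tops out at 1 kHz: the dipole-DFP average
    and the mean membrane potential carry a population shot-noise floor from
    spike/reset transients that scales as 1/K and, for desk-scale populations
    (hundreds of cells), dominates their spectra above roughly 1 kHz, masking
    the synaptic/membrane roll-off the slope is meant to measure.  At the
    full 4000-cell scale the slope ordering is band-insensitive.
    """

    segment_ms: float = 256.0
    overlap: float = 0.5
    slope_f_min_hz: float = 100.0
    slope_f_max_hz: float = 1000.0
    include_thalamic_in_mplb: bool = True


@dataclass
class RunConfig:
    """Complete, self-describing configuration of one simulation run."""

    geometry: Geometry = field(default_factory=Geometry)
    resistivities: Resistivities = field(default_factory=Resistivities)
    efficacies: EfficacyTable = field(default_factory=EfficacyTable)
    kinetics: SynapticTimes = field(default_factory=SynapticTimes)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    thalamic: NoiseParams = field(default_factory=NoiseParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    observation: ObservationParams = field(default_factory=ObservationParams)

    def derive(self) -> tuple[CircuitParameters, DerivedCoefficients]:
        """Run the electrotonic derivation with in-degrees implied by the network."""
        net = self.network
        return derive_parameters(
            self.geometry,
            self.resistivities,
            self.efficacies,
            tau_target_ms=self.alignment.tau_target_ms,
            p_exc_cortical=net.connection_prob * net.n_pyramidal,
            p_exc_thalamic=float(self.alignment.n_thalamic_fibres),
            q_eff=net.connection_prob * net.n_interneurons,
            r_m_length=self.alignment.r_m_length,
        )

    def kinetics_table(self) -> dict[str, dict[str, KineticsParams]]:
        """Per-target-population channel kinetics built from the config blocks."""
        k, e, n = self.kinetics, self.efficacies, self.network
        return {
            "pyramidal": {
                "ampa_rec": KineticsParams(k.ampa_on_pyr_tau_r_ms, k.ampa_on_pyr_tau_d_ms,
                                           e.j_ampa_rec_on_pyr_mv, n.tau_m_exc_ms, n.tau_l_ms),
                "ampa_thal": KineticsParams(k.ampa_on_pyr_tau_r_ms, k.ampa_on_pyr_tau_d_ms,
                                            e.j_ampa_thal_on_pyr_mv, n.tau_m_exc_ms, n.tau_l_ms),
                "gaba": KineticsParams(k.gaba_tau_r_ms, k.gaba_tau_d_ms,
                                       e.j_gaba_on_pyr_mv, n.tau_m_exc_ms, n.tau_l_ms),
            },
            "interneuron": {
                "ampa_rec": KineticsParams(k.ampa_on_int_tau_r_ms, k.ampa_on_int_tau_d_ms,
                                           e.j_ampa_rec_on_int_mv, n.tau_m_inh_ms, n.tau_l_ms),
                "ampa_thal": KineticsParams(k.ampa_on_int_tau_r_ms, k.ampa_on_int_tau_d_ms,
                                            e.j_ampa_thal_on_int_mv, n.tau_m_inh_ms, n.tau_l_ms),
                "gaba": KineticsParams(k.gaba_tau_r_ms, k.gaba_tau_d_ms,
                                       e.j_gaba_on_int_mv, n.tau_m_inh_ms, n.tau_l_ms),
            },
        }

    def to_dict(self) -> dict:
        return {f.name: dataclasses.asdict(getattr(self, f.name)) for f in fields(self)}


def _build(cls, data: dict, block: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in block '{block}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid block '{block}': {exc}") from exc


_BLOCKS = {
    "geometry": Geometry,
    "resistivities": Resistivities,
    "efficacies": EfficacyTable,
    "kinetics": SynapticTimes,
    "network": NetworkConfig,
    "thalamic": NoiseParams,
    "alignment": AlignmentParams,
    "observation": ObservationParams,
}


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated RunConfig from a nested dict; missing blocks use defaults."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError(f"top level must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ConfigError(
            f"unknown top-level block(s): {sorted(unknown)}; allowed: {sorted(_BLOCKS)}"
        )
    kwargs = {
        name: _build(cls, data.get(name) or {}, name) for name, cls in _BLOCKS.items()
    }
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file (empty file -> full defaults)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)
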