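import dataclasses

import pytest

import dipolelfp as d


@pytest.fixture(scope="session")
def derived():
    """Default electrotonic derivation: (CircuitParameters, DerivedCoefficients)."""
    return d.derive_parameters()


@pytest.fixture(scope="session")
def desk_run():
    """Scale-0.1 network, 100 ms, with full per-neuron pyramidal traces."""
    cfg = d.make_fixture_network(0.1, seed=123)
    cfg.network.duration_ms = 100.0
    circ, coef = cfg.derive()
    result = d.run_simulation(
        cfg.network, noise=cfg.thalamic, circ=circ, coef=coef,
        kinetics=cfg.kinetics_table(), record_traces=True,
    )
    return cfg, result


def scaled_run(scale: float, duration_ms: float, seed: int, c0: float = 1.6,
               record_traces: bool = False):
    """One seeded run of the scaled reference network at baseline rate c0."""
    cfg = d.make_fixture_network(scale, seed=seed)
    cfg.network.duration_ms = duration_ms
    cfg.thalamic = dataclasses.replace(cfg.thalamic, c0=c0)
    return cfg, d.run_scenario(cfg, record_traces=record_traces)
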