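"""Scenario presets, fixture scaling and self-describing output bundles.

The reference protocol drives the full network (4000 pyramidal + 1000
interneurons) for 2 s with a constant thalamic signal at one of three rates,
1.2, 1.6 or 2.4 spikes/ms; the presets ``rate-1.2``/``rate-1.6``/``rate-2.4``
encode exactly that.  :func:`make_fixture_network` scales the populations down
for desk-scale test runs, leaving all other parameters untouched.

:func:`reproduce_scenario` chains derivation -> simulation -> observation and
writes a plain-text artifact bundle (spikes.tsv, rates.tsv, lfp.tsv, psd.tsv,
params.json, manifest.json) that is bitwise reproducible from the recorded
seed and resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_from_dict
from .electrotonics import coefficients_report
from .network_sim import (
    INTERNEURON,
    PYRAMIDAL,
    SimulationResult,
    instantaneous_rate,
    run_simulation,
)
from .observables import power_spectrum

PRESETS = {
    "rate-1.2": {"c0": 1.2},
    "rate-1.6": {"c0": 1.6},
    "rate-2.4": {"c0": 2.4},
}
_PRESET_DURATION_MS = 2000.0
_MIN_POP = 10


def scenario_config(preset: str, scale: float = 1.0, seed: int = 0) -> RunConfig:
    """RunConfig for a named preset, optionally population-scaled."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    cfg = make_fixture_network(scale, seed)
    cfg.thalamic = dataclasses.replace(cfg.thalamic, c0=PRESETS[preset]["c0"])
    cfg.thalamic.validate_preset_range()
    cfg.network.duration_ms = _PRESET_DURATION_MS
    return cfg


def make_fixture_network(scale: float = 1.0, seed: int = 0) -> RunConfig:
    """Default configuration with populations scaled by ``scale`` (floor 10 each).

    Only the population counts change; thresholds, kinetics, noise and
    electrotonics keep their reference values, so desk-scale fixtures probe
    the same parameter regime.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    cfg = config_from_dict({})
    cfg.network.n_pyramidal = max(_MIN_POP, int(round(scale * cfg.network.n_pyramidal)))
    cfg.network.n_interneurons = max(_MIN_POP, int(round(scale * cfg.network.n_interneurons)))
    cfg.network.seed = seed
    return cfg


def write_tsv(path: Path, columns: dict[str, np.ndarray]) -> None:
    """Write named columns as a tab-separated table with a header line."""
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n]) for n in names]) if names else np.zeros((0, 0))
    header = "\t".join(names)
    np.savetxt(path, data, delimiter="\t", header=header, comments="")


def read_tsv(path: Path) -> dict[str, np.ndarray]:
    """Read a table written by :func:`write_tsv` back into named columns."""
    with open(path) as fh:
        names = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.size == 0:
        return {n: np.zeros(0) for n in names}
    return {n: data[:, i] for i, n in enumerate(names)}


def run_scenario(cfg: RunConfig, record_traces: bool = False) -> SimulationResult:
    """Derive parameters and integrate the network for one configuration."""
    circ, coef = cfg.derive()
    return run_simulation(
        cfg.network,
        noise=cfg.thalamic,
        circ=circ,
        coef=coef,
        kinetics=cfg.kinetics_table(),
        record_traces=record_traces,
    )


def reproduce_scenario(
    preset: str,
    out_dir: str | Path,
    scale: float = 1.0,
    seed: int = 0,
    make_figure: bool = False,
) -> dict[str, Path]:
    """Run a preset end to end and write the artifact bundle.

    Files written: ``spikes.tsv`` (time_ms, neuron_id, population),
    ``rates.tsv`` (1 ms-binned population rates plus the thalamic rate),
    ``lfp.tsv`` (L1..L4 and mean membrane potential), ``psd.tsv`` (Welch
    spectra of each measure), ``params.json`` (resolved config and derived
    coefficients) and ``manifest.json`` (seed, version, preset).  Returns the
    path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scenario_config(preset, scale=scale, seed=seed)
    result = run_scenario(cfg)
    obs = cfg.observation

    paths = {}
    paths["spikes"] = out / "spikes.tsv"
    write_tsv(paths["spikes"], {
        "time_ms": result.spike_times_ms,
        "neuron_id": result.spike_ids.astype(float),
        "population": result.spike_pop.astype(float),
    })

    duration = cfg.network.duration_ms
    centres, rate_p = instantaneous_rate(result.spikes_of(PYRAMIDAL),
                                         cfg.network.n_pyramidal, duration)
    _, rate_i = instantaneous_rate(result.spikes_of(INTERNEURON),
                                   cfg.network.n_interneurons, duration)
    # thalamic rate decimated onto the 1 ms grid
    step = max(1, int(round(1.0 / cfg.network.dt_ms)))
    lam_1ms = result.thalamic_rate.lam[step - 1::step][: centres.size]
    paths["rates"] = out / "rates.tsv"
    write_tsv(paths["rates"], {
        "time_ms": centres,
        "rate_pyramidal_per_ms": rate_p,
        "rate_interneuron_per_ms": rate_i,
        "rate_thalamic_per_ms": lam_1ms,
    })

    paths["lfp"] = out / "lfp.tsv"
    write_tsv(paths["lfp"], {"time_ms": result.lfp.t_ms, **result.lfp.as_columns()})

    segment = min(obs.segment_ms, duration / 2.0)
    psd_cols: dict[str, np.ndarray] = {}
    for name, trace in result.lfp.as_columns().items():
        freq, psd = power_spectrum(trace, result.lfp.fs_khz, segment_ms=segment,
                                   overlap=obs.overlap)
        psd_cols.setdefault("freq_hz", freq)
        psd_cols[f"psd_{name}"] = psd
    paths["psd"] = out / "psd.tsv"
    write_tsv(paths["psd"], psd_cols)

    paths["params"] = out / "params.json"
    with open(paths["params"], "w") as fh:
        json.dump({
            "config": cfg.to_dict(),
            "derived": coefficients_report(result.circuit, result.coefficients),
        }, fh, indent=2)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump({
            "preset": preset,
            "scale": scale,
            "seed": seed,
            "version": __version__,
            "files": {k: p.name for k, p in paths.items() if k != "manifest"},
        }, fh, indent=2)

    if make_figure:
        paths["figure"] = out / "overview.png"
        _overview_figure(result, centres, rate_p, rate_i, lam_1ms, paths["figure"])
    return paths


def _overview_figure(result, centres, rate_p, rate_i, lam_1ms, path: Path) -> None:
    """Quick-look panels: thalamic rate, raster, binned rates, L1, L4."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(5, 1, figsize=(9, 11), sharex=True)
    axes[0].plot(centres, lam_1ms, lw=0.7, color="k")
    axes[0].set_ylabel("thalamic rate\n(spikes/ms)")
    mask = result.spike_pop == PYRAMIDAL
    show = result.spike_ids[mask] < 200
    axes[1].plot(result.spike_times_ms[mask][show],
                 result.spike_ids[mask][show], ".", ms=1.5, color="k")
    axes[1].set_ylabel("pyramidal\nneuron id")
    axes[2].plot(centres, rate_i, lw=0.7, color="tab:blue", label="interneurons")
    axes[2].plot(centres, rate_p, lw=0.7, color="tab:red", label="pyramidal")
    axes[2].set_ylabel("rate\n(spikes/ms/neuron)")
    axes[2].legend(frameon=False, fontsize=8)
    axes[3].plot(result.lfp.t_ms, result.lfp.L1, lw=0.5, color="tab:purple")
    axes[3].set_ylabel("L1 (mV)")
    axes[4].plot(result.lfp.t_ms, result.lfp.L4, lw=0.5, color="tab:green")
    axes[4].set_ylabel("L4 (mV)")
    axes[4].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
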