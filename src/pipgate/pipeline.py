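"""End-to-end report: simulate -> idealize -> dwell/NPo -> fits -> energetics.

``pipeline_report`` runs one representative pass through every analysis stage
with a single seed and returns one JSON-serializable document containing all
intermediate results, parameters and the package version.  The output is
deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import __version__, electro, experiments, synth
from .coloc import coloc_report
from .idealize import dwell_summary, idealize, npo_result
from .kinetics import (
    effective_hill_slope,
    mean_sojourn_times,
    sequential_open_scheme,
    stationary_open_probability,
)

__all__ = ["RunConfig", "pipeline_report"]


@dataclass
class RunConfig:
    """Run settings: seed, temperature and the unit conventions echoed to outputs."""

    seed: int = 0
    temperature: float = 295.15  # K
    units: dict = field(default_factory=lambda: {
        "concentration": "uM", "time": "ms", "current": "pA",
        "voltage": "mV", "temperature": "K"})
    verbosity: int = 0


def pipeline_report(config: RunConfig | None = None) -> dict:
    """Run every analysis stage once and assemble a single report document."""
    config = config or RunConfig()
    seed = config.seed
    report: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
    }

    # kinetics: worked sequential-open scheme
    scheme = sequential_open_scheme(0.001, 0.01, 0.0005, 0.005)
    L = 20.0
    sj = mean_sojourn_times(scheme, L)
    report["kinetics"] = {
        "scheme": "C<->O1<->O2 (0.001, 0.01, 0.0005, 0.005)",
        "L_uM": L,
        "stationary_po": stationary_open_probability(scheme, L),
        "mean_open_ms": sj.mean_open,
        "mean_closed_ms": sj.mean_closed,
        "effective_hill_slope": effective_hill_slope(scheme, L),
    }

    # simulate + idealize + activity statistics
    trace, truth = synth.simulate_patch(
        1, scheme, L, duration_ms=60_000.0, unit_current=0.5, noise_sd=0.05,
        filter_cutoff=1000.0, sampling_rate=4000.0, seed=seed)
    events = idealize(trace, unit_current=0.5, max_levels=1, baseline=0.0)
    summary = dwell_summary(events)
    act = npo_result(trace, unit_current=0.5, baseline=0.0)
    report["idealization"] = {
        "n_events": len(events),
        "NPo": act.NPo, "N": act.N, "Po": act.Po,
        "mean_open_ms": summary.mean_open, "mean_closed_ms": summary.mean_closed,
        "ground_truth_npo": truth.time_average_level(),
    }

    # curve fits on synthetic datasets
    report["hill_fit"] = experiments.hill_recovery(seed)
    report["ghk_fit"] = experiments.ghk_recovery(seed)
    report["rate_slope_fit"] = experiments.rate_slope_recovery(seed)

    # colocalization on a synthetic image pair
    pair = synth.make_image_pair(seed=seed)
    coloc = coloc_report(pair)
    report["colocalization"] = {**coloc.to_dict(),
                               "ground_truth": pair.ground_truth}

    # electrostatics
    well = electro.energy_from_kd(15.0, 293.15)
    enc = electro.encounter_time()
    report["electrostatics"] = {
        "kd_uM": well.Kd, "temperature_K": well.temperature,
        "delta_G_kcal_mol": well.delta_G,
        "enhancement_factor": electro.enhancement_factor(well),
        "encounter": dataclasses.asdict(enc),
    }
    return _to_plain(report)


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
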