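"""Configuration schema and the run-from-config entry point.

A run is described by a small YAML (or JSON) document:

.. code-block:: yaml

    protocol: epsp_inhibition_sweep   # which virtual experiment to run
    seed: 0                           # governs stochastic synapse placement
    output_dir: results/sweep
    params:                           # protocol-specific parameters
      mode: inhibition_proximal
      g_ampa: 5.0

Outputs are CSV tables plus a ``run.json`` sidecar embedding the fully
resolved configuration and package version, so any result directory can be
re-run exactly.  Simulations themselves are deterministic; the single seed
only affects synapse placement.

The protocol names double as the pipeline's command surface; the numbered
scripts under ``analysis/`` are thin drivers over the same functions.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .morphology import (
    MorphologyParams,
    build_octopus_morphology,
    surface_areas,
    write_swc,
)
from .protocols import (
    SweepSpec,
    calibrated_reference,
    reference_site,
    run_current_step,
    run_epsp_inhibition_sweep,
    run_ipsp_visibility,
    run_local_ipsc,
    run_transfer_impedance,
)
from .synapses import load_default_density_table, place_synapses, synapse_count_report

__all__ = ["RunConfig", "ConfigError", "load_config", "run_from_config", "PROTOCOLS"]


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass(frozen=True)
class RunConfig:
    protocol: str
    output_dir: str
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def resolved(self) -> dict[str, Any]:
        out = asdict(self)
        out["octosim_version"] = __version__
        return out


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config: top level must be a mapping")
    for key in ("protocol", "output_dir"):
        if key not in raw:
            raise ConfigError(f"config: missing required field {key!r}")
    protocol = raw["protocol"]
    if protocol not in PROTOCOLS:
        raise ConfigError(
            f"config.protocol: unknown protocol {protocol!r} "
            f"(choose from {sorted(PROTOCOLS)})"
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("config.seed: must be an integer")
    params = raw.get("params", {}) or {}
    if not isinstance(params, dict):
        raise ConfigError("config.params: must be a mapping")
    return RunConfig(protocol=protocol, output_dir=raw["output_dir"],
                     seed=seed, params=params)


# ---- protocol runners -----------------------------------------------------

def _run_anatomy(cfg: RunConfig, outdir: str) -> None:
    p = cfg.params
    morph = build_octopus_morphology(
        MorphologyParams(**p.get("morphology", {})) if p.get("morphology") else None
    )
    write_swc(morph, os.path.join(outdir, "morphology.swc"))
    table = load_default_density_table()
    areas = surface_areas(morph)
    report = synapse_count_report(table, areas)
    pd.DataFrame(
        [
            {
                "population": pop,
                "soma": report.soma_counts[pop],
                "dendrite": report.dendrite_counts[pop],
                "total": report.totals[pop],
            }
            for pop in report.totals
        ]
    ).to_csv(os.path.join(outdir, "synapse_counts.csv"), index=False)
    pop = place_synapses(
        morph, table, p.get("populations", ["SGN_total", "glycinergic"]),
        seed=cfg.seed, mode=p.get("mode", "expected"),
    )
    pop.to_frame().to_csv(os.path.join(outdir, "placements.csv"), index=False)
    summary = {
        "soma_area_um2": areas.soma_area,
        "dendrite_area_um2": areas.dendrite_area,
        "dendritic_fraction_pct": report.dendritic_fraction,
        "ia_fraction_of_sgn_pct": report.ia_fraction_of_sgn,
        "e_i_ratio_soma": report.e_i_ratio_soma,
        "e_i_ratio_dendrite": report.e_i_ratio_dendrite,
    }
    with open(os.path.join(outdir, "anatomy_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def _run_step(cfg: RunConfig, outdir: str) -> None:
    p = cfg.params
    rows = []
    for condition in p.get("conditions", ["control", "kv_hcn_block"]):
        model, rest = calibrated_reference(condition)
        res = run_current_step(
            model, rest,
            amplitude_pa=p.get("amplitude_pa", -200.0),
            duration=p.get("duration_ms", 200.0),
        )
        pd.DataFrame({"t_ms": res.times, "v_soma_mv": res.soma_trace}).to_csv(
            os.path.join(outdir, f"step_{condition}.csv"), index=False
        )
        rows.append(
            {"condition": condition, "delta_vm_mv": res.delta_vm,
             "r_n_mohm": res.r_n, "steady": res.steady}
        )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "step_summary.csv"), index=False)


def _run_ipsp(cfg: RunConfig, outdir: str) -> None:
    p = cfg.params
    df = run_ipsp_visibility(
        g_gly_grid=p.get("g_gly_grid", list(range(1, 11))),
    )
    df.to_csv(os.path.join(outdir, "ipsp_visibility.csv"), index=False)


def _run_ipsc(cfg: RunConfig, outdir: str) -> None:
    p = cfg.params
    df = run_local_ipsc(g_gly_grid=p.get("g_gly_grid", list(range(1, 11))))
    df.to_csv(os.path.join(outdir, "local_ipsc.csv"), index=False)


def _run_zt(cfg: RunConfig, outdir: str) -> None:
    rows = []
    for condition in cfg.params.get("conditions", ["control", "kv_hcn_block"]):
        model, rest = calibrated_reference(condition)
        source = reference_site(model.morphology, "distal")
        target = model.soma_location()
        zt = run_transfer_impedance(model, rest, source, target)
        rows.append({"condition": condition, "zt_mohm": zt})
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "transfer_impedance.csv"), index=False
    )


def _run_sweep(cfg: RunConfig, outdir: str) -> None:
    p = cfg.params
    spec = SweepSpec(
        mode=p.get("mode", "inhibition_proximal"),
        d_grid=tuple(p.get("d_grid", (0.0, 0.25, 0.5, 0.75, 1.0))),
        g_gly_grid=tuple(p.get("g_gly_grid", (1.0, 2.0, 4.0, 6.0, 8.0, 10.0))),
        g_ampa=p.get("g_ampa", 5.0),
    )
    model, rest = calibrated_reference("control")
    df = run_epsp_inhibition_sweep(model, rest, spec)
    df.to_csv(os.path.join(outdir, "sweep.csv"), index=False)


PROTOCOLS = {
    "anatomy_report": _run_anatomy,
    "current_step": _run_step,
    "ipsp_visibility": _run_ipsp,
    "local_ipsc": _run_ipsc,
    "transfer_impedance": _run_zt,
    "epsp_inhibition_sweep": _run_sweep,
}


def run_from_config(path: str) -> str:
    """Execute the protocol described by a config file; returns output dir.

    Deterministic for a fixed config and seed; the resolved configuration
    is embedded in ``run.json`` in the output directory.
    """
    cfg = load_config(path)
    outdir = cfg.output_dir
    os.makedirs(outdir, exist_ok=True)
    PROTOCOLS[cfg.protocol](cfg, outdir)
    with open(os.path.join(outdir, "run.json"), "w") as fh:
        json.dump(cfg.resolved(), fh, indent=2)
    return outdir
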