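"""End-to-end orchestration with config, provenance and machine-readable reports.

A run is described by a TOML config (stage list plus per-stage sections) and
a seed.  Stages execute in dependency order; every artifact is written with
a provenance header (package version, config hash, seed), and the run is
deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, biophys, ensemble_stats, mutscreen, network, structio, synthgen

log = logging.getLogger("dimerlink")

KNOWN_STAGES = ("simulate", "network", "stats", "screen", "fit")


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    outdir: Path = Path("dimerlink-run")
    network_params: network.NetworkParams = field(default_factory=network.NetworkParams)
    source: str = "A:6"
    target: str = "B:6"
    planted: synthgen.PlantedEnsembleSpec | None = None
    screen: dict = field(default_factory=dict)
    fits: list[str] = field(default_factory=lambda: ["decay", "dose_response", "melt", "exchange"])
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty stage list")
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.outdir = Path(self.outdir)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    np_raw = raw.get("network", {})
    params = network.NetworkParams(
        contact_cutoff=np_raw.get("cutoff", 4.5),
        occupancy_min=np_raw.get("occupancy_min", 0.75),
        sigma_k=np_raw.get("sigma_k", 3.0),
        weight_convention=np_raw.get("weight_convention", "literal_var_over_mean"),
        neighbor_exclusion=np_raw.get("neighbor_exclusion", 1),
    )
    sim = raw.get("simulate", {})
    planted = synthgen.PlantedEnsembleSpec(
        n_per_chain=sim.get("n_per_chain", 30),
        n_frames=sim.get("n_frames", 2000),
        seed=run.get("seed", 0),
        cv_low=sim.get("cv_low", 0.02),
        cv_high=sim.get("cv_high", 0.065),
    )
    return RunConfig(
        stages=run.get("stages", []),
        seed=run.get("seed", 0),
        outdir=run.get("outdir", "dimerlink-run"),
        network_params=params,
        source=np_raw.get("source", "A:6"),
        target=np_raw.get("target", "B:6"),
        planted=planted,
        screen=raw.get("screen", {}),
        fits=raw.get("fit", {}).get("kinds", ["decay", "dose_response", "melt", "exchange"]),
        log_level=run.get("log_level", "INFO"),
        raw=raw,
    )


def _provenance(config: RunConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash, "seed": config.seed}


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"provenance": _provenance(config), **payload}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(map(str, obj))
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; failures abort dependents, not the run."""
    logging.basicConfig(level=config.log_level)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "provenance": _provenance(config)}
    ens = truth = None
    net = None

    for stage in [s for s in KNOWN_STAGES if s in config.stages]:
        try:
            if stage == "simulate":
                spec = config.planted or synthgen.PlantedEnsembleSpec(seed=config.seed)
                ens, truth = synthgen.make_planted_ensemble(spec)
                structio.write_pdb(ens.topology, outdir / "topology.pdb")
                report["stages"]["simulate"] = {
                    "n_frames": ens.n_frames,
                    "planted_path": [f"{c}:{n}" for c, n in truth.path],
                    "expected_weight": truth.expected_weight,
                }
            elif stage == "network":
                if ens is None:
                    raise RuntimeError("network stage needs an ensemble (run simulate first)")
                net = network.build_network(ens, config.network_params)
                network.edge_betweenness(net)
                crit = network.critical_edges(net)
                path = network.shortest_path(net, config.source, config.target)
                network.to_graphml(net, outdir / "network.graphml")
                tbl = network.edge_table(net)
                with open(outdir / "edges.tsv", "w") as fh:
                    fh.write(f"# dimerlink {_provenance(config)}\n")
                    tbl.to_csv(fh, sep="\t", index=False)
                payload = {
                    "n_nodes": net.graph.number_of_nodes(),
                    "n_edges": net.graph.number_of_edges(),
                    "critical_edges": [[f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}"] for u, v in crit],
                    "interprotomer_edges": [
                        [f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}"]
                        for u, v in network.interprotomer_edges(net)
                    ],
                    "path": path.labels,
                    "path_weight": round(path.path_weight, 2),
                    "path_weight_full": path.path_weight,
                }
                if truth is not None:
                    payload["planted_path_recovered"] = (
                        path.nodes == truth.path or path.nodes == truth.path[::-1]
                    )
                _write_json(outdir / "network.json", payload, config)
                report["stages"]["network"] = payload
            elif stage == "stats":
                if ens is None:
                    raise RuntimeError("stats stage needs an ensemble")
                prof = ensemble_stats.rmsf(ens, source="planted")
                modes = ensemble_stats.pca_modes(ens, n_modes=5)
                with open(outdir / "rmsf.tsv", "w") as fh:
                    fh.write(f"# dimerlink {_provenance(config)}\n")
                    prof.to_frame().to_csv(fh, sep="\t", index=False)
                payload = {
                    "rmsf_mean": float(np.mean(list(prof.values.values()))),
                    "pca_eigenvalues": modes.eigenvalues.tolist(),
                    "pca_explained": modes.explained.tolist(),
                }
                _write_json(outdir / "stats.json", payload, config)
                report["stages"]["stats"] = payload
            elif stage == "screen":
                records, struth = synthgen.make_ddg_table(
                    n_positions=config.screen.get("n_positions", 50),
                    pass_positions=tuple(config.screen.get("pass_positions", (16, 18, 91, 135))),
                    seed=config.seed,
                )
                result = mutscreen.screen_destabilizing(records, struth["criteria"])
                mutscreen.write_ddg_table(records, outdir / "ddg_table.tsv")
                payload = {
                    "n_records": len(records),
                    "survivors": [r.label for r in result.survivors],
                    "surviving_positions": sorted(result.surviving_positions),
                }
                _write_json(outdir / "screen.json", payload, config)
                report["stages"]["screen"] = payload
            elif stage == "fit":
                fits = {}
                for i, kind in enumerate(config.fits):
                    series, ftruth = synthgen.make_curves(kind, seed=config.seed + i)
                    if kind == "decay":
                        fr = biophys.fit_diffusion(synthgen.to_decay_experiment(series))
                    elif kind == "dose_response":
                        fr = biophys.fit_ec50_4pl(series.x, series.y)
                    elif kind == "melt":
                        fr = biophys.melt_tm(series.x, series.y)
                    else:
                        fr = biophys.fit_dimer_kd(series.x, series.y)
                    fits[kind] = {"params": fr.params, "truth": ftruth["params"]}
                _write_json(outdir / "fits.json", fits, config)
                report["stages"]["fit"] = fits
        except Exception as exc:  # keep going; report the failure
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"error": str(exc)}
            if stage == "simulate":
                ens = truth = None
    _write_json(outdir / "report.json", report, config)
    return report
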