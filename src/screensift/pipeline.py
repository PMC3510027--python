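"""End-to-end pipeline orchestration with a config file and provenance.

A run configuration is a flat INI-style text file with one section per
stage; every CLI flag has a corresponding config key.  Example::

    [inputs]
    kinetics = sim/kinetics.csv
    protein = sim/protein.csv
    layout = sim/layout.csv
    manifest = sim/manifest.csv
    obo = onto/ontology.obo
    gaf = onto/annotations.gaf
    population = onto/population.txt
    library = onto/library.txt
    interactome = net/interactome.sif

    [params]
    alpha = 0.05
    min_level = 2
    max_intervening = 1

    [output]
    dir = runs/demo

Stages run in order activity -> call-hits -> enrich -> network; any
failure aborts the run with a stage-specific exit code and the failing
stage named.  A machine-readable manifest (input checksums, parameters,
package version, per-stage row counts) is written alongside the stage
outputs so a rerun with identical inputs is byte-comparable.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import sys
from pathlib import Path

logger = logging.getLogger(__name__)

#: distinct exit codes per failing stage
STAGE_EXIT_CODES = {
    "config": 1,
    "activity": 2,
    "call_hits": 3,
    "enrich": 4,
    "network": 5,
}

STAGES = ("activity", "call_hits", "enrich", "network")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> configparser.ConfigParser:
    cfg = configparser.ConfigParser()
    read = cfg.read(path)
    if not read:
        raise PipelineError("config", f"cannot read config file {path}")
    if "inputs" not in cfg or "output" not in cfg:
        raise PipelineError("config", "config needs [inputs] and [output] sections")
    return cfg


def run_pipeline(config_path) -> Path:
    """Run the full pipeline described by a config file; returns the run dir."""
    from screensift import plate, screen
    from screensift import ontology as onto
    from screensift import enrichment as enr
    from screensift import network as netmod

    cfg = load_config(config_path)
    inputs = cfg["inputs"]
    params = cfg["params"] if "params" in cfg else {}
    run_dir = Path(cfg["output"]["dir"])
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("screensift")
    root.addHandler(handler)

    manifest: dict = {"stages": {}, "parameters": dict(params), "inputs": {}}
    try:
        from screensift import __version__

        manifest["version"] = __version__
        for key, value in inputs.items():
            p = Path(value)
            if not p.exists():
                stage = _stage_for_input(key)
                raise PipelineError(stage, f"input {key} missing: {value}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

        # ---- stage: activity ----------------------------------------
        try:
            reads = plate.read_kinetic_csv(inputs["kinetics"])
            protein = plate.read_protein_csv(inputs["protein"])
            layouts = plate.read_layout_csv(inputs["layout"])
            activities = plate.quantify_plates(reads, protein, layouts)
            plate.write_activity_tsv(activities, run_dir / "activities.tsv")
            manifest["stages"]["activity"] = {"rows": len(activities)}
            logger.info("activity: %d wells quantified", len(activities))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("activity", str(exc)) from exc

        # ---- stage: call_hits ---------------------------------------
        try:
            import pandas as pd

            man = pd.read_csv(inputs["manifest"], dtype={"plate_id": str})
            model = screen.SuppressorScreen(activities, man)
            sd_override = params.get("sd_override")
            res = model.fit(
                sd_override=float(sd_override) if sd_override else None
            )
            res.write_tsv(run_dir / "screen_summary.tsv")
            manifest["stages"]["call_hits"] = {
                "rows": len(res.records),
                "hits": res.n_hits,
                "screen_sd": res.screen_sd,
                "cutoff": res.cutoff,
            }
            logger.info("call_hits: %d hits of %d pools", res.n_hits, len(res.records))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("call_hits", str(exc)) from exc

        # ---- stage: enrich ------------------------------------------
        try:
            dag = onto.parse_obo(inputs["obo"])
            annots = onto.parse_gaf(inputs["gaf"])
            population = _read_gene_list(inputs["population"])
            library = (
                _read_gene_list(inputs["library"]) if "library" in inputs else None
            )
            study = set(res.hits["gene_id"]) & population
            if not study:
                raise ValueError("no hit genes present in the population list")
            emodel = enr.ParentChildEnrichment(dag, annots)
            eres = emodel.fit(
                study,
                population,
                library=library,
                alpha=float(params.get("alpha", 0.05)),
                min_level=int(params.get("min_level", 2)),
            )
            eres.write_tsv(run_dir / "enrichment.tsv")
            eres.to_dot(run_dir / "enrichment.dot")
            manifest["stages"]["enrich"] = {
                "rows": len(eres.results),
                "kept": len(eres.kept),
            }
            logger.info("enrich: %d terms kept", len(eres.kept))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc

        # ---- stage: network -----------------------------------------
        try:
            g = netmod.read_interactome(inputs["interactome"])
            seeds = set(res.hits["gene_id"])
            mode = params.get("mode", "direct")
            if mode == "direct":
                net = netmod.direct_subnetwork(g, seeds)
            elif mode == "paths":
                net = netmod.shortest_path_network(
                    g, seeds, max_intervening=int(params.get("max_intervening", 1))
                )
            else:
                raise ValueError(f"unknown network mode {mode!r}")
            focus = params.get("focus")
            if focus:
                net = netmod.add_focus_node(net, g, focus)
            netmod.write_graphml(net, run_dir / "network.graphml")
            netmod.write_dot(net, run_dir / "network.dot")
            netmod.degree_report(net).to_csv(
                run_dir / "network_degrees.tsv", sep="\t", index=False
            )
            manifest["stages"]["network"] = {
                "nodes": net.graph.number_of_nodes(),
                "edges": net.graph.number_of_edges(),
            }
            logger.info("network: %d nodes", net.graph.number_of_nodes())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("network", str(exc)) from exc

        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return run_dir
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage_for_input(key: str) -> str:
    return {
        "kinetics": "activity",
        "protein": "activity",
        "layout": "activity",
        "manifest": "call_hits",
        "obo": "enrich",
        "gaf": "enrich",
        "population": "enrich",
        "library": "enrich",
        "interactome": "network",
    }.get(key, "config")


def _read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def main_run(config_path) -> int:
    """Run the pipeline, mapping failures to stage exit codes."""
    try:
        run_dir = run_pipeline(config_path)
    except PipelineError as exc:
        print(str(exc), file=sys.stderr)
        return exc.exit_code
    print(f"run complete: {run_dir}")
    return 0
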