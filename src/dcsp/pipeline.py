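"""End-to-end orchestration: simulate/load -> PAS -> screen -> response stats.

A run is driven by a YAML (or plain dict) configuration and writes
self-describing TSV stage outputs plus a ``manifest.json`` with the tool
version, a config hash, the seeds, per-file digests and per-stage record
counts.  Deterministic stages reproduce digest-identical outputs when rerun
with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import (Cohort, read_cohort, read_directed_network, read_drivers,
                   read_drug_response, read_drug_targets, read_functional_network,
                   read_gmt, write_cohort, write_drivers, write_drug_response,
                   write_drug_targets, write_edge_list, write_gmt)
from .errors import ConfigError
from .pas import PASConfig, pas_matrix
from .response import DEFAULT_FRACTIONS, correlate_table, permutation_specificity_test, rdr_curve
from .screen import ScreenConfig, screen
from .simulate import PlantedTriplet, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def _sim_config(block: dict) -> SimConfig:
    planted = [PlantedTriplet(**p) for p in block.pop("planted", [])]
    try:
        return SimConfig(planted=tuple(planted), **block)
    except TypeError as exc:
        raise ConfigError(f"invalid simulate block: {exc}") from exc


def _load_inputs(block: dict):
    required = ["expression", "labels", "gmt", "targets", "drivers",
                "directed", "functional"]
    for key in required:
        if key not in block:
            raise ConfigError(f"config field 'inputs.{key}' is missing")
    cohort = read_cohort(block["expression"], block["labels"])
    response = read_drug_response(block["response"]) if "response" in block else None
    return (cohort, read_gmt(block["gmt"]), read_drug_targets(block["targets"]),
            read_drivers(block["drivers"]), read_directed_network(block["directed"]),
            read_functional_network(block["functional"]), response)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order and return the output directory.

    The config needs either a ``simulate`` block or an ``inputs`` block naming
    the expression/labels/GMT/targets/drivers/network files.  Optional blocks
    ``pas``, ``screen``, ``correlate`` and ``permtest`` tune the stages; an
    ``rdr`` block (simulated runs only) generates a validation cohort and
    writes a rediscovery-rate table.  Partial failures leave the completed
    stage outputs plus a failure record in the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir") or "dcsp_run")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "dcsp", "version": __version__,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "config_sha256": hashlib.sha256(
                          json.dumps(config, sort_keys=True, default=str).encode()
                      ).hexdigest(),
                      "seed": config.get("seed", 0),
                      "stages": {}, "files": {}}

    def _record(name: str, path: Path, n: int) -> None:
        manifest["stages"][name] = {"rows": int(n), "output": path.name}
        manifest["files"][path.name] = _sha256(path)

    try:
        if "simulate" in config:
            sim_block = dict(config["simulate"])
            sim_block.setdefault("seed", config.get("seed", 0))
            sim = simulate_cohort(_sim_config(dict(sim_block)))
            cohort, pathways, targets = sim.cohort, sim.pathways, sim.drug_targets
            drivers, directed, functional = sim.drivers, sim.directed, sim.functional
            response = sim.response
            write_cohort(cohort, out / "expression.tsv", out / "labels.tsv")
            write_gmt(pathways, out / "pathways.gmt")
            write_drug_targets(targets, out / "drug_targets.tsv")
            write_drivers(drivers, out / "drivers.tsv")
            write_edge_list(directed, out / "directed_network.tsv")
            write_edge_list(functional, out / "functional_network.tsv")
            write_drug_response(response, out / "drug_response.tsv")
            sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            _record("simulate", out / "truth.tsv", len(sim.truth))
        elif "inputs" in config:
            cohort, pathways, targets, drivers, directed, functional, response = \
                _load_inputs(config["inputs"])
        else:
            raise ConfigError("config field 'simulate' or 'inputs' is required")

        pas_cfg = PASConfig(seed=config.get("seed", 0), **config.get("pas", {}))
        pas_table = pas_matrix(cohort, pathways, targets, drivers, directed,
                               functional, pas_cfg)
        pas_table.to_csv(out / "pas.tsv", sep="\t", index=False)
        _record("pas", out / "pas.tsv", len(pas_table))

        screen_cfg = ScreenConfig(**config.get("screen", {}))
        dcsp_table = screen(pas_table, screen_cfg)
        dcsp_table.to_csv(out / "dcsp.tsv", sep="\t", index=False)
        _record("screen", out / "dcsp.tsv", len(dcsp_table))

        if response is not None:
            cor_cfg = config.get("correlate", {})
            cor = correlate_table(pas_table, response,
                                  direction=cor_cfg.get("direction", "upstream"),
                                  positive_only=cor_cfg.get("positive_only", True))
            cor.to_csv(out / "correlations.tsv", sep="\t", index=False)
            _record("correlate", out / "correlations.tsv", len(cor))

            if "rdr" in config and "simulate" in config:
                rdr_block = config["rdr"]
                val_block = dict(config["simulate"])
                val_block["seed"] = rdr_block.get(
                    "validation_seed", int(config.get("seed", 0)) + 10_000)
                val = simulate_cohort(_sim_config(dict(val_block)))
                val_pas = pas_matrix(val.cohort, val.pathways, val.drug_targets,
                                     val.drivers, val.directed, val.functional, pas_cfg)
                val_cor = correlate_table(val_pas, val.response,
                                          direction=cor_cfg.get("direction", "upstream"))
                curve = rdr_curve(cor, val_cor,
                                  alpha=rdr_block.get("alpha", 0.05),
                                  sign=rdr_block.get("sign", "negative"),
                                  fractions=rdr_block.get("fractions", DEFAULT_FRACTIONS))
                rdr_df = pd.DataFrame({"fraction": curve.fractions, "rdr": curve.rdr,
                                       "alpha": curve.alpha, "sign": curve.sign,
                                       "n_records": curve.n_records})
                rdr_df.to_csv(out / "rdr.tsv", sep="\t", index=False)
                _record("rdr", out / "rdr.tsv", len(rdr_df))

        if config.get("permtest") and not dcsp_table.empty:
            pt_cfg = config["permtest"]
            hits = dcsp_table[dcsp_table["is_dcsp"]]
            top = (hits if not hits.empty else dcsp_table).sort_values("T1",
                                                                       ascending=False).iloc[0]
            rows = []
            for comparison in pt_cfg.get("comparisons", ["Dbar_P", "D_Pbar", "Dbar_Pbar"]):
                res = permutation_specificity_test(
                    pas_table, top["drug"], top["pathway"], comparison=comparison,
                    n_perm=pt_cfg.get("n_perm", 10_000),
                    seed=config.get("seed", 0), cancer=top["cancer"])
                rows.append({"drug": top["drug"], "pathway": top["pathway"],
                             "cancer": top["cancer"], **asdict(res)})
            pt_df = pd.DataFrame(rows)
            pt_df.to_csv(out / "permtest.tsv", sep="\t", index=False)
            _record("permtest", out / "permtest.tsv", len(pt_df))
    except Exception as exc:  # record the failure, keep completed outputs
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
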