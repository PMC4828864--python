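"""End-to-end orchestration: scan -> filter -> score -> rank (+ variability, imaging).

A run is driven by one YAML/dict config; every stage is a pure function of
its inputs and the config, so re-running with an identical config reproduces
byte-identical outputs. A JSON manifest records the config hash, package
version and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .ontology import apply_filter, read_annotations
from .panel import read_panel
from .scan import find_fixed_substitutions, write_substitutions
from .scoring import (
    FROZEN_BLOSUM100_CALIBRATION,
    ProteinScore,
    derive_weights,
    load_matrix,
    rank_proteins,
    score_protein,
)
from .variability import cluster_summary, count_per_gene, read_variants, write_summary

log = logging.getLogger("humspec")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "consensus_mode": "unanimous",
    "matrix": "BLOSUM100",
    "rank_key": "weighted_per_length",
    "single_cell_area": 150,
    "min_area": 100,
    "cutoff_cells": [10, 30],
    "weight_range": [3, 15],
    "ignore_case": False,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order; return the manifest.

    Stage outputs land as TSVs under ``out_dir``; partial outputs of a
    failed run are retained. Stage names: ``scan``, ``filter``, ``score``,
    ``variability``.
    """
    cfg = {**DEFAULTS, **dict(config)}
    stages = cfg.get("stages", {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "stages": {},
    }

    per_protein: dict[str, list] = {}
    lengths: dict[str, int] = {}

    if stages.get("scan"):
        try:
            panel_dir = Path(cfg["panel_dir"])
            fastas = sorted(panel_dir.glob("*.fasta")) + sorted(panel_dir.glob("*.fa"))
            if not fastas:
                raise FileNotFoundError(f"no FASTA panels under {panel_dir}")
            for fp in fastas:
                panel = read_panel(fp)
                per_protein[panel.protein_id] = find_fixed_substitutions(
                    panel, cfg["consensus_mode"]
                )
                lengths[panel.protein_id] = len(panel.human_seqs[0].replace("-", ""))
            write_substitutions(per_protein, out_dir / "substitutions.tsv")
        except Exception as e:  # noqa: BLE001 — re-raised with stage name
            raise StageError("scan", str(e)) from e
        n_subs = sum(len(v) for v in per_protein.values())
        log.info("scan: %d proteins, %d fixed substitutions", len(per_protein), n_subs)
        manifest["stages"]["scan"] = {"proteins": len(per_protein), "substitutions": n_subs}

    selected = None
    if stages.get("filter"):
        try:
            records = read_annotations(cfg["annotations"])
            counts = {pid: len(subs) for pid, subs in per_protein.items()}
            summary = apply_filter(records, counts, cfg["ignore_case"])
            selected = summary.selected
            pd.DataFrame({"protein": sorted(selected)}).to_csv(
                out_dir / "selected_proteins.tsv", sep="\t", index=False
            )
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("filter", str(e)) from e
        log.info(
            "filter: %d records -> %d selected (%d with substitutions)",
            len(records), summary.n_selected, summary.n_with_substitution,
        )
        manifest["stages"]["filter"] = {
            "records": len(records),
            "selected": summary.n_selected,
            "with_substitution": summary.n_with_substitution,
        }

    if stages.get("score"):
        try:
            matrix = load_matrix(cfg["matrix"])
            calibration = (
                tuple(FROZEN_BLOSUM100_CALIBRATION)
                if matrix.name.upper() == "BLOSUM100"
                else None
            )
            weights = derive_weights(matrix, calibration)
            universe = selected if selected is not None else set(per_protein)
            scores = [
                score_protein(pid, per_protein.get(pid, []), lengths[pid], weights)
                for pid in sorted(universe)
                if pid in lengths
            ]
            ranked = rank_proteins(scores, cfg["rank_key"])
            ranked.to_csv(out_dir / "ranking.tsv", sep="\t", index=False)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("score", str(e)) from e
        log.info("score: ranked %d proteins by %s", len(ranked), cfg["rank_key"])
        manifest["stages"]["score"] = {"ranked": len(ranked), "key": cfg["rank_key"]}

    if stages.get("variability"):
        try:
            variants = read_variants(cfg["variants"])
            counts = count_per_gene(variants, cfg.get("distinct_positions", False))
            subs_map = pd.read_csv(cfg["lineage_subs"], sep="\t")
            lineage = dict(zip(subs_map["gene"], subs_map["n_subst"]))
            summary = cluster_summary(counts, lineage, cfg.get("focal"))
            write_summary(summary, out_dir / "variability.tsv")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("variability", str(e)) from e
        log.info("variability: %d genes, median %.1f", len(counts), summary.median)
        manifest["stages"]["variability"] = {
            "genes": len(counts),
            "median": summary.median,
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
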