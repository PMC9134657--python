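"""End-to-end orchestration: synth → build-library → observe → simulate →
rank → compare, with a run manifest for reproducibility.

The pipeline is driven by one flat config mapping (YAML on disk). Every
stage writes under the run's output directory; a JSON manifest recording
the config snapshot, seeds, input checksums, per-stage row counts and the
package version is written atomically at the end. Re-running the same
config and seed reproduces all outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .library import ExonLibrary, build_library
from .observed import filter_observed, parse_maf, write_observed
from .omics import OmicsMatrix, compare_sets, write_comparison
from .ranking import compute_ratios, log_ratio_distribution, select_tails, write_ranking
from .simulate import (BMRConfig, SimulationConfig, fold_indel_rate,
                       simulate_replicates)
from .synthetic import (SyntheticTruth, benchmark_truth, generate_cohort,
                        generate_genome, generate_omics)

log = logging.getLogger(__name__)

STAGES = ("synth", "build-library", "observe", "simulate", "rank", "compare")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "bmr": None,  # None -> published TCGA-OV rates
    "rate_scale": 1.0,
    "indel_mode": "add",
    "n_patients": 316,
    "n_replicates": 100,
    "k": 50,
    "barcode_prefix": None,
    "synth": None,  # set to a mapping to generate inputs
    "genome": None, "genes": None, "probes": None, "maf": None,
    "expression": None, "methylation": None, "site_map": None,
    "copy_number": None,
}

DEFAULT_SYNTH: dict[str, Any] = {
    "n_genes": 1000,
    "exons_per_gene": 2,
    "exon_length_min": 300,
    "exon_length_max": 700,
    "gc_fraction": 0.4,
    "cpg_enrichment": 2.0,
    "probe_fraction": 1.0,
    "cohort_patients": 300,
    "n_low": 20, "n_high": 20, "s_low": 0.1, "s_high": 10.0,
    "omics_samples": 300,
    "expression_delta": 1.0,
    "methylation_delta": -0.2,
    "copy_number_delta": 0.5,
}

# study-design preset: 316 patients x 100 replicates at published rates,
# selection and omics shifts planted as in the benchmark
STUDY_OVERRIDES: dict[str, Any] = {
    "n_patients": 316,
    "n_replicates": 100,
    "rate_scale": 1.0,
    "synth": {"cohort_patients": 316},
}


def load_config(path: str | Path | None, overrides: dict[str, Any] | None = None
                ) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    if cfg["synth"] is not None:
        synth = dict(DEFAULT_SYNTH)
        if isinstance(cfg["synth"], dict):
            synth.update(cfg["synth"])
        cfg["synth"] = synth
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _bmr(cfg: dict[str, Any]) -> BMRConfig:
    bmr = BMRConfig.tcga_ov() if cfg["bmr"] is None else BMRConfig(**cfg["bmr"])
    return bmr.scaled(float(cfg.get("rate_scale", 1.0)))


def run_pipeline(config: dict[str, Any] | str | Path, outdir: str | Path,
                 from_stage: str | None = None) -> dict[str, Any]:
    """Execute all stages in order; returns the manifest mapping.

    ``from_stage`` resumes at a named stage, reusing earlier outputs found
    in ``outdir``. Any stage failure leaves an ``.incomplete`` marker next
    to the partial outputs and re-raises with the stage name.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else load_config(None, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    marker.write_text("run in progress\n")
    start = STAGES.index(from_stage) if from_stage else 0
    manifest: dict[str, Any] = {
        "version": __version__, "config": _jsonable(cfg), "stages": {},
        "input_checksums": {},
    }
    try:
        _run_stages(cfg, outdir, start, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage "
                           f"{manifest.get('failed_stage', '?')}: {exc}") from exc
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, outdir / "manifest.json")
    marker.unlink(missing_ok=True)
    return manifest


def _run_stages(cfg, outdir: Path, start: int, manifest: dict) -> None:
    seed = int(cfg["seed"])
    bmr = _bmr(cfg)
    rates = fold_indel_rate(bmr, mode=cfg.get("indel_mode", "add"))

    # --- synth -----------------------------------------------------------
    stage = "synth"
    manifest["failed_stage"] = stage
    synth_cfg = cfg["synth"]
    if synth_cfg is not None and STAGES.index(stage) >= start:
        sdir = outdir / "synth"
        files = generate_genome(
            sdir, n_genes=synth_cfg["n_genes"],
            exons_per_gene=synth_cfg["exons_per_gene"],
            exon_length_range=(synth_cfg["exon_length_min"],
                               synth_cfg["exon_length_max"]),
            gc_fraction=synth_cfg["gc_fraction"],
            cpg_enrichment=synth_cfg["cpg_enrichment"],
            probe_fraction=synth_cfg["probe_fraction"], seed=seed)
        cfg["genome"], cfg["genes"], cfg["probes"] = map(str, (files.fasta, files.gtf,
                                                               files.probes))
        manifest["stages"][stage] = {"n_genes": synth_cfg["n_genes"]}

    # --- build-library ---------------------------------------------------
    stage = "build-library"
    manifest["failed_stage"] = stage
    libdir = outdir / "library"
    if STAGES.index(stage) >= start or not (libdir / "manifest.tsv").exists():
        lib = build_library(cfg["genome"], cfg["genes"], cfg["probes"])
        lib.save(libdir)
    else:
        lib = ExonLibrary.load(libdir)
    for key in ("genome", "genes", "probes"):
        if cfg[key]:
            manifest["input_checksums"][key] = _sha256(cfg[key])
    manifest["stages"][stage] = {"genes": len(lib.genes),
                                 "total_bases": lib.total_bases}

    # synth cohort + omics need the library, so they run here
    if synth_cfg is not None and STAGES.index("synth") >= start:
        truth = benchmark_truth(lib.genes, n_low=synth_cfg["n_low"],
                                n_high=synth_cfg["n_high"],
                                s_low=synth_cfg["s_low"],
                                s_high=synth_cfg["s_high"], seed=seed)
        truth.expression_delta = synth_cfg["expression_delta"]
        truth.methylation_delta = synth_cfg["methylation_delta"]
        truth.copy_number_delta = synth_cfg["copy_number_delta"]
        truth.save(outdir / "synth" / "truth.tsv")
        maf = outdir / "synth" / "cohort.maf"
        ledger = generate_cohort(lib, rates, truth,
                                 n_patients=synth_cfg["cohort_patients"],
                                 out_maf=maf, seed=seed)
        cfg["maf"] = str(maf)
        omics_paths = generate_omics(
            lib.genes, truth.nonmutated_set, truth.mutated_set,
            outdir / "synth" / "omics", n_samples=synth_cfg["omics_samples"],
            expression_delta=synth_cfg["expression_delta"],
            methylation_delta=synth_cfg["methylation_delta"],
            copy_number_delta=synth_cfg["copy_number_delta"], seed=seed)
        cfg["expression"] = str(omics_paths["expression"])
        cfg["methylation"] = str(omics_paths["methylation"])
        cfg["site_map"] = str(omics_paths["site_map"])
        cfg["copy_number"] = str(omics_paths["copy_number"])
        manifest["stages"]["synth"]["maf_records"] = ledger["__n_records__"]

    # --- observe ---------------------------------------------------------
    stage = "observe"
    manifest["failed_stage"] = stage
    cohort = parse_maf(cfg["maf"], barcode_prefix=cfg.get("barcode_prefix"))
    observed = filter_observed(cohort, library_genes=lib.genes)
    write_observed(observed, outdir / "observed.tsv")
    manifest["input_checksums"]["maf"] = _sha256(cfg["maf"])
    manifest["stages"][stage] = {"n_patients": cohort.n_patients,
                                 "records": cohort.n_records,
                                 "genes_retained": len(observed.genes)}

    # --- simulate --------------------------------------------------------
    stage = "simulate"
    manifest["failed_stage"] = stage
    sim_cfg = SimulationConfig(n_patients=int(cfg["n_patients"]),
                               n_replicates=int(cfg["n_replicates"]), seed=seed)
    sim = simulate_replicates(lib, rates, sim_cfg)
    sim.save(outdir / "sim")
    manifest["stages"][stage] = {"total_runs": sim.total_runs,
                                 "n_replicates": sim_cfg.n_replicates}

    # --- rank ------------------------------------------------------------
    stage = "rank"
    manifest["failed_stage"] = stage
    table = compute_ratios(observed, sim)
    k = int(cfg["k"])
    tails = select_tails(table, k)
    hist = log_ratio_distribution(table, tails=tails)
    write_ranking(table, tails, outdir / "ranks", hist=hist)
    manifest["stages"][stage] = {"genes_ranked": len(table), "k": tails.k,
                                 "clamped": tails.k != k}

    # --- compare ---------------------------------------------------------
    stage = "compare"
    manifest["failed_stage"] = stage
    cmp_info = {}
    cdir = outdir / "compare"
    specs = [("expression", cfg.get("expression"), "expression_RMA", None),
             ("methylation", cfg.get("methylation"), "methylation_beta",
              cfg.get("site_map")),
             ("copy_number", cfg.get("copy_number"), "copy_number", None)]
    for label, path, kind, site_map in specs:
        if not path:
            continue
        matrix = OmicsMatrix.read(path, kind, site_map_path=site_map)
        cmp = compare_sets(matrix, tails.nonmutated, tails.mutated)
        write_comparison(cmp, cdir, label)
        cmp_info[label] = {"D": cmp.ks.D, "p_value": cmp.ks.p_value,
                           "direction": cmp.direction}
        manifest["input_checksums"][label] = _sha256(path)
    manifest["stages"][stage] = cmp_info
    manifest.pop("failed_stage", None)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return "<table>"
    return obj
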