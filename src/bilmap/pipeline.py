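"""End-to-end pipeline: simulate or load inputs, then call segments, build
bins and the genetic map, normalize metabolites, scan for QTLs, and write a
JSON report plus a run manifest.

All stage outputs are deterministic for a fixed seed; the manifest records
the configuration snapshot, input checksums, seed, package version and
per-stage wall times (wall times are the only non-reproducible field, and
they live in the manifest only, never in the report or the data tables).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .bins import bin_genotype_matrix, bin_summary, bins_frame, build_bins
from .genmap import build_map
from .io import (
    read_chromosome_lengths,
    read_genotypes,
    read_marker_map,
    read_phenotypes,
    write_chromosome_lengths,
    write_genotypes,
    write_marker_map,
)
from .metabolites import fold_range, heatmap_matrix, normalize_to_control
from .qtl import ScanConfig, anova_scan, conserved_qtls, hk_scan
from .segments import call_all_segments, segments_frame, summarize_population
from .sim import PlantedQtl, SimulationConfig, simulate_phenotypes, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    block = dict(block)
    qtls = tuple(
        PlantedQtl(
            trait_id=str(q["trait"]),
            marker_id=str(q["marker"]),
            additive=float(q["additive"]),
            dominance=float(q.get("dominance", 0.0)),
        )
        for q in block.pop("planted_qtls", [])
    )
    block.pop("seed", None)
    return SimulationConfig(seed=seed, planted_qtls=qtls, **block)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, *, seed: int | None = None) -> dict:
    """Run every stage described by ``config`` and write results to ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    control_line = str(config.get("control_line", "RP"))
    stage_times: dict[str, float] = {}
    report: dict[str, Any] = {"seed": seed}
    manifest: dict[str, Any] = {
        "tool": "bilmap",
        "version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(dict(config), default=str)),
    }

    def _stage(name: str):
        logger.info("stage %s: start", name)
        return time.perf_counter(), name

    def _done(token: tuple[float, str]) -> None:
        t0, name = token
        stage_times[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, stage_times[name])

    # ---- inputs -----------------------------------------------------------
    experiments: dict[str, pd.DataFrame] = {}
    if "simulate" in config:
        tok = _stage("simulate")
        sim_cfg = _sim_config(config["simulate"], seed)
        sim = simulate_population(sim_cfg)
        genotypes = sim.genotypes
        marker_map = sim.marker_map
        chrom_table = sim.chromosome_table
        phen = simulate_phenotypes(sim.genotypes, sim_cfg, seed=seed + 1)
        if len(phen):
            experiments["homozygous"] = phen
        else:
            logger.info("no planted QTLs: phenotype stages will be skipped")
        genotype_sets = {"homozygous": genotypes}
        if sim.hybrid_genotypes is not None and experiments:
            hyb = sim.hybrid_genotypes.copy()
            hyb.index = [i.replace("xRP", "") for i in hyb.index]
            genotype_sets["hybrid"] = hyb
            experiments["hybrid"] = simulate_phenotypes(hyb, sim_cfg, seed=seed + 2)
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_marker_map(marker_map, out / "marker_map.tsv")
        write_chromosome_lengths(chrom_table, out / "chrom_lengths.tsv")
        for name, p in experiments.items():
            p.to_csv(out / f"phenotypes_{name}.tsv", sep="\t", index=False)
        _done(tok)
    else:
        tok = _stage("load")
        inputs = config["inputs"]
        marker_map = read_marker_map(inputs["marker_map"])
        chrom_table = read_chromosome_lengths(inputs["chrom_lengths"])
        genotypes = read_genotypes(
            inputs["genotypes"], marker_map, recode=config.get("recode")
        )
        genotype_sets = {"homozygous": genotypes}
        phen_paths = inputs.get("phenotypes", {})
        if isinstance(phen_paths, (str, Path)):
            phen_paths = {"exp1": phen_paths}
        for name, p in dict(phen_paths).items():
            experiments[name] = read_phenotypes(p, layout=config.get("phenotype_layout", "long"))
        manifest["input_checksums"] = {
            k: _sha256(Path(v))
            for k, v in {**{k: v for k, v in inputs.items() if isinstance(v, (str, Path))}}.items()
        }
        _done(tok)

    n_lines = len(genotypes)
    logger.info("inputs: %d lines, %d markers, %d experiments", n_lines, marker_map.n_markers, len(experiments))

    # ---- introgression calling -------------------------------------------
    tok = _stage("call-introgressions")
    segments = call_all_segments(genotypes, marker_map, chrom_table)
    segments_frame(segments).to_csv(out / "segments.tsv", sep="\t", index=False)
    pop = summarize_population(segments, n_lines, chrom_table)
    report["population"] = pop.to_dict()
    _done(tok)

    # ---- bins -------------------------------------------------------------
    tok = _stage("build-bins")
    bins = build_bins(genotypes, marker_map, chrom_table)
    bins_frame(bins).to_csv(out / "bins.tsv", sep="\t", index=False)
    bg = bin_genotype_matrix(bins, genotypes.index)
    bg.to_csv(out / "bin_genotypes.tsv", sep="\t", index_label="line_id")
    bs = bin_summary(bins)
    report["bins"] = {
        "n_bins": bs.n_bins,
        "mean_length_bp": bs.mean_length_bp,
        "mean_snps_per_bin": bs.mean_snps_per_bin,
    }
    _done(tok)

    # ---- genetic map ------------------------------------------------------
    tok = _stage("build-map")
    map_cfg = dict(config.get("map", {}))
    gmap = build_map(
        bg,
        bins,
        map_function=map_cfg.get("map_function", "haldane"),
        rf_correction=map_cfg.get("rf_correction"),
        design=tuple(map_cfg.get("design", (3, 10))),
    )
    gmap.to_frame().to_csv(out / "map.tsv", sep="\t", index=False)
    report["map"] = {
        "total_length_cm": gmap.total_length_cm,
        "n_groups": gmap.n_groups,
        "map_function": gmap.map_function,
    }
    _done(tok)

    # ---- metabolite normalization ----------------------------------------
    tok = _stage("normalize")
    report["metabolites"] = {}
    for name, phen in experiments.items():
        if control_line not in set(phen["line_id"]):
            logger.warning("experiment %s: control line %r absent; skipping normalization", name, control_line)
            continue
        fc = normalize_to_control(phen, control_line)
        fc.values.to_csv(out / f"fold_changes_{name}.tsv", sep="\t", index_label="line_id")
        complete = fc.values.dropna(axis=1, how="any").dropna(axis=0, how="any")
        log2 = heatmap_matrix(type(fc)(values=complete, control_line_id=fc.control_line_id))
        log2.to_csv(out / f"log2_matrix_{name}.tsv", sep="\t", index_label="line_id")
        lo, hi = fold_range(fc)
        report["metabolites"][name] = {"min_fold": lo, "max_fold": hi}
    _done(tok)

    # ---- QTL scan ---------------------------------------------------------
    tok = _stage("scan")
    scan_block = dict(config.get("scan", {}))
    method = scan_block.pop("method", "anova")
    scan_cfg = ScanConfig(seed=seed, **scan_block)
    all_qtls = []
    for name, phen in experiments.items():
        geno_set = genotype_sets.get(name, genotypes)
        bins_e = build_bins(geno_set, marker_map, chrom_table) if geno_set is not genotypes else bins
        bg_e = bin_genotype_matrix(bins_e, geno_set.index) if geno_set is not genotypes else bg
        if method == "hk":
            gmap_e = build_map(bg_e, bins_e, map_function=gmap.map_function) if geno_set is not genotypes else gmap
            res = hk_scan(phen, bg_e, gmap_e, bins_e, scan_cfg, experiment_id=name)
        else:
            res = anova_scan(phen, bg_e, bins_e, scan_cfg, experiment_id=name)
        all_qtls.extend(res.qtls)
        res.curves.to_csv(out / f"lod_curves_{name}.tsv", sep="\t", index=False)
    qtl_df = pd.DataFrame([q.__dict__ for q in all_qtls])
    qtl_df.to_csv(out / "qtl.tsv", sep="\t", index=False)
    report["qtl"] = {
        "method": method,
        "n_qtls": {name: int(sum(q.experiment_id == name for q in all_qtls)) for name in experiments},
    }
    _done(tok)

    # ---- conserved QTLs ---------------------------------------------------
    if len(experiments) >= 2:
        tok = _stage("conserved")
        cons = conserved_qtls(all_qtls)
        pd.DataFrame([c.__dict__ for c in cons]).assign(
            experiment_ids=lambda d: d["experiment_ids"].apply(",".join) if len(d) else d.get("experiment_ids")
        ).to_csv(out / "conserved.tsv", sep="\t", index=False)
        report["qtl"]["n_conserved"] = len(cons)
        _done(tok)

    # ---- report + manifest ------------------------------------------------
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["stage_wall_times_s"] = stage_times
    manifest["output_checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
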