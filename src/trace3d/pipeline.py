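"""End-to-end orchestration with a single config and a reproducibility manifest.

Stages run in dependency order (geometry -> matrices -> compartments ->
localenv -> coupling); every stage writes plain delimited tables plus a JSON
manifest recording the config, package version, seeds and input/output
checksums, so a rerun with an identical config is bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    FLOAT_FORMAT,
    read_locus_panel,
    read_traces,
    read_annotation_track,
    read_expression,
    write_json,
    validate_dataset,
)
from . import geometry as geo
from . import matrices as mat
from . import compartments as comp
from . import localenv as env
from . import coupling as cpl

log = logging.getLogger("trace3d")


@dataclass
class RunConfig:
    """Flat run configuration; every analysis constant is overridable here."""

    input_dir: str
    output_dir: str
    proximity_threshold_um: float = 0.75
    min_pair_observations: int = 20
    insulation_window_loci: int = 4
    kernel_sigma_um: float = 1.0
    min_total_weight: float = 0.5
    de_gene_window_bp: int = 100_000
    radial_bins: int = 10
    genotype_bins: int = 20
    n_pcs: int = 5
    matrix_source: str = "proximity"  # or "distance"
    min_loci_per_cell: int = 10
    min_profile_cells: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("proximity_threshold_um", "kernel_sigma_um", "insulation_window_loci",
                     "radial_bins", "genotype_bins", "n_pcs", "de_gene_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.matrix_source not in ("proximity", "distance"):
            raise ValueError("matrix_source must be 'proximity' or 'distance'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output dir)."""
    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}, "inputs": {}, "outputs": {}}

    def record_inputs(*paths: Path) -> None:
        for p in paths:
            if p.exists() and p.is_file():
                manifest["inputs"][str(p)] = _sha256(p)

    # ---- load ------------------------------------------------------------
    panel_path = in_dir / "panel.bed"
    cells_path = in_dir / "cells.tsv"
    obs_path = in_dir / "observations.tsv"
    for p, stage in ((panel_path, "load"), (cells_path, "load"), (obs_path, "load")):
        if not p.exists():
            raise StageError(stage, f"missing input file {p}")
    record_inputs(panel_path, cells_path, obs_path)
    panel = read_locus_panel(panel_path)
    dataset = read_traces(panel, cells_path, obs_path)
    qc_report, dataset = validate_dataset(dataset, config.min_loci_per_cell)
    manifest["stages"]["load"] = {"n_loci": len(panel), "n_cells": dataset.n_cells,
                                  "qc": qc_report}
    log.info("loaded %d loci, %d cells (%d removed by QC)", len(panel),
             dataset.n_cells, qc_report["n_cells_removed"])

    cell_types = dataset.cell_types()
    genotypes = sorted(set(dataset.cells["genotype"]))
    has_ko = "KO" in genotypes and "WT" in genotypes
    wt = "WT" if has_ko else None

    # ---- geometry --------------------------------------------------------
    geoms = geo.geometry_per_cell(dataset)
    geo_table = geo.geometry_table(dataset, geoms)
    geo_table.to_csv(out / "cell_geometry.tsv", sep="\t", index=False,
                     float_format=FLOAT_FORMAT)
    positions = geo.observation_radial_positions(dataset, geoms)
    positions_by_gt = {}
    if has_ko:
        for gt in ("WT", "KO"):
            keep = dataset.cells.loc[dataset.cells["genotype"] == gt, "cell_id"]
            positions_by_gt[gt] = positions[positions["cell_id"].isin(set(keep))]
        rad_profile = geo.radial_profile(dataset, positions=positions_by_gt["WT"])
    else:
        rad_profile = geo.radial_profile(dataset, positions=positions)
    rad_profile.values.to_csv(out / "radial_profile.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
    manifest["stages"]["geometry"] = {
        "n_degenerate": int(sum(g.degenerate for g in geoms.values()))}
    log.info("geometry: %d cells, %d profile rows", len(geoms), len(rad_profile.values))

    # ---- matrices --------------------------------------------------------
    (out / "matrices").mkdir(exist_ok=True)
    summaries: dict = {}
    insulation_rows = []
    for ct in cell_types:
        for chrom in panel.chroms:
            dist = mat.median_distance_matrix(
                dataset, ct, chrom, min_pair_observations=config.min_pair_observations,
                genotype=wt)
            prox = mat.pairwise_proximity_matrix(
                dataset, ct, chrom, threshold_um=config.proximity_threshold_um,
                min_pair_observations=config.min_pair_observations, genotype=wt)
            summaries[(ct, chrom)] = {"distance": dist, "proximity": prox}
            safe_ct = ct.replace("/", "_").replace(" ", "_")
            dist.matrix.to_csv(out / "matrices" / f"dist_{safe_ct}_{chrom}.tsv",
                               sep="\t", float_format=FLOAT_FORMAT)
            prox.matrix.to_csv(out / "matrices" / f"prox_{safe_ct}_{chrom}.tsv",
                               sep="\t", float_format=FLOAT_FORMAT)
            try:
                ins = mat.insulation_scores(prox, window_loci=config.insulation_window_loci)
                insulation_rows.append((ct, chrom, ins.iqr))
            except ValueError:
                insulation_rows.append((ct, chrom, np.nan))
    pd.DataFrame(insulation_rows, columns=["cell_type", "chrom", "nis_iqr"]).to_csv(
        out / "insulation_iqr.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    manifest["stages"]["matrices"] = {"n_matrices": len(summaries) * 2}
    log.info("matrices: %d (cell type, chromosome) pairs", len(summaries))

    # ---- compartments ----------------------------------------------------
    atac_path = in_dir / "tracks" / "atac.tsv"
    calls_by_type: dict[str, dict[str, comp.CompartmentCall]] = {}
    if atac_path.exists():
        record_inputs(atac_path)
        atac = read_annotation_track(panel, atac_path, name="atac")
        call_rows = []
        for ct in cell_types:
            try:
                acc = atac.for_cell_type(ct)
            except Exception as exc:
                raise StageError("compartments", f"no accessibility for {ct}: {exc}")
            calls_by_type[ct] = {}
            for chrom in panel.chroms:
                src = summaries[(ct, chrom)][config.matrix_source]
                call = comp.call_compartments_from_summary(src, panel, acc,
                                                           n_pcs=config.n_pcs)
                calls_by_type[ct][chrom] = call
                for lid in call.labels.index:
                    call_rows.append((ct, chrom, lid, call.labels[lid],
                                      call.pc_values[lid], call.selected_pc,
                                      call.corr_with_accessibility))
        pd.DataFrame(call_rows, columns=["cell_type", "chrom", "locus_id", "label",
                                         "pc_value", "selected_pc", "corr_accessibility"]
                     ).to_csv(out / "compartment_calls.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
        if len(cell_types) >= 2:
            switch_rows = []
            for i in range(len(cell_types)):
                for j in range(i + 1, len(cell_types)):
                    for chrom in panel.chroms:
                        sw = comp.compartment_switching(
                            calls_by_type[cell_types[i]][chrom],
                            calls_by_type[cell_types[j]][chrom])
                        switch_rows.append((cell_types[i], cell_types[j], chrom,
                                            *[sw.fractions[c] for c in
                                              ("A->A", "A->B", "B->A", "B->B")]))
            pd.DataFrame(switch_rows,
                         columns=["type_x", "type_y", "chrom", "AA", "AB", "BA", "BB"]
                         ).to_csv(out / "compartment_switching.tsv", sep="\t",
                                  index=False, float_format=FLOAT_FORMAT)
        manifest["stages"]["compartments"] = {
            "selected_pc": {f"{ct}:{chrom}": calls_by_type[ct][chrom].selected_pc
                            for ct in calls_by_type for chrom in calls_by_type[ct]}}
        log.info("compartments: called %d cell types", len(calls_by_type))
    else:
        manifest["stages"]["compartments"] = {"skipped": "no tracks/atac.tsv"}

    # ---- localenv --------------------------------------------------------
    if calls_by_type:
        labels_by_type = {
            ct: pd.concat([calls_by_type[ct][chrom].labels for chrom in panel.chroms])
            for ct in calls_by_type}
        profile = env.local_env_profile(dataset, labels_by_type,
                                        sigma_um=config.kernel_sigma_um,
                                        min_total_weight=config.min_total_weight,
                                        min_cells=config.min_profile_cells,
                                        genotype=wt)
        profile.values.to_csv(out / "local_ab_profile.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
        manifest["stages"]["localenv"] = {"n_rows": len(profile.values)}
        log.info("localenv: %d profile rows", len(profile.values))
        if has_ko:
            ko_profile = env.local_env_profile(dataset, labels_by_type,
                                               sigma_um=config.kernel_sigma_um,
                                               min_total_weight=config.min_total_weight,
                                               min_cells=config.min_profile_cells,
                                               genotype="KO")
            ko_profile.values.to_csv(out / "local_ab_profile_ko.tsv", sep="\t",
                                     index=False, float_format=FLOAT_FORMAT)

    # ---- coupling --------------------------------------------------------
    coupling_meta: dict = {}
    rna_path = in_dir / "tracks" / "rna.tsv"
    if rna_path.exists():
        record_inputs(rna_path)
        rna = read_annotation_track(panel, rna_path, name="rna")
        corr_rows = []
        for ct in cell_types:
            try:
                radial_ct = rad_profile.for_cell_type(ct)
                corr = cpl.radial_track_correlation(radial_ct, rna.for_cell_type(ct))
                corr_rows.append((ct, corr["spearman_r"], corr["pearson_r"], corr["n"]))
            except (ValueError, Exception):
                continue
        pd.DataFrame(corr_rows, columns=["cell_type", "spearman_r", "pearson_r", "n"]
                     ).to_csv(out / "radial_rna_correlation.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
        coupling_meta["radial_rna_correlation"] = len(corr_rows)
    if has_ko:
        delta_rows = []
        for ct in cell_types:
            prof_wt = geo.radial_profile(
                dataset, positions=positions_by_gt["WT"]).for_cell_type(ct) \
                if ct in set(positions_by_gt["WT"]["cell_type"]) else None
            prof_ko = geo.radial_profile(
                dataset, positions=positions_by_gt["KO"]).for_cell_type(ct) \
                if ct in set(positions_by_gt["KO"]["cell_type"]) else None
            if prof_wt is None or prof_ko is None:
                continue
            delta = cpl.genotype_delta(prof_wt, prof_ko)
            for lid, dv in delta.items():
                delta_rows.append((ct, lid, prof_wt[lid], dv))
        pd.DataFrame(delta_rows, columns=["cell_type", "locus_id", "wt_radial", "delta"]
                     ).to_csv(out / "radial_genotype_delta.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
        coupling_meta["radial_genotype_delta"] = len(delta_rows)
    manifest["stages"]["coupling"] = coupling_meta

    for p in sorted(out.rglob("*.tsv")):
        manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    write_json(manifest, out / "manifest.json")
    return manifest
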