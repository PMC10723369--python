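"""Shared fixtures: tiny hand-built panels/datasets and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import trace3d as t3
from trace3d import synthetic as syn


def make_panel(n_chrom: int = 2, loci_per_chrom: int = 5,
               spacing_bp: int = 1_000_000) -> t3.LocusPanel:
    rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        for i in range(loci_per_chrom):
            start = spacing_bp * (i + 1)
            rows.append((chrom, start, start + 50_000, f"{chrom}_L{i:03d}", "genome", None))
    return t3.LocusPanel(pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "locus_id", "panel_class",
                       "origin_cell_type"]))


def make_dataset(panel: t3.LocusPanel, coords: dict, cell_type: str = "T",
                 genotype: str = "WT") -> t3.TraceDataset:
    """coords: {(cell_id, locus_id, homolog): (x, y, z)}."""
    chrom_of = panel.df.set_index("locus_id")["chrom"].to_dict()
    obs = pd.DataFrame(
        [(c, l, chrom_of.get(l, "chr1"), h, x, y, z, 1.0)
         for (c, l, h), (x, y, z) in coords.items()],
        columns=["cell_id", "locus_id", "chrom", "homolog", "x_um", "y_um", "z_um",
                 "quality"])
    cells = pd.DataFrame(
        [(c, cell_type, genotype, "rep1") for c in dict.fromkeys(obs["cell_id"])],
        columns=["cell_id", "cell_type", "genotype", "replicate"])
    return t3.TraceDataset(panel=panel, cells=cells, observations=obs)


def random_dataset(seed: int = 0, n_cells: int = 5, n_chrom: int = 2,
                   loci_per_chrom: int = 5, box_um: float = 4.0,
                   detection: float = 0.9) -> t3.TraceDataset:
    """Random valid dataset: uniform coordinates, random dropout."""
    rng = np.random.default_rng(seed)
    panel = make_panel(n_chrom, loci_per_chrom)
    rows = []
    for c in range(n_cells):
        cell_id = f"cell{c:03d}"
        for _, locus in panel.df.iterrows():
            for hom in range(2):
                if rng.random() > detection:
                    continue
                x, y, z = rng.uniform(0, box_um, 3)
                rows.append((cell_id, locus["locus_id"], locus["chrom"], hom,
                             x, y, z, float(rng.uniform(0.5, 1.0))))
    obs = pd.DataFrame(rows, columns=["cell_id", "locus_id", "chrom", "homolog",
                                      "x_um", "y_um", "z_um", "quality"])
    cells = pd.DataFrame([(f"cell{c:03d}", "T", "WT", "rep1") for c in range(n_cells)],
                         columns=["cell_id", "cell_type", "genotype", "replicate"])
    return t3.TraceDataset(panel=panel, cells=cells, observations=obs)


@pytest.fixture(scope="session")
def small_sim():
    """Small two-type simulation with expression, shared across unit tests."""
    params = t3.SimParams(n_chrom=2, loci_per_chrom=20, n_cells_per_type=40,
                          n_se_per_type=4, seed=11)
    panel, truth, dataset, expr, tracks = t3.simulate(params)
    return {"params": params, "panel": panel, "truth": truth, "dataset": dataset,
            "expr": expr, "tracks": tracks}
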