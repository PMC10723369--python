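"""Shared data model and on-disk formats for chromatin-tracing analysis.

All spatial coordinates are micrometers; genomic coordinates are 0-based
half-open (BED convention) and genomic distances are midpoint-to-midpoint.
Missing observations are represented as absent rows, never as zero
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PANEL_CLASSES = ("genome", "super_enhancer", "tss")
GENOTYPES = ("WT", "KO", "NA")

#: fixed significant digits for all real-valued table output; gives absolute
#: round-trip error < 1e-9 for coordinates below ~1 mm and makes
#: write -> read -> write byte-stable.
FLOAT_FORMAT = "%.12g"


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class ParseError(ValueError):
    """Malformed on-disk input."""


# ---------------------------------------------------------------------------
# LocusPanel
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["chrom", "start_bp", "end_bp", "locus_id", "panel_class", "origin_cell_type"]


@dataclass(frozen=True)
class LocusPanel:
    """Ordered genomic loci (BED semantics) defining matrix axes.

    ``df`` is sorted by (chrom, start_bp) and indexed 0..n-1; locus midpoints
    define genomic distances between same-chromosome loci.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"panel missing columns: {missing}")
        if len(df):
            if (df["start_bp"] >= df["end_bp"]).any():
                bad = df.loc[df["start_bp"] >= df["end_bp"], "locus_id"].tolist()
                raise ValidationError(f"loci with start >= end: {bad}")
            if df["locus_id"].duplicated().any():
                dups = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
                raise ValidationError(f"duplicate locus ids: {dups}")
            if df.duplicated(subset=["chrom", "start_bp", "end_bp"]).any():
                raise ValidationError("duplicate intervals within panel")
            bad_class = set(df["panel_class"]) - set(PANEL_CLASSES)
            if bad_class:
                raise ValidationError(f"unknown panel classes: {sorted(bad_class)}")
        sorted_df = df.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "df", sorted_df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> pd.Index:
        return pd.Index(self.df["locus_id"])

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def midpoints(self) -> pd.Series:
        """Locus midpoints (bp), indexed by locus_id."""
        mid = (self.df["start_bp"] + self.df["end_bp"]) // 2
        return pd.Series(mid.to_numpy(), index=self.df["locus_id"].to_numpy(), name="midpoint_bp")

    def loci_for_chrom(self, chrom: str) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if sub.empty:
            raise ValidationError(f"chromosome {chrom!r} not in panel")
        return sub.reset_index(drop=True)

    def genomic_distance(self, locus_a: str, locus_b: str) -> int:
        """|mid_a - mid_b| for same-chromosome loci; error otherwise."""
        mids = self.midpoints()
        rows = self.df.set_index("locus_id")
        if rows.loc[locus_a, "chrom"] != rows.loc[locus_b, "chrom"]:
            raise ValidationError("genomic distance undefined across chromosomes")
        return int(abs(mids[locus_a] - mids[locus_b]))

    def genomic_distance_matrix(self, chrom: str) -> pd.DataFrame:
        sub = self.loci_for_chrom(chrom)
        mid = ((sub["start_bp"] + sub["end_bp"]) // 2).to_numpy()
        d = np.abs(mid[:, None] - mid[None, :])
        ids = sub["locus_id"].to_numpy()
        return pd.DataFrame(d, index=ids, columns=ids)

    def subset(self, locus_ids: Iterable[str]) -> "LocusPanel":
        keep = set(locus_ids)
        return LocusPanel(self.df[self.df["locus_id"].isin(keep)].reset_index(drop=True))


def read_locus_panel(path: str | Path, format: str = "bed") -> LocusPanel:
    """Read a locus panel from a BED-like file.

    Columns: chrom, start, end, name[, class[, origin_cell_type]].  Lines
    starting with '#' or 'track' are skipped.
    """
    if format != "bed":
        raise ValueError(f"unsupported panel format: {format!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            panel_class = parts[4] if len(parts) > 4 and parts[4] else "genome"
            origin = parts[5] if len(parts) > 5 and parts[5] not in ("", ".") else None
            rows.append((parts[0], start, end, parts[3], panel_class, origin))
    df = pd.DataFrame(rows, columns=_PANEL_COLUMNS)
    if df.empty:
        df = pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start_bp": pd.Series(dtype=np.int64),
             "end_bp": pd.Series(dtype=np.int64), "locus_id": pd.Series(dtype=str),
             "panel_class": pd.Series(dtype=str), "origin_cell_type": pd.Series(dtype=object)}
        )
    return LocusPanel(df)


def write_locus_panel(panel: LocusPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in panel.df.iterrows():
            origin = r["origin_cell_type"] if r["origin_cell_type"] else "."
            fh.write(f"{r['chrom']}\t{r['start_bp']}\t{r['end_bp']}\t"
                     f"{r['locus_id']}\t{r['panel_class']}\t{origin}\n")


# ---------------------------------------------------------------------------
# TraceDataset
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["cell_id", "cell_type", "genotype", "replicate"]
_OBS_COLUMNS = ["cell_id", "locus_id", "chrom", "homolog", "x_um", "y_um", "z_um", "quality"]


@dataclass(frozen=True)
class TraceDataset:
    """Per-cell, per-homolog 3D locus observations with cell metadata."""

    panel: LocusPanel
    cells: pd.DataFrame
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        cells = self.cells.reset_index(drop=True)
        obs = self.observations.reset_index(drop=True)
        for col in _CELL_COLUMNS:
            if col not in cells.columns:
                raise ValidationError(f"cells table missing column {col!r}")
        for col in _OBS_COLUMNS:
            if col not in obs.columns:
                raise ValidationError(f"observations table missing column {col!r}")
        if cells["cell_id"].duplicated().any():
            dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValidationError(f"duplicate cell ids: {dups}")
        bad_gt = set(cells["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValidationError(f"unknown genotypes: {sorted(bad_gt)}")
        if len(obs):
            unknown_loci = set(obs["locus_id"]) - set(self.panel.locus_ids)
            if unknown_loci:
                raise ValidationError(f"observations reference unknown loci: {sorted(unknown_loci)[:10]}")
            unknown_cells = set(obs["cell_id"]) - set(cells["cell_id"])
            if unknown_cells:
                raise ValidationError(f"observations reference unknown cells: {sorted(unknown_cells)[:10]}")
            coords = obs[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            if not np.isfinite(coords).all():
                raise ValidationError("non-finite coordinates in observations")
            if obs.duplicated(subset=["cell_id", "locus_id", "homolog"]).any():
                bad = obs.loc[obs.duplicated(subset=["cell_id", "locus_id", "homolog"]),
                              ["cell_id", "locus_id", "homolog"]]
                raise ValidationError(
                    f"duplicate (cell, locus, homolog) observations, e.g. {bad.iloc[0].tolist()}")
            if (obs["homolog"] < 0).any():
                raise ValidationError("negative homolog index")
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "observations", obs)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.cells["cell_type"]))

    def cells_of_type(self, cell_type: str, genotype: str | None = None) -> pd.DataFrame:
        sel = self.cells["cell_type"] == cell_type
        if not sel.any():
            raise ValidationError(f"unknown cell type {cell_type!r}")
        if genotype is not None:
            sel &= self.cells["genotype"] == genotype
        return self.cells[sel]

    def observations_for_cells(self, cell_ids: Iterable[str]) -> pd.DataFrame:
        keep = set(cell_ids)
        return self.observations[self.observations["cell_id"].isin(keep)]

    def detection_fraction(self) -> pd.Series:
        """Detected loci per cell / (panel size x 2 homologs), indexed by cell_id."""
        counts = self.observations.groupby("cell_id").size()
        denom = 2 * max(len(self.panel), 1)
        frac = counts.reindex(self.cells["cell_id"], fill_value=0) / denom
        frac.name = "detection_fraction"
        return frac


def read_traces(panel: LocusPanel, cells_path: str | Path, obs_path: str | Path) -> TraceDataset:
    """Read cell metadata and decoded 3D observations (tab-delimited, headered)."""
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "replicate": str})
    obs = pd.read_csv(obs_path, sep="\t", dtype={"cell_id": str, "locus_id": str, "chrom": str})
    if obs[["x_um", "y_um", "z_um"]].isna().any().any():
        raise ValidationError(f"{obs_path}: NaN coordinates")
    return TraceDataset(panel=panel, cells=cells, observations=obs)


def write_traces(dataset: TraceDataset, cells_path: str | Path, obs_path: str | Path) -> None:
    dataset.cells[_CELL_COLUMNS].to_csv(cells_path, sep="\t", index=False)
    dataset.observations[_OBS_COLUMNS].to_csv(
        obs_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def validate_dataset(dataset: TraceDataset, min_loci_per_cell: int) -> tuple[dict, TraceDataset]:
    """QC gate: drop cells with fewer detected loci than the threshold.

    Returns (report, filtered dataset); report lists the removed cells.
    """
    counts = dataset.observations.groupby("cell_id").size()
    counts = counts.reindex(dataset.cells["cell_id"], fill_value=0)
    removed = counts[counts < min_loci_per_cell].index.tolist()
    kept = dataset.cells[~dataset.cells["cell_id"].isin(removed)]
    obs = dataset.observations[dataset.observations["cell_id"].isin(set(kept["cell_id"]))]
    report = {
        "min_loci_per_cell": int(min_loci_per_cell),
        "n_cells_in": int(dataset.n_cells),
        "n_cells_removed": len(removed),
        "removed_cells": sorted(map(str, removed)),
        "warnings": ["all cells removed"] if len(kept) == 0 and dataset.n_cells > 0 else [],
    }
    filtered = TraceDataset(panel=dataset.panel, cells=kept.reset_index(drop=True),
                            observations=obs.reset_index(drop=True))
    return report, filtered


# ---------------------------------------------------------------------------
# AnnotationTrack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-(cell_type, locus) scalar annotation; higher = more of the property.

    Missing (cell_type, locus) pairs are absent, never imputed.
    """

    name: str
    values: pd.Series  # MultiIndex (cell_type, locus_id) -> float

    def __post_init__(self) -> None:
        vals = self.values
        if not isinstance(vals.index, pd.MultiIndex) or vals.index.nlevels != 2:
            raise ValidationError("track values need a (cell_type, locus_id) MultiIndex")
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise ValidationError(f"duplicate track key {dup}")
        object.__setattr__(self, "values", vals.astype(float))

    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.values.index.get_level_values(0)))

    def for_cell_type(self, cell_type: str) -> pd.Series:
        """Values for one cell type, indexed by locus_id (absent loci omitted)."""
        if cell_type not in self.values.index.get_level_values(0):
            raise ValidationError(f"track {self.name!r} has no cell type {cell_type!r}")
        return self.values.xs(cell_type, level=0)


def read_annotation_track(panel: LocusPanel, path: str | Path, name: str | None = None) -> AnnotationTrack:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str, "locus_id": str})
    for col in ("cell_type", "locus_id", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        raise ParseError(f"{path}: non-numeric value column")
    unknown = set(df["locus_id"]) - set(panel.locus_ids)
    if unknown:
        raise ValidationError(f"{path}: unknown loci {sorted(unknown)[:10]}")
    series = df.set_index(["cell_type", "locus_id"])["value"]
    return AnnotationTrack(name=name or path.stem, values=series)


def write_annotation_track(track: AnnotationTrack, path: str | Path) -> None:
    df = track.values.rename("value").reset_index()
    df.columns = ["cell_type", "locus_id", "value"]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def track_from_frame(name: str, df: pd.DataFrame) -> AnnotationTrack:
    """Build a track from a tidy frame with cell_type/locus_id/value columns."""
    return AnnotationTrack(name=name, values=df.set_index(["cell_type", "locus_id"])["value"])


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-cell UMI counts with gene TSS metadata."""

    genes: pd.DataFrame  # gene_id, tss_chrom, tss_bp, length_bp
    counts: pd.DataFrame  # genes x cells, integer
    cells: pd.DataFrame  # CellRecords

    def __post_init__(self) -> None:
        for col in ("gene_id", "tss_chrom", "tss_bp", "length_bp"):
            if col not in self.genes.columns:
                raise ValidationError(f"gene table missing column {col!r}")
        if self.genes["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids")
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if not np.array_equal(counts.to_numpy(), counts.to_numpy().astype(np.int64)):
            raise ValidationError("non-integer counts")
        if list(counts.index) != list(self.genes["gene_id"]):
            raise ValidationError("counts rows must match gene table order")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    def total_umis_per_cell(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_expression(path_genes: str | Path, path_counts: str | Path,
                    cells: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read gene metadata plus triplet counts (gene_id, cell_id, count).

    Omitted (gene, cell) triplets are zero.
    """
    genes = pd.read_csv(path_genes, sep="\t", dtype={"gene_id": str, "tss_chrom": str})
    trip = pd.read_csv(path_counts, sep="\t", dtype={"gene_id": str, "cell_id": str})
    for col in ("gene_id", "cell_id", "count"):
        if col not in trip.columns:
            raise ParseError(f"{path_counts}: missing column {col!r}")
    if (trip["count"] < 0).any():
        raise ValidationError("negative counts")
    unknown = set(trip["gene_id"]) - set(genes["gene_id"])
    if unknown:
        raise ValidationError(f"counts reference unknown genes: {sorted(unknown)[:10]}")
    cell_ids = (list(cells["cell_id"]) if cells is not None
                else sorted(set(trip["cell_id"])))
    dense = (trip.pivot_table(index="gene_id", columns="cell_id", values="count",
                              aggfunc="sum", fill_value=0)
             .reindex(index=genes["gene_id"], columns=cell_ids, fill_value=0))
    dense.index.name = "gene_id"
    dense.columns.name = None
    if cells is None:
        cells = pd.DataFrame({"cell_id": cell_ids, "cell_type": "NA",
                              "genotype": "NA", "replicate": "NA"})
    return ExpressionMatrix(genes=genes, counts=dense, cells=cells)


def write_expression(expr: ExpressionMatrix, path_genes: str | Path, path_counts: str | Path) -> None:
    expr.genes.to_csv(path_genes, sep="\t", index=False)
    stacked = expr.counts.stack()
    stacked = stacked[stacked > 0].rename("count").reset_index()
    stacked.columns = ["gene_id", "cell_id", "count"]
    stacked.to_csv(path_counts, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON run summaries
# ---------------------------------------------------------------------------


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
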