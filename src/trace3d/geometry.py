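"""Per-cell nuclear geometry: hull volumes, radial positions, intermixing.

The nuclear boundary is the convex hull of all decoded loci of the cell (no
membrane stain exists in the data model), the nuclear centroid is the mean
of all locus positions, and the normalized radial position of a locus is
its centroid distance divided by the centroid-to-hull-surface distance
along the same direction (0 = center, 1 = periphery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import pearsonr, spearmanr

from .data_model import TraceDataset

_RAY_TOL = 1e-9  # micrometers; facet-intersection tolerance


@dataclass(frozen=True)
class CellGeometry:
    cell_id: str
    centroid: np.ndarray          # (3,)
    nuclear_volume: float | None  # um^3; None when degenerate
    hull: ConvexHull | None
    degenerate: bool


def cell_geometry(cell_obs: pd.DataFrame, cell_id: str = "") -> CellGeometry:
    """Convex-hull geometry over all locus positions of one cell.

    Cells with fewer than 4 non-coplanar points are flagged degenerate and
    carry no volume or hull.
    """
    pts = cell_obs[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    centroid = pts.mean(axis=0) if len(pts) else np.full(3, np.nan)
    if len(pts) < 4:
        return CellGeometry(cell_id, centroid, None, None, True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return CellGeometry(cell_id, centroid, None, None, True)
    return CellGeometry(cell_id, centroid, float(hull.volume), hull, False)


def territory_volumes(cell_obs: pd.DataFrame) -> pd.DataFrame:
    """Convex-hull volume per (chrom, homolog); degenerate homologs absent."""
    rows = []
    for (chrom, hom), grp in cell_obs.groupby(["chrom", "homolog"], sort=True):
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if len(pts) < 4:
            continue
        try:
            vol = float(ConvexHull(pts).volume)
        except QhullError:
            continue
        rows.append((chrom, hom, vol, len(pts)))
    return pd.DataFrame(rows, columns=["chrom", "homolog", "volume_um3", "n_loci"])


def normalized_radial_position(geometry: CellGeometry, point: np.ndarray) -> float:
    """r = |p - c| / t*, with t* the centroid-to-hull distance along (p - c).

    The centroid maps to 0; numerical overshoot past the hull surface is
    clipped to 1.
    """
    if geometry.hull is None:
        raise ValueError("geometry is degenerate; no hull available")
    c = geometry.centroid
    d = np.asarray(point, dtype=float) - c
    dist = float(np.linalg.norm(d))
    if dist < _RAY_TOL:
        return 0.0
    d = d / dist
    # hull facets: A x + b <= 0 for interior points
    eqs = geometry.hull.equations
    denom = eqs[:, :3] @ d
    numer = -(eqs[:, :3] @ c + eqs[:, 3])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numer / denom
    t = t[(denom > _RAY_TOL) & np.isfinite(t)]
    t = t[t > _RAY_TOL]
    if len(t) == 0:
        raise ValueError("ray cast from centroid found no facet intersection")
    t_star = float(t.min())
    return min(dist / t_star, 1.0)


def geometry_per_cell(dataset: TraceDataset) -> dict[str, CellGeometry]:
    out = {}
    for cell_id, grp in dataset.observations.groupby("cell_id", sort=True):
        out[cell_id] = cell_geometry(grp, cell_id=cell_id)
    return out


def geometry_table(dataset: TraceDataset, geoms: dict[str, CellGeometry] | None = None
                   ) -> pd.DataFrame:
    """Per-cell nuclear volume/centroid summary joined with cell metadata."""
    geoms = geoms or geometry_per_cell(dataset)
    rows = []
    for cell_id, g in geoms.items():
        rows.append((cell_id, g.nuclear_volume if not g.degenerate else np.nan,
                     *g.centroid, g.degenerate))
    df = pd.DataFrame(rows, columns=["cell_id", "nuclear_volume_um3",
                                     "centroid_x", "centroid_y", "centroid_z", "degenerate"])
    return df.merge(dataset.cells, on="cell_id", how="left")


@dataclass(frozen=True)
class RadialProfile:
    """Per-(cell_type, locus) median normalized radial position in [0, 1]."""

    values: pd.DataFrame  # cell_type, locus_id, median_radial, n_cells

    def for_cell_type(self, cell_type: str) -> pd.Series:
        sub = self.values[self.values["cell_type"] == cell_type]
        return sub.set_index("locus_id")["median_radial"]


def _radial_positions_batch(geometry: CellGeometry, pts: np.ndarray) -> np.ndarray:
    """Vectorized normalized radial positions for many points of one cell."""
    c = geometry.centroid
    d = pts - c
    dist = np.linalg.norm(d, axis=1)
    out = np.zeros(len(pts))
    moving = dist >= _RAY_TOL
    dirs = d[moving] / dist[moving, None]
    eqs = geometry.hull.equations
    denom = dirs @ eqs[:, :3].T                      # (m, facets)
    numer = -(eqs[:, :3] @ c + eqs[:, 3])[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numer / denom
    t = np.where((denom > _RAY_TOL) & (t > _RAY_TOL) & np.isfinite(t), t, np.inf)
    t_star = t.min(axis=1)
    if np.isinf(t_star).any():
        raise ValueError("ray cast from centroid found no facet intersection")
    out[moving] = np.minimum(dist[moving] / t_star, 1.0)
    return out


def observation_radial_positions(dataset: TraceDataset,
                                 geoms: dict[str, CellGeometry] | None = None,
                                 genotype: str | None = None) -> pd.DataFrame:
    """Normalized radial position for every observation of non-degenerate cells."""
    geoms = geoms or geometry_per_cell(dataset)
    cells = dataset.cells
    if genotype is not None:
        cells = cells[cells["genotype"] == genotype]
    type_of = cells.set_index("cell_id")["cell_type"]
    frames = []
    for cell_id, grp in dataset.observations.groupby("cell_id", sort=True):
        if cell_id not in type_of.index:
            continue
        g = geoms[cell_id]
        if g.degenerate:
            continue
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        frames.append(pd.DataFrame({
            "cell_id": cell_id, "cell_type": type_of[cell_id],
            "locus_id": grp["locus_id"].to_numpy(),
            "homolog": grp["homolog"].to_numpy(),
            "radial": _radial_positions_batch(g, pts),
        }))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "cell_type", "locus_id", "homolog", "radial"])
    return pd.concat(frames, ignore_index=True)


def radial_profile(dataset: TraceDataset, geoms: dict[str, CellGeometry] | None = None,
                   genotype: str | None = None,
                   positions: pd.DataFrame | None = None) -> RadialProfile:
    """Median over all observations (both homologs, all cells) per (type, locus)."""
    if positions is None:
        positions = observation_radial_positions(dataset, geoms, genotype=genotype)
    rows = []
    for (cell_type, locus_id), grp in positions.groupby(["cell_type", "locus_id"], sort=True):
        rows.append((cell_type, locus_id, float(grp["radial"].median()),
                     int(grp["cell_id"].nunique())))
    return RadialProfile(values=pd.DataFrame(
        rows, columns=["cell_type", "locus_id", "median_radial", "n_cells"]))


def territory_intermixing(cell_obs: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-NN chromosome purity per homolog: the mean, over a homolog's loci, of
    the fraction of each locus's k nearest neighbors (same-homolog excluded)
    that belong to a different chromosome.  Scores are in [0, 1]; homologs
    with no trans candidates are absent.
    """
    pts = cell_obs[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    chrom = cell_obs["chrom"].to_numpy()
    hom = cell_obs["homolog"].to_numpy()
    n = len(pts)
    rows = []
    for (ch, hm), idx in pd.DataFrame({"c": chrom, "h": hom}).groupby(["c", "h"], sort=True).groups.items():
        idx = np.asarray(idx)
        fracs, flagged = [], False
        for i in idx:
            cand = np.flatnonzero(~((chrom == ch) & (hom == hm)))
            if len(cand) == 0:
                continue
            kk = min(k, len(cand))
            if len(cand) < k:
                flagged = True
            d = np.linalg.norm(pts[cand] - pts[i], axis=1)
            nearest = cand[np.argsort(d, kind="stable")[:kk]]
            fracs.append(float(np.mean(chrom[nearest] != ch)))
        if fracs:
            rows.append((ch, hm, float(np.mean(fracs)), flagged))
    return pd.DataFrame(rows, columns=["chrom", "homolog", "intermixing", "flagged"])


def celltype_scalar_correlation(scalars: pd.DataFrame, col_a: str, col_b: str
                                ) -> tuple[pd.DataFrame, dict]:
    """Cell-type medians of two per-cell scalars and their cross-type correlation.

    ``scalars`` needs cell_type plus the two value columns.  Requires >= 3
    cell types; constant medians make the correlation absent (None).
    """
    medians = scalars.groupby("cell_type")[[col_a, col_b]].median()
    if len(medians) < 3:
        raise ValueError("need >= 3 cell types for a cross-type correlation")
    stats: dict = {}
    a, b = medians[col_a].to_numpy(), medians[col_b].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        stats["pearson_r"] = stats["spearman_r"] = None
        stats["pearson_p"] = stats["spearman_p"] = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = pearsonr(a, b)
            sr = spearmanr(a, b)
        stats.update(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                     spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue))
    return medians, stats
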