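"""Trans-chromosomal local A/B density ratio and its cell-type profiles.

For each observed locus the local density of compartment-A (and -B) loci
from *other* chromosomes is a Gaussian-kernel-weighted sum over those
observations; the A/B ratio of these densities is a per-cell, per-locus
proxy for how active the locus's immediate nuclear neighborhood is.
Same-chromosome observations (either homolog) never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TraceDataset


def ab_density_ratio_points(points: np.ndarray, chrom_idx: np.ndarray,
                            lab_a: np.ndarray, lab_b: np.ndarray,
                            sigma_um: float = 1.0,
                            min_total_weight: float = 0.5) -> np.ndarray:
    """Per-point trans-chromosomal A/B density ratio for one cell.

    Parameters
    ----------
    points : (n, 3) coordinates in micrometers.
    chrom_idx : (n,) chromosome identity per point; same-chromosome points
        are excluded from every point's density.
    lab_a, lab_b : (n,) boolean masks; points in neither contribute to
        neither density (unassigned compartment).
    Returns (n,) ratios; NaN where the summed weight is below
    ``min_total_weight`` or the B density is zero.
    """
    n = len(points)
    if n == 0:
        return np.empty(0)
    diff = points[:, None, :] - points[None, :, :]
    w = np.exp(-np.sum(diff * diff, axis=-1) / (2.0 * sigma_um ** 2))
    trans = chrom_idx[:, None] != chrom_idx[None, :]
    rho_a = (w * (trans & lab_a[None, :])).sum(axis=1)
    rho_b = (w * (trans & lab_b[None, :])).sum(axis=1)
    ratio = np.full(n, np.nan)
    ok = (rho_a + rho_b >= min_total_weight) & (rho_b > 0)
    ratio[ok] = rho_a[ok] / rho_b[ok]
    return ratio


def local_ab_density_ratio(cell_obs: pd.DataFrame, labels: pd.Series,
                           sigma_um: float = 1.0,
                           min_total_weight: float = 0.5) -> pd.Series:
    """Per-observation local A/B density ratio within one cell.

    ``labels`` maps locus_id -> {A, B, unassigned} for the cell's type.
    Returns a Series aligned with ``cell_obs.index``; NaN where undefined.
    """
    lab = labels.reindex(cell_obs["locus_id"]).to_numpy()
    lab_a = lab == "A"
    lab_b = lab == "B"
    labeled_chroms = set(cell_obs["chrom"].to_numpy()[lab_a | lab_b])
    if len(labeled_chroms) < 2:
        warnings.warn("no labeled trans loci in cell; all ratios absent")
        return pd.Series(np.nan, index=cell_obs.index, name="ab_ratio")
    pts = cell_obs[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    chrom_codes = pd.factorize(cell_obs["chrom"])[0]
    ratio = ab_density_ratio_points(pts, chrom_codes, lab_a, lab_b,
                                    sigma_um=sigma_um,
                                    min_total_weight=min_total_weight)
    return pd.Series(ratio, index=cell_obs.index, name="ab_ratio")


@dataclass(frozen=True)
class LocalEnvProfile:
    """Per-(cell_type, locus) median local A/B density ratio with cell counts."""

    values: pd.DataFrame  # cell_type, locus_id, median_ratio, n_cells

    def for_cell_type(self, cell_type: str) -> pd.Series:
        sub = self.values[self.values["cell_type"] == cell_type]
        return sub.set_index("locus_id")["median_ratio"]


def per_observation_ratios(dataset: TraceDataset, labels_by_type: dict[str, pd.Series],
                           sigma_um: float = 1.0, min_total_weight: float = 0.5,
                           genotype: str | None = None) -> pd.DataFrame:
    """Ratios for every observation of every cell with labels for its type."""
    obs = dataset.observations
    frames = []
    for cell_type, labels in labels_by_type.items():
        cells = dataset.cells_of_type(cell_type, genotype=genotype)
        sub = obs[obs["cell_id"].isin(set(cells["cell_id"]))]
        for cell_id, cell_obs in sub.groupby("cell_id", sort=True):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratio = local_ab_density_ratio(cell_obs, labels, sigma_um=sigma_um,
                                               min_total_weight=min_total_weight)
            frames.append(pd.DataFrame({
                "cell_id": cell_id, "cell_type": cell_type,
                "locus_id": cell_obs["locus_id"].to_numpy(),
                "homolog": cell_obs["homolog"].to_numpy(),
                "ratio": ratio.to_numpy(),
            }))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "cell_type", "locus_id", "homolog", "ratio"])
    return pd.concat(frames, ignore_index=True)


def local_env_profile(dataset: TraceDataset, labels_by_type: dict[str, pd.Series],
                      sigma_um: float = 1.0, min_total_weight: float = 0.5,
                      min_cells: int = 10, genotype: str | None = None,
                      ratios: pd.DataFrame | None = None) -> LocalEnvProfile:
    """Median over cells of the per-observation ratios, per (cell_type, locus).

    Loci observed (with a defined ratio) in fewer than ``min_cells`` cells of
    a type are absent from the profile.
    """
    if ratios is None:
        ratios = per_observation_ratios(dataset, labels_by_type, sigma_um=sigma_um,
                                        min_total_weight=min_total_weight,
                                        genotype=genotype)
    valid = ratios.dropna(subset=["ratio"])
    rows = []
    for (cell_type, locus_id), grp in valid.groupby(["cell_type", "locus_id"], sort=True):
        n_cells = grp["cell_id"].nunique()
        if n_cells < min_cells:
            continue
        rows.append((cell_type, locus_id, float(grp["ratio"].median()), int(n_cells)))
    return LocalEnvProfile(values=pd.DataFrame(
        rows, columns=["cell_type", "locus_id", "median_ratio", "n_cells"]))


# ---------------------------------------------------------------------------
# Association heatmaps (DE genes, super-enhancers)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationHeatmap:
    """Median fractional ratio change, target cell type x reference cell type."""

    matrix: pd.DataFrame  # rows: reference type, cols: target type
    counts: pd.DataFrame  # loci entering each entry


def _heatmap(profile: LocalEnvProfile, loci_by_reference: dict[str, list[str]],
             cell_types: list[str]) -> AssociationHeatmap:
    mat = pd.DataFrame(np.nan, index=cell_types, columns=cell_types, dtype=float)
    cnt = pd.DataFrame(0, index=cell_types, columns=cell_types, dtype=int)
    for ref in cell_types:
        loci = loci_by_reference.get(ref, [])
        ref_prof = profile.for_cell_type(ref)
        for target in cell_types:
            tgt_prof = profile.for_cell_type(target)
            shared = [l for l in loci if l in ref_prof.index and l in tgt_prof.index]
            cnt.loc[ref, target] = len(shared)
            if target == ref:
                mat.loc[ref, target] = 0.0
                continue
            if not shared:
                continue
            frac = tgt_prof[shared].to_numpy() / ref_prof[shared].to_numpy() - 1.0
            mat.loc[ref, target] = float(np.median(frac))
    return AssociationHeatmap(matrix=mat, counts=cnt)


def de_locus_association(profile: LocalEnvProfile, panel, de_gene_sets: dict[str, pd.DataFrame],
                         window_bp: int = 100_000) -> AssociationHeatmap:
    """Heatmap over the loci associated with each reference type's DE genes.

    ``de_gene_sets[cell_type]`` is a frame with tss_chrom and tss_bp columns
    for that type's DE genes (one direction at a time).  A locus is
    associated if a DE-gene TSS falls within ``window_bp`` of the locus
    interval.
    """
    cell_types = sorted({ct for ct in profile.values["cell_type"]})
    loci_by_ref: dict[str, list[str]] = {}
    pdf = panel.df
    for ct, genes in de_gene_sets.items():
        hits = []
        for _, r in pdf.iterrows():
            sel = ((genes["tss_chrom"] == r["chrom"])
                   & (genes["tss_bp"] >= r["start_bp"] - window_bp)
                   & (genes["tss_bp"] < r["end_bp"] + window_bp))
            if sel.any():
                hits.append(r["locus_id"])
        loci_by_ref[ct] = hits
    return _heatmap(profile, loci_by_ref, cell_types)


def se_association(profile: LocalEnvProfile, panel, n_random: int | None = None,
                   seed: int = 0) -> tuple[AssociationHeatmap, AssociationHeatmap]:
    """Cell-type-specific super-enhancer heatmap plus a randomized control.

    The specific heatmap uses each type's own SE loci as reference set; the
    control redraws, per reference type, an equal-size seeded random subset
    of all SE loci regardless of origin.
    """
    cell_types = sorted({ct for ct in profile.values["cell_type"]})
    se = panel.df[panel.df["panel_class"] == "super_enhancer"]
    specific = {ct: se.loc[se["origin_cell_type"] == ct, "locus_id"].tolist()
                for ct in cell_types}
    rng = np.random.default_rng(seed)
    all_se = se["locus_id"].tolist()
    control = {}
    for ct in cell_types:
        k = n_random if n_random is not None else len(specific[ct])
        k = min(k, len(all_se))
        control[ct] = list(rng.choice(all_se, size=k, replace=False)) if k else []
    return _heatmap(profile, specific, cell_types), _heatmap(profile, control, cell_types)
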