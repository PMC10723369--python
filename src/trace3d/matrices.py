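"""Cell-type cis-chromosomal distance/proximity matrices and insulation scores.

Only same-homolog cis pairs enter these statistics: the two homologs of a
chromosome are independent polymers and trans-homolog distances are
excluded everywhere.  Matrix entries with fewer than ``min_pair_observations``
underlying homolog instances are masked absent (NaN) for median stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LocusPanel, TraceDataset

DEFAULT_PROXIMITY_THRESHOLD_UM = 0.75  # strict d < threshold (750 nm)
DEFAULT_MIN_PAIR_OBSERVATIONS = 20


@dataclass(frozen=True)
class MatrixSummary:
    """Square per-(cell_type, chrom) summary over the chromosome's panel loci."""

    cell_type: str
    chrom: str
    kind: str  # median_distance_um | proximity_frequency
    matrix: pd.DataFrame  # NaN = absent; diagonal absent
    n_obs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("median_distance_um", "proximity_frequency"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")


def _homolog_coordinate_stack(dataset: TraceDataset, cell_ids: set[str], chrom: str,
                              locus_ids: np.ndarray) -> np.ndarray:
    """(n_instances, n_loci, 3) array of per-homolog coordinates, NaN = absent."""
    obs = dataset.observations
    sub = obs[(obs["chrom"] == chrom) & obs["cell_id"].isin(cell_ids)]
    pos = pd.Index(locus_ids)
    instances = []
    for (_, _), grp in sub.groupby(["cell_id", "homolog"], sort=True):
        arr = np.full((len(pos), 3), np.nan)
        idx = pos.get_indexer(grp["locus_id"])
        arr[idx] = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        instances.append(arr)
    if not instances:
        return np.empty((0, len(pos), 3))
    return np.stack(instances)


def _pairwise_distances(stack: np.ndarray) -> np.ndarray:
    """(n_instances, L, L) Euclidean distances; NaN wherever a locus is absent."""
    diff = stack[:, :, None, :] - stack[:, None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def median_distance_matrix(dataset: TraceDataset, cell_type: str, chrom: str,
                           min_pair_observations: int = DEFAULT_MIN_PAIR_OBSERVATIONS,
                           genotype: str | None = None) -> MatrixSummary:
    """Median over homolog instances of same-homolog cis pairwise distances."""
    cells = dataset.cells_of_type(cell_type, genotype=genotype)
    locus_ids = dataset.panel.loci_for_chrom(chrom)["locus_id"].to_numpy()
    stack = _homolog_coordinate_stack(dataset, set(cells["cell_id"]), chrom, locus_ids)
    L = len(locus_ids)
    if len(stack) == 0:
        med = np.full((L, L), np.nan)
        n = np.zeros((L, L), dtype=int)
    else:
        d = _pairwise_distances(stack)
        n = np.sum(~np.isnan(d), axis=0)
        with np.errstate(all="ignore"):
            med = np.nanmedian(d, axis=0)
        med[n < min_pair_observations] = np.nan
    np.fill_diagonal(med, np.nan)
    return MatrixSummary(cell_type=cell_type, chrom=chrom, kind="median_distance_um",
                         matrix=pd.DataFrame(med, index=locus_ids, columns=locus_ids),
                         n_obs=pd.DataFrame(n, index=locus_ids, columns=locus_ids))


def pairwise_proximity_matrix(dataset: TraceDataset, cell_type: str, chrom: str,
                              threshold_um: float = DEFAULT_PROXIMITY_THRESHOLD_UM,
                              min_pair_observations: int = DEFAULT_MIN_PAIR_OBSERVATIONS,
                              genotype: str | None = None) -> MatrixSummary:
    """Per locus pair, fraction of observed homolog instances with d < threshold."""
    cells = dataset.cells_of_type(cell_type, genotype=genotype)
    locus_ids = dataset.panel.loci_for_chrom(chrom)["locus_id"].to_numpy()
    stack = _homolog_coordinate_stack(dataset, set(cells["cell_id"]), chrom, locus_ids)
    L = len(locus_ids)
    if len(stack) == 0:
        freq = np.full((L, L), np.nan)
        n = np.zeros((L, L), dtype=int)
    else:
        d = _pairwise_distances(stack)
        observed = ~np.isnan(d)
        n = observed.sum(axis=0)
        with np.errstate(invalid="ignore"):
            prox = (d < threshold_um) & observed
            freq = np.where(n > 0, prox.sum(axis=0) / np.maximum(n, 1), np.nan)
        freq[n < min_pair_observations] = np.nan
    np.fill_diagonal(freq, np.nan)
    return MatrixSummary(cell_type=cell_type, chrom=chrom, kind="proximity_frequency",
                         matrix=pd.DataFrame(freq, index=locus_ids, columns=locus_ids),
                         n_obs=pd.DataFrame(n, index=locus_ids, columns=locus_ids))


def proximity_frequency_by_gdist(dataset: TraceDataset, cell_type: str,
                                 gdist_bins: list[tuple[float, float]],
                                 threshold_um: float = DEFAULT_PROXIMITY_THRESHOLD_UM,
                                 genotype: str | None = None) -> pd.DataFrame:
    """Per cell and genomic-distance bin: proximal / measured cis pair ratio.

    ``gdist_bins`` are half-open [lo, hi) bp intervals and must not overlap.
    Cells with no measured pairs in a bin are absent (NaN).
    """
    bins = sorted(gdist_bins)
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if lo2 < hi1:
            raise ValueError("overlapping genomic-distance bins")
    cells = dataset.cells_of_type(cell_type, genotype=genotype)
    cell_ids = set(cells["cell_id"])
    rows = {}
    for chrom in dataset.panel.chroms:
        sub_panel = dataset.panel.loci_for_chrom(chrom)
        locus_ids = sub_panel["locus_id"].to_numpy()
        mids = ((sub_panel["start_bp"] + sub_panel["end_bp"]) // 2).to_numpy()
        gdist = np.abs(mids[:, None] - mids[None, :]).astype(float)
        obs = dataset.observations
        sub = obs[(obs["chrom"] == chrom) & obs["cell_id"].isin(cell_ids)]
        pos = pd.Index(locus_ids)
        for (cell_id, _), grp in sub.groupby(["cell_id", "homolog"], sort=True):
            arr = np.full((len(pos), 3), np.nan)
            arr[pos.get_indexer(grp["locus_id"])] = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            diff = arr[:, None, :] - arr[None, :, :]
            d = np.sqrt(np.sum(diff * diff, axis=-1))
            iu = np.triu_indices(len(pos), k=1)
            d_u, g_u = d[iu], gdist[iu]
            measured = ~np.isnan(d_u)
            for b_idx, (lo, hi) in enumerate(bins):
                in_bin = measured & (g_u >= lo) & (g_u < hi)
                key = (cell_id, b_idx)
                prox, tot = rows.get(key, (0, 0))
                rows[key] = (prox + int(((d_u < threshold_um) & in_bin).sum()),
                             tot + int(in_bin.sum()))
    out = []
    for (cell_id, b_idx), (prox, tot) in sorted(rows.items()):
        lo, hi = bins[b_idx]
        out.append((cell_id, lo, hi, prox, tot,
                    prox / tot if tot > 0 else np.nan))
    return pd.DataFrame(out, columns=["cell_id", "gdist_lo_bp", "gdist_hi_bp",
                                      "n_proximal", "n_measured", "ratio"])


def differential_matrix(summary1: MatrixSummary, summary2: MatrixSummary,
                        panel: LocusPanel,
                        mask_gdist_lt_bp: float = 2_000_000) -> pd.DataFrame:
    """Entrywise (summary2 - summary1); short-range pairs masked absent.

    Pairs present in only one summary are absent; pairs with genomic distance
    below ``mask_gdist_lt_bp`` are masked (the short-range trend dominates
    them and obscures long-range differences).
    """
    if summary1.kind != summary2.kind:
        raise ValueError("summaries differ in kind")
    if summary1.chrom != summary2.chrom:
        raise ValueError("summaries differ in chromosome")
    if list(summary1.matrix.index) != list(summary2.matrix.index):
        raise ValueError("summaries have mismatched locus axes")
    diff = summary2.matrix - summary1.matrix
    gdist = panel.genomic_distance_matrix(summary1.chrom).loc[diff.index, diff.columns]
    return diff.mask(gdist.to_numpy() < mask_gdist_lt_bp)


@dataclass(frozen=True)
class InsulationResult:
    cell_type: str
    chrom: str
    scores: pd.Series  # normalized insulation score per locus; NaN at ends/absent
    iqr: float


def insulation_scores(summary: MatrixSummary, window_loci: int = 4) -> InsulationResult:
    """Normalized insulation score and its IQR on a proximity-frequency matrix.

    IS(i) is the mean of present entries in the off-diagonal block
    {i-w..i-1} x {i+1..i+w}; NIS = IS / mean(IS over valid loci); loci within
    w of either chromosome end are excluded.  Minima of NIS mark domain
    (megadomain) boundaries; a large NIS IQR means prominent domain structure.
    """
    if window_loci < 1:
        raise ValueError("window_loci must be >= 1")
    m = summary.matrix.to_numpy(dtype=float)
    L = m.shape[0]
    if L < 2 * window_loci + 1:
        raise ValueError("chromosome shorter than 2*window + 1 loci")
    raw = np.full(L, np.nan)
    for i in range(window_loci, L - window_loci):
        block = m[i - window_loci:i, i + 1:i + 1 + window_loci]
        if np.isnan(block).all():
            continue
        raw[i] = np.nanmean(block)
    valid = ~np.isnan(raw)
    mean_is = np.nanmean(raw) if valid.any() else np.nan
    if not np.isfinite(mean_is) or mean_is == 0:
        nis = np.full(L, np.nan)
        iqr = np.nan
    else:
        nis = raw / mean_is
        q75, q25 = np.nanpercentile(nis[valid], [75, 25])
        iqr = float(q75 - q25)
    return InsulationResult(cell_type=summary.cell_type, chrom=summary.chrom,
                            scores=pd.Series(nis, index=summary.matrix.index,
                                             name="normalized_insulation"),
                            iqr=iqr)
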