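"""A/B compartment calling from cell-type summary matrices.

The classic pipeline: remove the genomic-distance decay (observed/expected),
correlate matrix rows, eigendecompose, and pick — among the top principal
components — the one best correlated with chromatin accessibility.  The
largest PC is not always the compartment PC: where megadomain structure
dominates, the compartment signal appears on PC2, and accessibility-guided
selection recovers it.  A-compartment loci are those with positive loading
after the eigenvector is oriented so its accessibility correlation is
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LocusPanel
from .matrices import MatrixSummary


# ---------------------------------------------------------------------------
# Genomic-distance expectation (O/E normalization)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedProfile:
    """Mean matrix entry as a function of genomic distance.

    Log-spaced bins (8 per decade); linear interpolation in log-distance with
    clamping to the terminal bins.
    """

    log_centers: np.ndarray
    means: np.ndarray

    def __call__(self, gdist) -> np.ndarray:
        g = np.asarray(gdist, dtype=float)
        out = np.interp(np.log10(np.maximum(g, 1.0)), self.log_centers, self.means)
        return out if out.shape else float(out)


def expected_profile(summary: MatrixSummary, panel: LocusPanel,
                     bins_per_decade: int = 8) -> ExpectedProfile:
    """Fit the distance-decay expectation from present matrix entries."""
    m = summary.matrix.to_numpy(dtype=float)
    gdist = panel.genomic_distance_matrix(summary.chrom).to_numpy(dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    vals, g = m[iu], gdist[iu]
    ok = ~np.isnan(vals) & (g > 0)
    if not ok.any():
        raise ValueError("matrix has no present entries")
    vals, g = vals[ok], g[ok]
    logg = np.log10(g)
    lo, hi = logg.min(), logg.max()
    n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(logg, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        # zero-mean bins (no observed contacts in the band) are undefined for
        # O/E and are skipped; the profile interpolates across them
        if sel.any() and vals[sel].mean() != 0:
            centers.append(logg[sel].mean())
            means.append(vals[sel].mean())
    if not centers:
        raise ValueError("expected profile is zero everywhere")
    return ExpectedProfile(log_centers=np.array(centers), means=np.array(means))


def normalize_matrix(summary: MatrixSummary, g: ExpectedProfile,
                     panel: LocusPanel) -> pd.DataFrame:
    """Observed/expected matrix; absent entries stay absent."""
    m = summary.matrix
    gdist = panel.genomic_distance_matrix(summary.chrom).loc[m.index, m.columns]
    expected = g(gdist.to_numpy())
    if np.any(expected == 0):
        raise ValueError("expected profile is zero at some genomic distance")
    return m / expected


# ---------------------------------------------------------------------------
# Correlation matrix and PC-based calling
# ---------------------------------------------------------------------------


def correlation_matrix(normalized: pd.DataFrame, min_shared: int = 10) -> pd.DataFrame:
    """Pearson correlation of rows i, j over columns k not in {i, j}.

    Entries with fewer than ``min_shared`` mutually present columns, or a
    zero-variance row, are absent.
    """
    m = normalized.to_numpy(dtype=float)
    L = m.shape[0]
    if L < 3:
        raise ValueError("need >= 3 loci")
    out = np.full((L, L), np.nan)
    present = ~np.isnan(m)
    for i in range(L):
        for j in range(i + 1, L):
            cols = present[i] & present[j]
            cols[i] = cols[j] = False
            if cols.sum() < min_shared:
                continue
            xi, xj = m[i, cols], m[j, cols]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            denom = np.sqrt((xi @ xi) * (xj @ xj))
            if denom == 0:
                continue
            out[i, j] = out[j, i] = (xi @ xj) / denom
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)


@dataclass(frozen=True)
class CompartmentCall:
    cell_type: str
    chrom: str
    labels: pd.Series       # locus_id -> A | B | unassigned
    pc_values: pd.Series    # oriented eigenvector loadings
    selected_pc: int        # 1-based
    corr_with_accessibility: float
    matrix_source: str      # proximity | distance

    def assigned(self) -> pd.Series:
        return self.labels[self.labels != "unassigned"]


def call_compartments(corr: pd.DataFrame, accessibility: pd.Series,
                      cell_type: str = "", chrom: str = "", n_pcs: int = 5,
                      matrix_source: str = "proximity",
                      max_absent_fraction: float = 0.5) -> CompartmentCall:
    """Accessibility-guided PC selection on the locus correlation matrix.

    Absent entries are imputed as 0 (diagonal 1) to keep the operator
    symmetric; loci with more than ``max_absent_fraction`` absent entries are
    reported unassigned.  Among the top ``n_pcs`` eigenvectors by eigenvalue
    the one with the largest |Pearson r| against accessibility (over covered
    loci) is selected and sign-flipped so the correlation is >= 0; positive
    loadings are A, negative B, exact zeros unassigned.
    """
    loci = corr.index
    acc = accessibility.reindex(loci)
    covered = acc.notna().to_numpy()
    if covered.sum() < max(2, int(0.5 * len(loci))):
        raise ValueError("accessibility covers fewer than half of the loci")
    m = corr.to_numpy(dtype=float).copy()
    absent_frac = np.isnan(m).mean(axis=1)
    m[np.isnan(m)] = 0.0
    np.fill_diagonal(m, 1.0)
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1][:n_pcs]
    best = None
    for rank, col in enumerate(order, start=1):
        v = evecs[:, col]
        sub_v = v[covered]
        sub_a = acc.to_numpy(dtype=float)[covered]
        if np.ptp(sub_v) == 0 or np.ptp(sub_a) == 0:
            continue
        r = float(stats.pearsonr(sub_v, sub_a).statistic)
        # ties broken by larger eigenvalue (earlier rank wins on strict >)
        if best is None or abs(r) > abs(best[1]):
            best = (rank, r, v)
    if best is None:
        raise ValueError("no usable principal component")
    rank, r, v = best
    if r < 0:
        v, r = -v, -r
    labels = np.where(v > 0, "A", np.where(v < 0, "B", "unassigned"))
    labels[absent_frac > max_absent_fraction] = "unassigned"
    return CompartmentCall(cell_type=cell_type, chrom=chrom,
                           labels=pd.Series(labels, index=loci, name="label"),
                           pc_values=pd.Series(v, index=loci, name="pc_value"),
                           selected_pc=rank, corr_with_accessibility=float(r),
                           matrix_source=matrix_source)


def call_compartments_from_summary(summary: MatrixSummary, panel: LocusPanel,
                                   accessibility: pd.Series, n_pcs: int = 5
                                   ) -> CompartmentCall:
    """Full chain: O/E normalize -> correlate -> accessibility-guided PCA.

    Distance-kind summaries are negated after O/E so that large values mean
    strong interaction in both sources and A/B sign conventions align.
    """
    g = expected_profile(summary, panel)
    oe = normalize_matrix(summary, g, panel)
    source = "proximity" if summary.kind == "proximity_frequency" else "distance"
    if source == "distance":
        oe = -oe
    corr = correlation_matrix(oe)
    return call_compartments(corr, accessibility, cell_type=summary.cell_type,
                             chrom=summary.chrom, n_pcs=n_pcs, matrix_source=source)


# ---------------------------------------------------------------------------
# Compartment switching between cell types
# ---------------------------------------------------------------------------

_SWITCH_CLASSES = ("A->A", "A->B", "B->A", "B->B")


@dataclass(frozen=True)
class SwitchTable:
    classes: pd.Series   # locus_id -> A->A | A->B | B->A | B->B | excluded
    fractions: dict      # class -> fraction over assigned loci

    @property
    def switched_fraction(self) -> float:
        return self.fractions["A->B"] + self.fractions["B->A"]


def compartment_switching(call_x: CompartmentCall, call_y: CompartmentCall) -> SwitchTable:
    """Per-locus compartment conservation/switch classes from X to Y."""
    if list(call_x.labels.index) != list(call_y.labels.index):
        raise ValueError("calls have mismatched locus axes")
    lx, ly = call_x.labels, call_y.labels
    classes = pd.Series("excluded", index=lx.index, name="switch_class")
    ok = (lx != "unassigned") & (ly != "unassigned")
    classes[ok] = lx[ok] + "->" + ly[ok]
    n_assigned = int(ok.sum())
    fractions = {c: (float((classes == c).sum()) / n_assigned if n_assigned else np.nan)
                 for c in _SWITCH_CLASSES}
    return SwitchTable(classes=classes, fractions=fractions)


def switch_expression_analysis(switch: SwitchTable, expr_x: pd.Series, expr_y: pd.Series,
                               pseudocount: float = 1.0) -> dict:
    """Per-class log2 fold change of expression with ANOVA + Tukey HSD.

    log2FC = log2((expr_y + pc) / (expr_x + pc)) per locus; classes with
    fewer than 2 loci are dropped with a warning entry.
    """
    lfc = np.log2((expr_y.reindex(switch.classes.index) + pseudocount)
                  / (expr_x.reindex(switch.classes.index) + pseudocount))
    groups, dropped = {}, []
    for cls in _SWITCH_CLASSES:
        vals = lfc[(switch.classes == cls) & lfc.notna()].to_numpy(dtype=float)
        if len(vals) >= 2:
            groups[cls] = vals
        elif len(vals) > 0 or (switch.classes == cls).any():
            dropped.append(cls)
    result = {"log2fc_by_class": groups, "dropped_classes": dropped,
              "f_statistic": None, "anova_p": None, "tukey": None}
    if len(groups) >= 2:
        vals = list(groups.values())
        if np.ptp(np.concatenate(vals)) == 0:
            result["f_statistic"] = 0.0
            result["anova_p"] = 1.0
            return result
        f = stats.f_oneway(*vals)
        result["f_statistic"] = float(f.statistic)
        result["anova_p"] = float(f.pvalue)
        tk = stats.tukey_hsd(*vals)
        names = list(groups)
        result["tukey"] = {
            f"{names[i]} vs {names[j]}": float(tk.pvalue[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))
        }
    return result
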