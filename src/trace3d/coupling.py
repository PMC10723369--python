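"""Coupling chromatin geometry to transcription.

Radial-position/activity profiles, gene-to-locus mapping, Welch-t
differential-expression scores, binned profiles with normal-approximation
confidence intervals, and WT-vs-KO genotype deltas with the associated
group tests (Mann-Whitney + Benjamini-Hochberg, Student t + Bonferroni,
one-way ANOVA + Tukey HSD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, LocusPanel


# ---------------------------------------------------------------------------
# Radial activity profiles and correlations
# ---------------------------------------------------------------------------


def radial_activity_fractions(radial: pd.Series, track: pd.Series,
                              n_bins: int = 10, pct: float = 25.0
                              ) -> pd.DataFrame:
    """Radial distribution of the most- and least-active loci.

    High set = top ``pct`` percent of loci by track value, low = bottom
    ``pct`` percent (ties included at the threshold).  Loci are binned by
    radial position into ``n_bins`` equal-width bins on [0, 1]; the per-bin
    fractions of each set are reported and each curve sums to 1.
    """
    shared = radial.index.intersection(track.index)
    if len(shared) < len(radial) / 2:
        raise ValueError("track covers fewer than half of the loci")
    r = radial[shared].to_numpy(dtype=float)
    t = track[shared].to_numpy(dtype=float)
    hi_thr = np.percentile(t, 100 - pct)
    lo_thr = np.percentile(t, pct)
    high = t >= hi_thr
    low = t <= lo_thr
    if not high.any() or not low.any():
        raise ValueError("empty high/low activity set")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        rows.append((edges[b], edges[b + 1],
                     float((sel & high).sum() / high.sum()),
                     float((sel & low).sum() / low.sum()),
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "frac_high", "frac_low", "n_loci"])


def radial_track_correlation(radial: pd.Series, track: pd.Series,
                             min_loci: int = 10) -> dict:
    """Spearman (and Pearson) correlation of per-locus radial position vs track."""
    shared = radial.index.intersection(track.index)
    if len(shared) < min_loci:
        raise ValueError(f"fewer than {min_loci} covered loci")
    r = radial[shared].to_numpy(dtype=float)
    t = track[shared].to_numpy(dtype=float)
    if np.ptp(t) == 0 or np.ptp(r) == 0:
        return {"spearman_r": None, "spearman_p": None,
                "pearson_r": None, "pearson_p": None, "n": len(shared)}
    sr = stats.spearmanr(r, t)
    pr = stats.pearsonr(r, t)
    return {"spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "n": int(len(shared))}


# ---------------------------------------------------------------------------
# Gene-to-locus mapping and DE scores
# ---------------------------------------------------------------------------


def map_genes_to_loci(genes: pd.DataFrame, panel: LocusPanel,
                      max_distance_bp: int | None = None) -> pd.DataFrame:
    """Nearest panel locus by |TSS - midpoint| on the same chromosome.

    Ties go to the locus with the lower start coordinate; genes on
    chromosomes absent from the panel, or beyond ``max_distance_bp``, are
    unmapped (NaN locus).
    """
    pdf = panel.df
    rows = []
    for _, g in genes.iterrows():
        sub = pdf[pdf["chrom"] == g["tss_chrom"]]
        if sub.empty:
            rows.append((g["gene_id"], np.nan, np.nan))
            continue
        mid = ((sub["start_bp"] + sub["end_bp"]) // 2).to_numpy()
        dist = np.abs(mid - int(g["tss_bp"]))
        best = int(np.argmin(dist))  # argmin takes the first = lower start_bp
        if max_distance_bp is not None and dist[best] > max_distance_bp:
            rows.append((g["gene_id"], np.nan, np.nan))
            continue
        rows.append((g["gene_id"], sub["locus_id"].iloc[best], int(dist[best])))
    return pd.DataFrame(rows, columns=["gene_id", "locus_id", "mapping_distance_bp"])


def normalize_counts(counts: pd.DataFrame, target: float = 10_000.0) -> pd.DataFrame:
    """Counts-per-``target`` per cell followed by log1p."""
    totals = counts.sum(axis=0)
    scaled = counts / totals.replace(0, np.nan) * target
    return np.log1p(scaled.fillna(0.0))


def de_score(expr: ExpressionMatrix, gene: str, group_a: list[str], group_b: list[str],
             pre_normalized: pd.DataFrame | None = None) -> float:
    """Welch two-sample t statistic for one gene, oriented group B - group A.

    Counts are library-normalized to 10k per cell and log1p-transformed
    unless ``pre_normalized`` values are supplied.  NaN when both groups have
    zero variance or a group has fewer than 2 cells.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 cells")
    norm = pre_normalized if pre_normalized is not None else normalize_counts(expr.counts)
    a = norm.loc[gene, group_a].to_numpy(dtype=float)
    b = norm.loc[gene, group_b].to_numpy(dtype=float)
    return welch_t(a, b)


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t oriented b - a; NaN when both samples are constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return float("nan")
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic)


def de_score_table(expr: ExpressionMatrix, group_a: list[str], group_b: list[str],
                   panel: LocusPanel, max_distance_bp: int | None = None) -> pd.DataFrame:
    """Welch-t DE scores for every gene, with nearest-locus mapping."""
    norm = normalize_counts(expr.counts)
    mapping = map_genes_to_loci(expr.genes, panel, max_distance_bp=max_distance_bp)
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    t_stats = [welch_t(a[i], b[i]) for i in range(a.shape[0])]
    out = mapping.copy()
    out["t_statistic"] = t_stats
    out["n_a"] = len(group_a)
    out["n_b"] = len(group_b)
    return out


# ---------------------------------------------------------------------------
# Binned profiles and genotype deltas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedProfile:
    table: pd.DataFrame  # bin, n, mean, ci95, x_lo, x_hi


def binned_profile(x: np.ndarray, y: np.ndarray, n_bins: int,
                   scheme: str = "equal_count") -> BinnedProfile:
    """Bin y by x; per bin report mean(y) and 95% CI (1.96 * sd / sqrt(n)).

    equal_count (default): quantile-like cuts with bin sizes differing by at
    most 1; ties broken by stable input order.  equal_width: uniform cuts
    over [min(x), max(x)].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < n_bins:
        raise ValueError("fewer items than bins")
    if scheme == "equal_count":
        order = np.argsort(x, kind="stable")
        sizes = np.full(n_bins, len(x) // n_bins)
        sizes[: len(x) % n_bins] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        members = [order[bounds[b]:bounds[b + 1]] for b in range(n_bins)]
    elif scheme == "equal_width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        members = [np.flatnonzero(idx == b) for b in range(n_bins)]
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    rows = []
    for b, mem in enumerate(members):
        if len(mem) == 0:
            rows.append((b, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        vals = y[mem]
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append((b, len(mem), float(vals.mean()),
                     float(1.96 * sd / np.sqrt(len(vals))),
                     float(x[mem].min()), float(x[mem].max())))
    return BinnedProfile(table=pd.DataFrame(
        rows, columns=["bin", "n", "mean", "ci95", "x_lo", "x_hi"]))


def genotype_delta(profile_wt: pd.Series, profile_ko: pd.Series) -> pd.Series:
    """Per-locus KO - WT difference of a cell-type locus profile.

    Loci absent from either profile are absent from the delta.  Downstream
    radial binning conventionally uses the WT profile as the x axis.
    """
    shared = profile_wt.index.intersection(profile_ko.index)
    return (profile_ko[shared] - profile_wt[shared]).rename("delta")


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def group_comparison(groups: dict[str, np.ndarray], test: str) -> dict:
    """Pairwise/omnibus tests with the stated multiple-testing correction.

    test: ``mwu_bh`` (pairwise two-sided Mann-Whitney U, Benjamini-Hochberg),
    ``ttest_bonferroni`` (pairwise Welch t, Bonferroni), ``anova_tukey``
    (one-way ANOVA F + Tukey HSD).  Groups smaller than 2 are skipped with a
    warning entry.
    """
    names = [k for k, v in groups.items() if len(v) >= 2]
    skipped = [k for k in groups if k not in names]
    if len(names) < 2:
        return {"test": test, "results": {}, "skipped": skipped,
                "warning": "fewer than two usable groups"}
    out: dict = {"test": test, "skipped": skipped}
    if test == "anova_tukey":
        vals = [np.asarray(groups[k], dtype=float) for k in names]
        if np.ptp(np.concatenate(vals)) == 0:
            out["f_statistic"], out["anova_p"], out["tukey"] = 0.0, 1.0, {}
            return out
        f = stats.f_oneway(*vals)
        tk = stats.tukey_hsd(*vals)
        out["f_statistic"] = float(f.statistic)
        out["anova_p"] = float(f.pvalue)
        out["tukey"] = {f"{names[i]} vs {names[j]}": float(tk.pvalue[i, j])
                        for i in range(len(names)) for j in range(i + 1, len(names))}
        return out
    pairs, raw_p, statistic = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if test == "mwu_bh":
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
            elif test == "ttest_bonferroni":
                if np.ptp(a) == 0 and np.ptp(b) == 0:
                    res = None
                else:
                    res = stats.ttest_ind(a, b, equal_var=False)
            else:
                raise ValueError(f"unknown test {test!r}")
            pairs.append(f"{names[i]} vs {names[j]}")
            statistic.append(float(res.statistic) if res is not None else 0.0)
            raw_p.append(float(res.pvalue) if res is not None else 1.0)
    method = "fdr_bh" if test == "mwu_bh" else "bonferroni"
    adj = multipletests(raw_p, method=method)[1] if raw_p else []
    out["results"] = {pair: {"statistic": s, "p_raw": p, "p_adjusted": float(q)}
                      for pair, s, p, q in zip(pairs, statistic, raw_p, adj)}
    return out


def one_sample_shift_tests(groups: dict[str, np.ndarray], popmean: float = 0.0) -> dict:
    """One-sample Student t of each group against ``popmean``, Bonferroni over groups.

    Used for location-shift questions (e.g. does the KO - WT delta of
    compartment-A loci differ from zero) where the comparison is against a
    fixed null value rather than another group.
    """
    names = [k for k, v in groups.items() if len(v) >= 2]
    raw = []
    stats_out = {}
    for k in names:
        res = stats.ttest_1samp(np.asarray(groups[k], dtype=float), popmean)
        stats_out[k] = {"statistic": float(res.statistic), "p_raw": float(res.pvalue)}
        raw.append(float(res.pvalue))
    adj = multipletests(raw, method="bonferroni")[1] if raw else []
    for k, q in zip(names, adj):
        stats_out[k]["p_adjusted"] = float(q)
    return stats_out
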