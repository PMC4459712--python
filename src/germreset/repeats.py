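"""Retrotransposon methylation and expression dynamics.

Per-locus coverage-filtered methylation, per-family summaries ordered by
evolutionary age, the close-to-full-length "active locus" filter, Pearson
methylation-expression correlation per subfamily, and quadrant
classification of differentially expressed repeat loci.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylomeTrack, RegionSet, ValidationError, GenomeLayout
from .tiling import CoverageFilter, quantify_regions

logger = logging.getLogger("germreset")

# Minimum lengths for near-full-length, potentially retrotransposition-
# competent loci.  Data-driven: annotations may override via the same table.
DEFAULT_FAMILY_INFO = pd.DataFrame([
    # family, age_rank (smaller = younger), active_min_length (bp; NaN = n/a)
    ("SVA",     1, 1600),
    ("L1HS",    1, 6000),
    ("AluY",    2, 268),
    ("AluYa-Yk", 2, 268),
    ("L1PA",    3, np.nan),
    ("ERV1",    4, np.nan),
    ("AluS",    5, np.nan),
    ("L1PB",    6, np.nan),
    ("AluJ",    7, np.nan),
    ("L1MA_ME", 8, np.nan),
], columns=["family", "age_rank", "active_min_length"])

REPEAT_FILTER = CoverageFilter(min_cpgs=5, min_depth=5, min_covered_frac=1e-9)


def repeat_locus_methylation(tracks: list[MethylomeTrack], repeats: RegionSet,
                             filt: CoverageFilter = REPEAT_FILTER,
                             layout: GenomeLayout | None = None,
                             common_only: bool = True) -> pd.DataFrame:
    """Per-locus coverage-weighted methylation for each sample.

    A locus needs >= ``filt.min_cpgs`` CpGs at >= ``filt.min_depth`` in a
    sample to be quantified there; with ``common_only`` the table keeps only
    loci passing in every sample (the "common repeat loci" set).
    """
    if "family" not in repeats.df.columns:
        raise ValidationError("repeats must carry family attributes")
    base = repeats.df[["name", "chrom", "start", "end", "family"]].copy()
    if "subfamily" in repeats.df.columns:
        base["subfamily"] = repeats.df["subfamily"]
    else:
        base["subfamily"] = repeats.df["family"]
    if "age_rank" in repeats.df.columns:
        base["age_rank"] = repeats.df["age_rank"]
    # repeat-locus filtering counts covered CpGs, not a covered fraction:
    # require min_cpgs CpGs at depth, regardless of locus CpG total
    for tr in tracks:
        q = quantify_regions(tr, repeats, CoverageFilter(
            min_cpgs=1, min_depth=filt.min_depth, min_covered_frac=1e-9), layout)
        lv = q["level"].to_numpy()
        lv = np.where(q["covered"].to_numpy() >= filt.min_cpgs, lv, np.nan)
        base[tr.sample_id] = lv
    sample_cols = [t.sample_id for t in tracks]
    if common_only:
        base = base[~base[sample_cols].isna().any(axis=1)].reset_index(drop=True)
    return base


def family_summary(locus_levels: pd.DataFrame,
                   locus_expression: pd.DataFrame | None = None,
                   family_info: pd.DataFrame = DEFAULT_FAMILY_INFO) -> dict:
    """Per-family mean methylation (and expression) per sample, ordered by
    evolutionary age, with a Spearman age-trend report per sample.

    Families present in ``family_info`` but with every locus filtered out
    are flagged absent rather than reported as zero.
    """
    meta_cols = [c for c in ["name", "chrom", "start", "end", "family",
                             "subfamily", "age_rank"] if c in locus_levels.columns]
    sample_cols = [c for c in locus_levels.columns if c not in meta_cols]
    info = family_info.set_index("family")
    grouped = locus_levels.groupby("family")
    rows = []
    for fam, sub in grouped:
        rank = info["age_rank"].get(fam, np.nan)
        row = {"family": fam, "age_rank": rank, "n_loci": len(sub)}
        for s in sample_cols:
            row[f"meth_{s}"] = float(sub[s].mean())
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("age_rank").reset_index(drop=True)
    absent = sorted(set(family_info["family"]) - set(summary["family"]))
    if locus_expression is not None:
        expr_cols = [c for c in locus_expression.columns if c != "name"]
        joined = locus_levels[["name", "family"]].merge(locus_expression, on="name")
        em = joined.groupby("family")[expr_cols].mean()
        for s in expr_cols:
            summary[f"expr_{s}"] = summary["family"].map(em[s])
    age_trend = {}
    ok = summary["age_rank"].notna()
    for s in sample_cols:
        if ok.sum() >= 3:
            rho, p = stats.spearmanr(summary.loc[ok, "age_rank"],
                                     summary.loc[ok, f"meth_{s}"])
            age_trend[s] = {"spearman_rho": float(rho), "p": float(p)}
    return {"summary": summary, "absent_families": absent, "age_trend": age_trend}


def filter_active_loci(repeats: RegionSet,
                       family_info: pd.DataFrame = DEFAULT_FAMILY_INFO) -> RegionSet:
    """Keep loci strictly longer than their family's near-full-length
    threshold (AluY/AluYa-Yk > 268 bp, L1HS > 6,000 bp, SVA > 1,600 bp).
    Loci of families without a threshold pass with a warning."""
    df = repeats.df
    thresholds = family_info.set_index("family")["active_min_length"]
    lengths = (df["end"] - df["start"]).to_numpy()
    fam_col = df["subfamily"] if "subfamily" in df.columns else df["family"]
    thr = fam_col.map(thresholds)
    # fall back to family-level threshold for subfamilies without one
    if "family" in df.columns:
        thr = thr.fillna(df["family"].map(thresholds))
    missing = thr.isna()
    if missing.any():
        logger.warning("%d locus/loci of families without an active-length "
                       "threshold pass unfiltered", int(missing.sum()))
    keep = missing | (lengths > thr.fillna(-1).to_numpy())
    return RegionSet(df[keep.to_numpy()].reset_index(drop=True))


def methylation_expression_correlation(locus_levels: pd.DataFrame,
                                       locus_log2_expr: pd.Series,
                                       sample: str,
                                       group_col: str = "subfamily",
                                       min_loci: int = 3) -> pd.DataFrame:
    """Pearson correlation between per-locus methylation (one sample) and
    log2 expression, per repeat subfamily.  Zero-variance groups report
    NaN r."""
    joined = locus_levels[["name", group_col, sample]].merge(
        locus_log2_expr.rename("log2_expr"), left_on="name", right_index=True)
    rows = []
    for grp, sub in joined.groupby(group_col):
        x = sub[sample].to_numpy(float)
        y = sub["log2_expr"].to_numpy(float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if len(x) < min_loci:
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((grp, len(x), np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((grp, len(x), float(r), float(p)))
    return pd.DataFrame(rows, columns=[group_col, "n_loci", "pearson_r", "p"])


def differential_repeat_loci(de_table: pd.DataFrame, meth_diff: pd.Series,
                             lfc_min: float = 2.0, p_max: float = 0.05,
                             min_expr_log2: float = 1.0) -> pd.DataFrame:
    """Quadrant classification of repeat loci from a DE table and a
    methylation difference.

    Labels: ``up``/``down`` for significant fold changes at adequate
    expression, ``low-expressed`` when max log2 counts < 0, else ``ns``.
    ``de_table`` needs columns log2fc, p, max_log2_count (from
    expression.differential_expression run on repeat loci).
    """
    out = de_table.copy()
    out["meth_diff"] = meth_diff.reindex(out.index)
    expr = out["max_log2_count"].to_numpy(float)
    lfc = out["log2fc"].to_numpy(float)
    p = out["p"].to_numpy(float)
    label = np.full(len(out), "ns", dtype=object)
    label[expr < 0] = "low-expressed"
    sig = (expr >= min_expr_log2) & (np.abs(lfc) > lfc_min) & (p < p_max)
    label[sig & (lfc > 0)] = "up"
    label[sig & (lfc < 0)] = "down"
    out["quadrant"] = label
    return out
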