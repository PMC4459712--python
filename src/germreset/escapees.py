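"""Detection and characterisation of demethylation escapees.

Escapees are regions that retain >=30% CpG methylation in otherwise
globally demethylated germ-cell methylomes.  Candidate windows are tested
for hypermethylation against the genome-wide background with a one-sided
binomial test (BH-corrected), filtered on the mean-methylation threshold,
merged, and then classified by repeat context, annotated by genomic
feature, scored for inter-individual variation, assigned to genes, and
compared across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, GenomeLayout, MethylomeTrack, RegionSet, ValidationError
from .tiling import (CoverageFilter, DEFAULT_FILTER, TileSet, _interval_overlap_bp,
                     _interval_stats, make_tiles, quantify_regions)

logger = logging.getLogger("germreset")

FEATURE_CATEGORIES = ["enhancer", "CGI", "promoter", "gene_body", "intergenic"]


@dataclass(frozen=True)
class EscapeeCallParams:
    min_meth: float = 0.30
    tile_size: int = 1000
    step: int = 500
    merge_gap: int = 1000
    alpha: float = 0.01
    repeat_frac: float = 0.10
    free_dist: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.min_meth < 1:
            raise ValidationError("min_meth must be in (0, 1)")
        if not 0 < self.repeat_frac < 1:
            raise ValidationError("repeat_frac must be in (0, 1)")


@dataclass
class EscapeeCallResult:
    regions: pd.DataFrame       # chrom,start,end,name,n_cpgs,level + per-track levels
    summary: dict               # n, median sizes, background rate


def call_escapees(tracks: list[MethylomeTrack], layout: GenomeLayout,
                  params: EscapeeCallParams = EscapeeCallParams(),
                  required_tracks: list[MethylomeTrack] | None = None,
                  filt: CoverageFilter = DEFAULT_FILTER,
                  tiles: TileSet | None = None) -> EscapeeCallResult:
    """Call significantly hypermethylated regions in hypomethylated methylomes.

    ``tracks`` are pooled per window; each window's pooled counts are tested
    one-sided against the pooled genome-wide background rate (binomial, BH
    q < alpha) and must reach ``min_meth`` coverage-weighted methylation.
    Candidate windows within ``merge_gap`` bp are merged; a merged region is
    kept only if its coverage-weighted mean is >= min_meth in the pooled data
    and in every ``required_tracks`` entry (individual methylomes).
    """
    from .tiling import pool_replicates

    if not tracks:
        raise ValidationError("no tracks given")
    pooled = tracks[0] if len(tracks) == 1 else pool_replicates(tracks, allow_mixed=True)
    background = pooled.global_level(exclude=layout.spike_chrom)
    if background >= params.min_meth:
        logger.warning("global background %.3f >= min_meth %.2f: caller is designed "
                       "for hypomethylated genomes", background, params.min_meth)
    if tiles is None:
        tiles = make_tiles(layout, params.tile_size, params.step)
    t = tiles.tiles
    sum_m = np.zeros(len(t), dtype=np.int64)
    sum_t = np.zeros(len(t), dtype=np.int64)
    n_cov = np.zeros(len(t), dtype=np.int64)
    for chrom, sub in t.groupby("chrom", sort=False):
        sm, st, nc = _interval_stats(pooled, chrom, sub["start"].to_numpy(),
                                     sub["end"].to_numpy(), filt.min_depth)
        sum_m[sub.index] = sm
        sum_t[sub.index] = st
        n_cov[sub.index] = nc
    n_cpgs = t["n_cpgs"].to_numpy()
    testable = ((n_cpgs >= filt.min_cpgs)
                & (n_cov >= filt.min_covered_frac * n_cpgs)
                & (sum_t > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(sum_t > 0, sum_m / np.maximum(sum_t, 1), np.nan)
    pvals = np.ones(len(t))
    idx = np.flatnonzero(testable)
    pvals[idx] = stats.binom.sf(sum_m[idx] - 1, sum_t[idx], background)
    qvals = np.ones(len(t))
    if len(idx):
        qvals[idx] = multipletests(pvals[idx], method="fdr_bh")[1]
    candidate = testable & (qvals < params.alpha) & (level >= params.min_meth)

    cand = t[candidate]
    window_sizes = (cand["end"] - cand["start"]).to_numpy()
    merged_rows = []
    for chrom, sub in cand.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + params.merge_gap:
                cur_e = max(cur_e, e)
            else:
                merged_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged_rows.append((chrom, cur_s, cur_e))

    # refine merged boundaries to the outermost methylated stretch: window
    # merging overshoots the true region edge by up to a window, so trim to
    # the first/last position where the local (3-CpG, depth-filtered) pooled
    # level still reaches half the call threshold; the region-mean filter
    # below re-asserts the full threshold
    kernel = np.ones(3)
    edge_level = params.min_meth / 2
    refined = []
    for chrom, s, e in merged_rows:
        pos, meth, unmeth = pooled.chrom_arrays(chrom)
        i0, i1 = np.searchsorted(pos, s), np.searchsorted(pos, e)
        p = pos[i0:i1]
        m = meth[i0:i1].astype(float)
        d = (m + unmeth[i0:i1]).astype(float)
        ok = d >= filt.min_depth
        sm = np.convolve(np.where(ok, m, 0), kernel, mode="same")
        sd = np.convolve(np.where(ok, d, 0), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            good = (sd > 0) & (sm / np.maximum(sd, 1e-9) >= edge_level)
        if good.any():
            refined.append((chrom, int(p[good][0]), int(p[good][-1]) + 2))
        else:
            refined.append((chrom, s, e))
    merged_rows = refined

    regions = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    if len(regions):
        regions["name"] = [f"escapee_{i + 1}" for i in range(len(regions))]
        rs = RegionSet(regions, category="escapee")
        q = quantify_regions(pooled, rs, filt, layout)
        regions["n_cpgs"] = q["n_cpgs"].to_numpy()
        regions["level"] = q["level"].to_numpy()
        keep = ~np.isnan(regions["level"]) & (regions["level"] >= params.min_meth)
        for tr in (required_tracks or []):
            qi = quantify_regions(tr, rs, filt, layout)
            regions[f"level_{tr.sample_id}"] = qi["level"].to_numpy()
            keep &= ~np.isnan(qi["level"]) & (qi["level"] >= params.min_meth)
        regions = regions[keep].reset_index(drop=True)
    else:
        regions = pd.DataFrame(columns=["chrom", "start", "end", "name", "n_cpgs", "level"])
    sizes = (regions["end"] - regions["start"]).to_numpy() if len(regions) else np.empty(0)
    summary = {
        "n_escapees": int(len(regions)),
        "background_rate": float(background),
        "median_size_merged": float(np.median(sizes)) if len(sizes) else float("nan"),
        "median_size_windows": float(np.median(window_sizes)) if len(window_sizes) else float("nan"),
        "n_candidate_windows": int(candidate.sum()),
    }
    return EscapeeCallResult(regions=regions, summary=summary)


# ---------------------------------------------------------------------------
# Classification and annotation
# ---------------------------------------------------------------------------

def repeat_class_percentages(n_total: int, n_repeat_poor: int) -> dict:
    """Percentages of repeat-rich and repeat-poor escapees from class counts,
    rounded to one decimal (the partition repeat_rich + repeat_poor = all)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    rich = n_total - n_repeat_poor
    return {
        "repeat_rich_pct": round(100.0 * rich / n_total, 1),
        "repeat_poor_pct": round(100.0 * n_repeat_poor / n_total, 1),
    }


def classify_by_repeat(escapees: pd.DataFrame, repeats: RegionSet,
                       params: EscapeeCallParams = EscapeeCallParams()) -> tuple[pd.DataFrame, dict]:
    """Classify escapees as repeat_rich (>= repeat_frac overlap with repeats),
    repeat_poor (< repeat_frac), and flag repeat_free (repeat_poor with no
    repeat within free_dist bp).  Returns the annotated table and summary
    counts/percentages."""
    if not len(repeats):
        raise ValidationError("repeats RegionSet is empty")
    out = escapees.copy()
    frac = np.zeros(len(out))
    free = np.ones(len(out), dtype=bool)
    for chrom, sub in out.groupby("chrom", sort=False):
        rs, re = repeats.merged_arrays(chrom)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if len(rs):
            ov = _interval_overlap_bp(s, e, rs, re)
            frac[sub.index.to_numpy() if hasattr(sub.index, "to_numpy") else sub.index] = ov / (e - s)
            free_ov = _interval_overlap_bp(np.maximum(s - params.free_dist, 0),
                                           e + params.free_dist, rs, re)
            free[sub.index] = free_ov == 0
    out["repeat_overlap_frac"] = frac
    out["repeat_class"] = np.where(frac >= params.repeat_frac, "repeat_rich", "repeat_poor")
    out["is_repeat_free"] = (out["repeat_class"] == "repeat_poor") & free
    counts = {
        "n_total": int(len(out)),
        "n_repeat_rich": int((out["repeat_class"] == "repeat_rich").sum()),
        "n_repeat_poor": int((out["repeat_class"] == "repeat_poor").sum()),
        "n_repeat_free": int(out["is_repeat_free"].sum()),
    }
    summary = dict(counts)
    if counts["n_total"]:
        summary.update(repeat_class_percentages(counts["n_total"], counts["n_repeat_poor"]))
    return out, summary


def annotate_features(escapees: pd.DataFrame,
                      annotations: dict[str, RegionSet]) -> tuple[pd.DataFrame, dict]:
    """Label each escapee with every overlapping feature class (enhancer,
    CGI, promoter, gene_body); regions overlapping nothing are intergenic.
    Returns the table with a ``features`` column plus a count distribution."""
    out = escapees.copy()
    feats = []
    for _, r in out.iterrows():
        hit = set()
        for name, rset in annotations.items():
            if len(rset) and len(rset.overlapping(r["chrom"], int(r["start"]), int(r["end"]))):
                hit.add(name)
        if not hit:
            hit = {"intergenic"}
        feats.append(sorted(hit))
    out["features"] = feats
    dist = {c: 0 for c in list(annotations) + ["intergenic"]}
    for f in feats:
        for c in f:
            dist[c] = dist.get(c, 0) + 1
    return out, dist


@dataclass(frozen=True)
class VariationFilterParams:
    """Filters for the inter-individual variation analysis: the region must
    reach min_max_meth in at least one individual and be well covered
    (min_cpgs, min_covered_frac at min_depth) in every individual."""

    min_max_meth: float = 0.40
    min_cpgs: int = 10
    min_covered_frac: float = 0.20
    min_depth: int = 5


def escapee_variation(escapees: pd.DataFrame,
                      individual_tracks: list[MethylomeTrack],
                      vparams: VariationFilterParams = VariationFilterParams(),
                      layout: GenomeLayout | None = None) -> dict:
    """Coefficient of variation of escapee methylation across individuals,
    plus pairwise Pearson correlations between individuals.

    CV uses the sample (n-1) standard deviation.  Regions failing the
    coverage filter in any individual or never reaching ``min_max_meth`` are
    dropped.
    """
    if len(individual_tracks) < 2:
        raise ValidationError("need >= 2 individual tracks")
    filt = CoverageFilter(min_cpgs=vparams.min_cpgs, min_depth=vparams.min_depth,
                          min_covered_frac=vparams.min_covered_frac)
    rset = RegionSet(escapees[["chrom", "start", "end", "name"]].copy(),
                     category="escapee")
    levels = {}
    for tr in individual_tracks:
        q = quantify_regions(tr, rset, filt, layout)
        levels[tr.sample_id] = q["level"].to_numpy()
    L = pd.DataFrame(levels, index=escapees["name"].to_numpy())
    ok = ~L.isna().any(axis=1) & (L.max(axis=1) >= vparams.min_max_meth)
    L = L[ok]
    mean = L.mean(axis=1)
    sd = L.std(axis=1, ddof=1)
    cv = sd / mean
    table = pd.DataFrame({"name": L.index, "mean": mean.to_numpy(),
                          "sd": sd.to_numpy(), "cv": cv.to_numpy()})
    pearson = L.corr(method="pearson") if len(L) >= 2 else None
    return {"table": table, "levels": L, "pearson": pearson,
            "n_regions": int(len(L))}


def genes_with_escapees(escapees: pd.DataFrame, genes: GeneSet,
                        min_meth: float = 0.30,
                        level_col: str = "level") -> set[str]:
    """Gene ids whose gene body (TSS-TES) overlaps at least one escapee with
    methylation above ``min_meth``."""
    lv = escapees[level_col].to_numpy(float) if level_col in escapees.columns \
        else np.full(len(escapees), 1.0)
    qual = escapees[~np.isnan(lv) & (lv > min_meth)]
    bodies = genes.gene_bodies()
    hit: set[str] = set()
    for _, r in qual.iterrows():
        ov = bodies.overlapping(r["chrom"], int(r["start"]), int(r["end"]))
        hit.update(ov["name"].tolist())
    return hit


# ---------------------------------------------------------------------------
# Cross-species comparisons
# ---------------------------------------------------------------------------

def homolog_overlap_test(set_a: set[str], set_b: set[str],
                         universe: set[str]) -> tuple[int, float]:
    """Overlap of two gene sets within an ortholog universe with a
    hypergeometric tail probability P(X >= observed).

    Population = |universe|, successes = |set_a|, draws = |set_b|.
    """
    stray_a = set(set_a) - set(universe)
    stray_b = set(set_b) - set(universe)
    if stray_a or stray_b:
        raise ValidationError(
            f"gene sets not subsets of universe; offenders: "
            f"A={sorted(stray_a)[:5]} B={sorted(stray_b)[:5]}")
    k = len(set(set_a) & set(set_b))
    M, n, N = len(universe), len(set_a), len(set_b)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return k, p


def conservation_report(n_conserved_regions: int,
                        n_methylated_orthologs: int) -> dict:
    """Bookkeeping for cross-species escapee conservation: the share of
    sequence-conserved escapee regions whose orthologous region stays
    methylated (>10%) in the other species, as a nearest-integer percent."""
    if n_conserved_regions <= 0:
        raise ValidationError("n_conserved_regions must be positive")
    pct = 100.0 * n_methylated_orthologs / n_conserved_regions
    return {
        "n_conserved_regions": int(n_conserved_regions),
        "n_methylated_orthologs": int(n_methylated_orthologs),
        "methylated_pct": int(round(pct)),
    }


# ---------------------------------------------------------------------------
# Enrichment and fate
# ---------------------------------------------------------------------------

def region_overlap_enrichment(escapees: pd.DataFrame, annotation: RegionSet,
                              layout: GenomeLayout, n_perm: int = 1000,
                              seed: int = 0) -> dict:
    """Fold enrichment of escapee overlap with an annotation versus random
    length-matched placement on the same chromosomes, with an empirical
    p-value (+1 correction)."""
    if not len(annotation):
        raise ValidationError("annotation is empty")
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: empirical p will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    merged = {c: annotation.merged_arrays(c) for c in layout.genomic_chroms()}

    def overlap_fraction(chroms, starts, ends):
        total_bp = int(np.sum(ends - starts))
        ov = 0
        for c in np.unique(chroms):
            rs, re = merged.get(c, (np.empty(0, np.int64), np.empty(0, np.int64)))
            if not len(rs):
                continue
            m = chroms == c
            ov += int(_interval_overlap_bp(starts[m], ends[m], rs, re).sum())
        return ov / total_bp if total_bp else 0.0

    chroms = escapees["chrom"].to_numpy()
    starts = escapees["start"].to_numpy(np.int64)
    ends = escapees["end"].to_numpy(np.int64)
    lengths = ends - starts
    observed = overlap_fraction(chroms, starts, ends)
    chrom_len = np.array([layout.chrom_lengths[c] for c in chroms], dtype=np.int64)
    perm_fracs = np.empty(n_perm)
    for i in range(n_perm):
        rnd = (rng.random(len(lengths)) * (chrom_len - lengths)).astype(np.int64)
        perm_fracs[i] = overlap_fraction(chroms, rnd, rnd + lengths)
    mean_perm = float(perm_fracs.mean())
    fold = observed / mean_perm if mean_perm > 0 else float("inf")
    p = (1 + int((perm_fracs >= observed).sum())) / (n_perm + 1)
    return {"observed_fraction": observed, "expected_fraction": mean_perm,
            "fold": fold, "p": p, "n_perm": n_perm}


def cluster_escapee_fate(levels: pd.DataFrame, k: int = 5, seed: int = 0) -> dict:
    """K-means fate clustering of escapee methylation across germline-cycle
    samples (hPGC stages, gametes, blastocyst); complete-case rows.

    ``levels``: rows = escapees, columns = samples.  Returns per-escapee
    cluster labels (clusters ordered by decreasing mean methylation) and
    per-cluster per-sample centroid summaries."""
    X = levels.dropna()
    if len(X) < k:
        raise ValidationError(f"{len(X)} complete escapees < k={k}")
    km = KMeansWrapper(k, seed).fit(X.to_numpy(float))
    labels = pd.Series(km.labels, index=X.index, name="fate_cluster")
    centroids = pd.DataFrame(km.centroids, columns=levels.columns)
    return {"labels": labels, "centroids": centroids, "inertia": km.inertia}


class KMeansWrapper:
    """Seeded k-means++ with mean-descending cluster relabelling (shared with
    the tile-dynamics clustering)."""

    def __init__(self, k: int, seed: int, n_init: int = 10):
        from sklearn.cluster import KMeans
        self._km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                          random_state=seed)
        self.k = k

    def fit(self, X: np.ndarray) -> "KMeansWrapper":
        raw = self._km.fit_predict(X)
        order = np.argsort(-self._km.cluster_centers_.mean(axis=1), kind="stable")
        relabel = np.empty(self.k, dtype=int)
        relabel[order] = np.arange(self.k)
        self.labels = relabel[raw]
        self.centroids = self._km.cluster_centers_[order]
        self.inertia = float(self._km.inertia_)
        return self
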