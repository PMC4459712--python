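"""Genome tiling and coverage-filtered methylation quantification.

Methylation over any interval is estimated coverage-weighted: summed
methylated calls over summed total calls across the CpGs in the interval
that reach the minimum depth.  A tile or region is reported missing (NaN)
when it holds fewer than ``min_cpgs`` CpGs or when fewer than
``min_covered_frac`` of its CpGs reach ``min_depth`` — the thresholds the
study applies to every methylation analysis (>=5 CpGs, >=20% of tile CpGs
at >=5x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (GeneSet, GenomeLayout, MethylomeTrack, RegionSet,
                 ValidationError, make_track)

logger = logging.getLogger("germreset")


@dataclass(frozen=True)
class CoverageFilter:
    """Minimum-evidence thresholds for quantifying an interval."""

    min_cpgs: int = 5
    min_depth: int = 5
    min_covered_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.min_cpgs <= 0 or self.min_depth <= 0:
            raise ValidationError("filter thresholds must be strictly positive")
        if not 0 < self.min_covered_frac <= 1:
            raise ValidationError("min_covered_frac must be in (0, 1]")


DEFAULT_FILTER = CoverageFilter()


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

@dataclass
class TileSet:
    """Sliding genomic windows with per-tile CpG and repeat bookkeeping.

    ``tiles`` columns: chrom, start, end, n_cpgs, repeat_overlap_bp,
    is_repeat_free, is_terminal.
    """

    tiles: pd.DataFrame
    tile_size: int = 1000
    step: int = 500

    def __len__(self) -> int:
        return len(self.tiles)

    def ids(self) -> pd.Series:
        t = self.tiles
        return t["chrom"].astype(str) + ":" + t["start"].astype(str) + "-" + t["end"].astype(str)


def make_tiles(layout: GenomeLayout, tile_size: int = 1000, step: int = 500,
               repeats: RegionSet | None = None, free_dist: int = 1000) -> TileSet:
    """Sliding windows over the genomic chromosomes (spike contig excluded).

    A window is emitted at every ``step`` while a full ``tile_size`` window
    fits; a short terminal window is appended (flagged) only when the last
    full window does not already reach the chromosome end.  With ``repeats``
    given, each tile records its repeat overlap in bp and whether no repeat
    lies within ``free_dist`` bp of it (repeat-free tiles).
    """
    if step > tile_size:
        raise ValidationError("step must be <= tile_size")
    chroms = layout.genomic_chroms()
    if not chroms:
        raise ValidationError("layout has no genomic chromosomes")
    frames = []
    for chrom in chroms:
        length = layout.chrom_lengths[chrom]
        if length < tile_size:
            starts = np.array([0], dtype=np.int64)
        else:
            starts = np.arange(0, length - tile_size + 1, step, dtype=np.int64)
        ends = np.minimum(starts + tile_size, length)
        terminal = np.zeros(len(starts), dtype=bool)
        if ends[-1] < length:
            nxt = starts[-1] + step
            starts = np.append(starts, nxt)
            ends = np.append(ends, length)
            terminal = np.append(terminal, True)
        cpg = layout.cpg_positions.get(chrom, np.empty(0, np.int64))
        n_cpgs = np.searchsorted(cpg, ends) - np.searchsorted(cpg, starts)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                           "n_cpgs": n_cpgs, "is_terminal": terminal})
        frames.append(df)
    tiles = pd.concat(frames, ignore_index=True)
    if repeats is not None:
        overlap = np.zeros(len(tiles), dtype=np.int64)
        free = np.ones(len(tiles), dtype=bool)
        for chrom, sub in tiles.groupby("chrom", sort=False):
            rs, re = repeats.merged_arrays(chrom)
            if not len(rs):
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            overlap[sub.index] = _interval_overlap_bp(s, e, rs, re)
            free[sub.index] = _interval_overlap_bp(
                np.maximum(s - free_dist, 0), e + free_dist, rs, re) == 0
        tiles["repeat_overlap_bp"] = overlap
        tiles["is_repeat_free"] = free
    else:
        tiles["repeat_overlap_bp"] = 0
        tiles["is_repeat_free"] = True
    return TileSet(tiles=tiles, tile_size=tile_size, step=step)


def _interval_overlap_bp(qs: np.ndarray, qe: np.ndarray,
                         rs: np.ndarray, re: np.ndarray) -> np.ndarray:
    """Overlap bp of each query [qs,qe) with merged sorted intervals (rs,re)."""
    cum = np.concatenate([[0], np.cumsum(re - rs)])

    def covered_before(x):
        # bp of merged intervals lying strictly left of coordinate x
        i = np.searchsorted(rs, x)  # intervals fully starting before x: rs < x
        out = cum[i].astype(np.int64)
        j = i - 1
        valid = j >= 0
        # subtract tail of partially covered interval
        tail = np.where(valid & (re[np.clip(j, 0, None)] > x),
                        re[np.clip(j, 0, None)] - x, 0)
        return out - tail

    return covered_before(qe) - covered_before(qs)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def _interval_stats(track: MethylomeTrack, chrom: str, starts: np.ndarray,
                    ends: np.ndarray, min_depth: int):
    """(sum_meth, sum_total, n_covered) over CpGs with depth >= min_depth,
    per query interval, via prefix sums on the sorted track arrays."""
    pos, meth, unmeth = track.chrom_arrays(chrom)
    depth = meth + unmeth
    ok = depth >= min_depth
    cm = np.concatenate([[0], np.cumsum(np.where(ok, meth, 0))])
    ct = np.concatenate([[0], np.cumsum(np.where(ok, depth, 0))])
    cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, ends)
    return cm[hi] - cm[lo], ct[hi] - ct[lo], cn[hi] - cn[lo]


def quantify_tiles(track: MethylomeTrack, tiles: TileSet,
                   filt: CoverageFilter = DEFAULT_FILTER):
    """Per-tile coverage-weighted methylation level for one sample.

    Returns (levels, covered_cpgs) arrays aligned with ``tiles.tiles``;
    levels are NaN where the coverage filter fails.
    """
    t = tiles.tiles
    levels = np.full(len(t), np.nan)
    covered = np.zeros(len(t), dtype=np.int64)
    for chrom, sub in t.groupby("chrom", sort=False):
        sm, st, nc = _interval_stats(track, chrom, sub["start"].to_numpy(),
                                     sub["end"].to_numpy(), filt.min_depth)
        covered[sub.index] = nc
        n_cpgs = sub["n_cpgs"].to_numpy()
        ok = ((n_cpgs >= filt.min_cpgs)
              & (nc >= filt.min_covered_frac * n_cpgs)
              & (nc > 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(st > 0, sm / np.maximum(st, 1), np.nan)
        levels[sub.index] = np.where(ok, lv, np.nan)
    return levels, covered


@dataclass
class TileMatrix:
    """Tiles x samples methylation levels with coverage bookkeeping."""

    tiles: TileSet
    sample_ids: list[str]
    levels: np.ndarray          # (n_tiles, n_samples), NaN = failed filter
    covered: np.ndarray         # (n_tiles, n_samples) covered-CpG counts
    stages: dict = field(default_factory=dict)

    @classmethod
    def build(cls, tracks: list[MethylomeTrack], tiles: TileSet,
              filt: CoverageFilter = DEFAULT_FILTER) -> "TileMatrix":
        levels = np.empty((len(tiles), len(tracks)))
        covered = np.empty((len(tiles), len(tracks)), dtype=np.int64)
        for j, tr in enumerate(tracks):
            levels[:, j], covered[:, j] = quantify_tiles(tr, tiles, filt)
        return cls(tiles=tiles, sample_ids=[t.sample_id for t in tracks],
                   levels=levels, covered=covered,
                   stages={t.sample_id: t.stage for t in tracks})

    def column(self, sample_id: str) -> np.ndarray:
        return self.levels[:, self.sample_ids.index(sample_id)]

    def common_mask(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Tiles passing the filter in every listed sample ("common tiles")."""
        ids = sample_ids or self.sample_ids
        cols = [self.sample_ids.index(s) for s in ids]
        return ~np.isnan(self.levels[:, cols]).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        t = self.tiles.tiles[["chrom", "start", "end", "n_cpgs"]].copy()
        for j, s in enumerate(self.sample_ids):
            t[s] = self.levels[:, j]
            t[f"{s}_covered"] = self.covered[:, j]
        return t

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pool_replicates(tracks: list[MethylomeTrack],
                    allow_mixed: bool = False) -> MethylomeTrack:
    """Sum per-CpG counts across replicate tracks of the same stage/sex."""
    if not tracks:
        raise ValidationError("no tracks to pool")
    stages = {(t.stage, t.sex) for t in tracks}
    if len(stages) > 1 and not allow_mixed:
        raise ValidationError(f"pooling across mixed stage/sex labels {stages}; "
                              "pass allow_mixed=True to override")
    merged = pd.concat([t.data for t in tracks], ignore_index=True)
    merged = merged.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    first = tracks[0]
    return MethylomeTrack(
        sample_id=f"{first.stage}_pooled", stage=first.stage, data=merged,
        sex=first.sex, individual_id="pooled")


def quantify_regions(track: MethylomeTrack, regions: RegionSet,
                     filt: CoverageFilter = DEFAULT_FILTER,
                     layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Coverage-weighted methylation over arbitrary intervals.

    Returns a DataFrame (name, chrom, start, end, n_cpgs, covered, level)
    with NaN level for regions failing the filter — failing regions are
    flagged, never dropped.
    """
    df = regions.df
    out_level = np.full(len(df), np.nan)
    out_cov = np.zeros(len(df), dtype=np.int64)
    out_ncpg = np.zeros(len(df), dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sm, st, nc = _interval_stats(track, chrom, starts, ends, filt.min_depth)
        if layout is not None:
            cpg = layout.cpg_positions.get(chrom, np.empty(0, np.int64))
            n_cpgs = np.searchsorted(cpg, ends) - np.searchsorted(cpg, starts)
        else:
            # without a layout, count CpGs observed in the track (any depth)
            pos, _, _ = track.chrom_arrays(chrom)
            n_cpgs = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        ok = ((n_cpgs >= filt.min_cpgs)
              & (nc >= filt.min_covered_frac * n_cpgs)
              & (nc > 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(st > 0, sm / np.maximum(st, 1), np.nan)
        out_level[sub.index] = np.where(ok, lv, np.nan)
        out_cov[sub.index] = nc
        out_ncpg[sub.index] = n_cpgs
    return pd.DataFrame({
        "name": df["name"].to_numpy(), "chrom": df["chrom"].to_numpy(),
        "start": df["start"].to_numpy(), "end": df["end"].to_numpy(),
        "n_cpgs": out_ncpg, "covered": out_cov, "level": out_level,
    })


def region_level_table(tracks: list[MethylomeTrack], regions: RegionSet,
                       filt: CoverageFilter = DEFAULT_FILTER,
                       layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Wide table: one row per region, one level column per sample."""
    base = None
    for tr in tracks:
        q = quantify_regions(tr, regions, filt, layout)
        if base is None:
            base = q[["name", "chrom", "start", "end", "n_cpgs"]].copy()
        base[tr.sample_id] = q["level"].to_numpy()
    return base


# ---------------------------------------------------------------------------
# Promoter CpG-density classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterClassParams:
    hcp_ratio: float = 0.75
    lcp_ratio: float = 0.48
    gc_min: float = 0.55


def classify_promoters(genes: GeneSet, layout: GenomeLayout,
                       params: PromoterClassParams = PromoterClassParams()) -> pd.DataFrame:
    """Classify promoters into LCP/ICP/HCP by CpG observed/expected ratio.

    HCP: ratio >= hcp_ratio and GC fraction >= gc_min; LCP: ratio < lcp_ratio;
    everything else ICP.  Requires layout sequence.
    """
    if layout.sequence is None:
        raise ValidationError("promoter classification requires layout sequence")
    rows = []
    proms = genes.promoters().df
    for (_, p), gid in zip(proms.iterrows(), genes.genes["gene_id"]):
        seq = layout.sequence[p["chrom"]][max(0, p["start"]):p["end"]].upper()
        L = len(seq)
        n_c = seq.count("C")
        n_g = seq.count("G")
        n_cpg = seq.count("CG")
        gc = (n_c + n_g) / L if L else 0.0
        ratio = (n_cpg * L / (n_c * n_g)) if n_c and n_g else 0.0
        if ratio >= params.hcp_ratio and gc >= params.gc_min:
            cls = "HCP"
        elif ratio < params.lcp_ratio:
            cls = "LCP"
        else:
            cls = "ICP"
        rows.append((gid, ratio, gc, cls))
    return pd.DataFrame(rows, columns=["gene_id", "cpg_ratio", "gc_frac", "promoter_class"])


def select_partially_methylated(region_levels: pd.DataFrame,
                                require_samples: list[str],
                                lo: float = 0.30, hi: float = 0.70) -> pd.DataFrame:
    """Rows of a wide region-level table with lo <= level <= hi in every
    required sample (used to pick Xi-methylated CGI promoters from female
    reference samples)."""
    missing = [s for s in require_samples if s not in region_levels.columns]
    if missing:
        raise ValidationError(f"required samples absent from table: {missing}")
    mask = np.ones(len(region_levels), dtype=bool)
    for s in require_samples:
        v = region_levels[s].to_numpy(float)
        mask &= ~np.isnan(v) & (v >= lo) & (v <= hi)
    return region_levels[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

def metagene_profile(track: MethylomeTrack, genes: GeneSet, flank: int = 5000,
                     flank_bin: int = 100, body_bins: int = 100,
                     filt: CoverageFilter = DEFAULT_FILTER) -> np.ndarray:
    """Strand-oriented average methylation from -flank through the scaled
    gene body to +flank; coverage-weighted within each bin over all genes.

    Returns a vector of length 2*(flank // flank_bin) + body_bins; bins with
    no qualifying CpGs are NaN.  Genes shorter than ``body_bins`` bp are
    skipped.
    """
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    meth_sum = np.zeros(n_bins)
    tot_sum = np.zeros(n_bins)
    for _, g in genes.genes.iterrows():
        lo, hi = sorted((int(g["tss"]), int(g["tes"])))
        if hi - lo <= body_bins:
            continue
        pos, meth, unmeth = track.chrom_arrays(g["chrom"])
        depth = meth + unmeth
        a = np.searchsorted(pos, lo - flank)
        b = np.searchsorted(pos, hi + flank)
        p, m, d = pos[a:b], meth[a:b], depth[a:b]
        ok = d >= filt.min_depth
        p, m, d = p[ok], m[ok], d[ok]
        if not len(p):
            continue
        rel = np.empty(len(p))
        before = p < lo
        after = p >= hi
        body = ~before & ~after
        rel[before] = (p[before] - (lo - flank)) / flank_bin
        rel[body] = n_flank + (p[body] - lo) / (hi - lo) * body_bins
        rel[after] = n_flank + body_bins + (p[after] - hi) / flank_bin
        bins = np.clip(rel.astype(int), 0, n_bins - 1)
        if g["strand"] == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth_sum, bins, m)
        np.add.at(tot_sum, bins, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot_sum > 0, meth_sum / np.maximum(tot_sum, 1), np.nan)
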