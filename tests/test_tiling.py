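"""Tiling, the coverage-weighted estimator, filters, and promoter classes."""

import numpy as np
import pandas as pd
import pytest

from germreset import (CoverageFilter, GenomeLayout, ValidationError,
                       make_track, make_tiles, metagene_profile,
                       pool_replicates, quantify_regions, quantify_tiles,
                       select_partially_methylated)
from germreset.io import GeneSet, RegionSet
from germreset.tiling import classify_promoters

from conftest import track_from_levels


def _layout(length=2500, spacing=100, chrom="c"):
    return GenomeLayout(
        chrom_lengths={chrom: length},
        cpg_positions={chrom: np.arange(10, length - 2, spacing,
                                        dtype=np.int64)})


class TestMakeTiles:
    def test_half_overlapping_windows(self):
        tiles = make_tiles(_layout(2500), tile_size=1000, step=500).tiles
        got = list(zip(tiles["start"], tiles["end"]))
        assert got == [(0, 1000), (500, 1500), (1000, 2000), (1500, 2500)]

    def test_short_terminal_tile_flagged(self):
        tiles = make_tiles(_layout(2300), tile_size=1000, step=500).tiles
        assert list(tiles["end"])[-1] == 2300
        assert bool(tiles["is_terminal"].iloc[-1])
        assert not tiles["is_terminal"].iloc[:-1].any()

    def test_repeat_overlap_and_free_flag(self):
        layout = _layout(5000)
        repeats = RegionSet(pd.DataFrame(
            {"chrom": ["c"], "start": [990], "end": [1200], "name": ["r"]}),
            category="repeat")
        tiles = make_tiles(layout, repeats=repeats, free_dist=1000).tiles
        first = tiles.iloc[0]
        assert first["repeat_overlap_bp"] == 10
        assert not first["is_repeat_free"]
        # a tile whose nearest repeat starts >1 kb away is repeat-free
        far = tiles[tiles["start"] == 2500].iloc[0]
        assert far["is_repeat_free"]

    def test_tiling_covers_each_cpg_twice_away_from_ends(self):
        layout = _layout(20_000)
        tiles = make_tiles(layout, tile_size=1000, step=500).tiles
        pos = layout.cpg_positions["c"]
        inner = pos[(pos >= 1000) & (pos < 19_000)]
        counts = ((tiles["start"].to_numpy()[:, None] <= inner)
                  & (inner < tiles["end"].to_numpy()[:, None])).sum(axis=0)
        assert (counts == 2).all()  # tile_size/step = 2

    def test_step_larger_than_tile_rejected(self):
        with pytest.raises(ValidationError):
            make_tiles(_layout(), tile_size=500, step=1000)


class TestQuantifyTiles:
    def test_coverage_weighted_level_matches_hand_summation(self):
        # 5 CpGs at (3/10, 1/10, 0/5, 2/5, 0/10): pooled 6/40 = 0.15
        layout = GenomeLayout(chrom_lengths={"c": 1000},
                              cpg_positions={"c": np.arange(100, 600, 100)})
        track = make_track("s", "x", ["c"] * 5, np.arange(100, 600, 100),
                           [3, 1, 0, 2, 0], [7, 9, 5, 3, 10])
        tiles = make_tiles(layout)
        levels, covered = quantify_tiles(track, tiles)
        assert levels[0] == pytest.approx(6 / 40)
        assert covered[0] == 5

    def test_too_few_cpgs_is_missing(self):
        layout = GenomeLayout(chrom_lengths={"c": 1000},
                              cpg_positions={"c": np.arange(100, 500, 100)})
        track = make_track("s", "x", ["c"] * 4, np.arange(100, 500, 100),
                           [5] * 4, [5] * 4)
        levels, _ = quantify_tiles(track, make_tiles(layout))
        assert np.isnan(levels[0])

    def test_low_covered_fraction_is_missing(self):
        # 10 CpGs, only 1 at depth >= 5: 10% < 20% required
        layout = GenomeLayout(chrom_lengths={"c": 1100},
                              cpg_positions={"c": np.arange(50, 1050, 100)})
        meth = [1] + [0] * 9
        unmeth = [9] + [1] * 9
        track = make_track("s", "x", ["c"] * 10, np.arange(50, 1050, 100),
                           meth, unmeth)
        levels, _ = quantify_tiles(track, make_tiles(layout))
        assert np.isnan(levels[0])

    def test_weighted_equals_unweighted_at_equal_depth(self):
        rng = np.random.default_rng(0)
        layout = _layout(30_000)
        pos = layout.cpg_positions["c"]
        meth = rng.integers(0, 11, len(pos))
        track = make_track("s", "x", ["c"] * len(pos), pos, meth, 10 - meth)
        tiles = make_tiles(layout)
        levels, _ = quantify_tiles(track, tiles)
        for i, t in tiles.tiles.iterrows():
            sel = (pos >= t["start"]) & (pos < t["end"])
            if not np.isnan(levels[i]):
                assert levels[i] == pytest.approx(np.mean(meth[sel] / 10))

    def test_levels_bounded(self, small_matrix):
        lv = small_matrix.levels
        ok = ~np.isnan(lv)
        assert (lv[ok] >= 0).all() and (lv[ok] <= 1).all()

    @pytest.mark.parametrize("tighten", ["min_depth", "min_cpgs"])
    def test_filter_monotonicity(self, tighten):
        """Strictly tightening a threshold never adds passing tiles."""
        rng = np.random.default_rng(3)
        layout = _layout(50_000)
        pos = layout.cpg_positions["c"]
        depth = rng.poisson(7, len(pos))
        keep = depth > 0
        meth = rng.binomial(depth[keep], 0.3)
        track = make_track("s", "x", ["c"] * keep.sum(), pos[keep], meth,
                           depth[keep] - meth)
        tiles = make_tiles(layout)
        loose = CoverageFilter()
        tight = CoverageFilter(**{**dict(min_cpgs=5, min_depth=5,
                                         min_covered_frac=0.2),
                                  tighten: 8})
        lv_loose, _ = quantify_tiles(track, tiles, loose)
        lv_tight, _ = quantify_tiles(track, tiles, tight)
        assert not np.any(np.isnan(lv_loose) & ~np.isnan(lv_tight))


class TestPooling:
    def test_counts_add_per_cpg(self):
        a = make_track("r1", "Wk7", ["c"], [100], [3], [7])
        b = make_track("r2", "Wk7", ["c"], [100], [2], [8])
        merged = pool_replicates([a, b])
        rec = merged.data.iloc[0]
        assert (rec["meth"], rec["unmeth"]) == (5, 15)
        assert rec["meth"] / (rec["meth"] + rec["unmeth"]) == 0.25

    def test_cpg_in_one_replicate_carried_through(self):
        a = make_track("r1", "Wk7", ["c"], [100], [3], [7])
        b = make_track("r2", "Wk7", ["c"], [300], [1], [4])
        merged = pool_replicates([a, b])
        assert len(merged) == 2

    def test_mixed_stages_need_override(self):
        a = make_track("r1", "Wk7", ["c"], [100], [3], [7])
        b = make_track("r2", "Wk9", ["c"], [100], [2], [8])
        with pytest.raises(ValidationError):
            pool_replicates([a, b])
        assert len(pool_replicates([a, b], allow_mixed=True)) == 1

    def test_pooling_never_reduces_passing_tiles(self):
        """Coverage filter pass rate is monotone under replicate pooling."""
        layout = _layout(50_000)
        pos = layout.cpg_positions["c"]
        tiles = make_tiles(layout)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            reps = []
            for r in range(2):
                depth = rng.poisson(4, len(pos))
                keep = depth > 0
                meth = rng.binomial(depth[keep], 0.2)
                reps.append(make_track(f"r{r}", "x", ["c"] * keep.sum(),
                                       pos[keep], meth, depth[keep] - meth))
            lv_single, _ = quantify_tiles(reps[0], tiles)
            lv_pooled, _ = quantify_tiles(pool_replicates(reps, allow_mixed=True),
                                          tiles)
            assert np.sum(~np.isnan(lv_pooled)) >= np.sum(~np.isnan(lv_single))


class TestQuantifyRegions:
    def test_fully_unmethylated_region(self, tiny_layout):
        track = track_from_levels(tiny_layout, {"chrA": 0.0})
        regions = RegionSet(pd.DataFrame({"chrom": ["chrA"], "start": [0],
                                          "end": [2000], "name": ["icr"]}))
        q = quantify_regions(track, regions, layout=tiny_layout)
        assert q["level"].iloc[0] == 0.0

    def test_low_depth_cpg_excluded_from_both_sums(self):
        layout = GenomeLayout(chrom_lengths={"c": 1000},
                              cpg_positions={"c": np.arange(100, 600, 100)})
        # CpG 3 has depth 4 (< 5) and would change the level if counted
        meth = [5, 5, 4, 5, 5]
        unmeth = [5, 5, 0, 5, 5]
        track = make_track("s", "x", ["c"] * 5, np.arange(100, 600, 100),
                           meth, unmeth)
        regions = RegionSet(pd.DataFrame({"chrom": ["c"], "start": [0],
                                          "end": [1000], "name": ["r"]}))
        q = quantify_regions(track, regions, layout=layout)
        assert q["level"].iloc[0] == pytest.approx(20 / 40)

    def test_failing_region_flagged_not_dropped(self, tiny_layout):
        track = track_from_levels(tiny_layout, {"chrA": 0.5})
        regions = RegionSet(pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "start": [0, 9900],
             "end": [2000, 9990], "name": ["ok", "thin"]}))
        q = quantify_regions(track, regions, layout=tiny_layout)
        assert len(q) == 2
        assert np.isnan(q.set_index("name").loc["thin", "level"])


class TestPromoterClasses:
    def _layout_with_seq(self, seq):
        cpgs = np.array([i for i in range(len(seq) - 1)
                         if seq[i:i + 2] == "CG"], dtype=np.int64)
        return GenomeLayout(chrom_lengths={"c": len(seq)},
                            cpg_positions={"c": cpgs},
                            sequence={"c": seq})

    def _genes(self, tss, tes=None):
        return GeneSet(genes=pd.DataFrame([{
            "gene_id": "g", "chrom": "c", "strand": "+",
            "tss": tss, "tes": tes or tss + 2000}]),
            upstream_bp=1000, downstream_bp=500)

    def test_poly_cg_promoter_is_hcp(self):
        seq = "CG" * 2000
        res = classify_promoters(self._genes(1000), self._layout_with_seq(seq))
        assert res.iloc[0]["promoter_class"] == "HCP"

    def test_cpg_free_promoter_is_lcp(self):
        seq = ("AT" * 1000) + ("CCGG" * 500)  # promoter region is CpG-free
        res = classify_promoters(self._genes(1000), self._layout_with_seq("AT" * 3000))
        assert res.iloc[0]["promoter_class"] == "LCP"

    def test_class_matches_brute_force_recount(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3],
                                 size=4000))
        layout = self._layout_with_seq(seq)
        genes = self._genes(1500)
        res = classify_promoters(genes, layout)
        sub = seq[500:2000]  # promoter [tss-1000, tss+500)
        n_c, n_g = sub.count("C"), sub.count("G")
        n_cpg = sum(1 for i in range(len(sub) - 1) if sub[i:i + 2] == "CG")
        ratio = n_cpg * len(sub) / (n_c * n_g)
        gc = (n_c + n_g) / len(sub)
        expected = ("HCP" if ratio >= 0.75 and gc >= 0.55
                    else "LCP" if ratio < 0.48 else "ICP")
        assert res.iloc[0]["promoter_class"] == expected
        assert res.iloc[0]["cpg_ratio"] == pytest.approx(ratio)


class TestPartialMethylationSelection:
    def test_band_selection(self):
        table = pd.DataFrame({"name": ["p1", "p2"],
                              "ESC": [0.50, 0.50], "soma": [0.55, 0.20]})
        out = select_partially_methylated(table, ["ESC", "soma"])
        assert list(out["name"]) == ["p1"]

    def test_missing_required_sample_errors(self):
        table = pd.DataFrame({"name": ["p"], "ESC": [0.5]})
        with pytest.raises(ValidationError):
            select_partially_methylated(table, ["ESC", "soma"])


class TestMetagene:
    def _genes(self, strand="+"):
        return GeneSet(genes=pd.DataFrame([{
            "gene_id": "g", "chrom": "chrA", "strand": strand,
            "tss": 3000 if strand == "+" else 7000,
            "tes": 7000 if strand == "+" else 3000}]))

    def test_uniform_methylome_gives_flat_profile(self, tiny_layout):
        track = track_from_levels(tiny_layout, {"chrA": 0.8})
        prof = metagene_profile(track, self._genes(), flank=2000,
                                flank_bin=100, body_bins=40)
        assert np.nanmax(np.abs(prof - 0.8)) < 1e-9

    def test_minus_strand_profile_mirrors_plus(self, tiny_layout):
        rng = np.random.default_rng(1)
        levels = rng.random(len(tiny_layout.cpg_positions["chrA"]))
        track = track_from_levels(tiny_layout, {"chrA": levels}, depth=100)
        plus = metagene_profile(track, self._genes("+"), flank=2000,
                                flank_bin=100, body_bins=40)
        minus = metagene_profile(track, self._genes("-"), flank=2000,
                                 flank_bin=100, body_bins=40)
        np.testing.assert_allclose(minus, plus[::-1], equal_nan=True)

    def test_hand_binned_average(self):
        layout = GenomeLayout(chrom_lengths={"c": 4000},
                              cpg_positions={"c": np.array([450, 1250, 2950])})
        # gene [1000, 3000), flank 1000/bin 500, body 4 bins of 500
        track = make_track("s", "x", ["c"] * 3, [450, 1250, 2950],
                           [8, 2, 6], [2, 8, 4])
        genes = GeneSet(genes=pd.DataFrame([{
            "gene_id": "g", "chrom": "c", "strand": "+",
            "tss": 1000, "tes": 3000}]))
        prof = metagene_profile(track, genes, flank=1000, flank_bin=500,
                                body_bins=4)
        # bins: [-1000,-500)=CpG450 -> 0.8; body bin 0 = CpG1250 -> 0.2;
        # body bin 3 = CpG2950 -> 0.6; everything else empty
        assert prof[0] == pytest.approx(0.8)
        assert prof[2] == pytest.approx(0.2)
        assert prof[5] == pytest.approx(0.6)
        assert np.isnan(prof[1])
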