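"""Escapee calling, classification, variation, and cross-species overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from germreset import (EscapeeCallParams, GenomeLayout, ValidationError,
                       VariationFilterParams, make_track)
from germreset.escapees import (annotate_features, call_escapees,
                                classify_by_repeat, cluster_escapee_fate,
                                conservation_report, escapee_variation,
                                genes_with_escapees, homolog_overlap_test,
                                region_overlap_enrichment,
                                repeat_class_percentages)
from germreset.io import GeneSet, RegionSet


def _uniform_genome(length=200_000, spacing=100, background=0.02, depth=10,
                    plants=(), plant_level=0.6, seed=0):
    """Binomial methylome over a single chromosome with planted intervals."""
    rng = np.random.default_rng(seed)
    pos = np.arange(50, length - 2, spacing, dtype=np.int64)
    level = np.full(len(pos), background)
    for s, e in plants:
        level[(pos >= s) & (pos < e)] = plant_level
    meth = rng.binomial(depth, level)
    track = make_track("s", "Wk7", ["c"] * len(pos), pos, meth, depth - meth)
    layout = GenomeLayout(chrom_lengths={"c": length},
                          cpg_positions={"c": pos})
    return layout, track


class TestCaller:
    def test_single_planted_region_recovered_with_tight_bounds(self):
        plant = (100_000, 102_000)
        layout, track = _uniform_genome(plants=[plant], seed=1)
        res = call_escapees([track], layout)
        assert len(res.regions) == 1
        r = res.regions.iloc[0]
        ov = min(r["end"], plant[1]) - max(r["start"], plant[0])
        assert ov >= 0.8 * (plant[1] - plant[0])
        assert ov >= 0.8 * (r["end"] - r["start"])

    def test_plant_below_threshold_not_called(self):
        layout, track = _uniform_genome(plants=[(100_000, 102_000)],
                                        plant_level=0.15, seed=2)
        res = call_escapees([track], layout)
        assert len(res.regions) == 0

    def test_all_zero_methylome_gives_empty_list(self):
        layout, track = _uniform_genome(background=0.0, seed=3)
        # keep one methylated call so global level is defined but ~0
        res = call_escapees([track], layout)
        assert len(res.regions) == 0

    def test_raising_min_meth_never_adds_regions(self):
        layout, track = _uniform_genome(
            plants=[(50_000, 52_000), (120_000, 122_000)], plant_level=0.45,
            seed=4)
        n_prev = None
        for mm in (0.30, 0.40, 0.50, 0.60):
            res = call_escapees([track], layout,
                                EscapeeCallParams(min_meth=mm))
            n = len(res.regions)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_region_must_pass_in_required_individuals(self):
        plant = (100_000, 102_000)
        layout, pooled = _uniform_genome(plants=[plant], seed=5)
        _, low_ind = _uniform_genome(plants=[plant], plant_level=0.1, seed=6)
        ok = call_escapees([pooled], layout, required_tracks=[pooled])
        vetoed = call_escapees([pooled], layout, required_tracks=[low_ind])
        assert len(ok.regions) == 1
        assert len(vetoed.regions) == 0


class TestClassification:
    def test_printed_count_bookkeeping(self):
        pct = repeat_class_percentages(116_618, 7_071)
        assert pct["repeat_rich_pct"] == 93.9

    def test_overlap_fraction_thresholds(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"], "level": [0.5]})
        repeats = RegionSet(pd.DataFrame({"chrom": ["c"], "start": [500],
                                          "end": [750], "name": ["r"]}),
                            category="repeat")
        out, summary = classify_by_repeat(esc, repeats)
        assert out.iloc[0]["repeat_overlap_frac"] == pytest.approx(0.125)
        assert out.iloc[0]["repeat_class"] == "repeat_rich"

    def test_nearby_repeat_blocks_repeat_free(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"], "level": [0.5]})
        repeats = RegionSet(pd.DataFrame({"chrom": ["c"], "start": [2500],
                                          "end": [2700], "name": ["r"]}),
                            category="repeat")
        out, _ = classify_by_repeat(esc, repeats)
        assert out.iloc[0]["repeat_class"] == "repeat_poor"
        assert not out.iloc[0]["is_repeat_free"]

    def test_partition_invariant_on_synthetic_set(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(500_000, 50, replace=False)) * 10
        esc = pd.DataFrame({"chrom": "c", "start": starts,
                            "end": starts + 2000,
                            "name": [f"e{i}" for i in range(50)]})
        rep_starts = np.sort(rng.choice(1_000_000, 300, replace=False)) * 5
        repeats = RegionSet(pd.DataFrame({
            "chrom": "c", "start": rep_starts, "end": rep_starts + 400,
            "name": [f"r{i}" for i in range(300)]}), category="repeat")
        out, summary = classify_by_repeat(esc, repeats)
        assert (out["repeat_class"].isin(["repeat_rich", "repeat_poor"])).all()
        assert summary["n_repeat_rich"] + summary["n_repeat_poor"] == 50
        assert (out.loc[out["is_repeat_free"], "repeat_class"]
                == "repeat_poor").all()


class TestFeatures:
    def test_multi_feature_and_intergenic_labels(self):
        esc = pd.DataFrame({"chrom": ["c", "c"], "start": [1000, 50_000],
                            "end": [2000, 52_000], "name": ["a", "b"]})
        annots = {
            "CGI": RegionSet(pd.DataFrame({"chrom": ["c"], "start": [1500],
                                           "end": [1800], "name": ["cgi"]})),
            "gene_body": RegionSet(pd.DataFrame({"chrom": ["c"], "start": [0],
                                                 "end": [3000], "name": ["g"]})),
        }
        out, dist = annotate_features(esc, annots)
        assert out.iloc[0]["features"] == ["CGI", "gene_body"]
        assert out.iloc[1]["features"] == ["intergenic"]
        assert dist == {"CGI": 1, "gene_body": 1, "intergenic": 1}

    def test_planted_feature_distribution_recovered(self, small_genome):
        truth = small_genome.truth["escapees"]
        esc = truth[["name", "chrom", "start", "end"]].copy()
        annots = {
            "enhancer": small_genome.enhancers,
            "CGI": small_genome.cgis,
            "promoter": small_genome.genes.promoters(),
            "gene_body": small_genome.genes.gene_bodies(),
        }
        out, _ = annotate_features(esc, annots)
        for feats, planted in zip(out["features"], truth["features"]):
            assert set(feats) == set(planted)


class TestVariation:
    def _tracks(self, levels_by_ind, spacing=100, depth=10):
        """Deterministic tracks over a 2 kb region with 20 CpGs."""
        pos = np.arange(50, 2000, spacing, dtype=np.int64)
        tracks = []
        for i, lv in enumerate(levels_by_ind):
            meth = np.rint(np.full(len(pos), lv) * depth).astype(np.int64)
            tracks.append(make_track(f"i{i}", "Wk7", ["c"] * len(pos), pos,
                                     meth, depth - meth))
        return tracks

    def test_constant_levels_give_zero_cv(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"]})
        res = escapee_variation(esc, self._tracks([0.4, 0.4, 0.4, 0.4]))
        assert res["table"]["cv"].iloc[0] == pytest.approx(0.0)

    def test_two_individual_cv_matches_hand_arithmetic(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"]})
        res = escapee_variation(esc, self._tracks([0.2, 0.6]))
        row = res["table"].iloc[0]
        assert row["mean"] == pytest.approx(0.4)
        assert row["sd"] == pytest.approx(0.2828, abs=1e-4)
        assert row["cv"] == pytest.approx(0.7071, abs=1e-4)

    def test_region_never_reaching_min_meth_excluded(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"]})
        res = escapee_variation(esc, self._tracks([0.3, 0.3, 0.2, 0.25]))
        assert res["n_regions"] == 0

    def test_single_individual_errors(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                            "name": ["e"]})
        with pytest.raises(ValidationError):
            escapee_variation(esc, self._tracks([0.4]))


class TestGeneAssignment:
    def _genes(self):
        return GeneSet(genes=pd.DataFrame([
            {"gene_id": "gA", "chrom": "c", "strand": "+", "tss": 1000,
             "tes": 5000},
            {"gene_id": "gB", "chrom": "c", "strand": "-", "tss": 6000,
             "tes": 3000},
            {"gene_id": "gC", "chrom": "c", "strand": "+", "tss": 20_000,
             "tes": 25_000},
        ]))

    def test_escapee_spanning_overlapping_genes_hits_both(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [3500], "end": [4500],
                            "name": ["e"], "level": [0.5]})
        assert genes_with_escapees(esc, self._genes()) == {"gA", "gB"}

    def test_upstream_escapee_excluded_from_gene_bodies(self):
        esc = pd.DataFrame({"chrom": ["c"], "start": [900], "end": [980],
                            "name": ["e"], "level": [0.5]})
        assert genes_with_escapees(esc, self._genes()) == set()

    def test_planted_host_genes_recovered_exactly(self, small_genome):
        truth = small_genome.truth["escapees"].copy()
        truth["level"] = 0.5
        hosts = set(truth["host_gene"]) - {""}
        got = genes_with_escapees(truth, small_genome.genes)
        assert got == hosts


class TestHomologOverlap:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        b = {"g0", "g1", "g2", "g9"}
        k, p = homolog_overlap_test(a, b, universe)
        assert k == 3
        assert p == pytest.approx(55 / 210)

    def test_zero_overlap_has_probability_at_most_one(self):
        universe = {f"g{i}" for i in range(10)}
        k, p = homolog_overlap_test({"g0"}, {"g9"}, universe)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_stray_genes_rejected_with_offenders(self):
        with pytest.raises(ValidationError, match="gX"):
            homolog_overlap_test({"gX"}, {"g0"}, {"g0", "g1"})

    @pytest.mark.parametrize("M,nA,nB", [(6, 3, 2), (8, 4, 4), (10, 5, 4),
                                         (12, 6, 3), (15, 7, 5)])
    def test_matches_exhaustive_enumeration(self, M, nA, nB):
        """Hypergeometric tail equals counting over all draw subsets."""
        universe = [f"g{i}" for i in range(M)]
        a = set(universe[:nA])
        for k_obs in range(min(nA, nB) + 1):
            total = math.comb(M, nB)
            count = sum(1 for b in itertools.combinations(universe, nB)
                        if len(a & set(b)) >= k_obs)
            b_set = set(universe[:k_obs]) | set(universe[nA:nA + nB - k_obs])
            k, p = homolog_overlap_test(a, b_set, set(universe))
            assert k == k_obs
            assert p == pytest.approx(count / total, rel=1e-12)

    def test_identical_sets_match_enumeration(self):
        universe = [f"g{i}" for i in range(8)]
        a = set(universe[:3])
        k, p = homolog_overlap_test(a, a, set(universe))
        count = sum(1 for b in itertools.combinations(universe, 3)
                    if len(a & set(b)) >= 3)
        assert k == 3
        assert p == pytest.approx(count / math.comb(8, 3))

    def test_conservation_bookkeeping(self):
        rep = conservation_report(3246, 104)
        assert rep["methylated_pct"] == 3


class TestEnrichment:
    def _layout(self, length=1_000_000):
        return GenomeLayout(chrom_lengths={"c": length},
                            cpg_positions={"c": np.arange(100, length - 2,
                                                          1000)})

    def test_genome_wide_annotation_gives_fold_one(self):
        layout = self._layout()
        esc = pd.DataFrame({"chrom": ["c"] * 5,
                            "start": [10_000, 50_000, 90_000, 200_000, 500_000],
                            "end": [12_000, 52_000, 92_000, 202_000, 502_000],
                            "name": list("abcde")})
        ann = RegionSet(pd.DataFrame({"chrom": ["c"], "start": [0],
                                      "end": [1_000_000], "name": ["all"]}))
        res = region_overlap_enrichment(esc, ann, layout, n_perm=200, seed=0)
        assert res["fold"] == pytest.approx(1.0)
        assert res["p"] > 0.5

    def test_self_annotation_in_sparse_genome_is_maximal(self):
        layout = self._layout()
        esc = pd.DataFrame({"chrom": ["c"] * 3,
                            "start": [100_000, 400_000, 800_000],
                            "end": [101_000, 401_000, 801_000],
                            "name": list("abc")})
        ann = RegionSet(esc.copy())
        res = region_overlap_enrichment(esc, ann, layout, n_perm=200, seed=1)
        assert res["fold"] > 10
        assert res["p"] == pytest.approx(1 / 201)

    def test_planted_five_fold_enrichment_recovered(self):
        """Escapees placed entirely inside an annotation covering 20% of the
        genome have expected fold 1/0.2 = 5."""
        layout = self._layout()
        ann = RegionSet(pd.DataFrame({"chrom": ["c"], "start": [0],
                                      "end": [200_000], "name": ["blk"]}))
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 198_000, 40)
        esc = pd.DataFrame({"chrom": "c", "start": starts,
                            "end": starts + 1000,
                            "name": [f"e{i}" for i in range(40)]})
        res = region_overlap_enrichment(esc, ann, layout, n_perm=1000, seed=3)
        assert 4.0 <= res["fold"] <= 6.0


class TestFateClusters:
    def _levels(self):
        rng = np.random.default_rng(9)
        def grp(sperm, oocyte, icm, n):
            return pd.DataFrame({
                "Wk7": 0.5 + rng.normal(0, 0.02, n),
                "sperm": sperm + rng.normal(0, 0.02, n),
                "oocyte": oocyte + rng.normal(0, 0.02, n),
                "ICM": icm + rng.normal(0, 0.02, n)})
        frames = [grp(0.9, 0.9, 0.5, 20), grp(0.9, 0.2, 0.4, 15),
                  grp(0.2, 0.9, 0.4, 15)]
        df = pd.concat(frames, ignore_index=True)
        df.index = [f"e{i}" for i in range(len(df))]
        return df

    def test_sperm_only_group_forms_one_cluster(self):
        lv = self._levels()
        res = cluster_escapee_fate(lv, k=3, seed=0)
        labels = res["labels"]
        sperm_only = labels.iloc[20:35]
        assert sperm_only.nunique() == 1
        assert labels.iloc[:20].nunique() == 1
        assert sperm_only.iloc[0] != labels.iloc[0]

    def test_k1_puts_everything_together(self):
        res = cluster_escapee_fate(self._levels(), k=1, seed=0)
        assert res["labels"].nunique() == 1

    def test_fixed_seed_reproducible(self):
        lv = self._levels()
        a = cluster_escapee_fate(lv, k=3, seed=5)["labels"]
        b = cluster_escapee_fate(lv, k=3, seed=5)["labels"]
        assert (a == b).all()
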