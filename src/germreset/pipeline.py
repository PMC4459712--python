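"""End-to-end orchestration: simulate -> tile -> quantify -> dynamics ->
imprints/X -> escapees -> repeats -> expression coupling -> motifs ->
cross-species, with a structured config, per-stage TSV/BED/JSON outputs,
and a deterministic summary JSON (identical config + seed => identical
bytes)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, escapees, expression, imprints, motifs, repeats, tiling
from .io import (RegionSet, ValidationError, estimate_conversion_rate,
                 write_cpg_calls, write_regions_bed)
from .motifs import default_zfp57_pwm
from .simulate import SimConfig, build_genome, build_genome_pair, \
    simulate_expression, simulate_methylome
from .tiling import TileMatrix, make_tiles, pool_replicates

logger = logging.getLogger("germreset")


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys in a config file are rejected."""

    outdir: str = "germreset_out"
    seed: int = 1
    autosome_bp: int = 10_000_000
    x_bp: int = 5_000_000
    stages: tuple = ("ESC", "soma", "Wk5.5", "Wk7", "Wk9", "sperm", "oocyte", "ICM")
    pgc_stages: tuple = ("Wk5.5", "Wk7", "Wk9")
    n_individuals: int = 4            # individual embryos per hPGC stage
    kmeans_k: int = 7
    fate_k: int = 5
    enrichment_perms: int = 200
    motif_perms: int = 100
    cross_species: bool = True
    mouse_stages: tuple = ("E10.5", "E13.5")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "pgc_stages", "mouse_stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "pgc_stages", "mouse_stages"):
            d[key] = list(d[key])
        return d


def _round(obj, nd: int = 6):
    """Round floats to significant digits so the summary JSON is byte-stable
    without flattening small p-values to zero."""
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return None if not np.isfinite(x) else float(f"{x:.{nd}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage on a synthetic study and persist results.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    Any stage failure aborts with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}
    stage_name = "setup"
    try:
        # ----- simulate -----
        stage_name = "simulate"
        sim_cfg = SimConfig.scaled(seed=config.seed,
                                   autosome_bp=config.autosome_bp,
                                   x_bp=config.x_bp)
        if config.cross_species:
            genome, mouse, tile_map, gene_map = build_genome_pair(sim_cfg)
        else:
            genome, mouse, tile_map, gene_map = build_genome(sim_cfg), None, None, None
        tracks = {}
        for stage in config.stages:
            n_ind = config.n_individuals if stage in config.pgc_stages else 1
            tracks[stage] = [simulate_methylome(
                genome, stage, individual=k,
                sample_id=(stage if n_ind == 1 else f"{stage}_i{k}"))
                for k in range(n_ind)]
        for stage, trs in tracks.items():
            write_cpg_calls(trs[0], out / f"{stage}.cov", fmt="bismark_cov")

        # ----- conversion QC -----
        stage_name = "qc-conversion"
        conv = {s: estimate_conversion_rate(trs[0], genome.layout).rate
                for s, trs in tracks.items()}
        summary["conversion_rates"] = conv

        # ----- tiles + quantification -----
        stage_name = "tiles"
        tiles = make_tiles(genome.layout, repeats=genome.repeats)
        pooled = {s: (trs[0] if len(trs) == 1 else pool_replicates(trs))
                  for s, trs in tracks.items()}
        matrix = TileMatrix.build([pooled[s] for s in config.stages], tiles)
        matrix.write_tsv(out / "tile_matrix.tsv")
        stage_name = "medians"
        medians = {}
        for s in config.stages:
            d = dynamics.methylation_distribution(matrix, pooled[s].sample_id)
            medians[s] = d["median"]
        summary["tile_medians"] = medians

        # ----- pairwise dynamics + clustering -----
        stage_name = "dynamics"
        if "ESC" in config.stages and "Wk5.5" in config.stages:
            pw = dynamics.pairwise_change(matrix, pooled["ESC"].sample_id,
                                          pooled["Wk5.5"].sample_id)
            summary["pairwise_ESC_Wk5.5"] = {"slope": pw.slope,
                                             "intercept": pw.intercept,
                                             "n_tiles": pw.n}
        cluster_samples = [pooled[s].sample_id for s in config.stages
                           if s != "ICM"]  # display-only column
        rf = matrix.tiles.tiles["is_repeat_free"].to_numpy()
        rf_matrix = TileMatrix(
            tiles=tiling.TileSet(matrix.tiles.tiles[rf].reset_index(drop=True),
                                 matrix.tiles.tile_size, matrix.tiles.step),
            sample_ids=matrix.sample_ids, levels=matrix.levels[rf],
            covered=matrix.covered[rf], stages=matrix.stages)
        km = dynamics.kmeans_dynamics(rf_matrix, cluster_samples,
                                      k=config.kmeans_k, seed=config.seed)
        pd.DataFrame({"tile_id": rf_matrix.tiles.ids(), "cluster": km.labels}
                     ).to_csv(out / "kmeans_clusters.tsv", sep="\t", index=False)
        summary["kmeans"] = {"k": config.kmeans_k,
                             "cluster_sizes": np.bincount(
                                 km.labels[km.labels >= 0],
                                 minlength=config.kmeans_k).tolist()}
        hc = dynamics.hierarchical_cluster(matrix, cluster_samples)
        (out / "hclust.json").write_text(json.dumps(
            {"samples": hc.sample_ids,
             "linkage": _round(hc.linkage_matrix.tolist())}, sort_keys=True))

        # ----- imprints & X -----
        stage_name = "imprints"
        icr_stages = {s: pooled[s] for s in config.stages}
        icr_rep = imprints.icr_dynamics(icr_stages, genome.icrs,
                                        layout=genome.layout)
        icr_rep.levels.to_csv(out / "icr_dynamics.tsv", sep="\t", index=False,
                              float_format="%.6g")
        summary["icr_retained_counts"] = {
            s: int(icr_rep.retained_counts[s]) for s in config.stages}
        stage_name = "x-reactivation"
        female_pgc = [s for s in config.pgc_stages if s in config.stages]
        if female_pgc and len(genome.truth["xi_promoters"]):
            xi = RegionSet(genome.truth["xi_promoters"].rename(
                columns={"gene_id": "name"}), category="promoter")
            xrep = imprints.x_reactivation_report(
                {s: pooled[s] for s in female_pgc}, xi, layout=genome.layout)
            summary["xi_frac_hypomethylated"] = \
                xrep["frac_hypomethylated"].to_dict()

        # ----- escapees -----
        stage_name = "escapees"
        call_stages = [s for s in ("Wk7", "Wk9") if s in config.stages]
        ind_tracks = [t for s in call_stages for t in tracks[s]]
        call = escapees.call_escapees([pooled[s] for s in call_stages],
                                      genome.layout,
                                      required_tracks=[pooled[s] for s in call_stages],
                                      tiles=tiles)
        classed, class_summary = escapees.classify_by_repeat(
            call.regions, genome.repeats)
        annots = {"enhancer": genome.enhancers, "CGI": genome.cgis,
                  "promoter": genome.genes.promoters(),
                  "gene_body": genome.genes.gene_bodies()}
        classed, feature_dist = escapees.annotate_features(classed, annots)
        classed.drop(columns=["features"]).to_csv(
            out / "escapees.tsv", sep="\t", index=False, float_format="%.6g")
        write_regions_bed(RegionSet(classed[["chrom", "start", "end", "name"]],
                                    category="escapee"), out / "escapees.bed")
        summary["escapees"] = {**call.summary, **class_summary,
                               "feature_distribution": feature_dist}
        if len(ind_tracks) >= 2 and len(classed):
            stage_name = "escapee-variation"
            var = escapees.escapee_variation(classed, ind_tracks,
                                             layout=genome.layout)
            summary["escapee_variation"] = {
                "n_regions": var["n_regions"],
                "median_cv": (float(var["table"]["cv"].median())
                              if len(var["table"]) else None)}
        stage_name = "escapee-fate"
        fate_stages = [s for s in ("sperm", "oocyte", "ICM") if s in config.stages]
        poor = classed[classed["repeat_class"] == "repeat_poor"] if len(classed) \
            else classed
        if len(poor) >= config.fate_k and fate_stages:
            fate_levels = tiling.region_level_table(
                [pooled[s] for s in call_stages + fate_stages],
                RegionSet(poor[["chrom", "start", "end", "name"]]),
                layout=genome.layout).set_index("name").drop(
                    columns=["chrom", "start", "end", "n_cpgs"])
            fate = escapees.cluster_escapee_fate(fate_levels, k=config.fate_k,
                                                 seed=config.seed)
            summary["escapee_fate_cluster_sizes"] = \
                fate["labels"].value_counts().sort_index().tolist()
        stage_name = "escapee-enrichment"
        if len(classed):
            enr = escapees.region_overlap_enrichment(
                classed, genome.enhancers, genome.layout,
                n_perm=config.enrichment_perms, seed=config.seed)
            summary["enhancer_enrichment"] = {"fold": enr["fold"], "p": enr["p"]}

        # ----- repeats -----
        stage_name = "repeats"
        rep_tracks = [pooled[s] for s in config.stages]
        locus = repeats.repeat_locus_methylation(rep_tracks, genome.repeats,
                                                 layout=genome.layout)
        locus.to_csv(out / "repeat_loci.tsv", sep="\t", index=False,
                     float_format="%.6g")

        # ----- expression -----
        stage_name = "expression"
        expr = simulate_expression(genome)
        counts = expr["counts"]
        counts.to_csv(out / "expression_counts.tsv", sep="\t")
        esc_samples = [c for c in counts.columns if c.startswith("ESC_")]
        wk7_samples = [c for c in counts.columns if c.startswith("Wk7_")]
        de = expression.differential_expression(counts, esc_samples, wk7_samples)
        de.to_csv(out / "de_ESC_vs_Wk7.tsv", sep="\t", float_format="%.6g")
        sched = expr["promoter_schedule"]
        coup = expression.coupling_quadrants(
            de.loc[de.index.intersection(sched.index)], sched, "ESC", "Wk7")
        summary["coupling_classes"] = \
            coup["coupling_class"].value_counts().to_dict()
        kz = expression.krab_zfp_panel(
            de.loc[de.index.intersection(sched.index)], sched, genome.genes,
            "ESC", "Wk7")
        summary["krab_zfp"] = {"n_high_in_b": kz["n_high_in_b"],
                               "n_esc_methylated": kz["n_esc_methylated"]}
        stage_name = "repeat-expression"
        meta = expr["feature_meta"]
        rep_counts = counts.loc[meta.index[meta["feature_type"] == "repeat"]]
        norm = expression.normalized_counts(rep_counts,
                                            expression.size_factors(counts))
        wk7_log2 = np.log2(norm[wk7_samples].mean(axis=1) + 1)
        fam = repeats.family_summary(
            locus, pd.DataFrame({"wk7_log2": wk7_log2}).rename_axis("name")
            .reset_index(), family_info=repeats.DEFAULT_FAMILY_INFO)
        fam["summary"].to_csv(out / "repeat_families.tsv", sep="\t",
                              index=False, float_format="%.6g")
        wk7_col = pooled["Wk7"].sample_id if "Wk7" in config.stages else None
        if wk7_col and wk7_col in locus.columns:
            corr = repeats.methylation_expression_correlation(
                locus, wk7_log2, wk7_col)
            sva = corr[corr["subfamily"] == "SVA"]
            if len(sva):
                summary["sva_meth_expr_pearson_r"] = \
                    float(sva["pearson_r"].iloc[0])

        # ----- motifs -----
        stage_name = "motifs"
        if genome.layout.sequence is not None and len(classed):
            poor_set = RegionSet(
                classed[classed["repeat_class"] == "repeat_poor"]
                [["chrom", "start", "end", "name"]].reset_index(drop=True))
            if len(poor_set):
                menr = motifs.motif_enrichment(
                    poor_set, default_zfp57_pwm(), genome.layout,
                    n_perm=config.motif_perms, seed=config.seed)
                summary["zfp57_fold_repeat_poor"] = menr["overall"]["fold"]

        # ----- cross-species -----
        stage_name = "cross-species"
        if config.cross_species and mouse is not None:
            m_tracks = {s: simulate_methylome(mouse, s)
                        for s in config.mouse_stages}
            m_tiles = make_tiles(mouse.layout, repeats=mouse.repeats)
            m_matrix = TileMatrix.build(list(m_tracks.values()), m_tiles)
            joined = dynamics.conserved_tile_compare(matrix, m_matrix, tile_map)
            joined.to_csv(out / "conserved_tiles.tsv", sep="\t", index=False,
                          float_format="%.6g")
            summary["n_conserved_tiles"] = int(len(joined))
            h_hosts = set(genome.truth["escapees"]["host_gene"]) - {""}
            m_hosts = set(mouse.truth["escapees"]["host_gene"]) - {""}
            gmap = dict(zip(gene_map["mouse_gene"], gene_map["human_gene"]))
            m_hosts_h = {gmap[g] for g in m_hosts if g in gmap}
            universe = set(gene_map["human_gene"])
            k, p = escapees.homolog_overlap_test(
                h_hosts & universe, m_hosts_h & universe, universe)
            summary["homolog_overlap"] = {"overlap": k, "p": p}

        stage_name = "summary"
        summary_rounded = _round(summary)
        (out / "summary.json").write_text(
            json.dumps(summary_rounded, sort_keys=True, indent=1))
        return summary_rounded
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc
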