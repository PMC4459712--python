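"""Synthetic germline-cycle genomes, methylomes, and expression matrices.

The generator emulates the statistical structure the analysis assumes so
every stage of the pipeline is testable without any external data:

* a small genome (autosome + X + unmethylated lambda spike-in) with CpG
  sites at realistic density, CpG-island clusters, RepeatMasker-style
  repeat annotation with family/age structure, an imprint-control-region
  panel, enhancers, and gene models;
* per-CpG beta-binomial methylomes with stage-specific global levels,
  negative-binomial sequencing depth, bisulfite non-conversion, and
  planted structure: demethylation escapees (repeat-rich / -poor / -free),
  an imprint-erasure schedule with evaders, Xi-methylated CGI promoters,
  and repeat families whose germline retention declines with evolutionary
  age;
* negative-binomial expression with germline genes activating on promoter
  demethylation and SVA loci whose expression couples negatively to locus
  methylation.

Every planted feature is recorded in a machine-readable ground-truth
ledger (``SimulatedGenome.truth``), and all randomness derives from the
config seed, so outputs are fully reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GeneSet, GenomeLayout, MethylomeTrack, RegionSet, ValidationError

PGC_STAGES = {"Wk5.5", "Wk7", "Wk9", "E10.5", "E13.5"}

DEFAULT_STAGE_MEDIANS = {
    # target median of filtered 1 kb tile methylation per stage
    "ESC": 0.80, "soma": 0.82, "Wk5.5": 0.16, "Wk7": 0.045, "Wk9": 0.05,
    "sperm": 0.87, "oocyte": 0.55, "ICM": 0.37, "E10.5": 0.25, "E13.5": 0.05,
}

STAGE_SEX = {"sperm": "M"}

# stage -> planted methylation for feature classes (values outside the
# background field); hPGC retention for repeats comes from the repeat plan
ICR_SCHEDULE = {"ESC": 0.45, "soma": 0.45, "sperm": 0.50, "oocyte": 0.50,
                "ICM": 0.25, "E10.5": 0.30}
ESCAPEE_SOMATIC = 0.85
REPEAT_SOMATIC = {"ESC": 0.85, "soma": 0.85, "sperm": 0.88, "oocyte": 0.80,
                  "ICM": 0.50}
PROMOTER_SCHEDULES = {
    # per gene class: stage -> planted promoter methylation
    "housekeeping": {},  # CGI promoter, unmethylated everywhere (background CGI ~0.05)
    "bystander": {"ESC": 0.60, "soma": 0.60, "Wk5.5": 0.20, "Wk7": 0.05,
                  "Wk9": 0.05, "sperm": 0.70, "oocyte": 0.70, "ICM": 0.30},
    "soma": {"ESC": 0.60, "soma": 0.60, "Wk5.5": 0.20, "Wk7": 0.05,
             "Wk9": 0.05, "sperm": 0.70, "oocyte": 0.70, "ICM": 0.30},
    "germline": {"ESC": 0.85, "soma": 0.85, "Wk5.5": 0.30, "Wk7": 0.08,
                 "Wk9": 0.05, "sperm": 0.85, "oocyte": 0.85, "ICM": 0.40},
    "krab_esc_methylated": {"ESC": 0.70, "soma": 0.15, "Wk5.5": 0.10,
                            "Wk7": 0.05, "Wk9": 0.05, "sperm": 0.70,
                            "oocyte": 0.70, "ICM": 0.30},
}
CGI_BACKGROUND = 0.05  # CGI promoters without a schedule sit here at all stages

ESCAPEE_FATES = ["gamete_programmed", "sperm_only", "oocyte_only", "partial"]
FATE_LEVELS = {
    "gamete_programmed": {"sperm": 0.85, "oocyte": 0.85, "ICM": 0.45},
    "sperm_only": {"sperm": 0.85, "oocyte": 0.25, "ICM": 0.40},
    "oocyte_only": {"sperm": 0.25, "oocyte": 0.85, "ICM": 0.40},
    "partial": {"sperm": 0.30, "oocyte": 0.30, "ICM": 0.35},
}


@dataclass(frozen=True)
class RepeatFamilyPlan:
    family: str
    age_rank: int
    n_auto: int
    n_x: int
    length: int
    pgc_level: float | None   # None => heterogeneous U(0.05, 0.95) per locus


DEFAULT_REPEAT_PLAN = (
    RepeatFamilyPlan("SVA", 1, 80, 0, 1700, None),
    RepeatFamilyPlan("L1HS", 1, 20, 0, 6100, 0.15),
    RepeatFamilyPlan("AluY", 2, 70, 10, 300, 0.35),
    RepeatFamilyPlan("AluYa-Yk", 2, 30, 0, 300, 0.35),
    RepeatFamilyPlan("L1PA", 3, 60, 0, 2000, 0.32),
    RepeatFamilyPlan("ERV1", 4, 40, 0, 1500, 0.25),
    RepeatFamilyPlan("AluS", 5, 60, 30, 300, 0.15),
    RepeatFamilyPlan("L1PB", 6, 40, 0, 2000, 0.10),
    RepeatFamilyPlan("AluJ", 7, 60, 0, 300, 0.06),
    RepeatFamilyPlan("L1MA_ME", 8, 40, 0, 2000, 0.04),
)

DEFAULT_GENE_PLAN = {"housekeeping": 90, "bystander": 100, "germline": 40,
                     "krab_zfp": 30, "soma": 20}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines output."""

    seed: int = 1
    autosome_bp: int = 10_000_000
    x_bp: int = 5_000_000
    spike_bp: int = 48_502
    chrom_prefix: str = ""
    cpg_spacing: int = 100            # mean background CpG spacing (bp)
    cgi_cpg_spacing: int = 10
    spike_cpg_spacing: int = 15
    stage_medians: tuple = tuple(sorted(DEFAULT_STAGE_MEDIANS.items()))
    tile_mean_concentration: float = 8.0
    cpg_concentration: float = 60.0
    depth_mean: float = 8.0
    depth_shape: float = 4.0
    nonconversion_rate: float = 0.004
    block_bp: int = 5000              # granularity of the latent methylation field
    pgc_like_stages: tuple = ()       # extra stage labels treated as hPGC-like
    calibrate_medians: bool = True    # bisect latent means to hit stage medians
    with_sequence: bool = True
    # escapee plan
    n_escapee_rich: int = 30
    n_escapee_poor: int = 15
    n_escapee_free: int = 5
    n_poor_in_genes: int = 8
    n_poor_in_enhancers: int = 4
    escapee_size: int = 2000
    escapee_level: float = 0.50
    escapee_individual_sd: float = 0.10
    # imprint plan
    n_icrs: int = 22
    icr_size: int = 2000
    icr_retained_wk55: int = 6
    icr_retained_level: float = 0.38
    icr_erased_level: float = 0.05
    icr_evaders: int = 2
    icr_evader_level: float = 0.32
    icr_basal_level: float = 0.03
    # X plan
    xi_promoter_count: int = 30
    xi_reference_level: float = 0.50
    xi_pgc_level: float = 0.05
    x_gene_count: int = 100
    # genes / repeats
    gene_plan: tuple = tuple(sorted(DEFAULT_GENE_PLAN.items()))
    repeat_plan: tuple = DEFAULT_REPEAT_PLAN
    n_enhancers: int = 40
    krab_pgc_high: int = 7
    krab_esc_methylated: int = 6
    host_shift: int = 0               # offset of escapee host-gene choice (species mirror)
    # expression plan
    n_reps: int = 2
    expression_stages: tuple = ("ESC", "soma", "Wk5.5", "Wk7", "Wk9")
    gene_expr_log2_base: float = 7.0
    gene_low_log2: float = 3.5
    activation_log2: float = 3.0      # germline-gene activation on promoter < 0.20
    krab_high_log2: float = 8.0
    krab_low_log2: float = 4.0
    soma_high_log2: float = 8.0
    gene_dispersion: float = 0.1
    library_sd: float = 0.15
    sva_expr_log2_base: float = 9.0
    sva_expr_dispersion: float = 0.02
    sva_coupling_slope: float = -0.5  # log2 expression per unit methylation
    repeat_expr_log2_base: float = 4.0
    repeat_expr_dispersion: float = 0.2

    def stage_median(self, stage: str) -> float:
        d = dict(self.stage_medians)
        if stage not in d:
            raise ValidationError(f"no stage median configured for {stage!r}")
        return d[stage]

    @classmethod
    def scaled(cls, seed: int = 1, autosome_bp: int = 10_000_000,
               x_bp: int = 5_000_000, **kwargs) -> "SimConfig":
        """Config with the feature plan scaled to a smaller genome.

        Gene, repeat, and enhancer counts shrink proportionally (with floors
        that preserve the panel structure: the 22-ICR panel, the escapee
        class counts, and the KRAB-ZFP sub-plan are kept as is).
        """
        f = min(1.0, autosome_bp / 10_000_000)
        if f >= 1.0:
            return cls(seed=seed, autosome_bp=autosome_bp, x_bp=x_bp, **kwargs)
        gene_plan = tuple(sorted({
            "housekeeping": max(int(90 * f), 10),
            "bystander": max(int(100 * f), 10),
            "germline": max(int(40 * f), 10),
            "krab_zfp": max(int(30 * f), 10),
            "soma": max(int(20 * f), 5),
        }.items()))
        repeat_plan = tuple(
            replace(p, n_auto=max(int(p.n_auto * f), 3 if p.n_auto else 0),
                    n_x=max(int(p.n_x * f), 3 if p.n_x else 0))
            for p in DEFAULT_REPEAT_PLAN)
        fx = min(1.0, x_bp / 5_000_000)
        return cls(seed=seed, autosome_bp=autosome_bp, x_bp=x_bp,
                   gene_plan=gene_plan, repeat_plan=repeat_plan,
                   n_enhancers=max(int(40 * f), 5),
                   x_gene_count=max(int(100 * fx), 35),
                   xi_promoter_count=min(30, max(int(30 * fx), 10)),
                   **kwargs)


def caller_benchmark_config(seed: int, n_regions: int = 20,
                            background: float = 0.03,
                            depth_mean: float = 10.0,
                            plant_level: float = 0.50) -> SimConfig:
    """Benchmark genome for the escapee caller: a 10 Mb chromosome with a
    uniform hypomethylated background and ``n_regions`` planted resistant
    regions, no gene/repeat annotation, plain (uncalibrated) stage mean."""
    medians = dict(DEFAULT_STAGE_MEDIANS)
    medians["bench"] = background
    return SimConfig(
        seed=seed, autosome_bp=10_000_000, x_bp=200_000,
        stage_medians=tuple(sorted(medians.items())),
        pgc_like_stages=("bench",), tile_mean_concentration=400.0,
        calibrate_medians=False, with_sequence=False,
        depth_mean=depth_mean,
        n_escapee_rich=0, n_escapee_poor=0, n_escapee_free=n_regions,
        n_poor_in_genes=0, n_poor_in_enhancers=0,
        escapee_level=plant_level, escapee_individual_sd=0.0,
        n_icrs=0, xi_promoter_count=0, x_gene_count=0,
        gene_plan=(), repeat_plan=(), n_enhancers=0)


def _rng(config: SimConfig, *tokens) -> np.random.Generator:
    """Deterministic substream: root seed + crc32-hashed stream tokens."""
    entropy = [config.seed] + [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    layout: GenomeLayout
    repeats: RegionSet
    cgis: RegionSet
    icrs: RegionSet
    enhancers: RegionSet
    genes: GeneSet
    truth: dict
    config: SimConfig

    @property
    def autosome(self) -> str:
        return self.config.chrom_prefix + "chr1"

    @property
    def x_chrom(self) -> str:
        return self.config.chrom_prefix + "chrX"


def build_genome(config: SimConfig = SimConfig()) -> SimulatedGenome:
    """Deterministically lay out the synthetic genome and its annotations."""
    cfg = config
    pre = cfg.chrom_prefix
    chrom_lengths = {pre + "chr1": cfg.autosome_bp, pre + "chrX": cfg.x_bp,
                     pre + "lambda": cfg.spike_bp}
    rng = _rng(cfg, "genome")

    gene_rows, repeat_rows, escapee_rows, icr_rows, enh_rows, cgi_rows = \
        [], [], [], [], [], []
    counters = {"gene": 0, "repeat": 0, "escapee": 0, "enh": 0}

    gene_plan = dict(cfg.gene_plan)
    n_hosts = min(cfg.n_poor_in_genes, gene_plan.get("housekeeping", 0))
    # escapee host genes: deterministic evenly spaced housekeeping indices;
    # for the mirror species, host_shift of them are nudged to neighbouring
    # indices so the cross-species host sets overlap partially but not fully
    hk_total = gene_plan.get("housekeeping", 0)
    if n_hosts:
        base = np.linspace(0, hk_total - 1, n_hosts).astype(int)
        shift = min(cfg.host_shift, n_hosts)
        if shift:
            base = base.copy()
            base[-shift:] = (base[-shift:] + 1) % hk_total
        host_idx = set(base.tolist())
    else:
        host_idx = set()

    def requests_for(chrom_kind: str):
        reqs = []
        if chrom_kind == "auto":
            for cls, n in gene_plan.items():
                for i in range(n):
                    host = cls == "housekeeping" and i in host_idx
                    glen = int(rng.uniform(8000, 12000)) if host \
                        else int(rng.uniform(4000, 9000))
                    reqs.append(("gene", 1500 + glen + 500,
                                 {"class": cls, "glen": glen, "host": host,
                                  "order": i}))
            for fam in cfg.repeat_plan:
                for _ in range(fam.n_auto):
                    reqs.append(("repeat", fam.length, {"fam": fam}))
            for _ in range(cfg.n_escapee_rich):
                reqs.append(("escapee_rich", cfg.escapee_size, {}))
            n_standalone_poor = (cfg.n_escapee_poor - min(cfg.n_poor_in_genes,
                                                          cfg.n_escapee_poor))
            n_enh_poor = min(cfg.n_poor_in_enhancers, n_standalone_poor)
            for _ in range(n_enh_poor):
                reqs.append(("escapee_poor_enh", cfg.escapee_size + 450, {}))
            for _ in range(n_standalone_poor - n_enh_poor):
                reqs.append(("escapee_poor", cfg.escapee_size + 450, {}))
            for _ in range(cfg.n_escapee_free):
                reqs.append(("escapee_free", cfg.escapee_size + 3000, {}))
            for _ in range(cfg.n_icrs):
                reqs.append(("icr", cfg.icr_size, {}))
            for _ in range(cfg.n_enhancers):
                reqs.append(("enhancer", 1000, {}))
        else:  # X
            for i in range(cfg.x_gene_count):
                glen = int(rng.uniform(4000, 9000))
                reqs.append(("gene", 1500 + glen + 500,
                             {"class": "x", "glen": glen, "host": False,
                              "xi": i < cfg.xi_promoter_count, "order": i}))
            for fam in cfg.repeat_plan:
                for _ in range(fam.n_x):
                    reqs.append(("repeat", fam.length, {"fam": fam}))
        rng.shuffle(reqs)
        return reqs

    def add_repeat(chrom, start, fam: RepeatFamilyPlan, length=None):
        counters["repeat"] += 1
        length = length if length is not None else fam.length
        pgc = fam.pgc_level if fam.pgc_level is not None \
            else float(rng.uniform(0.05, 0.95))
        repeat_rows.append((chrom, start, start + length,
                            f"{pre}rep{counters['repeat']:05d}", fam.family,
                            fam.family, fam.age_rank, pgc))
        return start + length

    sva_plan = next((f for f in cfg.repeat_plan if f.family == "SVA"), None)
    decoy_plan = next((f for f in cfg.repeat_plan if f.family == "AluS"),
                      RepeatFamilyPlan("AluS", 5, 0, 0, 300, 0.15))

    for chrom_kind, chrom in (("auto", pre + "chr1"), ("x", pre + "chrX")):
        length = chrom_lengths[chrom]
        reqs = requests_for(chrom_kind)
        total_fp = sum(fp for _, fp, _ in reqs)
        free = length - 40_000 - total_fp - 500 * len(reqs)
        if free < 0:
            raise ValidationError(f"feature plan exceeds capacity of {chrom}")
        # spread features over the whole chromosome: gaps are a random
        # partition of the free space (minimum 500 bp between features)
        gap_props = rng.dirichlet(np.ones(len(reqs)))
        gaps = 500 + (gap_props * free).astype(np.int64)
        cursor = 20_000
        for (kind, footprint, meta), gap in zip(reqs, gaps):
            cursor += int(gap)
            start = cursor
            end = start + footprint
            if end > length - 20_000:
                raise ValidationError(
                    f"feature plan exceeds capacity of {chrom} at {start}")
            if kind == "gene":
                counters["gene"] += 1
                gid = f"{pre}gene{counters['gene']:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                gs, ge = start + 1500, start + 1500 + meta["glen"]
                tss, tes = (gs, ge) if strand == "+" else (ge, gs)
                cls = meta["class"]
                has_cgi = cls in ("housekeeping", "germline", "krab_zfp") or \
                    meta.get("xi", False)
                order = meta["order"]
                gene_rows.append({
                    "gene_id": gid, "chrom": chrom, "strand": strand,
                    "tss": tss, "tes": tes, "class": cls,
                    "class_order": order,
                    "is_krab_zfp": cls == "krab_zfp",
                    "xi_methylated": bool(meta.get("xi", False)),
                    "has_cgi": has_cgi, "host": meta["host"],
                })
                if meta["host"]:
                    counters["escapee"] += 1
                    mid = (gs + ge) // 2
                    es, ee = mid - cfg.escapee_size // 2, mid + cfg.escapee_size // 2
                    escapee_rows.append((f"{pre}esc{counters['escapee']:03d}",
                                         chrom, es, ee, "repeat_poor",
                                         ("gene_body",), gid))
                    add_repeat(chrom, ee + 300, decoy_plan, length=150)
            elif kind == "repeat":
                add_repeat(chrom, start, meta["fam"])
            elif kind == "escapee_rich":
                counters["escapee"] += 1
                name = f"{pre}esc{counters['escapee']:03d}"
                escapee_rows.append((name, chrom, start, end, "repeat_rich",
                                     ("intergenic",), ""))
                add_repeat(chrom, start + 700, sva_plan or decoy_plan, length=600)
            elif kind in ("escapee_poor", "escapee_poor_enh"):
                counters["escapee"] += 1
                name = f"{pre}esc{counters['escapee']:03d}"
                es, ee = start, start + cfg.escapee_size
                feats = ("enhancer",) if kind == "escapee_poor_enh" else ("intergenic",)
                escapee_rows.append((name, chrom, es, ee, "repeat_poor", feats, ""))
                if kind == "escapee_poor_enh":
                    counters["enh"] += 1
                    enh_rows.append((chrom, es + 500, es + 1500,
                                     f"{pre}enh{counters['enh']:03d}"))
                add_repeat(chrom, ee + 300, decoy_plan, length=150)
            elif kind == "escapee_free":
                counters["escapee"] += 1
                es = start + 1500
                ee = es + cfg.escapee_size
                escapee_rows.append((f"{pre}esc{counters['escapee']:03d}",
                                     chrom, es, ee, "repeat_free",
                                     ("intergenic",), ""))
            elif kind == "icr":
                icr_rows.append((chrom, start, end))
            elif kind == "enhancer":
                counters["enh"] += 1
                enh_rows.append((chrom, start, end, f"{pre}enh{counters['enh']:03d}"))
            cursor = end

    if gene_rows:
        genes_df = pd.DataFrame(gene_rows)
    else:
        genes_df = pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss", "tes", "class", "class_order", "is_krab_zfp", "xi_methylated", "has_cgi", "host"])
    gene_set = GeneSet(genes=genes_df[["gene_id", "chrom", "strand", "tss",
                                       "tes", "is_krab_zfp"]].copy())

    # KRAB-ZFP sub-plan: first krab_pgc_high are hPGC-high; of those the first
    # krab_esc_methylated carry ESC-methylated promoters
    kz = genes_df.index[genes_df["class"] == "krab_zfp"]
    genes_df["krab_pgc_high"] = False
    genes_df["krab_esc_methylated"] = False
    genes_df.loc[kz[:cfg.krab_pgc_high], "krab_pgc_high"] = True
    genes_df.loc[kz[:cfg.krab_esc_methylated], "krab_esc_methylated"] = True

    # CGIs at flagged promoters (TSS +/- 500)
    for _, g in genes_df[genes_df["has_cgi"]].iterrows():
        cgi_rows.append((g["chrom"], max(0, g["tss"] - 500), g["tss"] + 500,
                         f"CGI_{g['gene_id']}"))

    # ICR schedule: first icr_retained_wk55 retained at Wk5.5; of those the
    # first icr_evaders stay methylated through Wk7/Wk9
    icr_recs = []
    for i, (chrom, s, e) in enumerate(icr_rows):
        retained = i < cfg.icr_retained_wk55
        evader = i < cfg.icr_evaders
        name = ("ICR_IGF2R" if i == 0 else "ICR_PEG10" if i == 1
                else f"ICR_{i + 1:02d}")
        icr_recs.append({
            "name": name, "chrom": chrom, "start": s, "end": e,
            "wk55_level": cfg.icr_retained_level if retained else cfg.icr_erased_level,
            "late_level": cfg.icr_evader_level if evader else cfg.icr_basal_level,
            "retained_wk55": retained, "evader": evader,
        })
    icr_truth = pd.DataFrame(icr_recs, columns=[
        "name", "chrom", "start", "end", "wk55_level", "late_level",
        "retained_wk55", "evader"])

    repeats_df = pd.DataFrame(repeat_rows or None, columns=[
        "chrom", "start", "end", "name", "family", "subfamily", "age_rank",
        "pgc_level"])
    escapee_truth = pd.DataFrame(escapee_rows, columns=[
        "name", "chrom", "start", "end", "class", "features", "host_gene"])
    escapee_truth["fate"] = [ESCAPEE_FATES[i % len(ESCAPEE_FATES)]
                             for i in range(len(escapee_truth))]
    enh_df = pd.DataFrame(enh_rows or None,
                          columns=["chrom", "start", "end", "name"])
    cgi_df = pd.DataFrame(cgi_rows or None,
                          columns=["chrom", "start", "end", "name"])

    # ----- CpG positions -----
    cpg_positions = {}
    for chrom, length in chrom_lengths.items():
        r = _rng(cfg, "cpg", chrom)
        if chrom == pre + "lambda":
            pos = np.arange(10, length - 2, cfg.spike_cpg_spacing, dtype=np.int64)
        else:
            n_exp = int(1.2 * length / cfg.cpg_spacing) + 100
            gaps = r.geometric(1.0 / cfg.cpg_spacing, n_exp) + 1
            pos = np.cumsum(gaps)
            pos = pos[pos < length - 2]
            dense = []
            for _, c in cgi_df[cgi_df["chrom"] == chrom].iterrows():
                dense.append(np.arange(c["start"] + 2, c["end"] - 2,
                                       cfg.cgi_cpg_spacing, dtype=np.int64))
            if dense:
                pos = np.concatenate([pos] + dense)
            pos = np.unique(pos)
            pos = pos[np.concatenate([[True], np.diff(pos) >= 2])]
        cpg_positions[chrom] = pos.astype(np.int64)

    # ----- sequence -----
    sequence = None
    if cfg.with_sequence:
        sequence = {}
        for chrom, length in chrom_lengths.items():
            r = _rng(cfg, "seq", chrom)
            bases = r.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                             p=[0.3, 0.2, 0.2, 0.3])
            pos = cpg_positions[chrom]
            bases[pos] = ord("C")
            bases[pos + 1] = ord("G")
            sequence[chrom] = bases.tobytes().decode("ascii")

    layout = GenomeLayout(chrom_lengths=chrom_lengths,
                          cpg_positions=cpg_positions, sequence=sequence,
                          spike_chrom=pre + "lambda")

    truth = {
        "escapees": escapee_truth,
        "icrs": icr_truth,
        "repeats": repeats_df,
        "genes": genes_df,
        "xi_promoters": _xi_promoter_truth(genes_df, gene_set),
    }
    return SimulatedGenome(
        layout=layout,
        repeats=RegionSet(repeats_df.drop(columns=["pgc_level"]), category="repeat"),
        cgis=RegionSet(cgi_df, category="CGI"),
        icrs=RegionSet(icr_truth[["chrom", "start", "end", "name"]].copy(),
                       category="ICR"),
        enhancers=RegionSet(enh_df, category="enhancer"),
        genes=gene_set,
        truth=truth,
        config=cfg,
    )


def _xi_promoter_truth(genes_df: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    if not len(genes_df):
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    proms = gene_set.promoters().df.set_index("name")
    xi = genes_df[genes_df["xi_methylated"]]
    rows = []
    for _, g in xi.iterrows():
        p = proms.loc[g["gene_id"]]
        rows.append((g["gene_id"], p["chrom"], p["start"], p["end"]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def build_genome_pair(config: SimConfig = SimConfig(), shared_hosts: int = 5):
    """Human genome plus a mirrored mouse genome with 1:1 tile and gene
    ortholog maps and a partially shared escapee-host gene set."""
    human = build_genome(config)
    mcfg = replace(config, seed=config.seed + 1_000_003, chrom_prefix="m",
                   host_shift=max(config.n_poor_in_genes - shared_hosts, 0))
    mouse = build_genome(mcfg)
    # gene orthologs pair by (class, within-class placement order), which is
    # stable across the two species' independent placement shuffles
    h = human.truth["genes"][["gene_id", "class", "class_order"]]
    m = mouse.truth["genes"][["gene_id", "class", "class_order"]]
    gm = h.merge(m, on=["class", "class_order"], suffixes=("_h", "_m"))
    gene_map = pd.DataFrame({"human_gene": gm["gene_id_h"].to_numpy(),
                             "mouse_gene": gm["gene_id_m"].to_numpy()})
    # tile orthologs: identity on coordinates (same chromosome plan)
    tile_rows = []
    for hc, mc in ((human.autosome, mouse.autosome), (human.x_chrom, mouse.x_chrom)):
        L = human.layout.chrom_lengths[hc]
        for s in range(0, L - 1000 + 1, 500):
            tile_rows.append((f"{hc}:{s}-{s + 1000}", f"{mc}:{s}-{s + 1000}"))
    tile_map = pd.DataFrame(tile_rows, columns=["human_id", "mouse_id"])
    return human, mouse, tile_map, gene_map


# ---------------------------------------------------------------------------
# Latent-mean calibration: the study prints medians of filtered tiles, so
# the generator bisects the latent beta mean until the simulated per-tile
# estimator median hits the configured stage value.
# ---------------------------------------------------------------------------

_LATENT_CACHE: dict = {}


def _chrom_draws(cfg: SimConfig, layout: GenomeLayout, stage: str,
                 individual: int, chrom: str):
    """Fixed uniform draws (and NB depths) for one chromosome of one sample.

    All randomness is realized as quantile transforms of these uniforms, so
    the median calibration can evaluate candidate latent means against the
    very random numbers the simulated track will use.
    """
    r = _rng(cfg, "meth", stage, individual, chrom)
    pos = layout.cpg_positions[chrom]
    n_blocks = layout.chrom_lengths[chrom] // cfg.block_bp + 1
    u_block = r.random(n_blocks)
    u_cpg = r.random(len(pos))
    u_depth = r.random(len(pos))
    u_read = r.random(len(pos))
    p_nb = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    depth = stats.nbinom.ppf(u_depth, cfg.depth_shape, p_nb).astype(np.int64)
    return pos, u_block, u_cpg, depth, u_read


def _chrom_counts(cfg: SimConfig, layout: GenomeLayout, chrom: str, draws,
                  latent: float, overrides: list[tuple[int, int, float]]):
    """(pos, depth, meth) for one chromosome given the latent background."""
    pos, u_block, u_cpg, depth, u_read = draws
    if chrom == layout.spike_chrom:
        level = np.zeros(len(pos))
    else:
        a = latent * cfg.tile_mean_concentration
        b = (1 - latent) * cfg.tile_mean_concentration
        block = stats.beta.ppf(u_block, a, b)
        base = block[pos // cfg.block_bp]
        for s, e, lv in overrides:
            i0, i1 = np.searchsorted(pos, s), np.searchsorted(pos, e)
            base[i0:i1] = lv
        base = np.clip(base, 1e-4, 1 - 1e-4)
        level = stats.beta.ppf(u_cpg, base * cfg.cpg_concentration,
                               (1 - base) * cfg.cpg_concentration)
    obs = level + (1 - level) * cfg.nonconversion_rate
    meth = stats.binom.ppf(u_read, np.maximum(depth, 1), obs).astype(np.int64)
    meth = np.where(depth > 0, meth, 0)
    return pos, depth, meth


def _latent_mean(genome: SimulatedGenome, stage: str, sex: str = "F",
                 min_depth: int = 5, min_cpgs: int = 5,
                 min_covered_frac: float = 0.20) -> float:
    """Latent background block-mean for a stage.

    With ``calibrate_medians`` (default) the value is bisected so the
    median of filtered 1 kb tile levels over the simulated genome (planted
    features included) hits the configured stage value — the quantity the
    study prints is a median of coverage-filtered tiles, not a raw mean.
    The bisection evaluates the actual simulation (same genome, overrides,
    and random draws as the emitted individual-0 track), so the realized
    median matches the target up to the solver tolerance.
    """
    cfg = genome.config
    target = cfg.stage_median(stage)
    if not cfg.calibrate_medians:
        return float(target)
    key = (cfg, stage, sex)
    if key in _LATENT_CACHE:
        return _LATENT_CACHE[key]
    layout = genome.layout
    overrides = _stage_overrides(genome, stage, sex, 0)
    ctx = []
    for chrom in layout.genomic_chroms():
        draws = _chrom_draws(cfg, layout, stage, 0, chrom)
        pos = draws[0]
        length = layout.chrom_lengths[chrom]
        starts = np.arange(0, max(length - 1000, 0) + 1, 500, dtype=np.int64)
        ends = np.minimum(starts + 1000, length)
        ncpg = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        ctx.append((chrom, draws, overrides[chrom], starts, ends, ncpg))

    def median_for(m: float) -> float:
        ests = []
        for chrom, draws, ivs, starts, ends, ncpg in ctx:
            pos, depth, meth = _chrom_counts(cfg, layout, chrom, draws, m, ivs)
            ok = depth >= min_depth
            cm = np.concatenate([[0], np.cumsum(np.where(ok, meth, 0))])
            ct = np.concatenate([[0], np.cumsum(np.where(ok, depth, 0))])
            cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
            lo_i = np.searchsorted(pos, starts)
            hi_i = np.searchsorted(pos, ends)
            sm = cm[hi_i] - cm[lo_i]
            st = ct[hi_i] - ct[lo_i]
            nc = cn[hi_i] - cn[lo_i]
            usable = (ncpg >= min_cpgs) & (nc >= min_covered_frac * ncpg) & (st > 0)
            ests.append(sm[usable] / st[usable])
        return float(np.median(np.concatenate(ests)))

    lo = max(1e-4, target / 6)
    hi = min(1 - 1e-4, target * 2.5 + 0.05)
    f_lo, f_hi = median_for(lo) - target, median_for(hi) - target
    if f_lo > 0 or f_hi < 0:
        result = float(target)  # degenerate target; fall back to identity
    else:
        result = float(optimize.brentq(lambda m: median_for(m) - target,
                                       lo, hi, xtol=2e-4))
    _LATENT_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _escapee_individual_levels(genome: SimulatedGenome, individual: int) -> np.ndarray:
    cfg = genome.config
    esc = genome.truth["escapees"]
    r = _rng(cfg, "escjitter", individual)
    jitter = r.normal(0, cfg.escapee_individual_sd, len(esc))
    return np.clip(cfg.escapee_level + jitter, 0.05, 0.95)


def _stage_overrides(genome: SimulatedGenome, stage: str, sex: str,
                     individual: int) -> dict[str, list[tuple[int, int, float]]]:
    """Planted (start, end, level) intervals per chromosome for one sample."""
    cfg = genome.config
    out: dict[str, list[tuple[int, int, float]]] = {c: [] for c in
                                                    genome.layout.genomic_chroms()}
    is_pgc = stage in PGC_STAGES or stage in cfg.pgc_like_stages
    # repeats
    rep = genome.truth["repeats"]
    rep_level = rep["pgc_level"].to_numpy() if is_pgc else \
        np.full(len(rep), REPEAT_SOMATIC.get(stage, 0.85))
    for (chrom, s, e), lv in zip(rep[["chrom", "start", "end"]].itertuples(index=False),
                                 rep_level):
        out[chrom].append((s, e, float(lv)))
    # gene promoters and CGIs
    genes_df = genome.truth["genes"]
    proms = genome.genes.promoters().df.set_index("name") if len(genes_df) \
        else pd.DataFrame()
    for _, g in genes_df.iterrows():
        p = proms.loc[g["gene_id"]]
        if g["xi_methylated"]:
            if stage in ("ESC", "soma"):
                lv = cfg.xi_reference_level
            elif is_pgc and sex == "F":
                lv = cfg.xi_pgc_level
            else:
                lv = CGI_BACKGROUND
        elif g["class"] == "krab_zfp" and g["krab_esc_methylated"]:
            lv = PROMOTER_SCHEDULES["krab_esc_methylated"].get(stage, CGI_BACKGROUND)
        elif g["class"] in PROMOTER_SCHEDULES and PROMOTER_SCHEDULES[g["class"]]:
            lv = PROMOTER_SCHEDULES[g["class"]].get(stage, CGI_BACKGROUND)
        elif g["has_cgi"]:
            lv = CGI_BACKGROUND
        else:
            continue
        out[p["chrom"]].append((int(p["start"]), int(p["end"]), float(lv)))
    # ICRs
    for _, icr in genome.truth["icrs"].iterrows():
        if stage == "Wk5.5":
            lv = icr["wk55_level"]
        elif stage in ("Wk7", "Wk9", "E13.5"):
            lv = icr["late_level"]
        else:
            lv = ICR_SCHEDULE.get(stage, 0.45)
        out[icr["chrom"]].append((int(icr["start"]), int(icr["end"]), float(lv)))
    # escapees (override last: they dominate their footprint)
    esc = genome.truth["escapees"]
    if is_pgc:
        esc_levels = _escapee_individual_levels(genome, individual)
    elif stage in ("sperm", "oocyte", "ICM"):
        esc_levels = np.array([FATE_LEVELS[f][stage] for f in esc["fate"]])
    else:
        esc_levels = np.full(len(esc), ESCAPEE_SOMATIC)
    for (chrom, s, e), lv in zip(esc[["chrom", "start", "end"]].itertuples(index=False),
                                 esc_levels):
        out[chrom].append((int(s), int(e), float(lv)))
    return out


def simulate_methylome(genome: SimulatedGenome, stage: str,
                       individual: int = 0, sex: str | None = None,
                       sample_id: str | None = None) -> MethylomeTrack:
    """One beta-binomial methylome for a stage/individual.

    Per CpG: a latent level drawn around the local block mean (planted
    features override the block mean), observed through negative-binomial
    depth, binomial methylated counts, and bisulfite non-conversion; the
    spike contig is unmethylated apart from non-conversion.
    """
    cfg = genome.config
    sex = sex or STAGE_SEX.get(stage, "F")
    layout = genome.layout
    latent = _latent_mean(genome, stage, sex)
    overrides = _stage_overrides(genome, stage, sex, individual)
    frames = []
    for chrom in layout.chrom_names:
        draws = _chrom_draws(cfg, layout, stage, individual, chrom)
        pos, depth, meth = _chrom_counts(cfg, layout, chrom, draws, latent,
                                         overrides.get(chrom, []))
        keep = depth > 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep], "meth": meth[keep],
            "unmeth": (depth - meth)[keep]}))
    data = pd.concat(frames, ignore_index=True)
    sid = sample_id or (f"{stage}" if individual == 0 else f"{stage}_i{individual}")
    return MethylomeTrack(sample_id=sid, stage=stage, data=data, sex=sex,
                          individual_id=f"ind{individual}")


def simulate_methylomes(genome: SimulatedGenome, stages: list[str],
                        n_individuals: int = 1) -> dict[str, list[MethylomeTrack]]:
    """Tracks per stage (``n_individuals`` independent embryos each)."""
    return {
        stage: [simulate_methylome(genome, stage, individual=k,
                                   sample_id=(stage if n_individuals == 1
                                              else f"{stage}_i{k}"))
                for k in range(n_individuals)]
        for stage in stages
    }


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def promoter_schedule(genome: SimulatedGenome,
                      stages: list[str] | None = None) -> pd.DataFrame:
    """Planted promoter methylation per gene per stage (the generator's own
    schedule; what a quantification of the simulated methylomes recovers)."""
    cfg = genome.config
    stages = list(stages or cfg.expression_stages)
    genes_df = genome.truth["genes"]
    rows = {}
    for _, g in genes_df.iterrows():
        vals = []
        for stage in stages:
            if g["xi_methylated"]:
                if stage in ("ESC", "soma"):
                    lv = cfg.xi_reference_level
                elif stage in PGC_STAGES or stage in cfg.pgc_like_stages:
                    lv = cfg.xi_pgc_level
                else:
                    lv = CGI_BACKGROUND
            elif g["class"] == "krab_zfp" and g["krab_esc_methylated"]:
                lv = PROMOTER_SCHEDULES["krab_esc_methylated"].get(stage, CGI_BACKGROUND)
            elif g["class"] in PROMOTER_SCHEDULES and PROMOTER_SCHEDULES[g["class"]]:
                lv = PROMOTER_SCHEDULES[g["class"]].get(stage, CGI_BACKGROUND)
            else:
                lv = CGI_BACKGROUND if g["has_cgi"] else \
                    genome.config.stage_median(stage)
            vals.append(lv)
        rows[g["gene_id"]] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=stages)


def _gene_log2_mean(cfg: SimConfig, g: pd.Series, stage: str,
                    prom_level: float) -> float:
    cls = g["class"]
    if cls == "germline":
        base = cfg.gene_low_log2
        if prom_level < 0.20:
            base += cfg.activation_log2
        return base
    if cls == "krab_zfp":
        if g["krab_pgc_high"]:
            return cfg.krab_high_log2 if stage in PGC_STAGES else cfg.krab_low_log2
        return 5.0
    if cls == "soma":
        return cfg.soma_high_log2 if stage == "soma" else cfg.gene_low_log2
    return cfg.gene_expr_log2_base


def simulate_expression(genome: SimulatedGenome,
                        stages: list[str] | None = None,
                        n_reps: int | None = None) -> dict:
    """Negative-binomial counts for genes and repeat loci.

    Germline genes activate (``activation_log2``) at stages where their
    planted promoter methylation drops below 0.20; SVA locus log2 mean
    decreases linearly in the locus's planted methylation with
    ``sva_coupling_slope``; everything else is independent of methylation.
    """
    cfg = genome.config
    stages = list(stages or cfg.expression_stages)
    n_reps = n_reps or cfg.n_reps
    sched = promoter_schedule(genome, stages)
    genes_df = genome.truth["genes"]
    rep = genome.truth["repeats"]
    r = _rng(cfg, "expr")

    samples = [f"{stage}_r{k + 1}" for stage in stages for k in range(n_reps)]
    sample_stage = {f"{stage}_r{k + 1}": stage for stage in stages
                    for k in range(n_reps)}
    lib = r.lognormal(0.0, cfg.library_sd, len(samples))

    feat_ids, rows, meta_rows, truth_rows = [], [], [], []
    for _, g in genes_df.iterrows():
        gid = g["gene_id"]
        means = []
        for s in samples:
            stage = sample_stage[s]
            lm = _gene_log2_mean(cfg, g, stage, sched.loc[gid, stage])
            means.append(2.0 ** lm)
        feat_ids.append(gid)
        rows.append(means)
        meta_rows.append((gid, "gene", g["class"], "", g["is_krab_zfp"]))
        truth_rows.append(means)
    for _, rp in rep.iterrows():
        fam = rp["family"]
        if fam == "SVA":
            lm = (cfg.sva_expr_log2_base
                  + cfg.sva_coupling_slope * rp["pgc_level"])
            disp = cfg.sva_expr_dispersion
        else:
            lm = cfg.repeat_expr_log2_base
            disp = cfg.repeat_expr_dispersion
        feat_ids.append(rp["name"])
        rows.append([2.0 ** lm] * len(samples))
        meta_rows.append((rp["name"], "repeat", fam, fam, False))
        truth_rows.append(rows[-1])

    mean_mat = np.asarray(rows) * lib[None, :]
    disp_vec = np.array([cfg.gene_dispersion if m[1] == "gene" else
                         (cfg.sva_expr_dispersion if m[2] == "SVA"
                          else cfg.repeat_expr_dispersion)
                         for m in meta_rows])
    n_param = 1.0 / disp_vec
    p_param = n_param[:, None] / (n_param[:, None] + mean_mat)
    counts = r.negative_binomial(n_param[:, None], p_param)
    counts_df = pd.DataFrame(counts, index=feat_ids, columns=samples)
    meta = pd.DataFrame(meta_rows, columns=["feature_id", "feature_type",
                                            "class", "family", "is_krab_zfp"]
                        ).set_index("feature_id")
    return {
        "counts": counts_df,
        "feature_meta": meta,
        "sample_stage": sample_stage,
        "expected_means": pd.DataFrame(truth_rows, index=feat_ids, columns=samples),
        "promoter_schedule": sched,
    }
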