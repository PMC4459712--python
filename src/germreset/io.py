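"""Core data containers and file formats for whole-genome bisulfite data.

This module holds the coordinate system (:class:`GenomeLayout`), per-sample
CpG methylation calls (:class:`MethylomeTrack`), labelled genomic intervals
(:class:`RegionSet`), gene models (:class:`GeneSet`), and the readers and
writers for the plain-text formats the pipeline exchanges with upstream
tools: Bismark coverage files, count bedGraphs, BED, minimal GTF, and FASTA.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based conventions of exchange formats happens only inside the readers and
writers here, never downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("germreset")

REGION_CATEGORIES = {
    "repeat", "CGI", "ICR", "enhancer", "gene", "promoter", "escapee", "custom",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class ParseError(ValueError):
    """Malformed input file (carries a line number where possible)."""


class ValidationError(ValueError):
    """Input parsed but violates an invariant (negative counts, dup positions...)."""


# ---------------------------------------------------------------------------
# GenomeLayout
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """Reference coordinate system: chromosomes, CpG positions, optional sequence.

    ``cpg_positions`` maps chromosome name to a sorted int array of 0-based
    positions of the C of each CpG dyad on the plus strand.  ``spike_chrom``
    names the unmethylated spike-in contig (lambda phage) used for bisulfite
    conversion QC; it is excluded from genomic tiling.
    """

    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    sequence: dict[str, str] | None = None
    spike_chrom: str | None = None

    def __post_init__(self) -> None:
        for chrom, pos in self.cpg_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.cpg_positions[chrom] = pos
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"CpG positions given for unknown chromosome {chrom!r}")
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ValidationError(f"CpG positions not strictly increasing on {chrom}")
                if pos[-1] >= self.chrom_lengths[chrom]:
                    raise ValidationError(f"CpG position beyond end of {chrom}")
        if self.sequence is not None:
            for chrom, pos in self.cpg_positions.items():
                seq = self.sequence.get(chrom)
                if seq is None:
                    continue
                arr = pos[pos < len(seq) - 1]
                for p in arr[:100]:  # spot-check; full check is O(genome)
                    if seq[p:p + 2] != "CG":
                        raise ValidationError(
                            f"position {p} on {chrom} does not hold 'CG'")
        if self.spike_chrom is not None and self.spike_chrom not in self.chrom_lengths:
            raise ValidationError(f"spike chromosome {self.spike_chrom!r} not in layout")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def genomic_chroms(self) -> list[str]:
        """Chromosome names excluding the spike-in contig."""
        return [c for c in self.chrom_lengths if c != self.spike_chrom]

    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))


# ---------------------------------------------------------------------------
# MethylomeTrack
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTrack:
    """Per-CpG methylated/unmethylated read counts for one sample.

    ``data`` has columns (chrom, pos, meth, unmeth), sorted by (chrom, pos),
    one row per covered CpG (meth + unmeth >= 1).  Counts from the two
    strands of a CpG dyad are assumed collapsed onto the plus-strand C.
    """

    sample_id: str
    stage: str
    data: pd.DataFrame
    sex: str = "U"
    individual_id: str = ""
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        required = ["chrom", "pos", "meth", "unmeth"]
        if list(df.columns[:4]) != required:
            df = df[required]
        if len(df):
            if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
                raise ValidationError("negative counts in methylome track")
            if ((df["meth"] + df["unmeth"]) < 1).any():
                raise ValidationError("stored records must have depth >= 1")
            if df.duplicated(["chrom", "pos"]).any():
                dup = df[df.duplicated(["chrom", "pos"], keep=False)].iloc[0]
                raise ValidationError(
                    f"duplicate CpG position {dup['chrom']}:{dup['pos']}")
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.data = df
        self._by_chrom = {}

    def __len__(self) -> int:
        return len(self.data)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, meth, unmeth) int64 arrays for one chromosome (cached)."""
        if chrom not in self._by_chrom:
            sub = self.data[self.data["chrom"] == chrom]
            self._by_chrom[chrom] = (
                sub["pos"].to_numpy(np.int64),
                sub["meth"].to_numpy(np.int64),
                sub["unmeth"].to_numpy(np.int64),
            )
        return self._by_chrom[chrom]

    def chroms(self) -> list[str]:
        return list(self.data["chrom"].unique())

    @property
    def levels(self) -> pd.Series:
        tot = self.data["meth"] + self.data["unmeth"]
        return self.data["meth"] / tot

    def global_level(self, exclude: str | None = None) -> float:
        """Genome-wide coverage-weighted methylation level."""
        df = self.data
        if exclude is not None:
            df = df[df["chrom"] != exclude]
        tot = int(df["meth"].sum() + df["unmeth"].sum())
        if tot == 0:
            raise ValidationError("track has no calls")
        return float(df["meth"].sum()) / tot


def make_track(sample_id, stage, chrom, pos, meth, unmeth, **meta) -> MethylomeTrack:
    """Convenience constructor from parallel arrays."""
    df = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "meth": np.asarray(meth, dtype=np.int64),
        "unmeth": np.asarray(unmeth, dtype=np.int64),
    })
    return MethylomeTrack(sample_id=sample_id, stage=stage, data=df, **meta)


# ---------------------------------------------------------------------------
# RegionSet
# ---------------------------------------------------------------------------

class RegionSet:
    """Labelled half-open genomic intervals with O(log n + k) overlap queries.

    Backed by a DataFrame with at least (chrom, start, end, name, category);
    repeat annotations additionally carry family / subfamily / age_rank.
    """

    def __init__(self, df: pd.DataFrame, category: str | None = None):
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = [f"region_{i}" for i in range(len(df))]
        if category is not None:
            df["category"] = category
        if "category" not in df.columns:
            df["category"] = "custom"
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.df = df.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}

    def __len__(self) -> int:
        return len(self.df)

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            sub = self.df[self.df["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), i) for i, s, e in
                zip(sub.index, sub["start"], sub["end"]))
        return self._trees[chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows overlapping [start, end) on chrom."""
        hits = self._tree(chrom).overlap(start, end)
        idx = sorted(h.data for h in hits)
        return self.df.loc[idx]

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Base pairs of [start, end) covered by the (merged) intervals."""
        hits = self._tree(chrom).overlap(start, end)
        if not hits:
            return 0
        ivs = sorted((max(h.begin, start), min(h.end, end)) for h in hits)
        total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return int(total)

    def any_within(self, chrom: str, start: int, end: int, dist: int) -> bool:
        """True if any interval lies within ``dist`` bp of [start, end)."""
        return bool(self._tree(chrom).overlap(start - dist, end + dist))

    def merged_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged, sorted (starts, ends) for one chromosome."""
        sub = self.df[self.df["chrom"] == chrom].sort_values("start")
        if not len(sub):
            return np.empty(0, np.int64), np.empty(0, np.int64)
        starts, ends = [], []
        for s, e in zip(sub["start"], sub["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        return np.asarray(starts, np.int64), np.asarray(ends, np.int64)

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.df[mask])

    @classmethod
    def from_records(cls, records: Iterable[tuple], category: str = "custom",
                     columns: Sequence[str] = ("chrom", "start", "end", "name")) -> "RegionSet":
        return cls(pd.DataFrame.from_records(list(records), columns=list(columns)),
                   category=category)


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Gene models with deterministic promoter derivation.

    ``genes`` columns: gene_id, chrom, strand, tss, tes, biotype, is_krab_zfp.
    tss/tes are 0-based; for minus-strand genes tss > tes.  Promoters extend
    ``upstream_bp`` before and ``downstream_bp`` after the TSS, strand-aware.
    """

    genes: pd.DataFrame
    upstream_bp: int = 1000
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        df = self.genes
        if len(df):
            if not df["strand"].isin(["+", "-"]).all():
                bad = df[~df["strand"].isin(["+", "-"])].iloc[0]
                raise ValidationError(f"unknown strand {bad['strand']!r} for {bad['gene_id']}")
            if (df["tss"] == df["tes"]).any():
                raise ValidationError("gene with tss == tes")
            if df["gene_id"].duplicated().any():
                dup = df[df["gene_id"].duplicated()].iloc[0]["gene_id"]
                raise ValidationError(f"duplicate gene_id {dup!r}")
        if "biotype" not in df.columns:
            df["biotype"] = "protein_coding"
        if "is_krab_zfp" not in df.columns:
            df["is_krab_zfp"] = False
        self.genes = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def promoters(self) -> RegionSet:
        g = self.genes
        plus = g["strand"] == "+"
        start = np.where(plus, g["tss"] - self.upstream_bp, g["tss"] - self.downstream_bp)
        end = np.where(plus, g["tss"] + self.downstream_bp, g["tss"] + self.upstream_bp)
        df = pd.DataFrame({
            "chrom": g["chrom"], "start": np.maximum(start, 0).astype(np.int64),
            "end": end.astype(np.int64), "name": g["gene_id"],
        })
        return RegionSet(df, category="promoter")

    def gene_bodies(self) -> RegionSet:
        g = self.genes
        start = np.minimum(g["tss"], g["tes"])
        end = np.maximum(g["tss"], g["tes"])
        df = pd.DataFrame({"chrom": g["chrom"], "start": start.astype(np.int64),
                           "end": end.astype(np.int64), "name": g["gene_id"]})
        return RegionSet(df, category="gene")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cpg_calls(path, fmt: str = "bismark_cov", **metadata) -> MethylomeTrack:
    """Read per-CpG calls into a :class:`MethylomeTrack`.

    ``bismark_cov`` is the 6-column Bismark coverage format
    (chrom, start1, end1, percent, meth, unmeth) with 1-based inclusive
    positions; ``bedgraph_counts`` is a 5-column 0-based variant
    (chrom, start0, end0, meth, unmeth).
    """
    path = Path(path)
    if fmt == "bismark_cov":
        cols = ["chrom", "start", "end", "pct", "meth", "unmeth"]
        offset = 1
    elif fmt == "bedgraph_counts":
        cols = ["chrom", "start", "end", "meth", "unmeth"]
        offset = 0
    else:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=cols,
                         dtype={"chrom": str}, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    for c in ("start", "meth", "unmeth"):
        vals = pd.to_numeric(df[c], errors="coerce") if len(df) else df[c]
        if len(df) and vals.isna().any():
            line = int(vals.isna().idxmax()) + 1
            raise ParseError(f"{path}: malformed value in column {c!r} at line {line}")
        df[c] = vals
    if len(df) and ((df["meth"] < 0).any() or (df["unmeth"] < 0).any()):
        raise ValidationError(f"{path}: negative counts")
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str) if len(df) else pd.Series(dtype=str),
        "pos": (df["start"].astype(np.int64) - offset) if len(df) else pd.Series(dtype=np.int64),
        "meth": df["meth"].astype(np.int64) if len(df) else pd.Series(dtype=np.int64),
        "unmeth": df["unmeth"].astype(np.int64) if len(df) else pd.Series(dtype=np.int64),
    })
    metadata.setdefault("sample_id", path.stem)
    metadata.setdefault("stage", "custom")
    return MethylomeTrack(data=out, **metadata)


def write_cpg_calls(track: MethylomeTrack, path, fmt: str = "bismark_cov") -> None:
    df = track.data
    if fmt == "bismark_cov":
        tot = df["meth"] + df["unmeth"]
        pct = np.where(tot > 0, 100.0 * df["meth"] / tot, 0.0)
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["pos"] + 1, "end": df["pos"] + 1,
            "pct": np.round(pct, 6), "meth": df["meth"], "unmeth": df["unmeth"],
        })
    elif fmt == "bedgraph_counts":
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1,
            "meth": df["meth"], "unmeth": df["unmeth"],
        })
    else:
        raise ValueError(f"unknown format {fmt!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


_BED_EXTRA = ["score", "strand", "family", "subfamily", "age_rank"]


def read_regions_bed(path, category: str = "custom",
                     layout: GenomeLayout | None = None) -> RegionSet:
    """Read BED3+ intervals; RepeatMasker-style extra columns become
    family/subfamily/age_rank attributes.  Intervals running past a known
    chromosome end are clipped with a logged warning."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(3))
    ncol = raw.shape[1]
    if len(raw) and ncol < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name"] + _BED_EXTRA
    raw.columns = names[:ncol]
    df = raw.copy()
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if "age_rank" in df.columns:
            df["age_rank"] = pd.to_numeric(df["age_rank"], errors="coerce")
    if layout is not None and len(df):
        for chrom, length in layout.chrom_lengths.items():
            over = (df["chrom"] == chrom) & (df["end"] > length)
            if over.any():
                logger.warning("%s: %d interval(s) on %s extend past chromosome end; clipped",
                               path, int(over.sum()), chrom)
                df.loc[over, "end"] = length
    return RegionSet(df, category=category)


def write_regions_bed(regions: RegionSet, path) -> None:
    cols = ["chrom", "start", "end", "name"]
    extra = [c for c in _BED_EXTRA if c in regions.df.columns]
    regions.df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path, fmt: str = "bed12", upstream_bp: int = 1000,
                     downstream_bp: int = 500) -> GeneSet:
    """Read gene models from BED12 or minimal GTF (gene lines only)."""
    path = Path(path)
    rows = []
    if fmt == "bed12":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        for _, r in df.iterrows():
            chrom, start, end, name, _score, strand = r[0], int(r[1]), int(r[2]), r[3], r[4], r[5]
            if strand == "+":
                tss, tes = start, end
            elif strand == "-":
                tss, tes = end, start
            else:
                raise ValidationError(f"{path}: unknown strand {strand!r} for {name}")
            rows.append((name, chrom, strand, tss, tes))
    elif fmt == "gtf_min":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise ParseError(f"{path}: line {lineno}: expected 9 GTF fields")
                if f[2] != "gene":
                    continue
                chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in f[8].rstrip(";").split(";") if kv.strip())
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}: line {lineno}: no gene_id attribute")
                if strand == "+":
                    tss, tes = start, end
                elif strand == "-":
                    tss, tes = end, start
                else:
                    raise ValidationError(f"{path}: unknown strand {strand!r} for {gid}")
                rows.append((gid, chrom, strand, tss, tes))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    return GeneSet(genes=genes, upstream_bp=upstream_bp, downstream_bp=downstream_bp)


def write_fasta(layout: GenomeLayout, path) -> None:
    """Write layout sequences as FASTA (requires layout.sequence)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if layout.sequence is None:
        raise ValidationError("layout has no sequence to write")
    recs = [SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in layout.sequence.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta_sequences(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Bisulfite conversion QC
# ---------------------------------------------------------------------------

@dataclass
class ConversionEstimate:
    rate: float
    n_calls: int


def estimate_conversion_rate(track: MethylomeTrack,
                             layout: GenomeLayout) -> ConversionEstimate:
    """Bisulfite conversion rate from the unmethylated spike-in contig.

    Every call on the spike contig comes from an unmethylated cytosine, so
    the conversion rate is the fraction of calls read as unmethylated.
    """
    if layout.spike_chrom is None:
        raise ValidationError("layout has no spike_chrom set")
    sub = track.data[track.data["chrom"] == layout.spike_chrom]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        raise ValidationError("no spike-in coverage")
    return ConversionEstimate(rate=float(sub["unmeth"].sum()) / total, n_calls=total)
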