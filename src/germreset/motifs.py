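"""Position-weight-matrix scanning and motif enrichment over region sets.

The default panel carries a consensus-derived matrix for the ZFP57
recognition hexamer TGCCGC; user matrices load from a simple tab-delimited
4 x L format (rows A, C, G, T of per-position base probabilities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeLayout, RegionSet, ValidationError

logger = logging.getLogger("germreset")

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWM:
    """4 x L base-probability matrix with log-odds scoring.

    ``threshold_frac`` sets the hit threshold as a fraction of the maximum
    achievable log-odds score (scale-free default 0.8).
    """

    name: str
    matrix: np.ndarray                       # rows A,C,G,T; columns positions
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_frac: float = 0.8
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValidationError("PWM must be 4 x L with L >= 4")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1) > 1e-9):
            raise ValidationError("PWM columns must sum to 1")
        self.log_odds = np.log2((self.matrix + self.pseudo)
                                / (self.background[:, None] + self.pseudo))
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score

    def reverse_complement(self) -> np.ndarray:
        """Log-odds matrix for scanning the minus strand in plus coordinates."""
        return self.log_odds[::-1, ::-1]


def default_zfp57_pwm(threshold_frac: float = 0.8) -> PWM:
    """Consensus-derived matrix for the ZFP57 hexamer TGCCGC (0.91 on the
    consensus base, 0.03 elsewhere)."""
    consensus = "TGCCGC"
    mat = np.full((4, len(consensus)), 0.03)
    for j, b in enumerate(consensus):
        mat[_BASES.index(b), j] = 0.91
    return PWM(name="ZFP57", matrix=mat, threshold_frac=threshold_frac)


def read_pwm_tsv(path, name: str | None = None, **kwargs) -> PWM:
    df = pd.read_csv(path, sep="\t", header=None)
    return PWM(name=name or str(path), matrix=df.to_numpy(float), **kwargs)


def write_pwm_tsv(pwm: PWM, path) -> None:
    pd.DataFrame(pwm.matrix).to_csv(path, sep="\t", header=False, index=False)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        out[arr == ord(b)] = i
    return out


def _scan_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Per-offset summed log-odds; offsets containing N score -inf."""
    L = log_odds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        c = codes[j:j + n]
        valid = c >= 0
        scores[valid] += log_odds[c[valid], j]
        bad |= ~valid
    scores[bad] = -np.inf
    return scores


def scan_pwm(layout: GenomeLayout, regions: RegionSet, pwm: PWM) -> pd.DataFrame:
    """Score the PWM at every offset on both strands of each region; hits are
    offsets with score >= threshold, reported as genomic (chrom, pos, strand,
    score), deduplicated by (position, strand)."""
    if layout.sequence is None:
        raise ValidationError("motif scanning requires layout sequence")
    rows = []
    rc = pwm.reverse_complement()
    for _, r in regions.df.iterrows():
        chrom = r["chrom"]
        seq = layout.sequence.get(chrom)
        if seq is None or r["end"] > len(seq):
            raise ValidationError(f"region beyond sequence on {chrom}")
        codes = _encode(seq[int(r["start"]):int(r["end"])])
        for strand, lo in (("+", pwm.log_odds), ("-", rc)):
            scores = _scan_scores(codes, lo)
            for off in np.flatnonzero(scores >= pwm.threshold):
                rows.append((chrom, int(r["start"]) + int(off), strand,
                             float(scores[off])))
    hits = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score"])
    return hits.drop_duplicates(["chrom", "pos", "strand"]).reset_index(drop=True)


def motif_enrichment(regions: RegionSet, pwm: PWM, layout: GenomeLayout,
                     background: str | RegionSet = "length_matched_random",
                     n_perm: int = 200, seed: int = 0,
                     class_col: str | None = None,
                     copy_min: int = 700) -> dict:
    """Motif hit density (hits/kb) in regions versus sampled background.

    Background is either random length-matched placements on the same
    chromosomes (``n_perm`` draws) or a provided RegionSet.  With
    ``class_col`` set, per-class folds are reported too; classes with
    <= ``copy_min`` member regions are excluded from the per-class report.
    """
    rng = np.random.default_rng(seed)

    def density(rset: RegionSet) -> float:
        total_kb = float((rset.df["end"] - rset.df["start"]).sum()) / 1000.0
        hits = scan_pwm(layout, rset, pwm)
        return len(hits) / total_kb if total_kb else 0.0

    def one_result(rset: RegionSet) -> dict:
        obs = density(rset)
        if isinstance(background, RegionSet):
            bg_densities = np.array([density(background)])
        else:
            chroms = rset.df["chrom"].to_numpy()
            lengths = (rset.df["end"] - rset.df["start"]).to_numpy(np.int64)
            clen = np.array([layout.chrom_lengths[c] for c in chroms], np.int64)
            bg_densities = np.empty(n_perm)
            for i in range(n_perm):
                starts = (rng.random(len(lengths)) * (clen - lengths)).astype(np.int64)
                draw = RegionSet(pd.DataFrame({
                    "chrom": chroms, "start": starts, "end": starts + lengths}))
                bg_densities[i] = density(draw)
        mean_bg = float(bg_densities.mean())
        if mean_bg == 0:
            fold, infinite = float("inf"), True
        else:
            fold, infinite = obs / mean_bg, False
        p = (1 + int((bg_densities >= obs).sum())) / (len(bg_densities) + 1)
        return {"density": obs, "background_density": mean_bg, "fold": fold,
                "fold_infinite": infinite, "p": p}

    result = {"overall": one_result(regions), "pwm": pwm.name, "n_perm": n_perm}
    if class_col is not None and class_col in regions.df.columns:
        per_class = {}
        for cls, sub in regions.df.groupby(class_col):
            if len(sub) <= copy_min:
                continue
            per_class[cls] = one_result(RegionSet(sub.reset_index(drop=True)))
        result["per_class"] = per_class
    return result
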