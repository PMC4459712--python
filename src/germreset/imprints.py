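"""Imprint-control-region erasure dynamics and X-reactivation reporting.

Built on the coverage-filtered region quantification: per-ICR per-stage
methylation with retained/evader bookkeeping (retained means strictly >20%
methylation), and per-promoter dynamics of Xi-methylated CGI promoters in
the female germline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeLayout, MethylomeTrack, RegionSet, ValidationError
from .tiling import CoverageFilter, DEFAULT_FILTER, region_level_table


@dataclass
class ICRReport:
    levels: pd.DataFrame          # one row per ICR, one level column per stage
    retained: pd.DataFrame        # boolean, same shape as level columns
    retained_counts: pd.Series    # per-stage count of ICRs > threshold
    evaders: list[str]            # retained at the final stage
    threshold: float


def icr_dynamics(tracks_by_stage: dict[str, MethylomeTrack], panel: RegionSet,
                 filt: CoverageFilter = DEFAULT_FILTER,
                 layout: GenomeLayout | None = None,
                 retain_threshold: float = 0.20) -> ICRReport:
    """Per-ICR methylation across stages with retained-ICR counts.

    An ICR is retained at a stage when its level is strictly greater than
    ``retain_threshold``; ICRs failing coverage are missing (never treated
    as erased).  Evaders are ICRs still retained at the last stage given.
    """
    if not len(panel):
        raise ValidationError("ICR panel is empty")
    stages = list(tracks_by_stage)
    tracks = list(tracks_by_stage.values())
    table = region_level_table(tracks, panel, filt, layout)
    rename = {t.sample_id: s for t, s in zip(tracks, stages)}
    table = table.rename(columns=rename)
    lv = table[stages]
    retained = lv.gt(retain_threshold) & lv.notna()
    counts = retained.sum(axis=0)
    evaders = table.loc[retained[stages[-1]], "name"].tolist()
    return ICRReport(levels=table, retained=retained,
                     retained_counts=counts, evaders=evaders,
                     threshold=retain_threshold)


def x_reactivation_report(tracks_by_stage: dict[str, MethylomeTrack],
                          xi_promoters: RegionSet,
                          filt: CoverageFilter = DEFAULT_FILTER,
                          layout: GenomeLayout | None = None,
                          hypo_threshold: float = 0.15) -> dict:
    """Methylation of Xi-marked CGI promoters across female germline stages.

    ``xi_promoters`` should come from selecting partially methylated
    (30-70%) X-CGI promoters in female reference samples (ESC and soma).
    Reports per-promoter per-stage levels and, per stage, the fraction of
    covered promoters below ``hypo_threshold`` (reactivation signature).
    """
    if not len(xi_promoters):
        raise ValidationError("empty Xi promoter set")
    for stage, tr in tracks_by_stage.items():
        if tr.sex not in ("F", "U"):
            raise ValidationError(
                f"female stages required; {stage} track is sex={tr.sex!r}")
    stages = list(tracks_by_stage)
    tracks = list(tracks_by_stage.values())
    table = region_level_table(tracks, xi_promoters, filt, layout)
    table = table.rename(columns={t.sample_id: s for t, s in zip(tracks, stages)})
    frac_hypo = {}
    for s in stages:
        v = table[s].to_numpy(float)
        v = v[~np.isnan(v)]
        frac_hypo[s] = float((v < hypo_threshold).mean()) if len(v) else float("nan")
    return {"levels": table, "frac_hypomethylated": pd.Series(frac_hypo),
            "threshold": hypo_threshold}
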