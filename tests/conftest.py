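"""Shared fixtures: small hand-built objects plus one session-scoped
synthetic study reused by the heavier integration and acceptance tests."""

import numpy as np
import pandas as pd
import pytest

from germreset import (GenomeLayout, MethylomeTrack, RegionSet, make_track)
from germreset.simulate import SimConfig, build_genome, simulate_methylome
from germreset.tiling import TileMatrix, make_tiles


@pytest.fixture()
def tiny_layout():
    """Two short chromosomes plus a spike contig; CpGs every 100 bp."""
    lengths = {"chrA": 10_000, "chrB": 5_000, "spike": 2_000}
    cpgs = {c: np.arange(50, L - 2, 100, dtype=np.int64)
            for c, L in lengths.items()}
    return GenomeLayout(chrom_lengths=lengths, cpg_positions=cpgs,
                        spike_chrom="spike")


def track_from_levels(layout, levels_by_chrom, depth=10, sample_id="t",
                      stage="custom", **meta):
    """Deterministic track: meth = round(level * depth) at every CpG."""
    frames = []
    for chrom, level in levels_by_chrom.items():
        pos = layout.cpg_positions[chrom]
        lv = np.broadcast_to(np.asarray(level, float), pos.shape)
        meth = np.rint(lv * depth).astype(np.int64)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth,
                                    "unmeth": depth - meth}))
    data = pd.concat(frames, ignore_index=True)
    return MethylomeTrack(sample_id=sample_id, stage=stage, data=data, **meta)


@pytest.fixture()
def uniform_track(tiny_layout):
    return track_from_levels(tiny_layout, {"chrA": 0.8, "chrB": 0.8})


# ---- session-scoped synthetic study (default full-size genome, seed 1) ----

@pytest.fixture(scope="session")
def full_genome():
    return build_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def full_tiles(full_genome):
    return make_tiles(full_genome.layout, repeats=full_genome.repeats)


@pytest.fixture(scope="session")
def wk55_track(full_genome):
    return simulate_methylome(full_genome, "Wk5.5")


@pytest.fixture(scope="session")
def wk7_track(full_genome):
    return simulate_methylome(full_genome, "Wk7")


@pytest.fixture(scope="session")
def small_genome():
    """Reduced genome for integration tests that exercise many stages."""
    return build_genome(SimConfig.scaled(seed=11, autosome_bp=3_000_000,
                                         x_bp=1_500_000))


@pytest.fixture(scope="session")
def small_tracks(small_genome):
    stages = ["ESC", "soma", "Wk5.5", "Wk7", "Wk9", "sperm", "oocyte", "ICM"]
    return {s: simulate_methylome(small_genome, s) for s in stages}


@pytest.fixture(scope="session")
def small_matrix(small_genome, small_tracks):
    tiles = make_tiles(small_genome.layout, repeats=small_genome.repeats)
    return TileMatrix.build(list(small_tracks.values()), tiles)


@pytest.fixture(scope="session")
def small_expression(small_genome):
    from germreset.simulate import simulate_expression
    return simulate_expression(small_genome)
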