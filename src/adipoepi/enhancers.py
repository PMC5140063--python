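"""Enhancer-universe construction and stage-specific enhancer calling.

Enhancers are defined operationally: H3K27ac-marked regions (pooled across
stages) that carry no H3K4me3 and lie outside every TSS +/- 2.5 kb window.
Per-stage H3K27ac RPKM over the universe is z-scored; a region is called
stage-specific where its z exceeds 1 and moderate activity (z > 0) is not
spread over too many other stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    SignalMatrix,
    merge_within_gap,
    quantify_rpkm,
    subtract,
    zscore_normalize,
)


@dataclass
class EnhancerUniverse:
    """Candidate distal enhancers with (optionally attached) per-stage signal."""

    regions: IntervalSet
    stages: list[str] = field(default_factory=list)
    rpkm: SignalMatrix | None = None
    zscore: SignalMatrix | None = None
    h3k4me1_zscore: SignalMatrix | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class StageSpecificEnhancerCall:
    region: GenomicInterval
    stages: list[str]
    zvector: np.ndarray


def tss_windows(genes: Sequence[GeneModel], pad: int = 2500) -> IntervalSet:
    """TSS +/- pad exclusion windows, one per transcript model."""
    return IntervalSet(
        GenomicInterval(g.chrom, max(0, g.tss - pad), g.tss + pad, name=g.gene_id)
        for g in genes
    )


def build_enhancer_universe(
    h3k27ac_peaks: Mapping[str, IntervalSet],
    h3k4me3_peaks: Mapping[str, IntervalSet],
    genes: Sequence[GeneModel],
    tss_pad: int = 2500,
) -> EnhancerUniverse:
    """Pool per-stage peaks and remove promoter-like regions.

    H3K27ac peaks from all stages are union-merged (gap 0); likewise
    H3K4me3. Any pooled H3K27ac region overlapping pooled H3K4me3 or a
    TSS +/- tss_pad window by >= 1 base is removed entirely.
    """
    all_k27 = [iv for s in h3k27ac_peaks for iv in h3k27ac_peaks[s]]
    if not all_k27:
        raise ValueError("no H3K27ac peaks supplied")
    pooled_k27 = merge_within_gap(IntervalSet(all_k27), 0)
    all_k4 = [iv for s in h3k4me3_peaks for iv in h3k4me3_peaks[s]]
    pooled_k4 = (
        merge_within_gap(IntervalSet(all_k4), 0) if all_k4 else IntervalSet()
    )
    universe = subtract(pooled_k27, pooled_k4)
    universe = subtract(universe, tss_windows(genes, tss_pad))
    return EnhancerUniverse(
        regions=universe,
        stages=list(h3k27ac_peaks),
        provenance={
            "h3k27ac_stages": list(h3k27ac_peaks),
            "h3k4me3_stages": list(h3k4me3_peaks),
            "tss_pad": tss_pad,
            "n_pooled_h3k27ac": len(pooled_k27),
            "n_universe": len(universe),
        },
    )


def quantify_universe(
    u: EnhancerUniverse,
    reads_per_stage: Mapping[str, IntervalSet],
    library_sizes: Mapping[str, float] | None = None,
    zscore_axis: str = "per_stage_across_regions",
    h3k4me1_reads_per_stage: Mapping[str, IntervalSet] | None = None,
    h3k4me1_library_sizes: Mapping[str, float] | None = None,
) -> EnhancerUniverse:
    """Attach per-stage H3K27ac RPKM + z-score (and optional H3K4me1 z)."""
    regions = list(u.regions)
    u.rpkm = quantify_rpkm(regions, reads_per_stage, library_sizes=library_sizes)
    u.zscore = zscore_normalize(u.rpkm, axis=zscore_axis)
    u.stages = list(u.rpkm.stages)
    if h3k4me1_reads_per_stage is not None:
        me1 = quantify_rpkm(
            regions, h3k4me1_reads_per_stage, library_sizes=h3k4me1_library_sizes
        )
        u.h3k4me1_zscore = zscore_normalize(me1, axis=zscore_axis)
    return u


def call_stage_specific_enhancers(
    u: EnhancerUniverse,
    z_high: float = 1.0,
    z_active: float = 0.0,
    max_additional: int = 3,
) -> list[StageSpecificEnhancerCall]:
    """Assign universe regions to stages where z > z_high, rejecting regions
    whose activity (z > z_active) spreads over more than ``max_additional``
    other stages. Multiple stage assignments are allowed.
    """
    if u.zscore is None or u.zscore.unit != "zscore":
        raise ValueError("universe must carry a z-scored signal matrix")
    z = u.zscore.values
    stages = u.zscore.stages
    active = z > z_active
    n_active = active.sum(axis=1)
    calls: list[StageSpecificEnhancerCall] = []
    for i, region in enumerate(u.zscore.regions):
        assigned = [
            stages[j]
            for j in range(len(stages))
            if z[i, j] > z_high and (n_active[i] - int(active[i, j])) <= max_additional
        ]
        if assigned:
            calls.append(StageSpecificEnhancerCall(region, assigned, z[i].copy()))
    return calls


def h3k4me1_concordance(
    u: EnhancerUniverse, calls: Sequence[StageSpecificEnhancerCall]
) -> list[dict]:
    """Per stage: mean H3K4me1 z at called enhancers vs the whole universe,
    and the fraction of calls with H3K4me1 z > 0 in their assigned stage."""
    if u.h3k4me1_zscore is None:
        raise ValueError("universe has no companion H3K4me1 signal")
    me1 = u.h3k4me1_zscore
    key = {(iv.chrom, iv.start, iv.end): i for i, iv in enumerate(me1.regions)}
    table = []
    for j, stage in enumerate(me1.stages):
        idx = [
            key[(c.region.chrom, c.region.start, c.region.end)]
            for c in calls
            if stage in c.stages
        ]
        col = me1.values[:, j]
        if idx:
            at_calls = col[idx]
            table.append(
                {
                    "stage": stage,
                    "n_calls": len(idx),
                    "mean_me1_z_calls": float(at_calls.mean()),
                    "mean_me1_z_universe": float(col.mean()),
                    "concordant_fraction": float((at_calls > 0).mean()),
                }
            )
        elif calls:
            table.append(
                {
                    "stage": stage,
                    "n_calls": 0,
                    "mean_me1_z_calls": float("nan"),
                    "mean_me1_z_universe": float(col.mean()),
                    "concordant_fraction": float("nan"),
                }
            )
    return table if calls else []
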