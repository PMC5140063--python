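"""Super-enhancer stitching, slope-cutoff ranking, and target assignment.

Active enhancers (z > 0 at a focal stage) lying within 12.5 kb of each other
are stitched into candidate spans; spans longer than 12.5 kb are ranked by
their focal-stage RPKM and the high-signal suffix of the ranked curve —
entered where the discrete slope on the unit-square rank/signal plot exceeds
a threshold — is called the super-enhancer (SE) set. SEs are assigned to
expressed genes within 100 kb by Pearson correlation of per-stage activity
with per-stage expression, with a weaker-correlation fallback and an
all-miRNAs-in-window rule; TF-defined SEs use nearest-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression import ExpressionMatrix
from .enhancers import EnhancerUniverse
from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    merge_with_constituents,
    quantify_rpkm,
)


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: list[GenomicInterval]
    stages: list[str]
    rpkm: np.ndarray  # per-stage RPKM over the merged span
    focal_stage: str

    @property
    def signal(self) -> float:
        return float(self.rpkm[self.stages.index(self.focal_stage)])

    @property
    def span(self) -> int:
        return len(self.interval)

    @property
    def se_id(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass
class SuperEnhancerCall:
    stitched: StitchedEnhancer
    is_se: bool
    rank: int  # ascending-signal rank (0 = weakest)
    rank_scaled: float  # rank rescaled to [0, 1]
    signal_scaled: float  # focal signal rescaled to [0, 1]
    stage: str


@dataclass
class SETargetAssignment:
    se_id: str
    target_id: str
    correlation: float
    mode: str  # corr_primary | corr_fallback | nearest_gene | mirna_window
    distance: int
    tie: bool = False


def stitch_active_enhancers(
    u: EnhancerUniverse,
    stage: str,
    reads_per_stage: Mapping[str, IntervalSet],
    library_sizes: Mapping[str, float] | None = None,
    gap: int = 12500,
    min_span: int = 12500,
) -> list[StitchedEnhancer]:
    """Stitch enhancers active at ``stage`` (z > 0) within ``gap`` bases and
    keep merged spans strictly longer than ``min_span``; per-stage RPKM is
    recomputed over each merged span (gaps included).
    """
    if u.zscore is None:
        raise ValueError("universe must be z-scored before stitching")
    zcol = u.zscore.stage_column(stage)
    active = IntervalSet(
        iv for iv, z in zip(u.zscore.regions, zcol) if z > 0
    )
    if len(active) == 0:
        return []
    merged = merge_with_constituents(active, gap)
    kept = [(span, cons) for span, cons in merged if len(span) > min_span]
    if not kept:
        return []
    spans = [span for span, _ in kept]
    sm = quantify_rpkm(spans, reads_per_stage, library_sizes=library_sizes)
    return [
        StitchedEnhancer(
            interval=span,
            constituents=cons,
            stages=list(sm.stages),
            rpkm=sm.values[i].copy(),
            focal_stage=stage,
        )
        for i, (span, cons) in enumerate(kept)
    ]


def rank_and_cut(
    candidates: Sequence[StitchedEnhancer], slope_threshold: float = 0.5
) -> list[SuperEnhancerCall]:
    """Rank candidates by focal-stage signal and call the high-signal suffix.

    Both axes of the rank-vs-signal curve are rescaled to [0, 1]. Scanning
    from the low-signal end, the cut is the first point whose forward
    discrete slope exceeds ``slope_threshold`` while the mean slope of the
    remaining curve also exceeds it (so the crossing is the entry into the
    high-signal regime, not a local wiggle). Every candidate strictly above
    the cut point is a super-enhancer; the SE set is always a suffix of the
    ranked list.
    """
    n = len(candidates)
    if n < 2:
        import warnings

        warnings.warn(
            "fewer than 2 stitched candidates: no ranked curve, nothing called",
            stacklevel=2,
        )
    order = sorted(range(n), key=lambda i: (candidates[i].signal, i))
    signals = np.array([candidates[i].signal for i in order], dtype=float)
    if n < 2 or signals[-1] == signals[0]:
        # no curve to cut: flat or singleton input -> nothing called
        x = np.linspace(0, 1, n) if n > 1 else np.zeros(n)
        return [
            SuperEnhancerCall(
                candidates[i], False, rank=r, rank_scaled=float(x[r]),
                signal_scaled=0.0, stage=candidates[i].focal_stage,
            )
            for r, i in enumerate(order)
        ]
    x = np.linspace(0.0, 1.0, n)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    cut: int | None = None
    for i in range(n - 1):
        fwd = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        trailing = (y[-1] - y[i]) / (x[-1] - x[i]) if x[i] < 1 else fwd
        if fwd > slope_threshold and trailing > slope_threshold:
            cut = i
            break
    calls = []
    for r, i in enumerate(order):
        calls.append(
            SuperEnhancerCall(
                candidates[i],
                is_se=(cut is not None and r > cut),
                rank=r,
                rank_scaled=float(x[r]),
                signal_scaled=float(y[r]),
                stage=candidates[i].focal_stage,
            )
        )
    return calls


def late_specific_ses(
    d7_ses: Sequence[SuperEnhancerCall],
    early_ses: Mapping[str, Sequence[SuperEnhancerCall]],
) -> list[SuperEnhancerCall]:
    """d7 SEs with zero overlap (>= 1 base) with any early-stage SE span."""
    early = IntervalSet(
        c.stitched.interval
        for calls in early_ses.values()
        for c in calls
        if c.is_se
    )
    return [
        c
        for c in d7_ses
        if c.is_se and not early.overlaps_any(c.stitched.interval)
    ]


def assign_se_targets(
    ses: Sequence[SuperEnhancerCall],
    expr: ExpressionMatrix,
    genes: Sequence[GeneModel],
    window: int = 100_000,
    r_primary: float = 0.75,
    r_fallback: float = 0.5,
    expr_min: float = 1.0,
    mirnas: Sequence[GeneModel] | None = None,
) -> list[SETargetAssignment]:
    """Correlation-based SE -> gene assignment.

    Candidate genes are expressed (FPKM > expr_min at any stage) with their
    TSS within ``window`` bases of the SE span (distance 0 inside). Per SE,
    every candidate with Pearson r > r_primary over the shared stage grid is
    assigned; if none qualifies, the single best candidate with r >
    r_fallback is. miRNA models inside the window are all assigned
    unconditionally. Constant profiles have undefined r and are never
    assigned by correlation.
    """
    out: list[SETargetAssignment] = []
    expressed = expr.data.index[(expr.data.values > expr_min).any(axis=1)]
    expr_sub = expr.data.loc[expressed]
    gene_by_id = {g.gene_id: g for g in genes}
    for call in ses:
        if not call.is_se:
            continue
        st = call.stitched
        if st.stages != expr.stages:
            raise ValueError(
                f"stage grid mismatch: SE {st.stages} vs expression {expr.stages}"
            )
        se_iv = st.interval
        se_vec = st.rpkm
        cands: list[tuple[str, float, int]] = []  # (gene, r, distance)
        for gid in expr_sub.index:
            g = gene_by_id.get(gid)
            if g is None or g.chrom != se_iv.chrom:
                continue
            d = se_iv.distance_to_point(g.tss)
            if d > window:
                continue
            gvec = expr_sub.loc[gid].values.astype(float)
            if np.ptp(gvec) == 0 or np.ptp(se_vec) == 0:
                continue
            r = float(np.corrcoef(gvec, se_vec)[0, 1])
            cands.append((gid, r, d))
        primary = [c for c in cands if c[1] > r_primary]
        if primary:
            for gid, r, d in primary:
                out.append(SETargetAssignment(st.se_id, gid, r, "corr_primary", d))
        else:
            fallback = [c for c in cands if c[1] > r_fallback]
            if fallback:
                gid, r, d = max(fallback, key=lambda c: c[1])
                out.append(SETargetAssignment(st.se_id, gid, r, "corr_fallback", d))
        if mirnas:
            for m in mirnas:
                if m.chrom == se_iv.chrom and se_iv.distance_to_point(m.tss) <= window:
                    out.append(
                        SETargetAssignment(
                            st.se_id,
                            m.gene_id,
                            float("nan"),
                            "mirna_window",
                            se_iv.distance_to_point(m.tss),
                        )
                    )
    return out


def assign_nearest_gene(
    ses: Sequence[SuperEnhancerCall], genes: Sequence[GeneModel]
) -> list[SETargetAssignment]:
    """Nearest-TSS gene per SE (distance 0 when the TSS lies inside the span);
    exact ties are all reported, flagged."""
    out: list[SETargetAssignment] = []
    for call in ses:
        if not call.is_se:
            continue
        iv = call.stitched.interval
        dists = [
            (iv.distance_to_point(g.tss), g.gene_id)
            for g in genes
            if g.chrom == iv.chrom
        ]
        if not dists:
            continue
        dmin = min(d for d, _ in dists)
        winners = sorted(gid for d, gid in dists if d == dmin)
        for gid in winners:
            out.append(
                SETargetAssignment(
                    call.stitched.se_id,
                    gid,
                    float("nan"),
                    "nearest_gene",
                    dmin,
                    tie=len(winners) > 1,
                )
            )
    return out
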