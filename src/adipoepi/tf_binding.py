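"""TF peak annotation, group-wise binding enrichment, and TSS distances.

Peaks from a TF ChIP experiment (SIX1-style) are classified by midpoint into
genome elements with a fixed priority, summed binding signal is compared
across d7 expression groups over their regulatory neighborhoods, and each
gene's distance to its closest peak is measured from the annotated TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval, IntervalSet

ELEMENT_PRIORITY = ("promoter", "exon", "intron", "tts", "intergenic")


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    element: str
    host_gene: str | None = None


@dataclass
class GroupEnrichment:
    group: str
    n_genes: int
    peak_count: int
    summed_rpkm: float
    empty: bool = False


def annotate_peaks(
    peaks: IntervalSet, genes: Sequence[GeneModel], promoter_pad: int = 2500
) -> list[PeakAnnotation]:
    """Classify each peak by its midpoint with priority
    promoter (TSS +/- pad) > exon > intron > TTS-proximal (+/- pad) > intergenic.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for peak in peaks:
        mid = peak.midpoint
        element, host = "intergenic", None
        best = len(ELEMENT_PRIORITY) - 1
        for g in by_chrom.get(peak.chrom, ()):
            if abs(mid - g.tss) <= promoter_pad:
                cls = 0
            elif any(s <= mid < e for s, e in zip(g.exon_starts, g.exon_ends)):
                cls = 1
            elif g.tx_start <= mid < g.tx_end:
                cls = 2
            elif abs(mid - g.tts) <= promoter_pad:
                cls = 3
            else:
                continue
            if cls < best:
                best, element, host = cls, ELEMENT_PRIORITY[cls], g.gene_id
        out.append(PeakAnnotation(peak, element, host))
    return out


def element_fractions(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks per element class; sums to 1 over any peak set."""
    n = len(annotations)
    fractions = {e: 0.0 for e in ELEMENT_PRIORITY}
    for a in annotations:
        fractions[a.element] += 1.0
    if n:
        for e in fractions:
            fractions[e] /= n
    return fractions


def regulatory_regions_for_groups(
    h3k27ac: IntervalSet,
    groups: Mapping[str, Sequence[str]],
    models: Sequence[GeneModel],
    window: int = 100_000,
) -> dict[str, IntervalSet]:
    """Per group, the H3K27ac peaks whose nearest edge lies within ``window``
    of any group-member TSS — the unbiased regulatory neighborhoods used for
    binding-enrichment comparison."""
    tss_by_id = {m.gene_id: (m.chrom, m.tss) for m in models}
    out: dict[str, IntervalSet] = {}
    for group, gene_ids in groups.items():
        tss_list = [tss_by_id[g] for g in gene_ids if g in tss_by_id]
        members = [
            iv
            for iv in h3k27ac
            if any(
                iv.chrom == c and iv.distance_to_point(t) <= window
                for c, t in tss_list
            )
        ]
        out[group] = IntervalSet(members)
    return out


def group_enrichment(
    peaks: IntervalSet,
    peak_rpkm: Mapping[tuple[str, int, int], float] | None,
    regulatory_regions: Mapping[str, IntervalSet],
    groups: Mapping[str, Sequence[str]],
) -> list[GroupEnrichment]:
    """Per group: count of TF peaks overlapping the group's regulatory
    regions and the summed RPKM of those peaks. ``peak_rpkm`` maps
    (chrom, start, end) to signal; when None, each peak's ``score`` field is
    used. Empty groups yield a zero row, flagged."""
    out = []
    for group, regions in regulatory_regions.items():
        n_genes = len(groups.get(group, ()))
        if n_genes == 0 or len(regions) == 0:
            out.append(GroupEnrichment(group, n_genes, 0, 0.0, empty=True))
            continue
        count, total = 0, 0.0
        for p in peaks:
            if regions.overlaps_any(p):
                count += 1
                total += (
                    peak_rpkm[(p.chrom, p.start, p.end)]
                    if peak_rpkm is not None
                    else p.score
                )
        out.append(GroupEnrichment(group, n_genes, count, total))
    return out


def nearest_peak_distance(
    gene_ids: Sequence[str], peaks: IntervalSet, models: Sequence[GeneModel]
) -> dict[str, int]:
    """Per gene, distance from the annotated TSS to the closest peak
    (0 when the TSS lies inside a peak)."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    model_by_id = {m.gene_id: m for m in models}
    out: dict[str, int] = {}
    for gid in gene_ids:
        m = model_by_id[gid]
        chrom_peaks = peaks.on_chrom(m.chrom)
        if not chrom_peaks:
            continue
        out[gid] = min(p.distance_to_point(m.tss) for p in chrom_peaks)
    return out
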