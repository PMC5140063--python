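"""Synthetic fixture generator with planted, recorded ground truth.

Emulates the statistical structure the comparative adipogenesis analysis
assumes — multi-stage lognormal expression with planted stage-specific,
lineage-specific, shared and transiently induced genes; H3K27ac/H3K4me3
peak sets with planted stage-specific enhancers, clustered super-enhancer
loci whose signal co-varies with planted target genes, and weak decoy
clusters; and TF peaks distributed over annotated genome elements — so that
every pipeline stage is testable without any external download.

The genome layout is deterministic given the config: each chromosome opens
with super-enhancer blocks (target gene + constituent cluster + decoy
genes), then weak-cluster blocks, then regularly spaced gene slots, a subset
of which carry a distal enhancer zone placed clear of every TSS +/- 2.5 kb
window. Randomness (group membership, slot assignment, noise, read
sampling) comes from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .intervals import GeneModel, GenomicInterval, IntervalSet

# fixed layout geometry (bases)
SLOT = 10_000
GENE_LEN = 6_000
EXONS_REL = ((0, 500), (2800, 3300), (5500, 6000))
SE_BLOCK = 200_000
WEAK_BLOCK = 100_000
SE_TARGET_OFFSET = 5_000
SE_DECOY_OFFSETS = (80_000, 110_000, 140_000)
SE_CLUSTER_OFFSET = 40_000
WEAK_CLUSTER_OFFSET = 40_000
ENH_ZONE_PLUS = 6_200  # distal enhancer offset within a + slot
ENH_ZONE_MINUS = 8_700  # within a - slot (clear of the TSS at slot+6000)
PROMOTER_PEAK_PAD = 1_000
GROUP_SLOT_STRIDE = 21  # lineage-group genes sit >= 210 kb apart


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixture. Defaults are the planted
    structure the pipeline is validated against: 2,000 coding genes with 40
    stage-specific genes per stage, 20 super-enhancer loci with co-varying
    targets, a 20x planted effect and lognormal noise of 0.2 on the log2
    scale."""

    seed: int = 1
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_200_000, "chr2": 12_200_000}
    )
    n_genes: int = 2000
    n_lncrnas: int = 300
    n_mirnas: int = 150
    stages_ba: tuple[str, ...] = ("d-3", "d0", "6h", "d2", "d7")
    stages_wa: tuple[str, ...] = ("d-4", "d0", "6h", "d2", "d7")
    # planted expression groups
    n_stage_specific_per_stage: int = 40
    n_ba_specific: int = 30
    n_wa_specific: int = 30
    n_common: int = 30
    n_bmp7_transient: int = 20
    n_lnc_stage_specific_per_stage: int = 10
    n_lnc_ba_specific: int = 15
    n_lnc_wa_specific: int = 15
    n_mirna_stage_specific_per_stage: int = 5
    # expression model
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.0
    lnc_baseline_log2_mean: float = 1.0
    lnc_baseline_log2_sd: float = 1.0
    mirna_baseline_log2_mean: float = 7.0
    mirna_baseline_log2_sd: float = 1.0
    effect: float = 20.0
    mirna_effect: float = 4.0
    noise_sd: float = 0.2  # lognormal sd on the log2 scale
    off_stage_max: float = 1.0  # off-stage FPKM drawn uniform [0, this)
    lnc_off_stage_max: float = 0.25
    # epigenome
    n_stage_enhancers_per_stage: int = 80
    n_constitutive_enhancers: int = 200
    n_se: int = 20
    se_constituents: int = 5
    se_spacing: int = 3500  # start-to-start; leaves 2.5 kb gaps
    n_weak_se: int = 8
    weak_se_constituents: int = 4
    weak_se_spacing: int = 4000
    enhancer_width: int = 1000
    reads_per_stage: int = 150_000
    read_length: int = 36
    background_read_fraction: float = 0.2
    enhancer_on_weight: float = 20.0
    enhancer_off_weight: float = 1.0
    constitutive_weight: float = 5.0
    weak_se_on_weight: float = 9.0
    promoter_active_weight: float = 5.0
    promoter_inactive_weight: float = 0.5
    active_fpkm: float = 5.0
    # TF peaks
    n_tf_peaks: int = 2000
    tf_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.35,
            "intron": 0.25,
            "exon": 0.05,
            "intergenic": 0.35,
        }
    )
    tf_enrichment: float = 4.0
    tf_peak_width: int = 400
    tf_base_count: float = 30.0
    # promoter-state fixture (count matrices per promoter window)
    promoter_mark_high: float = 200.0
    promoter_mark_base: float = 30.0
    k27me3_early: float = 150.0
    k27me3_late: float = 15.0
    n_promoter_background: int = 400

    def validate(self) -> None:
        planted = (
            5 * self.n_stage_specific_per_stage
            + self.n_ba_specific
            + self.n_wa_specific
            + self.n_common
            + self.n_bmp7_transient
            + self.n_se  # SE targets
            + self.n_se * len(SE_DECOY_OFFSETS)  # decoys
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene groups ({planted}) exceed n_genes ({self.n_genes})"
            )
        lnc_planted = (
            5 * self.n_lnc_stage_specific_per_stage
            + self.n_lnc_ba_specific
            + self.n_lnc_wa_specific
        )
        if lnc_planted > self.n_lncrnas:
            raise ValueError("planted lncRNA groups exceed n_lncrnas")
        if 5 * self.n_mirna_stage_specific_per_stage > self.n_mirnas:
            raise ValueError("planted miRNA groups exceed n_mirnas")
        if self.se_spacing - self.enhancer_width >= 12_500:
            raise ValueError("SE constituent gaps must stay below the stitch gap")
        if abs(sum(self.tf_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("tf_proportions must sum to 1")
        if len(self.stages_ba) != len(self.stages_wa):
            raise ValueError("lineages must share a stage-grid length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted structure, serializable alongside the fixture."""

    seed: int
    stages: dict[str, list[str]]
    stage_specific_coding: dict[str, dict[str, list[str]]]
    lineage_coding: dict[str, str]
    planted_common: list[str]
    bmp7_transient: list[str]
    se_targets: dict[str, str]
    decoy_genes: list[str]
    stage_specific_lncrna: dict[str, dict[str, list[str]]]
    lineage_lncrna: dict[str, str]
    stage_specific_mirna: dict[str, dict[str, list[str]]]
    se_loci: dict[str, dict] = field(default_factory=dict)
    weak_se_loci: dict[str, dict] = field(default_factory=dict)
    stage_specific_enhancers: dict[str, dict[str, list[list]]] = field(
        default_factory=dict
    )
    tf_peak_classes: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ExpressionSim:
    coding: dict[str, ExpressionMatrix]
    lncrna: dict[str, ExpressionMatrix]
    mirna: dict[str, ExpressionMatrix]
    truth: GroundTruth


@dataclass
class EpigenomeSim:
    genes: list[GeneModel]
    h3k27ac_peaks: dict[str, dict[str, IntervalSet]]
    h3k4me3_peaks: dict[str, dict[str, IntervalSet]]
    reads: dict[str, dict[str, dict[str, IntervalSet]]]  # lineage->mark->stage


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class _Layout:
    se_blocks: list[tuple[str, int]]
    weak_blocks: list[tuple[str, int]]
    slots: list[tuple[str, int, str]]  # (chrom, slot start, strand)

    def slot_gene(self, idx: int, gene_id: str) -> GeneModel:
        chrom, s, strand = self.slots[idx]
        return _make_gene(gene_id, chrom, s, strand)


def _make_gene(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        name=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=start + GENE_LEN,
        exon_starts=tuple(start + a for a, _ in EXONS_REL),
        exon_ends=tuple(start + b for _, b in EXONS_REL),
    )


def genome_layout(cfg: SimConfig) -> _Layout:
    chroms = sorted(cfg.chrom_lengths)
    n_chrom = len(chroms)
    se_per_chrom = [cfg.n_se // n_chrom + (1 if i < cfg.n_se % n_chrom else 0)
                    for i in range(n_chrom)]
    weak_per_chrom = [cfg.n_weak_se // n_chrom + (1 if i < cfg.n_weak_se % n_chrom else 0)
                      for i in range(n_chrom)]
    se_blocks, weak_blocks, slots = [], [], []
    for ci, chrom in enumerate(chroms):
        strand = "+" if ci % 2 == 0 else "-"
        pos = 0
        for _ in range(se_per_chrom[ci]):
            se_blocks.append((chrom, pos))
            pos += SE_BLOCK
        for _ in range(weak_per_chrom[ci]):
            weak_blocks.append((chrom, pos))
            pos += WEAK_BLOCK
        length = cfg.chrom_lengths[chrom]
        while pos + SLOT <= length:
            slots.append((chrom, pos, strand))
            pos += SLOT
    return _Layout(se_blocks, weak_blocks, slots)


# ---------------------------------------------------------------------------
# expression


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return 2.0 ** (sd * rng.standard_normal(shape))


def simulate_expression(cfg: SimConfig) -> ExpressionSim:
    """Per-lineage coding/lncRNA/miRNA matrices with planted ground truth.

    Background features are stage-independent lognormal; planted
    stage-specific features are elevated (baseline x effect) in exactly one
    stage and near-zero (uniform) elsewhere; lineage-specific features are
    elevated at d7 of one lineage only; shared and super-enhancer-target
    genes are elevated at d7 in both; transiently induced genes are elevated
    at d0 of the brown lineage only. Everything carries multiplicative
    lognormal noise.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    n_stages = len(cfg.stages_ba)
    d7, d0 = n_stages - 1, 1

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    order = list(rng.permutation(cfg.n_genes))

    def take(k: int) -> list[str]:
        return [gene_ids[order.pop()] for _ in range(k)]

    se_targets = take(cfg.n_se)
    decoys = take(cfg.n_se * len(SE_DECOY_OFFSETS))
    stage_sets = [take(cfg.n_stage_specific_per_stage) for _ in range(n_stages)]
    ba_ids = take(cfg.n_ba_specific)
    wa_ids = take(cfg.n_wa_specific)
    common_ids = take(cfg.n_common)
    bmp7_ids = take(cfg.n_bmp7_transient)

    idx = {g: i for i, g in enumerate(gene_ids)}
    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    def build(lineage: str) -> np.ndarray:
        mean = np.tile(base[:, None], (1, n_stages))
        for j, ids in enumerate(stage_sets):
            rows = [idx[g] for g in ids]
            mean[rows] = rng.uniform(0, cfg.off_stage_max, (len(rows), n_stages))
            mean[rows, j] = base[rows] * cfg.effect
        for ids, on in ((ba_ids, lineage == "BA"), (wa_ids, lineage == "WA")):
            rows = [idx[g] for g in ids]
            mean[rows] = rng.uniform(0, cfg.off_stage_max, (len(rows), n_stages))
            if on:
                mean[rows, d7] = base[rows] * cfg.effect
        for ids in (common_ids, se_targets):
            rows = [idx[g] for g in ids]
            mean[rows] = rng.uniform(0, cfg.off_stage_max, (len(rows), n_stages))
            mean[rows, d7] = base[rows] * cfg.effect
        rows = [idx[g] for g in bmp7_ids]
        if lineage == "BA":
            mean[rows] = rng.uniform(0, cfg.off_stage_max, (len(rows), n_stages))
            mean[rows, d0] = base[rows] * cfg.effect
        return mean * _noise(rng, mean.shape, cfg.noise_sd)

    stages = {"BA": list(cfg.stages_ba), "WA": list(cfg.stages_wa)}
    coding = {
        lin: ExpressionMatrix(
            pd.DataFrame(build(lin), index=gene_ids, columns=stages[lin]),
            feature_class="coding",
            lineage=lin,
        )
        for lin in ("BA", "WA")
    }

    # lncRNAs
    lnc_ids = [f"lnc{i:04d}" for i in range(cfg.n_lncrnas)]
    lnc_order = list(rng.permutation(cfg.n_lncrnas))

    def ltake(k: int) -> list[str]:
        return [lnc_ids[lnc_order.pop()] for _ in range(k)]

    lnc_stage_sets = [
        ltake(cfg.n_lnc_stage_specific_per_stage) for _ in range(n_stages)
    ]
    lnc_ba = ltake(cfg.n_lnc_ba_specific)
    lnc_wa = ltake(cfg.n_lnc_wa_specific)
    lnc_idx = {g: i for i, g in enumerate(lnc_ids)}
    lnc_base = 2.0 ** rng.normal(
        cfg.lnc_baseline_log2_mean, cfg.lnc_baseline_log2_sd, cfg.n_lncrnas
    )

    def build_lnc(lineage: str) -> np.ndarray:
        mean = np.tile(lnc_base[:, None], (1, n_stages))
        for j, ids in enumerate(lnc_stage_sets):
            rows = [lnc_idx[g] for g in ids]
            mean[rows] = rng.uniform(0, cfg.lnc_off_stage_max, (len(rows), n_stages))
            mean[rows, j] = lnc_base[rows] * cfg.effect
        for ids, on in ((lnc_ba, lineage == "BA"), (lnc_wa, lineage == "WA")):
            rows = [lnc_idx[g] for g in ids]
            mean[rows] = rng.uniform(0, cfg.lnc_off_stage_max, (len(rows), n_stages))
            if on:
                mean[rows, d7] = lnc_base[rows] * cfg.effect
        return mean * _noise(rng, mean.shape, cfg.noise_sd)

    lncrna = {
        lin: ExpressionMatrix(
            pd.DataFrame(build_lnc(lin), index=lnc_ids, columns=stages[lin]),
            feature_class="lncRNA",
            lineage=lin,
        )
        for lin in ("BA", "WA")
    }

    # miRNAs (array signal; planted = elevated at one stage)
    mir_ids = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]
    mir_order = list(rng.permutation(cfg.n_mirnas))
    mir_stage_sets = [
        [mir_ids[mir_order.pop()] for _ in range(cfg.n_mirna_stage_specific_per_stage)]
        for _ in range(n_stages)
    ]
    mir_idx = {g: i for i, g in enumerate(mir_ids)}
    mir_base = 2.0 ** rng.normal(
        cfg.mirna_baseline_log2_mean, cfg.mirna_baseline_log2_sd, cfg.n_mirnas
    )

    def build_mir(lineage: str) -> np.ndarray:
        mean = np.tile(mir_base[:, None], (1, n_stages))
        for j, ids in enumerate(mir_stage_sets):
            rows = [mir_idx[g] for g in ids]
            mean[rows, j] = mir_base[rows] * cfg.mirna_effect
        return mean * _noise(rng, mean.shape, cfg.noise_sd)

    mirna = {
        lin: ExpressionMatrix(
            pd.DataFrame(build_mir(lin), index=mir_ids, columns=stages[lin]),
            feature_class="miRNA",
            unit="array_signal",
            lineage=lin,
        )
        for lin in ("BA", "WA")
    }

    lineage_coding = {g: "BA_specific" for g in ba_ids}
    lineage_coding.update({g: "WA_specific" for g in wa_ids})
    lineage_coding.update({g: "common" for g in common_ids})
    lineage_coding.update({g: "common" for g in se_targets})
    lineage_coding.update({g: "common" for g in stage_sets[d7]})

    def per_lineage_stage_map(sets, extra_ba_d0=()):
        out = {}
        for lin in ("BA", "WA"):
            labels = stages[lin]
            m: dict[str, list[str]] = {labels[j]: sorted(sets[j]) for j in range(n_stages)}
            # d7-elevated lineage & shared groups are d7 stage-specific too
            out[lin] = m
        return out

    ss_coding = per_lineage_stage_map(stage_sets)
    for lin in ("BA", "WA"):
        lab7 = stages[lin][d7]
        extra = list(common_ids) + list(se_targets)
        extra += list(ba_ids) if lin == "BA" else list(wa_ids)
        ss_coding[lin][lab7] = sorted(set(ss_coding[lin][lab7]) | set(extra))
    ss_coding["BA"][stages["BA"][d0]] = sorted(
        set(ss_coding["BA"][stages["BA"][d0]]) | set(bmp7_ids)
    )

    ss_lnc = {}
    for lin in ("BA", "WA"):
        labels = stages[lin]
        m = {labels[j]: sorted(lnc_stage_sets[j]) for j in range(n_stages)}
        extra = lnc_ba if lin == "BA" else lnc_wa
        m[labels[d7]] = sorted(set(m[labels[d7]]) | set(extra))
        ss_lnc[lin] = m
    lineage_lnc = {g: "BA_specific" for g in lnc_ba}
    lineage_lnc.update({g: "WA_specific" for g in lnc_wa})
    lineage_lnc.update({g: "common" for g in lnc_stage_sets[d7]})

    ss_mir = {
        lin: {stages[lin][j]: sorted(mir_stage_sets[j]) for j in range(n_stages)}
        for lin in ("BA", "WA")
    }

    truth = GroundTruth(
        seed=cfg.seed,
        stages=stages,
        stage_specific_coding=ss_coding,
        lineage_coding=lineage_coding,
        planted_common=sorted(common_ids),
        bmp7_transient=sorted(bmp7_ids),
        se_targets={f"SE{i:02d}": g for i, g in enumerate(se_targets)},
        decoy_genes=sorted(decoys),
        stage_specific_lncrna=ss_lnc,
        lineage_lncrna=lineage_lnc,
        stage_specific_mirna=ss_mir,
    )
    return ExpressionSim(coding=coding, lncrna=lncrna, mirna=mirna, truth=truth)


# ---------------------------------------------------------------------------
# epigenome


def _assign_gene_slots(
    cfg: SimConfig, truth: GroundTruth, layout: _Layout, rng: np.random.Generator
) -> dict[str, GeneModel]:
    """Map gene ids to genomic positions. Lineage-group genes go on a coarse
    grid (>= 210 kb apart) so their regulatory neighborhoods stay disjoint;
    SE targets and decoys live inside SE blocks; everything else fills the
    remaining slots in random order."""
    models: dict[str, GeneModel] = {}
    se_names = sorted(truth.se_targets)
    for k, name in enumerate(se_names):
        chrom, b = layout.se_blocks[k]
        strand = "+" if chrom == sorted(cfg.chrom_lengths)[0] else "-"
        models[truth.se_targets[name]] = _make_gene(
            truth.se_targets[name], chrom, b + SE_TARGET_OFFSET, strand
        )
    decoys = list(truth.decoy_genes)
    di = 0
    for k in range(len(se_names)):
        chrom, b = layout.se_blocks[k]
        strand = "+" if chrom == sorted(cfg.chrom_lengths)[0] else "-"
        for off in SE_DECOY_OFFSETS:
            if di < len(decoys):
                models[decoys[di]] = _make_gene(decoys[di], chrom, b + off, strand)
                di += 1
    group_ids = sorted(
        g for g, c in truth.lineage_coding.items()
        if c in ("BA_specific", "WA_specific")
    )
    # planted shared genes join the grid too (SE targets are placed above)
    group_ids += list(truth.planted_common)
    group_ids = list(rng.permutation(group_ids))
    grid = list(range(0, len(layout.slots), GROUP_SLOT_STRIDE))
    if len(grid) < len(group_ids):
        raise ValueError("genome too small for the group-gene grid")
    used = set()
    for g, slot in zip(group_ids, grid):
        models[g] = layout.slot_gene(slot, g)
        used.add(slot)
    remaining_ids = [g for g in (f"g{i:04d}" for i in range(cfg.n_genes))
                     if g not in models]
    free_slots = [i for i in range(len(layout.slots)) if i not in used]
    if len(free_slots) < len(remaining_ids):
        raise ValueError("not enough gene slots for n_genes")
    free_slots = list(rng.permutation(free_slots))
    for g, slot in zip(remaining_ids, free_slots):
        models[g] = layout.slot_gene(slot, g)
    return models


def simulate_epigenome(cfg: SimConfig, sim: ExpressionSim) -> EpigenomeSim:
    """Peak sets and read intervals per lineage/mark/stage, plus gene models.

    H3K27ac peaks sit at active promoters, planted distal enhancers,
    super-enhancer constituent clusters and weak decoy clusters; H3K4me3
    marks active promoters only. Reads are multinomial over the weighted
    source regions plus a uniform genomic background; planted stage-specific
    enhancers get ``effect``-fold more weight in their stage, and SE
    constituent weight follows the target gene's expression profile.
    H3K4me1 reads are co-placed with H3K27ac (independent sampling).
    """
    cfg.validate()
    truth = sim.truth
    rng = np.random.default_rng([cfg.seed, 1])
    layout = genome_layout(cfg)
    models = _assign_gene_slots(cfg, truth, layout, rng)
    genes = sorted(models.values(), key=lambda m: (m.chrom, m.tx_start))
    n_stages = len(cfg.stages_ba)
    d7 = n_stages - 1

    # --- planted enhancer regions -----------------------------------------
    n_slots = len(layout.slots)
    n_enh = cfg.n_stage_enhancers_per_stage * n_stages + cfg.n_constitutive_enhancers
    enh_slots = rng.choice(n_slots, size=n_enh, replace=False)

    def enhancer_interval(slot_idx: int) -> GenomicInterval:
        chrom, s, strand = layout.slots[slot_idx]
        off = ENH_ZONE_PLUS if strand == "+" else ENH_ZONE_MINUS
        return GenomicInterval(chrom, s + off, s + off + cfg.enhancer_width)

    stage_enh: list[tuple[GenomicInterval, int]] = []  # (interval, stage idx)
    pos = 0
    for j in range(n_stages):
        for _ in range(cfg.n_stage_enhancers_per_stage):
            stage_enh.append((enhancer_interval(int(enh_slots[pos])), j))
            pos += 1
    const_enh = [enhancer_interval(int(i)) for i in enh_slots[pos:]]

    se_names = sorted(truth.se_targets)
    se_constituents: dict[str, list[GenomicInterval]] = {}
    for k, name in enumerate(se_names):
        chrom, b = layout.se_blocks[k]
        start = b + SE_CLUSTER_OFFSET
        se_constituents[name] = [
            GenomicInterval(
                chrom, start + i * cfg.se_spacing,
                start + i * cfg.se_spacing + cfg.enhancer_width,
            )
            for i in range(cfg.se_constituents)
        ]
        span_start = se_constituents[name][0].start
        span_end = se_constituents[name][-1].end
        if span_end > b + SE_BLOCK:
            raise ValueError(f"SE cluster {name} does not fit in its block")
        truth.se_loci[name] = {
            "chrom": chrom, "start": span_start, "end": span_end,
            "target": truth.se_targets[name],
        }
    weak_constituents: list[list[GenomicInterval]] = []
    for k, (chrom, b) in enumerate(layout.weak_blocks):
        start = b + WEAK_CLUSTER_OFFSET
        cons = [
            GenomicInterval(
                chrom, start + i * cfg.weak_se_spacing,
                start + i * cfg.weak_se_spacing + cfg.enhancer_width,
            )
            for i in range(cfg.weak_se_constituents)
        ]
        weak_constituents.append(cons)
        truth.weak_se_loci[f"weakSE{k:02d}"] = {
            "chrom": chrom, "start": cons[0].start, "end": cons[-1].end,
        }

    # record planted stage-specific enhancers (SE constituents count at d7,
    # where their signal is concentrated by construction)
    for lin in ("BA", "WA"):
        labels = truth.stages[lin]
        m: dict[str, list[list]] = {lab: [] for lab in labels}
        for iv, j in stage_enh:
            m[labels[j]].append([iv.chrom, iv.start, iv.end])
        for name in se_names:
            for iv in se_constituents[name]:
                m[labels[d7]].append([iv.chrom, iv.start, iv.end])
        truth.stage_specific_enhancers[lin] = m

    # --- source regions and per-stage weights ------------------------------
    fpkm = {lin: sim.coding[lin].data for lin in ("BA", "WA")}
    promoters = [
        GenomicInterval(
            g.chrom, max(0, g.tss - PROMOTER_PEAK_PAD), g.tss + PROMOTER_PEAK_PAD,
            name=g.gene_id,
        )
        for g in genes
    ]
    sources = (
        [iv for iv, _ in stage_enh]
        + const_enh
        + [iv for name in se_names for iv in se_constituents[name]]
        + [iv for cons in weak_constituents for iv in cons]
        + promoters
    )
    src_starts = np.array([iv.start for iv in sources])
    src_widths = np.array([len(iv) for iv in sources])
    src_chroms = np.array([iv.chrom for iv in sources], dtype=object)

    def stage_weights(lineage: str, j: int) -> np.ndarray:
        w = []
        for iv, sj in stage_enh:
            w.append(cfg.enhancer_on_weight if sj == j else cfg.enhancer_off_weight)
        w += [cfg.constitutive_weight] * len(const_enh)
        for name in se_names:
            target = truth.se_targets[name]
            prof = fpkm[lineage].loc[target].values
            scale = prof[j] / prof.max() if prof.max() > 0 else 0.0
            w += [cfg.enhancer_off_weight + cfg.enhancer_on_weight * scale] * len(
                se_constituents[name]
            )
        for cons in weak_constituents:
            w += [
                cfg.weak_se_on_weight if j == d7 else cfg.enhancer_off_weight
            ] * len(cons)
        active = fpkm[lineage].iloc[:, j] > cfg.active_fpkm
        act = {g: a for g, a in zip(fpkm[lineage].index, active)}
        w += [
            cfg.promoter_active_weight if act[p.name] else cfg.promoter_inactive_weight
            for p in promoters
        ]
        return np.asarray(w, dtype=float)

    chrom_names = sorted(cfg.chrom_lengths)
    chrom_len = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)

    def sample_reads(weights: np.ndarray) -> IntervalSet:
        p_src = weights / weights.sum() * (1 - cfg.background_read_fraction)
        p = np.append(p_src, cfg.background_read_fraction)
        counts = rng.multinomial(cfg.reads_per_stage, p)
        rep = np.repeat(np.arange(len(sources)), counts[:-1])
        span = np.maximum(src_widths[rep] - cfg.read_length, 1)
        starts = src_starts[rep] + rng.integers(0, span)
        chroms = src_chroms[rep]
        # uniform background
        n_bg = counts[-1]
        bg_ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_len / chrom_len.sum())
        bg_starts = rng.integers(
            0, (chrom_len[bg_ci] - cfg.read_length).astype(np.int64)
        )
        all_chroms = np.concatenate([chroms, np.array(chrom_names, dtype=object)[bg_ci]])
        all_starts = np.concatenate([starts, bg_starts]).astype(np.int64)
        strands = rng.choice(np.array(["+", "-"], dtype=object), size=len(all_starts))
        per_chrom = {}
        for ci, c in enumerate(chrom_names):
            mask = all_chroms == c
            per_chrom[c] = (
                all_starts[mask],
                all_starts[mask] + cfg.read_length,
                None,
                None,
                strands[mask],
            )
        return IntervalSet.from_arrays(per_chrom)

    reads: dict[str, dict[str, dict[str, IntervalSet]]] = {}
    h3k27ac_peaks: dict[str, dict[str, IntervalSet]] = {}
    h3k4me3_peaks: dict[str, dict[str, IntervalSet]] = {}
    for lin in ("BA", "WA"):
        labels = truth.stages[lin]
        reads[lin] = {"H3K27ac": {}, "H3K4me1": {}}
        h3k27ac_peaks[lin] = {}
        h3k4me3_peaks[lin] = {}
        for j, lab in enumerate(labels):
            w = stage_weights(lin, j)
            reads[lin]["H3K27ac"][lab] = sample_reads(w)
            reads[lin]["H3K4me1"][lab] = sample_reads(w)
            active = fpkm[lin].iloc[:, j] > cfg.active_fpkm
            act = {g: a for g, a in zip(fpkm[lin].index, active)}
            active_prom = [p for p in promoters if act[p.name]]
            distal = [iv for iv, sj in stage_enh if sj == j] + const_enh
            distal += [iv for name in se_names for iv in se_constituents[name]]
            distal += [iv for cons in weak_constituents for iv in cons]
            h3k27ac_peaks[lin][lab] = IntervalSet(active_prom + distal)
            h3k4me3_peaks[lin][lab] = IntervalSet(active_prom)
    return EpigenomeSim(
        genes=genes,
        h3k27ac_peaks=h3k27ac_peaks,
        h3k4me3_peaks=h3k4me3_peaks,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# TF peaks


def simulate_tf_peaks(
    cfg: SimConfig, genes: Sequence[GeneModel], truth: GroundTruth
) -> IntervalSet:
    """TF peaks distributed over genome elements with configured proportions.

    Promoter-class peaks are placed at the TSSs of planted lineage-group
    genes, with brown-specific and shared genes weighted ``tf_enrichment``-
    fold over white-specific genes; intron/exon peaks go to random gene
    bodies at offsets that classify unambiguously; intergenic peaks go to
    the empty block tails. Each peak's score carries its simulated signal
    (RPKM at a nominal 1M-read library).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    if cfg.n_tf_peaks == 0:
        return IntervalSet()
    # largest-remainder apportionment of peak counts by class
    classes = sorted(cfg.tf_proportions)
    raw = {c: cfg.tf_proportions[c] * cfg.n_tf_peaks for c in classes}
    counts = {c: int(raw[c]) for c in classes}
    rem = cfg.n_tf_peaks - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1

    model_by_id = {g.gene_id: g for g in genes}
    ba = [g for g, c in sorted(truth.lineage_coding.items()) if c == "BA_specific"]
    wa = [g for g, c in sorted(truth.lineage_coding.items()) if c == "WA_specific"]
    common = list(truth.planted_common)
    hosts = ba + common + wa
    host_w = np.array(
        [cfg.tf_enrichment] * (len(ba) + len(common)) + [1.0] * len(wa)
    )
    layout_blocks = [
        (v["chrom"], v["start"] - SE_CLUSTER_OFFSET, SE_BLOCK)
        for v in truth.se_loci.values()
    ] + [
        (v["chrom"], v["start"] - WEAK_CLUSTER_OFFSET, WEAK_BLOCK)
        for v in truth.weak_se_loci.values()
    ]
    half = cfg.tf_peak_width // 2
    peaks: list[GenomicInterval] = []

    def add_peak(chrom: str, mid: int, cls: str) -> None:
        count = rng.poisson(cfg.tf_base_count)
        rpkm = count / (cfg.tf_peak_width / 1000.0) / 1.0  # 1M-read library
        peaks.append(
            GenomicInterval(
                chrom, mid - half, mid + half, name=cls, score=float(rpkm)
            )
        )

    for _ in range(counts.get("promoter", 0)):
        g = model_by_id[hosts[rng.choice(len(hosts), p=host_w / host_w.sum())]]
        add_peak(g.chrom, g.tss + int(rng.integers(-300, 301)), "promoter")
    body_hosts = sorted(model_by_id)
    for _ in range(counts.get("intron", 0)):
        g = model_by_id[body_hosts[rng.integers(len(body_hosts))]]
        add_peak(g.chrom, g.tx_start + int(rng.integers(2550, 2750)), "intron")
    for _ in range(counts.get("exon", 0)):
        g = model_by_id[body_hosts[rng.integers(len(body_hosts))]]
        add_peak(g.chrom, g.tx_start + int(rng.integers(2850, 3250)), "exon")
    for _ in range(counts.get("intergenic", 0)):
        chrom, bstart, bsize = layout_blocks[rng.integers(len(layout_blocks))]
        lo = bstart + bsize - 30_000
        add_peak(chrom, int(rng.integers(lo, bstart + bsize - 5_000)), "intergenic")
    truth.tf_peak_classes = dict(counts)
    return IntervalSet(peaks)


# ---------------------------------------------------------------------------
# promoter-state count matrices (H3K4me1 / H3K27me3 configuration)


def simulate_promoter_mark_counts(
    cfg: SimConfig, truth: GroundTruth, genes: Sequence[GeneModel]
) -> dict[str, dict[str, "pd.DataFrame"]]:
    """Per-promoter read-count matrices emulating the planted chromatin
    configuration: H3K4me1 elevated at brown-specific promoters in the brown
    lineage only; H3K27me3 high early and lost by d7 in both lineages
    equally. Returns mark -> lineage -> (gene x stage) count DataFrame;
    stage columns are the first and last stages of each lineage's grid.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    ba = sorted(g for g, c in truth.lineage_coding.items() if c == "BA_specific")
    wa = sorted(g for g, c in truth.lineage_coding.items() if c == "WA_specific")
    common = sorted(g for g, c in truth.lineage_coding.items() if c == "common")
    group = set(ba) | set(wa) | set(common)
    model_ids = sorted(g.gene_id for g in genes)
    background = [g for g in model_ids if g not in group][: cfg.n_promoter_background]
    rows = ba + wa + common + background
    out: dict[str, dict[str, pd.DataFrame]] = {"H3K4me1": {}, "H3K27me3": {}}
    for lin in ("BA", "WA"):
        stages = [truth.stages[lin][0], truth.stages[lin][-1]]
        me1 = rng.poisson(cfg.promoter_mark_base, size=(len(rows), 2)).astype(float)
        if lin == "BA":
            me1[: len(ba)] = rng.poisson(cfg.promoter_mark_high, size=(len(ba), 2))
        k27 = np.empty((len(rows), 2))
        k27[:, 0] = rng.poisson(cfg.promoter_mark_base, size=len(rows))
        k27[:, 1] = rng.poisson(cfg.promoter_mark_base, size=len(rows))
        n_group = len(ba) + len(wa) + len(common)
        k27[:n_group, 0] = rng.poisson(cfg.k27me3_early, size=n_group)
        k27[:n_group, 1] = rng.poisson(cfg.k27me3_late, size=n_group)
        out["H3K4me1"][lin] = pd.DataFrame(me1, index=rows, columns=stages)
        out["H3K27me3"][lin] = pd.DataFrame(k27, index=rows, columns=stages)
    return out
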