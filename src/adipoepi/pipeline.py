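"""End-to-end orchestration: fixture I/O, the full comparative analysis,
and planted-truth recovery reporting.

The pipeline runs stage-specificity scoring, d7 lineage classification,
enhancer-universe construction and stage-specific enhancer calling,
super-enhancer stitching/ranking/target assignment, TF peak annotation and
enrichment, and the promoter chromatin-state comparison, reading a fixture
directory and writing TSV/BED outputs plus a manifest. Identical inputs and
config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionMatrix
from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    extend_reads_coverage,
    merge_within_gap,
    quantify_rpkm,
    read_bed,
    read_refflat,
    write_bed,
    write_refflat,
    zscore_normalize,
)
from . import enhancers as enh
from . import lineage as lin_mod
from . import stage_specificity as ss
from . import superenhancers as se_mod
from . import tf_binding as tf_mod
from .simulate import (
    EpigenomeSim,
    ExpressionSim,
    GroundTruth,
    SE_DECOY_OFFSETS,
    SimConfig,
    simulate_epigenome,
    simulate_expression,
    simulate_promoter_mark_counts,
    simulate_tf_peaks,
)

LINEAGES = ("BA", "WA")
MARKS = ("H3K27ac", "H3K4me1")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class Thresholds:
    """Every analysis threshold, named, with its standard default."""

    entropy_max: float = 2.0
    expr_min_coding: float = 5.0
    expr_min_lncrna: float = 0.5
    max_additional_stages: int = 3
    mirna_min_fold: float = 2.0
    mirna_floor: float = 1.0
    bmp7_up_fold: float = 2.0
    bmp7_down_fold: float = 2.0
    bmp7_expr_min: float = 5.0
    lineage_min_fold: float = 3.0
    lineage_other_max: float = 10.0
    lineage_lnc_min_fold: float = 5.0
    external_min_fold: float = 2.5
    group_expr_min: float = 5.0
    tss_pad: int = 2500
    read_extension: int = 300
    zscore_axis: str = "per_stage_across_regions"
    z_high: float = 1.0
    z_active: float = 0.0
    enh_max_additional: int = 3
    stitch_gap: int = 12500
    min_span: int = 12500
    slope_threshold: float = 0.5
    target_window: int = 100_000
    r_primary: float = 0.75
    r_fallback: float = 0.5
    target_expr_min: float = 1.0
    promoter_pad: int = 2500
    tf_group_window: int = 100_000
    early_stages_ba: tuple[str, ...] = ("d-3", "d0", "6h")
    early_stages_wa: tuple[str, ...] = ("d-4", "d0")


@dataclass
class PipelineResult:
    stage_coding: dict[str, list[ss.StageAssignment]]
    stage_lncrna: dict[str, list[ss.StageAssignment]]
    stage_mirna: dict[str, list[ss.StageAssignment]]
    bmp7: list[str]
    lineage_calls: dict[str, lin_mod.LineageCall]
    lineage_calls_lnc: dict[str, lin_mod.LineageCall]
    binding_groups: dict[str, set[str]]
    universes: dict[str, enh.EnhancerUniverse]
    enhancer_calls: dict[str, list[enh.StageSpecificEnhancerCall]]
    concordance: dict[str, list[dict]]
    se_calls: dict[str, dict[str, list[se_mod.SuperEnhancerCall]]]
    late_ses: dict[str, list[se_mod.SuperEnhancerCall]]
    se_targets: dict[str, list[se_mod.SETargetAssignment]]
    nearest_targets: dict[str, list[se_mod.SETargetAssignment]]
    tf_annotations: list[tf_mod.PeakAnnotation]
    tf_fractions: dict[str, float]
    tf_enrichment: list[tf_mod.GroupEnrichment]
    tf_distances: dict[str, dict[str, int]]
    promoter_summary: list[lin_mod.PromoterStateSummary]
    manifest: dict


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    cfg: SimConfig,
    sim: ExpressionSim,
    epi: EpigenomeSim,
    tf_peaks: IntervalSet,
    promoter_counts: Mapping[str, Mapping[str, pd.DataFrame]],
    out_dir,
) -> Path:
    out = Path(out_dir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    (out / "promoter_marks").mkdir(exist_ok=True)
    for lin in LINEAGES:
        sim.coding[lin].to_tsv(out / "expression" / f"coding_{lin}.tsv")
        sim.lncrna[lin].to_tsv(out / "expression" / f"lncrna_{lin}.tsv")
        sim.mirna[lin].to_tsv(out / "expression" / f"mirna_{lin}.tsv")
        for stage, peaks in epi.h3k27ac_peaks[lin].items():
            write_bed(peaks, out / "peaks" / f"h3k27ac_{lin}_{stage}.bed")
        for stage, peaks in epi.h3k4me3_peaks[lin].items():
            write_bed(peaks, out / "peaks" / f"h3k4me3_{lin}_{stage}.bed")
        for mark in MARKS:
            for stage, rd in epi.reads[lin][mark].items():
                write_bed(rd, out / "reads" / f"{mark.lower()}_{lin}_{stage}.bed")
    write_refflat(epi.genes, out / "genes.refflat")
    write_bed(tf_peaks, out / "tf_peaks.bed")
    for mark, per_lin in promoter_counts.items():
        for lin, df in per_lin.items():
            df.to_csv(
                out / "promoter_marks" / f"{mark}_{lin}.tsv",
                sep="\t", index_label="gene_id", float_format="%.6g",
            )
    sim.truth.to_json(out / "truth.json")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": cfg.seed, "config": cfg.to_dict()}, fh, sort_keys=True)
    return out


def simulate_fixture(cfg: SimConfig, out_dir) -> Path:
    """Generate the full synthetic fixture (expression + epigenome + TF +
    promoter marks) and write it to ``out_dir``."""
    sim = simulate_expression(cfg)
    epi = simulate_epigenome(cfg, sim)
    tf_peaks = simulate_tf_peaks(cfg, epi.genes, sim.truth)
    pm = simulate_promoter_mark_counts(cfg, sim.truth, epi.genes)
    return write_fixture(cfg, sim, epi, tf_peaks, pm, out_dir)


# ---------------------------------------------------------------------------
# pipeline


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(
    input_dir,
    output_dir,
    thresholds: Thresholds | None = None,
    lineages: Sequence[str] = LINEAGES,
) -> PipelineResult:
    """Execute the full comparative analysis on a fixture directory.

    Any stage failure raises PipelineError naming the stage and the
    offending input. All outputs (TSV/BED + manifest.yaml) are written with
    fixed float precision, so identical inputs give byte-identical outputs.
    """
    th = thresholds or Thresholds()
    inp, out = Path(input_dir), Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_name = "input_loading"
    try:
        coding = {
            lin: ExpressionMatrix.from_tsv(
                inp / "expression" / f"coding_{lin}.tsv", "coding", lineage=lin
            )
            for lin in lineages
        }
        lnc = {
            lin: ExpressionMatrix.from_tsv(
                inp / "expression" / f"lncrna_{lin}.tsv", "lncRNA", lineage=lin
            )
            for lin in lineages
        }
        mir = {
            lin: ExpressionMatrix.from_tsv(
                inp / "expression" / f"mirna_{lin}.tsv", "miRNA", "array_signal", lin
            )
            for lin in lineages
        }
        genes = read_refflat(inp / "genes.refflat")

        # ------------------------------------------------------------------
        stage_name = "stage_specificity"
        stage_coding = {
            lin: ss.select_stage_specific(
                coding[lin], th.entropy_max, th.expr_min_coding,
                th.max_additional_stages,
            )
            for lin in lineages
        }
        stage_lnc = {
            lin: ss.select_stage_specific(
                lnc[lin], th.entropy_max, th.expr_min_lncrna,
                th.max_additional_stages,
            )
            for lin in lineages
        }
        stage_mir = {
            lin: ss.select_stage_specific_mirna(
                ss.quantile_normalize(mir[lin]), th.mirna_min_fold, th.mirna_floor
            )
            for lin in lineages
        }
        bmp7 = (
            ss.select_bmp7_transient(
                coding["BA"],
                pre_stage=coding["BA"].stages[0],
                peak_stage=coding["BA"].stages[1],
                post_stages=tuple(coding["BA"].stages[2:4]),
                up_fold=th.bmp7_up_fold,
                down_fold=th.bmp7_down_fold,
                expr_min=th.bmp7_expr_min,
            )
            if "BA" in lineages
            else []
        )

        # ------------------------------------------------------------------
        stage_name = "lineage_analysis"
        d7 = {lin: coding[lin].stages[-1] for lin in lineages}
        d7_ids: set[str] = set()
        for lin in lineages:
            for a in stage_coding[lin]:
                if d7[lin] in a.stages:
                    d7_ids.add(a.feature_id)
        lineage_calls = {
            g: lin_mod.classify_d7_lineage_coding(
                g,
                float(coding["BA"].data.at[g, d7["BA"]]),
                float(coding["WA"].data.at[g, d7["WA"]]),
                th.lineage_min_fold,
                th.lineage_other_max,
            )
            for g in sorted(d7_ids)
        }
        d7_lnc_ids: set[str] = set()
        for lin in lineages:
            for a in stage_lnc[lin]:
                if d7[lin] in a.stages:
                    d7_lnc_ids.add(a.feature_id)
        lineage_calls_lnc = {
            g: lin_mod.classify_d7_lineage_lncrna(
                g,
                float(lnc["BA"].data.at[g, d7["BA"]]),
                float(lnc["WA"].data.at[g, d7["WA"]]),
                th.lineage_lnc_min_fold,
            )
            for g in sorted(d7_lnc_ids)
        }
        binding_groups = lin_mod.gene_groups_for_binding(
            coding["BA"].data[d7["BA"]].to_dict(),
            coding["WA"].data[d7["WA"]].to_dict(),
            th.group_expr_min,
        )

        # ------------------------------------------------------------------
        stage_name = "enhancer_analysis"
        universes, enhancer_calls, concordance = {}, {}, {}
        ext_reads: dict[str, dict[str, dict[str, IntervalSet]]] = {}
        lib_sizes: dict[str, dict[str, dict[str, int]]] = {}
        for lin in lineages:
            stages = coding[lin].stages
            k27_peaks, k4_peaks = {}, {}
            for stage in stages:
                p = inp / "peaks" / f"h3k27ac_{lin}_{stage}.bed"
                q = inp / "peaks" / f"h3k4me3_{lin}_{stage}.bed"
                if not p.exists():
                    raise FileNotFoundError(f"missing H3K27ac peaks: {p}")
                if not q.exists():
                    raise FileNotFoundError(f"missing H3K4me3 peaks: {q}")
                k27_peaks[stage] = read_bed(p)
                k4_peaks[stage] = read_bed(q)
            ext_reads[lin] = {}
            lib_sizes[lin] = {}
            for mark in MARKS:
                ext_reads[lin][mark] = {}
                lib_sizes[lin][mark] = {}
                for stage in stages:
                    r = inp / "reads" / f"{mark.lower()}_{lin}_{stage}.bed"
                    if not r.exists():
                        raise FileNotFoundError(f"missing {mark} reads: {r}")
                    raw = read_bed(r)
                    lib_sizes[lin][mark][stage] = len(raw)
                    ext_reads[lin][mark][stage] = extend_reads_coverage(
                        raw, th.read_extension
                    )
            u = enh.build_enhancer_universe(k27_peaks, k4_peaks, genes, th.tss_pad)
            u = enh.quantify_universe(
                u,
                ext_reads[lin]["H3K27ac"],
                lib_sizes[lin]["H3K27ac"],
                th.zscore_axis,
                ext_reads[lin]["H3K4me1"],
                lib_sizes[lin]["H3K4me1"],
            )
            universes[lin] = u
            enhancer_calls[lin] = enh.call_stage_specific_enhancers(
                u, th.z_high, th.z_active, th.enh_max_additional
            )
            concordance[lin] = enh.h3k4me1_concordance(u, enhancer_calls[lin])

        # ------------------------------------------------------------------
        stage_name = "super_enhancers"
        se_calls: dict[str, dict[str, list[se_mod.SuperEnhancerCall]]] = {}
        late_ses, se_targets, nearest_targets = {}, {}, {}
        early_map = {"BA": th.early_stages_ba, "WA": th.early_stages_wa}
        for lin in lineages:
            stages = coding[lin].stages
            se_calls[lin] = {}
            for stage in stages:
                cands = se_mod.stitch_active_enhancers(
                    universes[lin], stage, ext_reads[lin]["H3K27ac"],
                    lib_sizes[lin]["H3K27ac"], th.stitch_gap, th.min_span,
                )
                se_calls[lin][stage] = (
                    se_mod.rank_and_cut(cands, th.slope_threshold) if cands else []
                )
            d7s = stages[-1]
            late_ses[lin] = se_mod.late_specific_ses(
                se_calls[lin][d7s],
                {s: se_calls[lin][s] for s in early_map.get(lin, stages[:2])},
            )
            se_targets[lin] = se_mod.assign_se_targets(
                se_calls[lin][d7s], coding[lin], genes, th.target_window,
                th.r_primary, th.r_fallback, th.target_expr_min,
            )
            nearest_targets[lin] = se_mod.assign_nearest_gene(
                se_calls[lin][d7s], genes
            )

        # ------------------------------------------------------------------
        stage_name = "tf_binding"
        tf_peaks = read_bed(inp / "tf_peaks.bed")
        tf_ann = tf_mod.annotate_peaks(tf_peaks, genes, th.promoter_pad)
        tf_fracs = tf_mod.element_fractions(tf_ann)
        pooled_d7_k27 = merge_within_gap(
            IntervalSet(
                [iv for lin in lineages
                 for iv in universes[lin].regions]
                + [iv for lin in lineages
                   for iv in read_bed(
                       inp / "peaks" / f"h3k27ac_{lin}_{coding[lin].stages[-1]}.bed"
                   )]
            ),
            0,
        )
        groups_sorted = {g: sorted(v) for g, v in binding_groups.items()}
        reg_regions = tf_mod.regulatory_regions_for_groups(
            pooled_d7_k27, groups_sorted, genes, th.tf_group_window
        )
        tf_enrich = tf_mod.group_enrichment(
            tf_peaks, None, reg_regions, groups_sorted
        )
        tf_dists = {
            g: tf_mod.nearest_peak_distance(ids, tf_peaks, genes)
            for g, ids in groups_sorted.items()
            if ids
        }

        # ------------------------------------------------------------------
        stage_name = "promoter_chromatin_state"
        gene_by_id = {g.gene_id: g for g in genes}
        promoter_marks: dict[str, dict[str, object]] = {}
        pm_dir = inp / "promoter_marks"
        if pm_dir.exists():
            mark_files: dict[str, dict[str, Path]] = {}
            for f in sorted(pm_dir.glob("*.tsv")):
                mark, lin = f.stem.rsplit("_", 1)
                mark_files.setdefault(mark, {})[lin] = f
            for mark, per_lin in mark_files.items():
                promoter_marks[mark] = {}
                for lin, f in per_lin.items():
                    df = pd.read_csv(f, sep="\t", index_col=0)
                    windows = [
                        gene_by_id[g].promoter_window(th.tss_pad) for g in df.index
                    ]
                    sm = quantify_rpkm(
                        windows, counts=df.values, stages=list(df.columns),
                        library_sizes={s: 1e6 for s in df.columns},
                    )
                    promoter_marks[mark][lin] = zscore_normalize(sm, th.zscore_axis)
        call_groups = {
            "BA_specific": sorted(
                g for g, c in lineage_calls.items() if c.label == "BA_specific"
            ),
            "WA_specific": sorted(
                g for g, c in lineage_calls.items() if c.label == "WA_specific"
            ),
            "common": sorted(
                g for g, c in lineage_calls.items() if c.label == "common"
            ),
        }
        promoter_summary = (
            lin_mod.promoter_mark_summary(promoter_marks, call_groups)
            if promoter_marks
            else []
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{stage_name}] {exc}") from exc

    manifest = {
        "adipoepi_version": __version__,
        "thresholds": dataclasses.asdict(th),
        "counts": {
            "stage_specific_coding": {
                lin: len(stage_coding[lin]) for lin in lineages
            },
            "stage_specific_lncrna": {lin: len(stage_lnc[lin]) for lin in lineages},
            "stage_specific_mirna": {lin: len(stage_mir[lin]) for lin in lineages},
            "per_stage_coding": {
                lin: {
                    s: sum(1 for a in stage_coding[lin] if s in a.stages)
                    for s in coding[lin].stages
                }
                for lin in lineages
            },
            "bmp7_transient": len(bmp7),
            "lineage_classes": {
                c: sum(1 for v in lineage_calls.values() if v.label == c)
                for c in ("BA_specific", "WA_specific", "common")
            },
            "enhancer_universe": {
                lin: len(universes[lin].regions) for lin in lineages
            },
            "stage_specific_enhancers": {
                lin: len(enhancer_calls[lin]) for lin in lineages
            },
            "superenhancers_d7": {
                lin: sum(
                    1 for c in se_calls[lin][coding[lin].stages[-1]] if c.is_se
                )
                for lin in lineages
            },
            "late_specific_ses": {lin: len(late_ses[lin]) for lin in lineages},
            "se_target_assignments": {
                lin: len(se_targets[lin]) for lin in lineages
            },
            "tf_peaks": len(tf_peaks),
        },
    }
    result = PipelineResult(
        stage_coding=stage_coding,
        stage_lncrna=stage_lnc,
        stage_mirna=stage_mir,
        bmp7=bmp7,
        lineage_calls=lineage_calls,
        lineage_calls_lnc=lineage_calls_lnc,
        binding_groups=binding_groups,
        universes=universes,
        enhancer_calls=enhancer_calls,
        concordance=concordance,
        se_calls=se_calls,
        late_ses=late_ses,
        se_targets=se_targets,
        nearest_targets=nearest_targets,
        tf_annotations=tf_ann,
        tf_fractions=tf_fracs,
        tf_enrichment=tf_enrich,
        tf_distances=tf_dists,
        promoter_summary=promoter_summary,
        manifest=manifest,
    )
    _write_outputs(result, coding, out)
    return result


def _write_outputs(res: PipelineResult, coding, out: Path) -> None:
    for lin, assigns in res.stage_coding.items():
        with open(out / f"stage_genes_{lin}.tsv", "w") as fh:
            fh.write("feature_id\tentropy\tstages\n")
            for a in assigns:
                fh.write(f"{a.feature_id}\t{_fmt(a.entropy)}\t{','.join(a.stages)}\n")
    for lin, assigns in res.stage_lncrna.items():
        with open(out / f"stage_lncrna_{lin}.tsv", "w") as fh:
            fh.write("feature_id\tentropy\tstages\n")
            for a in assigns:
                fh.write(f"{a.feature_id}\t{_fmt(a.entropy)}\t{','.join(a.stages)}\n")
    for lin, assigns in res.stage_mirna.items():
        with open(out / f"stage_mirna_{lin}.tsv", "w") as fh:
            fh.write("feature_id\tstage\ttie\n")
            for a in assigns:
                fh.write(f"{a.feature_id}\t{a.stages[0]}\t{int(a.tie_broken)}\n")
    with open(out / "bmp7_transient.tsv", "w") as fh:
        fh.write("feature_id\n")
        for g in res.bmp7:
            fh.write(g + "\n")
    with open(out / "lineage_calls_coding.tsv", "w") as fh:
        fh.write("feature_id\tclass\td7_fold\n")
        for g, c in res.lineage_calls.items():
            fh.write(f"{g}\t{c.label}\t{_fmt(c.d7_fold)}\n")
    with open(out / "lineage_calls_lncrna.tsv", "w") as fh:
        fh.write("feature_id\tclass\td7_fold\n")
        for g, c in res.lineage_calls_lnc.items():
            fh.write(f"{g}\t{c.label}\t{_fmt(c.d7_fold)}\n")
    for lin, calls in res.enhancer_calls.items():
        stages = res.universes[lin].stages
        for s in stages:
            sel = [c for c in calls if s in c.stages]
            iv_set = IntervalSet(
                GenomicInterval(
                    c.region.chrom, c.region.start, c.region.end,
                    name=s, score=round(c.zvector[stages.index(s)] * 100),
                )
                for c in sel
            )
            write_bed(iv_set, out / f"enhancers_{lin}_{s}.bed")
        res.universes[lin].zscore.to_frame().to_csv(
            out / f"enhancer_activity_{lin}.tsv", sep="\t",
            index_label="region", float_format="%.6g",
        )
        with open(out / f"h3k4me1_concordance_{lin}.tsv", "w") as fh:
            fh.write(
                "stage\tn_calls\tmean_me1_z_calls\tmean_me1_z_universe"
                "\tconcordant_fraction\n"
            )
            for row in res.concordance[lin]:
                fh.write(
                    f"{row['stage']}\t{row['n_calls']}\t"
                    f"{_fmt(row['mean_me1_z_calls'])}\t"
                    f"{_fmt(row['mean_me1_z_universe'])}\t"
                    f"{_fmt(row['concordant_fraction'])}\n"
                )
    for lin, per_stage in res.se_calls.items():
        d7s = coding[lin].stages[-1]
        ses = [c for c in per_stage[d7s] if c.is_se]
        write_bed(
            IntervalSet(
                GenomicInterval(
                    c.stitched.interval.chrom, c.stitched.interval.start,
                    c.stitched.interval.end, name=str(c.rank),
                    score=round(c.signal_scaled * 1000),
                )
                for c in ses
            ),
            out / f"superenhancers_{lin}_{d7s}.bed",
        )
        write_bed(
            IntervalSet(
                GenomicInterval(
                    c.stitched.interval.chrom, c.stitched.interval.start,
                    c.stitched.interval.end, name=str(c.rank),
                    score=round(c.signal_scaled * 1000),
                )
                for c in res.late_ses[lin]
            ),
            out / f"late_specific_ses_{lin}.bed",
        )
        with open(out / f"se_targets_{lin}.tsv", "w") as fh:
            fh.write("se_id\ttarget\tr\tmode\tdistance\n")
            for t in res.se_targets[lin]:
                fh.write(
                    f"{t.se_id}\t{t.target_id}\t{_fmt(t.correlation)}\t"
                    f"{t.mode}\t{t.distance}\n"
                )
        with open(out / f"se_nearest_gene_{lin}.tsv", "w") as fh:
            fh.write("se_id\ttarget\tdistance\ttie\n")
            for t in res.nearest_targets[lin]:
                fh.write(f"{t.se_id}\t{t.target_id}\t{t.distance}\t{int(t.tie)}\n")
    with open(out / "tf_annotation.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\telement\thost_gene\n")
        for a in res.tf_annotations:
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t{a.element}\t"
                f"{a.host_gene or '.'}\n"
            )
    with open(out / "tf_element_fractions.tsv", "w") as fh:
        fh.write("element\tfraction\n")
        for e, f in res.tf_fractions.items():
            fh.write(f"{e}\t{_fmt(f)}\n")
    with open(out / "tf_group_enrichment.tsv", "w") as fh:
        fh.write("group\tn_genes\tpeak_count\tsummed_rpkm\tempty\n")
        for g in res.tf_enrichment:
            fh.write(
                f"{g.group}\t{g.n_genes}\t{g.peak_count}\t{_fmt(g.summed_rpkm)}\t"
                f"{int(g.empty)}\n"
            )
    with open(out / "tf_nearest_distance.tsv", "w") as fh:
        fh.write("group\tgene\tdistance\n")
        for grp, dd in res.tf_distances.items():
            for g, d in sorted(dd.items()):
                fh.write(f"{grp}\t{g}\t{d}\n")
    with open(out / "promoter_mark_summary.tsv", "w") as fh:
        fh.write("mark\tgroup\tstage\tlineage\tn\tmean_z\tt\tp\tdegenerate\n")
        for s in res.promoter_summary:
            t = _fmt(s.t_stat) if s.t_stat is not None else "NA"
            p = _fmt(s.p_value) if s.p_value is not None else "NA"
            fh.write(
                f"{s.mark}\t{s.group}\t{s.stage}\t{s.lineage}\t{s.n}\t"
                f"{_fmt(s.mean_z)}\t{t}\t{p}\t{int(s.degenerate)}\n"
            )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(res.manifest, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# planted-truth recovery


def _pair_metrics(detected: set, truth: set) -> dict:
    tp = len(detected & truth)
    return {
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(detected) if detected else float("nan"),
        "n_detected": len(detected),
        "n_truth": len(truth),
    }


def recovery_report(res: PipelineResult, truth: GroundTruth) -> dict:
    """Precision/recall per planted class, computed against ground truth."""
    report: dict = {}
    for lin in LINEAGES:
        det = {
            (a.feature_id, s) for a in res.stage_coding[lin] for s in a.stages
        }
        tru = {
            (g, s)
            for s, ids in truth.stage_specific_coding[lin].items()
            for g in ids
        }
        report[f"stage_genes_{lin}"] = _pair_metrics(det, tru)
        det_l = {
            (a.feature_id, s) for a in res.stage_lncrna[lin] for s in a.stages
        }
        tru_l = {
            (g, s)
            for s, ids in truth.stage_specific_lncrna[lin].items()
            for g in ids
        }
        report[f"stage_lncrna_{lin}"] = _pair_metrics(det_l, tru_l)
        det_m = {(a.feature_id, a.stages[0]) for a in res.stage_mirna[lin]}
        tru_m = {
            (g, s)
            for s, ids in truth.stage_specific_mirna[lin].items()
            for g in ids
        }
        report[f"stage_mirna_{lin}"] = _pair_metrics(det_m, tru_m)
    # lineage classes
    cls_report = {}
    for cls in ("BA_specific", "WA_specific", "common"):
        tru_ids = {g for g, c in truth.lineage_coding.items() if c == cls}
        det_ids = {g for g, c in res.lineage_calls.items() if c.label == cls}
        cls_report[cls] = _pair_metrics(det_ids, tru_ids)
    report["lineage_classes"] = cls_report
    report["bmp7"] = _pair_metrics(set(res.bmp7), set(truth.bmp7_transient))
    # enhancers: match called (region, stage) pairs to planted intervals
    for lin in LINEAGES:
        truth_sets = {
            s: IntervalSet(GenomicInterval(c, st, en) for c, st, en in ivs)
            for s, ivs in truth.stage_specific_enhancers[lin].items()
        }
        calls_by_stage: dict[str, list[GenomicInterval]] = {}
        for c in res.enhancer_calls[lin]:
            for s in c.stages:
                calls_by_stage.setdefault(s, []).append(c.region)
        n_tp = n_det = 0
        for s, regions in calls_by_stage.items():
            tset = truth_sets.get(s, IntervalSet())
            for r in regions:
                n_det += 1
                if tset.overlaps_any(r):
                    n_tp += 1
        n_truth = n_rec = 0
        for s, tset in truth_sets.items():
            called = IntervalSet(calls_by_stage.get(s, []))
            for iv in tset:
                n_truth += 1
                if called.overlaps_any(iv):
                    n_rec += 1
        report[f"enhancers_{lin}"] = {
            "recall": n_rec / n_truth if n_truth else float("nan"),
            "precision": n_tp / n_det if n_det else float("nan"),
            "n_detected": n_det,
            "n_truth": n_truth,
        }
    # super-enhancers and targets (d7, per lineage)
    for lin in LINEAGES:
        d7s = truth.stages[lin][-1]
        ses = [c for c in res.se_calls[lin][d7s] if c.is_se]
        se_by_id = {c.stitched.se_id: c for c in ses}
        targets_by_se: dict[str, set[str]] = {}
        for t in res.se_targets[lin]:
            targets_by_se.setdefault(t.se_id, set()).add(t.target_id)
        n_rec = n_pair = 0
        n_called_planted = 0
        for name, locus in truth.se_loci.items():
            span = GenomicInterval(locus["chrom"], locus["start"], locus["end"])
            hit = [c for c in ses if c.stitched.interval.overlaps(span)]
            if hit:
                n_rec += 1
                n_called_planted += 1
                if any(
                    locus["target"] in targets_by_se.get(c.stitched.se_id, set())
                    for c in hit
                ):
                    n_pair += 1
        decoys = set(truth.decoy_genes)
        n_decoy_assigned = sum(
            1
            for t in res.se_targets[lin]
            if t.target_id in decoys and t.mode in ("corr_primary", "corr_fallback")
        )
        n_decoy_candidates = n_called_planted * len(SE_DECOY_OFFSETS)
        report[f"superenhancers_{lin}"] = {
            "locus_recall": n_rec / len(truth.se_loci) if truth.se_loci else float("nan"),
            "target_pair_recall": n_pair / len(truth.se_loci)
            if truth.se_loci
            else float("nan"),
            "decoy_rate": n_decoy_assigned / n_decoy_candidates
            if n_decoy_candidates
            else 0.0,
            "n_se_called": len(ses),
        }
    # H3K4me1 concordance at calls
    for lin in LINEAGES:
        fracs = [
            r["concordant_fraction"]
            for r in res.concordance[lin]
            if r["n_calls"] > 0
        ]
        report[f"h3k4me1_concordance_{lin}"] = (
            float(np.mean(fracs)) if fracs else float("nan")
        )
    # promoter marks: BA-vs-WA Welch p at BA-specific promoters
    pvals: dict[str, dict[str, float]] = {}
    for s in res.promoter_summary:
        if s.group == "BA_specific" and s.lineage == "BA" and s.p_value is not None:
            pvals.setdefault(s.mark, {})[s.stage] = s.p_value
    report["promoter_mark_p"] = pvals
    # TF
    enrich = {g.group: g.summed_rpkm for g in res.tf_enrichment}
    ba_set = {g for g, c in truth.lineage_coding.items() if c == "BA_specific"}
    wa_set = {g for g, c in truth.lineage_coding.items() if c == "WA_specific"}
    n_ba_prom = sum(
        1 for a in res.tf_annotations
        if a.element == "promoter" and a.host_gene in ba_set
    )
    n_wa_prom = sum(
        1 for a in res.tf_annotations
        if a.element == "promoter" and a.host_gene in wa_set
    )
    report["tf"] = {
        "element_fractions": dict(res.tf_fractions),
        "promoter_peaks_ba_vs_wa_ratio": (
            n_ba_prom / n_wa_prom if n_wa_prom else float("nan")
        ),
        "ba_vs_wa_rpkm_ratio": (
            enrich.get("BA_specific", 0.0) / enrich["WA_specific"]
            if enrich.get("WA_specific")
            else float("nan")
        ),
        "common_vs_wa_rpkm_ratio": (
            enrich.get("common", 0.0) / enrich["WA_specific"]
            if enrich.get("WA_specific")
            else float("nan")
        ),
    }
    return report


def run_demo(seed: int = 1, out_dir="demo_out", cfg: SimConfig | None = None):
    """Generate a synthetic fixture, run the full pipeline on it, and write a
    planted-truth recovery report (precision/recall per planted class)."""
    cfg = cfg or SimConfig(seed=seed)
    out = Path(out_dir)
    fixture = simulate_fixture(cfg, out / "fixture")
    result = run_pipeline(fixture, out / "results")
    truth = GroundTruth.from_json(fixture / "truth.json")
    report = recovery_report(result, truth)
    with open(out / "recovery.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(report)), fh, sort_keys=True)
    return result, report
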