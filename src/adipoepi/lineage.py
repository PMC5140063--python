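"""Day-7 lineage-specific classification and promoter chromatin-state comparison.

Mature (d7) stage-specific genes from the brown (BA) and white (WA) lineages
are pooled and split into BA-specific, WA-specific and shared adipogenic
classes by fold-change rules, optionally cross-checked against primary-cell
and tissue expression. Promoter histone-mark levels are then compared between
lineages per gene group with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import SignalMatrix

CLASSES = ("BA_specific", "WA_specific", "common", "unclassified")


@dataclass
class LineageCall:
    feature_id: str
    label: str  # one of CLASSES
    d7_fold: float  # BA/WA fold (inf when WA d7 == 0)
    tissue_fold: float | None = None
    primary_fold: float | None = None
    external_checked: bool = False

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")


def _fold(num: float, den: float) -> float:
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def classify_d7_lineage_coding(
    feature_id: str,
    ba_d7: float,
    wa_d7: float,
    min_fold: float = 3.0,
    other_max: float = 10.0,
) -> LineageCall:
    """BA-specific iff BA d7 >= min_fold x WA d7 and WA d7 < other_max
    (i.e. not highly expressed in the other lineage); mirrored for WA.
    Genes passing neither rule are shared ("common") adipogenic genes.
    """
    if ba_d7 < 0 or wa_d7 < 0:
        raise ValueError("FPKM must be non-negative")
    ba_rule = ba_d7 >= min_fold * wa_d7 and wa_d7 < other_max
    wa_rule = wa_d7 >= min_fold * ba_d7 and ba_d7 < other_max
    if ba_rule and wa_rule:
        # only possible when both values are ~0; neither lineage is favored
        label = "common"
    elif ba_rule:
        label = "BA_specific"
    elif wa_rule:
        label = "WA_specific"
    else:
        label = "common"
    return LineageCall(feature_id, label, d7_fold=_fold(ba_d7, wa_d7))


def classify_d7_lineage_lncrna(
    feature_id: str, ba_d7: float, wa_d7: float, min_fold: float = 5.0
) -> LineageCall:
    """lncRNA lineage rule: BA-specific iff BA d7 is at least ``min_fold``
    times WA d7 (zero denominators pass when the numerator is positive);
    mirrored for WA; otherwise shared.
    """
    if ba_d7 < 0 or wa_d7 < 0:
        raise ValueError("FPKM must be non-negative")
    ba_rule = ba_d7 >= min_fold * wa_d7 and ba_d7 > 0
    wa_rule = wa_d7 >= min_fold * ba_d7 and wa_d7 > 0
    if ba_rule and not wa_rule:
        label = "BA_specific"
    elif wa_rule and not ba_rule:
        label = "WA_specific"
    else:
        label = "common"
    return LineageCall(feature_id, label, d7_fold=_fold(ba_d7, wa_d7))


def apply_external_validation(
    call: LineageCall,
    tissue_fold: float | None = None,
    primary_fold: float | None = None,
    min_fold: float = 2.5,
) -> LineageCall:
    """Cross-check a lineage call against tissue and primary-cell expression.

    Folds are supplied in the concordant direction (BA/WA for a BA_specific
    call, WA/BA for WA_specific). The call survives only when both auxiliary
    folds are >= ``min_fold``; otherwise it is downgraded to unclassified.
    With no auxiliary data the call passes through unchanged, flagged as
    unchecked.
    """
    if call.label not in ("BA_specific", "WA_specific"):
        return call
    if tissue_fold is None and primary_fold is None:
        return LineageCall(
            call.feature_id, call.label, call.d7_fold, external_checked=False
        )
    ok = (
        tissue_fold is not None
        and primary_fold is not None
        and tissue_fold >= min_fold
        and primary_fold >= min_fold
    )
    return LineageCall(
        call.feature_id,
        call.label if ok else "unclassified",
        call.d7_fold,
        tissue_fold=tissue_fold,
        primary_fold=primary_fold,
        external_checked=True,
    )


def gene_groups_for_binding(
    ba_d7: Mapping[str, float], wa_d7: Mapping[str, float], expr_min: float = 5.0
) -> dict[str, set[str]]:
    """Three disjoint d7 gene groups for binding-enrichment comparisons:
    BA-specific (>expr_min in BA, <expr_min in WA), WA-specific (mirrored),
    and common (>expr_min in both). Genes below the cutoff in both lineages
    belong to no group.
    """
    groups: dict[str, set[str]] = {
        "BA_specific": set(),
        "WA_specific": set(),
        "common": set(),
    }
    for g in set(ba_d7) & set(wa_d7):
        ba, wa = ba_d7[g], wa_d7[g]
        if ba > expr_min and wa < expr_min:
            groups["BA_specific"].add(g)
        elif wa > expr_min and ba < expr_min:
            groups["WA_specific"].add(g)
        elif ba > expr_min and wa > expr_min:
            groups["common"].add(g)
    return groups


@dataclass
class PromoterStateSummary:
    mark: str
    group: str
    stage: str
    lineage: str
    n: int
    mean_z: float
    values: np.ndarray
    t_stat: float | None = None  # BA-vs-WA Welch t for this (mark, group, stage)
    p_value: float | None = None
    degenerate: bool = False


def promoter_mark_summary(
    marks: Mapping[str, Mapping[str, SignalMatrix]],
    groups: Mapping[str, Sequence[str]],
) -> list[PromoterStateSummary]:
    """Between-lineage comparison of promoter histone-mark levels per gene group.

    ``marks`` maps mark name -> lineage name -> z-scored SignalMatrix whose
    region names are gene ids (promoter windows). For each (mark, group,
    stage) present in both lineages, the two z-value distributions are
    compared with Welch's two-sample t-test (two-sided). Groups with fewer
    than 2 genes yield a summary without a test, flagged degenerate.
    """
    out: list[PromoterStateSummary] = []
    for mark, per_lineage in marks.items():
        lineages = list(per_lineage)
        for sm in per_lineage.values():
            if sm.unit != "zscore":
                raise ValueError(f"promoter SignalMatrix for {mark} must be z-scored")
        for group, genes in groups.items():
            gene_set = set(genes)
            per_lin_stage: dict[tuple[str, str], np.ndarray] = {}
            for lin in lineages:
                sm = per_lineage[lin]
                idx = [i for i, n in enumerate(sm.region_names) if n in gene_set]
                for s in sm.stages:
                    per_lin_stage[(lin, s)] = sm.values[idx, sm.stages.index(s)]
            shared_stages = (
                set.intersection(*(set(per_lineage[l].stages) for l in lineages))
                if lineages
                else set()
            )
            for lin in lineages:
                sm = per_lineage[lin]
                for s in sm.stages:
                    vals = per_lin_stage[(lin, s)]
                    t = p = None
                    degen = len(vals) < 2
                    if (
                        len(lineages) == 2
                        and s in shared_stages
                        and not degen
                        and len(per_lin_stage[(lineages[1 - lineages.index(lin)], s)]) >= 2
                    ):
                        other = per_lin_stage[(lineages[1 - lineages.index(lin)], s)]
                        if np.std(vals) == 0 and np.std(other) == 0 and np.mean(
                            vals
                        ) == np.mean(other):
                            t, p = 0.0, 1.0
                        else:
                            res = stats.ttest_ind(vals, other, equal_var=False)
                            t, p = float(res.statistic), float(res.pvalue)
                    out.append(
                        PromoterStateSummary(
                            mark=mark,
                            group=group,
                            stage=s,
                            lineage=lin,
                            n=len(vals),
                            mean_z=float(np.mean(vals)) if len(vals) else float("nan"),
                            values=vals,
                            t_stat=t,
                            p_value=p,
                            degenerate=degen,
                        )
                    )
    return out
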