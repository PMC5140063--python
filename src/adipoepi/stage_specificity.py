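"""Entropy-based stage-specificity scoring and stage assignment.

A feature expressed in a single differentiation stage has Shannon entropy 0
over its relative-expression vector; a ubiquitously expressed feature has
entropy log2(N). Features with entropy below a cutoff are candidates, then
assigned to the stage(s) where they are highly expressed, provided high
expression is not seen too broadly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

#: Default expression cutoffs per feature class (FPKM for RNA-seq classes).
DEFAULT_EXPR_MIN = {"coding": 5.0, "lncRNA": 0.5}


@dataclass(frozen=True)
class EntropyScore:
    feature_id: str
    entropy: float  # bits; NaN when total expression is 0
    relative: np.ndarray


@dataclass
class StageAssignment:
    feature_id: str
    stages: list[str]
    entropy: float
    tie_broken: bool = False


def entropy_score_vector(e: np.ndarray) -> float:
    """Shannon entropy (base 2) of the relative-expression vector Ri = Ei/sum(E).

    0 * log2(0) is taken as 0. Returns NaN when the vector sums to 0.
    """
    e = np.asarray(e, dtype=float)
    if (e < 0).any():
        raise ValueError("expression values must be non-negative")
    total = e.sum()
    if total == 0:
        return float("nan")
    r = e / total
    nz = r[r > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_score(feature_id: str, e: np.ndarray) -> EntropyScore:
    e = np.asarray(e, dtype=float)
    h = entropy_score_vector(e)
    total = e.sum()
    rel = e / total if total > 0 else np.full_like(e, np.nan)
    return EntropyScore(feature_id, h, rel)


def entropy_scores(expr: ExpressionMatrix) -> pd.Series:
    """Entropy per feature; NaN for all-zero features (excluded downstream)."""
    v = expr.data.values.astype(float)
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    totals = v.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = v / totals[:, None]
        term = np.where(r > 0, r * np.log2(np.where(r > 0, r, 1.0)), 0.0)
    h = -term.sum(axis=1)
    h[totals == 0] = np.nan
    return pd.Series(h, index=expr.data.index, name="entropy")


def select_stage_specific(
    expr: ExpressionMatrix,
    entropy_max: float = 2.0,
    expr_min: float | None = None,
    max_additional_stages: int = 3,
) -> list[StageAssignment]:
    """Assign features to stages by the entropy + expression-breadth rule.

    A feature is assigned to stage s iff its entropy H < ``entropy_max``,
    its expression at s exceeds ``expr_min``, and fewer than or equal to
    ``max_additional_stages`` other stages also exceed ``expr_min``.
    Features may be assigned to several stages. All inequalities on the
    thresholds are strict.
    """
    if expr_min is None:
        if expr.feature_class not in DEFAULT_EXPR_MIN:
            raise ValueError(
                f"no default expression cutoff for class {expr.feature_class!r}; "
                "pass expr_min explicitly"
            )
        expr_min = DEFAULT_EXPR_MIN[expr.feature_class]
    h = entropy_scores(expr)
    v = expr.data.values.astype(float)
    high = v > expr_min
    n_high = high.sum(axis=1)
    stages = expr.stages
    out: list[StageAssignment] = []
    for i, fid in enumerate(expr.data.index):
        if not (h.iloc[i] < entropy_max):  # NaN fails too
            continue
        assigned = [
            stages[j]
            for j in range(len(stages))
            if high[i, j] and (n_high[i] - 1) <= max_additional_stages
        ]
        if assigned:
            out.append(StageAssignment(fid, assigned, float(h.iloc[i])))
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize array signal across stage columns.

    Each column is ranked; the value at rank r is replaced by the mean over
    columns of the rank-r order statistics. Ties within a column receive the
    mean of the values their span of ranks would map to.
    """
    if m.feature_class != "miRNA" or m.unit != "array_signal":
        raise ValueError("quantile normalization applies to miRNA array signal")
    df = m.data
    sorted_cols = np.sort(df.values, axis=0)
    rank_means = sorted_cols.mean(axis=1)  # mean per rank (0-based)
    ranks = df.rank(method="average").values  # 1-based, fractional on ties
    # fractional rank r maps to mean of rank_means at floor/ceil of (r-1)
    lo = np.floor(ranks - 1).astype(int)
    hi = np.ceil(ranks - 1).astype(int)
    normalized = (rank_means[lo] + rank_means[hi]) / 2.0
    out = pd.DataFrame(normalized, index=df.index, columns=df.columns)
    return ExpressionMatrix(
        out, feature_class=m.feature_class, unit=m.unit, lineage=m.lineage
    )


def select_stage_specific_mirna(
    m: ExpressionMatrix, min_fold: float = 2.0, floor: float = 1.0
) -> list[StageAssignment]:
    """Select miRNAs whose (quantile-normalized) signal varies by more than
    ``min_fold`` between stages; each is assigned to its argmax stage.

    The fold is max / max(min, floor); ``floor`` is a detection floor that
    keeps near-zero minima from producing unbounded folds. Ties at the
    maximum go to the earliest stage and are flagged.
    """
    v = m.data.values.astype(float)
    vmax = v.max(axis=1)
    denom = np.maximum(v.min(axis=1), floor)
    fold = vmax / denom
    out: list[StageAssignment] = []
    stages = m.stages
    for i, fid in enumerate(m.data.index):
        if fold[i] > min_fold:
            argmaxes = np.flatnonzero(v[i] == vmax[i])
            out.append(
                StageAssignment(
                    fid,
                    [stages[int(argmaxes[0])]],
                    entropy=float("nan"),
                    tie_broken=len(argmaxes) > 1,
                )
            )
    return out


def select_bmp7_transient(
    expr: ExpressionMatrix,
    pre_stage: str = "d-3",
    peak_stage: str = "d0",
    post_stages: tuple[str, ...] = ("6h", "d2"),
    up_fold: float = 2.0,
    down_fold: float = 2.0,
    expr_min: float = 5.0,
) -> list[str]:
    """Genes robustly but transiently induced between the pre-treatment stage
    and the committed (d0) stage, falling back after induction.

    Selected iff E(d0) >= up_fold * E(d-3), E(d0) >= down_fold * max over the
    post stages, and E(d0) > expr_min.
    """
    for s in (pre_stage, peak_stage, *post_stages):
        if s not in expr.stages:
            raise ValueError(f"required stage {s!r} absent from matrix")
    df = expr.data
    peak = df[peak_stage]
    pre = df[pre_stage]
    post = df[list(post_stages)].max(axis=1)
    mask = (peak >= up_fold * pre) & (peak >= down_fold * post) & (peak > expr_min)
    return list(df.index[mask])
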