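"""Stitching, slope-cutoff ranking, late-SE subtraction, target assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from adipoepi.enhancers import EnhancerUniverse
from adipoepi.expression import ExpressionMatrix
from adipoepi.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    SignalMatrix,
)
from adipoepi.superenhancers import (
    StitchedEnhancer,
    SuperEnhancerCall,
    assign_nearest_gene,
    assign_se_targets,
    late_specific_ses,
    rank_and_cut,
    stitch_active_enhancers,
)

STAGES = ["d-3", "d0", "6h", "d2", "d7"]


def textbook_pearson(x, y):
    """Independent sums-formula implementation of Pearson r."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def _universe(regions, z):
    z = np.asarray(z, dtype=float)
    u = EnhancerUniverse(regions=IntervalSet(regions), stages=STAGES)
    u.zscore = SignalMatrix(list(regions), STAGES, z, "zscore", zscore_axis="x")
    return u


def _reads_flat(chrom="chr1", span=60_000, per_kb=10):
    """Uniform stranded pseudo-reads so every stage has identical coverage."""
    ivs = [
        GenomicInterval(chrom, p, p + 36, strand="+")
        for p in range(0, span, 1000 // per_kb * 100)
    ]
    return {s: IntervalSet(ivs) for s in STAGES}


def _stitched(signal, start=0, length=20_000, stage="d7"):
    iv = GenomicInterval("chr1", start, start + length)
    rpkm = np.array([1.0, 1.0, 1.0, 1.0, signal])
    return StitchedEnhancer(
        interval=iv, constituents=[iv], stages=STAGES, rpkm=rpkm, focal_stage=stage
    )


# ---------------------------------------------------------------------------
# stitching


def test_stitch_examples():
    regions = [
        GenomicInterval("chr1", 0, 2000),
        GenomicInterval("chr1", 10_000, 12_000),
        GenomicInterval("chr1", 22_000, 24_000),
        GenomicInterval("chr1", 40_000, 41_000),  # inactive at focal stage
    ]
    z = [[0.5] * 5, [0.5] * 5, [0.5] * 5, [-1.0] * 5]
    u = _universe(regions, z)
    out = stitch_active_enhancers(u, "d7", _reads_flat(), gap=12_500, min_span=12_500)
    assert len(out) == 1
    assert (out[0].interval.start, out[0].interval.end) == (0, 24_000)
    assert len(out[0].constituents) == 3
    # short stitched spans are dropped
    u2 = _universe(
        [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000)],
        [[0.5] * 5, [0.5] * 5],
    )
    assert stitch_active_enhancers(u2, "d7", _reads_flat()) == []


def test_stitch_matches_brute_force_merge(rng):
    from tests.test_intervals import brute_merge

    for _ in range(100):
        n = int(rng.integers(1, 30))
        starts = np.sort(rng.choice(np.arange(0, 200_000, 700), n, replace=False))
        regions = [GenomicInterval("chrA", int(s), int(s) + 500) for s in starts]
        z = rng.normal(0, 1, (n, 5))
        u = _universe(regions, z)
        gap, min_span = 3000, 2000
        out = stitch_active_enhancers(
            u, "d7", {s: IntervalSet() for s in STAGES},
            library_sizes={s: 1e6 for s in STAGES}, gap=gap, min_span=min_span,
        )
        active = [r for r, zz in zip(regions, z) if zz[4] > 0]
        want = [
            (c, s, e)
            for c, s, e, _ in brute_merge(active, gap)
            if e - s > min_span
        ]
        got = [(c.interval.chrom, c.interval.start, c.interval.end) for c in out]
        assert sorted(got) == sorted(want)


# ---------------------------------------------------------------------------
# ranking


def test_rank_and_cut_single_outlier():
    cands = [_stitched(s) for s in [1, 1, 1, 1, 100]]
    calls = rank_and_cut(cands)
    assert [c.is_se for c in sorted(calls, key=lambda c: c.rank)] == [
        False, False, False, False, True
    ]


def test_rank_and_cut_flat_curve():
    cands = [_stitched(5.0) for _ in range(6)]
    assert not any(c.is_se for c in rank_and_cut(cands))


def test_rank_and_cut_threshold_monotone(rng):
    signals = np.concatenate([rng.random(30), 5 + rng.random(10)])
    cands = [_stitched(float(s)) for s in signals]
    prev = None
    for thr in [0.25, 0.5, 1.0, 2.0]:
        se_ids = {
            c.stitched.interval.start
            for c in rank_and_cut(cands, thr)
            if c.is_se
        }
        if prev is not None:
            assert se_ids <= prev
        prev = se_ids


def test_se_set_is_suffix_of_ranked_list(rng):
    for _ in range(50):
        cands = [_stitched(float(s)) for s in rng.random(20) * 10]
        calls = sorted(rank_and_cut(cands), key=lambda c: c.rank)
        flags = [c.is_se for c in calls]
        # once True, stays True
        assert flags == sorted(flags)


def test_rank_and_cut_warns_on_singleton():
    with pytest.warns(UserWarning, match="fewer than 2"):
        calls = rank_and_cut([_stitched(5.0)])
    assert not calls[0].is_se


# ---------------------------------------------------------------------------
# late-specific subtraction


def _se_call(start, end, is_se=True, stage="d7"):
    iv = GenomicInterval("chr1", start, end)
    st = StitchedEnhancer(iv, [iv], STAGES, np.ones(5), stage)
    return SuperEnhancerCall(st, is_se, 0, 0.0, 1.0, stage)


def test_late_specific_boundary_and_passthrough():
    d7 = [_se_call(0, 20_000), _se_call(100_000, 130_000)]
    early = {"d0": [_se_call(19_999, 40_000)]}  # 1-base overlap with the first
    out = late_specific_ses(d7, early)
    assert [c.stitched.interval.start for c in out] == [100_000]
    assert late_specific_ses(d7, {"d0": []}) == d7


def test_late_specific_matches_all_pairs_filter(rng):
    for _ in range(100):
        d7 = [
            _se_call(int(s), int(s) + int(rng.integers(1000, 30_000)))
            for s in rng.integers(0, 500_000, rng.integers(1, 12))
        ]
        early = {
            st: [
                _se_call(int(s), int(s) + int(rng.integers(1000, 30_000)), stage=st)
                for s in rng.integers(0, 500_000, rng.integers(0, 8))
            ]
            for st in ("d-3", "d0")
        }
        got = {c.stitched.interval.start for c in late_specific_ses(d7, early)}
        want = {
            c.stitched.interval.start
            for c in d7
            if not any(
                c.stitched.interval.overlaps(e.stitched.interval)
                for calls in early.values()
                for e in calls
            )
        }
        assert got == want


# ---------------------------------------------------------------------------
# target assignment


def _expr(profiles):
    df = pd.DataFrame.from_dict(profiles, orient="index").astype(float)
    df.columns = STAGES
    return ExpressionMatrix(df, feature_class="coding")


def _gene(gid, tss):
    return GeneModel(gid, gid, "chr1", "+", tss, tss + 1000, (tss,), (tss + 1000,))


def test_assign_targets_perfect_and_window():
    se = _se_call(200_000, 220_000)
    se.stitched.rpkm = np.array([1.0, 1.0, 2.0, 8.0, 10.0])
    expr = _expr({"hit": [2, 2, 4, 16, 20], "far": [2, 2, 4, 16, 20]})
    genes = [_gene("hit", 250_000), _gene("far", 400_000)]  # far: 180 kb away
    out = assign_se_targets([se], expr, genes)
    assert [(t.target_id, t.mode) for t in out] == [("hit", "corr_primary")]
    assert out[0].correlation == pytest.approx(1.0)


def test_assign_targets_fallback_picks_argmax():
    se = _se_call(200_000, 220_000)
    se.stitched.rpkm = np.array([1.0, 1.0, 2.0, 8.0, 10.0])
    # profiles chosen so 0.5 < r(B) < r(A) < 0.75
    expr = _expr({"A": [1, 5, 2, 4, 6], "B": [5, 2, 9, 6, 9]})
    genes = [_gene("A", 230_000), _gene("B", 240_000)]
    rA = textbook_pearson([1, 5, 2, 4, 6], [1, 1, 2, 8, 10])
    rB = textbook_pearson([5, 2, 9, 6, 9], [1, 1, 2, 8, 10])
    assert 0.5 < rB < rA < 0.75
    out = assign_se_targets([se], expr, genes)
    assert [(t.target_id, t.mode) for t in out] == [("A", "corr_fallback")]
    assert out[0].correlation == pytest.approx(rA, abs=1e-10)


def test_assign_targets_pearson_matches_textbook(rng):
    se = _se_call(100_000, 120_000)
    se.stitched.rpkm = rng.random(5) * 10
    profiles = {f"g{i}": list(rng.random(5) * 20 + 1) for i in range(30)}
    genes = [_gene(f"g{i}", 130_000 + i * 100) for i in range(30)]
    out = assign_se_targets(
        [se], _expr(profiles), genes, r_primary=-2, r_fallback=-2
    )
    for t in out:
        if t.mode == "corr_primary":
            want = textbook_pearson(profiles[t.target_id], list(se.stitched.rpkm))
            assert t.correlation == pytest.approx(want, abs=1e-10)


def test_assign_targets_skips_unexpressed_and_constant():
    se = _se_call(200_000, 220_000)
    se.stitched.rpkm = np.array([1.0, 1.0, 2.0, 8.0, 10.0])
    expr = _expr({"low": [0.1, 0.2, 0.3, 0.9, 0.95], "flat": [7, 7, 7, 7, 7]})
    genes = [_gene("low", 230_000), _gene("flat", 240_000)]
    assert assign_se_targets([se], expr, genes) == []


def test_assign_targets_mirna_window():
    se = _se_call(200_000, 220_000)
    se.stitched.rpkm = np.array([1.0, 1.0, 2.0, 8.0, 10.0])
    expr = _expr({"g": [2, 2, 4, 16, 20]})
    genes = [_gene("g", 250_000)]
    mirnas = [_gene("mir1", 280_000), _gene("mir2", 900_000)]
    out = assign_se_targets([se], expr, genes, mirnas=mirnas)
    modes = {(t.target_id, t.mode) for t in out}
    assert ("mir1", "mirna_window") in modes
    assert all(t.target_id != "mir2" for t in out)


def test_assign_targets_stage_grid_mismatch():
    se = _se_call(0, 20_000)
    expr = ExpressionMatrix(
        pd.DataFrame([[1.0, 2.0]], columns=["x", "y"], index=["g"])
    )
    with pytest.raises(ValueError, match="stage grid"):
        assign_se_targets([se], expr, [_gene("g", 5000)])


def test_nearest_gene_inside_beats_near():
    se = _se_call(100_000, 120_000)
    genes = [_gene("inside", 110_000), _gene("near", 125_000)]
    out = assign_nearest_gene([se], genes)
    assert [(t.target_id, t.distance, t.tie) for t in out] == [("inside", 0, False)]


def test_nearest_gene_minimum_and_ties():
    se = _se_call(100_000, 120_000)
    out = assign_nearest_gene([se], [_gene("a", 125_000), _gene("b", 128_000)])
    assert [(t.target_id, t.distance) for t in out] == [("a", 5001)]
    # symmetric distances: TSS 5000 bases off either edge
    g_left = _gene("left", 95_000)  # 100000 - 95000 = 5000
    g_right = _gene("right", 124_999)  # 124999 - 120000 + 1 = 5000
    out2 = assign_nearest_gene([se], [g_left, g_right])
    assert {t.target_id for t in out2} == {"left", "right"}
    assert all(t.tie for t in out2)
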