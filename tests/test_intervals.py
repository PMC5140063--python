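"""Interval algebra, BED/refFlat I/O, and signal quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipoepi.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    count_reads_in_regions,
    extend_reads_coverage,
    merge_with_constituents,
    merge_within_gap,
    quantify_rpkm,
    read_bed,
    read_refflat,
    subtract,
    write_bed,
    zscore_normalize,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def covered_bases(intervals):
    out = set()
    for iv in intervals:
        out.update(range(iv.start, iv.end))
    return out


def brute_subtract(a, b):
    """Keep a-intervals sharing no base with any b-interval (per-base check)."""
    b_bases = {}
    for iv in b:
        b_bases.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return [
        iv
        for iv in a
        if not (set(range(iv.start, iv.end)) & b_bases.get(iv.chrom, set()))
    ]


def brute_merge(intervals, max_gap):
    """O(n^2) transitive merge via repeated pairwise joining."""
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                if gi[0].chrom != gj[0].chrom:
                    continue
                si = min(x.start for x in gi)
                ei = max(x.end for x in gi)
                sj = min(x.start for x in gj)
                ej = max(x.end for x in gj)
                if sj - ei <= max_gap and si - ej <= max_gap:
                    groups[i] = gi + gj
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (
            g[0].chrom,
            min(x.start for x in g),
            max(x.end for x in g),
            len(g),
        )
        for g in groups
    )


def random_interval_set(rng, n_max=50, coord_max=2000, chroms=("chrA", "chrB")):
    n = rng.integers(0, n_max + 1)
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, coord_max))
        length = int(rng.integers(1, 120))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# GenomicInterval / IntervalSet basics


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, strand="x")


def test_interval_set_sorted_within_chrom():
    ivs = [
        GenomicInterval("chr2", 500, 600),
        GenomicInterval("chr2", 10, 20),
        GenomicInterval("chr2", 100, 300),
    ]
    out = list(IntervalSet(ivs))
    assert [iv.start for iv in out] == [10, 100, 500]


def test_count_overlapping_boundaries():
    s = IntervalSet([GenomicInterval("chr1", 100, 200)])
    assert s.count_overlapping("chr1", 199, 300) == 1  # 1-base overlap
    assert s.count_overlapping("chr1", 200, 300) == 0  # half-open: touching
    assert s.count_overlapping("chr1", 0, 100) == 0
    assert s.count_overlapping("chr2", 100, 200) == 0


# ---------------------------------------------------------------------------
# I/O


def test_read_bed_parses_and_sorts(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr2\t500\t600\tb\t1\t-\nchr2\t0\t100\ta\t2\t+\nchr1\t5\t9\n")
    s = read_bed(p)
    out = list(s)
    assert (out[0].chrom, out[0].start) == ("chr1", 5)
    assert out[1].name == "a" and out[1].strand == "+"
    assert out[2].score == 1.0


@pytest.mark.parametrize(
    "line", ["chr1\t100\t100", "chr1\tx\t200", "chr1\t100"]
)
def test_read_bed_malformed_names_line(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t10\n" + line + "\n")
    with pytest.raises(ValueError, match="line 2"):
        read_bed(p)


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2"]),
            st.integers(0, 10_000),
            st.integers(1, 500),
            st.sampled_from(["+", "-", "."]),
        ),
        max_size=30,
    )
)
@settings(max_examples=50, derandomize=True)
def test_bed_round_trip(tmp_path_factory, recs):
    ivs = IntervalSet(
        GenomicInterval(c, s, s + l, name=f"n{i}", score=float(i), strand=d)
        for i, (c, s, l, d) in enumerate(recs)
    )
    p = tmp_path_factory.mktemp("bed") / "rt.bed"
    write_bed(ivs, p)
    assert read_bed(p) == ivs


def test_read_refflat_strand_and_errors(tmp_path):
    p = tmp_path / "genes.refflat"
    p.write_text(
        "gp\tgp\tchr1\t+\t1000\t5000\t1000\t5000\t2\t1000,3000,\t2000,5000,\n"
        "gm\tgm\tchr1\t-\t1000\t5000\t1000\t5000\t1\t1000,\t5000,\n"
    )
    gp, gm = read_refflat(p)
    assert gp.tss == 1000 and gm.tss == 5000
    assert gp.tts == 5000 and gm.tts == 1000
    bad = tmp_path / "bad.refflat"
    bad.write_text(
        "g\tg\tchr1\t+\t0\t100\t0\t100\t2\t0,10,20,\t5,15,25,\n"
    )
    with pytest.raises(ValueError, match="exonCount"):
        read_refflat(bad)


def test_gene_model_exon_bounds():
    with pytest.raises(ValueError):
        GeneModel("g", "g", "chr1", "+", 100, 200, (50,), (150,))


# ---------------------------------------------------------------------------
# subtract / merge vs brute force


def test_subtract_examples():
    a = IntervalSet([GenomicInterval("chr1", 0, 100)])
    # region-level exclusion: any overlap removes the whole interval
    assert len(subtract(a, IntervalSet([GenomicInterval("chr1", 50, 60)]))) == 0
    assert list(subtract(a, IntervalSet([GenomicInterval("chr1", 200, 300)]))) == list(a)
    assert len(subtract(IntervalSet(), a)) == 0


def test_merge_examples():
    s = IntervalSet(
        [
            GenomicInterval("chr1", 0, 2000),
            GenomicInterval("chr1", 10_000, 12_000),
            GenomicInterval("chr1", 22_000, 24_000),
        ]
    )
    m = list(merge_within_gap(s, 12_500))
    assert len(m) == 1 and (m[0].start, m[0].end) == (0, 24_000)
    assert m[0].score == 3  # constituent count
    far = IntervalSet(
        [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 20_000, 21_000)]
    )
    assert len(merge_within_gap(far, 12_500)) == 2
    one = IntervalSet([GenomicInterval("chr1", 5, 10)])
    assert [(iv.start, iv.end) for iv in merge_within_gap(one, 100)] == [(5, 10)]


def test_subtract_and_merge_match_brute_force_on_random_sets(rng):
    for _ in range(200):
        a = random_interval_set(rng)
        b = random_interval_set(rng)
        got = [(iv.chrom, iv.start, iv.end) for iv in subtract(a, b)]
        want = [(iv.chrom, iv.start, iv.end) for iv in brute_subtract(a, b)]
        assert sorted(got) == sorted(want)
        gap = int(rng.integers(0, 300))
        if len(a):
            got_m = [
                (iv.chrom, iv.start, iv.end, int(iv.score))
                for iv in merge_within_gap(a, gap)
            ]
            assert sorted(got_m) == brute_merge(list(a), gap)


def test_merge_idempotent(rng):
    for _ in range(50):
        a = random_interval_set(rng)
        if not len(a):
            continue
        m1 = merge_within_gap(a, 75)
        m2 = merge_within_gap(m1, 75)
        assert [(iv.chrom, iv.start, iv.end) for iv in m1] == [
            (iv.chrom, iv.start, iv.end) for iv in m2
        ]


def test_merge_with_constituents_tracks_members():
    s = IntervalSet(
        [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 15, 25),
         GenomicInterval("chr1", 500, 510)]
    )
    out = merge_with_constituents(s, 10)
    assert [(span.start, span.end, len(cons)) for span, cons in out] == [
        (0, 25, 2), (500, 510, 1)
    ]


# ---------------------------------------------------------------------------
# read extension and quantification


def test_extend_reads_strand_arithmetic():
    reads = IntervalSet(
        [
            GenomicInterval("chr1", 100, 136, strand="+"),
            GenomicInterval("chr1", 100, 136, strand="-"),
            GenomicInterval("chr1", 500, 536, strand="-"),
        ]
    )
    out = sorted(
        [(iv.start, iv.end, iv.strand) for iv in extend_reads_coverage(reads, 300)]
    )
    assert out == [(0, 136, "-"), (100, 400, "+"), (236, 536, "-")]


def test_extend_reads_requires_strand_and_positive_extension():
    reads = IntervalSet([GenomicInterval("chr1", 0, 36)])
    with pytest.raises(ValueError, match="strand"):
        extend_reads_coverage(reads, 300)
    stranded = IntervalSet([GenomicInterval("chr1", 0, 36, strand="+")])
    with pytest.raises(ValueError):
        extend_reads_coverage(stranded, 0)


def test_rpkm_formula():
    regions = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 7500)]
    counts = np.array([[100.0, 0.0], [50.0, 50.0]])
    sm = quantify_rpkm(
        regions, counts=counts, stages=["a", "b"],
        library_sizes={"a": 10_000_000, "b": 5_000_000},
    )
    assert sm.unit == "rpkm"
    assert sm.values[0, 0] == pytest.approx(10.0)
    assert sm.values[0, 1] == 0.0
    assert sm.values[1, 1] == pytest.approx(50 / (2.5 * 5))  # 4.0


def test_rpkm_counts_overlap_of_one_base():
    regions = [GenomicInterval("chr1", 1000, 2000)]
    reads = IntervalSet(
        [
            GenomicInterval("chr1", 1999, 2035, strand="+"),  # 1-base overlap
            GenomicInterval("chr1", 2000, 2036, strand="+"),  # touching, excluded
            GenomicInterval("chr1", 900, 1001, strand="+"),
        ]
    )
    assert count_reads_in_regions(regions, reads)[0] == 2


def test_rpkm_linearity(rng):
    regions = [
        GenomicInterval("chr1", i * 1000, i * 1000 + int(rng.integers(200, 900)))
        for i in range(10)
    ]
    counts = rng.integers(0, 500, size=(10, 3)).astype(float)
    lib = {"a": 1e6, "b": 2e6, "c": 5e5}
    sm = quantify_rpkm(regions, counts=counts, stages=list(lib), library_sizes=lib)
    sm2 = quantify_rpkm(
        regions, counts=3 * counts, stages=list(lib), library_sizes=lib
    )
    np.testing.assert_allclose(sm2.values, 3 * sm.values)
    lib_half = {k: v / 2 for k, v in lib.items()}
    sm3 = quantify_rpkm(
        regions, counts=counts, stages=list(lib), library_sizes=lib_half
    )
    np.testing.assert_allclose(sm3.values, 2 * sm.values)


def test_rpkm_rejects_zero_library():
    with pytest.raises(ValueError, match="library"):
        quantify_rpkm(
            [GenomicInterval("chr1", 0, 100)],
            counts=np.zeros((1, 1)),
            stages=["a"],
            library_sizes={"a": 0},
        )


# ---------------------------------------------------------------------------
# z-score normalization


def _rpkm_matrix(values, stages=None):
    values = np.asarray(values, dtype=float)
    regions = [
        GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(values.shape[0])
    ]
    from adipoepi.intervals import SignalMatrix

    return SignalMatrix(
        regions, stages or [f"s{j}" for j in range(values.shape[1])], values, "rpkm"
    )


def test_zscore_hand_example():
    col = np.array([2, 4, 4, 4, 5, 5, 7, 9], dtype=float)
    sm = _rpkm_matrix(col[:, None])
    z = zscore_normalize(sm, "per_stage_across_regions")
    assert z.values[-1, 0] == pytest.approx(2.0)  # mean 5, population sd 2
    assert z.unit == "zscore" and z.zscore_axis == "per_stage_across_regions"


def test_zscore_degenerate_and_identities(rng):
    const = _rpkm_matrix(np.full((6, 2), 3.0))
    z = zscore_normalize(const)
    assert (z.values == 0).all()
    m = _rpkm_matrix(rng.random((40, 5)) * 10)
    for axis, np_axis in [
        ("per_stage_across_regions", 0),
        ("per_region_across_stages", 1),
    ]:
        z = zscore_normalize(m, axis)
        np.testing.assert_allclose(z.values.mean(axis=np_axis), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=np_axis), 1, atol=1e-9)


def test_zscore_rejects_non_rpkm():
    sm = _rpkm_matrix(np.ones((3, 2)))
    z = zscore_normalize(sm)
    with pytest.raises(ValueError, match="rpkm"):
        zscore_normalize(z)
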