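"""Genomic interval algebra, BED/refFlat I/O, and ChIP signal quantification.

Coordinates are 0-based half-open (BED convention) everywhere. Overlap means
at least one shared base. These primitives back every downstream stage:
enhancer-universe construction, super-enhancer stitching, promoter windows,
and peak annotation.

IntervalSet stores per-chromosome numpy arrays internally so that read-scale
collections (10^5-10^6 intervals) stay cheap; GenomicInterval objects are
materialized lazily on iteration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on a chromosome.

    ``score`` doubles as a generic numeric annotation slot (BED column 5);
    some producers store read counts or constituent counts there.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Bases from a point to the nearest edge; 0 if the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


class _ChromData:
    __slots__ = ("starts", "ends", "names", "scores", "strands", "ends_sorted")

    def __init__(self, starts, ends, names, scores, strands):
        order = np.lexsort((ends, starts))
        self.starts = starts[order]
        self.ends = ends[order]
        self.names = names[order]
        self.scores = scores[order]
        self.strands = strands[order]
        self.ends_sorted = np.sort(ends)


class IntervalSet:
    """An immutable collection of intervals grouped by chromosome, sorted by
    (start, end) within each chromosome. Query operations never mutate.
    Chromosomes iterate in lexicographic order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        buf: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            buf.setdefault(iv.chrom, []).append(iv)
        self._data: dict[str, _ChromData] = {}
        for chrom in sorted(buf):
            ivs = buf[chrom]
            self._data[chrom] = _ChromData(
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
                np.array([iv.name for iv in ivs], dtype=object),
                np.array([iv.score for iv in ivs], dtype=float),
                np.array([iv.strand for iv in ivs], dtype=object),
            )

    @classmethod
    def from_arrays(
        cls,
        chrom_arrays: Mapping[str, tuple],
    ) -> "IntervalSet":
        """Bulk constructor. ``chrom_arrays`` maps chromosome name to
        (starts, ends[, names, scores, strands]) arrays; omitted columns get
        defaults. Validates the interval invariants vectorized.
        """
        obj = cls()
        for chrom in sorted(chrom_arrays):
            cols = chrom_arrays[chrom]
            starts = np.asarray(cols[0], dtype=np.int64)
            ends = np.asarray(cols[1], dtype=np.int64)
            n = len(starts)
            if n == 0:
                continue
            if (starts < 0).any():
                raise ValueError(f"{chrom}: negative start coordinate")
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: empty or inverted interval")
            names = (
                np.asarray(cols[2], dtype=object)
                if len(cols) > 2 and cols[2] is not None
                else np.full(n, ".", dtype=object)
            )
            scores = (
                np.asarray(cols[3], dtype=float)
                if len(cols) > 3 and cols[3] is not None
                else np.zeros(n)
            )
            strands = (
                np.asarray(cols[4], dtype=object)
                if len(cols) > 4 and cols[4] is not None
                else np.full(n, ".", dtype=object)
            )
            bad = ~np.isin(strands.astype(str), STRANDS)
            if bad.any():
                raise ValueError(f"{chrom}: invalid strand value")
            obj._data[chrom] = _ChromData(starts, ends, names, scores, strands)
        return obj

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return sum(len(d.starts) for d in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, d in self._data.items():
            for i in range(len(d.starts)):
                yield GenomicInterval(
                    chrom,
                    int(d.starts[i]),
                    int(d.ends[i]),
                    d.names[i],
                    float(d.scores[i]),
                    d.strands[i],
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {len(self._data)} chroms)"

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._data)

    def chrom_arrays(self, chrom: str):
        """(starts, ends, names, scores, strands) arrays for one chromosome,
        or None if absent. Arrays are internal state: do not mutate."""
        d = self._data.get(chrom)
        if d is None:
            return None
        return d.starts, d.ends, d.names, d.scores, d.strands

    def on_chrom(self, chrom: str) -> tuple[GenomicInterval, ...]:
        d = self._data.get(chrom)
        if d is None:
            return ()
        return tuple(
            GenomicInterval(
                chrom,
                int(d.starts[i]),
                int(d.ends[i]),
                d.names[i],
                float(d.scores[i]),
                d.strands[i],
            )
            for i in range(len(d.starts))
        )

    # -- queries ------------------------------------------------------------
    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of member intervals sharing >= 1 base with [start, end)."""
        d = self._data.get(chrom)
        if d is None:
            return 0
        n = len(d.starts)
        # overlap iff member.start < end and member.end > start; the two
        # excluded groups are disjoint because member.start < member.end
        n_start_beyond = n - int(np.searchsorted(d.starts, end, side="left"))
        n_end_before = int(np.searchsorted(d.ends_sorted, start, side="right"))
        return n - n_start_beyond - n_end_before

    def count_overlapping_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized count_overlapping for query interval arrays."""
        d = self._data.get(chrom)
        if d is None:
            return np.zeros(len(starts), dtype=np.int64)
        n = len(d.starts)
        n_start_beyond = n - np.searchsorted(d.starts, ends, side="left")
        n_end_before = np.searchsorted(d.ends_sorted, starts, side="right")
        return n - n_start_beyond - n_end_before

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        return self.count_overlapping(iv.chrom, iv.start, iv.end) > 0


@dataclass(frozen=True)
class GeneModel:
    """A transcript model in refFlat terms: TSS is strand-dependent."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon start/end lists differ in length")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"exon [{s},{e}) outside transcript "
                    f"[{self.tx_start},{self.tx_end}) of {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination site (the end opposite the TSS)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    def promoter_window(self, pad: int = 2500) -> GenomicInterval:
        start = max(0, self.tss - pad)
        return GenomicInterval(self.chrom, start, self.tss + pad, name=self.gene_id)


@dataclass
class SignalMatrix:
    """Region x stage quantified ChIP signal.

    Unit transitions only raw_count -> rpkm -> zscore. A z-scored matrix
    records the axis it was standardized over.
    """

    regions: list[GenomicInterval]
    stages: list[str]
    values: np.ndarray
    unit: str  # raw_count | rpkm | zscore
    library_sizes: dict[str, float] | None = None
    zscore_axis: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.stages)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.stages)} stages"
            )
        if self.unit not in ("raw_count", "rpkm", "zscore"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit in ("raw_count", "rpkm") and (self.values < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")

    @property
    def region_names(self) -> list[str]:
        return [iv.name for iv in self.regions]

    def stage_column(self, stage: str) -> np.ndarray:
        return self.values[:, self.stages.index(stage)]

    def to_frame(self):
        import pandas as pd

        idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.regions]
        return pd.DataFrame(self.values, index=idx, columns=self.stages)


# ---------------------------------------------------------------------------
# I/O


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a sorted IntervalSet.

    name/score/strand columns are preserved when present. Malformed lines
    raise with the offending line number.
    """
    intervals = []
    handle = open(path) if not isinstance(path, io.IOBase) else path
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    finally:
        if handle is not path:
            handle.close()
    return IntervalSet(intervals)


def write_bed(iset: IntervalSet, path) -> None:
    """Write BED6 (tab-separated); score serialized with %g formatting."""
    handle = open(path, "w") if not isinstance(path, io.IOBase) else path
    try:
        for chrom in iset.chroms:
            starts, ends, names, scores, strands = iset.chrom_arrays(chrom)
            for i in range(len(starts)):
                handle.write(
                    f"{chrom}\t{starts[i]}\t{ends[i]}\t{names[i]}"
                    f"\t{scores[i]:g}\t{strands[i]}\n"
                )
    finally:
        if handle is not path:
            handle.close()


def read_refflat(path) -> list[GeneModel]:
    """Parse a refFlat table (geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds) into GeneModels."""
    models = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ValueError(f"{path}: line {lineno}: fewer than 11 columns")
            exon_count = int(f[8])
            starts = tuple(int(x) for x in f[9].rstrip(",").split(",") if x)
            ends = tuple(int(x) for x in f[10].rstrip(",").split(",") if x)
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ValueError(
                    f"{path}: line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            models.append(
                GeneModel(
                    gene_id=f[0],
                    name=f[1],
                    chrom=f[2],
                    strand=f[3],
                    tx_start=int(f[4]),
                    tx_end=int(f[5]),
                    exon_starts=starts,
                    exon_ends=ends,
                )
            )
    return models


def write_refflat(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as handle:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            handle.write(
                "\t".join(
                    [
                        m.gene_id,
                        m.name,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.tx_start),
                        str(m.tx_end),
                        str(len(m.exon_starts)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Region-level exclusion: drop every interval of `a` that shares >= 1
    base with any interval of `b`; surviving intervals pass through whole.

    This is deliberately not base-level subtraction — the pipeline treats
    enhancers as discrete regions, so a candidate touching an excluded zone
    is removed entirely.
    """
    out: dict[str, tuple] = {}
    for chrom in a.chroms:
        starts, ends, names, scores, strands = a.chrom_arrays(chrom)
        hits = b.count_overlapping_many(chrom, starts, ends)
        keep = hits == 0
        if keep.any():
            out[chrom] = (
                starts[keep],
                ends[keep],
                names[keep],
                scores[keep],
                strands[keep],
            )
    return IntervalSet.from_arrays(out)


def merge_within_gap(a: IntervalSet, max_gap: int) -> IntervalSet:
    """Transitively merge same-chromosome intervals whose end-to-start gap is
    <= max_gap. Output intervals are disjoint and sorted; each records its
    constituent count in ``score``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: dict[str, tuple] = {}
    for chrom in a.chroms:
        starts, ends, *_ = a.chrom_arrays(chrom)
        m_starts, m_ends, m_counts = [], [], []
        cur_start, cur_end, n = int(starts[0]), int(ends[0]), 1
        for s, e in zip(starts[1:], ends[1:]):
            if int(s) - cur_end <= max_gap:
                cur_end = max(cur_end, int(e))
                n += 1
            else:
                m_starts.append(cur_start)
                m_ends.append(cur_end)
                m_counts.append(n)
                cur_start, cur_end, n = int(s), int(e), 1
        m_starts.append(cur_start)
        m_ends.append(cur_end)
        m_counts.append(n)
        out[chrom] = (
            np.array(m_starts, dtype=np.int64),
            np.array(m_ends, dtype=np.int64),
            None,
            np.array(m_counts, dtype=float),
            None,
        )
    return IntervalSet.from_arrays(out)


def merge_with_constituents(
    a: IntervalSet, max_gap: int
) -> list[tuple[GenomicInterval, list[GenomicInterval]]]:
    """Like merge_within_gap but returns (merged span, constituent list) pairs."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[tuple[GenomicInterval, list[GenomicInterval]]] = []
    for chrom in a.chroms:
        ivs = a.on_chrom(chrom)
        cur: list[GenomicInterval] = [ivs[0]]
        cur_end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur.append(iv)
                cur_end = max(cur_end, iv.end)
            else:
                span = GenomicInterval(chrom, cur[0].start, cur_end, score=len(cur))
                out.append((span, cur))
                cur, cur_end = [iv], iv.end
        span = GenomicInterval(chrom, cur[0].start, cur_end, score=len(cur))
        out.append((span, cur))
    return out


def extend_reads_coverage(reads: IntervalSet, extension: int) -> IntervalSet:
    """Replace each read by a fixed-length interval anchored at its 5' end in
    strand direction (the standard fragment-length extension for ChIP
    coverage), clipped at position 0.
    """
    if extension <= 0:
        raise ValueError("extension must be > 0")
    out: dict[str, tuple] = {}
    for chrom in reads.chroms:
        starts, ends, names, scores, strands = reads.chrom_arrays(chrom)
        s_arr = strands.astype(str)
        if (s_arr == ".").any():
            raise ValueError(f"unstranded read on {chrom}: cannot extend")
        plus = s_arr == "+"
        new_starts = np.where(plus, starts, np.maximum(0, ends - extension))
        new_ends = np.where(plus, starts + extension, ends)
        out[chrom] = (new_starts, new_ends, names, scores, strands)
    return IntervalSet.from_arrays(out)


def count_reads_in_regions(
    regions: Sequence[GenomicInterval], reads: IntervalSet
) -> np.ndarray:
    """Per-region count of reads overlapping by >= 1 base."""
    regions = list(regions)
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        starts = np.array([regions[i].start for i in idx], dtype=np.int64)
        ends = np.array([regions[i].end for i in idx], dtype=np.int64)
        counts[idx] = reads.count_overlapping_many(chrom, starts, ends)
    return counts


def quantify_rpkm(
    regions: Sequence[GenomicInterval],
    reads_per_stage: Mapping[str, IntervalSet] | None = None,
    counts: np.ndarray | None = None,
    library_sizes: Mapping[str, float] | None = None,
    stages: Sequence[str] | None = None,
) -> SignalMatrix:
    """Reads Per Kilobase of region per Million sequenced reads.

    value = count / (region length in kb * library size in millions).
    Reads may arrive either as interval sets per stage or as a precomputed
    region x stage count matrix (``counts`` with ``stages``). When reads are
    supplied and library sizes are not, each stage's read count is used.
    """
    regions = list(regions)
    if reads_per_stage is not None:
        stages = list(reads_per_stage)
        counts = np.column_stack(
            [count_reads_in_regions(regions, reads_per_stage[s]) for s in stages]
        ).astype(float)
        if library_sizes is None:
            library_sizes = {s: len(reads_per_stage[s]) for s in stages}
    else:
        if counts is None or stages is None:
            raise ValueError("either reads_per_stage or (counts, stages) required")
        stages = list(stages)
        counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        raise ValueError("library_sizes required with a count matrix")
    lib = np.array([float(library_sizes[s]) for s in stages])
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    lengths_kb = np.array([len(r) / 1000.0 for r in regions])
    if len(regions) and (lengths_kb <= 0).any():
        raise ValueError("region lengths must be > 0")
    values = counts / lengths_kb[:, None] / (lib[None, :] / 1e6)
    return SignalMatrix(
        regions=regions,
        stages=stages,
        values=values,
        unit="rpkm",
        library_sizes={s: float(library_sizes[s]) for s in stages},
    )


def zscore_normalize(
    m: SignalMatrix, axis: str = "per_stage_across_regions"
) -> SignalMatrix:
    """Z-score transform of an RPKM matrix with population standard deviation.

    axis = per_stage_across_regions standardizes each stage column (the
    default, which damps batch/stage depth variation); axis =
    per_region_across_stages standardizes each region's profile. Degenerate
    (constant) slices map to z = 0 so downstream thresholds stay finite.
    """
    if m.unit != "rpkm":
        raise ValueError(f"zscore_normalize expects rpkm input, got {m.unit}")
    if axis == "per_stage_across_regions":
        np_axis = 0
    elif axis == "per_region_across_stages":
        np_axis = 1
    else:
        raise ValueError(f"unknown axis {axis!r}")
    mean = m.values.mean(axis=np_axis, keepdims=True)
    sd = m.values.std(axis=np_axis, keepdims=True)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m.values - mean) / sd
    z = np.where(np.broadcast_to(sd == 0, z.shape), 0.0, z)
    return SignalMatrix(
        regions=m.regions,
        stages=list(m.stages),
        values=z,
        unit="zscore",
        library_sizes=m.library_sizes,
        zscore_axis=axis,
    )
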