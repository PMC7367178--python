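"""Genomic interval arithmetic and signal quantification.

Primitives shared by every downstream stage: merged interval sets with
base-pair overlap arithmetic, fragment counting with RPKM normalisation,
stepwise signal tracks (bedGraph semantics) and metaplot binning.

All intervals are 0-based half-open.  Overlap is counted at single-base
resolution: two spans overlap iff they share >= 1 base.  Adjacent intervals
(gap 0) merge into one — the union-peak convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomeSpec

Interval = tuple[str, int, int]


class IntervalSet:
    """Per-chromosome sorted, merged collection of half-open spans.

    Construction merges overlapping and adjacent input spans, so the
    stored representation is always the minimal disjoint cover of the
    input union.
    """

    def __init__(
        self,
        intervals: Iterable[Interval] = (),
        genome: GenomeSpec | None = None,
    ) -> None:
        self.genome = genome
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if genome is not None:
                genome.validate_interval(chrom, start, end)
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            starts, ends = _merge_sorted(arr[:, 0], arr[:, 1])
            self._spans[chrom] = (starts, ends)

    @classmethod
    def _from_spans(
        cls,
        spans: Mapping[str, tuple[np.ndarray, np.ndarray]],
        genome: GenomeSpec | None,
    ) -> "IntervalSet":
        out = cls.__new__(cls)
        out.genome = genome
        out._spans = dict(spans)
        return out

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._spans))

    def spans(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays on ``chrom`` (empty arrays if absent)."""
        if chrom in self._spans:
            return self._spans[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def __iter__(self):
        for chrom in self.chroms:
            starts, ends = self._spans[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield (chrom, s, e)

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._spans.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def total_covered_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._spans.values())
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        _check_same_genome(self, other)
        return IntervalSet(list(self) + list(other), genome=self.genome or other.genome)

    def overlap_bp(self, other: "IntervalSet") -> int:
        return overlap_bp(self, other)

    def overlaps_any(self, chrom: str, start: int, end: int, min_bp: int = 1) -> bool:
        return overlaps_any((chrom, start, end), self, min_bp=min_bp)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-wise intersection as a new IntervalSet."""
        _check_same_genome(self, other)
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self._spans:
            if chrom not in other._spans:
                continue
            s = _intersect_sorted(*self._spans[chrom], *other._spans[chrom])
            if len(s[0]):
                out[chrom] = s
        return IntervalSet._from_spans(out, self.genome or other.genome)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start spans; adjacency (gap 0) merges too."""
    if len(starts) == 0:
        return starts, ends
    keep_start = [int(starts[0])]
    keep_end = [int(ends[0])]
    for s, e in zip(starts[1:].tolist(), ends[1:].tolist()):
        if s <= keep_end[-1]:  # overlap or adjacency
            keep_end[-1] = max(keep_end[-1], e)
        else:
            keep_start.append(s)
            keep_end.append(e)
    return np.array(keep_start, dtype=np.int64), np.array(keep_end, dtype=np.int64)


def _intersect_sorted(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    out_s, out_e = [], []
    i = j = 0
    while i < len(a_s) and j < len(b_s):
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if a_e[i] <= b_e[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValueError("interval sets belong to different genomes")


def merge(intervals: Iterable[Interval], genome: GenomeSpec | None = None) -> IntervalSet:
    """Minimal disjoint cover of the union of ``intervals``."""
    return IntervalSet(intervals, genome=genome)


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total shared bases between two interval sets (symmetric)."""
    _check_same_genome(a, b)
    total = 0
    for chrom in a._spans:
        if chrom not in b._spans:
            continue
        s, e = _intersect_sorted(*a._spans[chrom], *b._spans[chrom])
        total += int((e - s).sum())
    return total


def overlaps_any(query: Interval, subject: IntervalSet, min_bp: int = 1) -> bool:
    """True iff ``query`` shares at least ``min_bp`` bases with ``subject``."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    chrom, qs, qe = query
    starts, ends = subject.spans(chrom)
    if len(starts) == 0:
        return False
    lo = np.maximum(starts, qs)
    hi = np.minimum(ends, qe)
    return int(np.clip(hi - lo, 0, None).sum()) >= min_bp


class FragmentIndex:
    """Sorted index over aligned fragments on one genome, for O(log n) counting.

    Counting uses the >= 1 bp overlap rule: a fragment [fs, fe) overlaps a
    region [s, e) iff fs < e and fe > s.
    """

    def __init__(self, fragments: Iterable[Interval], genome: GenomeSpec | None = None):
        self.genome = genome
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for chrom, start, end in fragments:
            if start >= end:
                raise ValueError(f"empty fragment {chrom}:{start}-{end}")
            if genome is not None:
                genome.validate_interval(chrom, start, end)
            by_chrom.setdefault(chrom, []).append((start, end))
            n += 1
        self.n_fragments = n
        # starts and ends sorted independently: count(start<e) - count(end<=s)
        self._starts = {
            c: np.sort(np.array([p[0] for p in v], dtype=np.int64))
            for c, v in by_chrom.items()
        }
        self._ends = {
            c: np.sort(np.array([p[1] for p in v], dtype=np.int64))
            for c, v in by_chrom.items()
        }

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._starts:
            return 0
        starts = self._starts[chrom]
        ends = self._ends[chrom]
        n_start_before_end = int(np.searchsorted(starts, end, side="left"))
        n_end_at_or_before_start = int(np.searchsorted(ends, start, side="right"))
        return n_start_before_end - n_end_at_or_before_start

    def count_many(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorised `count_overlapping` over parallel start/end arrays."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=np.int64)
        fs = self._starts[chrom]
        fe = self._ends[chrom]
        return np.searchsorted(fs, ends, side="left") - np.searchsorted(
            fe, starts, side="right"
        )


def quantify_rpkm(
    region: Interval,
    fragments: FragmentIndex,
    library_size: int,
) -> float:
    """Reads-per-kilobase-per-million quantification of one region.

    RPKM = overlapping-fragment count * 1e9 / (library_size * region length).
    """
    chrom, start, end = region
    length = end - start
    if length <= 0:
        raise ValueError("zero-length region")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    count = fragments.count_overlapping(chrom, start, end)
    return count * 1e9 / (library_size * length)


@dataclass
class SignalTrack:
    """Stepwise per-base signal (bedGraph semantics): value 0 off-step.

    steps: chrom -> (starts, ends, values) sorted, non-overlapping.
    """

    genome: GenomeSpec
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    library_size: int | None = None

    def __post_init__(self) -> None:
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in self.steps.items():
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping bedGraph steps on {chrom}")
            area = (ends - starts).astype(np.float64) * values
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(area)])

    @classmethod
    def from_steps(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        genome: GenomeSpec,
        library_size: int | None = None,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            genome.validate_interval(chrom, start, end)
            by_chrom.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            steps[chrom] = (starts, ends, values)
        return cls(genome=genome, steps=steps, library_size=library_size)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); uncovered bases are 0."""
        if chrom not in self.steps:
            return 0.0
        starts, ends, values = self.steps[chrom]
        cum = self._cum[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        total = float(cum[j] - cum[i])
        # trim partial coverage at both flanks
        if starts[i] < start:
            total -= (start - starts[i]) * float(values[i])
        if ends[j - 1] > end:
            total -= (ends[j - 1] - end) * float(values[j - 1])
        return total

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return self.integral(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean value per bin; bins partition [start, end) left-closed with the
        trailing remainder folded into the last bin."""
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        width = (end - start) // n_bins
        if width < 1:
            raise ValueError("window narrower than bin count")
        edges = [start + k * width for k in range(n_bins)] + [end]
        return np.array(
            [self.mean(chrom, edges[k], edges[k + 1]) for k in range(n_bins)]
        )


def metaplot_matrix(
    regions: Sequence[Interval],
    track: SignalTrack,
    flank_bp: int,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean-signal matrix around region centres.

    Row i holds the binned mean depth over ``[center_i - flank, center_i +
    flank)``; the column means give the metaplot curve.  Regions whose
    window would extend past a chromosome edge are skipped (the count of
    skipped regions is returned and a warning emitted).

    Returns
    -------
    (matrix, column_means, n_skipped)
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not regions:
        raise ValueError("no regions supplied")
    rows = []
    skipped = 0
    for chrom, start, end in regions:
        center = (start + end) // 2
        lo, hi = center - flank_bp, center + flank_bp
        if lo < 0 or hi > track.genome.length_of(chrom):
            skipped += 1
            continue
        rows.append(track.binned_means(chrom, lo, hi, n_bins))
    if skipped:
        warnings.warn(f"metaplot: skipped {skipped} region(s) at chromosome edges")
    if not rows:
        raise ValueError("all regions fell off chromosome edges")
    matrix = np.vstack(rows)
    return matrix, matrix.mean(axis=0), skipped
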