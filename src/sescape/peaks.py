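"""Peak filtering, union-peak differential binding, and gene assignment.

The differential rule follows the fold-change-only convention: a union
peak is up-regulated in KO when its KO RPKM exceeds twice the WT RPKM and
down-regulated when it falls below WT/1.5, with a small pseudocount
stabilising ratios at near-zero WT signal.  All threshold comparisons are
strict, so boundary values are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import FragmentIndex, Interval, IntervalSet, SignalTrack, quantify_rpkm
from .io import GeneRecord, PeakRecord

DEFAULT_MIN_NEG_LOG10_P = 9.0
DEFAULT_MIN_FOLD_ENRICHMENT = 3.0
DEFAULT_PSEUDOCOUNT_RPKM = 0.25
UP_FOLD = 2.0
DOWN_FOLD = 1.5


def filter_peaks(
    peaks: Sequence[PeakRecord],
    min_neg_log10_p: float = DEFAULT_MIN_NEG_LOG10_P,
    min_fold_enrichment: float = DEFAULT_MIN_FOLD_ENRICHMENT,
) -> list[PeakRecord]:
    """Retain peaks with -log10 P strictly above ``min_neg_log10_p`` and
    fold enrichment strictly above ``min_fold_enrichment``."""
    if min_neg_log10_p < 0 or min_fold_enrichment < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        p
        for p in peaks
        if p.neg_log10_p > min_neg_log10_p and p.fold_enrichment > min_fold_enrichment
    ]


@dataclass(frozen=True)
class UnionPeak:
    chrom: str
    start: int
    end: int
    contributors: frozenset[str]

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


def union_peaks(
    peaks_wt: Sequence[PeakRecord], peaks_ko: Sequence[PeakRecord]
) -> list[UnionPeak]:
    """Merged union of two filtered peak sets, recording which condition(s)
    contributed to each merged span."""
    wt_set = IntervalSet(p.interval for p in peaks_wt)
    ko_set = IntervalSet(p.interval for p in peaks_ko)
    union = IntervalSet([p.interval for p in peaks_wt] + [p.interval for p in peaks_ko])
    out = []
    for chrom, start, end in union:
        contrib = set()
        if wt_set.overlaps_any(chrom, start, end):
            contrib.add("WT")
        if ko_set.overlaps_any(chrom, start, end):
            contrib.add("KO")
        out.append(UnionPeak(chrom, start, end, frozenset(contrib)))
    return out


@dataclass(frozen=True)
class DifferentialPeak:
    """A union peak classified by KO/WT RPKM fold change."""

    chrom: str
    start: int
    end: int
    rpkm_wt: float
    rpkm_ko: float
    ratio: float
    klass: str  # up | down | unchanged
    contributors: frozenset[str] = field(default_factory=frozenset)

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


def _classify_ratio(ratio: float) -> str:
    if ratio > UP_FOLD:
        return "up"
    if ratio < 1.0 / DOWN_FOLD:
        return "down"
    return "unchanged"


def classify_differential(
    union_peak: UnionPeak | Interval,
    fragments_wt: FragmentIndex,
    fragments_ko: FragmentIndex,
    lib_wt: int,
    lib_ko: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPKM,
) -> DifferentialPeak:
    """Classify one union peak as up / down / unchanged in KO vs WT.

    ratio = (RPKM_KO + eps) / (RPKM_WT + eps); up iff ratio > 2, down iff
    ratio < 1/1.5, else unchanged (strict comparisons).
    """
    if isinstance(union_peak, UnionPeak):
        chrom, start, end = union_peak.interval
        contributors = union_peak.contributors
    else:
        chrom, start, end = union_peak
        contributors = frozenset()
    rpkm_wt = quantify_rpkm((chrom, start, end), fragments_wt, lib_wt)
    rpkm_ko = quantify_rpkm((chrom, start, end), fragments_ko, lib_ko)
    ratio = (rpkm_ko + pseudocount) / (rpkm_wt + pseudocount)
    return DifferentialPeak(
        chrom, start, end, rpkm_wt, rpkm_ko, ratio, _classify_ratio(ratio), contributors
    )


def classify_differential_many(
    union: Sequence[UnionPeak],
    fragments_wt: FragmentIndex,
    fragments_ko: FragmentIndex,
    lib_wt: int,
    lib_ko: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_RPKM,
) -> list[DifferentialPeak]:
    return [
        classify_differential(u, fragments_wt, fragments_ko, lib_wt, lib_ko, pseudocount)
        for u in union
    ]


def assign_peaks_to_genes(
    peaks: Sequence[Interval] | Sequence[UnionPeak],
    genes: Sequence[GeneRecord],
    window_bp: int = 50_000,
) -> tuple[dict[int, list[str]], dict[str, list[int]]]:
    """Assign each peak to every gene whose TSS lies within ``window_bp``
    of the peak span (distance 0 when the TSS falls inside the peak).

    Returns (peak index -> gene ids, gene id -> peak indices); a peak may
    map to several genes and vice versa.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    peak_to_genes: dict[int, list[str]] = {}
    gene_to_peaks: dict[str, list[int]] = {}
    ivals = [p.interval if isinstance(p, (UnionPeak, DifferentialPeak)) else p for p in peaks]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, (chrom, start, end) in enumerate(ivals):
        by_chrom.setdefault(chrom, []).append((start, end, idx))
    for g in genes:
        tss = g.tss
        for start, end, idx in by_chrom.get(g.chrom, ()):
            if start <= tss < end:
                dist = 0
            elif tss < start:
                dist = start - tss
            else:
                dist = tss - (end - 1)
            if dist <= window_bp:
                peak_to_genes.setdefault(idx, []).append(g.gene_id)
                gene_to_peaks.setdefault(g.gene_id, []).append(idx)
    return peak_to_genes, gene_to_peaks


@dataclass(frozen=True)
class SignalChangeCorrelation:
    factor: str
    r: float | None  # None when a log-fold-change vector has zero variance
    p_value: float | None
    n: int


def signal_change_correlation(
    union: Sequence[UnionPeak] | Sequence[Interval],
    track_pairs: Mapping[str, tuple[SignalTrack, SignalTrack]],
    pseudocount: float = 0.5,
    reference: str = "YAP",
) -> dict[str, SignalChangeCorrelation]:
    """Pearson correlation of per-peak log2 fold changes between the
    reference factor and every other factor.

    For each union peak and factor, LFC = log2((KO + eps) / (WT + eps))
    where the signals are track means over the peak span.  Degenerate
    (zero-variance) LFC vectors yield r = None rather than a NaN crash.
    """
    if len(union) < 3:
        raise ValueError("need at least 3 union peaks")
    if reference not in track_pairs:
        raise ValueError(f"reference factor {reference!r} missing from track_pairs")
    ivals = [u.interval if isinstance(u, UnionPeak) else u for u in union]
    lfcs: dict[str, np.ndarray] = {}
    for factor, (wt, ko) in track_pairs.items():
        vals = np.array(
            [
                math.log2((ko.mean(c, s, e) + pseudocount) / (wt.mean(c, s, e) + pseudocount))
                for c, s, e in ivals
            ]
        )
        lfcs[factor] = vals
    ref = lfcs[reference]
    out: dict[str, SignalChangeCorrelation] = {}
    for factor, vec in lfcs.items():
        if factor == reference:
            continue
        if np.std(ref) == 0.0 or np.std(vec) == 0.0:
            out[factor] = SignalChangeCorrelation(factor, None, None, len(vec))
            continue
        r, p = stats.pearsonr(ref, vec)
        out[factor] = SignalChangeCorrelation(factor, float(r), float(p), len(vec))
    return out
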