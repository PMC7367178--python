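"""ROSE-style super-enhancer identification and cross-condition comparison.

The procedure follows Rank Ordering of Super-Enhancers: enhancer peaks
whose gaps are at most the stitching distance (canonically 12.5 kb) are
merged into candidate regions; each region is scored by input-subtracted
H3K27ac density times its length; regions are ranked and the ranked curve,
rescaled to the unit square, is split at the geometric inflection point —
the first rank where the discrete slope exceeds 1.  Regions above the
cutoff signal are super-enhancers (SEs), the rest typical enhancers (TEs).

Across two conditions, an SE is unique to a condition when its H3K27ac
signal over the same span is more than 2-fold higher there than in the
other condition; otherwise it is common.  SEs are also annotated with the
factors whose peaks overlap them by at least one base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import FragmentIndex, Interval, IntervalSet
from .io import GeneRecord, PeakRecord

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500
UNIQUE_SE_FOLD = 2.0


@dataclass
class StitchedRegion:
    """A stitched candidate enhancer region (the ROSE unit)."""

    chrom: str
    start: int
    end: int
    constituents: list[int]  # indices into the input peak list
    signal: float = 0.0
    rank: int | None = None  # 1 = strongest
    is_super: bool = False

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def tss_windows(genes: Sequence[GeneRecord], half_width: int = DEFAULT_TSS_EXCLUSION) -> IntervalSet:
    """TSS +/- half_width exclusion windows, clipped at chromosome starts."""
    spans = []
    for g in genes:
        spans.append((g.chrom, max(0, g.tss - half_width), g.tss + half_width + 1))
    return IntervalSet(spans)


def stitch(
    peaks: Sequence[PeakRecord],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: IntervalSet | None = None,
) -> list[StitchedRegion]:
    """Merge peaks whose inter-peak gap is <= ``stitch_distance`` (transitively).

    With ``tss_exclusion`` given, peaks fully inside an exclusion window
    are dropped before stitching (the promoter-proximal filter ROSE calls
    -t); exclusion is off by default.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    kept: list[tuple[int, PeakRecord]] = []
    for idx, p in enumerate(peaks):
        if tss_exclusion is not None:
            starts, ends = tss_exclusion.spans(p.chrom)
            i = np.searchsorted(starts, p.start, side="right") - 1
            if i >= 0 and p.start >= starts[i] and p.end <= ends[i]:
                continue
        kept.append((idx, p))
    by_chrom: dict[str, list[tuple[int, PeakRecord]]] = {}
    for idx, p in kept:
        by_chrom.setdefault(p.chrom, []).append((idx, p))
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[1].start, t[1].end))
        current: StitchedRegion | None = None
        for idx, p in items:
            if current is not None and p.start - current.end <= stitch_distance:
                current.end = max(current.end, p.end)
                current.constituents.append(idx)
            else:
                current = StitchedRegion(chrom, p.start, p.end, [idx])
                regions.append(current)
    return regions


def score_region(
    region: StitchedRegion | Interval,
    treat_fragments: FragmentIndex,
    input_fragments: FragmentIndex,
    lib_treat: int,
    lib_input: int,
) -> float:
    """Input-subtracted signal: max(0, RPKM_treat - RPKM_input) * length in kb.

    The unit (RPKM x kb) is invariant under any common positive rescaling
    of both libraries, so ranks do not depend on sequencing depth.
    """
    if lib_treat <= 0 or lib_input <= 0:
        raise ValueError("library sizes must be positive")
    chrom, start, end = (
        region.interval if isinstance(region, StitchedRegion) else region
    )
    length = end - start
    rpkm_t = treat_fragments.count_overlapping(chrom, start, end) * 1e9 / (lib_treat * length)
    rpkm_i = input_fragments.count_overlapping(chrom, start, end) * 1e9 / (lib_input * length)
    return max(0.0, rpkm_t - rpkm_i) * (length / 1000.0)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    rank_index: int | None  # index into the ascending-sorted signals, None if no crossing
    n_regions: int
    n_super: int


def find_cutoff(signals: Sequence[float]) -> CutoffResult:
    """Geometric inflection point of the ranked-signal (hockey-stick) curve.

    Signals are sorted ascending and both axes rescaled to [0, 1].  The
    cutoff sits where a line of slope 1 is tangent to the rescaled curve —
    equivalently, at the rank maximising x - y, the point after which the
    curve rises faster than the diagonal.  Ties break toward the smaller
    rank (more SEs).  Regions with signal strictly above the cutoff are
    super-enhancers.  A flat curve (all signals equal) has no inflection:
    the cutoff is the maximum and no region passes, with a warning.
    """
    sig = np.asarray(signals, dtype=np.float64)
    n = len(sig)
    if n < 3:
        raise ValueError("need at least 3 regions to locate an inflection point")
    order = np.sort(sig)
    lo, hi = order[0], order[-1]
    if hi == lo:
        warnings.warn("all region signals equal; no inflection point, zero SEs")
        return CutoffResult(cutoff=float(hi), rank_index=None, n_regions=n, n_super=0)
    x = np.arange(n, dtype=np.float64) / (n - 1)
    y = (order - lo) / (hi - lo)
    idx = int(np.argmax(x - y))  # argmax takes the first maximum: smaller rank
    cutoff = float(order[idx])
    n_super = int((sig > cutoff).sum())
    return CutoffResult(cutoff=cutoff, rank_index=idx, n_regions=n, n_super=n_super)


def rank_regions(regions: list[StitchedRegion]) -> None:
    """Assign 1-based descending-signal ranks and is_super flags in place
    (call after signals are set and a cutoff found)."""
    for r, region in enumerate(
        sorted(regions, key=lambda rg: -rg.signal), start=1
    ):
        region.rank = r


@dataclass
class ConditionSE:
    regions: list[StitchedRegion]
    cutoff: CutoffResult
    library_treat: int
    library_input: int


@dataclass
class SECall:
    """Two-condition SE call: per-condition stitched regions plus the
    cross-condition SE table (one row per SE in either condition)."""

    conditions: tuple[str, str]
    per_condition: dict[str, ConditionSE]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def call_condition(
    peaks: Sequence[PeakRecord],
    treat_fragments: FragmentIndex,
    input_fragments: FragmentIndex,
    lib_treat: int,
    lib_input: int,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: IntervalSet | None = None,
) -> ConditionSE:
    """Stitch -> score -> rank -> split one condition's enhancer landscape."""
    regions = stitch(peaks, stitch_distance=stitch_distance, tss_exclusion=tss_exclusion)
    if len(regions) < 3:
        raise ValueError("too few stitched regions to rank")
    for region in regions:
        region.signal = score_region(
            region, treat_fragments, input_fragments, lib_treat, lib_input
        )
    cut = find_cutoff([r.signal for r in regions])
    for region in regions:
        region.is_super = region.signal > cut.cutoff
    rank_regions(regions)
    return ConditionSE(regions, cut, lib_treat, lib_input)


def call_ses(
    peaks_by_condition: Mapping[str, Sequence[PeakRecord]],
    treat_by_condition: Mapping[str, FragmentIndex],
    input_by_condition: Mapping[str, FragmentIndex],
    libs_treat: Mapping[str, int],
    libs_input: Mapping[str, int],
    factor_peaks: Mapping[str, IntervalSet] | None = None,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: IntervalSet | None = None,
    fold_pseudocount: float = 1.0,
) -> SECall:
    """Call SEs in two conditions and classify each as condition-unique or
    common by the fold > 2 rule.

    For every SE the H3K27ac signal over its exact span is recomputed in
    both conditions; the SE is unique to its home condition iff
    (signal_home + eps) / (signal_other + eps) > 2.  Whether the span also
    overlaps an SE called in the other condition is recorded for users but
    does not enter the rule.
    """
    conds = tuple(peaks_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    for cond in conds:
        for store, label in (
            (treat_by_condition, "treat fragments"),
            (input_by_condition, "input fragments"),
        ):
            if cond not in store:
                raise ValueError(f"missing {label} for condition {cond!r}")
    per_condition = {
        cond: call_condition(
            peaks_by_condition[cond],
            treat_by_condition[cond],
            input_by_condition[cond],
            libs_treat[cond],
            libs_input[cond],
            stitch_distance=stitch_distance,
            tss_exclusion=tss_exclusion,
        )
        for cond in conds
    }
    rows = []
    for cond in conds:
        other = conds[1] if cond == conds[0] else conds[0]
        other_ses = IntervalSet(
            r.interval for r in per_condition[other].regions if r.is_super
        ) if any(r.is_super for r in per_condition[other].regions) else None
        for region in per_condition[cond].regions:
            if not region.is_super:
                continue
            sig_home = region.signal
            sig_other = score_region(
                region.interval,
                treat_by_condition[other],
                input_by_condition[other],
                libs_treat[other],
                libs_input[other],
            )
            fold = (sig_home + fold_pseudocount) / (sig_other + fold_pseudocount)
            unique_to = cond if fold > UNIQUE_SE_FOLD else "common"
            matched = (
                other_ses is not None
                and other_ses.overlaps_any(*region.interval)
            )
            bound = []
            if factor_peaks:
                bound = [
                    f
                    for f in sorted(factor_peaks)
                    if factor_peaks[f].overlaps_any(*region.interval)
                ]
            rows.append(
                {
                    "condition": cond,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "n_constituents": len(region.constituents),
                    "signal": sig_home,
                    "signal_other": sig_other,
                    "fold": fold,
                    "unique_to": unique_to,
                    "called_in_other": bool(matched),
                    "bound_by": ",".join(bound),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "condition", "chrom", "start", "end", "n_constituents", "signal",
            "signal_other", "fold", "unique_to", "called_in_other", "bound_by",
        ],
    )
    return SECall(conditions=conds, per_condition=per_condition, table=table)
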