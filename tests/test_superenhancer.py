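"""Stitching, region scoring, inflection cutoff, two-condition SE calls."""

import numpy as np
import pytest

from sescape import io as sio
from sescape.intervals import FragmentIndex, IntervalSet
from sescape.io import GeneRecord, PeakRecord
from sescape.peaks import filter_peaks
from sescape.superenhancer import (
    call_condition,
    call_ses,
    find_cutoff,
    score_region,
    stitch,
    tss_windows,
)


def peak(start, end, chrom="chr1"):
    return PeakRecord(chrom, start, end, f"p{start}", 15.0, 12.0)


def brute_force_stitch(spans, distance):
    """O(n^2) transitive closure: two peaks share a region iff a chain of
    gaps <= distance connects them."""
    n = len(spans)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            ci, cj = spans[i], spans[j]
            if ci[0] != cj[0]:
                continue
            gap = max(ci[1], cj[1]) - min(ci[2], cj[2])
            if gap <= distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(spans[i])
    regions = sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    )
    return regions


class TestStitch:
    def test_gap_rule(self):
        regions = stitch([peak(0, 500), peak(10_000, 10_500), peak(30_000, 30_500)])
        assert [(r.start, r.end) for r in regions] == [(0, 10_500), (30_000, 30_500)]

    def test_single_peak(self):
        (r,) = stitch([peak(100, 600)])
        assert (r.start, r.end) == (100, 600)
        assert r.constituents == [0]

    def test_matches_transitive_closure_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(1, 120))
            spans = [
                (f"chr{int(rng.integers(1, 3))}", int(s), int(s) + int(w))
                for s, w in zip(
                    rng.integers(0, 400_000, n), rng.integers(50, 2_000, n)
                )
            ]
            peaks = [peak(s, e, chrom=c) for c, s, e in spans]
            dist = int(rng.integers(0, 20_000))
            got = sorted((r.chrom, r.start, r.end) for r in stitch(peaks, dist))
            assert got == brute_force_stitch(spans, dist)

    def test_tss_exclusion_drops_contained_peaks(self):
        genes = [GeneRecord("g", "chr1", 10_000, 20_000, "+")]
        windows = tss_windows(genes, 2_500)
        peaks = [peak(9_000, 9_500), peak(50_000, 50_500)]
        kept = stitch(peaks, tss_exclusion=windows)
        assert [(r.start, r.end) for r in kept] == [(50_000, 50_500)]


class TestScoreRegion:
    def test_input_subtracted_rpkm_times_length(self):
        # region 10 kb; treat 100/1e6 -> RPKM 10; input 20/1e6 -> RPKM 2
        region = ("chr1", 0, 10_000)
        treat = FragmentIndex([("chr1", 0, 100)] * 100)
        ctrl = FragmentIndex([("chr1", 0, 100)] * 20)
        sig = score_region(region, treat, ctrl, 1_000_000, 1_000_000)
        assert sig == pytest.approx(80.0)

    def test_floored_at_zero_when_input_dominates(self):
        region = ("chr1", 0, 10_000)
        treat = FragmentIndex([("chr1", 0, 100)] * 5)
        ctrl = FragmentIndex([("chr1", 0, 100)] * 50)
        assert score_region(region, treat, ctrl, 1_000_000, 1_000_000) == 0.0


def brute_force_tangent(signals):
    """Independent O(n^2) search for the slope-1 tangent point: the rank
    whose unit-slope line leaves the fewest points below it."""
    order = sorted(signals)
    n = len(order)
    lo, hi = order[0], order[-1]
    x = [i / (n - 1) for i in range(n)]
    y = [(s - lo) / (hi - lo) for s in order]
    best, best_count = 0, n + 1
    for i in range(n):
        c = sum(1 for j in range(n) if y[j] < y[i] + (x[j] - x[i]))
        if c < best_count:
            best, best_count = i, c
    return best


class TestFindCutoff:
    def test_extreme_elbow_yields_one_se(self):
        res = find_cutoff([1.0] * 99 + [100.0])
        assert res.n_super == 1
        assert res.cutoff == 1.0

    def test_flat_curve_has_no_ses(self):
        with pytest.warns(UserWarning, match="no inflection"):
            res = find_cutoff([5.0] * 10)
        assert res.n_super == 0

    def test_two_regime_curve_hits_analytic_kink(self):
        for n, t, s1 in [(100, 0.8, 0.3), (400, 0.9, 0.5), (57, 0.7, 0.1)]:
            s2 = (1 - s1 * t) / (1 - t)
            x = np.arange(n) / (n - 1)
            y = np.where(x <= t, s1 * x, s1 * t + s2 * (x - t))
            signals = 3.0 + 40.0 * y  # arbitrary affine de-rescaling
            res = find_cutoff(signals)
            assert abs(res.rank_index - round(t * (n - 1))) <= 1

    def test_matches_brute_force_tangent_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            signals = np.sort(rng.gamma(1.5, 10.0, n))
            signals[-max(1, n // 20):] *= 10  # heavy top
            if signals[0] == signals[-1]:
                continue
            res = find_cutoff(signals)
            assert res.rank_index == brute_force_tangent(signals)

    def test_needs_three_regions(self):
        with pytest.raises(ValueError):
            find_cutoff([1.0, 2.0])


class TestRankMonotonicity:
    def test_more_treat_fragments_never_lowers_rank(self):
        peaks = [peak(i * 40_000, i * 40_000 + 500) for i in range(8)]
        ctrl = FragmentIndex([("chr1", 0, 100)] * 10)

        def ranks(counts):
            frags = []
            for p, c in zip(peaks, counts):
                frags += [("chr1", p.start, p.start + 200)] * c
            cond = call_condition(peaks, FragmentIndex(frags), ctrl, 10_000, 10_000)
            by_start = {r.start: r.rank for r in cond.regions}
            return [by_start[p.start] for p in peaks]

        counts = [5, 10, 20, 40, 80, 160, 320, 640]
        before = ranks(counts)
        counts[2] = 3000  # boost one region far beyond the rest
        after = ranks(counts)
        assert after[2] <= before[2]


class TestCallSes:
    def test_common_and_bound_by_on_constructed_landscape(self):
        # three well-separated regions; one shared strong SE with fold 1
        peaks = {
            c: [peak(0, 1000), peak(100_000, 101_000), peak(200_000, 201_000)]
            for c in ("wt", "ko")
        }
        frags = []
        for start, n in [(0, 30), (100_000, 30), (200_000, 1200)]:
            frags += [("chr1", start, start + 200)] * n
        fr = FragmentIndex(frags)
        ctrl = FragmentIndex([("chr1", 500_000, 500_100)] * 10)
        # YAP peak overlapping the strong SE by exactly one base
        factor = {"YAP": IntervalSet([("chr1", 200_999, 202_000)])}
        call = call_ses(
            peaks,
            {"wt": fr, "ko": fr},
            {"wt": ctrl, "ko": ctrl},
            {"wt": 100_000, "ko": 100_000},
            {"wt": 100_000, "ko": 100_000},
            factor_peaks=factor,
        )
        assert len(call.table) == 2  # the strong region, called in both
        assert set(call.table["unique_to"]) == {"common"}
        assert all("YAP" in b for b in call.table["bound_by"])

    def test_recovery_on_simulated_dataset(self, default_dataset):
        from sescape.pipeline import se_recovery

        ds = default_dataset
        genome = ds.genome
        pk = {
            c: filter_peaks(
                sio.read_peaks(ds.path(f"H3K27ac_{c}.narrowPeak"), "narrowPeak", genome)
            )
            for c in ("wt", "ko")
        }
        treat = {c: sio.read_fragments(ds.path(f"H3K27ac_{c}.fragments"), genome) for c in ("wt", "ko")}
        ctrl = {c: sio.read_fragments(ds.path(f"input_{c}.fragments"), genome) for c in ("wt", "ko")}
        call = call_ses(
            pk, treat, ctrl,
            {c: treat[c].n_fragments for c in ("wt", "ko")},
            {c: ctrl[c].n_fragments for c in ("wt", "ko")},
        )
        rec = se_recovery(call.table, ds.manifest)
        assert rec["se_recall"] >= 0.90
        assert rec["se_precision"] >= 0.85
        assert rec["ko_unique_se_recall"] >= 0.90
        # hockey-stick sanity: SEs are a small minority of stitched regions
        for cond in ("wt", "ko"):
            regions = call.per_condition[cond].regions
            n_se = sum(r.is_super for r in regions)
            assert n_se <= 0.2 * len(regions)
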