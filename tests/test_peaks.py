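"""Peak filtering, differential classification, gene assignment."""

import math

import numpy as np
import pytest

from sescape.genome import GenomeSpec
from sescape.intervals import FragmentIndex, IntervalSet, SignalTrack
from sescape.io import GeneRecord, PeakRecord
from sescape import io as sio
from sescape.peaks import (
    UnionPeak,
    assign_peaks_to_genes,
    classify_differential,
    filter_peaks,
    signal_change_correlation,
    union_peaks,
)


def peak(start, end, nlp=15.0, fe=12.0, chrom="chr1", name="p"):
    return PeakRecord(chrom, start, end, name, nlp, fe)


class TestFilterPeaks:
    @pytest.mark.parametrize(
        "nlp,fe,kept",
        [
            (15.0, 12.0, True),   # clears both thresholds
            (9.0, 12.0, False),   # boundary significance excluded (strict >)
            (15.0, 3.0, False),   # boundary enrichment excluded
            (8.9, 2.0, False),
        ],
    )
    def test_strict_thresholds(self, nlp, fe, kept):
        got = filter_peaks([peak(0, 100, nlp, fe)])
        assert bool(got) is kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_peaks([], min_neg_log10_p=-1)


class TestUnionPeaks:
    def test_overlapping_conditions_merge_with_both_contributors(self):
        (u,) = union_peaks([peak(0, 100)], [peak(50, 200)])
        assert (u.start, u.end) == (0, 200)
        assert u.contributors == {"WT", "KO"}

    def test_disjoint_peaks_keep_single_contributors(self):
        u = union_peaks([peak(0, 100)], [peak(500, 600)])
        assert [(x.start, x.contributors) for x in u] == [
            (0, frozenset({"WT"})), (500, frozenset({"KO"}))]

    def test_identical_sets(self):
        (u,) = union_peaks([peak(0, 100)], [peak(0, 100)])
        assert u.contributors == {"WT", "KO"}


def _frag_stack(region, n, chrom="chr1"):
    return [(chrom, region[0], region[1])] * n


class TestClassifyDifferential:
    # region 1 kb, library 1e6 makes RPKM equal the fragment count
    REGION = UnionPeak("chr1", 0, 1000, frozenset({"WT", "KO"}))

    def _classify(self, n_wt, n_ko, eps=0.0):
        fw = FragmentIndex(_frag_stack((0, 1000), n_wt))
        fk = FragmentIndex(_frag_stack((0, 1000), n_ko))
        return classify_differential(self.REGION, fw, fk, 1_000_000, 1_000_000, eps)

    def test_up_beyond_twofold(self):
        d = self._classify(4, 10)
        assert d.ratio == pytest.approx(2.5)
        assert d.klass == "up"

    def test_down_below_one_point_five_fold(self):
        d = self._classify(10, 4)
        assert d.ratio == pytest.approx(0.4)
        assert d.klass == "down"

    def test_within_band_unchanged(self):
        assert self._classify(5, 6).klass == "unchanged"

    def test_exact_twofold_is_not_up(self):
        assert self._classify(5, 10).klass == "unchanged"

    def test_monotone_in_ko_counts(self):
        order = {"down": 0, "unchanged": 1, "up": 2}
        last = -1
        for n_ko in range(0, 40, 4):
            d = self._classify(10, n_ko, eps=0.25)
            assert order[d.klass] >= last
            last = order[d.klass]


class TestAssignPeaksToGenes:
    GENES = [GeneRecord("gA", "chr1", 100_000, 120_000, "+")]

    def test_within_window(self):
        p2g, g2p = assign_peaks_to_genes([("chr1", 60_000, 61_000)], self.GENES)
        assert p2g == {0: ["gA"]}
        assert g2p == {"gA": [0]}

    def test_beyond_window(self):
        p2g, _ = assign_peaks_to_genes([("chr1", 10_000, 11_000)], self.GENES)
        assert p2g == {}

    def test_tss_inside_peak_distance_zero(self):
        p2g, _ = assign_peaks_to_genes([("chr1", 99_000, 101_000)], self.GENES, window_bp=0)
        assert p2g == {0: ["gA"]}


class TestSignalChangeCorrelation:
    GENOME = GenomeSpec(("chr1",), (100_000,))

    def _tracks(self, values):
        steps = [("chr1", i * 100, (i + 1) * 100, float(v)) for i, v in enumerate(values)]
        return SignalTrack.from_steps(steps, self.GENOME)

    def _regions(self, n):
        return [("chr1", i * 100, (i + 1) * 100) for i in range(n)]

    def test_scaled_tracks_have_zero_variance_flagged(self):
        wt = self._tracks([1, 2, 3, 4])
        ko = self._tracks([2, 4, 6, 8])
        out = signal_change_correlation(
            self._regions(4), {"YAP": (wt, ko), "B": (wt, ko)}, pseudocount=0.0
        )
        assert out["B"].r is None

    def test_proportional_changes_give_r_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, 50)
        yap_lfc = rng.normal(0, 1, 50)
        wt_y = self._tracks(base)
        ko_y = self._tracks(base * 2.0 ** yap_lfc)
        wt_b = self._tracks(base)
        ko_b = self._tracks(base * 2.0 ** (0.8 * yap_lfc))
        out = signal_change_correlation(
            self._regions(50), {"YAP": (wt_y, ko_y), "B": (wt_b, ko_b)}, pseudocount=0.0
        )
        assert out["B"].r > 0.999

    def test_independent_changes_give_small_r(self):
        rng = np.random.default_rng(1)
        small = 0
        for trial in range(10):
            base = np.ones(1000)
            ko_y = self._tracks(base * 2.0 ** rng.normal(0, 1, 1000))
            ko_b = self._tracks(base * 2.0 ** rng.normal(0, 1, 1000))
            wt = self._tracks(base)
            out = signal_change_correlation(
                self._regions(1000), {"YAP": (wt, ko_y), "B": (wt, ko_b)},
                pseudocount=0.0,
            )
            small += abs(out["B"].r) < 0.1
        assert small >= 8  # null correlations concentrate near zero

    def test_needs_three_regions(self):
        wt = self._tracks([1, 2])
        with pytest.raises(ValueError):
            signal_change_correlation(self._regions(2), {"YAP": (wt, wt)})


class TestRecoveryOnSimulatedData:
    def test_up_peaks_recover_planted_boosted_sites(self, default_dataset):
        from sescape.peaks import classify_differential_many
        from sescape.pipeline import diffpeak_recovery

        ds = default_dataset
        genome = ds.genome
        p_wt = filter_peaks(sio.read_peaks(ds.path("YAP_wt.narrowPeak"), "narrowPeak", genome))
        p_ko = filter_peaks(sio.read_peaks(ds.path("YAP_ko.narrowPeak"), "narrowPeak", genome))
        f_wt = sio.read_fragments(ds.path("YAP_wt.fragments"), genome)
        f_ko = sio.read_fragments(ds.path("YAP_ko.fragments"), genome)
        union = union_peaks(p_wt, p_ko)
        diffs = classify_differential_many(
            union, f_wt, f_ko, f_wt.n_fragments, f_ko.n_fragments
        )
        rec = diffpeak_recovery(diffs, ds.manifest)
        assert rec["up_peak_recall"] >= 0.90
        assert rec["up_peak_precision"] >= 0.85
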