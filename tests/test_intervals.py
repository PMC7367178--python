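"""Interval arithmetic, fragment counting and metaplot binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sescape.genome import GenomeSpec
from sescape.intervals import (
    FragmentIndex,
    IntervalSet,
    SignalTrack,
    merge,
    metaplot_matrix,
    overlap_bp,
    overlaps_any,
    quantify_rpkm,
)

GENOME = GenomeSpec(("chr1",), (10_000,))


def ivals(*pairs, chrom="chr1"):
    return [(chrom, s, e) for s, e in pairs]


class TestMerge:
    def test_overlapping_union(self):
        assert list(merge(ivals((0, 10), (5, 15)))) == ivals((0, 15))

    def test_adjacent_intervals_merge(self):
        assert list(merge(ivals((0, 10), (10, 20)))) == ivals((0, 20))

    def test_empty_input(self):
        assert list(merge([])) == []

    def test_total_covered(self):
        s = merge(ivals((0, 10), (20, 25)))
        assert s.total_covered_bp == 15


class TestOverlap:
    def test_partial_overlap(self):
        assert overlap_bp(merge(ivals((0, 100))), merge(ivals((50, 150)))) == 50

    def test_disjoint(self):
        assert overlap_bp(merge(ivals((0, 10))), merge(ivals((20, 30)))) == 0

    def test_self_overlap_is_coverage(self):
        s = merge(ivals((0, 100)))
        assert overlap_bp(s, s) == 100

    def test_single_base_overlap_counts(self):
        assert overlaps_any(("chr1", 0, 10), merge(ivals((9, 20))))

    def test_half_open_touching_does_not_overlap(self):
        assert not overlaps_any(("chr1", 0, 10), merge(ivals((10, 20))))

    def test_empty_subject(self):
        assert not overlaps_any(("chr1", 0, 10), merge([]))

    def test_mismatched_genomes_rejected(self):
        other = GenomeSpec(("chrX",), (5_000,))
        a = IntervalSet(ivals((0, 10)), genome=GENOME)
        b = IntervalSet([("chrX", 0, 10)], genome=other)
        with pytest.raises(ValueError, match="different genomes"):
            overlap_bp(a, b)


interval_lists = st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 60)).map(lambda t: (t[0], t[0] + t[1])),
    max_size=30,
)


@settings(max_examples=150, derandomize=True)
@given(interval_lists)
def test_merge_is_idempotent(pairs):
    once = merge(ivals(*pairs))
    twice = merge(list(once))
    assert list(once) == list(twice)


@settings(max_examples=150, derandomize=True)
@given(interval_lists, interval_lists)
def test_overlap_inclusion_exclusion_identity(pa, pb):
    """overlap(a,b) = cov(a) + cov(b) - cov(a union b) for arbitrary sets."""
    a, b = merge(ivals(*pa)), merge(ivals(*pb))
    union = a.union(b)
    assert overlap_bp(a, b) == a.total_covered_bp + b.total_covered_bp - union.total_covered_bp


def test_overlap_matches_bedtools(tmp_path):
    """Base-pair overlap agrees with `bedtools intersect` on random sets."""
    import shutil
    import subprocess

    if shutil.which("bedtools") is None:
        pytest.skip("bedtools not on PATH")
    rng = np.random.default_rng(9)

    def random_set(path):
        rows = sorted(
            ("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 9_000, 40), rng.integers(1, 500, 40))
        )
        path.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows))
        return merge(rows)

    a_path, b_path = tmp_path / "a.bed", tmp_path / "b.bed"
    a, b = random_set(a_path), random_set(b_path)
    out = subprocess.run(
        ["bedtools", "intersect", "-a", str(a_path), "-b", str(b_path)],
        capture_output=True, text=True, check=True,
    ).stdout
    spans = [line.split("\t") for line in out.strip().splitlines() if line]
    bedtools_bp = merge(
        [("chr1", int(s), int(e)) for _, s, e in spans]
    ).total_covered_bp
    assert overlap_bp(a, b) == bedtools_bp


class TestRpkm:
    def test_worked_example(self):
        frags = FragmentIndex([("chr1", 0, 100)] * 200)
        assert quantify_rpkm(("chr1", 0, 2000), frags, 20_000_000) == pytest.approx(5.0)

    def test_no_fragments(self):
        frags = FragmentIndex([])
        assert quantify_rpkm(("chr1", 0, 1000), frags, 1_000_000) == 0.0

    def test_second_example(self):
        frags = FragmentIndex([("chr1", 10, 50)] * 100)
        assert quantify_rpkm(("chr1", 0, 1000), frags, 10_000_000) == pytest.approx(10.0)

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            quantify_rpkm(("chr1", 5, 5), FragmentIndex([]), 1000)

    def test_linear_scaling(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9_000, 300)
        frags = FragmentIndex([("chr1", int(s), int(s) + 100) for s in starts])
        base = quantify_rpkm(("chr1", 2000, 4000), frags, 1_000_000)
        halved_lib = quantify_rpkm(("chr1", 2000, 4000), frags, 2_000_000)
        assert halved_lib == pytest.approx(base / 2)
        doubled = FragmentIndex(
            [("chr1", int(s), int(s) + 100) for s in np.concatenate([starts, starts])]
        )
        assert quantify_rpkm(("chr1", 2000, 4000), doubled, 1_000_000) == pytest.approx(2 * base)

    def test_counts_match_plain_scan(self):
        rng = np.random.default_rng(1)
        frag_list = [("chr1", int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 9_500, 500), rng.integers(1, 400, 500))]
        idx = FragmentIndex(frag_list)
        for _ in range(50):
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(1, 900))
            expected = sum(1 for _, fs, fe in frag_list if fs < e and fe > s)
            assert idx.count_overlapping("chr1", s, e) == expected


class TestMetaplot:
    def _track(self, steps):
        return SignalTrack.from_steps(steps, GENOME)

    def test_uniform_signal(self):
        track = self._track([("chr1", 0, 10_000, 2.0)])
        mat, curve, skipped = metaplot_matrix([("chr1", 4_000, 4_100)], track, 500, 10)
        assert np.allclose(mat, 2.0)
        assert np.allclose(curve, 2.0)
        assert skipped == 0

    def test_column_means_average_regions(self):
        track = self._track([("chr1", 0, 5_000, 1.0), ("chr1", 5_000, 10_000, 3.0)])
        regions = [("chr1", 2_000, 2_100), ("chr1", 7_000, 7_100)]
        _, curve, _ = metaplot_matrix(regions, track, 400, 8)
        assert np.allclose(curve, 2.0)

    def test_edge_region_skipped_with_warning(self):
        track = self._track([("chr1", 0, 10_000, 1.0)])
        regions = [("chr1", 0, 100), ("chr1", 5_000, 5_100)]
        with pytest.warns(UserWarning, match="skipped 1"):
            mat, _, skipped = metaplot_matrix(regions, track, 500, 5)
        assert skipped == 1
        assert mat.shape == (1, 5)

    def test_remainder_goes_to_last_bin(self):
        track = self._track([("chr1", 0, 10, 1.0)])
        # window [0, 10) with 3 bins: edges 0,3,6,10
        means = track.binned_means("chr1", 0, 10, 3)
        assert means.shape == (3,)
        assert np.allclose(means, 1.0)
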