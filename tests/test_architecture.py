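"""Neighbor distances, window counts and segment relations.

The vectorized batch operations are held to exact agreement with
O(n^2) brute-force scans on random layouts.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alueditability.annotations import GeneModel, GenicAlu, RepeatElement
from alueditability.architecture import (
    batch_nearest_reverse,
    batch_neighbor_counts,
    build_feature_table,
    classify_segment_relation,
    features_frame,
    nearest_reverse_neighbor,
    neighbor_counts,
    pair_gap_distance,
)


def random_layout(rng, n, span=200_000, allow_nested=True):
    starts = np.sort(rng.integers(0, span, n))
    lengths = rng.integers(50, 600, n)
    strands = rng.choice(["+", "-"], n)
    return [
        RepeatElement(f"r{i:04d}", "chr1", int(s), int(s + l), str(st_), "AluSx")
        for i, (s, l, st_) in enumerate(zip(starts, lengths, strands))
    ]


def brute_nearest_reverse(target, repeats):
    best = None
    for r in repeats:
        if r.chrom != target.chrom or r.strand == target.strand or r.id == target.id:
            continue
        key = (pair_gap_distance(target, r), r.start, r.id)
        if best is None or key < best:
            best = key
    return None if best is None else (best[2], best[0])


def brute_counts(target, repeats, window):
    nss = nrs = 0
    for r in repeats:
        if r.chrom != target.chrom or r.id == target.id:
            continue
        if pair_gap_distance(target, r) <= window:
            if r.strand == target.strand:
                nss += 1
            else:
                nrs += 1
    return nss, nrs


class TestPairGap:
    def test_disjoint_edge_gap(self, element):
        assert pair_gap_distance(element(100, 400), element(1000, 1300)) == 600

    def test_nested_is_zero(self, element):
        assert pair_gap_distance(element(100, 700), element(300, 400)) == 0

    def test_touching_is_zero(self, element):
        assert pair_gap_distance(element(100, 400), element(400, 700)) == 0

    def test_cross_chromosome_error(self, element):
        with pytest.raises(ValueError):
            pair_gap_distance(element(0, 10), element(0, 10, chrom="chr2"))

    @given(st.integers(0, 10 ** 6), st.integers(1, 600),
           st.integers(0, 10 ** 6), st.integers(1, 600),
           st.integers(-10 ** 5, 10 ** 5))
    def test_symmetry_and_translation(self, s1, l1, s2, l2, shift):
        a = RepeatElement("a", "c", s1, s1 + l1, "+", "AluSx")
        b = RepeatElement("b", "c", s2, s2 + l2, "-", "AluSx")
        d = pair_gap_distance(a, b)
        assert d == pair_gap_distance(b, a)
        off = max(shift, -min(s1, s2))  # keep coordinates non-negative
        a2 = RepeatElement("a", "c", s1 + off, s1 + l1 + off, "+", "AluSx")
        b2 = RepeatElement("b", "c", s2 + off, s2 + l2 + off, "-", "AluSx")
        assert pair_gap_distance(a2, b2) == d


class TestNearestReverse:
    def test_picks_minimal_gap(self, element):
        target = element(5000, 5300, "+", id="t")
        others = [element(1000, 1300, "-", id="far"),
                  element(6000, 6300, "-", id="near")]
        nb, d = nearest_reverse_neighbor(target, [target] + others)
        assert (nb.id, d) == ("near", 700)

    def test_absent_without_opposite_strand(self, element):
        target = element(5000, 5300, "+", id="t")
        assert nearest_reverse_neighbor(target, [target, element(0, 300, "+")]) is None

    def test_tie_broken_by_smaller_start(self, element):
        target = element(5000, 5300, "+", id="t")
        left = element(4100, 4400, "-", id="left")    # gap 600
        right = element(5900, 6200, "-", id="right")  # gap 600
        nb, d = nearest_reverse_neighbor(target, [target, left, right])
        assert (nb.id, d) == ("left", 600)

    def test_batch_matches_brute_force(self, rng):
        for trial in range(12):
            reps = random_layout(rng, int(rng.integers(5, 120)))
            batch = batch_nearest_reverse(reps)
            for r in reps:
                assert batch.get(r.id) == brute_nearest_reverse(r, reps), r.id


class TestNeighborCounts:
    def test_constructed_layout(self, element):
        target = element(50_000, 50_300, "+", id="t")
        reps = [target]
        reps += [element(50_000 + o, 50_300 + o, "+") for o in (1000, 2000, 9000)]
        reps += [element(50_000 - o - 300, 50_000 - o, "-") for o in (500, 4000)]
        reps.append(element(70_000, 70_300, "-"))  # beyond 10 kb
        assert neighbor_counts(target, reps, 10_000) == (3, 2)

    def test_empty_neighborhood(self, element):
        t = element(0, 300, "+", id="t")
        assert neighbor_counts(t, [t], 10_000) == (0, 0)

    def test_boundary_gap_is_inclusive(self, element):
        t = element(0, 300, "+", id="t")
        exact = element(10_300, 10_600, "+")  # gap exactly 10000
        assert neighbor_counts(t, [t, exact], 10_000) == (1, 0)

    def test_batch_matches_brute_force(self, rng):
        for trial in range(10):
            reps = random_layout(rng, int(rng.integers(5, 120)))
            window = int(rng.choice([2_000, 10_000]))
            batch = batch_neighbor_counts(reps, window)
            for r in reps:
                assert batch[r.id] == brute_counts(r, reps, window), r.id

    def test_narrow_window_bounded_by_wide(self, rng):
        reps = random_layout(rng, 200)
        wide = batch_neighbor_counts(reps, 10_000)
        narrow = batch_neighbor_counts(reps, 2_000)
        near = batch_nearest_reverse(reps)
        for r in reps:
            assert narrow[r.id][0] <= wide[r.id][0]
            assert narrow[r.id][1] <= wide[r.id][1]
            if r.id in near and near[r.id][1] <= 2_000:
                assert narrow[r.id][1] >= 1


class TestSegmentRelation:
    GENE = GeneModel("g", "chr1", "+", 0, 20_000,
                     ((0, 1_000), (5_000, 6_000), (10_000, 11_000)))

    def make(self, el):
        return GenicAlu(el, "g", "+", "polyA")

    def test_same_intron(self, element):
        a = self.make(element(2_000, 2_300, "+"))
        assert classify_segment_relation(a, element(3_000, 3_300, "-"),
                                         self.GENE) == "same_intron"

    def test_same_exon(self, element):
        a = self.make(element(5_100, 5_300, "+"))
        assert classify_segment_relation(a, element(5_500, 5_800, "-"),
                                         self.GENE) == "same_exon"

    def test_different_segment(self, element):
        a = self.make(element(5_100, 5_300, "+"))
        assert classify_segment_relation(a, element(2_000, 2_300, "-"),
                                         self.GENE) == "different_segment"

    def test_neighbor_outside_gene(self, element):
        a = self.make(element(5_100, 5_300, "+"))
        assert classify_segment_relation(a, element(30_000, 30_300, "-"),
                                         self.GENE) == "neighbor_outside_gene"


class TestBuildFeatureTable:
    def test_composition_matches_single_ops(self, rng):
        reps = random_layout(rng, 40, span=60_000)
        gene = GeneModel("g", "chr1", "+", 0, 70_000, ((0, 500), (69_500, 70_000)))
        genic = [GenicAlu(r, "g", "+", "polyA" if r.strand == "+" else "polyU")
                 for r in reps if r.end <= 70_000]
        feats = {f.alu_id: f for f in build_feature_table(genic, reps, [gene])}
        for ga in genic:
            f = feats[ga.element.id]
            expected = brute_nearest_reverse(ga.element, reps)
            if expected is None:
                assert f.d is None
            else:
                assert (f.neighbor_id, f.d) == expected
            assert (f.nss_10k, f.nrs_10k) == brute_counts(ga.element, reps, 10_000)
            assert (f.nss_2k, f.nrs_2k) == brute_counts(ga.element, reps, 2_000)
            assert f.pair_identity_pct is None  # no sequences supplied

    def test_identity_present_only_with_sequences(self, element):
        a = element(1_000, 1_012, "+", id="a")
        b = element(3_000, 3_012, "-", id="b")
        gene = GeneModel("g", "chr1", "+", 0, 5_000, ((0, 100), (4_900, 5_000)))
        genic = [GenicAlu(a, "g", "+", "polyA")]
        seqs = {"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"}
        (feat,) = build_feature_table(genic, [a, b], [gene], seqs)
        assert feat.pair_identity_pct is not None
        assert feat.same_subfamily is True and feat.same_family is True

    def test_frame_encodes_missing_as_nan(self, element):
        a = element(1_000, 1_300, "+", id="solo")
        gene = GeneModel("g", "chr1", "+", 0, 5_000, ((0, 100), (4_900, 5_000)))
        genic = [GenicAlu(a, "g", "+", "polyA")]
        df = features_frame(build_feature_table(genic, [a], [gene]))
        assert np.isnan(df.loc[0, "d"])
        assert df.loc[0, "segment_relation"] == "unknown"
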