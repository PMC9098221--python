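"""Peak merging, nearby assignment, High/Low splits, annotation enrichment."""

import numpy as np
import pytest

import bivalscape as bv


def peak(start, end, name="p", chrom="chr1", score=None):
    return bv.Peak(bv.GenomicInterval(chrom, start, end), name, score)


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=50_000):
    out = []
    for i in range(n):
        s = int(rng.integers(0, span))
        out.append(peak(s, s + int(rng.integers(50, 400)), f"p{i}",
                        chrom=str(rng.choice(chroms))))
    return out


class TestMergePeaks:
    def test_overlap_coalesces(self):
        (m,) = bv.merge_peaks([peak(0, 10)], [peak(5, 15)])
        assert (m.start, m.end) == (0, 15)

    def test_bookended_coalesce(self):
        (m,) = bv.merge_peaks([peak(0, 10), peak(10, 20)])
        assert (m.start, m.end) == (0, 20)

    def test_idempotent(self, rng):
        x = random_peaks(rng, 40)
        once = bv.merge_peaks(x)
        twice = bv.merge_peaks(x, x)
        assert [(p.chrom, p.start, p.end) for p in once] == [
            (p.chrom, p.start, p.end) for p in twice
        ]

    def test_sorted_disjoint_and_order_invariant(self, rng):
        a, b = random_peaks(rng, 30), random_peaks(rng, 30)
        merged = bv.merge_peaks(a, b)
        assert merged == bv.merge_peaks(b, a)
        spans = [(p.chrom, p.start, p.end) for p in merged]
        assert spans == sorted(spans)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2:
                assert s2 > e1  # strictly disjoint, not even bookended
        total = sum(p.end - p.start for p in merged)
        assert total <= sum(p.end - p.start for p in a + b)


class TestAssignNearby:
    def test_gap_arithmetic(self):
        rows = bv.assign_nearby([peak(1_000, 1_500, "a")],
                                [peak(3_000, 3_100, "q")], 2_000)
        assert len(rows) == 1 and rows[0].edge_distance == 1_500

    def test_out_of_range_anchor_excluded(self):
        rows = bv.assign_nearby([peak(1_000, 1_500, "a")],
                                [peak(4_000, 4_100, "q")], 2_000)
        assert rows == []

    def test_multi_query_anchor_duplicated(self):
        anchor = peak(1_000, 1_500, "a")
        rows = bv.assign_nearby(
            [anchor], [peak(1_600, 1_700, "q1"), peak(2_000, 2_100, "q2")], 2_000
        )
        assert len(rows) == 2
        assert all(r.anchor_peak == anchor for r in rows)

    def test_unique_query_keeps_closest_anchor(self):
        anchors = [peak(0, 100, "far"), peak(900, 1_000, "near")]
        rows = bv.assign_nearby(anchors, [peak(1_200, 1_300, "q")], 2_000,
                                unique_query=True)
        assert len(rows) == 1 and rows[0].anchor_peak.name == "near"

    def test_matches_all_pairs_oracle(self, rng):
        anchors = random_peaks(rng, 120)
        queries = random_peaks(rng, 150)
        got = {
            (r.anchor_peak.name, r.assigned_peak.name, r.edge_distance)
            for r in bv.assign_nearby(anchors, queries, 1_000)
        }
        expected = set()
        for a in anchors:
            for q in queries:
                d = a.interval.edge_distance(q.interval)
                if d is not None and d <= 1_000:
                    expected.add((a.name, q.name, d))
        assert got == expected


class TestSplitHighLow:
    def test_even_split(self):
        pks = [peak(i * 100, i * 100 + 50, f"p{i}") for i in range(4)]
        res = bv.split_high_low(pks, [4, 3, 2, 1])
        assert [p.name for p in res.high] == ["p0", "p1"]
        assert [p.name for p in res.low] == ["p2", "p3"]

    def test_odd_split_low_gets_extra(self):
        pks = [peak(i * 100, i * 100 + 50, f"p{i}") for i in range(5)]
        res = bv.split_high_low(pks, [5, 4, 3, 2, 1])
        assert (len(res.high), len(res.low)) == (2, 3)

    def test_partition_and_size_difference(self, rng):
        for n in (1, 2, 7, 101):
            pks = [peak(i * 10, i * 10 + 5, f"p{i}") for i in range(n)]
            res = bv.split_high_low(pks, list(rng.uniform(size=n)))
            assert len(res.high) + len(res.low) == n
            assert len(res.low) - len(res.high) in (0, 1)
            assert set(p.name for p in res.high).isdisjoint(
                p.name for p in res.low
            )

    def test_ties_broken_by_position(self):
        pks = [peak(200, 250, "b"), peak(100, 150, "a")]
        res = bv.split_high_low(pks, [1.0, 1.0])
        assert res.high[0].name == "a"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bv.split_high_low([], [])


class TestAnnotationEnrichment:
    def _peaks_with_midpoints(self, mids):
        return [peak(m - 10, m + 10, f"p{i}") for i, m in enumerate(mids)]

    def test_observed_equals_expected_is_zero(self):
        # 100 peaks, annotation covers 10% of the genome, 10 observed
        pks = self._peaks_with_midpoints(
            list(range(500, 10_500, 1_000)) + list(range(20_000, 110_000, 1_000))
        )
        annotations = {"promoter": [bv.GenomicInterval("chr1", 0, 10_000)]}
        (enr, p) = bv.annotation_enrichment(pks, annotations, 100_000)["promoter"]
        assert enr == pytest.approx(0.0)
        assert 0 < p <= 1

    def test_enrichment_arithmetic(self):
        # 100 peaks, expected 10, observed 40: log2(40.5 / 10.5)
        mids = list(range(500, 40_500, 1_000)) + list(range(50_000, 110_000, 1_000))
        pks = self._peaks_with_midpoints(mids)
        annotations = {"cpg": [bv.GenomicInterval("chr1", 0, 40_000)]}
        genome = 400_000
        (enr, p) = bv.annotation_enrichment(pks, annotations, genome)["cpg"]
        assert enr == pytest.approx(np.log2(40.5 / 10.5))
        from scipy import stats
        assert p == pytest.approx(float(stats.binom.sf(39, 100, 0.1)))

    def test_depletion_uses_lower_tail(self):
        pks = self._peaks_with_midpoints(range(50_000, 150_000, 1_000))
        annotations = {"desert": [bv.GenomicInterval("chr1", 0, 10_000)]}
        (enr, p) = bv.annotation_enrichment(pks, annotations, 100_000)["desert"]
        assert enr == pytest.approx(np.log2(0.5 / 10.5))
        from scipy import stats
        assert p == pytest.approx(float(stats.binom.cdf(0, 100, 0.1)))

    def test_enrichment_monotone_in_genome_size(self):
        """For fixed observed counts, growing the background genome shrinks
        the expectation, so enrichment can only rise."""
        pks = self._peaks_with_midpoints(range(500, 10_500, 1_000))
        annotations = {"a": [bv.GenomicInterval("chr1", 0, 10_000)]}
        enr = [
            bv.annotation_enrichment(pks, annotations, g)["a"][0]
            for g in (20_000, 100_000, 1_000_000)
        ]
        assert enr == sorted(enr)

    def test_zero_length_annotation_skipped_with_warning(self):
        pks = self._peaks_with_midpoints([100])
        with pytest.warns(UserWarning):
            out = bv.annotation_enrichment(pks, {"empty": []}, 1_000)
        assert out == {}
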