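"""Interval/track types and the BED/bedGraph/refGene readers and writers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bivalscape as bv
from bivalscape.io import DegenerateTrackError, FormatError


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end,strand",
        [("chr1", 100, 100, "+"), ("chr1", 200, 100, "+"), ("chr1", -1, 5, "+"),
         ("", 0, 5, "+"), ("chr1", 0, 5, "x")],
    )
    def test_invariant_violations_rejected(self, chrom, start, end, strand):
        with pytest.raises(ValueError):
            bv.GenomicInterval(chrom, start, end, strand)

    def test_edge_distance(self):
        a = bv.GenomicInterval("chr1", 1000, 1500)
        assert a.edge_distance(bv.GenomicInterval("chr1", 3000, 3100)) == 1500
        assert a.edge_distance(bv.GenomicInterval("chr1", 1400, 1600)) == 0
        assert a.edge_distance(bv.GenomicInterval("chr1", 500, 900)) == 100
        assert a.edge_distance(bv.GenomicInterval("chr2", 1000, 1500)) is None


class TestBed:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("")
        assert bv.read_bed(p) == []

    def test_field_mapping(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\tp1\t7.5\n")
        (peak,) = bv.read_bed(p)
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 200)
        assert peak.name == "p1" and peak.score == 7.5

    def test_autonamed_and_comments(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("# c\ntrack name=t\nchr1\t0\t10\nchr1\t20\t30\n")
        peaks = bv.read_bed(p)
        assert [pk.name for pk in peaks] == ["peak_0", "peak_1"]

    def test_inverted_coordinates_name_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(FormatError, match="1"):
            bv.read_bed(p)

    def test_duplicate_names_made_unique(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t10\ta\nchr1\t20\t30\ta\n")
        names = [pk.name for pk in bv.read_bed(p)]
        assert len(set(names)) == 2

    def test_round_trip(self, tmp_path):
        peaks = [
            bv.Peak(bv.GenomicInterval("chr1", 5, 50, "+"), "a", 1.25),
            bv.Peak(bv.GenomicInterval("chr2", 0, 9), "b", 3.0),
        ]
        path = tmp_path / "rt.bed"
        bv.write_bed(peaks, path)
        assert bv.read_bed(path) == peaks


class TestBedGraph:
    def test_mass(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        assert bv.read_bedgraph(p).total_mass == pytest.approx(200.0)

    def test_bookended_runs_kept(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t50\t1\nchr1\t50\t100\t1\n")
        track = bv.read_bedgraph(p)
        assert track.total_mass == pytest.approx(100.0)
        assert len(track.runs("chr1")[0]) == 2

    @pytest.mark.parametrize(
        "body", ["chr1\t0\t60\t1\nchr1\t50\t100\t1\n", "chr1\t0\t10\t-3\n",
                 "chr1\t10\t10\t1\n"]
    )
    def test_malformed_rejected(self, tmp_path, body):
        p = tmp_path / "t.bedgraph"
        p.write_text(body)
        with pytest.raises(FormatError):
            bv.read_bedgraph(p)

    def test_round_trip_drops_zero_runs(self, tmp_path):
        track = bv.SignalTrack.from_runs(
            [("chr1", 0, 10, 1.5), ("chr1", 20, 25, 0.0), ("chr2", 5, 8, 2.0)]
        )
        path = tmp_path / "rt.bedgraph"
        bv.write_bedgraph(track, path)
        assert bv.read_bedgraph(path).equals(track)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 500), st.integers(1, 50),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=0, max_size=20,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, raw):
        # stack runs end to end so they never overlap
        runs, pos = [], 0
        for gap, width, value in raw:
            pos += gap
            runs.append(("chr1", pos, pos + width, value))
            pos += width
        track = bv.SignalTrack.from_runs(runs)
        path = tmp_path_factory.mktemp("rt") / "t.bedgraph"
        bv.write_bedgraph(track, path)
        assert bv.read_bedgraph(path).equals(track)

    def test_total_mass_matches_per_base_sum(self, rng):
        runs, pos = [], 0
        for _ in range(30):
            pos += int(rng.integers(0, 50))
            w = int(rng.integers(1, 40))
            runs.append(("chr1", pos, pos + w, float(rng.uniform(0, 5))))
            pos += w
        track = bv.SignalTrack.from_runs(runs)
        dense = np.zeros(pos + 10)
        for _, s, e, v in runs:
            dense[s:e] += v
        assert track.total_mass == pytest.approx(dense.sum(), rel=1e-12)


class TestGeneTable:
    def test_plain_and_binned_rows_agree(self, tmp_path):
        a = tmp_path / "a.txt"
        a.write_text("NM_001\tchr1\t+\t1000\t5000\n")
        b = tmp_path / "b.txt"
        b.write_text("585\tNM_001\tchr1\t+\t1000\t5000\n")
        assert bv.read_gene_table(a) == bv.read_gene_table(b, has_bin_column=True)

    def test_unstranded_rejected(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("NM_001\tchr1\t.\t1000\t5000\n")
        with pytest.raises(FormatError):
            bv.read_gene_table(p)

    def test_duplicate_rows_retained(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("NM_001\tchr1\t+\t1000\t5000\n" * 2)
        assert len(bv.read_gene_table(p)) == 2


class TestNormalize:
    def test_scaling(self):
        track = bv.SignalTrack.from_runs([("chr1", 0, 100, 20.0)])  # mass 2000
        normed = bv.normalize_track(track, target_mass=1000.0)
        assert normed.runs("chr1")[2][0] == pytest.approx(10.0)
        assert normed.total_mass == pytest.approx(1000.0, rel=1e-9)

    def test_identity_at_target_mass(self):
        track = bv.SignalTrack.from_runs([("chr1", 0, 1000, 1000.0)])
        assert bv.normalize_track(track).equals(track, rtol=1e-12)

    def test_idempotent(self):
        track = bv.SignalTrack.from_runs(
            [("chr1", 0, 70, 3.0), ("chr2", 10, 20, 0.5)]
        )
        once = bv.normalize_track(track)
        assert bv.normalize_track(once).equals(once, rtol=1e-12)

    def test_empty_track_errors(self):
        with pytest.raises(DegenerateTrackError):
            bv.normalize_track(bv.SignalTrack())
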