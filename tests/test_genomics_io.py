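"""Data-model contracts and round-trips for the I/O layer."""

import numpy as np
import pytest

from phorcmap.genomics_io import (
    GeneExpressionRecord,
    GenomicInterval,
    IntensityTrack,
    PipelineParams,
    ProbeLayout,
    classify_active,
    read_bedgraph,
    read_fasta,
    read_intervals,
    read_probe_table,
    rpkm,
    tss_windows,
    write_fasta,
    write_intervals,
    write_probe_table,
    write_track,
)
from phorcmap.signal_pipeline import RatioProfile


def expr(gene, value, scale, chrom="chr2L", pos=1000, strand="+"):
    return GeneExpressionRecord(
        gene, value, scale, GenomicInterval(chrom, pos, pos + 1, strand=strand)
    )


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="c", start=-1, end=10),
            dict(chrom="c", start=10, end=10),
            dict(chrom="c", start=10, end=5),
            dict(chrom="c", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_overlap_bp(self):
        a = GenomicInterval("c", 0, 100)
        assert a.overlap_bp(GenomicInterval("c", 50, 150)) == 50
        assert a.overlap_bp(GenomicInterval("c", 100, 150)) == 0
        assert a.overlap_bp(GenomicInterval("d", 0, 100)) == 0


class TestProbeTable:
    def _write(self, tmp_path, rows, header="chrom\tstart\tlength\tchip_1\tchip_2\tinput_1\tinput_2"):
        p = tmp_path / "probes.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_round_trip(self, tmp_path):
        rows = [
            "chr1\t0\t25\t2.0\t4.0\t1.0\t1.0",
            "chr1\t36\t25\t1.0\t3.0\t2.0\t2.0",
            "chr1\t72\t25\t5.0\t5.0\t1.0\t3.0",
        ]
        track = read_probe_table(self._write(tmp_path, rows))
        assert track.chip.shape == (3, 2)
        assert track.input.shape == (3, 2)
        out = tmp_path / "again.tsv"
        write_probe_table(track, out)
        track2 = read_probe_table(out)
        assert track.layout == track2.layout
        np.testing.assert_allclose(track.chip, track2.chip, atol=1e-6)

    def test_shuffled_probes_sorted_to_same_track(self, tmp_path):
        rows = [
            "chr1\t72\t25\t5.0\t5.0\t1.0\t3.0",
            "chr1\t0\t25\t2.0\t4.0\t1.0\t1.0",
            "chr1\t36\t25\t1.0\t3.0\t2.0\t2.0",
        ]
        with pytest.warns(UserWarning, match="not sorted"):
            shuffled = read_probe_table(self._write(tmp_path, rows))
        ordered = read_probe_table(self._write(tmp_path, sorted(rows, key=lambda r: int(r.split("\t")[1]))))
        assert shuffled.layout == ordered.layout
        np.testing.assert_array_equal(shuffled.chip, ordered.chip)
        np.testing.assert_array_equal(shuffled.input, ordered.input)

    def test_negative_intensity_rejected(self, tmp_path):
        rows = ["chr1\t0\t25\t2.0\t-1.0\t1.0\t1.0"]
        with pytest.raises(ValueError, match="negative"):
            read_probe_table(self._write(tmp_path, rows))

    def test_malformed_value_reports_line(self, tmp_path):
        rows = ["chr1\t0\t25\t2.0\t4.0\t1.0\t1.0", "chr1\t36\t25\tok\t3.0\t2.0\t2.0"]
        with pytest.raises(ValueError, match="line 3"):
            read_probe_table(self._write(tmp_path, rows))

    def test_duplicate_probe_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ProbeLayout(["c", "c"], [0, 0], [25, 25])


class TestBed:
    def test_bed6_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t500\tpre1\t0\t+\n")
        (iv,) = read_intervals(p)
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.strand) == (
            "chr2L",
            100,
            500,
            "pre1",
            "+",
        )

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_intervals(p) == []

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr2L\t500\t100\n")
        with pytest.raises(ValueError, match="end <= start"):
            read_intervals(p)

    def test_write_read_identity_on_coordinates(self, tmp_path):
        ivs = [
            GenomicInterval("chr2L", 100, 500, "a", "+", 10.0),
            GenomicInterval("chr2L", 700, 900, "b", "-", 3.5),
        ]
        p = tmp_path / "rt.bed"
        write_intervals(ivs, p)
        back = read_intervals(p)
        assert [(i.chrom, i.start, i.end, i.name, i.strand) for i in back] == [
            (i.chrom, i.start, i.end, i.name, i.strand) for i in ivs
        ]


class TestTssWindows:
    @pytest.mark.parametrize(
        "pos,halfwidth,expected",
        [
            (1000, 300, (700, 1300)),  # the 600 bp fly windows
            (100, 700, (0, 800)),  # clipped at the chromosome start
            (1000, 700, (300, 1700)),  # the 1400 bp human windows
        ],
    )
    def test_window_arithmetic(self, pos, halfwidth, expected):
        (iv,) = tss_windows([expr("g", 1.0, "RPKM", pos=pos)], halfwidth)
        assert (iv.start, iv.end) == expected

    def test_width_equals_twice_halfwidth_away_from_edges(self):
        recs = [expr(f"g{i}", 1.0, "RPKM", pos=1000 + 100 * i) for i in range(5)]
        for iv in tss_windows(recs, 300):
            assert iv.width == 600


class TestClassifyActive:
    def test_rpkm_threshold_inclusive(self):
        recs = [expr("A", 350, "RPKM"), expr("B", 10, "RPKM"), expr("C", 300, "RPKM")]
        assert classify_active(recs, 300, "RPKM") == {"A", "C"}

    def test_rma_threshold_strict(self):
        assert classify_active([expr("A", 6.0, "RMA")], 6, "RMA") == set()
        assert classify_active([expr("A", 6.1, "RMA")], 6, "RMA") == {"A"}

    def test_empty_records(self):
        assert classify_active([], 300, "RPKM") == set()

    def test_mixed_scales_rejected(self):
        recs = [expr("A", 350, "RPKM"), expr("B", 7, "RMA")]
        with pytest.raises(ValueError, match="mixed"):
            classify_active(recs, 300, "RPKM")


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [(300, 1000, 1e6, 300.0), (0, 1000, 1e6, 0.0), (150, 500, 2e6, 150.0)],
    )
    def test_formula(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == pytest.approx(expected)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)


class TestTracks:
    def test_bedgraph_round_trip(self, tmp_path, layout_factory):
        layout = layout_factory(5)
        values = np.array([1.5, 2.25, np.nan, 0.875, 3.0])
        profile = RatioProfile(layout, values)
        p = tmp_path / "prof.bedgraph"
        write_track(profile, p, "bedgraph")
        assert len(p.read_text().splitlines()) == 4  # NaN probe omitted
        back_layout, back_values = read_bedgraph(p)
        defined = np.isfinite(values)
        np.testing.assert_array_equal(back_layout.starts, layout.starts[defined])
        np.testing.assert_allclose(back_values, values[defined], atol=1e-6)

    def test_wig_output_has_step_headers(self, tmp_path, layout_factory):
        profile = RatioProfile(layout_factory(3), np.array([1.0, 2.0, 3.0]))
        p = tmp_path / "prof.wig"
        write_track(profile, p, "wig")
        lines = p.read_text().splitlines()
        assert lines[0].startswith("variableStep chrom=chr1 span=25")
        assert len(lines) == 4


class TestFasta:
    def test_round_trip(self, tmp_path):
        seqs = {"chrA": "ACGTACGTAA", "chrB": "GGGCCC"}
        p = tmp_path / "g.fa"
        write_fasta(seqs, p)
        assert read_fasta(p) == seqs


class TestPipelineParams:
    def test_defaults_are_the_published_constants(self, params):
        assert params.smooth_window_bp == 675
        assert params.min_features_per_window == 10
        assert params.sd_multiplier == 3
        assert params.max_gap_bp == 500
        assert params.min_region_bp == 360
        assert params.peak_features == 6
        assert params.core_motif == "GCCAT"

    def test_yaml_round_trip(self, tmp_path, params):
        p = tmp_path / "params.yaml"
        params.replace(trim_fraction=0.2).to_yaml(p)
        assert PipelineParams.from_yaml(p).trim_fraction == 0.2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PipelineParams(trim_fraction=0.5)
        with pytest.raises(ValueError):
            PipelineParams(smooth_window_bp=0)
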