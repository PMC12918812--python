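"""Fragment classes, spike normalization, coverage, metaplots and HSE calls."""

import numpy as np
import pandas as pd
import pytest

from condensatekit import benchmarks, genomics, synthdata

from _oracles import coverage_loop, metaprofile_loop


def _frags(intervals, chrom="chr1", source="target"):
    return pd.DataFrame({
        "chrom": chrom,
        "start": [s for s, _ in intervals],
        "end": [e for _, e in intervals],
        "source": source,
    })


class TestClassifyFragments:
    @pytest.mark.parametrize("length,cls", [(120, "short"), (121, "middle"),
                                            (149, "middle"), (150, "long")])
    def test_boundary_lengths(self, length, cls):
        frags = _frags([(0, length)])
        short, long, middle = genomics.classify_fragments(frags)
        assert len({"short": short, "long": long, "middle": middle}[cls]) == 1

    def test_constructed_length_set(self):
        frags = _frags([(0, n) for n in (80, 100, 120, 130, 150, 200)])
        short, long, middle = genomics.classify_fragments(frags)
        assert (len(short), len(middle), len(long)) == (3, 1, 2)


class TestSpikeInFactor:
    @pytest.mark.parametrize("spike,total,expected", [
        (1000, 100_000, 100.0),
        (500, 500, 1.0),
        (250, 1_000_000, 4000.0),
    ])
    def test_printed_formula(self, spike, total, expected):
        assert genomics.spike_in_factor(spike, total) == pytest.approx(expected)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError):
            genomics.spike_in_factor(0, 100)


class TestCoverage:
    def test_single_fragment_scaled(self):
        track = genomics.coverage(_frags([(10, 20)]), scale=2.0,
                                  chrom_sizes={"chr1": 30})
        vals = track.values["chr1"]
        assert (vals[10:20] == 2.0).all()
        assert vals[:10].sum() == 0 and vals[20:].sum() == 0

    def test_matches_loop_oracle(self, rng):
        starts = rng.integers(0, 900, size=1000)
        ends = starts + rng.integers(1, 100, size=1000)
        frags = _frags(list(zip(starts, np.minimum(ends, 1000))))
        track = genomics.coverage(frags, scale=1.0, chrom_sizes={"chr1": 1000})
        np.testing.assert_allclose(track.values["chr1"],
                                   coverage_loop(starts, np.minimum(ends, 1000), 1000))

    def test_mass_conservation_exact(self, rng):
        starts = rng.integers(0, 500, size=200)
        lengths = rng.integers(1, 80, size=200)
        frags = _frags(list(zip(starts, np.minimum(starts + lengths, 600))))
        scale = 3.5
        track = genomics.coverage(frags, scale=scale, chrom_sizes={"chr1": 600})
        total_len = (frags["end"] - frags["start"]).sum()
        assert track.values["chr1"].sum() == pytest.approx(scale * total_len, abs=1e-9)

    def test_fragment_beyond_chromosome_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            track = genomics.coverage(_frags([(90, 120)]), scale=1.0,
                                      chrom_sizes={"chr1": 100})
        assert track.values["chr1"][90:].sum() == 10


class TestMetaprofile:
    def test_flat_track_gives_constant_profile(self):
        track = genomics.CoverageTrack(values={"chr1": np.full(1000, 4.0)})
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [480], "end": [520],
                             "name": ["x"], "strand": ["+"]})
        profile = genomics.metaprofile(track, loci, flank=100)
        assert (profile.values == 4.0).all()
        assert len(profile.positions) == 201

    def test_matches_loop_oracle_on_random_loci(self, rng):
        values = rng.random(5000)
        track = genomics.CoverageTrack(values={"chr1": values})
        starts = rng.integers(200, 4600, size=100)
        strands = rng.choice(["+", "-"], size=100)
        loci = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 20,
                             "name": "x", "strand": strands})
        profile = genomics.metaprofile(track, loci, flank=150)
        centers = (starts + starts + 20) // 2
        expected = metaprofile_loop(values, centers, 150,
                                    minus=list(strands == "-"))
        np.testing.assert_allclose(profile.values, expected)

    def test_replicates_averaged_equally(self):
        t1 = genomics.CoverageTrack(values={"chr1": np.full(200, 2.0)})
        t2 = genomics.CoverageTrack(values={"chr1": np.full(200, 6.0)})
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [110],
                             "name": ["x"], "strand": ["+"]})
        profile = genomics.metaprofile([t1, t2], loci, flank=20)
        assert (profile.values == 4.0).all()

    def test_out_of_range_locus_zero_padded_flagged(self):
        track = genomics.CoverageTrack(values={"chr1": np.full(100, 1.0)})
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                             "name": ["x"], "strand": ["+"]})
        with pytest.warns(UserWarning, match="zero-padded"):
            profile = genomics.metaprofile(track, loci, flank=50)
        assert profile.values[0] == 0.0

    def test_enriched_library_peaks_at_hse(self):
        truth = synthdata.FragmentLibraryTruth(enrichment_fold=5.0, spike_fraction=0.0)
        frags = synthdata.gen_fragment_library(truth, 50_000, seed=0)
        track = genomics.coverage(frags, scale=1.0,
                                  chrom_sizes={truth.chrom: truth.genome_length})
        loci = pd.DataFrame({"chrom": truth.chrom,
                             "start": [h - 5 for h in truth.hse_positions],
                             "end": [h + 5 for h in truth.hse_positions],
                             "name": "h", "strand": "."})
        profile = genomics.metaprofile(track, loci, flank=400)
        center = profile.values[len(profile.values) // 2]
        edges = (profile.values[0] + profile.values[-1]) / 2
        assert center >= 3 * edges


class TestHseClassify:
    def _track(self, values):
        return genomics.CoverageTrack(values={"chr1": np.asarray(values, dtype=float)})

    def test_equal_tracks_give_zero_log2fc(self):
        vals = np.full(1000, 5.0)
        loci = pd.DataFrame({"chrom": "chr1", "start": [200, 600], "end": [220, 620],
                             "name": ["a", "b"], "strand": "."})
        calls = genomics.hse_classify(self._track(vals), self._track(vals), loci)
        assert (calls["log2fc"] == 0).all()
        assert not calls["upregulated"].any()  # strict > 0

    def test_doubled_signal_approaches_log2fc_one(self):
        mock = np.full(1000, 500.0)
        stress = mock.copy()
        stress[150:250] *= 2
        loci = pd.DataFrame({"chrom": "chr1", "start": [195], "end": [205],
                             "name": ["a"], "strand": "."})
        calls = genomics.hse_classify(self._track(stress), self._track(mock), loci)
        assert calls.loc[0, "log2fc"] == pytest.approx(1.0, abs=0.01)
        assert calls.loc[0, "upregulated"]

    def test_planted_enrichment_classified_exactly(self):
        result = benchmarks.hse_classification_benchmark(seed=0)
        assert result["exact"]
        assert result["min_planted_log2fc"] > 0.5


class TestBackgroundSubtract:
    def test_constant_region_zeroed(self):
        mat = np.full((3, 11), 7.0)
        out = genomics.background_subtract(mat, np.arange(-5, 6))
        assert (out == 0).all()

    def test_minimum_subtracted(self):
        row = np.array([5.0, 3.0, 8.0])
        out = genomics.background_subtract(row, np.array([-1, 0, 1]))
        np.testing.assert_allclose(out, [2.0, 0.0, 5.0])

    def test_matches_loop_oracle(self, rng):
        mat = rng.random((10, 2001))
        positions = np.arange(-1000, 1001)
        out = genomics.background_subtract(mat, positions)
        for i in range(10):
            np.testing.assert_allclose(out[i], mat[i] - mat[i].min())


class TestIO:
    def test_bed_roundtrip(self, tmp_path, rng):
        loci = pd.DataFrame({
            "chrom": "chr1",
            "start": sorted(rng.integers(0, 1000, size=10)),
            "end": 0, "name": [f"x{i}" for i in range(10)],
            "score": "0", "strand": list(rng.choice(["+", "-", "."], size=10)),
        })
        loci["end"] = loci["start"] + 50
        path = tmp_path / "loci.bed"
        genomics.write_bed(loci, path)
        back = genomics.read_bed(path)
        pd.testing.assert_frame_equal(back[["chrom", "start", "end", "strand"]],
                                      loci[["chrom", "start", "end", "strand"]])

    def test_malformed_bed_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\nchr1\tfive\t20\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            genomics.read_bed(path)

    def test_one_based_conversion(self, tmp_path):
        path = tmp_path / "one.bed"
        path.write_text("chr1\t1\t10\n")
        out = genomics.read_bed(path, one_based=True)
        assert out.loc[0, "start"] == 0
        assert out.attrs["converted_from_one_based"]

    def test_empty_file_is_empty_set(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(genomics.read_bed(path)) == 0

    def test_fragment_roundtrip(self, tmp_path):
        truth = synthdata.FragmentLibraryTruth()
        frags = synthdata.gen_fragment_library(truth, 500, seed=0)
        path = tmp_path / "frags.tsv"
        genomics.write_fragments(frags, path)
        back = genomics.read_fragments(path)
        pd.testing.assert_frame_equal(back, frags[["chrom", "start", "end", "source"]])

    def test_bedgraph_roundtrip(self, tmp_path):
        frags = _frags([(5, 15), (10, 30), (40, 45)])
        track = genomics.coverage(frags, scale=2.0, chrom_sizes={"chr1": 50})
        path = tmp_path / "cov.bedgraph"
        genomics.write_bedgraph(track, path)
        back = genomics.read_bedgraph(path, chrom_sizes={"chr1": 50})
        np.testing.assert_allclose(back.values["chr1"], track.values["chr1"])


class TestHseNull:
    def test_null_library_splits_evenly(self):
        result = benchmarks.hse_null_fraction(seed=3)
        assert result["within_ci"]
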