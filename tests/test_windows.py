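import numpy as np
import pandas as pd
import pytest

from telandscape.repeatmasker import TEAnnotation
from telandscape.windows import (
    cds_density, chromosome_summary, gc_content, make_windows, repeat_density,
    telomere_profile,
)


def _te(chrom, start, end, div=1.0):
    return TEAnnotation(chrom, start, end, "+", div, "x", "LINE", "L1")


class TestMakeWindows:
    def test_trailing_half_window_kept(self):
        win = make_windows({"c": 250_000})
        assert list(zip(win.start, win.end)) == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)]

    def test_exact_multiple(self):
        assert len(make_windows({"c": 100_000})) == 1

    def test_short_tail_dropped(self):
        assert len(make_windows({"c": 249_999})) == 2

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 0})


class TestRepeatDensity:
    def test_simple_fraction(self):
        win = make_windows({"c": 100_000})
        out = repeat_density(win, [_te("c", 0, 10_000)])
        assert out.repeat_density[0] == pytest.approx(0.10)

    def test_overlapping_hits_use_interval_union(self):
        # [99,200) and [149,250): union is 151 bases, not 202
        win = make_windows({"c": 100_000})
        out = repeat_density(win, [_te("c", 99, 200), _te("c", 149, 250)])
        assert out.repeat_density[0] == pytest.approx(151 / 100_000)

    def test_no_records_zero(self):
        win = make_windows({"c": 100_000})
        assert repeat_density(win, []).repeat_density[0] == 0.0

    def test_record_beyond_chromosome_end_rejected(self):
        win = make_windows({"c": 100_000})
        with pytest.raises(ValueError):
            repeat_density(win, [_te("c", 99_000, 120_000)], {"c": 100_000})

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        recs = [_te("c", s, s + 500) for s in rng.integers(0, 99_000, 200)]
        win = make_windows({"c": 100_000}, window=10_000)
        a = repeat_density(win, recs).repeat_density
        b = repeat_density(win, recs[::-1]).repeat_density
        assert np.array_equal(a, b)


class TestGC:
    def _fasta(self, tmp_path, seqs):
        path = tmp_path / "g.fa"
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    def test_balanced_sequence(self, tmp_path):
        fa = self._fasta(tmp_path, {"c": "GGCCAATT" + "A" * 9_992})
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [8]})
        assert gc_content(win, fa).gc[0] == pytest.approx(0.5)

    def test_n_bases_excluded_from_denominator(self, tmp_path):
        fa = self._fasta(tmp_path, {"c": "GGNN" + "A" * 9_996})
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [4]})
        out = gc_content(win, fa)
        assert out.gc[0] == pytest.approx(1.0)
        assert out.n_effective_bases[0] == 2

    def test_all_n_window_missing(self, tmp_path):
        fa = self._fasta(tmp_path, {"c": "NNNN" + "A" * 9_996})
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [4]})
        assert np.isnan(gc_content(win, fa).gc[0])

    def test_missing_chromosome_rejected(self, tmp_path):
        fa = self._fasta(tmp_path, {"c": "ACGT" * 2_500})
        win = pd.DataFrame({"chrom": ["zz"], "start": [0], "end": [4]})
        with pytest.raises(KeyError):
            gc_content(win, fa)

    def test_soft_masked_counts_normally(self, tmp_path):
        fa = self._fasta(tmp_path, {"c": "gcgc" + "A" * 9_996})
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [4]})
        assert gc_content(win, fa).gc[0] == pytest.approx(1.0)


class TestCDSDensity:
    def _gff(self, tmp_path, rows):
        path = tmp_path / "a.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, s, e, tid in rows:
                fh.write(f"{chrom}\tx\tmRNA\t{s + 1}\t{e}\t.\t+\t.\tID={tid}\n")
                fh.write(f"{chrom}\tx\tCDS\t{s + 1}\t{e}\t.\t+\t0\tParent={tid}\n")
        return path

    def test_half_window(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 0, 50_000, "t1")])
        win = make_windows({"c": 100_000})
        assert cds_density(win, gff).cds_density[0] == pytest.approx(0.5)

    def test_shared_exon_counted_once(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 0, 30_000, "t1"), ("c", 0, 30_000, "t2")])
        win = make_windows({"c": 100_000})
        assert cds_density(win, gff).cds_density[0] == pytest.approx(0.3)

    def test_cds_spanning_window_boundary_split(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 90_000, 130_000, "t1")])
        win = make_windows({"c": 200_000})
        out = cds_density(win, gff)
        assert out.cds_density[0] == pytest.approx(10_000 / 100_000)
        assert out.cds_density[1] == pytest.approx(30_000 / 100_000)

    def test_no_cds_rejected(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\nc\tx\tgene\t1\t10\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError):
            cds_density(make_windows({"c": 100_000}), path)


class TestChromosomeSummary:
    def test_zero_variance_collapses_ci(self):
        win = pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                            "stat": [0.3] * 20})
        out = chromosome_summary(win, "stat", n_boot=100, seed=0)
        assert out.mean_stat[0] == pytest.approx(0.3)
        assert out.ci_low[0] == pytest.approx(0.3)
        assert out.ci_high[0] == pytest.approx(0.3)

    def test_single_window_point_ci(self):
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1], "stat": [0.4]})
        out = chromosome_summary(win, "stat", seed=0)
        assert out.ci_low[0] == out.ci_high[0] == pytest.approx(0.4)

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(3)
        win = pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                            "stat": rng.normal(0.4, 0.05, 100)})
        out = chromosome_summary(win, "stat", seed=1)
        assert out.ci_low[0] <= out.mean_stat[0] <= out.ci_high[0]

    def test_ci_width_shrinks_with_window_count(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (10, 100, 1000):
            win = pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                                "stat": rng.normal(0.4, 0.05, n)})
            out = chromosome_summary(win, "stat", seed=2)
            widths.append(out.ci_high[0] - out.ci_low[0])
        assert widths[0] > widths[1] > widths[2]

    def test_no_windows_rejected(self):
        win = pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                            "stat": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            chromosome_summary(win, "stat", seed=0)


class TestTelomereProfile:
    def test_terminal_enrichment_detected(self):
        sizes = {"c1": 1_000_000, "c2": 800_000}
        recs = []
        for chrom, L in sizes.items():
            for s in range(0, 90_000, 2_000):
                recs.append(_te(chrom, s, s + 1_000))
                recs.append(_te(chrom, L - s - 1_001, L - s - 1))
        prof = telomere_profile(recs, sizes, bin_size=100_000)
        assert prof.repeat_density[0] > 10 * prof.repeat_density[2:].fillna(0).max()

    def test_empty_records_all_zero(self):
        prof = telomere_profile([], {"c": 1_000_000}, bin_size=100_000)
        assert (prof.repeat_density.fillna(0) == 0).all()

    def test_oversized_bin_rejected(self):
        with pytest.raises(ValueError):
            telomere_profile([], {"c": 150_000}, bin_size=100_000)

    def test_uniform_placement_roughly_flat(self):
        rng = np.random.default_rng(5)
        sizes = {"c": 2_000_000}
        recs = [_te("c", s, s + 500) for s in rng.integers(0, 1_999_000, 4_000)]
        prof = telomere_profile(recs, sizes, bin_size=200_000)
        dens = prof.repeat_density.dropna()
        assert dens.max() - dens.min() < 0.15 * dens.mean() + 0.05
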