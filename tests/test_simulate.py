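import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from telandscape.repeatmasker import read_repeatmasker, records_to_frame
from telandscape.simulate import (
    PopGenParams, TELandscapeParams, default_chrom_lengths, make_fixture_suite,
    simulate_popgen, simulate_te_landscape,
)


class TestLandscape:
    def test_deletion_conserves_length(self):
        params = TELandscapeParams(chrom_lengths=[2_000_000, 1_000_000], seed=3)
        _, sizes, truth = simulate_te_landscape(params)
        for chrom, t in truth["chromosomes"].items():
            assert t["final_length"] == t["initial_length"] - t["deleted_bases"]
            assert sizes[chrom] == t["final_length"]

    def test_no_young_epoch_means_no_young_records(self):
        params = TELandscapeParams(chrom_lengths=[1_000_000], a_young=0.0, seed=4)
        records, _, _ = simulate_te_landscape(params)
        assert all(r.divergence >= 5.0 for r in records)

    def test_divergence_strata_match_epochs(self):
        params = TELandscapeParams(chrom_lengths=[2_000_000], seed=5)
        records, _, truth = simulate_te_landscape(params)
        divs = np.array([r.divergence for r in records])
        t = truth["chromosomes"]["chr1"]
        assert (divs < 5).sum() == t["n_young"]
        assert ((divs >= 5) & (divs <= 10)).sum() == t["n_old"]

    def test_excess_footprint_rejected(self):
        params = TELandscapeParams(chrom_lengths=[50_000], a_old=2000.0, seed=6)
        with pytest.raises(ValueError, match="footprint"):
            simulate_te_landscape(params)

    def test_records_within_chromosome(self):
        params = TELandscapeParams(chrom_lengths=[1_500_000], seed=7)
        records, sizes, _ = simulate_te_landscape(params)
        assert all(0 <= r.start < r.end <= sizes[r.chrom] for r in records)

    def test_size_dependent_deletion_compresses_old_spacing(self):
        """With d<0, small chromosomes delete more inter-TE sequence, so the
        young/old spacing ratio decreases with length (single-seed check)."""
        from telandscape.spacing import spacing_table
        from telandscape.stats import spearman

        params = TELandscapeParams(seed=8)
        records, sizes, _ = simulate_te_landscape(params)
        tab = spacing_table(records_to_frame(records))
        tab["length"] = tab["chrom"].map(sizes)
        rho, _ = spearman(tab["length"], tab["ratio_young_over_old"])
        assert rho < 0


class TestFixtureSuite:
    def test_same_seed_byte_identical(self, tmp_path):
        m1 = make_fixture_suite(tmp_path / "a", seed=3)
        m2 = make_fixture_suite(tmp_path / "b", seed=3)
        assert m1 == m2
        for name in m1:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seed_changes_vcf_body_not_header(self, tmp_path):
        make_fixture_suite(tmp_path / "a", seed=3)
        make_fixture_suite(tmp_path / "b", seed=4)

        def split(path):
            header, body = [], []
            for line in open(path):
                (header if line.startswith("#") else body).append(line)
            return header, body

        h1, b1 = split(tmp_path / "a" / "allsites.vcf")
        h2, b2 = split(tmp_path / "b" / "allsites.vcf")
        assert h1 == h2
        assert b1 != b2

    def test_outputs_parse_through_every_reader(self, fixture_dir):
        import pysam
        from cyvcf2 import VCF

        from telandscape.windows import read_cds_intervals, read_chrom_sizes

        records = read_repeatmasker(fixture_dir / "repeats.out")
        assert records
        sizes = read_chrom_sizes(fixture_dir / "chrom_sizes.tsv")
        with pysam.FastaFile(str(fixture_dir / "genome.fa")) as fa:
            assert dict(zip(fa.references, fa.lengths)) == sizes
        cds = read_cds_intervals(fixture_dir / "genes.gff3")
        assert len(cds) > 0
        n = sum(1 for _ in VCF(str(fixture_dir / "allsites.vcf")))
        assert n == sum(sizes.values())


class TestPopGen:
    def test_theta_zero_gives_invariant_vcf(self, tmp_path):
        from telandscape.diversity import pi_windows
        from telandscape.windows import make_windows

        fa = tmp_path / "g.fa"
        fa.write_text(">c\n" + "ACGT" * 1000 + "\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tmRNA\t1\t300\t.\t+\t.\tID=t1\n"
            "c\tx\tCDS\t1\t300\t.\t+\t0\tParent=t1\n"
        )
        vcf = tmp_path / "all.vcf"
        simulate_popgen(PopGenParams(theta_neutral=0.0, missing_rate=0.0, seed=1),
                        fa, gff, vcf)
        win = make_windows({"c": 4000}, 4000, min_tail=1)
        _, ctab = pi_windows(vcf, win)
        assert ctab.pi[0] == 0.0

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            PopGenParams(theta_neutral=0.2)

    def test_neutral_diversity_recovered(self, fixture_dir):
        """Genome-wide pi at neutral sites matches the generating theta."""
        from telandscape.diversity import pi_windows
        from telandscape.windows import make_windows, read_chrom_sizes

        sizes = read_chrom_sizes(fixture_dir / "chrom_sizes.tsv")
        win = make_windows(sizes, 20_000)
        _, ctab = pi_windows(fixture_dir / "allsites.vcf", win)
        truth = json.load(open(fixture_dir / "truth_popgen.json"))
        theta = truth["params"]["theta_neutral"]
        # all-sites pi is dominated by neutral sites; ~200 kb of sites
        pooled = np.average(ctab.pi_ratio_of_sums, weights=[sizes[c] for c in ctab.chrom])
        assert pooled == pytest.approx(theta, rel=0.12)

    def test_selected_sites_depleted_in_diversity(self, fixture_dir):
        from telandscape.diversity import pi_windows, read_bed
        from telandscape.degeneracy import build_coding_index, write_degeneracy_beds
        from telandscape.windows import make_windows, read_chrom_sizes

        index = build_coding_index(fixture_dir / "genome.fa",
                                   fixture_dir / "genes.gff3")
        p0, p4 = write_degeneracy_beds(index, str(fixture_dir / "sites"))
        sizes = read_chrom_sizes(fixture_dir / "chrom_sizes.tsv")
        win = make_windows(sizes, 200_000, min_tail=1)
        _, c0 = pi_windows(fixture_dir / "allsites.vcf", win, site_mask=read_bed(p0))
        _, c4 = pi_windows(fixture_dir / "allsites.vcf", win, site_mask=read_bed(p4))
        assert np.nansum(c0.pi_ratio_of_sums) < 0.5 * np.nansum(c4.pi_ratio_of_sums)

    def test_missing_rate_reflected_in_genotypes(self, fixture_dir):
        from cyvcf2 import VCF

        missing = total = 0
        for v in VCF(str(fixture_dir / "allsites.vcf")):
            g = np.array(v.genotypes)[:, :2]
            missing += int((g < 0).sum())
            total += g.size
            if total > 200_000:
                break
        assert missing / total == pytest.approx(0.05, abs=0.01)
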