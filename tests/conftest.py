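import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic miniature dataset (3 chromosomes, 8 diploids)."""
    from telandscape.simulate import make_fixture_suite

    outdir = tmp_path_factory.mktemp("fixture")
    make_fixture_suite(outdir, seed=7)
    return outdir


def write_allsites_vcf(path, chrom, refs, allele_matrix, alts=None):
    """Write a small all-sites VCF from an allele matrix.

    ``allele_matrix`` is (n_sites, n_haplotypes) of allele indices with -1
    for missing; haplotypes pair up into diploid genotypes.  ``refs`` is the
    reference base per site; ``alts`` the alternate base per site (default T
    unless ref is T).
    """
    allele_matrix = np.asarray(allele_matrix)
    n_sites, n_hap = allele_matrix.shape
    assert n_hap % 2 == 0
    n_ind = n_hap // 2
    if alts is None:
        alts = ["T" if r != "T" else "A" for r in refs]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom},length={n_sites}>\n")
        samples = "\t".join(f"s{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for s in range(n_sites):
            row = allele_matrix[s]
            alt = alts[s] if (row == 1).any() else "."
            gts = []
            for i in range(n_ind):
                a, b = row[2 * i], row[2 * i + 1]
                gts.append(f"{'.' if a < 0 else a}/{'.' if b < 0 else b}")
            fh.write(
                f"{chrom}\t{s + 1}\t.\t{refs[s]}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


def naive_pi(allele_matrix):
    """Average pairwise difference per site over haplotype pairs, full-call.

    Independent oracle: explicit double loop over haplotype pairs.
    """
    m = np.asarray(allele_matrix)
    n_sites, n_hap = m.shape
    total = 0
    n_pairs = 0
    for i in range(n_hap):
        for j in range(i + 1, n_hap):
            total += int(np.sum(m[:, i] != m[:, j]))
            n_pairs += 1
    return total / (n_pairs * n_sites)
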