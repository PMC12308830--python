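"""Ground-truth genome, TE-annotation and population-sample generators.

The landscape generator embodies the mechanism under study: TEs insert in
two discrete epochs (old copies at 5-10% divergence, young at <5%), and
between the epochs each stretch of unique sequence between adjacent old
copies loses a Binomial(gap, delta(L)) number of bases — a deletion-biased,
NAHR-like removal of inter-TE sequence whose rate delta(L) = c * (L/Mb)^d
can depend on chromosome length.  With d < 0, smaller chromosomes lose
unique sequence faster, which simultaneously raises their final TE density
and pulls their old copies closer together than their young ones — the two
qualitative signatures the analysis modules are meant to detect.  Insertion
rates are power laws lambda(L) = a * (L/Mb)^b per Mb (size-independent by
default).

The population generator writes an all-sites VCF with known per-site theta:
sites are independent (no linkage), neutral sites segregate in frequency
class i (of n sampled alleles) with probability theta/i — giving expected
pairwise diversity exactly theta — and 0-fold sites draw their class from
the Poisson-random-field expectation integrated over a gamma DFE.  Sampled
allele counts are assigned directly to haplotypes (the class probabilities
already describe the sample), and genotypes go missing at a fixed rate.

Default parameter choices mirror the observed scale of lepidopteran
genomes: ~30% of the assembly under TEs, TE fragments averaging ~1.2 kb,
chromosomes spanning a several-fold size range, synonymous-site diversity
near 0.008.
"""

from __future__ import annotations

import functools
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dfe import gamma_expected_unfolded
from .repeatmasker import TEAnnotation, write_repeatmasker

logger = logging.getLogger(__name__)

__all__ = [
    "TELandscapeParams",
    "PopGenParams",
    "simulate_te_landscape",
    "simulate_popgen",
    "simulate_sfs_pair",
    "make_fixture_suite",
    "default_chrom_lengths",
]

_MB = 1_000_000

#: small seeded motif catalogue for TE bodies and family labels
_TE_CATALOG = [
    ("L1-1_sim", "LINE", "L1", 0.35),
    ("RTE-2_sim", "LINE", "RTE", 0.20),
    ("Gypsy-1_sim", "LTR", "Gypsy", 0.15),
    ("hAT-3_sim", "DNA", "hAT", 0.15),
    ("SINE-1_sim", "SINE", "tRNA-Deu", 0.10),
    ("Helitron-1_sim", "RC", "Helitron", 0.05),
]


def default_chrom_lengths(n_chrom: int = 20, min_len: int = 5 * _MB,
                          max_len: int = 30 * _MB) -> list[int]:
    """Evenly log-spaced chromosome lengths spanning a realistic size range."""
    return [int(x) for x in np.geomspace(min_len, max_len, n_chrom)]


@dataclass
class TELandscapeParams:
    """Generating parameters for the two-epoch TE landscape.

    Insertion rates are per Mb: lambda(L) = a * (L/Mb)^b.  The deletion
    fraction applied to each inter-TE gap between the epochs is
    delta(L) = c * (L/Mb)^d, clipped to [0, 1].
    """

    chrom_lengths: list[int] = field(default_factory=default_chrom_lengths)
    a_old: float = 120.0
    b_old: float = 0.0
    a_young: float = 80.0
    b_young: float = 0.0
    c_del: float = 0.8
    d_del: float = -0.5
    te_length_mean: float = 1200.0
    te_length_sigma: float = 0.6  # lognormal sigma (log scale)
    te_length_min: int = 80
    gene_density: float = 8.0  # genes per Mb (sequence-emitting mode)
    gc_baseline: float = 0.38
    seed: int = 0

    def rate_old(self, L: float) -> float:
        return self.a_old * (L / _MB) ** self.b_old

    def rate_young(self, L: float) -> float:
        return self.a_young * (L / _MB) ** self.b_young

    def deletion_fraction(self, L: float) -> float:
        return float(np.clip(self.c_del * (L / _MB) ** self.d_del, 0.0, 1.0))


@dataclass
class PopGenParams:
    """Generating parameters for the all-sites population sample."""

    theta_neutral: float = 0.008  # per-site, 4D and noncoding
    n_diploids: int = 8
    dfe_beta: float = 0.3
    dfe_s_mean: float = 500.0  # magnitude of the mean scaled coefficient
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.theta_neutral < 0.1:
            raise ValueError("theta must lie in [0, 0.1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")


def _sample_te_lengths(rng, n, params) -> np.ndarray:
    mu = np.log(params.te_length_mean) - params.te_length_sigma ** 2 / 2
    lens = rng.lognormal(mu, params.te_length_sigma, size=n)
    return np.maximum(lens.astype(np.int64), params.te_length_min)


def _place_nonoverlapping(rng, L, lengths) -> tuple[np.ndarray, np.ndarray]:
    """Uniform non-overlapping placement: spread the free bases over gaps."""
    n = lengths.size
    total = int(lengths.sum())
    if total >= L:
        raise ValueError(
            f"expected TE footprint {total} exceeds chromosome length {L}"
        )
    free = L - total
    # n+1 gap sizes ~ uniform composition of the free sequence
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    gaps = np.diff(np.concatenate([[0], cuts, [free]]))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts, starts + lengths


def simulate_te_landscape(
    params: TELandscapeParams,
    outdir=None,
    emit_sequence: bool = False,
):
    """Generate a two-epoch TE landscape with NAHR-like inter-TE deletion.

    Returns ``(records, chrom_sizes, truth)`` where ``records`` is a list of
    :class:`TEAnnotation` on the final coordinates, ``chrom_sizes`` maps
    chromosome name to final length, and ``truth`` records every generating
    quantity.  With ``outdir`` set, a RepeatMasker-style ``.out`` file, a
    chromosome-size table and the truth JSON are written; ``emit_sequence``
    additionally writes a consistent FASTA and a GFF3 of non-overlapping
    genes (intended for the small fixture genomes).
    """
    rng = np.random.default_rng(params.seed)
    records: list[TEAnnotation] = []
    chrom_sizes: dict[str, int] = {}
    truth = {"params": asdict(params), "chromosomes": {}}
    sequences: dict[str, np.ndarray] = {}
    gene_rows = []

    for ci, L0 in enumerate(params.chrom_lengths, start=1):
        chrom = f"chr{ci}"
        L0 = int(L0)
        # epoch 1: old insertions
        n_old = rng.poisson(params.rate_old(L0) * L0 / _MB)
        old_lens = _sample_te_lengths(rng, n_old, params)
        old_starts, old_ends = _place_nonoverlapping(rng, L0, old_lens)
        # NAHR-like deletion of unique sequence between adjacent old copies
        delta = params.deletion_fraction(L0)
        deleted = 0
        if n_old >= 2 and delta > 0:
            gaps = old_starts[1:] - old_ends[:-1]
            losses = rng.binomial(gaps, delta)
            deleted = int(losses.sum())
            shift = np.concatenate([[0], np.cumsum(losses)])
            old_starts = old_starts - shift
            old_ends = old_ends - shift
        L1 = L0 - deleted
        # epoch 2: young insertions on the shrunken chromosome
        n_young = rng.poisson(params.rate_young(L1) * L1 / _MB)
        young_lens = _sample_te_lengths(rng, n_young, params)
        young_lens = np.minimum(young_lens, max(L1 - 1, 1))
        young_starts = rng.integers(0, np.maximum(L1 - young_lens, 1))
        young_ends = young_starts + young_lens

        # floor-quantise to the .out printed precision without crossing the
        # 5% young/old boundary
        old_div = np.floor(rng.uniform(5.0, 10.0, size=n_old) * 10) / 10
        young_div = np.floor(rng.uniform(0.0, 5.0, size=n_young) * 10) / 10
        cat_p = np.array([c[3] for c in _TE_CATALOG])
        all_starts = np.concatenate([old_starts, young_starts]).astype(np.int64)
        all_ends = np.concatenate([old_ends, young_ends]).astype(np.int64)
        all_divs = np.concatenate([old_div, young_div])
        all_kinds = rng.choice(len(_TE_CATALOG), size=all_starts.size, p=cat_p)
        for s, e, d, k in zip(all_starts, all_ends, all_divs, all_kinds):
            name, klass, family, _ = _TE_CATALOG[k]
            records.append(TEAnnotation(
                chrom=chrom, start=int(s), end=int(e), strand="+",
                divergence=float(d), repeat_name=name,
                te_class=klass, te_family=family,
                score=int(1000 - 50 * d),
            ))
        chrom_sizes[chrom] = L1
        truth["chromosomes"][chrom] = {
            "initial_length": L0,
            "final_length": L1,
            "deleted_bases": deleted,
            "deletion_fraction": delta,
            "n_old": int(n_old),
            "n_young": int(n_young),
        }
        if emit_sequence:
            seq = rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8), size=L1,
                p=[(1 - params.gc_baseline) / 2, params.gc_baseline / 2,
                   params.gc_baseline / 2, (1 - params.gc_baseline) / 2],
            )
            _write_te_bodies(rng, seq, all_starts, all_ends, all_divs,
                             all_kinds, _te_motifs(params.seed))
            sequences[chrom] = seq
            gene_rows.extend(_place_genes(rng, chrom, L1, params, seq))

    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_repeatmasker(records, outdir / "repeats.out")
        pd.DataFrame(
            {"chrom": list(chrom_sizes), "length": list(chrom_sizes.values())}
        ).to_csv(outdir / "chrom_sizes.tsv", sep="\t", header=False, index=False)
        with open(outdir / "truth_landscape.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        if emit_sequence:
            _write_fasta(sequences, outdir / "genome.fa")
            _write_gff3(gene_rows, outdir / "genes.gff3")
    return records, chrom_sizes, truth


@functools.lru_cache(maxsize=8)
def _te_motifs(seed: int) -> tuple[np.ndarray, ...]:
    """One seeded 2-kb consensus body per catalogue family."""
    rng = np.random.default_rng(seed ^ 0x7E5EED)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return tuple(rng.choice(alphabet, size=2000) for _ in _TE_CATALOG)


def _write_te_bodies(rng, seq, starts, ends, divs, kinds, motifs) -> None:
    """Stamp each TE body into the sequence: tiled consensus plus point
    mutations at the annotated divergence rate."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for s, e, d, k in zip(starts, ends, divs, kinds):
        motif = motifs[k]
        body = np.resize(motif, e - s).copy()
        mut = rng.random(e - s) < d / 100.0
        if mut.any():
            body[mut] = alphabet[rng.integers(0, 4, size=int(mut.sum()))]
        seq[s:e] = body


_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


def _place_genes(rng, chrom, L, params, seq) -> list[tuple]:
    """Non-overlapping single-CDS genes; coding sequence free of internal stops."""
    n_genes = rng.poisson(params.gene_density * L / _MB)
    if n_genes == 0:
        return []
    cds_lens = 3 * rng.integers(100, 400, size=n_genes)  # 300-1200 bp
    try:
        starts, ends = _place_nonoverlapping(rng, L, cds_lens.astype(np.int64))
    except ValueError:
        return []
    rows = []
    for gi, (s, e) in enumerate(zip(starts, ends), start=1):
        n_codon = (e - s) // 3
        codons = ["ATG"] + [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codon - 2)
        ] + ["TAA"]
        cds = "".join(codons)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            cds = "".join(comp[b] for b in reversed(cds))
        seq[s:e] = np.frombuffer(cds.encode(), dtype=np.uint8)
        rows.append((chrom, int(s), int(e), strand, f"{chrom}_g{gi}"))
    return rows


def _write_fasta(sequences: dict[str, np.ndarray], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _write_gff3(gene_rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, strand, gid in gene_rows:
            fh.write(f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n")
            fh.write(
                f"{chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            fh.write(
                f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1\n"
            )


def _neutral_class_probs(theta: float, n_hap: int) -> np.ndarray:
    """P(site segregates in sample class i) = theta / i, i = 1..n-1."""
    return theta / np.arange(1, n_hap)


def _selected_class_probs(theta: float, beta: float, s_mean: float, n_hap: int) -> np.ndarray:
    e = gamma_expected_unfolded(beta, s_mean, n_hap)
    return theta * e


def simulate_popgen(
    params: PopGenParams,
    fasta_path,
    annotation_path,
    out_vcf,
) -> dict:
    """Write an all-sites VCF over the given genome with known diversity.

    0-fold degenerate sites evolve under the gamma DFE; every other site
    (4-fold, other coding, noncoding) is neutral with per-site diversity
    ``theta_neutral``.  Returns the truth record (per-chromosome expected
    diversity, realised segregating-site counts, and the generating
    parameters).
    """
    import pysam

    from .degeneracy import build_coding_index

    rng = np.random.default_rng(params.seed)
    n_hap = 2 * params.n_diploids
    index = build_coding_index(fasta_path, annotation_path)
    sites_0d = index.positions("0D")

    p_neu = _neutral_class_probs(params.theta_neutral, n_hap)
    p_sel = _selected_class_probs(
        params.theta_neutral, params.dfe_beta, params.dfe_s_mean, n_hap
    )
    if p_neu.sum() >= 1 or p_sel.sum() >= 1:
        raise ValueError("theta too large: per-site segregation probability >= 1")

    truth = {
        "params": asdict(params),
        "n_haplotypes": n_hap,
        "expected_pi_neutral": params.theta_neutral,
        "chromosomes": {},
    }
    with pysam.FastaFile(str(fasta_path)) as fa, open(out_vcf, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in fa.references:
            L = fa.get_reference_length(chrom)
            out.write(f"##contig=<ID={chrom},length={L}>\n")
        samples = [f"ind{i + 1}" for i in range(params.n_diploids)]
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom in fa.references:
            L = fa.get_reference_length(chrom)
            ref = fa.fetch(chrom).upper()
            is_sel = np.zeros(L, dtype=bool)
            if chrom in sites_0d:
                is_sel[sites_0d[chrom]] = True
            # draw per-site sample class: 0 = invariant, i = alt count i
            u = rng.random(L)
            classes = np.zeros(L, dtype=np.int64)
            for probs, mask in ((p_neu, ~is_sel), (p_sel, is_sel)):
                edges = np.cumsum(probs)
                # u < edges[0] -> class 1 (count 1), ..., u >= edges[-1] -> invariant
                cls = np.searchsorted(edges, u, side="right") + 1
                seg = (cls <= n_hap - 1) & (u < edges[-1])
                classes[mask & seg] = cls[mask & seg]
            missing = rng.random((L, params.n_diploids)) < params.missing_rate
            seg_sites = np.flatnonzero(classes)
            # assign alt alleles to random haplotypes at each segregating site
            hap_alt = {}
            for pos in seg_sites:
                hap_alt[pos] = rng.choice(n_hap, size=classes[pos], replace=False)
            alt_bases = rng.integers(0, 3, size=L)
            lines = []
            for pos in range(L):
                rb = ref[pos]
                if rb not in "ACGT":
                    continue
                if classes[pos]:
                    alt_field = [b for b in "ACGT" if b != rb][alt_bases[pos]]
                    gt_alleles = np.zeros(n_hap, dtype=np.int64)
                    gt_alleles[hap_alt[pos]] = 1
                else:
                    gt_alleles = np.zeros(n_hap, dtype=np.int64)
                    alt_field = "."
                gts = []
                for ind in range(params.n_diploids):
                    if missing[pos, ind]:
                        gts.append("./.")
                    else:
                        gts.append(f"{gt_alleles[2 * ind]}/{gt_alleles[2 * ind + 1]}")
                lines.append(
                    f"{chrom}\t{pos + 1}\t.\t{rb}\t{alt_field}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                )
            out.write("\n".join(lines) + "\n")
            truth["chromosomes"][chrom] = {
                "length": int(L),
                "n_segregating": int(len(seg_sites)),
                "n_selected_sites": int(is_sel.sum()),
            }
    return truth


def simulate_sfs_pair(
    beta: float,
    s_mean: float,
    n_hap: int,
    L_syn: float,
    L_nonsyn: float,
    theta: float,
    seed: int,
):
    """Poisson-sample a synonymous/nonsynonymous folded SFS pair from the model.

    Synonymous classes have mean theta * L_syn / i (folded); nonsynonymous
    classes take the gamma-DFE expectation.  Used for parameter-recovery
    studies.
    """
    from .dfe import gamma_expected_folded, _grid_tables
    from .sfs import FoldedSFS

    rng = np.random.default_rng(seed)
    neutral_f = _grid_tables(n_hap)[3]
    b = gamma_expected_folded(beta, s_mean, n_hap)
    s = rng.poisson(theta * L_syn * neutral_f).astype(float)
    d = rng.poisson(theta * L_nonsyn * b).astype(float)
    return (
        FoldedSFS(n=n_hap, counts=s, L=L_syn, site_class="synonymous"),
        FoldedSFS(n=n_hap, counts=d, L=L_nonsyn, site_class="nonsynonymous"),
    )


def make_fixture_suite(outdir, seed: int = 0) -> dict:
    """Deterministic miniature dataset exercising every reader and writer.

    Three chromosomes (120/80/50 kb), eight diploids; returns a manifest of
    written files with SHA-256 checksums.  The same seed reproduces the
    files byte for byte.  The seed drives the population sample; the
    landscape itself is fixed so that the genome (and the VCF contig
    header) is identical across seeds while the genotype bodies differ.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # deletion power law rescaled to the sub-Mb fixture chromosomes
    # (delta ~ 0.20-0.31 across 120-50 kb, as on the Mb-scale defaults)
    land = TELandscapeParams(
        chrom_lengths=[120_000, 80_000, 50_000],
        a_old=120.0, a_young=80.0, c_del=0.07, d_del=-0.5,
        gene_density=120.0, seed=20_250,
    )
    simulate_te_landscape(land, outdir=outdir, emit_sequence=True)
    pop = PopGenParams(seed=seed)
    truth_pop = simulate_popgen(
        pop, outdir / "genome.fa", outdir / "genes.gff3", outdir / "allsites.vcf"
    )
    with open(outdir / "truth_popgen.json", "w") as fh:
        json.dump(truth_pop, fh, indent=1, sort_keys=True)
    manifest = {}
    for name in ["genome.fa", "genes.gff3", "repeats.out", "chrom_sizes.tsv",
                 "allsites.vcf", "truth_landscape.json", "truth_popgen.json"]:
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(outdir / "checksums.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
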