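"""Folded site-frequency spectra from classified SNPs.

The folded SFS tabulates minor-allele counts 1..n/2 at a fixed haploid
sample size n; no ancestral-state polarization is required.  Sites genotyped
in more individuals than the target are hypergeometrically projected down
(the expected fractional contribution of each subsampled allele count);
sites with fewer called alleles than the target are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF
from scipy.stats import hypergeom

__all__ = ["FoldedSFS", "fold", "project_site", "build_folded_sfs"]


@dataclass
class FoldedSFS:
    """Minor-allele-count spectrum at haploid sample size ``n``.

    ``counts[i-1]`` holds (possibly fractional, after projection) the number
    of sites in folded class i, i = 1..n//2.  ``L`` is the number of
    surveyed sites of this class (monomorphic included).
    """

    n: int
    counts: np.ndarray
    L: float
    site_class: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n // 2,):
            raise ValueError(f"expected {self.n // 2} classes for n={self.n}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")

    @property
    def n_segregating(self) -> float:
        return float(self.counts.sum())


def fold(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum over classes 1..n-1 into classes 1..n//2."""
    u = np.asarray(unfolded, dtype=float)
    n = u.size + 1
    half = n // 2
    folded = np.zeros(half)
    for i in range(1, half + 1):
        if i == n - i:
            folded[i - 1] = u[i - 1]
        else:
            folded[i - 1] = u[i - 1] + u[n - i - 1]
    return folded


def project_site(count: int, k: int, n: int) -> np.ndarray:
    """Expected unfolded class weights after subsampling n of k alleles.

    Returns weights over classes 0..n (hypergeometric probabilities of the
    alternate-allele count in a random subsample without replacement).
    """
    if n > k:
        raise ValueError("cannot project up")
    j = np.arange(n + 1)
    return hypergeom.pmf(j, k, count, n)


def build_folded_sfs(
    vcf_path,
    effect_of,
    n_target: int,
    L_syn: float,
    L_nonsyn: float,
    projection: bool = True,
) -> tuple[FoldedSFS, FoldedSFS]:
    """Folded synonymous and nonsynonymous SFS from a VCF.

    ``effect_of(chrom, pos0, ref, alt)`` labels each biallelic SNP
    ('synonymous' / 'nonsynonymous' / anything else ignored); a
    ``CodingIndex.snp_effect`` bound method fits directly.  With
    ``projection`` (default) sites called in more than ``n_target`` alleles
    contribute fractionally via hypergeometric projection; without it they
    contribute their minor-allele count only when exactly ``n_target``
    alleles are called.  Raises if no site reaches ``n_target`` called
    alleles.
    """
    if n_target < 4:
        raise ValueError("n_target must be >= 4")
    unfolded = {
        "synonymous": np.zeros(n_target + 1),
        "nonsynonymous": np.zeros(n_target + 1),
    }
    max_called = 0
    for v in VCF(str(vcf_path)):
        if not v.ALT or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        alleles = np.array(v.genotypes, dtype=np.int64)[:, :2].ravel()
        alleles = alleles[alleles >= 0]
        k = alleles.size
        max_called = max(max_called, k)
        if k < n_target:
            continue
        c = int((alleles == 1).sum())
        if c == 0 or c == k:
            continue
        label = effect_of(v.CHROM, v.POS - 1, v.REF, v.ALT[0])
        if label not in unfolded:
            continue
        if k == n_target:
            unfolded[label][c] += 1.0
        elif projection:
            unfolded[label] += project_site(c, k, n_target)
    if max_called < n_target:
        raise ValueError(
            f"n_target={n_target} exceeds the maximum called allele number {max_called}"
        )
    out = []
    for label, L in (("synonymous", L_syn), ("nonsynonymous", L_nonsyn)):
        folded = fold(unfolded[label][1:n_target])
        out.append(FoldedSFS(n=n_target, counts=folded, L=L, site_class=label))
    return tuple(out)
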