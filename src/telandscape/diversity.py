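"""Missing-data-aware nucleotide diversity from an all-sites VCF.

Per site with k called alleles, the number of pairwise differences is
summed over unordered allele pairs and the number of comparisons is
k(k-1)/2; window diversity is the ratio of the two sums over retained sites
(a ratio of sums, never a mean of per-site ratios), which stays unbiased
when genotypes are missing at random.  Invariant sites enter the denominator
— hence the all-sites VCF requirement.

Chromosome-level diversity is the unweighted mean of window values (windows
with zero comparisons are dropped and counted); the 0D/4D ratio divides the
chromosome means.  A site mask (e.g. a 0D or 4D BED) restricts which sites
contribute, and an exclusion BED removes low-quality sites.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .intervals import merge_intervals, points_in_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "site_diversity_arrays",
    "pi_windows",
    "chromosome_pi_ratio",
    "read_bed",
]


def read_bed(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """BED -> per-chromosome merged (starts, ends), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str},
                     comment="#")
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        out[chrom] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def site_diversity_arrays(allele_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (diffs, comparisons) from an allele-count matrix.

    ``allele_counts[s, a]`` is the number of called copies of allele ``a`` at
    site ``s``.  diffs = (k^2 - sum c_a^2)/2, comparisons = k(k-1)/2.
    """
    counts = np.asarray(allele_counts, dtype=np.int64)
    k = counts.sum(axis=1)
    diffs = (k * k - (counts * counts).sum(axis=1)) // 2
    comps = k * (k - 1) // 2
    return diffs, comps


def _mask_lookup(mask, chrom):
    if mask is None:
        return None
    if isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
        raise TypeError("pass masks through read_bed() first")
    return mask.get(chrom)


def pi_windows(
    vcf_path,
    windows: pd.DataFrame,
    site_mask: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
    exclude: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window and chromosome diversity from an all-sites VCF.

    Returns ``(window_table, chrom_table)``.  The window table adds ``pi``,
    ``n_diffs``, ``n_comparisons`` and ``n_sites`` columns; the chromosome
    table holds the unweighted mean of window pi (``pi``), the whole-
    chromosome ratio of sums (``pi_ratio_of_sums``), and the count of
    windows dropped for lacking comparisons.

    ``site_mask``/``exclude`` are per-chromosome merged interval dicts (see
    ``read_bed``).  When a mask is given only masked sites contribute.
    Chromosomes present in ``windows`` but absent from the VCF are an error.
    """
    win = windows.reset_index(drop=True).copy()
    diffs_sum = np.zeros(len(win), dtype=np.int64)
    comps_sum = np.zeros(len(win), dtype=np.int64)
    nsites = np.zeros(len(win), dtype=np.int64)

    vcf = VCF(str(vcf_path))
    vcf_chroms = set(vcf.seqnames)
    by_chrom = {c: idx for c, idx in win.groupby("chrom", sort=False).indices.items()}
    for chrom in by_chrom:
        if chrom not in vcf_chroms:
            raise KeyError(f"chromosome {chrom} absent from VCF {vcf_path}")

    starts = {c: win["start"].to_numpy()[i] for c, i in by_chrom.items()}
    ends = {c: win["end"].to_numpy()[i] for c, i in by_chrom.items()}

    cur_chrom = None
    cur_idx = cur_starts = cur_ends = None
    cur_mask = cur_excl = None
    for v in vcf:
        if v.CHROM != cur_chrom:
            cur_chrom = v.CHROM
            if cur_chrom in by_chrom:
                cur_idx = by_chrom[cur_chrom]
                cur_starts, cur_ends = starts[cur_chrom], ends[cur_chrom]
                cur_mask = _mask_lookup(site_mask, cur_chrom)
                cur_excl = _mask_lookup(exclude, cur_chrom)
            else:
                cur_idx = None
        if cur_idx is None:
            continue
        pos0 = v.POS - 1
        w = np.searchsorted(cur_starts, pos0, side="right") - 1
        if w < 0 or pos0 >= cur_ends[w]:
            continue
        pos_arr = np.array([pos0])
        if site_mask is not None:
            if cur_mask is None or not points_in_intervals(pos_arr, *cur_mask)[0]:
                continue
        if cur_excl is not None and points_in_intervals(pos_arr, *cur_excl)[0]:
            continue
        alleles = np.array(v.genotypes, dtype=np.int64)[:, :2].ravel()
        alleles = alleles[alleles >= 0]
        k = alleles.size
        if k < 2:
            continue
        counts = np.bincount(alleles)
        d = (k * k - int(counts @ counts)) // 2
        c = k * (k - 1) // 2
        gi = cur_idx[w]
        diffs_sum[gi] += d
        comps_sum[gi] += c
        nsites[gi] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(comps_sum > 0, diffs_sum / np.maximum(comps_sum, 1), np.nan)
    win["n_sites"] = nsites
    win["n_diffs"] = diffs_sum
    win["n_comparisons"] = comps_sum
    win["pi"] = pi

    rows = []
    for chrom, idx in by_chrom.items():
        vals = pi[idx]
        ok = ~np.isnan(vals)
        dropped = int((~ok).sum())
        mean_pi = float(vals[ok].mean()) if ok.any() else float("nan")
        tot_c = int(comps_sum[idx].sum())
        ros = float(diffs_sum[idx].sum() / tot_c) if tot_c else float("nan")
        rows.append((chrom, mean_pi, ros, int(ok.sum()), dropped))
    chrom_table = pd.DataFrame(
        rows, columns=["chrom", "pi", "pi_ratio_of_sums", "n_windows", "n_windows_dropped"]
    )
    return win, chrom_table


def chromosome_pi_ratio(
    pi_0d: pd.DataFrame, pi_4d: pd.DataFrame, pi_all: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge per-chromosome diversity tables and add the 0D/4D ratio.

    The ratio divides chromosome-mean 0D diversity by chromosome-mean 4D
    diversity; it is NaN (flagged) when the 4D mean is zero or missing.
    """
    out = pi_0d[["chrom", "pi"]].rename(columns={"pi": "pi_0d"}).merge(
        pi_4d[["chrom", "pi"]].rename(columns={"pi": "pi_4d"}), on="chrom", how="outer"
    )
    if pi_all is not None:
        out = out.merge(
            pi_all[["chrom", "pi"]].rename(columns={"pi": "pi_all"}),
            on="chrom", how="outer",
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = out["pi_0d"] / out["pi_4d"]
    ratio[~(out["pi_4d"] > 0)] = np.nan
    out["ratio_0d_4d"] = ratio
    n_flagged = int(out["ratio_0d_4d"].isna().sum())
    if n_flagged:
        logger.warning("%d chromosomes with undefined 0D/4D ratio", n_flagged)
    return out
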