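"""Windowed genomic feature densities and chromosome-level bootstrap summaries.

Chromosomes are tiled into fixed windows (default 100 kb); for each window we
compute repeat density (fraction of bases under the interval union of repeat
hits), GC content of the non-N sequence, and CDS density (union of coding
intervals across isoforms).  Chromosome-level means carry 95% percentile
bootstrap confidence intervals obtained by resampling windows with
replacement.

A trailing partial window is kept only if it spans at least half the window
size: short tails give high-variance density estimates, but dropping every
tail would systematically discard up to one window from each (especially
small) chromosome.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import merge_intervals, window_coverage
from .repeatmasker import TEAnnotation, records_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "make_windows",
    "repeat_density",
    "gc_content",
    "cds_density",
    "chromosome_summary",
    "telomere_profile",
    "read_chrom_sizes",
    "read_cds_intervals",
]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={"chrom": str})
    return dict(zip(df.chrom, df.length.astype(int)))


def make_windows(
    chrom_sizes: Mapping[str, int],
    window: int = 100_000,
    min_tail: int | None = None,
) -> pd.DataFrame:
    """Tile each chromosome into consecutive windows.

    Returns a DataFrame with columns chrom/start/end.  The trailing partial
    window is kept iff its span is at least ``min_tail`` (default:
    ``window // 2``).
    """
    if min_tail is None:
        min_tail = window // 2
    rows = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n_full = length // window
        for i in range(n_full):
            rows.append((chrom, i * window, (i + 1) * window))
        tail = length - n_full * window
        if tail >= min_tail and tail > 0:
            rows.append((chrom, n_full * window, length))
        if n_full == 0 and tail < min_tail:
            logger.warning("chromosome %s (%d bp) yields no windows", chrom, length)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _per_chrom_union(frame: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        out[chrom] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def _density_from_intervals(
    windows: pd.DataFrame,
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    column: str,
    chrom_sizes: Mapping[str, int] | None = None,
    what: str = "record",
) -> pd.DataFrame:
    if chrom_sizes is not None:
        for chrom, (s, e) in per_chrom.items():
            if chrom in chrom_sizes and e.size and e[-1] > chrom_sizes[chrom]:
                raise ValueError(
                    f"{what} on {chrom} ends at {e[-1]}, beyond chromosome "
                    f"length {chrom_sizes[chrom]}"
                )
    out = windows.copy()
    vals = np.zeros(len(windows))
    for chrom, idx in windows.groupby("chrom", sort=False).indices.items():
        if chrom not in per_chrom:
            continue
        s, e = per_chrom[chrom]
        ws = windows["start"].to_numpy()[idx]
        we = windows["end"].to_numpy()[idx]
        cov = window_coverage(ws, we, s, e)
        vals[idx] = cov / (we - ws)
    out[column] = vals
    return out


def repeat_density(
    windows: pd.DataFrame,
    records: Sequence[TEAnnotation] | pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of each window covered by the union of repeat hits.

    Overlapping hits are merged first so the density can never exceed 1.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    return _density_from_intervals(
        windows, _per_chrom_union(frame), "repeat_density", chrom_sizes, "repeat hit"
    )


def gc_content(windows: pd.DataFrame, fasta_path) -> pd.DataFrame:
    """GC fraction of the A/C/G/T bases of each window (case-insensitive).

    N and ambiguity codes are excluded from the denominator; a window with no
    unambiguous bases gets NaN.  Soft-masked lowercase counts normally.
    """
    out = windows.copy()
    gc = np.full(len(windows), np.nan)
    n_eff = np.zeros(len(windows), dtype=np.int64)
    with pysam.FastaFile(str(fasta_path)) as fa:
        present = set(fa.references)
        for i, row in enumerate(windows.itertuples(index=False)):
            if row.chrom not in present:
                raise KeyError(f"chromosome {row.chrom} missing from FASTA")
            seq = fa.fetch(row.chrom, row.start, row.end).upper()
            g = seq.count("G") + seq.count("C")
            at = seq.count("A") + seq.count("T")
            denom = g + at
            n_eff[i] = denom
            if denom:
                gc[i] = g / denom
    out["gc"] = gc
    out["n_effective_bases"] = n_eff
    return out


def read_cds_intervals(annotation_path) -> pd.DataFrame:
    """CDS intervals (chrom/start/end, 0-based half-open) from GFF3 or GTF."""
    import gffutils

    db = gffutils.create_db(
        str(annotation_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [(f.seqid, f.start - 1, f.end) for f in db.features_of_type("CDS")]
    if not rows:
        raise ValueError(f"no CDS features in {annotation_path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def cds_density(
    windows: pd.DataFrame,
    annotation,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of each window covered by the union of CDS intervals.

    Strand-agnostic; exons shared between isoforms count once.  ``annotation``
    is a GFF3/GTF path or a precomputed chrom/start/end frame.
    """
    cds = annotation if isinstance(annotation, pd.DataFrame) else read_cds_intervals(annotation)
    if cds.empty:
        raise ValueError("no CDS features")
    return _density_from_intervals(
        windows, _per_chrom_union(cds), "cds_density", chrom_sizes, "CDS feature"
    )


def chromosome_summary(
    windows: pd.DataFrame,
    stat: str,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-chromosome mean of a window statistic with a percentile bootstrap CI.

    Windows are resampled with replacement ``n_boot`` times with equal
    weights (partial windows included).  NaN windows are dropped first; a
    chromosome with no usable windows is an error.
    """
    if stat not in windows.columns:
        raise KeyError(f"no column {stat!r} in window table")
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2 * 100
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        vals = grp[stat].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"chromosome {chrom} has no windows with defined {stat}")
        mean = vals.mean()
        if vals.size == 1:
            lo = hi = mean
        else:
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boot_means = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [alpha, 100 - alpha])
        rows.append((chrom, mean, lo, hi, vals.size))
    return pd.DataFrame(
        rows, columns=["chrom", f"mean_{stat}", "ci_low", "ci_high", "n_windows"]
    )


def telomere_profile(
    records: Sequence[TEAnnotation] | pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Repeat density by distance to the nearer chromosome end, pooled.

    Bin k covers positions whose distance to the closer end lies in
    [k*bin_size, (k+1)*bin_size); density is union-covered bases over total
    bases contributed to that bin across chromosomes.  A flat profile argues
    against a telomeric origin of density differences.
    """
    min_len = min(int(v) for v in chrom_sizes.values())
    if bin_size > min_len / 2:
        raise ValueError(
            f"bin size {bin_size} exceeds half the smallest chromosome ({min_len})"
        )
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    unions = _per_chrom_union(frame)
    n_bins = max(int(np.ceil(L / 2 / bin_size)) for L in chrom_sizes.values())
    covered = np.zeros(n_bins, dtype=np.int64)
    total = np.zeros(n_bins, dtype=np.int64)
    for chrom, L in chrom_sizes.items():
        L = int(L)
        s, e = unions.get(chrom, (np.array([], dtype=np.int64),) * 2)
        mid = (L + 1) // 2  # positions < mid are nearer the left end
        for k in range(int(np.ceil(mid / bin_size))):
            lo, hi = k * bin_size, (k + 1) * bin_size
            # region from the left end plus its mirror from the right end
            regions = [(lo, min(hi, mid)), (max(L - hi, mid), L - lo)]
            for a, b in regions:
                if b <= a:
                    continue
                total[k] += b - a
                if s.size:
                    covered[k] += int(
                        window_coverage(np.array([a]), np.array([b]), s, e)[0]
                    )
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(total > 0, covered / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "distance_bin_start": np.arange(n_bins) * bin_size,
        "covered_bases": covered,
        "total_bases": total,
        "repeat_density": density,
    })
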