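"""Inter-TE spacing within age strata and the young/old spacing ratio.

For each chromosome, TE copies are split into young (<5% divergence) and old
(5-10%) strata; within a stratum the records are sorted by start and the gap
between each consecutive pair is recorded (bases strictly between the two
intervals, floored at zero for overlapping or nested copies).  The ratio of
the mean young gap to the mean old gap is the per-chromosome statistic: if
intervening unique sequence is progressively removed (e.g. by deletion-biased
non-allelic homologous recombination), old copies end up closer together than
young ones, and the ratio rises — more so on chromosomes losing sequence
faster.

Records of the other stratum lying between a pair do not break the pair;
pairs are formed within a stratum only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repeatmasker import TEAnnotation, age_classes, records_to_frame

__all__ = ["SpacingSummary", "inter_te_distances", "spacing_summary", "spacing_table"]


@dataclass(frozen=True)
class SpacingSummary:
    chrom: str
    mean_dist_young: float  # NaN when < 2 young records
    mean_dist_old: float
    ratio_young_over_old: float  # NaN when either mean undefined or old mean == 0
    n_pairs_young: int
    n_pairs_old: int


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def inter_te_distances(
    records,
    age: str,
    young_max: float = 5.0,
    old_min: float = 5.0,
    old_max: float = 10.0,
    distance_mode: str = "gap",
) -> np.ndarray:
    """Adjacent-pair distances among records of one age stratum.

    ``distance_mode='gap'`` measures next.start - prev.end floored at 0 (the
    intervening sequence); ``'start-to-start'`` measures start differences.
    Fewer than two records of the stratum yield an empty array.
    """
    frame = _as_frame(records)
    if frame.empty:
        return np.array([], dtype=np.int64)
    chroms = frame["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    labels = age_classes(frame["divergence"], young_max, old_min, old_max)
    sub = frame.loc[labels.to_numpy() == age]
    if len(sub) < 2:
        return np.array([], dtype=np.int64)
    sub = sub.sort_values(["start", "end"], kind="mergesort")
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = sub["end"].to_numpy(dtype=np.int64)
    if distance_mode == "gap":
        return np.maximum(starts[1:] - ends[:-1], 0)
    if distance_mode == "start-to-start":
        return starts[1:] - starts[:-1]
    raise ValueError(f"unknown distance_mode {distance_mode!r}")


def spacing_summary(
    records,
    chrom: str | None = None,
    young_max: float = 5.0,
    old_min: float = 5.0,
    old_max: float = 10.0,
    distance_mode: str = "gap",
) -> SpacingSummary:
    """Mean young/old gaps and their ratio for one chromosome.

    The ratio is NaN (flagged missing) when either stratum has fewer than two
    records or the old mean is zero.
    """
    frame = _as_frame(records)
    if chrom is None:
        chroms = frame["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("chrom must be given for multi/zero-chromosome input")
        chrom = chroms[0]
    else:
        frame = frame.loc[frame["chrom"] == chrom]
    kw = dict(young_max=young_max, old_min=old_min, old_max=old_max,
              distance_mode=distance_mode)
    d_young = inter_te_distances(frame, "young", **kw)
    d_old = inter_te_distances(frame, "old", **kw)
    mean_y = float(d_young.mean()) if d_young.size else float("nan")
    mean_o = float(d_old.mean()) if d_old.size else float("nan")
    if d_young.size and d_old.size and mean_o > 0:
        ratio = mean_y / mean_o
    else:
        ratio = float("nan")
    return SpacingSummary(chrom, mean_y, mean_o, ratio, d_young.size, d_old.size)


def spacing_table(records, **kwargs) -> pd.DataFrame:
    """Per-chromosome spacing summaries for a whole-genome record set."""
    frame = _as_frame(records)
    rows = []
    for chrom, grp in frame.groupby("chrom", sort=False):
        s = spacing_summary(grp, chrom=chrom, **kwargs)
        rows.append((s.chrom, s.n_pairs_young, s.mean_dist_young,
                     s.n_pairs_old, s.mean_dist_old, s.ratio_young_over_old))
    return pd.DataFrame(rows, columns=[
        "chrom", "n_pairs_young", "mean_dist_young",
        "n_pairs_old", "mean_dist_old", "ratio_young_over_old",
    ])
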