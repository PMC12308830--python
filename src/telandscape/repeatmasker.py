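"""RepeatMasker ``.out`` annotation I/O and TE age classification.

RepeatMasker writes a fixed-layout whitespace table: three header lines
followed by one row per hit with the Smith-Waterman score, percent
divergence/deletion/insertion to the library consensus, query coordinates
(1-based inclusive), strand (``+`` or ``C`` for complement), repeat name,
class/family, consensus coordinates, a hit ID and an optional ``*`` marking
a lower-scoring overlap.  No established Python package parses this dialect,
so the reader lives here.  Internally every record is 0-based half-open;
conversion happens only at the file boundary.

Divergence to the library consensus is the standard proxy for insertion age:
copies under 5% divergence are "young", copies at 5-10% are "old", and more
diverged copies are excluded from the age-stratified analyses.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TEAnnotation",
    "RepeatMaskerParseError",
    "read_repeatmasker",
    "write_repeatmasker",
    "classify_age",
    "age_classes",
    "filter_te_records",
    "records_to_frame",
    "frame_to_records",
    "NON_TE_CLASSES",
    "YOUNG_MAX",
    "OLD_MIN",
    "OLD_MAX",
]

#: divergence thresholds (percent) for the two age strata
YOUNG_MAX = 5.0
OLD_MIN = 5.0
OLD_MAX = 10.0

#: repeat classes that are not transposable elements
NON_TE_CLASSES = frozenset(
    {"Simple_repeat", "Low_complexity", "Satellite", "rRNA", "tRNA", "snRNA"}
)


class RepeatMaskerParseError(ValueError):
    """Raised when a ``.out`` data row cannot be interpreted."""


@dataclass(frozen=True)
class TEAnnotation:
    """One masked repeat interval (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    divergence: float
    repeat_name: str
    te_class: str
    te_family: str = ""
    score: int = 0
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


_HEADER_FIRST_TOKENS = {"SW", "score", "bit"}


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_repeatmasker(path, min_length: int = 0) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` file (optionally gzipped).

    Query coordinates are converted from 1-based inclusive to 0-based
    half-open; strand ``C`` becomes ``-``; the class/family column is split
    on its first ``/``.  Hits spanning fewer than ``min_length`` bases are
    dropped.  ``*``-flagged overlap rows are retained (callers decide
    whether to merge them).  A file with only header lines yields an empty
    list with a warning.
    """
    records: list[TEAnnotation] = []
    n_data = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] in _HEADER_FIRST_TOKENS:
                continue
            if not tokens[0].lstrip("-").isdigit():
                # second header line ("score div. del. ins. ...") or stray text
                if n_data == 0:
                    continue
                raise RepeatMaskerParseError(
                    f"{path}:{lineno}: unparseable row: {line.rstrip()!r}"
                )
            n_data += 1
            if not 14 <= len(tokens) <= 16:
                raise RepeatMaskerParseError(
                    f"{path}:{lineno}: expected 14-16 columns, got {len(tokens)}"
                )
            try:
                score = int(tokens[0])
                div = float(tokens[1])
                chrom = tokens[4]
                qbegin = int(tokens[5])
                qend = int(tokens[6])
                strand = tokens[8]
                repeat_name = tokens[9]
                class_family = tokens[10]
            except ValueError as exc:
                raise RepeatMaskerParseError(f"{path}:{lineno}: {exc}") from exc
            if strand == "C":
                strand = "-"
            if strand not in {"+", "-"}:
                raise RepeatMaskerParseError(
                    f"{path}:{lineno}: bad strand {strand!r}"
                )
            te_class, _, te_family = class_family.partition("/")
            start, end = qbegin - 1, qend  # 1-based inclusive -> 0-based half-open
            if end - start < min_length:
                continue
            records.append(
                TEAnnotation(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    divergence=div,
                    repeat_name=repeat_name,
                    te_class=te_class,
                    te_family=te_family,
                    score=score,
                    overlap_flag=tokens[-1] == "*",
                )
            )
    if n_data == 0:
        logger.warning("%s: no data rows (header-only or empty file)", path)
    return records


def write_repeatmasker(records: Iterable[TEAnnotation], path) -> None:
    """Write records back out in ``.out`` layout (1-based inclusive)."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "wt") as fh:
        fh.write(header)
        for i, r in enumerate(records, start=1):
            strand = "+" if r.strand == "+" else "C"
            cf = f"{r.te_class}/{r.te_family}" if r.te_family else r.te_class
            star = " *" if r.overlap_flag else ""
            fh.write(
                f"{r.score:5d} {r.divergence:5.1f}  0.0  0.0  {r.chrom} "
                f"{r.start + 1} {r.end} (0) {strand} {r.repeat_name} {cf} "
                f"1 {r.end - r.start} (0) {i}{star}\n"
            )


def classify_age(d: float) -> str:
    """Age stratum for a divergence value: young [0,5), old [5,10], else excluded."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    if d < YOUNG_MAX:
        return "young"
    if d <= OLD_MAX:
        return "old"
    return "excluded"


def age_classes(divergence, young_max: float = YOUNG_MAX,
                old_min: float = OLD_MIN, old_max: float = OLD_MAX) -> pd.Series:
    """Vectorised age labels for a divergence array/Series."""
    d = pd.Series(divergence).astype(float)
    if (d < 0).any():
        raise ValueError("divergence must be >= 0")
    out = pd.Series("excluded", index=d.index, dtype=object)
    out[(d >= old_min) & (d <= old_max)] = "old"
    out[d < young_max] = "young"
    return out


def filter_te_records(
    records: Sequence[TEAnnotation],
    keep_classes: set[str] | None = None,
    drop_non_te: bool = False,
) -> list[TEAnnotation]:
    """Filter parsed repeat records by class.

    ``drop_non_te`` removes simple repeats, low-complexity runs, satellites
    and structural RNAs, leaving transposable elements plus any unrecognised
    classes (kept and logged).  ``keep_classes`` then restricts to the named
    classes, as used for the per-TE-type analyses.
    """
    known = NON_TE_CLASSES | {
        "LINE", "SINE", "LTR", "DNA", "RC", "Rolling-circle", "Retroposon", "Unknown"
    }
    out = []
    unknown_seen: set[str] = set()
    for r in records:
        if drop_non_te and r.te_class in NON_TE_CLASSES:
            continue
        if r.te_class not in known and r.te_class not in unknown_seen:
            unknown_seen.add(r.te_class)
            logger.info("unrecognised repeat class kept: %s", r.te_class)
        if keep_classes is not None and r.te_class not in keep_classes:
            continue
        out.append(r)
    return out


_FRAME_COLS = [
    "chrom", "start", "end", "strand", "divergence",
    "repeat_name", "te_class", "te_family", "score",
]


def records_to_frame(records: Sequence[TEAnnotation]) -> pd.DataFrame:
    """Tabular view of annotation records (one row per hit)."""
    if not records:
        return pd.DataFrame(columns=_FRAME_COLS)
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.strand, r.divergence,
             r.repeat_name, r.te_class, r.te_family, r.score)
            for r in records
        ],
        columns=_FRAME_COLS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[TEAnnotation]:
    return [
        TEAnnotation(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            strand=row.strand, divergence=float(row.divergence),
            repeat_name=row.repeat_name, te_class=row.te_class,
            te_family=row.te_family, score=int(row.score),
        )
        for row in frame.itertuples(index=False)
    ]
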