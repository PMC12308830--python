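"""Codon-degeneracy site classification and SNP effect annotation.

Every coding position is labelled by how many of its three possible point
substitutions are synonymous under the standard nuclear genetic code:
3 synonymous -> 4-fold degenerate (4D), 0 synonymous -> 0-fold (0D),
anything in between -> "other" (2- and 3-fold sites).  Diversity at 4D sites
proxies neutral variation; at 0D sites every change alters the protein, so
the 0D/4D diversity ratio tracks the efficiency of purifying selection.

Positions covered by several transcripts that disagree are labelled
"conflicting" and excluded from the 0D/4D site sets.  Transcripts whose CDS
is not a whole number of codons after phase adjustment, or that contain an
internal stop, are skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "codon_position_label",
    "CodingIndex",
    "build_coding_index",
    "classify_degeneracy",
    "classify_snp_effect",
    "write_degeneracy_beds",
]

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    """Amino acid for a codon; stop codons -> '*'."""
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


def _build_degeneracy_lookup() -> dict[tuple[str, int], str]:
    lookup = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                aa = _translate_codon(codon)
                for pos in range(3):
                    syn = 0
                    for alt in _BASES:
                        if alt == codon[pos]:
                            continue
                        mutant = codon[:pos] + alt + codon[pos + 1:]
                        if _translate_codon(mutant) == aa:
                            syn += 1
                    lookup[(codon, pos)] = {3: "4D", 0: "0D"}.get(syn, "other")
    return lookup


_DEGENERACY: dict[tuple[str, int], str] = _build_degeneracy_lookup()


def codon_position_label(codon: str, pos: int) -> str:
    """Degeneracy label ('0D', '4D', 'other') of position ``pos`` in ``codon``."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if pos not in (0, 1, 2):
        raise ValueError("codon position must be 0, 1 or 2")
    return _DEGENERACY[(codon, pos)]


@dataclass
class _SiteContext:
    codon: str
    offset: int  # 0..2 within the codon, transcript sense
    strand: str


@dataclass
class CodingIndex:
    """Per-site degeneracy labels and codon contexts for a genome annotation."""

    labels: dict[tuple[str, int], str] = field(default_factory=dict)
    contexts: dict[tuple[str, int], list[_SiteContext]] = field(default_factory=dict)
    skipped_transcripts: list[tuple[str, str]] = field(default_factory=list)

    def degeneracy_frame(self) -> pd.DataFrame:
        """chrom / pos (0-based) / label table, sorted by coordinate."""
        rows = [(c, p, lab) for (c, p), lab in self.labels.items()]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "label"])
        return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def positions(self, label: str) -> dict[str, np.ndarray]:
        """Sorted 0-based positions per chromosome carrying ``label``."""
        out: dict[str, list[int]] = {}
        for (chrom, pos), lab in self.labels.items():
            if lab == label:
                out.setdefault(chrom, []).append(pos)
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    def snp_effect(self, chrom: str, pos: int, ref: str, alt: str) -> str:
        """'synonymous' / 'nonsynonymous' / 'other' for a substitution.

        Indels, SNPs outside any valid CDS, and sites whose transcripts
        disagree all return 'other'.
        """
        if len(ref) != 1 or len(alt) != 1:
            return "other"
        ref, alt = ref.upper(), alt.upper()
        if ref not in _BASES or alt not in _BASES or ref == alt:
            return "other"
        ctxs = self.contexts.get((chrom, int(pos)))
        if not ctxs:
            return "other"
        verdicts = set()
        for ctx in ctxs:
            a = alt if ctx.strand == "+" else reverse_complement(alt)
            r = ref if ctx.strand == "+" else reverse_complement(ref)
            if ctx.codon[ctx.offset] != r:
                logger.warning("reference mismatch at %s:%d", chrom, pos)
                return "other"
            mutant = ctx.codon[:ctx.offset] + a + ctx.codon[ctx.offset + 1:]
            same = _translate_codon(mutant) == _translate_codon(ctx.codon)
            verdicts.add("synonymous" if same else "nonsynonymous")
        if len(verdicts) != 1:
            return "other"
        return verdicts.pop()


def _iter_transcript_cds(annotation_path):
    """Yield (transcript_id, strand, [(chrom, start, end, phase), ...])."""
    import gffutils

    db = gffutils.create_db(
        str(annotation_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    strands: dict[str, str] = {}
    for f in db.features_of_type("CDS"):
        if "Parent" in f.attributes:
            tids = f.attributes["Parent"]
        elif "transcript_id" in f.attributes:
            tids = f.attributes["transcript_id"]
        else:
            tids = [f.id or f"cds_{f.seqid}_{f.start}"]
        phase = 0 if f.frame in (None, ".") else int(f.frame)
        for tid in tids:
            groups.setdefault(tid, []).append((f.seqid, f.start - 1, f.end, phase))
            strands[tid] = f.strand
    for tid in groups:
        yield tid, strands[tid], sorted(groups[tid], key=lambda x: x[1])


def build_coding_index(fasta_path, annotation_path) -> CodingIndex:
    """Classify every CDS base of every transcript by codon degeneracy.

    Reverse-strand transcripts are evaluated on the reverse complement; the
    phase of the first coding segment trims incomplete leading codons.
    """
    index = CodingIndex()
    per_site: dict[tuple[str, int], set[str]] = {}
    with pysam.FastaFile(str(fasta_path)) as fa:
        for tid, strand, segments in _iter_transcript_cds(annotation_path):
            chroms = {seg[0] for seg in segments}
            if len(chroms) != 1:
                index.skipped_transcripts.append((tid, "multi-chromosome CDS"))
                continue
            chrom = chroms.pop()
            seq_parts = []
            pos_parts = []
            for _, s, e, _ in segments:
                seq_parts.append(fa.fetch(chrom, s, e).upper())
                pos_parts.append(np.arange(s, e, dtype=np.int64))
            seq = "".join(seq_parts)
            positions = np.concatenate(pos_parts)
            if strand == "-":
                seq = reverse_complement(seq)
                positions = positions[::-1]
                phase = segments[-1][3]
            else:
                phase = segments[0][3]
            seq = seq[phase:]
            positions = positions[phase:]
            if len(seq) % 3 != 0:
                logger.warning("transcript %s: CDS length not divisible by 3; skipped", tid)
                index.skipped_transcripts.append((tid, "length not divisible by 3"))
                continue
            if any(b not in _BASES for b in seq):
                index.skipped_transcripts.append((tid, "ambiguous bases"))
                continue
            n_codons = len(seq) // 3
            aas = [_translate_codon(seq[3 * i: 3 * i + 3]) for i in range(n_codons)]
            if "*" in aas[:-1]:
                logger.warning("transcript %s: internal stop codon; skipped", tid)
                index.skipped_transcripts.append((tid, "premature stop"))
                continue
            for i in range(n_codons):
                codon = seq[3 * i: 3 * i + 3]
                for off in range(3):
                    gpos = int(positions[3 * i + off])
                    key = (chrom, gpos)
                    per_site.setdefault(key, set()).add(_DEGENERACY[(codon, off)])
                    index.contexts.setdefault(key, []).append(
                        _SiteContext(codon=codon, offset=off, strand=strand)
                    )
    for key, labs in per_site.items():
        index.labels[key] = labs.pop() if len(labs) == 1 else "conflicting"
    return index


def classify_degeneracy(fasta_path, annotation_path) -> pd.DataFrame:
    """Per-site degeneracy table (chrom, pos, label); see ``build_coding_index``."""
    return build_coding_index(fasta_path, annotation_path).degeneracy_frame()


def classify_snp_effect(snps, fasta_path, annotation_path) -> list[str]:
    """Effect labels for (chrom, pos, ref, alt) tuples (pos 0-based)."""
    index = build_coding_index(fasta_path, annotation_path)
    return [index.snp_effect(c, p, r, a) for c, p, r, a in snps]


def write_degeneracy_beds(index_or_frame, prefix) -> tuple[str, str]:
    """Write 0D and 4D site sets as BED (conflicting sites excluded)."""
    if isinstance(index_or_frame, CodingIndex):
        df = index_or_frame.degeneracy_frame()
    else:
        df = index_or_frame
    paths = []
    for label in ("0D", "4D"):
        sub = df.loc[df["label"] == label]
        path = f"{prefix}.{label}.bed"
        out = pd.DataFrame({
            "chrom": sub["chrom"],
            "start": sub["pos"],
            "end": sub["pos"] + 1,
        })
        out.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return tuple(paths)
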