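"""End-to-end analysis stages: density, spacing and population genomics.

Each stage reads the standard inputs (RepeatMasker ``.out``, FASTA, GFF3/GTF,
all-sites VCF, BED masks, chromosome-size TSV), writes plain TSV report
tables into the output directory, and returns them as DataFrames.  Outputs
are deterministic for a fixed config and seed: floats are printed at fixed
precision and run metadata (config hash, seed, package version) goes to a
separate JSON file so the tables themselves are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .degeneracy import build_coding_index, write_degeneracy_beds
from .diversity import chromosome_pi_ratio, pi_windows, read_bed
from .dfe import fit_gamma_dfe
from .repeatmasker import (age_classes, filter_te_records, read_repeatmasker,
                           records_to_frame)
from .sfs import build_folded_sfs
from .spacing import spacing_table
from .stats import ols_multiple_regression
from .windows import (cds_density, chromosome_summary, gc_content, make_windows,
                      read_chrom_sizes, repeat_density)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_density_analysis", "run_spacing_analysis",
           "run_popgen_analysis"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Inputs and parameters for the analysis stages.

    Precedence is CLI flag > config file > default; the effective config is
    dumped alongside the outputs.
    """

    outdir: str = "results"
    repeats: str | None = None
    fasta: str | None = None
    annotation: str | None = None
    vcf: str | None = None
    chrom_sizes: str | None = None
    exclude_bed: str | None = None
    window: int = 100_000
    young_max: float = 5.0
    old_min: float = 5.0
    old_max: float = 10.0
    boot_reps: int = 1000
    seed: int = 0
    n_target: int | None = None
    fdr_family: str = "per-analysis"
    exclude_chroms: list[str] = field(default_factory=list)
    te_classes: list[str] | None = None
    drop_partial_below: int | None = None

    def __post_init__(self) -> None:
        if self.window < 10_000:
            raise ValueError("window must be at least 10 kb")
        if not 0 < self.young_max <= self.old_min <= self.old_max:
            raise ValueError("need 0 < young_max <= old_min <= old_max")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise FileNotFoundError(f"config is missing required input: {name}")
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_outdir(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return outdir


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _safe_correlations(table: pd.DataFrame, stats: list[str],
                       size_col: str = "length") -> pd.DataFrame:
    """Per-statistic Spearman vs size with BH over the family; statistics
    that cannot be correlated (constant, or <3 usable chromosomes) get NaN
    rows instead of aborting the stage."""
    from .stats import bh_fdr, spearman

    rows = []
    for stat in stats:
        sub = table[[size_col, stat]].dropna()
        try:
            rho, p = spearman(sub[size_col].to_numpy(dtype=float),
                              sub[stat].to_numpy(dtype=float))
        except ValueError as exc:
            logger.warning("correlation for %s undefined: %s", stat, exc)
            rho, p = np.nan, np.nan
        rows.append((stat, rho, p, len(sub)))
    out = pd.DataFrame(rows, columns=["variable", "rho", "p_value", "n"])
    ok = out["p_value"].notna()
    adj = pd.Series(np.nan, index=out.index)
    if ok.any():
        adj[ok] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    out["p_adjusted"] = adj
    return out[["variable", "rho", "p_value", "p_adjusted", "n"]]


def _sizes(cfg: RunConfig) -> dict[str, int]:
    if cfg.chrom_sizes:
        sizes = read_chrom_sizes(cfg.chrom_sizes)
    elif cfg.fasta:
        import pysam

        with pysam.FastaFile(str(cfg.fasta)) as fa:
            sizes = dict(zip(fa.references, fa.lengths))
    else:
        raise FileNotFoundError("need chrom_sizes or fasta to define chromosomes")
    return {c: L for c, L in sizes.items() if c not in set(cfg.exclude_chroms)}


def run_density_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Windowed repeat/GC/CDS densities, bootstrap summaries, correlations.

    Writes ``windows.tsv``, ``chrom_summary.tsv``, ``correlations.tsv``,
    ``class_density.tsv`` and (when FASTA and annotation are available)
    ``regression.tsv``.
    """
    cfg.require("repeats")
    outdir = _prepare_outdir(cfg)
    sizes = _sizes(cfg)
    records = read_repeatmasker(cfg.repeats)
    records = filter_te_records(
        records,
        keep_classes=set(cfg.te_classes) if cfg.te_classes else None,
        drop_non_te=True,
    )
    records = [r for r in records if r.chrom in sizes]
    frame = records_to_frame(records)

    win = make_windows(sizes, cfg.window, cfg.drop_partial_below)
    win = repeat_density(win, frame, sizes)
    have_seq = cfg.fasta is not None
    have_ann = cfg.annotation is not None
    if have_seq:
        win = gc_content(win, cfg.fasta)
    if have_ann:
        win = cds_density(win, cfg.annotation, sizes)
    _write(win, outdir / "windows.tsv")

    stats_cols = ["repeat_density"] + (["gc"] if have_seq else []) \
        + (["cds_density"] if have_ann else [])
    summary = None
    for i, stat in enumerate(stats_cols):
        part = chromosome_summary(win, stat, cfg.boot_reps, seed=cfg.seed + i)
        part = part.rename(columns={"ci_low": f"ci_low_{stat}", "ci_high": f"ci_high_{stat}",
                                    "n_windows": f"n_windows_{stat}"})
        summary = part if summary is None else summary.merge(part, on="chrom")
    summary.insert(1, "length", [sizes[c] for c in summary["chrom"]])
    _write(summary, outdir / "chrom_summary.tsv")

    corr = _safe_correlations(summary, [f"mean_{s}" for s in stats_cols])
    _write(corr, outdir / "correlations.tsv")

    # per-TE-class and young-TE densities
    rows = []
    labels = age_classes(frame["divergence"], cfg.young_max, cfg.old_min, cfg.old_max) \
        if len(frame) else pd.Series(dtype=object)
    subsets = {f"class:{k}": frame.loc[frame["te_class"] == k]
               for k in sorted(frame["te_class"].unique())}
    subsets["age:young"] = frame.loc[labels.to_numpy() == "young"] if len(frame) else frame
    for name, sub in subsets.items():
        if sub.empty:
            continue
        w = repeat_density(make_windows(sizes, cfg.window, cfg.drop_partial_below),
                           sub, sizes)
        cs = chromosome_summary(w, "repeat_density", cfg.boot_reps, seed=cfg.seed)
        cs.insert(0, "subset", name)
        cs.insert(2, "length", [sizes[c] for c in cs["chrom"]])
        rows.append(cs)
    class_density = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    _write(class_density, outdir / "class_density.tsv")

    out = {"windows": win, "chrom_summary": summary, "correlations": corr,
           "class_density": class_density}
    if have_seq and have_ann and len(summary) >= 5:
        fit = ols_multiple_regression(
            summary["mean_repeat_density"],
            summary[["length", "mean_gc", "mean_cds_density"]],
        )
        reg = fit.summary_frame().reset_index(names="predictor")
        _write(reg, outdir / "regression.tsv")
        out["regression"] = reg
    return out


def run_spacing_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Inter-TE spacing summaries per chromosome and their size correlations."""
    cfg.require("repeats")
    outdir = _prepare_outdir(cfg)
    sizes = _sizes(cfg)
    records = read_repeatmasker(cfg.repeats)
    records = filter_te_records(records, drop_non_te=True)
    frame = records_to_frame([r for r in records if r.chrom in sizes])
    table = spacing_table(frame, young_max=cfg.young_max, old_min=cfg.old_min,
                          old_max=cfg.old_max)
    table.insert(1, "length", [sizes[c] for c in table["chrom"]])
    _write(table, outdir / "spacing.tsv")
    corr = _safe_correlations(
        table, ["mean_dist_young", "mean_dist_old", "ratio_young_over_old"])
    _write(corr, outdir / "spacing_correlations.tsv")
    return {"spacing": table, "correlations": corr}


def run_popgen_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Diversity (all/0D/4D), 0D/4D ratio, folded SFS and per-chromosome DFE.

    Writes ``pi_windows_*.tsv``, ``pi_chromosomes.tsv``, ``sfs_*.tsv``,
    ``dfe.tsv`` and correlation tables against chromosome size.
    """
    cfg.require("vcf", "fasta", "annotation")
    outdir = _prepare_outdir(cfg)
    sizes = _sizes(cfg)
    index = build_coding_index(cfg.fasta, cfg.annotation)
    deg = index.degeneracy_frame()
    write_degeneracy_beds(deg, str(outdir / "sites"))
    masks = {
        "0d": read_bed(outdir / "sites.0D.bed"),
        "4d": read_bed(outdir / "sites.4D.bed"),
    }
    exclude = read_bed(cfg.exclude_bed) if cfg.exclude_bed else None

    win = make_windows(sizes, cfg.window, cfg.drop_partial_below)
    chrom_tabs = {}
    for label, mask in (("all", None), ("0d", masks["0d"]), ("4d", masks["4d"])):
        wtab, ctab = pi_windows(cfg.vcf, win, site_mask=mask, exclude=exclude)
        _write(wtab, outdir / f"pi_windows_{label}.tsv")
        chrom_tabs[label] = ctab
    pis = chromosome_pi_ratio(chrom_tabs["0d"], chrom_tabs["4d"], chrom_tabs["all"])
    pis.insert(1, "length", [sizes[c] for c in pis["chrom"]])

    # folded SFS and DFE per chromosome
    n_target = cfg.n_target or _default_n_target(cfg.vcf)
    deg_counts = deg.groupby(["chrom", "label"]).size().unstack(fill_value=0)
    dfe_rows = []
    sfs_rows = []
    es = {}
    for chrom in pis["chrom"]:
        L0 = float(deg_counts.loc[chrom, "0D"]) if chrom in deg_counts.index else 0.0
        L4 = float(deg_counts.loc[chrom, "4D"]) if chrom in deg_counts.index else 0.0
        sub = _subset_vcf_lines(cfg.vcf, chrom, outdir)
        try:
            syn, nonsyn = build_folded_sfs(
                sub, index.snp_effect, n_target, L_syn=L4, L_nonsyn=L0,
            )
        except ValueError as exc:
            logger.warning("SFS for %s skipped: %s", chrom, exc)
            continue
        finally:
            sub.unlink()
        for i, (sc, nc) in enumerate(zip(syn.counts, nonsyn.counts), start=1):
            sfs_rows.append((chrom, i, sc, nc, L4, L0))
        try:
            fit = fit_gamma_dfe(syn, nonsyn)
        except (ValueError, RuntimeError) as exc:
            logger.warning("DFE fit for %s failed: %s", chrom, exc)
            continue
        es[chrom] = fit.s_mean
        dfe_rows.append((chrom, sizes[chrom], fit.beta, fit.s_mean, fit.theta,
                         fit.log_likelihood, int(fit.neutral_boundary)))
    sfs_tab = pd.DataFrame(sfs_rows, columns=[
        "chrom", "folded_class", "syn_count", "nonsyn_count", "L_syn", "L_nonsyn"])
    _write(sfs_tab, outdir / "sfs.tsv")
    dfe_tab = pd.DataFrame(dfe_rows, columns=[
        "chrom", "length", "beta", "s_mean", "theta", "log_likelihood",
        "neutral_boundary"])
    _write(dfe_tab, outdir / "dfe.tsv")

    pis["es"] = pis["chrom"].map(es)
    _write(pis, outdir / "pi_chromosomes.tsv")
    stats = ["pi_all", "pi_0d", "pi_4d", "ratio_0d_4d", "es"]
    corr = _safe_correlations(pis, stats)
    _write(corr, outdir / "popgen_correlations.tsv")
    return {"pi": pis, "sfs": sfs_tab, "dfe": dfe_tab, "correlations": corr}


def _default_n_target(vcf_path) -> int:
    from cyvcf2 import VCF

    v = VCF(str(vcf_path))
    return max(4, int(2 * len(v.samples) * 0.8) // 2 * 2)


def _subset_vcf_lines(vcf_path, chrom: str, outdir: Path):
    """Per-chromosome VCF subset (plain text; avoids requiring an index)."""
    sub = outdir / f"_subset_{chrom}.vcf"
    with open(vcf_path) as fin, open(sub, "w") as fout:
        for line in fin:
            if line.startswith("#") or line.split("\t", 1)[0] == chrom:
                fout.write(line)
    return sub
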