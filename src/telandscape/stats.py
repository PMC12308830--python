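"""Association of chromosome-level statistics with chromosome size.

Spearman rank correlation (mid-ranks for ties) with Benjamini-Hochberg FDR
adjustment across the declared family of tests, plus ordinary least squares
multiple regression of repeat density on chromosome size, GC content and CDS
density.

For small samples (n <= 10) the Spearman p-value comes from the exact
permutation distribution of the rank correlation rather than the
t-approximation; chromosome counts in practice (20-31) use the t branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman",
    "bh_fdr",
    "ols_multiple_regression",
    "correlate_across_chromosomes",
    "RegressionResult",
    "EXACT_PERMUTATION_MAX_N",
]

EXACT_PERMUTATION_MAX_N = 10


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  For n > 10 the p-value uses
    the t-approximation t = rho*sqrt((n-2)/(1-rho^2)); for n <= 10 the exact
    permutation distribution over all n! rank orderings is enumerated.
    Constant input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n > EXACT_PERMUTATION_MAX_N:
        p = float(scipy.stats.spearmanr(x, y).pvalue)
        return rho, p
    # exact permutation null: permute one rank vector over all n! orderings
    obs = abs(rho)
    count = total = 0
    chunk = []
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 40320:
            idx = np.array(chunk)
            rhos = (ry_c[idx] @ rx_c) / denom
            count += int(np.sum(np.abs(rhos) >= obs - 1e-12))
            total += idx.shape[0]
            chunk = []
    if chunk:
        idx = np.array(chunk)
        rhos = (ry_c[idx] @ rx_c) / denom
        count += int(np.sum(np.abs(rhos) >= obs - 1e-12))
        total += idx.shape[0]
    return rho, count / total


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RegressionResult:
    """OLS fit: per-predictor coefficients, SEs, t and p values, and R^2."""

    params: pd.Series
    bse: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    r_squared: float
    n: int
    std_params: pd.Series = field(default_factory=pd.Series)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params,
            "std_err": self.bse,
            "t_value": self.t_values,
            "p_value": self.p_values,
            "std_coef": self.std_params.reindex(self.params.index),
        })


def ols_multiple_regression(y, X: pd.DataFrame) -> RegressionResult:
    """OLS of y on the given predictors with intercept and two-sided t-tests.

    Raises on rank-deficient designs, naming the offending predictor.  Both
    raw and standardized (z-scored) coefficients are reported.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations for {p} predictors, got {n}")
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"predictor {col!r} is constant (collinear with intercept)")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        for col in X.columns:
            reduced = sm.add_constant(X.drop(columns=[col]))
            if np.linalg.matrix_rank(design.to_numpy()) == np.linalg.matrix_rank(
                reduced.to_numpy()
            ):
                raise ValueError(f"design is rank deficient: predictor {col!r} is redundant")
        raise ValueError("design is rank deficient")
    fit = sm.OLS(y, design).fit()
    z = (X - X.mean()) / X.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    std_fit = sm.OLS(zy, sm.add_constant(z)).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, t_values=fit.tvalues,
        p_values=fit.pvalues, r_squared=float(fit.rsquared), n=n,
        std_params=std_fit.params.drop("const"),
    )


def correlate_across_chromosomes(
    table: pd.DataFrame,
    stats: list[str],
    size_col: str = "length",
    exclude_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Spearman of each statistic against chromosome length, FDR-adjusted.

    ``stats`` declares the family over which BH correction applies.  Missing
    values are dropped pairwise per statistic; fewer than 3 usable
    chromosomes for a statistic is an error.
    """
    df = table
    if exclude_chroms:
        df = df.loc[~df["chrom"].isin(exclude_chroms)]
    rows = []
    for stat in stats:
        sub = df[[size_col, stat]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 chromosomes with defined {stat!r}")
        rho, p = spearman(sub[size_col].to_numpy(), sub[stat].to_numpy())
        rows.append((stat, rho, p, len(sub)))
    out = pd.DataFrame(rows, columns=["variable", "rho", "p_value", "n"])
    out["p_adjusted"] = bh_fdr(out["p_value"].to_numpy())
    return out[["variable", "rho", "p_value", "p_adjusted", "n"]]
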