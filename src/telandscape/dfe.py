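"""Gamma distribution of fitness effects from folded site-frequency spectra.

Model.  Under the Poisson random field, the density of segregating sites at
population frequency x for scaled selection coefficient S (negative =
deleterious) is

    h(x; S) = (1 - exp(-S(1-x))) / ((1 - exp(-S)) x (1-x)),    h(x; 0) = 1/x,

normalised so the neutral expected unfolded class i (of n sampled alleles)
is 1/i.  Expected sample-class masses are the binomial mixture
e_i(S) = integral C(n,i) x^i (1-x)^(n-i) h(x;S) dx, folded over minor-allele
classes.  Deleterious effects follow a gamma distribution with shape beta
and mean |S_mean| (no beneficial mass).

Demography and other class-specific distortions are absorbed by nuisance
factors r_i shared between the synonymous and nonsynonymous spectra
(r_1 fixed to 1): synonymous class i is Poisson(theta L_syn e_i(0) r_i),
nonsynonymous class i is Poisson(theta L_nonsyn E_gamma[e_i(S)] r_i).  The
mutation-rate scaling theta is common to both site classes, so the overall
deficit of segregating nonsynonymous sites relative to the surveyed-length
ratio — not just the spectrum shape — identifies the selection strength;
the r_i, dominated by the synonymous spectrum, stand in for an explicit
population-size-change model and suffice for comparing mean selection
strength across chromosomes.

Maximisation runs bounded quasi-Newton over (log beta, log |S_mean|) from
eight deterministic starts; the nuisance block (theta_s, theta_n, r_i) is
profiled out at every step by an iterative-proportional-fitting fixed point
that solves its stationarity equations exactly.
"""

from __future__ import annotations

import functools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln

from .sfs import FoldedSFS, fold

logger = logging.getLogger(__name__)

__all__ = [
    "expected_unfolded_sfs",
    "expected_folded_sfs",
    "gamma_expected_folded",
    "gamma_expected_unfolded",
    "fit_gamma_dfe",
    "profile_ci_s_mean",
    "DFEFit",
    "S_STABILITY_BOUND",
]

#: |S| beyond this is evaluated at the bound (boundary-layer width < 1e-6)
S_STABILITY_BOUND = 1e6

# integration grid over |S| for the gamma mixture
_S_GRID_MIN = 1e-4
_S_GRID_MAX = 1e5
_S_GRID_K = 220
_S_EDGES = np.logspace(np.log10(_S_GRID_MIN), np.log10(_S_GRID_MAX), _S_GRID_K + 1)
_S_MIDS = np.sqrt(_S_EDGES[:-1] * _S_EDGES[1:])


def _log_expm1(y: float) -> float:
    """log(exp(y) - 1) for y > 0, stable for large y."""
    if y > 30:
        return y + np.log1p(-np.exp(-y))
    return np.log(np.expm1(y))


def _h_ratio(x: np.ndarray, S: float) -> np.ndarray:
    """(1 - e^{-S(1-x)}) / (1 - e^{-S}), stable for strongly negative S."""
    if S == 0:
        return 1.0 - x
    if S < 0:
        a = -S  # > 0
        return np.exp(_log_expm1_arr(a * (1.0 - x)) - _log_expm1(a))
    # positive S: 1 - e^{-S(1-x)} in (0, 1); direct form is stable
    return np.expm1(-S * (1.0 - x)) / np.expm1(-S)


def _log_expm1_arr(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    out = np.where(y > 30, y + np.log1p(-np.exp(-np.minimum(y, 700))), 0.0)
    small = y <= 30
    with np.errstate(divide="ignore"):
        out = np.where(small, np.log(np.expm1(np.where(small, y, 1.0))), out)
    return out


def expected_unfolded_sfs(S: float, n: int) -> np.ndarray:
    """Expected unfolded class masses e_1..e_{n-1}; neutral normalisation 1/i."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if abs(S) > S_STABILITY_BOUND:
        warnings.warn(
            f"|S|={abs(S):g} beyond stability bound; evaluated at {S_STABILITY_BOUND:g}",
            RuntimeWarning,
        )
        S = np.sign(S) * S_STABILITY_BOUND
    if S == 0:
        return 1.0 / np.arange(1, n)
    out = np.empty(n - 1)
    # boundary layer: width ~ 1/|S| near x=0 for S<0, near x=1 for S>0
    layer = min(0.5, 20.0 / abs(S)) if abs(S) > 40 else None
    for i in range(1, n):
        lc = _log_c(n, i)

        def integrand(x, i=i, lc=lc):
            # C(n,i) x^(i-1) (1-x)^(n-i-1) * ratio, in logs for stability
            lv = lc
            if i > 1:
                lv += (i - 1) * math.log(x)
            if n - i - 1 > 0:
                lv += (n - i - 1) * math.log1p(-x)
            return math.exp(lv) * float(_h_ratio(np.float64(x), S))

        if layer is not None:
            pts = [layer] if S < 0 else [1.0 - layer]
            val, _ = quad(integrand, 0.0, 1.0, points=pts, limit=200)
        else:
            val, _ = quad(integrand, 0.0, 1.0, limit=200)
        out[i - 1] = val
    return out


@functools.lru_cache(maxsize=None)
def _log_c(n: int, i: int) -> float:
    return float(gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1))


def expected_folded_sfs(S: float, n: int) -> np.ndarray:
    """Expected folded class masses for scaled selection S at sample size n.

    Neutral limit (S=0, n=4): proportional to (1 + 1/3, 1/2).
    """
    return fold(expected_unfolded_sfs(S, n))


@functools.lru_cache(maxsize=8)
def _grid_tables(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed e(S) on the |S| grid: (unfolded K x n-1, folded K x n//2,
    neutral unfolded, neutral folded)."""
    unfolded = np.empty((_S_GRID_K, n - 1))
    for k, s in enumerate(_S_MIDS):
        unfolded[k] = expected_unfolded_sfs(-s, n)
    folded = np.vstack([fold(u) for u in unfolded])
    neutral_u = 1.0 / np.arange(1, n)
    return unfolded, folded, neutral_u, fold(neutral_u)


def _gamma_weights(beta: float, s_mean: float) -> tuple[float, np.ndarray, float]:
    """Probability mass of Gamma(shape=beta, mean=s_mean) per |S| grid cell."""
    scale = s_mean / beta
    cdf = gammainc(beta, _S_EDGES / scale)
    return float(cdf[0]), np.diff(cdf), float(1.0 - cdf[-1])


def gamma_expected_folded(beta: float, s_mean: float, n: int) -> np.ndarray:
    """Folded expected class masses under a gamma DFE with mean |S| = s_mean."""
    if beta <= 0 or s_mean <= 0:
        raise ValueError("beta and s_mean must be positive")
    _, folded, _, neutral_f = _grid_tables(n)
    w_lo, w, w_hi = _gamma_weights(beta, s_mean)
    return w_lo * neutral_f + w @ folded + w_hi * folded[-1]


def gamma_expected_unfolded(beta: float, s_mean: float, n: int) -> np.ndarray:
    if beta <= 0 or s_mean <= 0:
        raise ValueError("beta and s_mean must be positive")
    unfolded, _, neutral_u, _ = _grid_tables(n)
    w_lo, w, w_hi = _gamma_weights(beta, s_mean)
    return w_lo * neutral_u + w @ unfolded + w_hi * unfolded[-1]


def _profile_nuisance(
    s: np.ndarray, d: np.ndarray, A: np.ndarray, B: np.ndarray,
    max_iter: int = 500, tol: float = 1e-12,
) -> tuple[float, np.ndarray, float]:
    """ML (theta, r) for s_i ~ Po(theta A_i r_i), d_i ~ Po(theta B_i r_i).

    ``A = L_syn * e_i(0)`` and ``B = L_nonsyn * E[e_i(S)]``: the mutation
    rate theta is shared, so the overall deficit of segregating
    nonsynonymous sites carries the selection-strength signal.  Solves the
    Poisson stationarity equations by fixed point; the scale redundancy
    between theta and r is resolved afterwards by r_1 = 1.
    Returns (theta, r, negative log-likelihood).
    """
    r = np.ones_like(A)
    tot = s.sum() + d.sum()
    ab = A + B
    theta = tot / (ab @ r)
    prev = np.inf
    for _ in range(max_iter):
        denom = theta * ab
        r = np.where(denom > 0, (s + d) / np.maximum(denom, 1e-300), 0.0)
        abr = ab @ r
        theta = tot / abr if abr > 0 else 0.0
        lam_s = theta * A * r
        lam_d = theta * B * r
        nll = float(lam_s.sum() + lam_d.sum()
                    - (s * np.log(np.maximum(lam_s, 1e-300))).sum()
                    - (d * np.log(np.maximum(lam_d, 1e-300))).sum())
        if abs(prev - nll) < tol * (1 + abs(nll)):
            prev = nll
            break
        prev = nll
    if r[0] > 0:
        theta *= r[0]
        r = r / r[0]
    return theta, r, prev


@dataclass
class DFEFit:
    """Fitted gamma DFE.

    ``s_mean`` is the mean scaled selection coefficient of new deleterious
    mutations, reported negative; ``beta`` the gamma shape.  ``theta`` is
    the shared per-site mutation-rate scaling and ``r`` the frequency-class
    nuisance factors (r_1 = 1).
    """

    beta: float
    s_mean: float
    theta: float
    r: np.ndarray
    log_likelihood: float
    n: int
    neutral_boundary: bool = False
    n_starts_converged: int = 0
    ci_s_mean: tuple[float, float] | None = None

    @property
    def es(self) -> float:
        """Mean scaled selection coefficient (alias used in reports)."""
        return self.s_mean

    def mean_s(self, ne: float) -> float:
        """Unscaled mean selection coefficient given Ne (S = 4 Ne s)."""
        return self.s_mean / (4.0 * ne)


_DEFAULT_STARTS = tuple(
    (b, sm) for b in (0.1, 0.3, 1.0, 3.0) for sm in (10.0, 1000.0)
)

_BOUNDS = ((np.log(1e-3), np.log(50.0)), (np.log(1e-3), np.log(5e4)))


def fit_gamma_dfe(
    sfs_syn: FoldedSFS,
    sfs_nonsyn: FoldedSFS,
    starts=_DEFAULT_STARTS,
) -> DFEFit:
    """Joint ML fit of (beta, S_mean, thetas, r) to a folded SFS pair.

    Raises when the spectra disagree in sample size, have fewer than three
    folded classes (unidentifiable), or no start converges.
    """
    if sfs_syn.n != sfs_nonsyn.n:
        raise ValueError("synonymous and nonsynonymous SFS have different n")
    n = sfs_syn.n
    half = n // 2
    if half < 3:
        raise ValueError(f"only {half} folded classes at n={n}: unidentifiable")
    if not (sfs_syn.L > 0 and sfs_nonsyn.L > 0):
        raise ValueError("both SFS need positive surveyed-site counts L")
    s = np.asarray(sfs_syn.counts, dtype=float)
    d = np.asarray(sfs_nonsyn.counts, dtype=float)
    if (s == 0).any():
        logger.warning("synonymous SFS has empty classes; r_i weakly determined")
    _, _, _, neutral_f = _grid_tables(n)
    A = sfs_syn.L * neutral_f

    def objective(z: np.ndarray) -> float:
        beta, sm = np.exp(z)
        B = sfs_nonsyn.L * gamma_expected_folded(beta, sm, n)
        return _profile_nuisance(s, d, A, B)[2]

    best = None
    n_converged = 0
    for b0, sm0 in starts:
        res = minimize(
            objective, x0=np.log([b0, sm0]), method="L-BFGS-B", bounds=_BOUNDS,
        )
        if not np.isfinite(res.fun):
            continue
        n_converged += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_converged == 0:
        raise RuntimeError(
            "gamma-DFE fit failed to converge from any start; "
            f"last diagnostics: {None if best is None else best.message}"
        )
    beta, sm = np.exp(best.x)
    B = sfs_nonsyn.L * gamma_expected_folded(beta, sm, n)
    theta, r, nll = _profile_nuisance(s, d, A, B)
    neutral = sm <= np.exp(_BOUNDS[1][0]) * 1.01
    if neutral:
        logger.warning("S_mean at neutral boundary: nonsynonymous SFS "
                       "indistinguishable from neutral spectrum")
    return DFEFit(
        beta=float(beta),
        s_mean=-float(sm),
        theta=float(theta),
        r=r,
        log_likelihood=-nll,
        n=n,
        neutral_boundary=bool(neutral),
        n_starts_converged=n_converged,
    )


def profile_ci_s_mean(
    fit: DFEFit,
    sfs_syn: FoldedSFS,
    sfs_nonsyn: FoldedSFS,
    level: float = 0.95,
    n_grid: int = 25,
    span: float = 30.0,
) -> tuple[float, float]:
    """Profile-likelihood CI for |S_mean| (beta re-optimised at each point)."""
    from scipy.stats import chi2

    n = fit.n
    s = np.asarray(sfs_syn.counts, dtype=float)
    d = np.asarray(sfs_nonsyn.counts, dtype=float)
    A = sfs_syn.L * _grid_tables(n)[3]
    crit = chi2.ppf(level, df=1) / 2.0
    sm_hat = abs(fit.s_mean)
    grid = np.logspace(np.log10(sm_hat / span), np.log10(sm_hat * span), n_grid)
    nll_hat = -fit.log_likelihood

    def prof(sm: float) -> float:
        def obj(lb):
            B = sfs_nonsyn.L * gamma_expected_folded(np.exp(lb[0]), sm, n)
            return _profile_nuisance(s, d, A, B)[2]

        res = minimize(obj, x0=np.log([fit.beta]), method="L-BFGS-B",
                       bounds=[_BOUNDS[0]])
        return res.fun

    drops = np.array([prof(sm) - nll_hat for sm in grid])
    inside = drops <= crit
    if not inside.any():
        return (float("nan"), float("nan"))
    lo = grid[inside][0]
    hi = grid[inside][-1]
    return (-float(hi), -float(lo))  # on the reported (negative) scale
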