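"""Simultaneous confidence intervals via the equicoordinate multivariate t.

Given a fitted cell-means model and a contrast matrix C, the contrast
estimates C beta are jointly (approximately) multivariate t around the true
contrasts, with correlation R derived from C vcov(beta) C'. Single-step
multiplicity adjustment uses the equicoordinate two-sided quantile c solving

    P( max_k |T_k| <= c ) = 1 - alpha,   T ~ t_nu(0, R),

so all T-1 intervals  estimate_k +/- c * se_k  hold simultaneously at
familywise level alpha, and the adjusted p-value of row k is
1 - P(max_j |T_j| <= |t_k|) under the same joint law (max-t adjustment).

Rectangle probabilities are computed with SciPy's randomized quasi-Monte
Carlo integrator for the multivariate t (multivariate normal when the
degrees of freedom are infinite); the randomization is seeded, so repeated
calls with the same seed reproduce the critical value exactly. Every
probability evaluation inside one call re-seeds the integrator identically,
which makes the estimated P(c) a deterministic, monotone function of c —
root finding is then well behaved and the test/interval duality
(adjusted p < alpha iff the interval excludes zero) holds exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import (
    ContractError,
    DegenerateContrastError,
    DomainError,
    NumericAccuracyWarning,
)
from .contrasts import ContrastMatrix
from .lmm import LmmFit

__all__ = [
    "SimultaneousCI",
    "contrast_moments",
    "equicoordinate_quantile",
    "simultaneous_ci",
    "QuantileResult",
]

#: default randomized-QMC point budget for one rectangle probability
DEFAULT_QMC_BUDGET = 2**17


class QuantileResult(NamedTuple):
    crit: float
    mc_error: float
    achieved: float
    seed: int


@dataclass
class SimultaneousCI:
    """Per-contrast estimates with simultaneous intervals and adjusted p.

    ``rows`` columns: label, estimate, se, lower, upper, t_statistic,
    adjusted_p. ``crit`` is the equicoordinate critical value, ``corr`` the
    contrast correlation matrix, ``df`` the reference degrees of freedom
    (may be inf), ``mc_error`` the Monte-Carlo standard error of the
    quantile computation.
    """

    rows: pd.DataFrame
    crit: float
    corr: np.ndarray
    df: float
    alpha: float
    mc_error: float
    seed: int
    ctype: str
    singular_fit: bool = False

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# contrast_type\t{self.ctype}\n")
            fh.write(f"# alpha\t{self.alpha}\n")
            fh.write(f"# df\t{self.df}\n")
            fh.write(f"# critical_value\t{self.crit:.6f}\n")
            fh.write(f"# mc_error\t{self.mc_error:.2e}\n")
            fh.write(f"# seed\t{self.seed}\n")
            if self.singular_fit:
                fh.write("# warning\tsingular model fit; SEs may be underestimated\n")
            self.rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def contrast_moments(
    fit: LmmFit, C: ContrastMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimates C beta, their covariance C vcov C' and correlation."""
    W = np.asarray(C.weights, dtype=float)
    if W.shape[1] != len(fit.beta):
        raise ContractError(
            f"contrast matrix has {W.shape[1]} columns but the fit has "
            f"{len(fit.beta)} time-point means"
        )
    est = W @ fit.beta
    cov = W @ fit.vcov_beta @ W.T
    cov = 0.5 * (cov + cov.T)
    var = np.diag(cov)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateContrastError(
            f"contrast row(s) {[C.row_labels[i] for i in bad]} have zero variance"
        )
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return est, cov, corr


def _validate_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DomainError("correlation matrix must be square")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise DomainError("correlation matrix must have unit diagonal")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise DomainError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise DomainError("correlation matrix is not positive semi-definite")
    return corr


def _reduce_duplicates(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop coordinates perfectly (anti)correlated with an earlier one.

    |T_i| = |T_j| almost surely when |r_ij| = 1, so such coordinates do not
    change the distribution of the maximum; removing them keeps the
    integrand full-rank.
    """
    k = corr.shape[0]
    keep: list[int] = []
    for i in range(k):
        if all(abs(corr[i, j]) < 1.0 - 1e-12 for j in keep):
            keep.append(i)
    keep_arr = np.array(keep, dtype=int)
    return corr[np.ix_(keep_arr, keep_arr)], keep_arr


def _rect_prob(
    c: float,
    corr: np.ndarray,
    df: float,
    seed: int,
    maxpts: int,
) -> float:
    """P(max_k |T_k| <= c) for a central multivariate t (normal if df=inf)."""
    if c <= 0:
        return 0.0
    k = corr.shape[0]
    if k == 1:
        if math.isinf(df):
            return float(2.0 * stats.norm.cdf(c) - 1.0)
        return float(2.0 * stats.t.cdf(c, df) - 1.0)
    lower = np.full(k, -c)
    upper = np.full(k, c)
    rng = np.random.default_rng(seed)
    if math.isinf(df):
        p = stats.multivariate_normal.cdf(
            upper,
            mean=np.zeros(k),
            cov=corr,
            allow_singular=True,
            lower_limit=lower,
            maxpts=maxpts,
            rng=rng,
        )
    else:
        p = stats.multivariate_t.cdf(
            upper,
            loc=np.zeros(k),
            shape=corr,
            df=df,
            allow_singular=True,
            lower_limit=lower,
            maxpts=maxpts,
            random_state=rng,
        )
    return float(min(max(p, 0.0), 1.0))


def equicoordinate_quantile(
    corr: np.ndarray,
    df: float = math.inf,
    alpha: float = 0.05,
    seed: int = 0,
    tol: float = 1e-3,
    maxpts: int = DEFAULT_QMC_BUDGET,
) -> QuantileResult:
    """Two-sided equicoordinate (1 - alpha) quantile of a central mv t.

    Solves P(max_k |T_k| <= c) = 1 - alpha by bracketed root finding on c,
    with rectangle probabilities from seeded randomized QMC. The bracket is
    [univariate two-sided quantile, Bonferroni quantile], which provably
    contains the root. ``mc_error`` is the standard error of the achieved
    coverage across integrator re-randomizations; a
    :class:`NumericAccuracyWarning` is raised when it exceeds ``tol``.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    if df <= 0:
        raise DomainError(f"degrees of freedom must be positive, got {df}")
    corr = _validate_corr(corr)
    red, _ = _reduce_duplicates(corr)
    k = red.shape[0]

    def uni_q(a2: float) -> float:
        return float(stats.norm.ppf(1 - a2) if math.isinf(df) else stats.t.ppf(1 - a2, df))

    lo = uni_q(alpha / 2)
    if k == 1:
        return QuantileResult(lo, 0.0, 1 - alpha, seed)
    hi = uni_q(alpha / (2 * k))  # Bonferroni upper bound

    target = 1.0 - alpha

    def f(c: float) -> float:
        return _rect_prob(c, red, df, seed, maxpts) - target

    f_lo = f(lo)
    if f_lo >= 0.0:
        crit = lo
    else:
        f_hi = f(hi)
        if f_hi <= 0.0:  # pragma: no cover - QMC noise at the Bonferroni bound
            crit = hi
        else:
            crit = optimize.brentq(f, lo, hi, xtol=1e-4, rtol=1e-10)

    achieved = [_rect_prob(crit, red, df, seed + i, maxpts) for i in range(4)]
    mc_error = float(np.std(achieved, ddof=1))
    if abs(np.mean(achieved) - target) > max(tol, 3 * mc_error):
        warnings.warn(
            f"equicoordinate quantile achieved coverage {np.mean(achieved):.5f} "
            f"vs target {target:.5f} (mc_error {mc_error:.1e})",
            NumericAccuracyWarning,
        )
    return QuantileResult(float(crit), mc_error, float(achieved[0]), seed)


def simultaneous_ci(
    fit: LmmFit,
    C: ContrastMatrix,
    alpha: float = 0.05,
    df_method: str = "residual",
    seed: int = 0,
    tol: float = 1e-3,
    maxpts: int = DEFAULT_QMC_BUDGET,
    compute_adjusted_p: bool = True,
) -> SimultaneousCI:
    """Simultaneous (1 - alpha) confidence intervals for C beta.

    ``df_method`` chooses the reference distribution's degrees of freedom:
    ``"residual"`` (N - T, default), ``"containment"`` (clusters - T) or
    ``"normal"`` (infinite — multivariate normal reference). With
    ``compute_adjusted_p=False`` the adjusted p column is NaN (saves one
    integration per contrast row; significance can still be read off the
    intervals).
    """
    est, cov, corr = contrast_moments(fit, C)
    if df_method == "residual":
        df: float = float(fit.df_residual)
    elif df_method == "containment":
        df = float(fit.df_containment)
    elif df_method == "normal":
        df = math.inf
    else:
        raise DomainError(f"unknown df_method {df_method!r}")
    if df <= 0:
        raise DomainError(
            f"df_method {df_method!r} gives nonpositive degrees of freedom ({df})"
        )
    se = np.sqrt(np.diag(cov))
    tstat = est / se

    qres = equicoordinate_quantile(corr, df=df, alpha=alpha, seed=seed, tol=tol, maxpts=maxpts)
    c = qres.crit
    red, _ = _reduce_duplicates(corr)

    if compute_adjusted_p:
        adj_p = np.array(
            [1.0 - _rect_prob(abs(t), red, df, seed, maxpts) for t in tstat]
        )
        adj_p = np.clip(adj_p, 0.0, 1.0)
    else:
        adj_p = np.full(len(tstat), np.nan)

    rows = pd.DataFrame(
        {
            "label": C.row_labels,
            "estimate": est,
            "se": se,
            "lower": est - c * se,
            "upper": est + c * se,
            "t_statistic": tstat,
            "adjusted_p": adj_p,
        }
    )
    return SimultaneousCI(
        rows=rows,
        crit=c,
        corr=corr,
        df=df,
        alpha=alpha,
        mc_error=qres.mc_error,
        seed=seed,
        ctype=C.ctype,
        singular_fit=fit.singular,
    )
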