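"""Cell-means linear mixed model with one random intercept per cluster.

The model for the N-vector of (log) expression values is

    y = X beta + Z u + eps,   u ~ N(0, sigma2_cluster I),  eps ~ N(0, sigma2_resid I)

where X is the N x T matrix of time-point indicators *without* an intercept
(mean parameterization: beta_t is the adjusted mean of time point t) and Z
is the N x M matrix of cluster (mother) indicators. Variance components are
estimated by REML; beta is the GLS estimate at the optimum and
vcov(beta) = (X' V^-1 X)^-1 with V = sigma2_cluster ZZ' + sigma2_resid I.

Because clusters are nested within time points, V is block diagonal per
cluster and X' V^-1 X is diagonal, so the restricted likelihood profiles
down to a one-dimensional problem in the variance ratio
theta = sigma2_cluster / sigma2_resid: for a cluster of size k,

    (I + theta J_k)^-1 = I - theta/(1 + theta k) J_k,
    log det(I + theta J_k) = log(1 + theta k),

which gives closed forms for the GLS means, the profiled residual variance
and the restricted log-likelihood. The optimizer is a bounded scalar search
on log(theta) combined with an explicit boundary evaluation at theta = 0;
a boundary solution is returned flagged ``singular`` (standard errors may
then be underestimated — a warning condition, not an error).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._errors import DegenerateDataError, UnderDeterminedError
from .dataio import ExpressionDataset

__all__ = ["LmmFit", "build_design", "fit_cell_means_lmm"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LmmFit:
    """REML fit of the cell-means random-intercept model.

    ``beta`` holds the adjusted per-time-point means (in timepoint_order),
    ``vcov_beta`` their covariance. ``singular`` flags a cluster variance at
    (or numerically within tolerance of) the zero boundary. ``df_residual``
    is N - T; ``df_containment`` is (number of clusters) - T.
    """

    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2_cluster: float
    sigma2_resid: float
    reml_loglik: float
    df_residual: int
    df_containment: int
    n_per_timepoint: np.ndarray
    timepoint_order: list[str]
    singular: bool
    converged: bool

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def summary_frame(self):
        """Per-time-point estimates as a DataFrame (for TSV export)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "timepoint": self.timepoint_order,
                "n": self.n_per_timepoint,
                "estimate": self.beta,
                "se": self.se_beta,
            },
            index=range(1, len(self.beta) + 1),
        )


def build_design(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Indicator design matrices (X, Z) for the cell-means model.

    X is N x T with one 1 per row marking the observation's time point (no
    intercept column); Z is N x M marking its cluster, clusters ordered by
    first appearance.
    """
    tp_idx = ds.timepoint_index()
    T = ds.n_timepoints
    clusters = ds.clusters
    cl_map = {c: j for j, c in enumerate(clusters)}
    cl_idx = ds.observations["cluster"].map(cl_map).to_numpy()
    N = ds.n_obs
    X = np.zeros((N, T))
    X[np.arange(N), tp_idx] = 1.0
    Z = np.zeros((N, len(clusters)))
    Z[np.arange(N), cl_idx] = 1.0
    return X, Z


def _cluster_stats(ds: ExpressionDataset):
    """Per-cluster size, sum, sum of squares and time-point index."""
    obs = ds.observations
    tp_map = {t: i for i, t in enumerate(ds.timepoint_order)}
    g = obs.assign(
        _tp=obs["timepoint"].astype(str).map(tp_map),
        _v=obs["value"].astype(float),
        _v2=obs["value"].astype(float) ** 2,
    ).groupby("cluster", sort=False)
    k = g.size().to_numpy(dtype=float)
    s = g["_v"].sum().to_numpy(dtype=float)
    ss = g["_v2"].sum().to_numpy(dtype=float)
    tp = g["_tp"].first().to_numpy(dtype=int)
    return k, s, ss, tp


def _profiled_neg2_reml(
    theta: float, k, s, ss, tp, T: int, N: int
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """-2 restricted log-likelihood profiled over beta and sigma2_resid.

    Returns (-2 l_R, beta, sigma2_resid, diag of X'V^-1 X at unit scale).
    """
    w = 1.0 / (1.0 + theta * k)  # per-cluster shrinkage
    a = np.bincount(tp, weights=k * w, minlength=T)  # diag(X' Vt^-1 X)
    b = np.bincount(tp, weights=s * w, minlength=T)  # X' Vt^-1 y
    beta = b / a
    yvy = float(np.sum(ss) - theta * np.sum(w * s**2))
    rss = yvy - float(beta @ b)
    df = N - T
    rss = max(rss, 0.0)
    if rss <= 0.0:
        raise DegenerateDataError("zero residual variance: data carry no noise")
    sigma2 = rss / df
    logdet_v = float(np.sum(np.log1p(theta * k)))
    logdet_xvx = float(np.sum(np.log(a)))
    neg2 = df * (_LOG_2PI + math.log(sigma2) + 1.0) + logdet_v + logdet_xvx
    return neg2, beta, sigma2, a


def fit_cell_means_lmm(
    ds: ExpressionDataset,
    tol: float = 1e-8,
    max_iter: int = 200,
    singular_tol: float = 1e-6,
) -> LmmFit:
    """Fit the cell-means random-intercept model by REML.

    Parameters
    ----------
    ds
        Validated clustered dataset; requires N > T.
    tol
        Convergence tolerance on the profiled objective (in log-theta).
    max_iter
        Iteration cap for the scalar search.
    singular_tol
        Variance-ratio threshold below which the fit is flagged singular.

    Raises
    ------
    UnderDeterminedError
        If N <= T.
    DegenerateDataError
        If the data carry no variance at all (all values identical).
    """
    N, T = ds.n_obs, ds.n_timepoints
    if N <= T:
        raise UnderDeterminedError(f"N = {N} observations cannot identify T = {T} means")
    values = ds.observations["value"].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        raise DegenerateDataError("all observations identical: zero total variance")

    k, s, ss, tp = _cluster_stats(ds)
    M = len(k)

    def objective(log_theta: float) -> float:
        return _profiled_neg2_reml(math.exp(log_theta), k, s, ss, tp, T, N)[0]

    # boundary candidate theta = 0
    neg2_zero = _profiled_neg2_reml(0.0, k, s, ss, tp, T, N)[0]
    res = optimize.minimize_scalar(
        objective,
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    converged = bool(res.success)
    if not converged:  # pragma: no cover - bounded Brent rarely fails
        warnings.warn("REML scalar search did not converge", RuntimeWarning)

    if res.fun < neg2_zero - 1e-12:
        theta = math.exp(res.x)
    else:
        theta = 0.0
    singular = theta <= singular_tol

    neg2, beta, sigma2, a = _profiled_neg2_reml(theta, k, s, ss, tp, T, N)
    vcov = np.diag(sigma2 / a)
    return LmmFit(
        beta=beta,
        vcov_beta=vcov,
        sigma2_cluster=theta * sigma2,
        sigma2_resid=sigma2,
        reml_loglik=-0.5 * neg2,
        df_residual=N - T,
        df_containment=M - T,
        n_per_timepoint=ds.n_per_timepoint(),
        timepoint_order=list(ds.timepoint_order),
        singular=singular,
        converged=converged,
    )
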