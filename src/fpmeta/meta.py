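"""Univariate and multivariate meta-analytic estimators.

These are the second-stage primitives: inverse-variance common-effect
(CE) pooling, DerSimonian-Laird and REML heterogeneity estimation for
the univariate (per-grid-point) case, and generalized-least-squares
multivariate pooling with REML or method-of-moments between-study
covariance for the coefficient-vector case.  Negative heterogeneity
estimates are truncated at zero (eigenvalue truncation in the matrix
case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ValidationError

logger = logging.getLogger("fpmeta")

_MODELS = ("ce", "re")


@dataclass
class UnivariateMeta:
    """Pooled scalar estimate with heterogeneity and normalized weights."""

    pooled: float
    pooled_var: float
    tau2: float
    weights: np.ndarray   # normalized, sum to 1
    q: float              # Cochran's Q (CE weights)


def tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of tau^2, truncated at zero."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - 1)) / denom)


def _reml_nll_univariate(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    vi = v + tau2
    w = 1.0 / vi
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(vi)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    """Univariate REML tau^2 by bounded 1-D minimization."""
    hi = max(10.0 * np.var(y), 10.0 * np.max(v), 1e-8)
    res = optimize.minimize_scalar(
        _reml_nll_univariate, bounds=(0.0, hi), args=(y, v), method="bounded",
        options={"xatol": 1e-12},
    )
    # compare against the boundary explicitly: REML solutions at 0 are common
    if _reml_nll_univariate(0.0, y, v) <= res.fun:
        return 0.0
    return max(0.0, float(res.x))


def univariate_meta(
    estimates,
    variances,
    model: str = "ce",
    tau2_method: str = "dl",
) -> UnivariateMeta:
    """Inverse-variance meta-analysis of scalar estimates.

    CE: weights 1/v_i and tau^2 = 0.  RE: tau^2 by DerSimonian-Laird
    (default) or REML, weights 1/(v_i + tau^2).  A single study under RE
    degrades to CE with a warning (no heterogeneity is estimable).
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim != 1 or y.shape != v.shape or y.size == 0:
        raise ValidationError("estimates and variances must be equal-length 1-D")
    if np.any(v <= 0):
        raise ValidationError("variances must be strictly positive")
    if model not in _MODELS:
        raise ValidationError(f"model must be one of {_MODELS}, got {model!r}")

    w_ce = 1.0 / v
    mu_ce = np.sum(w_ce * y) / np.sum(w_ce)
    q = float(np.sum(w_ce * (y - mu_ce) ** 2))

    tau2 = 0.0
    if model == "re":
        if y.size == 1:
            logger.warning("single study: RE meta-analysis degrades to CE")
        elif tau2_method == "dl":
            tau2 = tau2_dl(y, v)
        elif tau2_method == "reml":
            tau2 = tau2_reml(y, v)
        else:
            raise ValidationError(f"unknown tau2 method {tau2_method!r}")
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_var = float(1.0 / np.sum(w))
    return UnivariateMeta(
        pooled=pooled, pooled_var=pooled_var, tau2=float(tau2),
        weights=w / np.sum(w), q=q,
    )


# ---------------------------------------------------------------------------
# multivariate pooling

def _check_psd(S: np.ndarray, tol: float = 1e-8) -> bool:
    if not np.allclose(S, S.T, atol=1e-8 * (1.0 + np.abs(S).max())):
        return False
    eig = np.linalg.eigvalsh(0.5 * (S + S.T))
    return bool(eig.min() >= -tol * max(1.0, eig.max()))


def _psd_truncate(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def _gls_pool(B: np.ndarray, V: np.ndarray):
    """GLS pooled mean for b_i ~ N(beta, V_i); returns (beta, cov, W_i)."""
    Vinv = np.linalg.inv(V)
    M = Vinv.sum(axis=0)
    cov = np.linalg.inv(M)
    beta = cov @ np.einsum("ijk,ik->j", Vinv, B)
    W = np.einsum("jk,ikl->ijl", cov, Vinv)
    return beta, cov, W


def _reml_nll_multivariate(psi: np.ndarray, B: np.ndarray, S: np.ndarray) -> float:
    V = S + psi[None, :, :]
    sign, logdet = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        return np.inf
    Vinv = np.linalg.inv(V)
    M = Vinv.sum(axis=0)
    sign_m, logdet_m = np.linalg.slogdet(M)
    if sign_m <= 0:
        return np.inf
    beta = np.linalg.solve(M, np.einsum("ijk,ik->j", Vinv, B))
    r = B - beta[None, :]
    quad = np.einsum("ij,ijk,ik->", r, Vinv, r)
    return 0.5 * (logdet.sum() + logdet_m + quad)


def _chol_to_psi(theta: np.ndarray, m: int) -> np.ndarray:
    L = np.zeros((m, m))
    L[np.tril_indices(m)] = theta
    return L @ L.T


def psi_mom(B: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Method-of-moments between-study covariance.

    The unweighted moment estimator: sample covariance of the study
    coefficient vectors minus the average within-study covariance,
    eigenvalue-truncated to the PSD cone.  Closed-form and robust; used
    as the REML starting value and available as a fast alternative.
    """
    I = B.shape[0]
    if I < 2:
        return np.zeros((B.shape[1], B.shape[1]))
    C = np.cov(B, rowvar=False, ddof=1).reshape(B.shape[1], B.shape[1])
    return _psd_truncate(C - S.mean(axis=0))


def psi_reml(B: np.ndarray, S: np.ndarray) -> np.ndarray:
    """REML estimate of the between-study covariance matrix.

    Maximizes the restricted likelihood of ``b_i ~ N(beta, S_i + Psi)``
    over a Cholesky parameterization of Psi (so the estimate is PSD by
    construction), starting from the method-of-moments value.
    """
    I, m = B.shape
    if I < 2:
        return np.zeros((m, m))
    start = psi_mom(B, S)
    # jitter for a valid Cholesky start
    scale = np.sqrt(np.mean(np.diagonal(S, axis1=1, axis2=2), axis=0))
    L0 = np.linalg.cholesky(start + 1e-8 * np.diag(scale**2 + 1e-12))
    theta0 = L0[np.tril_indices(m)]

    def nll(theta):
        return _reml_nll_multivariate(_chol_to_psi(theta, m), B, S)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10,
                                     "maxiter": 20000, "maxfev": 20000})
    best = res.x
    # also consider the zero-heterogeneity boundary
    if nll(np.zeros_like(theta0)) < res.fun:
        best = np.zeros_like(theta0)
    return _chol_to_psi(best, m)


def pool_multivariate(
    B,
    S,
    model: str = "ce",
    psi_method: str = "reml",
):
    """Multivariate meta-analysis of coefficient vectors.

    Parameters
    ----------
    B : (I, m) study coefficient vectors
    S : (I, m, m) within-study covariance matrices
    model : "ce" or "re"
    psi_method : "reml" (default) or "mom" for the RE between-study matrix

    Returns
    -------
    (beta, cov, psi, W) with ``W`` the (I, m, m) stack of study weight
    matrices satisfying ``sum_i W_i = I_m``.
    """
    B = np.asarray(B, dtype=float)
    S = np.asarray(S, dtype=float)
    if model not in _MODELS:
        raise ValidationError(f"model must be one of {_MODELS}, got {model!r}")
    I, m = B.shape
    psi = np.zeros((m, m))
    if model == "re":
        if I == 1:
            logger.warning("single study: RE multivariate pooling degrades to CE")
        elif psi_method == "reml":
            psi = psi_reml(B, S)
        elif psi_method == "mom":
            psi = psi_mom(B, S)
        else:
            raise ValidationError(f"unknown psi method {psi_method!r}")
    beta, cov, W = _gls_pool(B, S + psi[None, :, :])
    return beta, cov, psi, W
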