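"""REML variance components and BLUP for the genomic mixed model.

Model: y = Xb + u + e with u ~ N(0, G sigma_g^2) and e ~ N(0, I sigma_e^2),
G a genomic relationship matrix over the phenotyped lines.  The restricted
likelihood is profiled on the eigenbasis of G, leaving a one-dimensional
problem in the variance ratio gamma = sigma_g^2 / sigma_e^2 that Brent's
method solves robustly; sigma_e^2 has a closed-form profile solution.
Standard errors come from the numerically evaluated curvature of the
restricted likelihood at the optimum.

Genomic heritability on a single-record basis is

    h^2 = d(G) sigma_g^2 / (d(G) sigma_g^2 + sigma_e^2)

with d(G) the average diagonal element of G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix
from .io import GranosError

logger = logging.getLogger("granos")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MixedModelFit:
    """REML fit of the genomic mixed model."""

    sigma_g2: float
    sigma_e2: float
    se_sigma_g2: float
    se_sigma_e2: float
    b_hat: np.ndarray
    b_names: list
    u_hat: np.ndarray
    pev: np.ndarray
    h2: float
    loglik: float
    converged: bool
    n_iter: int
    line_ids: np.ndarray = None  # type: ignore[assignment]

    @property
    def corrected_y(self):
        """Stored only by fitting helpers that retain y - X b_hat."""
        return getattr(self, "_corrected_y", None)


def _reml_profile(y, X, d, ytil, Xtil):
    """Return f(log_gamma) -> (-2 * profile restricted loglik, extras)."""
    n, p = X.shape

    def parts(log_gamma):
        gamma = np.exp(log_gamma)
        delta = gamma * d + 1.0  # V = sigma_e^2 * diag(delta) in eigenbasis
        w = 1.0 / delta
        XtWX = Xtil.T @ (Xtil * w[:, None])
        XtWy = Xtil.T @ (ytil * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ytil - Xtil @ beta
        quad = float(np.sum(r * r * w))
        sigma_e2 = quad / (n - p)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(sigma_e2)
            + np.sum(np.log(delta))
            + logdet_XtWX
            + (n - p)
            + (n - p) * _LOG_2PI
        )
        return ll, beta, sigma_e2, gamma

    return parts


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> MixedModelFit:
    """REML estimates, BLUEs and BLUPs for y = Xb + u + e, u ~ N(0, K.G s2g).

    One eigendecomposition of G, then Brent's method on log(gamma) with a
    boundary check at gamma -> 0 (sigma_g^2 floored at zero there).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n or K.G.shape[0] != n:
        raise GranosError("y, X and K must cover the same lines")
    # drop aliased fixed-effect columns
    qr_rank = np.linalg.matrix_rank(X)
    if qr_rank < X.shape[1]:
        _, Rq, piv = _qr_pivot(X)
        keep = sorted(piv[:qr_rank])
        X = X[:, keep]
        logger.warning("dropped %d aliased fixed-effect columns",
                       len(piv) - qr_rank)
    p = X.shape[1]

    d, U = np.linalg.eigh(K.G)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise GranosError(
            f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})"
        )
    d = np.clip(d, 0.0, None)
    ytil = U.T @ y
    Xtil = U.T @ X
    parts = _reml_profile(y, X, d, ytil, Xtil)

    neg = lambda lg: -parts(lg)[0]
    res = minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": tol})
    ll_opt, beta, sigma_e2, gamma = parts(res.x)
    converged = bool(res.success)
    n_iter = int(res.nfev)

    # boundary: gamma -> 0 (no genetic variance)
    ll_zero, beta0, s2e0, _ = parts(-30.0)
    if ll_zero >= ll_opt - 1e-10:
        gamma, beta, sigma_e2, ll_opt = 0.0, beta0, s2e0, ll_zero
    sigma_g2 = gamma * sigma_e2

    # BLUPs on the eigenbasis: u = gamma G (gamma G + I)^-1 (y - Xb)
    rtil = ytil - Xtil @ beta
    delta = gamma * d + 1.0
    u_hat = U @ (gamma * d / delta * rtil)

    # PEV via P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 ; PEV = s2g*G - C P C
    Vinv_diag = 1.0 / (sigma_e2 * delta)
    XtVinvX = Xtil.T @ (Xtil * Vinv_diag[:, None])
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    C = U * (sigma_g2 * d)[None, :]  # = s2g * G U on eigenbasis columns
    CV = C * Vinv_diag[None, :]
    A = CV @ C.T  # s2g G V^-1 s2g G
    B = CV @ Xtil
    pev = sigma_g2 * np.diag(K.G) - np.diag(A) + np.einsum(
        "ij,jk,ik->i", B, XtVinvX_inv, B
    )
    pev = np.clip(pev, 0.0, None)

    avg_diag = K.avg_diag
    h2 = (
        avg_diag * sigma_g2 / (avg_diag * sigma_g2 + sigma_e2)
        if (avg_diag * sigma_g2 + sigma_e2) > 0 else 0.0
    )

    se_g = se_e = np.nan
    if compute_se:
        se_g, se_e = _variance_ses(parts, sigma_g2, sigma_e2, d, ytil, Xtil)

    fit = MixedModelFit(
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2),
        se_sigma_g2=float(se_g), se_sigma_e2=float(se_e),
        b_hat=beta, b_names=list(range(p)), u_hat=u_hat, pev=pev,
        h2=float(h2), loglik=float(ll_opt), converged=converged,
        n_iter=n_iter, line_ids=np.asarray(K.line_ids),
    )
    fit._corrected_y = y - X @ beta
    fit._X = X
    return fit


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, list(piv)


def _reml_loglik_at(sg2, se2, d, ytil, Xtil):
    """Restricted loglik at explicit (sigma_g^2, sigma_e^2)."""
    n = len(ytil)
    p = Xtil.shape[1]
    v = sg2 * d + se2
    if np.any(v <= 0):
        return -np.inf
    w = 1.0 / v
    XtWX = Xtil.T @ (Xtil * w[:, None])
    beta = np.linalg.solve(XtWX, Xtil.T @ (ytil * w))
    r = ytil - Xtil @ beta
    _, logdet = np.linalg.slogdet(XtWX)
    return -0.5 * (
        np.sum(np.log(v)) + logdet + float(np.sum(r * r * w))
        + (n - p) * _LOG_2PI
    )


def _variance_ses(parts, sg2, se2, d, ytil, Xtil):
    """Asymptotic SEs from the numerical Hessian of the restricted loglik."""
    f = lambda a, b: _reml_loglik_at(a, b, d, ytil, Xtil)
    h1 = max(sg2, 1e-4 * se2, 1e-10) * 1e-3
    h2 = max(se2, 1e-10) * 1e-3
    x, yv = sg2, se2
    try:
        H = np.empty((2, 2))
        H[0, 0] = (f(x + h1, yv) - 2 * f(x, yv) + f(x - h1, yv)) / h1**2 \
            if x - h1 > 0 else (f(x + 2 * h1, yv) - 2 * f(x + h1, yv) + f(x, yv)) / h1**2
        H[1, 1] = (f(x, yv + h2) - 2 * f(x, yv) + f(x, yv - h2)) / h2**2
        H[0, 1] = H[1, 0] = (
            f(x + h1, yv + h2) - f(x + h1, yv - h2)
            - f(x - h1 if x - h1 > 0 else x, yv + h2)
            + f(x - h1 if x - h1 > 0 else x, yv - h2)
        ) / (4 * h1 * h2)
        cov = np.linalg.inv(-H)
        var = np.clip(np.diag(cov), 0.0, None)
        return float(np.sqrt(var[0])), float(np.sqrt(var[1]))
    except np.linalg.LinAlgError:
        return np.nan, np.nan


def heritability(fit: MixedModelFit, K: KinshipMatrix) -> float:
    """Single-record genomic heritability d(G)s2g / (d(G)s2g + s2e)."""
    denom = K.avg_diag * fit.sigma_g2 + fit.sigma_e2
    return float(K.avg_diag * fit.sigma_g2 / denom) if denom > 0 else 0.0


def predict_unphenotyped(
    fit: MixedModelFit,
    K_full: KinshipMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """Conditional-mean GEBVs for lines without phenotypes.

    u_test = s2g * G[test, train] V_train^-1 (y_train - X_train b_hat),
    algebraically identical to G[test, train] G[train, train]^-1 u_train
    under the fitted covariance, but needing no inverse of the (possibly
    singular) train block of G.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise GranosError("train and test line sets overlap")
    r = fit._corrected_y
    G = K_full.G
    Vtt = fit.sigma_g2 * G[np.ix_(train_idx, train_idx)] + fit.sigma_e2 * np.eye(
        len(train_idx)
    )
    rhs = np.linalg.solve(Vtt, r)
    return fit.sigma_g2 * G[np.ix_(test_idx, train_idx)] @ rhs


def snp_blup_backsolve(
    fit: MixedModelFit, Z2: np.ndarray, denom: float
) -> np.ndarray:
    """Per-SNP effects from a GBLUP fit built on the same Z2.

    With G = Z2 Z2'/denom, matched-variance SNP-BLUP gives
    a_hat = (s2g/denom) Z2' V^-1 (y - X b_hat), and Z2 a_hat reproduces
    u_hat exactly.
    """
    if denom <= 0:
        raise GranosError("non-positive VanRaden denominator")
    r = fit._corrected_y
    n = len(r)
    G = (Z2 @ Z2.T) / denom
    V = fit.sigma_g2 * G + fit.sigma_e2 * np.eye(n)
    rhs = np.linalg.solve(V, r)
    return (fit.sigma_g2 / denom) * (Z2.T @ rhs)
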