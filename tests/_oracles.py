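"""Independent brute-force references used only by the tests.

These deliberately avoid the package's computational paths: the REML
oracle builds the marginal covariance explicitly and evaluates the
restricted density through an orthonormal basis of error contrasts; the
Legendre oracle runs the three-term recurrence directly.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from rrpersist.reml_engine import _fullrank_columns, dense_V


def legendre_recurrence(x: float, order: int) -> np.ndarray:
    """Classical Legendre polynomials P_0..P_{order-1} at x via
    (m+1) P_{m+1} = (2m+1) x P_m - m P_{m-1}."""
    P = np.zeros(order)
    P[0] = 1.0
    if order > 1:
        P[1] = x
    for m in range(1, order - 1):
        P[m + 1] = ((2 * m + 1) * x * P[m] - m * P[m - 1]) / (m + 1)
    return P


def error_contrast_reml(params, design, y=None) -> float:
    """REML log-likelihood via an explicit orthonormal error-contrast
    basis: logL = log N(K'y; 0, K'VK) with K spanning null(X')."""
    if y is None:
        y = design.y
    V = dense_V(params, design)
    Xr = design.X[:, _fullrank_columns(design.X)]
    K = null_space(Xr.T)
    S = K.T @ V @ K
    return float(
        multivariate_normal.logpdf(K.T @ y, mean=np.zeros(S.shape[0]), cov=S)
    )


def gls_blup(params, X, Z, W, y, harvest_index, plot_index) -> dict:
    """Textbook GLS/BLUP: beta = (X'V^-1 X)^- X'V^-1 y and
    u_hat = G U' V^-1 (y - X beta) computed from the marginal covariance,
    without Henderson's equations."""
    n = len(y)
    blocks = []
    G_parts = []
    if Z is not None and params.K_g is not None:
        ng = Z.shape[1] // params.K_g.shape[0]
        blocks.append(Z)
        G_parts.append(np.kron(np.eye(ng), params.K_g))
    if W is not None and params.K_p is not None:
        npl = W.shape[1] // params.K_p.shape[0]
        blocks.append(W)
        G_parts.append(np.kron(np.eye(npl), params.K_p))
    U = np.hstack(blocks)
    from scipy.linalg import block_diag

    G = block_diag(*G_parts)
    if params.structure == "homogeneous":
        R = float(params.residual) * np.eye(n)
    elif params.structure == "diagonal":
        R = np.diag(np.asarray(params.residual, float)[harvest_index])
    else:
        Sigma = np.asarray(params.residual, float)
        R = np.zeros((n, n))
        for p in np.unique(plot_index):
            rows = np.flatnonzero(plot_index == p)
            R[np.ix_(rows, rows)] = Sigma[
                np.ix_(harvest_index[rows], harvest_index[rows])
            ]
    V = U @ G @ U.T + R
    Vi = np.linalg.inv(V)
    keep = _fullrank_columns(X)
    Xr = X[:, keep]
    beta = np.linalg.solve(Xr.T @ Vi @ Xr, Xr.T @ Vi @ y)
    u = G @ U.T @ Vi @ (y - Xr @ beta)
    return {"beta": beta, "u": u, "keep": keep}
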