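"""REML estimation of the random-regression mixed model.

Model:  y = X beta + Z alpha + W p + e, with
alpha ~ N(0, K_g (x) I_ng) genotype regression coefficients,
p ~ N(0, K_p (x) I_np) plot (permanent-environment) coefficients,
e ~ N(0, R) with R homogeneous, diagonal-by-harvest, or unstructured
within plots across harvests.

The restricted log-likelihood is defined through an orthonormal basis of
error contrasts (any K with K'X = 0, K'K = I):

    logL_R = log N(K'y; 0, K'VK)
           = -1/2 [ (n-r) log 2pi + log|V| + log|X_r' V^-1 X_r|
                    - log|X_r' X_r| + y' P y ],

with X_r a full-rank column basis of X (selected by pivoted QR; the
replication indicators and the phi_0 fixed-regression column are
confounded, so X is rank deficient by one), V = Z G_g Z' + W G_p W' + R
and P the usual REML projection.  The value does not depend on which
error-contrast basis or full-rank X basis is used.

Two evaluation paths are provided and cross-checked in the test suite:

* :func:`restricted_loglik` forms V densely — transparent, O(n^3), used
  as the public, auditable definition;
* the fitting path absorbs random effects genotype by genotype (plots
  nest within genotypes, so the mixed-model-equation matrix is
  block-diagonal after absorbing the fixed part), with all per-genotype
  Cholesky factorizations batched.  This is exact, not an approximation,
  and is what makes simulation studies at trial scale affordable.

Variance parameters are optimized on a log-Cholesky scale (guaranteeing
positive definiteness) by L-BFGS-B with multiple starting points, since
REML surfaces of random-regression models are multimodal and published
analyses of this design report non-convergent candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize

from .longitudinal_design import (
    DesignMatrices,
    HarvestSchedule,
    ModelSpec,
    PhenotypeTable,
    build_design,
)

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)
DEFAULT_SEED = 20180913


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class VarianceParameters:
    """REML variance parameters: coefficient covariance matrices for the
    genetic (K_g) and permanent-environment (K_p) random regressions and
    the residual parameters.

    ``residual`` is a scalar array () for homogeneous structure, a vector
    (one variance per measured harvest) for diagonal, or a full symmetric
    PSD matrix across harvests for unstructured.  ``K_g`` / ``K_p`` may be
    None when the corresponding random term is omitted (reduced models for
    likelihood-ratio testing).
    """

    K_g: np.ndarray | None
    K_p: np.ndarray | None
    residual: np.ndarray
    structure: str

    def validate(self, n_harvests: int) -> None:
        for name, K in (("K_g", self.K_g), ("K_p", self.K_p)):
            if K is None:
                continue
            K = np.asarray(K, float)
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(K)) < -1e-8 * max(1.0, np.trace(K)):
                raise ValueError(f"{name} must be positive semidefinite")
        r = np.asarray(self.residual, float)
        if self.structure == "homogeneous":
            if r.ndim != 0 or r <= 0:
                raise ValueError("homogeneous residual must be a positive scalar")
        elif self.structure == "diagonal":
            if r.shape != (n_harvests,) or np.any(r <= 0):
                raise ValueError("diagonal residual needs one positive variance per harvest")
        elif self.structure == "unstructured":
            if r.shape != (n_harvests, n_harvests):
                raise ValueError("unstructured residual must be a full harvest matrix")
            if not np.allclose(r, r.T, atol=1e-10):
                raise ValueError("unstructured residual must be symmetric")
            if np.min(np.linalg.eigvalsh(r)) <= 0:
                raise ValueError("unstructured residual must be positive definite")
        else:
            raise ValueError(f"unknown residual structure {self.structure!r}")

    def residual_variance_at_harvest(self, j: int) -> float:
        r = np.asarray(self.residual, float)
        if self.structure == "homogeneous":
            return float(r)
        if self.structure == "diagonal":
            return float(r[j])
        return float(r[j, j])

    def scaled(self, c2: float) -> "VarianceParameters":
        return VarianceParameters(
            K_g=None if self.K_g is None else self.K_g * c2,
            K_p=None if self.K_p is None else self.K_p * c2,
            residual=np.asarray(self.residual) * c2,
            structure=self.structure,
        )


@dataclass
class FitOptions:
    """Optimizer controls for :func:`fit_reml`."""

    n_starts: int = 3
    max_iter: int = 500
    gtol: float = 1e-4
    ftol: float = 1e-8
    seed: int = DEFAULT_SEED
    include_genetic: bool = True
    include_perm: bool = True
    variance_floor_frac: float = 1e-10
    dead_plot_as_zero: bool = False


@dataclass
class FittedModel:
    """REML estimates, BLUP coefficient solutions and prediction-error
    covariance blocks for one candidate model on one data set."""

    spec: ModelSpec
    schedule: HarvestSchedule
    params: VarianceParameters
    beta: np.ndarray
    x_names: list[str]
    alpha_hat: np.ndarray | None      # (ng, M_a) genotype coefficient BLUPs
    p_hat: np.ndarray | None          # (np, M_p) plot coefficient BLUPs
    logL: float
    pev_blocks: np.ndarray | None     # (ng, M_a, M_a)
    genotype_ids: list[str]
    plot_ids: list[str]
    dropped_genotypes: list[str]
    n_records: int
    rank_X: int
    converged: bool
    boundary: bool
    n_iter: int
    include_genetic: bool = True
    include_perm: bool = True

    @property
    def label(self) -> str:
        return self.spec.label

    def genotype_index(self, genotype_id: str) -> int:
        try:
            return self.genotype_ids.index(str(genotype_id))
        except ValueError:
            raise KeyError(f"genotype {genotype_id!r} not in fit") from None

    def genetic_blups(self) -> pd.DataFrame:
        """BLUP regression coefficients per genotype, one column per
        basis order."""
        if self.alpha_hat is None:
            raise ValueError("fit has no genetic term")
        cols = [f"alpha_{m}" for m in range(self.alpha_hat.shape[1])]
        df = pd.DataFrame(self.alpha_hat, columns=cols)
        df.insert(0, "genotype", self.genotype_ids)
        return df

    def plot_blups(self) -> pd.DataFrame:
        """BLUP permanent-environment coefficients per plot."""
        if self.p_hat is None:
            raise ValueError("fit has no permanent-environment term")
        cols = [f"p_{m}" for m in range(self.p_hat.shape[1])]
        df = pd.DataFrame(self.p_hat, columns=cols)
        df.insert(0, "plot", self.plot_ids)
        return df

    def to_dict(self) -> dict:
        """JSON-serializable summary (parameters, logL, convergence)."""
        p = self.params
        return {
            "model": self.label,
            "logL": self.logL,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_records": self.n_records,
            "rank_X": self.rank_X,
            "K_g": None if p.K_g is None else p.K_g.tolist(),
            "K_p": None if p.K_p is None else p.K_p.tolist(),
            "residual": np.asarray(p.residual).tolist(),
            "residual_structure": p.structure,
            "beta": dict(zip(self.x_names, np.asarray(self.beta).tolist())),
        }


# ---------------------------------------------------------------------------
# helpers: full-rank X, log-Cholesky packing
# ---------------------------------------------------------------------------


def _fullrank_columns(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Indices of a full-rank column basis of X via pivoted QR; rank is
    judged numerically (singular values > rtol * largest)."""
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > rtol * diag[0])) if diag.size else 0
    return np.sort(piv[:rank])


def _n_tri(k: int) -> int:
    return k * (k + 1) // 2


def _chol_to_theta(K: np.ndarray) -> np.ndarray:
    """Pack a PD matrix as log-Cholesky parameters (row-wise lower
    triangle; diagonal entries stored as logs)."""
    L = np.linalg.cholesky(K)
    out = []
    for i in range(K.shape[0]):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.asarray(out)


def _theta_to_chol(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L


def _theta_to_cov(theta: np.ndarray, k: int) -> np.ndarray:
    L = _theta_to_chol(theta, k)
    return L @ L.T


# ---------------------------------------------------------------------------
# dense restricted log-likelihood (public definition)
# ---------------------------------------------------------------------------


def _dense_R(params: VarianceParameters, design: DesignMatrices) -> np.ndarray:
    n = design.n_records
    h = design.harvest_index
    if params.structure == "homogeneous":
        return float(params.residual) * np.eye(n)
    if params.structure == "diagonal":
        return np.diag(np.asarray(params.residual, float)[h])
    R = np.zeros((n, n))
    Sigma = np.asarray(params.residual, float)
    plots = design.records["plot_idx"].to_numpy()
    for p in np.unique(plots):
        rows = np.flatnonzero(plots == p)
        R[np.ix_(rows, rows)] = Sigma[np.ix_(h[rows], h[rows])]
    return R


def dense_V(params: VarianceParameters, design: DesignMatrices) -> np.ndarray:
    """Marginal covariance V = Z (K_g (x) I) Z' + W (K_p (x) I) W' + R."""
    V = _dense_R(params, design)
    if params.K_g is not None:
        ma = params.K_g.shape[0]
        ng = len(design.genotype_ids)
        V += design.Z @ np.kron(np.eye(ng), params.K_g) @ design.Z.T
    if params.K_p is not None:
        mp = params.K_p.shape[0]
        npl = len(design.plot_ids)
        V += design.W @ np.kron(np.eye(npl), params.K_p) @ design.W.T
    return V


def restricted_loglik(
    params: VarianceParameters, design: DesignMatrices, y: np.ndarray | None = None
) -> float:
    """REML log-likelihood of y under the candidate variance parameters,
    profiled over fixed effects (error-contrast normalization).

    This is the transparent dense-matrix definition: it forms V explicitly
    and is intended for moderate n (validation, small analyses); the fitter
    uses an algebraically identical absorption path.
    """
    if y is None:
        y = design.y
    y = np.asarray(y, float)
    params.validate(design.schedule.n_measured)
    n = design.n_records
    V = dense_V(params, design)
    keep = _fullrank_columns(design.X)
    Xr = design.X[:, keep]
    r = Xr.shape[1]
    try:
        cV = sla.cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(f"singular marginal covariance V: {exc}")
    logdetV = 2.0 * np.sum(np.log(np.diag(cV[0])))
    ViX = sla.cho_solve(cV, Xr)
    Viy = sla.cho_solve(cV, y)
    XtViX = Xr.T @ ViX
    cXVX = sla.cho_factor(XtViX, lower=True)
    logdet_XtViX = 2.0 * np.sum(np.log(np.diag(cXVX[0])))
    beta = sla.cho_solve(cXVX, Xr.T @ Viy)
    yPy = float(y @ Viy - (Xr.T @ Viy) @ beta)
    sign, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    return -0.5 * (
        (n - r) * LOG2PI + logdetV + logdet_XtViX - logdet_XtX + yPy
    )


# ---------------------------------------------------------------------------
# compact (absorption) representation
# ---------------------------------------------------------------------------


class _CompactData:
    """Per-plot slotted arrays for the fast likelihood.

    Every plot owns one row slot per measured harvest; unobserved slots are
    zeroed and masked.  Plots are ordered so that each genotype's plots are
    contiguous, which lets the per-genotype absorption run as batched
    linear algebra over genotypes with equal plot counts.
    """

    def __init__(self, design: DesignMatrices, spec: ModelSpec):
        rec = design.records
        nh = design.schedule.n_measured
        self.nh = nh
        self.keep_x = _fullrank_columns(design.X)
        Xr = design.X[:, self.keep_x]
        self.px = Xr.shape[1]
        self.rank_X = self.px
        self.ma = spec.genetic_order
        self.mp = spec.perm_order
        self.n = design.n_records

        plot_geno = (
            rec.groupby("plot_idx")["genotype_idx"].first().sort_index().to_numpy()
        )
        npl = len(design.plot_ids)
        self.n_plots = npl
        self.n_geno = len(design.genotype_ids)
        order = np.lexsort((np.arange(npl), plot_geno))
        self.plot_order = order                      # original plot idx per slot-row
        inv = np.empty(npl, int)
        inv[order] = np.arange(npl)
        self.plot_geno_sorted = plot_geno[order]

        prow = inv[rec["plot_idx"].to_numpy()]
        hcol = rec["harvest_idx"].to_numpy()
        # basis rows straight from the record metadata
        from .longitudinal_design import legendre_matrix

        t = rec["t_star"].to_numpy()
        A = legendre_matrix(t, self.ma)
        P = legendre_matrix(t, self.mp)
        y = rec["yield"].to_numpy(float)

        self.obs = np.zeros((npl, nh), bool)
        self.obs[prow, hcol] = True
        d = self.ma + self.mp + self.px + 1
        self.d = d
        B = np.zeros((npl, nh, d))
        B[prow, hcol, : self.ma] = A
        B[prow, hcol, self.ma : self.ma + self.mp] = P
        B[prow, hcol, self.ma + self.mp : -1] = Xr
        B[prow, hcol, -1] = y
        self.B = B
        _, self.logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)

        # genotype grouping by plot count
        self.groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        counts = np.bincount(self.plot_geno_sorted, minlength=self.n_geno)
        starts = np.concatenate([[0], np.cumsum(counts)])
        for k in np.unique(counts):
            gsel = np.flatnonzero(counts == k)
            rows = np.stack(
                [np.arange(starts[g], starts[g] + k) for g in gsel]
            )  # (G, k) slot-row indices
            self.groups.append((int(k), gsel, rows))

    # -- residual precision -------------------------------------------------

    def _lambda_and_logdetR(self, params: VarianceParameters):
        """Per-plot residual precision over harvest slots and log|R|.

        Missing slots are handled exactly by replacing their rows/columns of
        the per-plot covariance with identity (block-diagonal completion):
        the observed block's inverse and determinant are unchanged and the
        zeroed data rows contribute nothing.
        Returns (weights (npl, nh) or None, Lambda (npl, nh, nh) or None,
        logdetR)."""
        obs = self.obs
        if params.structure in ("homogeneous", "diagonal"):
            if params.structure == "homogeneous":
                v = np.full(self.nh, float(params.residual))
            else:
                v = np.asarray(params.residual, float)
            w = obs / v[None, :]
            logdetR = float(np.sum(obs * np.log(v)[None, :]))
            return w, None, logdetR
        Sigma = np.asarray(params.residual, float)
        npl, nh = obs.shape
        S = np.broadcast_to(Sigma, (npl, nh, nh)).copy()
        m = ~obs
        S[m[:, :, None] | m[:, None, :]] = 0.0
        diag = np.arange(nh)
        S[:, diag, diag] = np.where(obs, S[:, diag, diag], 1.0)
        cho = np.linalg.cholesky(S)
        logdetR = float(2.0 * np.sum(np.log(cho[:, diag, diag])))
        Lam = np.linalg.inv(S)
        Lam[m[:, :, None] | m[:, None, :]] = 0.0
        Lam[:, diag, diag] = np.where(obs, Lam[:, diag, diag], 0.0)
        return None, Lam, logdetR

    # -- -2 logL ------------------------------------------------------------

    def neg2_restricted_loglik(self, params: VarianceParameters) -> float:
        ma = self.ma if params.K_g is not None else 0
        mp = self.mp if params.K_p is not None else 0
        try:
            w, Lam, logdetR = self._lambda_and_logdetR(params)
        except np.linalg.LinAlgError:
            return np.inf
        if not np.isfinite(logdetR):
            return np.inf
        B = self.B
        if ma == 0 or mp == 0:
            cols = np.r_[
                np.arange(ma),
                np.arange(self.ma, self.ma + mp),
                np.arange(self.ma + self.mp, self.d),
            ]
            B = B[:, :, cols]
        d = B.shape[2]
        pt = self.px + 1
        if w is not None:
            A = np.einsum("pji,pj,pjl->pil", B, w, B, optimize=True)
        else:
            A = np.matmul(np.swapaxes(B, 1, 2), np.matmul(Lam, B))

        logdetG = 0.0
        logdetC = 0.0
        T_tt = A[:, ma + mp :, ma + mp :].sum(axis=0)

        if ma > 0:
            sK, ldKg = np.linalg.slogdet(params.K_g)
            if sK <= 0:
                return np.inf
            logdetG += self.n_geno * ldKg
            Kg_inv = np.linalg.inv(params.K_g)
        if mp > 0:
            sK, ldKp = np.linalg.slogdet(params.K_p)
            if sK <= 0:
                return np.inf
            logdetG += self.n_plots * ldKp
            Kp_inv = np.linalg.inv(params.K_p)

        if ma == 0 and mp == 0:
            T_adj = T_tt
        else:
            T_adj = T_tt.copy()
            if ma == 0:
                # plots are independent given no genetic term: absorb per plot
                U = A[:, :mp, :mp] + Kp_inv[None]
                Vut = A[:, :mp, mp:]
                try:
                    cho = np.linalg.cholesky(U)
                except np.linalg.LinAlgError:
                    return np.inf
                logdetC += float(
                    2.0 * np.sum(np.log(cho[:, np.arange(mp), np.arange(mp)]))
                )
                sol = np.linalg.solve(U, Vut)
                T_adj -= np.einsum("pdi,pdj->ij", Vut, sol, optimize=True)
            else:
                for k, gsel, rows in self.groups:
                    Ag = A[rows]                       # (G, k, d, d)
                    du = ma + k * mp
                    G = Ag.shape[0]
                    U = np.zeros((G, du, du))
                    Vut = np.zeros((G, du, pt))
                    U[:, :ma, :ma] = Ag[:, :, :ma, :ma].sum(axis=1) + Kg_inv[None]
                    Vut[:, :ma, :] = Ag[:, :, :ma, ma + mp :].sum(axis=1)
                    for j in range(k):
                        sl = slice(ma + j * mp, ma + (j + 1) * mp)
                        if mp > 0:
                            U[:, sl, sl] = (
                                Ag[:, j, ma : ma + mp, ma : ma + mp] + Kp_inv[None]
                            )
                            U[:, :ma, sl] = Ag[:, j, :ma, ma : ma + mp]
                            U[:, sl, :ma] = np.swapaxes(
                                Ag[:, j, :ma, ma : ma + mp], 1, 2
                            )
                            Vut[:, sl, :] = Ag[:, j, ma : ma + mp, ma + mp :]
                    try:
                        cho = np.linalg.cholesky(U)
                    except np.linalg.LinAlgError:
                        return np.inf
                    logdetC += float(
                        2.0 * np.sum(np.log(cho[:, np.arange(du), np.arange(du)]))
                    )
                    sol = np.linalg.solve(U, Vut)
                    T_adj -= np.einsum("gdi,gdj->ij", Vut, sol, optimize=True)

        xx = T_adj[: self.px, : self.px]
        xy = T_adj[: self.px, -1]
        yy = T_adj[-1, -1]
        try:
            cxx = sla.cho_factor(xx, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_xx = 2.0 * np.sum(np.log(np.diag(cxx[0])))
        yPy = float(yy - xy @ sla.cho_solve(cxx, xy))
        n, r = self.n, self.px
        return (
            (n - r) * LOG2PI
            + logdetR
            + logdetG
            + logdetC
            + logdet_xx
            - self.logdet_XtX
            + yPy
        )


# ---------------------------------------------------------------------------
# dense mixed-model equations (BLUPs, PEV) — also used for sufficiency tests
# ---------------------------------------------------------------------------


def _floored_inv(K: np.ndarray) -> np.ndarray:
    """Inverse with eigenvalues floored at a small fraction of the trace;
    keeps the mixed-model equations solvable when a variance estimate sits
    on the boundary."""
    K = np.asarray(K, float)
    w, V = np.linalg.eigh(K)
    floor = 1e-10 * max(np.trace(K), 1e-30)
    w = np.maximum(w, floor)
    return (V / w) @ V.T


def solve_mme(
    X: np.ndarray,
    Z: np.ndarray | None,
    W: np.ndarray | None,
    y: np.ndarray,
    params: VarianceParameters,
    harvest_index: np.ndarray,
    plot_index: np.ndarray,
    n_geno: int,
    n_plots: int,
):
    """Solve Henderson's mixed-model equations at fixed variance parameters.

    Returns (beta, alpha (n_geno, M_a) or None, p (n_plots, M_p) or None,
    pev_blocks (n_geno, M_a, M_a) or None, keep_x indices).  The genetic
    PEV blocks are the genotype-diagonal blocks of the inverse coefficient
    matrix, i.e. Var(alpha_hat - alpha).
    """
    n = len(y)
    keep = _fullrank_columns(X)
    Xr = X[:, keep]
    # residual precision row-weighting
    if params.structure == "homogeneous":
        Rinv = None
        wts = np.full(n, 1.0 / float(params.residual))
    elif params.structure == "diagonal":
        Rinv = None
        wts = 1.0 / np.asarray(params.residual, float)[harvest_index]
    else:
        Sigma = np.asarray(params.residual, float)
        Rinv = np.zeros((n, n))
        for p in np.unique(plot_index):
            rows = np.flatnonzero(plot_index == p)
            sub = Sigma[np.ix_(harvest_index[rows], harvest_index[rows])]
            Rinv[np.ix_(rows, rows)] = np.linalg.inv(sub)
        wts = None

    blocks = [Xr]
    ginvs = [np.zeros((Xr.shape[1], Xr.shape[1]))]
    if Z is not None and params.K_g is not None:
        blocks.append(Z)
        ginvs.append(np.kron(np.eye(n_geno), _floored_inv(params.K_g)))
    if W is not None and params.K_p is not None:
        blocks.append(W)
        ginvs.append(np.kron(np.eye(n_plots), _floored_inv(params.K_p)))
    M = np.hstack(blocks)
    if wts is not None:
        MtRi = (M * wts[:, None]).T
    else:
        MtRi = M.T @ Rinv
    C = MtRi @ M + sla.block_diag(*ginvs)
    rhs = MtRi @ y
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Cinv = np.linalg.pinv(C)
    sol = Cinv @ rhs

    px = Xr.shape[1]
    beta = sol[:px]
    off = px
    alpha = p_hat = pev = None
    if Z is not None and params.K_g is not None:
        ma = params.K_g.shape[0]
        alpha = sol[off : off + n_geno * ma].reshape(n_geno, ma)
        pev = np.stack(
            [
                Cinv[off + i * ma : off + (i + 1) * ma, off + i * ma : off + (i + 1) * ma]
                for i in range(n_geno)
            ]
        )
        pev = 0.5 * (pev + np.swapaxes(pev, 1, 2))
        off += n_geno * ma
    if W is not None and params.K_p is not None:
        mp = params.K_p.shape[0]
        p_hat = sol[off : off + n_plots * mp].reshape(n_plots, mp)
    return beta, alpha, p_hat, pev, keep


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _pack(params: VarianceParameters, ma: int, mp: int, nh: int) -> np.ndarray:
    parts = []
    if params.K_g is not None:
        parts.append(_chol_to_theta(params.K_g))
    if params.K_p is not None:
        parts.append(_chol_to_theta(params.K_p))
    r = np.asarray(params.residual, float)
    if params.structure == "homogeneous":
        parts.append(np.log([float(r)]))
    elif params.structure == "diagonal":
        parts.append(np.log(r))
    else:
        parts.append(_chol_to_theta(r))
    return np.concatenate(parts)


def _unpack(
    theta: np.ndarray,
    ma: int,
    mp: int,
    nh: int,
    structure: str,
    include_genetic: bool,
    include_perm: bool,
) -> VarianceParameters:
    off = 0
    K_g = K_p = None
    if include_genetic:
        K_g = _theta_to_cov(theta[off : off + _n_tri(ma)], ma)
        off += _n_tri(ma)
    if include_perm:
        K_p = _theta_to_cov(theta[off : off + _n_tri(mp)], mp)
        off += _n_tri(mp)
    if structure == "homogeneous":
        residual = np.exp(theta[off])
        residual = np.asarray(residual)
    elif structure == "diagonal":
        residual = np.exp(theta[off : off + nh])
    else:
        residual = _theta_to_cov(theta[off : off + _n_tri(nh)], nh)
    return VarianceParameters(K_g=K_g, K_p=K_p, residual=residual, structure=structure)


def _diag_param_mask(ma: int, mp: int, nh: int, structure: str,
                     include_genetic: bool, include_perm: bool) -> np.ndarray:
    """Boolean mask of log-diagonal parameters (bounded below)."""
    mask = []
    def tri_mask(k):
        return [i == j for i in range(k) for j in range(i + 1)]
    if include_genetic:
        mask += tri_mask(ma)
    if include_perm:
        mask += tri_mask(mp)
    if structure == "homogeneous":
        mask += [True]
    elif structure == "diagonal":
        mask += [True] * nh
    else:
        mask += tri_mask(nh)
    return np.asarray(mask, bool)


def _starting_points(
    ma: int, mp: int, nh: int, structure: str,
    include_genetic: bool, include_perm: bool,
    n_starts: int, rng: np.random.Generator,
) -> list[np.ndarray]:
    """Starting parameter vectors on the y-standardized scale
    (phenotypic variance ~ 1): an identity-scaled start, a
    phenotypic-variance partitioned start, and jittered copies."""
    def build(kg_diag, kp_diag, res_var):
        K_g = np.diag(kg_diag[:ma]) if include_genetic else None
        K_p = np.diag(kp_diag[:mp]) if include_perm else None
        if structure == "homogeneous":
            residual = np.asarray(res_var)
        elif structure == "diagonal":
            residual = np.full(nh, res_var)
        else:
            residual = res_var * np.eye(nh)
        return _pack(
            VarianceParameters(K_g, K_p, residual, structure), ma, mp, nh
        )

    starts = [
        build(np.full(5, 0.3), np.full(5, 0.3), 0.5),
        build(np.array([0.8, 0.2, 0.1, 0.05, 0.02]),
              np.array([0.4, 0.1, 0.05, 0.02, 0.01]), 0.4),
    ]
    base = starts[1]
    while len(starts) < n_starts:
        starts.append(base + rng.normal(0.0, 0.3, size=base.shape))
    return starts[:n_starts]


def fit_reml(
    table: PhenotypeTable,
    schedule: HarvestSchedule,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FittedModel:
    """Fit the random-regression model by REML.

    Maximizes the restricted log-likelihood over a log-Cholesky
    parameterization of (K_g, K_p, residual), reports BLUP coefficient
    solutions and per-genotype prediction-error covariance blocks from the
    mixed-model-equation inverse at the optimum, and records convergence
    status rather than raising on non-convergence.
    """
    opts = options or FitOptions()
    spec.validate_against(schedule)
    design = build_design(
        table, schedule, spec, dead_plot_as_zero=opts.dead_plot_as_zero
    )
    return _fit_from_design(design, spec, opts)


def _fit_from_design(
    design: DesignMatrices, spec: ModelSpec, opts: FitOptions
) -> FittedModel:
    compact = _CompactData(design, spec)
    nh = design.schedule.n_measured
    ma, mp = spec.genetic_order, spec.perm_order
    n_params = (
        (_n_tri(ma) if opts.include_genetic else 0)
        + (_n_tri(mp) if opts.include_perm else 0)
        + {"homogeneous": 1, "diagonal": nh, "unstructured": _n_tri(nh)}[
            spec.residual_structure
        ]
    )
    p_count = n_params
    if design.n_records < 3 * p_count:
        warnings.warn(
            f"only {design.n_records} records for {p_count} variance "
            f"parameters; estimates may be poorly identified",
            stacklevel=2,
        )

    # standardize y for optimizer conditioning; exact rescaling afterwards
    y = design.y
    c = float(np.std(y))
    if c <= 0:
        c = 1.0
    compact.B[:, :, -1] /= c

    rng = np.random.default_rng(opts.seed)
    struct = spec.residual_structure

    def objective(theta: np.ndarray) -> float:
        params = _unpack(
            theta, ma, mp, nh, struct, opts.include_genetic, opts.include_perm
        )
        val = compact.neg2_restricted_loglik(params)
        if not np.isfinite(val):
            return 1e12
        return val

    dmask = _diag_param_mask(
        ma, mp, nh, struct, opts.include_genetic, opts.include_perm
    )
    floor_log = np.log(np.sqrt(max(opts.variance_floor_frac, 1e-14)))
    bounds = [
        (floor_log, None) if is_diag else (None, None) for is_diag in dmask
    ]

    best = None
    n_iter_total = 0
    for theta0 in _starting_points(
        ma, mp, nh, struct, opts.include_genetic, opts.include_perm,
        opts.n_starts, rng,
    ):
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.max_iter,
                "ftol": opts.ftol,
                "gtol": opts.gtol,
                "maxcor": 20,
            },
        )
        n_iter_total += res.nit
        ok = bool(res.success and np.isfinite(res.fun))
        if best is None or (ok and not best[1]) or (
            ok == best[1] and res.fun < best[0].fun
        ):
            best = (res, ok)
    res, converged = best
    theta_hat = res.x
    boundary = bool(np.any(theta_hat[dmask] <= floor_log + 1e-6))
    if boundary:
        logger.info("variance parameter at boundary floor for %s", spec.label)

    params_s = _unpack(
        theta_hat, ma, mp, nh, struct, opts.include_genetic, opts.include_perm
    )
    params = params_s.scaled(c * c)
    neg2 = compact.neg2_restricted_loglik(params_s)
    logL = -0.5 * neg2 - (compact.n - compact.rank_X) * np.log(c)

    beta_s, alpha, p_hat, pev, keep = solve_mme(
        design.X,
        design.Z if opts.include_genetic else None,
        design.W if opts.include_perm else None,
        design.y,
        params,
        design.harvest_index,
        design.records["plot_idx"].to_numpy(),
        len(design.genotype_ids),
        len(design.plot_ids),
    )
    beta = np.zeros(design.X.shape[1])
    beta[keep] = beta_s

    return FittedModel(
        spec=spec,
        schedule=design.schedule,
        params=params,
        beta=beta,
        x_names=design.x_names,
        alpha_hat=alpha,
        p_hat=p_hat,
        logL=float(logL),
        pev_blocks=pev,
        genotype_ids=design.genotype_ids,
        plot_ids=design.plot_ids,
        dropped_genotypes=design.dropped_genotypes,
        n_records=design.n_records,
        rank_X=compact.rank_X,
        converged=converged,
        boundary=boundary,
        n_iter=n_iter_total,
        include_genetic=opts.include_genetic,
        include_perm=opts.include_perm,
    )


def predict_genetic_coefficients(
    fit: FittedModel, genotype_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP coefficient vector and its prediction-error covariance block for
    one genotype.  A genotype known to the fit only through the index map
    (no usable records) is shrunk fully to zero with PEV = K_g."""
    if fit.params.K_g is None or fit.alpha_hat is None:
        raise ValueError("fit has no genetic term")
    gid = str(genotype_id)
    if gid in fit.dropped_genotypes:
        ma = fit.params.K_g.shape[0]
        return np.zeros(ma), fit.params.K_g.copy()
    i = fit.genotype_index(gid)
    return fit.alpha_hat[i].copy(), fit.pev_blocks[i].copy()
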