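"""Back-transformation of fitted coefficient covariances and BLUPs to the
original time scale.

A coefficient covariance matrix K on the normalized Legendre basis defines
a covariance *function* over the trial period: the covariance between days
d1 and d2 is phi(t1*)' K phi(t2*).  From a converged fit this module
derives

* variance trajectories (genetic, permanent-environment, residual,
  phenotypic) and the heritability curve h2(t);
* per-genotype genetic-value curves g_i(t) = sum_m alpha_im phi_m(t*),
  including prediction at unmeasured harvests;
* selection accuracy from the prediction-error variance,
  r(t) = sqrt(1 - PEV(t) / var_g(t));
* eigenfunctions of the genetic covariance function: the eigenvectors of
  K_g contracted with the basis, each explaining its eigenvalue's share of
  the genetic variation.  A near-constant leading eigenfunction indicates
  variation acting uniformly across all harvests; later eigenfunctions
  with sign changes capture rank reversals between growth seasons
  (genotype-by-environment interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .longitudinal_design import HarvestSchedule, legendre_matrix, standardize_time
from .reml_engine import FittedModel


@dataclass
class CovarianceFunction:
    """An evaluable covariance surface: coefficient matrix + basis order +
    standardization anchors (days)."""

    K: np.ndarray
    day_min: int
    day_max: int

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    @property
    def order(self) -> int:
        return self.K.shape[0]

    def _phi(self, days) -> np.ndarray:
        days = np.atleast_1d(np.asarray(days, float))
        lo, hi = self.day_min, self.day_max
        if np.any(days < lo) or np.any(days > hi):
            raise ValueError(
                f"day outside standardization range [{lo}, {hi}]; "
                "no extrapolation"
            )
        t = 2.0 * (days - lo) / (hi - lo) - 1.0
        return legendre_matrix(t, self.order)

    def variance_at(self, day1, day2=None) -> float | np.ndarray:
        """Covariance between two days on the original scale,
        phi(t1*)' K phi(t2*); the variance at a single day when day2 is
        omitted.  Vectorized over day1 (with day2 broadcast)."""
        if day2 is None:
            day2 = day1
        p1 = self._phi(day1)
        p2 = self._phi(day2)
        out = np.einsum("ij,jk,ik->i", p1, self.K, p2)
        if np.isscalar(day1) and np.isscalar(day2):
            return float(out[0])
        return out


def variance_at(cf: CovarianceFunction, day1, day2=None):
    return cf.variance_at(day1, day2)


def _residual_step(fit: FittedModel, days: np.ndarray) -> np.ndarray:
    """Residual variance on an arbitrary day grid: piecewise constant,
    each day assigned the variance of the nearest measured harvest."""
    meas = np.asarray(fit.schedule.measured_days, float)
    days = np.asarray(days, float)
    nearest = np.argmin(np.abs(days[:, None] - meas[None, :]), axis=1)
    per_harvest = np.array(
        [fit.params.residual_variance_at_harvest(j) for j in range(len(meas))]
    )
    return per_harvest[nearest]


def trajectories(
    fit: FittedModel,
    grid,
    include_perm_in_h2: bool = True,
) -> pd.DataFrame:
    """Variance and heritability trajectories on a day grid.

    Genetic and permanent-environment variances come from the fitted
    coefficient covariance functions; residual variance is the (piecewise
    constant) harvest-level estimate; h2(t) = var_g / (var_g + var_pe +
    var_e) by default, with a flag to exclude the permanent-environment
    term from the denominator.
    """
    grid = np.asarray(grid, int)
    anchors = (fit.schedule.day_min, fit.schedule.day_max)
    var_g = CovarianceFunction(fit.params.K_g, *anchors).variance_at(grid)
    if fit.params.K_p is not None:
        var_pe = CovarianceFunction(fit.params.K_p, *anchors).variance_at(grid)
    else:
        var_pe = np.zeros_like(var_g)
    var_e = _residual_step(fit, grid)
    denom = var_g + var_e + (var_pe if include_perm_in_h2 else 0.0)
    h2 = np.where(denom > 0, var_g / denom, 0.0)
    return pd.DataFrame(
        {
            "day": grid,
            "var_genetic": var_g,
            "var_perm": var_pe,
            "var_residual": var_e,
            "var_phenotypic": var_g + var_pe + var_e,
            "h2": h2,
        }
    )


@dataclass
class GeneticValueSurface:
    """Estimated genetic values (and the day grid they were evaluated on)
    for every genotype in a fit."""

    genotype_ids: list[str]
    days: np.ndarray
    values: np.ndarray  # (ng, n_days)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.genotype_ids, name="genotype"),
            columns=self.days,
        )
        out = df.reset_index().melt(
            id_vars="genotype", var_name="day", value_name="genetic_value"
        )
        out["day"] = out["day"].astype(int)
        return out


def genetic_values(fit: FittedModel, grid) -> GeneticValueSurface:
    """Genetic-value curves g_i(t) = sum_m alpha_im phi_m(t*) for every
    genotype on a day grid; unmeasured days inside the standardization
    range are legitimate prediction targets."""
    if fit.alpha_hat is None:
        raise ValueError("fit has no genetic term")
    grid = np.asarray(grid, int)
    t = standardize_time(grid, fit.schedule)
    phi = legendre_matrix(np.atleast_1d(t), fit.spec.genetic_order)
    values = fit.alpha_hat @ phi.T
    return GeneticValueSurface(
        genotype_ids=list(fit.genotype_ids), days=grid, values=values
    )


def accuracy(fit: FittedModel, grid, form: str = "sqrt") -> np.ndarray:
    """Selection accuracy per genotype and day from the prediction-error
    variance of the genetic value, PEV_i(t) = phi(t*)' PEV_block_i phi(t*).

    ``form='sqrt'`` gives the standard r = sqrt(max(0, 1 - PEV/var_g));
    ``form='linear'`` omits the square root.  Days where the genetic
    variance vanishes are reported as accuracy 0.
    """
    if form not in ("sqrt", "linear"):
        raise ValueError("form must be 'sqrt' or 'linear'")
    if fit.pev_blocks is None:
        raise ValueError("fit has no prediction-error covariance blocks")
    grid = np.asarray(grid, int)
    t = standardize_time(grid, fit.schedule)
    phi = legendre_matrix(np.atleast_1d(t), fit.spec.genetic_order)
    anchors = (fit.schedule.day_min, fit.schedule.day_max)
    var_g = CovarianceFunction(fit.params.K_g, *anchors).variance_at(grid)
    pev = np.einsum("dj,ijk,dk->id", phi, fit.pev_blocks, phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(var_g[None, :] > 0, pev / var_g[None, :], 1.0)
    r2 = np.clip(1.0 - rel, 0.0, 1.0)
    return np.sqrt(r2) if form == "sqrt" else r2


@dataclass
class EigenfunctionSet:
    """Eigendecomposition of a genetic covariance function: eigenvalues
    (descending), their percent shares of the trace, eigenvector
    coefficients on the Legendre basis, and the eigenfunctions evaluated
    on a day grid."""

    eigenvalues: np.ndarray
    proportions_pct: np.ndarray
    coefficients: np.ndarray  # (order, order), column i = eigenvector i
    days: np.ndarray
    values: np.ndarray  # (order, n_days), row i = Psi_i on the grid

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.eigenvalues)):
            for d, v in zip(self.days, self.values[i]):
                rows.append(
                    {
                        "eigenfunction": i + 1,
                        "eigenvalue": self.eigenvalues[i],
                        "proportion_pct": self.proportions_pct[i],
                        "day": int(d),
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)


def eigenfunctions(
    K_g: np.ndarray,
    anchors: tuple[int, int],
    grid,
) -> EigenfunctionSet:
    """Eigenfunctions Psi_i(t) = sum_m c_im phi_m(t*) of the genetic
    covariance function, with eigenvalues sorted descending and percent
    shares of the trace.

    Because the basis is orthonormal on [-1, 1], the eigenfunctions are
    orthonormal under the same inner product.  Eigenvectors are
    sign-ambiguous; the sign is fixed so each eigenfunction is nonnegative
    at the first anchor day (falling back to the first nonzero grid value).
    """
    K_g = np.asarray(K_g, float)
    if K_g.ndim != 2 or K_g.shape[0] != K_g.shape[1]:
        raise ValueError("K_g must be square")
    if not np.allclose(K_g, K_g.T, atol=1e-8 * max(1.0, np.abs(K_g).max())):
        raise ValueError("K_g must be symmetric")
    grid = np.asarray(grid, int)
    vals, vecs = np.linalg.eigh(K_g)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    total = vals.sum()
    proportions = 100.0 * vals / total if total > 0 else np.zeros_like(vals)

    cf_anchor = CovarianceFunction(np.eye(K_g.shape[0]), *anchors)
    phi_grid = cf_anchor._phi(grid)
    phi_min = cf_anchor._phi(anchors[0])[0]
    values = (phi_grid @ vecs).T  # (order, n_days)
    for i in range(K_g.shape[0]):
        v0 = float(phi_min @ vecs[:, i])
        if abs(v0) > 1e-12:
            sign = np.sign(v0)
        else:
            nz = values[i][np.abs(values[i]) > 1e-12]
            sign = np.sign(nz[0]) if nz.size else 1.0
        vecs[:, i] *= sign
        values[i] *= sign
    return EigenfunctionSet(
        eigenvalues=vals,
        proportions_pct=proportions,
        coefficients=vecs,
        days=grid,
        values=values,
    )
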