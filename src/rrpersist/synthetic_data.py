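"""Synthetic multi-harvest clone-trial data with known truth.

The generator is the random-regression model read forward: genotype
coefficient vectors are drawn from K_g, plot (permanent-environment)
coefficients from K_p, residuals from the chosen harvest-level structure,
and records are

    y = fixed curve + replication effect + genetic + permanent + residual,

with an optional per-harvest death process that removes a plot's records
from its death harvest onward (mimicking clones that die out of the trial
in late seasons).  Ground truth (coefficients, genetic-value surface,
variance trajectories) is returned alongside the phenotype table so that
estimation can be scored exactly.

``paper_like_config`` freezes the emulated trial: 100 clonal genotypes x 2
replications, five measured harvests at days {250, 500, 815, 1405, 1615}
plus the unmeasured day 1090, a quartic mean curve interpolating the
harvest means (12.51, 29.60, 19.60, 15.28, 19.07 Mg/ha), a genetic
coefficient covariance dominated by its constant component (leading
eigenvalue share ~86%), an order-1 permanent-environment term, and
diagonal residual variances derived from target per-harvest
heritabilities spanning 0.45-0.75 with the second harvest the most
environment-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_extraction import CovarianceFunction
from .longitudinal_design import (
    HarvestSchedule,
    ModelSpec,
    PhenotypeTable,
    legendre_matrix,
    standardize_time,
)

#: harvest means (Mg dry biomass per hectare) the default mean curve
#: interpolates, and the target per-harvest heritabilities the default
#: residual variances are derived from.
DEFAULT_HARVEST_MEANS = (12.51, 29.60, 19.60, 15.28, 19.07)
DEFAULT_H2_TARGETS = (0.65, 0.45, 0.70, 0.72, 0.69)
DEFAULT_EIGEN_SHARES = (0.85, 0.07, 0.05, 0.03)
DEFAULT_GENETIC_SCALE = 24.0  # trace of K_g; baseline genetic SD ~3.2 Mg/ha
DEFAULT_PERM_VARIANCE = 4.0   # K_p[0,0]; plot-level variance 2.0 Mg^2/ha^2


@dataclass
class SimulationConfig:
    """Everything that defines one simulated trial (including the seed:
    regenerating with the same config reproduces the table bit-for-bit)."""

    ng: int
    n_rep: int
    schedule: HarvestSchedule
    beta: np.ndarray            # fixed-curve coefficients on the basis (M_b,)
    rep_effects: np.ndarray     # one fixed offset per replication (n_rep,)
    K_g: np.ndarray
    K_p: np.ndarray
    residual_structure: str
    residual: np.ndarray        # scalar / per-harvest vector / full matrix
    death_prob: float = 0.0     # per-harvest hazard of plot death (from 2nd on)
    seed: int = 20180913

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.rep_effects = np.asarray(self.rep_effects, float)
        self.K_g = np.asarray(self.K_g, float)
        self.K_p = np.asarray(self.K_p, float)
        self.residual = np.asarray(self.residual, float)
        if len(self.rep_effects) != self.n_rep:
            raise ValueError("need one replication effect per replication")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob must be a probability")
        for name, K in (("K_g", self.K_g), ("K_p", self.K_p)):
            if not np.allclose(K, K.T, atol=1e-10) or np.min(
                np.linalg.eigvalsh(K)
            ) < -1e-10 * max(1.0, np.trace(K)):
                raise ValueError(f"{name} must be symmetric PSD")
        if self.residual_structure == "unstructured":
            S = self.residual
            if not np.allclose(S, S.T, atol=1e-10) or np.min(
                np.linalg.eigvalsh(S)
            ) <= 0:
                raise ValueError("unstructured residual must be symmetric PD")
        elif np.any(np.atleast_1d(self.residual) <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def genetic_order(self) -> int:
        return self.K_g.shape[0]

    @property
    def perm_order(self) -> int:
        return self.K_p.shape[0]


@dataclass
class SimulatedDataset:
    """A simulated phenotype table plus the truth that generated it."""

    table: PhenotypeTable
    config: SimulationConfig
    alpha: np.ndarray            # (ng, M_a) true genotype coefficients
    p_effects: np.ndarray        # (ng * n_rep, M_p) true plot coefficients
    genotype_ids: list[str]
    plot_ids: list[str]

    def true_genetic_values(self, grid) -> np.ndarray:
        """True genetic-value surface (ng, n_days) on a day grid."""
        t = np.atleast_1d(standardize_time(np.asarray(grid), self.config.schedule))
        phi = legendre_matrix(t, self.config.genetic_order)
        return self.alpha @ phi.T

    def true_variance_trajectory(self, grid) -> dict[str, np.ndarray]:
        sched = self.config.schedule
        anchors = (sched.day_min, sched.day_max)
        var_g = CovarianceFunction(self.config.K_g, *anchors).variance_at(grid)
        var_pe = CovarianceFunction(self.config.K_p, *anchors).variance_at(grid)
        return {"var_genetic": np.atleast_1d(var_g), "var_perm": np.atleast_1d(var_pe)}


def _psd_factor(K: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor of a PSD matrix; exact (all-zero) for
    the zero matrix, unlike a jittered Cholesky."""
    w, V = np.linalg.eigh(np.asarray(K, float))
    return V * np.sqrt(np.clip(w, 0.0, None))


def _residual_draws(
    config: SimulationConfig, rng: np.random.Generator, n_plots: int, nh: int
) -> np.ndarray:
    """(n_plots, nh) residual draws honoring within-plot cross-harvest
    correlation for the unstructured structure."""
    if config.residual_structure == "homogeneous":
        return rng.normal(0.0, np.sqrt(float(config.residual)), size=(n_plots, nh))
    if config.residual_structure == "diagonal":
        sd = np.sqrt(np.asarray(config.residual, float))
        return rng.normal(0.0, 1.0, size=(n_plots, nh)) * sd[None, :]
    L = np.linalg.cholesky(np.asarray(config.residual, float))
    return rng.normal(0.0, 1.0, size=(n_plots, nh)) @ L.T


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one trial from the model the analysis assumes.

    Genotype and plot coefficients are sampled from K_g and K_p, records
    assembled on the measured harvest days, and the death process applied:
    from the second measured harvest on, each live plot dies before the
    next harvest with probability ``death_prob``; records from the death
    harvest onward are absent.
    """
    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    meas_days = np.asarray(sched.measured_days)
    nh = len(meas_days)
    ng, n_rep = config.ng, config.n_rep
    n_plots = ng * n_rep

    t = np.atleast_1d(standardize_time(meas_days, sched))
    phi_b = legendre_matrix(t, len(config.beta))
    phi_a = legendre_matrix(t, config.genetic_order)
    phi_p = legendre_matrix(t, config.perm_order)

    La = _psd_factor(config.K_g)
    Lp = _psd_factor(config.K_p)
    alpha = rng.normal(0.0, 1.0, size=(ng, config.genetic_order)) @ La.T
    p_eff = rng.normal(0.0, 1.0, size=(n_plots, config.perm_order)) @ Lp.T
    resid = _residual_draws(config, rng, n_plots, nh)

    # death process: plot alive at harvest 0; hazard applies per transition
    alive = np.ones((n_plots, nh), bool)
    if config.death_prob > 0:
        death = rng.random(size=(n_plots, nh - 1)) < config.death_prob
        dead = np.cumsum(death, axis=1) > 0
        alive[:, 1:] = ~dead

    genotype_ids = [f"G{i + 1:03d}" for i in range(ng)]
    mean_curve = phi_b @ config.beta  # (nh,)
    # yield is nonnegative; the rare sub-zero Gaussian draw (low-mean first
    # harvest, ~0.3% of records at default settings) is truncated at zero

    rows = []
    plot_ids = []
    plot = 0
    for i in range(ng):
        g_curve = phi_a @ alpha[i]
        for k in range(n_rep):
            pid = f"{genotype_ids[i]}_r{k + 1}"
            plot_ids.append(pid)
            pe_curve = phi_p @ p_eff[plot]
            y = (
                mean_curve
                + config.rep_effects[k]
                + g_curve
                + pe_curve
                + resid[plot]
            )
            y = np.maximum(y, 0.0)
            for j, day in enumerate(meas_days):
                rows.append(
                    {
                        "genotype": genotype_ids[i],
                        "replication": k + 1,
                        "plot": pid,
                        "day": int(day),
                        "yield": y[j] if alive[plot, j] else np.nan,
                    }
                )
            plot += 1

    table = PhenotypeTable(pd.DataFrame(rows))
    return SimulatedDataset(
        table=table,
        config=config,
        alpha=alpha,
        p_effects=p_eff,
        genotype_ids=genotype_ids,
        plot_ids=plot_ids,
    )


def _rotation_from_shares(shares: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal eigenvector matrix close to the identity: the leading
    eigenvector is dominated by the constant basis function with small
    loadings on the higher terms, so the leading eigenfunction is
    near-constant without being exactly proportional to phi_0."""
    M = np.eye(order)
    tilt = np.array([0.01, 0.006, 0.004])[: order - 1]
    M[1:, 0] = tilt
    M[0, 1:] = -tilt
    Q, _ = np.linalg.qr(M)
    # fix column signs so Q is a proper near-identity rotation
    Q *= np.sign(np.diag(Q))[None, :]
    return Q


def paper_like_config(
    seed: int = 20180913,
    death_prob: float = 0.005,
) -> SimulationConfig:
    """The frozen default trial the simulation studies run on (see module
    docstring for the emulated design).  Residual variances are solved
    from the target heritabilities:

        var_e_j = var_g(d_j) * (1 - h2_j) / h2_j - var_pe.
    """
    schedule = HarvestSchedule.default()
    meas_days = np.asarray(schedule.measured_days)
    t = np.atleast_1d(standardize_time(meas_days, schedule))

    # quartic mean curve through the five harvest means
    phi_b = legendre_matrix(t, 5)
    beta = np.linalg.solve(phi_b, np.asarray(DEFAULT_HARVEST_MEANS))

    shares = np.asarray(DEFAULT_EIGEN_SHARES)
    shares = shares / shares.sum()
    Q = _rotation_from_shares(shares, 4)
    K_g = Q @ np.diag(DEFAULT_GENETIC_SCALE * shares) @ Q.T
    K_g = 0.5 * (K_g + K_g.T)
    K_p = np.array([[DEFAULT_PERM_VARIANCE]])

    anchors = (schedule.day_min, schedule.day_max)
    var_g = CovarianceFunction(K_g, *anchors).variance_at(meas_days)
    var_pe = CovarianceFunction(K_p, *anchors).variance_at(meas_days)
    h2 = np.asarray(DEFAULT_H2_TARGETS)
    var_e = var_g * (1.0 - h2) / h2 - var_pe
    if np.any(var_e <= 0):
        raise RuntimeError("inconsistent default variance targets")

    return SimulationConfig(
        ng=100,
        n_rep=2,
        schedule=schedule,
        beta=beta,
        rep_effects=np.array([0.5, -0.5]),
        K_g=K_g,
        K_p=K_p,
        residual_structure="diagonal",
        residual=var_e,
        death_prob=death_prob,
        seed=seed,
    )
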