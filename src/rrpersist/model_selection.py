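"""Candidate-model comparison: Schwarz BIC and likelihood-ratio tests.

Candidate random-regression models differ in the Legendre orders of the
genetic and permanent-environment terms and in the residual structure
across harvests (homogeneous H, diagonal D, unstructured US).  Models are
compared by

    BIC = -2 logL + p * ln(n - rank(X)),

with p the number of variance parameters, n the number of records and
rank(X) the (numerical) rank of the fixed-effects matrix; smaller is
better.  The contribution of each random term is screened by a
likelihood-ratio test against the fit that omits it.  Following common
practice in the multi-harvest forage literature, every LRT statistic is
referred to the chi-square 1-df upper-1% critical value (6.63); the
parameter-difference df and its critical value are reported alongside as
an extension, since removing a whole coefficient covariance matrix drops
more than one parameter and the null lies on the boundary of the
parameter space (both make the 1-df rule conservative in opposite
directions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .longitudinal_design import (
    HarvestSchedule,
    ModelSpec,
    PhenotypeTable,
    count_parameters,
)
from .reml_engine import FitOptions, FittedModel, fit_reml

logger = logging.getLogger(__name__)

#: chi-square(1 df) upper 1% critical value, rounded to the conventional
#: two decimals used when screening variance components.
CHI2_1DF_1PCT = round(float(stats.chi2.ppf(0.99, df=1)), 2)


def default_model_grid() -> list[ModelSpec]:
    """The standard 12-model candidate grid: genetic orders {3, 4} x
    permanent-environment orders {1, 2} x residual structures {H, D, US},
    ordered by residual structure."""
    grid = []
    for structure in ("homogeneous", "diagonal", "unstructured"):
        for ga in (3, 4):
            for pe in (1, 2):
                grid.append(
                    ModelSpec(
                        genetic_order=ga,
                        perm_order=pe,
                        residual_structure=structure,
                    )
                )
    return grid


def bic(logL: float, p: int, n: int, rank_X: int) -> float:
    """Schwarz Bayesian information criterion, natural logarithm."""
    if n <= rank_X:
        raise ValueError(f"need n > rank_X, got n={n}, rank_X={rank_X}")
    if p < 0:
        raise ValueError("p must be nonnegative")
    return -2.0 * logL + p * np.log(n - rank_X)


@dataclass
class LRTResult:
    statistic: float
    significant_1pct: bool
    df: int
    critical_value_df: float

    def __iter__(self):
        return iter((self.statistic, self.significant_1pct))


def lrt(full: FittedModel, reduced: FittedModel) -> LRTResult:
    """Likelihood-ratio test of a random term: the reduced fit must omit
    the genetic or the permanent-environment term of the full fit.

    The statistic 2(logL_full - logL_reduced) is clipped at zero and the
    significance flag compares it with the chi-square(1 df) 1% critical
    value; the parameter-difference df and its own critical value are
    carried along for reference.
    """
    drops_genetic = full.include_genetic and not reduced.include_genetic
    drops_perm = full.include_perm and not reduced.include_perm
    if not (drops_genetic or drops_perm):
        raise ValueError(
            "reduced model must omit the genetic or permanent-environment "
            "term of the full model"
        )
    if reduced.include_genetic and (
        reduced.spec.genetic_order != full.spec.genetic_order
    ):
        raise ValueError("non-nested specs: genetic orders differ")
    if reduced.include_perm and (reduced.spec.perm_order != full.spec.perm_order):
        raise ValueError("non-nested specs: permanent-environment orders differ")
    if reduced.spec.residual_structure != full.spec.residual_structure:
        raise ValueError("non-nested specs: residual structures differ")
    if reduced.n_records != full.n_records:
        raise ValueError("fits use different data")

    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    df = 0
    if drops_genetic:
        ma = full.spec.genetic_order
        df += ma * (ma + 1) // 2
    if drops_perm:
        mp = full.spec.perm_order
        df += mp * (mp + 1) // 2
    crit_df = float(stats.chi2.ppf(0.99, df=max(df, 1)))
    return LRTResult(
        statistic=stat,
        significant_1pct=bool(stat > CHI2_1DF_1PCT),
        df=df,
        critical_value_df=crit_df,
    )


@dataclass
class ModelComparison:
    """Result of a model scan: one row per candidate, the fits themselves,
    and the minimum-BIC selection among converged candidates."""

    table: pd.DataFrame
    fits: dict[str, FittedModel]
    best_label: str | None

    @property
    def best(self) -> FittedModel | None:
        return None if self.best_label is None else self.fits[self.best_label]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def scan_models(
    table: PhenotypeTable,
    schedule: HarvestSchedule,
    specs: list[ModelSpec] | None = None,
    options: FitOptions | None = None,
    compute_lrt: bool = True,
) -> ModelComparison:
    """Fit each candidate model, compute p, BIC and LRTs for its random
    terms, and select the minimum-BIC model among converged fits.

    Reduced fits needed for the LRTs are cached: the no-genetic fit
    depends only on (perm order, residual structure) and the no-perm fit
    only on (genetic order, residual structure).  Per-fit failures are
    recorded as non-converged rows, not raised.
    """
    if specs is None:
        specs = default_model_grid()
    if not specs:
        raise ValueError("no candidate models given")
    opts = options or FitOptions()
    nh = schedule.n_measured

    fits: dict[str, FittedModel] = {}
    reduced_cache: dict[tuple, FittedModel] = {}
    rows = []
    for spec in specs:
        try:
            fit = fit_reml(table, schedule, spec, opts)
        except Exception as exc:  # recorded, not fatal
            logger.warning("fit of %s failed: %s", spec.label, exc)
            rows.append(
                {
                    "model": spec.label,
                    "genetic_order": spec.genetic_order,
                    "perm_order": spec.perm_order,
                    "residual_structure": spec.residual_structure,
                    "p": count_parameters(spec, nh),
                    "converged": False,
                    "logL": np.nan,
                    "BIC": np.nan,
                    "LRT_genetic": np.nan,
                    "LRT_perm": np.nan,
                    "sig_genetic_1pct": False,
                    "sig_perm_1pct": False,
                }
            )
            continue
        fits[spec.label] = fit
        p = count_parameters(spec, nh)
        row = {
            "model": spec.label,
            "genetic_order": spec.genetic_order,
            "perm_order": spec.perm_order,
            "residual_structure": spec.residual_structure,
            "p": p,
            "converged": fit.converged,
            "logL": fit.logL,
            "BIC": bic(fit.logL, p, fit.n_records, fit.rank_X)
            if fit.converged
            else np.nan,
            "LRT_genetic": np.nan,
            "LRT_perm": np.nan,
            "sig_genetic_1pct": False,
            "sig_perm_1pct": False,
        }
        if compute_lrt and fit.converged:
            for which in ("genetic", "perm"):
                if which == "genetic":
                    key = ("nog", spec.perm_order, spec.residual_structure)
                    ropts = FitOptions(
                        **{**opts.__dict__, "include_genetic": False}
                    )
                else:
                    key = ("nop", spec.genetic_order, spec.residual_structure)
                    ropts = FitOptions(**{**opts.__dict__, "include_perm": False})
                try:
                    if key not in reduced_cache:
                        reduced_cache[key] = fit_reml(table, schedule, spec, ropts)
                    result = lrt(fit, reduced_cache[key])
                    row[f"LRT_{which}"] = result.statistic
                    row[f"sig_{which}_1pct"] = result.significant_1pct
                except Exception as exc:
                    logger.warning(
                        "LRT (%s) for %s failed: %s", which, spec.label, exc
                    )
        rows.append(row)

    frame = pd.DataFrame(rows)
    conv = frame[frame["converged"] & frame["BIC"].notna()]
    best_label = None
    if not conv.empty:
        best_label = str(conv.loc[conv["BIC"].idxmin(), "model"])
    return ModelComparison(table=frame, fits=fits, best_label=best_label)
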