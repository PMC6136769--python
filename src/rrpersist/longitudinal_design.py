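"""Harvest schedules, time standardization, the normalized Legendre basis,
and mixed-model design matrices for multi-harvest clone trials.

The trial layout served here is a replicated clonal field experiment in
which the same plots are cut repeatedly over successive growth seasons.
Yield trajectories are modelled on a polynomial time scale: calendar days
since the uniformity harvest are mapped affinely onto [-1, 1] and expanded
in normalized Legendre polynomials

    phi_m(x) = sqrt((2m + 1) / 2) * P_m(x),

where ``P_m`` is the classical Legendre polynomial. The normalization makes
the basis orthonormal on [-1, 1], which is the convention used throughout
the covariance-function literature. "Order" counts coefficients, so an
order-k expansion has polynomial degree k - 1 (a quartic mean curve is
order 5).

Design matrices follow the standard random-regression mixed model

    y = X beta + Z alpha + W p + e

with a fixed replication effect plus a fixed mean regression in ``X``, one
block of genetic regression coefficients per genotype in ``Z``, and one
block of permanent-environment coefficients per plot in ``W``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg

logger = logging.getLogger(__name__)

RESIDUAL_STRUCTURES = ("homogeneous", "diagonal", "unstructured")
_STRUCTURE_CODES = {"H": "homogeneous", "D": "diagonal", "US": "unstructured"}
_STRUCTURE_LABELS = {v: k for k, v in _STRUCTURE_CODES.items()}


# ---------------------------------------------------------------------------
# schedules and time standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarvestSchedule:
    """Harvest days (days since the uniformity harvest) and which of them
    carry phenotypic records.

    ``measured[i]`` is False for prediction-only time points (harvests where
    no yield was recorded but genetic values are still wanted).  ``day_min``
    and ``day_max`` anchor the affine map onto the polynomial scale [-1, 1];
    they default to the first and last *measured* day.
    """

    days: tuple[int, ...]
    measured: tuple[bool, ...]
    day_min: int
    day_max: int

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        measured = tuple(bool(m) for m in self.measured)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "measured", measured)
        if len(days) != len(measured):
            raise ValueError("days and measured must have equal length")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("harvest days must be strictly increasing")
        if sum(measured) < 2:
            raise ValueError("a schedule needs at least 2 measured days")
        if self.day_min > min(days) or self.day_max < max(days):
            raise ValueError("anchors must bracket all harvest days")
        if self.day_min >= self.day_max:
            raise ValueError("day_min must be < day_max")

    @classmethod
    def from_days(
        cls,
        days: Sequence[int],
        measured: Sequence[bool] | None = None,
        anchors: tuple[int, int] | None = None,
    ) -> "HarvestSchedule":
        days = tuple(int(d) for d in days)
        if measured is None:
            measured = tuple(True for _ in days)
        measured = tuple(bool(m) for m in measured)
        meas_days = [d for d, m in zip(days, measured) if m]
        if anchors is None:
            anchors = (min(meas_days), max(meas_days))
        return cls(days=days, measured=measured, day_min=anchors[0], day_max=anchors[1])

    @classmethod
    def default(cls) -> "HarvestSchedule":
        """Five measured harvests at unequally spaced days plus one
        unmeasured (prediction-only) harvest at day 1090."""
        return cls.from_days(
            days=(250, 500, 815, 1090, 1405, 1615),
            measured=(True, True, True, False, True, True),
        )

    @property
    def measured_days(self) -> tuple[int, ...]:
        return tuple(d for d, m in zip(self.days, self.measured) if m)

    @property
    def n_measured(self) -> int:
        return sum(self.measured)

    def standardize(self, day):
        return standardize_time(day, self)


def standardize_time(day, schedule: HarvestSchedule):
    """Affine map of calendar day onto the polynomial scale [-1, 1].

    t* = 2 (day - day_min) / (day_max - day_min) - 1, so the anchors map to
    -1 and +1 exactly.  Days outside the anchor range raise: extrapolation
    beyond the observed trajectory must be requested explicitly, never
    performed silently.
    """
    day_arr = np.asarray(day, dtype=float)
    lo, hi = float(schedule.day_min), float(schedule.day_max)
    if np.any(day_arr < lo) or np.any(day_arr > hi):
        raise ValueError(
            f"day {day!r} outside standardization range [{schedule.day_min}, "
            f"{schedule.day_max}]; no extrapolation"
        )
    t = 2.0 * (day_arr - lo) / (hi - lo) - 1.0
    if np.isscalar(day) or day_arr.ndim == 0:
        return float(t)
    return t


def legendre_row(t_star: float, order: int) -> np.ndarray:
    """Evaluate the normalized Legendre basis (phi_0 ... phi_{order-1}) at a
    standardized time t* in [-1, 1]."""
    return legendre_matrix(np.asarray([t_star], dtype=float), order)[0]


def legendre_matrix(t_star: np.ndarray, order: int) -> np.ndarray:
    """Rows of normalized Legendre values for an array of standardized times.

    Returns an (n, order) matrix with entry (i, m) = phi_m(t_star[i]).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    t = np.asarray(t_star, dtype=float)
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise ValueError("standardized times must lie in [-1, 1]")
    t = np.clip(t, -1.0, 1.0)
    vander = npleg.legvander(t, order - 1)
    norms = np.sqrt((2.0 * np.arange(order) + 1.0) / 2.0)
    return vander * norms


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate random-regression model: Legendre orders for the fixed
    mean curve, the genetic effect and the permanent-environment effect,
    plus a residual-variance structure across harvests.

    The conventional label is ``Leg<ga>.<pe>.<H|D|US>``, e.g. ``Leg4.1.D``
    for genetic order 4, permanent-environment order 1 and one residual
    variance per harvest (diagonal).
    """

    genetic_order: int
    perm_order: int
    residual_structure: str = "diagonal"
    fixed_order: int = 5

    def __post_init__(self) -> None:
        if self.residual_structure not in RESIDUAL_STRUCTURES:
            raise ValueError(
                f"residual_structure must be one of {RESIDUAL_STRUCTURES}, "
                f"got {self.residual_structure!r}"
            )
        for name in ("genetic_order", "perm_order", "fixed_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genetic_order > self.fixed_order or self.perm_order > self.fixed_order:
            raise ValueError("random-effect orders cannot exceed the fixed order")

    @property
    def label(self) -> str:
        return (
            f"Leg{self.genetic_order}.{self.perm_order}."
            f"{_STRUCTURE_LABELS[self.residual_structure]}"
        )

    @classmethod
    def from_label(cls, label: str, fixed_order: int = 5) -> "ModelSpec":
        """Parse a label like 'Leg4.1.D' into a ModelSpec."""
        if not label.startswith("Leg"):
            raise ValueError(f"cannot parse model label {label!r}")
        parts = label[3:].split(".")
        if len(parts) != 3 or parts[2] not in _STRUCTURE_CODES:
            raise ValueError(f"cannot parse model label {label!r}")
        return cls(
            genetic_order=int(parts[0]),
            perm_order=int(parts[1]),
            residual_structure=_STRUCTURE_CODES[parts[2]],
            fixed_order=fixed_order,
        )

    def validate_against(self, schedule: HarvestSchedule) -> None:
        nh = schedule.n_measured
        if max(self.genetic_order, self.perm_order, self.fixed_order) > nh:
            raise ValueError(
                f"model orders {self.label} exceed the {nh} measured harvests"
            )


def count_parameters(spec: ModelSpec, n_measured_harvests: int) -> int:
    """Number of (co)variance parameters of a candidate model: the genetic
    and permanent-environment coefficient covariance matrices plus the
    residual parameters (1, one per harvest, or a full symmetric matrix)."""
    if n_measured_harvests < 1:
        raise ValueError("need at least one measured harvest")
    ka = spec.genetic_order * (spec.genetic_order + 1) // 2
    kp = spec.perm_order * (spec.perm_order + 1) // 2
    n = n_measured_harvests
    r = {
        "homogeneous": 1,
        "diagonal": n,
        "unstructured": n * (n + 1) // 2,
    }[spec.residual_structure]
    return ka + kp + r


def count_parameters_multitrait(n_harvests: int) -> int:
    """Parameter count of the unstructured multi-trait alternative (one
    trait per harvest): a full genetic covariance matrix plus a full
    residual covariance matrix."""
    return n_harvests * (n_harvests + 1)


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("genotype", "replication", "day", "yield")


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one row per (plot, harvest day).

    Columns: genotype (str), replication (int), plot (str), day (int),
    yield (float, Mg dry biomass per hectare; NaN for missing/dead plots).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks required columns {missing}")
        df["genotype"] = df["genotype"].astype(str)
        df["replication"] = df["replication"].astype(int)
        df["day"] = df["day"].astype(int)
        df["yield"] = pd.to_numeric(df["yield"], errors="coerce")
        if "plot" not in df.columns:
            df["plot"] = df["genotype"] + "_r" + df["replication"].astype(str)
        df["plot"] = df["plot"].astype(str)
        neg = df["yield"] < 0
        if neg.any():
            raise ValueError(f"{int(neg.sum())} records have negative yield")
        self.data = df[["genotype", "replication", "plot", "day", "yield"]]

    @classmethod
    def read(cls, path: str | Path) -> "PhenotypeTable":
        """Read a delimited text file (separator auto-detected)."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    def validate_against(self, schedule: HarvestSchedule) -> None:
        bad = set(self.data["day"]) - set(schedule.measured_days)
        if bad:
            raise ValueError(
                f"records on days {sorted(bad)} that are not measured days of "
                f"the schedule {schedule.measured_days}"
            )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrices:
    """Dense incidence/regression matrices for one model on one data set.

    Rows correspond to the retained (non-missing) records, sorted by
    (genotype, replication, day) so that estimates are invariant to the
    input row order.  ``records`` carries per-row metadata used by the
    residual structures (harvest index, plot index).
    """

    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    y: np.ndarray
    harvest_index: np.ndarray
    records: pd.DataFrame
    genotype_ids: list[str]
    plot_ids: list[str]
    dropped_genotypes: list[str]
    rep_levels: list[int]
    x_names: list[str]
    spec: ModelSpec
    schedule: HarvestSchedule
    n_dropped_missing: int

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


def build_design(
    table: PhenotypeTable,
    schedule: HarvestSchedule,
    spec: ModelSpec,
    *,
    dead_plot_as_zero: bool = False,
) -> DesignMatrices:
    """Assemble X (replication indicators + fixed Legendre regression),
    Z (per-genotype genetic regression blocks) and W (per-plot
    permanent-environment blocks).

    Records with missing yield are dropped and logged (or encoded as zero
    yield when ``dead_plot_as_zero``); genotypes left with no records are
    dropped from the Z index map with a warning; a duplicated (plot, day)
    pair is a hard error.
    """
    spec.validate_against(schedule)
    table.validate_against(schedule)
    df = table.data.copy()
    if df.empty:
        raise ValueError("phenotype table is empty")

    dup = df.duplicated(subset=["plot", "day"])
    if dup.any():
        pairs = df.loc[dup, ["plot", "day"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (plot, day) records: {pairs[:5]}")

    if dead_plot_as_zero:
        n_missing = int(df["yield"].isna().sum())
        df["yield"] = df["yield"].fillna(0.0)
    else:
        n_missing = int(df["yield"].isna().sum())
        if n_missing:
            logger.info("dropping %d records with missing yield", n_missing)
        df = df[df["yield"].notna()]
    if df.empty:
        raise ValueError("no records left after removing missing yields")

    all_genotypes = table.genotypes
    kept_genotypes = sorted(df["genotype"].unique())
    dropped = sorted(set(all_genotypes) - set(kept_genotypes))
    if dropped:
        logger.warning(
            "genotypes with zero usable records dropped from Z: %s", dropped
        )

    df = df.sort_values(["genotype", "replication", "day"], kind="mergesort")
    df = df.reset_index(drop=True)

    meas_days = list(schedule.measured_days)
    day_to_h = {d: j for j, d in enumerate(meas_days)}
    geno_index = {g: i for i, g in enumerate(kept_genotypes)}
    plot_ids = sorted(df["plot"].unique(), key=lambda p: (
        df.loc[df["plot"] == p, "genotype"].iloc[0], p))
    plot_index = {p: i for i, p in enumerate(plot_ids)}

    n = len(df)
    g_idx = df["genotype"].map(geno_index).to_numpy()
    p_idx = df["plot"].map(plot_index).to_numpy()
    h_idx = df["day"].map(day_to_h).to_numpy()
    t_star = standardize_time(df["day"].to_numpy(), schedule)
    t_star = np.atleast_1d(t_star)

    rep_levels = sorted(df["replication"].unique())
    rep_map = {r: j for j, r in enumerate(rep_levels)}
    X_rep = np.zeros((n, len(rep_levels)))
    X_rep[np.arange(n), df["replication"].map(rep_map).to_numpy()] = 1.0
    X_leg = legendre_matrix(t_star, spec.fixed_order)
    X = np.hstack([X_rep, X_leg])
    x_names = [f"rep_{r}" for r in rep_levels] + [
        f"phi_{m}" for m in range(spec.fixed_order)
    ]

    phi_a = legendre_matrix(t_star, spec.genetic_order)
    phi_p = legendre_matrix(t_star, spec.perm_order)
    ng, npl = len(kept_genotypes), len(plot_ids)
    Z = np.zeros((n, ng * spec.genetic_order))
    W = np.zeros((n, npl * spec.perm_order))
    rows = np.arange(n)
    for m in range(spec.genetic_order):
        Z[rows, g_idx * spec.genetic_order + m] = phi_a[:, m]
    for m in range(spec.perm_order):
        W[rows, p_idx * spec.perm_order + m] = phi_p[:, m]

    records = pd.DataFrame(
        {
            "genotype": df["genotype"].to_numpy(),
            "replication": df["replication"].to_numpy(),
            "plot": df["plot"].to_numpy(),
            "day": df["day"].to_numpy(),
            "t_star": t_star,
            "yield": df["yield"].to_numpy(),
            "genotype_idx": g_idx,
            "plot_idx": p_idx,
            "harvest_idx": h_idx,
        }
    )

    return DesignMatrices(
        X=X,
        Z=Z,
        W=W,
        y=df["yield"].to_numpy(float),
        harvest_index=h_idx,
        records=records,
        genotype_ids=kept_genotypes,
        plot_ids=plot_ids,
        dropped_genotypes=dropped,
        rep_levels=rep_levels,
        x_names=x_names,
        spec=spec,
        schedule=schedule,
        n_dropped_missing=0 if dead_plot_as_zero else n_missing,
    )
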