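"""End-to-end analysis pipeline: read phenotypes, scan candidate models,
extract genetic information from the selected fit, rank clones by
persistence, and write tabular/plot/report artifacts.

The pipeline is a pure function of (input data, configuration, seed) up to
timestamps in the report.  Model selection is minimum BIC among converged
fits; a ``force_model`` override lets users pin a specific candidate (for
example to favour a more parsimonious model whose BIC is close).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetic_extraction import (
    accuracy,
    eigenfunctions,
    genetic_values,
    trajectories,
)
from .longitudinal_design import HarvestSchedule, ModelSpec, PhenotypeTable
from .model_selection import ModelComparison, scan_models
from .persistence import persistence_index
from .reml_engine import DEFAULT_SEED, FitOptions, FittedModel

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "input",
    "output_dir",
    "schedule_days",
    "schedule_measured",
    "anchors",
    "model_grid",
    "accuracy_form",
    "h2_include_perm",
    "persistence_grid",
    "persistence_range",
    "force_model",
    "seed",
    "n_starts",
    "make_plots",
    "compute_lrt",
    "log_level",
    "dead_plot_as_zero",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input: str
    output_dir: str = "rrpersist_out"
    schedule_days: list[int] | None = None
    schedule_measured: list[bool] | None = None
    anchors: tuple[int, int] | None = None
    model_grid: list[str] | None = None
    accuracy_form: str = "sqrt"
    h2_include_perm: bool = True
    persistence_grid: str = "daily"       # 'daily' | 'harvests'
    persistence_range: tuple[int, int] = (250, 1615)
    force_model: str | None = None
    seed: int = DEFAULT_SEED
    n_starts: int = 3
    make_plots: bool = False
    compute_lrt: bool = True
    dead_plot_as_zero: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.accuracy_form not in ("sqrt", "linear"):
            raise ValueError("accuracy_form must be 'sqrt' or 'linear'")
        if self.persistence_grid not in ("daily", "harvests"):
            raise ValueError("persistence_grid must be 'daily' or 'harvests'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.anchors is not None:
            cfg.anchors = tuple(cfg.anchors)
        cfg.persistence_range = tuple(cfg.persistence_range)
        return cfg

    def schedule(self, table: PhenotypeTable) -> HarvestSchedule:
        if self.schedule_days is not None:
            return HarvestSchedule.from_days(
                self.schedule_days, self.schedule_measured, self.anchors
            )
        days = sorted(table.data["day"].unique())
        return HarvestSchedule.from_days(days, None, self.anchors)


def summarize_harvest_means(table: PhenotypeTable) -> dict:
    """Arithmetic mean yield per measured day (non-missing records) and the
    percent excess of the top mean over the second-highest (None when only
    one day is present)."""
    df = table.data[table.data["yield"].notna()]
    if df.empty:
        raise ValueError("no records with yield")
    means = df.groupby("day")["yield"].mean().sort_index()
    excess = None
    if len(means) >= 2:
        top2 = np.sort(means.to_numpy())[::-1][:2]
        excess = (
            0.0 if top2[1] == 0 and top2[0] == top2[1]
            else 100.0 * (top2[0] - top2[1]) / top2[1] if top2[1] != 0 else None
        )
    return {"means": means, "top_vs_second_excess_pct": excess}


@dataclass
class RunReport:
    """JSON-serializable record of one pipeline run."""

    chosen_model: str
    forced: bool
    comparison: list[dict]
    harvest_means: dict
    h2_range: tuple[float, float]
    variance_peaks: dict
    eigen_proportions_pct: list[float]
    mean_accuracy_by_day: dict
    persistence_top: list[dict]
    n_records: int
    seed: int
    version: str
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): float(v) for k, v in obj.items()}
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, table: PhenotypeTable | None = None) -> RunReport:
    """Execute the full analysis and write artifacts to the output
    directory: comparison.csv, trajectories.csv, genetic_values.csv,
    accuracy.csv, eigenfunctions.csv, persistence.csv, report.json, and
    optional plots."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(out / "run.log", mode="w")
    log_file.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logging.getLogger("rrpersist").addHandler(log_file)

    if table is None:
        table = PhenotypeTable.read(config.input)
    schedule = config.schedule(table)
    logger.info(
        "input %s: %d records, %d genotypes, measured days %s",
        config.input, table.n_records, len(table.genotypes),
        schedule.measured_days,
    )

    specs = None
    if config.model_grid:
        specs = [ModelSpec.from_label(lbl) for lbl in config.model_grid]
    opts = FitOptions(
        seed=config.seed,
        n_starts=config.n_starts,
        dead_plot_as_zero=config.dead_plot_as_zero,
    )
    comparison = scan_models(
        table, schedule, specs=specs, options=opts, compute_lrt=config.compute_lrt
    )
    comparison.to_csv(out / "comparison.csv")

    forced = False
    if config.force_model is not None:
        if config.force_model not in comparison.fits:
            raise ValueError(
                f"force_model {config.force_model!r} was not fitted"
            )
        fit = comparison.fits[config.force_model]
        forced = True
    else:
        fit = comparison.best
    if fit is None or not fit.converged:
        raise RuntimeError(
            "no converged model; attempted fits:\n"
            + comparison.table.to_string(index=False)
        )
    logger.info("selected model %s (forced=%s)", fit.label, forced)

    with open(out / "fit.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, default=_jsonify)
    fit.genetic_blups().to_csv(out / "blup_genetic.csv", index=False)
    if fit.p_hat is not None:
        fit.plot_blups().to_csv(out / "blup_perm.csv", index=False)

    lo, hi = schedule.day_min, schedule.day_max
    daily = np.arange(lo, hi + 1)
    traj = trajectories(fit, daily, include_perm_in_h2=config.h2_include_perm)
    traj.to_csv(out / "trajectories.csv", index=False)

    gv_grid = daily if config.persistence_grid == "daily" else np.asarray(
        schedule.days
    )
    surface = genetic_values(fit, gv_grid)
    surface.to_frame().to_csv(out / "genetic_values.csv", index=False)

    acc_days = np.asarray(schedule.days)
    acc = accuracy(fit, acc_days, form=config.accuracy_form)
    acc_df = pd.DataFrame(
        acc, index=pd.Index(fit.genotype_ids, name="genotype"), columns=acc_days
    )
    acc_df.reset_index().melt(
        id_vars="genotype", var_name="day", value_name="accuracy"
    ).to_csv(out / "accuracy.csv", index=False)

    eig = eigenfunctions(fit.params.K_g, (lo, hi), daily)
    eig.to_frame().to_csv(out / "eigenfunctions.csv", index=False)

    pers = persistence_index(surface, config.persistence_range)
    pers.to_csv(out / "persistence.csv", index=False)

    hm = summarize_harvest_means(table)
    report = RunReport(
        chosen_model=fit.label,
        forced=forced,
        comparison=comparison.table.to_dict(orient="records"),
        harvest_means={
            "means": {str(k): float(v) for k, v in hm["means"].items()},
            "top_vs_second_excess_pct": hm["top_vs_second_excess_pct"],
        },
        h2_range=(float(traj["h2"].min()), float(traj["h2"].max())),
        variance_peaks={
            "genetic_peak_day": int(traj.loc[traj["var_genetic"].idxmax(), "day"]),
            "phenotypic_peak_day": int(
                traj.loc[traj["var_phenotypic"].idxmax(), "day"]
            ),
        },
        eigen_proportions_pct=[float(x) for x in eig.proportions_pct],
        mean_accuracy_by_day={
            str(d): float(acc[:, j].mean()) for j, d in enumerate(acc_days)
        },
        persistence_top=pers.head(10).to_dict(orient="records"),
        n_records=fit.n_records,
        seed=config.seed,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    report.to_json(out / "report.json")
    logger.info(
        "wrote artifacts to %s: %d comparison rows, %d trajectory days, "
        "%d clones ranked", out, len(comparison.table), len(traj), len(pers),
    )

    if config.make_plots:
        _make_plots(out, traj, surface, eig, pers)
    logging.getLogger("rrpersist").removeHandler(log_file)
    log_file.close()
    return report


def _make_plots(out: Path, traj, surface, eig, pers) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col, style in (
        ("var_genetic", "-"),
        ("var_perm", "--"),
        ("var_residual", ":"),
        ("var_phenotypic", "-."),
    ):
        ax.plot(traj["day"], traj[col], style, label=col.replace("var_", ""))
    ax2 = ax.twinx()
    ax2.plot(traj["day"], traj["h2"], color="k", alpha=0.4, label="h2")
    ax2.set_ylim(0, 1)
    ax2.set_ylabel("heritability")
    ax.set_xlabel("days since uniformity harvest")
    ax.set_ylabel("variance (Mg/ha)$^2$")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i in range(len(eig.eigenvalues)):
        ax.plot(
            eig.days,
            eig.values[i],
            label=f"$\\Psi_{i + 1}$ ({eig.proportions_pct[i]:.2f}%)",
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("days since uniformity harvest")
    ax.set_ylabel("eigenfunction value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "eigenfunctions.png", dpi=120)
    plt.close(fig)

    top = pers.head(10)["genotype"].tolist()
    bottom = pers.tail(5)["genotype"].tolist()
    pct = dict(zip(pers["genotype"], pers["persistence_pct"]))
    idx = {g: i for i, g in enumerate(surface.genotype_ids)}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g in top:
        ax.plot(surface.days, surface.values[idx[g]], label=f"{g} ({pct[g]:.2f})")
    for g in bottom:
        ax.plot(
            surface.days, surface.values[idx[g]], "--", lw=0.8,
            label=f"{g} ({pct[g]:.2f})",
        )
    ax.set_xlabel("days since uniformity harvest")
    ax.set_ylabel("estimated genetic value (Mg/ha)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out / "persistence.png", dpi=120)
    plt.close(fig)
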