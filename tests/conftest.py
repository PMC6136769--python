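import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rrpersist as rr
from rrpersist.synthetic_data import SimulationConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule() -> rr.HarvestSchedule:
    return rr.HarvestSchedule.default()


@pytest.fixture(scope="session")
def paper_cfg() -> SimulationConfig:
    return rr.paper_like_config(seed=20180913)


def small_config(
    paper_cfg: SimulationConfig,
    ng: int = 4,
    n_rep: int = 2,
    seed: int = 0,
    death_prob: float = 0.0,
) -> SimulationConfig:
    """A scaled-down copy of the default trial for cheap exact checks."""
    return SimulationConfig(
        ng=ng,
        n_rep=n_rep,
        schedule=paper_cfg.schedule,
        beta=paper_cfg.beta,
        rep_effects=np.resize(paper_cfg.rep_effects, n_rep),
        K_g=paper_cfg.K_g,
        K_p=paper_cfg.K_p,
        residual_structure=paper_cfg.residual_structure,
        residual=paper_cfg.residual,
        death_prob=death_prob,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim(paper_cfg):
    return rr.simulate(small_config(paper_cfg, ng=4, seed=42))


@pytest.fixture(scope="session")
def paper_fit(paper_cfg):
    """One trial at full scale fitted with the generating model; reused by
    the extraction/accuracy/persistence tests."""
    sim = rr.simulate(rr.paper_like_config(seed=7))
    spec = rr.ModelSpec(genetic_order=4, perm_order=1, residual_structure="diagonal")
    fit = rr.fit_reml(sim.table, sim.config.schedule, spec, rr.FitOptions(n_starts=1))
    assert fit.converged
    return sim, fit


def tiny_table(days=(250, 500, 1615), genotypes=("A", "B"), reps=(1, 2), seed=0):
    """Small dense phenotype table with arbitrary positive yields."""
    rng = np.random.default_rng(seed)
    rows = [
        {
            "genotype": g,
            "replication": r,
            "day": d,
            "yield": float(rng.uniform(5.0, 30.0)),
        }
        for g in genotypes
        for r in reps
        for d in days
    ]
    return rr.PhenotypeTable(pd.DataFrame(rows))
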