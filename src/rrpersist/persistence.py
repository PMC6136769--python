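"""Genotype-ideotype persistence index over the genetic-value grid.

Persistence — sustained high yield across successive growth seasons — is
quantified against an *ideotype*: the per-day maximum estimated genetic
value within the evaluated cohort.  For clone i,

    D_i = sum_j (g_ij - max_i' g_i'j)^2      (j over days in the range)
    Persistence_i = (1 / D_i) / sum_i' (1 / D_i') * 100,

so indices are positive, sum to 100, and rank clones by how closely their
whole trajectory tracks the best genetic value of each day.  The ideotype
is cohort-relative: it must be recomputed after any subsetting of clones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genetic_extraction import GeneticValueSurface


def ideotype(gvalues: GeneticValueSurface) -> np.ndarray:
    """Per-day maximum genetic value across the cohort."""
    if gvalues.values.size == 0 or len(gvalues.genotype_ids) == 0:
        raise ValueError("empty genetic-value surface")
    return gvalues.values.max(axis=0)


def persistence_index(
    gvalues: GeneticValueSurface,
    day_range: tuple[int, int] = (250, 1615),
) -> pd.DataFrame:
    """Persistence table: genotype, squared genotype-ideotype deviation D,
    normalized percent index, and descending rank.

    The sum runs over the surface's grid days inside ``day_range``
    (inclusive); the default analysis evaluates genetic values at integer
    -day resolution so the sum has day_range span + 1 terms.  A clone that
    *is* the ideotype at every day (D = 0, impossible once two distinct
    curves cross) has its raw score replaced by 1/eps with
    eps = 1e-12 * mean(D), flagged in the ``degenerate`` column.
    """
    if len(gvalues.genotype_ids) < 2:
        raise ValueError("persistence needs at least 2 genotypes")
    lo, hi = day_range
    mask = (gvalues.days >= lo) & (gvalues.days <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"surface grid has fewer than 2 days inside [{lo}, {hi}]"
        )
    days = gvalues.days[mask]
    if days.min() != lo or days.max() != hi:
        raise ValueError(
            f"surface grid does not cover the day range [{lo}, {hi}]"
        )
    G = gvalues.values[:, mask]
    ideo = G.max(axis=0)
    D = np.sum((G - ideo[None, :]) ** 2, axis=1)

    degenerate = D <= 0.0
    scores = np.empty_like(D)
    if degenerate.any():
        mean_D = D.mean()
        eps = 1e-12 * (mean_D if mean_D > 0 else 1.0)
        scores[degenerate] = 1.0 / eps
        scores[~degenerate] = 1.0 / D[~degenerate]
    else:
        scores = 1.0 / D
    pct = 100.0 * scores / scores.sum()

    out = pd.DataFrame(
        {
            "genotype": gvalues.genotype_ids,
            "D": D,
            "persistence_pct": pct,
            "degenerate": degenerate,
        }
    )
    out = out.sort_values(
        ["persistence_pct", "genotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
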