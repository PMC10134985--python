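"""Pearson chi-squared test of haplotype-frequency homogeneity.

Tests whether the haplotype composition differs among selected populations
(e.g. foraging areas), on the contingency table of haplotype counts.
Haplotypes absent from every selected population are dropped before the
degrees of freedom are computed.  No continuity correction is applied and
the p-value is asymptotic by default; a Monte-Carlo p-value conditioned on
the observed column totals is available for tables with sparse cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import HaplotypeCountTable

__all__ = ["HomogeneityResult", "chisq_homogeneity"]


@dataclass
class HomogeneityResult:
    statistic: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    dropped_rows: list[str]
    monte_carlo_p: float | None = None


def _pearson(observed: np.ndarray) -> tuple[float, np.ndarray]:
    res = stats.chi2_contingency(observed, correction=False)
    return float(res.statistic), res.expected_freq


def chisq_homogeneity(
    table: HaplotypeCountTable,
    population_ids: list[str],
    monte_carlo: int | None = None,
    rng_seed: int | None = None,
) -> HomogeneityResult:
    """Pearson X^2 homogeneity test across the selected populations.

    Parameters
    ----------
    monte_carlo
        If given, additionally estimate a Monte-Carlo p-value from this many
        tables simulated under homogeneity with the observed column totals
        (haplotypes drawn from the pooled frequencies).

    Raises
    ------
    ValueError
        For fewer than two populations or an all-zero selection.
    """
    if len(population_ids) < 2:
        raise ValueError("need at least 2 populations to test homogeneity")
    for pop in population_ids:
        if pop not in table.counts.columns:
            raise KeyError(f"unknown population {pop!r}")
    obs = table.counts[list(population_ids)]
    if (obs.sum(axis=0) == 0).any():
        raise ValueError("every selected population must have at least one sequence")

    dropped = [h for h in obs.index if obs.loc[h].sum() == 0]
    obs = obs.drop(index=dropped)

    o = obs.to_numpy(dtype=float)
    statistic, expected = _pearson(o)
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0

    mc_p = None
    if monte_carlo:
        rng = np.random.default_rng(rng_seed)
        pooled = o.sum(axis=1) / o.sum()
        col_n = o.sum(axis=0).astype(int)
        exceed = 0
        for _ in range(monte_carlo):
            sim = np.column_stack([rng.multinomial(n, pooled) for n in col_n])
            sim = sim[sim.sum(axis=1) > 0]  # all-zero rows contribute nothing
            s, _ = _pearson(sim.astype(float))
            exceed += s >= statistic - 1e-12
        mc_p = (exceed + 1) / (monte_carlo + 1)

    return HomogeneityResult(
        statistic=statistic,
        df=df,
        p_value=p,
        observed=obs,
        expected=pd.DataFrame(expected, index=obs.index, columns=obs.columns),
        dropped_rows=dropped,
        monte_carlo_p=mc_p,
    )
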