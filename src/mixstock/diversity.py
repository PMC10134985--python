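"""Nei haplotype (gene) diversity and its sampling variance.

For a sample of n sequences with haplotype relative frequencies x_i, the
unbiased haplotype diversity is

    h = n/(n-1) * (1 - sum_i x_i^2)

with large-sample variance (Nei 1987, eq. 8.12)

    V(h) = 2/(n(n-1)) * { 2(n-2) [sum x_i^3 - (sum x_i^2)^2]
                          + sum x_i^2 - (sum x_i^2)^2 }.

h is the probability that two sequences drawn without replacement carry
different haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .tables import HaplotypeCountTable

__all__ = ["DiversityResult", "haplotype_diversity", "diversity_profile"]


class UndefinedDiversityError(ValueError):
    """Raised when n < 2, where the unbiased estimator is undefined."""


@dataclass(frozen=True)
class DiversityResult:
    h: float
    variance: float
    sd: float
    n: int
    k: int


def haplotype_diversity(counts) -> DiversityResult:
    """Nei's unbiased haplotype diversity from per-haplotype counts.

    Zero counts are ignored.  Requires n >= 2.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedDiversityError(f"need at least 2 sequences, got n={int(n)}")
    x = c / n
    s2 = float(np.sum(x**2))
    s3 = float(np.sum(x**3))
    h = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2 * s2) + s2 - s2 * s2)
    var = max(var, 0.0)  # guard tiny negative round-off in monomorphic samples
    return DiversityResult(h=h, variance=var, sd=sqrt(var), n=int(n), k=int(len(c)))


def diversity_profile(table: HaplotypeCountTable) -> pd.DataFrame:
    """Per-population diversity for every column of a haplotype table."""
    rows = {}
    for pop in table.population_ids:
        r = haplotype_diversity(table.counts[pop])
        rows[pop] = {"h": r.h, "sd": r.sd, "variance": r.variance, "n": r.n, "k": r.k}
    out = pd.DataFrame(rows).T
    out[["n", "k"]] = out[["n", "k"]].astype(int)
    return out
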