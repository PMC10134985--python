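"""Bayesian mixed-stock analysis by Gibbs sampling.

The model is the standard Dirichlet-multinomial mixture for genetic
stock-identification (Pella & Masuda 2001).  A mixture of n individuals
with observed haplotypes y_i is assumed drawn from S baseline stocks with
unknown contribution vector theta ~ Dirichlet(alpha) and unknown per-stock
haplotype frequencies q_s ~ Dirichlet(beta_s), informed by baseline counts
b_s.  The full conditionals are conjugate, giving a three-block Gibbs sweep:

1. latent origins:  P(z_i = s) proportional to theta_s * q_{s, y_i}
2. contributions:   theta ~ Dirichlet(alpha + origin counts)
3. frequencies:     q_s ~ Dirichlet(beta_s + b_s + mixture counts assigned to s)

Several chains are run from overdispersed starting points (one dominant
stock per chain); convergence is checked with the Gelman-Rubin potential
scale reduction factor on the post-burn-in draws, and posterior summaries
(mean, sd, 95% equal-tailed credible interval) are computed on the pooled
kept draws.

The baseline-frequency pseudocounts are beta_{s,h} = 1/H, H being the
number of haplotypes in the model (union of baseline and mixture), so each
stock's frequency prior sums to one; the flat mixture prior is
alpha_s = 1/S and the weighted prior scales the per-stock nesting-females-
per-year weights to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import MixtureSample, StockBaseline

__all__ = [
    "MSAConfig",
    "MixturePosterior",
    "build_prior",
    "run_msa",
    "gelman_rubin",
    "summarize",
]

logger = logging.getLogger(__name__)


class OrphanHaplotypeError(ValueError):
    """Raised when the mixture still contains baseline-absent haplotypes."""


class ConvergenceWarning(UserWarning):
    """Emitted when any Gelman-Rubin shrink factor exceeds its threshold."""


@dataclass(frozen=True)
class MSAConfig:
    """Sampler configuration.

    Defaults follow common practice for mtDNA mixed-stock analyses: 7
    chains of 15,000 sweeps with a 10,000-sweep burn-in (35,000 pooled
    kept draws for a 7-stock baseline), convergence declared at shrink
    factor 1.2.
    """

    n_chains: int = 7
    chain_length: int = 15_000
    burn_in: int = 10_000
    prior_mode: str = "flat"  # "flat" | "weighted"
    rng_seed: int = 0
    init_dominance: float = 0.90
    gr_threshold: float = 1.2

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if not 0.0 < self.init_dominance < 1.0:
            raise ValueError("init_dominance must lie in (0, 1)")
        if self.prior_mode not in ("flat", "weighted"):
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def kept_per_chain(self) -> int:
        return self.chain_length - self.burn_in


@dataclass
class MixturePosterior:
    """Posterior draws of stock contributions with summaries and diagnostics.

    ``draws`` has shape (n_chains, kept, n_stocks); every draw is a
    probability vector.  ``gelman_rubin`` holds the per-stock shrink factor
    computed across chains on the kept draws.
    """

    draws: np.ndarray
    stock_ids: list[str]
    config: MSAConfig
    gelman_rubin: pd.Series = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.draws.shape[0] >= 2:
            rhat = gelman_rubin(self.draws)
        else:  # diagnostics need at least two chains
            rhat = np.full(self.draws.shape[-1], np.nan)
        self.gelman_rubin = pd.Series(rhat, index=self.stock_ids, name="rhat")
        self.converged = bool(np.all(np.isnan(rhat) | (rhat <= self.config.gr_threshold)))

    @property
    def pooled(self) -> np.ndarray:
        """Kept draws pooled across chains, shape (n_chains*kept, n_stocks)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def mean(self) -> pd.Series:
        return pd.Series(self.pooled.mean(axis=0), index=self.stock_ids, name="mean")

    def summary(self) -> pd.DataFrame:
        return summarize(self)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, step, stock, value."""
        m, n, s = self.draws.shape
        idx = pd.MultiIndex.from_product(
            [range(m), range(n), self.stock_ids], names=["chain", "step", "stock"]
        )
        return pd.DataFrame({"value": self.draws.reshape(-1)}, index=idx).reset_index()


def build_prior(baseline: StockBaseline, mode: str = "flat") -> np.ndarray:
    """Dirichlet parameters for the stock-contribution prior, summing to 1.

    Flat: alpha_s = 1/S.  Weighted: alpha_s proportional to the stock's
    nesting-females-per-year weight.
    """
    s = len(baseline.stock_ids)
    if mode == "flat":
        return np.full(s, 1.0 / s)
    if mode == "weighted":
        w = baseline.weights.to_numpy(dtype=float)
        total = w.sum()
        if not total > 0:
            raise ValueError("weighted prior requires a positive total stock weight")
        return w / total
    raise ValueError(f"unknown prior mode {mode!r}")


def origin_probabilities(theta: np.ndarray, q: np.ndarray) -> np.ndarray:
    """P(origin = s | haplotype h, theta, q) for every haplotype.

    ``q`` is (S, H); the result is (H, S) with rows summing to 1.  A
    haplotype with zero likelihood under every stock is uninformative and
    gets a uniform row (logged by the sampler when it occurs).
    """
    p = theta[None, :] * q.T  # H x S
    rows = p.sum(axis=1, keepdims=True)
    uniform = np.full_like(p, 1.0 / p.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(rows > 0, p / np.where(rows == 0, 1.0, rows), uniform)
    return p


def _align(mix: MixtureSample, baseline: StockBaseline):
    """Common haplotype axis (baseline union mixture) and count matrices."""
    haps = list(baseline.haplotype_ids)
    haps += [h for h in mix.haplotype_ids if h not in haps]
    b = baseline.counts.reindex(columns=haps, fill_value=0).to_numpy(dtype=float)
    m = mix.counts.reindex(haps, fill_value=0).to_numpy(dtype=int)
    present = m > 0
    orphan = present & (b.sum(axis=0) <= 0)
    if orphan.any():
        names = [haps[i] for i in np.flatnonzero(orphan)]
        raise OrphanHaplotypeError(
            f"mixture haplotypes absent from every baseline stock: {names}; "
            "remove them with filter_orphans() first"
        )
    return haps, b, m


def _run_chain(
    rng: np.random.Generator,
    b: np.ndarray,
    m: np.ndarray,
    alpha: np.ndarray,
    beta: float,
    config: MSAConfig,
    dominant: int,
) -> np.ndarray:
    s, h = b.shape
    theta = np.full(s, (1.0 - config.init_dominance) / max(s - 1, 1))
    theta[dominant] = config.init_dominance if s > 1 else 1.0
    g0 = b + beta
    q = g0 / g0.sum(axis=1, keepdims=True)  # init at baseline posterior mean

    kept = np.empty((config.kept_per_chain, s))
    warned = False
    for t in range(config.chain_length):
        raw = theta[None, :] * q.T  # H x S
        rows = raw.sum(axis=1, keepdims=True)
        if not warned and np.any(rows[m > 0] == 0):
            logger.info("haplotype with zero likelihood under all stocks; treated as uninformative")
            warned = True
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows > 0, raw / np.where(rows == 0, 1.0, rows), 1.0 / s)
        assigned = rng.multinomial(m, p)  # H x S
        theta = rng.dirichlet(alpha + assigned.sum(axis=0))
        gam = rng.standard_gamma(b + beta + assigned.T)
        q = gam / gam.sum(axis=1, keepdims=True)
        if t >= config.burn_in:
            kept[t - config.burn_in] = theta
    return kept


def run_msa(
    mix: MixtureSample,
    baseline: StockBaseline,
    config: MSAConfig | None = None,
) -> MixturePosterior:
    """Fit the mixed-stock model to an orphan-free mixture.

    Chain k starts with contribution ``init_dominance`` on stock k mod S and
    the remainder split evenly, so each stock is the dominant starting point
    of at least one chain in the default 7-chain, 7-stock setting.  Results
    are reproducible given ``config.rng_seed`` (one child stream per chain).

    Raises
    ------
    OrphanHaplotypeError
        If any mixture haplotype has zero count in every baseline stock.

    Warns
    -----
    ConvergenceWarning
        If any per-stock shrink factor exceeds ``config.gr_threshold``; the
        posterior is still returned with ``converged=False``.
    """
    config = config or MSAConfig()
    _, b, m = _align(mix, baseline)
    alpha = build_prior(baseline, config.prior_mode)
    s = b.shape[0]
    beta = 1.0 / b.shape[1]

    streams = np.random.SeedSequence(config.rng_seed).spawn(config.n_chains)
    draws = np.stack(
        [
            _run_chain(np.random.default_rng(ss), b, m, alpha, beta, config, k % s)
            for k, ss in enumerate(streams)
        ]
    )
    post = MixturePosterior(draws=draws, stock_ids=list(baseline.stock_ids), config=config)
    if not post.converged:
        worst = post.gelman_rubin.idxmax()
        warnings.warn(
            f"Gelman-Rubin shrink factor {post.gelman_rubin[worst]:.3f} for stock "
            f"{worst!r} exceeds {config.gr_threshold}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return post


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per stock.

    ``draws`` is (n_chains, n_kept, n_stocks) (a 2-D input is treated as a
    single quantity).  Classic formula from between-chain (B) and
    within-chain (W) variances of the kept draws:

        Rhat = sqrt( ((n-1)/n * W + B/n) / W )

    Chains with zero variance everywhere (a degenerate posterior) give
    Rhat = 1 by convention.
    """
    a = np.asarray(draws, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    m, n, s = a.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    w = a.var(axis=1, ddof=1).mean(axis=0)
    b = n * a.mean(axis=1).var(axis=0, ddof=1)
    vhat = (n - 1) / n * w + b / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(vhat / w)
    return np.where(w > 0, rhat, 1.0)


def summarize(posterior: MixturePosterior) -> pd.DataFrame:
    """Per-stock mean, sd, and 95% equal-tailed credible interval."""
    pooled = posterior.pooled
    if pooled.size == 0:
        raise ValueError("empty posterior")
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "q2.5": np.quantile(pooled, 0.025, axis=0),
            "q97.5": np.quantile(pooled, 0.975, axis=0),
            "rhat": posterior.gelman_rubin.to_numpy(),
        },
        index=posterior.stock_ids,
    )
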