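"""Haplotype count tables, rookery-to-stock pooling, and mixture assembly.

The central container is :class:`HaplotypeCountTable`, the in-memory form of a
haplotype-by-population frequency table: rows are mtDNA control-region
haplotypes, columns are sampled populations (nesting rookeries or foraging
aggregations), and cells are individual counts.  Rookeries are pooled into
genetic stocks (management units) with :func:`pool_rookeries`, foraging
samples are combined into a single mixture with :func:`build_mixture`, and
haplotypes unseen in any baseline stock ("orphans") are removed with
:func:`filter_orphans` before mixed-stock analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeCountTable",
    "StockGrouping",
    "StockBaseline",
    "MixtureSample",
    "read_haplotype_table",
    "pool_rookeries",
    "build_mixture",
    "filter_orphans",
    "load_packaged_table",
    "load_packaged_grouping",
]

ROOKERY = "rookery"
FORAGING = "foraging"

#: Reserved row labels in the CSV dialect (not haplotype ids).
_SPECIAL_ROWS = ("N", "NFpy", "role")


class TableValidationError(ValueError):
    """Raised when a haplotype count table violates its invariants."""


@dataclass
class HaplotypeCountTable:
    """Integer haplotype counts per population.

    Parameters
    ----------
    counts
        DataFrame indexed by haplotype id with one column per population.
    roles
        Mapping population id -> ``"rookery"`` or ``"foraging"``.
    nfpy
        Estimated nesting females per year, for rookery populations only.
        Used as prior weights in the weighted mixed-stock analysis.
    """

    counts: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    nfpy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise TableValidationError("duplicate haplotype names")
        if c.columns.has_duplicates:
            raise TableValidationError("duplicate population names")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise TableValidationError("non-integer haplotype count")
            self.counts = c.astype(int)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise TableValidationError("negative haplotype count")
        for pop, role in self.roles.items():
            if role not in (ROOKERY, FORAGING):
                raise TableValidationError(f"unknown role {role!r} for {pop!r}")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def population_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sizes(self) -> pd.Series:
        """Per-population sample size N (column sums)."""
        return self.counts.sum(axis=0)

    def role_of(self, population: str) -> str:
        return self.roles.get(population, ROOKERY if population in self.nfpy else FORAGING)

    def column(self, population: str) -> pd.Series:
        if population not in self.counts.columns:
            raise KeyError(f"unknown population {population!r}")
        return self.counts[population]


@dataclass
class StockGrouping:
    """Pooling of rookery populations into genetic stocks.

    ``mapping`` sends each rookery population id to its stock id; ``weights``
    optionally overrides the per-stock nesting-females-per-year weight
    (by default pooled from the table's NFpy values).
    """

    stock_ids: list[str]
    mapping: dict[str, str]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, stock in self.mapping.items():
            if stock not in self.stock_ids:
                raise ValueError(f"population {pop!r} mapped to unknown stock {stock!r}")
        for w in self.weights.values():
            if not np.isfinite(w) or w < 0:
                raise ValueError("stock weights must be finite and non-negative")

    def members(self, stock: str) -> list[str]:
        return [p for p, s in self.mapping.items() if s == stock]

    @classmethod
    def from_dict(cls, stocks: dict[str, list[str]], weights: dict[str, float] | None = None) -> "StockGrouping":
        mapping = {pop: stock for stock, pops in stocks.items() for pop in pops}
        return cls(stock_ids=list(stocks), mapping=mapping, weights=weights or {})

    @classmethod
    def from_json(cls, path: str | Path) -> "StockGrouping":
        with open(path) as fh:
            obj = json.load(fh)
        return cls.from_dict(obj["stocks"], obj.get("weights"))


@dataclass
class StockBaseline:
    """Per-stock haplotype counts (stock x haplotype) with prior weights."""

    counts: pd.DataFrame  # index: stock ids, columns: haplotype ids
    weights: pd.Series  # nesting females per year, per stock

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise TableValidationError("negative baseline count")
        self.weights = self.weights.reindex(self.counts.index)

    @property
    def stock_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class MixtureSample:
    """Pooled foraging-ground haplotype counts, the mixture in the MSA.

    ``excluded_orphans`` records haplotype -> count removed by
    :func:`filter_orphans`; it is empty until filtering.
    """

    counts: pd.Series  # index: haplotype ids
    provenance: list[str] = field(default_factory=list)
    excluded_orphans: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise TableValidationError("negative mixture count")
        self.counts = self.counts.astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.index)

    def exclusion_report(self) -> dict:
        return {
            "provenance": list(self.provenance),
            "n_retained": self.n,
            "excluded_orphans": dict(self.excluded_orphans),
            "n_excluded": int(sum(self.excluded_orphans.values())),
        }


def read_haplotype_table(path: str | Path) -> HaplotypeCountTable:
    """Read a haplotype-by-population CSV table.

    The dialect has a header row of population ids, haplotype ids in the
    first column, and three optional special rows: ``N`` (declared sample
    sizes, validated against the column sums), ``NFpy`` (nesting females per
    year for rookeries), and ``role`` (``rookery``/``foraging``).

    Raises
    ------
    TableValidationError
        On negative or non-integer cells, duplicate names, or a column sum
        disagreeing with its declared N.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)

    roles: dict[str, str] = {}
    nfpy: dict[str, float] = {}
    declared_n: pd.Series | None = None

    if "role" in raw.index:
        roles = {pop: v.strip() for pop, v in raw.loc["role"].items() if v.strip()}
    if "NFpy" in raw.index:
        nfpy = {pop: float(v) for pop, v in raw.loc["NFpy"].items() if v.strip()}
    if "N" in raw.index:
        declared_n = raw.loc["N"].map(lambda v: int(v) if v.strip() else 0)

    body = raw.drop(index=[r for r in _SPECIAL_ROWS if r in raw.index])
    try:
        counts = body.replace("", "0").astype(float)
    except ValueError as exc:
        raise TableValidationError(f"malformed count cell: {exc}") from exc

    table = HaplotypeCountTable(counts=counts, roles=roles, nfpy=nfpy)

    if declared_n is not None:
        sums = table.sample_sizes
        for pop in table.population_ids:
            if int(sums[pop]) != int(declared_n[pop]):
                raise TableValidationError(
                    f"column {pop!r} sums to {int(sums[pop])} but declares N={int(declared_n[pop])}"
                )
    return table


def write_haplotype_table(table: HaplotypeCountTable, path: str | Path) -> None:
    """Write a table back to the CSV dialect read by :func:`read_haplotype_table`."""
    out = table.counts.copy().astype(object)
    out.loc["N"] = table.sample_sizes
    if table.nfpy:
        out.loc["NFpy"] = pd.Series({p: table.nfpy.get(p, "") for p in table.population_ids})
    if table.roles:
        out.loc["role"] = pd.Series({p: table.role_of(p) for p in table.population_ids})
    out.index.name = "haplotype"
    out.to_csv(path)


def pool_rookeries(table: HaplotypeCountTable, grouping: StockGrouping) -> StockBaseline:
    """Pool rookery columns into stock rows; stock weight = sum of member NFpy."""
    for pop in grouping.mapping:
        if pop not in table.counts.columns:
            raise KeyError(f"unknown population {pop!r} in grouping")
    rows = {}
    weights = {}
    for stock in grouping.stock_ids:
        members = grouping.members(stock)
        rows[stock] = table.counts[members].sum(axis=1)
        if stock in grouping.weights:
            weights[stock] = float(grouping.weights[stock])
        else:
            weights[stock] = float(sum(table.nfpy.get(p, 0.0) for p in members))
    counts = pd.DataFrame(rows).T  # stock x haplotype
    counts = counts[table.haplotype_ids]
    return StockBaseline(counts=counts, weights=pd.Series(weights))


def build_mixture(table: HaplotypeCountTable, foraging_ids: list[str]) -> MixtureSample:
    """Combine foraging-ground columns into a single mixture sample."""
    for pop in foraging_ids:
        if pop not in table.counts.columns:
            raise KeyError(f"unknown population {pop!r}")
    if foraging_ids:
        counts = table.counts[list(foraging_ids)].sum(axis=1)
    else:
        counts = pd.Series(0, index=table.counts.index)
    counts = counts[counts > 0]
    return MixtureSample(counts=counts, provenance=list(foraging_ids))


def filter_orphans(mix: MixtureSample, baseline: StockBaseline) -> MixtureSample:
    """Remove mixture haplotypes absent from every baseline stock.

    Such orphan haplotypes carry no information about stock of origin and are
    excluded before the mixed-stock analysis; removals are recorded in
    ``excluded_orphans``.  Idempotent.
    """
    baseline_totals = baseline.counts.sum(axis=0)
    orphans = {}
    keep = []
    for hap, cnt in mix.counts.items():
        if hap in baseline_totals.index and baseline_totals[hap] > 0:
            keep.append(hap)
        else:
            orphans[hap] = int(cnt)
    merged = dict(mix.excluded_orphans)
    merged.update(orphans)
    return MixtureSample(
        counts=mix.counts[keep],
        provenance=list(mix.provenance),
        excluded_orphans=merged,
    )


def _data_path(name: str):
    return resources.files("mixstock.data").joinpath(name)


def load_packaged_table() -> HaplotypeCountTable:
    """The packaged Atlantic/Indian-Ocean leatherback haplotype table.

    Eleven nesting rookeries and four foraging aggregations (ES, SBR, BA,
    UR), 763-bp control-region haplotypes, with sample sizes and
    nesting-females-per-year weights.
    """
    with resources.as_file(_data_path("table1.csv")) as p:
        return read_haplotype_table(p)


def load_packaged_grouping() -> StockGrouping:
    """The seven-stock grouping of the eleven packaged rookeries.

    ACR/FLA/DR pool into NWCG and TRI/GUI/FWI into SECG; the remaining
    rookeries are singleton stocks.
    """
    with resources.as_file(_data_path("stocks.json")) as p:
        return StockGrouping.from_json(p)
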