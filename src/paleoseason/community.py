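"""Assemblage data model, I/O, transforms and dissimilarity measures.

Site-by-taxon abundance matrices (counts or percentages) are the common
currency of the whole pipeline: the modern training set pairs such a matrix
with per-site environmental variables, while fossil matrices carry calibrated
ages instead.  Matrices are kept dense (a few hundred sites by a few tens of
taxa at most), sites as rows and taxa as columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

__all__ = [
    "TaxonTable",
    "EnvTable",
    "DissimilarityMatrix",
    "to_percentages",
    "sqrt_transform",
    "bray_curtis",
    "squared_chord",
    "pairwise_dissimilarity",
    "cross_dissimilarity",
    "read_taxon_csv",
    "write_taxon_csv",
    "read_env_csv",
    "write_env_csv",
]

#: tolerance for accepting a "percent" row as summing to 100 (absorbs the
#: rounding found in published tables); rows inside it are renormalized.
PERCENT_SUM_TOL = 0.5

AGE_COLUMN = "age_calBP"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = [i for i, c in seen.items() if c > 1]
    if dups:
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclass(frozen=True)
class TaxonTable:
    """Site-by-taxon abundance matrix.

    Parameters
    ----------
    site_ids, taxon_ids
        Row and column labels; duplicates are rejected.
    values
        Non-negative abundances, shape ``(n_sites, n_taxa)``.
    kind
        ``"counts"`` for raw individual counts, ``"percent"`` for rows summing
        to 100 (within :data:`PERCENT_SUM_TOL`; renormalized exactly).
    ages
        Optional per-site age in calibrated years BP (fossil sequences only);
        must be strictly monotone along the stored order, larger = older.
    """

    site_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "counts"
    ages: np.ndarray | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.site_ids), len(self.taxon_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.taxon_ids)} taxa"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite abundance values")
        if np.any(vals < 0):
            raise ValueError("negative abundance values")
        _check_unique(self.site_ids, "site")
        _check_unique(self.taxon_ids, "taxon")
        if self.kind not in ("counts", "percent"):
            raise ValueError(f"kind must be 'counts' or 'percent', got {self.kind!r}")
        if self.kind == "percent":
            sums = vals.sum(axis=1)
            bad = np.where(np.abs(sums - 100.0) > PERCENT_SUM_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"percent rows not summing to 100 (±{PERCENT_SUM_TOL}): "
                    f"sites {[self.site_ids[i] for i in bad[:5]]}"
                )
            vals = vals / sums[:, None] * 100.0
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        if self.ages is not None:
            ages = np.asarray(self.ages, dtype=float)
            if ages.shape != (len(self.site_ids),):
                raise ValueError("ages length does not match number of sites")
            d = np.diff(ages)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("ages must be strictly monotone along the sequence")
            ages.setflags(write=False)
            object.__setattr__(self, "ages", ages)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.site_ids),
                          columns=list(self.taxon_ids))
        df.index.name = "site_id"
        return df

    def select_sites(self, idx: Sequence[int]) -> "TaxonTable":
        """Subset (or resample: repeated indices get suffixed ids) sites.

        Ages are kept only when the selection preserves a strict ordering.
        """
        idx = np.asarray(idx, dtype=int)
        ids: list[str] = []
        seen: dict[str, int] = {}
        for i in idx:
            base = self.site_ids[i]
            n = seen.get(base, 0)
            seen[base] = n + 1
            ids.append(base if n == 0 else f"{base}.{n}")
        ages = None
        if self.ages is not None:
            a = self.ages[idx]
            d = np.diff(a)
            if a.size < 2 or np.all(d > 0) or np.all(d < 0):
                ages = a
        return TaxonTable(tuple(ids), self.taxon_ids, self.values[idx],
                          kind=self.kind, ages=ages, meta=dict(self.meta))

    def align_taxa(self, taxon_ids: Sequence[str]) -> tuple["TaxonTable", float]:
        """Reindex columns onto ``taxon_ids``, dropping unmatched taxa.

        Returns the realigned table plus the worst per-site fraction of
        abundance lost to unmatched taxa (0 when taxonomies coincide).
        """
        taxon_ids = tuple(str(t) for t in taxon_ids)
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        out = np.zeros((self.n_sites, len(taxon_ids)))
        for j, t in enumerate(taxon_ids):
            if t in pos:
                out[:, j] = self.values[:, pos[t]]
        tot = self.values.sum(axis=1)
        kept = out.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            lost = np.where(tot > 0, 1.0 - kept / tot, 0.0)
        tab = TaxonTable(self.site_ids, taxon_ids, out, kind="counts",
                         ages=self.ages, meta=dict(self.meta))
        if self.kind == "percent":
            # rows may no longer sum to 100; keep them as raw abundances
            tab = replace(tab, kind="counts")
        return tab, float(lost.max(initial=0.0))


@dataclass(frozen=True)
class EnvTable:
    """Per-site environmental variables aligned one-to-one with a TaxonTable."""

    site_ids: tuple[str, ...]
    variables: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "variables", tuple(str(v) for v in self.variables))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.site_ids), len(self.variables)):
            raise ValueError("values shape does not match site/variable ids")
        if not np.all(np.isfinite(vals)):
            raise ValueError("missing or non-finite environmental values")
        _check_unique(self.site_ids, "site")
        _check_unique(self.variables, "variable")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def __getitem__(self, variable: str) -> np.ndarray:
        try:
            j = self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown environmental variable {variable!r}") from None
        return self.values[:, j]

    def subset(self, variables: Sequence[str]) -> "EnvTable":
        cols = [self.variables.index(v) for v in variables]
        return EnvTable(self.site_ids, tuple(variables), self.values[:, cols])

    def select_sites(self, idx: Sequence[int]) -> "EnvTable":
        idx = np.asarray(idx, dtype=int)
        return EnvTable(tuple(self.site_ids[i] for i in idx),
                        self.variables, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.site_ids),
                          columns=list(self.variables))
        df.index.name = "site_id"
        return df

    def check_aligned(self, table: TaxonTable) -> None:
        if self.site_ids != table.site_ids:
            raise ValueError("environment and taxon tables have different site ids")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    site_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if vals.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match ids")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix diagonal not zero")
        if np.any(vals < -1e-12):
            raise ValueError("negative dissimilarities")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def condensed(self) -> np.ndarray:
        return _ssd.squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.site_ids),
                            columns=list(self.site_ids))


# ---------------------------------------------------------------------------
# transforms


def to_percentages(table: TaxonTable) -> TaxonTable:
    """Convert a counts table to row percentages (idempotent on percent)."""
    sums = table.values.sum(axis=1)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero abundance row(s): {[table.site_ids[i] for i in zero[:5]]}"
        )
    return TaxonTable(table.site_ids, table.taxon_ids,
                      table.values / sums[:, None] * 100.0,
                      kind="percent", ages=table.ages, meta=dict(table.meta))


def sqrt_transform(table: TaxonTable | np.ndarray) -> np.ndarray:
    """Element-wise square root of a percentage matrix (ordination transform)."""
    vals = table.values if isinstance(table, TaxonTable) else np.asarray(table, float)
    if np.any(vals < 0):
        raise ValueError("negative abundances cannot be square-root transformed")
    return np.sqrt(vals)


# ---------------------------------------------------------------------------
# dissimilarities


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def squared_chord(x: np.ndarray, y: np.ndarray) -> float:
    """Squared-chord distance Σ(√xᵢ−√yᵢ)², the standard analogue metric
    for percentage data (range [0, 200] for percent vectors)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative abundances")
    return float(((np.sqrt(x) - np.sqrt(y)) ** 2).sum())


_METRICS = ("bray_curtis", "squared_chord")


def _pairwise(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric == "bray_curtis":
        return _ssd.cdist(a, b, metric="braycurtis")
    if metric == "squared_chord":
        return _ssd.cdist(np.sqrt(a), np.sqrt(b), metric="sqeuclidean")
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def pairwise_dissimilarity(table: TaxonTable, metric: str = "bray_curtis") -> DissimilarityMatrix:
    """All pairwise dissimilarities between the sites of one table."""
    d = _pairwise(table.values, table.values, metric)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(table.site_ids, (d + d.T) / 2.0, metric=metric)


def cross_dissimilarity(a: TaxonTable, b: TaxonTable, metric: str = "squared_chord") -> np.ndarray:
    """Dissimilarities between the sites of two tables (rows: a, cols: b).

    Taxonomies must already be aligned (same taxon_ids in the same order).
    """
    if a.taxon_ids != b.taxon_ids:
        raise ValueError("taxonomies differ; align taxa first")
    return _pairwise(a.values, b.values, metric)


# ---------------------------------------------------------------------------
# CSV I/O: header row of taxon names, first column the site id, optional
# age_calBP column.  UTF-8; delimiter/decimal configurable for ";" locales.


def read_taxon_csv(path, kind: str = "counts", sep: str = ",",
                   decimal: str = ".") -> TaxonTable:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate site id(s): {dup}")

    def to_num(col):
        if decimal != ".":
            col = col.str.replace(decimal, ".", regex=False)
        return pd.to_numeric(col, errors="raise")

    ages = None
    if AGE_COLUMN in df.columns:
        ages = to_num(df.pop(AGE_COLUMN)).to_numpy()
    try:
        vals = df.apply(to_num).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric abundance cell ({exc})") from None
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValueError(f"{path}: missing value at site {df.index[i]!r}, "
                         f"taxon {df.columns[j]!r}")
    return TaxonTable(tuple(df.index), tuple(df.columns), vals, kind=kind, ages=ages)


def write_taxon_csv(table: TaxonTable, path, sep: str = ",", decimal: str = ".") -> None:
    df = table.to_frame()
    if table.ages is not None:
        df.insert(0, AGE_COLUMN, table.ages)
    df.to_csv(path, sep=sep, decimal=decimal)


def read_env_csv(path, sep: str = ",", decimal: str = ".") -> EnvTable:
    df = pd.read_csv(path, sep=sep, decimal=decimal, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate site id(s): {dup}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing values in variable {col!r}")
    return EnvTable(tuple(df.index.astype(str)), tuple(df.columns),
                    df.to_numpy(dtype=float))


def write_env_csv(env: EnvTable, path, sep: str = ",", decimal: str = ".") -> None:
    env.to_frame().to_csv(path, sep=sep, decimal=decimal)
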