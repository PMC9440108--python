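"""Seasonal variance attribution of mean-annual-temperature change.

Given reconstructed (or true) per-season temperature series, this module
asks *which season drives the variability of the annual mean*.  Since MAT is
the arithmetic average of the four seasonal temperatures, a season whose
temperature varies strongly within a time window necessarily moves the MAT;
the share of each season is quantified as its sample variance within the
window divided by the sum of the four seasonal variances.

Procedure: interpolate the series onto a uniform 100-yr grid (removing the
imprint of irregular sampling resolution), compute per-season sample
variances Vi = (1/(n−1)) Σ (Ti − Tm)² in 1000-yr windows (±500 yr, about 11
grid points) sliding every 100 yr, convert to percentage contributions,
then summarize as frequency distributions and LOWESS-smoothed trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "SEASONS",
    "SeasonalSeries",
    "WindowVariance",
    "ContributionRecord",
    "mat_from_seasons",
    "interpolate_uniform",
    "window_variance",
    "contribution_percent",
    "sliding_contributions",
    "contributions_frame",
    "contribution_histogram",
    "lowess_smooth",
]

SEASONS = ("T_spring", "T_summer", "T_autumn", "T_winter")


@dataclass(frozen=True)
class SeasonalSeries:
    """Per-sample ages (cal yr BP, monotone) with four seasonal temperature
    series and optionally MAT; ``uniform`` flags an exact 100-yr grid."""

    ages: np.ndarray
    temperatures: dict[str, np.ndarray]   # keys = SEASONS (+ optionally MAT)
    uniform: bool = False
    dt: float | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        d = np.diff(ages)
        if ages.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ages must be strictly monotone")
        temps = {}
        for season in SEASONS:
            if season not in self.temperatures:
                raise ValueError(f"missing season {season}")
        for key, v in self.temperatures.items():
            v = np.asarray(v, dtype=float)
            if v.shape != ages.shape:
                raise ValueError(f"{key} length does not match ages")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{key} contains non-finite values")
            temps[key] = v
        if self.uniform:
            if self.dt is None:
                raise ValueError("uniform series needs dt")
            if ages.size >= 2 and not np.allclose(np.abs(d), self.dt, atol=1e-6):
                raise ValueError(f"grid spacing is not uniformly {self.dt}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "temperatures", temps)

    @property
    def n(self) -> int:
        return self.ages.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age_calBP": self.ages})
        for key, v in self.temperatures.items():
            df[key] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, uniform: bool = False,
                   dt: float | None = None) -> "SeasonalSeries":
        temps = {c: df[c].to_numpy(dtype=float)
                 for c in df.columns if c != "age_calBP"}
        return cls(df["age_calBP"].to_numpy(dtype=float), temps,
                   uniform=uniform, dt=dt)


@dataclass(frozen=True)
class WindowVariance:
    """Per-season sample variance within one time window."""

    center: float
    n: dict[str, int]
    mean: dict[str, float]            # Tm per season, °C
    variance: dict[str, float]        # Vi per season, °C²
    partial: bool = False             # window truncated at a series edge

    def defined(self) -> bool:
        return all(v >= 2 for v in self.n.values())


@dataclass(frozen=True)
class ContributionRecord:
    """Percentage contribution of each season to the four-season variance sum
    in one window; ``None`` percentages mark an undefined (flat) window."""

    center: float
    percent: dict[str, float] | None
    partial: bool = False


def mat_from_seasons(s: SeasonalSeries) -> np.ndarray:
    """MATᵢ = (T_springᵢ + T_summerᵢ + T_autumnᵢ + T_winterᵢ) / 4."""
    return np.mean([s.temperatures[k] for k in SEASONS], axis=0)


def with_mat(s: SeasonalSeries) -> SeasonalSeries:
    temps = dict(s.temperatures)
    temps["MAT"] = mat_from_seasons(s)
    return SeasonalSeries(s.ages, temps, uniform=s.uniform, dt=s.dt)


def interpolate_uniform(s: SeasonalSeries, dt: float = 100.0) -> SeasonalSeries:
    """Linearly interpolate every series onto a uniform ``dt``-yr age grid.

    The grid runs from the smallest grid multiple ≥ min(age) to the largest
    ≤ max(age); no extrapolation beyond the data.  Grid points that coincide
    with sample ages reproduce the sampled values exactly.
    """
    ages = s.ages
    if ages.size < 2:
        raise ValueError("need at least 2 samples to interpolate")
    if np.unique(ages).size != ages.size:
        raise ValueError("duplicate ages")
    lo, hi = float(ages.min()), float(ages.max())
    start = np.ceil(lo / dt) * dt
    stop = np.floor(hi / dt) * dt
    if start > stop:
        raise ValueError("no grid point inside the sampled age range")
    grid = np.arange(start, stop + dt / 2, dt)
    asc = ages if ages[0] < ages[-1] else ages[::-1]
    temps = {}
    for key, v in s.temperatures.items():
        vv = v if ages[0] < ages[-1] else v[::-1]
        temps[key] = np.interp(grid, asc, vv)
    return SeasonalSeries(grid, temps, uniform=True, dt=dt)


def window_variance(s: SeasonalSeries, center: float,
                    halfwidth: float = 500.0) -> WindowVariance:
    """Per-season sample variance (divisor n−1) in
    [center − halfwidth, center + halfwidth], bounds inclusive."""
    lo, hi = center - halfwidth, center + halfwidth
    mask = (s.ages >= lo - 1e-9) & (s.ages <= hi + 1e-9)
    partial = bool(s.ages.min() > lo + 1e-9 or s.ages.max() < hi - 1e-9)
    ns, means, variances = {}, {}, {}
    for season in SEASONS:
        t = s.temperatures[season][mask]
        ns[season] = int(t.size)
        if t.size >= 2:
            means[season] = float(t.mean())
            variances[season] = float(t.var(ddof=1))
        else:
            means[season] = float(t.mean()) if t.size else np.nan
            variances[season] = np.nan
    return WindowVariance(center, ns, means, variances, partial=partial)


def contribution_percent(w: WindowVariance) -> ContributionRecord:
    """cᵢ = 100 · Vi / Σⱼ Vj over the four seasons; a window where every
    season is flat (or undefined) yields a flagged null record."""
    if not w.defined():
        return ContributionRecord(w.center, None, partial=w.partial)
    total = sum(w.variance[k] for k in SEASONS)
    if total <= 0:
        return ContributionRecord(w.center, None, partial=w.partial)
    pct = {k: 100.0 * w.variance[k] / total for k in SEASONS}
    return ContributionRecord(w.center, pct, partial=w.partial)


def sliding_contributions(s: SeasonalSeries, step: float = 100.0,
                          window: float = 1000.0) -> list[ContributionRecord]:
    """Contribution records at every grid center, window sliding by ``step``.

    Edge windows that the series only partially covers still produce a
    record (flagged ``partial``) as long as they hold ≥ 2 grid points.
    """
    if not s.uniform:
        raise ValueError("sliding contributions need a uniform grid "
                         "(use interpolate_uniform first)")
    if s.ages.max() - s.ages.min() < window / 2:
        raise ValueError("series shorter than half a window")
    half = window / 2.0
    centers = np.arange(s.ages.min(), s.ages.max() + step / 2, step)
    out = []
    for c in centers:
        w = window_variance(s, float(c), halfwidth=half)
        if max(w.n.values()) < 2:
            continue
        out.append(contribution_percent(w))
    return out


def contributions_frame(records: list[ContributionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"age_calBP": r.center, "partial": r.partial,
               "defined": r.percent is not None}
        for k in SEASONS:
            row[k] = np.nan if r.percent is None else r.percent[k]
        rows.append(row)
    return pd.DataFrame(rows)


def contribution_histogram(records: list[ContributionRecord],
                           bin_width: float = 10.0) -> pd.DataFrame:
    """Frequency distribution of percentage contributions per season.

    Bins cover [0, 100]; the top edge is inclusive.  Undefined records are
    skipped, so total counts = 4 × number of defined records.
    """
    defined = [r for r in records if r.percent is not None]
    if not defined:
        raise ValueError("no defined contribution records to histogram")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for k in SEASONS:
        vals = np.array([r.percent[k] for r in defined])
        counts, _ = np.histogram(vals, bins=edges)
        out[k] = counts
    return pd.DataFrame(out)


def lowess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.1,
                  n_iter: int = 3) -> np.ndarray:
    """Locally weighted (tricube) linear regression smoother evaluated at
    the input abscissae; ``span`` is the fraction of points per local fit
    and ``n_iter`` the number of robustifying reweights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points to smooth")
    if span * x.size < 2:
        raise ValueError(f"span {span} leaves fewer than 2 points per local fit")
    sm = _sm_lowess(y, x, frac=span, it=n_iter, return_sorted=True)
    # map back onto the original (possibly unsorted) x order
    return np.interp(x, sm[:, 0], sm[:, 1])
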