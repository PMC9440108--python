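"""Transfer-function calibration models and cross-validated reconstruction.

The inverse problem: predict an environmental variable (here a seasonal mean
temperature or MAT) from taxon percentages, calibrated on a modern training
set.  Implemented model family:

* **WA** — weighted averaging: taxon optima are abundance-weighted means of
  the environment; site predictions are abundance-weighted means of the
  optima, corrected by a deshrinking regression (``inverse`` or
  ``classical``).
* **WA-PLS** — weighted-averaging partial least squares: successive
  components re-use the residuals of the previous fit as site scores, so
  later components exploit structure in the residual assemblage signal.
  Component 1 with inverse deshrinking is algebraically identical to WA.
* **MAT** — modern analogue technique: a 1/d-weighted mean of the ``k``
  most similar training sites.
* **LW-WA / LW-WAPLS** — locally-weighted variants that refit the base model
  on each fossil sample's ``m_local`` nearest analogues only.

All deshrinking/standardization regressions are weighted by site abundance
totals, the convention under which the WA ≡ WA-PLS(1) identity is exact; for
percentage input (rows summing to 100) the weights are uniform and this
coincides with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .community import TaxonTable, cross_dissimilarity, pairwise_dissimilarity

__all__ = [
    "MethodSpec",
    "WAModel",
    "WAPLSModel",
    "CrossValStats",
    "ReconstructionSeries",
    "wa_fit",
    "wapls_fit",
    "wapls_predict",
    "mat_predict",
    "lw_predict",
    "bootstrap_validate",
    "select_n_components",
    "reconstruct",
    "SEASON_TARGETS",
]

SEASON_TARGETS = ("T_spring", "T_summer", "T_autumn", "T_winter", "MAT")

ZERO_DIST = 1e-9  # below this an analogue is treated as an exact match


@dataclass(frozen=True)
class MethodSpec:
    """Declarative description of a calibration method and its knobs."""

    method: str = "LW-WAPLS"          # WA | WAPLS | MAT | LW-WA | LW-WAPLS
    n_components: int = 2             # WAPLS family
    deshrinking: str = "inverse"      # inverse | classical
    k: int = 10                       # MAT analogues
    m_local: int | None = None        # LW neighborhood (None -> default rule)
    metric: str = "squared_chord"     # analogue/locality metric
    sqrt_abundance: bool = False      # optional sqrt transform before fitting

    def resolve_m_local(self, n_sites: int) -> int:
        if self.m_local is not None:
            return min(self.m_local, n_sites)
        return min(100, max(2, int(round(0.3 * n_sites))))


def _prep(values: np.ndarray, spec_sqrt: bool) -> np.ndarray:
    return np.sqrt(values) if spec_sqrt else values


# ---------------------------------------------------------------------------
# WA


@dataclass
class WAModel:
    target: str
    taxon_ids: tuple[str, ...]
    optima: np.ndarray
    deshrinking: str
    coef: tuple[float, float]         # (intercept, slope) of the regression
    kept: np.ndarray                  # boolean mask of taxa present in training
    sqrt_abundance: bool = False

    def raw_predict(self, values: np.ndarray) -> np.ndarray:
        y = _prep(np.asarray(values, float), self.sqrt_abundance)[:, self.kept]
        tot = y.sum(axis=1)
        if np.any(tot <= 0):
            raise ValueError("sample with no abundance in training taxa")
        return (y @ self.optima) / tot

    def predict(self, values: np.ndarray) -> np.ndarray:
        x0 = self.raw_predict(values)
        a, b = self.coef
        if self.deshrinking == "inverse":
            return a + b * x0
        return (x0 - a) / b


def _weighted_ls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted simple linear regression y ~ a + b x."""
    w = w / w.sum()
    xm, ym = w @ x, w @ y
    sxx = w @ ((x - xm) ** 2)
    if sxx <= 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
        raise ValueError("degenerate deshrinking: predictions have no spread "
                         "(constant environment across training sites?)")
    b = (w @ ((x - xm) * (y - ym))) / sxx
    return float(ym - b * xm), float(b)


def wa_fit(training: TaxonTable, env_values: np.ndarray, target: str = "env",
           deshrinking: str = "inverse", sqrt_abundance: bool = False) -> WAModel:
    """Weighted-averaging calibration with deshrinking.

    Taxon optimum: û_k = Σᵢ yᵢₖ xᵢ / Σᵢ yᵢₖ.  Initial site prediction:
    x̂ᵢ = Σₖ yᵢₖ ûₖ / Σₖ yᵢₖ.  Inverse deshrinking regresses x on x̂ and
    predicts from that regression; classical regresses x̂ on x and inverts.
    """
    if deshrinking not in ("inverse", "classical"):
        raise ValueError(f"unknown deshrinking {deshrinking!r}")
    x = np.asarray(env_values, dtype=float)
    if x.shape != (training.n_sites,):
        raise ValueError("environment values do not match training sites")
    y = _prep(training.values, sqrt_abundance)
    colsum = y.sum(axis=0)
    kept = colsum > 0
    if not kept.all():
        missing = [training.taxon_ids[j] for j in np.where(~kept)[0]]
        warnings.warn(f"taxa absent from all training sites excluded: "
                      f"{missing[:5]}", stacklevel=2)
    yk = y[:, kept]
    optima = (yk.T @ x) / yk.sum(axis=0)
    tot = yk.sum(axis=1)
    if np.any(tot <= 0):
        raise ValueError("training site with zero total abundance")
    x0 = (yk @ optima) / tot
    w = tot / tot.sum()
    if deshrinking == "inverse":
        coef = _weighted_ls(x0, x, w)
    else:
        coef = _weighted_ls(x, x0, w)
    return WAModel(target, training.taxon_ids, optima, deshrinking, coef,
                   kept, sqrt_abundance)


# ---------------------------------------------------------------------------
# WA-PLS


@dataclass
class WAPLSModel:
    """Fitted WA-PLS model storing, per component, the taxon scores plus the
    orthogonalization/standardization constants needed to reproduce site
    scores for new samples."""

    target: str
    taxon_ids: tuple[str, ...]
    n_components: int
    x_mean: float
    taxon_scores: np.ndarray          # (n_kept_taxa, n_components)
    ortho: np.ndarray                 # (n_components, n_components) lower-tri
    score_mean: np.ndarray
    score_sd: np.ndarray
    beta: np.ndarray
    kept: np.ndarray
    sqrt_abundance: bool = False

    def predict(self, values: np.ndarray, n_components: int | None = None) -> np.ndarray:
        return wapls_predict(self, values, n_components)

    def predict_all_components(self, values: np.ndarray) -> np.ndarray:
        """Predictions for every component count 1..n_components,
        shape (n_samples, n_components)."""
        y = _prep(np.asarray(values, float), self.sqrt_abundance)[:, self.kept]
        tot = y.sum(axis=1)
        if np.any(tot <= 0):
            raise ValueError("sample with no abundance in training taxa")
        n = y.shape[0]
        f = np.empty((n, self.n_components))
        for a in range(self.n_components):
            s = (y @ self.taxon_scores[:, a]) / tot
            for b in range(a):
                s = s - self.ortho[a, b] * f[:, b]
            f[:, a] = (s - self.score_mean[a]) / self.score_sd[a]
        cum = np.cumsum(self.beta[None, :] * f, axis=1)
        return self.x_mean + cum


def wapls_fit(training: TaxonTable, env_values: np.ndarray, n_components: int = 2,
              target: str = "env", sqrt_abundance: bool = False) -> WAPLSModel:
    """Weighted-averaging partial least squares calibration.

    Iterative algorithm: the current environmental residuals serve as site
    scores; taxon scores are their abundance-weighted averages; new site
    scores (weighted averages of taxon scores) are orthogonalized against
    earlier components and standardized (weights = site totals), and the
    environment is regressed on all components so far.  Each component's
    taxon-score vector plus the orthogonalization constants are stored so the
    score construction replays exactly on unseen samples.
    """
    x = np.asarray(env_values, dtype=float)
    if x.shape != (training.n_sites,):
        raise ValueError("environment values do not match training sites")
    y = _prep(training.values, sqrt_abundance)
    kept = y.sum(axis=0) > 0
    if not kept.all():
        missing = [training.taxon_ids[j] for j in np.where(~kept)[0]]
        warnings.warn(f"taxa absent from all training sites excluded: "
                      f"{missing[:5]}", stacklevel=2)
    y = y[:, kept]
    n, m = y.shape
    limit = min(m, n - 1)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}] for "
                         f"{n} sites x {m} taxa, got {n_components}")
    rowsum = y.sum(axis=1)
    if np.any(rowsum <= 0):
        raise ValueError("training site with zero total abundance")
    colsum = y.sum(axis=0)
    w = rowsum / rowsum.sum()
    x_mean = float(w @ x)
    resid = x - x_mean

    taxon_scores = np.empty((m, n_components))
    ortho = np.zeros((n_components, n_components))
    score_mean = np.empty(n_components)
    score_sd = np.empty(n_components)
    beta = np.empty(n_components)
    f = np.empty((n, n_components))
    for a in range(n_components):
        u = (y.T @ resid) / colsum
        s = (y @ u) / rowsum
        for b in range(a):
            ortho[a, b] = float(w @ (s * f[:, b]))
            s = s - ortho[a, b] * f[:, b]
        score_mean[a] = float(w @ s)
        sd = float(np.sqrt(w @ ((s - score_mean[a]) ** 2)))
        if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
            raise ValueError(
                f"WA-PLS component {a + 1} is degenerate (no residual "
                "assemblage signal); reduce n_components")
        score_sd[a] = sd
        f[:, a] = (s - score_mean[a]) / sd
        beta[a] = float(w @ (x * f[:, a]))   # components are w-orthonormal
        taxon_scores[:, a] = u
        fitted = x_mean + f[:, :a + 1] @ beta[:a + 1]
        resid = x - fitted
    return WAPLSModel(target, training.taxon_ids, n_components, x_mean,
                      taxon_scores, ortho, score_mean, score_sd, beta,
                      kept, sqrt_abundance)


def wapls_predict(model: WAPLSModel, values: np.ndarray,
                  n_components: int | None = None) -> np.ndarray:
    """Predict with the first ``n_components`` components (default: all)."""
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    return model.predict_all_components(values)[:, a - 1]


# ---------------------------------------------------------------------------
# MAT


def mat_predict(training: TaxonTable, env_values: np.ndarray,
                samples: np.ndarray, k: int = 10,
                metric: str = "squared_chord") -> tuple[np.ndarray, np.ndarray]:
    """Modern analogue technique prediction.

    Returns ``(predictions, min_dissimilarity)``.  The prediction is the
    1/d-weighted mean of the environment at the ``k`` nearest training sites;
    exact (zero-distance) analogues take over with equal weight.  Ties among
    equidistant analogues break by training-site order, which is stable.
    """
    x = np.asarray(env_values, dtype=float)
    if k < 1 or k > training.n_sites:
        raise ValueError(f"k must be in [1, {training.n_sites}]")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    dummy = TaxonTable(tuple(f"q{i}" for i in range(samples.shape[0])),
                       training.taxon_ids, samples)
    d = cross_dissimilarity(dummy, training, metric=metric)
    preds = np.empty(samples.shape[0])
    dmin = np.empty(samples.shape[0])
    for i, row in enumerate(d):
        nn = np.argsort(row, kind="stable")[:k]
        dn = row[nn]
        dmin[i] = dn[0]
        exact = dn < ZERO_DIST
        if exact.any():
            preds[i] = x[nn[exact]].mean()
        else:
            wgt = 1.0 / dn
            preds[i] = float((wgt * x[nn]).sum() / wgt.sum())
    return preds, dmin


# ---------------------------------------------------------------------------
# locally-weighted fitting


def _fit_global(spec: MethodSpec, training: TaxonTable, x: np.ndarray,
                target: str = "env"):
    if spec.method in ("WA", "LW-WA"):
        return wa_fit(training, x, target=target, deshrinking=spec.deshrinking,
                      sqrt_abundance=spec.sqrt_abundance)
    if spec.method in ("WAPLS", "LW-WAPLS"):
        ncomp = min(spec.n_components,
                    min(int((training.values.sum(axis=0) > 0).sum()),
                        training.n_sites - 1))
        return wapls_fit(training, x, n_components=ncomp, target=target,
                         sqrt_abundance=spec.sqrt_abundance)
    raise ValueError(f"no global fit for method {spec.method!r}")


def lw_predict(training: TaxonTable, env_values: np.ndarray,
               samples: np.ndarray, base: str = "WAPLS",
               m_local: int | None = None, n_components: int = 2,
               metric: str = "squared_chord", deshrinking: str = "inverse",
               sqrt_abundance: bool = False,
               ) -> tuple[np.ndarray, list[tuple[str, ...]], np.ndarray]:
    """Locally-weighted calibration: per sample, refit the base model on its
    ``m_local`` nearest training analogues only.

    Returns ``(predictions, local_site_ids_per_sample, mat_fallback_flags)``.
    Samples whose local subset has fewer than two distinct environment values
    (an untrainable regression) fall back to MAT within the subset and are
    flagged.
    """
    x = np.asarray(env_values, dtype=float)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    spec = MethodSpec(method="LW-" + base, n_components=n_components,
                      deshrinking=deshrinking, metric=metric,
                      m_local=m_local, sqrt_abundance=sqrt_abundance)
    m = spec.resolve_m_local(training.n_sites)
    dummy = TaxonTable(tuple(f"q{i}" for i in range(samples.shape[0])),
                       training.taxon_ids, samples)
    d = cross_dissimilarity(dummy, training, metric=metric)
    preds = np.empty(samples.shape[0])
    prov: list[tuple[str, ...]] = []
    fallback = np.zeros(samples.shape[0], dtype=bool)
    for i, row in enumerate(d):
        nn = np.argsort(row, kind="stable")[:m]
        sub = training.select_sites(nn)
        xs = x[nn]
        prov.append(sub.site_ids)
        if np.unique(xs).size < 2:
            p, _ = mat_predict(sub, xs, samples[i], k=min(spec.k, m),
                               metric=metric)
            preds[i] = p[0]
            fallback[i] = True
            continue
        try:
            model = _fit_global(spec, sub, xs)
            preds[i] = float(model.predict(samples[i][None, :])[0])
        except ValueError:
            p, _ = mat_predict(sub, xs, samples[i], k=min(spec.k, m),
                               metric=metric)
            preds[i] = p[0]
            fallback[i] = True
    return preds, prov, fallback


def _predict_with(spec: MethodSpec, training: TaxonTable, x: np.ndarray,
                  samples: np.ndarray) -> np.ndarray:
    """Dispatch: predict ``samples`` from a training set under ``spec``."""
    if spec.method == "MAT":
        preds, _ = mat_predict(training, x, samples, k=spec.k,
                               metric=spec.metric)
        return preds
    if spec.method.startswith("LW-"):
        preds, _, _ = lw_predict(training, x, samples, base=spec.method[3:],
                                 m_local=spec.m_local,
                                 n_components=spec.n_components,
                                 metric=spec.metric,
                                 deshrinking=spec.deshrinking,
                                 sqrt_abundance=spec.sqrt_abundance)
        return preds
    model = _fit_global(spec, training, x)
    return model.predict(samples)


# ---------------------------------------------------------------------------
# bootstrap validation


@dataclass
class CrossValStats:
    """Bootstrap cross-validation performance of one calibration model.

    ``rmsep`` is the square root of the across-site mean of each site's mean
    squared out-of-bag prediction error; ``r2`` is the squared Pearson
    correlation between observations and mean out-of-bag predictions;
    ``max_bias`` is the largest absolute mean residual across 10 equal-width
    segments of the environmental gradient (it may be smaller than
    ``|avg_bias|`` would suggest since segment means can cancel).
    """

    target: str
    method: str
    rmsep: float
    r2: float
    avg_bias: float
    max_bias: float
    n_boot: int
    predicted: np.ndarray = field(repr=False)
    per_component: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {"target": self.target, "method": self.method,
                "RMSEP": self.rmsep, "R2": self.r2,
                "avg_bias": self.avg_bias, "max_bias": self.max_bias,
                "n_boot": self.n_boot}


def _bias_stats(obs: np.ndarray, pred: np.ndarray,
                n_segments: int = 10) -> tuple[float, float]:
    resid = pred - obs
    avg = float(np.nanmean(resid))
    edges = np.linspace(obs.min(), obs.max(), n_segments + 1)
    seg = np.clip(np.searchsorted(edges, obs, side="right") - 1, 0, n_segments - 1)
    maxb = 0.0
    for s in range(n_segments):
        mask = seg == s
        if mask.any() and np.isfinite(resid[mask]).any():
            maxb = max(maxb, abs(float(np.nanmean(resid[mask]))))
    return avg, maxb


def bootstrap_validate(spec: MethodSpec, training: TaxonTable,
                       env_values: np.ndarray, n_boot: int = 1000,
                       seed: int = 0, target: str = "env",
                       fossil_values: np.ndarray | None = None,
                       ) -> tuple[CrossValStats, np.ndarray | None]:
    """Bootstrap cross-validation (and, optionally, sample-specific errors).

    Each cycle resamples training sites with replacement, fits under
    ``spec``, and predicts the out-of-bag sites.  When ``fossil_values`` is
    given, every cycle also predicts the fossil samples; the returned
    sample-specific error is √(s1² + s2²) with s1 the SD of a sample's
    bootstrap predictions and s2 the RMSEP.
    """
    x = np.asarray(env_values, dtype=float)
    n = training.n_sites
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sums = np.zeros(n)
    sq_sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    is_wapls = spec.method == "WAPLS"
    if is_wapls:
        ncomp = spec.n_components
        c_sums = np.zeros((n, ncomp))
        c_sqs = np.zeros((n, ncomp))
    if fossil_values is not None:
        nf = fossil_values.shape[0]
        f_sums = np.zeros(nf)
        f_sqs = np.zeros(nf)
        f_counts = 0
    for _ in range(n_boot):
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), bag)
        if oob.size == 0:
            continue
        sub = training.select_sites(bag)
        # resampling can empty taxa or flatten env; skip degenerate draws
        try:
            if is_wapls:
                limit = min(int((sub.values.sum(axis=0) > 0).sum()), n - 1)
                model = wapls_fit(sub, x[bag], n_components=min(ncomp, limit),
                                  sqrt_abundance=spec.sqrt_abundance)
                allc = model.predict_all_components(training.values[oob])
                got = allc.shape[1]
                c_sums[oob, :got] += allc
                c_sqs[oob, :got] += allc ** 2
                preds = allc[:, min(ncomp, got) - 1]
                if fossil_values is not None:
                    fp = model.predict_all_components(fossil_values)
                    fp = fp[:, min(ncomp, fp.shape[1]) - 1]
            else:
                preds = _predict_with(spec, sub, x[bag], training.values[oob])
                if fossil_values is not None:
                    fp = _predict_with(spec, sub, x[bag], fossil_values)
        except ValueError:
            continue
        sums[oob] += preds
        sq_sums[oob] += preds ** 2
        counts[oob] += 1
        if fossil_values is not None:
            f_sums += fp
            f_sqs += fp ** 2
            f_counts += 1
    never = counts == 0
    if never.any():
        warnings.warn(f"{int(never.sum())} site(s) never out-of-bag; "
                      "increase n_boot", stacklevel=2)
    cseen = np.maximum(counts, 1)
    mean_pred = np.where(never, np.nan, sums / cseen)
    mse_site = sq_sums / cseen - 2 * x * sums / cseen + x ** 2
    rmsep = float(np.sqrt(np.nanmean(np.where(never, np.nan, mse_site))))
    ok = ~never
    r2 = float(np.corrcoef(x[ok], mean_pred[ok])[0, 1] ** 2) if ok.sum() > 2 else np.nan
    avg_bias, max_bias = _bias_stats(x[ok], mean_pred[ok])
    per_component = None
    if is_wapls:
        rows = []
        for a in range(ncomp):
            mp = np.where(never, np.nan, c_sums[:, a] / cseen)
            mse = c_sqs[:, a] / cseen - 2 * x * c_sums[:, a] / cseen + x ** 2
            rm = float(np.sqrt(np.nanmean(np.where(never, np.nan, mse))))
            rr = (float(np.corrcoef(x[ok], mp[ok])[0, 1] ** 2)
                  if ok.sum() > 2 else np.nan)
            ab, mb = _bias_stats(x[ok], mp[ok])
            rows.append({"n_components": a + 1, "RMSEP": rm, "R2": rr,
                         "avg_bias": ab, "max_bias": mb})
        per_component = pd.DataFrame(rows)
    stats = CrossValStats(target, spec.method, rmsep, r2, avg_bias, max_bias,
                          n_boot, mean_pred, per_component)
    errors = None
    if fossil_values is not None and f_counts > 1:
        mean_f = f_sums / f_counts
        var_f = np.maximum(f_sqs / f_counts - mean_f ** 2, 0.0)
        s1 = np.sqrt(var_f * f_counts / (f_counts - 1))
        errors = np.sqrt(s1 ** 2 + rmsep ** 2)
    return stats, errors


def select_n_components(per_component: pd.DataFrame | Sequence[float],
                        tol: float = 0.05) -> int:
    """Smallest component count whose RMSEP is within ``tol`` (default 5%) of
    the global minimum RMSEP."""
    if isinstance(per_component, pd.DataFrame):
        rmseps = per_component["RMSEP"].to_numpy(dtype=float)
    else:
        rmseps = np.asarray(per_component, dtype=float)
    best = np.nanmin(rmseps)
    for a, r in enumerate(rmseps, start=1):
        if r <= (1.0 + tol) * best:
            return a
    return int(len(rmseps))


# ---------------------------------------------------------------------------
# reconstruction


@dataclass
class ReconstructionSeries:
    """Per-sample reconstructed values (one column per target) with optional
    ±1 SD sample-specific errors."""

    ages: np.ndarray
    predictions: pd.DataFrame
    errors: pd.DataFrame | None = None
    flagged_low_coverage: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.predictions.copy()
        df.insert(0, "age_calBP", self.ages)
        if self.errors is not None:
            for col in self.errors.columns:
                df[f"{col}_sd"] = self.errors[col].to_numpy()
        if self.flagged_low_coverage is not None:
            df["low_taxon_coverage"] = self.flagged_low_coverage
        return df


def reconstruct(spec: MethodSpec, training: TaxonTable, env_values: dict[str, np.ndarray],
                fossil: TaxonTable, with_errors: bool = False,
                n_boot: int = 1000, seed: int = 0) -> ReconstructionSeries:
    """Reconstruct one or more target variables for a fossil sequence.

    Fossil taxa are mapped onto the training taxonomy; unmatched taxa are
    dropped (with a warning) and samples losing more than half their
    abundance that way are flagged.  With ``with_errors`` every target also
    gets a bootstrap sample-specific ±1 SD error column.
    """
    aligned, worst_lost = fossil.align_taxa(training.taxon_ids)
    unmatched = set(fossil.taxon_ids) - set(training.taxon_ids)
    if unmatched:
        warnings.warn(f"{len(unmatched)} fossil taxa not in training set "
                      f"dropped (worst per-sample abundance loss "
                      f"{worst_lost:.0%})", stacklevel=2)
    tot_before = fossil.values.sum(axis=1)
    tot_after = aligned.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lost = np.where(tot_before > 0, 1.0 - tot_after / tot_before, 1.0)
    flagged = lost > 0.5
    if np.any(tot_after <= 0):
        bad = [aligned.site_ids[i] for i in np.where(tot_after <= 0)[0]]
        raise ValueError(f"fossil sample(s) with no training-taxon abundance: "
                         f"{bad[:5]}")
    # re-close to percentages over the shared taxonomy
    samples = aligned.values / tot_after[:, None] * 100.0
    preds: dict[str, np.ndarray] = {}
    errs: dict[str, np.ndarray] = {}
    for i, (target, x) in enumerate(env_values.items()):
        preds[target] = _predict_with(spec, training, np.asarray(x, float), samples)
        if with_errors:
            _, e = bootstrap_validate(spec, training, np.asarray(x, float),
                                      n_boot=n_boot, seed=seed + i,
                                      target=target, fossil_values=samples)
            errs[target] = e if e is not None else np.full(samples.shape[0], np.nan)
    ages = fossil.ages if fossil.ages is not None else np.arange(fossil.n_sites, dtype=float)
    return ReconstructionSeries(
        ages=np.asarray(ages, dtype=float),
        predictions=pd.DataFrame(preds, index=list(fossil.site_ids)),
        errors=pd.DataFrame(errs, index=list(fossil.site_ids)) if with_errors else None,
        flagged_low_coverage=flagged,
        meta={"method": spec.method, "spec": spec, "seed": seed,
              "worst_taxon_loss": worst_lost},
    )
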