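"""Analogue goodness-of-fit and the random-reconstruction significance test.

Two independent checks on whether a fossil sequence can legitimately be
pushed through a modern calibration set:

* **Analogue classification.**  Each fossil sample's minimum dissimilarity
  to the training set is compared with percentiles of the training set's own
  inter-site dissimilarity distribution: below the 5th percentile the sample
  has a *good* analogue, above the 10th percentile it is *no-analogue*, and
  in between it is *fair*.  Thresholds are computed from the training set
  only — fossil data never contaminate the null distribution.

* **Significance test.**  The variance of the (square-root transformed)
  fossil assemblage matrix explained by the real reconstruction — measured
  by single-predictor RDA — is ranked against reconstructions trained on
  random environmental variables drawn over the observed training range.  A
  reconstruction no better at explaining the fossil data than random noise
  carries no environmental signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import MethodSpec, _predict_with
from .community import (
    TaxonTable,
    _pairwise,
    pairwise_dissimilarity,
    sqrt_transform,
    to_percentages,
)
from .ordination import rda_explained_variance

__all__ = [
    "AnalogueClassification",
    "SignificanceResult",
    "analogue_thresholds",
    "classify_analogues",
    "significance_test",
]

GOOD, FAIR, NO_ANALOGUE = "good", "fair", "no-analogue"


@dataclass
class AnalogueClassification:
    sample_ids: tuple[str, ...]
    min_dissimilarity: np.ndarray
    classes: tuple[str, ...]
    q5: float
    q10: float
    metric: str

    def counts(self) -> dict[str, int]:
        out = {GOOD: 0, FAIR: 0, NO_ANALOGUE: 0}
        for c in self.classes:
            out[c] += 1
        return out

    def fraction_good_or_fair(self) -> float:
        c = self.counts()
        return (c[GOOD] + c[FAIR]) / max(len(self.classes), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.sample_ids),
                             "min_dissimilarity": self.min_dissimilarity,
                             "analogue_class": list(self.classes)})


@dataclass
class SignificanceResult:
    target: str
    observed_fraction: float
    random_fractions: np.ndarray
    p_value: float
    proportion_exceeded: float
    n_random: int
    seed: int

    def as_dict(self) -> dict:
        return {"target": self.target,
                "observed_fraction": self.observed_fraction,
                "p_value": self.p_value,
                "proportion_exceeded": self.proportion_exceeded,
                "n_random": self.n_random, "seed": self.seed}


def analogue_thresholds(training_d: np.ndarray) -> tuple[float, float]:
    """5th and 10th percentiles of the training inter-site dissimilarities.

    Accepts a square dissimilarity matrix (its strict upper triangle is
    used) or an already-condensed vector.  Percentiles use the
    linear-interpolation convention (numpy default, R type 7); class
    boundaries depend on this choice, hence it is fixed and documented.
    """
    d = np.asarray(training_d, dtype=float)
    if d.ndim == 2:
        if d.shape[0] < 2:
            raise ValueError("need at least 2 training sites")
        iu = np.triu_indices(d.shape[0], k=1)
        d = d[iu]
    q5, q10 = np.percentile(d, [5.0, 10.0])
    return float(q5), float(q10)


def classify_analogues(fossil: TaxonTable, training: TaxonTable,
                       metric: str = "squared_chord") -> AnalogueClassification:
    """Classify each fossil sample as good / fair / no-analogue.

    Distances below the training 5th percentile are good analogues, above
    the 10th percentile no-analogue, in between fair.  Fossil taxa are
    aligned onto the training taxonomy first; both tables are compared as
    re-closed percentages.
    """
    if np.any(fossil.values.sum(axis=1) <= 0):
        bad = [fossil.site_ids[i]
               for i in np.where(fossil.values.sum(axis=1) <= 0)[0]]
        raise ValueError(f"empty fossil sample(s): {bad[:5]}")
    train_pct = to_percentages(training)
    q5, q10 = analogue_thresholds(pairwise_dissimilarity(train_pct, metric).values)
    aligned, _ = fossil.align_taxa(training.taxon_ids)
    tots = aligned.values.sum(axis=1)
    vals = np.where(tots[:, None] > 0,
                    aligned.values / np.maximum(tots, 1e-300)[:, None] * 100.0,
                    0.0)
    d = _pairwise(vals, train_pct.values, metric)
    # a sample sharing no taxa with the training set sits at the metric
    # maximum; give it +inf min-distance rather than a spurious number
    dmin = np.where(tots > 0, d.min(axis=1), np.inf)
    classes = tuple(GOOD if m < q5 else (NO_ANALOGUE if m > q10 else FAIR)
                    for m in dmin)
    return AnalogueClassification(fossil.site_ids, dmin, classes, q5, q10, metric)


def significance_test(training: TaxonTable, env_values: np.ndarray,
                      fossil: TaxonTable, spec: MethodSpec,
                      n_random: int = 999, seed: int = 0,
                      target: str = "env", null: str = "uniform",
                      ) -> SignificanceResult:
    """Random-reconstruction significance test for one target variable.

    The observed statistic is the fraction of variance of the square-root
    transformed, column-centered fossil percentage matrix explained (RDA) by
    the real reconstruction.  Each of ``n_random`` trials draws a synthetic
    environmental variable — i.i.d. uniform over the observed training range
    (``null="gaussian"`` matches the training mean/SD instead) — trains the
    same method on it and scores its reconstruction the same way.
    p = (1 + #{random ≥ observed}) / (n_random + 1); the complement
    proportion of random reconstructions the observed one strictly exceeds
    is reported alongside.
    """
    if n_random < 99:
        warnings.warn(f"n_random={n_random} gives a coarse p-value resolution",
                      stacklevel=2)
    x = np.asarray(env_values, dtype=float)
    aligned, _ = fossil.align_taxa(training.taxon_ids)
    tots = aligned.values.sum(axis=1)
    if np.any(tots <= 0):
        raise ValueError("fossil sample(s) share no taxa with the training set")
    samples = aligned.values / tots[:, None] * 100.0
    response = sqrt_transform(samples)

    observed_recon = _predict_with(spec, training, x, samples)
    observed = rda_explained_variance(response, observed_recon)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = float(x.min()), float(x.max())
    fractions = np.empty(n_random)
    for t in range(n_random):
        if null == "uniform":
            xr = rng.uniform(lo, hi, size=x.size)
        elif null == "gaussian":
            xr = rng.normal(x.mean(), x.std(), size=x.size)
        else:
            raise ValueError(f"unknown null {null!r}")
        recon = _predict_with(spec, training, xr, samples)
        if np.ptp(recon) <= 1e-12:
            fractions[t] = 0.0
        else:
            fractions[t] = rda_explained_variance(response, recon)
    count = int(np.sum(fractions >= observed - 1e-12))
    p = (1.0 + count) / (n_random + 1.0)
    prop = float(np.sum(fractions < observed)) / n_random
    return SignificanceResult(target, float(observed), fractions, p, prop,
                              n_random, seed)
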