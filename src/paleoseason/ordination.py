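"""Ordination screening of the modern training set.

Covers the exploratory chain used before any transfer function is fitted:
principal coordinates analysis (PCoA) of Bray-Curtis dissimilarities,
detrended-correspondence-analysis (DCA) gradient length to justify unimodal
methods, canonical correspondence analysis (CCA) with variance-inflation
screening, forward selection and Monte Carlo permutation tests, non-metric
multidimensional scaling (NMDS) for fossil-modern overlap, and the
single-predictor redundancy-analysis (RDA) explained-variance fraction used
by the reconstruction significance test.

CA/CCA are implemented directly on the chi-square standardized residual
matrix (the textbook eigen-formulation) because the permutation and
forward-selection machinery needs partial (conditioned) constrained inertia,
which wrapper libraries do not expose.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist
from sklearn.manifold import MDS

from .community import DissimilarityMatrix, EnvTable

__all__ = [
    "OrdinationResult",
    "PermutationTestResult",
    "pcoa",
    "dca_gradient_length",
    "cca",
    "vif_filter",
    "permutation_test",
    "forward_select",
    "nmds",
    "nmds_project",
    "rda_explained_variance",
]


@dataclass
class OrdinationResult:
    method: str
    site_scores: np.ndarray
    eigenvalues: np.ndarray | None = None
    taxon_scores: np.ndarray | None = None
    variable_scores: np.ndarray | None = None
    explained_fraction: float | None = None
    stress: float | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)


@dataclass
class PermutationTestResult:
    variable: str
    statistic: float
    n_perm: int
    p_value: float
    mode: str = "single"


# ---------------------------------------------------------------------------
# PCoA


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest additive constant making the distances Euclidean-embeddable
    n = d.shape[0]
    d1 = _double_center(d ** 2)
    d2 = _double_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(ev.real))


def pcoa(d: DissimilarityMatrix, n_axes: int | None = None,
         negative_correction: str = "cailliez") -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigen-decomposition of the double-centered squared-distance matrix.
    Non-Euclidean inputs (Bray-Curtis typically is) produce negative
    eigenvalues; when any falls below ``-1e-8 * max``, the Cailliez additive
    constant is applied before decomposing, so that all axes are real.
    """
    dm = d.values
    n = dm.shape[0]
    b = _double_center(dm ** 2)
    eigval, eigvec = np.linalg.eigh(b)
    correction = 0.0
    if negative_correction == "cailliez" and eigval.size and \
            eigval.min() < -1e-8 * max(eigval.max(), 1e-300):
        correction = _cailliez_constant(dm)
        dmc = dm + correction
        np.fill_diagonal(dmc, 0.0)
        b = _double_center(dmc ** 2)
        eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    n_pos = int(np.sum(eigval > max(eigval.max(initial=0.0), 1.0) * 1e-12))
    if n_pos == 0:  # all sites coincide
        k = n_axes or 1
        return OrdinationResult("PCoA", np.zeros((n, k)), eigenvalues=np.zeros(k),
                                extras={"correction": correction})
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive PCoA axes available; truncating "
                      f"from {n_axes}", stacklevel=2)
        n_axes = n_pos
    scores = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    return OrdinationResult("PCoA", scores, eigenvalues=eigval[:n_axes],
                            extras={"correction": correction,
                                    "all_eigenvalues": eigval})


# ---------------------------------------------------------------------------
# correspondence analysis core


def _ca_residuals(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square standardized residual matrix Q̄ plus row/column masses."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative abundances")
    tot = y.sum()
    if tot <= 0:
        raise ValueError("empty abundance matrix")
    p = y / tot
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("empty rows/columns must be removed before CA")
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return q, r, c


def ca(y: np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Plain correspondence analysis (reciprocal averaging)."""
    q, r, c = _ca_residuals(y)
    u, s, vt = np.linalg.svd(q, full_matrices=False)
    keep = s > 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    if n_axes is not None:
        u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    site = (u * s) / np.sqrt(r)[:, None]            # principal coordinates
    taxon = vt.T / np.sqrt(c)[:, None]              # standard coordinates
    total = float((q ** 2).sum())
    return OrdinationResult("CA", site, eigenvalues=s ** 2, taxon_scores=taxon,
                            explained_fraction=float((s ** 2).sum() / total),
                            extras={"total_inertia": total, "row_mass": r,
                                    "col_mass": c})


def _weighted_design(env_values: np.ndarray, r: np.ndarray,
                     names: tuple[str, ...]) -> np.ndarray:
    """Row-mass weighted, centered design matrix in sqrt-weight space."""
    x = np.asarray(env_values, dtype=float)
    mean = r @ x
    xc = x - mean
    xw = np.sqrt(r)[:, None] * xc
    rank = np.linalg.matrix_rank(xw, tol=1e-10 * max(1.0, np.abs(xw).max()))
    if rank < xw.shape[1]:
        # name the first variable linearly dependent on its predecessors
        for j in range(1, xw.shape[1] + 1):
            if np.linalg.matrix_rank(xw[:, :j]) < j:
                raise ValueError(
                    f"predictor {names[j - 1]!r} is collinear to singularity "
                    "with the preceding variables")
    return xw


def _constrained_inertia(q: np.ndarray, xw: np.ndarray,
                         zw: np.ndarray | None = None) -> tuple[float, np.ndarray,
                                                                np.ndarray, np.ndarray]:
    """Inertia of Q̄ projected onto span(xw), optionally partialling out zw."""
    if zw is not None and zw.shape[1] > 0:
        hz, *_ = np.linalg.lstsq(zw, q, rcond=None)
        q = q - zw @ hz
        hx, *_ = np.linalg.lstsq(zw, xw, rcond=None)
        xw = xw - zw @ hx
    beta, *_ = np.linalg.lstsq(xw, q, rcond=None)
    qfit = xw @ beta
    u, s, vt = np.linalg.svd(qfit, full_matrices=False)
    keep = s > 1e-12
    return float((s[keep] ** 2).sum()), u[:, keep], s[keep], vt[keep]


def cca(y: np.ndarray, env: EnvTable, variables: list[str] | None = None,
        n_axes: int | None = None) -> OrdinationResult:
    """Canonical correspondence analysis.

    Constrained eigenvalues come from the SVD of the chi-square residual
    matrix projected onto the row-mass-weighted span of the predictors; the
    explained-variance fraction is their sum over the total CA inertia.
    """
    variables = list(variables if variables is not None else env.variables)
    q, r, c = _ca_residuals(y)
    sub = env.subset(variables)
    xw = _weighted_design(sub.values, r, tuple(variables))
    inertia, u, s, vt = _constrained_inertia(q, xw)
    if n_axes is not None:
        u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    site = (u * s) / np.sqrt(r)[:, None]
    taxon = vt.T / np.sqrt(c)[:, None]
    # biplot arrows: weighted correlation of each predictor with the LC axes
    lc = u  # orthonormal in sqrt-weight space
    xn = xw / np.linalg.norm(xw, axis=0, keepdims=True)
    arrows = xn.T @ lc
    total = float((q ** 2).sum())
    return OrdinationResult("CCA", site, eigenvalues=s ** 2, taxon_scores=taxon,
                            variable_scores=arrows,
                            explained_fraction=inertia / total,
                            extras={"total_inertia": total,
                                    "constrained_inertia": inertia,
                                    "variables": variables})


# ---------------------------------------------------------------------------
# DCA gradient length


def dca_gradient_length(y: np.ndarray, n_rescale_iter: int = 4) -> float:
    """Axis-1 compositional gradient length in standard-deviation (SD) units.

    First CA axis followed by nonlinear rescaling in the spirit of
    detrending-by-segments DCA: taxon scores (abundance-weighted means of
    site scores, expanded to undo the weighted-averaging shrinkage) spread
    around each site's score by the local taxon turnover SD, and the axis is
    stretched piecewise until that SD is one unit everywhere; the length is
    the range of the rescaled site scores.  Detrending proper only affects
    axes 2+, so it is not needed for the length of axis 1.  A length beyond
    ~2 SD is the conventional threshold for preferring unimodal (CA/CCA)
    over linear ordination methods.
    """
    y = np.asarray(y, dtype=float)
    keep_r = y.sum(axis=1) > 0
    keep_c = y.sum(axis=0) > 0
    y = y[np.ix_(keep_r, keep_c)]
    if y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("gradient length needs at least 2 sites and 2 taxa")
    q, r, c = _ca_residuals(y)
    u, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[0] <= 1e-10:  # no compositional variation
        return 0.0
    x = (u[:, 0] * s[0]) / np.sqrt(r)

    tot_i = y.sum(axis=1)
    w_i = tot_i / tot_i.sum()
    for _ in range(n_rescale_iter):
        taxon = (y.T @ x) / y.sum(axis=0)
        # undo the WA shrinkage of taxon scores: rescale them so that their
        # weighted averages reproduce the site scores with unit slope
        shrunk = (y @ taxon) / tot_i
        zc = shrunk - w_i @ shrunk
        xc = x - w_i @ x
        szz = w_i @ (zc ** 2)
        if szz > 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
            slope = (w_i @ (zc * xc)) / szz
            if slope > 0:
                taxon = taxon * slope
        disp = (y * (taxon[None, :] - x[:, None]) ** 2).sum(axis=1) / tot_i
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            return 0.0
        sigma = float(np.sqrt(w_i @ disp))
        if sigma <= 1e-9 * (hi - lo):
            # every site is effectively monospecific: turnover is complete
            # between sites and the SD length is unbounded
            return float("inf")
        x = x / sigma
    return float(x.max() - x.min())


# ---------------------------------------------------------------------------
# VIF screening


def variance_inflation_factors(env: EnvTable, variables: list[str]) -> dict[str, float]:
    x = env.subset(variables).values
    x = x - x.mean(axis=0)
    out: dict[str, float] = {}
    for j, name in enumerate(variables):
        others = np.delete(x, j, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        a = np.column_stack([np.ones(x.shape[0]), others])
        coef, *_ = np.linalg.lstsq(a, x[:, j], rcond=None)
        resid = x[:, j] - a @ coef
        tss = float((x[:, j] ** 2).sum())
        rss = float((resid ** 2).sum())
        if tss <= 0:
            out[name] = np.inf
        else:
            r2 = 1.0 - rss / tss
            out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(env: EnvTable, candidates: list[str] | None = None,
               threshold: float = 20.0) -> list[str]:
    """Iteratively drop the highest-VIF variable until all VIFs ≤ threshold.

    Deterministic: ties are broken by original candidate order.  Warns if
    fewer than two variables survive.
    """
    selected = list(candidates if candidates is not None else env.variables)
    while len(selected) >= 2:
        vifs = variance_inflation_factors(env, selected)
        worst = max(selected, key=lambda v: (vifs[v], -selected.index(v)))
        if vifs[worst] <= threshold:
            break
        selected.remove(worst)
    if len(selected) < 2:
        warnings.warn("fewer than 2 variables survive VIF screening", stacklevel=2)
    return selected


# ---------------------------------------------------------------------------
# permutation tests and forward selection


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def permutation_test(y: np.ndarray, env: EnvTable, variable: str,
                     n_perm: int = 999, seed: int = 0, mode: str = "single",
                     conditioning: list[str] | None = None) -> PermutationTestResult:
    """Monte Carlo permutation test of one constraining variable.

    ``single`` permutes the variable's values against the assemblages and
    uses its constrained inertia as the statistic.  ``forward-conditional``
    tests the variable's *additional* inertia given already-selected
    conditioning variables, permuting its residuals after regressing on them
    (reduced-model permutation).  p = (1 + #{perm ≥ obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution",
                      stacklevel=2)
    q, r, c = _ca_residuals(y)
    v = env[variable].astype(float)
    if mode == "single" or not conditioning:
        xw = _weighted_design(v[:, None], r, (variable,))
        obs, *_ = _constrained_inertia(q, xw)
        rng = _child_rng(seed, zlib.crc32(variable.encode()))
        count = 0
        for _ in range(n_perm):
            vp = v[rng.permutation(v.size)]
            xwp = np.sqrt(r)[:, None] * (vp - r @ vp)[:, None]
            stat, *_ = _constrained_inertia(q, xwp)
            if stat >= obs - 1e-12:
                count += 1
    elif mode == "forward-conditional":
        zw = _weighted_design(env.subset(conditioning).values, r,
                              tuple(conditioning))
        xw = _weighted_design(v[:, None], r, (variable,))
        obs, *_ = _constrained_inertia(q, xw, zw=zw)
        # reduced model: permute the candidate's residuals given conditioning
        beta, *_ = np.linalg.lstsq(zw, xw, rcond=None)
        fitted = zw @ beta
        resid = xw - fitted
        rng = _child_rng(seed, zlib.crc32(variable.encode()))
        count = 0
        for _ in range(n_perm):
            xwp = fitted + resid[rng.permutation(resid.shape[0])]
            stat, *_ = _constrained_inertia(q, xwp, zw=zw)
            if stat >= obs - 1e-12:
                count += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = (1.0 + count) / (n_perm + 1.0)
    return PermutationTestResult(variable, obs, n_perm, p, mode=mode)


def forward_select(y: np.ndarray, env: EnvTable, candidates: list[str],
                   alpha: float = 0.05, n_perm: int = 999,
                   seed: int = 0) -> list[tuple[str, float, float]]:
    """Greedy forward selection of constraining variables.

    At each step the candidate adding the most constrained inertia
    (conditional on the current selection) is tested by reduced-model
    permutation; it enters if its p-value ≤ alpha, otherwise selection stops.
    Returns ``(variable, added_inertia, p_value)`` in selection order.
    """
    q, r, c = _ca_residuals(y)
    selected: list[str] = []
    results: list[tuple[str, float, float]] = []
    remaining = list(candidates)
    while remaining:
        gains = []
        zw = (_weighted_design(env.subset(selected).values, r, tuple(selected))
              if selected else None)
        for name in remaining:
            xw = _weighted_design(env[name][:, None], r, (name,))
            gain, *_ = _constrained_inertia(q, xw, zw=zw)
            gains.append(gain)
        best = int(np.argmax(gains))
        name = remaining[best]
        test = permutation_test(y, env, name, n_perm=n_perm, seed=seed,
                                mode="forward-conditional" if selected else "single",
                                conditioning=selected or None)
        if test.p_value > alpha:
            break
        selected.append(name)
        results.append((name, float(gains[best]), test.p_value))
        remaining.pop(best)
    return results


# ---------------------------------------------------------------------------
# NMDS


def nmds(d: DissimilarityMatrix, k: int = 2, n_starts: int = 50,
         seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric multidimensional scaling (Kruskal stress-1, best of
    ``n_starts`` random starts)."""
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_starts, max_iter=max_iter, eps=1e-6, init="random",
                random_state=np.random.RandomState(seed),
                normalized_stress=True)
    coords = model.fit_transform(d.values)
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("NMDS did not converge in any start; returning best "
                      "configuration found", stacklevel=2)
    # least-squares scale mapping input dissimilarities onto configuration
    # distances (the configuration's overall scale is arbitrary); needed to
    # place new points passively on the same footing
    conf_d = cdist(coords, coords)
    iu = np.triu_indices(coords.shape[0], k=1)
    denom = float((d.values[iu] ** 2).sum())
    scale = float((conf_d[iu] * d.values[iu]).sum() / denom) if denom > 0 else 1.0
    return OrdinationResult("NMDS", coords, stress=float(model.stress_),
                            converged=converged,
                            extras={"k": k, "dissimilarity_scale": scale})


def nmds_project(result: OrdinationResult, cross_d: np.ndarray) -> np.ndarray:
    """Passively place new (fossil) points into a fitted NMDS configuration.

    Each new point is positioned by least-squares matching of its configuration
    distances to its observed dissimilarities against the fixed modern points;
    the modern configuration is never altered.  Starts from the position of
    the nearest modern point.
    """
    conf = result.site_scores
    scale = result.extras.get("dissimilarity_scale", 1.0)
    out = np.empty((cross_d.shape[0], conf.shape[1]))
    for i, delta in enumerate(cross_d * scale):
        start = conf[int(np.argmin(delta))]

        def loss(z, delta=delta):
            dist = np.sqrt(((conf - z) ** 2).sum(axis=1))
            return float(((dist - delta) ** 2).sum())

        res = optimize.minimize(loss, start, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        out[i] = res.x
    return out


# ---------------------------------------------------------------------------
# RDA explained variance


def rda_explained_variance(response: np.ndarray, predictor: np.ndarray) -> float:
    """Fraction of total (column-centered) response variance captured by a
    single-predictor redundancy analysis — i.e. by least-squares regression
    of every response column on the predictor."""
    y = np.asarray(response, dtype=float)
    y = y - y.mean(axis=0)
    x = np.asarray(predictor, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("predictor length does not match response rows")
    xc = x - x.mean()
    ss_x = float((xc ** 2).sum())
    if ss_x <= 1e-300 * max(1.0, float(np.abs(x).max()) ** 2):
        raise ValueError("constant predictor has no explanatory power")
    beta = (xc @ y) / ss_x
    fitted = np.outer(xc, beta)
    total = float((y ** 2).sum())
    if total == 0:
        return 0.0
    return float((fitted ** 2).sum() / total)
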