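"""Synthetic modern training sets, temperature histories and fossil sequences.

Every stage of the pipeline is exercised on data whose generative truth is
known, emulating the statistical structure the analysis assumes for a
mid-latitude East Asian mollusk dataset:

* a modern training set of 382 surface-soil sites spanning wide seasonal
  temperature gradients (winter means −23 … 5.9 °C, summer 10.9 … 27.9 °C)
  with strong inter-season correlation (default 0.8),
* taxa with unimodal (Gaussian) responses to one designated driver season
  plus a weaker mean-annual-temperature term — enough niche structure for a
  compositional gradient several SD long,
* multinomial counting noise at a fixed count depth per sample,
* a piecewise-smooth 20 kyr temperature history: cold glacial state,
  deglacial warming ramp, an early-to-mid-Holocene thermal maximum plateau
  (9–4 ka) and late-Holocene cooling, with per-season amplitudes (winter
  largest at 5.5 °C, then summer, spring, autumn) plus AR(1) noise,
* fossil sequences sampled from that history at ~250 yr resolution.

All generators are deterministic under a fixed seed and expose their full
generative truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .community import EnvTable, TaxonTable
from .attribution import SEASONS

__all__ = [
    "SimConfig",
    "SpeciesResponse",
    "HistoryParams",
    "TemperatureHistory",
    "make_species_responses",
    "expected_composition",
    "simulate_training_set",
    "simulate_temperature_history",
    "simulate_fossil_sequence",
    "inject_no_analogue",
]

#: per-season training gradient ranges (°C); winter and summer follow the
#: coldest/warmest seasonal spans of the modern survey region, spring and
#: autumn sit in between.
DEFAULT_SEASON_RANGES: dict[str, tuple[float, float]] = {
    "T_spring": (-6.0, 20.0),
    "T_summer": (10.9, 27.9),
    "T_autumn": (-4.0, 21.0),
    "T_winter": (-23.0, 5.9),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic modern survey."""

    n_sites: int = 382
    n_species: int = 40
    count_depth: int = 500                  # individuals counted per sample
    inter_season_corr: float = 0.8
    season_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_RANGES))
    fossil_resolution: float = 250.0        # yr per fossil sample
    max_site_retries: int = 50

    def __post_init__(self) -> None:
        if self.count_depth < 50:
            raise ValueError("count depth below 50 gives unusably noisy "
                             "percentages")
        c = self.inter_season_corr
        corr = np.full((4, 4), c)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("inter-season correlation matrix not PSD")


@dataclass(frozen=True)
class SpeciesResponse:
    """Gaussian niche of one taxon: unimodal response on a designated driver
    season, multiplied by a broader Gaussian term on MAT."""

    species_id: str
    driver: str                  # one of SEASONS
    optimum: float               # °C on the driver gradient
    tolerance: float             # °C, > 0
    peak: float                  # maximal expected relative abundance weight
    mat_optimum: float
    mat_tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.mat_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.peak <= 0:
            raise ValueError("peak abundance must be positive")


def make_species_responses(cfg: SimConfig, seed: int = 0) -> list[SpeciesResponse]:
    """Draw a species pool: optima spread over each driver gradient,
    tolerances ~1/8 of the gradient span (so the survey's compositional
    gradient exceeds 5 SD, as in long modern training sets), lognormal peak
    abundances."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    mat_lo = np.mean([r[0] for r in cfg.season_ranges.values()])
    mat_hi = np.mean([r[1] for r in cfg.season_ranges.values()])
    per_driver = {s: 0 for s in SEASONS}
    n_per = int(np.ceil(cfg.n_species / len(SEASONS)))
    out = []
    for i in range(cfg.n_species):
        driver = SEASONS[i % len(SEASONS)]
        lo, hi = cfg.season_ranges[driver]
        span = hi - lo
        # species packing: optima regularly spaced along the driver gradient
        # (with jitter) so no part of the gradient is left uncovered
        j = per_driver[driver]
        per_driver[driver] += 1
        slot = lo - 0.1 * span + (j + 0.5) / n_per * 1.2 * span
        opt = slot + rng.normal(0.0, 0.03 * span)
        tol = rng.uniform(0.07, 0.13) * span
        peak = float(rng.lognormal(0.0, 0.5))
        mat_opt = rng.uniform(mat_lo, mat_hi)
        mat_tol = rng.uniform(0.8, 1.5) * (mat_hi - mat_lo)
        out.append(SpeciesResponse(f"sp{i:03d}", driver, float(opt), float(tol),
                                   peak, float(mat_opt), float(mat_tol)))
    return out


def expected_composition(responses: list[SpeciesResponse],
                         temps: dict[str, float]) -> np.ndarray:
    """Expected relative abundances (summing to 1) at one site, given its
    per-season temperatures; MAT is their arithmetic mean."""
    mat = float(np.mean([temps[s] for s in SEASONS]))
    w = np.array([
        r.peak
        * np.exp(-0.5 * ((temps[r.driver] - r.optimum) / r.tolerance) ** 2)
        * np.exp(-0.5 * ((mat - r.mat_optimum) / r.mat_tolerance) ** 2)
        for r in responses])
    tot = w.sum()
    return w / tot if tot > 0 else w


def _draw_site_env(cfg: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    # Gaussian copula: correlated normals mapped to uniforms over each range
    c = cfg.inter_season_corr
    corr = np.full((4, 4), c)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(4), corr, method="cholesky")
    u = norm.cdf(z)
    return {s: cfg.season_ranges[s][0]
            + u[i] * (cfg.season_ranges[s][1] - cfg.season_ranges[s][0])
            for i, s in enumerate(SEASONS)}


def simulate_training_set(cfg: SimConfig, responses: list[SpeciesResponse] | None = None,
                          seed: int = 0) -> tuple[TaxonTable, EnvTable]:
    """Generate a modern site-by-taxon counts table with its environment.

    Site climates are drawn with the configured inter-season correlation;
    counts are multinomial at the configured depth around the Gaussian-niche
    expected composition.  Sites where every taxon's expected abundance is
    essentially zero are redrawn (bounded retries).  The environment table
    carries the four seasonal means, their arithmetic mean (MAT) and a
    precipitation-like nuisance variable (MAP) correlated with summer
    temperature.
    """
    if responses is None:
        responses = make_species_responses(cfg, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    counts = np.zeros((cfg.n_sites, cfg.n_species))
    env_rows = []
    for i in range(cfg.n_sites):
        for _ in range(cfg.max_site_retries):
            temps = _draw_site_env(cfg, rng)
            p = expected_composition(responses, temps)
            if p.sum() > 0 and p.max() > 1e-12:
                break
        else:
            raise RuntimeError("could not draw a viable site climate")
        counts[i] = rng.multinomial(cfg.count_depth, p)
        mat = float(np.mean([temps[s] for s in SEASONS]))
        mapv = 180.0 + 22.0 * (temps["T_summer"] - 19.4) + rng.normal(0.0, 60.0)
        env_rows.append([temps[s] for s in SEASONS] + [mat, max(mapv, 5.0)])
    site_ids = tuple(f"site{i:03d}" for i in range(cfg.n_sites))
    taxa = TaxonTable(site_ids, tuple(r.species_id for r in responses), counts,
                      kind="counts", meta={"seed": seed, "count_depth": cfg.count_depth})
    env = EnvTable(site_ids, tuple(SEASONS) + ("MAT", "MAP"),
                   np.asarray(env_rows))
    return taxa, env


# ---------------------------------------------------------------------------
# temperature history


@dataclass(frozen=True)
class HistoryParams:
    """Shape of the 20 kyr per-season temperature history.

    The common shape is 0 during the glacial, ramps to 1 over the
    deglaciation, stays 1 across the Holocene thermal maximum plateau and
    declines linearly to ``1 − late_cooling_frac`` by the present.  Each
    season scales it by its own amplitude above a glacial base level.
    """

    age_max: float = 20000.0
    glacial_end: float = 17000.0        # cal yr BP: deglacial ramp starts
    plateau_start: float = 9000.0       # HTM plateau (9–4 ka by default)
    plateau_end: float = 4000.0
    late_cooling_frac: float = 0.35     # fraction of the amplitude lost by 0 ka
    dt: float = 100.0
    base: dict[str, float] = field(default_factory=lambda: {
        "T_spring": 1.5, "T_summer": 16.0, "T_autumn": 4.5, "T_winter": -13.0})
    amplitude: dict[str, float] = field(default_factory=lambda: {
        "T_spring": 2.75, "T_summer": 4.0, "T_autumn": 2.0, "T_winter": 5.5})
    #: millennial-scale AR(1) variability, as a fraction of each season's
    #: deglacial amplitude: seasons with the largest orbital-scale change
    #: also fluctuate hardest at sub-orbital scales, so window variances
    #: rank like the amplitudes
    noise_sd_frac: float = 0.3
    noise_phi: float = 0.7

    def noise_sd(self, season: str) -> float:
        return self.noise_sd_frac * self.amplitude[season]

    def __post_init__(self) -> None:
        if not (self.age_max >= self.glacial_end > self.plateau_start
                > self.plateau_end >= 0.0):
            raise ValueError("history intervals must satisfy age_max ≥ "
                             "glacial_end > plateau_start > plateau_end ≥ 0")
        if not 0.0 <= self.late_cooling_frac <= 1.0:
            raise ValueError("late_cooling_frac must be in [0, 1]")

    def shape(self, ages: np.ndarray) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        s = np.empty_like(a)
        s[a >= self.glacial_end] = 0.0
        ramp = (a < self.glacial_end) & (a >= self.plateau_start)
        s[ramp] = (self.glacial_end - a[ramp]) / (self.glacial_end - self.plateau_start)
        s[(a < self.plateau_start) & (a >= self.plateau_end)] = 1.0
        late = a < self.plateau_end
        s[late] = 1.0 - self.late_cooling_frac * (self.plateau_end - a[late]) / self.plateau_end
        return s


@dataclass(frozen=True)
class TemperatureHistory:
    """True per-season temperature curves on a dense age grid."""

    ages: np.ndarray                      # ascending, cal yr BP
    temperatures: dict[str, np.ndarray]
    params: HistoryParams
    seed: int

    def at(self, ages: np.ndarray) -> dict[str, np.ndarray]:
        a = np.asarray(ages, dtype=float)
        return {s: np.interp(a, self.ages, v)
                for s, v in self.temperatures.items()}

    def mat(self) -> np.ndarray:
        return np.mean([self.temperatures[s] for s in SEASONS], axis=0)


def simulate_temperature_history(params: HistoryParams | None = None,
                                 seed: int = 0) -> TemperatureHistory:
    """Piecewise-smooth per-season truth curves plus AR(1) noise.

    Winter stays colder than summer at every age (the amplitude and base
    defaults guarantee a wide margin against the noise)."""
    params = params or HistoryParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    ages = np.arange(0.0, params.age_max + params.dt / 2, params.dt)
    shape = params.shape(ages)
    temps = {}
    for season in SEASONS:
        sd = params.noise_sd(season)
        sd_innov = sd * np.sqrt(1.0 - params.noise_phi ** 2)
        noise = np.empty(ages.size)
        noise[0] = rng.normal(0.0, sd)
        for t in range(1, ages.size):
            noise[t] = params.noise_phi * noise[t - 1] + rng.normal(0.0, sd_innov)
        temps[season] = params.base[season] + params.amplitude[season] * shape + noise
    if np.any(temps["T_winter"] >= temps["T_summer"]):
        raise RuntimeError("generated history violates winter < summer")
    return TemperatureHistory(ages, temps, params, seed)


def simulate_fossil_sequence(history: TemperatureHistory,
                             responses: list[SpeciesResponse],
                             resolution: float = 250.0, count_depth: int = 500,
                             seed: int = 0,
                             ) -> tuple[TaxonTable, dict[str, np.ndarray]]:
    """Sample a fossil sequence from the true history.

    Samples sit every ``resolution`` years from the youngest to the oldest
    grid age (inclusive); assemblages are multinomial draws around the niche
    model evaluated at the true seasonal temperatures.  Returns the fossil
    counts table (ages ascending, youngest first) and the truth — the per-
    sample true seasonal temperatures plus MAT — for recovery tests.
    """
    if resolution < history.params.dt:
        raise ValueError("resolution below the history grid spacing")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    ages = np.arange(history.ages.min(), history.ages.max() + resolution / 2,
                     resolution)
    truth = history.at(ages)
    counts = np.zeros((ages.size, len(responses)))
    for i in range(ages.size):
        temps = {s: float(truth[s][i]) for s in SEASONS}
        p = expected_composition(responses, temps)
        counts[i] = rng.multinomial(count_depth, p)
    site_ids = tuple(f"fos{i:03d}" for i in range(ages.size))
    table = TaxonTable(site_ids, tuple(r.species_id for r in responses),
                       counts, kind="counts", ages=ages,
                       meta={"seed": seed, "resolution": resolution,
                             "count_depth": count_depth})
    truth["MAT"] = np.mean([truth[s] for s in SEASONS], axis=0)
    return table, truth


def inject_no_analogue(fossil: TaxonTable, fraction: float,
                       mode: str = "novel_taxon", seed: int = 0,
                       ) -> tuple[TaxonTable, list[str]]:
    """Replace a fraction of fossil samples with compositions outside the
    modern training cloud.

    ``novel_taxon`` concentrates the sample into a taxon the training set
    has never seen (appended column); ``extreme_mixture`` puts all abundance
    on the sample's two rarest taxa.  Returns the altered table and the
    manifest of altered sample ids.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    n_alter = int(round(fraction * fossil.n_sites))
    chosen = np.sort(rng.choice(fossil.n_sites, size=n_alter, replace=False))
    totals = fossil.values.sum(axis=1)
    if mode == "novel_taxon":
        vals = np.hstack([fossil.values, np.zeros((fossil.n_sites, 1))])
        for i in chosen:
            vals[i] = 0.0
            vals[i, -1] = max(totals[i], 1.0)
        taxa = fossil.taxon_ids + ("novel_taxon",)
    elif mode == "extreme_mixture":
        vals = fossil.values.copy()
        rarity = np.argsort(fossil.values.sum(axis=0), kind="stable")
        for i in chosen:
            vals[i] = 0.0
            vals[i, rarity[0]] = 0.6 * max(totals[i], 1.0)
            vals[i, rarity[1]] = 0.4 * max(totals[i], 1.0)
        taxa = fossil.taxon_ids
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = TaxonTable(fossil.site_ids, taxa, vals, kind=fossil.kind,
                       ages=fossil.ages,
                       meta={**fossil.meta, "injected_mode": mode})
    return table, [fossil.site_ids[i] for i in chosen]
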