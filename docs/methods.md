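# Methods

`paleoseason` implements the quantitative chain that turns modern mollusk
(land-snail) assemblage surveys into seasonal-temperature reconstructions
for fossil loess-palaeosol sequences, and then attributes the variability of
mean annual temperature (MAT) to the four seasons. This note documents the
models, the defaults and why they are set where they are, what the synthetic
data emulate, and the numerical conventions that matter for reproducing any
number the package prints.

## The inverse model

A transfer function predicts an environmental variable x (a seasonal mean
temperature in °C, or MAT) from a vector of taxon percentages y, calibrated
on a modern training set of sites where both are observed. All methods here
assume taxa respond unimodally to temperature, which is checked before
calibration via the DCA gradient length (> 2 SD of compositional turnover ⇒
unimodal methods appropriate; the default synthetic survey sits near 5 SD).

**Weighted averaging (WA).** Taxon optima are abundance-weighted means of
the environment, û_k = Σᵢ yᵢₖ xᵢ / Σᵢ yᵢₖ; the raw site estimate is the
abundance-weighted mean of the optima. Because averaging twice compresses
the variance, a deshrinking regression follows: *inverse* regresses x on x̂
(default), *classical* regresses x̂ on x and inverts. Deshrinking (and every
other WA/WA-PLS regression) is weighted by site abundance totals; for
percentage input the weights are uniform, so this coincides with ordinary
least squares, and it makes the identity below exact for any input.

**WA-PLS.** Partial-least-squares extension: component a uses the residuals
of the previous fit as site scores, computes taxon scores as their weighted
averages, orthogonalizes and standardizes the resulting site scores against
earlier components (weights = site totals), and regresses x on all
components so far. Component 1 with inverse deshrinking is algebraically
identical to WA — the package tests this to 1e-10. The number of components
is selected as the smallest count whose cross-validated RMSEP is within 5%
of the minimum; default 2.

**MAT (modern analogue technique).** Prediction is the 1/d-weighted mean of
the environment at the k (default 10) most dissimilar-distance-nearest
training sites; an exact (zero-distance) analogue takes over with equal
weight. Ties among equidistant analogues break by training-site order.

**LW-WA / LW-WAPLS.** Locally-weighted variants refit the base model, per
fossil sample, on its m_local nearest training analogues only (default
min(100, 30% of the training set)); the local subset ids are recorded per
sample. A local subset with fewer than two distinct environment values
cannot support a regression, so the sample falls back to MAT and is flagged.

The analogue/locality metric defaults to squared-chord distance,
Σ(√xᵢ−√yᵢ)², the standard choice for percentage data; Bray-Curtis,
Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), is used for the PCoA/NMDS ordinations and available
everywhere by configuration. Calibration consumes raw percentages; the
square-root transform is applied for ordination (and optionally, behind a
flag, for calibration).

## Validation and errors

Performance is assessed by bootstrap cross-validation (default n_boot =
1000; pipeline and acceptance runs use 100, which stabilizes RMSEP to a few
percent at these problem sizes). Each cycle resamples sites with
replacement, fits, and predicts the out-of-bag sites. RMSEP is the square
root of the across-site mean of per-site mean squared out-of-bag error; R²
is between observations and mean out-of-bag predictions; average bias is the
mean residual; maximum bias is the largest absolute mean residual over 10
equal-width segments of the environmental gradient (it can be smaller than
|avg bias| since segment means cancel differently). Sample-specific
reconstruction errors are √(s1² + s2²), s1 = SD of a fossil sample's
bootstrap predictions, s2 = RMSEP; reported as ±1 SD.

## Analogue screening and significance

Analogue quality compares each fossil sample's minimum dissimilarity to the
training set against percentiles of the training set's own inter-site
distances: < 5th percentile ⇒ *good*, > 10th percentile ⇒ *no-analogue*,
between ⇒ *fair* (the "fair" band is this package's reading of the
between-thresholds region). Percentiles use linear interpolation (numpy
default, R type 7) — class boundaries depend on this convention, so it is
fixed. Thresholds are computed from the training set only; fossil data
never enter the null distribution.

The random-reconstruction significance test asks whether the real
reconstruction explains more of the fossil assemblage matrix than
reconstructions trained on noise. The statistic is the variance fraction of
the square-root-transformed, column-centered fossil percentage matrix
explained by the reconstruction in a single-predictor RDA. Null variables
are i.i.d. uniform over the observed training range (Gaussian alternative by
configuration); p = (1 + #{random ≥ observed}) / (n_random + 1), and the
share of random reconstructions the observed one beats is reported
(defaults: 999 random reconstructions; 199 in the acceptance run).

*Known conservativeness.* Along long compositional gradients the fossil
matrix has arch-shaped (nonlinear) structure, and occasionally a
random-trained model aligns with it better than the real, linearly-aligned
reconstruction; the minimum p is then not attainable even for a strongly
forced fossil sequence. The test reaches minimum p reliably when the fossil
trajectory stays within the linear response range of the taxa, which is how
the strong-signal unit test is constructed.

## Ordination conventions

CA/CCA operate on the chi-square standardized residual matrix; constrained
eigenvalues come from its projection onto the row-mass-weighted, centered
predictor span, and the explained fraction is constrained inertia over total
CA inertia. Partial (conditioned) projections support forward selection:
greedy addition of the candidate with the largest extra inertia, admitted
when its reduced-model permutation p ≤ α (residuals of the candidate given
the current selection are permuted). Single-variable tests permute the
variable itself; all permutation p-values are (1 + #{≥ obs})/(n_perm + 1)
with 999 permutations by default. Variance-inflation screening iteratively
drops the worst variable while any VIF exceeds 20 (a deliberately permissive
default — the screening is meant to remove near-singularity, not to model
select; forward selection does the latter).

DCA gradient length: the first CA axis is rescaled iteratively (4 rounds)
so that the within-site dispersion SD of taxon scores — taxon scores being
weighted averages of site scores, expanded to undo their weighted-averaging
shrinkage — equals one axis unit; the length is the range of the rescaled
scores. The rescaling uses the pooled (global) dispersion rather than
per-segment local stretching: against `vegan::decorana` axis-1 lengths on
simulated gradients spanning 1–8 tolerances the pooled version agrees to
within ~3–9%, while segment-local stretching tracked the reference worse.
Matrices whose sites are effectively monospecific have no measurable
within-site turnover SD and report an infinite length (complete turnover).

PCoA applies the Cailliez additive correction whenever an eigenvalue falls
below −1e-8 × the largest (Bray-Curtis is generally non-Euclidean); NMDS is
Kruskal stress-1, best of 50 random starts (8 in the pipeline default),
convergence at stress change < 1e-6, with fossil samples placed passively
by least-squares matching against the fixed modern configuration after
rescaling dissimilarities to the configuration's arbitrary scale.

## Seasonal attribution

MAT is the arithmetic mean of the four seasonal temperatures. Series are
linearly interpolated onto a uniform 100-yr grid (linear: no overshoot, the
standard for palaeo series; no extrapolation beyond the data). In 1000-yr
windows (±500 yr inclusive, ≈11 grid points) sliding every 100 yr, each
season's sample variance Vi = (1/(n−1)) Σ (Ti − Tm)² is computed, and its
percentage contribution is 100·Vi/ΣVj over the four seasons. Windows are
computed on the grid (the raw-sample alternative is available by
configuration); edge windows with ≥ 2 points are kept and flagged partial;
windows where every season is flat yield flagged null records, never zeros.
Contribution series are summarized as frequency histograms (bins over
[0,100], default width 10) and LOWESS-smoothed trends (tricube locally
weighted linear regression, 3 robustifying iterations; default span 0.1 for
temperature series, 0.3 for contribution trends).

Because window variances of *reconstructed* series include reconstruction
error, a season reconstructed with larger per-sample error is credited with
spuriously high contribution; the attribution is most meaningful when
genuine millennial variability exceeds the reconstruction error, which the
synthetic defaults ensure (below) and which real applications should check
against the sample-specific errors.

## The synthetic study conditions

The generator emulates a mid-latitude East Asian snail survey and
loess-palaeosol fossil sequences:

* **Modern survey** — 382 sites; seasonal means drawn by Gaussian copula
  with inter-season correlation 0.8 (mid-latitude seasonal temperatures
  covary strongly) over winter −23…5.9 °C, summer 10.9…27.9 °C, spring
  −6…20 °C, autumn −4…21 °C; MAT is their mean; a precipitation-like
  nuisance variable (MAP) correlates with summer temperature.
* **Taxa** — 40 species, each with a Gaussian niche on one designated driver
  season (10 per season) times a broad Gaussian MAT term. Optima are
  regularly spaced per driver (species packing) with jitter, so no part of
  any gradient is uncovered; tolerances are uniform on 7–13% of the driver
  span, which puts the square-root-transformed survey's DCA gradient near
  5 SD. Counts are multinomial at depth 500 per sample (the only noise
  source by default).
* **History** — 20 kyr at 100-yr grid: glacial state to 17 ka, linear
  deglacial ramp to the Holocene thermal maximum plateau at 9–4 ka, then
  late-Holocene cooling losing 35% of the amplitude by 0 ka. Deglacial
  amplitudes: winter 5.5 °C (the dominant season), summer 4.0, spring 2.75,
  autumn 2.0. Millennial variability is AR(1) (lag-100-yr φ = 0.7) with SD
  = 0.3 × the season's amplitude — seasons with the largest orbital-scale
  change also fluctuate hardest at sub-orbital scales, which keeps window
  variances ranked like the amplitudes rather than noise-blurred.
* **Fossil sequence** — sampled every 250 yr (81 samples over 20 kyr),
  multinomial assemblages from the niche model at the true temperatures;
  the full truth is returned for recovery tests.

What the generator does *not* emulate: taphonomic loss and shell
fragmentation, age-model uncertainty (ages are exact), identification
ambiguity, spatial autocorrelation of survey sites, and secular changes in
species' niches. Passing recovery tests therefore demonstrate that the
pipeline's statistics do what they claim under the stated noise model — not
that any real sequence meets those assumptions.

Under these defaults the end-to-end chain recovers each season's history
with r ≥ 0.9 (LW-WAPLS, 2 components), classifies planted training copies
as good analogues and injected out-of-cloud samples as no-analogue, and
ranks mean seasonal contributions by the generative amplitudes.

## Numerical conventions and edge cases

* Percent rows are renormalized when they sum to 100 ± 0.5 (published-table
  rounding), rejected otherwise; all-zero rows are rejected by site id.
* Ages are calibrated years BP (larger = older) and must be strictly
  monotone within a sequence.
* Dissimilarity of two all-zero vectors is undefined and rejected; a fossil
  sample sharing no taxa with the training set gets infinite minimum
  distance (hence no-analogue), and reconstruction refuses such samples.
* Bootstrap cycles whose resample empties taxa or flattens the environment
  are skipped; sites never out-of-bag trigger a warning and are excluded
  from the statistics.
* All randomness flows from explicit seeds; per-variable and per-stage
  child seeds derive deterministically (CRC32 of the variable name,
  SHA-256 of the stage name), so identical configurations reproduce
  bit-identical outputs.
* Problem sizes in the test-suite null calibrations (25–100 training sites,
  99 permutations / 99 random reconstructions, 100–200 replicates) are
  chosen to keep Monte-Carlo error within the asserted binomial bands while
  the whole suite runs in well under a minute.

## Known limitations

* WA-family methods compress extremes at gradient ends; the maximum-bias
  statistic quantifies but does not remove this.
* The significance test's conservativeness along long gradients (above).
* The LW neighborhood, MAT k, and WA-PLS component count are exposed as
  configuration with the defaults stated here; none is estimated from the
  fossil data itself.
* The attribution inherits the reconstruction's error structure; interpret
  contribution shifts smaller than the corresponding ±1 SD bands with care.
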