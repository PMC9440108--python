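# paleoseason

Seasonal-temperature transfer functions from terrestrial mollusk
assemblages, with ordination screening, analogue diagnostics,
random-reconstruction significance testing, and seasonal variance
attribution of mean annual temperature.

## The problem

Most Quaternary temperature proxies record one season — or an unknown blend
of seasons — which is a central obstacle to comparing Holocene
reconstructions with climate-model output. Land-snail assemblages from
surface soils and loess-palaeosol sequences are abundant enough, and
sensitive enough to seasonal temperature, to calibrate *separate* transfer
functions for spring, summer, autumn and winter mean temperatures, plus MAT.
`paleoseason` is a tested reimplementation of that full analysis chain for
palaeoecologists and community-ecology statisticians:

1. **Screening** — is seasonal temperature a primary control on assemblage
   composition? PCoA (Bray-Curtis, Cailliez-corrected), DCA gradient length
   in SD units (> 2 SD ⇒ unimodal methods), CCA with VIF screening,
   forward selection, and Monte Carlo permutation tests (999 permutations).
2. **Calibration** — WA, WA-PLS, MAT, LW-WA, LW-WAPLS transfer functions
   with bootstrap cross-validation (RMSEP, R², average and maximum bias)
   and sample-specific ±1 SD reconstruction errors.
3. **Assessment** — analogue quality against the 5th/10th percentiles of
   training inter-site dissimilarities (good / fair / no-analogue), and the
   random-reconstruction significance test (RDA explained variance vs 999
   models trained on random environmental variables).
4. **Attribution** — interpolate reconstructions to a uniform 100-yr grid
   and, in 1000-yr sliding windows, compute each season's variance
   Vi = (1/(n−1)) Σ (Ti − Tm)² and its share 100·Vi/ΣVj of the four-season
   sum: the percentage contribution of that season to MAT variability.
5. **Synthesis** — a generator of modern training surveys (Gaussian niches
   on correlated seasonal gradients, multinomial counts) and 20-kyr fossil
   sequences with known truth, so every stage is testable end to end.

The core calibration model, WA-PLS, estimates taxon optima as
abundance-weighted means, û_k = Σᵢ yᵢₖ xᵢ / Σᵢ yᵢₖ, and extends weighted
averaging with components built from the residuals of the previous fit;
component 1 with inverse deshrinking is exactly classical WA. Locally
weighted variants refit the model on each fossil sample's nearest modern
analogues (squared-chord distance). See `docs/methods.md` for the complete
model documentation and all defaults.

## Worked example

```python
import numpy as np
import paleoseason as ps
from paleoseason import attribution as at

# synthetic study: modern survey + 20 kyr fossil sequence
cfg = ps.SimConfig()                       # 382 sites, 40 taxa, N = 500
responses = ps.make_species_responses(cfg, seed=1)
modern, env = ps.simulate_training_set(cfg, responses, seed=1)
history = ps.simulate_temperature_history(seed=1)
fossil, truth = ps.simulate_fossil_sequence(history, responses, seed=1)
pct = ps.to_percentages(modern)

print(f"DCA gradient length: {ps.dca_gradient_length(ps.sqrt_transform(pct)):.2f} SD")
print(f"fossil analogue quality: {ps.classify_analogues(fossil, modern).counts()}")

spec = ps.MethodSpec(method="LW-WAPLS", n_components=2)
series = ps.reconstruct(spec, pct, {"T_winter": env["T_winter"]}, fossil,
                        with_errors=True, n_boot=100, seed=1)
r = np.corrcoef(series.predictions["T_winter"], truth["T_winter"])[0, 1]
print(f"winter reconstruction: r = {r:.3f} vs truth, "
      f"mean +/-1 SD = {series.errors['T_winter'].mean():.2f} degC")

recon = {s: ps.reconstruct(spec, pct, {s: env[s]}, fossil).predictions[s].to_numpy()
         for s in at.SEASONS}
grid = at.interpolate_uniform(at.SeasonalSeries(fossil.ages, recon), dt=100.0)
contrib = at.contributions_frame(at.sliding_contributions(grid))
print("mean seasonal contributions to MAT variance:")
print(contrib[list(at.SEASONS)].mean().round(1).to_string())
```

prints

```
DCA gradient length: 5.03 SD
fossil analogue quality: {'good': 81, 'fair': 0, 'no-analogue': 0}
winter reconstruction: r = 0.988 vs truth, mean +/-1 SD = 1.56 degC
mean seasonal contributions to MAT variance:
T_spring    20.0
T_summer    22.8
T_autumn     8.4
T_winter    48.8
```

Read: the synthetic survey spans ~5 SD of compositional turnover (long
enough for unimodal methods), every fossil sample has a good modern
analogue, the locally-weighted WA-PLS model recovers the known winter
history at r ≈ 0.99 with ±1.6 °C sample-specific errors, and winter — the
season given the largest generative amplitude (5.5 °C deglacial warming) —
contributes most to MAT variability, as it should.

## Command line

The same chain runs from a shell over CSV inputs (or the built-in
synthesizer) with a YAML configuration:

```sh
paleoseason run-all --seed 1 --outdir out          # simulate + full chain
paleoseason reconstruct --config my_study.yaml     # one stage on real CSVs
```

Stages (`simulate`, `ordinate`, `calibrate`, `reconstruct`, `assess`,
`attribute`) write CSV/JSON outputs plus a manifest (input checksums,
config hash, stage seed); deterministic stages rerun bit-identically.

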