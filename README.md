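# rangeabund

What makes a tree species locally abundant — and is it the same inside
and outside its native range? `rangeabund` is a reusable pipeline for
community ecologists studying that question with vegetation-plot data:
it filters forest plots, computes each focal species' relative abundance
and its functional position relative to co-occurring woody species,
derives a 12-month drought index (SPEI) from monthly climate, and fits a
two-level hierarchical Bayesian regression in which species-specific
slopes are themselves regressed on species traits. A seeded
synthetic-data module generates plot communities and model-forward
datasets with known parameters, so every stage is testable without any
external downloads.

## The model

For focal species *j* in plot *p* (observation *i*), with
*y* the standardized ln relative abundance and nine standardized
predictors *x* = (trait dissimilarity, ΔSLA, ΔH, ΔSM, ΔWD, HII, SPEI,
range, richness):

```
y_i      ~ N( α_j + Σ_k β_jk x_ik + Σ_{k∈I} δ_k x_ik·r_i + u_p , σ_ε² )
α_j      ~ N( γ_α0 + Σ_m γ_αm T_jm , σ_α² )
β_jk     ~ N( γ_k0 + Σ_m γ_km T_jm , σ_k² )
u_p      ~ N( 0 , σ_u² )
```

Level 1 lets every species respond in its own way to each predictor,
with seven global range interactions δ (I excludes richness and range
itself); level 2 explains the species-specific intercepts and slopes by
the species' own traits *T* (SLA, H, SM, WD on the standardized ln
scale). Priors are N(0, 10³) on all location parameters and
Uniform(0, 100) on all standard deviations. Inference is a blocked
Gibbs sampler (the model is conditionally conjugate); the reference
protocol is 3 chains × 10,000 retained iterations after 1,000 burn-in,
with Gelman–Rubin univariate and multivariate PSRF and variance
inflation factors reported alongside. Key community metrics:

* **relative abundance** — the focal species' share of total woody
  cover in a plot;
* **multivariate trait dissimilarity** — Gower distance between the
  focal species' ln traits and the cover-weighted mean (CWM) of
  co-occurring woody species, range-normalized to [0, 1];
* **competitive trait differences** — Δ = focal ln trait − CWM ln
  trait, one per trait, positive when the focal exceeds its community;
* **SPEI** — trailing 12-month water balance (P − Thornthwaite PET)
  standardized through a per-calendar-month log-logistic fit.

A companion analysis compares mean relative abundance between native
and alien ranges with a crossed random-intercepts mixed model
(species + plot) and a 1-df likelihood-ratio χ².

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

Simulate an 80-plot, two-continent dataset and run the full pipeline:

```bash
rangeabund simulate plots --seed 7 --n-plots 80 --out example/
cat > example/config.yaml <<'YAML'
paths:
  plots: example/plots.csv
  traits: example/traits.csv
  climate: example/climate.csv
  hii: example/hii.csv
seed: 1
model: {chains: 3, iterations: 6000, burn_in: 1000}
YAML
rangeabund run --config example/config.yaml --out example/artifacts
rangeabund report --artifacts example/artifacts
```

The report prints per-range effects composed from the posterior
(`γ_k0 + δ_k·r_range`), the trait-moderation coefficients, and the
diagnostics. Abridged output from the run above:

```
Main effects by range (median [95% CI])
==============================================
    dissim native: +0.081 [-0.482, +0.634]
    dissim  alien: -0.078 [-0.653, +0.487]
       hii native: -0.102 [-0.283, +0.077]
       hii  alien: +0.232 [-0.047, +0.505]
  richness native: -0.129 [-0.461, +0.179]
  richness  alien: -0.129 [-0.461, +0.179]
...
max univariate PSRF: 1.0205
multivariate PSRF:   1.0631
max VIF:             2.02
Bayesian R2:         0.582
```

Each line is a standardized effect size: here none of the wide
intervals excludes zero — expected for a 10-focal-species toy dataset —
and the PSRF above 1.01 correctly flags that this short toy fit would
need longer chains before being quoted. The artifacts directory also
holds `analysis_rows.csv` (one row per focal × plot with all
predictors), `range_comparison.json` (native-vs-alien means and χ²),
`species_contrasts.csv` and a `manifest.json` with input hashes, seed
and per-stage row counts; re-running with the same seed reproduces
every file byte for byte.

Library use mirrors the CLI: `synthetic_data.gen_plots` /
`gen_design`, `plot_prep.filter_plots`, `trait_metrics.build_analysis_rows`,
`climate_spei.plot_mean_spei`, `hier_model.sample_posterior`,
`range_compare.fit_range_lmm`.

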