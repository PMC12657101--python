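# lipidstore

Estimation of total body lipid stores in free-ranging whales, combining UAV
(drone) photogrammetry with tag-derived tissue density.

Lipid reserves are the energy currency of large whales, but no direct
measurement exists for animals that cannot be captured. Two indirect
body-condition methods are in wide use: overhead photogrammetry measures how
*big* a whale is (total length and body volume), and hydrodynamic modelling
of glides in biologging records measures how *dense* its tissue is — which
tracks the proportion of low-density lipid. Neither alone yields the lipid
store in absolute units. `lipidstore` implements the combined analysis: it
links both observation streams to a shared latent body-condition state in a
hierarchical Bayesian measurement-error model, converts tissue density to
lipid proportion against a Monte Carlo-simulated lean reference body, and
multiplies by gas-corrected body mass to report per-whale lipid mass in
tonnes with credible intervals.

## The model

**Densitometry.** A body of tissue density ρ_t against a lipid-free (lean)
reference of density ρ_ζ has lipid mass fraction (Siri-type equation)

    Pl = (1/ρ_t) · ρ_ζ ρ_l / (ρ_ζ − ρ_l) − ρ_l / (ρ_ζ − ρ_l)

with ρ_l the lipid density (≈ 860 kg m⁻³ for sperm whale oil at body
temperature). The lean density ρ_ζ is not observable in vivo; it is
simulated by a Monte Carlo over eight tissue compartments (skeleton,
muscle, organs, viscera, blubber, sound production apparatus, other, blood),
each a mixture of water/lipid/protein/ash with literature-calibrated
compositions, so that reference-body uncertainty propagates into the final
estimates.

**Hierarchical model.** Per whale *w*, latent length L_w, lipid-proportion
deviation δPl_w ~ N(0, σ_δPl) and process residual ε_w drive

    log V_w = log α_v + β_v log L_w + β_δPl δPl_w + ε_w
    ρ_w     = k / (δPl_w + c),   k = ρ̄ ρ_l/(ρ̄ − ρ_l),  c = ρ_l/(ρ̄ − ρ_l)

with informative priors on the allometry (log α_v ~ N(−4.048, 0.086),
β_v ~ N(2.861, 0.041)), on the population mean tissue density
(ρ̄ ~ Gamma(5412, 5.255)) and a weakly informative N(0, 50) on β_δPl.
Per-image length/volume observations carry whale-level error SDs pooled
hierarchically from repeated images; density observations carry their known
standard errors. Whales observed by only one modality stay in the model and
have the missing quantities imputed through the shared process. Sampling is
adaptive Metropolis-within-Gibbs with joint ridge/scale moves (3 chains,
burn-in, thinning; Gelman-Rubin and effective-sample-size diagnostics).

**Post hoc.** Posterior (ρ_t, V) draws are paired with lean-density draws:
Pl via the equation above, whole-body density via the diving-gas correction
ρ_b = (ρ_t + M_g)/(1 + V_g), body mass M_b = V·ρ_b, lipid mass
M_l = Pl·M_b, plus the spermaceti share held in the sound production
apparatus.

## Worked example

Simulate a study-like population (30 whales: 16 with tag + UAV, 10 tag-only,
4 UAV-only), fit the scaled-down MCMC and estimate lipid stores:

```python
from lipidstore import lipid_pipeline as lp

cfg = lp.PipelineConfig(seed=1, outdir="results", n_reference_draws=100_000,
                        mcmc_iterations=4000, mcmc_thin=2)
res = lp.run_pipeline(cfg)
print(res["table"].head())
```

which prints (abridged):

```
whale_id  n_subglides   rho_t  n_images  length_m  volume_m3  dpl_pct  lipid_t  spermaceti_t
    sw01        113.0 1029.95         5     12.70      25.37    -0.01     5.86          1.16
    sw02         68.0 1025.91         6     16.69      64.34     1.98    15.36          3.02
    sw04        124.0 1030.42         5     16.40      56.56    -0.24    12.41          2.45
    sw05          NaN     NaN         3     10.90      18.65     0.36     4.15          0.82
    sw06         70.0 1028.51         6     11.86      22.76     0.70     5.21          1.03
```

Each row is one whale: its tag subglide count and observed tissue density
(kg m⁻³), number of UAV images, mean photogrammetric length and volume, the
posterior lipid-proportion deviation from the population-average whale
(percentage points), and absolute lipid store in tonnes, including the
spermaceti fraction. Whale `sw05` has no tag record — its composition is
imputed through the fitted volume-density relationship (with accordingly
wider intervals). The run also writes `sensitivity.json` (here: +1 m³ of
volume ↦ +8.9% lipid mass, −1 kg m⁻³ of density ↦ +4.6%), `energetics.json`
(tissue energy density 14.92 ± 0.64 kJ g⁻¹, cost of growth 23.15 kJ g⁻¹,
structural growth cost 23.8 GJ m⁻³) and `diagnostics.json` (R-hat, ESS,
posterior-predictive coverage).

A `lipidstore` console script exposes the same steps
(`simulate`, `morphometry`, `reference`, `pipeline`) for shell use.

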