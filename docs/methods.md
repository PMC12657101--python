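# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `lipidstore`. It describes what the code computes; all
empirical numbers quoted here are produced by the test suite or the
acceptance script.

## 1. Densitometry (`lipidstore.densitometry`)

The body is treated as a mixture of mutually insoluble compartments. With
mass fractions P_c and densities ρ_c the whole density is the mass-weighted
harmonic mean 1/ρ = Σ P_c/ρ_c (equivalently the volume-weighted arithmetic
mean over volume fractions); `solve_final_compartment` inverts this exactly
for one unknown compartment, P_n = ρ_n (1/ρ − Σ P_c/ρ_c), and the two are
verified against each other to 1e−12 on random mixtures.

Lipid proportion from tissue density uses the Siri-type reference-body
equations: the general form for a reference body (ρ_γ, Pl_γ) gaining or
losing reserve tissue (ρ_τ, Pl_τ), its δPl specialisation that needs no
reference lipid content, and the lean-reference special case
(Pl_γ = 0, ρ_γ = ρ_ζ, Pl_τ = 1, ρ_τ = ρ_l), under which Pl = δPl. δPl is
linear in 1/ρ_t, strictly decreasing in ρ_t, and zero at the reference
density; these invariants are property-tested.

Tissue densities slightly outside [ρ_l, ρ_ζ] can arise from measurement
noise; the lean equation extrapolates with a warning rather than failing.

**Constituent density defaults** (config-overridable): ρ_water = 994,
ρ_protein = 1340, ρ_ash = 2300, ρ_lipid = 860 kg m⁻³. These are
literature-calibrated reconstructions chosen so the canonical lean
composition (69.1/27.4/3.4 water/protein/ash by mass) reproduces a lean
density of ≈1093.5 kg m⁻³ and the whole-body composition
(52.8/20.9/23.5/2.6) a tissue density of ≈1027–1029 kg m⁻³; ρ_lipid ≈ 860
matches sperm whale oil at body temperature. The diving gas load defaults
to P_g = 30 ml per kg of tissue; the gas correction
V_g = P_g·10⁻⁶·ρ_t, M_g = V_g·ρ_g, ρ_b = (ρ_t + M_g)/(1 + V_g) is
implemented verbatim on a per-1-m³-of-tissue basis for bit-compatibility
with its standard statement, with ρ_g = 1.225 kg m⁻³ (air at 1 atm).

## 2. Volumetrics (`lipidstore.morphometry`)

Width profiles follow the MorphoMetrix convention: total length plus widths
at 5% stations from rostrum (0) to fluke notch (1). The 0% and 100%
stations are forced to zero width (the body closes at both ends). Heights
come from body-site-specific height:width ratios, H(s) = W(s)·ratio(s),
never interpolated across the midline; the packaged ratio table
(`hw_ratios_synthetic.csv`) is a plausible synthetic reconstruction of a
sperm-whale body plan and is intended to be replaced by measured ratios
where available.

Each inter-station segment is a stack of ellipses with linearly varying
axes; the cross-section area is quadratic along the segment and integrates
in closed form, V_s = (π/4)·l·[(W₁H₁ + W₂H₂)/3 + (W₁H₂ + W₂H₁)/6]. The
closed form is verified against adaptive quadrature to 1e−10 relative
error. Total volume is the sum of the 20 segments. Discretization bias for
a smooth convex body is below 1% (a prolate spheroid sampled at 5% stations
comes out ≈0.9% low, because the square-root radius profile has unbounded
slope at the poles where chords undercut); volume is exactly invariant
under station reversal and scales cubically with linear size.

Images are kept at image level — repeated measurements per whale feed the
model's measurement-error estimation; they are never pre-averaged.

## 3. Reference bodies (`lipidstore.reference_body`)

Each simulated whale draws a length uniformly on 8–17 m; total mass follows
M = a·L^b (defaults a = 18.5 kg, b = 2.88, the product of the volume
allometry and a whole-body density near 1026 kg m⁻³). Compartment mass
fractions and per-compartment constituent compositions are drawn as
independent truncated Gaussians (negatives rejected) and renormalised to
sum to one — a Dirichlet-like scheme chosen because the available
information is per-compartment means and SDs, not a joint law. Lean
quantities exclude the lipid terms from the constituent sums; densities are
mass/volume ratios through the constituent densities.

The packaged table (`compartments_synthetic.csv`) is produced by
`scripts/calibrate_compartments.py`: literature-plausible initial
compositions are adjusted by iterative proportional fitting so the
zero-variance aggregate reproduces the canonical whole-body composition
(52.8% water, 20.9% protein, 23.5% lipid, 2.6% ash). Everything downstream
(lean ≈1092 kg m⁻³, whole-body ≈1027 kg m⁻³, spermaceti share ≈0.20 of
total lipid) follows from that aggregate; nothing else is fitted. The
per-compartment SDs were set once to plausible relative spreads; they give
a lean-density SD of ≈4–5 kg m⁻³ and whole-body SD of ≈5 kg m⁻³ — the same
order as, but somewhat tighter than, whaling-data-derived spreads, so
reference-body uncertainty in this package's outputs is, if anything,
mildly optimistic.

Because compositions are drawn independently of length, simulated density
and composition show no length trend (rank correlation ≈ 0); external
validation reports the fraction of independent density or lipid-yield
observations inside the central 95% simulation envelope per length bin.

## 4. Synthetic study generator (`lipidstore.synthetic_data`)

The generator's defaults are the study conditions: 30 whales (16 with both
modalities, 10 tag-only, 4 UAV-only, assigned by largest-remainder counts
and a seeded shuffle), lengths uniform on 8–17 m (no length distribution is
otherwise specified), allometry V = 0.018·L^2.88 with β_δPl = 6.75,
population mean density 1029.7 kg m⁻³, δPl ~ N(0, 0.009) truncated so the
implied density stays in [1015, 1045] kg m⁻³ (the observed range plus
margin), process residual SD 0.02, per-whale length CVs uniform on
0.005–0.035 and volume CVs on 0.03–0.10 (spanning the reported ranges),
1–6 images per imaged whale, and density SEs uniform on 0.03–0.13 kg m⁻³.
Length noise is additive Gaussian; volume noise multiplicative lognormal
(volumes are strictly positive and their error scales with size). True
density derives from δPl by inverting the δPl equation at the
population-average reference, so δPl = 0 gives exactly ρ̄.

What it does *not* emulate: altimeter bias, pose/quality filtering,
correlated errors within a flight day, length-dependent sampling effort,
or any systematic lean-composition trend with size. Passing recovery tests
therefore demonstrate statistical self-consistency of the estimator under
the assumed observation process, not robustness to those field effects.

## 5. Hierarchical model and sampler (`lipidstore.bayes_model`)

Latents per whale: L_w ~ U(4, 25) m, δPl_w ~ N(0, σ_δPl),
ε_w ~ N(0, σ_proc); process log V_w = log α_v + β_v log L_w + β_δPl δPl_w
+ ε_w and ρ_w = k/(δPl_w + c) with the average-whale reference, so δPl
means "difference in lipid proportion from the average whale". Observation
model: per-image length ~ N(L_w, σ_L,w) and volume ~ N(V_w, σ_V,w) with
whale-level SDs pooled through lognormal hierarchies (whales with a single
image borrow the population distribution), density ~ N(ρ_w, SE_w) with the
SE supplied by the upstream tag analysis. A replication mode accepts
photogrammetry rows with known SEs instead (used for published summary
tables).

Priors: log α_v ~ N(−4.048, 0.08646); the scaling-exponent prior is
N(2.861, 0.04094) applied to β_v directly by default. The hyperparameter
table that motivates these priors labels the exponent prior "log β_v", but
exp(2.861) ≈ 17.5 is not a credible volume exponent while 2.861 itself is,
and the fitted exponent lands near 2.88; both readings are implemented
behind `ModelConfig.beta_v_prior_scale`, defaulting to the linear reading.
ρ̄ ~ Gamma(shape 5412, rate 5.255) (mean 1029.9, SD 14.0 kg m⁻³);
β_δPl ~ N(0, 50), a deliberately conservative slope prior; all remaining
scales uniform on generous ranges (σ_δPl < 0.2, σ_proc < 0.5, log-sigma
locations in [−7, 1]/[−7, 2.5], log-sigma SDs in [0.01, 3]).

The exact likelihood of the original analysis is deferred to supplementary
material not available here; the concrete form above is isolated behind
`build_model` so it can be swapped verbatim if needed.

**Sampler.** Adaptive random-walk Metropolis within Gibbs (the default
strategy of general-purpose MCMC engines for models of this shape), fully
hand-seeded: scalar updates for the ten globals; vectorised per-whale
updates exploiting conditional independence given the globals; and four
kinds of joint moves that fix the posterior's strong correlations at modest
chain lengths — (i) ridge translations of log α_v, β_v, β_δPl with the
per-whale residuals shifted to keep every latent volume fixed (likelihood-
invariant; acceptance from priors only); (ii) a ρ̄ translation that remaps
all δPl_w to hold latent densities fixed (Jacobian (k'/k)ⁿ); (iii) an
(α_v, β_v) pair move along the direction that preserves the fitted volume
at the mean log-length; (iv) multiplicative scale moves rescaling
(σ, deviations) jointly with Jacobian a^(n+1), which remove the classic
funnel between hierarchical scales and their residuals. Step sizes adapt
toward 0.44 acceptance with a diminishing-adaptation schedule. The
full-scale protocol is 3 chains × 100,000 iterations, half burn-in, thin
50; simulation studies and tests use 3 × 4,000, thin 2, which attains
R-hat ≲ 1.05 on the global parameters under study-like data. Convergence
failures (R-hat > 1.1) warn and are flagged in the diagnostics, not fatal.

**Posterior predictive checks.** For each retained draw a replicate
observation table is simulated; reported coverages are the fractions of
real observations inside central 95% predictive intervals. On training
data these are conservative (typically ≳0.95 up to 1.0) because latent
states and whale-level error scales adapt to their own observations — a
uniform systematic corruption of one table is therefore *not* visible as a
coverage failure; it surfaces as saturation of σ_proc against its prior
bound, reported as `sigma_proc_at_bound` (≈0 for a well-specified model).
Tests assert both behaviours.

## 6. Post-hoc pipeline (`lipidstore.lipid_pipeline`)

Per whale, 3,000 posterior (ρ_t, V, δPl) draws (resampled with replacement,
preserving within-draw correlation) are paired with independently resampled
lean-density and spermaceti-share draws from the reference simulation —
posterior and reference-body uncertainty are treated as independent
sources. Each pair passes through the lean-reference equation, the gas
correction and M_l = Pl·M_b (lipid proportion clipped to [0, 1] for the
mass product only). Reports give means with central 95% credible intervals
and the relative interval width (CRI width / mean), the study's headline
precision metric; per-whale frequentist CIs for raw repeated measurements
use the t distribution and are left blank for single-image whales.

Sensitivity is a posterior-averaged finite difference at a 12 m reference
whale: volume +1 m³ carries the model-implied δPl change
(Δ log V = β_δPl ΔδPl at fixed length); density −1 kg m⁻³ carries the
model-implied volume change. Energetics uses energy densities 23.6 (protein)
and 42.5 (lipid) kJ g⁻¹ with deposition efficiencies 0.47 and 0.79;
structural cost per m³ multiplies the growth cost by tissue density, and
the per-metre figure uses the allometric volume increment V(L+1) − V(L),
a one-metre finite difference chosen because point-slope readings of the
allometry do not reproduce any published per-metre figure exactly.

## 7. Problem sizes

Defaults chosen for the package's analyses: reference simulations use 10⁵
draws (SD estimates stable to ~1%); simulation studies use 20 replicates of
the 30-whale design at 3 × 4,000 iterations; the full-protocol settings
remain available through configuration. The slope-recovery study in
`scripts/acceptance.py` completes in about six minutes on one CPU.

## 8. Known limitations

- The compartment table and H:W ratio table are calibrated/synthetic
  reconstructions, not transcriptions of the original supplementary data;
  both are package data intended to be replaced by users with access to
  measured values.
- Reference-body spread is somewhat tighter than whaling-data-derived
  spreads (see §3), so absolute-lipid credible intervals are mildly
  optimistic about reference uncertainty.
- Volume observation error is Gaussian in the model but lognormal in the
  generator; at the observed CVs (≤0.10) the mismatch is negligible, but
  the model form would mis-state errors for very imprecise volumes.
- The sampler is exact but not gradient-based; posteriors with far more
  whales (hundreds) would warrant an HMC backend.
- Imputation for single-modality whales assumes the fitted population
  process transfers to them; no allowance is made for modality-dependent
  sampling bias.
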