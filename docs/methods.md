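# Methods

`greenmig` quantifies the structural complexity of habitats from
ordinary digital photographs and models how insectivorous bats respond
to that complexity in urban green spaces. This note describes the
index, the survey reductions, the statistical pipeline, the synthetic
study generator, and the numerical choices behind each.

## Mean information gain (MIG)

A photograph is reduced to its HSV value channel, V = max(R, G, B)/255
per pixel — the intensity band, which is robust for quantifying
structure in natural scenes. Intensities are quantized into `M`
equal-width bins (γ = min(⌊vM⌋, M−1)). Two Shannon entropies are
estimated with plug-in relative frequencies (0·ln 0 ≡ 0):

* **marginal entropy** `H₁ = −Σᵢ p(γᵢ) ln p(γᵢ)` over all pixels —
  aspatial heterogeneity (how varied the intensities are, wherever
  they sit);
* **joint entropy** `H₄ = −Σⱼ p(χⱼ) ln p(χⱼ)` over the configurations
  χ of 2×2-pixel neighbourhoods (k = 4) — spatial heterogeneity.

The index is

```
MIG = (H₄ − H₁) / ln(M^k / M) = (H₄ − H₁) / ((k − 1) ln M)
```

MIG = 0 for a uniform image (single colour) and for deterministic
periodic patterns such as a checkerboard; MIG → 1 for spatially random
(iid) images as the image grows. The normalization makes the value
identical in any logarithm base.

Numerical choices:

* **Window scheme.** Overlapping (sliding) 2×2 windows over the valid
  interior; only windows fully inside the image count, no padding or
  wraparound. A disjoint tiling would discard three-quarters of the
  spatial associations; padding would fabricate configurations.
* **Bins.** Default `M = 256`, the native resolution of 8-bit
  channels — the highest value that adds no quantization loss. `M` is
  configurable; small images need small `M` because the joint entropy
  is capped by ln(number of windows) — at 64×64 the cap truncates the
  index for M ≥ 16, so analyses at that resolution here use M = 4.
* **No clamping.** Plug-in estimates on tiny images can put MIG
  slightly outside [0, 1] (a 64×64 checkerboard gives −1.5·10⁻⁸
  because 3969 windows cannot split the two configurations evenly);
  values are reported as computed.
* **No bias correction** of the entropy estimates, no gamma
  correction, no resizing.

Per site, five views are photographed (four cardinal side views, one
upward top view) and summarized as `mig_sides` (mean of four),
`mig_top`, and `mig_all` = (4·mig_sides + mig_top)/5.

## Field vegetation descriptors

The cover-board protocol records foliage presence/absence at 17
positions (plot centre + four positions at 5-m intervals per cardinal
direction) in 10 height classes (0–0.5 up to >15 m). Derived
descriptors: clutter per height class (touched positions / 17),
vertical heterogeneity (Shannon H over classes with touch counts as
abundances, natural log; an all-zero profile is defined as H = 0 with
a warning — no vegetation, no heterogeneity), mean ground cover,
canopy cover and vegetation height over positions, tree density
(DBH > 0.16 m, strict), large-tree count (DBH > 0.30 m, strict) and
their mean DBH (undefined without large trees; the pipeline imputes 0
for model assembly, i.e. "no large-tree biomass"). Tree density is per
plot (20-m radius, 400π m²); a per-hectare conversion is provided.

## Acoustic responses

Call records carry site, night (1–3), species label from a closed
14-taxon vocabulary (11 species + 3 acoustic groups merged for call
similarity: P. kuhlii/P. nathusii, M. brandtii/M. mystacinus, Plecotus
auritus/austriacus) and call-sequence length (s). **Activity** is the
median over the three survey nights of the summed sequence length per
night; a surveyed night without records contributes 0. The alternative
reading — median of pooled individual sequence lengths — is available
(`method="pooled"`) but nightly totals are the default because a
per-night intensity is commensurate with call counts. **Richness** is
the number of distinct taxa over all nights after merging. Summaries
are produced for the totals, for edge-space foragers (6 taxa) and
open-space foragers (3 taxa), and for two representative species
(N. noctula, P. pygmaeus).

Note that activity defined as a median is not superadditive: guild
activities can exceed the total when nightly patterns differ between
guilds. Subset monotonicity (a single species never exceeds its guild)
does hold.

## Statistical pipeline

1. **Pearson screen** of all candidate-predictor pairs; |r| > 0.5
   flagged, zero-variance columns reported as undefined.
2. **VIF filter** over the field-based descriptors: iteratively drop
   the predictor with the largest VIF (VIFⱼ = 1/(1−R²ⱼ) from an OLS of
   predictor j on the rest, intercept included) while any VIF > 2;
   ties break alphabetically, making the result order-invariant. The
   MIG indices are the focal complexity measures and are appended to
   the candidate set *after* the filter: image complexity deliberately
   summarizes the same canopy structure several field descriptors
   measure, and the point of the analysis is to let it stand in for
   them rather than be deleted as their collinear twin.
3. **Transforms.** Activity → ln(activity+1) (the offset keeps silent
   sites defined); continuous predictors z-scored; the green-space
   size quartile enters as its class index (1–4), standardized.
4. **Activity models.** Gaussian linear mixed model with a random
   intercept per green-space type. Model comparison uses ML
   likelihoods with AIC = −2·llf + 2·(p + 2) (fixed effects plus the
   random-intercept and residual variances), the same convention for
   every candidate; reported coefficients come from a REML refit.
   Optimizers are tried in the order bfgs → cg → powell and a fit is
   accepted only with finite log-likelihood (L-BFGS on these profiled
   likelihoods occasionally reports convergence at a degenerate
   point). A boundary fit (zero type variance) is a warning, not an
   error.
5. **Richness models.** Poisson GLM with log link. The dispersion
   φ = Pearson χ²/df is always estimated; if φ > 1.5 the standard
   errors are rescaled by √φ and the family reported as
   quasi-Poisson. AIC is that of the Poisson likelihood.
6. **Selection.** Bidirectional stepwise AIC starting from the full
   post-filter model; single-term add/drop moves; stops when no move
   lowers AIC; failed candidate fits are skipped with a warning; the
   path is logged.
7. **Pseudo-R².** GLMs: 1 − D/D₀ (deviance based). Mixed models: the
   marginal variance-partition form var(Xβ̂)/(var(Xβ̂) + τ̂² + σ̂²),
   which quantifies the fixed-effects share of total variation.

## Synthetic study generator

The generator reproduces the statistical structure the pipeline
assumes so every stage can be exercised without field data: 9
green-space classes × 4 size quartiles × 5 sites = 180 sampling
points, 3 survey nights each (540 site-nights), five photographs and a
cover-board survey per site.

Each site has latent complexity values c_top, c_side ∈ [0, 1] (type
means from ~0.1 for pastures to ~0.85 for forests; within-type SD
0.18 — urban green spaces of one class vary widely, and the
within-type variation is what identifies effects once the type
intercept absorbs the between-type differences) and a ground-cover
percentage g (type means 30–90%, SD 20).

* **Images** mix a smooth low-frequency background (vertical gradient
  for side views, radial for the top view, plus a weak sinusoid) with
  iid pixel noise: each pixel is replaced by noise with probability
  equal to the latent complexity. Realized MIG is monotone in the
  latent and anchored at both ends (MIG < 0.05 at c = 0, > 0.95 at
  c = 1 for 512×512, M = 4). Default rendering is 256×256 (the index
  stabilizes far below camera resolution); the tiny profile uses
  64×64.
* **Vegetation.** Touch probabilities scale multiplicatively with the
  latents (understorey/mid-storey with c_side and g, canopy classes
  with a site-level vegetation state veg_top = c_top + N(0, 0.22²)
  clipped to [0, 1]). The decoupling noise keeps the correlation
  between image complexity and canopy descriptors moderate (~0.6) —
  photographs see every structure in a scene while the cover board
  sees vegetation only — instead of making the field descriptors
  perfect duplicates of the image index. Cover readings, vegetation
  height and tree counts (Poisson, mean 1 + 14·veg_top) follow the
  same state.
* **Surveys.** Site-level log activity per guild follows
  ln(A+1) = b₀ + b_mig·z(c_top) + b_gc·z(g) + b_size·z(size) + b_type + ε
  with b_type ~ N(0, τ²) shared across guilds and ε of variance σ²
  split into a shared site component (50%) and a guild-specific
  component — night conditions and insect supply affect all bats at a
  site jointly. Defaults: τ = 0.3, σ = 0.5, and guild coefficients
  (edge: −0.20 canopy, +0.25 ground; open: −0.35 canopy, +0.25
  ground, −0.10 size; other taxa: −0.10, +0.15). Magnitudes are
  chosen to be comparable to effects reported for urban bat
  assemblages at this design size and detectable at n = 180; the open
  guild responds more negatively to canopy complexity than the edge
  guild by construction. The guild's activity is distributed over its
  present species (occupancy Bernoulli draws, logit-modulated by the
  latents; defaults range from 0.93 for the common pipistrelles down
  to 0.03; shares proportional to occupancy; a guild with activity
  but no presence draw is attributed to its most ubiquitous species,
  since recorded calls imply presence) and over the three nights with
  Dirichlet(8,8,8) weights, so the median nightly total tracks A.

Everything is a deterministic function of (config, seed);
`make_fixture_bundle` writes the images and CSV tables in exactly the
schemas the loaders consume, and `generate_study_tables` is the same
draw kept in memory.

**What the generator does not emulate:** real vegetation texture
(scenes are noise mixtures, not rendered foliage), spatial
autocorrelation between neighbouring sites, weather covariates,
detection bias of quiet-calling species, and anthropogenic structures
in images. Passing tests therefore show that the pipeline recovers
the structure it assumes from data of realistic size and noise — not
that the index or the models are unbiased on real photographs.

## Replicated checks and problem sizes

The replicated analyses use sizes chosen to keep a full run on one
CPU short while preserving the design: parameter recovery fits the
edge-guild activity GLMM on the generating covariates (the edge guild
is present at >99.5% of sites, so its generating model is the fitted
model to excellent approximation; the total is a sum over guilds with
different slopes and has no single true coefficient). End-to-end
sign-structure replicates render the scenes at 64×64 with M = 4 —
the setting where the latent→MIG map stays monotone over the whole
range — and measure the guild contrast with complexity-only models
(MIG parameters + size), the configuration in which guild responses
to complexity are reported most directly.

## Known limitations

* The mixed-model AIC counts the boundary-constrained variance as a
  full parameter; all candidates share the convention, so selection
  is unaffected, but the absolute AIC is not comparable to other
  software's.
* Quasi-Poisson correction rescales SEs after Poisson-AIC selection;
  selection itself does not account for overdispersion.
* MIG on very small or strongly quantized images is biased upward by
  plug-in estimation (more windows than repeats of each
  configuration); compare values only across images of the same size
  and M.
* The VIF filter's alphabetical tie-break is a convention; genuinely
  tied predictors are scientifically interchangeable there.
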