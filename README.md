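# greenmig

Image-derived habitat complexity and bat-response modelling for urban
green spaces.

Structural complexity — how much vegetation there is and how it is
arranged — shapes where insectivorous bats can fly, echolocate and
hunt. Measuring it in the field (cover boards, tree inventories) is
slow; `greenmig` implements the image-based alternative: **mean
information gain (MIG)**, a spatial-entropy index computed from
ordinary photographs, together with the full analysis pipeline that
relates complexity to bat activity and species richness. It is aimed
at urban ecologists and bat researchers who want to score many sites
quickly and fit the standard response models in one reproducible run.

## The index

For the HSV value channel of an image, quantized into `M` bins,

```
MIG = (H₄ − H₁) / ((k − 1) · ln M),        k = 4
```

where `H₁` is the Shannon entropy of single-pixel intensities
(aspatial heterogeneity) and `H₄` the entropy of sliding 2×2-pixel
configurations (spatial heterogeneity). MIG is 0 for uniform or
perfectly periodic scenes and tends to 1 for spatially random ones;
vegetation photographs fall in between, higher for more complex
structure. Each site is summarized from five views: `mig_sides` (four
cardinal views), `mig_top` (upward canopy view) and their combination
`mig_all`.

Around the index, the package provides:

* **field_vegetation** — cover-board reductions: clutter per height
  class, Shannon vertical heterogeneity, cover/height means, tree
  densities with strict DBH thresholds;
* **acoustic_response** — bat activity (median of nightly summed
  call-sequence lengths) and species richness over a closed 14-taxon
  vocabulary with acoustic-group merging, totals and functional-guild
  (edge-space / open-space forager) summaries;
* **stats_pipeline** — Pearson screening, iterative VIF filtering,
  standardization, Gaussian mixed models with a green-space-type
  random intercept, Poisson/quasi-Poisson richness GLMs, bidirectional
  stepwise AIC, pseudo-R²;
* **synthetic_data** — a generator that emulates the full study design
  (9 green-space classes × 4 size quartiles × 5 sites, 3 survey
  nights, five photographs per site) with known effect structure;
* a thin CLI (`greenmig simulate|mig|veg|responses|run`).

## Worked example

`examples/01_image_complexity.py` scores two constructed scenes:

```
  lawn: MIG = 0.006 (H_marginal = 0.693, H_joint = 0.716 nats, M = 4)
canopy: MIG = 1.000 (H_marginal = 1.386, H_joint = 5.543 nats, M = 4)
```

The smooth lawn gradient is nearly ordered — its 2×2 neighbourhoods
add almost no information beyond the pixel histogram — while the
speckled canopy is spatially random, so each neighbourhood carries
four pixels' worth of fresh information and the normalized gain is 1.

`examples/03_bat_responses.py` reduces a small call-record table:

```
site_id  activity_total  richness_total  activity_edge  ...
      A            53.0               3           53.0
      B             4.0               2            0.0
```

Site A's nightly totals are 53/65/47 s, so its activity is the median
53; its P. kuhlii and P. nathusii records merge into one acoustic
group, giving richness 3. Site B had two near-silent nights, which
dominate the median.

The remaining examples run a complete simulated study
(`04_simulated_study.py`) and check that the activity mixed model
recovers the generator's known coefficients (`05_parameter_recovery.py`).

The same stages are available from the shell:

```bash
greenmig simulate --seed 7 --profile tiny --out study/
greenmig run --data study/ --out report/ --bins 8 --response activity_total
```

which writes per-stage CSVs (`mig.csv`, `descriptors.csv`,
`responses.csv`, `correlations.csv`, `coefficients.csv`) and a JSON
run manifest that suffices to reproduce the run.

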