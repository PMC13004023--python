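# nichedyn

Tools for quantifying how the realized climatic niche of an introduced
species differs between its native range and the region it was introduced
to, for modelling what drives those differences, and for measuring how
niche change degrades the transfer of native-range suitability models.

The package is aimed at invasion macroecologists who work with gridded
climate and presence data. Because global range and climate datasets are
large and license-encumbered, everything here is exercised on *virtual
species*: a built-in generator creates two-region worlds with known niche
geometry, so every estimator in the package can be scored against analytic
ground truth.

## What it computes

**Niche dynamics.** For one species × realm comparison, climates of both
regions are pooled into a correlation-matrix PCA; occurrence densities are
kernel-smoothed on a shared R×R grid (R = 100) in the first two axes; and,
restricted to *analog* climates (conditions available in both regions),
three density-weighted indices are computed:

- expansion `E` — share of the alien occupancy density in climates not
  occupied in the native range;
- stability `S = 1 − E`;
- unfilling `U` — share of the native occupancy density in climates not
  occupied in the alien range.

Climate novelty is screened with the two extrapolation-detection scores
(`NT1` ≤ 0 for univariate range extrapolation, `NT2` ≥ 0 for Mahalanobis
combinational novelty), and indices are binarized at ≥ 0.1 for mapping and
summaries.

**Drivers.** Eleven species-by-realm covariates (range size and loss,
dispersal, fast-growth index, specialization `ln(100/(foods × habitats))`,
introduction effort `√(locations × pathways)`, residence time, insularity,
human disturbance, native-mammal richness, community similarity) are
transformed (Yeo-Johnson / Box-Cox / log), standardized, and VIF-screened.
A binary expansion outcome (threshold from exact 1-D 2-means clustering) is
modelled with a binomial-logit mixed model and the √-transformed unfilling
proportion with a beta-logit mixed model, each with random intercepts and
the random effects integrated by a Laplace approximation. All 2^11 = 2048
additive candidate models are ranked by AICc, nested variants of better
simpler models are discarded, and estimates are *full-averaged* (absent
coefficients count as zero) over the ΔAICc < 4 confidence set with Akaike
weights.

**Transferability.** A native-range ensemble of boosted classification
trees (5 pseudo-absence sets × 3 stratified 70/30 splits, 200 shallow
trees, replicates kept when calibration AUC > 0.7) is projected to the
alien region with range clamping and scored against alien presences with
AUC, maximized TSS, Sensitivity, Specificity, and the Continuous Boyce
Index, under a tiered pseudo-absence fallback. Mixed models then relate
each metric to the realized expansion and unfilling.

## Worked example

```
python analysis/01_simulate_world.py --seed 1
python analysis/02_niche_dynamics.py --seed 1
```

prints

```
wrote 3 scenarios to results/world
  conserved  true E = 0.000, true U = 0.006
  unfilled   true E = 0.000, true U = 0.496
  expanded   true E = 0.598, true U = 0.598
scenario     estimated E (true)   estimated U (true)   novel climate %
  conserved  0.034 (0.000)       0.026 (0.006)       37.6
  unfilled   0.028 (0.000)       0.417 (0.496)       37.1
  expanded   0.563 (0.598)       0.597 (0.598)       37.4
```

Three virtual species share a Gaussian climatic niche. The first colonizes
the alien region freely (conserved niche: E ≈ U ≈ 0); the second reaches
only climates on one side of its optimum, leaving half of the native
occupancy mass unfilled (U ≈ 0.5); the third shifts its optimum into
conditions unused natively (E ≈ 0.6). The pipeline recovers each truth to
within ±0.1; roughly a third of alien-background cells are climatically
novel (the alien region extends beyond the native envelope), which is
exactly what the analog-climate restriction excludes from the indices.

`analysis/03_driver_inference.py` then recovers all eight built-in driver
effects by full model averaging (e.g. introduction effort on expansion:
true +0.8, averaged +1.06 with 95% CI [+0.74, +1.39]), and
`analysis/04_sdm_transferability.py` shows the directional fingerprint of
niche change on model transfer — optimum shifts degrade discrimination
(median AUC 0.96 → 0.82) and calibration (CBI 0.92 → 0.23), while patchy
colonization leaves sensitivity high (97.7%) but drags the Boyce index
down (0.53).

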