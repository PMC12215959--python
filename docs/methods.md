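# Methods notes

This note records the models implemented in `reefaes`, the parameter
choices that matter, the numerical decisions, and what the synthetic
data can and cannot establish.

## Synthetic quadrat generator

**What it emulates.** Overhead 50×50 cm benthic quadrat photographs
from three habitat conditions. Coral colonies are parametric shapes per
growth form (dendritic strokes for branching, lobed blobs for
massive/submassive, discs for tabulate/mushroom, elongated ellipses for
encrusting, annuli for foliose, short thick strokes for digitate) over
a sand/rubble substrate, with hexagonal restoration-frame bars in the
restored habitat and near-black shadow painted next to colonies. The
label mask is pixel-exact: ground-truth covers are the realized pixel
fractions, not the sampled targets.

**Cover sampling.** Per-quadrat coral and rubble covers are drawn from
[0, 100]-truncated normals. Truncation shifts the mean of a plain
truncated normal by several points at the habitat presets' parameter
values, so the generator solves for the underlying normal location such
that the *post-truncation* mean equals the preset mean (deep tail
targets use the asymptotic location `-sd²/target`). When the two draws
exceed 100% combined, the habitat's dominant substrate keeps its draw
and the minor one is capped at the remainder; a joint rescale would
bias both means low. Batch means therefore reproduce the preset means
to well under one percentage point before sampling error.

**Site structure.** The preset SDs describe the total within-habitat
spread. The study pipeline splits them into a between-site component
(SD 14 cover points for coral, 12 for rubble, drawn once per site) and
the residual within-site SD (`HabitatPreset.site_realization`), keeping
the habitat-level statistics while giving sites distinct means — the
variance structure a site-level random intercept is meant to absorb.

**Colour realism and why it matters.** Real benthic photographs have
colour statistics that are only loosely coupled across feature axes:
rubble carries variable turf cover, sand runs from neutral grey to warm
cream, colonies of one species may be pale or vivid, and a high-cover
stand can be monochrome. The generator reproduces this with per-quadrat
substrate tints (sand grey↔cream, rubble grey↔turf-brown), brown
algae-covered rock patches, an occasional pale-colony probability, and
a per-quadrat random subset of the habitat colour palette. Without
these, grey share is an almost deterministic complement of coral cover
(r ≈ −0.96) and the collinearity screen collapses the feature set —
unlike real data, where the screen removes only the grey/diversity
pair.

**Latent aesthetic model.** The latent score is a linear combination on
the Elo scale (400-point base-10 logistic), so that choice simulation
and rating recovery are self-consistent:

```
score = 2600·colour_simpson + 6·pct_live_coral + 40·n_morphologies
        + 0·pct_rubble + N(0, 60)
```

`colour_simpson` is the rendered photograph's own 64-bin Gini–Simpson
diversity — respondents judge the image, so the image's colour
diversity is the natural driver — and the weights are calibrated so
that colour diversity ranks first and live coral cover second among
the measured features' associations with the score, the ordering the
analysis is designed to detect. The weights give diversity and cover
comparable SD contributions (~500 and ~200 Elo points) against 60
points of taste noise; rubble carries no penalty beyond the cover and
colour it displaces. This latent structure is a stand-in for recovery
testing, not a claim about human perception.

**Respondents.** Socio-cultural attributes are drawn from the survey
population's published marginal frequencies (country, education,
diving experience, coral knowledge; gender and age filled with
plausible values); 2.87% of respondents report colour-vision deficiency
and are excluded before rating. Each respondent judges 30 distinct
random pairs; A beats B with probability `1/(1+10^((s_B − s_A′)/400))`.
Attribute effects enter as an additive shift on the first-presented
photo's score for carriers of a level — the only main-effect structure
a binomial left-win GLMM can detect — and default to zero.

## Elo rating

Defaults: start 0, k = 100, 1,000 order-bootstrap runs. The absolute
scale is irrelevant downstream (every analysis is rank-based or
location/scale-free), so the start value is a convention; zero makes
the exact zero-sum invariant (mean rating = start after any run) easy
to verify. The bootstrap is vectorized as a runs × photos rating matrix
updated one record-position at a time, with per-run shuffle substreams
spawned from one master seed.

## Predictor

A compact convolutional regressor trained from scratch:
5×5 conv (stride 2, 16 ch) → ReLU → 2×2 mean-pool → 3×3 conv (32 ch)
→ ReLU → global mean *and mean-square* pooling, concatenated with the
input's per-channel mean/SD → linear head. Second-moment pooling lets a
linear readout represent sum-of-squared-share statistics — the family
colour diversity belongs to; without it the model systematically
under-transmits the diversity signal. Training: Adam (lr 3·10⁻³, batch
32, 40 epochs), MSE on ratings standardized by the training mean/SD,
augmentation by ±180° rotation with reflect padding plus horizontal and
vertical flips, parameters restored from the best-validation epoch.
Inputs are 64×64 crops produced by nearest-neighbour subsampling:
interpolation invents blended colours and measurably degrades the small
image's colour-diversity fidelity to the rated full-size image
(r = 0.981 bilinear vs 0.9999 nearest). Backpropagation is exact
(verified against numeric differentiation at 10⁻¹¹ relative error).
A linear model on the nine extracted features is available as a
transparent baseline backend.

## Statistics

**Collinearity screen.** Iteratively, the most correlated offending
pair (|r| > 0.7) is examined and the member with the weaker absolute
correlation to the rating is removed; ties keep the alphabetically
first name; constant features are dropped with a warning.

**Stepwise OLS.** Features scaled to unit variance, response unscaled;
the largest-p feature with p > 0.05 is deleted per iteration,
alphabetical tie-break for determinism.

**Importance.** LMG: each feature's sequential R² increment averaged
over all orderings of entry, computed exactly through the subset-weight
identity over all 2^k subsets (refused above k = 10), normalized to
percent. Squared-standardized-coefficient shares are available as an
alternative; outputs are labelled with the method.

**Mixed models.** The Gaussian random-intercept LMM is fitted by direct
maximization of the closed-form marginal likelihood (Woodbury inverse
per group, β profiled by GLS); ML for the likelihood-ratio test, REML
refit for estimates and standard errors. Gamma(log), Poisson and
binomial GLMMs use adaptive Gauss–Hermite quadrature (15 nodes centred
and scaled at the per-group Newton mode of the concave log-integrand)
with L-BFGS-B over (β, log σ_u, [log shape]). Both fitters agree with
`statsmodels.MixedLM` / `lme4::glmer` to ≲10⁻³ on shared problems and
tolerate the σ_u = 0 boundary (flagged `singular`, never fatal).
Simpson values of exactly 0 are nudged to a tiny positive value before
Gamma fits (support excludes 0) and the nudge is recorded in the result
notes.

**Post-hoc contrasts.** All three habitat contrasts on the linear
predictor scale; family-wise adjustment by the exact trivariate-normal
distribution of the max-|z| statistic (so adjusted p ≥ raw p always);
compact letters by maximal-clique cover of the not-separable graph,
ordered by estimated means.

**Respondent effects.** One binomial GLMM (left-photo-wins response,
photo random intercept, dummy blocks per attribute); per-attribute
Wald chi-square block tests from the single fit — the standard
analysis-of-deviance table for mixed models — with single-level
attributes dropped with a warning.

## Calibration and problem sizes

The default study runs at 3 habitats × 6 sites × 50 photos (900
images, 192 px renders), a 300-photo survey subset, 300 respondents ×
30 choices, 1,000 Elo bootstraps, and a 64 px CNN — a desk-scale
configuration chosen so the complete chain (including the acceptance
script) runs in minutes on one CPU. Test simulations use the smallest
sizes at which each property is decidable: rating recovery at 100
photos × 6,000 choices, predictor recovery at 300 photos, LRT power at
the study's own 6 sites × 50 images, LRT null calibration at 15 sites ×
15 images per habitat and 1,000 replicates.

The null calibration deliberately uses more sites than the study
itself: with only 6 sites per habitat the asymptotic χ² reference for
the LRT is intrinsically liberal (rejection ≈ 0.07–0.09 at nominal
0.05, measured identically with this package's fitter and with
statsmodels), a small-cluster property of the method rather than of the
implementation. At 15 sites the test is calibrated (≈ 0.05–0.06).
Habitat p-values from 6-site designs should therefore be read as mildly
anti-conservative near the threshold; the habitat effects the study
design targets are far from it.

## What passing tests do and do not show

The synthetic study demonstrates that the pipeline recovers known
structure: latent ratings (Spearman ≥ 0.98 at survey scale), predictor
signal (held-out R² ≈ 0.85–0.93 on signal, ≈ 0 on shuffled labels),
habitat contrasts (restored ≈ healthy, both above degraded), and the
designed importance ordering (colour diversity, then live coral cover).
It does not show that real photographs are this predictable, that human
preference is linear in these features, or that a from-scratch CNN at
64 px matches a fine-tuned deep network on real reef imagery. Two
residual synthetic-vs-real differences: the colour count and morphology
count correlate with diversity/cover above the 0.7 screen threshold
here and are filtered out, whereas field data kept them in the final
model; and the rendered scenes contain no fish, water-column effects or
lighting gradients.
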