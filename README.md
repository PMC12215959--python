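# reefaes

Quantifying the aesthetic value of coral-reef benthic communities — from
pairwise human preferences between quadrat photographs to Elo aesthetic
ratings, image colour/shape features, a trainable image-to-rating
predictor, feature-importance decomposition, and mixed-model comparison
of healthy, restored and degraded reef habitats.

The package is aimed at reef-restoration scientists and quantitative
ecologists who want to measure a reef's visual appeal as an ecosystem
service: does active restoration of a blast-fished rubble field recover
not just coral cover, but the *look* of a healthy reef? Every stage of
the analysis runs on synthetic quadrat photographs with pixel-exact
ground truth, so the whole chain — rating recovery, predictor accuracy,
statistical calibration — is verifiable end to end without any field
data.

## The analysis chain

1. **Pairwise preferences → Elo ratings** (`reefaes.elo`).
   Respondents choose the more beautiful photo of a random pair. After
   each choice the winner gains and the loser loses
   `k·(1 − E_w)` rating points, where

   `E_w = 1 / (1 + 10^((r_loser − r_winner)/400))`

   is the winner's expected score. Because the result depends on
   processing order, the sequence is re-shuffled (1,000 bootstrap runs
   by default) and per-photo means and SDs are reported.

2. **Colour and shape features** (`reefaes.imaging`,
   `reefaes.annotation`). Each standardized photograph (700×700 px) is
   reduced to a 64-bin RGB *colour thumbprint* (4 equal divisions per
   channel); bins merge into black / blue / green / yellow / grey /
   other groups; colour diversity is the Gini–Simpson index
   `1 − Σ p_i²` plus a count of bins holding >1% of pixels. Benthic
   cover comes from 50 random point intercepts on the annotation mask
   (each hit = 2% cover) and coral growth forms (branching, digitate,
   encrusting, foliose, massive, submassive, mushroom, tabulate) are
   counted as a shape-diversity proxy.

3. **Image → rating predictor** (`reefaes.predictor`). A compact
   convolutional regressor trained from scratch on 64×64 crops with a
   70/15/15 train/validation/test split, rotation/flip augmentation and
   best-validation-epoch selection; accuracy is the squared Pearson
   correlation between predictions and held-out ratings.

4. **Drivers and habitat comparison** (`reefaes.stats`). Features with
   pairwise |r| > 0.7 are screened (keeping the better rating
   correlate), backward stepwise OLS retains the significant set, and
   LMG decomposition (sequential R² averaged over all orderings)
   attributes explained variance per feature. Each response is compared
   across habitats with `value ~ habitat + (1 | site)` mixed models
   (Gaussian, Gamma-log or Poisson), likelihood-ratio tested against the
   null, with Tukey all-pair contrasts and compact letters. A binomial
   GLMM with a photo random intercept checks whether any respondent
   attribute (age, gender, country, education, diving experience, coral
   knowledge) shifts the choices.

5. **Synthetic study** (`reefaes.synthgen`, `reefaes.pipeline`).
   Quadrats are rendered per habitat preset (coral cover 70.5±23.0%
   healthy, 61.3±22.0% restored, 11.7±21.3% degraded; rubble 74.9±29.6%
   in degraded) with per-pixel class/morphology masks; simulated
   respondents make 30 pairwise choices each from latent aesthetic
   scores via the Elo-consistent logistic rule.

## Worked example

```python
from reefaes import synthgen, imaging, annotation, elo

# render one restored-reef quadrat with ground truth
preset = synthgen.HABITAT_PRESETS["restored"]
img, mask, truth = synthgen.generate_quadrat(preset, seed=7, side=256)

tp = imaging.colour_thumbprint(img.pixels)
groups = imaging.group_shares(tp)
fv = annotation.assemble_features(img, tp, groups, mask, seed=7)
print(f"true coral cover = {truth.true_cover['hard_coral']:.1f}%")
print(f"simpson = {fv.simpson:.3f}, n_colours = {fv.n_colours}, "
      f"point-count coral cover = {fv.pct_live_coral:.0f}%")
```

prints

```
true coral cover = 68.8%
simpson = 0.896, n_colours = 14, point-count coral cover = 70%
```

— the 50-point intercept estimate (70%) sits within sampling error of
the pixel-exact cover (68.8%), and the quadrat's colours spread over 14
of the 64 RGB bins with high evenness (Simpson 0.896). Rating a small
simulated survey:

```python
scores = {}
for s in range(6):
    _, _, t = synthgen.generate_quadrat(preset, seed=100 + s, side=64,
                                        image_id=f"photo-{s}")
    scores[f"photo-{s}"] = t.latent_aesthetic

records = synthgen.exclude_colour_deficient(
    synthgen.simulate_choices(scores, n_respondents=120, pairs_each=10, seed=0))
ratings = elo.rate(records, elo.EloConfig(n_bootstrap=200, seed=1))
print(ratings.table.round(1))
```

```
          rating_mean  rating_sd  n_comparisons
image_id
photo-0         216.6       83.7            390
photo-1         182.2       88.7            391
photo-2         -67.6       98.1            382
photo-3        -207.7       90.1            384
photo-4        -289.4       91.7            379
photo-5         165.9       95.4            394
```

Ratings are zero-sum around the start value; the order-bootstrap SD
(~90 points here) shows how much a single processing order would
mislead. The full study — 900 photos, QC, survey, Elo, CNN, regression
and habitat models — runs with:

```bash
reefaes run-all --out study_out --seed 1
```

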