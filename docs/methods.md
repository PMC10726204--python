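# Methods

## Problem setting

Plot-level yield prediction for winter wheat from UAV multispectral
imagery. The input is a table with one row per experimental plot: mean
surface reflectance in five bands (blue, green, red, red-edge, NIR),
the water-stress treatment (W1–W4), cultivar, replication, and observed
yield in t·ha⁻¹. From the five bands a library of 35 yield-sensitive
vegetation indices (VIs) is computed; the scientific question is which
subset of those 35 indices best supports a yield-prediction model, and
how much an integrated feature-selection procedure improves accuracy
over using all indices.

## The vegetation-index library

All 35 indices are deterministic arithmetic functions of the five
bands. Two dialects are shipped:

* `as_printed` (default) implements the index compilation literally,
  including forms that deviate from the wider literature — e.g.
  TVI = NDVI + 0.5 without the square root, NLI with linear 0.12·NIR
  terms instead of NIR², CCCI as a left-to-right chain of divisions,
  and ATSAVI with its literal printed constants (a trailing 1.22 where
  the literature has the soil line intercept 0.03, and the literal
  constant 1.222 where the literature has 1.22²). This dialect exists
  for reproducibility against the compilation.
* `corrected` substitutes the standard literature forms only where the
  printed form is a known typographic variant: TVI = √(NDVI+0.5),
  CCCI = NDRE/NDVI, NLI = (NIR²−R)/(NIR²+R),
  MNLI = 1.5(NIR²−R)/(NIR²+R+0.5), and ATSAVI with a = 1.22, b = 0.03,
  X = 0.08. WDRVI, MCARI and TCARI are printed in their standard forms
  already, so the two dialects agree there.

Two pairs are printed with identical formulas (GCI ≡ CIg = NIR/G − 1
and RECI ≡ CIre = NIR/RE − 1). They are kept as separate, perfectly
collinear columns because downstream subset counts treat them as
distinct features.

A zero denominator makes an index value *missing* (NaN), never a
clamped or sentinel number — silent clamping would corrupt feature
rankings. Reflectance outside [0, 1] triggers a warning, not an error,
because radiometric pipelines occasionally overshoot. Index names are
matched case-sensitively, and the table order of the 35 names is the
package-wide tie-break order.

## Integrated feature selection (PCRF-RFE)

Three classical selection families are composed:

1. **Filter (PC).** Each index is scored by |r(X, y)| where r is the
   Pearson correlation with observed yield. The magnitude, not the
   signed value, is used: strongly negatively correlated indices (RI,
   NormR, RGR) are exactly as informative as positive ones. Indices
   with score strictly above a threshold (default 0.53) are retained.
   Missing values are dropped pairwise; zero-variance columns score 0
   with a warning.
2. **Embedded (RF).** Indices are scored by random-forest permutation
   importance: a bagged ensemble of regression trees (defaults in the
   style of the classical R implementation — 500 trees, mtry = ⌊p/3⌋,
   minimum node size 5) is grown on bootstrap samples, and for each
   tree the out-of-bag MSE after permuting one feature is compared to
   the baseline out-of-bag MSE. Scores are reported as percent increase
   in OOB MSE. The retention threshold defaults to 1.9 on that scale;
   because absolute importance scales are data-dependent, a quantile
   mode (retain the top fraction) is provided as an alternative.
3. **Wrapper (RFE).** The union of the two retained sets seeds
   recursive feature elimination over a pluggable base model. Each
   iteration fits the base model on the current subset, scores the
   subset by inner k-fold cross-validated RMSE (default 10 folds), and
   removes the least important feature by the base model's own
   importance measure — attribute usage for the rule tree, permutation
   importance for the recurrent network. The best subset seen is
   tracked; "improvement" means an inner-CV RMSE strictly lower than
   the best seen minus 1e−9. Elimination stops after `patience`
   consecutive non-improving removals (default 10) or when a single
   feature remains, and the best-seen subset is returned with its full
   score trace.

Whether the original procedure scored RFE iterations on training or
cross-validated error is not documented; inner-CV RMSE is this
package's choice because training error decreases almost monotonically
with model refitting and cannot signal over-pruning. Ties everywhere
break by index-table order, so the whole pipeline is reproducible
bit-for-bit given its seeds.

## Base regressors

**Rule model tree ("cubist" family).** An M5-style model tree:
standard-deviation-reduction splits (minimum 4 rows to split, 2 per
side, growth stops when node SD < 5% of the root SD), an OLS model in
every node, bottom-up pruning that replaces a subtree whenever the
node's own penalised error (MAE × (n+ν)/(n−ν), ν = parameter count) is
no worse, and M5 path smoothing with k = 15. Node models prefer all
features when the design is full-rank and large enough, falling back to
the features used by subtree splits, then to the node mean;
rank-deficient designs (the index bank contains exactly collinear
pairs) fall through with a warning. Predictions are capped at the
training-target range extended by 5% — the extrapolation control that
rule-based model trees conventionally apply — because unconstrained
leaf-OLS extrapolation on extreme ratio-index values occasionally
destabilised validation folds. One committee, no instance-based
correction; fitting is deterministic. A tree with no admissible split
reduces exactly to the global OLS fit.

**Recurrent regressor ("rnn" family).** The d features of a plot
(index-table order) are presented as a length-d sequence of scalars to
a single Elman recurrent layer (hidden size 32, tanh); the final hidden
state maps linearly to yield. Training is full-batch backpropagation
through time with Adam (learning rate 0.01), at most 500 epochs, early
stopping on a seeded 20% held-out split with patience 25 and
best-checkpoint restore. Features and target are z-scored internally
from the training data; the rule tree, by contrast, consumes raw
features (model trees need no scaling). The scalar-per-step sequence
arrangement and all architecture constants are this package's choices
— nothing about feeding a tabular feature vector to a recurrent
network is standardised — and all are exposed in the model spec.
Non-finite training loss raises an error naming the epoch.

Both families serialize to JSON and reload with bit-identical
predictions (Python float repr round-trips exactly).

## Evaluation

Accuracy is R² = 1 − SS_res/SS_tot and RMSE = √(Σ(ŷ−y)²/N) in t·ha⁻¹,
estimated by k-fold cross-validation (default k = 10): a seeded random
partition (stratified-by-treatment mode available), each fold once as
validation, per-fold metrics averaged. R² is recorded as NaN on a
degenerate validation fold (size 1 or constant observations, e.g.
leave-one-out) and the mean is taken over defined folds. Descriptive
yield statistics use the sample SD (n−1), type-7 linear-interpolation
quartiles, and CV = SD/mean in percent. Treatment comparisons are
Welch two-sample t-tests (two-sided, Welch–Satterthwaite df), chosen
because treatment yield SDs differ markedly; p-values are reported raw
to match the convention of the motivating analysis, with an optional
Holm adjustment.

## Synthetic trial generator

The restricted field data are emulated by a seeded generator with the
same design: 4 irrigation treatments × 10 cultivars × 3 replications =
120 plots. Defaults reproduce the observed treatment yield moments
(means 7.77/8.32/8.97/8.19 t·ha⁻¹, SDs 1.56/1.39/1.19/1.26 t·ha⁻¹).
Per plot, a latent canopy-vigor deviate u ~ N(0,1) drives both yield
(yield = treatment mean + cultivar intercept + s_t·(a·u + √(1−a²)·ε),
truncated at 0.1 t·ha⁻¹; a = signal strength ∈ [0,1], default 0.9;
cultivar intercepts ~ N(0, 0.3 t·ha⁻¹); s_t scaled so the treatment SD
matches its configured value) and the bands: NIR increases (+0.06 per
vigor unit) and red decreases (−0.03) with the full vigor signal
z = a·(treatment shift + u), while blue, green and red-edge are
independent noise. Band noise SD defaults to 0.02 reflectance units.
One global seed drives a per-plot counter-based substream, so record
order can never change results.

Routing the signal through bands (rather than injecting it into chosen
index columns) makes the strongly inter-correlated index families of
real canopies arise naturally. The defaults were calibrated so that the
default trial reproduces the selection structure reported for the real
experiment — roughly 25 indices above the 0.53 PC threshold, 13 above
the 1.9 RF threshold, and a union near 26.

Two consequences of the band-mediated design matter for interpreting
tests. First, *every* index inherits some signal (all 35 involve NIR
or red), so no library index is pure noise on a raw trial; recovery
tests therefore use `planted_only_vitable`, which decouples every
non-planted column by a seeded within-column permutation (preserving
marginals) to produce the "three informative indices among noise"
condition. Second, permutation importance is diluted among the ~15
near-collinear NIR/red indices, which is a well-known property of the
measure, not a defect of the forest. The band model is phenomenological
— no radiative transfer, no configured inter-band covariance — so
passing tests demonstrate correct selector behaviour under a plausible
correlation structure, not performance on real canopies.

## Problem sizes used in automated checks

Selector-recovery rates are estimated over 100 seeds (150-tree forests,
inner RFE CV of 5 folds); the pipeline-ordering property (selected
subset beats all 35 features for the rule tree) over 20 seeds; the
determinism check runs the full two-model pipeline twice at 150 trees.
These sizes give stable pass/fail margins while keeping a full run in
the minutes range on one core.

## Known limitations

* The `as_printed` ATSAVI/IVI/NLI constants are reproduced without
  errata; their scientific interpretation is doubtful, and the
  `corrected` dialect should be preferred for real analyses.
* The RF importance threshold 1.9 is on the percent-increase-in-OOB-MSE
  scale; other importance conventions are not directly comparable, so
  quantile mode is recommended when transferring to new data.
* The recurrent regressor is a minimal baseline, not a tuned deep
  model; it exists to make the two-base-model comparison runnable.
* Yields are truncated at 0.1 t·ha⁻¹; with default moments the
  truncation is essentially never active.
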