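# Methods

## The problem

When whole blood waits between draw and centrifugation, cellular metabolism
keeps running: glycolysis consumes glucose and produces lactate and pyruvate,
cooling-induced hemolysis releases lipids, and many other plasma constituents
shift. In biobanked sample collections the pre-centrifugation delay time and
temperature are often poorly documented ("legacy" samples), so these
handling-induced changes masquerade as biology. plasmadrift models the
handling drift of NMR metabolomics feature tables, predicts unknown handling
conditions from the data themselves, and corrects intensities back to a
common reference state (1 h delay).

## Normalization (PQN)

Sample-wise intensities are normalized by the probabilistic quotient: for
sample *i* with reference spectrum *r*,
`factor_i = median_f { x_if / r_f : x_if > 0, r_f > 0 }` and
`x'_if = x_if / factor_i`. The reference defaults to the feature-wise median
spectrum of the table; an external reference (e.g. the training batch's
median spectrum) can be supplied so that a later batch with a global
peak-shape shift is normalized onto the training scale before prediction or
correction. No total-area pre-normalization is applied.

A known limitation: PQN assumes the majority of features do not change
between samples. Late in the delay course the drift is asymmetric (strong
increases outweigh decreases), which biases the median quotient by a few
percent and makes weakly drifting features appear slightly anti-drifting.
In practice this inflates the irreproducible-feature count (the flatness
tolerance absorbs only part of the bias); the drift clusters and their
correction are essentially unaffected because the bias is shared by all
features of a sample.

## Drift modeling

Per temperature, with the 1/3/8/24/36 h design:

1. **Fold-change profiles.** For subject *s*, feature *f*:
   `FC_f(s, t) = x_f(s, t) / x_f(s, t_ref)` with `t_ref = 1 h`. This removes
   subject baselines and makes drift multiplicative and comparable across
   features. The mean profile averages FC over subjects. Features with a
   non-positive intensity anywhere (division impossible) are set aside as
   unassignable.
2. **Reproducibility filter.** Reproducibility = median pairwise Pearson
   correlation between subjects' log FC profiles (pairs involving a
   zero-variance profile contribute 0). A feature is excluded as
   *irreproducible* iff reproducibility < 0.5 **and** its mean profile
   departs from flat by more than 0.05 absolute log units at some time
   point; flat-but-noisy features stay in as "stable" because a flat profile
   has no shape to agree on. Both knobs are config-exposed
   (`DriftConfig.repro_threshold`, `flat_tol`).
3. **Clustering.** Hierarchical agglomerative clustering (average linkage,
   Euclidean distance on log mean profiles); the cluster count k is chosen
   in 2–30 by maximum mean silhouette width, ties toward the smallest k.
   Identical profiles collapse to a single cluster.
4. **Drift functions.** Each cluster's mean profile is fitted with a natural
   cubic spline — interpolating when there are at most 5 time points (the
   study design), a generalized-cross-validation smoothing spline for richer
   designs — then re-anchored by dividing by its value at `t_ref`, so
   `g_c(t_ref) = 1` exactly. Evaluation outside the observed range clamps to
   the boundary (extrapolating a cubic is unsafe; clamping is conservative).
   If an anchored spline dips non-positive anywhere on a dense grid, the
   cluster falls back to a piecewise-linear interpolant with a warning:
   drift factors must stay positive for multiplicative correction.

Every input feature ends up in exactly one cluster or on the excluded list —
the accounting is asserted after each fit.

## Correction

For sample *i* at time `t_i`, feature *f* in cluster *c*:
`x'_if = x_if / g_c(t_i)`. Excluded features pass through unchanged and are
reported (downstream users decide what to do with them). Times come from
recorded metadata or from model predictions; the prediction route classifies
temperature first, then regresses time with the temperature-matched model,
clamps to the fitted range and applies the matched drift model. Correction
refuses to run when less than 95% of the model's features are present
(config-exposed). Because `g_c(1) = 1`, misrouting a sample with a true
delay near 1 h is nearly harmless: both temperatures' corrections are close
to the identity there.

## Predicting handling conditions (rdCV random forests)

Temperature (4 vs 22 °C) is a two-class random-forest problem; delay time is
a per-temperature random-forest regression. Both run inside repeated double
cross-validation:

* outer folds (default 6) provide strictly held-out predictions;
* inner folds (default `n_outer - 1`) perform recursive variable
  elimination: forests are fitted along a schedule of decreasing variable
  counts (`ceil(var_ratio × current)`, default ratio 0.75, down to 2),
  variables ranked by forest importance within each inner training fold;
  the count minimizing mean inner fitness (misclassification count or RMSEP)
  wins, ties toward fewer variables;
* the outer-fold model is refit at the winning count on the consensus
  ranking and predicts only its held-out fold;
* everything repeats over `n_rep` (default 20) random partitions, and
  per-sample predictions are averaged (class-vote fractions or hours).

Variable ranking never sees the outer fold — that is what makes the
selection unbiased. Q² = 1 − PRESS/TSS is computed from the cross-validated
predictions only; R² from the consensus-ensemble refit on all data, so
Q² ≤ R² on simulations. Fold partitions are stratified (by class, or
snake-dealt across outcome quantiles for regression) and subject-aware by
default: all samples of one subject stay in the same fold, since subject
baselines would otherwise leak across folds and inflate performance.
Forests use the conventional mtry defaults (√p classification, p/3
regression). Consensus variable sets of minimal / middle / maximal size
across the repetitions' optima are kept; external prediction uses the middle
set, with exact class ties broken toward the training-majority class.

**Permutation testing.** The full rdCV procedure is refit on outcome
permutations (default n = 100; permutation refits may reduce `n_rep`,
recorded in the result). `p_empirical = (#{null ≤ observed} + 1)/(n_perm+1)`
is floor-limited at `1/(n_perm+1)`; a one-sided Student-t tail fitted to the
null values (`p_parametric`) is reported alongside because a strongly
separated observation deserves a smaller value than the permutation count
can resolve.

## The synthetic generator

The generator draws the full study design: 16 subjects × {1, 3, 8, 24, 36} h
× {4, 22} °C × 478 features,

`x(s, f, t, T) = baseline(s, f) · g(f, T, t) · dilution(s, t, T) · ε`

with log-normal subject baselines (sd 0.3), per-sample dilution (sd 0.1),
and measurement noise (sd 0.05, all on the log scale). Population feature
levels are a deterministic property of the simulated assay, shared between
independently seeded draws — which is what lets an "external batch" be
scored by a model trained on another draw. Drift curves are
exponential-saturation kinetics anchored at draw time (t = 0), so the two
temperatures already differ slightly at the 1 h reference — drift from
needle to 1 h happens at temperature. The default planted clusters:

| cluster | archetype | n | max log2 FC at 22 °C | cold attenuation | τ (h) |
|---|---|---|---|---|---|
| lactate-like | increase | 90 | 1.8 | 2.5 | 20 |
| pyruvate-like | increase | 50 | 0.55 | 1.1 | 8 |
| lipid-like | increase | 40 | 0.25 | 0.25 (cold-enhanced) | 6 |
| glucose-like | decrease | 130 | 0.8 | 3.5 | 16 |
| stable | — | 90 | 0 | — | — |
| 3 h excursion | transient | 50 | 0.6 | 4 °C only | — |

plus 28 irreproducible features whose log2 fold-changes are independent
uniform draws per subject and time point. Effect sizes were calibrated so
the planted clusters reproduce the per-cluster CV magnitudes typical of
delayed-processing studies (strongest increase cluster CV ≈ 0.6 at 22 °C,
decrease ≈ 0.35–0.4); the heterogeneous cold attenuations (glycolysis slows
strongly, pyruvate barely, hemolysis-driven lipid release is stronger in the
cold) are what make temperature identifiable from a single sample — a single
global attenuation factor would make a 4 °C/36 h sample mimic a 22 °C/~5 h
sample. The excursion archetype is a unimodal bump (zero at 1 h, peak near
3.3 h, zero from 8 h) active only at 4 °C.

The legacy-batch generator draws independent donors at 22 °C, one sample
each, with true times uniform inside three documentation levels
(3–8, 8–24, 24–30 h) of which only the level label is exposed, plus a
global multiplicative batch factor removed by PQN against the training
reference.

What the generator does **not** emulate: peak overlap and alignment errors,
heteroscedastic noise across the intensity range, correlated noise between
neighboring chemical-shift features, non-stationary subject physiology, and
drift kinetics outside the planted archetype families. Passing recovery
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not performance guarantees on real spectra.

## Evaluation

Data quality is the per-feature CV (sample sd / mean) pooled over all
samples spanning 1–36 h (a per-subject variant would condition out
between-subject spread; the pooled form is the package's reporting choice).
Cluster reports aggregate member features and test the paired CV change with
a two-sided Wilcoxon signed-rank (star-coded at 0.05/0.01/0.001; p is NaN
for single-member clusters and 1 when nothing changed). Deviation surfaces
pool `x/x_ref(subject) − 1` over subjects × features per time point and
report requested quantiles; columns are non-decreasing in the percentile
level by construction. Predicted times across coarse groups are compared by
one-way ANOVA with Tukey-HSD adjusted pairwise tests.

## Numerical and scale choices

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seed + config + data give
  bit-identical models.
* Model documents are versioned JSON; drift splines round-trip through
  their piecewise-polynomial coefficients (≤ 1e-10), prediction models
  embed their training data and refit their forests deterministically on
  load, so reloaded models predict identically.
* The test-suite and acceptance runs use scaled-down rdCV settings
  (n_rep 3, 150–300 trees, elimination ratio 0.5; permutation tests at
  n_perm 20 with n_rep 1, and on reduced feature subsets where noted) —
  chosen as this package's single-CPU defaults for its own validation runs;
  the library defaults remain n_rep 20 / 500 trees / ratio 0.75 / n_perm
  100.
* Silhouette ties, inner-fitness ties, and class-vote ties all break
  deterministically (smallest k, fewest variables, training-majority
  class).

## Known limitations

* The irreproducibility filter keys on between-subject correlation of log
  fold-changes; with only 5 time points its power is limited, and the PQN
  bias described above pushes some genuinely stable features over the
  flatness tolerance. They are excluded from modeling but pass through
  correction unchanged, so the cost is coverage, not bias.
* Correction assumes cluster-homogeneous kinetics; a feature whose true
  kinetics sit between two clusters is corrected with its cluster's average
  curve.
* Random-forest time regression cannot extrapolate beyond the training
  range; predicted times are clamped to [1, 36] h, and predictions compress
  toward the interior near the boundaries.
* At a true delay near the reference time the temperature signal is
  intrinsically weak; temperature misclassification concentrates there,
  where the correction consequences are smallest.
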