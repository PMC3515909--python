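# Methods

This note records the statistical procedures metavote implements, the
assumptions behind them, the design choices that were genuinely open, and
what the synthetic test-bed does and does not establish.

## Data model

A *study* is a genes × samples matrix of log-scale expression values with
a binary outcome per sample (1 = metastasis, the minority class), a
platform tag, and a role: *feature definer* (used only for gene
selection), *training set*, or *test set*. Training studies may double as
feature definers — that mirrors the protocol being re-enacted and is one
of its acknowledged information leaks (see "Leakage modes").

## Synthetic multi-study generator

Per study, baseline expression is i.i.d. Normal(0, `noise_sd`) per gene
and sample; the `n_planted` planted genes get an additive shift of
`effect_size · noise_sd` in metastasis samples only, so `effect_size` is
a standardized mean difference in σ units. Each platform then applies a
fixed per-gene linear distortion `x → a_g·x + b_g`, with
`log a_g ~ N(0, platform_scale_sd)` and `b_g ~ N(0, platform_shift_sd)`.
Class counts are fixed by rounding (`round(metastasis_fraction ·
samples_per_study)`), not sampled — the class balance is a condition of
the experiment, not a random variable. Planted genes always belong to
the cross-platform shared gene set so the pool-intersection step can in
principle recover all of them.

Defaults (the study conditions used throughout the calibration tests):
8 studies of 60 samples on two 2000-gene platforms sharing half their
genes, 50 planted genes at effect 1.0, 25% metastasis fraction,
`noise_sd` 1.0, platform scale/shift sds 0.25/0.5. No published estimate
of cross-platform distortion magnitude exists for this design, so the
distortion sds are free parameters, not calibrated to any platform pair.

What the generator deliberately does **not** model: probe-level effects,
two-channel dye chemistry, correlated gene modules, heavy-tailed noise,
censored survival times, or nonlinear platform response. Consequently,
passing tests show the *pipeline* behaves as specified under its
generative assumptions; they say nothing about absolute accuracies
attainable on real cohorts.

## Cross-study rank feature selection

Within each study, gene *g* is scored by the signal-to-noise ratio
`(m₁ − m₀) / (s₁ + s₀)` with sample standard deviations (n−1
denominator; the population/sample choice is not determined by the
protocol being re-enacted — sample sd was chosen). The denominator is
floored at 1e−8 so constant genes are defined. Rank 1 is the most
positive statistic; ties are broken by lexicographic gene id, which makes
every run reproducible. Ranks are normalized to `rank/(n+1) ∈ (0,1)`
because platforms have different gene counts and raw ranks are not
comparable; the per-gene mean normalized rank is taken over the studies
containing the gene, with genes in fewer than `min_studies` studies
(default: all) dropped.

**Permutation null.** Outcome labels are permuted independently within
each study, statistics re-ranked, and mean normalized ranks recomputed.
The two-sided p-value for gene *g* asks how often `|mean rank − 0.5|`
is at least the observed value under the null. Because all genes present
in the same number of studies have exchangeable null mean ranks, the
null is **pooled across genes within each such stratum**. This is the
load-bearing numerical choice: a per-gene null with B permutations
cannot produce p-values below 1/(B+1), and in a screen of m genes the
Benjamini–Hochberg threshold for k discoveries is 0.05·k/m — with
m = 2000 and B = 200 that is below 1/201 for any k < 50, so a per-gene
null could never select anything at practical permutation counts.
Pooling gives resolution 1/(n_genes·B) at no extra simulation cost.
Sampled p-values carry the +1 correction; when the joint space of
distinct within-study label assignments is no larger than the requested
number of permutations, it is enumerated exhaustively and p-values are
exact (this path is verified against an independent brute-force oracle).
Selection is at BH q ≤ 0.05, the conventional FDR cutoff.

## Preprocessing

Standardization is **per gene within a study** (mean 0, sample sd 1
across that study's samples; constant genes map to zero rows). Whether
the original protocol standardized per gene or per array is not stated;
per gene is the reading that makes gene-wise classifier features
transferable and is the conventional one. Each dataset is standardized
with its *own* statistics — test sets are not normalized with training
parameters, mirroring a protocol that normalizes all datasets up front.
A consequence used below: any per-gene linear distortion applied
*before* standardization is removed exactly by it.

Gene matching restricts studies to pool ∩ (genes in every study), in
pool order, identical in all studies. Duplicate symbols within a study
collapse to the highest-variance row (common microarray practice), first
row on exact ties.

## Classifiers and model building

Seven methods, all via scikit-learn: random forest (`ntree` grid 2000,
3000, 4000, 5000 at full scale; `mtry` from tokens resolving to
{1, 0.5√p, √p, 2√p, p} clipped to [1, p] and deduplicated — the printed
description of the mtry settings is degenerate if read as multiples of p
itself, so multiples of √p, the canonical default, were adopted);
unpenalized logistic regression (no grid; separation is handled by the
lbfgs iteration cap, with scikit-learn's convergence warning as the
signal); SVMs with radial, linear, polynomial and sigmoid kernels
(C ∈ {0.01, 0.1, 1, 10}, γ ∈ {0.001, 0.01, 0.1, 1}, degree ∈ {2, 3, 4}
for the polynomial kernel; the linear kernel has no γ); and a
single-hidden-layer neural network with logistic activations
(hidden units ∈ {1, 3, 5}, weight decay ∈ {0, 0.01, 0.1} — the original
sizes are unstated, so a small grid is searched like the other methods).
Probabilistic methods classify at probability 0.5; SVMs at the sign of
the decision function; no class weighting — balance is enforced through
the model-selection criterion instead.

Candidate features are ordered by random-forest permutation variable
importance (mean accuracy drop over permutations of a feature's values,
seeded and deterministic; exact ties keep pool order). Forward building
then evaluates every (prefix length k, grid point) by ten-times repeated
stratified 10-fold CV — stratification is necessary because unstratified
folds can lose the minority class entirely at a 25% metastasis fraction
— scoring the balanced accuracy pooled over all out-of-fold predictions.
The winner is a single joint argmax over (k, grid point); whether
feature-count selection and grid search were nested or joint in the
original work is unspecified, and the joint reading matches a "grid-like
search … during model building". Ties prefer the more balanced
sensitivity/specificity, then fewer features, then the earlier grid
point. The winning configuration is refit on the full training set; that
refit object, with its feature list and hyperparameters, is the unit
transferred to external validation.

**Leakage modes.** In `paper` mode the importance ranking is computed
once on the full training set before CV — this leaks test-fold
information and inflates internal estimates, exactly as the re-enacted
protocol acknowledges. In `clean` mode the ranking is recomputed inside
every CV training fold (the final model still uses the full-set
ranking). The suite checks that `paper` mode's CV bAcc exceeds `clean`
mode's on average over seeds on signal-bearing data.

## Voting

Internal: each sample accrues exactly 10 votes per method, one per CV
repetition, **ordered by repetition index** — the protocol's "first
nine votes" rule presupposes an order it never defines, and repetition
order under the stored seed is this package's convention. The majority
of the first nine votes (odd, tie-free) gives the per-method label; the
seven per-method labels are combined by simple majority (again odd).
External: one vote per method, seven-voter majority. Voting is on hard
labels only. Voting correctness is guaranteed whenever ≥4 of 7 voters
are correct (checked exhaustively over all 128 patterns), but voting can
lose to its best member when several voters share mistakes — the suite
contains a fixture demonstrating this, because the cross-platform
experiment shows exactly that behaviour.

## Evaluation and the comparison test

Balanced accuracy is (sensitivity + specificity)/2, with sensitivity the
true-positive rate on the metastasis class; it is invariant to
duplicating majority-class samples. For comparing classifiers A and B on
an imbalanced test set: repeatedly (default 1000×) downsample the
majority class uniformly without replacement to equality, count
`a_only` (A correct, B wrong) and `b_only` (B correct, A wrong) on the
subset, and test the two counts with a Pearson χ² (1 df) against an even
split — a McNemar-style discordant-pair test **without** continuity
correction, which is the reading adopted for an ambiguous "binomial
χ²-test" phrase; an exact two-sided binomial alternative is available
behind a flag. m = 0 discordant pairs gives p = 1 by convention. The
reported statistic is the median p over repetitions (even counts: mean
of the two central order statistics). The test is symmetric in A and B
under a shared seed. Internal comparisons use each method's consolidated
nine-vote CV label per sample (whether the original tested per-repeat or
consolidated labels is unstated; consolidated was chosen).

## Experiment orchestration

One master seed is split into named sub-seeds (simulate / rank / cv /
compare). The internal experiment trains and scores every training
study and averages; external experiments train on one study and average
over test studies; all 28 pairs of the 8 voters are compared on pooled
samples. Reports are TSVs with fixed row order and fixed float
formatting, so identical configurations produce byte-identical files.

**Cross-platform regime.** A per-gene linear distortion applied to raw
data is removed exactly by per-gene standardization (see above), so
distorting a raw training study would make the cross-platform run
identical to the same-platform run — standardization would be
"sufficient", contrary to what cross-platform transfer actually shows.
The cross-platform regime therefore applies the distortion to the
**already standardized** training study and trains on it without
re-standardizing: the injected distortion models the residual
platform-to-platform shift that survives normalization. With both
distortion sds zero the regime reduces exactly to the same-platform run.

## Problem sizes used by the test suite

The re-enactment runs (directional checks and the acceptance script) use
a scaled-down configuration: 8 feature-definer studies (the first two
doubling as training sets) of 40 samples on two 150-gene platforms
sharing half their genes, 15 planted genes at effect 1.5, at most four
features per model, 25-tree forests, 100 permutations for gene
selection, and 1000 downsampling repetitions for comparisons. Two
aspects of the scale-down proved load-bearing and are deliberate: models
must carry several features (single- or two-feature models make the
seven methods nearly identical, which removes the ensemble diversity
that majority voting feeds on), and every SVM keeps a grid that spans
its full-scale C/γ ranges rather than one fixed point (a single
arbitrary (C, γ) can leave a kernel degenerate — a sigmoid kernel at
γ = 0.1, C = 1 collapses to a feeble near-linear machine). Full-scale
grids and `max_features=40` remain the library defaults. Calibration
checks (FDR control, recovery, comparison-test error rates) run at the
generator's default conditions listed above.

## Known limitations

* Absolute accuracies on synthetic data are not comparable to published
  cohort accuracies; only directional and calibration properties are
  asserted.
* The permutation null for the rank meta-analysis is a stand-in for an
  upstream method whose exact null construction is not restated in the
  protocol being re-enacted; pooling across genes is this package's
  choice and is flagged as such.
* With few features per model, the realized cross-platform distortion on
  the selected genes is a handful of random draws, so the size of the
  cross-platform performance drop varies substantially between seeds.
* More fundamentally, the per-gene affine distortion is invertible and
  therefore preserves all class information; a trained classifier is
  affected only through calibration — rescaled weights and a shifted
  decision threshold. Under class imbalance, a 0.5-threshold classifier
  is typically miscalibrated toward specificity, and a random threshold
  shift *improves* its balanced accuracy with probability close to one
  half. Distortion therefore lowers the methods' mean balanced accuracy
  on average, but individual methods can gain in individual
  realizations, at any distortion magnitude. Reproducing a uniform
  "every method degrades" outcome would require a distortion that
  destroys information (noise injection, nonlinear compression), which
  this generator intentionally does not model.
* Logistic regression relies on capped iterations under separation
  rather than penalization, matching the re-enacted protocol rather than
  modern practice.
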