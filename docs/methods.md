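# Methods

## Problem and model

An epigenetic clock is a linear model of chronological age on DNA
methylation: given beta values `x` (fraction of methylated signal at each
CpG site, in [0, 1]) and ages `y` in years, the clock solves the elastic
net

    argmin_{β, b}  Σ_i (y_i − b − x_i·β)² + λ₁ Σ_j |β_j| + λ₂ Σ_j β_j²

The L1 term drops uninformative CpGs by shrinking their coefficients to
exactly zero; the L2 term stabilises groups of correlated CpGs that the
lasso alone would thin arbitrarily. Internally, fitting is delegated to
scikit-learn's coordinate-descent elastic net; the identities
λ₁ = 2n·α·ρ and λ₂ = n·α·(1−ρ) map the penalties above onto sklearn's
(α, l1_ratio) parametrisation exactly, and the pair (0, 0) is solved by
ordinary least squares. When `penalty_grid=None`, (λ₁, λ₂) are tuned by
5-fold seeded cross-validation over an automatic log-spaced strength path
crossed with L1 shares {0.1, 0.5, 0.9} — a standard default grid for
this model family. Features are not standardized by default (betas already
share the [0, 1] scale); a `standardize` flag is available, and
coefficients are always reported on the raw beta scale.

R² is the plain coefficient of determination, 1 − SS_res/SS_tot, on the
evaluation samples; it is reported as NaN when the evaluation ages are
constant. Absolute errors are in years; the summary MAE/median-AE pool the
per-sample errors across evaluation splits.

## Selectors

The array measures ~5·10⁵ CpGs on a few hundred samples, so feature
selection is the heart of the toolkit. All selectors share one contract —
`select(matrix) → FeatureSet` — so they compose; everywhere, ties are
broken by larger score first, then lexicographic CpG id, which makes every
selector deterministic and invariant to column order.

**Correlation screen (KBest).** Ranks CpGs by |Pearson r| with age and
keeps the top k. "Correlation with the target" is implemented as absolute
Pearson r, which is ranking-equivalent to the univariate F statistic for a
single regressor. Zero-variance probes are assigned r = 0 so they rank
last rather than producing NaNs.

**Variance threshold.** Keeps CpGs whose population variance (ddof = 0)
strictly exceeds t. Exploratory only — variance is not a proxy for age
information.

**SelectFromModel.** One estimator fit; keep features with importance ≥
threshold. Importance is |coefficient| for the penalized-linear estimator
(raw, unstandardized — betas share a scale) and mean impurity importance
for the extremely-randomized-trees ensemble. The penalized-linear
estimator is an elastic net with a fixed small penalty (α = 0.01,
l1_ratio = 0.5): strong enough to be stable on p ≫ n design matrices,
weak enough not to zero genuine signal before thresholding. A threshold
above the maximum importance returns an empty set, not an error, since
threshold sweeps legitimately cross that point.

**%-RFE.** Classic recursive feature elimination removes a fixed number of
features per refit, which is computationally hopeless at array scale. %-RFE
removes `max(1, floor(pct · current_p))` of the *current* feature space per
iteration (floor, not round: at 1% this removes 4730 of 473,035 and exactly
1 of 100) — aggressive early, meticulous late. The percentage applies to
the current, not original, count; that is what makes the step size scale
down as the space shrinks. When a step would overshoot the target, only
`current_p − target_n` features are removed, so the loop terminates at
exactly `target_n`. The default importance source is the penalized-linear
estimator above; a tree-ensemble mode exists for parity with
SelectFromModel.

**Shadow-feature (Boruta-style) selection.** All-relevant selection: each
round, every column is duplicated and the copy row-permuted (a "shadow"),
preserving the marginal distribution while destroying any age association.
A random forest is fit on the doubled matrix and a real feature scores a
hit when its impurity importance beats the benchmark — the max over all
shadows by default; an own-shadow mode is provided behind `compare="own"`
because the informal description "beat their shadow counterparts" supports
either reading. Shadows are regenerated every round, making hit counts
repeated trials; "consistently beats" is formalised as a one-sided exact
binomial test of hits against Binomial(iterations, 0.5) with Bonferroni
correction across features at familywise level α = 0.05 (the canonical
construction for this family of methods). There is no "tentative" verdict:
unconfirmed features are rejected, because the downstream workflow needs a
single set. The forest uses `max_features="sqrt"` (configurable): the
doubled matrix makes each of the 100 rounds a full forest fit, and
square-root feature subsampling is the standard forest default that keeps
the loop tractable without changing which features win the competition.
De-novo runs on an unreduced space use 7–8 trees; after a cheaper selector
has pre-reduced the space the default 100 trees are used.

**Genetic algorithm.** A population of "creatures" — subsets of exactly
`subset_size` CpGs — evolves under fitness = validation R² of an
elastic-net model on the creature's features. One train/validation split
(default 80/20) is derived from the run seed and shared by all creatures
in a run, so fitnesses are comparable and cacheable. Per generation: cull
the `floor(cull_fraction · population)` weakest; refill by breeding —
child features drawn without replacement from the union of two uniformly
chosen surviving parents (padded from the global pool if the union is
short); each child mutates with probability 0.5, swapping
`floor(0.3 · subset_size)` of its features for random unused CpGs.
Mutation quota and trigger probability are configurable; the trigger
probability is a design choice (the qualitative description "on a random
chance" fixes no number). Elitism — survivors, including the best
creature, pass through unmodified — is on by default and makes best
fitness non-decreasing; disabling it switches to full generational
replacement. Parent pairing is uniform among survivors by default;
rank-weighted ("polygamous") pairing and fitness-scaled litters exist
behind flags, off by default. Stopping is a fixed generation count, with
an optional fitness threshold. Full-scale defaults are 3000 creatures × 50
features for 20 generations; the test suite runs 200 × 50 × 15, which
recovers planted signal in seconds.

**Neural-network perturbation selection.** A small feed-forward regressor
(one hidden layer of 32 tanh units by default, MSE loss, lbfgs optimiser
with a fixed iteration budget) is trained once on all features; its
held-out R² is the benchmark. For each feature the network is retrained
twice on modified copies of the data — the feature's column forced to 1
everywhere (fully methylated) and to 0 (fully unmethylated); both extremes
are needed because a site's natural level may already sit near either end.
The score is |benchmark − mean(two perturbed scores)| (absolute: either
direction of swing indicates influence). All 1 + 2p trainings reuse the
same seeded initialisation so deltas reflect the perturbation, not init
randomness; per-feature retraining uses the training split only, with the
same modification applied to the scoring split. The procedure requires a
pre-reduced space (≤ `prefilter_target`, default 100, typically reached
via %-RFE); the conventional full-scale selection window is the top 50–75
features (default 65), enforced in strict mode and relaxable for small
test problems. scikit-learn's MLPRegressor is the network implementation:
deterministic per seed, no extra dependency, and the procedure only needs
a minimal feed-forward regressor.

## Workflow

Selection is unstable on wide data, so the workflow treats stability
itself as signal. The samples are split into 10 CV folds (seeded KFold);
every (possibly chained) selector runs on each fold's *training* portion
only — the held-out fold never reaches a selector, and a test asserts
this with a spy selector. Per-fold selections are then post-processed:

* **aggregate_unique** — per method, the deduplicated union over folds
  (sorted order for determinism);
* **intersect_per_fold_then_refine** — per fold, the intersection across
  methods; union those consensus sets over folds; refine with a
  shadow-feature pass;
* **top_frequent** — count, over all (method, fold) records, how many
  records each CpG appears in, and keep the n most frequent (one count
  per record; a per-method counting variant is a flag away);
* **post_selection_intersection** — CpGs in every method's aggregated set
  (an empty result is returned, not raised).

Every resulting set is scored by `evaluate_feature_set`: by default 10
seeded 80/20 train/test splits, each fitting a fresh clock on the training
part (the literal reading of a repeated-holdout protocol); a strict
10-fold mode (`mode="kfold"`, 90/10) is provided because summary tables
of this kind are sometimes computed either way, and no claim is made
about which mode reproduces any published number. A selector failing on
one fold is recorded and skipped with a warning rather than aborting the
run — at array scale a single degenerate fold should not destroy hours of
computation.

`external_validate` applies a fitted clock to another cohort with no
refitting; `transfer_fit` instead re-derives a clock in the new cohort
from the transferred CpG list, using the same repeated-split evaluation.

## Synthetic data

The generator emulates the statistical skeleton of a blood-methylation
aging cohort: `n_samples` ages uniform on `age_range`; `n_informative`
planted CpGs whose mean methylation is `clamp01(base_j + effect_j · (age −
midpoint))` with observed beta `clamp01(mean + N(0, noise_sd))`; all other
CpGs age-independent draws `clamp01(base_j + N(0, noise_sd))` around
per-site baselines spread over [0.05, 0.95]. Planted baselines are centred
so the linear drift never clamps at the default effect sizes; a spec whose
effects saturate every sample warns rather than errors.

Defaults — 200 samples × 1000 CpGs, 5 planted sites with slopes of
±0.004 beta/year, noise SD 0.03, ages 20–90 — mimic the
signal-to-noise of the strongest known single-CpG age markers (a
±0.004/year slope spans ~0.28 beta units over the age range, ~9× the
noise SD, ELOVL2-promoter-like) while keeping every selector's runtime in
seconds, and are the fixed study conditions of the recovery tests.

Randomness is split into two streams. `seed` drives *sampling* (ages,
noise); `structure_seed` drives *structure* (which CpGs are informative,
their baselines). Two draws with different `seed` and the same
`structure_seed` are independent cohorts measuring the same underlying
age-CpGs — exactly the situation cross-cohort transfer and external
validation assume; without the split, "independent draws of the same
spec" would plant different sites and transfer would be meaningless.

What the generator does *not* emulate: probe chemistry and its
beta-value heteroscedasticity, cell-composition confounding, batch
structure, nonlinear (e.g. logistic) age trajectories, and correlation
between CpGs. Passing recovery tests therefore demonstrates algorithmic
correctness — each selector finds planted monotone age signal against
independent noise — not performance on real cohorts, where correlated
probes and confounders make selection strictly harder.

## Numerical choices and degenerate inputs

* Ties: everywhere, larger score first, then lexicographic CpG id; %-RFE
  removes lexicographically smaller ids first among equal-importance
  features at the elimination boundary.
* Zero-variance columns: correlation 0 in the screen, coefficient 0 in
  penalized fits, removed by any variance threshold.
* Missing betas: NaN in memory; empty cells and `NA`/`NaN` tokens on
  disk. Selectors and clock fitting refuse matrices with missing values;
  `drop_incomplete_cpgs` restricts one or more matrices to the CpGs
  complete in all of them (first matrix's column order kept).
* Table orientation (samples-in-rows vs CpGs-in-rows) is always an
  explicit flag, never guessed — silent transposition is the classic
  methylation-table bug. Ages are required at load except via the
  dedicated prediction-only loader, because every selector is supervised.
  Ages are accepted as arbitrary non-negative reals.
* Clock serialization is plain TSV with full-precision `repr` floats:
  human-diffable and bit-exact on round trip.
* All randomness flows from `numpy.random.default_rng` on user-supplied
  integer seeds; forest and network estimators receive seeds derived from
  that stream, so every entry point is rerun-identical.

## Problem sizes in the test suite

Recovery tests run the documented study conditions (200 × 1000, 5 planted
sites) over 10 seeds; the shadow-feature null control uses 100 × 50 pure
noise; the %-RFE/classic-RFE equivalence uses 30 features so that every
step removes exactly one; the GA runs 200 creatures × 15 generations; the
NN toy uses 8 features noiselessly (17 trainings per seed). These sizes
were chosen so the full property suite demonstrates each mechanism with
clear margins at interactive runtimes.

## Known limitations

* The shadow-feature binomial null assumes a 0.5 per-round beat
  probability for irrelevant features; with `compare="max"` the true null
  rate is below 0.5, making the test conservative (fewer false positives,
  slightly less power).
* The GA's fitness model uses a fixed small elastic-net penalty for
  speed; creatures are ranked, not calibrated — reported best fitness is
  an optimistic estimate, as in any selection-by-validation scheme.
* NN perturbation deltas conflate a feature's influence with training
  variance when the network is under-trained; the fixed shared
  initialisation mitigates but does not remove this.
* `evaluate_feature_set` scores feature sets selected on the *full*
  matrix when called directly; the CV workflow avoids that optimism for
  selection, but the final evaluation splits are still drawn from the
  same cohort the features were selected in — as in any within-cohort
  protocol, external validation is the honest generalisation check.
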