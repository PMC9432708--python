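# cpgclock

Feature-selection toolkit for building **low-CpG epigenetic clocks** from
DNA-methylation data.

Epigenetic clocks predict chronological age from methylation beta values
(the fraction of methylated signal at a CpG site, in [0, 1]). Arrays
measure ~5·10⁵ CpGs on cohorts of a few hundred samples, and the standard
recipe — elastic-net regression over all sites — yields clocks with
hundreds of CpGs. Explicit feature selection finds far smaller CpG panels
that predict age as well or better, are cheap to measure with targeted
sequencing, and point at biologically interpretable loci. This package is
for computational biologists who want a reproducible, composable selection
pipeline in front of their clock fits.

## What's in the box

* **Selectors**, all sharing a `select(matrix) → FeatureSet` contract so
  they can be chained:
  * `select_k_best` — |Pearson r|-with-age screen;
  * `variance_threshold`;
  * `select_from_model` — single penalized-linear or extra-trees fit,
    importance ≥ threshold;
  * `pct_rfe_select` — **percentage-based recursive feature elimination**:
    each refit removes `max(1, floor(pct · current_p))` of the *current*
    feature space (at 1%: 4730 features when 473,035 remain, 1 when 100
    remain), making RFE tractable at array scale;
  * `boruta_select` — all-relevant selection against row-permuted
    "shadow" copies under a random forest, with an exact binomial
    hit-count test;
  * `evolve` — genetic-algorithm search over fixed-size CpG subsets with
    validation-R² fitness;
  * `nn_perturbation_select` — rank features by how much forcing a CpG
    fully methylated/unmethylated swings a small neural network's score.
* **Workflow** — 10-fold cross-validated selection (selectors see training
  folds only), per-method union, per-fold intersection with shadow-feature
  refinement, frequency ranking, and repeated-split evaluation of every
  resulting CpG panel.
* **Clock** — elastic-net fitting
  (`argmin Σ(yᵃ − β·x − b)² + λ₁Σ|β| + λ₂Σβ²`, penalties tuned by internal
  CV), prediction, external validation and cross-cohort feature transfer,
  with diffable text serialization.
* **Synthetic data** — planted-signal methylation cohorts (monotone
  age-CpGs among independent noise) so the whole pipeline is testable
  without any download.
* **CLI** — `cpgclock simulate | select | evaluate | clock-train |
  clock-predict | clock-validate | clock-transfer`, driven by seeds and a
  YAML config; reruns are byte-identical.

Input is delimited text (TSV/CSV) in either orientation — samples in rows,
or CpGs in rows as in GEO series-matrix exports — with an age column/row;
the orientation is always an explicit flag. See `docs/methods.md` for the
model, parameter meanings and design rationale.

## Worked example

```bash
# a 200-sample x 1000-CpG cohort with 5 planted age-CpGs
cpgclock simulate --n 200 --p 1000 --k 5 --seed 7 \
    --out-matrix cohort.tsv --out-truth truth.tsv

cat > run.yaml <<'YAML'
input: {path: cohort.tsv}
methods:
  - {kind: kbest, k: 25}
  - kind: chain
    name: kbest-2000-then-boruta
    stages:
      - {kind: kbest, k: 200}
      - {kind: boruta}
folds: 10
seed: 7
outdir: run/
YAML
cpgclock select --config run.yaml   # ~3 min on one CPU
cat run/report.tsv
```

which prints (this exact output, seed 7):

```
feature_set                        n_features  mean_r2   r2_std    mae_years  median_ae_years
kbest-25                           68          0.974353  0.006178  2.606119   2.416605
kbest-2000-then-boruta             6           0.974803  0.006099  2.595181   2.149951
top-5-most-frequent                5           0.974532  0.006245  2.633020   2.279318
top-10-most-frequent               10          0.974427  0.005983  2.629258   2.244338
post-selection-intersection        6           0.974803  0.006099  2.595181   2.149951
per-fold-intersection-then-boruta  6           0.974803  0.006099  2.595180   2.149988
```

Read: the plain correlation screen is unstable across folds — its
per-fold top-25 lists union to 68 distinct CpGs — yet needs all of them
for a mean held-out R² of 0.974 and a 2.6-year mean absolute error.
Chaining the screen into the shadow-feature selector matches that accuracy
with a 6-CpG panel containing all 5 planted age-CpGs (compare
`run/records.tsv` against `truth.tsv`), and the consensus operations
(frequency ranking, intersections) converge on the same panel. The top-5
frequency panel is exactly the planted set.

From the library, the same panel transfers to an independent cohort:

```python
from cpgclock import SyntheticSpec, generate_clock_dataset, transfer_fit

cohort_a, truth = generate_clock_dataset(SyntheticSpec(seed=7))
cohort_b, _ = generate_clock_dataset(SyntheticSpec(seed=8))
report = transfer_fit(truth, cohort_b, repeats=10, seed=0)
print(round(report.mean_r2, 3), round(report.mae_years, 2))  # 0.969 2.75
```

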