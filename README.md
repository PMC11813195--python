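# burnoutprev

Nonresponse-adjusted estimation of physician burnout prevalence from
survey responses and EHR-use features.

Voluntary well-being surveys risk response bias: physicians who do not
respond may differ systematically in burnout from those who do. This
package implements a pipeline that corrects for that, plus a synthetic
cohort generator with known ground truth to validate it:

1. **Scoring** — 10 burnout items (0–4 Likert) averaged and rescaled to
   0–10 (×2.5); a score ≥ 3.325 flags burnout symptoms; an invitation
   counts as a *response* when ≥ 4 of 10 items are answered. Physicians
   are categorized as never / partial / always responders.
2. **Descriptive comparison** — Kruskal–Wallis (unpaired continuous),
   Wilcoxon signed rank (paired continuous, exact sign-permutation at
   small n), Fisher exact (categorical; exact enumeration through 2×3,
   seeded Monte Carlo beyond).
3. **Response propensity** — elastic-net penalized logistic regression
   with 10-fold cross-validation grouped by physician; penalty chosen
   by pooled out-of-fold deviance; every invitation's propensity is
   out-of-fold.
4. **Weighting schemas** — unweighted, 1/p (propensity floored at 0.1,
   so weights lie in [1, 10]), and 1−p (weights in [0, 1]).
5. **Burnout ensemble** — three weighted elastic-net linear models of
   the continuous score, a physician-grouped 80/20 train/calibration
   split of always responders, OLS bias-correction of actual scores on
   the three predictions, and a logistic sigmoid (centered at 3.325,
   scale matched to calibration residuals) converting scores to burnout
   probabilities. Evaluated on partial responders (AUROC, AUPRC,
   sensitivity/specificity at a Youden threshold, physician-bootstrap
   CIs).
6. **Population estimate** — observed burnout flags among responses
   combined with predicted probabilities among nonresponses (survey- or
   physician-level weighting), with bootstrap CIs.
7. **Synthetic response-rate reduction** — per-physician mean
   propensities are jittered (triangular, −0.5..0.5) over 100 cycles;
   physicians in the lowest 20% in ≥ 50 cycles have their responses
   concealed, the whole pipeline is rerun, and the estimate shift is
   reported.

The `cohort` module generates physician cohorts with correlated
log-normal EHR-use style features, a latent burnout score linked to the
features, binomially thinned item responses, and a response mechanism
whose missing-at-random / missing-not-at-random character is
configurable (`mnar_strength` = log-odds of response per unit latent
burnout).

## CLI

```sh
# generate a cohort from a YAML generator config
burnoutprev simulate --config gen.yaml --out cohort_dir/

# full pipeline: scores, comparisons, propensities, model, estimate
burnoutprev run --cohort cohort_dir/ --seed 1 --out artifacts/

# individual stages
burnoutprev score --records cohort_dir/records.csv --out scores.csv
burnoutprev compare --features cohort_dir/features.csv --scores scores.csv --out cmp.csv
burnoutprev propensity --features cohort_dir/features.csv --scores scores.csv --out prop.csv
burnoutprev train --records cohort_dir/records.csv --features cohort_dir/features.csv --out model.json
burnoutprev estimate --records cohort_dir/records.csv --features cohort_dir/features.csv --out prev.csv
burnoutprev reduce --records cohort_dir/records.csv --features cohort_dir/features.csv --out reduction.csv
```

Artifacts of `run`: `scores.csv`, `categories.csv`, `comparisons.csv`,
`propensities.csv`, `propensity_coefficients.csv`, `weights.csv`,
`model.json` (versioned, human-readable), `evaluation.csv`,
`prevalence.csv`, and `manifest.json` (config echo, versions, seeds).
Reruns with the same config are identical.

## Python API

```python
from burnoutprev import generate_cohort, PipelineConfig, analyze_cohort
from burnoutprev.cohort import example_config

records, features, truth = generate_cohort(example_config(2000, seed=1, mnar_strength=-0.6))
result = analyze_cohort(records, features, PipelineConfig.with_seed(1))
print(result.estimate.population_prevalence, truth.true_prevalence)
```
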