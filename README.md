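# mpgs-pls

Multi-polygenic-score analysis of a binary case/control outcome with partial
least squares regression.

## The problem

Modern PRS pipelines can compute hundreds of polygenic scores per subject
from the public score catalogs, but the scores are heavily multicollinear —
the same trait is often scored by several near-duplicate published scoring
files, and genetically correlated traits share weight. Ordinary regression
cannot rank such predictors, and p ≫ n makes it unusable outright. This
package implements the analysis used to ask which of hundreds of polygenic
scores best predict a history of peripartum depression (PPD) in parous
women with mood disorders (MDD or BD): a single-response partial least
squares (PLS) regression that projects the score panel onto a few latent
components maximising covariance with the outcome, then ranks every score
by its variable importance in projection (VIP).

It is aimed at statistical-genetics and psychiatric-epidemiology analysts
who have a subjects × scores matrix (e.g. from `pgsc_calc`), per-score
trait-category labels, and a binary phenotype.

## The method

With autoscaled predictors X (n × p) and autoscaled 0/1 outcome y, NIPALS
extracts components a = 1…A:

    w_a ∝ X_aᵀ y_a,  ‖w_a‖ = 1        (predictive weights)
    t_a = X_a w_a                      (latent variable / component score)
    p_a = X_aᵀ t_a / t_aᵀ t_a,  q_a = y_aᵀ t_a / t_aᵀ t_a
    X_{a+1} = X_a − t_a p_aᵀ,  y_{a+1} = y_a − q_a t_a

with per-component R²X and R²Y, regression coefficients b = W(PᵀW)⁻¹q, and

    VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ),  SSY_a = q_a² t_aᵀt_a

normalised so mean(VIP²) = 1; scores with VIP > 1 (strict) are the selected
contributors, and the sign of the first-component weight gives the direction
of association. A is chosen by stratified 7-fold cross-validation (Q² =
1 − PRESS/TSS with a 0.01 parsimony tolerance), the first latent variable is
evaluated as a classifier via ROC/AUC, and per-category contribution tables
count selected scores by direction. A Table-1-style cohort battery
(pooled-variance t + Cohen's d, uncorrected Pearson χ² + Cramér's V) rounds
out the report, computable from raw columns or from published summary
statistics.

Because no suitable score panel is publicly deposited, the package includes
a synthetic generator that emulates the study conditions: 178 subjects
(62 cases / 116 controls, 72 MDD / 106 BD), 341 scores in four categories
(67 psychiatric, 89 hormone/pregnancy, 131 immune-inflammatory, 54
sleep/circadian), within-phenotype correlation blocks (ρ = 0.9), and a
sparse planted liability signal with exact case/control margins.

## Worked example

```
$ mpgs-pls simulate --out demo --seed 7
wrote 178 x 341 panel (62 cases) to demo

$ mpgs-pls run --scores demo/scores.tsv --meta demo/score_meta.tsv \
    --pheno demo/phenotypes.tsv --subgroup all --seed 7 --out demo_run
{
 "subgroup": "all",
 "n_samples": 178,
 "selected_components": 1,
 "r2y_cumulative": 0.5703,
 "q2_selected": 0.0189,
 "n_selected_vip": 93,
 "auc_in_sample": 0.9644,
 "auc_cv": 0.6664
}
```

Cross-validation picked a single latent component which explains 57% of the
outcome variance in-sample; 93 of the 341 scores exceed VIP = 1. The
in-sample AUC of the first latent variable (0.96) is far above its
cross-validated counterpart (0.67) — the expected optimism gap at
n = 178, p = 341, which is why the report always shows both. The top of
`demo_run/vip_ranking.tsv`:

```
score_id  phenotype            category     weight  vip    rank  selected  direction
SC0005    psychiatric_trait02  psychiatric  0.1843  3.407  1     True      positive
SC0002    psychiatric_trait01  psychiatric  0.1781  3.293  2     True      positive
```

Both top scores belong to planted causal blocks (`demo/ground_truth.tsv`).
`demo_run/` also contains `category_summary.tsv`, `roc_points.tsv`,
`metrics.json`, `cohort_table.tsv`, `model.json` and `run_report.json`.
Subgroup analyses (`--subgroup MDD` / `BD`) refit after re-autoscaling
within the subgroup; the diagnosis covariate enters the predictor block
only in the whole-sample run and is never part of the VIP ranking.

The same things are available as a library:

```python
import mpgs_pls as m
panel, pheno, truth = m.generate_panel(m.SimConfig(seed=7))
report = m.run_analysis(m.RunConfig(subgroup="all", seed=7),
                        panel=panel, phenotypes=pheno)
```

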