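# ionsig

Ion-channel gene-signature risk scoring and survival analysis for lung
adenocarcinoma cohorts.

Ion channels regulate proliferation, apoptosis and invasion across cancer
types, and their expression is systematically dysregulated in lung
adenocarcinoma. `ionsig` implements the full analysis behind an ion-channel
prognostic signature as a reusable, tested pipeline for bulk expression
cohorts:

1. **Differential-expression screening** — paired t-tests (tumor vs matched
   normal tissue) or Welch t-tests (adenocarcinoma vs squamous-cell
   carcinoma), Benjamini–Hochberg FDR control within the tested gene panel,
   and geometric-mean fold changes from log2 expression.
2. **Sign-weighted risk scoring** — a frozen signature whose gene weights
   are the sign of the discovery fold change, scored per patient as

   $$s \;=\; \sum_{i=1}^{n} \operatorname{sgn}(\log_2 fc_i)\,
       \frac{e_i - \mu_i}{\tau_i}$$

   where $e_i$ is the patient's log2 expression of gene $i$ and $\mu_i$,
   $\tau_i$ are that gene's mean and SD across all samples of the scored
   cohort. Patients above the cohort-median score are signature-positive.
3. **Survival stratification** — Kaplan–Meier curves with log-rank tests,
   and univariate / multivariate Cox proportional-hazards models (hazard
   ratios with Wald 95% CIs) for the dichotomized status, the continuous
   score, and clinical covariates (age, gender, stage, smoking, Myc level,
   EGFR/KRAS/ALK mutation status).
4. **Resampling null** — the signature's survival association, summarized
   as $Z$ = the sum over cohorts of the Cox coefficient for dichotomized
   status, is referenced against $B$ random same-size gene signatures built
   by the same sign rule; $p = (1 + \#\{Z_{\text{null}} \ge
   Z_{\text{obs}}\})/(B+1)$.
5. **Cross-cohort validation** — correlation of log10 p-values and log2
   fold changes between discovery and validation screens, PCA projection of
   samples on a gene panel, Ward/Manhattan hierarchical clustering for
   heatmap layout, and contingency chi-square comparison of stage
   distributions.

The package ships the two published discovery tables as fixtures: the
37-gene normal-vs-tumor ion-channel signature (10 up-, 27 down-regulated;
`ionsig.ilas_signature()`) and the 30-gene adenocarcinoma-vs-squamous
contrast (21 up, 9 down; `ionsig.subtype_signature()`). A synthetic-cohort
generator (`ionsig.simulate`) produces paired, two-subtype and
survival-annotated cohorts with known planted effects so every stage is
testable without external data.

## Worked example

Discover a signature on a synthetic paired cohort with 30 planted fold
changes, then evaluate it on an independent cohort whose hazard follows the
true risk score (calibrated to a positive-vs-negative hazard ratio of ~2):

```python
import numpy as np, pandas as pd
import ionsig as isg

cfg = isg.SimulationConfig(n_genes=400, n_de=30, n_pairs=60,
                           log2fc_range=(1.0, 2.5), sigma_gene=0.5, seed=1)
discovery, truth = isg.generate_paired(cfg)
de = isg.de_screen(discovery, design="paired", alpha=0.001)
sig = isg.build_signature(de, source_cohort="synthetic-discovery")

rng = np.random.default_rng(2)
expr = isg.ExpressionCohort(
    pd.DataFrame(rng.normal(8, 1, (400, 300)), index=discovery.gene_ids,
                 columns=[f"V{i}" for i in range(300)]),
    cohort_name="validation")
true_sig = isg.build_signature(pd.DataFrame(
    {"fold_change": 2.0 ** truth.planted_log2fc[truth.planted_log2fc != 0]}))
true_scores = isg.score(expr, true_sig).scores
beta = np.log(2) / (1.5958 * true_scores.std(ddof=1))
clin = isg.generate_survival(
    isg.SimulationConfig(beta_score=float(beta), baseline_hazard=5e-4,
                         seed=3), true_scores)

res = isg.SignatureRiskModel(expr, clin, sig).fit(
    covariates=["age", "gender", "stage"])
print(res.summary())
```

prints

```
Signature risk model
============================================================
cohort:            validation
outcome:           overall survival
signature:         30 genes (15 up, 15 down; 0 absent from platform)
patients (events): 300 (164)
median risk score: +0.078
log-rank P:        0.003831

Univariate Cox (status positive vs negative):
           hazard_ratio          ci95        p  coefficient
covariate
status         1.573853  (1.15, 2.15)  0.00413     0.453526

Continuous score: +6.2% hazard per point (P = 2.288e-05)

Multivariate Cox:
           hazard_ratio          ci95         p  coefficient
covariate
status         1.574114  (1.15, 2.15)  0.004246     0.453693
age            1.009823  (0.99, 1.03)  0.347403     0.009775
gender         1.033246  (0.76, 1.41)  0.837954     0.032705
stage          1.059565  (0.88, 1.28)  0.547663     0.057859
```

The screen recovered all 30 planted genes; signature-positive patients die
at ~1.6 times the rate of signature-negative patients (true marginal HR ≈ 2
before score-estimation noise and non-collapsibility attenuate the binary
split), the effect survives adjustment for the (null) clinical covariates,
and each one-point score increment raises the hazard by ~6%.

The same analysis runs from the shell:

```sh
ionsig simulate --design paired --n-de 30 --n-pairs 60 --seed 3 --outdir demo
ionsig de --expression demo/expression.tsv --pairing demo/pairing.tsv \
          --design paired --alpha 0.001 --out demo/de.tsv
ionsig run-all --config study.yaml     # full pipeline from a YAML config
```

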