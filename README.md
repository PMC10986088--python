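# mrmediate

Two-sample Mendelian randomization (MR) mediation analysis from GWAS
summary statistics, built for drug-target questions of the form *"how
much of a drug target's protective effect on a disease runs through an
intermediate biomarker?"*.

Genetic variants that perturb a drug target (for instance expression of
a transporter gene, instrumented through its downstream effect on a
clinical biomarker) serve as instrumental variables: because alleles
are assigned at conception, the variant→outcome association is immune
to the confounding and reverse causation that plague observational
comparisons. `mrmediate` implements the complete analysis battery
around that idea:

- **Instrument construction** — p-value thresholding with a suggestive
  fallback when fewer than 3 SNPs survive, greedy LD clumping within a
  kilobase window, a colocalization gate for expression-based
  instruments (shared-causal-variant posterior PP4 > 0.70), per-SNP
  F statistics with the conventional F > 10 strength rule, and allele
  harmonization between GWAS sources (strand flips, palindromic SNPs).
- **Univariable MR** — Wald ratio, inverse-variance weighted (IVW),
  MR-Egger with its pleiotropy intercept test, weighted median,
  simple/weighted mode, and Cochran's Q heterogeneity statistics.
- **MR-PRESSO** — resampling-based global pleiotropy test, per-SNP
  outlier detection, outlier-corrected estimate, and distortion test.
- **MR-BMA** — multivariable MR Bayesian model averaging to prioritize
  the causal factor among correlated candidates, with marginal
  inclusion probabilities (MIP), model-averaged causal effects (MACE),
  permutation p-values and FDR adjustment.
- **Colocalization** — Wakefield approximate Bayes factors assembled
  into the five regional hypothesis posteriors PP0–PP4.
- **Two-step mediation** — indirect effect β₁β₂, proportion mediated
  β₁β₂ / total, delta-method confidence intervals, Benjamini–Hochberg
  FDR utilities (q ≤ 0.10 rule).
- **Synthetic data** — generators with known causal structure for every
  stage, so the whole pipeline is testable without any external data.

## The model

For SNP *j*, let β̂<sub>Xj</sub> (se σ<sub>Xj</sub>) be its association
with the exposure and β̂<sub>Yj</sub> (se σ<sub>Yj</sub>) its
harmonized association with the outcome. The IVW estimate is the
weighted regression of β̂<sub>Yj</sub> on β̂<sub>Xj</sub> through the
origin with weights σ<sub>Yj</sub>⁻², equivalently the
inverse-variance-weighted mean of the per-SNP Wald ratios
β̂<sub>Yj</sub>/β̂<sub>Xj</sub>. MR-Egger adds an intercept (average
directional pleiotropy); the median and mode estimators are robust to
up to half, or a plurality, of invalid instruments.

In the two-step mediation design, β₁ (exposure→mediator) and β₂
(mediator→outcome) are estimated from non-overlapping instrument sets;
the mediated share of the total effect T is

&nbsp;&nbsp;&nbsp;&nbsp;proportion = β₁β₂ / T,&nbsp;&nbsp;
Var(β₁β₂) ≈ β₁²se₂² + β₂²se₁²,

with the proportion CI from the first-order delta method assuming the
three estimates come from independent samples.

MR-BMA works on the inverse-variance-weighted scale (all associations
divided by σ<sub>Yj</sub>), places a zero-mean normal prior (default
variance 0.5) on standardized causal effects and a prior inclusion
probability (default 0.1) on each factor, and averages over every
subset of candidate factors; each factor's MIP is the summed posterior
of the models containing it.

## Worked example

```python
from mrmediate import ivw, mr_egger, mediate
from mrmediate.simulate import (
    UniSimConfig, simulate_univariable,
    ChainSimConfig, simulate_mediation_chain,
)

# 50 instruments, true causal effect -0.5, no pleiotropy
h, truth = simulate_univariable(UniSimConfig(n_snps=50, true_theta=-0.5, seed=7))
est = ivw(h)
egger, pleio = mr_egger(h)
```

prints (via f-strings over the fitted attributes):

```
IVW estimate -0.530 (se 0.118), 95% CI [-0.762, -0.298], p = 7.37e-06
Egger slope -0.596, intercept 0.0047 (p = 0.712)
```

The IVW interval covers the generating effect −0.5 and the Egger
intercept is compatible with zero, as it should be without pleiotropy.
A full mediation chain with a true mediated proportion of 0.20:

```python
arms, truth = simulate_mediation_chain(ChainSimConfig(seed=11))
e1, e2, et = (ivw(arms[k]) for k in
              ("exposure_mediator", "mediator_outcome", "exposure_outcome"))
res = mediate(e1.beta, e1.se, e2.beta, e2.se, et.beta, et.se)
```

```
b1 0.431(0.068)  b2 0.504(0.061)  total 1.044(0.070)
indirect 0.2175 (p<1e-4); proportion 0.2083, 95% CI [0.1227, 0.2940]
```

The estimated proportion 0.208 sits on the generating value 0.20 and
its interval covers it.

Every estimator is also available as a scikit-learn style class
(`IVWEstimator`, `EggerEstimator`, `WeightedMedianEstimator`,
`ModeEstimator`, `MRPressoEstimator`, `MRBMAEstimator`) with
`fit(X, y, x_se=..., y_se=...)` and trailing-underscore fitted
attributes.

A command line mirrors the library:

```
mrmediate run --exposure x.tsv --outcome y.tsv --seed 17 --out table1.tsv
mrmediate bma --exposures m1.tsv,m2.tsv --outcome y.tsv --seed 17 --out table3.tsv
mrmediate coloc --trait1 a.tsv --trait2 b.tsv --out coloc.json
mrmediate mediate --beta1 0.43 --se1 0.07 --beta2 0.50 --se2 0.06 --total 1.04 --se-total 0.07
mrmediate pipeline --config run.yaml --exposure x.tsv --biomarkers b1.tsv,b2.tsv --outcome y.tsv --out results/
mrmediate simulate chain --seed 3 --out sims/
```

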