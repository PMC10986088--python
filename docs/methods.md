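# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, the numerical decisions, and what
the synthetic-data generators do and do not emulate.

## Summary-data model and harmonization

All estimators consume per-SNP summary associations: exposure effects
β̂_Xj with standard errors σ_Xj, and outcome effects β̂_Yj with σ_Yj,
assumed independent across SNPs (instruments are LD-pruned) and across
the two samples (non-overlapping GWAS).

Harmonization expresses β̂_Yj for the exposure's effect allele.
Swapped alleles negate the outcome effect; strand flips are resolved by
complementation before declaring a mismatch. Palindromic (A/T, C/G)
variants cannot be strand-resolved from alleles: they are dropped when
either study's effect-allele frequency lies within a window of 0.5
(default half-width 0.08, the common conservative choice) or is
missing; otherwise the strand is inferred from whether the two
frequencies fall on the same side of 0.5. Harmonization is idempotent
and equivariant to re-expressing any input record for its other allele.

Instrument selection applies a primary p-value threshold (default
5e-8) with a suggestive fallback (5e-7) when fewer than `min_snps`
(default 3) survive, mirroring common practice for sparsely
instrumented biomarkers. Clumping is greedy: candidates are visited by
ascending p (ties broken by position then identifier, for determinism)
and each kept SNP removes candidates with r² at or above the threshold
within the kilobase window on the same chromosome. SNPs absent from
the supplied LD matrix are treated as independent and kept, so partial
LD information can be used; positions are 1-based and the kb distance
is |Δpos|/1000 with inclusive comparison. Instrument strength is
summarized by F_j = (β̂_Xj/σ_Xj)², the squared-z approximation, because
per-SNP sample sizes and allele frequencies may be missing;
F ≤ 10 flags a weak instrument.

Expression-based (drug-target) instruments additionally pass a
colocalization gate: the candidate region must show a shared-causal-
variant posterior PP4 above 0.70 between the expression signal and the
downstream trait. The gate uses PP4 alone rather than PP3+PP4, since
"evidence of colocalization" conventionally means the shared-variant
hypothesis.

## Univariable estimators

- **Wald ratio**: β̂_Yj/β̂_Xj with first-order se σ_Yj/|β̂_Xj|; a
  second-order option adds the exposure-side term.
- **IVW**: weighted regression of β̂_Y on β̂_X through the origin,
  weights σ_Y⁻². The default is the multiplicative random-effects
  variant — the fixed-effect se inflated by max(1, √(Q/df)) — matching
  the defaults of the widely used two-sample MR packages; the
  fixed-effect variant is available by flag. The point estimate is
  unchanged between variants.
- **MR-Egger**: the same regression with an intercept, after orienting
  SNPs so all β̂_Xj ≥ 0 (the intercept is only meaningful under a
  common orientation). The slope is the causal estimate under InSIDE;
  the intercept estimates average directional pleiotropy. Random-
  effects scaling uses df = n−2. Egger additionally assumes the
  exposure associations are measured essentially without error (NOME);
  see the generator notes below.
- **Weighted median**: per-SNP ratios ordered ascending with
  normalized first-order inverse-variance weights w_j; the estimate is
  the linear interpolation of the weighted quantile function through
  the points (cumsum(w)_j − w_j/2, ratio_j) at 0.5. Consistent when
  valid instruments carry at least half the weight.
- **Mode-based**: Gaussian kernel density over the ratios (uniform
  weights for the simple mode, inverse-variance for the weighted
  mode); bandwidth is the modified Silverman rule
  0.9·min(sd, 1.4826·MAD)·n^(−1/5) times a user factor (default 1),
  and the estimate is the density argmax on a 10,000-point grid
  spanning the ratio range. If all ratios coincide the common value is
  returned.
- Median and mode standard errors come from a parametric bootstrap
  (default 1000 draws, mandatory seed): β̂_X and β̂_Y are resampled
  from normal distributions at the observed values and standard
  errors, the estimator recomputed, and the bootstrap standard
  deviation used with normal-theory intervals.
- **Cochran's Q** about the fixed-effect IVW fit (df = n−1) or the
  Egger fit (df = n−2), with the upper chi-square tail as p-value.

All confidence intervals and p-values are normal-theory. Odds ratios
are presentation-layer exponentiations applied consistently to the
estimate and both CI bounds when the outcome is flagged binary.

## MR-PRESSO

The observed statistic is the leave-one-out residual sum of squares
RSS = Σ_j w_j (β̂_Yj − β̂^(−j) β̂_Xj)², w_j = σ_Yj⁻². The null
distribution comes from parametric simulation (default 1000 draws)
under the leave-one-out fitted model with the observed standard
errors; the global p uses add-one smoothing,
p = (1 + #{RSS* ≥ RSS}) / (1 + n_sim), so it is never exactly zero.
Per-SNP outlier p-values compare each SNP's observed squared residual
with its simulated distribution, Bonferroni-adjusted across SNPs and
flagged below 0.05. The corrected estimate is IVW on unflagged SNPs
(identical to plain IVW when nothing is flagged). The distortion test
compares the relative shift of the estimate after removing the flagged
SNPs with the shifts produced by removing random subsets of the same
size (1000 resamples); it is reported but drives no decision. All
resampling is seeded and bit-reproducible.

## MR-BMA

Work on the inverse-variance-weighted scale: ỹ_j = β̂_Yj/σ_Yj and
x̃_jk = β̂_Xjk/σ_Yj, so residuals have unit variance. Each factor
column is standardized to unit Euclidean norm on this scale ("unit
weighted second moment"), which makes a single prior variance
meaningful across factors; reported MACE values are rescaled back to
the input effect scale. For a model S (a subset of factors) with a
zero-mean normal prior of variance σ² (default 0.5) on each
standardized coefficient, the marginal likelihood is the closed
conjugate form ỹ ~ N(0, I + σ² X_S X_Sᵀ), evaluated through the k×k
Woodbury identity; X_SᵀX_S + I/σ² is positive definite for any σ² > 0,
so rank-deficient designs need no special casing. Model priors are
p^|S|(1−p)^(d−|S|) with prior inclusion probability p (default 0.1).

The model space is the empty model plus all non-empty subsets up to
`max_model_size` (default: all sizes; full enumeration guarded at
d ≤ 20). Including the empty model in the normalization is what makes
the method calibrated: with no signal, a factor's Bayes factor against
the empty model is O(1) and its marginal inclusion probability sits
near the prior p, rather than near 1/d. MIP_k sums the posterior over
models containing factor k; MACE_k sums posterior × per-model
posterior-mean coefficient (zero contribution from models excluding
k). Permutation p-values permute the outcome vector across SNPs
(default 10,000 permutations, vectorized), use add-one smoothing, and
receive Benjamini–Hochberg adjustment across factors.

Diagnostics run on the highest-posterior model's OLS fit: Cook's
distance with default threshold the median of F(k, n−k), and per-SNP
squared standardized residuals with default threshold the upper 1%
chi-square(1) point Bonferroni-corrected across SNPs — a ~1%
familywise false-flag rate on clean data, so clean datasets are
usually left untouched. The pipeline refits after excluding flagged
SNPs.

## Colocalization

Per SNP and trait, the Wakefield approximate Bayes factor with
shrinkage r = sd²/(sd² + se²) is log ABF = ½log(1−r) + ½z²r (prior
effect sd 0.15 per trait, the quantitative-trait convention). The five
regional hypotheses use per-SNP priors p1 = p2 = 1e-4 and p12 = 1e-5
and are assembled in log space (log-sum-exp); the two-distinct-variants
term subtracts the same-SNP diagonal stably via log1p. Posteriors sum
to 1 and are invariant to SNP order.

## Mediation and FDR

Indirect effect β₁β₂ with Var ≈ β₁²se₂² + β₂²se₁²; proportion β₁β₂/T
with the full three-term delta variance, assuming zero covariances
(non-overlapping samples; the result object carries an explicit flag
for this assumption). The proportion is computed on the additive
(log-odds) scale; odds ratios are presentation transforms. The delta
CI is symmetric and first-order: with large relative errors on the
inputs (≳20%) it will deviate from the skewed exact distribution of
the ratio — the tests compare it with a parametric bootstrap at
moderate relative errors.

BH q-values use the step-up formula q_i = min_{p_j ≥ p_i} (p_j·m /
rank_j) capped at 1, with a configurable family size m that may exceed
the number of supplied p-values (for adjusting a displayed subset of a
wider screen); significance is declared at q ≤ 0.10 inclusive.

## Two-step screening pipeline

Step 1 estimates the exposure's effect on each biomarker using the
exposure's instruments, with BH-FDR over the biomarker family (default
family size: the number of biomarkers supplied; configurable, since a
published subset may belong to a wider tested family). Step 2
instruments each step-1-significant biomarker (5e-8/5e-7 fallback,
clump r² 0.001 / 10,000 kb) and estimates its effect on the outcome,
with FDR over the set actually tested; biomarkers without sufficient
instruments are reported as `no_instruments`, never fatal. Factors
significant in both steps enter MR-BMA (aligned to the outcome's
effect alleles over the union of their instruments), and the top-MIP
factor's mediation is computed against the exposure's total effect.
A single top-level seed expands into fixed per-stage seeds recorded in
the run log; identical configuration and seed reproduce every output
file byte-for-byte. Pleiotropy screening against external association
databases is replaced by an optional user-supplied SNP exclusion list.

## Synthetic-data generators

Summary statistics are generated directly at the summary level — no
individual genotypes — with independence across instruments except in
the regional (LD) generator. Generated p-values are exactly the
two-sided normal tails of beta/se, and every generator is a pure
function of its config and seed.

- **Univariable**: true SNP-exposure effects γ_j ~ N(0.055, 0.05²)
  observed with se 0.01, outcome noise se 0.05. The median per-SNP F
  is ≈ 30 (a strong-instrument regime), while the exposure-side error
  is small relative to the spread of effects so Egger's NOME
  assumption holds: with comparable error and spread the intercept
  acquires a regression-dilution bias of order θ·mean(γ)·se²/var(γ).
  Pleiotropy modes: none; balanced (zero-mean, sd = magnitude);
  directional (mean = magnitude, sd = magnitude/2).
- **Mediation chain**: three non-overlapping 100-SNP arms with slopes
  θ_xm, θ_my and θ_direct + θ_xm·θ_my (the linear-scale total);
  defaults 0.4/0.5/0.8 imply a true mediated proportion of 0.20.
- **Region pair**: AR(ρ) LD (default ρ = 0.9) over 200 SNPs; causal
  z-scores (non-centrality 8) propagate through the LD matrix to
  marginal non-centralities and one MVN draw gives the observed
  z-vector; betas/ses correspond to standardized traits at n = 10,000.
- **MVMR panel**: zero-mean SNP-factor effects with pairwise factor
  correlation 0.6 (sd 0.09, observation error 0.02), one causal factor
  with θ = 0.3 — the regime where model averaging must separate a
  causal factor from correlated proxies.
- **Screen suite**: an exposure block (20 SNPs) and 10 biomarker
  blocks (10 SNPs each) on separate chromosomes over a shared panel;
  instrument effects N(0.15, 0.04²) with se 0.015 emulate strong
  cis-acting eQTL/pQTL signals (per-SNP F ≈ 100), and the outcome se
  of 0.02 emulates a very large case-control meta-analysis. One
  biomarker sits on the causal chain; optionally another responds to
  the exposure but does not affect the outcome.

What the generators do **not** emulate: realistic allele-frequency
spectra and frequency-dependent standard errors, sample overlap
between the two samples, winner's-curse selection of instruments in
the univariable generator, population stratification, and LD between
instruments outside the regional generator. Passing tests therefore
demonstrate correctness and calibration of the estimators under their
stated assumptions, not robustness to these real-data complications.

## Known limitations

- The proportion-mediated CI ignores covariance between the indirect
  and total effects; with overlapping GWAS samples it would be
  anti-conservative.
- MR-BMA's fixed-variance conjugate prior is one of several marginal-
  likelihood conventions in use; results are verified against this
  package's own quadrature oracle, not against external software.
- Correlated-instrument IVW (generalized least squares with an LD
  matrix), Steiger filtering, multivariable MR-PRESSO and stochastic
  model search for large factor panels are out of scope.
- The simple/weighted mode p-values derive from the bootstrap se and
  normal theory; mode estimators are the least efficient of the
  battery and their intervals should be read accordingly.
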