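# Methods

`twasbench` benchmarks statistical models that impute cis-regulated gene
expression from local SNP genotypes — the model-training stage of a
transcriptome-wide association study (TWAS) — and carries the trained models
through to gene-level association testing.  Because the reference datasets
such studies use (matched genotype + RNA-seq cohorts, case/control GWAS
panels) are access-restricted, the package evaluates everything on a
synthetic cis-eQTL cohort generator whose knobs correspond to the design
axes of interest: genetic architecture, cis-heritability, training sample
size, ancestry divergence, and tissue sharing.

## Prediction models

For each gene, expression `y` is regressed on the dosages `X` of SNPs within
1 Mb of the gene start/end (closed interval; no covariates).  Columns of `X`
are centered and scaled to unit variance with training-set statistics before
every fit; stored SNP weights are back-transformed to the dosage scale.

**Penalized regression.**  Ridge minimizes `(y-Xb)^2 + λ Σ b_j^2`; the lasso
`(y-Xb)^2 + λ Σ |b_j|`; the elastic net
`(y-Xb)^2 + λ(½(1-α) Σ b_j^2 + α Σ |b_j|)`.  Note the ½ on the L2 term:
`α=0` therefore equals ridge at penalty `λ/2`, and `α=1` equals the lasso —
both identities are asserted in tests.  Lasso/elastic-net solutions come
from coordinate descent (scikit-learn backend; the objective maps exactly
onto it with `alpha_sk = λ/(2n)`, `l1_ratio = α`); ridge is solved in closed
form.  The λ path is 100 log-spaced values from
`λ_max = 2·max|Xᵀy| / max(α, 0.001)` down to `λ_max·10⁻³`; `λ_max` is the
smallest penalty at which the lasso solution is exactly zero under this
objective scaling.  The tuned elastic net searches α over {0, 0.05, …, 1}.

**BLUP.**  The polygenic model `y = μ1 + u + ε`, `u ~ N(0, σ_u² G)` with
`G = XXᵀ/p` over standardized genotypes.  Variance components maximize the
restricted likelihood via a spectral decomposition of `G` (the likelihood is
one-dimensional in the heritability ratio once the scale and intercept are
profiled out; 50-point grid plus bounded Brent refinement, tolerance 1e-6).
New samples are predicted through the cross-relationship matrix
`G_new,train = X_new X_trainᵀ/p`, which is equivalent to per-SNP weights
`w = X_trainᵀ σ_u² V⁻¹(y-μ)/p` — so BLUP models serialize to weight tables.

**BSLMM.**  The spike-and-slab mixed model
`y = μ1 + Xβ + u + ε`, `β_j ~ π N(0, σ_a²/τ) + (1-π) δ₀`,
`u ~ N(0, σ_b²/τ K)`, `K = XXᵀ/p`.  Hyperparameters are the inclusion
probability π, PVE ρ (total genetic variance fraction) and PGE h (sparse
share of it); this symbol assignment (PVE=ρ, PGE=h) follows the benchmark
convention even though the original model's papers swap the letters, so the
code names the fields `pve`/`pge` rather than the Greek symbols.  Priors:
ρ, h uniform on (0,1), log π uniform on [log(1/p), 0], improper 1/τ on the
residual precision.  Inference is Metropolis-within-Gibbs:

* inclusion indicators γ move by add/remove/swap proposals whose acceptance
  uses the marginal likelihood with β **and** τ integrated out (10 proposals
  per sweep; sparse-set size capped at 300);
* τ, β, the polygenic effect (sampled in the eigenbasis of K, zero mass on
  null-space directions), and μ have conjugate updates;
* (π, ρ, h) move by reflected uniform random walks, accepted against the
  β/u/γ prior terms; σ_a², σ_b² are derived as
  `σ_b² = v(1-h)`, `σ_a² = v·h/(πp)` with `v = ρ/(1-ρ)`.

Defaults are 1,000 burn-in + 10,000 sampling iterations.  Predictions are
posterior means of `μ + X_new β + û_new`; because
`û_new = G_new,train K⁺ u = X_new (X_trainᵀ K⁺ u)/p`, the polygenic part has
an exact per-SNP representation and BSLMM models also serialize to weight
tables.  Two forced modes collapse the sampler for verification: π=1 with
the polygenic term disabled (a Bayesian ridge) and γ≡∅ (a pure LMM whose
predictions track BLUP).  Chain quality is judged by the lag-100
autocorrelation of each hyperparameter trace: good mixing iff strictly
inside (−0.1, 0.1), and a model is poorly mixed if any of the three chains
fails.  The lag-k cross term is averaged over its n−k overlapping pairs
(an exactly periodic chain then scores 1 at a matching lag); zero-variance
chains get an infinite sentinel, classified poor.

**Random Forests.**  Bagged regression trees with feature subsampling
(500 trees, `mtry = max(1, ⌊p/3⌋)`, minimum node size 5 — standard
regression conventions).  Forests have no weight-table representation and
are carried as opaque fitted ensembles.

## Evaluation

Accuracy of a gene/method pair is the arithmetic mean over the 10 outer
folds of the Pearson R between predicted and observed expression in the
held-out fold.  Penalized methods tune λ (and α, for the tuned elastic net)
in an inner 10-fold CV on each outer training set, maximizing the mean
per-inner-fold R; ties break toward the sparser model (larger λ, larger α).
BSLMM, BLUP and forests have no inner loop.  Conventions: a zero-variance
prediction scores R = 0; folds with fewer than 3 test samples, or whose fit
fails, are skipped and the mean runs over the remaining folds; negative R
values are kept.  Reduced-training designs train on `train_folds` of the 10
groups (cyclically chosen) and test on the complement, reusing one fold
assignment per seed so results are paired across training fractions.

Cross-population evaluation trains on population A (hyperparameters tuned by
10-fold CV within A), predicts population B over the shared SNP set, and
optionally subsamples A to 90% to match the training-set geometry of the
within-A CV.  Mixed-population CV down-samples the merged panel to a target
size preserving population proportions (largest-remainder rounding).
Cross-tissue evaluation scores the same outer-fold predictions against the
second tissue's expression.

## Heritability

Cis-heritability — the ceiling on prediction R² — is estimated per gene by
REML under `y ~ N(μ1, σ_u² G + σ_e² I)` using the same spectral
machinery as BLUP; estimates are clamped to [0,1] after optimization, with
boundary fits flagged.

## TWAS stage

Trained weight tables are applied to a case/control dosage panel
(`ŷ = intercept + Σ dosage·weight` over the SNPs shared between table and
panel; absent or allele-mismatched SNPs are dropped with a logged count).
Each gene's imputed expression is standardized — so effect sizes are per SD
and comparable across methods — and tested by maximum-likelihood logistic
regression with no covariates; Wald z and two-sided p are reported with the
Bonferroni threshold 0.05/(genes tested).  Perfect separation falls back to
Firth-penalized scoring, flagged `firth`.  Genes with constant imputed
expression are skipped with a flag.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism:

* **Ancestral frequencies** uniform on `maf_range` (default 0.05–0.5).
* **Population divergence**: Balding–Nichols — population frequencies are
  Beta(p(1−F)/F, (1−p)(1−F)/F) draws at target Fst F, clipped to
  (0.001, 0.999).  Hudson's estimator on simulated panels recovers F.
* **LD**: haplotypes are AR(1) latent Gaussians (adjacent-SNP correlation
  `ld_rho`, default 0.7, optionally population-specific) thresholded at the
  population frequency quantile; dosages are sums of two haplotypes, hence
  exactly {0,1,2}.  One parameter, analytically checkable against the
  thresholded bivariate normal.
* **Layout**: each gene sits at the center of its own 2.2 Mb segment with
  SNP positions uniform on the segment, so the 1 Mb cis window excludes the
  outer flanks non-trivially.  SNPs with realized MAF < 0.01 in any
  population are removed at generation (the per-population QC real panels
  get).
* **Expression**: `y = X_std β + ε` on the normalized (Gaussian) scale.
  Sparse genes draw `n_causal` (default 2) effects N(0,1) among cis SNPs and
  rescale so the in-sample heritability equals `h2_cis` exactly; polygenic
  genes give every cis SNP an effect N(0, h2/p), matching `h2_cis` in
  expectation.  Default `h2_cis` is 0.2, the order of typical cis
  heritabilities of expression.  A second tissue (optional) keeps each
  causal effect with probability `tissue_sharing` and redraws the rest.
* **Binary trait**: disease probability `expit(c + odds_scale·g)` with `g`
  the standardized genetic value of one mediating gene and `c` solved so the
  expected prevalence matches; `odds_scale = 0` is an exact null.

What the generator does **not** emulate: coalescent LD structure and
recombination maps, RNA-seq count noise and normalization artifacts,
genotyping/imputation error, trans effects, and covariate structure.
Passing tests therefore demonstrate correctness of the estimators and the
direction of the design effects under the assumed model, not real-data
effect sizes; headline real-cohort numbers (which depend on restricted data)
are out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script run the study designs at desk scale, chosen
to resolve each effect rather than to mirror cohort sizes: 30–100 genes per
design, n = 300–400 reference samples (2,000 GWAS samples for calibration),
50–250 cis SNPs per gene.  Two design axes deserve note:

* the sample-size sweep uses `h2_cis = 0.1` so the learning curve is still
  rising at the largest training fraction — at higher heritabilities the
  curve saturates and its top end is pure Monte-Carlo noise;
* the cross-ancestry design uses dense cis panels (250 SNPs) with
  population-specific LD (`ld_rho` 0.9 vs 0.6), Fst 0.15, per-gene
  heritabilities spread over 0.05–0.6, and the polygenic BLUP predictor:
  with sparse panels a sparse solver identifies causal SNPs directly and —
  since Pearson R is invariant to affine transforms of the prediction —
  transfers across populations almost losslessly, whereas a predictor that
  spreads weight over LD proxies loses accuracy when their tagging decays in
  the target population, which is the mechanism behind the real-data
  deficit.  Heterogeneous per-gene heritability is also what makes
  gene-level accuracy estimates comparable across designs (mixed- vs
  single-population CV, TWAS power vs imputation accuracy): with one common
  h² all between-gene variation is Monte-Carlo noise.

Other numerics: elastic-net coordinate descent runs at tolerance 1e-8
(path evaluations skip redundant input validation and use Fortran-ordered
designs); REML uses eigenvalue clipping at zero and flags boundary
estimates; BSLMM floors derived prior variances at 1e-8 and caps ρ, h inside
(10⁻³, 0.999) to keep the reparameterization finite; constant genotype
columns standardize to zero (weight 0) rather than dividing by zero; fold
shuffles, forests and samplers draw from seeded generators, and pipeline
runs derive named substreams from one root seed, so identical configurations
are byte-identical.

## Known limitations

The BSLMM sampler is a single-chain design; between-chain diagnostics
(R-hat) are out of scope, as are effective-sample-size summaries.  The
collapsed γ updates condition on the current polygenic effect, so in very
high-PVE, dense-architecture regimes mixing over γ can be slow — which the
lag-100 diagnostic is designed to flag.  Weight tables store alt-allele
dosage weights without strand reconciliation; real-data inputs with strand
ambiguity need upstream harmonization.  Forest models are not portable
across library versions.
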