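# Methods

## Model

For a binary trait on n individuals the package fits the logistic mixed
model

    logit(μ_i) = X_i α + G_i γ + b_i,      b ~ N(0, Σ_s τ_s V_s),

where X_i are non-genetic covariates (with intercept), G_i are minor-allele
dosages for p SNPs, and V_1 is a genetic similarity matrix (GRM)
V = G̃G̃ᵀ/p built from standardized genotypes
g̃_ij = (g_ij − 2p_j)/√(2p_j(1−p_j)); further PSD matrices V_2, …, V_S can
encode shared environment.  With p ≫ n the SNP effects γ carry a lasso
penalty λ Σ_j v_j|γ_j|, giving simultaneous variable selection and effect
estimation while the random effect absorbs population structure and
relatedness.

Fitting uses penalized quasi-likelihood (PQL): each iteration linearizes
the likelihood into a working linear mixed model
Ỹ = X̃β + b + ε, ε ~ N(0, W⁻¹), with working response
Ỹ_i = η_i + (y_i − μ_i)/W_i and weight W_i = μ_i(1−μ_i) for the canonical
logit link (dispersion φ is fixed at 1 for the Bernoulli family).

## Two-step estimation

Variance components are estimated **once**, under the null model γ = 0
(the "population parameters previously determined" strategy), and held
fixed along the whole regularization path:

1. **Null model.** PQL alternates the working linearization with one
   average-information REML Newton step for τ on the working LMM.  With
   Σ = W⁻¹ + Σ_s τ_s V_s and the REML projection P, the update uses
   score_s = ½(ỸᵀPV_sPỸ − tr(PV_s)) and AI_st = ½ỸᵀPV_sPV_tPỸ, with
   step-halving when a step goes negative and a floor of 1e-6·Var(Ỹ).
   Convergence: largest relative change of (α, τ) below 1e-5, at most 100
   iterations.  Initial values: α from a plain logistic fit, τ_s =
   0.1·Var(Ỹ)/S.  PQL variance components for binary traits are known to
   be biased toward zero when the true variance is large; the package
   inherits this property (it affects the amount of shrinkage applied to
   the random effect, not the validity of selection or prediction, and the
   recovery tests document the achievable accuracy).

2. **Penalized path.**  Given τ̂, the penalized working objective has
   covariance Σ = W⁻¹ + K with K = Σ_s τ̂_s V_s.  Because W_i ≤ 1/4 for the
   logistic curvature, Σ ⪰ Σ_b := 4I + K, and replacing Σ⁻¹ by Σ_b⁻¹ gives
   a valid majorize–minimize surrogate whose covariance is *fixed*: a
   single eigendecomposition K = U D Uᵀ serves the entire path.  In the
   rotated basis (Y* = UᵀỸ, X* = UᵀX̃) the random effect profiles out in
   closed form, b*_i = s_i(Y*_i − X*_iβ) with s_i = d_i/(4 + d_i), leaving
   a weighted lasso with per-observation weights w_i = 1/(4 + d_i).  Each
   outer iteration re-linearizes with the bound (Ỹ = η + 4(y − μ)),
   re-rotates the response (an O(n²) matrix–vector product) and runs cyclic
   coordinate descent.

An identity-link Gaussian mode (W = I/φ, c = φ) exercises the same code
path without the curvature bound being an approximation; it reproduces a
penalized LMM exactly and is cross-checked against a dense whitened solve.

## Coordinate descent, strong rules, KKT repair

The λ grid is log-spaced over 100 values from λ_max (the smallest penalty
at which every penalized coefficient is zero, computed at the converged
unpenalized-only surrogate fit) down to 0.01·λ_max.  Each λ is warm-started
from the previous solution.  Predictors are screened by the sequential
strong rule |g_j(λ_{k−1})| < v_j(2λ_k − λ_{k−1}); after the strong set
converges, a full KKT sweep over all p predictors adds violators and the
fit repeats, so every reported solution satisfies the KKT conditions over
all columns (verified to 1e-6 in tests).  Inner convergence:
max_j |Δβ_j|·√(Σ_i w_i X*_ij²) < 1e-7; outer convergence: relative change
of the penalized objective below 1e-6, at most 50 outer iterations (the
remaining objective motion at the dense end of the path is orders of
magnitude below coefficient scale; a warning is logged when the cap is
hit).  The coordinate cycle follows the input column order, making fits
bit-reproducible.  An optional `max_active` cap truncates the path once
the active set exceeds a target size — the usual early exit when only the
sparse end is of interest.

The reported quasi-likelihood ℓ_PQL at each solution uses the actual
Bernoulli log-likelihood and ridge term at the converged coefficients, not
the bound surrogate, so AIC reflects the model rather than the optimizer.

Penalty factors default to v_j = 1 on standardized SNPs and v_j = 0 on the
intercept and covariates; κ > 0 switches to adaptive-lasso weights
v_j = |β̂_j|^{−κ} from per-SNP marginal logistic fits (separation-flagged
fits are ridge-stabilized and logged; weights are capped at 1e6).

## Model selection and prediction

AIC is −2ℓ_PQL + 2·df with df the number of nonzero fixed-effect
coefficients (df for the lasso is a design choice; counting all nonzero
fixed effects is the simplest consistent definition).  Holdout selection
maximizes validation AUC (Mann–Whitney with ½ tie credit) of the
mixed-model predictions; ties break toward the larger λ, so the sparser
model wins.  Data splitting is family-aware: connected components of the
thresholded GRM graph (default threshold 0.0884 ≈ twice the third-degree
kinship coefficient) are assigned to sets atomically, largest first, into
the set with the greatest remaining deficit, with component order
randomized by the seed.

For n_s new individuals with cross-GRM V12 (test genotypes standardized
with *training* allele frequencies), the mixed-model prediction is the
conditional expectation

    μ̂_s = expit( X̃_s β̂ + τ̂₁ V12 (W⁻¹ + τ̂₁V₁)⁻¹ (Ỹ − X̃β̂) ),

evaluated with the same bound weights W = I/4 used in fitting, so
training-set self-prediction reproduces the fitted linear predictor
exactly.  On the training-PC basis the random-effect coefficients equal
ridge-penalized GLS with per-component penalty 1/(τ̂₁Λ_i) — every PC
direction is kept but shrunk smoothly by τ̂₁Λ_i/(4 + τ̂₁Λ_i) — whereas the
PC-adjustment GLM baseline (top-r PCs as fixed effects, test projections
V12·U_r) keeps r directions unshrunk and discards the rest.  Only S = 1
(a single GRM) is supported for prediction.

## Synthetic study design

The generator draws structured genotypes from the Balding–Nichols / PSD
admixture model: ancestral frequencies ~ Uniform(0.01, 0.5); subpopulation
frequencies ~ Beta(p(1−F_u)/F_u, (1−p)(1−F_u)/F_u) with a drift ladder
F linearly spaced 0.05→0.2 across K subpopulations; admixture proportions
either a 1D Gaussian kernel (width σ_geo = 1) over subpopulations placed at
1..K with individuals equispaced, or one-hot blocks for independent
subpopulations; genotypes ~ Binomial(2, Σ_u q_iu p_uj), with SNPs below
sample MAF 0.01 redrawn.  A disjoint panel (default 50 000 SNPs; the
desk-scale experiments use 10 000) supplies the GRM.

Phenotypes follow a logistic liability with variance budget
σ² = (π²/3)/(1 − h_g² − h_b²), so the logistic residual variance is the
non-genetic share: causal effects β_j ~ N(0, h_g²σ²/|S|) act on
standardized candidate genotypes; the polygenic confounder is b = Uδ with
δ ~ N(0, h_b²σ²·D) drawn in the eigenbasis of the realized panel GRM,
which ties it to population structure by construction; covariates enter as
−log(1.3)·Sex + log(1.05)·Age/10 with Age ~ N(50, 5²),
Sex ~ Bernoulli(0.5).  Defaults are the first study scenario: n = 2500,
p = 5000, 1% causal, h_g² = 0.5, h_b² = 0.4, π₀ = 0.1, K = 10 with 1D
geography.  All randomness flows from one seed; a replicate is
bit-reproducible from (config, seed).

What the generator does *not* emulate: linkage disequilibrium between
SNPs, genotyping error and missingness patterns, real minor-allele
frequency spectra, and cryptic relatedness beyond what admixture induces.
Passing tests therefore demonstrate correct behavior under confounding by
structure, not performance on LD-structured real panels.

## Scored comparisons

`run_scenario1` compares the penalized GLMM against a logistic lasso with
and without top-10-PC adjustment (both are the τ = 0 special case of the
same path code; the PC variant adds unpenalized PC columns and projects
them onto the test set through the cross-GRM).  Each replicate is split
80/20 at random (no family structure exists in the admixture design
beyond admixture itself), the path is fitted on the training portion, and
at each target model size the nearest path point is scored: TPR (selected
∩ causal over causal), RMSE over all p SNP coefficients, precision, and
test-set AUC.  The headline desk-scale quantity is the mean TPR at model
size 50 over 5 replicates of the default scenario, reported in percent by
`scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Eigenvalues of K are clamped at zero; matrices with eigenvalues below
  −1e-8·max(d) are rejected as non-PSD.  Symmetry tolerance 1e-8.
- μ is clipped to [1e-10, 1−1e-10] before forming working responses, so
  saturated linear predictors stay finite.
- Monomorphic SNPs are dropped (warning); missing genotypes are
  mean-imputed, i.e. 0 after standardization; all-missing columns error.
- Allele orientation always counts the minor allele; .bed columns stored
  the other way round are flipped on read and logged.
- Phenotype codings {0,1}, {1,2} (PLINK), {control,case} are accepted.
- λ grid floor at 0.01·λ_max with 100 points; coordinate order fixed;
  strong-rule repair slack 1e-7.
- The problem sizes used by the test suite and acceptance script (10 000
  panel SNPs, 5 scenario replicates, 10 reduced replicates for the
  subpopulation comparison) are the package's desk-scale defaults for
  reproducible checks; all are configurable upward.

## Known limitations

- PQL's downward bias in τ̂ for binary traits with strong random effects;
  no bias correction is applied.
- Multi-component (S > 1) prediction is unsupported (fitting supports it).
- No SCAD/MCP/relaxed-lasso penalties, no k-fold deviance CV, no sparse
  GRMs or leave-one-chromosome-out panels, no PLINK 2/BGEN/VCF input.
- The CLI's full-path fits at the dense end of the grid can be slow under
  heavy saturation; use `max_active` (library) or a larger
  `--lambda-min-ratio` when only sparse models are needed.
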