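# Methods

## Model family

All five models are Gaussian mixed models on phenotype records y_ij (hybrid
j in environment i, grain yield in kg ha⁻¹):

| Model | Random terms (besides intercept μ and residual e) |
|-------|---------------------------------------------------|
| M1    | E, g_P1, g_P2 |
| M2    | M1 + g_P1×P2 (SCA) |
| M3    | M2 + gE_P1, gE_P2, gE_P1×P2 (reaction norm against the environment identity) |
| M4    | M2 + gw_P1, gw_P2, gw_P1×P2 (reaction norm against the environmental kinship Ω) |
| M5    | M3 + M4 combined (10 random terms) |

Each term is zero-mean Gaussian with covariance σ²·K for a known kernel K.
The environment main effect E is random (N(0, σ²_E I) over environments),
not fixed, so it participates in the variance partition like every other
term. Observation-level kernels factorize into entity-level pieces gathered
onto observations:

* GCA terms: Z_g G Z_g′ with G = X X′/p on major-allele counts (0/1/2);
* SCA: (Z_gP1 G_P1 Z′_gP1) ∘ (Z_gP2 G_P2 Z′_gP2), identical to expanding the
  hybrid-level Hadamard kernel G_P1 ∘ G_P2 (Schur-product theorem keeps it
  PSD);
* ×E interactions: the genetic kernels Hadamard-multiplied with Z_E Z_E′;
* ×W interactions: Hadamard with Z_E Ω Z_E′, Ω = WW′/q.

The factorized form is kept at prediction time, so cross-covariances to
arbitrary (hybrid, environment) cells are exact: for an environment absent
from training, every factor carrying the environment identity contributes
exactly zero, while Ω-carrying factors contribute through the weather-based
similarity between the new and the training environments. This is what
gives M4/M5 their ability to say something about unobserved environments
(CV0/CV00) that M3 structurally cannot.

### Marker coding and GRM centering

Genotype calls are coded per locus as counts of the major allele (frequency
≥ 0.5; an exact tie goes to the lexicographically smaller allele so the
coding is deterministic). Loci with more than two alleles are dropped;
missing calls are imputed to the rounded locus mean. `grm()` computes
X X′/p on the raw counts by default, with a `center` flag for the
VanRaden-style column-centered version.

The pipeline and the generator default to **centered** GRMs. With raw 0/2
counts the uncentered GRM is dominated by a near-constant positive block
(the squared mean marker profile), which makes every G×E kernel nearly
collinear with the environment main effect: in direct experiments the E
variance leaked almost entirely into the GCA×E terms and the partition
became meaningless. Centering removes that shared component and restores
identifiability; the uncentered mode remains available and tested.

## Environmental covariates

Hourly weather series (8 covariates: temperature, dew point, relative
humidity, rain, wind speed/direction/gust, solar radiation) are aligned per
environment so planting day is day 0, on a day × hour × covariate grid
(default 131 days → 25,152 cells). Alignment fails if coverage drops below
a configurable threshold (default 90%). Rows are stacked into W
(environments × q), missing cells imputed with the cross-environment column
mean, constant columns dropped, and the remaining columns standardized to
mean 0, SD 1 across environments (flag to disable; standardization is the
default because the covariates mix units — °C, mm, W m⁻² — and Ω would
otherwise be dominated by the largest-scale covariate). Ω = WW′/q over the
retained q columns; the column layout (covariate, day, hour) is fixed and
documented but immaterial, since Ω is invariant to column order.

## Inference

Bayesian kernel regression via Gibbs sampling. Each term's effect vector is
parameterized in the eigenbasis of its observation-level kernel
(eigenvalues below 1e-10 of the maximum are truncated), giving diagonal
Gaussian full conditionals at O(n·rank) per term and iteration; μ has a
flat prior; variances get scaled-inverse-χ² full conditionals.

Defaults: 6,000 iterations, 1,000 burn-in, thinning 5; prior df 5 with
total prior scale `prior_var_share`·var(y) split equally among the random
terms (the residual gets the same share whole). `prior_var_share` defaults
to 0.1: with df 5, larger scales put a per-term prior mean of several
percent of the total variance on every component, which measurably inflates
near-zero variance components — kernels with flat spectra (e.g. SCA×E on a
sparse design) sit on a likelihood ridge with the residual and the prior
decides where on the ridge the posterior mass sits. 0.1 keeps the prior
weakly informative while letting null components collapse.

Posterior means of the variance components are Rao-Blackwellized (the
conditional means (df₀s₀ + SS)/(df₀ + rank − 2) are averaged rather than
the draws), a pure Monte-Carlo-noise reduction. A split-chain potential
scale reduction factor on σ²_e above 1.2 emits a convergence warning
(non-fatal). Before model fitting every term kernel is rescaled to mean
diagonal 1 (flag `rescale_kernels`), making σ² comparable across terms.

The variance partition weights each posterior-mean σ² by the mean diagonal
of its kernel (1 after rescaling; identity for the residual) and normalizes
to 100%.

Predictions for arbitrary cells are per-term Gaussian conditional means
K_new,train K⁺_train g̅_train computed in the training eigenbasis; for
in-sample cells they coincide exactly with the fitted values.

## Cross-validation schemes

* **CV2** deals each hybrid's records round-robin across k folds (random
  order and offset). This guarantees every test hybrid with ≥ 2 records
  keeps training records in other environments — the defining property of
  the scheme — and keeps every environment represented in each training
  set; a pure per-environment stratification can strand all of a hybrid's
  records in one test fold, silently turning CV2 cells into CV1 cells.
* **CV1** splits hybrids into k folds and masks all records of held-out
  hybrids. Fold assignment ignores relatedness (plain random masking).
* **CV0** is leave-one-environment-out (one fold per environment; on a
  balanced 30-environment layout each fold masks 1/30 ≈ 3.33%).
* **CV00** crosses the k hybrid folds with environments: each fold masks an
  entire environment plus one hybrid group everywhere; the test set is that
  group in that environment, so neither the test hybrids nor the test
  environment touch the training set.

Defaults: k = 5 for CV2/CV1/CV00 (CV1 then masks ~20% per fold). Folds with
fewer than 10 training records are skipped with a warning.

## Evaluation

Per-environment Pearson correlations r_i between predicted and observed
values (environments with < 3 pairs or zero variance are dropped with a
warning), sampling variance V(r_i) = (1 − r_i²)/(n_i − 2), and the
inverse-variance-weighted average r_φ with the normal-approximation 95% CI
r_φ ± 1.96·√(1/Σ 1/V_i) — the natural companion of inverse-variance
weighting; the CI construction is an assumption, not a theorem. |r_i| = 1
gets an ε = 1e-8 variance floor so weights stay finite. A Fisher-z variant
(average on the z scale, back-transform) is available behind a flag for
sensitivity analysis; the default weights raw correlations.

## Synthetic data generator

The generator emulates the structure of a two-pool hybrid testing program:

* **Genotypes** — fully homozygous inbreds (0/2 counts), per-locus allele
  frequency uniform in (0.1, 0.5), monomorphic loci redrawn; optional
  residual heterozygosity. Defaults: 60 parent-1 inbreds, 8 testers, 500
  loci.
* **Design** — parent-1 lines used nearly uniquely (cycled), testers reused
  heavily; distinct parent pairs; observed cells sampled per environment
  (each environment ≥ 30 hybrids where feasible, every hybrid observed at
  least once). Defaults: 300 hybrids × 10 environments at 30% observed —
  inside the 19–36% range such multi-environment trials show.
* **Weather** — per covariate: an environment-level mean shift (strictly
  positive between-environment variance), a seasonal half-sine, a diurnal
  sinusoid and AR(1) noise; rain is zero-inflated exponential with an
  environment wetness level; planting dates staggered around early May.
* **Phenotypes** — the full ten-term decomposition: each effect vector is
  drawn N(0, K σ²_t) in the kernel eigenbasis with σ²_t = fraction_t ×
  total variance (kernels at mean diagonal 1, so expected variance shares
  match the fractions); μ = 9065.5 and total SD = 2979.2 echo the scale of
  public maize yield trials. The default fractions put ~57% on
  environments, ~10% on genetic main effects, ~12% on interactions and
  ~21% on the residual.

G×W effects are generated from the same full-window Ω later available to
the model (well-specified case). `misspecified_window=(d0, d1)` instead
generates them from a hidden kinship restricted to a phenology window while
the fit sees only the naive full-window Ω — the qualitative situation in
which naive season-long covariates underperform.

What the generator does **not** emulate: linkage disequilibrium and
within-pool population structure, spatial field trends, year effects beyond
the environment label, heteroscedastic residuals, non-Gaussian yields.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behavior of the schemes under the assumed generative model, not
performance on real trials.

## Study sizes and numerical choices

The bundled studies run at desk scale, chosen so the full suite executes in
minutes on one CPU:

* GBLUP-oracle agreement: 10 single-kernel fixtures, n = 50, default chain.
* Partition recovery: 300 hybrids, 10 environments, 10 seeds, chains of
  3,000 (1,000 burn-in). Recovery is summarized by the Spearman correlation
  between the generating fractions and the across-seed **mean** partition
  (plus Pearson on the raw scale). Per-seed Spearman is also reported: on a
  single realization the near-zero components (e.g. SCA×E at 0.1%) are not
  rank-identifiable from n ≈ 900 records — their posterior mass sits on the
  ridge shared with the residual — so the single-seed number is
  intrinsically noisier (~0.7).
* Scheme ordering: 20 replicates of 100 hybrids × 10 environments at 50%
  observed, chains of 800, CV2 with the default k = 5 and CV00 with k = 2
  genotype folds (fewer folds than the default to keep the 10 × k fold grid
  affordable).

Other numerics: kernels validate symmetry to 1e-10 and smallest eigenvalue
≥ −1e-8 × largest; QC uses the closed interval mean ± 3 sample SD per
environment (candidate included, single pass); degenerate inputs (constant
y, zero kernels, single-record environments) are handled explicitly and
tested.

## Known limitations

* Variance components of terms with flat-spectrum kernels are only weakly
  identified at desk scale; their posterior means inherit prior
  sensitivity. Rank-based conclusions should use multi-seed averages.
* The Gibbs sampler runs a single chain; the split-chain R̂ on σ²_e is a
  heuristic, not a guarantee.
* CV2's hybrid-balanced dealing slightly perturbs exact per-environment
  fold balance (immaterial beyond toy sizes).
* The CI for r_φ ignores correlation between environments sharing hybrids.
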