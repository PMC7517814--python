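# Methods

## Model

The core object is the additive genetic covariance matrix **G** of *t*
quantitative traits, estimated from pedigreed phenotypes by a multivariate
animal model

y_i = μ_gen(i) + a_i + d_dam(i) + s_sire(i) + e_i,

with vec(a) ~ N(0, G ⊗ A), dam and sire effects N(0, D ⊗ I) / N(0, S ⊗ I)
absorbing maternal/paternal common-environment variance, and residuals
N(0, R ⊗ I). Generation enters as a fixed block factor, which removes
between-generation mean differences (environmental trends and, inevitably,
part of any genetic trend — a known cost of this standard parameterization).
**A** is built by the tabular recursion (A_jj = 1 + 0.5·A_sire(j),dam(j);
A_ij = 0.5·(A_i,sire(j) + A_i,dam(j))); unknown parents contribute zero,
selfed matings are handled by the same recursion. A is stored dense, which
is comfortable to a few thousand individuals — the scale this package
targets.

### Sampler

Estimation is a blocked Gibbs sampler:

* **Breeding values** are updated as one exact block. With one record per
  individual, the eigendecomposition A = U Λ Uᵀ (computed once) rotates
  the system so that each transformed individual has an independent
  t-variate normal full conditional — no single-site updates, no tuning.
* **Covariance components** get conditional inverse-Wishart updates. The
  prior is stated in the (V, ν) convention common in Bayesian mixed-model
  software — limit variance 1, covariance 0, degree of belief ν = 0.002 —
  i.e. an inverse-Wishart with scale Ψ = ν·V, V = I. The default is weakly
  informative; sensitivity to V = 0.1·I and 10·I is exercised in tests.
* **Missing trait values** are imputed each sweep from their conditional
  normal given the individual's observed traits (data augmentation), so
  individuals with partial records stay in the analysis.
* **Dam/sire terms** whose groups are all singletons are dropped with a
  warning (confounded with the residual); a founders-only pedigree (A = I)
  triggers an identifiability warning because a and e are then confounded.

Chains are deterministic given a seed. The publication-scale setting
(1.2M iterations, 200k burn-in, thinning 500 → 2000 draws) is available as
`FULL_CHAIN`; the package default (20k/5k/15) is sized for desk-scale
analyses, where the examples here mix well (lag-1 autocorrelation of G
elements below 0.1 is checked by `diagnostics()`). Draws that come back
numerically non-PSD are repaired by eigenvalue clipping and counted;
point estimates (elementwise KDE mode by default, mean optionally) are
projected to the nearest PSD matrix.

## Transformations and units

Volatile-type traits are ln(x+1)-transformed; all traits are z-scored,
within generation by default (normalizing scale differences between
generations) with a global option. The transformation record stores
per-generation means and SDs so predictions can be restated in raw units.
Predicted and observed changes are reported in parental-generation
phenotypic SDs: Δz_obs = (mean(last gen) − mean(first gen)) / SD(parental
gen).

## Selection gradients

Two estimators, matching two designs:

* **Truncation selection**: S = mean(selected) − mean(all) per generation;
  β_h = S / V_P (sample variance, ddof = 1 by default and configurable —
  the convention is stated rather than assumed); the cumulative gradient
  over generations is the sum of the per-generation values.
* **Fitness-based selection**: the Lande–Arnold partial regression of
  relative fitness w on standardized traits, replicate as an additive
  fixed factor, all generations and replicates pooled. w is seed set
  divided by the mean seed set of the replicate × generation cohort, so w
  averages exactly 1 per cohort. Non-significant gradients are retained.
  Quadratic/correlational gradients (squared and cross terms, diagonal
  coefficients doubled per the standard convention) are available but are
  not used by predictions. A design condition-number guard reports
  collinear trait columns instead of silently dropping them.

For predictions the pooled regression vector is applied once in Δz = Gβ
(one-step reading) even when the observed change spans several
generations; a compounded per-generation application is not attempted
because the pooled β has no per-generation resolution.

## Prediction, decomposition, classification

Δz = Gβ per posterior draw; direct component G_ii·β_i, indirect component
Σ_{j≠i} G_ij·β_j (they sum to the total exactly; asserted to 1e-10).
Summaries use the shortest-interval (HPD) estimator on sorted draws;
"significant" means the 95% HPD excludes zero. Traits are tagged
(rule table in `classify_trait`): *enhanced* when direct and indirect
components agree in sign; *constrained* when they oppose, the total
opposes the direct component, or the total is smaller in magnitude than
the direct component (and also when the observed and direct responses
oppose); *direct-target candidate* when the observed change lies inside
the total's HPD and shares the direct component's sign; *indeterminate*
when everything is zero.

## Constraint angles

θ = angle(Δz, g_max), folded to [0, 90]° because eigenvector sign is
arbitrary, computed per G draw to give a posterior; γ = angle(Δz, β),
unfolded ([0, 180]°) because both vectors carry meaningful signs, computed
once from point inputs. Degenerate eigenvalues are ordered by a
deterministic lexicographic tie-break on loadings, with each vector's
largest-magnitude loading made positive — seed-independent by
construction.

## G-matrix comparison

* **Random skewers**: skewers are isotropic unit vectors (normalized
  standard normals; a uniform-component option is provided for
  compatibility with older implementations — isotropy is preferred because
  it is rotation-invariant). The per-skewer statistic is the cosine of the
  angle (vector correlation) between the two response vectors; the
  reported statistic is the mean over 10,000 skewers by default.
* **Flury hierarchy**: log-likelihood-ratio statistics for equality
  (pooled-matrix fit), proportionality (ML fit of S_i = ρ_i·Σ by
  alternating updates), and CPC, each measured against the
  unrelated-matrices alternative. The common basis minimizes
  Σ n_i·log(det(diag(BᵀS_iB))/det(S_i)) by pairwise rotations; each 2×2
  subproblem is solved globally by a coarse grid over the rotation angle
  plus a bounded Brent polish (the textbook fixed-point eigen-iteration
  can stall on saddle points; the grid+polish variant matches a dense
  1-parameter grid search to 1e-4 and keeps the objective non-increasing).
  Up to 500 sweeps, objective tolerance 1e-8.
* **Significance** for both is empirical: the observed statistic is ranked
  in a null distribution built by pairing randomized G estimates (from the
  permutation machinery below). Pairing is independent by default
  (index-paired optionally, since how the original analyses paired their
  randomized estimates is not documented); both tails are reported with
  the extreme one flagged.

## Permutation significance of G elements

Within each generation, offspring are reassigned dams and sires by
permuting the dam and sire lists independently (a pair-preserving option
exists); the multiset of parents per generation is preserved exactly. The
model is re-fit on each shuffled pedigree (N replicates; each replicate's
seed derives from (master seed, replicate index), so batched runs
reproduce a single run bit-for-bit) and the posterior-mode G of each
re-fit forms the null. The per-element empirical P is the rank of the
observed element among null values, folded so that an extreme rank in
either direction is small, and floored at 1/N (never 0). Benjamini–
Hochberg FDR is applied jointly over all t(t+1)/2 unique elements by
default (variances and covariances as separate families optionally — the
appropriate family is a judgement call and both summaries are emitted).
Null replicates default to scaled-down chains; hundreds of full-length
chains are cluster-scale work.

## The simulator

The simulator draws founder breeding values MVN(0, G_true), transmits them
as parental midpoint plus a Mendelian-sampling deviation
MVN(0, 0.5·(1 − (F_s + F_d)/2)·G_true) with inbreeding tracked by an
incremental kinship recursion, and adds per-parent dam/sire effects and
residuals. Two designs are emulated:

* **Artificial selection**: a 150-plant parental cohort shared by three
  lines (top 10 on trait 1, bottom 10, random 10), randomly hand-pollinated
  within line, ~50 offspring per line per generation for 3 generations
  (~600 plants). Realized selection differentials are logged per line,
  generation and trait.
* **Pollinator-style selection**: 3 replicates × 36 plants; fitness is
  linear-with-floor, w = max(0, 1 + β_trueᵀz + ε) — the Lande–Arnold
  regression estimates the gradient of a linear fitness surface, so
  linearity makes β_true the recoverable truth (a log-linear option
  exists). Visitation subsamples plants (5 pollinators ×
  up to 3 distinct plants each, truncated-Poisson plant counts), unvisited
  plants set no seed, seed set = round(w × 30), and the next cohort is
  sown proportionally (target·seeds_j/Σseeds, fractions below 0.5 rounded
  up to 1, deterministically trimmed/padded to the exact cohort size).
  Nine selection rounds are followed by a random inter-replicate crossing
  generation. Baseline seed set 30 and fitness noise SD 0.3 are
  field-realistic choices where no value was dictated by the designs being
  emulated.

All randomness flows from one master seed through named substreams
(founders, selection, mating, noise, fitness), so stages are independently
reproducible. The simulator does **not** model explicit loci, linkage, or
evolution of G_true itself (G changes only through the realized
relationship structure), plasticity, or measurement error distinct from
the residual — so passing recovery tests demonstrates correctness of the
estimation machinery under the infinitesimal model, not robustness to
real-data pathologies such as non-normal volatiles beyond what ln(x+1)
fixes, G × E, or pedigree errors.

## Numerical and design choices

* HPD intervals use the shortest-window estimator on sorted draws, not
  equal tails.
* A-matrix eigenvalues are floored at 1e-10 before inversion; conditional
  covariances in the imputation step get a 1e-12 jitter.
* Variance divisor for V_P is n−1 (configurable), stated rather than
  assumed.
* The three selection lines may share the parental generation or not; the
  loaders and `subset_line` support both (restricting a pedigree without
  ancestors re-flags out-of-subset parents as unknown founders).
* Problem sizes in tests and the acceptance script (n ≈ 400–600, t = 2–4,
  chains 6000/1500/5, 50-replicate permutation nulls) are chosen so the
  whole validation surface runs on a single CPU in minutes while keeping
  Monte-Carlo error well inside the asserted tolerances; the
  publication-scale settings remain one configuration switch away.

## Known limitations

* Control-line G estimates at the emulated study scale (~160 line members,
  10 effective parents per generation) carry large sampling variance;
  single-seed point estimates can miss G_true by a factor of two even
  though the 5-seed average recovery is unbiased to < 0.15 SD². This
  mirrors the wide HPD intervals such experiments report.
* The generation fixed effect absorbs part of genetic drift, biasing
  additive variance slightly downward in deep random-mating pedigrees.
* REML/frequentist fits, DIC/WAIC model comparison, genomic relationship
  matrices, and multi-generation forecasting with an evolving G are out of
  scope.
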