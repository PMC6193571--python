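# Methods

This note documents the generative model behind the simulator, the
statistical model and estimation algorithm, the numerical choices, and the
known limitations. It is the package's own account of its science; every
number quoted here is computed by the test suite or the acceptance script.

## The model

The multiple-matrix animal model is the linear mixed model

y = Xβ + Σ_k Z_k u_k + r,  u_k ~ N(0, S_k V_k),  r ~ N(0, I V_r),

with X an intercept column by default. Each random term k is a pair
(covariance source, carrier). The source supplies the symmetric PSD
structure S_k over the term's levels:

* **A** — additive relatedness, A_ij = 2θ_ij with θ the coefficient of
  coancestry and diagonal 1 + F_i; built from the pedigree by the
  recursive tabular method, so inbreeding is exact.
* **S_n** — environmental similarity. Environmental measures are centered
  and scaled per column; S_n(i,j) = 1 − d_ij / max(d) with d the pairwise
  Euclidean distance, so the diagonal is 1 and the most dissimilar pair
  scores exactly 0. max(d) is taken over all phenotyped pairs.
* **S_epi** — the same kernel over per-island methylation counts.
* **S_c** — social similarity 1/(1 + g_ij) from unweighted geodesic
  distances; disconnected pairs get 0, the diagonal is 1.
* **identity** — an unstructured grouping factor (e.g. "maternal identity"
  as a plain random effect).

The carrier decides Z_k: `self` gives one level per record (identity Z
when each individual is measured once); `dam` maps each record to its
mother's level, which is how maternal genetic (A over dams) and maternal
environmental (S_n over dams) variance enter. Dams missing from a
nongenetic similarity source — the phantom founders that parent the first
generation — are appended as extra levels with unit diagonal and zero
similarity to everyone, the usual missing-data convention; because max(d)
is computed over the phenotyped set, this never changes existing entries.

Heritability is reported as h² = V̂_a / (Σ_k V̂_k + V̂_r), i.e. the
denominator includes every estimated component.

## Estimation

Variance components are estimated by restricted maximum likelihood.
The restricted log-likelihood is evaluated densely,

ℓ(θ) = −½ [ log|V| + log|X'V⁻¹X| + y'Py ],  V = Σ_k V_k Z_k S_k Z_k' + V_r I,

via Cholesky factorization, and maximized with average-information (AI)
updates. Each Newton step uses the AI matrix ½ W'PW (columns of W are
G_k P y); step-halving enforces a non-decreasing likelihood, and when the
AI step is unusable (indefinite AI matrix, or no acceptable step length) a
positivity-preserving fixed-point update V_k ← V_k · (y'P G_k P y)/tr(P G_k)
— which shares the AI stationary points — is substituted. Starting values
split the sample phenotypic variance equally across all terms.

Convergence requires relative likelihood change < 1e-8 and maximum
relative parameter change < 1e-6 (cap 100 iterations; non-convergence is
flagged, never fatal). Parameters are kept above a soft bound of
1e-6 · Var(y); estimates ending on the bound are flagged rather than
dropped. Standard errors come from the inverse AI matrix at the optimum
(verified against a numerical Hessian of the restricted likelihood in the
tests), heritability SEs by the delta method. Per-term p-values are
offered two ways: one-sided Wald tests (reported with every fit) and
likelihood-ratio tests of nested fits with the boundary-corrected null
mixture ½χ²₀ + ½χ²₁, which is the canonical choice for a variance
component tested at zero.

Everything is dense linear algebra: at the target scale (n ≈ 2·10³
phenotyped individuals) a factorization costs well under a second, and
simplicity wins over the sparse-inverse machinery of dedicated animal-model
software.

## The simulator

The simulator produces the study conditions the models are evaluated on;
its defaults are the conditions, not tuning knobs.

**Pedigree.** Ten semelparous generations, each of 150–250 individuals
(uniform draw), sexes balanced by construction. Half of each generation is
selected at random into monogamous breeding pairs; offspring of the next
generation are allocated to pairs uniformly. Exactly round(0.10 · N)
offspring per generation are extra-pair: one parent (dam or sire with
equal probability) is reselected uniformly among the other same-sex
breeders — the deterministic count makes the rate exact and auditable via
the `extra_pair` column. Generation 0 consists of phantom founder pairs
(unrelated, non-inbred, as many pairs as a typical generation forms) whose
only role is to give generation 1 sibship structure, maternal carriers,
and maternal environments; phantoms carry no phenotypes.

**Space and environments.** Individuals live on a 50×50 cell grid. Five
environmental variables are independent Gaussian random fields with
covariance exp(−φ·d), φ = 0.15 per cell of Euclidean distance, realized by
Cholesky factorization of the 2500×2500 cell covariance (with a 1e-10
jitter retry on failure). Each draw is standardized to sample mean 0 /
variance 1 over cells, and the five draws are decorrelated over cells —
both are linear maps across same-kernel fields, so each variable remains a
GRF with the stated kernel while the between-variable sample covariances
are negligible by construction. Generations 0 and 1 are placed uniformly;
each later individual starts at its dam's cell and moves a lognormal(μ=1,
σ²=1) distance (log-scale parameters, i.e. median e¹ ≈ 2.7 cells) in a
uniform direction, rounded to the nearest cell and reflected at the grid
edges. Reflection preserves marginal coverage without torus artifacts.
An individual's environmental vector is the field value at its cell,
verbatim.

**Epialleles.** 230 CpG islands with methylation counts in [0, 20]:
100 respond to the individual's own environment — count ~ Binomial(20,
logistic(w·k_i)) with a fixed island-specific unit-norm weight vector w
(the response function is this package's choice; it keeps counts bounded,
monotone in the environment, and heterogeneous across islands); 30 are
maternally transmissible — the dam's count is copied, or reset to the
own-environment rule with probability 0.5; 100 are uniform noise.

**Social network.** A simple undirected graph over the non-phantom
generations. Within a generation, P(edge) = p₀·exp(−d/λ) with p₀ = 0.8,
λ = 4 cells; between adjacent generations the same probability is
attenuated by α = 0.25, except mother–offspring pairs connect with
p_m = 0.9 regardless of distance; generations further apart are never
linked. These four values are package defaults chosen for a moderate mean
degree (≈5–15) and informative geodesic structure, and are exposed in the
config.

**Traits.** Breeding values follow the pedigree: founders N(0, 1),
offspring = midparent + Mendelian deviation with variance
½(1 − (F_dam + F_sire)/2), so cov(a_i, a_j) = A_ij exactly (checked
against gene-dropping in the tests). A second, independent run of the same
recursion gives the maternal genetic values behind Ma. The direct
environmental effect is n_i = Σ_l β_l k_{l,i} with β_l = 1/√5, so Var(n)
≈ 1; the maternal environmental effect Mn applies the same weights to the
dam's environment (a config switch substitutes independent random unit-norm
weights; limited dispersal induces an n–Mn correlation either way, which
is the point of the exercise). Residuals are iid N(0, 1) per trait. The
three phenotypes are exact sums of the stored components:
y1 = a+n+r, y2 = a+n+Mn+r, y3 = a+Ma+n+Mn+r.

### What the simulator does and does not emulate

Limited maternal dispersal across an autocorrelated field makes relatives
share environments — the confound that inflates naive V̂_a and that the
similarity matrices resolve. Realization-to-realization, the variance
realized by n and Mn over *individuals* fluctuates (roughly 0.75–1.1)
because lineages cluster in space and sample the field unevenly; averages
over replicates sit near 1. The induced n–Mn covariance also means
Var(y2) and Var(y3) exceed the naive component counts (≈5 and ≈6 rather
than 4 and 5 on average) — the tests account for this explicitly.

Not represented: overlapping generations or repeated measures, selection
on phenotype, genomic (marker) relatedness, direct–maternal genetic
covariance, paternal effects, temporal environmental change, weighted or
directed networks, and locus-level epigenetic architecture. Passing tests
therefore demonstrate correct recovery under a clean additive generative
model, not robustness to these real-data complications.

## Numerical choices and edge cases

* Similarity kernels are not guaranteed PSD; `make_psd` clips eigenvalues
  below 1e-8, reassembles, restores the unit diagonal by symmetric
  normalization, and logs the maximum entry perturbation. PSD inputs pass
  through unchanged (< 1e-10).
* Constant feature columns are dropped from similarity construction with a
  warning (their scale is undefined); fully identical rows are rejected
  (max distance 0).
* The LRT statistic is floored at zero; a reduced model with materially
  higher likelihood than the full model is an error.
* Gene-dropping (Monte-Carlo allele transmission) is used only as a test
  oracle for A and for the breeding-value covariances, never in the
  fitting path, and likewise the AI-REML optimum is cross-checked against
  derivative-free maximization of an independently coded error-contrast
  likelihood.

## Problem sizes used in the shipped studies

The replicated recovery study (acceptance script and full-scale tests)
uses 5 replicates at the full scale — 10 generations of 150–250, ≈2000
phenotyped individuals — for the true-model fits of all three traits, and
10 replicates for the misspecified genetic-only fit of trait 1. The unit
and property tests run on scaled-down populations (3–6 generations of
20–100) where every fit takes well under a second; the data-requirements
study defaults to fractions {0.25, 0.5, 0.75, 1.0}.

## Known limitations

* Dense algebra bounds practical problem size at roughly n ≈ 10⁴ records.
* Maternal genetic and maternal environmental variance are intrinsically
  hard to separate when related mothers share environments; the full model
  for trait 3 recovers them on average but with visibly larger standard
  errors — increased data sizes help (see the subsampling study).
* The AI fallback update is heuristic: it guarantees positivity and shares
  the AI stationary points, but pathological likelihood surfaces could in
  principle stall progress; such fits are flagged as non-converged.
* Delta-method h² standard errors are first-order and can differ from
  resampling-based intervals near the boundary of the parameter space.
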