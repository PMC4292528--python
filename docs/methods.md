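# Methods

`famrare` implements transmission-based and case–control association tests
for groups of rare variants, together with a simulator of nuclear families
ascertained on affected offspring and a replication engine for estimating
power and type-I error. This note documents the model, the statistics, the
numerical choices, and what the synthetic data do and do not represent.

## Disease model

Each subject carries a genotype `g = (g_1, …, g_m)` of minor-allele counts
over `m` biallelic variants. Affection is Bernoulli with the logistic
penetrance

    P(affected | g) = expit( logit(c) + Σ_i β_i g_i )

where `c ∈ (0,1)` is the background affection probability of a non-carrier
(it absorbs unmeasured genetic and environmental risk) and `β_i = log OR_i`
is the per-allele effect of variant `i` (`β_i = 0` for non-causal variants).
Variants are independent and in Hardy–Weinberg equilibrium in the source
population; no linkage disequilibrium, covariates, X-linked inheritance or
de novo mutation are modelled.

`population_prevalence` computes the exact expectation of the penetrance
over HWE genotype frequencies by grouping variants with identical
`(MAF, β)` and convolving their count distributions — feasible because `m`
is small. Under the default causal scenario (10 variants, MAF 0.5%,
`c = 0.01`, four causal variants with OR 2.0) the exact prevalence is
1.040%; published prevalence figures for comparable configurations
(≈1.1–1.2%) differ somewhat from this closed-form value, so prevalence is
documented but never asserted as a test.

## Family structures and ascertainment

Three sampling units are supported:

* **trio** — two parents, one affected child;
* **ASP** — affected sib-pair: two parents, both of two children affected;
* **enriched trio** — an ASP from which one affected sibling is discarded,
  modelling selection of one case per multiplex family.

Ascertainment conditions the sample on offspring affection, which tilts
genotype distributions away from HWE (causal alleles are enriched in cases,
most strongly under ASP/enriched ascertainment). Naive rejection sampling
is exact but needs `O(1/prevalence)` parental draws per trio and
`O(1/prevalence²)` per ASP — prohibitive at 1% prevalence. The default
sampler is an exact *tilted* sampler:

1. enumerate parental carrier configurations — the per-variant pair of
   parental genotypes — up to a total parental minor-allele count `k`
   (default 4; at MAF 0.5% the neglected prior mass is ≈2·10⁻⁶ and is
   folded into the zero-carrier configuration; if the residual exceeds
   10⁻⁴ the budget is increased automatically, up to full enumeration);
2. for each configuration, compute the ascertainment probability by
   summing the penetrance over the ≤3⁴ joint Mendelian child outcomes
   (for ASPs the two children are conditionally independent given the
   parents, so the probability that both are affected is the square of the
   single-child expectation);
3. sample configurations from the prior×ascertainment-tilted distribution,
   then child genotypes from the conditional affected distribution. The
   retained enriched-trio child is drawn from the ASP-tilted conditional,
   which is exactly "simulate an ASP, keep one affected child".

The rejection sampler is retained as an independent oracle (the test suite
checks χ² goodness of fit of the joint parent–child law at n = 10⁵) and as
the fallback for high-prevalence/common-variant models where enumeration is
intractable; it also records which allele each parent transmitted, used
only to cross-check the phase-free transmission counting rule.

Unrelated controls are screened (unaffected) by default; at ~1% prevalence
screened and population controls are nearly indistinguishable, and under
the global null screening has no effect at all. The number of controls
defaults to the number of cases. Stratified sampling draws each family
wholly from one of several (weight, panel, model) strata.

## Transmission counts and data transformations

For trio `i` and variant `j`, with unphased genotypes only:

    B_ij = g_child − #(parents homozygous minor)   minor transmissions from
                                                   heterozygous parents
    C_ij = #(heterozygous parents) − B_ij          major transmissions
    X_ij = B_ij − C_ij

Homozygous parents transmit deterministically and cancel; only heterozygous
parents are informative. ASPs are treated as two trios sharing parents (no
prior linkage hypothesis, so transmissions to each sibling are
independent).

* **PCC** (pseudo-case–control): per trio, one pseudo-control built from
  both untransmitted parental alleles, `g_pseudo = g_father + g_mother −
  g_case`; cases are the affected offspring. Only this one of the three
  possible pseudo-controls is generated (the unmatched-design choice).
  The identity `column-sums of X = case − pseudo-control allele-count
  contrast` makes the transmission score and the PCC score the same
  statistic up to scaling, which is why family-format and PCC tests have
  near-identical power.
* **UCC** (unrelated case–control): affected offspring plus simulated
  population controls; parental genotypes are discarded.
* **Clustering**: sibling cases violate the independence assumed by
  case–control tests. `cluster_related` sums minor-allele counts of
  related cases into one composite case and sums controls in matching
  block sizes (pseudo-controls with their own family; unrelated controls
  blocked in input order — any exchangeable grouping has the same null
  law). This halves the ASP sample size and restores validity at a cost in
  power.

## Test statistics

All five multivariate score tests are functionals of the score vector and
its empirical covariance,

    U = Σ_i X_i ,   V = Σ_i (X_i − X̄)(X_i − X̄)ᵀ

(family format; rows of X), or of the logistic null score
`U = Gᵀ(y − ȳ)`, `V = ȳ(1−ȳ) Σ_i (g_i − ḡ)(g_i − ḡ)ᵀ` (case–control
format). V carries no Bessel correction — the sum-of-outer-products form
keeps the sum/score/SSUw statistics scale-consistent; at n ≥ 600 the
n/(n−1) distinction is immaterial, and a user wanting the other convention
can rescale V.

* **TDT / single-SNP association** — per variant `(b−c)²/(b+c)` (or the
  1-df score χ²), Bonferroni-corrected minimum p over informative variants;
  variants with no informative transmissions (or monomorphic) are excluded
  from both the minimum and the correction count, since they carry no
  information and would otherwise produce 0/0.
* **UminP** — `max_j U_j²/V_jj`; p-value as the complement of the joint
  multivariate-normal rectangle probability with correlation from V (Genz
  quadrature, singularity-tolerant); falls back to sign-flip Monte Carlo
  (10⁴ flips) for m > 20 or if the integration fails.
* **score** — `Uᵀ V⁻ U` with eigenvalue pseudo-inverse (relative cutoff
  10⁻⁸·λ_max), χ² with df = rank(V).
* **SSU** — `UᵀU`, null law `Σ_j λ_j χ²₁` with λ the eigenvalues of V.
* **SSUw** — `Uᵀ diag(V)⁻¹ U` over variants with `V_jj > 0`, mixture law
  from the correlation-scaled V.
* **sum** — `(1ᵀU)²/(1ᵀV1)`, χ²₁; a burden-style test that assumes equal
  effects and loses power when risk and protective effects cancel.
* **C-alpha** — overdispersion of the case/control split of the `n_j`
  copies of variant `j`: `T = Σ_j [(a_j − n_j p₀)² − n_j p₀(1−p₀)]` with
  `p₀` the case fraction; the analytic variance sums exact binomial fourth
  moments per copy-count class, `Z = T/√c` referred to the upper normal
  tail. The binomial model treats copies as independently assigned to
  cases, ignoring subject-level clustering of copies, and the normal
  approximation degrades at the very low counts typical of rare variants —
  hence the permutation version (label shuffling, one-sided, add-one
  estimator) is used in all simulation batteries.
* **SKAT** — `Q = (y−ȳ)ᵀ G W Gᵀ (y−ȳ)` with `W = diag(w_j²)`,
  `w_j = Beta(maf̂_j; a1, a2)` density weights on combined-sample observed
  MAFs (default Beta(1, 25); Beta(1, 1) gives unit weights, in which case
  Q ≡ SSU exactly, p-values included — an identity the test suite asserts).
  Null law from the eigenvalues of the weighted centred genotype
  cross-product scaled by `ȳ(1−ȳ)`.
* **KBAC** — genotype-class frequency contrast
  `Σ_i k_i (n_iᴬ/nᴬ − n_iᵁ/nᵁ)` over distinct non-null multi-variant
  genotypes, with `k_i` the cumulative hypergeometric probability of
  observing at most `n_iᴬ` cases among the class's carriers (small-sample
  kernel, cumulative including the observed count). One-sided in the risk
  direction; p by label permutation with per-permutation class re-counting
  (class tables are hashed once, only case counts are re-tallied).

### Mixture-of-χ² tail probabilities

SSU/SSUw/SKAT p-values need `P(Σ λ_j χ²₁ > t)`. This is computed by exact
inversion of the characteristic function (Imhof's integral). The integrand
`sin θ(u)/(u ρ(u))` is truncated where its oscillation-averaged envelope
bound drops below 10⁻¹⁰ and integrated by vectorized Simpson quadrature
with panel doubling until the value stabilises (typically < 5 ms, accurate
to ~10⁻⁹ even at tail probabilities of 10⁻⁸); the Liu–Tang–Zhang
moment-matched non-central χ² approximation is the fallback if the
quadrature fails to converge. Eigenvalues below 10⁻¹⁰·λ_max are dropped.

### Permutation p-values

All permutation tests use the add-one estimator `(1 + #{T* ≥ T})/(n_perm +
1)` with ties counted as exceedances (conservative, and valid for any
n_perm). Default budgets: 1000 permutations.

## Replication engine

A scenario fixes the structure, panel, disease model, test roster and
budgets. Each replicate simulates one family sample, builds family, PCC
and UCC datasets *from the same families* (as one would with real data),
applies clustering where the roster demands, and records each test's
p-value; rejection uses the strict inequality `p < α` (consistent with the
conservative permutation estimator). Per-replicate RNG substreams are
derived deterministically from `(seed, replicate index)`, so results are
reproducible and independent of execution order. `calibrate_or` finds the
shared causal OR reaching a target power by a coarse monotone scan followed
by bisection at reduced replicate counts; the baseline ORs 2.00 (trios),
1.72 (ASPs) and 1.54 (enriched trios) give the most powerful test roughly
90% power at 1200 cases.

The scenario batteries mirror the baseline study design: null, baseline,
varying causal-variant count (1–10), total variant count, OR sweeps for one
and four causal variants, protective-variant replacement (reciprocal ORs),
±20% OR fluctuation, stratified populations (stratum parameters must be
supplied by the user) and case-count subsampling (both arms reduced
proportionally, 100–1100 cases).

## Problem sizes and runtime

The reference experiments (`famrare.benchmarks`, reported by
`scripts/acceptance.py`) use the baseline study conditions: 1200 cases
(1200 trios / 600 ASPs / 1200 enriched trios), 10 variants at MAF 0.5%,
`c = 0.01`, α = 0.05, 1000 replicates for closed-form tests and 500
replicates × 1000 permutations for the permutation-calibrated tests (KBAC,
permutation C-alpha) — a full run takes ~2 minutes on one CPU thanks to
the tilted sampler. At these budgets the binomial Monte-Carlo standard
error is ≈0.7 points for a 5% rate and ≈1.5 points for a 50% power value.

## What the simulator does and does not show

The generator reproduces the mechanisms the tests are sensitive to —
HWE parental genotypes, Mendelian transmission, logistic penetrance,
ascertainment on affection, sibling dependence, population stratification —
so passing tests demonstrate calibration and power ordering *under those
mechanisms*. Real data additionally feature linkage disequilibrium,
genotyping error, missingness, covariates and uncertain variant grouping,
none of which are modelled; conclusions about relative test performance
transfer only to the extent those features are secondary. The analytic
C-alpha p-value is included for completeness but is knowingly unreliable at
rare-variant counts; batteries use the permutation version.

## Known limitations

* No linkage disequilibrium between variants; transmissions are
  independent across variants and siblings.
* Pedigrees beyond two-child nuclear families are out of scope, as are
  quantitative traits, covariate adjustment and haplotype-level
  pseudo-controls.
* The tilted sampler requires a tractable parental-configuration
  enumeration; for many common variants it falls back (explicitly, with an
  error suggesting it) to rejection sampling.
* UminP's asymptotic rectangle probability relies on multivariate-normal
  quadrature; with fewer than ~20 informative transmissions per variant
  its p-values, like those of all asymptotic tests here, become
  conservative and discrete.
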