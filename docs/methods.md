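# Methods

## Model

Phenotypes are related to genotypes by the standard whole-genome linear
regression

    y = 1 μ + W β + ε,        ε ~ N(0, I σe²),

where W is the n×p column-standardized genotype matrix,
w_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)), with x_ij ∈ {0,1,2} the
reference-allele count and p_j the sample reference-allele frequency.
Each SNP effect is assigned a finite normal-mixture prior

    β_j | π, σg² ~ Σ_k π_k N(0, γ_k σg²),
    γ = (0, 10⁻⁴, 10⁻³, 10⁻²) by default,

whose first component is a point mass at zero: sparsity and effect-size
shrinkage come from one prior. σg², the genetic variance tied to the
mixture scale, is estimated from the data rather than fixed; the mixture
proportions π carry a Dirichlet prior (concentration 1 per component by
default). The number of components and γ are configurable, so e.g. a
fifth class with γ = 10⁻⁵ is a flag away.

## Gibbs scheme

All unknowns (μ, β, z, π, σg², σe²) are updated from their full
conditionals per cycle:

* μ from the conjugate normal given the current residual;
* each SNP, in a fresh uniform random permutation per cycle: its
  component allocation z_j from the categorical with mass
  π_k·BF_k(rhs, w'w), where BF_k is the marginal likelihood of the SNP's
  sufficient statistic under effect variance v_k = γ_k σg² relative to
  the null, then β_j from the conjugate normal (zero if z_j = 1);
* π from Dirichlet(α + m);
* σg² from the scaled inverse chi-square with degrees of freedom
  ν_g + m_nonnull and sum of squares Σ_j β_j²/γ_{z_j};
* σe² from the scaled inverse chi-square with ν_e + n degrees of freedom.

The residual e = y − 1μ − Wβ is maintained incrementally (one O(n)
update per changed effect) and recomputed from scratch every 1,000
cycles to bound floating-point drift. Allocation sampling happens in the
log domain with log-sum-exp normalization. All randomness flows through
one generator stream seeded from the chain config, so runs are
bit-reproducible.

Random update order is applied in every cycle, not only under the
reduced scheme, to avoid order artifacts.

### Reduced ("500 SNPs") scheme

For large panels most sweep time is spent shuffling tiny polygenic
effects in and out of the model. Optionally, after `full_sweep_iters`
(default 5,000) full sweeps, each cycle traverses the permutation only
until `nonzero_quota` (default 500) SNP updates have landed in a
non-null component; remaining SNPs keep their previous effects for that
cycle. The quota counts every update whose *post-update* state is
non-zero (not distinct SNPs entering the model), the most literal
reading of the scheme, and the one that makes the work per cycle
directly proportional to the quota.

### Hyperpriors and initialization

The σg² hyperprior is scaled inverse chi-square with ν_g = 4 and scale
matched so the prior mean equals h2_init·var(y) (h2_init = 0.5); σe²
gets the flat prior ν_e = −2, S2_e = 0. These are our choices — weakly
informative defaults standard in the Bayesian-alphabet literature; at
GWAS sample sizes the conditionals are data-dominated and the posterior
is insensitive to them. Chains start from the null model: β = 0, all
SNPs in the spike, μ = ȳ, σe² = var(y)/2, σg² = h2_init·var(y), π at the
normalized Dirichlet concentration.

The default chain runs 50,000 cycles with a 20,000-cycle burn-in and
keeps every 10th draw (3,000 retained samples). We provide traces for
convergence inspection rather than automated diagnostics.

## Posterior summaries

* **SNP-based heritability.** Per retained draw,
  h_g² = var(Wβ)/(var(Wβ) + σe²) with the sample variance (divisor
  n−1) of the realized genetic values, so linkage between columns is
  respected. (For independent standardized SNPs this converges to the
  Σβ²-based version; under LD they differ slightly.) Wβ is recovered in
  O(n) per draw from the maintained residual.
* **Variance partition.** Per draw, component k's share is
  V_k/Σ_k V_k with V_k the *sum of squared sampled effects* of SNPs
  currently allocated to k — deliberately a different convention from
  h_g², mirroring how architecture is conventionally reported for this
  model. Per-chromosome and per-chromosome-per-component shares are
  computed the same way. Intervals are equal-tailed 95%.
* **Model size** is reported as the posterior mean of the number of
  SNPs in non-null components (not a count of SNPs above a PIP cutoff).
* **PIPs.** Allocation counts over retained draws, normalized per SNP;
  rows sum to one by construction.
* **Liability scale.** For 0/1 traits analyzed by linear regression,
  observed-scale h² converts to the liability scale by
  h²_liab = h²_obs · K²(1−K)²/(z² P(1−P)), with K the population
  prevalence, P the sample case proportion, and z the standard normal
  density at the threshold Φ⁻¹(1−K).

## Prediction and discovery evaluation

Prediction uses posterior-mean effects: ŷ = μ̄ + W_val β̄, with
validation genotypes standardized using *training* allele frequencies
(prevents leakage; the model file stores the frequencies for this
reason). Metrics: Pearson r, Mann–Whitney AUC for binary traits, and
the calibration slope cov(y, ŷ)/var(ŷ) (1 = unbiased). Train/validation
splits default to 80/20.

Discovery is scored at the region level because multi-SNP methods dilute
a causal signal across neighbors in LD: the genome is tiled with
non-overlapping half-open windows (default 250 kb, two grid offsets 0
and 125 kb), each window's evidence is the summed PIPs of the two
largest effect classes over member SNPs (the polygenic class is
excluded — it mimics background, not mappable signal), and ROC curves
sweep the distinct observed evidence values (plus +∞ for the origin)
with TPR/FPR averaged across the two offsets at matched cutoffs. For
independent-SNP simulations, per-SNP evidence 1 − PIP(null) replaces
windows. The single-SNP baseline is marginal linear regression with
t-distributed (n−2 df) p-values; its window evidence is the minimum
p-value in the region.

## Synthetic data

The generator reproduces two designs:

1. **Three-class architecture:** causal SNPs split into classes with
   effect variances 10⁻², 10⁻³, 10⁻⁴ in count ratio 10 : 310 : 2,680
   (at p = 5,000 the scaled preset uses (5, 150, 1,300), preserving the
   ratios). Effects act on standardized genotypes, so the expected
   genetic-variance shares are analytic: c_k v_k / Σ c v ≈ 15%, 46%,
   40%.
2. **Independent-SNP sensitivity design:** genotypes Binomial(2, p_j)
   with p_j ~ Uniform(0.05, 0.5) (we read "univariate distribution with
   interval [0.05, 0.5]" as uniform), effects either standard normal or
   gamma(shape 0.44, scale 1.66) magnitudes with fair random signs (the
   sign convention is ours; the gamma law is heavier-tailed than the
   normal — more small and fewer large effects).

Residual variance is anchored to the *realized* genetic variance,
σe² = var(g)(1−h²)/h², so each replicate hits its target heritability up
to residual-draw noise. SNPs sit on pseudo-chromosomes with 100 kb
spacing so window-based evaluation works.

What the generator does *not* emulate: linkage disequilibrium (real
panels get LD from real genotypes; simulating it is out of scope),
minor-allele-frequency/effect-size coupling, population structure and
relatedness, genotyping error and missingness patterns. Passing tests
therefore demonstrate correctness of the sampler and estimators under
the stated model, and unbiased h² recovery for independent SNPs — not
robustness to LD or confounding.

## Problem sizes and numerical choices

The heritability-recovery checks run at n = 1,000, p = 5,000 with
8,000-cycle chains and 5 replicates per heritability level in the
acceptance script (a few minutes per level), and at p = 2,500 with
5,000-cycle chains in the test suite; both keep the canonical class
ratios. At these sizes the per-replicate posterior-mean h_g² is noisy
(sd ≈ 0.09 at h² = 0.5) but centered on the simulated value; larger n
tightens it.

A caution for heavily scaled-down designs: when p greatly exceeds n and
the true heritability is low, the posterior acquires a second, dense
regime in which σg² settles low enough that allocating a SNP to the
smallest non-null class costs almost nothing (the Occam penalty vanishes
as γ₂σg² → 0) while the Dirichlet's rich-get-richer feedback on π makes
recruitment self-reinforcing; thousands of SNPs then absorb noise
variance and h_g² is overestimated. Which regime dominates depends on
the dataset. At n = 1,000, p = 5,000 and h² = 0.2 roughly one dataset
in five lands there; the effect fades as n/p grows and is absent at the
sample sizes the model is intended for.

Degenerate inputs are rejected early: zero-variance phenotypes,
all-monomorphic panels, windows with unsorted positions, correlation of
constant vectors. A non-finite chain state aborts with the failing
iteration index. On *null* phenotypes σg² deflates until the non-null
classes are indistinguishable from the spike; h_g² and the explained
variance then correctly sit near zero, but component occupancies are
not identified and should not be interpreted (with any real signal the
spike is well separated and sparsity holds).

The sweep kernel is numba-compiled with fastmath restricted to flags
that preserve NaN/inf semantics (the divergence guard depends on them);
dot products use contiguous per-SNP rows of Wᵀ. The kernel uses numpy's
legacy global RNG (numba does not support Generator objects), seeded
once per chain; Dirichlet draws are composed from gamma draws.
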