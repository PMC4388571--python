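# bayesr

Bayesian mixture-model analysis of genome-wide association data. One
Gibbs-sampled posterior simultaneously delivers what usually takes four
separate analyses:

* **SNP discovery** — posterior inclusion probabilities per SNP and per
  effect-size class;
* **SNP-based heritability** — the fraction of phenotypic variance
  explained jointly by all fitted SNPs, h_g²;
* **genetic architecture** — the split of genetic variance across
  effect-size classes and chromosomes, and the posterior number of
  contributing SNPs;
* **polygenic prediction** — calibrated phenotype/risk scores for new
  samples from posterior-mean effects.

It is aimed at quantitative geneticists working with PLINK-format
genotypes on continuous traits or 0/1 case-control status (analyzed by
linear regression, with a liability-scale conversion for heritability).

## Model

For phenotypes y and column-standardized genotypes W,

    y = 1μ + Wβ + ε,   ε ~ N(0, I σe²),
    β_j | π, σg² ~ π₁·δ₀ + Σ_{k>1} π_k N(0, γ_k σg²),

with fixed relative variances γ = (0, 10⁻⁴, 10⁻³, 10⁻²) by default: a
SNP in the largest class explains 1% of the genetic variance σg², the
smallest non-null class mimics a polygenic background, and the point
mass at zero gives sparsity. π has a Dirichlet prior and σg² is
estimated from the data under a scaled-inverse-chi-square hyperprior.
Everything is sampled by Gibbs updates from closed-form conditionals;
see `docs/methods.md` for the full scheme, conventions and limitations.

## Worked example

```python
import numpy as np
from bayesr import BayesRRegressor
from bayesr.simulate import ArchitectureSpec, simulate_dataset
from bayesr.evaluate import split_train_validation, pearson_accuracy, bias_slope

rng = np.random.default_rng(7)
spec = ArchitectureSpec(class_counts=(3, 75, 650), h2_target=0.5)
raw, std, y, truth = simulate_dataset(1000, 2500, spec, rng)
print(f"simulated: n=1000, p=2500, {len(truth.causal_indices)} causal SNPs, "
      f"realized h2 = {truth.realized_h2:.3f}")

train, val = split_train_validation(1000, 0.8, rng)
est = BayesRRegressor(n_iter=5000, burn_in=2000, thin=5, random_state=11)
est.fit(std.W[train], y[train], chrom=std.snps.chrom)
print(f"posterior h_g2 = {est.h2_:.3f} (sd {est.h2_sd_:.3f}, "
      f"95% CI {est.h2_ci_[0]:.3f}-{est.h2_ci_[1]:.3f})")
print(f"posterior mean model size = {est.model_size_:.1f} SNPs")
rep = est.architecture()
print("variance shares by class (small, medium, large):",
      np.round(rep.component_fraction_mean[1:], 3))
yhat = est.predict(std.W[val])
print(f"validation: pearson r = {pearson_accuracy(y[val], yhat):.3f}, "
      f"calibration slope = {bias_slope(y[val], yhat):.3f}")
```

Output:

```
simulated: n=1000, p=2500, 728 causal SNPs, realized h2 = 0.501
posterior h_g2 = 0.499 (sd 0.064, 95% CI 0.377-0.616)
posterior mean model size = 897.6 SNPs
variance shares by class (small, medium, large): [0.137 0.442 0.421]
validation: pearson r = 0.516, calibration slope = 1.139
```

Reading this: the phenotype was simulated with heritability 0.5 from a
three-class architecture (3 moderate, 75 small, 650 polygenic causal
SNPs). The fitted posterior puts h_g² at 0.499 with a credible interval
covering the truth; roughly nine hundred SNPs carry non-zero effects in
an average draw; the large-effect class carries ~42% of the genetic
variance in this replicate; out-of-sample prediction correlates 0.52
with the phenotype (≈ √h² is the ceiling) and the calibration slope is
near 1, i.e. predictions are approximately unbiased.

The estimator follows scikit-learn conventions (`get_params`, `clone`,
`fit`/`predict`), so it composes with sklearn model selection; the
underlying library functions (`bayesr.sampler.run_chain`,
`bayesr.summarize`, `bayesr.evaluate`, `bayesr.io`) are all public.

## Command line

```bash
bayesr simulate --out data --n 1000 --p 5000 --h2 0.5 --seed 1
bayesr fit --bed data/genotypes.bed --pheno data/phenotypes.txt \
           --out fit --iters 50000 --burnin 20000 --thin 10 --seed 1
bayesr predict --model fit/model.tsv --bed newdata/genotypes.bed --out pred
bayesr evaluate --snps fit/snps.tsv --truth data/truth.tsv --out eval
```

`fit` writes a hyperparameter trace (`trace.tsv`), a per-SNP table of
PIPs and posterior-mean effects (`snps.tsv`) and a model file for
prediction; `--reduced` switches to the quota-based sweep after 5,000
full cycles, and `--gamma 0,1e-5,1e-4,1e-3,1e-2` fits a five-class
model. Every output directory carries a `manifest.json` with the seed,
config and input digests; equal seeds reproduce trace files
byte-for-byte.

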