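"""Synthetic genotype/phenotype generation for the two study designs.

Two architectures are covered:

1. A three-class causal mixture mimicking a typical GWAS architecture:
   a handful of moderate effects (variance 1e-2), a few hundred smaller
   ones (1e-3) and a large polygenic group (1e-4), in count ratio
   10 : 310 : 2,680, with phenotype heritability 0.2, 0.5 or 0.8.
2. A sensitivity design on independent SNPs: Binomial(2, p) genotypes
   with allele frequency Uniform(0.05, 0.5) per SNP and effects drawn
   either from a normal law or from gamma(shape 0.44, scale 1.66)
   magnitudes with random signs (more small and fewer large effects than
   the normal).

Effects act on *standardized* genotypes, so each causal SNP's expected
contribution to genetic variance equals its effect variance; the residual
variance is anchored to the realized var(g) so every replicate hits its
target heritability exactly up to noise in the residual draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RawGenotypes, SnpInfo, StandardizedGenotypes, standardize

#: Causal class counts and effect variances of the genome-scale design.
THREE_CLASS_COUNTS = (10, 310, 2_680)
THREE_CLASS_VARIANCES = (1e-2, 1e-3, 1e-4)

#: Scaled-down preset preserving the class ratios (for tests / quick runs).
SCALED_CLASS_COUNTS = (5, 150, 1_300)


@dataclass
class ArchitectureSpec:
    """Causal architecture: how many SNPs per effect class, and the law."""

    class_counts: tuple[int, ...] = THREE_CLASS_COUNTS
    class_variances: tuple[float, ...] = THREE_CLASS_VARIANCES
    effect_law: str = "normal_mixture"  # normal_mixture | standard_normal | gamma
    gamma_shape: float = 0.44
    gamma_scale: float = 1.66
    h2_target: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_law not in ("normal_mixture", "standard_normal", "gamma"):
            raise ValueError(f"unknown effect law {self.effect_law!r}")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be non-negative")
        if self.effect_law == "normal_mixture":
            if len(self.class_counts) != len(self.class_variances):
                raise ValueError("class_counts and class_variances lengths differ")
            if any(v <= 0 for v in self.class_variances):
                raise ValueError("class variances must be positive")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")

    @property
    def n_causal(self) -> int:
        return int(sum(self.class_counts))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype replicate."""

    causal_indices: np.ndarray
    true_effects: np.ndarray
    true_class_labels: np.ndarray  # 1-based class of each causal SNP
    realized_h2: float
    class_variance_fractions: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not (len(self.causal_indices) == len(self.true_effects) == len(self.true_class_labels)):
            raise ValueError("truth arrays must have matching lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.causal_indices,
                "class": self.true_class_labels,
                "effect": self.true_effects,
            }
        )


def simulate_genotypes(
    n: int,
    p: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_chromosomes: int = 10,
    rng: np.random.Generator | None = None,
) -> RawGenotypes:
    """Independent Binomial(2, p_j) genotypes, p_j ~ Uniform(maf_low, maf_high).

    SNPs are split evenly across ``n_chromosomes`` pseudo-chromosomes with
    100 kb spacing, so window-based evaluation works on simulated panels.
    """
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = rng or np.random.default_rng()
    freqs = rng.uniform(maf_low, maf_high, size=p)
    counts = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)

    per_chrom = -(-p // n_chromosomes)
    chrom = np.array([str(1 + j // per_chrom) for j in range(p)])
    pos = np.array([100_000 * (1 + j % per_chrom) for j in range(p)], dtype=np.int64)
    snps = SnpInfo(
        ids=np.array([f"snp{j + 1}" for j in range(p)]),
        chrom=chrom,
        pos=pos,
        allele1=np.full(p, "A"),
        allele2=np.full(p, "G"),
    )
    fam = pd.DataFrame({"fid": [f"F{i + 1}" for i in range(n)],
                        "iid": [f"I{i + 1}" for i in range(n)]})
    return RawGenotypes(counts=counts, sample_ids=fam, snps=snps)


def sample_effects(
    spec: ArchitectureSpec, p: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw causal indices, effects and class labels for one replicate.

    normal_mixture: class k effects ~ N(0, class_variances[k]).
    standard_normal: all causal effects ~ N(0, 1).
    gamma: |effect| ~ Gamma(shape, scale) with a fair random sign.
    """
    rng = rng or np.random.default_rng()
    n_causal = spec.n_causal
    if n_causal > p:
        raise ValueError(f"{n_causal} causal SNPs exceed panel size {p}")
    causal = rng.choice(p, size=n_causal, replace=False)
    labels = np.repeat(np.arange(1, len(spec.class_counts) + 1), spec.class_counts)

    if spec.effect_law == "normal_mixture":
        sd = np.sqrt(np.repeat(spec.class_variances, spec.class_counts))
        effects = rng.standard_normal(n_causal) * sd
    elif spec.effect_law == "standard_normal":
        effects = rng.standard_normal(n_causal)
        labels = np.ones(n_causal, dtype=np.int64)
    else:  # gamma magnitudes, symmetric signs
        mags = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=n_causal)
        signs = rng.choice([-1.0, 1.0], size=n_causal)
        effects = mags * signs
        labels = np.ones(n_causal, dtype=np.int64)
    return causal, effects, labels


def simulate_phenotype(
    W_causal: np.ndarray,
    effects: np.ndarray,
    h2: float,
    rng: np.random.Generator | None = None,
    causal_indices: np.ndarray | None = None,
    class_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, SimulationTruth]:
    """Phenotype y = W_causal effects + e with e scaled to hit h2.

    The residual variance is set from the realized genetic variance,
    sigma_e2 = var(g) (1 - h2) / h2, so realized_h2 equals the target up
    to the sampling noise of the residual draw.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    rng = rng or np.random.default_rng()
    effects = np.asarray(effects, dtype=np.float64)
    g = W_causal @ effects
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ValueError("genetic values have zero variance; no causal effects?")
    sigma_e2 = var_g * (1.0 - h2) / h2
    e = rng.standard_normal(len(g)) * np.sqrt(sigma_e2)
    y = g + e
    realized = var_g / (var_g + float(np.var(e, ddof=1)))
    n_causal = len(effects)
    truth = SimulationTruth(
        causal_indices=(causal_indices if causal_indices is not None
                        else np.arange(n_causal)),
        true_effects=effects,
        true_class_labels=(class_labels if class_labels is not None
                           else np.ones(n_causal, dtype=np.int64)),
        realized_h2=realized,
    )
    if class_labels is not None:
        fracs = []
        for c in np.unique(class_labels):
            gc = W_causal[:, class_labels == c] @ effects[class_labels == c]
            fracs.append(float(np.var(gc, ddof=1)))
        fr = np.asarray(fracs)
        truth.class_variance_fractions = fr / fr.sum()
    return y, truth


def expected_class_fractions(spec: ArchitectureSpec) -> np.ndarray:
    """Expected share of genetic variance per class: c_k v_k / sum c v.

    On standardized genotypes each causal SNP's expected variance
    contribution equals its effect variance, so the three-class design
    yields roughly 15%, 46% and 40% for the moderate, small and polygenic
    classes.
    """
    if spec.effect_law != "normal_mixture":
        raise ValueError("class fractions are defined for the normal_mixture law")
    prod = np.asarray(spec.class_counts, dtype=float) * np.asarray(spec.class_variances)
    total = prod.sum()
    if total == 0:
        raise ValueError("architecture explains zero variance")
    return prod / total


def simulate_dataset(
    n: int,
    p: int,
    spec: ArchitectureSpec,
    rng: np.random.Generator | None = None,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_chromosomes: int = 10,
) -> tuple[RawGenotypes, StandardizedGenotypes, np.ndarray, SimulationTruth]:
    """One full replicate: genotypes, standardized matrix, phenotype, truth."""
    rng = rng or np.random.default_rng()
    raw = simulate_genotypes(n, p, maf_low, maf_high, n_chromosomes, rng)
    std = standardize(raw)
    if std.n_snps != p:  # MAF >= 0.05 by construction; drops are pathological
        raise RuntimeError("simulated SNP unexpectedly dropped by MAF filter")
    causal, effects, labels = sample_effects(spec, p, rng)
    y, truth = simulate_phenotype(
        std.W[:, causal], effects, spec.h2_target, rng,
        causal_indices=causal, class_labels=labels,
    )
    return raw, std, y, truth
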