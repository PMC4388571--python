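"""Posterior summaries: heritability, PIPs, architecture, liability scale."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PosteriorSamples

logger = logging.getLogger(__name__)


def summarize_h2(samples: PosteriorSamples) -> tuple[float, float, tuple[float, float]]:
    """Posterior mean, sd and central 95% interval of the h_g2 draws."""
    draws = samples.h_g2
    if len(draws) < 2:
        raise ValueError("need at least two retained draws")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(draws.mean()), float(draws.std(ddof=0)), (float(lo), float(hi))


def liability_h2(h2_observed: float, prevalence: float, case_proportion: float) -> float:
    """Convert observed-scale (0/1 regression) heritability to liability scale.

    Uses the standard threshold-model transformation with ascertainment:

        h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)),

    where K is the population prevalence, P the sample case proportion and
    z the standard normal density at the liability threshold Phi^-1(1-K).
    """
    K, P = prevalence, case_proportion
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("prevalence and case proportion must lie in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return h2_observed * K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))


def pips(samples: PosteriorSamples) -> np.ndarray:
    """Per-SNP posterior inclusion probabilities over the K components.

    Row j gives the fraction of retained draws in which SNP j sat in each
    component; rows sum to one.
    """
    return samples.alloc_counts / samples.n_draws


@dataclass
class ArchitectureReport:
    """Posterior partition of genetic variance by component and chromosome.

    Variance shares follow the squared-effect convention: per draw,
    fraction_k = V_k / sum_k V_k with V_k the sum of squared sampled
    effects of SNPs currently allocated to component k.
    """

    component_fraction_mean: np.ndarray          # (K,) null entry = 0
    component_fraction_ci: np.ndarray            # (K, 2)
    chromosome_fraction_mean: pd.Series          # share of total, by chromosome
    chromosome_component_mean: pd.DataFrame      # per-chromosome class shares
    model_size_mean: float
    component_count_mean: np.ndarray             # (K,) posterior mean m_k


def architecture_partition(samples: PosteriorSamples) -> ArchitectureReport:
    """Summarize the variance partition across components and chromosomes."""
    V = samples.comp_ss                      # (n_draws, K); column 0 is zero
    tot = V.sum(axis=1)
    ok = tot > 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.info("architecture_partition: %d draws explain zero variance", n_zero)
    frac = np.zeros_like(V)
    frac[ok] = V[ok] / tot[ok, None]

    Vc = samples.chrom_comp_ss               # (n_draws, n_chrom, K)
    chrom_tot = Vc.sum(axis=(1, 2))
    okc = chrom_tot > 0
    chrom_frac = np.zeros(Vc.shape[:2])
    chrom_frac[okc] = Vc[okc].sum(axis=2) / chrom_tot[okc, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_chrom_comp = np.where(
            Vc.sum(axis=2, keepdims=True) > 0,
            Vc / Vc.sum(axis=2, keepdims=True),
            0.0,
        )

    m = samples.m
    labels = samples.chrom_labels
    return ArchitectureReport(
        component_fraction_mean=frac.mean(axis=0),
        component_fraction_ci=np.quantile(frac, [0.025, 0.975], axis=0).T,
        chromosome_fraction_mean=pd.Series(chrom_frac.mean(axis=0), index=labels),
        chromosome_component_mean=pd.DataFrame(
            per_chrom_comp.mean(axis=0), index=labels,
            columns=[f"component_{k + 1}" for k in range(V.shape[1])],
        ),
        model_size_mean=float(m[:, 1:].sum(axis=1).mean()),
        component_count_mean=m.mean(axis=0),
    )


def snp_table(samples: PosteriorSamples, snp_ids, chrom, pos) -> pd.DataFrame:
    """Per-SNP report: id, position, PIP per component, posterior-mean effect."""
    P = pips(samples)
    tab = pd.DataFrame({"id": snp_ids, "chrom": chrom, "bp": pos})
    for k in range(P.shape[1]):
        tab[f"pip_{k + 1}"] = P[:, k]
    tab["beta_mean"] = samples.beta_mean
    return tab


def trace_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Hyperparameter trace of the retained draws."""
    K = samples.n_components
    tab = pd.DataFrame(
        {
            "draw": np.arange(samples.n_draws),
            "mu": samples.mu,
            "sigma_g2": samples.sigma_g2,
            "sigma_e2": samples.sigma_e2,
            "h_g2": samples.h_g2,
        }
    )
    for k in range(K):
        tab[f"pi_{k + 1}"] = samples.pi[:, k]
    for k in range(K):
        tab[f"m_{k + 1}"] = samples.m[:, k]
    return tab
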