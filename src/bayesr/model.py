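"""Model containers: mixture prior, hyperpriors, chain settings, state.

The model is the standard whole-genome linear regression

    y = 1 mu + W beta + e,    e ~ N(0, I sigma_e2),

with each SNP effect drawn a priori from a K-component normal mixture

    beta_j ~ sum_k pi_k N(0, gamma_k * sigma_g2),

where gamma_1 = 0 (a point mass at zero giving sparsity) and sigma_g2,
the additive genetic variance tied to the mixture scale, is itself
estimated from the data under a scaled-inverse-chi-square hyperprior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_GAMMA = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class MixturePrior:
    """Finite normal mixture prior on SNP effects.

    gamma holds the relative variances (multiplying sigma_g2) of the K
    components; the first must be exactly zero (the null spike).
    dirichlet_alpha is the concentration of the Dirichlet prior on the
    mixture proportions pi.
    """

    gamma: tuple[float, ...] = DEFAULT_GAMMA
    dirichlet_alpha: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.gamma = tuple(float(g) for g in self.gamma)
        if len(self.gamma) < 2:
            raise ValueError("need at least two mixture components")
        if self.gamma[0] != 0.0:
            raise ValueError("first mixture component must have zero variance")
        if np.any(np.diff(self.gamma) <= 0):
            raise ValueError("gamma must be strictly increasing")
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = tuple(1.0 for _ in self.gamma)
        else:
            self.dirichlet_alpha = tuple(float(a) for a in self.dirichlet_alpha)
        if len(self.dirichlet_alpha) != len(self.gamma):
            raise ValueError("dirichlet_alpha length must match gamma")
        if np.any(np.asarray(self.dirichlet_alpha) <= 0):
            raise ValueError("dirichlet_alpha must be positive")

    @property
    def n_components(self) -> int:
        return len(self.gamma)


@dataclass
class HyperParameters:
    """Scaled-inverse-chi-square hyperpriors for the two variances.

    Defaults put a weakly informative prior on sigma_g2 (nu_g = 4 with the
    scale matched to half the phenotypic variance via ``scale_for``) and a
    flat prior on sigma_e2 (nu_e = -2, S2_e = 0), standard practice in the
    Bayesian-alphabet literature; at GWAS sample sizes the data dominate
    either choice.
    """

    nu_g: float = 4.0
    S2_g: float = 1.0
    nu_e: float = -2.0
    S2_e: float = 0.0

    def __post_init__(self) -> None:
        if self.nu_g < 0 or self.S2_g < 0 or self.S2_e < 0:
            raise ValueError("degrees of freedom and scales must be non-negative")
        if self.nu_e < -2:
            raise ValueError("nu_e must be >= -2")

    @classmethod
    def scale_for(cls, var_y: float, h2_init: float = 0.5, nu_g: float = 4.0) -> "HyperParameters":
        """Hyperparameters whose sigma_g2 prior mean is var_y * h2_init."""
        if nu_g <= 2:
            raise ValueError("nu_g must exceed 2 for a finite prior mean")
        return cls(nu_g=nu_g, S2_g=var_y * h2_init * (nu_g - 2.0) / nu_g)


@dataclass
class ChainConfig:
    """Gibbs-chain run settings.

    Defaults mirror a 50,000-cycle chain with a 20,000-cycle burn-in,
    keeping every 10th draw (3,000 retained samples).  The reduced scheme
    sweeps all SNPs for the first ``full_sweep_iters`` cycles and
    thereafter visits SNPs (in random order) only until ``nonzero_quota``
    updates have landed in a non-null component; unvisited SNPs keep their
    previous effect.
    """

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    reduced_scheme: bool = False
    full_sweep_iters: int = 5_000
    nonzero_quota: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.nonzero_quota < 1:
            raise ValueError("thin and nonzero_quota must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelState:
    """Current values of all unknowns plus the maintained residual.

    ``z`` holds 0-based component labels (0 = null); beta[j] is zero
    exactly when z[j] == 0.  ``resid`` is kept equal to
    y - mu - W beta incrementally.
    """

    mu: float
    beta: np.ndarray
    z: np.ndarray
    pi: np.ndarray
    sigma_g2: float
    sigma_e2: float
    resid: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        """Component occupancies m_k."""
        return np.bincount(self.z, minlength=len(self.pi))

    def recompute_resid(self, W: np.ndarray, y: np.ndarray) -> np.ndarray:
        return y - self.mu - W @ self.beta

    def resid_error(self, W: np.ndarray, y: np.ndarray) -> float:
        """Relative drift of the incrementally maintained residual."""
        exact = self.recompute_resid(W, y)
        denom = np.linalg.norm(y) or 1.0
        return float(np.linalg.norm(self.resid - exact) / denom)


@dataclass
class PosteriorSamples:
    """Thinned posterior draws and per-SNP tallies from one chain.

    Per retained draw: hyperparameters, h_g2 (realized var(W beta) over
    [var(W beta) + sigma_e2]), mixture proportions, component occupancies
    m_k, per-component squared-effect sums V_k, and per-chromosome
    per-component squared-effect sums.  Per SNP: allocation counts over
    components and the running posterior-mean effect.
    """

    mu: np.ndarray
    sigma_g2: np.ndarray
    sigma_e2: np.ndarray
    h_g2: np.ndarray
    pi: np.ndarray                 # (n_draws, K)
    m: np.ndarray                  # (n_draws, K) int
    comp_ss: np.ndarray            # (n_draws, K)  V_k = sum_{z_j = k} beta_j^2
    chrom_comp_ss: np.ndarray      # (n_draws, n_chrom, K)
    chrom_labels: np.ndarray       # (n_chrom,) unique chromosome labels
    alloc_counts: np.ndarray       # (p, K) int
    beta_mean: np.ndarray          # (p,) posterior-mean effects
    mu_mean: float

    @property
    def n_draws(self) -> int:
        return len(self.h_g2)

    @property
    def n_components(self) -> int:
        return self.pi.shape[1]


def init_state(
    W: np.ndarray,
    y: np.ndarray,
    prior: MixturePrior,
    rng: np.random.Generator | None = None,
    h2_init: float = 0.5,
) -> ModelState:
    """Deterministic starting point: null model with data-scaled variances.

    All effects start at zero (every SNP in the null component), pi at the
    normalized Dirichlet concentration, and the two variances split the
    phenotypic variance (sigma_e2 = var(y)/2, sigma_g2 = var(y)*h2_init).
    """
    y = np.asarray(y, dtype=np.float64)
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise ValueError("degenerate phenotype: zero variance")
    p = W.shape[1]
    alpha = np.asarray(prior.dirichlet_alpha, dtype=np.float64)
    mu = float(np.mean(y))
    return ModelState(
        mu=mu,
        beta=np.zeros(p),
        z=np.zeros(p, dtype=np.int64),
        pi=alpha / alpha.sum(),
        sigma_g2=var_y * h2_init,
        sigma_e2=var_y / 2.0,
        resid=y - mu,
    )
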