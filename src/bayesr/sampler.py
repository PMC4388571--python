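"""Gibbs sampler for the normal-mixture whole-genome regression.

Every unknown is drawn from its full conditional:

* intercept       mu | .         ~ N(mean(y - W beta), sigma_e2 / n)
* component       z_j | .        ~ categorical with mass pi_k * BF_k, where
                                   BF_k is the marginal likelihood of SNP j's
                                   data under effect variance v_k = gamma_k
                                   sigma_g2, relative to the null component
* effect          beta_j | z_j=k ~ N(rhs / (w'w + sigma_e2/v_k),
                                     sigma_e2 / (w'w + sigma_e2/v_k))
* proportions     pi | .         ~ Dirichlet(alpha + m)
* genetic scale   sigma_g2 | .   ~ (SS + nu_g S2_g) / chi2(nu_g + m_nonnull),
                                   SS = sum_j beta_j^2 / gamma_{z_j}
* error variance  sigma_e2 | .   ~ (e'e + nu_e S2_e) / chi2(nu_e + n)

with rhs = w_j'(resid + w_j beta_j_old), the residual with SNP j's own
contribution added back.  The module exposes each conditional as a small
pure function (unit-testable against closed forms) and a numba-compiled
chain kernel used by :func:`run_chain` for realistic problem sizes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import (
    ChainConfig,
    HyperParameters,
    MixturePrior,
    ModelState,
    PosteriorSamples,
)

__all__ = [
    "component_log_marginals",
    "sample_intercept",
    "sample_component",
    "sample_effect",
    "update_snp",
    "sample_pi",
    "sample_sigma_g2",
    "sample_sigma_e2",
    "h_g2_of_state",
    "run_chain",
]


# ---------------------------------------------------------------------------
# Reference conditionals (numpy, Generator-based)
# ---------------------------------------------------------------------------

def component_log_marginals(
    rhs: float, wtw: float, sigma_e2: float, sigma_g2: float, gamma: np.ndarray
) -> np.ndarray:
    """Log Bayes factors of each mixture component against the null.

    For component k with effect variance v = gamma_k * sigma_g2 the
    marginal of SNP j's sufficient statistics relative to beta_j = 0 is

        -0.5 log(1 + v w'w / sigma_e2) + 0.5 rhs^2 v / (sigma_e2 (v w'w + sigma_e2)).

    The null component scores exactly zero.
    """
    if not np.isfinite(rhs):
        raise FloatingPointError("non-finite rhs in component_log_marginals")
    gamma = np.asarray(gamma, dtype=np.float64)
    v = gamma * sigma_g2
    scores = np.zeros_like(v)
    nz = v > 0
    scores[nz] = (
        -0.5 * np.log1p(v[nz] * wtw / sigma_e2)
        + 0.5 * rhs * rhs * v[nz] / (sigma_e2 * (v[nz] * wtw + sigma_e2))
    )
    return scores


def sample_component(
    log_scores: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> int:
    """Draw a component index with probability proportional to pi_k e^score_k."""
    pi = np.asarray(pi, dtype=np.float64)
    logp = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)) + log_scores, -np.inf)
    m = logp.max()
    if not np.isfinite(m):
        raise ValueError("no component has positive posterior mass")
    w = np.exp(logp - m)
    w /= w.sum()
    return int(rng.choice(len(pi), p=w))


def sample_effect(
    rhs: float, wtw: float, sigma_e2: float, v_k: float, rng: np.random.Generator
) -> float:
    """Conjugate normal draw for a non-null effect with prior variance v_k."""
    lam = wtw + sigma_e2 / v_k
    return rhs / lam + rng.standard_normal() * math.sqrt(sigma_e2 / lam)


def sample_intercept(state: ModelState, rng: np.random.Generator) -> None:
    """Update mu from N(mean(y - W beta), sigma_e2/n); residual maintained."""
    n = state.resid.shape[0]
    r_mean = state.resid.mean() + state.mu  # mean of y - W beta
    new_mu = r_mean + rng.standard_normal() * math.sqrt(state.sigma_e2 / n)
    state.resid += state.mu - new_mu
    state.mu = new_mu


def update_snp(
    state: ModelState,
    W: np.ndarray,
    j: int,
    gamma: np.ndarray,
    rng: np.random.Generator,
    wtw: float | None = None,
) -> None:
    """One Gibbs update of SNP j: component allocation, effect, residual."""
    wj = W[:, j]
    if wtw is None:
        wtw = float(wj @ wj)
    b_old = state.beta[j]
    rhs = float(wj @ state.resid) + wtw * b_old
    scores = component_log_marginals(rhs, wtw, state.sigma_e2, state.sigma_g2, gamma)
    k = sample_component(scores, state.pi, rng)
    if k == 0:
        b_new = 0.0
    else:
        b_new = sample_effect(rhs, wtw, state.sigma_e2, gamma[k] * state.sigma_g2, rng)
    if b_new != b_old:
        state.resid += wj * (b_old - b_new)
    state.beta[j] = b_new
    state.z[j] = k


def sample_pi(counts: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(alpha + counts) draw of the mixture proportions."""
    return rng.dirichlet(np.asarray(alpha, dtype=np.float64) + counts)


def sample_sigma_g2(
    state: ModelState, hyper: HyperParameters, gamma: np.ndarray, rng: np.random.Generator
) -> float:
    """Scaled-inverse-chi-square draw for the genetic variance scale."""
    nz = state.z > 0
    m = int(nz.sum())
    ss = float(np.sum(state.beta[nz] ** 2 / np.asarray(gamma)[state.z[nz]]))
    df = hyper.nu_g + m
    draw = (ss + hyper.nu_g * hyper.S2_g) / rng.chisquare(df)
    state.sigma_g2 = draw
    return draw


def sample_sigma_e2(
    state: ModelState, hyper: HyperParameters, rng: np.random.Generator
) -> float:
    """Scaled-inverse-chi-square draw for the residual variance."""
    n = state.resid.shape[0]
    sse = float(state.resid @ state.resid)
    draw = (sse + hyper.nu_e * hyper.S2_e) / rng.chisquare(hyper.nu_e + n)
    state.sigma_e2 = draw
    return draw


def h_g2_of_state(state: ModelState, W: np.ndarray) -> float:
    """Realized SNP-based heritability var(W beta)/(var(W beta) + sigma_e2).

    Sample variance with divisor n-1, so linkage between columns is
    reflected in the genetic-value variance.
    """
    g = W @ state.beta
    var_g = float(np.var(g, ddof=1))
    return var_g / (var_g + state.sigma_e2)


# ---------------------------------------------------------------------------
# Compiled chain kernel
# ---------------------------------------------------------------------------

# fastmath restricted to flags that keep NaN/inf semantics intact (the
# divergence guard relies on isfinite); reassociation still vectorizes dots.
@njit(cache=True, fastmath={"contract", "arcp", "nsz", "reassoc"})
def _chain_kernel(
    Wt,                # (p, n) row-contiguous standardized genotypes
    wtw,               # (p,) column squared norms
    y,                 # (n,)
    gamma,             # (K,)
    alpha,             # (K,)
    nu_g, S2_g, nu_e, S2_e,
    n_iter, burn_in, thin,
    seed,
    reduced, full_sweep_iters, quota,
    chrom_codes, n_chrom,
    mu0, sigma_g2_0, sigma_e2_0, pi0,
    update_mu, update_pi, update_sg2, update_se2,
    recompute_every,
):
    np.random.seed(seed)
    p, n = Wt.shape
    K = gamma.shape[0]
    n_keep = (n_iter - burn_in) // thin

    beta = np.zeros(p)
    z = np.zeros(p, dtype=np.int64)
    m = np.zeros(K, dtype=np.int64)
    m[0] = p
    pi = pi0.copy()
    mu = mu0
    sigma_g2 = sigma_g2_0
    sigma_e2 = sigma_e2_0
    resid = y - mu

    out_mu = np.empty(n_keep)
    out_sg2 = np.empty(n_keep)
    out_se2 = np.empty(n_keep)
    out_h = np.empty(n_keep)
    out_pi = np.empty((n_keep, K))
    out_m = np.zeros((n_keep, K), dtype=np.int64)
    out_css = np.zeros((n_keep, K))
    out_ccss = np.zeros((n_keep, n_chrom, K))
    alloc = np.zeros((p, K), dtype=np.int64)
    beta_sum = np.zeros(p)
    mu_sum = 0.0

    perm = np.arange(p)
    error_iter = -1

    for it in range(n_iter):
        # --- intercept ---
        if update_mu:
            r_mean = resid.mean() + mu
            new_mu = r_mean + np.random.standard_normal() * math.sqrt(sigma_e2 / n)
            delta = mu - new_mu
            for i in range(n):
                resid[i] += delta
            mu = new_mu

        # --- SNP sweep in a fresh random permutation ---
        np.random.shuffle(perm)
        use_quota = reduced and it >= full_sweep_iters
        n_nonzero_updates = 0
        for t in range(p):
            if use_quota and n_nonzero_updates >= quota:
                break
            j = perm[t]
            wj = Wt[j]
            b_old = beta[j]
            rhs = np.dot(wj, resid) + wtw[j] * b_old

            # component log-masses, tracking the max for log-sum-exp
            best = -np.inf
            logp = np.empty(K)
            for k in range(K):
                if pi[k] <= 0.0:
                    logp[k] = -np.inf
                    continue
                v = gamma[k] * sigma_g2
                if v > 0.0:
                    score = (
                        -0.5 * math.log1p(v * wtw[j] / sigma_e2)
                        + 0.5 * rhs * rhs * v / (sigma_e2 * (v * wtw[j] + sigma_e2))
                    )
                else:
                    score = 0.0
                logp[k] = math.log(pi[k]) + score
                if logp[k] > best:
                    best = logp[k]
            total = 0.0
            for k in range(K):
                logp[k] = math.exp(logp[k] - best)
                total += logp[k]
            u = np.random.random() * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += logp[k]
                if u <= acc:
                    k_new = k
                    break

            if k_new == 0:
                b_new = 0.0
            else:
                v = gamma[k_new] * sigma_g2
                lam = wtw[j] + sigma_e2 / v
                b_new = rhs / lam + np.random.standard_normal() * math.sqrt(sigma_e2 / lam)
            if b_new != b_old:
                diff = b_old - b_new
                for i in range(n):
                    resid[i] += wj[i] * diff
            if z[j] != k_new:
                m[z[j]] -= 1
                m[k_new] += 1
                z[j] = k_new
            beta[j] = b_new
            if k_new != 0:
                n_nonzero_updates += 1

        # --- mixture proportions ---
        if update_pi:
            s = 0.0
            for k in range(K):
                g = np.random.gamma(alpha[k] + m[k], 1.0)
                pi[k] = g
                s += g
            for k in range(K):
                pi[k] /= s

        # --- genetic variance scale ---
        if update_sg2:
            ss = 0.0
            mm = 0
            for j in range(p):
                if z[j] > 0:
                    ss += beta[j] * beta[j] / gamma[z[j]]
                    mm += 1
            sigma_g2 = (ss + nu_g * S2_g) / np.random.chisquare(nu_g + mm)

        # --- residual variance ---
        if update_se2:
            sse = np.dot(resid, resid)
            sigma_e2 = (sse + nu_e * S2_e) / np.random.chisquare(nu_e + n)

        if not (math.isfinite(mu) and math.isfinite(sigma_g2) and math.isfinite(sigma_e2)):
            error_iter = it
            break

        # --- bound float drift of the incremental residual ---
        if recompute_every > 0 and (it + 1) % recompute_every == 0:
            fresh = y - mu
            for j in range(p):
                if beta[j] != 0.0:
                    bj = beta[j]
                    wj = Wt[j]
                    for i in range(n):
                        fresh[i] -= wj[i] * bj
            resid = fresh

        # --- record ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            d = (it - burn_in) // thin
            # genetic values g = y - mu - resid; sample variance, divisor n-1
            gs = 0.0
            for i in range(n):
                gs += y[i] - mu - resid[i]
            gbar = gs / n
            vg = 0.0
            for i in range(n):
                gi = y[i] - mu - resid[i] - gbar
                vg += gi * gi
            vg /= n - 1
            out_mu[d] = mu
            out_sg2[d] = sigma_g2
            out_se2[d] = sigma_e2
            out_h[d] = vg / (vg + sigma_e2)
            for k in range(K):
                out_pi[d, k] = pi[k]
                out_m[d, k] = m[k]
            for j in range(p):
                alloc[j, z[j]] += 1
                if z[j] > 0:
                    b2 = beta[j] * beta[j]
                    out_css[d, z[j]] += b2
                    out_ccss[d, chrom_codes[j], z[j]] += b2
                beta_sum[j] += beta[j]
            mu_sum += mu

    return (
        out_mu, out_sg2, out_se2, out_h, out_pi, out_m, out_css, out_ccss,
        alloc, beta_sum, mu_sum, error_iter,
    )


def run_chain(
    W: np.ndarray,
    y: np.ndarray,
    prior: MixturePrior | None = None,
    hyper: HyperParameters | None = None,
    config: ChainConfig | None = None,
    chrom: np.ndarray | None = None,
    h2_init: float = 0.5,
    fix_mu: float | None = None,
    fix_pi: np.ndarray | None = None,
    fix_sigma_g2: float | None = None,
    fix_sigma_e2: float | None = None,
    recompute_every: int = 1_000,
) -> PosteriorSamples:
    """Run the Gibbs chain and return thinned posterior samples.

    Each iteration performs one intercept update, a SNP sweep in a fresh
    random permutation, then the pi, sigma_g2 and sigma_e2 updates.  With
    ``config.reduced_scheme``, iterations after ``full_sweep_iters``
    traverse the permutation only until ``nonzero_quota`` SNP updates have
    landed in a non-null component; the remaining SNPs keep their effects
    for that cycle.  The ``fix_*`` arguments freeze a parameter at the
    given value (used for validation against closed-form oracles).

    The run is fully reproducible given ``config.seed``.
    """
    W = np.asarray(W, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = W.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} entries for {n} genotype rows")
    prior = prior or MixturePrior()
    config = config or ChainConfig()
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise ValueError("degenerate phenotype: zero variance")
    if hyper is None:
        hyper = HyperParameters.scale_for(var_y, h2_init=h2_init)

    gamma = np.asarray(prior.gamma, dtype=np.float64)
    alpha = np.asarray(prior.dirichlet_alpha, dtype=np.float64)
    K = len(gamma)

    if chrom is None:
        chrom_labels = np.array(["0"])
        chrom_codes = np.zeros(p, dtype=np.int64)
    else:
        chrom_labels, chrom_codes = np.unique(np.asarray(chrom, dtype=str), return_inverse=True)
        chrom_codes = chrom_codes.astype(np.int64)

    Wt = np.ascontiguousarray(W.T)
    wtw = np.einsum("ji,ji->j", Wt, Wt)
    if np.any(wtw <= 0):
        raise ValueError("zero-norm genotype column; standardize first")

    mu0 = float(np.mean(y)) if fix_mu is None else float(fix_mu)
    pi0 = (alpha / alpha.sum()) if fix_pi is None else np.asarray(fix_pi, dtype=np.float64)
    sg2_0 = var_y * h2_init if fix_sigma_g2 is None else float(fix_sigma_g2)
    se2_0 = var_y / 2.0 if fix_sigma_e2 is None else float(fix_sigma_e2)

    (mu_s, sg2_s, se2_s, h_s, pi_s, m_s, css, ccss, alloc, beta_sum, mu_sum,
     error_iter) = _chain_kernel(
        Wt, wtw, y, gamma, alpha,
        float(hyper.nu_g), float(hyper.S2_g), float(hyper.nu_e), float(hyper.S2_e),
        config.n_iter, config.burn_in, config.thin,
        int(config.seed) & 0x7FFFFFFF,
        config.reduced_scheme, config.full_sweep_iters, config.nonzero_quota,
        chrom_codes, len(chrom_labels),
        mu0, sg2_0, se2_0, pi0,
        fix_mu is None, fix_pi is None, fix_sigma_g2 is None, fix_sigma_e2 is None,
        recompute_every,
    )
    if error_iter >= 0:
        raise FloatingPointError(
            f"chain diverged to a non-finite state at iteration {error_iter}"
        )
    n_keep = config.n_retained
    return PosteriorSamples(
        mu=mu_s,
        sigma_g2=sg2_s,
        sigma_e2=se2_s,
        h_g2=h_s,
        pi=pi_s,
        m=m_s,
        comp_ss=css,
        chrom_comp_ss=ccss,
        chrom_labels=chrom_labels,
        alloc_counts=alloc,
        beta_mean=beta_sum / n_keep,
        mu_mean=mu_sum / n_keep,
    )
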