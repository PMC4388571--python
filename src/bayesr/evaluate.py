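"""Prediction accuracy, calibration and causal-region discovery metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


def predict(W_val: np.ndarray, mu: float, beta: np.ndarray) -> np.ndarray:
    """Genomic prediction y_hat = mu + W beta with posterior-mean effects.

    Validation genotypes must be standardized with *training* frequencies.
    """
    W_val = np.asarray(W_val, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if W_val.shape[1] != beta.shape[0]:
        raise ValueError(
            f"model has {beta.shape[0]} SNPs but genotypes have {W_val.shape[1]} columns"
        )
    return mu + W_val @ beta


def pearson_accuracy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation between observed and predicted phenotype."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) < 3:
        raise ValueError("need at least three pairs")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(y, y_hat).statistic)


def auc(y_binary: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve: P(score_case > score_control) + tie/2."""
    y_binary = np.asarray(y_binary)
    if len(np.unique(y_binary)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y_binary, scores))


def bias_slope(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Slope of the regression of phenotype on prediction (1 = unbiased)."""
    y_hat = np.asarray(y_hat, float)
    v = np.var(y_hat)
    if v == 0:
        raise ValueError("zero-variance prediction")
    return float(np.cov(y, y_hat, ddof=1)[0, 1] / np.var(y_hat, ddof=1))


def split_train_validation(
    n: int, fraction: float = 0.8, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index split (default 80/20)."""
    if n < 5:
        raise ValueError("need at least five samples to split")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# Region-level evidence and ROC
# ---------------------------------------------------------------------------

@dataclass
class RegionEvidence:
    """Windowed evidence of association for one offset of the window grid."""

    table: pd.DataFrame  # columns: chrom, start, end, evidence, contains_causal
    offset: int


def _window_table(
    chrom: np.ndarray,
    pos: np.ndarray,
    per_snp_evidence: np.ndarray,
    causal_mask: np.ndarray,
    window_bp: int,
    offset: int,
    aggregate: str = "sum",
) -> pd.DataFrame:
    rows = []
    for c in pd.unique(chrom):
        sel = chrom == c
        cpos = pos[sel]
        if np.any(np.diff(cpos) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
        ev = per_snp_evidence[sel]
        cm = causal_mask[sel]
        # half-open windows [start, start + window) beginning at -offset
        win = (cpos + offset) // window_bp
        for w in np.unique(win):
            in_w = win == w
            rows.append(
                {
                    "chrom": c,
                    "start": int(w * window_bp - offset),
                    "end": int((w + 1) * window_bp - offset),
                    "evidence": float(ev[in_w].sum() if aggregate == "sum"
                                      else ev[in_w].max()),
                    "contains_causal": bool(cm[in_w].any()),
                }
            )
    return pd.DataFrame(rows)


def region_evidence(
    evidence_per_snp: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    causal_mask: np.ndarray | None = None,
    window_bp: int = 250_000,
    offsets: tuple[int, ...] = (0, 125_000),
    aggregate: str = "sum",
) -> list[RegionEvidence]:
    """Aggregate per-SNP evidence into non-overlapping windows per offset.

    For the mixture model the per-SNP evidence is the summed inclusion
    probability of the two largest effect classes (the polygenic class is
    excluded); for single-SNP regressions pass -log10(p) with
    ``aggregate='max'`` so a window scores its strongest SNP (equivalent
    to the minimum p-value within the region).
    """
    chrom = np.asarray(chrom, dtype=str)
    pos = np.asarray(pos, dtype=np.int64)
    evidence_per_snp = np.asarray(evidence_per_snp, dtype=np.float64)
    if causal_mask is None:
        causal_mask = np.zeros(len(pos), dtype=bool)
    if aggregate not in ("sum", "max"):
        raise ValueError("aggregate must be 'sum' or 'max'")
    out = []
    for off in offsets:
        tab = _window_table(chrom, pos, evidence_per_snp, np.asarray(causal_mask, bool),
                            window_bp, int(off), aggregate)
        out.append(RegionEvidence(table=tab, offset=int(off)))
    return out


def mixture_region_evidence(
    pip_matrix: np.ndarray, large_classes: tuple[int, ...] = (-2, -1)
) -> np.ndarray:
    """Per-SNP evidence: summed PIPs of the large-effect classes.

    Default takes the two largest-variance components (the polygenic
    class and the null are excluded).
    """
    return np.asarray(pip_matrix)[:, list(large_classes)].sum(axis=1)


def roc_curve_regions(regions: list[RegionEvidence]) -> tuple[np.ndarray, np.ndarray]:
    """ROC over window evidence, rates averaged across the window offsets.

    Cutoffs sweep the distinct observed evidence values (plus +inf for the
    (0,0) point); at each cutoff, windows with evidence >= cutoff count as
    positives, those containing a causal SNP as true positives.  TPR/FPR
    are averaged over offsets at matched cutoffs.
    """
    if not any(r.table["contains_causal"].any() for r in regions):
        raise ValueError("no window contains a causal SNP")
    cuts = np.unique(np.concatenate([r.table["evidence"].to_numpy() for r in regions]))
    cuts = np.append(cuts[::-1], np.inf)[::-1]  # ascending, +inf last
    tprs = np.zeros((len(regions), len(cuts)))
    fprs = np.zeros_like(tprs)
    for i, r in enumerate(regions):
        ev = r.table["evidence"].to_numpy()
        causal = r.table["contains_causal"].to_numpy()
        n_pos = causal.sum()
        n_neg = (~causal).sum()
        for c, cut in enumerate(cuts):
            hit = ev >= cut
            tprs[i, c] = (hit & causal).sum() / max(n_pos, 1)
            fprs[i, c] = (hit & ~causal).sum() / max(n_neg, 1)
    tpr = tprs.mean(axis=0)[::-1]
    fpr = fprs.mean(axis=0)[::-1]
    order = np.lexsort((tpr, fpr))
    return fpr[order], tpr[order]


def single_snp_gwas(W: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Marginal linear regression of y on each SNP; two-sided t-test p-values.

    Vectorized over SNPs; the t statistic uses n-2 degrees of freedom.
    """
    W = np.asarray(W, float)
    y = np.asarray(y, float)
    n = len(y)
    if n <= 2:
        raise ValueError("need more than two samples")
    yc = y - y.mean()
    Wc = W - W.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Wc, Wc)
    slope = (Wc.T @ yc) / sxx
    sse = np.sum(yc**2) - slope**2 * sxx
    se = np.sqrt(np.maximum(sse / (n - 2), 0.0) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.DataFrame({"slope": slope, "t": t, "p": p})
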