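"""PLINK binary genotype and phenotype input/output.

Genotypes are held as reference-allele counts in {0, 1, 2} with missing
calls encoded as -1.  The reference allele is PLINK allele 1 (bim column
5), so the stored count is the number of copies of A1.  Standardization
follows the usual GWAS convention

    w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),

with p_j the sample frequency of the reference allele, computed from
non-missing calls; missing calls are mean-imputed before centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> A1 counts; 0b01 is the missing-call code.
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

MISSING = np.int8(-1)


class PlinkFormatError(ValueError):
    """Raised for malformed .bed/.bim/.fam triplets."""


class PhenotypeError(ValueError):
    """Raised for unusable phenotype files (no ID overlap, bad values)."""


@dataclass
class SnpInfo:
    """Per-SNP metadata from a .bim file (positions are 1-based bp)."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise PlinkFormatError("duplicate SNP identifiers")
        if np.any(self.pos < 0):
            raise PlinkFormatError("negative base-pair position")

    def take(self, idx: np.ndarray) -> "SnpInfo":
        return SnpInfo(
            ids=self.ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            allele1=self.allele1[idx],
            allele2=self.allele2[idx],
        )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class RawGenotypes:
    """n x p matrix of reference-allele counts plus sample/SNP metadata.

    ``counts`` entries are in {0, 1, 2} with -1 for missing calls.
    """

    counts: np.ndarray
    sample_ids: pd.DataFrame  # columns: fid, iid
    snps: SnpInfo

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, p = self.counts.shape
        if n < 2 or p < 1:
            raise PlinkFormatError(f"need n >= 2 samples and p >= 1 SNPs, got {n} x {p}")
        if len(self.sample_ids) != n or len(self.snps) != p:
            raise PlinkFormatError("metadata dimensions do not match genotype matrix")
        bad = ~np.isin(self.counts, [0, 1, 2, -1])
        if bad.any():
            raise PlinkFormatError("genotype entries must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]


@dataclass
class StandardizedGenotypes:
    """Column-standardized genotype matrix W with retained-SNP metadata."""

    W: np.ndarray
    freq: np.ndarray  # reference-allele frequency per retained SNP
    snps: SnpInfo
    column_sq_norms: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.W = np.ascontiguousarray(self.W, dtype=np.float64)
        if self.column_sq_norms is None:
            self.column_sq_norms = np.einsum("ij,ij->j", self.W, self.W)
        if np.any(self.column_sq_norms <= 0):
            raise ValueError("zero-variance column survived standardization")

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_snps(self) -> int:
        return self.W.shape[1]


@dataclass
class PhenotypeVector:
    """Phenotypes aligned to the genotype sample order."""

    y: np.ndarray
    sample_index: np.ndarray  # row indices into the genotype matrix
    is_binary: bool
    case_proportion: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if not np.all(np.isfinite(self.y)):
            raise PhenotypeError("non-finite phenotype values")


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def read_bim(path: str | Path) -> SnpInfo:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    return SnpInfo(
        ids=bim["id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(dtype=np.int64),
        allele1=bim["a1"].to_numpy(),
        allele2=bim["a2"].to_numpy(),
    )


def read_fam(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    return fam[["fid", "iid"]].copy()


def read_plink(
    bed_path: str | Path,
    bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> RawGenotypes:
    """Read a PLINK 1 binary triplet into a RawGenotypes container.

    ``bim_path``/``fam_path`` default to the .bed path with swapped
    extensions.  Only the SNP-major v1.0 layout (magic 6C 1B, mode 01)
    is supported.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path is not None else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path is not None else bed_path.with_suffix(".fam")

    snps = read_bim(bim_path)
    fam = read_fam(fam_path)
    n, p = len(fam), len(snps)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: not a PLINK v1 .bed file (bad magic)")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if raw.size != expected:
        raise PlinkFormatError(
            f"{bed_path}: expected {expected} bytes for {n} samples x {p} SNPs, "
            f"found {raw.size}"
        )

    body = raw[3:].reshape(p, bytes_per_snp)
    # Unpack 2-bit codes, low-order pair = first sample.
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T  # -> n x p
    return RawGenotypes(counts=np.ascontiguousarray(counts), sample_ids=fam, snps=snps)


def write_plink(raw: RawGenotypes, prefix: str | Path) -> None:
    """Write bed/bim/fam files for a RawGenotypes (SNP-major v1 layout)."""
    prefix = Path(prefix)
    n, p = raw.counts.shape
    bytes_per_snp = (n + 3) // 4

    count_to_code = np.zeros(4, dtype=np.uint8)
    for cnt, code in _COUNT_TO_CODE.items():
        count_to_code[cnt % 4] = code  # -1 -> index 3
    codes = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, :n] = count_to_code[raw.counts.T % 4]
    body = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        body |= codes[:, k::4] << (2 * k)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(body.tobytes())

    s = raw.snps
    bim = pd.DataFrame(
        {"chrom": s.chrom, "id": s.ids, "cm": 0, "pos": s.pos, "a1": s.allele1, "a2": s.allele2}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = raw.sample_ids.copy()
    fam["father"] = 0
    fam["mother"] = 0
    fam["sex"] = 0
    fam["pheno"] = -9
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(raw: RawGenotypes, maf_min: float = 0.01) -> StandardizedGenotypes:
    """Center and scale genotype columns to w = (x - 2p) / sqrt(2p(1-p)).

    Missing calls are imputed to the column mean of the observed calls
    before centering.  Columns that are monomorphic or have minor-allele
    frequency below ``maf_min`` are dropped (indices recorded in
    ``dropped``).
    """
    counts = raw.counts
    n, p = counts.shape
    X = counts.astype(np.float64)
    miss = counts == MISSING
    X[miss] = np.nan

    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs == 0):
        raise PlinkFormatError("SNP with no observed genotypes")
    col_mean = np.nanmean(X, axis=0)
    freq = col_mean / 2.0  # A1 frequency from non-missing calls

    maf = np.minimum(freq, 1.0 - freq)
    observed_var = np.nanvar(X, axis=0)
    keep = (maf >= maf_min) & (observed_var > 0)
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        logger.info("standardize: dropping %d of %d SNPs (MAF < %g or monomorphic)",
                    dropped.size, p, maf_min)
    if not keep.any():
        raise PlinkFormatError("all SNPs dropped by MAF/monomorphic filter")

    X = X[:, keep]
    freq = freq[keep]
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[keep][inds[1]]
    W = (X - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    return StandardizedGenotypes(
        W=W,
        freq=freq,
        snps=raw.snps.take(np.flatnonzero(keep)),
        dropped=dropped,
    )


def standardize_with(
    counts: np.ndarray, freq: np.ndarray
) -> np.ndarray:
    """Standardize a count matrix with externally supplied frequencies.

    Used for validation samples, which must be scaled with training-set
    frequencies; missing calls are imputed to 2*freq (the training mean).
    """
    X = np.asarray(counts, dtype=np.float64)
    miss = counts == MISSING
    if miss.any():
        X = X.copy()
        inds = np.where(miss)
        X[inds] = 2.0 * freq[inds[1]]
    return (X - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, sample_ids: pd.DataFrame) -> PhenotypeVector:
    """Read a whitespace (FID IID value) phenotype file, aligned to fam order.

    Samples without a parsable phenotype are excluded; remaining values
    are returned in genotype order together with their row indices.  A
    value set within {0, 1} flags a binary (case/control) trait.
    """
    tab = pd.read_csv(
        path, sep=r"\s+", header=None, names=["fid", "iid", "value"],
        dtype={"fid": str, "iid": str},
    )
    values = pd.to_numeric(tab["value"], errors="coerce")
    n_bad = int(values.isna().sum())
    if n_bad:
        logger.info("read_phenotypes: excluding %d rows with missing/non-numeric values", n_bad)
    tab = tab.assign(value=values).dropna(subset=["value"])
    if len(tab) and not np.isfinite(tab["value"]).all():
        raise PhenotypeError("non-finite phenotype value")

    key = sample_ids["fid"].str.cat(sample_ids["iid"], sep="\t")
    lookup = pd.Series(tab["value"].to_numpy(),
                       index=tab["fid"].str.cat(tab["iid"], sep="\t"))
    lookup = lookup[~lookup.index.duplicated(keep="first")]
    matched = key.map(lookup)
    idx = np.flatnonzero(matched.notna().to_numpy())
    if idx.size == 0:
        raise PhenotypeError("no phenotype IDs overlap the genotype samples")
    y = matched.to_numpy(dtype=np.float64)[idx]

    uniq = np.unique(y)
    is_binary = np.all(np.isin(uniq, [0.0, 1.0])) and uniq.size <= 2
    return PhenotypeVector(
        y=y,
        sample_index=idx,
        is_binary=bool(is_binary),
        case_proportion=float(y.mean()) if is_binary else None,
    )


def write_phenotypes(path: str | Path, sample_ids: pd.DataFrame, y: np.ndarray) -> None:
    out = sample_ids.copy()
    out["value"] = np.asarray(y)
    out.to_csv(path, sep="\t", header=False, index=False)
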