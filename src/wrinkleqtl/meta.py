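"""Two-trait meta-analysis of signed single-SNP statistics.

Each SNP carries a 2-vector t of signed score statistics (one per trait); the
combined statistic is the quadratic form chi2 = t' V^-1 t where V is the 2x2
correlation matrix of the signed statistics across all scanned SNPs.  Under
the null chi2 follows a 2-df chi-square, whose tail has the closed form
P = exp(-chi2/2).  With hundreds of individuals the distinction between
t-statistics and normal scores is negligible, so the mixed-model z-scores are
used directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import ScanResult

log = logging.getLogger(__name__)

MAX_ABS_R = 0.999  # clamp to keep V positive definite

__all__ = ["TCorrelation", "estimate_t_correlation", "multitrait_chi2",
           "meta_scan", "p_to_signed_z"]


@dataclass
class TCorrelation:
    """2x2 correlation matrix of the signed statistics of the two traits."""

    r: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r):
            raise ValueError("correlation must be finite")
        if abs(self.r) >= 1.0:
            log.warning("|r| >= 1 (degenerate); clamped to %.3f", MAX_ABS_R)
            self.r = float(np.sign(self.r) * MAX_ABS_R)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[1.0, self.r], [self.r, 1.0]])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def estimate_t_correlation(scan1, scan2) -> TCorrelation:
    """Pearson correlation of the two scans' signed z over the shared SNPs."""
    r1 = scan1.records if isinstance(scan1, ScanResult) else scan1
    r2 = scan2.records if isinstance(scan2, ScanResult) else scan2
    merged = pd.merge(
        r1[["snp", "z"]], r2[["snp", "z"]], on="snp", suffixes=("1", "2")
    )
    n_drop = max(len(r1), len(r2)) - len(merged)
    if n_drop:
        log.info("%d SNPs not shared between scans", n_drop)
    if len(merged) < 100:
        raise ValueError(f"only {len(merged)} shared SNPs; need >= 100")
    r = float(np.corrcoef(merged["z1"], merged["z2"])[0, 1])
    return TCorrelation(r)


def multitrait_chi2(t, V: TCorrelation) -> tuple[float, float]:
    """Quadratic-form statistic t' V^-1 t and its 2-df tail P = exp(-chi2/2)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite signed statistics")
    chi2 = float(t @ V.inverse @ t)
    return chi2, float(np.exp(-chi2 / 2.0))


def p_to_signed_z(p: float, sign: float) -> float:
    """Two-sided P to a signed normal score carrying the effect's sign."""
    return float(np.sign(sign) * stats.norm.isf(p / 2.0))


def meta_scan(scan1: ScanResult, scan2: ScanResult, V: TCorrelation | None = None) -> pd.DataFrame:
    """Combine two scans SNP-by-SNP; returns snp, chrom, pos, t1, t2, chi2, p."""
    if V is None:
        V = estimate_t_correlation(scan1, scan2)
    merged = pd.merge(
        scan1.records[["snp", "chrom", "pos", "z"]],
        scan2.records[["snp", "z"]],
        on="snp",
        suffixes=("1", "2"),
    ).rename(columns={"z1": "t1", "z2": "t2"})
    Vinv = V.inverse
    t = merged[["t1", "t2"]].to_numpy()
    chi2 = np.einsum("ij,jk,ik->i", t, Vinv, t)
    merged["chi2"] = chi2
    merged["p"] = np.clip(np.exp(-chi2 / 2.0), np.finfo(float).tiny, 1.0)
    return merged
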