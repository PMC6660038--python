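"""Mixed-model single-SNP association scan (GRAMMAR/mmscore style).

The polygenic model is fitted once (module :mod:`wrinkleqtl.polygenic`); each
SNP is then score-tested against the GLS residuals using the fitted inverse
covariance W = Sigma^-1:

    U = g~' W r,   V = g~' W g~,   z = U / sqrt(V),   chi2 = z^2 (1 df)

with g~ the dosage centered on its W-weighted mean.  The per-SNP effect
estimate is U/V (allele-substitution scale).  Thresholds follow Bonferroni
(0.05/N genome-wide, 1/N suggestive); inflation lambda uses the median-chi2
estimator; the top-locus confidence interval uses a 2-unit -log10(p) drop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .polygenic import PolygenicFit

log = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

__all__ = [
    "ScanResult",
    "mmscore_scan",
    "genome_thresholds",
    "inflation_lambda",
    "lod_drop_interval",
    "variance_explained",
]


@dataclass
class ScanResult:
    """Per-SNP association records plus scan-level summaries.

    ``records`` columns: snp, chrom, pos, allele, effect, z, p, n_used, flag
    (flag marks SNPs with <2 genotype classes, reported with p = 1).
    """

    records: pd.DataFrame
    lambda_gc: float
    threshold_genomewide: float
    threshold_suggestive: float
    qq: tuple = field(default=None, repr=False)

    def write(self, prefix) -> None:
        self.records.to_csv(f"{prefix}.tsv", sep="\t", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "lambda_gc": self.lambda_gc,
                    "threshold_genomewide": self.threshold_genomewide,
                    "threshold_suggestive": self.threshold_suggestive,
                    "n_snps": int(len(self.records)),
                },
                fh,
                indent=2,
            )


def genome_thresholds(n_snps: int) -> tuple[float, float]:
    """Bonferroni genome-wide (0.05/N) and suggestive (1/N) P thresholds."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return 0.05 / n_snps, min(1.0 / n_snps, 1.0)


def inflation_lambda(z: np.ndarray) -> float:
    """Genomic inflation: median(z^2) / median of the 1-df chi-square."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 100:
        log.warning("lambda computed on only %d statistics", len(z))
    if len(z) == 0 or np.all(z == 0):
        log.warning("all statistics null; lambda = 0")
        return 0.0
    return float(np.median(z**2) / CHI2_1DF_MEDIAN)


def _qq_points(p: np.ndarray):
    obs = -np.log10(np.sort(p))
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return exp, obs


def mmscore_scan(
    g: GenotypeMatrix,
    fit: PolygenicFit,
    phenotype: np.ndarray,
    covariates=None,
) -> ScanResult:
    """Score-test every SNP against the polygenic-model residuals.

    ``fit`` must come from the same samples in the same order.  Individuals
    missing a SNP are dropped for that SNP only (the covariance is then
    re-inverted on the sub-block).  SNPs with fewer than two genotype classes
    among the used samples are emitted flagged with p = 1, never dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = g.dosages.shape
    if len(y) != n or fit.eigvecs.shape[0] != n:
        raise ValueError("phenotype/fit dimensions do not match genotypes")
    X = fit.covariates
    r = y - X @ fit.beta
    Wr = fit.sigma_inv_matmul(r)
    Wone = fit.sigma_inv_matmul(np.ones(n))
    one_W_one = float(np.ones(n) @ Wone)

    D = g.dosage_float()
    has_missing = np.isnan(D).any(axis=0)
    z_out = np.zeros(m)
    eff = np.zeros(m)
    pvals = np.ones(m)
    n_used = np.full(m, n)
    flags = np.zeros(m, dtype=bool)

    # vectorized path: SNPs without missing calls
    full = np.nonzero(~has_missing)[0]
    if full.size:
        Dc = D[:, full]
        wmean = (Wone @ Dc) / one_W_one
        Gc = Dc - wmean  # W-weighted centering
        U = Gc.T @ Wr
        WG = fit.sigma_inv_matmul(Gc)
        V = np.einsum("ij,ij->j", Gc, WG)
        ok = V > 1e-12
        zi = np.zeros(full.size)
        zi[ok] = U[ok] / np.sqrt(V[ok])
        z_out[full] = zi
        eff[full[ok]] = U[ok] / V[ok]
        pvals[full] = stats.chi2.sf(zi**2, 1)
        pvals[full[~ok]] = 1.0
        flags[full[~ok]] = True
        # a SNP with a single genotype class has V == 0 after centering

    # per-SNP path: missing calls; covariance re-inverted on the sub-block
    K = fit.eigvecs @ (fit.eigvals[:, None] * fit.eigvecs.T)
    for j in np.nonzero(has_missing)[0]:
        use = ~np.isnan(D[:, j])
        n_used[j] = int(use.sum())
        gj = D[use, j]
        if len(np.unique(gj)) < 2 or n_used[j] < 3:
            flags[j] = True
            continue
        Sigma_sub = fit.VA * K[np.ix_(use, use)] + fit.VR * np.eye(n_used[j])
        W = np.linalg.inv(Sigma_sub)
        rj = r[use]
        ones = np.ones(n_used[j])
        gc = gj - (ones @ W @ gj) / (ones @ W @ ones)
        U = float(gc @ W @ rj)
        V = float(gc @ W @ gc)
        if V <= 1e-12:
            flags[j] = True
            continue
        z_out[j] = U / np.sqrt(V)
        eff[j] = U / V
        pvals[j] = float(stats.chi2.sf(z_out[j] ** 2, 1))

    records = pd.DataFrame(
        {
            "snp": g.snp_map["id"],
            "chrom": g.snp_map["chrom"].astype(str),
            "pos": g.snp_map["pos"],
            "allele": g.snp_map["allele_alt"],
            "effect": eff,
            "z": z_out,
            "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
            "n_used": n_used,
            "flag": flags,
        }
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    lam = inflation_lambda(records.loc[~records["flag"], "z"].to_numpy())
    gw, sugg = genome_thresholds(len(records))
    qq = _qq_points(records.loc[~records["flag"], "p"].to_numpy())
    return ScanResult(records, lam, gw, sugg, qq)


def lod_drop_interval(
    result: ScanResult | pd.DataFrame, drop: float = 2.0, threshold: float | None = None
):
    """Confidence interval of the top locus by the 2-unit -log10(p) drop rule.

    Around the most significant SNP (ties broken by smallest position), the
    maximal contiguous run of same-chromosome SNPs whose -log10(p) stays
    within ``drop`` of the peak defines the interval.  Returns
    (chrom, start_bp, end_bp) or None when no SNP passes the genome-wide
    threshold.
    """
    rec = result.records if isinstance(result, ScanResult) else result
    if threshold is None:
        threshold = (
            result.threshold_genomewide
            if isinstance(result, ScanResult)
            else genome_thresholds(len(rec))[0]
        )
    pmin = rec["p"].min()
    if pmin >= threshold:
        return None
    top = rec[rec["p"] == pmin].sort_values("pos").iloc[0]
    chrom_rec = rec[rec["chrom"] == top["chrom"]].sort_values("pos").reset_index(drop=True)
    logp = -np.log10(chrom_rec["p"].to_numpy())
    peak_idx = int(np.nonzero(chrom_rec["pos"].to_numpy() == top["pos"])[0][0])
    floor = logp[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and logp[lo - 1] >= floor:
        lo -= 1
    hi = peak_idx
    while hi < len(logp) - 1 and logp[hi + 1] >= floor:
        hi += 1
    return (
        str(top["chrom"]),
        int(chrom_rec["pos"].iloc[lo]),
        int(chrom_rec["pos"].iloc[hi]),
    )


def _dummies(labels) -> np.ndarray:
    """Treatment-coded dummies, dropping the first level and any constant."""
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    cols = [(labels == lev).astype(float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def _ols_ms(y, X) -> float:
    """Residual mean square SS/(n - p) of an OLS fit."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("collinear design in variance-explained model")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid) / (n - p)


def variance_explained(y, sex, batch, g_top) -> float:
    """Percent of phenotypic variance explained by the top SNP.

    Compares residual mean squares of three nested OLS models:
    mean+sex+batch (reduce1), mean+sex+batch+SNP (full), mean only (reduce):
    var% = (MS_reduce1 - MS_full) / MS_reduce * 100.
    """
    y = np.asarray(y, dtype=float)
    g_top = np.asarray(g_top, dtype=float)
    if len(np.unique(g_top[~np.isnan(g_top)])) < 2:
        raise ValueError("top SNP has fewer than 2 genotype classes")
    n = len(y)
    ones = np.ones((n, 1))
    covs = np.column_stack([ones, _dummies(sex), _dummies(batch)])
    ms_reduce1 = _ols_ms(y, covs)
    ms_full = _ols_ms(y, np.column_stack([covs, g_top]))
    ms_reduce = _ols_ms(y, ones)
    return (ms_reduce1 - ms_full) / ms_reduce * 100.0
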