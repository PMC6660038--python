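"""LD-aware gene-based association test.

Per-SNP signed statistics within a gene are combined as T = sum z_j^2.  Under
the null, T is distributed as a weighted sum of 1-df chi-squares with weights
the eigenvalues of the SNPs' genotype correlation matrix R (the LD matrix).
The tail probability uses Satterthwaite moment matching (scaled chi-square
with scale = sum(lam^2)/sum(lam) and df = (sum lam)^2 / sum(lam^2)); a
Monte-Carlo exact tail is available for small P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .gwas import ScanResult

log = logging.getLogger(__name__)

RIDGE = 1e-6  # diagonal regularization of R

__all__ = ["GeneModel", "map_snps_to_genes", "gene_statistic", "gene_threshold",
           "gene_scan", "read_bed"]


@dataclass
class GeneModel:
    """A gene body (1-based inclusive) with the indices of its SNPs."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def read_bed(path) -> pd.DataFrame:
    """Parse a BED file (0-based half-open) into chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}: line {lineno}: invalid interval")
            name = fields[3] if len(fields) > 3 else f"gene_{lineno}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def map_snps_to_genes(snp_map: pd.DataFrame, genes) -> list[GeneModel]:
    """Assign each SNP to every gene body containing its position.

    ``genes`` is a BED path or a chrom/start/end/name DataFrame (0-based
    half-open, converted to 1-based inclusive).  No flanking window is used.
    Only genes covered by at least one SNP are returned.
    """
    bed = genes if isinstance(genes, pd.DataFrame) else read_bed(genes)
    chroms = snp_map["chrom"].astype(str).to_numpy()
    pos = snp_map["pos"].to_numpy()
    models = []
    n_empty = 0
    for _, row in bed.iterrows():
        start1, end1 = int(row["start"]) + 1, int(row["end"])
        mask = (chroms == str(row["chrom"])) & (pos >= start1) & (pos <= end1)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            n_empty += 1
            continue
        models.append(GeneModel(str(row["name"]), str(row["chrom"]), start1, end1, idx))
    if n_empty:
        log.info("%d genes without SNPs excluded from testing", n_empty)
    return models


def gene_statistic(
    z_vector, R, monte_carlo: int | None = None, rng=None
) -> tuple[float, float]:
    """Sum-of-chi-square gene statistic with an LD-aware null.

    Returns (T, p) where T = sum z^2 and p approximates
    P(sum lam_i chi2_1 >= T) with lam the eigenvalues of R (Satterthwaite by
    default, Monte-Carlo with ``monte_carlo`` draws when requested).
    """
    z = np.asarray(z_vector, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.shape != (len(z), len(z)):
        raise ValueError("R dimensions do not match z")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R is not symmetric")
    lam = np.linalg.eigvalsh(R + RIDGE * np.eye(len(z)))
    lam = np.clip(lam, 0.0, None)
    T = float(np.sum(z**2))
    s1 = float(np.sum(lam))
    s2 = float(np.sum(lam**2))
    if s1 <= 0:
        return T, 1.0
    if monte_carlo:
        rng = rng or np.random.default_rng(0)
        draws = (lam[None, :] * rng.chisquare(1, size=(monte_carlo, len(lam)))).sum(axis=1)
        p = (np.sum(draws >= T) + 1.0) / (monte_carlo + 1.0)
    else:
        scale = s2 / s1
        df = s1**2 / s2
        p = float(stats.chi2.sf(T / scale, df))
    return T, float(np.clip(p, np.finfo(float).tiny, 1.0))


def gene_threshold(n_genes_tested: int) -> float:
    """Bonferroni threshold 0.05 / number of genes tested."""
    if n_genes_tested < 1:
        raise ValueError("need at least one tested gene")
    return 0.05 / n_genes_tested


def _ld_matrix(g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    d = g.dosage_float()[:, idx]
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(d, rowvar=False)
    if R.ndim == 0:  # single SNP
        R = np.array([[1.0]])
    return np.nan_to_num(R, nan=0.0) + np.eye(len(idx)) * 0.0


def gene_scan(
    g: GenotypeMatrix, scan: ScanResult, genes, monte_carlo: int | None = None
) -> pd.DataFrame:
    """Run the gene test for every covered gene using a scan's z-scores.

    The scan must have been produced from ``g`` (same SNP order).
    """
    models = map_snps_to_genes(g.snp_map, genes) if not isinstance(genes, list) else genes
    z = scan.records.set_index("snp")["z"]
    snp_ids = g.snp_map["id"].to_numpy()
    rows = []
    for gm in models:
        ids = snp_ids[gm.snp_indices]
        zg = z.reindex(ids).to_numpy()
        ok = np.isfinite(zg)
        if not ok.any():
            continue
        idx = gm.snp_indices[ok]
        R = _ld_matrix(g, idx)
        T, p = gene_statistic(zg[ok], R, monte_carlo=monte_carlo)
        rows.append((gm.gene_id, gm.chrom, gm.start, gm.end, int(ok.sum()), T, p))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "n_snps", "T", "p"]
    )
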