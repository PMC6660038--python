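"""Sliding-window selection statistics: Tajima's D, Weir-Cockerham FST, XPEHH.

All three statistics are computed over 200 kb windows advancing by 100 kb
(half-overlap) by default.  Tajima's D follows the 1989 normalization with
the constants a1..e2 derived from the number of sequences; from unphased
genotypes the sequence count is twice the individual count and pi uses the
unbiased n/(n-1) frequency form.  FST is the Weir & Cockerham (1984)
single-SNP theta averaged across window SNPs.  XPEHH integrates extended
haplotype homozygosity outward from each core SNP (trapezoid over physical
distance, stopping where the pooled-sample EHH drops below a cutoff) and is
standardized genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAX_EXTEND_BP = 500_000
MIN_SNPS_PER_WINDOW = 5

__all__ = [
    "Window",
    "make_windows",
    "tajima_constants",
    "tajimas_d",
    "weir_fst",
    "ehh_decay",
    "xpehh",
    "standardize_xpehh",
    "xpehh_scan",
    "selection_scan",
]


@dataclass
class Window:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    masked: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def make_windows(
    snp_map: pd.DataFrame,
    window_bp: int = 200_000,
    step_bp: int = 100_000,
    min_snps: int = MIN_SNPS_PER_WINDOW,
) -> list[Window]:
    """Tile half-overlapping windows over the span of the SNP map.

    Windows advance by ``step_bp`` from the first SNP; windows holding fewer
    than ``min_snps`` SNPs are flagged masked but kept, so genomic
    coordinates stay aligned across statistics.
    """
    if step_bp > window_bp:
        raise ValueError("step must not exceed window size")
    pos = snp_map["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    chrom = str(snp_map["chrom"].iloc[0])
    lo, hi = int(pos.min()), int(pos.max())
    span = hi - lo + 1
    n_steps = max(0, -(-(span - window_bp) // step_bp))  # ceil
    windows = []
    for k in range(n_steps + 1):
        start = lo + k * step_bp
        end = start + window_bp - 1
        idx = np.nonzero((pos >= start) & (pos <= end))[0]
        windows.append(
            Window(chrom, start, end, idx, masked=len(idx) < min_snps)
        )
    return windows


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict:
    """The 1989 normalization constants for ``n`` sequences."""
    if n < 4:
        raise ValueError("need at least 4 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(data: np.ndarray, is_haplotype: bool = False) -> float | None:
    """Tajima's D for one population over one window of sites.

    ``data`` is (individuals, sites) dosages or (haplotypes, sites) binary
    alleles.  Returns None (absent) when no site segregates.
    """
    data = np.asarray(data)
    if is_haplotype:
        n = data.shape[0]
        c = data.sum(axis=0).astype(float)
    else:
        n = 2 * data.shape[0]
        c = data.astype(float).sum(axis=0)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return None
    c = c[seg]
    pi = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (pi - theta_w) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------


def weir_fst(g1: np.ndarray, g2: np.ndarray):
    """Per-SNP Weir & Cockerham (1984) theta and the window mean.

    ``g1``/``g2`` are dosage matrices of the two populations over the same
    SNPs.  SNPs monomorphic in both populations are excluded from the mean;
    small negative estimates are legal and preserved.  Returns
    (per_snp_theta with NaN for skipped SNPs, mean_theta or None).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    r = 2.0
    n1 = np.sum(~np.isnan(g1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(g2), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p1 = np.nansum(g1, axis=0) / (2 * n1)
        p2 = np.nansum(g2, axis=0) / (2 * n2)
        h1 = np.nansum(g1 == 1, axis=0) / n1
        h2 = np.nansum(g2 == 1, axis=0) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    mono = ((pbar <= 0) | (pbar >= 1)) & (hbar == 0)
    theta = np.where(mono | (n1 < 2) | (n2 < 2), np.nan, theta)
    mean = float(np.nanmean(theta)) if np.isfinite(theta).any() else None
    return theta, mean


def weir_fst_ratio_of_sums(g1, g2) -> float | None:
    """Multi-SNP FST as sum(a)/sum(a+b+c) (Weir's recommended combination)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    theta, _ = weir_fst(g1, g2)  # recompute components below
    # reuse the component arithmetic explicitly
    r = 2.0
    n1 = np.sum(~np.isnan(g1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(g2), axis=0).astype(float)
    p1 = np.nansum(g1, axis=0) / (2 * n1)
    p2 = np.nansum(g2, axis=0) / (2 * n2)
    h1 = np.nansum(g1 == 1, axis=0) / n1
    h2 = np.nansum(g2 == 1, axis=0) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    keep = np.isfinite(theta)
    if not keep.any():
        return None
    denom = np.sum((a + b + c)[keep])
    return float(np.sum(a[keep]) / denom) if denom > 0 else None


# ---------------------------------------------------------------------------
# EHH / XPEHH
# ---------------------------------------------------------------------------


def _ehh_one_side(hap_all, n1, positions, core, direction, cutoff, max_extend):
    """EHH curves (pooled, pop1, pop2) extending from the core in one direction.

    Group membership is tracked with integer ids refined site by site; the
    per-population EHH is read off the pooled group ids restricted to each
    population's rows.  Stops when pooled EHH < cutoff, the distance cap is
    hit, or the chromosome ends.
    """
    n_hap, m = hap_all.shape

    def three_ehh(gids, n_groups):
        c_all = np.bincount(gids, minlength=n_groups)
        c1 = np.bincount(gids[:n1], minlength=n_groups)
        c2 = c_all - c1
        k1, k2 = n1, n_hap - n1

        def hom(c, k):
            return float(np.sum(c * (c - 1)) / (k * (k - 1))) if k >= 2 else 0.0

        return hom(c_all, n_hap), hom(c1, k1), hom(c2, k2)

    gids = hap_all[:, core].astype(np.int64)
    eh_all, eh1, eh2 = three_ehh(gids, 2)
    xs = [0.0]
    pooled = [eh_all]
    e1 = [eh1]
    e2 = [eh2]
    n_groups = 2
    j = core
    while True:
        j += direction
        if j < 0 or j >= m:
            break
        dist = abs(positions[j] - positions[core])
        if dist > max_extend:
            break
        key = gids * 2 + hap_all[:, j]
        uniq, gids = np.unique(key, return_inverse=True)
        n_groups = len(uniq)
        eh_all, eh1, eh2 = three_ehh(gids, n_groups)
        xs.append(float(dist))
        pooled.append(eh_all)
        e1.append(eh1)
        e2.append(eh2)
        if eh_all < cutoff:
            break
    return np.array(xs), np.array(pooled), np.array(e1), np.array(e2)


def xpehh(
    hap1: np.ndarray,
    hap2: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
    max_extend_bp: int = MAX_EXTEND_BP,
) -> float | None:
    """Raw XPEHH = ln(iHH_pop1 / iHH_pop2) at one core SNP.

    Both populations are integrated over the same physical range (fixed by
    the pooled-sample EHH decay), which makes the statistic exactly
    antisymmetric under swapping the populations.  Returns None when either
    integral is zero.
    """
    hap_all = np.vstack([hap1, hap2]).astype(np.int64)
    pooled_col = hap_all[:, core]
    if pooled_col.min() == pooled_col.max():
        return None  # core monomorphic in the pooled sample
    ihh1 = ihh2 = 0.0
    for direction in (-1, 1):
        xs, _, e1, e2 = _ehh_one_side(
            hap_all, len(hap1), positions, core, direction, cutoff, max_extend_bp
        )
        if len(xs) > 1:
            ihh1 += float(np.trapezoid(e1, xs))
            ihh2 += float(np.trapezoid(e2, xs))
    if ihh1 <= 0 or ihh2 <= 0:
        log.debug("zero iHH at core %d; XPEHH absent", core)
        return None
    return float(np.log(ihh1 / ihh2))


def ehh_decay(hap, positions, core, cutoff=0.0, max_extend_bp=MAX_EXTEND_BP):
    """EHH curve of one haplotype sample around a core (for inspection)."""
    hap = np.asarray(hap, dtype=np.int64)
    out = {}
    for direction in (-1, 1):
        xs, pooled, _, _ = _ehh_one_side(
            hap, hap.shape[0], positions, core, direction, cutoff, max_extend_bp
        )
        out["left" if direction == -1 else "right"] = (xs, pooled)
    return out


def standardize_xpehh(scores: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardization, ignoring absent (NaN) scores."""
    scores = np.asarray(scores, dtype=float)
    mu = np.nanmean(scores)
    sd = np.nanstd(scores)
    if not np.isfinite(sd) or sd == 0:
        return np.full_like(scores, np.nan)
    return (scores - mu) / sd


def xpehh_scan(
    hap1, hap2, positions, cores=None, cutoff=EHH_CUTOFF, max_extend_bp=MAX_EXTEND_BP
):
    """Raw and standardized XPEHH over the requested core SNPs (default all)."""
    m = hap1.shape[1]
    cores = np.arange(m) if cores is None else np.asarray(cores)
    raw = np.full(m, np.nan)
    for c in cores:
        val = xpehh(hap1, hap2, positions, int(c), cutoff, max_extend_bp)
        if val is not None:
            raw[c] = val
    return raw, standardize_xpehh(raw)


# ---------------------------------------------------------------------------
# Windowed scan over two populations
# ---------------------------------------------------------------------------


def selection_scan(
    pop1,
    pop2,
    window_bp: int = 200_000,
    step_bp: int = 100_000,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    xpehh_cores=None,
    cutoff: float = EHH_CUTOFF,
    max_extend_bp: int = MAX_EXTEND_BP,
    fst_min_maf: float = 0.05,
) -> pd.DataFrame:
    """Windowed Tajima's D (both populations), FST and max standardized XPEHH.

    ``pop1``/``pop2`` are PopulationSample objects sharing a SNP map (pop1 is
    the putatively selected population).  Masked windows report NaN, not 0.
    Tajima's D and XPEHH use every segregating site; the window FST mean is
    restricted to SNPs with pooled MAF >= ``fst_min_maf`` (a chip-like common
    variant set - the per-SNP estimator is very noisy on rare variants and
    would swamp the window mean).
    """
    snp_map = pop1.snp_map
    if snp_map["chrom"].nunique() > 1:
        raise ValueError(
            "selection_scan works per chromosome; subset first "
            "(PopulationSample.subset_chrom)"
        )
    positions = snp_map["pos"].to_numpy()
    windows = make_windows(snp_map, window_bp, step_bp, min_snps)
    raw_x, std_x = xpehh_scan(
        pop1.haplotypes, pop2.haplotypes, positions, cores=xpehh_cores,
        cutoff=cutoff, max_extend_bp=max_extend_bp,
    )
    g1 = pop1.genotypes.astype(float)
    g2 = pop2.genotypes.astype(float)
    n_hap_total = len(g1) * 2 + len(g2) * 2
    p_pool = (g1.sum(axis=0) + g2.sum(axis=0)) / n_hap_total
    common = np.minimum(p_pool, 1 - p_pool) >= fst_min_maf
    rows = []
    for w in windows:
        if w.masked:
            rows.append((w.chrom, w.start_bp, w.end_bp, w.n_snps,
                         np.nan, np.nan, np.nan, np.nan))
            continue
        idx = w.snp_indices
        d1 = tajimas_d(pop1.haplotypes[:, idx], is_haplotype=True)
        d2 = tajimas_d(pop2.haplotypes[:, idx], is_haplotype=True)
        idx_c = idx[common[idx]]
        fst = weir_fst(g1[:, idx_c], g2[:, idx_c])[1] if idx_c.size else None
        xs = std_x[idx]
        xmax = float(np.nanmax(xs)) if np.isfinite(xs).any() else np.nan
        rows.append((
            w.chrom, w.start_bp, w.end_bp, w.n_snps,
            np.nan if d1 is None else d1,
            np.nan if d2 is None else d2,
            np.nan if fst is None else fst,
            xmax,
        ))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps",
                 "tajima_d_pop1", "tajima_d_pop2", "fst_mean", "xpehh_max_std"],
    )
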