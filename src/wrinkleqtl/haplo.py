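"""Regional haplotype reconstruction and neighbor-joining trees.

Phasing of a target region uses partition-ligation EM: maximum-likelihood
haplotype frequencies are estimated by EM within blocks of up to 6 SNPs,
adjacent blocks are ligated by EM over the cross products of the retained
(top 8) block haplotypes, and each individual is assigned its
maximum-posterior haplotype pair.  Truth-phase (simulator sidecar) and
external-phase (phased VCF) modes bypass the EM so downstream tree results
do not depend on the reconstruction's accuracy.

Unique haplotypes (with multiplicities) are compared by Hamming distance and
joined by the Saitou-Nei neighbor-joining algorithm; bootstrap support per
internal edge comes from resampling SNP columns with replacement.  Trees are
serialized as Newick with supports as internal labels.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EM_TOL = 1e-6
EM_MAX_ITER = 200
EM_RESTARTS = 5
BLOCK_SNPS = 6
LIGATION_KEEP = 8
MAX_EM_SNPS = 64

__all__ = [
    "PhasedRegion",
    "HaploTree",
    "phase_region",
    "haplotype_distance",
    "nj_tree",
    "bootstrap_support",
    "favored_clade_recall",
    "em_haplotype_frequencies",
]


@dataclass
class PhasedRegion:
    """Phased haplotypes over a SNP region.

    ``haplotypes`` is (2n, k); rows 2i, 2i+1 belong to individual i and sum
    to that individual's genotype at every site.  ``certainty`` holds each
    individual's posterior probability of its assigned pair (1.0 for truth or
    external phase).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    sample_ids: list
    certainty: np.ndarray
    method: str = "em"

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be twice the sample count")

    def unique_haplotypes(self):
        """(unique (u, k) matrix, multiplicities, row->unique index)."""
        uniq, inverse, counts = np.unique(
            self.haplotypes, axis=0, return_inverse=True, return_counts=True
        )
        return uniq, counts, inverse


@dataclass
class HaploTree:
    """Unrooted NJ tree over unique haplotypes with bootstrap supports."""

    newick: str
    labels: list
    multiplicities: np.ndarray
    supports: dict = field(default_factory=dict)  # bipartition -> support
    negative_branches_clamped: int = 0

    def skbio_tree(self):
        import skbio

        return skbio.TreeNode.read(io.StringIO(self.newick))


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------


def _compatible_pairs(geno_row, haplotypes):
    """Indices (a, b), a <= b, of haplotype pairs compatible with a genotype.

    Missing genotype entries (negative) are compatible with anything.
    """
    known = geno_row >= 0
    h = haplotypes[:, known]
    gsum = geno_row[known]
    u = len(haplotypes)
    pairs = []
    for a in range(u):
        # vectorized over b >= a
        ok = np.all(h[a] + h[a:] == gsum, axis=1)
        for off in np.nonzero(ok)[0]:
            pairs.append((a, a + off))
    return pairs


def em_haplotype_frequencies(
    genotypes: np.ndarray,
    haplotypes: np.ndarray,
    rng: np.random.Generator | None = None,
    n_restarts: int = EM_RESTARTS,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
):
    """ML haplotype frequencies by EM over an explicit haplotype list.

    Returns (frequencies, loglik, per-individual pair posteriors as a list of
    (pairs, probs)).  Individuals with no compatible pair are an error.
    """
    rng = rng or np.random.default_rng(0)
    n, _ = genotypes.shape
    u = len(haplotypes)
    pair_list = [_compatible_pairs(genotypes[i], haplotypes) for i in range(n)]
    for i, pl in enumerate(pair_list):
        if not pl:
            raise ValueError(f"individual {i}: no compatible haplotype pair")
    # flatten for vectorized E-steps
    pair_a = np.array([a for pl in pair_list for a, _ in pl])
    pair_b = np.array([b for pl in pair_list for _, b in pl])
    ind_of = np.repeat(np.arange(n), [len(pl) for pl in pair_list])
    mult = np.where(pair_a == pair_b, 1.0, 2.0)
    tiny = 1e-300

    def e_step(f):
        w = mult * f[pair_a] * f[pair_b]
        tot = np.bincount(ind_of, weights=w, minlength=n)
        ll = float(np.sum(np.log(np.maximum(tot, tiny))))
        w = w / np.maximum(tot, tiny)[ind_of]
        return w, ll

    best = None
    for restart in range(n_restarts):
        f = np.full(u, 1.0 / u) if restart == 0 else rng.dirichlet(np.ones(u))
        ll_old = -np.inf
        for _ in range(max_iter):
            w, ll = e_step(f)
            expected = np.bincount(pair_a, weights=w, minlength=u)
            expected += np.bincount(pair_b, weights=w, minlength=u)
            f = expected / (2.0 * n)
            if abs(ll - ll_old) < tol:
                break
            ll_old = ll
        if best is None or ll > best[1]:
            best = (f.copy(), ll)
    f, ll = best
    w, _ = e_step(f)
    posteriors = []
    offset = 0
    for pl in pair_list:
        posteriors.append((pl, w[offset: offset + len(pl)]))
        offset += len(pl)
    return f, ll, posteriors


def _enumerate_haplotypes(k: int) -> np.ndarray:
    return np.array(
        [[(h >> (k - 1 - j)) & 1 for j in range(k)] for h in range(2**k)],
        dtype=np.uint8,
    )


def _phase_em(genotypes, rng):
    """Partition-ligation EM phase of an (n, k) genotype block, k <= 64."""
    n, k = genotypes.shape
    if k > MAX_EM_SNPS:
        raise ValueError(f"EM phasing limited to {MAX_EM_SNPS} SNPs (got {k})")
    blocks = [slice(s, min(s + BLOCK_SNPS, k)) for s in range(0, k, BLOCK_SNPS)]

    def solve_block(sub_geno, hap_pool):
        f, _, post = em_haplotype_frequencies(sub_geno, hap_pool, rng)
        order = np.argsort(f)[::-1]
        keep = order[: min(LIGATION_KEEP, np.sum(f > 1e-9) or 1)]
        keep = keep[f[keep] > 1e-9]
        kept = set(int(i) for i in keep) or {int(order[0])}
        # every individual must retain a compatible pair, else ligation
        # would orphan it; rescue its maximum-posterior pair
        for pairs, probs in post:
            if not any(a in kept and b in kept for a, b in pairs):
                a, b = pairs[int(np.argmax(probs))]
                kept |= {a, b}
        return hap_pool[sorted(kept)]

    # per-block candidate haplotypes
    cur_haps = None
    cur_cols = 0
    for bl in blocks:
        sub = genotypes[:, bl]
        pool = _enumerate_haplotypes(sub.shape[1])
        kept = solve_block(sub, pool)
        if cur_haps is None:
            cur_haps, cur_cols = kept, sub.shape[1]
            continue
        # ligate: cross product of retained left and right haplotypes
        left, right = cur_haps, kept
        combo = np.array(
            [np.concatenate([a, b]) for a in left for b in right], dtype=np.uint8
        )
        cur_cols += sub.shape[1]
        combo_kept = solve_block(genotypes[:, :cur_cols], combo)
        cur_haps = combo_kept

    f, _, posteriors = em_haplotype_frequencies(genotypes, cur_haps, rng)
    hap_rows = np.empty((2 * n, k), dtype=np.uint8)
    certainty = np.empty(n)
    for i, (pairs, probs) in enumerate(posteriors):
        j = int(np.argmax(probs))
        a, b = pairs[j]
        hap_rows[2 * i] = cur_haps[a]
        hap_rows[2 * i + 1] = cur_haps[b]
        certainty[i] = float(probs[j])
    return hap_rows, certainty


def phase_region(
    g,
    region: tuple[str, int, int],
    method: str = "em",
    truth_haplotypes: np.ndarray | None = None,
    phased_vcf: str | None = None,
    seed: int = 0,
) -> PhasedRegion:
    """Phase the SNPs of ``g`` inside region (chrom, start, end), 1-based.

    Methods: ``em`` (partition-ligation EM), ``truth`` (simulator phase,
    ``truth_haplotypes`` = full (2n, m) matrix aligned to ``g``), ``external``
    (phased VCF covering the region with the same samples).  Individuals with
    more than 50% missing genotypes in the region are excluded with a
    warning.
    """
    chrom, start, end = region
    snp_map = g.snp_map
    mask = (
        (snp_map["chrom"].astype(str) == str(chrom))
        & (snp_map["pos"] >= start)
        & (snp_map["pos"] <= end)
    ).to_numpy()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no SNPs in region")
    positions = snp_map["pos"].to_numpy()[idx]
    ids = list(g.samples["id"])

    if method == "truth":
        if truth_haplotypes is None:
            raise ValueError("truth mode requires truth_haplotypes")
        hap = truth_haplotypes[:, idx].astype(np.uint8)
        return PhasedRegion(hap, positions, ids, np.ones(len(ids)), "truth")

    if method == "external":
        from .genio import load_genotypes

        gv = load_genotypes(phased_vcf, format="vcf")
        from cyvcf2 import VCF

        vcf = VCF(str(phased_vcf))
        sample_order = {s: i for i, s in enumerate(vcf.samples)}
        rows = []
        for var in vcf:
            if str(var.CHROM) != str(chrom) or not start <= var.POS <= end:
                continue
            alleles = np.array(var.genotypes)[:, :2]  # (n, 2)
            rows.append(alleles)
        arr = np.stack(rows, axis=2)  # (n, 2, k)
        take = [sample_order[s] for s in ids]
        hap = arr[take].reshape(-1, arr.shape[2]).astype(np.uint8)
        return PhasedRegion(hap, positions, ids, np.ones(len(ids)), "external")

    if method != "em":
        raise ValueError(f"unknown phasing method {method!r}")

    geno = g.dosages[:, idx].astype(np.int8)
    miss_rate = (geno < 0).mean(axis=1)
    keep = miss_rate <= 0.5
    if not keep.all():
        log.warning("excluding %d individuals with >50%% regional missingness",
                    int((~keep).sum()))
    geno = geno[keep]
    ids = [s for s, k in zip(ids, keep) if k]
    rng = np.random.default_rng(seed)
    hap, certainty = _phase_em(geno, rng)
    return PhasedRegion(hap, positions, ids, certainty, "em")


# ---------------------------------------------------------------------------
# Distances and NJ
# ---------------------------------------------------------------------------


def haplotype_distance(region: PhasedRegion):
    """Hamming distance matrix over unique haplotypes (+ labels, counts)."""
    uniq, counts, _ = region.unique_haplotypes()
    if len(uniq) < 3:
        raise ValueError("need at least 3 unique haplotypes")
    D = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2).astype(float)
    labels = [f"H{i:03d}" for i in range(len(uniq))]
    return D, labels, counts, uniq


def _nj_join(D: np.ndarray, labels: list[str]):
    """Saitou-Nei joins; returns (newick string without supports,
    list of (bipartition frozenset, node key), n_clamped)."""
    n = len(labels)
    active = list(range(n))
    dist = D.copy()
    node_newick = {i: labels[i] for i in range(n)}
    node_leaves = {i: frozenset([labels[i]]) for i in range(n)}
    next_id = n
    clamped = 0
    edges = []  # (leafset, newick key) for internal edges
    while len(active) > 2:
        k = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        a, b = active[i_s], active[j_s]
        dab = sub[i_s, j_s]
        la = 0.5 * dab + (r[i_s] - r[j_s]) / (2.0 * (k - 2))
        lb = dab - la
        if la < 0:
            clamped += 1
            la = 0.0
        if lb < 0:
            clamped += 1
            lb = 0.0
        # distances from the new node to the rest
        new_row = np.zeros(dist.shape[0] + 1)
        for idx_c, c in enumerate(active):
            if c in (a, b):
                continue
            new_row[c] = 0.5 * (dist[a, c] + dist[b, c] - dab)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[next_id, : next_id] = new_row[:next_id]
        dist[: next_id, next_id] = new_row[:next_id]
        node_newick[next_id] = (
            f"({node_newick[a]}:{la:.10g},{node_newick[b]}:{lb:.10g})"
        )
        node_leaves[next_id] = node_leaves[a] | node_leaves[b]
        edges.append((node_leaves[next_id], next_id))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    a, b = active
    dab = dist[a, b]
    if dab < 0:
        clamped += 1
        dab = 0.0
    newick = f"({node_newick[a]}:{dab / 2.0:.10g},{node_newick[b]}:{dab / 2.0:.10g});"
    return newick, edges, node_leaves, clamped


def _normalized_bipartitions(D, labels) -> set:
    """Internal-edge bipartitions of the NJ tree of D, normalized to the side
    not containing the first label."""
    _, edges, node_leaves, _ = _nj_join(D, labels)
    all_leaves = frozenset(labels)
    ref = labels[0]
    out = set()
    for leafset, _ in edges:
        side = leafset if ref not in leafset else all_leaves - leafset
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def nj_tree(D: np.ndarray, labels: list[str], multiplicities=None) -> HaploTree:
    """Neighbor-joining tree from a distance matrix.

    Ties in the Q matrix break on the first (row-major) minimum; negative
    branch lengths are clamped to zero and counted in
    ``negative_branches_clamped``.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix has non-finite entries")
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    newick, edges, node_leaves, clamped = _nj_join(D, labels)
    if multiplicities is None:
        multiplicities = np.ones(len(labels), dtype=int)
    return HaploTree(
        newick=newick,
        labels=list(labels),
        multiplicities=np.asarray(multiplicities),
        negative_branches_clamped=clamped,
    )


def bootstrap_support(
    region: PhasedRegion, n_boot: int = 1000, seed: int = 0
) -> HaploTree:
    """NJ tree with per-edge bootstrap supports from resampled SNP columns.

    Unique haplotypes are fixed by the original data (labels are stable);
    each resample redraws SNP columns with replacement, recomputes Hamming
    distances between those fixed haplotypes, rebuilds the NJ tree and
    collects its bipartitions.  Support = fraction of resamples containing
    each original internal-edge bipartition.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    D, labels, counts, uniq = haplotype_distance(region)
    tree = nj_tree(D, labels, counts)
    main_parts = _normalized_bipartitions(D, labels)
    hits = {bp: 0 for bp in main_parts}
    k = uniq.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, k, size=k)
        sub = uniq[:, cols]
        Db = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).astype(float)
        parts = _normalized_bipartitions(Db, labels)
        for bp in main_parts:
            if bp in parts:
                hits[bp] += 1
    tree.supports = {bp: hits[bp] / n_boot for bp in main_parts}
    # annotate the newick with supports as internal labels
    newick, edges, node_leaves, _ = _nj_join(D, labels)
    all_leaves = frozenset(labels)
    ref = labels[0]
    annotated = {}
    for leafset, node in edges:
        side = leafset if ref not in leafset else all_leaves - leafset
        annotated[node] = tree.supports.get(side)
    tree.newick = _annotated_newick(D, labels, annotated)
    return tree


def _annotated_newick(D, labels, support_by_node) -> str:
    """Rebuild the NJ newick with supports written as internal labels."""
    n = len(labels)
    newick, edges, node_leaves, _ = _nj_join(D, labels)
    # rebuild with labels: repeat the join sequence, attaching supports
    active = list(range(n))
    dist = np.asarray(D, dtype=float).copy()
    node_newick = {i: labels[i] for i in range(n)}
    next_id = n
    while len(active) > 2:
        k = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        a, b = active[i_s], active[j_s]
        dab = sub[i_s, j_s]
        la = max(0.5 * dab + (r[i_s] - r[j_s]) / (2.0 * (k - 2)), 0.0)
        lb = max(dab - la, 0.0)
        new_row = np.zeros(dist.shape[0] + 1)
        for c in active:
            if c in (a, b):
                continue
            new_row[c] = 0.5 * (dist[a, c] + dist[b, c] - dab)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[next_id, : next_id] = new_row[:next_id]
        dist[: next_id, next_id] = new_row[:next_id]
        sup = support_by_node.get(next_id)
        lab = f"{sup:.3f}" if sup is not None else ""
        node_newick[next_id] = (
            f"({node_newick[a]}:{la:.10g},{node_newick[b]}:{lb:.10g}){lab}"
        )
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    a, b = active
    dab = max(dist[a, b], 0.0)
    return f"({node_newick[a]}:{dab / 2.0:.10g},{node_newick[b]}:{dab / 2.0:.10g});"


# ---------------------------------------------------------------------------
# Sweep-haplotype clustering
# ---------------------------------------------------------------------------


def favored_clade_recall(region: PhasedRegion, favored_flags: np.ndarray) -> float:
    """Fraction of favored-allele haplotype copies inside the best clade.

    ``favored_flags`` marks each haplotype row (2n) carrying the favored
    allele.  Over all bipartition sides of the NJ tree in which favored
    copies form the majority, returns the maximum recall of favored copies;
    0.0 if no majority-favored clade exists.
    """
    D, labels, counts, uniq = haplotype_distance(region)
    _, inverse = np.unique(region.haplotypes, axis=0, return_inverse=True)
    favored_flags = np.asarray(favored_flags, dtype=bool)
    fav_per_uniq = np.zeros(len(labels))
    tot_per_uniq = np.zeros(len(labels))
    for row, u in enumerate(inverse):
        tot_per_uniq[u] += 1
        if favored_flags[row]:
            fav_per_uniq[u] += 1
    total_fav = fav_per_uniq.sum()
    if total_fav == 0:
        return 0.0
    parts = _normalized_bipartitions(D, labels)
    # include single-leaf "clades" too (a fully swept region may collapse)
    singletons = {frozenset([lab]) for lab in labels}
    best = 0.0
    label_idx = {lab: i for i, lab in enumerate(labels)}
    for side in set(parts) | singletons:
        idx = [label_idx[lab] for lab in side]
        fav_in = fav_per_uniq[idx].sum()
        tot_in = tot_per_uniq[idx].sum()
        if tot_in == 0 or fav_in <= tot_in / 2.0:
            continue
        best = max(best, fav_in / total_fav)
    return float(best)
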