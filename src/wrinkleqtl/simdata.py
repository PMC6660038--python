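"""Two-population genotype and phenotype simulator with an optional sweep.

Emulates the study design the pipeline targets: a herd of 332 domestic pigs
(168 castrated males, 164 females) genotyped on a medium-density chip over a
6 Mb chromosome segment, contrasted against a small wild-boar sample, with a
selective sweep at a focal SNP in the domestic population and two correlated
wrinkle phenotypes driven by a major QTL at the swept SNP plus a polygenic
background.

The generator works in two stages:

1. *Founders*: the chromosome is cut into blocks; within each block founder
   haplotypes are drawn from a Hudson-style single-population coalescent
   without recombination (exponential coalescence times, Poisson mutations on
   branches, infinite sites).  This gives a neutral site-frequency spectrum
   and LD that decays across block boundaries.
2. *Forward Wright-Fisher*: the founder pool is copied into a domestic and a
   wild population which evolve independently for ``split_generations`` with
   random mating and uniform recombination (1 cM/Mb by default); the domestic
   population additionally experiences genic selection on the favored allele
   at the focal site.

Phenotypes follow  y = mu + sex + batch + a*g_qtl + u + e  with the polygenic
term drawn with covariance GRM * (h2 - q) * sigma^2, and the cross-trait
polygenic/residual correlation solved so the total phenotypic correlation hits
its target (0.777 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)

MORGAN_PER_CM = 0.01
BP_PER_MB = 1_000_000

__all__ = [
    "SweepSpec",
    "TraitSpec",
    "PhenoSpec",
    "SimConfig",
    "PopulationSample",
    "simulate_founders",
    "simulate_two_populations",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SweepSpec:
    """Genic selection on a favored allele at a focal chip SNP."""

    focal_position_bp: int = 2_835_986  # offset within the simulated segment
    selection_coefficient: float = 0.1
    initial_frequency: float = 0.05
    favored_allele: str = "G"
    # carriers of the standing variant share descent from one haplotype;
    # mean one-sided IBD tract ~1/(r*T) for an allele ~50 generations old
    ibd_tract_mean_bp: float = 2_000_000.0

    def validate(self, chrom_length_bp: int) -> None:
        if not 0 < self.focal_position_bp <= chrom_length_bp:
            raise ValueError("focal position outside the chromosome")
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 < self.initial_frequency < 1.0:
            raise ValueError("initial frequency must lie in (0, 1)")


@dataclass
class TraitSpec:
    """Calibration of one quantitative trait."""

    name: str
    mean: float
    sd: float
    h2: float
    qtl_variance_fraction: float
    sex_effect: float = 0.0  # female minus male difference
    batch_effects: tuple = (0.0, 0.0)

    def validate(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"{self.name}: h2 outside [0, 1]")
        if not 0.0 <= self.qtl_variance_fraction <= self.h2:
            raise ValueError(f"{self.name}: QTL fraction must lie in [0, h2]")
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")


@dataclass
class PhenoSpec:
    """Two-trait phenotype calibration.

    Defaults reproduce the herd the pipeline is calibrated to: wrinkle pixel
    ratio (wpr) 0.09 +- 0.027 with h2 0.681 and a QTL explaining 21.8% of
    variance; wrinkle score 3.20 +- 1.04 with h2 0.737 and QTL fraction
    31.3%; phenotypic correlation 0.777.  The QTL effect is positive on the
    favored (G) dosage, i.e. negative per copy of the alternative A allele.
    """

    traits: tuple = (
        TraitSpec("wpr", 0.09, 0.027, 0.681, 0.218, sex_effect=0.01,
                  batch_effects=(-0.00135, 0.00135)),
        TraitSpec("score", 3.20, 1.04, 0.737, 0.313, sex_effect=0.29,
                  batch_effects=(-0.052, 0.052)),
    )
    phenotypic_correlation: float = 0.777
    n_batches: int = 2

    def validate(self) -> None:
        for t in self.traits:
            t.validate()
            if len(t.batch_effects) != self.n_batches:
                raise ValueError(f"{t.name}: need {self.n_batches} batch effects")
        if not -1.0 < self.phenotypic_correlation < 1.0:
            raise ValueError("phenotypic correlation must lie in (-1, 1)")


@dataclass
class SimConfig:
    """Genotype-simulation parameters; defaults are the study conditions."""

    n_domestic: int = 332
    n_wild: int = 21
    n_males: int = 168
    n_females: int = 164
    chrom_length_bp: int = 6_000_000
    chrom: str = "7"
    pos_offset_bp: int = 32_000_000  # segment emulates SSC7 32-38 Mb
    n_background_chroms: int = 3  # neutral chromosomes backing the GRM
    target_snp_count: int = 3000  # per chromosome
    block_length_bp: int = 50_000
    split_generations: int = 60
    effective_size: int = 500  # diploids per population during forward sim
    recomb_cm_per_mb: float = 1.0
    sweep: SweepSpec | None = field(default_factory=SweepSpec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_domestic", "n_wild", "n_males", "n_females",
                     "chrom_length_bp", "target_snp_count", "block_length_bp",
                     "effective_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_males + self.n_females != self.n_domestic:
            raise ValueError("n_males + n_females must equal n_domestic")
        if self.block_length_bp > self.chrom_length_bp:
            raise ValueError("block longer than chromosome")
        if self.split_generations < 0:
            raise ValueError("split_generations must be >= 0")
        if max(self.n_domestic, self.n_wild) > self.effective_size:
            raise ValueError("cannot sample more diploids than the population holds")
        if self.sweep is not None:
            self.sweep.validate(self.chrom_length_bp)


@dataclass
class PopulationSample:
    """Sampled diploids from one population with truth phase."""

    haplotypes: np.ndarray  # (2n, m) uint8
    snp_map: pd.DataFrame  # id, chrom, pos (offset applied), allele_ref/alt
    samples: pd.DataFrame  # id, sex, population
    qtl_index: int | None = None

    def __post_init__(self) -> None:
        pos = self.snp_map["pos"].to_numpy()
        chrom = self.snp_map["chrom"].to_numpy()
        for c in pd.unique(chrom):
            if np.any(np.diff(pos[chrom == c]) <= 0):
                raise ValueError(f"positions must be strictly increasing on {c}")

    @property
    def genotypes(self) -> np.ndarray:
        """Dosage matrix (n, m): sum of the two haplotype alleles."""
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.genotypes, self.snp_map.copy(), self.samples.copy())

    def subset_chrom(self, chrom: str) -> "PopulationSample":
        """Restrict to one chromosome (e.g. the sweep-bearing one)."""
        mask = (self.snp_map["chrom"].astype(str) == str(chrom)).to_numpy()
        idx = np.nonzero(mask)[0]
        qtl = None
        if self.qtl_index is not None and mask[self.qtl_index]:
            qtl = int(np.nonzero(idx == self.qtl_index)[0][0])
        return PopulationSample(
            self.haplotypes[:, idx].copy(),
            self.snp_map.iloc[idx].reset_index(drop=True),
            self.samples.copy(),
            qtl,
        )


# ---------------------------------------------------------------------------
# Founders: block coalescent
# ---------------------------------------------------------------------------


def _coalescent_block(rng: np.random.Generator, n_hap: int, theta: float):
    """Site patterns of one non-recombining block under the Kingman coalescent.

    Returns a list of leaf-index arrays, one per segregating site (the derived
    carriers).  Mutations fall as Poisson(theta/2 per lineage per coalescent
    time unit) on the genealogy of ``n_hap`` haplotypes.
    """
    lineages = [np.array([i]) for i in range(n_hap)]
    sites: list[np.ndarray] = []
    k = n_hap
    while k > 1:
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate)
        n_mut = rng.poisson(theta / 2.0 * k * dt)
        for _ in range(n_mut):
            sites.append(lineages[rng.integers(k)])
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        lineages[i] = np.concatenate([lineages[i], lineages[j]])
        lineages[j] = lineages[k - 1]
        lineages.pop()
        k -= 1
    return sites


_HARMONIC_CACHE: dict[int, float] = {}


def _a1(n: int) -> float:
    if n not in _HARMONIC_CACHE:
        _HARMONIC_CACHE[n] = float(np.sum(1.0 / np.arange(1, n)))
    return _HARMONIC_CACHE[n]


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw the founder haplotype pool: (2*effective_size, m) matrix + positions.

    The chromosome is tiled with ``block_length_bp`` blocks simulated as
    independent non-recombining coalescent trees; the per-block mutation rate
    is calibrated so the expected total number of segregating sites equals
    ``target_snp_count``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.effective_size
    L = config.chrom_length_bp
    bl = config.block_length_bp
    edges = list(range(0, L, bl)) + [L]
    n_blocks_eff = (L / bl)
    theta_full = config.target_snp_count / (_a1(n_hap) * n_blocks_eff)

    cols: list[np.ndarray] = []
    positions: list[int] = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        theta = theta_full * (b1 - b0) / bl
        sites = _coalescent_block(rng, n_hap, theta)
        if not sites:
            continue
        span = b1 - b0
        pos = rng.choice(span, size=min(len(sites), span), replace=False)
        for carriers, p in zip(sites, np.sort(pos)):
            col = np.zeros(n_hap, dtype=np.uint8)
            col[carriers] = 1
            cols.append(col)
            positions.append(b0 + int(p) + 1)  # 1-based
    if not cols:
        raise RuntimeError("no segregating sites simulated; raise target_snp_count")
    order = np.argsort(positions, kind="stable")
    H = np.stack([cols[i] for i in order], axis=1)
    pos = np.array([positions[i] for i in order], dtype=np.int64)
    return H, pos


# ---------------------------------------------------------------------------
# Forward Wright-Fisher with recombination and genic selection
# ---------------------------------------------------------------------------


def _evolve_genome(
    rng: np.random.Generator,
    chroms: list[tuple[np.ndarray, np.ndarray]],
    length_bp: int,
    n_generations: int,
    recomb_cm_per_mb: float,
    mu_per_gamete: float = 0.0,
    sel_chrom: int | None = None,
    sel_index: int | None = None,
    s: float = 0.0,
    prune_every: int = 10,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Evolve a multi-chromosome population of 2N haplotypes per chromosome.

    Each generation one set of diploid parents is drawn (fitness-weighted by
    the favored-allele count on the selected chromosome when a sweep is
    active) and every chromosome is transmitted through those same parents
    with independent assortment and uniform within-chromosome crossover.
    New mutations enter at ``mu_per_gamete`` expected events per gamete per
    chromosome per generation, keeping the site-frequency spectrum at
    mutation-drift equilibrium instead of bleeding rare variants; columns
    born here that are lost again are pruned, while founder columns are kept
    even when fixed or lost so both populations retain a shared site set.
    Returns [(haplotypes, positions), ...]; appended positions are unsorted
    (callers sort when assembling samples).
    """
    state = [(H.copy(), np.asarray(p, dtype=np.int64).copy()) for H, p in chroms]
    m0s = [H.shape[1] for H, _ in state]
    n_hap = state[0][0].shape[0]
    N = n_hap // 2
    morgans = length_bp / BP_PER_MB * recomb_cm_per_mb * MORGAN_PER_CM
    for gen in range(n_generations):
        if sel_index is not None and s > 0:
            Hs = state[sel_chrom][0]
            g = Hs[0::2, sel_index].astype(np.float64) + Hs[1::2, sel_index]
            w = (1.0 + s) ** g
            parents = rng.choice(N, size=n_hap, p=w / w.sum())
        else:
            parents = rng.integers(0, N, size=n_hap)
        for ci, (H, positions) in enumerate(state):
            start = rng.integers(0, 2, size=n_hap)  # independent assortment
            n_cross = rng.poisson(morgans, size=n_hap)
            new_H = H[2 * parents + start]
            for idx in np.nonzero(n_cross)[0]:
                cuts = np.sort(rng.uniform(0, length_bp, size=n_cross[idx]))
                parity = np.searchsorted(cuts, positions) % 2
                a = H[2 * parents[idx] + start[idx]]
                b = H[2 * parents[idx] + 1 - start[idx]]
                new_H[idx] = np.where(parity == 1, b, a)
            H = new_H
            if mu_per_gamete > 0:
                n_new = rng.poisson(mu_per_gamete * n_hap)
                if n_new:
                    cols = np.zeros((n_hap, n_new), dtype=np.uint8)
                    cols[rng.integers(0, n_hap, size=n_new), np.arange(n_new)] = 1
                    H = np.concatenate([H, cols], axis=1)
                    positions = np.concatenate(
                        [positions, rng.integers(1, length_bp + 1, size=n_new)]
                    )
            if prune_every and (gen + 1) % prune_every == 0 and H.shape[1] > m0s[ci]:
                m0 = m0s[ci]
                born = H[:, m0:]
                alive = born.sum(axis=0) > 0
                H = np.concatenate([H[:, :m0], born[:, alive]], axis=1)
                positions = np.concatenate([positions[:m0], positions[m0:][alive]])
            state[ci] = (H, positions)
    return state


def _inject_focal_site(
    rng: np.random.Generator,
    H: np.ndarray,
    positions: np.ndarray,
    focal_pos: int,
    freq: float,
    ibd_tract_mean_bp: float = 2_000_000.0,
):
    """Plant a favored allele at ``freq`` at the focal position.

    The allele is modelled as a single recent mutation that drifted up to
    ``freq``: all carriers descend from one founder haplotype, so each
    carrier's local background is copied from a template over an
    exponentially distributed IBD tract (mean ~1 Mb per side, matching a
    variant on the order of a hundred generations old at 1 cM/Mb).  Without
    this shared background the sweep would start from dozens of unrelated
    haplotypes and leave no haplotype signature.
    """
    n_hap = H.shape[0]
    k = max(1, int(round(freq * n_hap)))
    carriers = rng.choice(n_hap, size=k, replace=False)
    H = H.copy()
    template = H[carriers[0]].copy()
    for c in carriers[1:]:
        left = rng.exponential(ibd_tract_mean_bp)
        right = rng.exponential(ibd_tract_mean_bp)
        in_tract = (positions >= focal_pos - left) & (positions <= focal_pos + right)
        H[c, in_tract] = template[in_tract]
    col = np.zeros(n_hap, dtype=np.uint8)
    col[carriers] = 1
    hit = np.nonzero(positions == focal_pos)[0]
    if hit.size:
        H[:, hit[0]] = col
        return H, positions, int(hit[0])
    j = int(np.searchsorted(positions, focal_pos))
    H = np.insert(H, j, col, axis=1)
    positions = np.insert(positions, j, focal_pos)
    return H, positions, j


FOCAL_SNP_ID = "rs_focal"
_RETRY_CAP = 20


def _snp_map_chrom(chrom: str, positions, offset: int, rng,
                   qtl_index=None, favored="G") -> pd.DataFrame:
    m = len(positions)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]
    pos = np.asarray(positions) + offset
    ids = [f"snp_{chrom}_{p}" for p in pos]
    if qtl_index is not None:
        ref[qtl_index] = "A"
        alt[qtl_index] = favored
        ids[qtl_index] = FOCAL_SNP_ID
    return pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": pos,
         "allele_ref": ref, "allele_alt": alt}
    )


def _merge_private_sites(dom, dom_pos, wild, wild_pos, m0, keep_exact=None):
    """Union of founder sites and each population's private new mutations.

    Private sites appear as zero columns in the other population.  Position
    collisions are resolved by bumping the later site (never ``keep_exact``).
    Returns (dom, wild, positions, new_index_of_keep_exact).
    """
    n_dom_new = dom.shape[1] - m0
    n_wild_new = wild.shape[1] - m0
    dom = np.concatenate(
        [dom, np.zeros((dom.shape[0], n_wild_new), dtype=np.uint8)], axis=1
    )
    wild = np.concatenate(
        [wild[:, :m0],
         np.zeros((wild.shape[0], n_dom_new), dtype=np.uint8),
         wild[:, m0:]],
        axis=1,
    )
    all_pos = np.concatenate([dom_pos, wild_pos[m0:]])
    seen: dict[int, int] = {}
    for i, p in enumerate(all_pos):
        p = int(p)
        if keep_exact is not None and i == keep_exact:
            if p in seen:  # displace the earlier site, never the focal one
                j = seen.pop(p)
                q = p + 1
                while q in seen:
                    q += 1
                seen[q] = j
                all_pos[j] = q
        else:
            while p in seen:
                p += 1
        seen[p] = i
        all_pos[i] = p
    order = np.argsort(all_pos, kind="stable")
    new_keep = None
    if keep_exact is not None:
        new_keep = int(np.nonzero(order == keep_exact)[0][0])
    return dom[:, order], wild[:, order], all_pos[order], new_keep


def simulate_two_populations(
    config: SimConfig,
    founders: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationSample, PopulationSample]:
    """Split the founder pool into domestic and wild populations and evolve.

    The domestic population undergoes genic selection at the focal site when a
    sweep is configured; if the favored allele is lost the sweep is retried
    with a fresh stream (cap 20), then the simulation fails loudly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # chromosome layout: neutral background chromosomes (lexicographically
    # before the focal one so record order matches (chrom, pos) sorting),
    # then the focal chromosome carrying the sweep
    bg_names = []
    k = 1
    while len(bg_names) < config.n_background_chroms:
        if str(k) != config.chrom:
            bg_names.append(str(k))
        k += 1
    chrom_names = bg_names + [config.chrom]
    focal_ci = len(chrom_names) - 1

    if founders is None:
        founders = [simulate_founders(config, rng) for _ in chrom_names]
    elif isinstance(founders, tuple):
        founders = [founders]
    founders = list(founders)

    qtl_index = None
    if config.sweep is not None:
        H0, pos0 = founders[focal_ci]
        H0, pos0, qtl_index = _inject_focal_site(
            rng, H0, pos0, config.sweep.focal_position_bp,
            config.sweep.initial_frequency,
        )
        founders[focal_ci] = (H0, pos0)

    # per-gamete mutation rate consistent with the founder theta, so the
    # site-frequency spectrum stays at mutation-drift equilibrium forward
    n_hap = 2 * config.effective_size
    theta_total = config.target_snp_count / _a1(n_hap)
    mu = theta_total / (2.0 * n_hap)

    for attempt in range(_RETRY_CAP + 1):
        if config.sweep is not None:
            dom_state = _evolve_genome(
                rng, founders, config.chrom_length_bp,
                config.split_generations, config.recomb_cm_per_mb, mu,
                sel_chrom=focal_ci, sel_index=qtl_index,
                s=config.sweep.selection_coefficient,
            )
            if dom_state[focal_ci][0][:, qtl_index].any():
                break
            log.warning("favored allele lost (attempt %d); retrying", attempt + 1)
        else:
            dom_state = _evolve_genome(
                rng, founders, config.chrom_length_bp,
                config.split_generations, config.recomb_cm_per_mb, mu,
            )
            break
    else:
        raise RuntimeError(
            f"favored allele lost in all {_RETRY_CAP} sweep attempts"
        )
    wild_state = _evolve_genome(
        rng, founders, config.chrom_length_bp,
        config.split_generations, config.recomb_cm_per_mb, mu,
    )

    dom_blocks, wild_blocks, map_blocks = [], [], []
    for ci, name in enumerate(chrom_names):
        m0 = founders[ci][0].shape[1]
        keep = qtl_index if ci == focal_ci else None
        d, w, pos, new_keep = _merge_private_sites(
            dom_state[ci][0], dom_state[ci][1],
            wild_state[ci][0], wild_state[ci][1], m0, keep_exact=keep,
        )
        offset = config.pos_offset_bp if ci == focal_ci else 0
        qtl_local = new_keep
        if ci == focal_ci and qtl_local is None and config.sweep is None:
            # anchor the QTL at the common SNP nearest the focal position
            freq = d.mean(axis=0)
            common = np.nonzero((freq >= 0.1) & (freq <= 0.9))[0]
            if common.size:
                target = SweepSpec().focal_position_bp
                qtl_local = int(common[np.argmin(np.abs(pos[common] - target))])
        favored = config.sweep.favored_allele if config.sweep else "G"
        map_blocks.append(
            _snp_map_chrom(name, pos, offset, rng, qtl_local, favored)
        )
        dom_blocks.append(d)
        wild_blocks.append(w)
        if ci == focal_ci and qtl_local is not None:
            qtl_index = qtl_local + sum(b.shape[1] for b in dom_blocks[:-1])

    dom = np.concatenate(dom_blocks, axis=1)
    wild = np.concatenate(wild_blocks, axis=1)
    snp_map = pd.concat(map_blocks, ignore_index=True)

    dom_ids = rng.choice(config.effective_size, size=config.n_domestic, replace=False)
    wild_ids = rng.choice(config.effective_size, size=config.n_wild, replace=False)

    def _sample(H, idx, prefix, population, sexes):
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        samples = pd.DataFrame(
            {
                "id": [f"{prefix}{i:04d}" for i in range(len(idx))],
                "sex": sexes,
                "population": population,
            }
        )
        return PopulationSample(H[rows].copy(), snp_map.copy(), samples, qtl_index)

    sexes = np.array(["M"] * config.n_males + ["F"] * config.n_females)
    rng.shuffle(sexes)
    domestic = _sample(dom, dom_ids, "EHL", "domestic", sexes)
    wild_sexes = np.where(rng.integers(0, 2, size=config.n_wild) == 0, "M", "F")
    wild_s = _sample(wild, wild_ids, "WB", "wild", wild_sexes)
    return domestic, wild_s


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _grm_chol(G: np.ndarray) -> np.ndarray:
    n = G.shape[0]
    return np.linalg.cholesky(G + 1e-6 * np.eye(n))


def simulate_phenotypes(
    sample: PopulationSample,
    spec: PhenoSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw the two correlated traits for a sampled population.

    Per trait:  y = mean + sex + batch + a*g_qtl + u + e  with
    Var(a*g) = q*sigma^2, Cov(u) = GRM*(h2-q)*sigma^2, Var(e) = (1-h2)*sigma^2
    where sigma = the trait's target SD.  The polygenic and residual draws
    share one cross-trait correlation rho solved so the total phenotypic
    correlation matches the target; an infeasible target raises ValueError.
    Returns the phenotype table and a truth record (a, u, e, rho).
    """
    spec = spec or PhenoSpec()
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample.qtl_index is None:
        raise ValueError("sample has no QTL index")
    g = sample.genotypes[:, sample.qtl_index].astype(float)
    var_g = g.var()
    if var_g == 0:
        raise ValueError("QTL is monomorphic in the sample; cannot scale effect")
    n = len(g)

    t1, t2 = spec.traits
    # cross-trait correlation of the shared polygenic/residual draws
    q1, q2 = t1.qtl_variance_fraction, t2.qtl_variance_fraction
    denom = (
        np.sqrt((t1.h2 - q1) * (t2.h2 - q2)) + np.sqrt((1 - t1.h2) * (1 - t2.h2))
    )
    rho = (spec.phenotypic_correlation - np.sqrt(q1 * q2)) / denom
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"target correlation {spec.phenotypic_correlation} infeasible given "
            f"the variance split (needs rho={rho:.3f})"
        )

    from .polygenic import compute_grm  # deferred: avoids import cycle

    # polygenic background lives on the chip's common variants (MAF >= 1%),
    # the same variant class the analysis GRM is built from
    gm = sample.to_genotype_matrix()
    common = np.nonzero(gm.maf() >= 0.01)[0]
    K = compute_grm(gm.subset(snp_idx=common), skip_monomorphic=True).matrix
    # scale to unit mean diagonal so Var(u_i) averages exactly (h2-q)*sigma^2
    K = K / np.mean(np.diag(K))
    Lk = _grm_chol(K)
    gc = g - g.mean()

    sex = sample.samples["sex"].to_numpy()
    sex_sign = np.where(sex == "F", 0.5, -0.5)
    batch = rng.integers(0, spec.n_batches, size=n)

    z_u = rng.standard_normal((n, 2))
    z_u[:, 1] = rho * z_u[:, 0] + np.sqrt(1 - rho**2) * z_u[:, 1]
    z_e = rng.standard_normal((n, 2))
    z_e[:, 1] = rho * z_e[:, 0] + np.sqrt(1 - rho**2) * z_e[:, 1]

    out = {"id": sample.samples["id"], "sex": sex, "batch": batch + 1}
    truth: dict = {"rho": float(rho), "qtl_index": int(sample.qtl_index)}
    for k, trait in enumerate(spec.traits):
        sigma2 = trait.sd**2
        q = trait.qtl_variance_fraction
        a = np.sqrt(q * sigma2 / var_g) if q > 0 else 0.0
        u = np.sqrt(max(trait.h2 - q, 0.0) * sigma2) * (Lk @ z_u[:, k])
        e = np.sqrt((1 - trait.h2) * sigma2) * z_e[:, k]
        y = (
            trait.mean
            + trait.sex_effect * sex_sign
            + np.asarray(trait.batch_effects)[batch]
            + a * gc
            + u
            + e
        )
        out[trait.name] = y
        truth[trait.name] = {
            "a": float(a),
            "u": u,
            "e": e,
            "h2": trait.h2,
            "qtl_variance_fraction": q,
        }
    return pd.DataFrame(out), truth


def simulate_dataset(
    config: SimConfig | None = None,
    pheno: PhenoSpec | None = None,
    seed: int | None = None,
):
    """Convenience wrapper: genotypes for both populations plus phenotypes."""
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    domestic, wild = simulate_two_populations(config, rng=rng)
    phenotypes, truth = simulate_phenotypes(domestic, pheno, rng)
    return domestic, wild, phenotypes, truth


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def _write_ped_map(samples: list[PopulationSample], prefix: Path) -> None:
    snp_map = samples[0].snp_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for s in samples:
            ref = s.snp_map["allele_ref"].to_numpy()
            alt = s.snp_map["allele_alt"].to_numpy()
            for i, srow in s.samples.iterrows():
                h1 = s.haplotypes[2 * i]
                h2 = s.haplotypes[2 * i + 1]
                alleles = np.empty(2 * len(ref), dtype=object)
                alleles[0::2] = np.where(h1 == 1, alt, ref)
                alleles[1::2] = np.where(h2 == 1, alt, ref)
                sex_code = {"M": "1", "F": "2"}.get(srow["sex"], "0")
                fh.write(
                    f"{srow['population']}\t{srow['id']}\t0\t0\t{sex_code}\t-9\t"
                    + "\t".join(alleles)
                    + "\n"
                )


def _write_vcf(samples: list[PopulationSample], path: Path) -> None:
    snp_map = samples[0].snp_map
    all_ids = [i for s in samples for i in s.samples["id"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(all_ids)
            + "\n"
        )
        hap = np.vstack([s.haplotypes for s in samples])
        for j, (_, row) in enumerate(snp_map.iterrows()):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(len(all_ids))
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['allele_ref']}\t"
                f"{row['allele_alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_gene_bed(config: SimConfig, sample: PopulationSample, path: Path,
                    gene_length_bp: int = 40_000, gap_bp: int = 10_000) -> None:
    """Synthetic gene annotation tiling every chromosome (BED, half-open).

    On the focal chromosome the tiling is phase-shifted so one gene contains
    the focal site.
    """
    pitch = gene_length_bp + gap_bp
    chroms = list(pd.unique(sample.snp_map["chrom"]))
    focal_chrom = None
    if sample.qtl_index is not None:
        focal_chrom = str(sample.snp_map["chrom"].iloc[sample.qtl_index])
    with open(path, "w") as fh:
        k = 0
        for chrom in chroms:
            lo = config.pos_offset_bp if str(chrom) == config.chrom else 0
            hi = lo + config.chrom_length_bp
            shift = 0
            if focal_chrom == str(chrom):
                focal = int(sample.snp_map["pos"].iloc[sample.qtl_index])
                shift = (focal - lo - gene_length_bp // 2) % pitch
            start = lo + shift - pitch  # one extra gene upstream for coverage
            while start < hi:
                end = min(start + gene_length_bp, hi)
                if end > lo:
                    fh.write(f"{chrom}\t{max(start, lo)}\t{end}\tgene{k:04d}\n")
                    k += 1
                start += pitch


def write_dataset(
    samples,
    phenotypes: pd.DataFrame,
    out_dir,
    config: SimConfig | None = None,
    truth: dict | None = None,
) -> dict:
    """Write PLINK text, phased VCF, phenotype TSV, gene BED and truth JSON.

    ``samples`` is one PopulationSample or a list (domestic first).  Returns
    the mapping of logical names to written paths.
    """
    if isinstance(samples, PopulationSample):
        samples = [samples]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig()

    prefix = out_dir / "genotypes"
    _write_ped_map(samples, prefix)
    vcf_path = out_dir / "genotypes.vcf"
    _write_vcf(samples, vcf_path)
    pheno_path = out_dir / "phenotypes.tsv"
    phenotypes.to_csv(pheno_path, sep="\t", index=False)
    bed_path = out_dir / "genes.bed"
    _write_gene_bed(config, samples[0], bed_path)

    truth_out: dict = {"qtl_index": samples[0].qtl_index}
    if samples[0].qtl_index is not None:
        truth_out["qtl_snp_id"] = str(samples[0].snp_map["id"].iloc[samples[0].qtl_index])
        truth_out["qtl_pos"] = int(samples[0].snp_map["pos"].iloc[samples[0].qtl_index])
    if config.sweep is not None:
        truth_out["sweep"] = asdict(config.sweep)
    if truth is not None:
        truth_out["phenotypes"] = {
            name: {"a": rec["a"], "h2": rec["h2"],
                   "qtl_variance_fraction": rec["qtl_variance_fraction"]}
            for name, rec in truth.items()
            if isinstance(rec, dict) and "a" in rec
        }
        truth_out["rho"] = truth.get("rho")
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth_out, indent=2))
    return {
        "ped": str(prefix.with_suffix(".ped")),
        "map": str(prefix.with_suffix(".map")),
        "vcf": str(vcf_path),
        "phenotypes": str(pheno_path),
        "genes": str(bed_path),
        "truth": str(truth_path),
    }
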