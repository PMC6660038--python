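"""Shared fixtures: scaled-down and study-scale synthetic datasets.

Session-scoped fixtures generate data once; tests only read from them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wrinkleqtl import genio, gwas, polygenic, simdata


def small_config(seed: int = 0, sweep: str = "default") -> simdata.SimConfig:
    """A cheap two-population configuration for unit tests."""
    cfg = simdata.SimConfig(
        seed=seed,
        n_domestic=60,
        n_males=30,
        n_females=30,
        n_wild=12,
        effective_size=120,
        target_snp_count=600,
        split_generations=25,
        n_background_chroms=1,
        chrom_length_bp=4_000_000,
    )
    if sweep is None:
        cfg.sweep = None
    return cfg


def fit_wpr(dom, pheno):
    """QC + GRM + polygenic fit for the first trait of a dataset."""
    g, _ = genio.qc_filter(dom.to_genotype_matrix())
    K = polygenic.compute_grm(g)
    covs = np.column_stack([
        (pheno["sex"] == "F").to_numpy(float),
        (pheno["batch"] == 2).to_numpy(float),
    ])
    fit = polygenic.fit_polygenic(pheno["wpr"].to_numpy(), covs, K)
    return g, covs, fit


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale dataset at the generator defaults (sweep + QTL)."""
    return simdata.simulate_dataset(seed=20_260_101)


def make_neutral_dataset(seed: int):
    """Study-scale dataset with no sweep and no QTL effect (polygenic only)."""
    cfg = simdata.SimConfig(seed=seed, sweep=None)
    spec = simdata.PhenoSpec(
        traits=(
            simdata.TraitSpec("wpr", 0.09, 0.027, 0.681, 0.0, sex_effect=0.01,
                              batch_effects=(-0.00135, 0.00135)),
            simdata.TraitSpec("score", 3.20, 1.04, 0.737, 0.0, sex_effect=0.29,
                              batch_effects=(-0.052, 0.052)),
        ),
        phenotypic_correlation=0.777,
    )
    rng = np.random.default_rng(cfg.seed)
    dom, wild = simdata.simulate_two_populations(cfg, rng=rng)
    pheno, truth = simdata.simulate_phenotypes(dom, spec, rng)
    return dom, wild, pheno, truth


@pytest.fixture(scope="session")
def neutral_dataset():
    return make_neutral_dataset(77)


@pytest.fixture(scope="session")
def neutral_scans(neutral_dataset):
    """Null mixed-model scans over three neutral replicates (for lambda and
    gene-level calibration, which need replication to beat seed noise)."""
    out = []
    for seed in (77, 78, 79):
        dom, wild, pheno, truth = (
            neutral_dataset if seed == 77 else make_neutral_dataset(seed)
        )
        g, covs, fit = fit_wpr(dom, pheno)
        scan = gwas.mmscore_scan(g, fit, pheno["wpr"].to_numpy())
        out.append({"g": g, "scan": scan, "h2": fit.h2})
    return out


@pytest.fixture(scope="session")
def replicate_summaries():
    """Per-replicate calibration summaries at the generator defaults.

    50 replicates; the polygenic fit and association scan (the expensive
    part) are computed for the first 20 only.
    """
    rows = []
    for i in range(50):
        dom, wild, pheno, truth = simdata.simulate_dataset(seed=10_000 + i)
        y = pheno["wpr"].to_numpy()
        rec = {
            "corr": float(np.corrcoef(pheno["wpr"], pheno["score"])[0, 1]),
            "var_pct": gwas.variance_explained(
                y, pheno["sex"], pheno["batch"],
                dom.genotypes[:, dom.qtl_index],
            ),
            "score_mean": float(pheno["score"].mean()),
            "score_sd": float(pheno["score"].std(ddof=1)),
        }
        if i < 20:
            g, covs, fit = fit_wpr(dom, pheno)
            scan = gwas.mmscore_scan(g, fit, y)
            qtl_id = dom.snp_map["id"].iloc[dom.qtl_index]
            rec["h2_wpr"] = fit.h2
            rec["focal_p"] = float(scan.records.set_index("snp").loc[qtl_id, "p"])
            rec["n_snps"] = len(scan.records)
            interval = gwas.lod_drop_interval(scan)
            qtl_pos = int(dom.snp_map["pos"].iloc[dom.qtl_index])
            if interval is None or interval[0] != "7":
                rec["interval_dist_bp"] = np.inf
            elif interval[1] <= qtl_pos <= interval[2]:
                rec["interval_dist_bp"] = 0.0
            else:
                rec["interval_dist_bp"] = float(
                    min(abs(interval[1] - qtl_pos), abs(interval[2] - qtl_pos))
                )
        rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sweep_scan():
    """Selection scan + focal metadata for one default sweep replicate."""
    from wrinkleqtl import selscan

    dom, wild, pheno, truth = simdata.simulate_dataset(seed=20_260_107)
    dom7 = dom.subset_chrom("7")
    wild7 = wild.subset_chrom("7")
    cores = np.arange(0, dom7.haplotypes.shape[1], 10)
    df = selscan.selection_scan(dom7, wild7, xpehh_cores=cores)
    focal = int(dom7.snp_map["pos"].iloc[dom7.qtl_index])
    return {"dom7": dom7, "wild7": wild7, "windows": df, "focal_pos": focal}
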