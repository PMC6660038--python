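"""Genotype/phenotype file IO, quality control and X-chromosome male coding.

Genotypes are held as an individuals x SNPs dosage matrix counting copies of a
designated allele (the VCF ALT allele, or the minor allele for PLINK text
input, where ``.map`` carries no allele designation).  Missing calls are coded
``-1`` and are never imputed silently; downstream consumers decide how to
handle them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "load_genotypes",
    "load_phenotypes",
    "qc_filter",
    "encode_x_males",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with its SNP map and sample table.

    Attributes
    ----------
    dosages : (n, m) int8 array
        Count of the counted allele per individual and SNP; ``-1`` = missing.
    snp_map : DataFrame
        Columns ``id, chrom, pos, allele_ref, allele_alt`` (``allele_alt`` is
        the counted allele; ``pos`` is 1-based).
    samples : DataFrame
        Columns ``id, sex, population``; sex in {"M", "F", "U"}.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame
    x_het_males_masked: int = 0

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.snp_map) != m:
            raise ValueError(
                f"inconsistent dimensions: dosages {self.dosages.shape}, "
                f"{len(self.samples)} samples, {len(self.snp_map)} SNPs"
            )
        pos = self.snp_map["pos"].to_numpy()
        chrom = self.snp_map["chrom"].to_numpy()
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return (self.dosages != MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def ind_missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=1)

    def subset(self, snp_idx=None, ind_idx=None) -> "GenotypeMatrix":
        snp_idx = np.arange(self.m) if snp_idx is None else np.asarray(snp_idx)
        ind_idx = np.arange(self.n) if ind_idx is None else np.asarray(ind_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind_idx, snp_idx)].copy(),
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            samples=self.samples.iloc[ind_idx].reset_index(drop=True),
            x_het_males_masked=self.x_het_males_masked,
        )


@dataclass
class QcReport:
    """Accounting of the SNP/individual filters, applied in the fixed order
    call-rate -> MAF -> individual missingness."""

    n_snps_in: int
    n_removed_missing: int
    n_removed_maf: int
    n_individuals_removed: int
    n_snps_out: int
    mendel_filter_applied: bool = False
    removed_snps_missing: list = field(default_factory=list)
    removed_snps_maf: list = field(default_factory=list)
    removed_individuals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (
            self.n_snps_in
            == self.n_removed_missing + self.n_removed_maf + self.n_snps_out
        ), "QC accounting identity violated"

    def to_json(self) -> str:
        d = {
            k: getattr(self, k)
            for k in (
                "n_snps_in",
                "n_removed_missing",
                "n_removed_maf",
                "n_individuals_removed",
                "n_snps_out",
                "mendel_filter_applied",
            )
        }
        return json.dumps(d, indent=2)

    def write(self, path) -> None:
        path = Path(path)
        path.with_suffix(".json").write_text(self.to_json())
        rows = [
            ("snps_in", self.n_snps_in),
            ("snps_removed_call_rate", self.n_removed_missing),
            ("snps_removed_maf", self.n_removed_maf),
            ("individuals_removed", self.n_individuals_removed),
            ("snps_out", self.n_snps_out),
        ]
        pd.DataFrame(rows, columns=["item", "count"]).to_csv(
            path.with_suffix(".tsv"), sep="\t", index=False
        )
        removed = (
            [("snp_call_rate", s) for s in self.removed_snps_missing]
            + [("snp_maf", s) for s in self.removed_snps_maf]
            + [("individual_missingness", s) for s in self.removed_individuals]
        )
        pd.DataFrame(removed, columns=["filter", "id"]).to_csv(
            path.with_suffix(".removed.tsv"), sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "M", "2": "F"}


def _load_plink_text(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str},
    )
    m = len(snp_map)

    fids, iids, sexes = [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(fields)}"
                )
            fids.append(fields[0])
            iids.append(fields[1])
            sexes.append(_SEX_CODE.get(fields[4], "U"))
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows)  # (n, 2m) strings
    n = alleles.shape[0]
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]

    dosages = np.empty((n, m), dtype=np.int8)
    ref = np.empty(m, dtype=object)
    alt = np.empty(m, dtype=object)
    for j in range(m):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise ValueError(
                f"SNP {snp_map['id'].iloc[j]} has >2 alleles: {obs}"
            )
        if len(obs) == 0:
            obs = ["0", "0"]
        if len(obs) == 1:
            obs = [obs[0], obs[0]]
        # counted allele = minor allele; tie broken lexicographically
        c0 = np.sum(col == obs[0])
        c1 = np.sum(col == obs[1])
        counted, other = (obs[1], obs[0]) if c1 <= c0 else (obs[0], obs[1])
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dosages[:, j] = (a1[:, j] == counted).astype(np.int8) + (
            a2[:, j] == counted
        )
        dosages[miss, j] = MISSING
        ref[j], alt[j] = other, counted

    snp_map = snp_map[["id", "chrom", "pos"]].copy()
    snp_map["allele_ref"] = ref
    snp_map["allele_alt"] = alt
    samples = pd.DataFrame({"id": iids, "sex": sexes, "population": fids})
    return GenotypeMatrix(dosages, snp_map, samples)


def _load_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.ID or var.POS} is not biallelic")
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dos.astype(np.int8))
    dosages = np.stack(rows, axis=1) if rows else np.zeros((len(vcf.samples), 0), np.int8)
    snp_map = pd.DataFrame(
        {
            "id": ids,
            "chrom": chroms,
            "pos": poss,
            "allele_ref": refs,
            "allele_alt": alts,
        }
    )
    samples = pd.DataFrame(
        {"id": vcf.samples, "sex": "U", "population": "pop"}
    )
    return GenotypeMatrix(dosages, snp_map, samples)


def load_genotypes(path: str | Path, format: str = "plink_text") -> GenotypeMatrix:
    """Load genotypes from PLINK text (``.ped``/``.map`` prefix) or VCF.

    Dosage counts the ALT allele (VCF) or the minor allele (PLINK text).
    """
    if format == "plink_text":
        return _load_plink_text(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def load_phased_vcf(path: str | Path):
    """Phased haplotypes from a VCF with '|'-separated GT.

    Returns (haplotypes (2n, m) uint8, snp_map DataFrame, sample ids).
    Unphased records are an error: phase is load-bearing downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, chroms, poss, refs, alts = [], [], [], [], []
    cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.ID or var.POS} is not biallelic")
        gt = np.array(var.genotypes)  # (n, 3): allele1, allele2, phased flag
        if not np.all(gt[:, 2]):
            raise ValueError(f"unphased genotypes at {var.CHROM}:{var.POS}")
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(gt[:, :2].reshape(-1).astype(np.uint8))
    hap = np.stack(cols, axis=1)
    snp_map = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss,
         "allele_ref": refs, "allele_alt": alts}
    )
    return hap, snp_map, list(vcf.samples)


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate TSV with columns id, sex, batch, then traits."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str, "batch": str})
    for col in ("id", "sex", "batch"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    return df


def attach_sex(g: GenotypeMatrix, phenotypes: pd.DataFrame) -> GenotypeMatrix:
    """Fill sample sex from a phenotype table (for VCF input)."""
    sex = phenotypes.set_index("id")["sex"]
    new = g.samples.copy()
    new["sex"] = new["id"].map(sex).fillna(new["sex"])
    return GenotypeMatrix(g.dosages, g.snp_map, new, g.x_het_males_masked)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    snp_call_rate: float = 0.90,
    maf: float = 0.01,
    ind_missing: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the fixed-order QC: call rate, MAF, individual missingness.

    All comparisons are strict: SNPs with call rate < ``snp_call_rate`` are
    removed, then SNPs with MAF < ``maf`` (computed over non-missing calls),
    then individuals with missingness > ``ind_missing`` over the surviving
    SNPs.  Pedigree Mendelian-error filtering is not applied (no pedigree is
    modelled); ``QcReport.mendel_filter_applied`` records this.
    """
    for t in (snp_call_rate, maf, ind_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    m_in = g.m
    cr = g.call_rate()
    keep_cr = cr >= snp_call_rate
    removed_cr = list(g.snp_map["id"][~keep_cr])

    g1 = g.subset(snp_idx=np.nonzero(keep_cr)[0])
    mafs = g1.maf()
    keep_maf = mafs >= maf
    removed_maf = list(g1.snp_map["id"][~keep_maf])
    g2 = g1.subset(snp_idx=np.nonzero(keep_maf)[0])
    if g2.m == 0:
        raise ValueError("all SNPs removed by QC")

    imiss = g2.ind_missing_rate()
    keep_ind = imiss <= ind_missing
    removed_ind = list(g2.samples["id"][~keep_ind])
    g3 = g2.subset(ind_idx=np.nonzero(keep_ind)[0])
    if g3.n == 0:
        raise ValueError("all individuals removed by QC")

    report = QcReport(
        n_snps_in=m_in,
        n_removed_missing=len(removed_cr),
        n_removed_maf=len(removed_maf),
        n_individuals_removed=len(removed_ind),
        n_snps_out=g3.m,
        removed_snps_missing=removed_cr,
        removed_snps_maf=removed_maf,
        removed_individuals=removed_ind,
    )
    log.info(
        "QC: %d SNPs in, %d removed (call rate), %d removed (MAF), "
        "%d individuals removed, %d SNPs out",
        m_in,
        len(removed_cr),
        len(removed_maf),
        len(removed_ind),
        g3.m,
    )
    return g3, report


def encode_x_males(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recode male X-chromosome genotypes as homozygous dosages {0, 2}.

    A male carries one X, so a heterozygous male X call is a genotyping
    anomaly: it is set to missing and counted in ``x_het_males_masked``.
    Female X genotypes are unchanged.
    """
    is_x = (g.snp_map["chrom"].astype(str) == "X").to_numpy()
    if not is_x.any():
        return g
    sex = g.samples["sex"].to_numpy()
    if np.any(sex == "U"):
        raise ValueError("X SNPs present but some samples have unknown sex")
    male = sex == "M"
    d = g.dosages.copy()
    block = d[np.ix_(male, is_x)]
    n_het = int(np.sum(block == 1))
    block[block == 1] = MISSING
    d[np.ix_(male, is_x)] = block
    if n_het:
        log.warning("masked %d heterozygous male X calls", n_het)
    return GenotypeMatrix(d, g.snp_map, g.samples, g.x_het_males_masked + n_het)
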