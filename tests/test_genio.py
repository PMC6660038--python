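"""Genotype IO, QC filters and X-male coding."""

import numpy as np
import pandas as pd
import pytest

from wrinkleqtl import genio, simdata
from wrinkleqtl.genio import MISSING, GenotypeMatrix, load_genotypes, qc_filter

from conftest import small_config


def write_plink(tmp_path, ped_rows, map_rows, name="toy"):
    (tmp_path / f"{name}.ped").write_text("\n".join(ped_rows) + "\n")
    (tmp_path / f"{name}.map").write_text("\n".join(map_rows) + "\n")
    return tmp_path / name


class TestPlinkLoading:
    def test_dosage_counts_minor_allele(self, tmp_path):
        # SNP1 alleles A/G, G minor -> "A A" = 0; SNP2 all A (monomorphic)
        prefix = write_plink(
            tmp_path,
            [
                "f1 i1 0 0 1 -9 A A A A",
                "f1 i2 0 0 2 -9 A G A A",
                "f1 i3 0 0 2 -9 G G A A",
                "f1 i4 0 0 1 -9 A A A A",
            ],
            ["1 snp1 0 100", "1 snp2 0 200"],
        )
        g = load_genotypes(prefix, "plink_text")
        assert list(g.dosages[:, 0]) == [0, 1, 2, 0]
        assert g.snp_map["allele_alt"].iloc[0] == "G"
        assert list(g.samples["sex"]) == ["M", "F", "F", "M"]

    def test_missing_code_zero_zero(self, tmp_path):
        prefix = write_plink(
            tmp_path,
            ["f1 i1 0 0 1 -9 0 0", "f1 i2 0 0 1 -9 A G"],
            ["1 snp1 0 100"],
        )
        g = load_genotypes(prefix, "plink_text")
        assert g.dosages[0, 0] == MISSING

    def test_ragged_row_errors_with_line_number(self, tmp_path):
        prefix = write_plink(
            tmp_path,
            ["f1 i1 0 0 1 -9 A A", "f1 i2 0 0 1 -9 A"],
            ["1 snp1 0 100"],
        )
        with pytest.raises(ValueError, match="line 2"):
            load_genotypes(prefix, "plink_text")

    def test_triallelic_errors_with_snp_id(self, tmp_path):
        prefix = write_plink(
            tmp_path,
            ["f1 i1 0 0 1 -9 A A", "f1 i2 0 0 1 -9 C G"],
            ["1 snpX 0 100"],
        )
        with pytest.raises(ValueError, match="snpX"):
            load_genotypes(prefix, "plink_text")


class TestRoundTrip:
    def test_vcf_round_trip_matches_truth_dosages(self, tmp_path):
        cfg = small_config(seed=4)
        dom, wild, pheno, truth = simdata.simulate_dataset(cfg)
        paths = simdata.write_dataset([dom, wild], pheno, tmp_path, config=cfg)
        g = load_genotypes(paths["vcf"], "vcf")
        both = np.vstack([dom.genotypes, wild.genotypes])
        assert np.array_equal(g.dosages, both)
        assert np.array_equal(
            g.snp_map["pos"].to_numpy(), dom.snp_map["pos"].to_numpy()
        )

    def test_ped_round_trip_up_to_allele_flip(self, tmp_path):
        cfg = small_config(seed=4)
        dom, wild, pheno, truth = simdata.simulate_dataset(cfg)
        paths = simdata.write_dataset([dom, wild], pheno, tmp_path, config=cfg)
        g = load_genotypes(str(tmp_path / "genotypes"), "plink_text")
        both = np.vstack([dom.genotypes, wild.genotypes])
        flip_ok = (g.dosages == both) | (g.dosages == 2 - both)
        assert flip_ok.all()

    def test_map_positions_equal_snp_map(self, tmp_path):
        cfg = small_config(seed=4)
        dom, wild, pheno, truth = simdata.simulate_dataset(cfg)
        simdata.write_dataset([dom, wild], pheno, tmp_path, config=cfg)
        mp = pd.read_csv(tmp_path / "genotypes.map", sep="\t", header=None)
        assert np.array_equal(mp[3].to_numpy(), dom.snp_map["pos"].to_numpy())

    def test_vcf_gt_phased_separator(self, tmp_path):
        cfg = small_config(seed=4)
        dom, wild, pheno, truth = simdata.simulate_dataset(cfg)
        paths = simdata.write_dataset([dom, wild], pheno, tmp_path, config=cfg)
        for line in open(paths["vcf"]):
            if line.startswith("#"):
                continue
            gts = line.rstrip("\n").split("\t")[9:]
            assert all("|" in gt for gt in gts)


def toy_matrix(dosages, chrom="1", sex=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snp_map = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 10,
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"i{i}" for i in range(n)],
            "sex": sex if sex is not None else ["M"] * n,
            "population": "p",
        }
    )
    return GenotypeMatrix(dosages, snp_map, samples)


class TestQcFilter:
    def test_call_rate_below_90_removed(self):
        # SNP 0 typed in 89 of 100 individuals -> removed (strict <0.90)
        d = np.ones((100, 2), dtype=np.int8)
        d[:11, 0] = MISSING  # call rate 0.89
        d[:, 1] = np.tile([0, 1], 50)  # clean SNP, MAF 0.5
        g = toy_matrix(d)
        out, report = qc_filter(g)
        assert report.n_removed_missing == 1
        assert list(out.snp_map["id"]) == ["s1"]

    def test_maf_boundary_is_retained(self):
        # MAF exactly 0.01 at n=100: one het among 100 -> freq 0.005 removed;
        # two hets -> 0.01 retained (strict <0.01)
        d = np.zeros((100, 2), dtype=np.int8)
        d[0, 0] = 1  # MAF 0.005
        d[:2, 1] = 1  # MAF 0.01
        g = toy_matrix(d)
        out, report = qc_filter(g)
        assert list(out.snp_map["id"]) == ["s1"]
        assert report.n_removed_maf == 1

    def test_planted_defects_match_hand_count(self):
        # brute-force oracle on a 20-SNP toy
        rng = np.random.default_rng(0)
        n = 50
        d = rng.integers(0, 3, size=(n, 20)).astype(np.int8)
        d[: int(n * 0.2), [0, 5]] = MISSING  # call rate 0.8 -> removed
        d[:, 3] = 0  # monomorphic -> MAF 0
        d[:, 7] = 0
        d[0, 7] = 1  # MAF 0.01 exactly -> kept
        g = toy_matrix(d)
        out, report = qc_filter(g)
        # exhaustive hand count
        expected_kept = 0
        for j in range(20):
            col = d[:, j].astype(float)
            obs = col[col != MISSING]
            if len(obs) / n < 0.90:
                continue
            p = obs.mean() / 2
            if min(p, 1 - p) < 0.01:
                continue
            expected_kept += 1
        assert report.n_snps_out == expected_kept
        assert (
            report.n_snps_in
            == report.n_removed_missing + report.n_removed_maf + report.n_snps_out
        )

    def test_individual_missingness_filter(self):
        d = ((np.arange(10)[:, None] + np.arange(20)[None, :]) % 3).astype(np.int8)
        d[0, :15] = MISSING  # 75% missing -> removed
        g = toy_matrix(d)
        out, report = qc_filter(g)
        assert report.n_individuals_removed == 1
        assert out.n == 9

    def test_idempotent_on_clean_data(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(60, 30)).astype(np.int8)
        g = toy_matrix(d)
        out1, _ = qc_filter(g)
        out2, rep2 = qc_filter(out1)
        assert rep2.n_removed_missing == 0
        assert rep2.n_removed_maf == 0
        assert rep2.n_individuals_removed == 0
        assert np.array_equal(out1.dosages, out2.dosages)

    def test_all_snps_removed_is_error(self):
        d = np.zeros((10, 3), dtype=np.int8)  # all monomorphic
        with pytest.raises(ValueError, match="all SNPs"):
            qc_filter(toy_matrix(d))


class TestXMaleCoding:
    def make_x(self, sex):
        d = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        g = toy_matrix(d, chrom="X", sex=sex)
        return g

    def test_male_het_masked_and_counted(self):
        g = self.make_x(["M", "M", "F"])
        out = genio.encode_x_males(g)
        assert out.dosages[0, 1] == MISSING  # het male masked
        assert out.dosages[1, 0] == MISSING
        assert out.x_het_males_masked == 2

    def test_male_homozygous_calls_kept_as_0_2(self):
        g = self.make_x(["M", "M", "F"])
        out = genio.encode_x_males(g)
        assert out.dosages[0, 0] == 0
        assert out.dosages[1, 1] == 2
        assert out.dosages[2, 0] == 2  # female row untouched

    def test_female_rows_unchanged(self):
        g = self.make_x(["F", "F", "F"])
        out = genio.encode_x_males(g)
        assert np.array_equal(out.dosages, g.dosages)

    def test_unknown_sex_with_x_errors(self):
        g = self.make_x(["M", "U", "F"])
        with pytest.raises(ValueError, match="unknown sex"):
            genio.encode_x_males(g)
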