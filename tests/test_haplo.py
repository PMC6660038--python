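"""EM phasing, haplotype distances, NJ trees and bootstrap supports."""

import io
import itertools

import numpy as np
import pytest

from wrinkleqtl import haplo
from wrinkleqtl.haplo import (
    PhasedRegion,
    bootstrap_support,
    em_haplotype_frequencies,
    haplotype_distance,
    nj_tree,
    phase_region,
)


def brute_force_em(genotypes, n_iter=500):
    """Reference EM over all 2^k haplotypes, written independently."""
    n, k = genotypes.shape
    haps = list(itertools.product([0, 1], repeat=k))
    u = len(haps)
    f = np.full(u, 1.0 / u)
    pairs_per_ind = []
    for i in range(n):
        pl = [
            (a, b)
            for a in range(u)
            for b in range(a, u)
            if all(haps[a][j] + haps[b][j] == genotypes[i, j] for j in range(k))
        ]
        pairs_per_ind.append(pl)
    for _ in range(n_iter):
        exp = np.zeros(u)
        for pl in pairs_per_ind:
            w = np.array([(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pl])
            w /= w.sum()
            for (a, b), p in zip(pl, w):
                exp[a] += p
                exp[b] += p
        f = exp / (2 * n)
    return np.array(haps), f


def region_from(haplotypes, positions=None):
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n2, k = haplotypes.shape
    positions = positions if positions is not None else np.arange(1, k + 1) * 100
    ids = [f"i{i}" for i in range(n2 // 2)]
    return PhasedRegion(haplotypes, np.asarray(positions), ids, np.ones(n2 // 2))


class TestEmPhasing:
    def test_single_het_is_unambiguous(self):
        from test_genio import toy_matrix

        d = np.array([[1, 0, 2], [0, 0, 2], [2, 0, 2]], dtype=np.int8)
        g = toy_matrix(d)
        region = phase_region(g, ("1", 1, 100), method="em")
        # each individual's haplotype pair sums to its genotype
        geno = region.haplotypes[0::2] + region.haplotypes[1::2]
        assert np.array_equal(geno, d)
        assert region.certainty[0] == pytest.approx(1.0)

    def test_three_snp_block_matches_exhaustive_em(self):
        rng = np.random.default_rng(0)
        true_haps = np.array([[0, 0, 0], [1, 1, 0], [0, 1, 1]])
        draws = rng.integers(0, 3, size=(40, 2))
        geno = true_haps[draws[:, 0]] + true_haps[draws[:, 1]]
        haps_ref, f_ref = brute_force_em(geno)
        f_pkg, ll, _ = em_haplotype_frequencies(
            geno.astype(np.int8), haps_ref.astype(np.uint8),
            rng=np.random.default_rng(1),
        )
        np.testing.assert_allclose(np.sort(f_pkg), np.sort(f_ref), atol=1e-3)
        # the truly present haplotypes carry essentially all the mass
        top = np.argsort(f_pkg)[::-1][:3]
        assert f_pkg[top].sum() > 0.99

    def test_switch_error_low_on_common_snps(self, default_dataset):
        dom, wild, pheno, truth = default_dataset
        dom7 = dom.subset_chrom("7")
        gm = dom7.to_genotype_matrix()
        maf = gm.maf()
        pos = dom7.snp_map["pos"].to_numpy()
        # 12 common SNPs in a tight region, 100 individuals
        idx = np.nonzero((maf > 0.1) & (pos > 33_000_000) & (pos < 33_500_000))[0][:12]
        sub = gm.subset(snp_idx=idx, ind_idx=np.arange(100))
        region = phase_region(
            sub, ("7", int(pos[idx].min()), int(pos[idx].max())), method="em"
        )
        truth_hap = dom7.haplotypes[:200][:, idx]
        switches = total_hets = 0
        for i in range(100):
            a, b = region.haplotypes[2 * i], region.haplotypes[2 * i + 1]
            ta, tb = truth_hap[2 * i], truth_hap[2 * i + 1]
            het = a != b
            if het.sum() < 2:
                continue
            # orientation sequence vs truth at heterozygous sites
            orient = (a[het] == ta[het]).astype(int)
            switches += np.sum(np.abs(np.diff(orient)))
            total_hets += het.sum() - 1
        assert total_hets > 0
        assert switches / total_hets < 0.05

    def test_truth_mode_reproduces_simulator_phase(self, default_dataset):
        dom, *_ = default_dataset
        dom7 = dom.subset_chrom("7")
        focal = int(dom7.snp_map["pos"].iloc[dom7.qtl_index])
        region = phase_region(
            dom7.to_genotype_matrix(), ("7", focal - 50_000, focal + 50_000),
            method="truth", truth_haplotypes=dom7.haplotypes,
        )
        geno = region.haplotypes[0::2] + region.haplotypes[1::2]
        pos = dom7.snp_map["pos"].to_numpy()
        idx = np.nonzero((pos >= focal - 50_000) & (pos <= focal + 50_000))[0]
        assert np.array_equal(geno, dom7.genotypes[:, idx])


class TestDistances:
    def test_hamming_and_collapse(self):
        region = region_from(
            [[0, 0, 0], [0, 0, 0], [0, 1, 1], [1, 1, 1], [0, 0, 0], [1, 0, 1]]
        )
        D, labels, counts, uniq = haplotype_distance(region)
        assert len(uniq) == 4
        assert counts.sum() == 6
        i000 = next(i for i, h in enumerate(uniq) if list(h) == [0, 0, 0])
        i011 = next(i for i, h in enumerate(uniq) if list(h) == [0, 1, 1])
        assert D[i000, i011] == 2
        assert np.all(np.diag(D) == 0)
        assert np.array_equal(D, D.T)


class TestNj:
    def test_four_taxa_additive_quartet(self):
        # d(A,B)=2, d(C,D)=2, cross distances 3 -> (A,B|C,D), internal 1
        D = np.array(
            [
                [0, 2, 3, 3],
                [2, 0, 3, 3],
                [3, 3, 0, 2],
                [3, 3, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, ["A", "B", "C", "D"])
        import skbio

        t = skbio.TreeNode.read(io.StringIO(tree.newick))
        tips = {frozenset(x.name for x in n.tips()) for n in t.non_tips()}
        assert frozenset({"A", "B"}) in tips or frozenset({"C", "D"}) in tips
        # internal branch length 1 (the root join splits it 0.5/0.5)
        dist = t.find("A").distance(t.find("C"))
        assert dist == pytest.approx(3.0, abs=1e-9)
        assert t.find("A").distance(t.find("B")) == pytest.approx(2.0, abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(D, ["A", "B", "C"])
        import skbio

        t = skbio.TreeNode.read(io.StringIO(tree.newick))
        # a = (dAB + dAC - dBC)/2 = 1, b = 2, c = 3
        assert t.find("A").distance(t.find("B")) == pytest.approx(3.0, abs=1e-9)
        assert t.find("A").distance(t.find("C")) == pytest.approx(4.0, abs=1e-9)
        assert t.find("B").distance(t.find("C")) == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [6, 8, 10])
    def test_recovers_random_additive_trees(self, n_leaves):
        import skbio

        rng = np.random.default_rng(n_leaves)
        # build a random additive tree by sequential leaf attachment
        newick = self._random_tree_newick(rng, n_leaves)
        t_true = skbio.TreeNode.read(io.StringIO(newick))
        labels = sorted(x.name for x in t_true.tips())
        D = np.zeros((n_leaves, n_leaves))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = t_true.find(a).distance(t_true.find(b))
        tree = nj_tree(D, labels)
        t_est = skbio.TreeNode.read(io.StringIO(tree.newick))
        # every pairwise path length reproduced -> topology + lengths correct
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert t_est.find(a).distance(t_est.find(b)) == pytest.approx(
                        D[i, j], abs=1e-6
                    )

    @staticmethod
    def _random_tree_newick(rng, n_leaves):
        import skbio

        t = skbio.TreeNode.read(io.StringIO("(L0:1.0,L1:1.5);"))
        for k in range(2, n_leaves):
            edges = [n for n in t.traverse() if n.length is not None]
            host = edges[rng.integers(len(edges))]
            # split the host edge and hang the new leaf off the midpoint
            new_internal = skbio.TreeNode(length=host.length / 2)
            leaf = skbio.TreeNode(name=f"L{k}", length=float(rng.uniform(0.5, 2.0)))
            parent = host.parent
            parent.remove(host)
            host.length = host.length / 2
            new_internal.append(host)
            new_internal.append(leaf)
            parent.append(new_internal)
        return str(t)

    def test_agreement_with_skbio_nj_topology(self):
        import skbio

        rng = np.random.default_rng(12)
        pts = rng.standard_normal((7, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = [f"T{i}" for i in range(7)]
        mine = nj_tree(D, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        t1 = skbio.TreeNode.read(io.StringIO(mine.newick))

        def bipartitions(t):
            tips = {x.name for x in t.tips()}
            out = set()
            for node in t.non_tips():
                s = frozenset(x.name for x in node.tips())
                s = s if "T0" not in s else frozenset(tips - s)
                if 1 < len(s) < len(tips) - 1:
                    out.add(s)
            return out

        assert bipartitions(t1) == bipartitions(ref)

    def test_non_finite_distance_errors(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(D, ["a", "b", "c"])


class TestBootstrap:
    def region_two_clusters(self):
        # two clusters separated at 12 sites plus private marker sites:
        # the cluster bipartition survives any column resample
        sep = 12
        a1 = np.zeros(sep + 2, dtype=int)
        a2 = a1.copy()
        a2[sep] = 1
        b1 = np.concatenate([np.ones(sep, dtype=int), [0, 0]])
        b2 = b1.copy()
        b2[sep + 1] = 1
        rows = np.repeat(np.array([a1, a2, b1, b2]), 3, axis=0)
        return region_from(rows)

    def test_certain_clade_has_full_support(self):
        region = self.region_two_clusters()
        tree = bootstrap_support(region, n_boot=100, seed=0)
        assert tree.supports
        assert all(0.0 <= s <= 1.0 for s in tree.supports.values())
        assert max(tree.supports.values()) == pytest.approx(1.0)

    def test_newick_round_trip(self):
        region = self.region_two_clusters()
        tree = bootstrap_support(region, n_boot=20, seed=1)
        import skbio

        t = skbio.TreeNode.read(io.StringIO(tree.newick))
        assert sorted(x.name for x in t.tips()) == sorted(tree.labels)
        # re-serialize and re-parse: pairwise distances stable to 1e-9
        t2 = skbio.TreeNode.read(io.StringIO(str(t)))
        for a in tree.labels[:3]:
            for b in tree.labels[-3:]:
                if a != b:
                    assert t.find(a).distance(t.find(b)) == pytest.approx(
                        t2.find(a).distance(t2.find(b)), abs=1e-9
                    )

    def test_sweep_haplotypes_cluster_with_favored_allele(self, sweep_scan):
        dom7 = sweep_scan["dom7"]
        focal = sweep_scan["focal_pos"]
        region = phase_region(
            dom7.to_genotype_matrix(), ("7", focal - 100_000, focal + 100_000),
            method="truth", truth_haplotypes=dom7.haplotypes,
        )
        favored = dom7.haplotypes[:, dom7.qtl_index] == 1
        assert haplo.favored_clade_recall(region, favored) >= 0.9
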