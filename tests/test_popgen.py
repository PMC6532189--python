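"""Variant filters, MAF screen, kinship, PCA, LD decay, NJ trees."""

import numpy as np
import pandas as pd
import pytest

from spec2gwas.io_formats import GenotypeMatrix
from spec2gwas.popgen import (
    apply_variant_filters,
    kinship,
    ld_profile,
    maf_filter,
    minor_allele_frequency,
    nj_tree,
    p_distance_matrix,
    pca_covariates,
)
from spec2gwas.synthetic_data import SimulationConfig, simulate_ld_population, simulate_population


def variants_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])


class TestVariantFilters:
    def test_snp_cluster_removes_both(self):
        v = variants_table(
            [("1", 100, "A", "T", "SNP"), ("1", 103, "A", "T", "SNP"),
             ("1", 250, "A", "T", "SNP")]
        )
        kept, removed = apply_variant_filters(v)
        assert list(kept.pos) == [250]
        assert sorted(removed.pos) == [100, 103]
        assert all(removed.rule == "snp-cluster")

    def test_snp_near_indel_removes_snp_only(self):
        v = variants_table(
            [("1", 500, "A", "T", "SNP"), ("1", 503, "A", "AT", "indel")]
        )
        kept, removed = apply_variant_filters(v)
        assert list(kept.vtype) == ["indel"]
        assert list(removed.rule) == ["near-indel"]

    @pytest.mark.parametrize(
        "gap,both_removed", [(9, True), (10, False)]
    )
    def test_adjacent_indels_strict_inequality(self, gap, both_removed):
        v = variants_table(
            [("1", 700, "A", "AT", "indel"), ("1", 700 + gap, "A", "AT", "indel")]
        )
        kept, removed = apply_variant_filters(v)
        assert (len(kept) == 0) == both_removed

    def test_snp_pair_at_exactly_5bp_removed(self):
        v = variants_table(
            [("1", 100, "A", "T", "SNP"), ("1", 105, "A", "T", "SNP")]
        )
        kept, _ = apply_variant_filters(v)
        assert kept.empty

    def test_snp_pair_at_6bp_kept(self):
        v = variants_table(
            [("1", 100, "A", "T", "SNP"), ("1", 106, "A", "T", "SNP")]
        )
        kept, _ = apply_variant_filters(v)
        assert len(kept) == 2

    def test_rules_apply_to_original_set_and_idempotent(self):
        # chain 100,105,110: middle removal must not rescue the ends
        v = variants_table(
            [("1", 100, "A", "T", "SNP"), ("1", 105, "A", "T", "SNP"),
             ("1", 110, "A", "T", "SNP")]
        )
        kept, removed = apply_variant_filters(v)
        assert kept.empty and len(removed) == 3
        kept2, removed2 = apply_variant_filters(kept)
        assert kept2.empty and removed2.empty

    def test_chromosomes_independent(self):
        v = variants_table(
            [("1", 100, "A", "T", "SNP"), ("2", 103, "A", "T", "SNP")]
        ).sort_values(["chrom", "pos"]).reset_index(drop=True)
        kept, _ = apply_variant_filters(v)
        assert len(kept) == 2

    def test_unsorted_rejected(self):
        v = variants_table(
            [("1", 200, "A", "T", "SNP"), ("1", 100, "A", "T", "SNP")]
        )
        with pytest.raises(ValueError, match="sorted"):
            apply_variant_filters(v)


class TestMafFilter:
    def test_examples(self):
        n = 80
        rare = np.zeros(n)
        rare[0] = 2  # alt count 2 of 160 alleles: MAF 0.0125
        boundary = np.zeros(n)
        boundary[:4] = 2  # MAF exactly 0.05
        mono = np.zeros(n)
        common = np.tile([0, 1, 2, 1], n // 4)
        g = GenotypeMatrix(np.column_stack([rare, boundary, mono, common]),
                           [f"S{i}" for i in range(n)])
        out, _, keep = maf_filter(g)
        np.testing.assert_array_equal(keep, [False, True, False, True])

    def test_missing_ignored_in_maf(self):
        col = np.array([0.0, 2.0, np.nan, np.nan])
        maf = minor_allele_frequency(col[:, None])
        assert maf[0] == pytest.approx(0.5)

    def test_all_missing_marker_dropped(self):
        g = GenotypeMatrix(np.full((4, 1), np.nan), list("abcd"))
        out, _, keep = maf_filter(g)
        assert not keep[0]


class TestKinship:
    def test_duplicated_individual_attains_max_offdiag(self, rng):
        x = rng.binomial(2, 0.4, size=(12, 300)).astype(float)
        x[5] = x[2]
        K = kinship(GenotypeMatrix(x, [f"S{i}" for i in range(12)])).to_numpy()
        off = K - np.diag(np.diag(K))
        assert off.max() == pytest.approx(K[2, 5])

    def test_identical_samples_match_diagonal(self, rng):
        x = rng.binomial(2, 0.5, size=(8, 200)).astype(float)
        x[1] = x[0]
        K = kinship(GenotypeMatrix(x, [f"S{i}" for i in range(8)])).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_structure_recovery(self):
        cfg = SimulationConfig(n_samples=60, n_snps=800, k_subpops=3, fst=0.25, seed=8)
        g, _, lab = simulate_population(cfg)
        K = kinship(g).to_numpy()
        within, between = [], []
        for i in range(60):
            for j in range(i + 1, 60):
                (within if lab[i] == lab[j] else between).append(K[i, j])
        assert np.mean(within) > np.mean(between)

    def test_symmetry_and_estimator_tag(self, rng):
        x = rng.binomial(2, 0.3, size=(10, 100)).astype(float)
        K = kinship(GenotypeMatrix(x, [f"S{i}" for i in range(10)]))
        assert K.attrs["estimator"] == "vanraden"
        np.testing.assert_allclose(K.to_numpy(), K.to_numpy().T, atol=1e-12)


class TestPca:
    def test_two_subpop_separation(self):
        cfg = SimulationConfig(n_samples=80, n_snps=600, k_subpops=2, fst=0.3, seed=9)
        g, _, lab = simulate_population(cfg)
        pc1 = pca_covariates(g, 2).PC1.to_numpy()
        # point-biserial R^2 between PC1 and the subpop label
        r = np.corrcoef(pc1, lab)[0, 1]
        assert r * r > 0.8

    def test_permutation_equivariance_and_orthogonality(self, rng):
        cfg = SimulationConfig(n_samples=30, n_snps=300, seed=10)
        g, _, _ = simulate_population(cfg)
        q = pca_covariates(g, 3)
        perm = rng.permutation(30)
        gp = GenotypeMatrix(g.dosages[perm], [g.samples[i] for i in perm])
        qp = pca_covariates(gp, 3)
        np.testing.assert_allclose(
            qp.to_numpy(), q.to_numpy()[perm], atol=1e-8
        )
        gram = q.to_numpy().T @ q.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_q_bound(self):
        cfg = SimulationConfig(n_samples=10, n_snps=50, seed=0)
        g, _, _ = simulate_population(cfg)
        with pytest.raises(ValueError):
            pca_covariates(g, 10)


class TestLdProfile:
    def test_duplicated_marker_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.5, size=20).astype(float)
        x = np.column_stack([col, col])
        v = variants_table([("1", 100, "A", "T", "SNP"), ("1", 200, "A", "T", "SNP")])
        prof = ld_profile(GenotypeMatrix(x, [f"S{i}" for i in range(20)]), v)
        assert prof.pairs.r2.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_markers_null_level(self):
        rng = np.random.default_rng(1)
        n, m = 50, 200
        x = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        v = variants_table(
            [("1", (j + 1) * 100, "A", "T", "SNP") for j in range(m)]
        )
        prof = ld_profile(GenotypeMatrix(x, [f"S{i}" for i in range(n)]), v)
        # E[r^2] for independent markers is about 1/(n-1)
        assert prof.pairs.r2.mean() == pytest.approx(1 / (n - 1), rel=0.3)

    def test_planted_ld50_recovery(self):
        g, v = simulate_ld_population(
            n_samples=150, n_snps=400, spacing_bp=2000, ld50_bp=60_000, seed=2
        )
        prof = ld_profile(g, v, window_bp=400_000, bin_bp=2000)
        assert prof.ld50_bp == pytest.approx(60_000, rel=0.25)

    def test_window_respected(self):
        g, v = simulate_ld_population(n_samples=30, n_snps=50, spacing_bp=2000, seed=0)
        prof = ld_profile(g, v, window_bp=10_000)
        assert prof.pairs.distance_bp.max() <= 10_000


class TestNjTree:
    @staticmethod
    def _block_genotypes(blocks, m=100):
        """Taxa distinguished by disjoint marker blocks -> additive p-distances."""
        taxa = sorted({t for members, _ in blocks for t in members})
        x = {t: np.zeros(m) for t in taxa}
        cursor = 0
        for members, size in blocks:
            for t in members:
                x[t][cursor : cursor + size] = 1
            cursor += size
        return GenotypeMatrix(np.vstack([x[t] for t in taxa]), taxa)

    def test_four_taxon_additive_recovery(self):
        # branch lengths (in p-distance units): A .10, B .05, internal .20, C .08, D .12
        g = self._block_genotypes(
            [({"A"}, 10), ({"B"}, 5), ({"A", "B"}, 20), ({"C"}, 8), ({"D"}, 12)]
        )
        tree, _ = nj_tree(g)
        tt = tree.tip_tip_distances()
        expected = {
            ("A", "B"): 0.15, ("A", "C"): 0.38, ("A", "D"): 0.42,
            ("B", "C"): 0.33, ("B", "D"): 0.37, ("C", "D"): 0.20,
        }
        for (i, j), d in expected.items():
            assert tt[i, j] == pytest.approx(d, abs=1e-12)

    def test_three_taxon_closed_form(self):
        g = self._block_genotypes([({"A"}, 10), ({"B"}, 5), ({"C"}, 28)])
        tree, _ = nj_tree(g)
        tt = tree.tip_tip_distances()
        # closed form: d(A,B)=0.15, d(A,C)=0.38, d(B,C)=0.33
        assert tt["A", "B"] == pytest.approx(0.15, abs=1e-12)
        assert tt["A", "C"] == pytest.approx(0.38, abs=1e-12)
        assert tt["B", "C"] == pytest.approx(0.33, abs=1e-12)

    def test_identical_samples_zero_branch(self):
        g = self._block_genotypes([({"A"}, 10), ({"C"}, 12)])  # B identical to nothing
        x = np.vstack([g.dosages[0], g.dosages[0], g.dosages[1]])
        gm = GenotypeMatrix(x, ["A1", "A2", "C"])
        tree, _ = nj_tree(gm)
        assert tree.tip_tip_distances()["A1", "A2"] == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_supports_clean_clades(self):
        cfg = SimulationConfig(n_samples=10, n_snps=400, k_subpops=2, fst=0.4, seed=12)
        g, _, lab = simulate_population(cfg)
        tree, supports = nj_tree(
            g, bootstrap_reps=50, rng=np.random.default_rng(0)
        )
        clade = frozenset(np.array(g.samples)[lab == 0])
        other = frozenset(np.array(g.samples)[lab == 1])
        key = min(clade, other, key=lambda s: (len(s), sorted(s)))
        assert key in supports
        assert supports[key] >= 0.95

    def test_p_distance_definition(self):
        x = np.array([[0.0, 1.0, 2.0, np.nan], [0.0, 2.0, 2.0, 1.0], [2.0, 2.0, 0.0, 1.0]])
        dm = p_distance_matrix(GenotypeMatrix(x, ["a", "b", "c"]))
        assert dm["a", "b"] == pytest.approx(1 / 3)  # one mismatch of three shared
        assert dm["b", "c"] == pytest.approx(0.5)
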