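"""Mixed-model scan: REML, OLS reduction, calibration, thresholds, loci."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spec2gwas.gwas_mlm import (
    MixedLMGwas,
    fit_null_mlm,
    locus_intervals,
    qq_diagnostics,
    scan,
    thresholds,
)
from spec2gwas.io_formats import GenotypeMatrix
from spec2gwas.popgen import kinship, pca_covariates
from spec2gwas.synthetic_data import SimulationConfig, simulate_population, simulate_trait


def ols_oracle(y, Q, X):
    """Per-marker OLS of y on [1, Q, x]: effect, se, z and Gaussian p."""
    n = len(y)
    ones = np.ones((n, 1))
    base = ones if Q is None else np.hstack([ones, np.asarray(Q, float)])
    out = []
    for j in range(X.shape[1]):
        D = np.hstack([base, X[:, j : j + 1]])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            out.append((np.nan,) * 4)
            continue
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        r = y - D @ beta
        df = n - D.shape[1]
        s2 = float(r @ r) / df
        cov = s2 * np.linalg.inv(D.T @ D)
        se = np.sqrt(cov[-1, -1])
        z = beta[-1] / se
        out.append((beta[-1], se, z, 2 * stats.norm.sf(abs(z))))
    return np.array(out)


@pytest.fixture(scope="module")
def small_panel():
    cfg = SimulationConfig(n_samples=60, n_snps=120, fst=0.15, seed=21)
    g, v, lab = simulate_population(cfg)
    y, truth = simulate_trait(g, cfg, lab)
    return g, v, y.to_numpy(), truth


class TestNullFit:
    def test_identity_K_flat_profile_detected(self, small_panel):
        g, _, y, _ = small_panel
        fit = fit_null_mlm(y, None, np.eye(len(y)))
        assert not fit.delta_identifiable

    def test_h2_recovery(self):
        cfg = SimulationConfig(
            n_samples=300, n_snps=1500, n_causal=1500, h2=0.5,
            fst=0.5, k_subpops=30, seed=1,
        )
        g, _, lab = simulate_population(cfg)
        y, _ = simulate_trait(g, cfg, lab)
        fit = fit_null_mlm(y.to_numpy(), None, kinship(g))
        assert fit.h2 == pytest.approx(0.5, abs=0.15)

    def test_pure_noise_h2_near_zero(self):
        low = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_samples=150, n_snps=500, h2=0.0,
                                   fst=0.5, k_subpops=15, seed=seed)
            g, _, lab = simulate_population(cfg)
            y, _ = simulate_trait(g, cfg, lab)
            fit = fit_null_mlm(y.to_numpy(), None, kinship(g))
            low += fit.h2 <= 0.1
        assert low / n_seeds >= 0.9

    def test_non_psd_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            fit_null_mlm(np.array([0.1, -0.2]), None, K)


class TestScan:
    def test_identity_K_reduces_to_ols(self, small_panel):
        g, v, y, _ = small_panel
        Q = pca_covariates(g, 3)
        fit = fit_null_mlm(y, Q, np.eye(len(y)))
        res = scan(g, y, Q, fit, variants=v)
        oracle = ols_oracle(y, Q.to_numpy(), g.imputed())
        ok = np.isfinite(oracle[:, 0])
        assert ok.sum() > 100
        np.testing.assert_array_equal(np.isfinite(res.table.p), ok)
        np.testing.assert_allclose(res.table.effect[ok], oracle[ok, 0], atol=1e-10)
        np.testing.assert_allclose(res.table.se[ok], oracle[ok, 1], atol=1e-10)
        np.testing.assert_allclose(res.table.stat[ok], oracle[ok, 2], atol=1e-10)
        np.testing.assert_allclose(res.table.p[ok], oracle[ok, 3], atol=1e-10)

    def test_affine_trait_invariance(self, small_panel):
        g, v, y, _ = small_panel
        K = kinship(g)
        Q = pca_covariates(g, 3)
        res1 = MixedLMGwas(y, g, K, Q=Q, variants=v).fit(call_loci=False)
        res2 = MixedLMGwas(5.0 * y + 3.0, g, K, Q=Q, variants=v).fit(call_loci=False)
        np.testing.assert_allclose(res1.table.p, res2.table.p, atol=1e-5)

    def test_allele_flip_negates_effect_keeps_p(self, small_panel):
        g, v, y, _ = small_panel
        K = kinship(g)
        fit = fit_null_mlm(y, None, K)
        res = scan(g, y, None, fit, variants=v)
        flipped = GenotypeMatrix(g.dosages.copy(), list(g.samples))
        flipped.dosages[:, 0] = 2 - flipped.dosages[:, 0]
        res_f = scan(flipped, y, None, fit, variants=v)
        assert res_f.table.effect.iloc[0] == pytest.approx(-res.table.effect.iloc[0], abs=1e-10)
        assert res_f.table.p.iloc[0] == pytest.approx(res.table.p.iloc[0], abs=1e-12)

    def test_collinear_marker_flagged_missing(self, small_panel):
        g, v, y, _ = small_panel
        gg = GenotypeMatrix(g.dosages.copy(), list(g.samples))
        gg.dosages[:, 5] = 1.0  # constant: collinear with intercept
        fit = fit_null_mlm(y, None, kinship(g))
        res = scan(gg, y, None, fit, variants=v)
        assert np.isnan(res.table.p.iloc[5])

    def test_p3d_and_exact_agree(self):
        """P3D tracks per-marker REML closely for polygenic signals.

        A marker carrying a visible share of the heritability can deviate
        more (the known conservativeness of fixing variance components on
        the null model), so the bound is on the median deviation and on
        the ranking, not on the worst marker.
        """
        cfg = SimulationConfig(n_samples=200, n_snps=60, n_causal=60, h2=0.3, seed=31)
        g, v, lab = simulate_population(cfg)
        y, _ = simulate_trait(g, cfg, lab)
        K = kinship(g)
        m = MixedLMGwas(y, g, K, variants=v)
        p3d = m.fit(mode="p3d", call_loci=False)
        exact = m.fit(mode="exact", call_loci=False)
        keep = p3d.table.p < 0.5
        a = -np.log10(p3d.table.p[keep])
        b = -np.log10(exact.table.p[keep])
        assert np.median(np.abs(a - b) / a) < 0.10
        rho = stats.spearmanr(p3d.table.p, exact.table.p).statistic
        assert rho > 0.99

    def test_duplicated_sample_K_still_scans(self, small_panel):
        g, v, y, _ = small_panel
        x = g.dosages.copy()
        x[1] = x[0]
        y2 = y.copy()
        y2[1] = y2[0]
        gg = GenotypeMatrix(x, list(g.samples))
        res = MixedLMGwas(y2, gg, kinship(gg), variants=v).fit(call_loci=False)
        # collinear/monomorphic markers may be flagged missing; the rest scan fine
        assert np.isfinite(res.table.p).mean() > 0.9


class TestCalibration:
    def test_structured_null_lambda_and_ols_inflation(self):
        rng = np.random.default_rng(5)
        lams, lams_ols = [], []
        for seed in range(4):
            cfg = SimulationConfig(n_samples=200, n_snps=600, fst=0.3, seed=seed)
            g, v, lab = simulate_population(cfg)
            y = rng.normal(size=cfg.k_subpops)[lab] + rng.normal(size=cfg.n_samples)
            Q = pca_covariates(g, 5)
            fit = fit_null_mlm(y, Q, kinship(g))
            lams.append(qq_diagnostics(scan(g, y, Q, fit).table.p)[1])
            fit0 = fit_null_mlm(y, None, np.eye(len(y)))
            lams_ols.append(qq_diagnostics(scan(g, y, None, fit0).table.p)[1])
        assert np.mean(lams_ols) > np.mean(lams)
        assert 0.9 <= np.mean(lams) <= 1.1

    def test_planted_causal_ranks_top(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_samples=300, n_snps=1000, n_causal=1,
                                   h2=0.2, fst=0.2, seed=seed)
            g, v, lab = simulate_population(cfg)
            y, truth = simulate_trait(g, cfg, lab)
            res = MixedLMGwas(
                y, g, kinship(g), Q=pca_covariates(g, 5), variants=v
            ).fit(call_loci=False)
            rank = res.table.p.rank().iloc[truth.causal_indices[0]]
            hits += rank <= 5
        assert hits / n_seeds >= 0.9


class TestThresholds:
    @pytest.mark.parametrize(
        "n,sig,sug",
        [(1_000_000, 1e-8, 1e-7), (1, 0.01, 0.1), (2000, 5e-6, 5e-5)],
    )
    def test_bonferroni_arithmetic(self, n, sig, sug):
        s, g = thresholds(n)
        assert s.p_threshold == pytest.approx(sig)
        assert g.p_threshold == pytest.approx(sug)

    def test_effective_n_overrides(self):
        s, g = thresholds(5000, effective_n=100)
        assert s.n == 100 and s.p_threshold == pytest.approx(1e-4)


class TestLociAndQq:
    @staticmethod
    def _panel_with_block(seed=41):
        rng = np.random.default_rng(seed)
        n = 120
        lead = rng.binomial(2, 0.5, size=n).astype(float)
        cols, pos = [], []
        # LD block: 5 markers highly correlated with the lead around pos 5000
        for k in range(5):
            noisy = lead.copy()
            flip = rng.random(n) < 0.05
            noisy[flip] = rng.binomial(2, 0.5, size=flip.sum())
            cols.append(noisy)
            pos.append(4000 + k * 500)
        # unlinked markers
        for k in range(10):
            cols.append(rng.binomial(2, 0.5, size=n).astype(float))
            pos.append(20_000 + k * 1000)
        order = np.argsort(pos)
        X = np.column_stack(cols)[:, order]
        pos = np.array(pos)[order]
        v = pd.DataFrame(
            {"chrom": "1", "pos": pos, "ref": "A", "alt": "T", "vtype": "SNP"}
        )
        g = GenotypeMatrix(X, [f"S{i}" for i in range(n)])
        y = lead * 1.0 + rng.normal(scale=0.5, size=n)
        return g, v, y

    def test_interval_covers_ld_block(self):
        g, v, y = self._panel_with_block()
        fit = fit_null_mlm(y, None, np.eye(len(y)))
        res = scan(g, y, None, fit, variants=v)
        loci = locus_intervals(res, g, v, r2_min=0.6)
        assert len(loci) == 1
        row = loci.iloc[0]
        assert row.start <= 4000 and row.end >= 6000
        assert row.start >= 4000 - 1  # no unlinked marker swallowed
        assert row.end < 20_000

    def test_lead_without_neighbors_single_position(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.binomial(2, 0.5, size=(n, 6)).astype(float)
        y = x[:, 2] * 1.2 + rng.normal(scale=0.4, size=n)
        v = pd.DataFrame(
            {"chrom": "1", "pos": (np.arange(6) + 1) * 1000,
             "ref": "A", "alt": "T", "vtype": "SNP"}
        )
        g = GenotypeMatrix(x, [f"S{i}" for i in range(n)])
        fit = fit_null_mlm(y, None, np.eye(n))
        res = scan(g, y, None, fit, variants=v)
        loci = locus_intervals(res, g, v, r2_min=0.6)
        assert len(loci) == 1
        assert loci.iloc[0].start == loci.iloc[0].end == 3000

    def test_linked_leads_merge(self):
        g, v, y = self._panel_with_block()
        fit = fit_null_mlm(y, None, np.eye(len(y)))
        res = scan(g, y, None, fit, variants=v)
        loci = locus_intervals(res, g, v, r2_min=0.6)
        sig = res.table[res.table.p <= res.significant_threshold]
        assert len(sig) >= 2       # several block markers are significant
        assert len(loci) == 1      # but they collapse to one locus

    def test_qq_uniform_lambda_one(self, rng):
        p = rng.uniform(size=20_000)
        table, lam = qq_diagnostics(p)
        assert lam == pytest.approx(1.0, abs=0.05)
        assert len(table) == 20_000

    def test_qq_all_ones_lambda_zero(self):
        _, lam = qq_diagnostics(np.ones(50))
        assert lam == 0.0

    def test_summary_mentions_thresholds(self, small_panel):
        g, v, y, _ = small_panel
        res = MixedLMGwas(y, g, kinship(g), variants=v).fit(call_loci=False)
        text = res.summary()
        assert "significant P" in text and "markers tested" in text


class TestLoco:
    def test_loco_boosts_signal_at_causal_marker(self):
        """Excluding the tested chromosome from K removes proximal
        contamination: the causal marker's p-value never worsens much and
        typically strengthens when the trait is strongly genetic."""
        cfg = SimulationConfig(n_samples=80, n_snps=600, n_causal=2, h2=0.7, seed=3)
        g, v, lab = simulate_population(cfg)
        y, truth = simulate_trait(g, cfg, lab)
        m = MixedLMGwas(y, g, kinship(g), Q=pca_covariates(g, 3), variants=v)
        plain = m.fit(call_loci=False)
        loco = m.fit(call_loci=False, loco=True)
        assert loco.mode == "p3d-loco"
        assert len(loco.table) == len(plain.table)
        j = truth.causal_indices[np.argmax(np.abs(truth.causal_effects))]
        assert loco.table.p.iloc[j] <= plain.table.p.iloc[j] * 10

    def test_loco_requires_multiple_chromosomes(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, size=(30, 20)).astype(float)
        g = GenotypeMatrix(x, [f"S{i}" for i in range(30)])
        v = pd.DataFrame({"chrom": "1", "pos": (np.arange(20) + 1) * 1000,
                          "ref": "A", "alt": "T", "vtype": "SNP"})
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="two chromosomes"):
            MixedLMGwas(y, g, kinship(g), variants=v).fit(loco=True)
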