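"""Mixed-model engine: kinship, REML, scans, conditioning, PCA, inflation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from legacygwas import (CausalSpec, KinshipMatrix, SimConfig, compute_kinship,
                        conditional_scan, impute_missing, inflation, pca_structure,
                        qc_filter, scan_binary, scan_quantitative,
                        simulate_genotypes, simulate_trait_binary,
                        simulate_trait_quantitative)
from legacygwas.mixed_model_scan import ScanResult, reml_fit

from conftest import panel_from_dosages


def gls_oracle(panel, y, K, null):
    """Explicit per-marker V-inverse GLS; independent of the scan path."""
    n = len(y)
    V = null.sigma2_g * K + null.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    ps, betas = [], []
    for j in range(panel.n_markers):
        X = np.column_stack([np.ones(n), panel.dosages[:, j]])
        A = X.T @ Vi @ X
        b = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ b
        s2 = (r @ Vi @ r) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(A)[1, 1])
        ps.append(stats.f.sf((b[1] / se) ** 2, 1, n - 2))
        betas.append(b[1])
    return np.array(ps), np.array(betas)


class TestKinship:
    def test_identical_individuals_match_diagonal(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (10, 80)).astype(float)
        d[5] = d[3]  # duplicate individual
        K = compute_kinship(panel_from_dosages(d)).K
        assert abs(K[3, 5] - K[3, 3]) < 1e-12

    def test_order_free_in_markers(self, imputed_panel):
        K1 = compute_kinship(imputed_panel).K
        rng = np.random.default_rng(1)
        perm = rng.permutation(imputed_panel.n_markers)
        shuffled = imputed_panel.subset_markers(np.sort(perm))  # same set
        K2 = compute_kinship(shuffled).K
        np.testing.assert_allclose(K1, K2)

    def test_unrelated_panel_off_diagonal_near_zero(self):
        cfg = SimConfig(n_individuals=100, markers_per_chromosome=500,
                        n_chromosomes=1, switch_rate=1.0, n_founders=50,
                        missing_rate=0.0, seed=2)
        K = compute_kinship(simulate_genotypes(cfg)).K
        off = K[~np.eye(100, dtype=bool)]
        assert abs(off.mean()) < 0.05


class TestRemlFit:
    def test_pure_noise_gives_near_zero_heritability(self, imputed_panel, kinship):
        h2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=imputed_panel.n_varieties)
            fit = reml_fit(y, np.ones((len(y), 1)), kinship.K)
            h2s.append(fit.heritability)
        assert np.median(h2s) < 0.1

    def test_recovers_moderate_heritability(self, kinship):
        lam, U = np.linalg.eigh(kinship.K)
        lam = np.clip(lam, 0, None)
        h2s = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            g = U @ (np.sqrt(lam) * rng.normal(size=len(lam)))
            g /= g.std()
            e = rng.normal(size=len(g))
            e /= e.std()
            y = np.sqrt(0.5) * g + np.sqrt(0.5) * e
            fit = reml_fit(y, np.ones((len(y), 1)), kinship.K)
            h2s.append(fit.heritability)
        assert abs(np.median(h2s) - 0.5) < 0.15

    def test_refit_reproduces_loglik(self, imputed_panel, kinship):
        rng = np.random.default_rng(0)
        y = rng.normal(size=imputed_panel.n_varieties)
        f1 = reml_fit(y, np.ones((len(y), 1)), kinship.K)
        f2 = reml_fit(y, np.ones((len(y), 1)), kinship.K)
        assert abs(f1.loglik_reml - f2.loglik_reml) < 1e-8

    def test_duplicating_individuals_with_fresh_noise_preserves_ratio(self, kinship):
        # duplicated genetic values with independent residual draws leave the
        # variance-ratio estimate near the original (carrying the residuals
        # over verbatim would instead force the ratio to 1, as duplicated
        # totals can only be explained genetically)
        rng = np.random.default_rng(5)
        n = len(kinship.varieties)
        lam, U = np.linalg.eigh(kinship.K)
        g = U @ (np.sqrt(np.clip(lam, 0, None)) * rng.normal(size=n))
        g = g / g.std()
        y1 = g + rng.normal(size=n)
        fit1 = reml_fit(y1, np.ones((n, 1)), kinship.K)
        idx = np.concatenate([np.arange(n), np.arange(n)])
        K2 = kinship.K[np.ix_(idx, idx)]
        y2 = g[idx] + rng.normal(size=2 * n)
        fit2 = reml_fit(y2, np.ones((2 * n, 1)), K2)
        assert abs(fit1.heritability - 0.5) < 0.25
        assert abs(fit2.heritability - 0.5) < 0.25


class TestScanQuantitative:
    def test_identity_kinship_reduces_to_ols(self, imputed_panel):
        rng = np.random.default_rng(1)
        n = imputed_panel.n_varieties
        y = pd.Series(rng.normal(size=n), index=imputed_panel.varieties)
        K = KinshipMatrix(list(imputed_panel.varieties), np.eye(n))
        scan = scan_quantitative(imputed_panel, y, K)
        yv = y.to_numpy()
        for j in [0, 7, 31]:
            x = imputed_panel.dosages[:, j]
            X = np.column_stack([np.ones(n), x])
            b, *_ = np.linalg.lstsq(X, yv, rcond=None)
            r = yv - X @ b
            s2 = (r @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            p_ols = stats.f.sf((b[1] / se) ** 2, 1, n - 2)
            assert abs(scan.df["p"].iloc[j] - p_ols) < 1e-8

    def test_matches_explicit_inverse_oracle(self):
        cfg = SimConfig(n_individuals=100, markers_per_chromosome=25,
                        n_chromosomes=2, missing_rate=0.0, seed=11)
        panel = qc_filter(simulate_genotypes(cfg))
        kin = compute_kinship(panel)
        mid = str(panel.markers["id"].iloc[5])
        trait, _ = simulate_trait_quantitative(panel, [CausalSpec(mid, 1.0, "t")],
                                               0.4, seed=2)
        y = trait.per_variety_values("t")
        scan = scan_quantitative(panel, y, kin)
        null = reml_fit(y.loc[panel.varieties].to_numpy(),
                        np.ones((100, 1)), kin.K)
        p_or, b_or = gls_oracle(panel, y.loc[panel.varieties].to_numpy(),
                                kin.K, null)
        ok = scan.df["excluded_reason"] == ""
        rel = np.abs(scan.df.loc[ok, "p"].to_numpy() - p_or[ok]) / p_or[ok]
        assert rel.max() < 1e-6

    def test_noiseless_monogenic_trait_top_hit_is_causal(self, imputed_panel, kinship):
        mid = str(imputed_panel.markers["id"].iloc[40])
        trait, _ = simulate_trait_quantitative(imputed_panel,
                                               [CausalSpec(mid, 1.0, "t")],
                                               1.0, seed=0)
        scan = scan_quantitative(imputed_panel, trait.per_variety_values("t"),
                                 kinship)
        top = str(scan.top_marker()["id"])
        x_causal = imputed_panel.dosages[:, imputed_panel.marker_index(mid)]
        x_top = imputed_panel.dosages[:, imputed_panel.marker_index(top)]
        r = np.corrcoef(x_causal, x_top)[0, 1]
        assert top == mid or abs(r) > 1 - 1e-10  # causal or a perfect proxy

    def test_affine_invariance_of_pvalues(self, imputed_panel, kinship):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        p1 = scan_quantitative(imputed_panel, y, kinship).df["p"]
        p2 = scan_quantitative(imputed_panel, 3.0 * y + 7.0, kinship).df["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_permutation_invariance(self, imputed_panel, kinship):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        p1 = scan_quantitative(imputed_panel, y, kinship).df["p"]
        perm = rng.permutation(imputed_panel.n_varieties)
        names = [imputed_panel.varieties[i] for i in perm]
        shuffled = imputed_panel.subset_varieties(names)
        p2 = scan_quantitative(shuffled, y, kinship).df["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_exact_per_marker_reml_close_to_p3d(self):
        # at genome scale no single marker dominates K, so re-estimating
        # variance components per marker barely moves the p-values
        cfg = SimConfig(n_individuals=80, markers_per_chromosome=200,
                        n_chromosomes=1, missing_rate=0.0, seed=4)
        panel = qc_filter(simulate_genotypes(cfg))
        kin = compute_kinship(panel)
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=panel.n_varieties), index=panel.varieties)
        mlp_p3d = scan_quantitative(panel, y, kin, p3d=True).df["minus_log10_p"]
        mlp_full = scan_quantitative(panel, y, kin, p3d=False).df["minus_log10_p"]
        assert np.nanmax(np.abs(mlp_p3d - mlp_full)) < 0.3


class TestScanBinary:
    def test_power_on_liability_trait(self):
        hits = 0
        for seed in range(5):
            cfg = SimConfig(n_individuals=500, markers_per_chromosome=150,
                            n_chromosomes=2, missing_rate=0.0, seed=700 + seed)
            panel = qc_filter(simulate_genotypes(cfg))
            kin = compute_kinship(panel)
            mid = str(panel.markers["id"].iloc[75])
            try:
                trait, _ = simulate_trait_binary(panel, [CausalSpec(mid, 1.0, "t")],
                                                 0.6, prevalence=0.4, seed=seed)
            except ValueError:
                continue
            scan = scan_binary(panel, trait.per_variety_values("t"), kin)
            top = str(scan.top_marker()["id"])
            top_pos = int(scan.top_marker()["pos"])
            causal_pos = int(panel.markers.at[panel.marker_index(mid), "pos"])
            if top == mid or abs(top_pos - causal_pos) < 2_000_000:
                hits += 1
        assert hits >= 4

    def test_rejects_non_binary_values(self, imputed_panel, kinship):
        y = pd.Series(np.linspace(0, 2, imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        with pytest.raises(ValueError, match="0/1"):
            scan_binary(imputed_panel, y, kinship)

    def test_rejects_single_class(self, imputed_panel, kinship):
        y = pd.Series(np.ones(imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        with pytest.raises(ValueError, match="class"):
            scan_binary(imputed_panel, y, kinship)


class TestConditionalScan:
    def test_conditioning_on_causal_absorbs_region(self, imputed_panel, kinship):
        mid = str(imputed_panel.markers["id"].iloc[30])
        trait, _ = simulate_trait_quantitative(imputed_panel,
                                               [CausalSpec(mid, 1.0, "t")],
                                               1.0, seed=0)
        y = trait.per_variety_values("t")
        scan = conditional_scan(imputed_panel, y, kinship, [mid])
        pos = int(imputed_panel.markers.at[imputed_panel.marker_index(mid), "pos"])
        chrom = imputed_panel.markers.at[imputed_panel.marker_index(mid), "chrom"]
        region = scan.df[(scan.df["chrom"] == chrom)
                         & (scan.df["pos"].between(pos - 2_000_000, pos + 2_000_000))
                         & (scan.df["excluded_reason"] == "")]
        # an empty frame means every region marker was a perfect proxy:
        # conditioning absorbed the signal entirely
        assert region.empty or region["minus_log10_p"].max() < 2.0

    def test_conditioning_marker_excluded_with_reason(self, imputed_panel, kinship):
        mid = str(imputed_panel.markers["id"].iloc[30])
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        scan = conditional_scan(imputed_panel, y, kinship, [mid])
        row = scan.df[scan.df["id"] == mid].iloc[0]
        assert row["excluded_reason"] == "conditioning/proxy"
        assert np.isnan(row["p"])

    def test_conditioning_on_other_chromosome_barely_moves_peak(self, imputed_panel,
                                                                kinship):
        causal = str(imputed_panel.markers["id"].iloc[20])  # chr1
        other_chrom = imputed_panel.markers[imputed_panel.markers["chrom"] == "chr2"]
        far = str(other_chrom["id"].iloc[len(other_chrom) // 2])
        trait, _ = simulate_trait_quantitative(imputed_panel,
                                               [CausalSpec(causal, 1.0, "t")],
                                               0.5, seed=3)
        y = trait.per_variety_values("t")
        base = scan_quantitative(imputed_panel, y, kinship)
        cond = conditional_scan(imputed_panel, y, kinship, [far])
        m1 = float(base.df.loc[base.df["id"] == causal, "minus_log10_p"].iloc[0])
        m2 = float(cond.df.loc[cond.df["id"] == causal, "minus_log10_p"].iloc[0])
        assert abs(m1 - m2) < 1.0

    def test_unknown_conditioning_marker_rejected(self, imputed_panel, kinship):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=imputed_panel.n_varieties),
                      index=imputed_panel.varieties)
        with pytest.raises(KeyError, match="not shared"):
            conditional_scan(imputed_panel, y, kinship, ["nonexistent"])


class TestPcaStructure:
    def test_two_founder_pools_separate_on_pc1(self):
        c1 = SimConfig(n_individuals=60, markers_per_chromosome=200,
                       n_chromosomes=1, n_founders=4, missing_rate=0.0, seed=1)
        c2 = SimConfig(n_individuals=60, markers_per_chromosome=200,
                       n_chromosomes=1, n_founders=4, missing_rate=0.0, seed=99)
        a, b = simulate_genotypes(c1), simulate_genotypes(c2)
        merged = panel_from_dosages(np.vstack([a.dosages, b.dosages]))
        scores, frac = pca_structure(merged, 2)
        g1, g2 = scores[:60, 0], scores[60:, 0]
        assert (g1.max() < g2.min()) or (g2.max() < g1.min())

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (20, 50)).astype(float)
        d[4] = d[9]
        scores, _ = pca_structure(panel_from_dosages(d), 3)
        np.testing.assert_allclose(scores[4], scores[9], atol=1e-10)

    def test_variance_fractions_non_increasing(self, imputed_panel):
        _, frac = pca_structure(imputed_panel, 5)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self):
        panel = panel_from_dosages(np.random.default_rng(0)
                                   .integers(0, 3, (5, 10)).astype(float))
        with pytest.raises(ValueError):
            pca_structure(panel, 6)


class TestInflation:
    @staticmethod
    def _scan_from_pvals(p):
        df = pd.DataFrame({
            "id": [f"m{i}" for i in range(len(p))], "chrom": "chr1",
            "pos": np.arange(1, len(p) + 1) * 1000,
            "beta": 0.0, "se": 1.0, "stat": 0.0, "p": p,
            "minus_log10_p": -np.log10(p), "n_used": 100,
            "excluded_reason": "",
        })
        return ScanResult(df=df, n_used=100, method="synthetic")

    def test_uniform_pvalues_give_lambda_near_one(self):
        rng = np.random.default_rng(0)
        lam, qq = inflation(self._scan_from_pvals(rng.uniform(size=5000)))
        assert 0.9 < lam < 1.1
        assert {"expected", "observed"} <= set(qq.columns)

    def test_inflated_pvalues_detected(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=5000) ** 2
        lam, _ = inflation(self._scan_from_pvals(p))
        assert lam > 1.2

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="100"):
            inflation(self._scan_from_pvals(np.full(50, 0.5)))
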