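"""Genotype QC, structure, LD utilities and scan calibration/power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import pleionet as pn
from pleionet.assoc_scan import _mlm_scan, _ols_scan
from pleionet.containers import GenotypeMatrix, ParameterError
from tests.conftest import line_values_table, single_env_phenotypes


def _toy_geno(dosages, positions=None, chroms=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 1000
    chroms = chroms if chroms is not None else ["1"] * m
    snps = pd.DataFrame({"chrom": chroms, "pos": positions,
                         "id": [f"s{j}" for j in range(m)],
                         "ref": "A", "alt": "T"})
    return GenotypeMatrix(dosages=dosages, lines=[f"L{i}" for i in range(n)], snps=snps)


class TestQC:
    def test_planted_failures_removed(self):
        rng = np.random.default_rng(0)
        X = rng.choice([0.0, 2.0], size=(40, 10), p=[0.5, 0.5])
        X[:, 3] = 0.0                      # monomorphic -> MAF 0
        X[: int(0.25 * 40), 5] = np.nan    # 25% missing
        X[:, 7] = 0.0
        X[:3, 7] = 2.0                     # MAF 3/40 = 0.075 >= 0.05: kept
        X[:1, 8] = np.nan                  # 2.5% missing: kept
        X[:, 9] = 0.0
        X[0, 9] = 2.0                      # MAF 0.0125 < 0.05: removed
        g = _toy_geno(X)
        filtered, report = pn.qc_genotypes(g)
        kept_ids = set(filtered.snps["id"])
        assert "s3" not in kept_ids and "s5" not in kept_ids and "s9" not in kept_ids
        assert {"s7", "s8"} <= kept_ids
        assert report.n_removed_missing == 1
        assert report.n_removed_maf == 2
        assert report.n_kept + report.n_removed_missing + report.n_removed_maf == 10

    def test_all_removed_is_error(self):
        g = _toy_geno(np.zeros((10, 3)))
        with pytest.raises(ParameterError):
            pn.qc_genotypes(g)


class TestPCA:
    def test_shapes_and_ordering(self, structured_panel):
        scores, frac = pn.pca(structured_panel, k=11)
        assert scores.shape == (structured_panel.n_lines, 11)
        assert len(frac) == 11
        assert np.all(np.diff(frac) <= 1e-12) and frac.sum() <= 1.0 + 1e-9

    def test_duplicated_lines_get_identical_scores(self, small_panel):
        g = small_panel
        dup = g.subset_lines(np.r_[np.arange(g.n_lines), 0])
        scores, _ = pn.pca(dup, k=3)
        assert np.allclose(scores[0], scores[-1], atol=1e-8)

    def test_pc1_separates_two_subpopulations(self):
        spec = pn.PanelSpec(n_lines=300, n_snps=800, n_chromosomes=2,
                            n_blocks_per_chrom=40, n_subpops=2, fst=0.15,
                            seed=13, admixture=0.0)
        g = pn.simulate_genotypes(spec)
        scores, _ = pn.pca(g, k=2)
        r = np.corrcoef(scores[:, 0], (g.subpop == 1).astype(float))[0, 1]
        assert abs(r) > 0.9

    def test_invalid_k(self, small_panel):
        with pytest.raises(ParameterError):
            pn.pca(small_panel, k=0)


class TestKinship:
    def test_symmetric_psd_and_identical_lines(self, small_panel):
        g = small_panel
        dup = g.subset_lines(np.r_[np.arange(g.n_lines), 0])
        K = pn.kinship(dup)
        assert np.allclose(K, K.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-8
        # duplicated line: off-diagonal equals the shared diagonal
        assert K[0, -1] == pytest.approx(K[0, 0], abs=1e-10)

    def test_within_subpop_relatedness_exceeds_between(self, structured_panel):
        K = pn.kinship(structured_panel)
        sp = structured_panel.subpop
        same = (sp[:, None] == sp[None, :]) & ~np.eye(len(sp), dtype=bool)
        diff = ~(sp[:, None] == sp[None, :])
        assert K[same].mean() > K[diff].mean()


class TestLD:
    def test_identical_and_hand_computed(self):
        x = np.array([0, 0, 2, 2, 0, 2], dtype=float)
        y = np.array([0, 2, 2, 2, 0, 0], dtype=float)
        g = _toy_geno(np.column_stack([x, x, y]))
        assert pn.ld_r2(g, 0, 1) == pytest.approx(1.0)
        manual = np.corrcoef(x, y)[0, 1] ** 2
        assert pn.ld_r2(g, 0, 2) == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        g = _toy_geno(np.column_stack([np.zeros(6), np.r_[np.zeros(3), 2 * np.ones(3)]]))
        with pytest.raises(ParameterError):
            pn.ld_r2(g, 0, 1)

    def test_null_r2_mean_near_one_over_n(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.choice([0.0, 2.0], size=(n, 300))
        g = _toy_geno(X)
        r2 = pn.ld_matrix(g)
        off = r2[np.triu_indices(300, k=1)]
        assert np.nanmean(off) == pytest.approx(1.0 / n, rel=0.15)

    def test_decay_curve_monotone_and_bounded(self, small_panel):
        curve = pn.ld_decay(small_panel, max_dist=600_000, bin_width=50_000)
        assert curve["bin_end"].max() <= 600_000
        means = curve["mean_r2"].dropna()
        rho = ss.spearmanr(np.arange(len(means)), means).statistic
        assert rho <= 0
        # empty bins are NaN, not zero
        assert curve.loc[curve["n_pairs"] == 0, "mean_r2"].isna().all()

    def test_single_snp_curve_empty(self):
        g = _toy_geno(np.array([[0.0], [2.0], [0.0], [2.0]]))
        curve = pn.ld_decay(g)
        assert curve["n_pairs"].sum() == 0

    def test_per_subgroup_mode(self, structured_panel):
        curves = pn.ld_decay_by_subgroup(structured_panel, max_dist=400_000,
                                         bin_width=100_000)
        assert set(curves) == set(np.unique(structured_panel.subpop))


class TestScan:
    def test_ols_matches_statsmodels(self, small_panel):
        """Closed-form vectorized scan equals a reference per-SNP OLS fit."""
        import statsmodels.api as sm
        g = small_panel
        rng = np.random.default_rng(8)
        y = rng.standard_normal(g.n_lines) + 0.2 * g.dosages[:, 5]
        scores, _ = pn.pca(g, k=3)
        blup = line_values_table(g, y)
        stats = pn.gwas_scan(g, blup, "T", covariates=scores, model="ols")
        for j in [0, 5, 17, 200]:
            X = sm.add_constant(np.column_stack([scores, g.dosages[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert stats["BETA"].iloc[j] == pytest.approx(fit.params[-1], abs=1e-10)
            assert stats["SE"].iloc[j] == pytest.approx(fit.bse[-1], abs=1e-10)
            assert stats["P"].iloc[j] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_mlm_reduces_to_ols_for_identity_kinship(self, small_panel):
        """With K = I the variance structure is iid, so GLS equals OLS."""
        g = small_panel
        rng = np.random.default_rng(9)
        y = rng.standard_normal(g.n_lines)
        blup = line_values_table(g, y)
        sub = g.subset_snps(np.arange(50))
        ols = pn.gwas_scan(sub, blup, "T", model="ols")
        mlm = pn.gwas_scan(sub, blup, "T", model="mlm", K=np.eye(g.n_lines))
        assert np.nanmax(np.abs(ols["BETA"] - mlm["BETA"])) <= 1e-8

    def test_null_scan_calibrated(self):
        """Null trait on low-LD SNPs: uniform p, nominal type-I, lambda in band."""
        lams, pvals = [], []
        for seed in range(5):
            spec = pn.PanelSpec(n_lines=400, n_snps=1000, n_chromosomes=4,
                                n_blocks_per_chrom=250, n_subpops=4, fst=0.1,
                                seed=500 + seed)
            g = pn.simulate_genotypes(spec)
            rng = np.random.default_rng(600 + seed)
            blup = line_values_table(g, rng.standard_normal(g.n_lines))
            scores, _ = pn.pca(g, 11)
            stats = pn.gwas_scan(g, blup, "T", covariates=scores)
            lams.append(pn.genomic_lambda(stats))
            pvals.append(stats["P"].to_numpy())
        pv = np.concatenate(pvals)
        assert ss.kstest(pv, "uniform").pvalue > 0.01
        assert 0.9 < np.mean(lams) < 1.1
        t1 = (pv < 0.01).mean()
        lo, hi = ss.binom.interval(0.95, len(pv), 0.01)
        assert lo / len(pv) <= t1 <= hi / len(pv)

    def test_planted_snp_power(self):
        """5%-of-plot-variance causal SNP at n=500 found in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = pn.PanelSpec(n_lines=500, n_snps=600, n_chromosomes=2,
                                n_blocks_per_chrom=30, n_subpops=2, fst=0.05,
                                seed=700 + seed)
            g = pn.simulate_genotypes(spec)
            arch = pn.TraitArchitecture(trait_names=["T"], n_causal=30,
                                        h2_target=0.7, gxe_fraction=0.2,
                                        n_envs=3, n_reps=2)
            vs = 0.05 * arch.plot_variance("T")
            arch.shared_regions = [pn.SharedRegion(
                snp_indices=np.array([123]), traits=["T"],
                effect_corr=np.eye(1), var_share=vs)]
            raw = pn.simulate_phenotypes(g, arch, seed=800 + seed)
            _, blup = pn.blup_all_traits(raw)
            scores, _ = pn.pca(g, 5)
            stats = pn.gwas_scan(g, blup, "T", covariates=scores)
            hits += stats["P"].iloc[123] < pn.SIGNIFICANCE_THRESHOLD
        assert hits / n_seeds >= 0.9

    def test_permutation_destroys_signal(self, small_panel):
        g = small_panel
        rng = np.random.default_rng(11)
        y = g.dosages[:, 10] * 0.8 + rng.standard_normal(g.n_lines) * 0.3
        blup = line_values_table(g, y)
        stats = pn.gwas_scan(g, blup, "T")
        assert stats["P"].iloc[10] < 1e-10
        perm = line_values_table(g, rng.permutation(y))
        stats_p = pn.gwas_scan(g, perm, "T")
        assert stats_p["P"].min() > pn.SIGNIFICANCE_THRESHOLD / 100

    def test_z_consistent_with_beta_se(self, small_panel):
        rng = np.random.default_rng(12)
        blup = line_values_table(small_panel, rng.standard_normal(small_panel.n_lines))
        stats = pn.gwas_scan(small_panel, blup, "T")
        assert np.nanmax(np.abs(stats["Z"] - stats["BETA"] / stats["SE"])) < 1e-10
        assert (stats["SE"].dropna() > 0).all()

    def test_mismatched_lines_rejected(self, small_panel):
        blup = pn.BLUPTable(values=pd.DataFrame({"T": [1.0, 2.0]},
                                                index=["X1", "X2"]))
        with pytest.raises(ParameterError):
            pn.gwas_scan(small_panel, blup, "T")


class TestSignificance:
    def test_strict_threshold_boundary(self):
        stats = pd.DataFrame({
            "CHR": "1", "POS": [1, 2, 3], "ID": ["a", "b", "c"],
            "A1": "T", "A2": "A", "MAF": 0.2,
            "BETA": 1.0, "SE": 1.0, "Z": 1.0,
            "P": [5.61e-6, 5.60e-6, 1e-8], "N": 100})
        sig = pn.significant_snps(stats, threshold=5.61e-6)
        assert sig["ID"].tolist() == ["c", "b"]  # sorted by p; boundary excluded

    def test_empty_when_nothing_significant(self):
        stats = pd.DataFrame({
            "CHR": "1", "POS": [1], "ID": ["a"], "A1": "T", "A2": "A",
            "MAF": 0.2, "BETA": 1.0, "SE": 1.0, "Z": 1.0, "P": [0.5], "N": 100})
        assert pn.significant_snps(stats).empty


class TestPVE:
    def test_zero_beta_and_bounds(self):
        stats = pd.DataFrame({"MAF": [0.3, 0.5], "BETA": [0.0, 100.0]})
        pve = pn.snp_pve(stats, trait_variance=1.0)
        assert pve.iloc[0] == 0.0
        assert ((pve >= 0) & (pve <= 100)).all()

    def test_planted_five_percent_recovered(self):
        """Single causal SNP explaining 5% of variance: mean PVE ~ 5%."""
        ests = []
        for seed in range(10):
            spec = pn.PanelSpec(n_lines=500, n_snps=400, n_chromosomes=2,
                                n_blocks_per_chrom=200, n_subpops=1, fst=0.0,
                                seed=900 + seed)
            g = pn.simulate_genotypes(spec)
            rng = np.random.default_rng(1000 + seed)
            x = g.dosages[:, 50]
            beta = np.sqrt(0.05 / x.var())
            y = x * beta + rng.standard_normal(g.n_lines) * np.sqrt(0.95)
            blup = line_values_table(g, y)
            stats = pn.gwas_scan(g, blup, "T")
            ests.append(pn.snp_pve(stats, float(np.var(y, ddof=1))).iloc[50])
        assert np.mean(ests) == pytest.approx(5.0, abs=1.5)

    def test_invalid_variance_rejected(self):
        stats = pd.DataFrame({"MAF": [0.3], "BETA": [1.0]})
        with pytest.raises(ParameterError):
            pn.snp_pve(stats, trait_variance=0.0)


def test_pve_summary_layout(small_panel):
    rng = np.random.default_rng(2)
    y = small_panel.dosages[:, 3] * 1.0 + rng.standard_normal(small_panel.n_lines) * 0.5
    blup = line_values_table(small_panel, y)
    stats = pn.gwas_scan(small_panel, blup, "T")
    out = pn.pve_summary({"T": stats}, {"T": float(np.var(y, ddof=1))})
    assert {"n_snps", "mean_pve", "min_pve", "median_pve", "max_pve"} <= set(out.columns)
    assert out.loc["T", "n_snps"] >= 1
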