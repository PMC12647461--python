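"""LD scores, LD-score regression, and the multi-trait joint estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import pleionet as pn
from pleionet.containers import GenotypeMatrix, ParameterError
from pleionet.multi_trait import _harmonize
from tests.conftest import single_env_phenotypes


def make_stats(ids, z, N=500.0, a1="T", a2="A", p_from="normal"):
    z = np.asarray(z, dtype=float)
    se = np.full(len(z), 1.0 / np.sqrt(N))
    p = 2 * ss.norm.sf(np.abs(z))
    return pd.DataFrame({
        "CHR": "1", "POS": np.arange(1, len(z) + 1) * 1000,
        "ID": ids, "A1": a1, "A2": a2, "MAF": 0.3,
        "BETA": z * se, "SE": se, "Z": z, "P": p, "N": N,
    })


def ldsc_table(ids, l, window=1_000_000):
    return pn.LDScoreTable(table=pd.DataFrame({"ID": ids, "L2": l}),
                           M=len(ids), window_bp=window)


class TestLDScores:
    def test_perfect_block_counts_members(self):
        x = np.random.default_rng(0).choice([0.0, 2.0], size=200)
        dos = np.tile(x[:, None], (1, 5))
        snps = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 6) * 100,
                             "id": [f"s{j}" for j in range(5)],
                             "ref": "A", "alt": "T"})
        g = GenotypeMatrix(dosages=dos, lines=[f"L{i}" for i in range(200)], snps=snps)
        lds = pn.ld_scores(g, window_bp=10_000, adjusted=False)
        assert np.allclose(lds.table["L2"], 5.0)

    def test_window_smaller_than_gaps_gives_self_only(self, small_panel):
        lds = pn.ld_scores(small_panel, window_bp=1)
        assert np.allclose(lds.table["L2"], 1.0)

    def test_independent_snps_bias_corrected_near_one(self):
        rng = np.random.default_rng(3)
        n = 300
        dos = rng.choice([0.0, 2.0], size=(n, 400))
        snps = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 401) * 10,
                             "id": [f"s{j}" for j in range(400)],
                             "ref": "A", "alt": "T"})
        g = GenotypeMatrix(dosages=dos, lines=[f"L{i}" for i in range(n)], snps=snps)
        lds = pn.ld_scores(g, window_bp=10_000, adjusted=True)
        assert lds.table["L2"].mean() == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_window_rejected(self, small_panel):
        with pytest.raises(ParameterError):
            pn.ld_scores(small_panel, window_bp=0)


class TestLdscH2:
    def test_null_trait_slope_zero_intercept_one(self):
        rng = np.random.default_rng(4)
        m = 2000
        ids = [f"s{j}" for j in range(m)]
        l = rng.uniform(1, 20, m)
        h2s, iceps = [], []
        for _ in range(5):
            stats = make_stats(ids, rng.standard_normal(m), N=800)
            h2, icept = pn.ldsc_h2(stats, ldsc_table(ids, l))
            h2s.append(h2)
            iceps.append(icept)
        assert abs(np.mean(h2s)) < 0.05
        assert np.mean(iceps) == pytest.approx(1.0, abs=0.05)

    def test_model_scaling_doubles_slope_with_n(self):
        """Z drawn from the LDSC model: doubling N doubles E[chi2]-1 slope."""
        rng = np.random.default_rng(5)
        m, h2 = 3000, 0.4
        ids = [f"s{j}" for j in range(m)]
        l = rng.uniform(1, 30, m)
        est = {}
        for N in (400.0, 800.0):
            mean_chi2 = 1.0 + N * h2 * l / m
            z = rng.standard_normal(m) * np.sqrt(mean_chi2)
            h2_hat, _ = pn.ldsc_h2(make_stats(ids, z, N=N), ldsc_table(ids, l))
            est[N] = h2_hat  # same h2 back at either N if slope scales with N
        assert est[400.0] == pytest.approx(h2, abs=0.15)
        assert est[800.0] == pytest.approx(h2, abs=0.15)

    def test_h2_recovery_from_genotype_simulation(self, structured_panel):
        """Polygenic trait h2 = 0.5: LDSC estimate tracks the target."""
        ests = []
        for seed in range(4):
            corr = np.eye(1)
            arch = pn.TraitArchitecture(trait_names=["T"], n_causal=structured_panel.n_snps,
                                        h2_target=0.5, gxe_fraction=0.0,
                                        n_envs=1, n_reps=1)
            arch.shared_regions = [pn.SharedRegion(
                snp_indices=np.arange(structured_panel.n_snps), traits=["T"],
                effect_corr=corr)]
            _, blup = single_env_phenotypes(structured_panel, arch, seed=60 + seed)
            stats = pn.gwas_scan(structured_panel, blup, "T")
            lds = pn.ld_scores(structured_panel, window_bp=1_000_000)
            h2, _ = pn.ldsc_h2(stats, lds)
            ests.append(h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.2)

    def test_too_few_snps_rejected(self):
        ids = [f"s{j}" for j in range(20)]
        stats = make_stats(ids, np.zeros(20))
        with pytest.raises(ParameterError):
            pn.ldsc_h2(stats, ldsc_table(ids, np.ones(20)))


class TestCrossTrait:
    def test_self_correlation_is_one(self, structured_panel):
        arch = pn.TraitArchitecture(trait_names=["T"], n_causal=structured_panel.n_snps,
                                    h2_target=0.5, gxe_fraction=0.0, n_envs=1, n_reps=1)
        arch.shared_regions = [pn.SharedRegion(
            snp_indices=np.arange(structured_panel.n_snps), traits=["T"],
            effect_corr=np.eye(1))]
        _, blup = single_env_phenotypes(structured_panel, arch, seed=70)
        stats = pn.gwas_scan(structured_panel, blup, "T")
        lds = pn.ld_scores(structured_panel, window_bp=1_000_000)
        fit = pn.cross_trait_ldsc(stats, stats, lds)
        assert fit.r_g == pytest.approx(1.0, abs=0.05)

    def test_allele_flip_harmonized(self):
        ids = [f"s{j}" for j in range(100)]
        s1 = make_stats(ids, np.linspace(-2, 2, 100))
        s2 = s1.copy()
        s2["A1"], s2["A2"] = s1["A2"], s1["A1"]
        s2["Z"] = -s2["Z"]
        s2["BETA"] = -s2["BETA"]
        a1, a2, dropped = _harmonize(s1, s2)
        assert dropped == 0
        assert np.allclose(a1["Z"], a2["Z"])

    def test_unharmonizable_alleles_dropped(self):
        ids = [f"s{j}" for j in range(100)]
        s1 = make_stats(ids, np.zeros(100))
        s2 = make_stats(ids, np.zeros(100), a1="G", a2="C")
        _, _, dropped = _harmonize(s1, s2)
        assert dropped == 100

    def test_overlap_confounding_goes_to_intercept(self):
        """Genetically independent traits on shared samples: intercept > 0,
        r_g near 0."""
        rng = np.random.default_rng(8)
        m, N, rho_p = 3000, 800.0, 0.5
        ids = [f"s{j}" for j in range(m)]
        l = rng.uniform(1, 30, m)
        h2 = 0.4
        rgs, intercepts = [], []
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            # independent genetic signals, correlated sampling noise
            g1 = r2.standard_normal(m) * np.sqrt(N * h2 * l / m)
            g2 = r2.standard_normal(m) * np.sqrt(N * h2 * l / m)
            e = r2.multivariate_normal([0, 0], [[1, rho_p], [rho_p, 1]], size=m)
            s1 = make_stats(ids, g1 + e[:, 0], N=N)
            s2 = make_stats(ids, g2 + e[:, 1], N=N)
            fit = pn.cross_trait_ldsc(s1, s2, ldsc_table(ids, l))
            rgs.append(fit.r_g)
            intercepts.append(fit.intercept)
        assert abs(np.mean(rgs)) < 0.15
        assert np.mean(intercepts) > 0.2


class TestOmegaSigma:
    def test_independent_traits_near_diagonal(self):
        rng = np.random.default_rng(9)
        m, N, h2 = 3000, 800.0, 0.5
        ids = [f"s{j}" for j in range(m)]
        l = rng.uniform(1, 30, m)
        off, diag = [], []
        for seed in range(4):
            r2 = np.random.default_rng(100 + seed)
            z1 = r2.standard_normal(m) * np.sqrt(1 + N * h2 * l / m)
            z2 = r2.standard_normal(m) * np.sqrt(1 + N * h2 * l / m)
            omega, overlap = pn.estimate_omega_sigma(
                [make_stats(ids, z1, N=N), make_stats(ids, z2, N=N)],
                ldsc_table(ids, l))
            off.append(abs(omega[0, 1]))
            diag.append(np.sqrt(omega[0, 0] * omega[1, 1]))
            assert np.min(np.linalg.eigvalsh(omega)) >= -1e-10
        assert np.mean(off) < 0.2 * np.mean(diag)

    def test_disjoint_samples_overlap_near_zero(self):
        rng = np.random.default_rng(10)
        m, N, h2 = 3000, 800.0, 0.5
        ids = [f"s{j}" for j in range(m)]
        l = rng.uniform(1, 30, m)
        vals = []
        for seed in range(5):
            r2 = np.random.default_rng(200 + seed)
            z1 = r2.standard_normal(m) * np.sqrt(1 + N * h2 * l / m)
            z2 = r2.standard_normal(m) * np.sqrt(1 + N * h2 * l / m)
            _, overlap = pn.estimate_omega_sigma(
                [make_stats(ids, z1, N=N), make_stats(ids, z2, N=N)],
                ldsc_table(ids, l))
            vals.append(overlap[0, 1])
        assert abs(np.mean(vals)) < 0.1


class TestMtag:
    def test_single_trait_identity(self):
        ids = [f"s{j}" for j in range(60)]
        stats = make_stats(ids, np.linspace(-3, 3, 60))
        res = pn.mtag([stats], omega=np.array([[0.001]]))
        out = res.tables[res.traits[0]]
        for col in ("BETA", "SE", "Z", "P"):
            assert np.allclose(out[col], stats[col], atol=1e-10)

    def test_diagonal_omega_identity(self):
        ids = [f"s{j}" for j in range(80)]
        rng = np.random.default_rng(11)
        s1 = make_stats(ids, rng.standard_normal(80) * 2, N=400)
        s2 = make_stats(ids, rng.standard_normal(80) * 2, N=900)
        omega = np.diag([0.002, 0.001])
        res = pn.mtag([s1, s2], omega, sigma_overlap=np.eye(2),
                      trait_names=["A", "B"])
        for name, src in (("A", s1), ("B", s2)):
            out = res.tables[name]
            assert np.allclose(out["BETA"], src["BETA"], atol=1e-8)
            assert np.allclose(out["SE"], src["SE"], atol=1e-8)
            assert np.allclose(out["P"], src["P"], atol=1e-8)

    def test_perfect_correlation_equal_se_is_ivw_meta(self):
        """Omega of rank one with equal diagonals: joint Z = (Z1+Z2)/sqrt(2)."""
        ids = [f"s{j}" for j in range(50)]
        rng = np.random.default_rng(12)
        z1 = rng.standard_normal(50) * 2
        z2 = rng.standard_normal(50) * 2
        s1, s2 = make_stats(ids, z1, N=500), make_stats(ids, z2, N=500)
        omega = 0.002 * np.ones((2, 2))
        res = pn.mtag([s1, s2], omega, sigma_overlap=np.eye(2),
                      trait_names=["A", "B"])
        expected = (z1 + z2) / np.sqrt(2)
        assert np.allclose(res.tables["A"]["Z"], expected, atol=1e-10)
        assert np.allclose(res.tables["B"]["Z"], expected, atol=1e-10)

    def test_trait_order_invariance(self):
        ids = [f"s{j}" for j in range(40)]
        rng = np.random.default_rng(13)
        s1 = make_stats(ids, rng.standard_normal(40), N=300)
        s2 = make_stats(ids, rng.standard_normal(40), N=700)
        omega = np.array([[0.002, 0.001], [0.001, 0.003]])
        res_ab = pn.mtag([s1, s2], omega, trait_names=["A", "B"])
        omega_ba = omega[::-1, ::-1]
        res_ba = pn.mtag([s2, s1], omega_ba, trait_names=["B", "A"])
        for name in ("A", "B"):
            assert np.allclose(res_ab.tables[name]["Z"],
                               res_ba.tables[name]["Z"], atol=1e-10)

    def test_allele_flip_equivariance(self):
        ids = [f"s{j}" for j in range(40)]
        rng = np.random.default_rng(14)
        s1 = make_stats(ids, rng.standard_normal(40) * 2)
        s2 = make_stats(ids, rng.standard_normal(40) * 2)
        omega = np.array([[0.002, 0.0015], [0.0015, 0.002]])
        base = pn.mtag([s1, s2], omega, trait_names=["A", "B"])
        flipped = s2.copy()
        flipped["A1"], flipped["A2"] = s2["A2"], s2["A1"]
        flipped["Z"], flipped["BETA"] = -s2["Z"], -s2["BETA"]
        res = pn.mtag([s1, flipped], omega, trait_names=["A", "B"])
        assert np.allclose(res.tables["A"]["P"], base.tables["A"]["P"], atol=1e-10)
        assert np.allclose(res.tables["B"]["P"], base.tables["B"]["P"], atol=1e-10)
        # outputs are reported in the harmonized (reference) orientation, so
        # the effect is identical once the allele columns are accounted for
        out_b = res.tables["B"]
        assert (out_b["A1"] == base.tables["B"]["A1"]).all()
        assert np.allclose(out_b["BETA"], base.tables["B"]["BETA"], atol=1e-10)

    def test_null_calibration_pooled(self):
        """End-to-end null: estimated Omega is near zero and joint p uniform."""
        rng0 = np.random.default_rng(301)
        ids = [f"s{j}" for j in range(1500)]
        l = rng0.uniform(1, 20, 1500)
        pooled = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            s1 = make_stats(ids, rng.standard_normal(1500))
            s2 = make_stats(ids, rng.standard_normal(1500))
            omega, overlap = pn.estimate_omega_sigma([s1, s2], ldsc_table(ids, l))
            res = pn.mtag([s1, s2], omega, overlap, trait_names=["A", "B"])
            pooled.append(res.tables["A"]["P"].to_numpy())
        assert ss.kstest(np.concatenate(pooled), "uniform").pvalue > 0.01

    def test_nonconformable_omega_rejected(self):
        ids = [f"s{j}" for j in range(60)]
        s = make_stats(ids, np.zeros(60))
        with pytest.raises(ParameterError):
            pn.mtag([s, s], omega=np.eye(3))


class TestMtagSignificant:
    def test_set_algebra(self):
        res = pn.MtagResult(
            tables={"T1": make_stats(["a", "b", "c"], [6.0, 6.0, 6.0]),
                    "T2": make_stats(["a", "b", "c"], [0.0, 6.0, 0.0])},
            omega=np.eye(2), sigma_overlap=np.eye(2), traits=["T1", "T2"])
        out = pn.mtag_significant(res, {"T1": {"b", "c", "d"}})
        assert out["shared"] == {"b", "c"}
        assert out["mtag_only"] == {"a"}
        assert out["gwas_only"] == {"d"}
        assert out["pleiotropic"] == {"b": ["T1", "T2"]}

    def test_disjoint_sets(self):
        res = pn.MtagResult(
            tables={"T1": make_stats(["a", "b"], [6.0, 6.0])},
            omega=np.eye(1), sigma_overlap=np.eye(1), traits=["T1"])
        out = pn.mtag_significant(res, {"T1": {"c"}})
        assert out["shared"] == set()
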