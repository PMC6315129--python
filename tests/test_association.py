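import numpy as np
import pandas as pd
import pytest

import faceasym as fa
from faceasym.association import GenotypeMatrix, write_genotype_tsv

from _bruteforce import bf_bh, bf_ols


def _gm(codes, ids=None, snps=None):
    codes = np.asarray(codes, float)
    ids = ids or [f"s{i}" for i in range(codes.shape[0])]
    snps = snps or [f"snp{j}" for j in range(codes.shape[1])]
    info = pd.DataFrame({"chrom": 1, "pos": np.arange(len(snps)) + 1}, index=snps)
    return GenotypeMatrix(pd.DataFrame(codes, index=ids, columns=snps), info)


class TestGenotypeIO:
    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            _gm([[0, 3], [1, 2]])

    def test_tsv_roundtrip(self, tmp_path, rng):
        gm = _gm(rng.integers(0, 3, size=(6, 4)).astype(float))
        gm.codes.iloc[0, 0] = np.nan
        write_genotype_tsv(gm, tmp_path / "g.tsv")
        back = fa.read_genotype_tsv(tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(back.codes, gm.codes)
        pd.testing.assert_frame_equal(back.info, gm.info)

    def test_plink_text_reader_counts_minor_alleles(self, tmp_path):
        (tmp_path / "toy.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "toy.ped").write_text(
            "f1 s1 0 0 1 0 A A G T\n"
            "f2 s2 0 0 2 0 A C T T\n"
            "f3 s3 0 0 1 0 C C 0 0\n")
        gm = fa.read_plink_text(tmp_path / "toy.ped", tmp_path / "toy.map")
        # rs1: alleles A(3) C(3) -> minor by tie-break 'A'; rs2: G minor (1 of 4)
        assert gm.codes.loc["s1", "rs1"] == 2.0
        assert gm.codes.loc["s2", "rs1"] == 1.0
        assert gm.codes.loc["s3", "rs1"] == 0.0
        assert gm.codes.loc["s1", "rs2"] == 1.0
        assert np.isnan(gm.codes.loc["s3", "rs2"])


class TestMacFilter:
    def test_carrier_count_boundary(self):
        # SNP0: 4 heterozygote carriers of 100 -> removed; SNP1: 5 -> kept
        codes = np.zeros((100, 2))
        codes[:4, 0] = 1
        codes[:5, 1] = 1
        kept = fa.mac_filter(_gm(codes), min_subjects=5)
        assert list(kept.codes.columns) == ["snp1"]

    def test_monomorphic_removed(self):
        codes = np.zeros((50, 1))
        with pytest.warns(UserWarning, match="removed every SNP"):
            out = fa.mac_filter(_gm(codes))
        assert out.n_snps == 0

    def test_major_allele_coding_flipped(self):
        # 96 homozygous-alt subjects: the minor allele is the REFERENCE one,
        # carried by the 4 subjects with code < 2 -> removed at threshold 5
        codes = np.full((100, 1), 2.0)
        codes[:4, 0] = 1.0
        assert fa.mac_filter(_gm(codes), min_subjects=5).n_snps == 0
        assert fa.mac_filter(_gm(codes), min_subjects=4).n_snps == 1

    def test_allele_count_mode(self):
        codes = np.zeros((100, 1))
        codes[:3, 0] = 2  # 3 carriers but 6 allele copies
        assert fa.mac_filter(_gm(codes), min_subjects=5, mode="carrier").n_snps == 0
        assert fa.mac_filter(_gm(codes), min_subjects=5, mode="allele").n_snps == 1


class TestGenotypePCs:
    def test_two_populations_separate_on_pc1(self, rng):
        n, m = 60, 200
        maf_a = rng.uniform(0.05, 0.5, m)
        shift = rng.choice([-0.3, 0.3], m)
        maf_b = np.clip(maf_a + shift, 0.05, 0.95)
        codes = np.vstack([rng.binomial(2, maf_a, (n // 2, m)),
                           rng.binomial(2, maf_b, (n // 2, m))]).astype(float)
        pcs = fa.genotype_pcs(_gm(codes), k=2)
        a, b = pcs.iloc[:n // 2, 0], pcs.iloc[n // 2:, 0]
        assert a.max() < b.min() or b.max() < a.min()  # no overlap of PC1 scores

    def test_scores_orthogonal(self, rng):
        codes = rng.binomial(2, 0.3, (40, 100)).astype(float)
        pcs = fa.genotype_pcs(_gm(codes), k=4).to_numpy()
        gram = pcs.T @ pcs
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_sign_deterministic(self, rng):
        codes = rng.binomial(2, 0.3, (30, 50)).astype(float)
        p1 = fa.genotype_pcs(_gm(codes), k=3)
        p2 = fa.genotype_pcs(_gm(codes), k=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_k_above_rank_rejected(self):
        codes = np.array([[0, 0, 1, 1.0], [1, 1, 2, 2], [2, 2, 0, 0]])  # rank <= 2
        with pytest.raises(ValueError, match="rank"):
            fa.genotype_pcs(_gm(codes), k=4)


class TestLinearAssoc:
    def test_exact_linear_relationship(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        st = fa.linear_assoc(2.0 * g, g)
        assert st.beta == pytest.approx(2.0, abs=1e-10)
        assert st.p < 1e-200

    def test_matches_normal_equations_oracle(self, rng):
        n = 40
        g = rng.integers(0, 3, n).astype(float)
        cov = rng.normal(size=(n, 3))
        y = 0.5 * g + cov @ [1, -2, 0.3] + rng.normal(size=n)
        st = fa.linear_assoc(y, g, cov)
        X = [[1.0, g[i], *cov[i]] for i in range(n)]
        beta = bf_ols(y.tolist(), X)
        assert st.beta == pytest.approx(beta[1], abs=1e-9)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 60
        g = rng.integers(0, 3, n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * g + cov[:, 0] + rng.normal(size=n)
        st = fa.linear_assoc(y, g, cov)
        fit = sm.OLS(y, np.column_stack([np.ones(n), g, cov])).fit()
        assert st.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert st.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert st.p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_missing_genotypes_complete_case(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        y = g + rng.normal(size=30)
        g_miss = g.copy()
        g_miss[:5] = np.nan
        st = fa.linear_assoc(y, g_miss)
        ref = fa.linear_assoc(y[5:], g[5:])
        assert st.n == 25 and st.beta == pytest.approx(ref.beta, abs=1e-12)

    def test_collinear_design_names_column(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        cov = pd.DataFrame({"age": rng.normal(size=30)})
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValueError, match="age_copy"):
            fa.linear_assoc(rng.normal(size=30), g, cov)

    def test_type_one_error_nominal(self, rng):
        # null simulation: fraction of p < 0.05 over 1,000 independent SNPs
        n = 300
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        G = rng.binomial(2, 0.3, size=(n, 1000)).astype(float)
        gm = _gm(G)
        res = fa.association_scan(pd.DataFrame({"y": y}, index=gm.codes.index), gm,
                                  pd.DataFrame(cov, index=gm.codes.index))
        frac = (res["P"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestScanVectorization:
    def test_scan_equals_per_snp_ols(self, rng):
        n, m = 50, 20
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        G[0, 3] = np.nan  # exercise the complete-case fallback path too
        cov = pd.DataFrame({"age": rng.uniform(3, 40, n), "sex": rng.integers(0, 2, n)})
        y = rng.normal(size=n) + 0.4 * G[:, 5]
        gm = _gm(G)
        cov.index = gm.codes.index
        res = fa.association_scan(pd.DataFrame({"y": y}, index=gm.codes.index), gm, cov)
        for j in [0, 3, 5, 11]:
            st = fa.linear_assoc(y, G[:, j], cov)
            row = res[res.SNP == f"snp{j}"].iloc[0]
            assert row.BETA == pytest.approx(st.beta, abs=1e-9)
            assert row.SE == pytest.approx(st.se, abs=1e-9)
            assert row.P == pytest.approx(st.p, rel=1e-6)

    def test_global_bh_pools_phenotypes(self, rng):
        n, m = 40, 10
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        gm = _gm(G)
        ph = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                          index=gm.codes.index)
        res = fa.association_scan(ph, gm)
        assert len(res) == 2 * m
        np.testing.assert_allclose(res["P_FDR"], fa.bh_adjust(res["P"].to_numpy()))


class TestBH:
    def test_hand_worked_example(self):
        adj = fa.bh_adjust(np.array([1e-4, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(adj, [4e-4, 0.04, 0.04, 0.5], atol=1e-12)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fa.bh_adjust(np.full(10, 0.05)), 0.05, atol=1e-15)

    def test_adjusted_at_least_raw_and_matches_oracles(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        adj = fa.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        np.testing.assert_allclose(adj, bf_bh(p.tolist()), atol=1e-12)
        from statsmodels.stats.multitest import multipletests
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            fa.bh_adjust(np.array([0.0, 0.5]))


class TestCovariateTests:
    def test_perfect_pearson(self):
        out = fa.covariate_tests(np.array([2, 4, 6.0]), np.array([1, 2, 3.0]),
                                 np.array([0, 1, 0]))
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_null_sex_association_rarely_significant(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            out = fa.covariate_tests(r.normal(size=200), r.uniform(3, 40, 200),
                                     r.integers(0, 2, 200))
            hits += out["kendall_p"] < 0.05
        assert hits <= 10

    def test_tau_antisymmetric_in_sex_coding(self, rng):
        s = rng.normal(size=100)
        sex = rng.integers(0, 2, 100)
        a = fa.covariate_tests(s, np.arange(100.0), sex)
        b = fa.covariate_tests(s, np.arange(100.0), 1 - sex)
        assert a["kendall_tau"] == pytest.approx(-b["kendall_tau"], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fa.covariate_tests(np.ones(10), np.arange(10.0), np.arange(10) % 2)


class TestManhattanTable:
    def test_threshold_flags(self):
        res = pd.DataFrame({"PHENO": "a", "SNP": ["x", "y", "z"], "CHR": [1, 2, 3],
                            "POS": [1, 2, 3], "BETA": 0.0, "SE": 1.0, "T": 0.0,
                            "P": [6e-8, 4e-8, 0.2], "N": 10})
        table = fa.manhattan_table(res)
        top = table.iloc[0]
        assert top.SNP == "y" and bool(top.SIGNIFICANT)
        x_row = table[table.SNP == "x"].iloc[0]
        assert bool(x_row.SUGGESTIVE) and not bool(x_row.SIGNIFICANT)

    def test_empty_results(self):
        res = pd.DataFrame(columns=["PHENO", "SNP", "CHR", "POS", "BETA", "SE", "T", "P", "N"])
        assert len(fa.manhattan_table(res)) == 0

    def test_plot_written(self, tmp_path, rng):
        res = pd.DataFrame({"PHENO": "a", "SNP": [f"s{i}" for i in range(50)],
                            "CHR": rng.integers(1, 5, 50), "POS": rng.integers(1, 1000, 50),
                            "BETA": 0.0, "SE": 1.0, "T": 0.0,
                            "P": rng.uniform(1e-9, 1, 50), "N": 10})
        fa.manhattan_table(res, plot_path=tmp_path / "man.png")
        assert (tmp_path / "man.png").stat().st_size > 0
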