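"""Mixed-model association scan: oracle equivalence, calibration, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedgwas import popgen, synthetic
from seedgwas.gwas import (bonferroni_threshold, fit_null_mlm,
                           manhattan_qq_export, mlm_scan, qei_scan)


@pytest.fixture(scope="module")
def small_panel():
    spec = synthetic.PanelSpec(n_accessions=200, markers_per_chromosome=25,
                               chromosomes=synthetic.WHEAT_CHROMOSOMES[:8],
                               seed=31)
    return synthetic.generate_genotype_panel(spec)


class TestNullFit:
    def test_identity_kinship_recovers_ols(self, small_panel):
        """With K = I the GLS collapses to OLS: scan p-values equal the
        simple-regression F-test to 1e-8."""
        rng = np.random.default_rng(0)
        n = small_panel.n_accessions
        y = rng.normal(size=n)
        res = mlm_scan(y, None, small_panel, np.eye(n))
        for j in range(0, small_panel.n_markers, 37):
            x = small_panel.dosages[:, j].astype(float)
            if x.std() == 0:
                continue
            lr = stats.linregress(x, y)
            assert res["p"].iloc[j] == pytest.approx(lr.pvalue, abs=1e-8)

    def test_no_polygenic_signal_pushes_delta_up(self, default_panel):
        rng = np.random.default_rng(1)
        K = popgen.kinship_vanraden(default_panel)
        n = default_panel.n_accessions
        high = sum(fit_null_mlm(rng.normal(size=n), None, K).h2 < 0.05
                   for _ in range(100))
        assert high >= 90

    def test_polygenic_heritability_recovered(self, small_panel):
        rng = np.random.default_rng(2)
        K = popgen.kinship_vanraden(small_panel)
        n = small_panel.n_accessions
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        h2s = []
        for s in range(20):
            g = L @ rng.normal(size=n)
            g = g / g.std() * np.sqrt(0.8)
            y = g + rng.normal(size=n) * np.sqrt(0.2)
            h2s.append(fit_null_mlm(y, None, K).h2)
        assert 0.6 <= np.median(h2s) <= 0.95

    def test_singular_covariates_rejected(self, small_panel):
        n = small_panel.n_accessions
        Q = np.ones((n, 2))
        with pytest.raises(ValueError):
            fit_null_mlm(np.zeros(n), Q, np.eye(n))


class TestScan:
    def test_planted_qtn_is_top_hit(self, small_panel):
        """A QTN explaining ~10% of variance is the minimum-p marker in
        most runs."""
        rng = np.random.default_rng(3)
        K = popgen.kinship_vanraden(small_panel)
        _, scores, _ = popgen.pca_genotypes(K)
        n = small_panel.n_accessions
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        hits = 0
        runs = 15
        for s in range(runs):
            j = int(rng.integers(small_panel.n_markers))
            x = small_panel.dosages[:, j].astype(float)
            if x.std() == 0:
                hits += 1
                continue
            beta = np.sqrt(0.1 / x.var())
            g = L @ rng.normal(size=n)
            g = g / g.std() * np.sqrt(0.3)
            y = beta * x + g + rng.normal(size=n) * np.sqrt(0.6)
            res = mlm_scan(y, scores[:, :3], small_panel, K)
            hits += int(np.nanargmin(res["p"].to_numpy())) == j
        assert hits / runs >= 0.8

    def test_monomorphic_marker_flagged_not_tested(self):
        dos = np.random.default_rng(4).integers(0, 3, (50, 5)).astype(np.int8)
        dos[:, 2] = 2
        markers = pd.DataFrame({"id": [f"m{j}" for j in range(5)],
                                "chrom": ["1A"] * 5, "genome": ["A"] * 5,
                                "cm": np.arange(5.0)})
        acc = pd.DataFrame({"id": [f"a{i}" for i in range(50)]})
        panel = popgen.GenotypePanel(dos, markers, acc)
        y = np.random.default_rng(5).normal(size=50)
        res = mlm_scan(y, None, panel, np.eye(50))
        assert not res["tested"].iloc[2]
        assert np.isnan(res["p"].iloc[2])

    def test_permuted_phenotype_is_null(self, small_panel):
        """Permuting y breaks the genotype link: QQ slope ~ 1."""
        rng = np.random.default_rng(6)
        K = popgen.kinship_vanraden(small_panel)
        n = small_panel.n_accessions
        x = small_panel.dosages[:, 10].astype(float)
        y = 0.8 * x + rng.normal(size=n)
        yperm = rng.permutation(y)
        res = mlm_scan(yperm, None, small_panel, np.eye(n))
        _, qq = manhattan_qq_export(res)
        slope = np.polyfit(qq["expected_neglog10p"],
                           qq["observed_neglog10p"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_genomic_control_lambda_near_one(self, small_panel):
        rng = np.random.default_rng(7)
        K = popgen.kinship_vanraden(small_panel)
        _, scores, _ = popgen.pca_genotypes(K)
        lambdas = []
        for s in range(20):
            y = rng.normal(size=small_panel.n_accessions)
            res = mlm_scan(y, scores[:, :3], small_panel, K)
            p = res["p"].dropna().to_numpy()
            lam = np.median(stats.chi2.isf(p, 1)) / stats.chi2.isf(0.5, 1)
            lambdas.append(lam)
        assert 0.9 <= np.median(lambdas) <= 1.1

    def test_marker_and_accession_order_invariance(self, small_panel):
        rng = np.random.default_rng(8)
        y = rng.normal(size=small_panel.n_accessions)
        K = popgen.kinship_vanraden(small_panel)
        res1 = mlm_scan(y, None, small_panel, K)
        # permute chromosome blocks (keeps within-chromosome map order)
        chroms = list(small_panel.markers["chrom"].unique())
        order = np.concatenate([
            np.flatnonzero(small_panel.markers["chrom"] == c)
            for c in rng.permutation(chroms)])
        # and permute accessions consistently across y, dosages and K
        aperm = rng.permutation(small_panel.n_accessions)
        shuffled = popgen.GenotypePanel(
            small_panel.dosages[np.ix_(aperm, order)],
            small_panel.markers.iloc[order].reset_index(drop=True),
            small_panel.accessions.iloc[aperm].reset_index(drop=True))
        res2 = mlm_scan(y[aperm], None, shuffled, K[np.ix_(aperm, aperm)])
        merged = res1.merge(res2, on="marker", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_a"], merged["p_b"], equal_nan=True,
                           rtol=1e-8)

    def test_p3d_false_agrees_with_p3d_true_on_clean_signal(self, small_panel):
        rng = np.random.default_rng(9)
        n = small_panel.n_accessions
        sub = popgen.GenotypePanel(
            small_panel.dosages[:, :12],
            small_panel.markers.iloc[:12].reset_index(drop=True),
            small_panel.accessions)
        K = popgen.kinship_vanraden(small_panel)
        y = rng.normal(size=n)
        r1 = mlm_scan(y, None, sub, K, p3d=True)
        r2 = mlm_scan(y, None, sub, K, p3d=False)
        assert np.allclose(r1["p"].dropna(), r2["p"].dropna(), rtol=0.2)


class TestBonferroni:
    @pytest.mark.parametrize("m, alpha, expected", [
        (100, 0.05, 5e-4),
        (1, 0.05, 0.05),
    ])
    def test_threshold(self, m, alpha, expected):
        assert bonferroni_threshold(m, alpha) == pytest.approx(expected)

    def test_wheat_panel_size_threshold(self):
        m = 15_951 + 21_864 + 5_710
        thr = bonferroni_threshold(m)
        assert thr == pytest.approx(1.1488e-6, rel=1e-4)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestQEI:
    def test_single_environment_rejected(self, small_panel):
        with pytest.raises(ValueError):
            qei_scan({"e1": np.zeros(small_panel.n_accessions)}, None,
                     small_panel, np.eye(small_panel.n_accessions))

    def test_equal_effects_are_null_for_interaction(self, small_panel):
        rng = np.random.default_rng(10)
        n = small_panel.n_accessions
        K = np.eye(n)
        x = small_panel.dosages[:, 40].astype(float)
        ps = []
        for s in range(40):
            y1 = 0.5 * x + rng.normal(size=n)
            y2 = 0.5 * x + rng.normal(size=n)
            res = qei_scan({"e1": y1, "e2": y2}, None, small_panel, K)
            ps.append(res["p_interaction"].iloc[40])
        # type-I at alpha = 0.1 stays near nominal
        assert np.mean(np.array(ps) < 0.1) == pytest.approx(0.1, abs=0.1)

    def test_opposite_signs_give_interaction_power(self, small_panel):
        rng = np.random.default_rng(11)
        n = small_panel.n_accessions
        K = np.eye(n)
        x = small_panel.dosages[:, 41].astype(float)
        y1 = 0.6 * x + rng.normal(size=n)
        y2 = -0.6 * x + rng.normal(size=n)
        res = qei_scan({"e1": y1, "e2": y2}, None, small_panel, K)
        y = (y1 + y2) / 2
        main = mlm_scan(y, None, small_panel, K)
        assert res["p_interaction"].iloc[41] < main["p"].iloc[41]


class TestExports:
    def test_uniform_pvalues_sit_on_the_diagonal(self):
        rng = np.random.default_rng(12)
        m = 4000
        res = pd.DataFrame({
            "marker": [f"m{j}" for j in range(m)],
            "chrom": ["1A"] * m,
            "cm": np.sort(rng.uniform(0, 150, m)),
            "p": rng.uniform(size=m),
        })
        _, qq = manhattan_qq_export(res)
        inner = qq.iloc[int(0.05 * m):]  # drop the noisy extreme tail
        assert np.abs(inner["observed_neglog10p"]
                      - inner["expected_neglog10p"]).max() < 0.25

    def test_single_chromosome_coordinate_is_cm(self):
        res = pd.DataFrame({"marker": ["a", "b"], "chrom": ["2B", "2B"],
                            "cm": [3.0, 40.0], "p": [0.5, 0.1]})
        manh, _ = manhattan_qq_export(res)
        assert np.allclose(manh["genome_cm"], manh["cm"])

    def test_output_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        res = pd.DataFrame({
            "marker": [f"m{j}" for j in range(30)],
            "chrom": ["1A"] * 15 + ["2A"] * 15,
            "cm": np.tile(np.sort(rng.uniform(0, 100, 15)), 2),
            "p": rng.uniform(size=30),
        })
        m1, q1 = manhattan_qq_export(res)
        m2, q2 = manhattan_qq_export(res.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(q1, q2)
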