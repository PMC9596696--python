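"""LD, kinship, PCA, clustering and neighbor joining."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest

from seedgwas.popgen import (GenotypePanel, cluster_accessions,
                             kinship_distance, kinship_vanraden, ld_decay_curve,
                             ld_summary, loess_curve, marker_genome_shares,
                             nj_tree, pairwise_ld, pca_genotypes,
                             percent_significant)


def make_panel(dosages, cm=None, chrom=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    markers = pd.DataFrame({
        "id": [f"m{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1A"] * m,
        "genome": ["A"] * m,
        "cm": cm if cm is not None else np.arange(m, dtype=float),
    })
    acc = pd.DataFrame({"id": [f"a{i}" for i in range(dosages.shape[0])]})
    return GenotypePanel(dosages=dosages, markers=markers, accessions=acc)


class TestPairwiseLD:
    def test_duplicated_marker_has_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 30)
        panel = make_panel(np.column_stack([x, x]))
        rec, _ = pairwise_ld(panel)
        assert rec["r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_two_marker_r2(self):
        x = np.array([0, 1, 2, 2, 1, 0, 1, 2])
        y = np.array([0, 0, 1, 2, 1, 1, 0, 2])
        # direct arithmetic on the n=8 toy
        sx, sy = x - x.mean(), y - y.mean()
        r2_hand = (np.sum(sx * sy) ** 2
                   / (np.sum(sx**2) * np.sum(sy**2)))
        rec, _ = pairwise_ld(make_panel(np.column_stack([x, y])))
        assert rec["r2"].iloc[0] == pytest.approx(r2_hand, abs=1e-12)

    def test_allele_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (40, 6))
        rec1, _ = pairwise_ld(make_panel(d))
        rec2, _ = pairwise_ld(make_panel(2 - d))
        assert np.allclose(rec1["r2"], rec2["r2"])

    def test_monomorphic_markers_skipped_with_count(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (30, 4))
        d[:, 2] = 1
        rec, skipped = pairwise_ld(make_panel(d))
        assert skipped == 1
        assert not (rec[["marker_i", "marker_j"]] == "m2").any().any()

    def test_null_significance_calibration(self):
        """Independent markers: the significant fraction at alpha=0.001
        stays at the nominal level (~1e4 pairs, n=300)."""
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(300, 150))
        rec, _ = pairwise_ld(make_panel(d), alpha=0.001)
        frac = rec["significant"].mean()
        assert frac == pytest.approx(0.001, abs=0.001)


class TestLDSummary:
    @pytest.mark.parametrize("sig, total, expected", [
        (700_991, 1_858_425, 37.72),
        (847_725, 1_867_575, 45.39),
        (10, 10, 100.00),
    ])
    def test_percent_significant(self, sig, total, expected):
        assert percent_significant(sig, total) == expected

    def test_marker_genome_shares(self):
        shares = marker_genome_shares({"A": 15_951, "B": 21_864, "D": 5_710})
        assert shares["B"] == 50.2
        assert shares["D"] == 13.1
        # A: 15951/43525 = 36.65%, half a tick below the commonly quoted
        # 36.7; the three shares still cover the panel
        assert shares["A"] == pytest.approx(36.65, abs=0.06)

    def test_summary_counts_partition_by_genome(self, default_panel):
        rec, _ = pairwise_ld(default_panel)
        summ = ld_summary(rec)
        per_genome = summ[summ["genome"] != "all"]
        assert per_genome["n_pairs"].sum() == int(rec["same_chrom"].sum())
        allrow = summ[summ["genome"] == "all"].iloc[0]
        assert allrow["pct_significant"] == percent_significant(
            int((rec["p"] < 0.001).sum()), len(rec))


class TestLoess:
    def test_linear_trend_reproduced_exactly(self):
        x = np.linspace(0, 10, 60)
        y = 0.4 - 0.03 * x
        grid = np.linspace(1, 9, 15)
        fit = loess_curve(x, y, grid, frac=0.4)
        assert np.allclose(fit, 0.4 - 0.03 * grid, atol=1e-6)

    def test_full_bandwidth_equals_direct_weighted_ls(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 0.7, 0.8, 0.2, 0.4])
        x0 = 1.7
        fit = loess_curve(x, y, np.array([x0]), frac=1.0)[0]
        # explicit tricube-weighted regression at the same point
        h = np.max(np.abs(x - x0))
        w = (1 - np.abs((x - x0) / h) ** 3) ** 3
        X = np.column_stack([np.ones_like(x), x - x0])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert fit == pytest.approx(beta[0], abs=1e-10)

    def test_identical_distances_rejected(self):
        with pytest.raises(ValueError):
            loess_curve(np.ones(30), np.ones(30), np.array([1.0]))

    def test_decay_curve_on_block_ld_panel(self, default_panel):
        rec, _ = pairwise_ld(default_panel)
        curve, _ = ld_decay_curve(rec, frac=0.4)
        at = lambda d: np.interp(d, curve["dist_cm"], curve["r2_smooth"])
        assert at(1.0) > at(20.0)


class TestKinship:
    def test_duplicated_accessions_share_diagonal(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (20, 60))
        d[1] = d[0]
        K = kinship_vanraden(make_panel(d))
        assert K[0, 1] == pytest.approx((K[0, 0] + K[1, 1]) / 2, abs=1e-10)

    def test_positive_semidefinite(self, structured_panel):
        K = kinship_vanraden(structured_panel)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_within_exceeds_between_subpopulation_kinship(
            self, kinship_scores, structured_panel):
        K, _, _ = kinship_scores
        sub = structured_panel.accessions["subpop"].to_numpy()
        same = sub[:, None] == sub[None, :]
        off = ~np.eye(len(K), dtype=bool)
        assert K[same & off].mean() > K[~same].mean()

    def test_monomorphic_markers_warn(self):
        d = np.array([[0, 2, 1], [1, 2, 0], [2, 2, 1], [1, 2, 2]])
        with pytest.warns(UserWarning):
            kinship_vanraden(make_panel(d))


class TestPCA:
    def test_identity_kinship_spreads_variance_evenly(self):
        _, _, pct = pca_genotypes(np.eye(6))
        assert np.allclose(pct, 100 / 6)

    def test_rank_one_concentrates_on_pc1(self):
        v = np.arange(1.0, 5.0)
        _, _, pct = pca_genotypes(np.outer(v, v))
        assert pct[0] == pytest.approx(100.0)

    def test_percent_variance_contract(self, kinship_scores):
        _, _, pct = pca_genotypes(kinship_scores[0])
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert (pct >= 0).all() and (np.diff(pct) <= 1e-12).all()

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            pca_genotypes(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestClustering:
    def test_two_blobs_perfectly_partitioned(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, (20, 3)),
                         rng.normal(5, 0.1, (20, 3))])
        labels, _ = cluster_accessions(pts, 2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_recovers_three_subpopulations(self, kinship_scores,
                                           structured_panel):
        from sklearn.metrics import adjusted_rand_score

        _, scores, _ = kinship_scores
        labels, _ = cluster_accessions(scores, 3, seed=0)
        ari = adjusted_rand_score(structured_panel.accessions["subpop"],
                                  labels)
        assert ari >= 0.8

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_accessions(np.zeros((3, 2)), 5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 3))
        l1, _ = cluster_accessions(pts, 3, seed=9)
        l2, _ = cluster_accessions(pts, 3, seed=9)
        assert np.array_equal(l1, l2)


class TestNeighborJoining:
    def _patristic(self, newick):
        from skbio import TreeNode

        return TreeNode.read(StringIO(newick))

    def test_three_taxa_closed_form(self):
        # three-point equations: dAX=(dAB+dAC-dBC)/2 etc.
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        t = self._patristic(nj_tree(D, ["A", "B", "C"]))
        assert t.find("A").distance(t.find("B")) == pytest.approx(4.0)
        assert t.find("A").distance(t.find("C")) == pytest.approx(6.0)
        assert t.find("B").distance(t.find("C")) == pytest.approx(8.0)

    def test_additive_four_taxon_metric_recovered_exactly(self):
        # generated from tree ((A:2,B:3):1,(C:4,D:5)): all pairwise paths
        D = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                      [7, 8, 0, 9], [8, 9, 9, 0]], float)
        t = self._patristic(nj_tree(D, list("ABCD")))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert t.find(a).distance(t.find(b)) == \
                        pytest.approx(D[i, j], abs=1e-9)

    def test_duplicated_taxa_give_zero_length_cherry(self):
        D = np.array([[0, 0, 6, 6], [0, 0, 6, 6],
                      [6, 6, 0, 4], [4 + 2, 6, 4, 0]], float)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        t = self._patristic(nj_tree(D, list("ABCD")))
        assert t.find("A").distance(t.find("B")) == pytest.approx(0.0)

    def test_nan_distances_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))

    def test_kinship_distance_properties(self, kinship_scores):
        D = kinship_distance(kinship_scores[0])
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and np.allclose(D, D.T)
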