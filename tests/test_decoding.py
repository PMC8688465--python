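"""PLS1 decoding: closed-form weights, bootstrap ranking, validation."""

import numpy as np
import pandas as pd
import pytest

import varitx
from varitx.decoding import (bootstrap_z, pls1_fit, predictive_validation,
                             select_gene_lists)


def toy_xy(V=60, G=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((V, G))
    y = X[:, 0] * 0.8 + 0.4 * rng.standard_normal(V)
    return X, y


class TestPls1Fit:
    def test_single_informative_gene_gives_perfect_scores(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(40)
        X = np.column_stack([y, rng.standard_normal(40)])
        res = pls1_fit(X, y)
        assert res.r_scores_y > 0.6
        # one gene exactly equal to y dominates the weights
        assert abs(res.weights[0]) > abs(res.weights[1])

    def test_weights_proportional_to_gene_map_correlations(self):
        """With z-scored X and univariate y the PLS1 weight of each gene is
        proportional to corr(gene, y)."""
        X, y = toy_xy()
        res = pls1_fit(X, y)
        corrs = np.array([np.corrcoef(X[:, g], y)[0, 1]
                          for g in range(X.shape[1])])
        ratio = res.weights / corrs
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_orientation_invariant_to_response_sign(self):
        X, y = toy_xy(seed=2)
        a = pls1_fit(X, y)
        b = pls1_fit(X, -y)
        assert a.r_scores_y >= 0 and b.r_scores_y >= 0
        np.testing.assert_allclose(np.abs(a.scores), np.abs(b.scores),
                                   atol=1e-10)

    def test_matches_sklearn_first_component(self):
        """Independent cross-check: scikit-learn's PLS regression first
        component spans the same direction."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = toy_xy(V=80, G=12, seed=3)
        res = pls1_fit(X, y)
        skl = PLSRegression(n_components=1).fit(X, y)
        w_skl = skl.x_weights_[:, 0]
        cos = abs(w_skl @ res.weights) / np.linalg.norm(w_skl)
        assert cos == pytest.approx(1.0, abs=1e-8)
        r = abs(np.corrcoef(skl.x_scores_[:, 0], res.scores)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_gene_column_order_invariance(self):
        X, y = toy_xy(seed=4)
        perm = np.random.default_rng(5).permutation(X.shape[1])
        a = pls1_fit(X, y)
        b = pls1_fit(X[:, perm], y)
        np.testing.assert_allclose(b.weights, a.weights[perm], atol=1e-12)
        np.testing.assert_allclose(b.scores, a.scores, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        X, y = toy_xy()
        with pytest.raises(ValueError, match="constant"):
            pls1_fit(X, np.ones_like(y))
        Xc = X.copy()
        Xc[:, 2] = 5.0
        with pytest.raises(ValueError, match="constant columns"):
            pls1_fit(Xc, y)


class TestBootstrapZ:
    def test_deterministic_under_seed(self):
        X, y = toy_xy()
        a = bootstrap_z(X, y, n_boot=150, seed=7)
        b = bootstrap_z(X, y, n_boot=150, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_gene_columns_get_equal_z(self):
        X, y = toy_xy(seed=8)
        Xd = np.column_stack([X, X[:, 0]])
        z = bootstrap_z(Xd, y, n_boot=150, seed=9)
        assert z[0] == pytest.approx(z[-1], rel=1e-10)

    def test_signal_genes_dominate_ranking(self, planted_expression,
                                           planted_pls):
        """>= 80% of planted signal genes land in the top 5% of |Z|."""
        z = np.abs(planted_pls.z)
        top_k = int(0.05 * z.size)
        cutoff = np.sort(z)[::-1][top_k - 1]
        in_top = z >= cutoff
        signal = planted_expression["signal"]
        assert (in_top & signal).sum() / signal.sum() >= 0.8

    def test_bootstrap_se_shrinks_with_voxels(self):
        """Weight SEs decrease monotonically across nested problem sizes."""
        rng = np.random.default_rng(10)
        ses = []
        for V in (100, 400, 1600):
            g = rng.uniform(0, 1, V)
            expr, _ = varitx.simulate_expression(
                g, varitx.ExpressionConfig(n_genes=40, n_signal_genes=5,
                                           effect=0.6, seed=11))
            X = expr.to_numpy()
            y = g + 0.2 * rng.standard_normal(V)
            z = bootstrap_z(X, y, n_boot=200, seed=12)
            w = pls1_fit(X, y).weights
            ses.append(np.mean(np.abs(w) / np.abs(z)))
        assert ses[0] > ses[1] > ses[2]

    def test_too_few_voxels_rejected(self):
        X, y = toy_xy(V=8)
        with pytest.raises(ValueError, match="10 voxels"):
            bootstrap_z(X, y, n_boot=150)


class TestSelectGeneLists:
    def test_all_zero_z_gives_empty_lists(self):
        plus, minus = select_gene_lists(np.zeros(5), list("abcde"))
        assert plus == [] and minus == []

    def test_bh_on_three_gene_example(self):
        plus, minus = select_gene_lists(np.array([10.0, -10.0, 0.1]),
                                        ["gene1", "gene2", "gene3"])
        assert plus == ["gene1"]
        assert minus == ["gene2"]

    def test_lists_disjoint_and_ranked_by_abs_z(self, planted_pls):
        assert not (set(planted_pls.plus_list) & set(planted_pls.minus_list))
        z = dict(zip(planted_pls.gene_symbols, np.abs(planted_pls.z)))
        ranks = [z[g] for g in planted_pls.plus_list]
        assert ranks == sorted(ranks, reverse=True)


class TestGradientRecovery:
    def test_pls1_scores_track_planted_gradient(self, planted_expression,
                                                planted_pls):
        r = np.corrcoef(planted_pls.scores,
                        planted_expression["gradient"])[0, 1]
        assert abs(r) >= 0.9


class TestPredictiveValidation:
    def test_each_fold_trains_on_remaining_sessions(self):
        rng = np.random.default_rng(13)
        maps = rng.standard_normal((4, 50))
        X = rng.standard_normal((50, 6))
        folds = predictive_validation(maps, X)
        assert len(folds) == 4
        assert (folds["n_train_sessions"] == 3).all()

    def test_noiseless_rank_one_limit(self):
        rng = np.random.default_rng(14)
        y = rng.standard_normal(60)
        X = np.column_stack([y + 0.01 * rng.standard_normal(60)
                             for _ in range(4)])
        maps = np.tile(y, (3, 1))
        folds = predictive_validation(maps, X)
        assert (folds["r"] > 0.99).all()

    def test_broken_voxel_correspondence_kills_prediction(
            self, default_cohort, default_variability):
        """With the voxel correspondence between expression and the session
        maps destroyed, the mean fold r sits near zero.

        Note the null must permute the maps, not just the expression rows:
        reusing the same X for training and prediction projects the
        training map onto X's column space, which correlates with a
        reliable held-out map (~ sqrt(n_genes/n_voxels)) even for
        signal-free expression."""
        expr, _ = varitx.simulate_expression(
            default_cohort.gradient,
            varitx.ExpressionConfig(n_genes=120, n_signal_genes=15,
                                    effect=0.8, seed=15))
        rng = np.random.default_rng(16)
        maps = np.stack([m[rng.permutation(m.size)]
                         for m in default_variability.V])
        folds = predictive_validation(maps, expr.to_numpy())
        assert abs(folds["r"].mean()) < 0.1

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 session"):
            predictive_validation(np.random.default_rng(0).standard_normal(
                (1, 30)), np.random.default_rng(1).standard_normal((30, 4)))


class TestPLSModelSurface:
    def test_fit_from_dataframe_reports_summary(self, planted_pls):
        text = planted_pls.summary()
        assert "PLS1+" in text and "bootstrap" in text
        table = planted_pls.gene_table()
        assert {"gene", "weight", "z", "p", "q", "list"} <= set(table.columns)
        assert table["z"].abs().is_monotonic_decreasing
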