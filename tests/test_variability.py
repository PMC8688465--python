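"""FC-variability pipeline against hand formulas and brute-force oracles."""

import math
import warnings
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import varitx
from varitx.containers import FCProfileStack
from varitx.variability import (adjust_variability, compute_fc_profile,
                                network_aggregate, noise_map_from_runs,
                                stack_from_runs, technical_noise)


def random_stack(V, S, T, seed=0):
    rng = np.random.default_rng(seed)
    return FCProfileStack(values=rng.uniform(-1, 1, size=(V, S, T, V - 1)))


class TestComputeFCProfile:
    def test_identical_target_gives_unit_correlation(self):
        run = np.vstack([[1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5],
                         [5.0, 1, 4, 2, 3]])
        r = compute_fc_profile(run, 0)
        assert r[0] == pytest.approx(1.0)

    def test_reversed_target_gives_minus_one(self):
        run = np.vstack([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        assert compute_fc_profile(run, 0)[0] == pytest.approx(-1.0)

    def test_matches_pairwise_pearson_formula(self):
        """3-voxel, 6-timepoint fixture against the explicit formula."""
        run = np.array([[2.0, 4, 1, 7, 3, 5],
                        [1.0, 3, 2, 6, 4, 4],
                        [9.0, 2, 8, 1, 5, 3]])
        prof = compute_fc_profile(run, 0)
        for k, tgt in enumerate([1, 2]):
            expected = stats.pearsonr(run[0], run[tgt]).statistic
            assert prof[k] == pytest.approx(expected, abs=1e-14)

    def test_constant_seed_rejected_and_constant_target_flagged(self):
        run = np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4], [2.0, 2, 2, 2]])
        with pytest.raises(ValueError, match="constant"):
            compute_fc_profile(run, 0)
        with pytest.warns(UserWarning, match="constant target"):
            prof = compute_fc_profile(run, 1)
        assert np.isnan(prof[1])


class TestIntersubjectSimilarity:
    def test_three_subject_brute_force(self):
        stack = random_stack(4, 3, 1, seed=1)
        R, n_pairs = varitx.intersubject_similarity(stack, 0)
        for v in range(4):
            prof = stack.values[v, :, 0, :]
            pairs = [stats.pearsonr(prof[p], prof[q]).statistic
                     for p, q in combinations(range(3), 2)]
            assert R[v] == pytest.approx(np.mean(pairs), abs=1e-12)
        assert np.all(n_pairs == 3)

    def test_identical_subjects_give_zero_variability(self):
        rng = np.random.default_rng(2)
        one = rng.uniform(-1, 1, size=(5, 1, 1, 4))
        stack = FCProfileStack(values=np.repeat(one, 4, axis=1))
        R, _ = varitx.intersubject_similarity(stack, 0)
        assert np.allclose(R, 1.0)
        assert np.allclose(1.0 - R, 0.0)

    def test_common_profile_offset_leaves_R_unchanged(self):
        stack = random_stack(3, 4, 1, seed=3)
        shifted = FCProfileStack(values=np.clip(stack.values * 0.5 + 0.2,
                                                -1, 1))
        # correlation is location/scale invariant: same R from an affine
        # transform applied to every subject's profile
        R0, _ = varitx.intersubject_similarity(stack, 0)
        R1, _ = varitx.intersubject_similarity(shifted, 0)
        np.testing.assert_allclose(R0, R1, atol=1e-12)


class TestIntrasubjectVariability:
    def test_identical_sessions_give_zero(self):
        rng = np.random.default_rng(4)
        one = rng.uniform(-1, 1, size=(5, 3, 1, 4))
        stack = FCProfileStack(values=np.repeat(one, 4, axis=2))
        _, N, n_pairs = varitx.intrasubject_variability(stack)
        assert np.allclose(N, 0.0, atol=1e-12)
        assert np.all(n_pairs == math.comb(4, 2))

    def test_matches_brute_force_loop(self):
        stack = random_stack(6, 2, 3, seed=5)
        N_subject, N, _ = varitx.intrasubject_variability(stack)
        for s in range(2):
            for v in range(6):
                prof = stack.values[v, s, :, :]
                pairs = [stats.pearsonr(prof[m], prof[n]).statistic
                         for m, n in combinations(range(3), 2)]
                assert N_subject[s, v] == pytest.approx(
                    1.0 - np.mean(pairs), abs=1e-12)
        np.testing.assert_allclose(N, N_subject.mean(axis=0), atol=1e-12)


class TestTechnicalNoise:
    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        run = rng.uniform(50, 150, size=(8, 40))
        np.testing.assert_allclose(technical_noise(run),
                                   technical_noise(3.7 * run), atol=1e-12)

    def test_printed_example(self):
        run = np.array([[9.0, 11, 9, 11]])
        noise = technical_noise(run)
        assert noise[0] == pytest.approx(math.sqrt(4 / 3) / 10, abs=1e-10)
        assert 1.0 / noise[0] == pytest.approx(8.6603, abs=1e-4)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="zero temporal SD"):
            noise = technical_noise(np.array([[5.0, 5, 5], [1.0, 2, 3]]))
        assert np.isnan(noise[0]) and np.isfinite(noise[1])


class TestAdjustVariability:
    def test_orthogonal_regressors_give_zero_betas(self):
        rng = np.random.default_rng(7)
        r_adj = rng.uniform(0, 1, 50)
        # construct regressors with exactly zero sample covariance with r_adj
        y = r_adj - r_adj.mean()
        raw_n = rng.standard_normal(50)
        raw_noise = rng.standard_normal(50)
        N = raw_n - (raw_n @ y) / (y @ y) * y
        noise = raw_noise - (raw_noise @ y) / (y @ y) * y
        V, glm = adjust_variability(r_adj, N, noise)
        assert glm.beta1 == pytest.approx(0.0, abs=1e-10)
        assert glm.beta2 == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(V, r_adj - r_adj.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(8)
        r_adj = rng.uniform(0, 1, 80)
        N = rng.uniform(0, 1, 80)
        noise = rng.uniform(0.05, 0.2, 80)
        V, _ = adjust_variability(r_adj, N, noise)
        assert abs(np.corrcoef(V, N)[0, 1]) < 1e-10
        assert abs(np.corrcoef(V, noise)[0, 1]) < 1e-10
        assert abs(V.mean()) < 1e-12

    def test_five_voxel_normal_equations_oracle(self):
        r_adj = np.array([0.3, 0.5, 0.4, 0.7, 0.6])
        N = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        noise = np.array([0.11, 0.09, 0.12, 0.10, 0.14])
        X = np.column_stack([np.ones(5), N, noise])
        beta = np.linalg.solve(X.T @ X, X.T @ r_adj)
        _, glm = adjust_variability(r_adj, N, noise)
        assert glm.c == pytest.approx(beta[0], abs=1e-10)
        assert glm.beta1 == pytest.approx(beta[1], abs=1e-10)
        assert glm.beta2 == pytest.approx(beta[2], abs=1e-10)

    def test_collinear_regressors_rejected(self):
        r_adj = np.linspace(0, 1, 10)
        N = np.linspace(0.2, 0.4, 10)
        with pytest.raises(ValueError, match="collinear"):
            adjust_variability(r_adj, N, 2.0 * N + 1.0)


class TestNetworkAggregate:
    def test_single_network_equals_global_mean(self):
        vals = np.array([0.2, 0.4, 0.9])
        out = network_aggregate(vals, np.array([3, 3, 3]))
        assert out.loc[3] == pytest.approx(vals.mean())

    def test_two_network_arithmetic(self):
        out = network_aggregate(np.array([0.1, 0.3, 0.5]),
                                np.array([1, 1, 2]))
        assert out.loc[1] == pytest.approx(0.2)
        assert out.loc[2] == pytest.approx(0.5)

    def test_empty_network_reported_missing(self):
        with pytest.warns(UserWarning, match="no voxels"):
            out = network_aggregate(np.array([0.1, 0.2]), np.array([1, 1]))
        assert np.isnan(out.loc[5])
        assert not (out.fillna(0) == 0).loc[1]

    def test_label_zero_excluded(self):
        out = network_aggregate(np.array([10.0, 0.4]), np.array([0, 2]))
        assert out.loc[2] == pytest.approx(0.4)


class TestModelEquivalenceWithNaiveReference:
    def test_full_pipeline_matches_double_loop(self):
        """R, N, noise and V from the model equal an explicit double-loop
        reference to 1e-12 on a 10-voxel, 3-subject, 2-session cohort."""
        cfg = varitx.CohortConfig(n_subjects=3, n_sessions=2, n_voxels=10,
                                  n_timepoints=30, n_runs_per_session=2,
                                  seed=21)
        cohort = varitx.simulate_cohort(cfg, mode="timeseries")
        model = varitx.VariabilityModel.from_runs(cohort.runs)
        res = model.fit()

        # --- naive reference: explicit loops, scipy pearsonr, lin solve
        profiles = {}
        for (s, t), run_list in cohort.runs.items():
            data = np.concatenate(run_list, axis=1)
            for v in range(10):
                others = [w for w in range(10) if w != v]
                profiles[(v, s, t)] = np.array(
                    [stats.pearsonr(data[v], data[w]).statistic
                     for w in others])
        R_ref = np.empty((2, 10))
        for t in range(2):
            for v in range(10):
                pairs = [stats.pearsonr(profiles[(v, p, t)],
                                        profiles[(v, q, t)]).statistic
                         for p, q in combinations(range(3), 2)]
                R_ref[t, v] = np.mean(pairs)
        N_ref = np.empty(10)
        for v in range(10):
            per_subj = []
            for s in range(3):
                pairs = [stats.pearsonr(profiles[(v, s, m)],
                                        profiles[(v, s, n)]).statistic
                         for m, n in combinations(range(2), 2)]
                per_subj.append(1.0 - np.mean(pairs))
            N_ref[v] = np.mean(per_subj)
        noise_maps = []
        for run_list in cohort.runs.values():
            for run in run_list:
                noise_maps.append(run.std(axis=1, ddof=1) / run.mean(axis=1))
        noise_ref = np.mean(noise_maps, axis=0)
        V_ref = np.empty((2, 10))
        for t in range(2):
            X = np.column_stack([np.ones(10), N_ref, noise_ref])
            beta = np.linalg.solve(X.T @ X, X.T @ (1.0 - R_ref[t]))
            V_ref[t] = (1.0 - R_ref[t]) - X @ beta

        np.testing.assert_allclose(res.R, R_ref, atol=1e-12)
        np.testing.assert_allclose(res.N, N_ref, atol=1e-12)
        np.testing.assert_allclose(res.noise, noise_ref, atol=1e-12)
        np.testing.assert_allclose(res.V, V_ref, atol=1e-12)
        np.testing.assert_allclose(res.V_mean, V_ref.mean(axis=0),
                                   atol=1e-12)


class TestVariabilityResults:
    def test_summary_reports_design(self, default_variability):
        text = default_variability.summary()
        assert "subjects: 20" in text and "sessions: 4" in text
        assert "GLM" in text

    def test_network_table_has_twelve_rows(self, default_cohort,
                                           default_variability):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = default_variability.network_table(
                default_cohort.network_labels)
        assert table.shape[0] == 12
        assert {"unadjusted", "adjusted"} <= set(table.columns)
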