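"""Noise normalization, fold scheme, correlations, decoding, crossnobis."""

import itertools

import numpy as np
import pytest

import somastab as st
from somastab import mvpa, synthgen


class TestNoiseCovariance:
    def test_iid_unit_variance_limit_gives_identity(self, rng):
        residuals = [rng.standard_normal((20_000, 8))]
        sigma, inv_sqrt = st.estimate_noise_covariance(residuals)
        np.testing.assert_allclose(sigma, np.eye(8), atol=0.05)
        np.testing.assert_allclose(inv_sqrt, np.eye(8), atol=0.05)

    def test_full_shrinkage_is_exactly_diagonal(self, rng):
        residuals = [rng.standard_normal((50, 6)) @ rng.standard_normal((6, 6))]
        sigma, _ = st.estimate_noise_covariance(residuals, regularization=1.0)
        np.testing.assert_allclose(sigma, np.diag(np.diag(sigma)))

    def test_shrinkage_beats_sample_covariance_at_small_t(self, rng):
        # Monte-Carlo: Frobenius error of the shrunk estimate below the
        # unshrunk sample covariance when timepoints are scarce.
        n_vox, t = 20, 15
        noise = st.NoiseModel(voxel_noise_sd=1.0, spatial_corr_length=2.0)
        truth = noise.covariance(n_vox)
        chol = np.linalg.cholesky(truth)
        err_shrunk, err_sample = [], []
        for _ in range(40):
            res = rng.standard_normal((t, n_vox)) @ chol.T
            sigma, _ = st.estimate_noise_covariance([res])
            centered = res - res.mean(0)
            sample = centered.T @ centered / (t - 1)
            err_shrunk.append(np.linalg.norm(sigma - truth))
            err_sample.append(np.linalg.norm(sample - truth))
        assert np.mean(err_shrunk) < np.mean(err_sample)

    def test_invalid_inputs_rejected(self, rng):
        bad = rng.standard_normal((10, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            st.estimate_noise_covariance([bad])
        with pytest.raises(st.ConfigurationError):
            st.estimate_noise_covariance(
                [rng.standard_normal((10, 4))], regularization=1.5
            )


class TestWhitening:
    def test_identity_whitener_is_a_noop(self, rng):
        betas = rng.standard_normal((3, 5))
        np.testing.assert_array_equal(st.whiten_patterns(betas, np.eye(5)), betas)

    def test_diagonal_covariance_rescales(self, rng):
        # Sigma ~ 4I -> whitener ~ I/2 -> betas halved
        betas = rng.standard_normal((3, 5))
        residuals = rng.standard_normal((20_000, 5)) * 2.0
        _, inv_sqrt = st.estimate_noise_covariance([residuals],
                                                   regularization=1.0)
        whitened = st.whiten_patterns(betas, inv_sqrt)
        np.testing.assert_allclose(whitened, betas / 2.0, rtol=0.05)

    def test_euclidean_on_whitened_equals_mahalanobis(self, rng):
        # algebraic oracle: ||W(x - y)||^2 == (x - y)' Sigma^-1 (x - y)
        n_vox = 12
        res = rng.standard_normal((300, n_vox)) @ rng.standard_normal((n_vox, n_vox))
        sigma, inv_sqrt = st.estimate_noise_covariance([res])
        x, y = rng.standard_normal((2, n_vox))
        euclid = np.sum((st.whiten_patterns(x, inv_sqrt)
                         - st.whiten_patterns(y, inv_sqrt)) ** 2)
        mahal = (x - y) @ np.linalg.inv(sigma) @ (x - y)
        assert euclid == pytest.approx(mahal, rel=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            st.whiten_patterns(rng.standard_normal((3, 5)), np.eye(4))


class TestFolds:
    @pytest.mark.parametrize(
        "n1, n2, expected", [(4, 4, 36), (2, 2, 1), (3, 4, 18)]
    )
    def test_fold_counts_match_brute_force(self, n1, n2, expected):
        folds = st.enumerate_between_session_folds(range(n1), range(n2))
        assert len(folds) == expected
        # brute-force oracle: unordered 2-subsets crossed
        brute = {
            (a, b)
            for a in itertools.combinations(range(n1), 2)
            for b in itertools.combinations(range(n2), 2)
        }
        assert {(f.partition_a, f.partition_b) for f in folds} == brute

    def test_deterministic_lexicographic_order(self):
        folds = st.enumerate_between_session_folds([4, 2, 1, 3], [2, 1])
        assert folds[0].partition_a == (1, 2)
        assert all(f.partition_b == (1, 2) for f in folds)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            st.enumerate_between_session_folds([1], [1, 2])


class TestIntraFingerCorrelation:
    def test_identical_sessions_correlate_perfectly(self, small_cohort):
        spec = st.CohortSpec(n_controls=1, n_cases=0, n_voxels=98)
        noiseless = st.NoiseModel(voxel_noise_sd=0.0, run_effect_sd=0.0,
                                  session_effect_sd=0.0,
                                  n_residual_timepoints=5)
        cohort = synthgen.simulate_cohort(spec, noise=noiseless)
        r = st.intra_finger_correlation(
            cohort, "sub-01", "thumb", ("Pre1", "Pre2")
        )
        assert r == pytest.approx(1.0)

    def test_independent_noise_patterns_decorrelate(self, rng):
        spec = st.CohortSpec(n_controls=1, n_cases=0, n_voxels=98)
        model = st.default_somatotopy()
        null_model = synthgen.SomatotopyModel(
            segment_centers=model.segment_centers,
            tuning_width=model.tuning_width,
            amplitudes={c: 0.0 for c in model.conditions},
        )
        cohort = synthgen.simulate_cohort(
            spec, model=null_model,
            noise=st.NoiseModel(voxel_noise_sd=1.0, spatial_corr_length=0.0,
                                n_residual_timepoints=5),
        )
        r = st.intra_finger_correlation(cohort, "sub-01", "thumb", ("Pre1", "Pre2"))
        assert abs(r) < 0.35  # 36 folds of ~64-voxel correlations

    def test_six_unique_session_comparisons(self):
        pairs = mvpa.session_pairs(st.DEFAULT_SESSIONS)
        assert len(pairs) == 6
        assert ("Pre1", "Pre2") in pairs and ("Post3m", "Post6m") in pairs


class TestDecoding:
    def test_noiseless_separable_fingers_decode_perfectly(self):
        spec = st.CohortSpec(n_controls=1, n_cases=0, n_voxels=98)
        noiseless = st.NoiseModel(voxel_noise_sd=0.0, run_effect_sd=0.0,
                                  session_effect_sd=0.0,
                                  n_residual_timepoints=5)
        cohort = synthgen.simulate_cohort(spec, noise=noiseless)
        table = st.pairwise_decoding(
            cohort, "sub-01", "Pre1", "Pre2", whiten=False
        )
        assert table.n_combinations == 72
        assert len(table.accuracies) == 10
        assert table.mean_accuracy == 1.0

    def test_zero_selectivity_drops_pre_to_post_decoding_to_chance(self):
        spec = st.CohortSpec(n_controls=0, n_cases=1, n_voxels=98, seed=4)
        effects = st.CaseEffects(onset_session="Post3m", selectivity_scale=0.0)
        cohort = synthgen.simulate_cohort(spec, case_effects=effects)
        pre = st.pairwise_decoding(cohort, "case-01", "Pre1", "Pre2")
        cross = st.pairwise_decoding(cohort, "case-01", "Pre1", "Post6m")
        assert pre.mean_accuracy > 0.95
        assert abs(cross.mean_accuracy - 0.5) < 0.15

    def test_degenerate_training_recorded_as_chance(self, rng):
        pats = {1: np.zeros((2, 6)), 2: np.zeros((2, 6))}
        test_pats = {1: rng.standard_normal((2, 6)),
                     2: rng.standard_normal((2, 6))}
        with pytest.warns(UserWarning, match="identical training"):
            cells = mvpa._decode_pair(pats, test_pats, 0, 1)
        assert cells == [0.5]

    def test_label_permutation_helper_shuffles_only_selected_columns(self, rng,
                                                                     small_cohort):
        run = small_cohort.runs_for("sub-01", "Pre1")[0]
        permuted = st.permute_condition_labels(run, st.FINGERS, rng)
        np.testing.assert_array_equal(
            permuted.beta_for(st.LIPS), run.beta_for(st.LIPS)
        )
        orig = run.pattern_matrix(st.FINGERS)
        new = permuted.pattern_matrix(st.FINGERS)
        assert sorted(map(tuple, orig)) == sorted(map(tuple, new))


class TestCrossnobis:
    def test_identical_condition_patterns_give_zero(self, rng):
        pat = rng.standard_normal((1, 10))
        pats = {r: np.vstack([pat, pat]) for r in range(1, 5)}
        d2 = mvpa.crossnobis_from_patterns(pats, pats, [(0, 1)])
        assert d2[0] == 0.0

    def test_constant_offset_recovers_squared_norm(self, rng):
        v = rng.standard_normal(10)
        base = rng.standard_normal(10)
        pats = {r: np.vstack([base, base + v]) for r in range(1, 5)}
        d2 = mvpa.crossnobis_from_patterns(pats, pats, [(0, 1)])
        assert d2[0] == pytest.approx(np.sum(v**2), rel=1e-10)

    def test_vectorized_equals_fold_loop_oracle(self, rng):
        pats_a = {r: rng.standard_normal((5, 12)) for r in range(1, 5)}
        pats_b = {r: rng.standard_normal((5, 12)) for r in range(1, 5)}
        pairs = list(itertools.combinations(range(5), 2))
        d2 = mvpa.crossnobis_from_patterns(pats_a, pats_b, pairs)
        # literal double loop over folds
        for k, (y, z) in enumerate(pairs):
            folds = []
            for pa in itertools.combinations(sorted(pats_a), 2):
                for pb in itertools.combinations(sorted(pats_b), 2):
                    ma = (pats_a[pa[0]] + pats_a[pa[1]]) / 2
                    mb = (pats_b[pb[0]] + pats_b[pb[1]]) / 2
                    folds.append((ma[y] - ma[z]) @ (mb[y] - mb[z]))
            assert d2[k] == pytest.approx(np.mean(folds), rel=1e-10)

    def test_symmetric_in_partition_assignment(self, rng):
        pats_a = {r: rng.standard_normal((2, 8)) for r in range(1, 5)}
        pats_b = {r: rng.standard_normal((2, 8)) for r in range(1, 5)}
        d_ab = mvpa.crossnobis_from_patterns(pats_a, pats_b, [(0, 1)])
        d_ba = mvpa.crossnobis_from_patterns(pats_b, pats_a, [(0, 1)])
        assert d_ab[0] == pytest.approx(d_ba[0], rel=1e-12)

    def test_null_distances_unbiased_with_negative_folds(self, rng):
        # same true pattern + independent noise: mean d^2 ~ 0, negatives occur
        truth = rng.standard_normal(15)
        means = []
        any_negative = False
        for _ in range(300):
            pats_a = {r: truth + rng.standard_normal((2, 15)) for r in range(4)}
            pats_b = {r: truth + rng.standard_normal((2, 15)) for r in range(4)}
            d2 = mvpa.crossnobis_from_patterns(pats_a, pats_b, [(0, 1)])
            means.append(d2[0])
            any_negative = any_negative or d2[0] < 0
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se
        assert any_negative

    def test_cohort_level_table(self, small_cohort):
        table = st.crossnobis_distances(small_cohort, "sub-01", ("Pre1", "Pre2"))
        assert table.n_folds == 36
        assert len(table.entries) == 10
        assert table.distance("thumb", "index") == table.distance("index", "thumb")
        # real finger information: distances clearly positive
        assert table.mean_distance > 0


class TestSelectivityMonotonicity:
    def test_selectivity_scale_monotone_in_distance_and_accuracy(self):
        from scipy import stats as sps

        scales = np.linspace(0.0, 1.0, 10)
        dists, accs = [], []
        for i, scale in enumerate(scales):
            spec = st.CohortSpec(n_controls=0, n_cases=1, n_voxels=98, seed=100)
            effects = st.CaseEffects(onset_session="Post3m",
                                     selectivity_scale=float(scale))
            cohort = synthgen.simulate_cohort(spec, case_effects=effects)
            d = st.crossnobis_distances(cohort, "case-01", ("Pre1", "Post6m"))
            a = st.pairwise_decoding(cohort, "case-01", "Pre1", "Post6m")
            dists.append(d.mean_distance)
            accs.append(a.mean_accuracy)
        rho_d = sps.spearmanr(scales, dists).statistic
        assert rho_d > 0.9
        # accuracy saturates at ceiling; require monotone non-decreasing trend
        rho_a = sps.spearmanr(scales, accs).statistic
        assert rho_a > 0.7


class TestTypicality:
    def test_case_equal_to_control_mean_gives_rho_one(self, rng):
        ctrl = rng.standard_normal((8, 10))
        assert st.typicality_score(ctrl.mean(0), ctrl) == pytest.approx(1.0)

    def test_rank_reversed_case_gives_minus_one(self, rng):
        ctrl = np.tile(np.arange(10.0), (6, 1)) + rng.normal(0, 0.01, (6, 10))
        case = -ctrl.mean(0)
        assert st.typicality_score(case, ctrl) == pytest.approx(-1.0)

    def test_leave_one_out_excludes_own_distances(self, rng):
        ctrl = rng.standard_normal((6, 10))
        base = st.typicality_score(ctrl[0], ctrl, exclude_index=0)
        perturbed = ctrl.copy()
        perturbed[0] = ctrl[0]  # same row scored...
        perturbed_other = ctrl.copy()
        perturbed_other[0] += 100.0  # ...even if its stored copy changes
        ref_a = np.delete(ctrl, 0, axis=0).mean(0)
        ref_b = np.delete(perturbed_other, 0, axis=0).mean(0)
        np.testing.assert_array_equal(ref_a, ref_b)
        assert st.typicality_score(ctrl[0], perturbed_other,
                                   exclude_index=0) == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.typicality_score(np.ones(10), np.random.default_rng(0)
                                .standard_normal((5, 10)))
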