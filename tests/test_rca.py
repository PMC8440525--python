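import numpy as np
import pytest
from scipy import linalg

from ssvep_rca import rca
from ssvep_rca.rca import FeatureTrials
from ssvep_rca.spectral import HarmonicSet, SpectralCoefficients


def make_trials(X, mask=None, freqs=None):
    n_trials, n_sensors, n_feat = X.shape
    mask = mask if mask is not None else np.ones((n_trials, n_sensors), bool)
    freqs = freqs or HarmonicSet(
        role="deviant", frequencies=tuple(2.0 * k for k in range(1, n_feat // 2 + 1))
    )
    Xm = X.copy()
    Xm[~mask] = np.nan
    return FeatureTrials(X=Xm, mask=mask, freqs=freqs,
                         subject_ids=np.array(["s0"] * n_trials),
                         condition_ids=np.array(["c"] * n_trials))


def coeffs_block(c, mask=None, subject="s0"):
    n_freq = c.shape[2]
    mask = mask if mask is not None else np.ones(c.shape[:2], bool)
    return SpectralCoefficients(
        coeffs=c, valid_mask=mask,
        freqs=HarmonicSet(role="deviant",
                          frequencies=tuple(2.0 * k for k in range(1, n_freq + 1))),
        subject_id=subject,
    )


class TestBuildFeatureTrials:
    def test_four_harmonics_give_eight_features(self, rng):
        c = rng.normal(size=(5, 6, 4)) + 1j * rng.normal(size=(5, 6, 4))
        trials = rca.build_feature_trials(coeffs_block(c))
        assert trials.n_features == 8
        np.testing.assert_allclose(trials.X[:, :, 0::2], c.real)
        np.testing.assert_allclose(trials.X[:, :, 1::2], c.imag)

    def test_one_harmonic_two_features(self, rng):
        c = rng.normal(size=(3, 4, 1)) + 0j
        trials = rca.build_feature_trials(coeffs_block(c))
        assert trials.n_features == 2

    def test_mask_propagates_per_trial(self, rng):
        c = (rng.normal(size=(4, 5, 2)) + 0j)
        mask = np.ones((4, 5), bool)
        mask[2, 3] = False
        c[~mask] = np.nan
        trials = rca.build_feature_trials(coeffs_block(c, mask=mask))
        assert np.all(np.isnan(trials.X[2, 3]))
        assert np.all(np.isfinite(trials.X[0, 3]))
        assert not trials.mask[2, 3]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rca.build_feature_trials([])

    def test_harmonic_subset(self, rng):
        c = rng.normal(size=(3, 4, 4)) + 0j
        trials = rca.build_feature_trials(coeffs_block(c), harmonic_subset=(2.0, 6.0))
        assert trials.n_features == 4
        assert trials.freqs.frequencies == (2.0, 6.0)

    def test_unknown_harmonic_rejected(self, rng):
        c = rng.normal(size=(3, 4, 4)) + 0j
        with pytest.raises(ValueError, match="not computed"):
            rca.build_feature_trials(coeffs_block(c), harmonic_subset=(5.0,))


class TestTrainRca:
    def test_dense_generalized_eig_oracle(self, rng):
        # eigenvalues match a brute-force dense generalized eigensolve
        n_trials, n_sensors, n_feat = 12, 6, 8
        X = rng.normal(size=(n_trials, n_sensors, n_feat))
        X += np.outer(rng.normal(size=n_sensors),
                      rng.normal(size=n_feat))  # shared structure
        trials = make_trials(X)
        model = rca.train_rca(trials, n_components=3)

        R_within, R_across = rca._covariances(trials)
        oracle_vals = linalg.eigh(R_across, R_within, eigvals_only=True)[::-1]
        k = model.rank_k
        np.testing.assert_allclose(model.eigenvalues, oracle_vals[:k], atol=1e-8)

        # eigenvectors match up to sign/scale: check generalized eig identity
        for j in range(model.n_components):
            w = model.W[:, j]
            lhs = R_across @ w
            rhs = model.eigenvalues[j] * (R_within @ w)
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_three_sensor_two_trial_toy(self, rng):
        X = rng.normal(size=(2, 3, 4))
        trials = make_trials(X)
        model = rca.train_rca(trials, n_components=1)
        R_within, R_across = rca._covariances(trials)
        oracle = linalg.eigh(R_across, R_within, eigvals_only=True)[::-1]
        np.testing.assert_allclose(model.eigenvalues, oracle[: model.rank_k],
                                   atol=1e-8)

    def test_rank_one_plant_recovery(self, rng):
        # identical rank-1 trials + isotropic noise: leading filter recovers
        # the planted direction
        n_sensors, n_feat, n_trials = 8, 6, 40
        u = rng.normal(size=n_sensors)
        u /= np.linalg.norm(u)
        v = rng.normal(size=n_feat)
        X = np.stack([np.outer(u, v) + 0.05 * rng.normal(size=(n_sensors, n_feat))
                      for _ in range(n_trials)])
        model = rca.train_rca(make_trials(X), n_components=1)
        # compare projection direction against u-projection oracle
        proj = model.W[:, 0] / np.linalg.norm(model.W[:, 0])
        assert abs(proj @ u) >= 0.99 or abs(np.corrcoef(model.A[:, 0], u)[0, 1]) >= 0.99

    def test_pure_noise_eigenvalue_within_permutation_null(self, rng):
        # on i.i.d. noise the leading eigenvalue is not significantly above
        # a trial-label permutation null
        n_trials, n_sensors, n_feat = 30, 5, 6
        X = rng.normal(size=(n_trials, n_sensors, n_feat))
        observed = rca.train_rca(make_trials(X), n_components=1).eigenvalues[0]
        null = []
        for _ in range(60):
            Xp = X.copy()
            for s in range(n_sensors):  # break sensor alignment across trials
                Xp[:, s, :] = Xp[rng.permutation(n_trials), s, :]
            null.append(rca.train_rca(make_trials(Xp),
                                      n_components=1).eigenvalues[0])
        assert observed <= np.quantile(null, 0.95) * 1.25

    def test_too_few_trials_rejected(self, rng):
        X = rng.normal(size=(1, 4, 2))
        with pytest.raises(ValueError, match="2 trials"):
            rca.train_rca(make_trials(X))

    def test_n_components_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(6, 4, 2))
        with pytest.raises(ValueError, match="rank"):
            rca.train_rca(make_trials(X), n_components=5)

    def test_deterministic(self, rng):
        X = rng.normal(size=(10, 6, 4))
        m1 = rca.train_rca(make_trials(X), n_components=2)
        m2 = rca.train_rca(make_trials(X), n_components=2)
        np.testing.assert_array_equal(m1.W, m2.W)


class TestForwardModel:
    def test_identity_covariance_orthonormal_w(self):
        W, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(6, 2)))
        A = rca.forward_model_matrix(W, np.eye(6))
        np.testing.assert_allclose(A, W, atol=1e-10)

    def test_forward_model_identity_holds(self, rng):
        X = rng.normal(size=(10, 6, 4))
        model = rca.train_rca(make_trials(X), n_components=2)
        G = model.W.T @ model.R_within @ model.W
        np.testing.assert_allclose(
            model.A, model.R_within @ model.W @ np.linalg.inv(G), atol=1e-8)

    def test_scaling_data_leaves_direction(self, rng):
        X = rng.normal(size=(12, 5, 4))
        m1 = rca.train_rca(make_trials(X), n_components=1)
        m2 = rca.train_rca(make_trials(10.0 * X), n_components=1)
        a1 = m1.A[:, 0] / np.linalg.norm(m1.A[:, 0])
        a2 = m2.A[:, 0] / np.linalg.norm(m2.A[:, 0])
        np.testing.assert_allclose(np.abs(a1), np.abs(a2), atol=1e-8)

    def test_planted_topography_recovered(self, rng):
        n_sensors, n_feat = 10, 8
        topo = rng.normal(size=n_sensors)
        topo /= np.linalg.norm(topo)
        v = rng.normal(size=n_feat)
        X = np.stack([np.outer(topo, 2.0 * v)
                      + 0.3 * rng.normal(size=(n_sensors, n_feat))
                      for _ in range(60)])
        model = rca.train_rca(make_trials(X), n_components=1)
        assert abs(np.corrcoef(model.A[:, 0], topo)[0, 1]) >= 0.95


class TestAlignSigns:
    def _model_and_trials(self, rng):
        topo = np.zeros(6)
        topo[2] = 1.0
        v = rng.normal(size=4)
        X = np.stack([np.outer(topo, v) + 0.1 * rng.normal(size=(6, 4))
                      for _ in range(30)])
        trials = make_trials(X)
        return rca.train_rca(trials, n_components=1), trials

    def test_idempotent(self, rng):
        model, trials = self._model_and_trials(rng)
        once = rca.align_signs(model, trials)
        twice = rca.align_signs(once, trials)
        np.testing.assert_array_equal(once.W, twice.W)

    def test_involution_restores_flipped_column(self, rng):
        model, trials = self._model_and_trials(rng)
        aligned = rca.align_signs(model, trials)
        negated = rca.align_signs(model, trials)
        negated.W = -negated.W
        negated.A = -negated.A
        restored = rca.align_signs(negated, trials)
        np.testing.assert_allclose(restored.W, aligned.W, atol=1e-10)

    def test_stable_under_random_sign_flips(self, rng):
        model, trials = self._model_and_trials(rng)
        reference = rca.align_signs(model, trials).A[:, 0]
        for seed in range(20):
            flip = -1.0 if np.random.default_rng(seed).random() < 0.5 else 1.0
            m = rca.train_rca(trials, n_components=1)
            m.W = m.W * flip
            m.A = m.A * flip
            aligned = rca.align_signs(m, trials)
            np.testing.assert_allclose(aligned.A[:, 0], reference, atol=1e-8)


class TestReliabilityExplained:
    def test_simple_normalization(self):
        np.testing.assert_allclose(rca.reliability_explained(np.array([3.0, 1.0])),
                                   [0.75, 0.25])

    def test_single(self):
        np.testing.assert_allclose(rca.reliability_explained(np.array([1.0])), [1.0])

    def test_negative_excluded_from_denominator(self):
        # direct arithmetic: [2, 1, -0.5] -> positive total 3
        out = rca.reliability_explained(np.array([2.0, 1.0, -0.5]))
        np.testing.assert_allclose(out, [2 / 3, 1 / 3, 0.0])

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rca.reliability_explained(np.array([-1.0, 0.0]))

    def test_fractions_sum_to_one(self, rng):
        lam = rng.normal(size=10)
        lam[0] = abs(lam[0]) + 1  # ensure a positive one
        assert rca.reliability_explained(lam).sum() == pytest.approx(1.0)


class TestProject:
    def test_indicator_filter_selects_sensor(self, rng):
        c = rng.normal(size=(4, 6, 3)) + 1j * rng.normal(size=(4, 6, 3))
        trials = rca.build_feature_trials(coeffs_block(c))
        model = rca.train_rca(trials, n_components=1)
        w = np.zeros((6, 1))
        w[5, 0] = 1.0
        model.W = w
        out = rca.project(trials, model)
        np.testing.assert_allclose(out[:, 0, :], c[:, 5, :], atol=1e-12)

    def test_linearity(self, rng):
        c = rng.normal(size=(3, 4, 2)) + 1j * rng.normal(size=(3, 4, 2))
        trials = rca.build_feature_trials(coeffs_block(c))
        model = rca.train_rca(trials, n_components=1)
        model.W = np.full((4, 1), 0.25)
        out = rca.project(trials, model)
        np.testing.assert_allclose(out[:, 0, :], 0.25 * c.sum(axis=1), atol=1e-12)

    def test_matrix_multiply_oracle(self, rng):
        c = rng.normal(size=(8, 5, 4)) + 1j * rng.normal(size=(8, 5, 4))
        trials = rca.build_feature_trials(coeffs_block(c))
        model = rca.train_rca(trials, n_components=2)
        out = rca.project(trials, model)
        oracle = np.einsum("sc,tsf->tcf", model.W, c)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        c = rng.normal(size=(4, 6, 2)) + 0j
        trials = rca.build_feature_trials(coeffs_block(c))
        model = rca.train_rca(trials, n_components=1)
        c2 = rng.normal(size=(4, 7, 2)) + 0j
        other = rca.build_feature_trials(coeffs_block(c2))
        with pytest.raises(ValueError, match="sensor count"):
            rca.project(other, model)


class TestTopographyCorrelation:
    def test_identical(self, rng):
        a = rng.normal(size=16)
        assert rca.topography_correlation(a, a) == pytest.approx(1.0)

    def test_negated(self, rng):
        a = rng.normal(size=16)
        assert rca.topography_correlation(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rca.topography_correlation(np.ones(8), np.arange(8.0))

    def test_shared_source_across_conditions(self, rng):
        # two datasets sharing a planted source: forward models correlate
        topo = rng.normal(size=12)
        topo /= np.linalg.norm(topo)
        models = []
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            X = np.stack([np.outer(topo, r.normal(size=6) + 3)
                          + 0.3 * r.normal(size=(12, 6)) for _ in range(50)])
            models.append(rca.train_rca(make_trials(X), n_components=1))
        r = rca.topography_correlation(models[0].A[:, 0], models[1].A[:, 0])
        assert abs(r) >= 0.95


class TestTrainJoint:
    def test_duplicated_condition_equals_single(self, rng):
        X = rng.normal(size=(10, 5, 4))
        t1, t2 = make_trials(X), make_trials(X)
        single = rca.train_rca(make_trials(np.concatenate([X, X])),
                               n_components=2)
        joint = rca.train_joint([t1, t2], n_components=2)
        np.testing.assert_allclose(np.abs(joint.W), np.abs(single.W), atol=1e-8)

    def test_common_source_recovered(self, rng):
        topo = rng.normal(size=10)
        topo /= np.linalg.norm(topo)
        conds = []
        for seed in (3, 4):
            r = np.random.default_rng(seed)
            X = np.stack([np.outer(topo, r.normal(size=4) + 2)
                          + 0.4 * r.normal(size=(10, 4)) for _ in range(40)])
            conds.append(make_trials(X))
        joint = rca.train_joint(conds, n_components=1)
        assert abs(np.corrcoef(joint.A[:, 0], topo)[0, 1]) >= 0.95

    def test_empty_condition_rejected(self, rng):
        X = rng.normal(size=(5, 4, 2))
        empty = make_trials(np.empty((0, 4, 2)))
        with pytest.raises(ValueError, match="no trials"):
            rca.train_joint([make_trials(X), empty])

    def test_mismatched_layout_rejected(self, rng):
        a = make_trials(rng.normal(size=(5, 4, 2)))
        b = make_trials(rng.normal(size=(5, 4, 6)))
        with pytest.raises(ValueError, match="incompatible"):
            rca.train_joint([a, b])

    def test_single_condition_rejected(self, rng):
        with pytest.raises(ValueError, match="2 conditions"):
            rca.train_joint([make_trials(rng.normal(size=(5, 4, 2)))])


class TestMissingData:
    def test_pairwise_complete_covariance_matches_oracle(self, rng):
        # brute-force per-entry accumulation oracle
        X = rng.normal(size=(8, 4, 3))
        mask = rng.random((8, 4)) > 0.2
        mask[:, 0] = True  # keep one sensor always valid
        trials = make_trials(X, mask=mask)
        R_within, R_across = rca._covariances(trials)

        S, F = 4, 3
        w_oracle = np.zeros((S, S))
        a_oracle = np.zeros((S, S))
        for s1 in range(S):
            for s2 in range(S):
                w_num = w_cnt = a_num = a_cnt = 0.0
                for i in range(8):
                    if mask[i, s1] and mask[i, s2]:
                        w_num += X[i, s1] @ X[i, s2]
                        w_cnt += 1
                    for j in range(8):
                        if i != j and mask[i, s1] and mask[j, s2]:
                            a_num += X[i, s1] @ X[j, s2]
                            a_cnt += 1
                w_oracle[s1, s2] = w_num / (w_cnt * F) if w_cnt else 0.0
                a_oracle[s1, s2] = a_num / (a_cnt * F) if a_cnt else 0.0
        np.testing.assert_allclose(R_within, 0.5 * (w_oracle + w_oracle.T),
                                   atol=1e-10)
        np.testing.assert_allclose(R_across, 0.5 * (a_oracle + a_oracle.T),
                                   atol=1e-10)
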