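"""Generic-covariance pooling, the regularized CSP objective and the
beta/gamma tuning protocol."""

import numpy as np
import pytest

from mitransfer import regcsp as rc
from mitransfer.spectral import csp_from_covariances
from mitransfer.synthetic import EpochSet


def make_mi_epochs(data, labels, sfreq=250.0, subject_id=1):
    return EpochSet(data=np.asarray(data, float), labels=np.asarray(labels),
                    condition="MI", modality="MEG", subject_id=subject_id,
                    sfreq=sfreq, t0=-0.5)


class TestSubjectClassCovariances:
    def test_white_noise_near_diagonal(self, rng):
        data = rng.standard_normal((60, 5, 400))
        labels = np.repeat([1, -1], 30)
        sc = rc.subject_class_covariances(make_mi_epochs(data, labels))
        corr = sc.pooled / np.sqrt(np.outer(np.diag(sc.pooled),
                                            np.diag(sc.pooled)))
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_planted_correlation_recovered(self, rng):
        n_ep, n_s = 40, 400
        data = rng.standard_normal((n_ep, 4, n_s))
        shared = rng.standard_normal((n_ep, n_s))
        data[:, 0] += 2.0 * shared
        data[:, 1] += 2.0 * shared
        labels = np.repeat([1, -1], n_ep // 2)
        sc = rc.subject_class_covariances(make_mi_epochs(data, labels))
        off = np.abs(sc.pooled.copy())
        np.fill_diagonal(off, 0.0)
        assert np.unravel_index(np.argmax(off), off.shape) in ((0, 1), (1, 0))

    def test_duplicated_epochs_leave_covariance_unchanged(self, rng):
        data = rng.standard_normal((10, 3, 200))
        labels = np.repeat([1, -1], 5)
        a = rc.subject_class_covariances(make_mi_epochs(data, labels))
        b = rc.subject_class_covariances(
            make_mi_epochs(np.concatenate([data, data]),
                           np.concatenate([labels, labels])))
        np.testing.assert_allclose(a.pooled, b.pooled, atol=1e-12)

    def test_single_class_rejected(self, rng):
        data = rng.standard_normal((10, 3, 100))
        with pytest.raises(ValueError):
            rc.subject_class_covariances(
                EpochSet(data=data, labels=np.ones(10, int), condition="rest",
                         modality="MEG", subject_id=1, sfreq=250.0, t0=0.0))


def _cov_subject(sid, C_pos, C_neg, pooled):
    return rc.SubjectCovariances(subject_id=sid, C_pos=C_pos, C_neg=C_neg,
                                 pooled=pooled)


class TestGenericCovariance:
    def test_single_subject_unit_distance(self):
        C = np.array([[2.0, 0.3], [0.3, 1.0]])
        test_pooled = np.eye(2)
        # pooled at Frobenius distance 1 from the test covariance
        train_pooled = np.eye(2) + np.array([[1.0, 0.0], [0.0, 0.0]])
        gen = rc.generic_covariance([_cov_subject(1, C, C, train_pooled)],
                                    test_pooled)
        np.testing.assert_allclose(gen.G_pos, C)
        np.testing.assert_allclose(gen.weights, [1.0])

    def test_two_subject_hand_computed_weights(self):
        """fn values of 1 and 4 give weights 1 and 1/4, averaged by 1/N."""
        test_pooled = np.eye(2)
        p1 = np.eye(2) + np.diag([1.0, 0.0])  # fn = 1
        p2 = np.eye(2) + np.diag([2.0, 0.0])  # fn = 4
        C1 = np.array([[1.0, 0.2], [0.2, 0.5]])
        C2 = np.array([[0.4, 0.0], [0.0, 2.0]])
        gen = rc.generic_covariance(
            [_cov_subject(1, C1, C1, p1), _cov_subject(2, C2, C2, p2)],
            test_pooled)
        np.testing.assert_allclose(gen.weights, [1.0, 0.25])
        np.testing.assert_allclose(gen.G_pos, (1.0 * C1 + 0.25 * C2) / 2.0)

    def test_equal_covariances_give_proportional_pool(self):
        C = np.array([[1.0, 0.1], [0.1, 1.0]])
        pooled = np.eye(2) * 1.5
        subs = [_cov_subject(i, C, C, pooled) for i in range(3)]
        gen = rc.generic_covariance(subs, np.eye(2))
        ratio = gen.G_pos / C
        assert np.allclose(ratio, ratio.flat[0])

    def test_identical_pooled_covariance_caps_weight(self):
        C = np.eye(2)
        gen = rc.generic_covariance([_cov_subject(1, C, C, np.eye(2))],
                                    np.eye(2))
        assert gen.weights[0] == rc._WEIGHT_CAP

    def test_order_invariance(self, rng):
        subs = []
        for i in range(4):
            A = rng.standard_normal((3, 3))
            C = A @ A.T / 3
            subs.append(_cov_subject(i, C, C + 0.1 * np.eye(3), C))
        test_pooled = np.eye(3)
        g1 = rc.generic_covariance(subs, test_pooled)
        g2 = rc.generic_covariance(subs[::-1], test_pooled)
        np.testing.assert_allclose(g1.G_pos, g2.G_pos)
        np.testing.assert_allclose(g1.G_neg, g2.G_neg)


class TestFitRegCSP:
    def covpair(self, rng, d=6):
        A = rng.standard_normal((d, d))
        B = rng.standard_normal((d, d))
        return A @ A.T / d, B @ B.T / d

    def test_zero_regularization_equals_plain_csp(self, rng):
        C1, C2 = self.covpair(rng)
        gen = rc.generic_covariance(
            [_cov_subject(1, np.eye(6), np.eye(6), np.eye(6))], 2 * np.eye(6))
        params = rc.RegCSPParams(beta=0.0, gamma=0.0)
        a = rc.fit_regcsp(C1, C2, gen, params, n_components=4)
        b = csp_from_covariances(C1, C2, 4)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(np.abs(a.filters), np.abs(b.filters),
                                   atol=1e-8)

    def test_full_pooling_ignores_subject_covariances(self, rng):
        Ca1, Ca2 = self.covpair(rng)
        Cb1, Cb2 = self.covpair(rng)
        G1, G2 = self.covpair(rng)
        gen = rc.GenericCovariance(G_pos=G1, G_neg=G2, weights=np.ones(1),
                                   n_subjects=1)
        params = rc.RegCSPParams(beta=1.0, gamma=0.0)
        a = rc.fit_regcsp(Ca1, Ca2, gen, params, 4)
        b = rc.fit_regcsp(Cb1, Cb2, gen, params, 4)
        np.testing.assert_allclose(a.filters, b.filters, atol=1e-10)

    def test_full_shrinkage_gives_flat_spectrum(self, rng):
        C1, C2 = self.covpair(rng)
        gen = rc.GenericCovariance(G_pos=C1, G_neg=C2, weights=np.ones(1),
                                   n_subjects=1)
        params = rc.RegCSPParams(beta=0.0, gamma=1.0)
        model = rc.fit_regcsp(C1, C2, gen, params, 4)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-9)

    def test_minus_identity_variant_stays_finite(self, rng):
        C1, C2 = self.covpair(rng)
        gen = rc.GenericCovariance(G_pos=C1, G_neg=C2, weights=np.ones(1),
                                   n_subjects=1)
        params = rc.RegCSPParams(beta=0.2, gamma=0.5, identity_sign="minus")
        model = rc.fit_regcsp(C1, C2, gen, params, 4)
        assert np.isfinite(model.filters).all()
        assert np.isfinite(model.eigenvalues).all()

    def test_eigenvalues_invariant_to_joint_scaling(self, rng):
        C1, C2 = self.covpair(rng)
        a = csp_from_covariances(C1, C2, 4)
        b = csp_from_covariances(7.0 * C1, 7.0 * C2, 4)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)

    def test_off_grid_params_rejected(self):
        with pytest.raises(ValueError):
            rc.RegCSPParams(beta=0.35, gamma=0.0)
        with pytest.raises(ValueError):
            rc.RegCSPParams(beta=0.3, gamma=1.4)


class TestTuning:
    def _subjects(self, rng, n=5):
        subs = []
        for i in range(n):
            data = rng.standard_normal((8, 4, 100))
            labels = np.repeat([1, -1], 4)
            es = make_mi_epochs(data, labels, subject_id=i + 1)
            from mitransfer.spectral import epoch_covariances
            subs.append(rc.RegCspSubject(
                covs=rc.subject_class_covariances(es),
                epoch_covs=epoch_covariances(es.data, trace_norm=False),
                labels=labels))
        return subs

    def test_split_halves_even_odd_by_id(self, rng):
        subs = self._subjects(rng, 5)
        opt, train = rc.split_halves(subs[::-1])  # order must not matter
        assert [s.subject_id for s in opt] == [1, 3, 5]
        assert [s.subject_id for s in train] == [2, 4]

    def test_tie_break_returns_origin(self, rng, monkeypatch):
        subs = self._subjects(rng, 5)
        monkeypatch.setattr(rc, "_score", lambda *a, **k: 0.5)
        params = rc.tune_regcsp(subs, n_components=2)
        assert (params.beta, params.gamma) == (0.0, 0.0)

    def test_unique_argmax_recovered(self, rng, monkeypatch):
        subs = self._subjects(rng, 5)
        target = (0.3, 0.1)
        current = {}
        orig_fit_eval = rc._fit_eval

        def fit_eval(train_half, pooled, params, n_components):
            current["p"] = (params.beta, params.gamma)
            return orig_fit_eval(train_half, pooled, params, n_components)

        monkeypatch.setattr(rc, "_fit_eval", fit_eval)
        monkeypatch.setattr(
            rc, "_score",
            lambda *a, **k: 0.9 if np.allclose(current["p"], target) else 0.5)
        params = rc.tune_regcsp(subs, n_components=2)
        assert (params.beta, params.gamma) == pytest.approx(target)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            rc.tune_regcsp(self._subjects(rng, 3), n_components=2)
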