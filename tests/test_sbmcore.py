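"""Order selection, whitening and Infomax ICA.

The MDL tests check the implementation against an independently coded
evaluation of the criterion; the ICA tests check blind-source-separation
quality against ground truth (Amari index, Hungarian matching) and the
optimizer against an exhaustive one-parameter rotation search.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from sbmgm import InfomaxICA, amari_index, estimate_order_mdl, mdl_curve, whiten
from sbmgm.errors import InsufficientDataError, RankError
from sbmgm.sbmcore import center, infomax_ica


def mdl_reference(x):
    """Independent MDL evaluation: SVD-based eigenvalues, explicit sums."""
    x = np.asarray(x, dtype=float)
    n, v = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    xc = xc - xc.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    lam = (sv**2) / v
    p = n - 1
    lam = lam[:p]
    out = []
    for k in range(p):
        tail = lam[k:]
        log_geo = sum(math.log(t) for t in tail) / len(tail)
        log_arith = math.log(sum(tail) / len(tail))
        data_term = -(p - k) * v * (log_geo - log_arith)
        penalty = 0.5 * k * (2 * p - k + 1) * math.log(v)
        out.append(data_term + penalty)
    return np.array(out)


class TestMDL:
    def test_curve_matches_independent_evaluation(self, rng):
        x = rng.standard_normal((20, 300)) + 2.0 * rng.standard_normal(
            (20, 1)
        ) * rng.standard_normal((1, 300))
        np.testing.assert_allclose(mdl_curve(x), mdl_reference(x), rtol=1e-8)

    def test_recovers_five_strong_sources(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((60, 5))
        s = rng.standard_normal((5, 4000))
        x = a @ s + 0.1 * rng.standard_normal((60, 4000))
        curve = mdl_curve(x)
        assert int(np.argmin(curve)) == 5
        assert estimate_order_mdl(x) == 5
        assert int(np.argmin(mdl_reference(x))) == 5

    def test_rank_one_signal(self):
        rng = np.random.default_rng(1)
        x = np.outer(rng.standard_normal(30), rng.standard_normal(2000))
        x += 1e-4 * rng.standard_normal(x.shape)
        assert estimate_order_mdl(x) == 1

    def test_pure_noise_stays_low(self):
        low = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            low += estimate_order_mdl(rng.standard_normal((60, 4000))) <= 3
        assert low >= 95

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            estimate_order_mdl(np.ones((2, 10)))

    def test_subsampling_correction_on_smooth_noise(self, default_cohort):
        # smoothed noise inflates the classic criterion; random-voxel
        # subsampling restores the planted order
        _, truth, x = default_cohort
        assert estimate_order_mdl(x) > truth.sources_true.shape[0]
        assert (
            estimate_order_mdl(x, subsample_fraction=0.1)
            == truth.sources_true.shape[0]
        )


class TestWhiten:
    def test_identity_covariance(self, rng):
        x = rng.standard_normal((20, 500))
        z, dw, ev, disc = whiten(x, 10)
        cov = z @ z.T / z.shape[1]
        np.testing.assert_allclose(cov, np.eye(10), atol=1e-6)

    def test_dewhitening_restores_rank_k_approximation(self, rng):
        x = rng.standard_normal((15, 400))
        xc, _, _ = center(x)
        for k in (3, 14):
            z, dw, ev, disc = whiten(x, k)
            recon = dw @ z
            rel = np.linalg.norm(xc - recon) / np.linalg.norm(xc)
            assert rel <= disc**0.5 + 1e-6
        z, dw, ev, disc = whiten(x, 14)  # full rank after centering
        assert np.linalg.norm(xc - dw @ z) / np.linalg.norm(xc) < 1e-6

    def test_k_exceeding_rank_raises(self, rng):
        x = rng.standard_normal((10, 200))
        with pytest.raises(RankError):
            whiten(x, 10)  # N-1 = 9 is the cap with cohort centering
        low_rank = np.outer(rng.standard_normal(10), rng.standard_normal(200))
        with pytest.raises(RankError):
            whiten(low_rank, 5)


class TestInfomax:
    def test_separates_uniform_mixture_extended(self):
        """Uniform sources are sub-Gaussian: the extended (kurtosis-
        switching) update separates them to near-zero Amari index."""
        rng = np.random.default_rng(1)
        s = rng.uniform(-np.sqrt(3), np.sqrt(3), (2, 20000))
        a = np.array([[1.0, 0.6], [0.4, 1.0]])
        z, dw, _, _ = whiten(a @ s, 2, remove_mean_map=False)
        d = infomax_ica(z, dw, seed=3, extended=True)
        assert amari_index(d.mixing, a) < 0.05

    def test_separates_laplace_mixture_plain(self):
        rng = np.random.default_rng(2)
        s = rng.laplace(size=(2, 20000))
        a = np.array([[1.0, 0.6], [0.4, 1.0]])
        z, dw, _, _ = whiten(a @ s, 2, remove_mean_map=False)
        d = infomax_ica(z, dw, seed=3)
        assert amari_index(d.mixing, a) < 0.05

    def test_recovers_planted_cohort_sources(self, default_cohort):
        _, truth, x = default_cohort
        k = truth.sources_true.shape[0]
        est = InfomaxICA(n_components=k, random_state=0).fit(x)
        corr = np.abs(np.corrcoef(est.components_, truth.sources_true)[:k, k:])
        rows, cols = linear_sum_assignment(-corr)
        assert (corr[rows, cols] > 0.9).all()

    def test_reconstruction_bound_and_conventions(self, default_cohort):
        _, truth, x = default_cohort
        est = InfomaxICA(n_components=8, random_state=0).fit(x)
        d = est.decomposition_
        xc, _, _ = center(x)
        rel = np.linalg.norm(xc - d.mixing @ d.sources) / np.linalg.norm(xc)
        # squared relative Frobenius error equals the discarded variance
        assert rel**2 <= d.discarded_variance + 1e-6
        # unit-variance sources, zero mean, positive skew, ordered by
        # explained subject-space variance
        np.testing.assert_allclose(d.sources.std(axis=1), 1.0, atol=1e-8)
        assert np.abs(d.sources.mean(axis=1)).max() < 1e-8
        from scipy.stats import skew

        assert (skew(d.sources, axis=1) > 0).all()
        ev = np.sum(d.mixing**2, axis=0)
        assert (np.diff(ev) <= 1e-9).all()

    def test_seeded_determinism_bitwise(self, default_cohort):
        _, _, x = default_cohort
        a = InfomaxICA(n_components=4, random_state=5).fit(x)
        b = InfomaxICA(n_components=4, random_state=5).fit(x)
        assert np.array_equal(a.components_, b.components_)
        assert np.array_equal(a.mixing_, b.mixing_)

    def test_different_seeds_agree_after_alignment(self, default_cohort):
        _, _, x = default_cohort
        a = InfomaxICA(n_components=8, random_state=1).fit(x)
        b = InfomaxICA(n_components=8, random_state=2).fit(x)
        corr = np.abs(np.corrcoef(a.components_, b.components_)[:8, 8:])
        rows, cols = linear_sum_assignment(-corr)
        assert (corr[rows, cols] > 0.95).all()

    def test_matches_exhaustive_rotation_search(self):
        """On a noiseless 2-source super-Gaussian mixture, the Infomax
        unmixing rotation matches the argmax of the logistic likelihood
        over a 0.001-rad grid to within 0.01 rad."""
        rng = np.random.default_rng(5)
        s = rng.laplace(size=(2, 8000))
        a = np.array([[1.2, 0.5], [-0.3, 1.0]])
        z, dw, _, _ = whiten(a @ s, 2, remove_mean_map=False)
        d = infomax_ica(z, dw, seed=2, tol=1e-9, max_iter=2048)
        w_eff = d.sources @ z.T @ np.linalg.inv(z @ z.T)
        u, _, vt = np.linalg.svd(w_eff)
        rot = u @ vt
        ang_est = np.arctan2(rot[0, 1], rot[0, 0]) % (np.pi / 2)

        thetas = np.arange(0.0, np.pi, 0.001)
        best_ll, best_theta = -np.inf, None
        for theta in thetas:
            c, sn = np.cos(theta), np.sin(theta)
            u2 = np.array([[c, sn], [-sn, c]]) @ z
            ll = float(np.sum(-u2 - 2.0 * np.log1p(np.exp(-u2))))
            if ll > best_ll:
                best_ll, best_theta = ll, theta
        ang_grid = best_theta % (np.pi / 2)
        diff = abs(ang_est - ang_grid)
        assert min(diff, np.pi / 2 - diff) < 0.01

    def test_transform_recovers_fitted_loadings(self, default_cohort):
        _, _, x = default_cohort
        est = InfomaxICA(n_components=6, random_state=0).fit(x)
        np.testing.assert_allclose(est.transform(x), est.mixing_, atol=1e-6)

    def test_sklearn_params_roundtrip(self):
        est = InfomaxICA(n_components=4, tol=1e-7)
        assert est.get_params()["tol"] == 1e-7
        est.set_params(extended=True)
        assert est.extended


class TestAmariIndex:
    def test_zero_for_scaled_permutation(self, rng):
        a = rng.standard_normal((5, 5))
        perm = np.eye(5)[rng.permutation(5)]
        scale = np.diag(rng.uniform(0.5, 2.0, 5) * rng.choice([-1, 1], 5))
        assert amari_index(a @ perm @ scale, a) < 1e-10
        assert amari_index(a, a) < 1e-12

    def test_worst_case_all_ones(self):
        # P = |pinv(I) @ ones| = all-ones: hand evaluation of the formula
        # gives row terms 2*(2/1-1)=2, column terms 2, so (2+2)/(2*2*1)=1
        a_true = np.ones((2, 2))
        assert amari_index(np.eye(2), a_true) == pytest.approx(1.0)

    def test_singular_estimate_raises(self):
        with pytest.raises(RankError):
            amari_index(np.ones((3, 3)), np.eye(3))

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_scale_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        a = rng.standard_normal((k, k)) + np.eye(k)
        perm = np.eye(k)[rng.permutation(k)]
        scale = np.diag(rng.uniform(0.5, 2.0, k))
        assert amari_index(a @ perm @ scale, a) < 1e-8
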