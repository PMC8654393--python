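"""Group inference: BMR, PEB, random-effects model selection."""

import numpy as np
import pytest

from microdcm.cmc import ModelError
from microdcm.group import (ReductionError, bayesian_model_reduction,
                            bms_random_effects, build_design, peb_fit,
                            DesignMatrix)
from microdcm.inversion import Posterior


def conjugate_fit(A, y, sd, v0):
    P = A.T @ A / sd ** 2 + np.diag(1 / v0)
    S = np.linalg.inv(P)
    mu = S @ (A.T @ y / sd ** 2)
    return mu, S


def log_evidence(A, y, sd, v0, m0=None):
    m0 = np.zeros(v0.size) if m0 is None else m0
    C = A @ np.diag(v0) @ A.T + np.eye(y.size) * sd ** 2
    r = y - A @ m0
    s, ld = np.linalg.slogdet(C)
    return float(-0.5 * (r @ np.linalg.solve(C, r) + ld
                         + y.size * np.log(2 * np.pi)))


class TestBayesianModelReduction:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.A = rng.standard_normal((30, 4))
        self.sd = 0.2
        self.y = self.A @ np.array([0.4, 0.0, -0.3, 0.1]) \
            + rng.standard_normal(30) * self.sd
        self.v0 = np.full(4, 0.5)
        self.mu, self.S = conjugate_fit(self.A, self.y, self.sd, self.v0)

    def test_identity_reduction_changes_nothing(self):
        mu_r, S_r, dF = bayesian_model_reduction(
            self.mu, self.S, np.zeros(4), self.v0, np.zeros(4), self.v0)
        assert dF == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(mu_r, self.mu, atol=1e-12)

    def test_matches_direct_inversion_under_reduced_prior(self):
        vr = self.v0.copy()
        vr[1] = 1e-10
        mu_r, S_r, dF = bayesian_model_reduction(
            self.mu, self.S, np.zeros(4), self.v0, np.zeros(4), vr)
        mu_d, S_d = conjugate_fit(self.A, self.y, self.sd, vr)
        np.testing.assert_allclose(mu_r, mu_d, atol=1e-8)
        np.testing.assert_allclose(S_r, S_d, atol=1e-8)
        exact = (log_evidence(self.A, self.y, self.sd, vr)
                 - log_evidence(self.A, self.y, self.sd, self.v0))
        assert dF == pytest.approx(exact, abs=1e-8)

    def test_pinning_a_barely_informed_null_parameter_raises_evidence(self):
        # a nuisance parameter with a weak design column and zero true
        # effect: pinning it saves complexity without losing accuracy
        rng = np.random.default_rng(12)
        A = np.hstack([self.A, 0.05 * rng.standard_normal((30, 1))])
        v0 = np.append(self.v0, 0.5)
        mu, S = conjugate_fit(A, self.y, self.sd, v0)
        vr = v0.copy()
        vr[-1] = 1e-10
        _, _, dF = bayesian_model_reduction(mu, S, np.zeros(5), v0,
                                            np.zeros(5), vr)
        exact = (log_evidence(A, self.y, self.sd, vr)
                 - log_evidence(A, self.y, self.sd, v0))
        assert dF == pytest.approx(exact, abs=1e-8)
        assert dF > 0   # complexity saving

    def test_singular_posterior_raises_advice(self):
        S = np.zeros((2, 2))
        with pytest.raises(ReductionError, match="floor"):
            bayesian_model_reduction(np.zeros(2), S, np.zeros(2),
                                     np.ones(2), np.zeros(2), np.ones(2))


def _toy_posts(rng, design, true_b, p=3, sig_btw=0.1, sig_meas=0.1,
               v0=None):
    v0 = np.full(p, 1 / 16) if v0 is None else v0
    posts = []
    for i in range(design.X.shape[0]):
        th = design.X[i] @ true_b + rng.standard_normal(p) * sig_btw
        y = th + rng.standard_normal(p) * sig_meas
        P = np.eye(p) / sig_meas ** 2 + np.diag(1 / v0)
        S = np.linalg.inv(P)
        mu = S @ (y / sig_meas ** 2)
        posts.append(Posterior(names=[f"p{j}" for j in range(p)], mean=mu,
                               cov=S, prior_mean=np.zeros(p),
                               prior_cov=np.diag(v0),
                               hyper_mean=np.zeros(1), hyper_cov=np.eye(1),
                               free_energy=0.0))
    return posts


class TestPeb:
    def test_homogeneous_cohort_recovers_common_mean(self):
        rng = np.random.default_rng(21)
        D = DesignMatrix(np.ones((20, 1)), ["mean"])
        true_b = np.array([[0.2, -0.1, 0.0]])
        posts = _toy_posts(rng, D, true_b, sig_btw=0.01, sig_meas=0.02)
        res = peb_fit(posts, D)
        np.testing.assert_allclose(res.beta_mean[0], true_b[0], atol=0.03)

    def test_no_spurious_effects_on_null_contrasts(self):
        rng = np.random.default_rng(22)
        D = build_design(["Con"] * 15 + ["PScz"] * 15)
        posts = _toy_posts(rng, D, np.zeros((2, 3)))
        res = peb_fit(posts, D)
        assert np.all(res.probability[1:] < 0.95)

    def test_group_effect_detected_with_correct_sign(self):
        rng = np.random.default_rng(23)
        D = build_design(["Con"] * 20 + ["PScz"] * 20 + ["Rel"] * 20,
                         scheme="risk-diagnosis")
        true_b = np.zeros((3, 3))
        true_b[2, 0] = 0.25
        posts = _toy_posts(rng, D, true_b)
        res = peb_fit(posts, D)
        r = res.regressors.index("diagnosis:PScz>Rel")
        assert res.probability[r, 0] > 0.95
        assert res.beta_mean[r, 0] > 0.1

    def test_rank_deficient_design_names_columns(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        X[:, 2] = 2 * np.arange(10)
        with pytest.raises(ModelError, match="collinear"):
            DesignMatrix(X, ["mean", "a", "b"])

    def test_single_subject_identity_design_resembles_subject(self):
        rng = np.random.default_rng(24)
        D = DesignMatrix(np.ones((1, 1)), ["mean"])
        posts = _toy_posts(rng, D, np.array([[0.3, -0.2, 0.1]]),
                           sig_btw=0.0, sig_meas=0.05)
        res = peb_fit(posts, D)
        np.testing.assert_allclose(res.beta_mean[0], posts[0].mean,
                                   atol=0.05)

    def test_random_covariate_leaves_effect_signs(self):
        rng = np.random.default_rng(25)
        labels = ["Con"] * 15 + ["PScz"] * 15
        true_b = np.zeros((2, 3))
        true_b[1, 0] = 0.3
        flips = 0
        for rep in range(5):
            base = build_design(labels)
            posts = _toy_posts(np.random.default_rng(100 + rep), base,
                               true_b)
            r0 = peb_fit(posts, base)
            cov = rng.standard_normal(30)
            with_cov = build_design(labels, covariates=cov[:, None],
                                    covariate_names=["junk"])
            posts_c = _toy_posts(np.random.default_rng(100 + rep), base,
                                 true_b)
            r1 = peb_fit(posts_c, with_cov)
            i = r0.regressors.index("PScz>Con")
            if np.sign(r0.beta_mean[i, 0]) != np.sign(r1.beta_mean[i, 0]):
                flips += 1
        assert flips == 0

    def test_bma_pruning_keeps_real_effects(self):
        rng = np.random.default_rng(26)
        D = build_design(["Con"] * 20 + ["PScz"] * 20)
        true_b = np.zeros((2, 3))
        true_b[1, 0] = 0.3
        posts = _toy_posts(rng, D, true_b)
        res = peb_fit(posts, D, prune=True)
        i = res.regressors.index("PScz>Con")
        assert abs(res.bma_mean[i, 0]) > 0.1
        # pruned null effects shrink toward zero
        assert abs(res.bma_mean[i, 2]) < abs(res.beta_mean[i, 2]) + 1e-12


class TestBms:
    def test_identical_evidences_give_chance_probabilities(self):
        res = bms_random_effects(np.zeros((20, 4)), seed=1)
        np.testing.assert_allclose(res.protected_xp, 0.25, atol=0.01)
        assert res.bor > 0.9

    def test_dominant_model_wins_outright(self):
        L = np.zeros((20, 3))
        L[:, 1] = 10.0
        res = bms_random_effects(L, seed=2)
        assert res.protected_xp[1] > 0.99

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(3)
        res = bms_random_effects(rng.normal(0, 3, (15, 5)), seed=3)
        assert res.exceedance_p.sum() == pytest.approx(1.0)
        assert res.protected_xp.sum() == pytest.approx(1.0)

    def test_model_permutation_permutes_outputs(self):
        rng = np.random.default_rng(4)
        L = rng.normal(0, 2, (12, 4))
        perm = [2, 0, 3, 1]
        r1 = bms_random_effects(L, seed=5)
        r2 = bms_random_effects(L[:, perm], seed=5)
        np.testing.assert_allclose(r2.expected_p, r1.expected_p[perm],
                                   atol=1e-9)
        np.testing.assert_allclose(r2.protected_xp, r1.protected_xp[perm],
                                   atol=0.01)

    def test_single_model_rejected(self):
        with pytest.raises(ModelError):
            bms_random_effects(np.zeros((10, 1)))
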