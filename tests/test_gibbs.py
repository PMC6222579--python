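"""Gibbs sampler correctness: truncated-normal draws, BLUP and kernel-trick
oracles, degenerate models, summaries and DIC."""

import numpy as np
import pytest
from scipy import stats

import omisurv as ov
from omisurv.containers import KernelMatrix
from omisurv.gibbs import (BayesKernelSurvival, batch_means_mcse, deviance,
                           dic, sample_truncated_normal, summarize)
from _oracles import blup_solution, feature_space_gibbs


class TestTruncatedNormal:
    def test_unconstrained_limit(self, rng):
        d = sample_truncated_normal(2.0, 3.0, -np.inf, rng=rng, size=100_000)
        assert abs(d.mean() - 2.0) < 4 * 3.0 / np.sqrt(100_000)

    def test_half_normal_mean(self, rng):
        d = sample_truncated_normal(0.0, 1.0, 0.0, rng=rng, size=100_000)
        target = np.sqrt(2 / np.pi)
        assert abs(d.mean() - target) / target < 0.01

    def test_support_contract(self, rng):
        lower = rng.normal(size=1000)
        d = sample_truncated_normal(0.0, 1.0, lower, rng=rng)
        assert np.all(d > lower)

    def test_extreme_tail_stable_and_supported(self, rng):
        for a in (8.5, 12.0, 30.0):
            d = sample_truncated_normal(0.0, 1.0, a, rng=rng, size=2000)
            assert np.all(np.isfinite(d)) and np.all(d > a)
            # conditional mean ~ a + 1/a for far tails
            assert abs(d.mean() - (a + 1 / a)) < 0.05 * (a + 1 / a)

    def test_matches_scipy_distribution(self, rng):
        # two-sample KS against scipy's truncnorm for a hard tail
        a = 4.0
        mine = sample_truncated_normal(1.0, 2.0, 1.0 + a * 2.0, rng=rng, size=5000)
        ref = stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=2.0, size=5000,
                                  random_state=rng)
        assert stats.ks_2samp(mine, ref).pvalue > 1e-3

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            sample_truncated_normal(0.0, 0.0, 1.0)


def _toy_instance(rng, n=30, p=10, sig2_beta=0.08, sig2e=0.25):
    """Small uncensored regression with a single linear kernel.

    With K = Zc Zc' * s (s chosen so mean(diag K) = 1), the feature-space
    prior beta_j ~ N(0, sig2_beta) corresponds to sig2_k = sig2_beta / s.
    """
    Z = rng.normal(size=(n, p))
    Zc = Z - Z.mean(axis=0)
    beta = rng.normal(0, np.sqrt(sig2_beta), p)
    y = 1.5 + Zc @ beta + rng.normal(0, np.sqrt(sig2e), n)
    K = Zc @ Zc.T
    s = 1.0 / np.mean(np.diag(K))
    km = KernelMatrix.from_matrix(K * s, list(range(n)))
    sig2_k = sig2_beta / s
    return Zc, y, km, sig2_k, sig2_beta, sig2e


class TestGibbsOracles:
    def test_blup_fixed_variances(self, rng):
        """Posterior mean with fixed variances, no censoring, equals the
        closed-form mixed-model (BLUP) solution within 3 MC SEs."""
        Zc, y, km, sig2_k, _, sig2e = _toy_instance(rng)
        n = len(y)
        est = BayesKernelSurvival(
            n_iter=12000, burn_in=2000, thin=2,
            fixed_variances={"k": sig2_k, "residual": sig2e}, random_state=7)
        est.fit(None, np.c_[np.exp(y), np.zeros(n)], kernels={"k": km})
        ch = est.chains_
        X = np.ones((n, 1))
        _, (u_ref,), eta_ref = blup_solution(
            X, y, [(km.eigenvectors, km.eigenvalues, sig2_k)], sig2e)
        u_hat = ch.u["k"].mean(axis=0)
        mcse = np.array([batch_means_mcse(ch.u["k"][:, i]) for i in range(n)])
        z = np.abs(u_hat - u_ref) / np.maximum(mcse, 1e-12)
        assert np.max(z) < 3.0, f"max |u - BLUP| = {np.max(z):.2f} MC SEs"

    def test_kernel_trick_equivalence(self, rng):
        """Kernel-representation predictions equal the explicit per-feature
        ridge-prior sampler's within 3 combined MC SEs."""
        Zc, y, km, sig2_k, sig2_beta, sig2e = _toy_instance(rng)
        n = len(y)
        est = BayesKernelSurvival(
            n_iter=12000, burn_in=2000, thin=2,
            fixed_variances={"k": sig2_k, "residual": sig2e}, random_state=8)
        est.fit(None, np.c_[np.exp(y), np.zeros(n)], kernels={"k": km})
        eta_kernel = est.chains_.eta
        etas_feat = feature_space_gibbs(np.ones((n, 1)), y, Zc, sig2_beta=sig2_beta,
                                        sig2e=sig2e, n_iter=12000, burn_in=2000, seed=9)
        for i in range(n):
            se = np.hypot(batch_means_mcse(eta_kernel[:, i]),
                          batch_means_mcse(etas_feat[:, i]))
            assert abs(eta_kernel[:, i].mean() - etas_feat[:, i].mean()) < 3 * se

    def test_no_kernels_reduces_to_least_squares(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = 0.7 + 0.5 * x + rng.normal(0, 0.3, n)
        est = BayesKernelSurvival(n_iter=6000, burn_in=1000, thin=1, random_state=3)
        est.fit(x[:, None], np.c_[np.exp(y), np.zeros(n)])
        ch = est.chains_
        ls = np.linalg.lstsq(np.c_[np.ones(n), x], y, rcond=None)[0]
        for j in range(2):
            mcse = batch_means_mcse(ch.alpha[:, j])
            assert abs(ch.alpha[:, j].mean() - ls[j]) < 4 * mcse + 1e-3

    def test_prior_predictive_variances(self):
        """With every outcome masked the chain has no data: variance draws
        must reproduce the scaled-inv-chi2 prior mean S/(df-2)."""
        n = 5
        rng = np.random.default_rng(0)
        K = np.eye(n)
        est = BayesKernelSurvival(n_iter=40000, burn_in=2000, thin=2, prior_df=5.0,
                                  prior_scales={"k": 0.9, "residual": 1.2},
                                  random_state=17)
        y = np.c_[np.full(n, np.nan), np.full(n, np.nan)]
        mask = np.ones(n, dtype=bool)
        mask[0] = False  # one token uncensored row, its time carries no surprise
        y[0] = [1.0, 0.0]
        est.fit(None, y, kernels={"k": K}, mask=mask)
        ch = est.chains_
        # prior mean with df=5: S/(df-2) = S/3
        assert abs(ch.sigma2["k"].mean() - 0.9 / 3) < 0.04
        assert abs(ch.sigma2_e.mean() - 1.2 / 3) < 0.12


class TestCensoring:
    def test_latent_draws_exceed_bounds_full_chain(self, small_dataset, small_kernels):
        spec = ov.ModelSpec(fixed=["age"], kernels=["methylation"],
                            n_iter=1500, burn_in=500, thin=1)
        from omisurv import gibbs
        est = gibbs.fit(spec, small_dataset.cohort, small_kernels, random_state=5)
        ch = est.chains_
        cens = ch.censor == 1
        bounds = ch.log_time[cens]
        assert ch.ylat[:, cens].min(axis=0).shape == bounds.shape
        assert np.all(ch.ylat[:, cens] > bounds[None, :])

    def test_zero_rank_kernel_errors(self, rng):
        n = 10
        y = np.c_[np.exp(rng.normal(size=n)), np.zeros(n)]
        with pytest.raises(ValueError, match="zero retained rank"):
            BayesKernelSurvival(n_iter=200, burn_in=50).fit(
                None, y, kernels={"null": np.zeros((n, n))})

    def test_requires_uncensored_observation(self, rng):
        n = 10
        y = np.c_[np.exp(rng.normal(size=n)), np.ones(n)]
        with pytest.raises(ValueError, match="uncensored"):
            BayesKernelSurvival(n_iter=200, burn_in=50).fit(None, y)


class TestSummarize:
    def _const_chains(self, v=2.5, S=400, n=4):
        from omisurv.gibbs import PosteriorChains
        return PosteriorChains(
            alpha=np.full((S, 1), 1.0), sigma2={"k": np.full(S, v)},
            sigma2_e=np.full(S, 0.5), u={"k": np.zeros((S, n))},
            eta=np.zeros((S, n)), ylat=np.zeros((S, n)),
            sample_ids=list(range(n)), log_time=np.zeros(n),
            censor=np.zeros(n), mask=np.zeros(n, bool), fixed_names=["intercept"])

    def test_constant_chain(self):
        s = summarize(self._const_chains())
        row = s.variance_table.loc["k"]
        assert row["mean"] == 2.5 and row["sd"] == 0.0 and row["mc_error"] == 0.0
        assert not row["mc_error_flag"]

    def test_proportions_sum_to_one(self, small_dataset, small_kernels):
        from omisurv import gibbs
        spec = ov.ModelSpec(fixed=[], kernels=["methylation", "expression"],
                            n_iter=1200, burn_in=400, thin=2)
        est = gibbs.fit(spec, small_dataset.cohort, small_kernels, random_state=1)
        s = summarize(est.chains_)
        assert abs(s.variance_table["proportion"].sum() - 1.0) < 1e-8

    def test_iid_chain_mc_error(self):
        # batch-means SE of an IID N(0,1) mean ~ 1/sqrt(S)
        rng = np.random.default_rng(5)
        errs = [batch_means_mcse(rng.standard_normal(4000)) for _ in range(40)]
        assert abs(np.mean(errs) - 1 / np.sqrt(4000)) / (1 / np.sqrt(4000)) < 0.3

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="draws"):
            summarize(self._const_chains(S=50))


class TestDIC:
    def test_single_draw_degenerate(self):
        from omisurv.gibbs import PosteriorChains
        n = 6
        rng = np.random.default_rng(2)
        logt = rng.normal(size=n)
        eta = np.full(n, logt.mean())
        ch = PosteriorChains(
            alpha=np.full((1, 1), logt.mean()), sigma2={}, sigma2_e=np.array([0.8]),
            u={}, eta=eta[None, :], ylat=logt[None, :], sample_ids=list(range(n)),
            log_time=logt, censor=np.zeros(n), mask=np.zeros(n, bool))
        expected = deviance(logt, np.zeros(n), eta, 0.8)
        assert abs(dic(ch) - expected) < 1e-10  # p_D = 0 for a single draw

    def test_deviance_additivity_under_duplication(self, rng):
        n = 20
        logt = rng.normal(size=n)
        eta = rng.normal(size=n)
        cens = (rng.random(n) < 0.3).astype(float)
        d1 = deviance(logt, cens, eta, 0.7)
        d2 = deviance(np.r_[logt, logt], np.r_[cens, cens], np.r_[eta, eta], 0.7)
        assert abs(d2 - 2 * d1) < 1e-9

    def test_extreme_censored_tail_is_finite(self):
        # survival probability ~ Phi(-20): log computed in stable tail form
        d = deviance(np.array([20.0]), np.array([1.0]), np.array([0.0]), 1.0)
        assert np.isfinite(d) and d > 0


class TestPredict:
    def test_intercept_only_predicts_posterior_mean_mu(self, rng):
        n = 40
        y = rng.normal(2.0, 1.0, n)
        mask = np.zeros(n, bool)
        mask[:10] = True
        est = BayesKernelSurvival(n_iter=3000, burn_in=500, thin=1, random_state=4)
        est.fit(None, np.c_[np.exp(y), np.zeros(n)], mask=mask)
        preds = est.predict()
        assert preds.shape == (10,)
        mu_bar = est.chains_.alpha[:, 0].mean()
        np.testing.assert_allclose(preds, mu_bar, atol=0.05)

    def test_identical_subjects_get_equal_predictions(self, rng):
        """Two rows identical in the kernel (one masked) predict alike."""
        n = 24
        Z = rng.normal(size=(n, 8))
        Z[-1] = Z[0]  # masked row duplicates a training row
        Zc = Z - Z.mean(axis=0)
        beta = rng.normal(0, 1.0, 8)
        y = Zc @ beta  # noiseless
        K = Zc @ Zc.T / np.mean(np.diag(Zc @ Zc.T / 8)) / 8
        mask = np.zeros(n, bool)
        mask[-1] = True
        est = BayesKernelSurvival(n_iter=8000, burn_in=2000, thin=2,
                                  fixed_variances={"residual": 1e-4},
                                  random_state=6)
        est.fit(None, np.c_[np.exp(y), np.zeros(n)], kernels={"k": K}, mask=mask)
        eta = est.chains_.posterior_mean_eta()
        assert abs(eta[-1] - eta[0]) < 0.05

    def test_projection_agrees_with_masked_fit(self, small_dataset, small_kernels):
        """Cross-kernel projection of posterior-mean effects reproduces the
        masked-outcome (transductive) predictions."""
        from omisurv import gibbs
        cohort = small_dataset.cohort
        n = cohort.n
        mask = np.zeros(n, bool)
        mask[-15:] = True
        spec = ov.ModelSpec(fixed=[], kernels=["methylation"],
                            n_iter=4000, burn_in=1000, thin=2)
        est = gibbs.fit(spec, cohort, small_kernels, mask=mask, random_state=10)
        trans = est.predict()

        km = small_kernels["methylation"]
        train_ids = [s for s, m in zip(cohort.sample_ids, mask) if not m]
        test_ids = [s for s, m in zip(cohort.sample_ids, mask) if m]
        est2 = BayesKernelSurvival(n_iter=4000, burn_in=1000, thin=2, random_state=10)
        y = np.c_[cohort.time, cohort.censor][~mask]
        est2.fit(None, y, kernels={"methylation": km.subset(train_ids)})
        proj = est2.predict_out_of_sample(
            None, {"methylation": km.cross(test_ids, train_ids)})
        # two different chains and conditioning sets: agreement is statistical
        assert np.corrcoef(trans, proj)[0, 1] > 0.9
        assert np.abs(trans - proj).mean() < 0.2


def test_dic_prefers_true_kernel_over_permuted():
    """Destroying the kernel's sample correspondence by permutation removes
    most of its DIC advantage: the true kernel wins in >= 90% of replicates."""
    import omisurv as ov
    from omisurv import gibbs as g

    wins = 0
    reps = 10
    for rep in range(reps):
        cfg = ov.SimConfig(n_patients=100, features_per_omic={"methylation": 500},
                           true_variance_components={"methylation": 0.6},
                           residual_variance=0.4, fixed_effects={}, seed=900 + rep)
        ds = ov.simulate_dataset(cfg)
        km = ov.build_kernels(dict(ds.omics))["methylation"]
        rng = np.random.default_rng(rep)
        perm = rng.permutation(km.n)
        km_perm = KernelMatrix.from_matrix(km.K[np.ix_(perm, perm)], km.sample_ids)
        spec = ov.ModelSpec(fixed=[], kernels=["k"], n_iter=1500, burn_in=500, thin=2)
        dic_true = g.fit(spec, ds.cohort, {"k": km}, random_state=rep).dic()
        dic_perm = g.fit(spec, ds.cohort, {"k": km_perm}, random_state=rep).dic()
        wins += dic_true < dic_perm
    assert wins >= 9
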