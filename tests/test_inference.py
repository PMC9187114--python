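"""Hierarchical estimation: convergence diagnostics, prior recovery, DIC
and posterior predictive checks."""

import numpy as np
import pytest

from itcvigour.inference import (dic, fit_hierarchical, posterior_predictive_rt,
                                 rhat_report)
from itcvigour.models import ModelSpec
from itcvigour.sampler import MCMCConfig
from itcvigour.stats import effective_sample_size, hdi, split_rhat
from itcvigour import wfpt


class TestSplitRhat:
    def test_identical_chains_give_one(self):
        x = np.sin(np.arange(4000.0))
        assert split_rhat(np.stack([x, x])) == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        assert split_rhat(chains) > 2.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (2, 500))
        assert split_rhat(chains) == pytest.approx(split_rhat(3.0 * chains - 7.0), rel=1e-12)

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, (2, 1000)) + np.array([[0.0], [0.3]])
        ours = split_rhat(chains)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).normal(size=(1, 100)))


class TestHDI:
    def test_normal_hdi_matches_quantiles(self):
        draws = np.random.default_rng(3).normal(0, 1, 200_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        draws = np.random.default_rng(4).gamma(2.0, size=50_000)
        lo, hi = hdi(draws, 0.95)
        ref = az.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)


class TestFitting:
    def test_softmax_recovery_on_small_cohort(self, softmax_cohort_small, short_cfg):
        """Refitting the generating softmax model recovers the empirical
        group means of the simulated subjects."""
        post = fit_hierarchical(softmax_cohort_small.trials,
                                ModelSpec("softmax", "null", "absolute"), cfg=short_cfg)
        sp = softmax_cohort_small.subject_params
        assert post.group_mean("logk") == pytest.approx(sp.logk.mean(), abs=0.5)
        assert post.group_mean("s") == pytest.approx(sp.s.mean(), abs=0.4)
        assert post.group_mean("log_beta") == pytest.approx(np.log(sp.beta).mean(), abs=0.5)
        report = rhat_report(post)
        assert (report["rhat"] < 1.2).all()

    def test_prior_only_run_recovers_hyperprior(self, softmax_cohort_small):
        """With the likelihood disabled the sampler reproduces the prior
        means of the hyperparameters (narrow priors keep MC error small)."""
        from itcvigour.sampler import HyperPrior
        cfg = MCMCConfig(n_chains=2, burn_in=500, n_samples=2000, seed=13)
        priors = [HyperPrior(mean_loc=loc, mean_scale=1.0, sd_scale=0.5)
                  for loc in (-4.0, 0.0, 0.5)]
        post = fit_hierarchical(softmax_cohort_small.trials,
                                ModelSpec("softmax", "null", "absolute"),
                                priors=priors, cfg=cfg, prior_only=True)
        assert post.group_mean("logk") == pytest.approx(-4.0, abs=0.4)
        assert post.group_mean("s") == pytest.approx(0.0, abs=0.4)
        assert post.group_mean("log_beta") == pytest.approx(0.5, abs=0.4)
        # group SD hyperprior: half-normal(0, 0.5), mean 0.5*sqrt(2/pi) = 0.4
        sig = post.sigma[:, :, 0].ravel()
        assert sig.mean() == pytest.approx(0.4, abs=0.15)

    def test_thinning_halves_draws_not_posterior(self, softmax_cohort_small):
        spec = ModelSpec("softmax", "null", "absolute")
        thin1 = MCMCConfig(n_chains=2, burn_in=300, n_samples=400, thinning=1, seed=3)
        thin2 = MCMCConfig(n_chains=2, burn_in=300, n_samples=200, thinning=2, seed=3)
        a = fit_hierarchical(softmax_cohort_small.trials, spec, cfg=thin1)
        b = fit_hierarchical(softmax_cohort_small.trials, spec, cfg=thin2)
        assert a.mu.shape[1] == 2 * b.mu.shape[1]
        assert a.group_mean("logk") == pytest.approx(b.group_mean("logk"), abs=0.25)

    def test_single_subject_rejected(self, softmax_cohort_small, short_cfg):
        one = softmax_cohort_small.trials.query("subject_id == 's001'")
        with pytest.raises(ValueError):
            fit_hierarchical(one, ModelSpec("softmax", "null", "absolute"), cfg=short_cfg)


class TestDIC:
    def test_point_mass_posterior_has_zero_pd(self, softmax_cohort_small, short_cfg):
        post = fit_hierarchical(softmax_cohort_small.trials,
                                ModelSpec("softmax", "null", "absolute"), cfg=short_cfg)
        # freeze every draw at one subject-level parameter point
        post.theta = np.broadcast_to(post.theta[0, 0], post.theta.shape).copy()
        from itcvigour.models import build_choice_data, natural_theta, subject_loglik
        data = build_choice_data(softmax_cohort_small.trials)
        ll = subject_loglik(natural_theta(post.theta[0, 0], post.params), data, post.spec)
        post.deviance = np.full_like(post.deviance, -2 * ll.sum())
        out = dic(post, softmax_cohort_small.trials)
        assert out["pD"] == pytest.approx(0.0, abs=1e-6)
        assert out["dic"] == pytest.approx(out["deviance_at_mean"], abs=1e-6)

    def test_effective_parameters_nonnegative(self, softmax_cohort_small, short_cfg):
        post = fit_hierarchical(softmax_cohort_small.trials,
                                ModelSpec("softmax", "null", "absolute"), cfg=short_cfg)
        out = dic(post, softmax_cohort_small.trials)
        assert out["pD"] > -1.0  # positive up to MC error
        # more subjects' worth of parameters than the 3 group means alone
        assert out["pD"] > 3.0


class TestPosteriorPredictive:
    def test_point_posterior_matches_analytic_mixture(self, default_trials):
        """With a point posterior the predictive signed-RT density is the
        analytic WFPT mixture over the trial-wise drifts."""
        from itcvigour.cohort import simulate_cohort, default_truth, GeneratingTruth
        from itcvigour.models import ModelSpec as MS
        truth = GeneratingTruth(
            MS("ddm", "sigmoid", "absolute"),
            dict(default_truth("ddm-sig-absolute").group_means),
            group_sds={k: 0.0 for k in
                       ["log_alpha", "log_tau", "logit_z", "log_vcoeff",
                        "log_vmax", "logk", "s"]})
        cohort = simulate_cohort(truth, 2, seed=8)
        cfg = MCMCConfig(n_chains=2, burn_in=5, n_samples=10, seed=1)
        post = fit_hierarchical(cohort.trials, truth.model, cfg=cfg)
        # freeze the posterior at the generating values (point posterior)
        from itcvigour.models import model_params
        vals = {"log_alpha": np.log(3.27), "log_tau": np.log(1.23),
                "logit_z": np.log(0.51 / 0.49), "log_vcoeff": np.log(0.77),
                "log_vmax": np.log(1.07), "logk": -4.45, "s": -0.82}
        for i, p in enumerate(post.params):
            post.theta[:, :, :, i] = vals[p.name]
        ppc = posterior_predictive_rt(post, cohort.trials, n_datasets=40, seed=2)
        sid = cohort.subject_params.subject_id.iloc[0]
        sim = ppc[sid]["simulated"]
        # predictive mass on the negative axis ~ P(SS) implied by the params
        from itcvigour.models import build_choice_data, natural_theta, trial_drift
        data = build_choice_data(cohort.trials)
        theta = natural_theta(post.theta[0, 0], post.params)
        v = trial_drift(theta, data, post.spec)[0]
        p_ll = wfpt.upper_probability(v, 3.27, 0.51).mean()
        assert np.mean(sim < 0) == pytest.approx(1 - p_ll, abs=0.03)

    def test_single_dataset_is_valid(self, default_trials):
        from itcvigour.cohort import simulate_cohort, default_truth
        cohort = simulate_cohort(default_truth("ddm-sig-absolute"), 2, seed=9)
        cfg = MCMCConfig(n_chains=2, burn_in=30, n_samples=30, seed=1)
        post = fit_hierarchical(cohort.trials, cohort.truth.model, cfg=cfg)
        ppc = posterior_predictive_rt(post, cohort.trials, n_datasets=1, seed=3)
        sid = cohort.subject_params.subject_id.iloc[0]
        assert len(ppc[sid]["simulated"]) > 0
        dens = ppc[sid]["kde"](np.linspace(-10, 10, 50))
        assert np.all(np.isfinite(dens)) and dens.max() > 0


def test_effective_sample_size_of_iid_draws():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 2000))
    ess = effective_sample_size(x)
    assert 2500 < ess < 5500  # ~n for iid draws
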