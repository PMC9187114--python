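"""Hierarchical Bayesian estimation, convergence checking, DIC model
comparison and posterior predictive response-time distributions.

Subject parameters are drawn from group-level Gaussians on unconstrained
sampling scales; hyperpriors are weakly informative (group means
Normal(0, 10^2), the log-discount-rate mean centred at -4; group SDs
half-Normal(0, 2^2)).  Any correct MCMC scheme satisfies the contract;
the bundled sampler is Metropolis-within-Gibbs (see :mod:`.sampler`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec
from .models import (ChoiceData, ModelSpec, Param, build_choice_data,
                     model_params, natural_theta, subject_loglik)
from .sampler import (DESK_PROFILE, HyperPrior, MCMCConfig, run_chain)
from .stats import effective_sample_size, hdi, split_rhat
from .wfpt import simulate_ddm_trials
from .models import trial_drift

__all__ = [
    "PosteriorSamples", "fit_hierarchical", "rhat_report", "dic",
    "compare_models", "posterior_predictive_rt", "default_hyperpriors",
]


def default_hyperpriors(params: list[Param]) -> list[HyperPrior]:
    return [HyperPrior(mean_loc=p.hyper_mean, mean_scale=10.0, sd_scale=2.0) for p in params]


@dataclass
class PosteriorSamples:
    """MCMC draws of one fitted model.

    Group-level arrays have shape (n_chains, n_draws, P); subject-level
    draws (n_chains, n_draws, n_subjects, P).  Parameters are stored on
    the sampling scale; ``group_mean_natural`` reports back-transformed
    group means.
    """

    spec: ModelSpec
    cfg: MCMCConfig
    params: list[Param]
    subject_ids: list
    mu: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    deviance: np.ndarray
    accept_rate: np.ndarray

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def _idx(self, name: str) -> int:
        return self.param_names.index(name)

    def mu_draws(self, name: str) -> np.ndarray:
        """Flattened group-mean draws of one parameter (sampling scale)."""
        return self.mu[:, :, self._idx(name)].ravel()

    def group_mean(self, name: str) -> float:
        """Posterior mean of the group-level mean, sampling scale."""
        return float(self.mu_draws(name).mean())

    def group_mean_natural(self, name: str) -> float:
        """Group mean mapped to the natural scale (e.g. ``exp`` for
        log-sampled parameters); keyed by sampling-scale name."""
        p = self.params[self._idx(name)]
        return float(p.to_natural(self.group_mean(name)))

    def group_hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        return hdi(self.mu_draws(name), prob)

    def subject_natural(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters on the natural scale."""
        mean_theta = self.theta.mean(axis=(0, 1))  # (n_subjects, P)
        nat = natural_theta(mean_theta, self.params)
        out = pd.DataFrame(nat)
        out.insert(0, "subject_id", self.subject_ids)
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.params):
            d = self.mu[:, :, i]
            lo, hi_ = hdi(d.ravel(), 0.95)
            rows.append({
                "parameter": f"mu_{p.name}",
                "mean": d.mean(),
                "sd": d.std(),
                "hdi95_lo": lo,
                "hdi95_hi": hi_,
                "natural_mean": p.to_natural(d.mean()),
                "rhat": split_rhat(d),
                "ess": effective_sample_size(d),
            })
            s = self.sigma[:, :, i]
            lo, hi_ = hdi(s.ravel(), 0.95)
            rows.append({
                "parameter": f"sigma_{p.name}",
                "mean": s.mean(),
                "sd": s.std(),
                "hdi95_lo": lo,
                "hdi95_hi": hi_,
                "natural_mean": np.nan,
                "rhat": split_rhat(s),
                "ess": effective_sample_size(s),
            })
        return pd.DataFrame(rows)

    def converged(self) -> bool:
        return bool((rhat_report(self)["rhat"] <= self.cfg.rhat_threshold).all())

    def to_long_csv(self, path) -> None:
        """Group-level draws in long format (chain, iter, parameter, value)."""
        rows = []
        C, D, P = self.mu.shape
        for c in range(C):
            for i, p in enumerate(self.params):
                rows.append(pd.DataFrame({
                    "chain": c,
                    "iter": np.arange(D),
                    "parameter": f"mu_{p.name}",
                    "value": self.mu[c, :, i],
                }))
                rows.append(pd.DataFrame({
                    "chain": c,
                    "iter": np.arange(D),
                    "parameter": f"sigma_{p.name}",
                    "value": self.sigma[c, :, i],
                }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def fit_hierarchical(trials: pd.DataFrame, spec: ModelSpec,
                     priors: list[HyperPrior] | None = None,
                     cfg: MCMCConfig | None = None,
                     design: DesignSpec | None = None,
                     prior_only: bool = False,
                     verbose: bool = False) -> PosteriorSamples:
    """Fit a hierarchical model to a long trial table.

    The table must already be preprocessed (RT exclusions and, for DDM
    variants, per-subject tail trimming).  At least two subjects are
    required.  Non-convergence (any split R-hat above the configured
    threshold) is flagged via ``PosteriorSamples.converged()`` — the
    result is returned either way, never silently accepted.
    """
    cfg = cfg or DESK_PROFILE
    design = design or DesignSpec()
    data = build_choice_data(trials, design)
    if data.n_subjects < 2:
        raise ValueError("hierarchical estimation needs at least two subjects")
    if spec.family == "ddm" and np.isnan(
            np.where(data.mask, data.signed_rt, 1.0)).any():
        raise ValueError("DDM fits require response times for every trial")
    params = model_params(spec)
    hyper = priors or default_hyperpriors(params)

    def loglik_fn(theta_sampling: np.ndarray) -> np.ndarray:
        return subject_loglik(natural_theta(theta_sampling, params), data, spec)

    init = np.array([p.init for p in params])
    results = []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng((cfg.seed, c))
        results.append(run_chain(loglik_fn, data.n_subjects, hyper, init, cfg, rng,
                                 prior_only=prior_only))
        if verbose:
            print(f"chain {c}: mean acceptance {results[-1].accept_rate.round(2)}")
    post = PosteriorSamples(
        spec=spec, cfg=cfg, params=params, subject_ids=data.subject_ids,
        mu=np.stack([r.mu for r in results]),
        sigma=np.stack([r.sigma for r in results]),
        theta=np.stack([r.theta for r in results]),
        deviance=np.stack([r.deviance for r in results]),
        accept_rate=np.stack([r.accept_rate for r in results]),
    )
    return post


def rhat_report(samples: PosteriorSamples) -> pd.DataFrame:
    """Split R-hat and effective sample size per group-level parameter."""
    if samples.mu.shape[0] < 2:
        raise ValueError("R-hat needs at least two chains")
    rows = []
    for i, p in enumerate(samples.params):
        for kind, arr in (("mu", samples.mu), ("sigma", samples.sigma)):
            c = arr[:, :, i]
            rows.append({
                "parameter": f"{kind}_{p.name}",
                "rhat": split_rhat(c),
                "ess": effective_sample_size(c),
            })
    return pd.DataFrame(rows)


def dic(samples: PosteriorSamples, trials: pd.DataFrame,
        design: DesignSpec | None = None) -> dict:
    """Deviance information criterion: DIC = Dbar + pD, pD = Dbar - D(theta_bar).

    The plug-in deviance is evaluated at the posterior mean of the
    subject-level parameters on the unconstrained sampling scale.
    """
    data = build_choice_data(trials, design or DesignSpec())
    if data.subject_ids != samples.subject_ids:
        raise ValueError("trial table does not match the fitted subjects")
    dbar = float(samples.deviance.mean())
    theta_bar = samples.theta.mean(axis=(0, 1))
    ll = subject_loglik(natural_theta(theta_bar, samples.params), data, samples.spec)
    d_hat = -2.0 * float(ll.sum())
    if not np.isfinite(d_hat):
        raise ValueError("non-finite deviance at the posterior mean")
    pd_ = dbar - d_hat
    return {"dic": dbar + pd_, "pD": pd_, "mean_deviance": dbar, "deviance_at_mean": d_hat}


def compare_models(fits: dict[str, PosteriorSamples], trials: pd.DataFrame,
                   design: DesignSpec | None = None) -> pd.DataFrame:
    """Rank fitted variants by DIC (rank 1 = lowest DIC)."""
    rows = []
    for label, post in fits.items():
        d = dic(post, trials, design)
        rows.append({"model": label, "dic": d["dic"], "pD": d["pD"]})
    out = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def posterior_predictive_rt(samples: PosteriorSamples, trials: pd.DataFrame,
                            n_datasets: int = 100, seed: int = 0,
                            design: DesignSpec | None = None) -> dict:
    """Simulate signed-RT datasets from posterior draws and pool them.

    For each simulated dataset one posterior draw of the subject-level
    parameters is used to generate a full cohort of choices and RTs from
    the Wiener process.  Returns per-subject pooled signed RTs plus the
    observed signed RTs, ready for kernel-density overlay.
    """
    from scipy.stats import gaussian_kde

    if samples.spec.family != "ddm":
        raise ValueError("posterior predictive RTs require a DDM fit")
    if n_datasets < 1:
        raise ValueError("need at least one simulated dataset")
    design = design or DesignSpec()
    data = build_choice_data(trials, design)
    rng = np.random.default_rng(seed)
    C, D = samples.mu.shape[:2]
    pooled: dict = {sid: [] for sid in data.subject_ids}
    for d in range(n_datasets):
        c = int(rng.integers(C))
        i = int(rng.integers(D))
        theta = natural_theta(samples.theta[c, i], samples.params)
        v = trial_drift(theta, data, samples.spec)
        a = np.broadcast_to(theta["alpha"][:, None], v.shape)
        tau = np.broadcast_to(theta["tau"][:, None], v.shape)
        z = np.broadcast_to(theta["z"][:, None], v.shape)
        if samples.spec.variant == "sigmoid-shift":
            a = a + data.I * theta["s_alpha"][:, None]
            tau = tau + data.I * theta["s_tau"][:, None]
            z = z + data.I * theta["s_z"][:, None]
        m = data.mask
        srt = simulate_ddm_trials(v[m], a[m], tau[m], z[m],
                                  seed=int(rng.integers(2**31)))
        subj_idx = np.broadcast_to(np.arange(data.n_subjects)[:, None], v.shape)[m]
        for j, sid in enumerate(data.subject_ids):
            pooled[sid].append(srt[subj_idx == j])
    out = {}
    for j, sid in enumerate(data.subject_ids):
        sim = np.concatenate(pooled[sid])
        obs = data.signed_rt[j][data.mask[j]]
        out[sid] = {
            "simulated": sim,
            "observed": obs,
            "kde": gaussian_kde(sim),
        }
    return out
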