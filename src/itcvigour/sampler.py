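"""Metropolis-within-Gibbs sampler for the group-Gaussian hierarchy.

Every model shares the same structure: subject-level parameters theta_jp
(on unconstrained sampling scales) are drawn from group Gaussians
N(mu_p, sigma_p^2); group means get Normal hyperpriors, group SDs
half-Normal hyperpriors.  Updates per iteration:

* subject-level parameters: vectorised random-walk Metropolis, one
  parameter block at a time across all subjects (subjects are
  conditionally independent);
* group means: exact conjugate Gibbs draw;
* group SDs: slice sampling on log(sigma).

Proposal scales adapt towards ~44% acceptance during burn-in only, so the
retained draws come from a fixed transition kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``burn_in`` draws are discarded, then
    ``n_samples`` draws are retained per chain after ``thinning``."""

    n_chains: int = 2
    burn_in: int = 2000
    n_samples: int = 2000
    thinning: int = 1
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in < 0 or self.n_samples < 1 or self.thinning < 1:
            raise ValueError("invalid MCMC sizes")

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


#: Conservative long-run settings (2 chains, burn-in 50,000, thinning 2),
#: the classic JAGS-style configuration for hierarchical DDMs.
FULL_PROFILE = MCMCConfig(n_chains=2, burn_in=50_000, n_samples=25_000, thinning=2)
#: Desk-scale default used by the bundled analyses and tests.
DESK_PROFILE = MCMCConfig(n_chains=2, burn_in=2000, n_samples=2000, thinning=1)
#: Reduced profile for the costlier DDM fits.
REDUCED_PROFILE = MCMCConfig(n_chains=2, burn_in=1500, n_samples=1500, thinning=1)


@dataclass(frozen=True)
class HyperPrior:
    """Normal hyperprior on a group mean and half-Normal on its SD."""

    mean_loc: float = 0.0
    mean_scale: float = 10.0
    sd_scale: float = 2.0


def slice_sample(logpdf: Callable[[float], float], x0: float, rng: np.random.Generator,
                 width: float = 1.0, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping-out scheme)."""
    logy = logpdf(x0) + np.log(rng.uniform())
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logpdf(left) <= logy:
            break
        left -= width
    for _ in range(max_steps):
        if logpdf(right) <= logy:
            break
        right += width
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


@dataclass
class ChainResult:
    mu: np.ndarray        # (n_draws, P)
    sigma: np.ndarray     # (n_draws, P)
    theta: np.ndarray     # (n_draws, n_subjects, P)
    deviance: np.ndarray  # (n_draws,)
    accept_rate: np.ndarray  # (P,)


def run_chain(loglik_fn: Callable[[np.ndarray], np.ndarray],
              n_subjects: int,
              hyper: list[HyperPrior],
              init: np.ndarray,
              cfg: MCMCConfig,
              rng: np.random.Generator,
              prior_only: bool = False) -> ChainResult:
    """Run one MCMC chain.

    ``loglik_fn`` maps a (n_subjects, P) sampling-scale matrix to
    per-subject log-likelihoods; ``init`` gives sampling-scale starting
    values per parameter; ``hyper`` one :class:`HyperPrior` per parameter.
    """
    P = len(init)
    theta = np.tile(init, (n_subjects, 1)) + 0.05 * rng.standard_normal((n_subjects, P))
    mu = init.astype(float).copy()
    sigma = np.full(P, 0.3)
    scales = np.full(P, 0.25)
    if prior_only:
        loglik = lambda th: np.zeros(n_subjects)  # noqa: E731
    else:
        loglik = loglik_fn
    ll = loglik(theta)

    n_iter = cfg.burn_in + cfg.n_samples * cfg.thinning
    keep = cfg.n_samples
    out_mu = np.empty((keep, P))
    out_sigma = np.empty((keep, P))
    out_theta = np.empty((keep, n_subjects, P))
    out_dev = np.empty(keep)
    acc = np.zeros(P)
    n_adapt = np.zeros(P)
    acc_post = np.zeros(P)
    n_post = np.zeros(P)
    kept = 0

    for it in range(n_iter):
        adapting = it < cfg.burn_in
        for p in range(P):
            prop = theta.copy()
            prop[:, p] = theta[:, p] + scales[p] * rng.standard_normal(n_subjects)
            ll_prop = loglik(prop)
            logr = (
                ll_prop - ll
                - 0.5 * ((prop[:, p] - mu[p]) ** 2 - (theta[:, p] - mu[p]) ** 2) / sigma[p] ** 2
            )
            accept = np.log(rng.uniform(size=n_subjects)) < logr
            theta[accept, p] = prop[accept, p]
            ll[accept] = ll_prop[accept]
            if adapting:
                acc[p] += accept.mean()
                n_adapt[p] += 1
                if n_adapt[p] % 25 == 0:
                    rate = acc[p] / 25.0
                    scales[p] *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    acc[p] = 0.0
            else:
                acc_post[p] += accept.mean()
                n_post[p] += 1

        # group means: conjugate normal-normal
        for p in range(P):
            prec = n_subjects / sigma[p] ** 2 + 1.0 / hyper[p].mean_scale ** 2
            mean = (theta[:, p].sum() / sigma[p] ** 2
                    + hyper[p].mean_loc / hyper[p].mean_scale ** 2) / prec
            mu[p] = mean + rng.standard_normal() / np.sqrt(prec)

        # group SDs: slice sample log(sigma), half-normal prior + Jacobian
        for p in range(P):
            resid2 = float(np.sum((theta[:, p] - mu[p]) ** 2))
            s_scale = hyper[p].sd_scale

            def logpost(logs: float) -> float:
                s = np.exp(logs)
                return (-n_subjects * logs - resid2 / (2.0 * s * s)
                        - s * s / (2.0 * s_scale**2) + logs)

            sigma[p] = np.exp(slice_sample(logpost, float(np.log(sigma[p])), rng, width=0.5))

        if not adapting and (it - cfg.burn_in + 1) % cfg.thinning == 0 and kept < keep:
            out_mu[kept] = mu
            out_sigma[kept] = sigma
            out_theta[kept] = theta
            out_dev[kept] = -2.0 * float(ll.sum())
            kept += 1

    return ChainResult(out_mu, out_sigma, out_theta, out_dev,
                       acc_post / np.maximum(n_post, 1))
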