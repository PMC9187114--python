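"""Decision-conflict and value outcomes, the hierarchical Bayesian linear
regression linking them to response vigour and fixation shifts, and the
posterior decision machinery (directional Bayes factors, HDIs, ROPE).

Conflict from the softmax rule is the LL choice probability with values
above 0.5 flipped (``1 - p``), so 0.5 is maximal conflict; the flipped
probabilities are binned into five equal intervals of [0, 0.5].  The
regression is

    y_t = alpha + beta1*a_t + beta2*b_t + beta3*c_t + beta4*d_t

with y the conflict or value outcome, a/b/c the within-subject z-scored
grip amplitude/centroid/width and d the absolute fixation-shift count;
subject-level coefficients are drawn from group Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import MCMCConfig, DESK_PROFILE, slice_sample
from .stats import bf_evidence_label, directional_bayes_factor, hdi
from .valuation import DiscountParams, DriftScaling, drift_sigmoid

OUTCOME_KINDS = ("softmax-conflict", "drift-rate", "value-difference",
                 "value-sum-subjective", "value-sum-objective")

ROPE_LIMITS = (-0.05, 0.05)


def conflict_from_softmax(p_ll) -> np.ndarray:
    """Flip choice probabilities above 0.5; the result lies in [0, 0.5]
    with 0.5 = maximum conflict."""
    p = np.asarray(p_ll, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("choice probabilities must lie in [0, 1]")
    out = np.where(p <= 0.5, p, 1.0 - p)
    return out if out.ndim else float(out)


def bin_conflict(flipped) -> np.ndarray:
    """Five equal-width conflict bins on [0, 0.5].

    Convention: bins are upper-edge inclusive, (0.1*(i-1), 0.1*i], with
    bin 1 additionally closed at 0 — so 0.07 -> bin 1, 0.10 -> bin 1,
    0.47 -> bin 5.  The exact tie behaviour of interior edges is a
    documented convention; any single consistent choice leaves the binned
    series invariant under the flip p <-> 1-p.
    """
    y = np.asarray(flipped, dtype=float)
    if np.any((y < 0) | (y > 0.5)):
        raise ValueError("flipped conflict must lie in [0, 0.5]")
    edges = np.array([0.1, 0.2, 0.3, 0.4])
    # round away float noise so p and 1-p land in the same bin
    bins = 1 + np.searchsorted(edges, np.round(y, 12), side="left")
    out = bins.astype(int)
    return out if out.ndim else int(out)


def conflict_from_drift(dsv, posterior_means: dict, I=0) -> np.ndarray:
    """Trial-wise drift rate at posterior-mean DDM parameters."""
    scaling = DriftScaling(
        v_coeff=posterior_means["v_coeff"], v_max=posterior_means["v_max"],
        s_vcoeff=posterior_means.get("s_vcoeff", 0.0),
        s_vmax=posterior_means.get("s_vmax", 0.0))
    return drift_sigmoid(dsv, scaling, I)


def value_outcomes(trials: pd.DataFrame, subject_params: pd.DataFrame,
                   condition: str = "all") -> pd.DataFrame:
    """Per-trial |dSV|, subjective value sum and objective amount sum.

    Subjective values use each subject's discount parameters (typically
    posterior means from the absolute-value DDM fit).  ``condition``
    restricts to ``low``/``high`` trials for the split value-sum
    regressions.
    """
    sp = subject_params.set_index("subject_id")
    out = []
    for sid, g in trials.groupby("subject_id", sort=False):
        p = DiscountParams(k=float(sp.loc[sid, "logk"]), s=float(sp.loc[sid, "s"]))
        from .valuation import value_table
        vt = value_table(g, p)
        vt["abs_dsv"] = vt["dsv"].abs()
        vt["ssv_objective"] = vt["ll_amount"] + vt["ss_amount"]
        out.append(vt)
    df = pd.concat(out, ignore_index=True)
    if condition != "all":
        want = 1 if condition == "high" else 0
        df = df[df["condition"] == want].reset_index(drop=True)
    return df


def zscore_within_subject(df: pd.DataFrame, cols, subject_col: str = "subject_id") -> pd.DataFrame:
    """Within-subject z-standardisation of the given columns."""
    out = df.copy()
    for c in cols:
        def z(x):
            sd = x.std(ddof=0)
            return (x - x.mean()) / sd if sd > 0 else x * 0.0
        out[c] = df.groupby(subject_col)[c].transform(z)
    return out


def build_regression_design(fits: pd.DataFrame, trials: pd.DataFrame,
                            standardise_d: bool = False) -> pd.DataFrame:
    """Assemble the regression predictors: within-subject z-scored grip
    amplitude/centroid/width and the (by default unstandardised) absolute
    fixation-shift count."""
    df = fits.merge(trials[["subject_id", "trial", "n_fixation_shifts"]],
                    on=["subject_id", "trial"])
    df = df[df["converged"]] if "converged" in df else df
    df = df.rename(columns={"a": "amp", "b": "cen", "c": "wid"})
    df = zscore_within_subject(df, ["amp", "cen", "wid"])
    df["d"] = df["n_fixation_shifts"].astype(float)
    if standardise_d:
        df = zscore_within_subject(df, ["d"])
    return df[["subject_id", "trial", "amp", "cen", "wid", "d"]]


@dataclass
class HierRegressionPosterior:
    """Posterior draws of the hierarchical regression: group-level means
    (chains, draws, 5) ordered (intercept, beta1..beta4), plus group SDs
    and subject-level coefficients."""

    coef_names: list
    mu: np.ndarray
    sigma: np.ndarray
    beta_subj: np.ndarray  # (chains, draws, n_subjects, 5)
    sigma_resid: np.ndarray
    subject_ids: list = field(default_factory=list)

    def draws(self, name: str) -> np.ndarray:
        return self.mu[:, :, self.coef_names.index(name)].ravel()


def fit_hier_linear_regression(y: np.ndarray, X: pd.DataFrame,
                               cfg: MCMCConfig | None = None) -> HierRegressionPosterior:
    """Gibbs sampler for the hierarchical linear regression.

    Subject-level coefficient vectors are multivariate-normal conjugate
    given the group Gaussians and the residual variance; group means are
    normal-normal conjugate; group SDs are slice-sampled under
    half-Normal(0, 2) priors; the residual variance gets a conjugate
    inverse-gamma(0.5, 0.5) prior.  Trials trimmed upstream must already
    be absent from both ``y`` and ``X``.
    """
    cfg = cfg or DESK_PROFILE
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("outcome and design lengths differ")
    subjects = sorted(X["subject_id"].unique())
    cols = ["amp", "cen", "wid", "d"]
    for c in cols:
        if np.allclose(X[c].to_numpy(dtype=float).std(), 0.0):
            raise ValueError(f"zero-variance predictor {c!r}")
    Xs, ys = [], []
    for sid in subjects:
        m = (X["subject_id"] == sid).to_numpy()
        Xs.append(np.column_stack([np.ones(m.sum()), X.loc[m, cols].to_numpy(dtype=float)]))
        ys.append(y[m])
    n_subj, P = len(subjects), 5
    xtx = [x.T @ x for x in Xs]
    xty = [x.T @ yy for x, yy in zip(Xs, ys)]

    coef_names = ["alpha", "beta1", "beta2", "beta3", "beta4"]
    keep = cfg.n_samples
    mu_out = np.empty((cfg.n_chains, keep, P))
    sig_out = np.empty((cfg.n_chains, keep, P))
    beta_out = np.empty((cfg.n_chains, keep, n_subj, P))
    resid_out = np.empty((cfg.n_chains, keep))
    n_total = sum(len(yy) for yy in ys)

    for c in range(cfg.n_chains):
        rng = np.random.default_rng((cfg.seed, 7, c))
        mu = np.zeros(P)
        sigma = np.full(P, 0.5)
        beta = np.tile(mu, (n_subj, 1)) + 0.1 * rng.standard_normal((n_subj, P))
        s2 = 1.0
        kept = 0
        n_iter = cfg.burn_in + keep * cfg.thinning
        for it in range(n_iter):
            # subject coefficients: MVN conjugate
            prior_prec = np.diag(1.0 / sigma**2)
            for j in range(n_subj):
                prec = xtx[j] / s2 + prior_prec
                cov = np.linalg.inv(prec)
                mean = cov @ (xty[j] / s2 + mu / sigma**2)
                beta[j] = rng.multivariate_normal(mean, cov, method="cholesky")
            # group means: normal-normal with N(0, 10^2) hyperprior
            for p in range(P):
                prec = n_subj / sigma[p] ** 2 + 1.0 / 100.0
                mean = beta[:, p].sum() / sigma[p] ** 2 / prec
                mu[p] = mean + rng.standard_normal() / np.sqrt(prec)
            # group SDs: slice sampling on log sigma, half-normal(0,2) prior
            for p in range(P):
                resid2 = float(np.sum((beta[:, p] - mu[p]) ** 2))

                def logpost(logs: float) -> float:
                    s = np.exp(logs)
                    return (-n_subj * logs - resid2 / (2 * s * s)
                            - s * s / 8.0 + logs)

                sigma[p] = np.exp(slice_sample(logpost, float(np.log(sigma[p])), rng, width=0.5))
            # residual variance: conjugate inverse-gamma(0.5, 0.5)
            sse = sum(float(np.sum((yy - x @ b) ** 2))
                      for x, yy, b in zip(Xs, ys, beta))
            s2 = 1.0 / rng.gamma(0.5 + n_total / 2.0, 1.0 / (0.5 + sse / 2.0))
            if it >= cfg.burn_in and (it - cfg.burn_in + 1) % cfg.thinning == 0 and kept < keep:
                mu_out[c, kept] = mu
                sig_out[c, kept] = sigma
                beta_out[c, kept] = beta
                resid_out[c, kept] = np.sqrt(s2)
                kept += 1

    return HierRegressionPosterior(coef_names, mu_out, sig_out, beta_out,
                                   resid_out, subjects)


def hdi_and_rope(draws: np.ndarray, rope=ROPE_LIMITS) -> dict:
    """85%/95% HDIs, ROPE overlap of the 95% HDI and the decision rule:
    reject the null if the 95% HDI lies wholly outside the ROPE, accept it
    if wholly inside, otherwise undecided."""
    h85 = hdi(draws, 0.85)
    h95 = hdi(draws, 0.95)
    lo, hi = rope
    overlap = max(0.0, min(h95[1], hi) - max(h95[0], lo))
    width = h95[1] - h95[0]
    overlap_pct = 100.0 * overlap / width if width > 0 else (100.0 if lo <= h95[0] <= hi else 0.0)
    if h95[1] < lo or h95[0] > hi:
        decision = "reject-null"
    elif lo <= h95[0] and h95[1] <= hi:
        decision = "accept-null"
    else:
        decision = "undecided"
    return {"hdi85_lo": h85[0], "hdi85_hi": h85[1],
            "hdi95_lo": h95[0], "hdi95_hi": h95[1],
            "rope_overlap_pct": overlap_pct, "decision": decision}


def regression_report(post: HierRegressionPosterior, rope=ROPE_LIMITS) -> pd.DataFrame:
    """Per-coefficient report: posterior median, HDIs, directional BF
    (mass below / mass above zero), ROPE overlap and decision."""
    rows = []
    for name in post.coef_names:
        d = post.draws(name)
        bf = directional_bayes_factor(d)
        entry = {"coefficient": name, "median": float(np.median(d)), "bf": bf,
                 "evidence": bf_evidence_label(bf)}
        entry.update(hdi_and_rope(d, rope))
        rows.append(entry)
    return pd.DataFrame(rows)
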