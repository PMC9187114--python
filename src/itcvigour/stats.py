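"""Shared posterior summaries: split R-hat, effective sample size, highest
density intervals, and KDE-based directional Bayes factors."""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde


def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on split chains.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half,
    giving 2*n_chains sequences.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n: 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk ESS via Geyer's initial positive sequence of autocorrelations."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    centred = chains - chains.mean(axis=1, keepdims=True)
    var = centred.var(axis=1).mean()
    if var == 0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        cov = np.mean([np.dot(c[:-lag], c[lag:]) / n for c in centred])
        rho[lag - 1] = cov / var
    # sum consecutive pairs while positive
    tau = 1.0
    for t in range(0, max_lag - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(m * n / tau)


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (sorted-draw
    sweep; deterministic given the draws)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 4:
        raise ValueError("too few draws for a stable HDI")
    m = max(int(np.ceil(prob * n)), 2)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def directional_bayes_factor(draws: np.ndarray, grid_size: int = 4096,
                             span_sd: float = 8.0) -> float:
    """Posterior-mass ratio below vs. above zero via Gaussian KDE.

    The density (Silverman bandwidth) is integrated with the trapezoid
    rule on a grid of ``grid_size`` points spanning ``span_sd`` posterior
    SDs either side of the draws.  A side with (numerically) zero mass
    yields a capped ratio.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if len(x) < 1000:
        raise ValueError("need at least 1000 draws for a stable KDE ratio")
    sd = x.std()
    if sd == 0:
        return 1.0 if x[0] == 0 else (np.inf if x[0] < 0 else 0.0)
    kde = gaussian_kde(x, bw_method="silverman")
    lo = min(x.min(), 0.0) - span_sd * sd
    hi = max(x.max(), 0.0) + span_sd * sd
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    below = np.trapezoid(np.where(grid < 0, dens, 0.0), grid)
    above = np.trapezoid(np.where(grid >= 0, dens, 0.0), grid)
    cap = 1e308
    if above <= 0:
        return cap
    if below <= 0:
        return 1.0 / cap
    return float(below / above)


BF_BANDS = (
    (100.0, "extreme"),
    (30.0, "very strong"),
    (10.0, "strong"),
    (3.0, "moderate"),
    (1.0, "anecdotal"),
)


def bf_evidence_label(bf: float) -> str:
    """Verbal evidence band for a directional Bayes factor; ratios below 1
    are labelled for the opposite direction with the inverse strength."""
    direction = "below zero" if bf >= 1 else "above zero"
    mag = bf if bf >= 1 else 1.0 / max(bf, 1e-308)
    for cut, name in BF_BANDS:
        if mag > cut:
            return f"{name} ({direction})"
    return f"anecdotal ({direction})"
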