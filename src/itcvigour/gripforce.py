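"""Grip-force preprocessing, trial-wise Gaussian pulse fits and the
condition (magnitude) tests on response vigour and behaviour.

Raw traces are sampled at 2000 Hz in kgf.  Preprocessing order is fixed:
baseline correction (mean of the first ``baseline_samples`` samples),
normalisation to the subject's maximal voluntary contraction (MVC), then a
50-sample moving average (shrinking window at the edges).  Each trial's
pulse is then fitted with ``f(x) = a * exp(-((x - b)/c)^2) + h`` by
nonlinear least squares; ``b`` and ``c`` are reported in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import ttest_rel, wilcoxon
from statsmodels.stats.diagnostic import lilliefors

SAMPLING_RATE_HZ = 2000
SMOOTHING_WINDOW = 50
BASELINE_SAMPLES = 100


@dataclass(frozen=True)
class MVCRecord:
    """Maximal voluntary contraction: peak forces of three maximal grips
    and their maximum."""

    peaks: tuple[float, float, float]
    mvc: float

    def __post_init__(self) -> None:
        if self.mvc <= 0:
            raise ValueError("MVC must be positive")
        if any(p > self.mvc + 1e-12 for p in self.peaks):
            raise ValueError("MVC must dominate every contraction peak")


def compute_mvc(contractions: list[np.ndarray]) -> MVCRecord:
    """MVC from three maximal-contraction traces (kgf)."""
    if len(contractions) != 3 or any(len(c) == 0 for c in contractions):
        raise ValueError("need three non-empty contraction traces")
    peaks = tuple(float(np.max(c)) for c in contractions)
    mvc = max(peaks)
    if mvc <= 0:
        raise ValueError("MVC must be positive")
    return MVCRecord(peaks, mvc)


def moving_average(x: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window > len(x):
        raise ValueError("smoothing window exceeds trace length")
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - window // 2, 0)
    hi = np.minimum(idx + (window - window // 2), n)
    return (c[hi] - c[lo]) / (hi - lo)


def preprocess_trace(raw: np.ndarray, mvc: MVCRecord,
                     baseline_samples: int = BASELINE_SAMPLES,
                     window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Baseline-correct, MVC-normalise and smooth one force trace."""
    raw = np.asarray(raw, dtype=float)
    if len(raw) <= window:
        raise ValueError("trace shorter than the smoothing window")
    baseline = raw[: min(baseline_samples, len(raw))].mean()
    return moving_average((raw - baseline) / mvc.mvc, window)


def gaussian_pulse(t, a, b, c, h):
    return a * np.exp(-(((t - b) / c) ** 2)) + h


@dataclass
class GaussianPulseFit:
    """Trial-wise pulse-model estimates (amplitude in MVC fraction,
    centroid/width in seconds) with fit quality."""

    a: float
    b: float
    c: float
    h: float
    r2: float
    adj_r2: float
    rmse: float
    converged: bool


def fit_gaussian_pulse(trace: np.ndarray, time_s: np.ndarray | None = None) -> GaussianPulseFit:
    """Nonlinear least-squares fit of the Gaussian pulse model.

    Deterministic initialisation: ``a = max - min``, ``b`` at the peak,
    ``c`` from the half-width at half maximum, ``h = min``; ``a`` and
    ``c`` bounded positive.  Non-convergence is flagged (downstream code
    excludes flagged trials), never raised.
    """
    y = np.asarray(trace, dtype=float)
    t = np.arange(len(y)) / SAMPLING_RATE_HZ if time_s is None else np.asarray(time_s, dtype=float)
    ymin, ymax = float(y.min()), float(y.max())
    if ymax <= ymin:
        return GaussianPulseFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    i_peak = int(np.argmax(y))
    half = ymin + (ymax - ymin) / 2.0
    above = np.where(y >= half)[0]
    hwhm = max((t[above[-1]] - t[above[0]]) / 2.0, 2.0 / SAMPLING_RATE_HZ)
    p0 = [ymax - ymin, t[i_peak], hwhm / np.sqrt(np.log(2.0)), ymin]
    try:
        popt, _ = curve_fit(
            gaussian_pulse, t, y, p0=p0,
            bounds=([0.0, t[0] - 1.0, 1e-6, -np.inf],
                    [np.inf, t[-1] + 1.0, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError:
        return GaussianPulseFit(*p0, np.nan, np.nan, np.nan, False)
    resid = y - gaussian_pulse(t, *popt)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    n, k = len(y), 4
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if sst > 0 else np.nan
    return GaussianPulseFit(*map(float, popt), r2, adj, float(np.sqrt(sse / n)), True)


def fit_pulses(traces, subject_id=None) -> pd.DataFrame:
    """Fit many preprocessed traces; ``traces`` yields (trial, time_s,
    trace).  Returns a tidy per-trial fit table."""
    rows = []
    for trial, t, y in traces:
        fit = fit_gaussian_pulse(y, t)
        rows.append({"subject_id": subject_id, "trial": trial, "a": fit.a, "b": fit.b,
                     "c": fit.c, "h": fit.h, "r2": fit.r2, "adj_r2": fit.adj_r2,
                     "rmse": fit.rmse, "converged": fit.converged})
    return pd.DataFrame(rows)


def magnitude_tests(condition_means: pd.DataFrame) -> pd.DataFrame:
    """Magnitude-effect tests on paired per-subject condition means.

    ``condition_means`` needs columns ``subject_id, condition`` (low/high)
    and any of ``amplitude, centroid, width, p_ll, mean_rt``.  Per
    measure: Lilliefors normality on the paired differences; Wilcoxon
    signed-rank for the grip parameters (one-tailed high > low for
    amplitude, one-tailed low > high for centroid, two-tailed for width;
    zero differences dropped) and paired t-tests (one-tailed) for LL
    proportion (high > low) and mean RT (low > high).
    """
    wide = condition_means.pivot(index="subject_id", columns="condition")
    specs = {
        "amplitude": ("wilcoxon", "greater"),
        "centroid": ("wilcoxon", "less"),
        "width": ("wilcoxon", "two-sided"),
        "p_ll": ("ttest", "greater"),
        "mean_rt": ("ttest", "less"),
    }
    rows = []
    for measure, (test, alternative) in specs.items():
        if measure not in {c[0] for c in wide.columns}:
            continue
        sub = wide[measure]
        if sub.isna().any().any():
            raise ValueError(f"missing subjects for measure {measure!r}")
        low = sub["low"].to_numpy(dtype=float)
        high = sub["high"].to_numpy(dtype=float)
        diff = high - low
        lf_stat, lf_p = lilliefors(diff) if (np.ptp(diff) > 0 and len(diff) >= 5) \
            else (np.nan, np.nan)
        if test == "wilcoxon":
            nz = diff[diff != 0.0]  # classic signed-rank zero policy
            if len(nz) == 0:
                stat, p, zstat = 0.0, 1.0, 0.0
            else:
                res = wilcoxon(nz, alternative=alternative, method="approx")
                stat, p = float(res.statistic), float(res.pvalue)
                zstat = float(res.zstatistic)
        else:
            res = ttest_rel(high, low, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
            zstat = np.nan
        rows.append({"measure": measure, "test": test, "alternative": alternative,
                     "statistic": stat, "z": zstat, "p": p,
                     "lilliefors_stat": lf_stat, "lilliefors_p": lf_p,
                     "n": len(diff)})
    return pd.DataFrame(rows)


def condition_means_from_fits(fits: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-condition means of pulse parameters plus LL
    proportion and mean RT, ready for :func:`magnitude_tests`."""
    merged = fits.merge(trials, on=["subject_id", "trial"])
    merged = merged[merged["converged"]]
    cond = merged["condition"]
    if cond.dtype.kind not in "OUS":
        merged = merged.assign(condition=np.where(cond == 1, "high", "low"))
    ll = (merged["choice"] == "LL") if merged["choice"].dtype.kind in "OUS" \
        else merged["choice"] == 1
    merged = merged.assign(is_ll=ll.astype(float))
    g = merged.groupby(["subject_id", "condition"])
    return g.agg(amplitude=("a", "mean"), centroid=("b", "mean"),
                 width=("c", "mean"), p_ll=("is_ll", "mean"),
                 mean_rt=("rt_s", "mean")).reset_index()
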