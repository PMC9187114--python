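"""Subjective valuation: hyperbolic discounting, softmax choice rule, and
value-to-drift mappings.

The discounted value of the delayed (LL) reward is

    SV(LL) = A / (1 + exp(k + I*s) * IRI)

where ``A`` is the LL amount, ``IRI`` the delay in days, ``k`` the
log-space discount rate of the *low* condition, ``s`` the additive shift in
log(k) for the *high* condition and ``I`` the 0/1 condition indicator.  The
SS reward is immediate, so SV(SS) equals its amount.

Value differences map to drift rates either linearly (``v = v_coeff*dSV``)
or through a sigmoid centred at zero with asymptote +-v_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec


@dataclass(frozen=True)
class DiscountParams:
    """Hyperbolic discounting parameters: ``k`` is log-space (low
    condition); ``s`` shifts log(k) in the high condition."""

    k: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and np.isfinite(self.s)):
            raise ValueError("discount parameters must be finite")


@dataclass(frozen=True)
class SoftmaxParams:
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("inverse temperature must be non-negative")


@dataclass(frozen=True)
class DriftScaling:
    """Drift mapping parameters of the sigmoid DDM variants.

    ``v_coeff`` scales the value difference to the intermediate slope
    ``m = (v_coeff + I*s_vcoeff) * dSV``; ``v_max`` is the drift asymptote,
    shifted by ``s_vmax`` in the high condition.
    """

    v_coeff: float
    v_max: float
    s_vcoeff: float = 0.0
    s_vmax: float = 0.0

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.v_max + self.s_vmax <= 0:
            raise ValueError("drift asymptote must stay positive in both conditions")


def subjective_value(A, IRI, I, p: DiscountParams):
    """Discounted value of a delayed amount (vectorised).

    Equals ``A`` at zero delay and decreases monotonically with delay.
    """
    A = np.asarray(A, dtype=float)
    IRI = np.asarray(IRI, dtype=float)
    if np.any(A <= 0):
        raise ValueError("amounts must be positive")
    if np.any(IRI < 0):
        raise ValueError("delays must be non-negative")
    rate = np.exp(p.k + np.asarray(I, dtype=float) * p.s)
    out = A / (1.0 + rate * IRI)
    return out if out.ndim else float(out)


def value_table(trials: pd.DataFrame, p: DiscountParams,
                design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-trial subjective values, differences and sums.

    Columns added: ``sv_ss, sv_ll, dsv, ssv`` plus the per-condition
    max-LL-normalised counterparts ``sv_ss_norm, sv_ll_norm, dsv_norm,
    ssv_norm`` (divisors 38/76 EUR under the default design).
    """
    design = design or DesignSpec()
    I = trials["condition"].to_numpy(dtype=int)
    sv_ll = subjective_value(trials["ll_amount"].to_numpy(), trials["delay_days"].to_numpy(), I, p)
    sv_ss = trials["ss_amount"].to_numpy(dtype=float)
    div = np.array([design.max_ll_amount(c) for c in (0, 1)])[I]
    if np.any(div == 0):
        raise ValueError("zero normalisation divisor")
    out = trials.copy()
    out["sv_ss"] = sv_ss
    out["sv_ll"] = sv_ll
    out["dsv"] = sv_ll - sv_ss
    out["ssv"] = sv_ll + sv_ss
    out["sv_ss_norm"] = sv_ss / div
    out["sv_ll_norm"] = sv_ll / div
    out["dsv_norm"] = out["dsv"] / div
    out["ssv_norm"] = out["ssv"] / div
    return out


def softmax_probability(sv_ss, sv_ll, beta: float):
    """P(choose LL) under the softmax rule, overflow-safe via the
    logistic of ``beta * (sv_ll - sv_ss)``."""
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    x = beta * (np.asarray(sv_ll, dtype=float) - np.asarray(sv_ss, dtype=float))
    out = _logistic(x)
    return out if out.ndim else float(out)


def _logistic(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def drift_linear(dsv, v_coeff: float):
    """Linear value-difference-to-drift mapping ``v = v_coeff * dSV``."""
    out = v_coeff * np.asarray(dsv, dtype=float)
    return out if out.ndim else float(out)


def drift_sigmoid(dsv, scaling: DriftScaling, I=0):
    """Sigmoid drift mapping, bounded in (-V, V) with V the (possibly
    condition-shifted) asymptote; odd in the scaled difference ``m``."""
    I = np.asarray(I, dtype=float)
    V = scaling.v_max + I * scaling.s_vmax
    if np.any(V <= 0):
        raise ValueError("effective drift asymptote must be positive")
    m = (scaling.v_coeff + I * scaling.s_vcoeff) * np.asarray(dsv, dtype=float)
    out = 2.0 * V * _logistic(m) - V
    return out if out.ndim else float(out)
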