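"""Model variants and their subject-level likelihoods.

Two model families over the same hyperbolic-discounting valuation:

* ``softmax`` — choices only, logistic in ``beta * dSV``;
* ``ddm`` — choices and response times through the Wiener first-passage
  likelihood, with the drift either constant (``null``), linear in the
  subjective value difference (``linear``), or a bounded sigmoid of the
  scaled difference (``sigmoid``); ``sigmoid-shift`` adds additive
  high-condition shifts for boundary separation, non-decision time, start
  bias and the two drift-scaling parameters.

Values enter either in euros (``absolute``) or divided by the largest LL
amount of each magnitude condition (``normalised``).

Subject-level parameters are sampled on unconstrained scales (log for
strictly positive quantities, logit for the start fraction); the group
Gaussians of the hierarchy live on those scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec
from .wfpt import encode_stimulus_coding, wfpt_logdensity

FAMILIES = ("softmax", "ddm")
VARIANTS = ("null", "linear", "sigmoid", "sigmoid-shift")
VALUE_SCALES = ("absolute", "normalised")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    variant: str = "null"
    value_scale: str = "absolute"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"unknown value scale {self.value_scale!r}")
        if self.family == "softmax" and self.variant != "null":
            raise ValueError("the softmax family admits no drift variants")

    @property
    def label(self) -> str:
        if self.family == "softmax":
            return f"SM_{'abs' if self.value_scale == 'absolute' else 'norm'}"
        tag = {"null": "0", "linear": "lin", "sigmoid": "sig", "sigmoid-shift": "sig-shift"}
        return f"DDM_{tag[self.variant]}_{'abs' if self.value_scale == 'absolute' else 'norm'}"


@dataclass(frozen=True)
class Param:
    """One subject-level parameter: ``name`` on the sampling scale,
    ``transform`` mapping sampling scale -> natural scale."""

    name: str
    transform: str = "identity"  # identity | exp | logit
    hyper_mean: float = 0.0      # centre of the group-mean hyperprior
    init: float = 0.0            # sampler initialisation (sampling scale)

    def to_natural(self, x):
        if self.transform == "identity":
            return x
        if self.transform == "exp":
            return np.exp(x)
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))

    def to_sampling(self, y):
        if self.transform == "identity":
            return y
        if self.transform == "exp":
            return np.log(y)
        y = np.asarray(y, dtype=float)
        return np.log(y / (1.0 - y))

    @property
    def natural_name(self) -> str:
        return NATURAL_NAMES.get(self.name, self.name)


NATURAL_NAMES = {
    "log_beta": "beta",
    "log_alpha": "alpha",
    "log_tau": "tau",
    "logit_z": "z",
    "log_vcoeff": "v_coeff",
    "log_vmax": "v_max",
}

_DISCOUNT = [
    Param("logk", "identity", hyper_mean=-4.0, init=-4.0),
    Param("s", "identity", hyper_mean=0.0, init=0.0),
]
_DDM_BASE = [
    Param("log_alpha", "exp", hyper_mean=np.log(2.0), init=np.log(2.5)),
    Param("log_tau", "exp", hyper_mean=0.0, init=np.log(0.8)),
    Param("logit_z", "logit", hyper_mean=0.0, init=0.0),
]
_SHIFTS = [
    Param("s_alpha"), Param("s_tau"), Param("s_z"),
    Param("s_vcoeff"), Param("s_vmax"),
]


def model_params(spec: ModelSpec) -> list[Param]:
    """Subject-level parameter list of a model variant, in sampling order."""
    if spec.family == "softmax":
        return _DISCOUNT + [Param("log_beta", "exp", init=0.0)]
    if spec.variant == "null":
        return _DDM_BASE + [Param("v", "identity", init=0.2)]
    params = _DDM_BASE + [Param("log_vcoeff", "exp", init=np.log(0.5))] + _DISCOUNT
    if spec.variant == "linear":
        return params
    params = params[:4] + [Param("log_vmax", "exp", init=0.0)] + params[4:]
    if spec.variant == "sigmoid":
        return params
    return params + _SHIFTS


# ---------------------------------------------------------------------------
# data container

@dataclass
class ChoiceData:
    """Padded per-subject arrays built from a long trial table.

    All arrays have shape (n_subjects, max_trials); ``mask`` marks real
    trials.  ``norm_div`` holds the per-condition value-normalisation
    divisor of each trial.
    """

    subject_ids: list
    A: np.ndarray
    IRI: np.ndarray
    I: np.ndarray
    ss: np.ndarray
    choice: np.ndarray      # 1 = LL
    signed_rt: np.ndarray   # NaN where no RT
    norm_div: np.ndarray
    mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_trials(self) -> int:
        return int(self.mask.sum())


def build_choice_data(trials: pd.DataFrame, design: DesignSpec | None = None) -> ChoiceData:
    """Assemble :class:`ChoiceData` from a long trial table with columns
    ``subject_id, condition, ss_amount, ll_amount, delay_days, choice``
    and optionally ``rt_s``."""
    design = design or DesignSpec()
    if trials["subject_id"].nunique() < 1:
        raise ValueError("empty trial table")
    subjects = sorted(trials["subject_id"].unique())
    groups = {sid: g for sid, g in trials.groupby("subject_id")}
    nmax = max(len(g) for g in groups.values())
    n = len(subjects)

    def padded(fill=0.0):
        return np.full((n, nmax), fill, dtype=float)

    A, IRI, I, ss, ch, srt, div = (padded() for _ in range(7))
    mask = np.zeros((n, nmax), dtype=bool)
    for j, sid in enumerate(subjects):
        g = groups[sid]
        m = len(g)
        A[j, :m] = g["ll_amount"].to_numpy(dtype=float)
        IRI[j, :m] = g["delay_days"].to_numpy(dtype=float)
        cond = g["condition"].to_numpy()
        if cond.dtype.kind in "OUS":
            cond = (cond == "high").astype(int)
        I[j, :m] = cond
        ss[j, :m] = g["ss_amount"].to_numpy(dtype=float)
        c = g["choice"].to_numpy()
        if c.dtype.kind in "OUS":
            c = (c == "LL").astype(int)
        ch[j, :m] = c
        if "rt_s" in g:
            rt = g["rt_s"].to_numpy(dtype=float)
            srt[j, :m] = np.where(np.isnan(rt), np.nan, encode_stimulus_coding(c, np.where(np.isnan(rt), 1.0, rt)))
        else:
            srt[j, :m] = np.nan
        div[j, :m] = np.array([design.max_ll_amount(int(i)) for i in I[j, :m]])
        mask[j, :m] = True
    # keep padded entries valid for vectorised evaluation
    A[~mask] = 20.0
    IRI[~mask] = 1.0
    div[~mask] = 1.0
    srt_pad = np.where(mask, srt, 3.0)
    return ChoiceData(subjects, A, IRI, I, ss, ch, srt_pad, div, mask)


# ---------------------------------------------------------------------------
# likelihoods

def _dsv(theta: dict, data: ChoiceData, scale: str) -> np.ndarray:
    k = theta["logk"][:, None]
    s = theta["s"][:, None]
    rate = np.exp(k + data.I * s)
    sv_ll = data.A / (1.0 + rate * data.IRI)
    dsv = sv_ll - data.ss
    if scale == "normalised":
        dsv = dsv / data.norm_div
    return dsv


def trial_drift(theta: dict, data: ChoiceData, spec: ModelSpec) -> np.ndarray:
    """Per-trial drift rates (n_subjects x max_trials) for a DDM variant."""
    if spec.variant == "null":
        return np.broadcast_to(theta["v"][:, None], data.A.shape)
    dsv = _dsv(theta, data, spec.value_scale)
    if spec.variant == "linear":
        return theta["v_coeff"][:, None] * dsv
    vc = theta["v_coeff"][:, None]
    vm = theta["v_max"][:, None]
    if spec.variant == "sigmoid-shift":
        vc = vc + data.I * theta["s_vcoeff"][:, None]
        vm = vm + data.I * theta["s_vmax"][:, None]
    m = vc * dsv
    # 2V/(1+e^-m) - V, overflow-safe
    return vm * np.tanh(m / 2.0)


def subject_loglik(theta: dict, data: ChoiceData, spec: ModelSpec) -> np.ndarray:
    """Per-subject log-likelihood under natural-scale parameter arrays.

    ``theta`` maps natural parameter names to (n_subjects,) arrays.
    Subjects whose (shifted) parameters violate the DDM constraints get
    ``-inf``.
    """
    if spec.family == "softmax":
        x = theta["beta"][:, None] * _dsv(theta, data, spec.value_scale)
        ll = -np.where(data.choice == 1, np.logaddexp(0.0, -x), np.logaddexp(0.0, x))
        return np.sum(np.where(data.mask, ll, 0.0), axis=1)

    a = np.broadcast_to(theta["alpha"][:, None], data.A.shape)
    tau = np.broadcast_to(theta["tau"][:, None], data.A.shape)
    z = np.broadcast_to(theta["z"][:, None], data.A.shape)
    if spec.variant == "sigmoid-shift":
        a = a + data.I * theta["s_alpha"][:, None]
        tau = tau + data.I * theta["s_tau"][:, None]
        z = z + data.I * theta["s_z"][:, None]
    valid = (
        np.all((a > 0) | ~data.mask, axis=1)
        & np.all((tau > 0) | ~data.mask, axis=1)
        & np.all(((z > 0) & (z < 1)) | ~data.mask, axis=1)
    )
    v = trial_drift(theta, data, spec)
    a_c = np.clip(a, 1e-6, None)
    tau_c = np.clip(tau, 1e-6, None)
    z_c = np.clip(z, 1e-6, 1 - 1e-6)
    ll = wfpt_logdensity(data.signed_rt, v, a_c, tau_c, z_c)
    out = np.sum(np.where(data.mask, ll, 0.0), axis=1)
    out[~valid] = -np.inf
    return out


def natural_theta(theta_sampling: np.ndarray, params: list[Param]) -> dict:
    """Map a (n_subjects, P) sampling-scale matrix to a dict of
    natural-scale arrays keyed by natural names."""
    return {p.natural_name: p.to_natural(theta_sampling[:, i]) for i, p in enumerate(params)}


def dataset_loglik(trials: pd.DataFrame, subject_params: pd.DataFrame,
                   spec: ModelSpec, design: DesignSpec | None = None) -> float:
    """Total log-likelihood of a trial table under natural-scale
    per-subject parameters (one row per subject, natural names)."""
    data = build_choice_data(trials, design)
    sp = subject_params.set_index("subject_id").loc[data.subject_ids] \
        if "subject_id" in subject_params else subject_params
    theta = {p.natural_name: sp[p.natural_name].to_numpy(dtype=float)
             for p in model_params(spec)}
    ll = subject_loglik(theta, data, spec)
    return float(ll.sum())
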