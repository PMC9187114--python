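"""Synthetic cohorts with known ground truth.

Generates the full task design, draws subject-level parameters from
group Gaussians on the sampling scales, simulates choices (softmax) or
choices + response times (drift diffusion), and synthesises trial-wise
grip-force pulses and fixation-shift counts whose couplings to value sum
and value difference are explicit, recoverable parameters.

The default generating truths use the group-level posterior means
reported for this task (see the module constants); group SDs default to
0.5 for log(k) and 0.3 for all other parameters on their sampling scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, build_design, condition_label
from .models import ModelSpec, model_params, trial_drift, build_choice_data, natural_theta
from .valuation import DiscountParams, softmax_probability, value_table
from .wfpt import simulate_ddm_trials

SAMPLING_RATE_HZ = 2000

DEFAULT_SD_LOGK = 0.5
DEFAULT_SD_OTHER = 0.3


@dataclass(frozen=True)
class GripCoupling:
    """Generative coupling of the Gaussian grip pulse to valuation.

    Amplitudes are fractions of MVC; slopes act on within-subject
    z-scored value sums/differences.  ``centroid_slope_diff`` (s per SD)
    shifts the pulse centre relative to the response time.
    """

    base_amplitude: float = 0.2142
    slope_sum: float = 0.02
    slope_diff: float = 0.01
    centroid_slope_diff: float = 0.0
    width_s: float = 0.13
    offset: float = 0.0
    amplitude_sd: float = 0.02   # trial-level motor variability of the peak
    noise_sd: float = 0.004      # additive trace noise
    amplitude_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.base_amplitude <= 1:
            raise ValueError("base amplitude must lie in (0, 1] of MVC")
        if self.width_s <= 0 or self.noise_sd < 0:
            raise ValueError("invalid grip coupling")


@dataclass(frozen=True)
class FixationModel:
    """Poisson fixation-shift counts with log-rate
    ``base_log_rate - slope * z(|dSV|)``."""

    base_log_rate: float = float(np.log(3.2))
    slope: float = 0.3

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("fixation slope must be non-negative")


@dataclass(frozen=True)
class GeneratingTruth:
    """Ground truth of a simulated cohort.

    ``group_means`` holds natural-scale means per model parameter;
    ``group_sds`` the group SDs on the sampling scales (log for strictly
    positive parameters, logit for the start fraction).
    """

    model: ModelSpec
    group_means: dict
    group_sds: dict = field(default_factory=dict)
    grip: GripCoupling = GripCoupling()
    fixation: FixationModel = FixationModel()

    def __post_init__(self) -> None:
        params = model_params(self.model)
        missing = [p.natural_name for p in params if p.natural_name not in self.group_means]
        if missing:
            raise ValueError(f"missing group means for {missing}")
        if any(sd < 0 for sd in self.group_sds.values()):
            raise ValueError("group SDs must be non-negative")

    def sd_for(self, sampling_name: str) -> float:
        if sampling_name in self.group_sds:
            return self.group_sds[sampling_name]
        return DEFAULT_SD_LOGK if sampling_name == "logk" else DEFAULT_SD_OTHER


#: Group posterior means of the softmax fit on absolute values.
SOFTMAX_ABS_MEANS = {"logk": -4.44, "s": -0.80, "beta": 0.43}
#: Group posterior means of the softmax fit on normalised values.
SOFTMAX_NORM_MEANS = {"logk": -4.44, "s": -0.74, "beta": 27.23}
#: Group posterior means of the sigmoid-drift DDM on absolute values.
DDM_SIG_ABS_MEANS = {
    "alpha": 3.27, "tau": 1.23, "z": 0.51,
    "v_coeff": 0.77, "v_max": 1.07, "logk": -4.45, "s": -0.82,
}


def default_truth(kind: str) -> GeneratingTruth:
    """Canonical generating truths: ``softmax-absolute``,
    ``softmax-normalised`` or ``ddm-sig-absolute``."""
    if kind == "softmax-absolute":
        return GeneratingTruth(ModelSpec("softmax", "null", "absolute"),
                               dict(SOFTMAX_ABS_MEANS))
    if kind == "softmax-normalised":
        return GeneratingTruth(ModelSpec("softmax", "null", "normalised"),
                               dict(SOFTMAX_NORM_MEANS))
    if kind == "ddm-sig-absolute":
        return GeneratingTruth(ModelSpec("ddm", "sigmoid", "absolute"),
                               dict(DDM_SIG_ABS_MEANS))
    raise ValueError(f"unknown truth kind {kind!r}")


def draw_subject_params(truth: GeneratingTruth, n_subjects: int, seed: int) -> pd.DataFrame:
    """Draw per-subject natural-scale parameters from the group Gaussians.

    Bounded parameters are drawn on their unconstrained sampling scale
    (log / logit) and back-transformed, so the group-Gaussian statement
    holds on the unconstrained scale.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    params = model_params(truth.model)
    out = {"subject_id": [f"s{j + 1:03d}" for j in range(n_subjects)]}
    for p in params:
        centre = p.to_sampling(truth.group_means[p.natural_name])
        draws = centre + truth.sd_for(p.name) * rng.standard_normal(n_subjects)
        out[p.natural_name] = np.asarray(p.to_natural(draws))
    return pd.DataFrame(out)


def simulate_choices_softmax(trials: pd.DataFrame, subject_params: pd.Series | dict,
                             seed: int, value_scale: str = "absolute",
                             design: DesignSpec | None = None) -> np.ndarray:
    """Bernoulli choices (1 = LL) from the softmax rule for one subject."""
    design = design or DesignSpec()
    p = DiscountParams(k=float(subject_params["logk"]), s=float(subject_params["s"]))
    vt = value_table(trials, p, design)
    dsv = vt["dsv_norm" if value_scale == "normalised" else "dsv"].to_numpy()
    prob_ll = softmax_probability(0.0, dsv, float(subject_params["beta"]))
    rng = np.random.default_rng(seed)
    return (rng.uniform(size=len(trials)) < prob_ll).astype(int)


def simulate_choices_rts_ddm(trials: pd.DataFrame, subject_params: pd.Series | dict,
                             variant: str, seed: int, value_scale: str = "absolute",
                             design: DesignSpec | None = None,
                             dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """First-passage choices and RTs for one subject under a DDM variant.

    Returns ``(choices, rts)`` with choices 1 = LL (upper boundary); all
    RTs exceed the non-decision time.
    """
    design = design or DesignSpec()
    spec = ModelSpec("ddm", variant, value_scale)
    df = trials.copy()
    df["subject_id"] = "tmp"
    df["choice"] = 0
    data = build_choice_data(df, design)
    theta = {k: np.atleast_1d(np.asarray(v, dtype=float))
             for k, v in dict(subject_params).items() if k != "subject_id"}
    v = trial_drift(theta, data, spec)[0][data.mask[0]]
    if not np.all(np.isfinite(v)):
        bad = np.where(~np.isfinite(v))[0]
        raise ValueError(f"non-finite drift on trials {bad.tolist()}")
    a = float(theta["alpha"][0])
    tau = float(theta["tau"][0])
    z = float(theta["z"][0])
    I = data.I[0][data.mask[0]]
    aa = np.full_like(v, a)
    tt = np.full_like(v, tau)
    zz = np.full_like(v, z)
    if variant == "sigmoid-shift":
        aa = aa + I * float(theta["s_alpha"][0])
        tt = tt + I * float(theta["s_tau"][0])
        zz = zz + I * float(theta["s_z"][0])
    srt = simulate_ddm_trials(v, aa, tt, zz, seed=seed, dt=dt)
    return (srt > 0).astype(int), np.abs(srt)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def synthesize_grip_trace(rt: float, z_value_sum: float, z_value_diff: float,
                          coupling: GripCoupling, seed: int,
                          amplitude: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One Gaussian grip pulse sampled at 2000 Hz.

    The pulse is centred near the response time, spans ``centroid + 6
    widths`` and rides on baseline noise.  Amplitude couples to the
    within-subject z-scored value sum and difference (plus trial-level
    motor variability ``amplitude_sd``) and is clipped to (0, 1] of MVC;
    a negative computed amplitude is clipped to a small positive floor
    with a warning.  ``amplitude`` overrides the computed peak, used when
    the cohort generator has already drawn it.

    Returns ``(time_s, force)`` with ``ceil(duration * 2000)`` samples.
    """
    if rt <= 0:
        raise ValueError("response time must be positive")
    rng = np.random.default_rng(seed)
    if amplitude is not None:
        amp = float(amplitude)
    else:
        amp = (coupling.base_amplitude
               + coupling.slope_sum * z_value_sum
               + coupling.slope_diff * z_value_diff
               + coupling.amplitude_sd * rng.standard_normal())
    if amp <= 0:
        warnings.warn("computed grip amplitude non-positive; clipped to floor")
        amp = coupling.amplitude_floor
    amp = min(amp, 1.0)
    centroid = rt + coupling.centroid_slope_diff * z_value_diff
    duration = centroid + 6.0 * coupling.width_s
    n = int(np.ceil(duration * SAMPLING_RATE_HZ))
    t = np.arange(n) / SAMPLING_RATE_HZ
    pulse = amp * np.exp(-(((t - centroid) / coupling.width_s) ** 2)) + coupling.offset
    if coupling.noise_sd > 0:
        pulse = pulse + coupling.noise_sd * rng.standard_normal(n)
    return t, pulse


def synthesize_fixation_count(z_abs_dsv, fixation: FixationModel, seed: int) -> np.ndarray:
    """Poisson fixation-shift counts with log-rate decreasing in the
    z-scored absolute value difference."""
    rng = np.random.default_rng(seed)
    z = np.atleast_1d(np.asarray(z_abs_dsv, dtype=float))
    rate = np.exp(fixation.base_log_rate - fixation.slope * z)
    return rng.poisson(rate)


@dataclass
class SyntheticCohort:
    """A simulated cohort: long trial table, per-subject true parameters
    and the generating truth."""

    trials: pd.DataFrame
    subject_params: pd.DataFrame
    truth: GeneratingTruth
    design: DesignSpec
    seed: int


def simulate_cohort(truth: GeneratingTruth, n_subjects: int, seed: int,
                    design: DesignSpec | None = None,
                    with_vigour: bool = False) -> SyntheticCohort:
    """Simulate a full cohort from a generating truth.

    Each subject gets an independently permuted copy of the design grid.
    For softmax truths the RT column is NaN (choices carry the signal);
    DDM truths produce Wiener first-passage RTs.  With ``with_vigour``,
    per-trial fixation-shift counts and grip-pulse parameters (amplitude,
    centroid) are added; raw traces are synthesised on demand by
    :func:`grip_traces_for_subject`.
    """
    design = design or DesignSpec()
    params = draw_subject_params(truth, n_subjects, seed)
    rng = np.random.default_rng((seed, 1))
    frames = []
    for j, row in params.iterrows():
        sub_design = DesignSpec(design.ss_amounts, design.ratios, design.delays,
                                randomise_order=design.randomise_order,
                                seed=int(rng.integers(2**31)))
        df = build_design(sub_design)
        df.insert(0, "subject_id", row["subject_id"])
        trial_seed = int(rng.integers(2**31))
        if truth.model.family == "softmax":
            choice = simulate_choices_softmax(df, row, trial_seed,
                                              truth.model.value_scale, design)
            rt = np.full(len(df), np.nan)
        else:
            choice, rt = simulate_choices_rts_ddm(df, row, truth.model.variant,
                                                  trial_seed, truth.model.value_scale,
                                                  design)
        df["choice"] = np.where(choice == 1, "LL", "SS")
        df["rt_s"] = rt
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)

    if with_vigour:
        trials = _add_vigour_columns(trials, params, truth, seed)
    return SyntheticCohort(trials, params, truth, design, seed)


def _add_vigour_columns(trials: pd.DataFrame, params: pd.DataFrame,
                        truth: GeneratingTruth, seed: int) -> pd.DataFrame:
    out = []
    rng = np.random.default_rng((seed, 2))
    for sid, g in trials.groupby("subject_id", sort=False):
        row = params.set_index("subject_id").loc[sid]
        p = DiscountParams(k=float(row["logk"]), s=float(row["s"]))
        vt = value_table(g, p)
        zsum = _zscore(vt["ssv"].to_numpy())
        zdiff = _zscore(vt["dsv"].to_numpy())
        zabs = _zscore(np.abs(vt["dsv"].to_numpy()))
        g = g.copy()
        g["n_fixation_shifts"] = synthesize_fixation_count(
            zabs, truth.fixation, int(rng.integers(2**31)))
        rt = g["rt_s"].to_numpy()
        rt = np.where(np.isnan(rt), 3.0, rt)
        amp = (truth.grip.base_amplitude
               + truth.grip.slope_sum * zsum
               + truth.grip.slope_diff * zdiff
               + truth.grip.amplitude_sd * rng.standard_normal(len(g)))
        g["grip_amplitude_true"] = np.clip(amp, truth.grip.amplitude_floor, 1.0)
        g["grip_centroid_true"] = rt + truth.grip.centroid_slope_diff * zdiff
        g["z_value_sum"] = zsum
        g["z_value_diff"] = zdiff
        out.append(g)
    return pd.concat(out, ignore_index=True)


def grip_traces_for_subject(cohort: SyntheticCohort, subject_id: str, seed: int):
    """Yield ``(trial, time_s, force)`` synthetic traces for one subject;
    requires a cohort simulated ``with_vigour``."""
    g = cohort.trials[cohort.trials["subject_id"] == subject_id]
    if "z_value_sum" not in g:
        raise ValueError("cohort was simulated without vigour columns")
    for _, row in g.iterrows():
        rt = row["rt_s"] if np.isfinite(row["rt_s"]) else 3.0
        t, f = synthesize_grip_trace(
            float(rt), float(row["z_value_sum"]), float(row["z_value_diff"]),
            cohort.truth.grip, seed=(seed * 1_000_003 + int(row["trial"])) % (2**31),
            amplitude=float(row["grip_amplitude_true"]))
        yield int(row["trial"]), t, f


# ---------------------------------------------------------------------------
# round-trip I/O

TRIAL_COLUMNS = ["subject_id", "trial", "condition", "ss_amount", "ll_amount",
                 "delay_days", "side_ll", "choice", "rt_s", "n_fixation_shifts"]


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write the cohort: trial table CSV, per-subject true parameters CSV
    and a JSON truth sidecar.  Round-trips losslessly through
    :func:`read_trials`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = cohort.trials.copy()
    if "n_fixation_shifts" not in df:
        df["n_fixation_shifts"] = np.nan
    df["condition"] = [condition_label(c) if not isinstance(c, str) else c
                       for c in df["condition"]]
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    df[cols].to_csv(out / "trials.csv", index=False)
    cohort.subject_params.to_csv(out / "subject_params.csv", index=False)
    sidecar = {
        "model": asdict(cohort.truth.model),
        "group_means": cohort.truth.group_means,
        "group_sds": cohort.truth.group_sds,
        "grip": asdict(cohort.truth.grip),
        "fixation": asdict(cohort.truth.fixation),
        "seed": cohort.seed,
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return out / "trials.csv"


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV, mapping condition labels back to 0/1."""
    df = pd.read_csv(path)
    if df["condition"].dtype.kind in "OUS":
        df["condition"] = (df["condition"] == "high").astype(int)
    return df
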