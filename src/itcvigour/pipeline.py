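"""End-to-end pipeline: simulate -> preprocess -> fit -> compare -> ppc ->
grip -> regress -> report, with every artefact carrying the seed and a
config hash for auditability."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (SyntheticCohort, default_truth, grip_traces_for_subject,
                     read_trials, simulate_cohort, write_cohort)
from .conflict import (build_regression_design, fit_hier_linear_regression,
                       regression_report, value_outcomes)
from .gripforce import condition_means_from_fits, fit_pulses, magnitude_tests
from .inference import compare_models, fit_hierarchical, posterior_predictive_rt, rhat_report
from .models import ModelSpec
from .preprocess import PipelineConfig, apply_rt_exclusions, trim_rt_tails
from .sampler import DESK_PROFILE, FULL_PROFILE, REDUCED_PROFILE

STAGES = ("simulate", "preprocess", "fit", "compare", "ppc", "grip", "regress", "report")

PROFILES = {"desk": DESK_PROFILE, "reduced": REDUCED_PROFILE, "full": FULL_PROFILE}


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(out_dir, cfg: PipelineConfig | None = None,
                 stages=STAGES,
                 truth_kind: str = "ddm-sig-absolute",
                 n_subjects: int = 8,
                 variants=("null", "linear", "sigmoid"),
                 n_grip_subjects: int = 4) -> Path:
    """Run the requested stages in order on a synthetic cohort.

    Artefacts land under ``out_dir`` in ``data/``, ``posteriors/``,
    ``comparison/``, ``grip/``, ``regressions/`` and ``report/``; a
    ``run.json`` logs seed, config hash and per-stage wall time.  A
    missing upstream artefact fails fast naming the stage.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = PROFILES[cfg.mcmc_profile].with_seed(cfg.seed)
    log = {"seed": cfg.seed, "config_hash": config_hash(cfg), "stages": {}}
    cohort: SyntheticCohort | None = None
    fits = {}

    def _need(path, stage):
        if not Path(path).exists():
            raise FileNotFoundError(f"stage '{stage}' needs missing artefact {path}")
        return path

    if "simulate" in stages:
        t0 = time.time()
        truth = default_truth(truth_kind)
        cohort = simulate_cohort(truth, n_subjects, cfg.seed, with_vigour=True)
        write_cohort(cohort, out / "data")
        log["stages"]["simulate"] = round(time.time() - t0, 2)

    if "preprocess" in stages:
        t0 = time.time()
        trials = read_trials(_need(out / "data" / "trials.csv", "preprocess"))
        kept, report = apply_rt_exclusions(trials, cfg)
        trimmed = trim_rt_tails(kept, cfg.trim_fraction)
        (out / "data").mkdir(exist_ok=True)
        kept.to_csv(out / "data" / "trials_clean.csv", index=False)
        trimmed.to_csv(out / "data" / "trials_trimmed.csv", index=False)
        report.summary().to_csv(out / "data" / "exclusions.csv", index=False)
        log["stages"]["preprocess"] = round(time.time() - t0, 2)

    if "fit" in stages or "compare" in stages:
        t0 = time.time()
        trimmed = pd.read_csv(_need(out / "data" / "trials_trimmed.csv", "fit"))
        (out / "posteriors").mkdir(exist_ok=True)
        for variant in variants:
            spec = ModelSpec("ddm", variant, "absolute")
            post = fit_hierarchical(trimmed, spec, cfg=profile)
            fits[spec.label] = post
            post.summary().to_csv(out / "posteriors" / f"{spec.label}_summary.csv", index=False)
            post.to_long_csv(out / "posteriors" / f"{spec.label}_draws.csv")
            rhat_report(post).to_csv(out / "posteriors" / f"{spec.label}_convergence.csv",
                                     index=False)
        log["stages"]["fit"] = round(time.time() - t0, 2)

    if "compare" in stages:
        t0 = time.time()
        trimmed = pd.read_csv(_need(out / "data" / "trials_trimmed.csv", "compare"))
        (out / "comparison").mkdir(exist_ok=True)
        table = compare_models(fits, trimmed)
        table.to_csv(out / "comparison" / "dic.csv", index=False)
        log["stages"]["compare"] = round(time.time() - t0, 2)

    if "ppc" in stages:
        t0 = time.time()
        trimmed = pd.read_csv(_need(out / "data" / "trials_trimmed.csv", "ppc"))
        if not fits:
            raise FileNotFoundError("stage 'ppc' needs fitted posteriors from 'fit'")
        label = min(fits, key=lambda k: compare_models(fits, trimmed)
                    .set_index("model").loc[k, "dic"]) if len(fits) > 1 else next(iter(fits))
        ppc = posterior_predictive_rt(fits[label], trimmed, n_datasets=20, seed=cfg.seed)
        (out / "comparison").mkdir(exist_ok=True)
        rows = [{"subject_id": sid,
                 "predicted_ss_fraction": float(np.mean(d["simulated"] < 0)),
                 "observed_ss_fraction": float(np.mean(d["observed"] < 0)),
                 "predicted_mean_abs_rt": float(np.mean(np.abs(d["simulated"]))),
                 "observed_mean_abs_rt": float(np.mean(np.abs(d["observed"])))}
                for sid, d in ppc.items()]
        pd.DataFrame(rows).to_csv(out / "comparison" / f"ppc_{label}.csv", index=False)
        log["stages"]["ppc"] = round(time.time() - t0, 2)

    if "grip" in stages:
        t0 = time.time()
        if cohort is None:
            raise FileNotFoundError("stage 'grip' needs the in-memory cohort from 'simulate'")
        (out / "grip").mkdir(exist_ok=True)
        all_fits = []
        for sid in cohort.subject_params["subject_id"][:n_grip_subjects]:
            traces = grip_traces_for_subject(cohort, sid, seed=cfg.seed)
            all_fits.append(fit_pulses(traces, subject_id=sid).assign(subject_id=sid))
        pulse_fits = pd.concat(all_fits, ignore_index=True)
        pulse_fits.to_csv(out / "grip" / "pulse_fits.csv", index=False)
        cm = condition_means_from_fits(pulse_fits, cohort.trials)
        magnitude_tests(cm).to_csv(out / "grip" / "magnitude_tests.csv", index=False)
        log["stages"]["grip"] = round(time.time() - t0, 2)

    if "regress" in stages:
        t0 = time.time()
        if cohort is None:
            raise FileNotFoundError("stage 'regress' needs the in-memory cohort from 'simulate'")
        (out / "regressions").mkdir(exist_ok=True)
        pulse_fits = pd.read_csv(_need(out / "grip" / "pulse_fits.csv", "regress"))
        sub = cohort.trials[cohort.trials["subject_id"].isin(pulse_fits["subject_id"].unique())]
        X = build_regression_design(pulse_fits, sub)
        vo = value_outcomes(sub, cohort.subject_params)
        merged = X.merge(vo[["subject_id", "trial", "abs_dsv", "ssv"]],
                         on=["subject_id", "trial"])
        for outcome in ("abs_dsv", "ssv"):
            post = fit_hier_linear_regression(merged[outcome].to_numpy(), merged,
                                              cfg=profile)
            regression_report(post).to_csv(out / "regressions" / f"{outcome}.csv", index=False)
        log["stages"]["regress"] = round(time.time() - t0, 2)

    if "report" in stages:
        lines = [f"seed: {cfg.seed}", f"config: {config_hash(cfg)}", ""]
        for f in sorted(out.rglob("*.csv")):
            lines.append(str(f.relative_to(out)))
        (out / "report").mkdir(exist_ok=True)
        (out / "report" / "report.txt").write_text("\n".join(lines) + "\n")

    (out / "run.json").write_text(json.dumps(log, indent=2))
    return out
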