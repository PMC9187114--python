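#!/usr/bin/env python
"""Hierarchical regressions of conflict and value outcomes on response
vigour and fixation shifts.

For a synthetic DDM cohort with grip pulses and fixation counts, builds
the regression design (within-subject z-scored amplitude/centroid/width,
raw fixation counts), constructs four outcomes — softmax conflict
(flipped choice probabilities), trial-wise drift rate, |dSV| and the
subjective value sum — and fits the hierarchical Bayesian regression for
each, reporting directional Bayes factors, 85/95% HDIs and ROPE
decisions.  Outputs under results/regressions/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from itcvigour.cohort import default_truth, grip_traces_for_subject, simulate_cohort
from itcvigour.conflict import (build_regression_design, conflict_from_drift,
                                conflict_from_softmax, fit_hier_linear_regression,
                                regression_report, value_outcomes)
from itcvigour.gripforce import fit_pulses
from itcvigour.sampler import MCMCConfig
from itcvigour.valuation import softmax_probability

OUT = Path("results/regressions")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_SUBJECTS = 10
CFG = MCMCConfig(n_chains=2, burn_in=400, n_samples=800, seed=SEED)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(default_truth("ddm-sig-absolute"), N_SUBJECTS,
                             seed=SEED, with_vigour=True)
    fits = pd.concat([
        fit_pulses(grip_traces_for_subject(cohort, sid, seed=SEED), subject_id=sid)
        for sid in cohort.subject_params.subject_id
    ], ignore_index=True)
    X = build_regression_design(fits, cohort.trials)
    vo = value_outcomes(cohort.trials, cohort.subject_params)
    merged = X.merge(vo, on=["subject_id", "trial"])

    # outcomes; conflict/drift use the subjects' true parameters in lieu of
    # posterior means (this cohort is synthetic and self-contained)
    sp = cohort.subject_params.set_index("subject_id")
    beta = 0.43
    p_ll = softmax_probability(merged.sv_ss, merged.sv_ll, beta)
    outcomes = {
        "conflict_softmax": conflict_from_softmax(p_ll),
        "drift_rate": conflict_from_drift(
            merged.dsv.to_numpy(),
            {"v_coeff": 0.77, "v_max": 1.07}, merged.condition.to_numpy()),
        "abs_dsv": _z(merged, "abs_dsv"),
        "ssv_subjective": _z(merged, "ssv"),
    }
    for name, y in outcomes.items():
        post = fit_hier_linear_regression(np.asarray(y, dtype=float), merged, cfg=CFG)
        rep = regression_report(post)
        rep.to_csv(OUT / f"{name}.csv", index=False)
        print(f"\n[{name}]")
        cols = ["coefficient", "median", "bf", "hdi95_lo", "hdi95_hi", "decision"]
        print(rep[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))


def _z(df: pd.DataFrame, col: str) -> np.ndarray:
    return df.groupby("subject_id")[col].transform(
        lambda x: (x - x.mean()) / x.std()).to_numpy()


if __name__ == "__main__":
    main()
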