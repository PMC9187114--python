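#!/usr/bin/env python
"""Simulate the synthetic cohorts used by the downstream analyses.

Builds the 192-trial intertemporal-choice design (2 SS magnitudes x 16
LL/SS ratios x 6 delays), draws subjects from the published group means,
and simulates choices, Wiener first-passage RTs, grip pulses and fixation
counts.  Writes the trial tables, per-subject truths and exclusion report
under results/cohorts/.
"""

import sys
from pathlib import Path

from itcvigour.cohort import default_truth, simulate_cohort, write_cohort
from itcvigour.preprocess import PipelineConfig, apply_rt_exclusions, trim_rt_tails

OUT = Path("results/cohorts")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    for kind, n in (("softmax-absolute", 40), ("softmax-normalised", 40),
                    ("ddm-sig-absolute", 20)):
        cohort = simulate_cohort(default_truth(kind), n, seed=SEED,
                                 with_vigour=kind.startswith("ddm"))
        path = write_cohort(cohort, OUT / kind)
        print(f"{kind}: {len(cohort.trials)} trials -> {path}")
        if kind.startswith("ddm"):
            kept, report = apply_rt_exclusions(cohort.trials, cfg)
            trimmed = trim_rt_tails(kept, cfg.trim_fraction)
            trimmed.to_csv(OUT / kind / "trials_trimmed.csv", index=False)
            report.summary().to_csv(OUT / kind / "exclusions.csv", index=False)
            print(f"  exclusions: {report.n_removed} removed "
                  f"({report.pct_removed:.2f}%), trimmed table: {len(trimmed)} trials")


if __name__ == "__main__":
    main()
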