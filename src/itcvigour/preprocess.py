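"""Trial exclusions, per-subject RT tail trimming and the pipeline
configuration.

Exclusion order is fixed and asserted by tests: RT bounds (below 200 ms or
above 10 s), then sub-threshold-force flags, then — for DDM fitting only —
removal of each subject's fastest and slowest 2.5% of trials (floor counts
per tail).  Trimmed trials are likewise dropped from grip and gaze tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, typed pipeline settings; unknown keys in a config file are
    errors."""

    seed: int = 0
    mcmc_profile: str = "desk"          # desk | reduced | full
    rt_min_s: float = 0.200
    rt_max_s: float = 10.0
    trim_fraction: float = 0.025        # per tail, DDM fits only
    force_threshold_kgf: float = 0.70   # acquisition logging threshold
    smoothing_window: int = 50
    sampling_rate_hz: int = 2000
    rope_limit: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim fraction must lie in [0, 0.5)")
        if self.rt_min_s >= self.rt_max_s:
            raise ValueError("rt_min must be below rt_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ExclusionReport:
    """Counts and identities of removed trials per rule and subject."""

    removed: dict            # rule -> DataFrame of removed rows (disjoint)
    n_total: int
    empty_subjects: list = None  # subjects left with zero trials

    @property
    def n_removed(self) -> int:
        return sum(len(df) for df in self.removed.values())

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_total if self.n_total else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [{"rule": rule, "n_removed": len(df),
                 "n_subjects": df["subject_id"].nunique() if len(df) else 0}
                for rule, df in self.removed.items()]
        rows.append({"rule": "total", "n_removed": self.n_removed,
                     "n_subjects": np.nan})
        return pd.DataFrame(rows)


def apply_rt_exclusions(trials: pd.DataFrame,
                        cfg: PipelineConfig | None = None) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials with RT below 200 ms or above 10 s, and trials flagged
    as sub-threshold force (column ``below_force_threshold`` if present).

    Subjects losing all their trials are flagged in the report under
    ``empty_subjects``.
    """
    cfg = cfg or PipelineConfig()
    rt = trials["rt_s"]
    fast = trials[rt < cfg.rt_min_s]
    kept = trials[~trials.index.isin(fast.index)]
    slow = kept[kept["rt_s"] > cfg.rt_max_s]
    kept = kept[~kept.index.isin(slow.index)]
    removed = {"rt_below_min": fast, "rt_above_max": slow}
    if "below_force_threshold" in trials:
        forced = kept[kept["below_force_threshold"].astype(bool)]
        kept = kept[~kept.index.isin(forced.index)]
        removed["force_below_threshold"] = forced
    empty = sorted(set(trials["subject_id"].unique()) - set(kept["subject_id"].unique()))
    report = ExclusionReport(removed, n_total=len(trials), empty_subjects=empty)
    return kept.reset_index(drop=True), report


def trim_rt_tails(trials: pd.DataFrame, trim_fraction: float = 0.025) -> pd.DataFrame:
    """Remove each subject's ``floor(n * trim_fraction)`` fastest and
    slowest trials (applied once, after the RT exclusions, before DDM
    fitting).  Returns the surviving rows; apply the same (subject, trial)
    set to grip and gaze tables."""
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim fraction must lie in [0, 0.5)")
    out = []
    for sid, g in trials.groupby("subject_id", sort=False):
        k = int(np.floor(len(g) * trim_fraction))
        if k == 0:
            out.append(g)
            continue
        order = g["rt_s"].to_numpy().argsort(kind="stable")
        keep_idx = g.index.to_numpy()[order[k:-k]]
        out.append(g.loc[np.sort(keep_idx)])
    return pd.concat(out).reset_index(drop=True)
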