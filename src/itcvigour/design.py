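"""Experimental design of the intertemporal choice task.

The task crosses two smaller-sooner (SS) magnitudes (a *low* and a *high*
condition), sixteen larger-later (LL) to SS amount ratios, and six delays,
yielding 192 trials per subject.  The SS option is always immediate; the LL
option pays ``ss_amount * ratio`` euros after ``delay_days`` days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: LL/SS amount ratios of the default design.
DEFAULT_RATIOS: tuple[float, ...] = (
    1.03, 1.05, 1.10, 1.15, 1.20, 1.25, 1.35, 1.45,
    1.50, 1.70, 1.90, 2.20, 2.50, 2.90, 3.30, 3.80,
)

#: LL delays in days of the default design.
DEFAULT_DELAYS: tuple[int, ...] = (1, 7, 13, 31, 58, 122)

#: SS amounts in euro, keyed by condition indicator (0 = low, 1 = high).
DEFAULT_SS_AMOUNTS: tuple[float, float] = (10.0, 20.0)

CONDITION_LABELS = ("low", "high")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the choice-trial grid.

    ``n_trials`` is implied by the full crossing and exposed as a property;
    the invariants of the printed design (16 ratios, 6 delays, ratios > 1,
    delays >= 1) are checked on construction for any custom grid.
    """

    ss_amounts: tuple[float, ...] = DEFAULT_SS_AMOUNTS
    ratios: tuple[float, ...] = field(default=DEFAULT_RATIOS)
    delays: tuple[int, ...] = field(default=DEFAULT_DELAYS)
    randomise_order: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.ratios)) != len(self.ratios):
            raise ValueError("duplicate ratios in design")
        if len(set(self.delays)) != len(self.delays):
            raise ValueError("duplicate delays in design")
        if len(set(self.ss_amounts)) != len(self.ss_amounts):
            raise ValueError("duplicate SS amounts in design")
        if any(r <= 1 for r in self.ratios):
            raise ValueError("all LL/SS ratios must exceed 1")
        if any(d < 1 for d in self.delays):
            raise ValueError("all delays must be at least 1 day")
        if any(a <= 0 for a in self.ss_amounts):
            raise ValueError("SS amounts must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.ss_amounts) * len(self.ratios) * len(self.delays)

    def max_ll_amount(self, condition: int) -> float:
        """Largest LL amount of one condition; the per-condition value
        normalisation divisor (38 EUR low / 76 EUR high by default)."""
        return self.ss_amounts[condition] * max(self.ratios)


def build_design(spec: DesignSpec | None = None) -> pd.DataFrame:
    """Build the full trial grid as a tidy table.

    Returns a DataFrame with one row per trial and columns
    ``trial, condition, ss_amount, ll_amount, delay_days, side_ll``.
    ``condition`` is the 0/1 indicator (0 = low, 1 = high).  When
    ``spec.randomise_order`` is set, trial order and the LL screen side are
    permuted with ``spec.seed``; the multiset of trials is unchanged.
    """
    spec = spec or DesignSpec()
    rows = []
    for cond, ss in enumerate(spec.ss_amounts):
        for ratio in spec.ratios:
            for delay in spec.delays:
                rows.append((cond, ss, ss * ratio, delay))
    df = pd.DataFrame(rows, columns=["condition", "ss_amount", "ll_amount", "delay_days"])
    rng = np.random.default_rng(spec.seed)
    df["side_ll"] = rng.choice(["L", "R"], size=len(df))
    if spec.randomise_order:
        df = df.sample(frac=1.0, random_state=np.random.RandomState(spec.seed))
        df = df.reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def condition_label(indicator: int) -> str:
    return CONDITION_LABELS[int(indicator)]
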