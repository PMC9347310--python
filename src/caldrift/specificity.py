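"""Stimulus specificity of cross-day response change.

For each neuron and day pair, a fixed-effects two-way ANOVA of trial
response magnitude on day (2 levels) × stimulus (S levels) with
interaction. A significant interaction means the day-to-day change was
stimulus-specific (a change in sound selectivity) rather than a uniform
gain shift. Effect size of the interaction is Hays' ω²:

    ω² = (SS_int − df_int · MS_err) / (SS_total + MS_err)

which is ~0 under pure gain change and grows with selective remapping.
Type I sums of squares are used on balanced data (where the
decomposition is exact and order-free); Type II when trial exclusions
unbalance the cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["InteractionResult", "day_stimulus_anova"]


@dataclass(frozen=True)
class InteractionResult:
    neuron_id: int
    day_pair: tuple[int, int]
    F_interaction: float
    p_interaction: float
    omega_squared: float
    significant: bool


def day_stimulus_anova(
    trials: pd.DataFrame,
    alpha: float = 0.05,
    neuron_id: int = -1,
    day_pair: tuple[int, int] = (-1, -1),
) -> InteractionResult:
    """Two-way day × stimulus ANOVA with interaction for one neuron.

    ``trials`` needs columns ``response_mag``, ``day`` (exactly 2
    levels), ``stimulus_id`` (>= 2 levels), one row per trial, already
    z-scored (F, p and ω² are invariant to that affine transform).
    Raises on empty cells or fewer than 2 trials in any (day, stimulus)
    cell.
    """
    df = trials[["response_mag", "day", "stimulus_id"]].dropna().copy()
    days = sorted(df["day"].unique())
    stims = sorted(df["stimulus_id"].unique())
    if len(days) != 2:
        raise ValueError(f"expected 2 day levels, got {days}")
    if len(stims) < 2:
        raise ValueError("need >= 2 stimulus levels")
    counts = df.groupby(["day", "stimulus_id"], sort=True).size()
    if len(counts) < 2 * len(stims) or counts.min() < 2:
        raise ValueError("need >= 2 trials in every (day, stimulus) cell")
    balanced = counts.nunique() == 1

    model = smf.ols(
        "response_mag ~ C(day) * C(stimulus_id)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=1 if balanced else 2)
    inter = "C(day):C(stimulus_id)"
    ss_int = float(table.loc[inter, "sum_sq"])
    df_int = float(table.loc[inter, "df"])
    ms_err = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    y = df["response_mag"].to_numpy()
    ss_total = float(((y - y.mean()) ** 2).sum())
    omega2 = (ss_int - df_int * ms_err) / (ss_total + ms_err)
    f = float(table.loc[inter, "F"])
    p = float(table.loc[inter, "PR(>F)"])
    return InteractionResult(
        neuron_id=neuron_id,
        day_pair=day_pair,
        F_interaction=f,
        p_interaction=p,
        omega_squared=float(omega2),
        significant=p < alpha,
    )
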