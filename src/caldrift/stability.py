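"""Cross-day response-change quantification.

The day-to-day drift measures: a per-(neuron, stimulus) shuffle test for
significant change in mean z-scored response magnitude between two days,
the percent of included responses that changed, the fraction of neurons
changing for at least one stimulus (Bonferroni over stimuli), the
Euclidean distance between a neuron's response profiles on two days, and
the enumeration of day pairs per interval for multi-day analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .responsiveness import shuffled_mean_differences

__all__ = [
    "ChangeRecord",
    "cross_day_change_test",
    "percent_changed",
    "neuron_changed",
    "profile_euclidean_distance",
    "interval_pairs",
]


@dataclass(frozen=True)
class ChangeRecord:
    """Outcome of one (neuron, stimulus, day-pair) change test."""

    neuron_id: int
    stimulus_id: int
    day_pair: tuple[int, int]
    observed_change: float
    change_quantile: float  # fraction of shuffled |diffs| strictly below observed
    magnitude_pass: bool
    significant: bool
    included: bool  # response passed the responsiveness test on >= 1 day

    @property
    def interval_days(self) -> int:
        return self.day_pair[1] - self.day_pair[0]


def _relative_magnitude_pass(m1: float, m2: float, margin: float) -> bool:
    # |Δ| relative to the larger day magnitude; symmetric in day order.
    denom = max(abs(m1), abs(m2))
    if denom == 0:
        return False
    return abs(m2 - m1) / denom >= margin


def cross_day_change_test(
    day1_trials: np.ndarray,
    day2_trials: np.ndarray,
    n_shuffles: int = 1000,
    quantile: float = 0.95,
    margin: float = 0.10,
    seed: int | np.random.Generator = 0,
    neuron_id: int = -1,
    stimulus_id: int = -1,
    day_pair: tuple[int, int] = (-1, -1),
    included: bool = True,
) -> ChangeRecord:
    """Shuffle test for a change in mean response magnitude across days.

    Inputs are z-scored per-trial response magnitudes. The change
    statistic is |mean(day2) − mean(day1)|, compared against the same
    absolute difference under ``n_shuffles`` random relabelings of the
    pooled trials (counts preserved); significant iff it strictly
    exceeds the ``quantile`` of the null AND the relative change
    magnitude is at least ``margin``.
    """
    d1 = np.asarray(day1_trials, dtype=float)
    d2 = np.asarray(day2_trials, dtype=float)
    if d1.size < 3 or d2.size < 3:
        raise ValueError("need >= 3 trials per day")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m1, m2 = float(d1.mean()), float(d2.mean())
    observed = abs(m2 - m1)
    mag_ok = _relative_magnitude_pass(m1, m2, margin)

    pool = np.concatenate([d1, d2])
    if np.ptp(pool) == 0:
        return ChangeRecord(
            neuron_id, stimulus_id, day_pair, observed, 0.0, mag_ok, False, included
        )
    null = shuffled_mean_differences(d2, d1, n_shuffles, rng, absolute=True)
    q = float(np.mean(null < observed))
    significant = (q > quantile) and mag_ok and included
    return ChangeRecord(
        neuron_id, stimulus_id, day_pair, observed, q, mag_ok, significant, included
    )


def percent_changed(records: list[ChangeRecord]) -> float:
    """100 × (#significant among included) / (#included)."""
    included = [r for r in records if r.included]
    if not included:
        raise ValueError("no included change records")
    return 100.0 * sum(r.significant for r in included) / len(included)


def neuron_changed(
    records: list[ChangeRecord],
    n_stimuli: int,
    quantile: float = 0.95,
) -> bool:
    """True iff the neuron changed significantly for >= 1 stimulus under
    a Bonferroni-tightened quantile 1 − (1 − quantile)/n_stimuli."""
    pairs = {r.day_pair for r in records}
    if len(pairs) > 1:
        raise ValueError(f"records span multiple day pairs: {sorted(pairs)}")
    thresh = 1.0 - (1.0 - quantile) / n_stimuli
    return any(
        r.included and r.magnitude_pass and r.change_quantile > thresh
        for r in records
    )


def profile_euclidean_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Euclidean distance between two response profiles,
    sqrt(Σᵢ (xᵢ − yᵢ)²) over stimuli in a fixed shared order."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share stimulus order and count")
    return float(np.sqrt(((a - b) ** 2).sum()))


def interval_pairs(
    n_days: int = 5, first_day: int = 0
) -> dict[int, list[tuple[int, int]]]:
    """Day pairs per interval: interval k maps to [(d, d+k)] for all valid
    start days; for 5 days that is 4, 3, 2, 1 pairs for k = 1..4.

    ``first_day`` sets the label of the first day (0 for array indices,
    1 for day-numbered reporting).
    """
    if n_days < 2:
        raise ValueError("need >= 2 days")
    return {
        k: [(d + first_day, d + k + first_day) for d in range(n_days - k)]
        for k in range(1, n_days)
    }
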