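"""Bootstrap responsiveness testing of single-neuron sound responses.

A neuron is responsive to a stimulus on a day if the difference between
its mean trial response magnitude and the mean prestimulus magnitude
(pooled over all sounds of the protocol) exceeds the 97.5% quantile of
1000 label-shuffled differences, and its mean sound response clears a
10% margin over the prestimulus baseline. Neuron-level sound
responsiveness applies a Bonferroni correction over stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponsivenessResult",
    "stimulus_responsiveness_test",
    "sound_responsive",
    "shuffled_mean_differences",
]


@dataclass(frozen=True)
class ResponsivenessResult:
    neuron_id: int
    day: int
    stimulus_id: int
    observed_diff: float
    shuffle_quantile: float  # fraction of shuffled diffs strictly below observed
    margin_pass: bool
    responsive: bool


def shuffled_mean_differences(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    absolute: bool = False,
) -> np.ndarray:
    """Null distribution of mean(group_a) − mean(group_b) under random
    relabeling of the pooled values, preserving group sizes.

    Each shuffle permutes the pool without replacement; with
    ``absolute`` the |difference| is returned (two-sided null).
    """
    pool = np.concatenate([group_a, group_b])
    n_a = group_a.size
    mat = np.tile(pool, (n_shuffles, 1))
    rng.permuted(mat, axis=1, out=mat)
    diffs = mat[:, :n_a].mean(axis=1) - mat[:, n_a:].mean(axis=1)
    return np.abs(diffs) if absolute else diffs


def _margin_pass(mean_sound: float, mean_prestim: float, margin: float) -> bool:
    # "at least `margin` greater than prestim" is ill-posed at non-positive
    # baselines (median ΔF/F makes prestim means ~0): literal rule when
    # prestim > 0, positivity otherwise.
    if mean_prestim > 0:
        return mean_sound >= (1.0 + margin) * mean_prestim
    return mean_sound > 0


def stimulus_responsiveness_test(
    sound_trials: np.ndarray,
    prestim_pool: np.ndarray,
    n_shuffles: int = 1000,
    quantile: float = 0.975,
    margin: float = 0.10,
    seed: int | np.random.Generator = 0,
    neuron_id: int = -1,
    day: int = -1,
    stimulus_id: int = -1,
) -> ResponsivenessResult:
    """Shuffle test of one neuron's responsiveness to one stimulus.

    ``sound_trials`` are the per-trial response magnitudes to the
    stimulus; ``prestim_pool`` the prestimulus magnitudes of all trials
    of the protocol. Responsive iff the observed mean difference
    strictly exceeds more than ``quantile`` of the shuffled differences
    and the margin criterion passes. Operates on raw (non-z-scored)
    ΔF/F magnitudes.
    """
    sound = np.asarray(sound_trials, dtype=float)
    pre = np.asarray(prestim_pool, dtype=float)
    if sound.size < 3:
        raise ValueError("need >= 3 sound trials")
    if pre.size == 0:
        raise ValueError("empty prestim pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = float(sound.mean() - pre.mean())
    margin_ok = _margin_pass(float(sound.mean()), float(pre.mean()), margin)

    pool = np.concatenate([sound, pre])
    if np.ptp(pool) == 0:  # zero-variance pool: no evidence possible
        return ResponsivenessResult(
            neuron_id, day, stimulus_id, observed, 0.0, margin_ok, False
        )
    null = shuffled_mean_differences(sound, pre, n_shuffles, rng)
    q = float(np.mean(null < observed))
    responsive = (q > quantile) and margin_ok
    return ResponsivenessResult(
        neuron_id, day, stimulus_id, observed, q, margin_ok, responsive
    )


def sound_responsive(
    results: list[ResponsivenessResult],
    n_stimuli: int | None = None,
    quantile: float = 0.975,
) -> bool:
    """Neuron-day sound responsiveness: responsive to >= 1 stimulus under
    a Bonferroni-tightened shuffle quantile 1 − (1 − quantile)/n_stimuli."""
    if not results:
        return False
    n = n_stimuli if n_stimuli is not None else len(results)
    thresh = 1.0 - (1.0 - quantile) / n
    return any(r.shuffle_quantile > thresh and r.margin_pass for r in results)
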