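"""From raw session traces to quality-filtered, trial-resolved responses.

The pipeline stage that turns a neurons × frames fluorescence matrix into
a tidy trial table: ΔF/F normalization against the session median, ROI
quality gating (compactness and trace skewness), extraction of per-trial
response and prestimulus magnitudes in fixed windows around each sound
onset, locomotion-based trial exclusion, and the per-neuron z-scoring
applied before any cross-day comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "SessionRecording",
    "dff",
    "qc_mask",
    "extract_trials",
    "zscore_day_pair",
    "TRIAL_COLUMNS",
]

#: Columns of the trial table produced by :func:`extract_trials`.
TRIAL_COLUMNS = [
    "neuron_id",
    "day",
    "stimulus_id",
    "trial",
    "response_mag",
    "prestim_mag",
    "excluded",
    "reason",
]


@dataclass
class SessionRecording:
    """One imaging day of one focal plane.

    traces are raw fluorescence (a.u.), neurons × frames; events is a
    sequence of (onset_frame, stimulus_id); locomotion_mask flags frames
    acquired while the animal ran; roi_stats holds per-neuron
    (compactness, skewness) from segmentation QC.
    """

    traces: np.ndarray
    frame_rate_hz: float
    events: np.ndarray  # (n_events, 2) int: onset_frame, stimulus_id
    locomotion_mask: np.ndarray  # (n_frames,) bool
    day_index: int
    plane_id: str = "plane0"
    roi_stats: np.ndarray | None = None  # (n_neurons, 2): compactness, skewness

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.locomotion_mask = np.asarray(self.locomotion_mask, dtype=bool)
        if self.traces.ndim != 2:
            raise ValueError("traces must be neurons x frames")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.events.size and (
            self.events[:, 0].min() < 0
            or self.events[:, 0].max() >= self.traces.shape[1]
        ):
            raise ValueError("event onset frames outside trace length")
        if self.locomotion_mask.shape != (self.traces.shape[1],):
            raise ValueError("locomotion_mask length must equal n_frames")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


def dff(trace: np.ndarray) -> np.ndarray:
    """ΔF/F against the session median: (F(t) − F₀)/F₀ with F₀ = median(F).

    Raises if the median is non-positive (the ratio is meaningless);
    callers exclude such neurons and log the reason.
    """
    f = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("trace contains non-finite values")
    f0 = np.median(f)
    if f0 <= 0:
        raise ValueError(f"session median fluorescence {f0:.3g} <= 0")
    return (f - f0) / f0


def qc_mask(roi_stats: np.ndarray) -> np.ndarray:
    """Keep neurons with compactness > 0.8 AND trace skewness > 1.1.

    Both gates are strict inequalities. Missing (NaN) statistics fail
    the gate.
    """
    stats = np.asarray(roi_stats, dtype=float)
    if stats.ndim != 2 or stats.shape[1] != 2:
        raise ValueError("roi_stats must be (n_neurons, 2): compactness, skewness")
    compactness, skewness = stats[:, 0], stats[:, 1]
    with np.errstate(invalid="ignore"):
        keep = (compactness > 0.8) & (skewness > 1.1)
    return np.where(np.isnan(compactness) | np.isnan(skewness), False, keep)


def trace_skewness(dff_trace: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness of a full-session ΔF/F trace."""
    return float(sp_stats.skew(np.asarray(dff_trace, float), bias=False))


def roi_compactness(mask: np.ndarray) -> float:
    """Circularity 4π·area/perimeter² of a boolean ROI mask (disk → 1)."""
    from skimage.measure import label, regionprops

    props = regionprops(label(np.asarray(mask, bool).astype(int)))
    if not props:
        raise ValueError("empty ROI mask")
    r = max(props, key=lambda p: p.area)
    if r.perimeter == 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * r.area / r.perimeter**2))


def _window_frames(onset: int, lo_s: float, hi_s: float, rate: float) -> np.ndarray:
    """Frames whose start time relative to onset lies in [lo_s, hi_s).

    Half-open on the right so adjacent windows never share a frame.
    """
    lo = int(np.ceil(lo_s * rate - 1e-9))
    hi = int(np.floor(hi_s * rate - 1e-9)) + 1  # first offset with time >= hi_s excluded
    return onset + np.arange(lo, hi)


def extract_trials(
    session: SessionRecording,
    response_window_s: tuple[float, float] = (0.0, 1.5),
    prestim_window_s: tuple[float, float] = (-1.5, 0.0),
    apply_qc: bool = True,
) -> pd.DataFrame:
    """Per-trial response and prestimulus ΔF/F magnitudes for every neuron.

    response_mag is the mean ΔF/F over frames whose start time falls in
    the response window (default 0–1.5 s from onset, half-open);
    prestim_mag analogously for −1.5–0 s. A trial is excluded with
    reason "locomotion" if any response-window frame is flagged in the
    locomotion mask, "edge" if either window runs off the session, and
    "qc" (all trials of a neuron) if the neuron fails the ROI gates or
    has non-positive median fluorescence.
    """
    rate = session.frame_rate_hz
    n_frames = session.n_frames
    keep = (
        qc_mask(session.roi_stats)
        if (apply_qc and session.roi_stats is not None)
        else np.ones(session.n_neurons, bool)
    )

    dffs = np.zeros_like(session.traces)
    valid = keep.copy()
    for i in range(session.n_neurons):
        if not keep[i]:
            continue
        try:
            dffs[i] = dff(session.traces[i])
        except ValueError:
            valid[i] = False

    rows: list[tuple] = []
    trial_counter: dict[int, int] = {}
    for onset, stim in session.events:
        trial_idx = trial_counter.get(stim, 0)
        trial_counter[stim] = trial_idx + 1
        resp_f = _window_frames(onset, *response_window_s, rate)
        pre_f = _window_frames(onset, *prestim_window_s, rate)
        edge = resp_f[0] < 0 or resp_f[-1] >= n_frames or pre_f[0] < 0 or pre_f[-1] >= n_frames
        loco = (not edge) and bool(session.locomotion_mask[resp_f].any())
        for i in range(session.n_neurons):
            if not valid[i]:
                rows.append((i, session.day_index, stim, trial_idx, np.nan, np.nan, True, "qc"))
            elif edge:
                rows.append((i, session.day_index, stim, trial_idx, np.nan, np.nan, True, "edge"))
            elif loco:
                rows.append((i, session.day_index, stim, trial_idx, np.nan, np.nan, True, "locomotion"))
            else:
                rows.append(
                    (
                        i,
                        session.day_index,
                        stim,
                        trial_idx,
                        float(dffs[i, resp_f].mean()),
                        float(dffs[i, pre_f].mean()),
                        False,
                        "",
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def zscore_day_pair(table: pd.DataFrame) -> pd.DataFrame:
    """z-score one neuron's response magnitudes across a day pair.

    The table must hold one neuron's trials for the stimuli of one
    protocol on exactly two days. Mean and SD (population, n
    denominator) are taken over all pooled non-excluded trial responses
    across both days and all stimuli; response_mag is transformed to
    (x − μ)/σ. Raises if fewer than two usable trials or σ = 0.
    """
    if table["neuron_id"].nunique() > 1:
        raise ValueError("zscore_day_pair expects a single neuron's trials")
    days = sorted(table["day"].unique())
    if len(days) != 2:
        raise ValueError(f"expected exactly 2 days, got {days}")
    pool = table.loc[~table["excluded"], "response_mag"].to_numpy()
    if pool.size < 2:
        raise ValueError("need >= 2 non-excluded trials to z-score")
    mu, sigma = pool.mean(), pool.std()  # population SD
    if sigma == 0:
        raise ValueError("zero variance across pooled trials")
    out = table.copy()
    out["response_mag"] = (out["response_mag"] - mu) / sigma
    return out
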