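"""Synthetic stimuli, recordings, and field-of-view images.

Emulates the statistical structure of a multi-day awake two-photon
experiment in auditory cortex: 500 ms sounds (log-spaced pure tones and
broadband spectrotemporally modulated complex sounds) presented 10 times
each per session at jittered interstimulus intervals, GCaMP6f-like
fluorescence traces sampled at 3 frames/s, day-to-day response drift
(multiplicative gain and stimulus-specific remapping) with known ground
truth, locomotion epochs, and translated/perturbed mean-fluorescence
images for cross-day neuron matching.

Every operation is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import SessionRecording

__all__ = [
    "StimulusSet",
    "SynthConfig",
    "GroundTruth",
    "make_stimulus_set",
    "make_experiment",
    "make_fov_pair",
]

PT = "PT"
CXS = "CxS"


@dataclass(frozen=True)
class StimulusSet:
    """A set of equally long waveforms with class tags (PT or CxS)."""

    waveforms: list[np.ndarray]
    sample_rate_hz: float
    labels: list[str]
    sound_class: list[str]
    duration_s: float

    def __post_init__(self) -> None:
        n = len(self.waveforms)
        if not (n == len(self.labels) == len(self.sound_class)):
            raise ValueError("waveforms, labels, sound_class lengths differ")
        lens = {w.size for w in self.waveforms}
        if len(lens) > 1:
            raise ValueError("waveforms must share one length")
        if set(self.sound_class) - {PT, CXS}:
            raise ValueError(f"sound_class values must be in {{{PT}, {CXS}}}")
        for w in self.waveforms:
            if not np.all(np.isfinite(w)):
                raise ValueError("waveform amplitudes must be finite")

    @property
    def n_stimuli(self) -> int:
        return len(self.waveforms)

    def class_indices(self, cls: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.sound_class) if c == cls])


def _cosine_ramps(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp == 0:
        return env
    r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = r
    env[-n_ramp:] = r[::-1]
    return env


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Band-limited Gaussian noise via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


def make_stimulus_set(
    seed: int,
    n_pt: int = 8,
    n_cxs: int = 8,
    sample_rate_hz: float = 97_600.0,
    duration_s: float = 0.5,
    f_lo_hz: float = 2_000.0,
    f_hi_hz: float = 32_000.0,
) -> StimulusSet:
    """Synthesize pure tones and broadband complex sounds.

    Pure tones are log-spaced sinusoids from ``f_lo_hz`` to ``f_hi_hz``
    with 5 ms cosine on/off ramps. Complex sounds are sums of 3-5
    band-limited noise components whose center bands and amplitudes are
    re-drawn every 50-100 ms; the first two components are pinned to a
    low (2-4 kHz) and a high (20-35 kHz) band so every complex sound is
    guaranteed broadband. By construction every complex sound has higher
    occupied bandwidth, spectral entropy, and modulation index than
    every pure tone.
    """
    if n_pt < 1 or n_cxs < 1:
        raise ValueError("need at least one stimulus per class")
    if sample_rate_hz <= 2 * f_hi_hz:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz below Nyquist for {f_hi_hz} Hz tones"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    ramp = _cosine_ramps(n, int(round(0.005 * sample_rate_hz)))

    waveforms: list[np.ndarray] = []
    labels: list[str] = []
    classes: list[str] = []

    for f in np.geomspace(f_lo_hz, f_hi_hz, n_pt):
        waveforms.append(0.9 * np.sin(2 * np.pi * f * t) * ramp)
        labels.append(f"PT_{f/1000:.1f}kHz")
        classes.append(PT)

    nyq = sample_rate_hz / 2
    for j in range(n_cxs):
        n_comp = int(rng.integers(3, 6))
        x = np.zeros(n)
        for c in range(n_comp):
            pos = 0
            while pos < n:
                seg = int(rng.uniform(0.05, 0.10) * sample_rate_hz)
                seg = min(seg, n - pos)
                if c == 0:
                    center = rng.uniform(2_000, 4_000)
                elif c == 1:
                    center = rng.uniform(20_000, 35_000)
                else:
                    center = np.exp(rng.uniform(np.log(1_500), np.log(38_000)))
                half_oct = rng.uniform(0.15, 0.75)
                lo = max(200.0, center / 2**half_oct)
                hi = min(nyq * 0.95, center * 2**half_oct)
                amp = rng.uniform(0.1, 1.0)
                x[pos : pos + seg] += amp * _band_noise(
                    rng, seg, sample_rate_hz, lo, hi
                ) * _cosine_ramps(seg, max(2, int(0.002 * sample_rate_hz)))
                pos += seg
        x = 0.9 * x / np.abs(x).max()
        waveforms.append(x * ramp)
        labels.append(f"CxS_{j}")
        classes.append(CXS)

    return StimulusSet(
        waveforms=waveforms,
        sample_rate_hz=sample_rate_hz,
        labels=labels,
        sound_class=classes,
        duration_s=duration_s,
    )


@dataclass
class SynthConfig:
    """Knobs of the synthetic multi-day experiment.

    ``noise_sd`` (ΔF/F units) is the single noise scale: it sets the
    additive pink-noise SD of the trace and, scaled by
    ``trial_amp_sigma_factor``, the multiplicative lognormal trial
    amplitude jitter; zero yields fully deterministic responses.
    ``tuning_drift_prob`` is the per-day probability that a responsive
    (neuron, stimulus) pair remaps (its amplitude is re-drawn); it may
    be a scalar or a ``{"PT": p, "CxS": p}`` mapping to give the two
    protocols different drift rates. ``gain_drift_sd`` is a per-day
    multiplicative lognormal session gain (excitability/imaging scale);
    ``uniform_offset_drift_sd`` (ΔF/F units) instead adds a per-neuron
    per-day offset to every stimulus's transient amplitude — the "pure
    gain" that shifts all response magnitudes equally and therefore
    carries no day × stimulus interaction. Baseline fluorescence (~100 a.u.)
    and transient amplitude statistics are free parameters of the
    emulation — no reference values exist for them — and are documented
    defaults, not fitted quantities.
    """

    n_neurons: int = 40
    n_days: int = 5
    n_trials: int = 10
    frame_rate_hz: float = 3.0
    isi_mean_s: float = 1.5
    isi_jitter_s: float = 0.3
    stimulus_duration_s: float = 0.5
    frac_responsive: float = 0.35
    kernel_decay_s: float = 0.7
    amp_mean_dff: float = 0.5
    amp_sigma_log: float = 0.3
    noise_sd: float = 0.08
    trial_amp_sigma_factor: float = 3.0
    gain_drift_sd: float = 0.1
    uniform_offset_drift_sd: float = 0.0
    tuning_drift_prob: float | dict = 0.1
    locomotion_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_neurons, self.n_days, self.n_trials) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.frac_responsive <= 1:
            raise ValueError("frac_responsive must be in [0,1]")
        for p in self._drift_probs().values():
            if not 0 <= p <= 1:
                raise ValueError("tuning_drift_prob must be in [0,1]")
        if (
            self.noise_sd < 0
            or self.gain_drift_sd < 0
            or self.uniform_offset_drift_sd < 0
            or self.locomotion_rate < 0
        ):
            raise ValueError("noise/drift/locomotion scales must be nonnegative")

    def _drift_probs(self) -> dict:
        if isinstance(self.tuning_drift_prob, dict):
            return {PT: float(self.tuning_drift_prob[PT]), CXS: float(self.tuning_drift_prob[CXS])}
        return {PT: float(self.tuning_drift_prob), CXS: float(self.tuning_drift_prob)}

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests.

    responsive_mask: (n_days, n_neurons, n_stimuli) bool;
    drift_labels: (n_days-1, n_neurons, n_stimuli) strings in
    {stable, gain, remap} ("" for never-responsive pairs);
    true_gains: (n_neurons, n_days).
    """

    responsive_mask: np.ndarray
    drift_labels: np.ndarray
    true_gains: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "responsive_mask": self.responsive_mask.astype(int).tolist(),
                "drift_labels": self.drift_labels.tolist(),
                "true_gains": self.true_gains.tolist(),
            }
        )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-shaped noise (flat below the first nonzero bin)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def make_experiment(
    config: SynthConfig, stimuli: StimulusSet
) -> tuple[list[SessionRecording], GroundTruth]:
    """Simulate ``config.n_days`` sessions of one focal plane.

    Responsive (neuron, stimulus) pairs emit one-frame-rise exponential
    transients at stimulus onsets; trial amplitude = base amplitude ×
    day gain × lognormal trial jitter. Between consecutive days each
    responsive pair remaps (amplitude re-drawn) with its class's
    ``tuning_drift_prob``; otherwise it carries the label "gain" (or
    "stable" when gain_drift_sd is 0). Events are 10 pseudorandom
    block-shuffled repetitions per stimulus at jittered ISI; locomotion
    epochs of 1-3 s arrive with Poisson count ``locomotion_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_neu, n_days, n_stim = config.n_neurons, config.n_days, stimuli.n_stimuli
    probs = config._drift_probs()
    cls = np.array(stimuli.sound_class)

    base_resp = rng.random((n_neu, n_stim)) < config.frac_responsive
    amps = np.where(
        base_resp,
        rng.lognormal(np.log(config.amp_mean_dff), config.amp_sigma_log, (n_neu, n_stim)),
        0.0,
    )
    gains = np.exp(rng.normal(0.0, config.gain_drift_sd, (n_neu, n_days)))
    offsets = (
        rng.normal(0.0, config.uniform_offset_drift_sd, (n_neu, n_days))
        if config.uniform_offset_drift_sd > 0
        else np.zeros((n_neu, n_days))
    )

    # per-day amplitude matrices, with remap events between consecutive days
    day_amps = np.empty((n_days, n_neu, n_stim))
    day_amps[0] = amps
    drift_labels = np.full((max(n_days - 1, 0), n_neu, n_stim), "", dtype="<U6")
    for d in range(1, n_days):
        prev = day_amps[d - 1].copy()
        remap = (rng.random((n_neu, n_stim)) < np.array([probs[c] for c in cls])) & base_resp
        redraw = rng.lognormal(np.log(config.amp_mean_dff), config.amp_sigma_log, (n_neu, n_stim))
        # a remap re-draws the tuning: a currently responding stimulus may
        # be lost entirely (amplitude 0), a silent one regained
        lose = rng.random((n_neu, n_stim)) < 0.5
        redraw = np.where(lose & (prev > 0), 0.0, redraw)
        day_amps[d] = np.where(remap, redraw, prev)
        has_gain = config.gain_drift_sd > 0 or config.uniform_offset_drift_sd > 0
        lbl = np.where(remap, "remap", "gain" if has_gain else "stable")
        lbl = np.where(base_resp, lbl, "")
        drift_labels[d - 1] = lbl

    responsive_mask = (day_amps > 0) & base_resp[None, :, :]

    rate = config.frame_rate_hz
    trial_sigma = config.noise_sd * config.trial_amp_sigma_factor
    baselines = rng.normal(100.0, 5.0, n_neu).clip(min=50.0)
    # kernel: one-frame rise then exponential decay, long enough to vanish
    n_k = int(np.ceil(5 * config.kernel_decay_s * rate)) + 1
    kernel = np.exp(-np.arange(n_k) / (config.kernel_decay_s * rate))

    sessions: list[SessionRecording] = []
    for d in range(n_days):
        # pseudorandom order: shuffled blocks, each block one repeat of all stimuli
        order = np.concatenate(
            [rng.permutation(n_stim) for _ in range(config.n_trials)]
        )
        gaps = config.stimulus_duration_s + rng.uniform(
            config.isi_mean_s - config.isi_jitter_s,
            config.isi_mean_s + config.isi_jitter_s,
            order.size,
        )
        onsets_s = 3.0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        onset_frames = np.round(onsets_s * rate).astype(int)
        n_frames = int(onset_frames[-1] + np.ceil(3.0 * rate) + 1)
        events = np.column_stack([onset_frames, order])

        traces = np.tile(baselines[:, None], (1, n_frames))
        if config.noise_sd > 0:
            for i in range(n_neu):
                traces[i] += (
                    config.noise_sd * baselines[i] * _pink_noise(rng, n_frames)
                )
        resp = np.zeros((n_neu, n_frames))
        for onset, stim in events:
            a = day_amps[d, :, stim] * gains[:, d] + offsets[:, d]
            if trial_sigma > 0:
                a = a * np.exp(rng.normal(0.0, trial_sigma, n_neu))
            end = min(n_frames, onset + n_k)
            resp[:, onset:end] += a[:, None] * kernel[: end - onset]
        traces += resp * baselines[:, None]

        loco = np.zeros(n_frames, bool)
        for _ in range(rng.poisson(config.locomotion_rate)):
            start = int(rng.integers(0, n_frames))
            dur = int(np.ceil(rng.uniform(1.0, 3.0) * rate))
            loco[start : start + dur] = True

        roi_stats = np.column_stack(
            [rng.uniform(0.85, 0.98, n_neu), rng.uniform(1.5, 3.0, n_neu)]
        )
        sessions.append(
            SessionRecording(
                traces=traces,
                frame_rate_hz=rate,
                events=events,
                locomotion_mask=loco,
                day_index=d,
                plane_id="synthetic_plane",
                roi_stats=roi_stats,
            )
        )

    truth = GroundTruth(
        responsive_mask=responsive_mask,
        drift_labels=drift_labels,
        true_gains=gains,
    )
    return sessions, truth


def make_fov_pair(
    seed: int,
    n_neurons: int,
    shift_px: tuple[int, int] = (0, 0),
    morph_noise: float = 0.0,
    image_size: int = 256,
    margin: int = 32,
    min_sep: float = 14.0,
    return_centers: bool = False,
):
    """A pair of mean-fluorescence images of the same cell layout.

    Image B is image A's Gaussian cell bodies translated by ``shift_px``
    with per-cell brightness and size perturbations of relative scale
    ``morph_noise``. Returns (imageA, imageB, identity correspondence),
    plus the day-1 cell centers when ``return_centers`` is set. Raises
    if ``n_neurons`` cells cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    lo, hi = margin, image_size - margin
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_neurons:
        cand = rng.uniform(lo, hi, 2)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
        tries += 1
        if tries > 200 * n_neurons:
            raise ValueError(
                f"cannot place {n_neurons} non-overlapping cells in "
                f"{image_size}x{image_size} field"
            )
    centers_arr = np.array(centers)
    # distinctive somata: elliptical, oriented, with a darker nucleus, so
    # patch similarity can discriminate cells the way real anatomy does
    amp = rng.uniform(0.6, 1.0, n_neurons)
    sigma = rng.uniform(2.5, 4.0, n_neurons)
    axis_ratio = rng.uniform(1.0, 2.0, n_neurons)
    theta = rng.uniform(0, np.pi, n_neurons)
    ring = rng.uniform(0.0, 0.6, n_neurons)

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)

    def render(ctrs, amps, sigmas):
        img = np.zeros((image_size, image_size))
        for i, ((cy, cx), a, s) in enumerate(zip(ctrs, amps, sigmas)):
            dy_, dx_ = yy - cy, xx - cx
            u = np.cos(theta[i]) * dy_ + np.sin(theta[i]) * dx_
            v = -np.sin(theta[i]) * dy_ + np.cos(theta[i]) * dx_
            su, sv = s, s / axis_ratio[i]
            body = np.exp(-(u**2 / (2 * su**2) + v**2 / (2 * sv**2)))
            nucleus = np.exp(-(u**2 + v**2) / (2 * (s / 2.5) ** 2))
            img += a * (body - ring[i] * nucleus)
        return img

    # shared neuropil-like background texture, translated with the field
    from scipy.ndimage import gaussian_filter

    background = 0.1 + 0.08 * gaussian_filter(
        rng.standard_normal((image_size, image_size)), 3.0
    )

    dy, dx = shift_px
    image_a = background + render(centers_arr, amp, sigma)
    amp_b = amp * (1.0 + morph_noise * rng.standard_normal(n_neurons))
    sigma_b = (sigma * (1.0 + morph_noise * rng.standard_normal(n_neurons))).clip(min=1.0)
    image_b = np.roll(background, (dy, dx), axis=(0, 1)) + render(
        centers_arr + np.array([dy, dx]), np.abs(amp_b), sigma_b
    )
    correspondence = np.arange(n_neurons)
    if return_centers:
        return image_a, image_b, correspondence, centers_arr
    return image_a, image_b, correspondence
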