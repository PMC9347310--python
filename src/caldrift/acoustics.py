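"""Sound-complexity metrics for auditory stimuli.

Quantifies how spectrally broad and temporally modulated a sound is, the
axis that separates pure tones from complex, vocalization-like sounds:

* **occupied bandwidth** — frequency span between the 0.5% and 99.5%
  crossings of the integrated power spectrum;
* **spectral entropy** — Shannon entropy (bits) of the normalized power
  spectrum; near 0 for a tone, near ``log2(n_bins)`` for white noise;
* **spectrotemporal modulation index** — one minus the mean pairwise
  Pearson correlation of 20 time-binned spectrogram power columns;
  ~0 for a stationary sound, >1 when frequency content anticorrelates
  across time;
* **spectral centroid** — power-weighted mean frequency.

All metrics are invariant to overall amplitude scaling of the waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "Spectrum",
    "ComplexityMetrics",
    "compute_power_spectrum",
    "occupied_bandwidth",
    "spectral_entropy",
    "spectral_centroid",
    "spectrotemporal_modulation_index",
    "overlapping_tone_set",
    "waveform_metrics",
]


@dataclass(frozen=True)
class Spectrum:
    """Single-sided power spectrum on an ascending frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("freqs_hz and power must be 1-D with equal length")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(p))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(p < 0):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)

    @property
    def total_power(self) -> float:
        return float(self.power.sum())

    def normalized(self) -> np.ndarray:
        """Power as a probability distribution over bins."""
        tot = self.total_power
        if tot <= 0:
            raise ValueError("zero spectrum has no normalized form")
        return self.power / tot


@dataclass(frozen=True)
class ComplexityMetrics:
    occupied_bandwidth_hz: float
    spectral_entropy_bits: float
    modulation_index: float
    spectral_centroid_hz: float


def compute_power_spectrum(waveform: np.ndarray, sample_rate_hz: float) -> Spectrum:
    """Full-signal single-sided periodogram (Hann window, next-pow2 FFT).

    A Hann window keeps sidelobe energy well below the 0.5% tail used by
    :func:`occupied_bandwidth`, so a pure tone's occupied bandwidth stays
    at main-lobe width (a few Hz for 500 ms) rather than being inflated
    by leakage.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        raise ValueError("waveform is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite values")
    nfft = 1 << (int(x.size - 1)).bit_length()
    freqs, power = sp_signal.periodogram(
        x, fs=sample_rate_hz, window="hann", nfft=nfft, detrend=False
    )
    if power.sum() == 0:
        warnings.warn("all-zero waveform: zero spectrum (entropy undefined)")
    return Spectrum(freqs_hz=freqs, power=power)


def occupied_bandwidth(
    spectrum: Spectrum, lo_frac: float = 0.005, hi_frac: float = 0.995
) -> float:
    """Frequency span between the lo_frac and hi_frac crossings of
    integrated power; f(q) is the first frequency where cumulative power
    reaches q × total."""
    if spectrum.total_power <= 0:
        raise ValueError("occupied bandwidth undefined for zero spectrum")
    if spectrum.power.size == 1:
        return 0.0
    cum = np.cumsum(spectrum.power)
    tot = cum[-1]
    # first index where cumulative >= q * total (tolerate fp round-off)
    eps = tot * 1e-12
    i_lo = int(np.searchsorted(cum, lo_frac * tot - eps))
    i_hi = int(np.searchsorted(cum, hi_frac * tot - eps))
    return float(spectrum.freqs_hz[i_hi] - spectrum.freqs_hz[i_lo])


def spectral_entropy(spectrum: Spectrum) -> float:
    """Shannon entropy (bits) of the normalized power distribution."""
    p = spectrum.normalized()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def spectral_centroid(spectrum: Spectrum) -> float:
    """Power-weighted mean frequency, Σ fᵢ pᵢ / Σ pᵢ."""
    p = spectrum.normalized()
    return float((spectrum.freqs_hz * p).sum())


def _truncate_trailing_silence(spec_power: np.ndarray, rel_thresh: float = 0.01) -> np.ndarray:
    """Drop trailing spectrogram columns whose broadband power falls below
    ``rel_thresh`` of the peak column power (silence padding at the end)."""
    col_power = spec_power.sum(axis=0)
    peak = col_power.max()
    if peak <= 0:
        return spec_power
    keep = np.nonzero(col_power >= rel_thresh * peak)[0]
    return spec_power[:, : keep[-1] + 1]


def spectrotemporal_modulation_index(
    waveform: np.ndarray,
    sample_rate_hz: float,
    n_time_bins: int = 20,
    nperseg: int = 1024,
) -> float:
    """One minus the mean pairwise Pearson correlation of time-binned
    spectrogram power columns.

    The spectrogram (Hann window, 50% overlap) is truncated of trailing
    silence, its columns averaged into ``n_time_bins`` equal time bins,
    and the Pearson correlation computed over every unordered distinct
    pair of binned frequency-power vectors. Pairs involving a
    zero-variance vector are dropped with a warning. Values lie in
    [0, 2]: 0 for a stationary sound, above 1 when the frequency content
    of different bins anticorrelates.
    """
    x = np.asarray(waveform, dtype=float)
    freqs, times, sxx = sp_signal.spectrogram(
        x,
        fs=sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        mode="psd",
    )
    sxx = _truncate_trailing_silence(sxx)
    if sxx.shape[1] < n_time_bins:
        raise ValueError(
            f"waveform yields {sxx.shape[1]} spectrogram columns after silence "
            f"truncation; need at least {n_time_bins}"
        )
    binned = np.stack(
        [chunk.mean(axis=1) for chunk in np.array_split(sxx, n_time_bins, axis=1)],
        axis=1,
    )  # (n_freq, n_time_bins)
    sd = binned.std(axis=0)
    valid = sd > 0
    n_dropped_pairs = 0
    corrs = []
    if valid.sum() >= 2:
        c = np.corrcoef(binned[:, valid].T)
        iu = np.triu_indices_from(c, k=1)
        corrs = c[iu]
    n_valid = int(valid.sum())
    n_dropped_pairs = (n_time_bins * (n_time_bins - 1) - n_valid * (n_valid - 1)) // 2
    if n_dropped_pairs:
        warnings.warn(
            f"{n_dropped_pairs} bin pairs dropped (zero-variance power vector)"
        )
    if len(corrs) == 0:
        raise ValueError("no valid bin pairs: all binned vectors are constant")
    return float(1.0 - np.mean(corrs))


def overlapping_tone_set(
    cxs_spectrum: Spectrum, tone_freqs_hz: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the ``k`` tones whose ±1/3-octave neighborhoods capture
    the most integrated power of a complex sound's spectrum.

    Ties are broken toward the lower-frequency tone. Mirrors the
    assignment of pure-tone frequencies that maximally overlap a complex
    sound's spectrum.
    """
    tones = np.asarray(tone_freqs_hz, dtype=float)
    if not (1 <= k <= tones.size):
        raise ValueError("k must be in [1, len(tone_freqs_hz)]")
    third_oct = 2.0 ** (1.0 / 3.0)
    local = np.empty(tones.size)
    for i, f0 in enumerate(tones):
        lo, hi = f0 / third_oct ** 0.5, f0 * third_oct ** 0.5
        in_band = (cxs_spectrum.freqs_hz >= lo) & (cxs_spectrum.freqs_hz <= hi)
        local[i] = cxs_spectrum.power[in_band].sum()
    # stable sort on (-power, frequency): ties go to the lower frequency
    order = np.lexsort((tones, -local))
    return np.sort(order[:k])


def waveform_metrics(waveform: np.ndarray, sample_rate_hz: float) -> ComplexityMetrics:
    """All four complexity metrics of a single waveform."""
    spec = compute_power_spectrum(waveform, sample_rate_hz)
    return ComplexityMetrics(
        occupied_bandwidth_hz=occupied_bandwidth(spec),
        spectral_entropy_bits=spectral_entropy(spec),
        modulation_index=spectrotemporal_modulation_index(waveform, sample_rate_hz),
        spectral_centroid_hz=spectral_centroid(spec),
    )
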