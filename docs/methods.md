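# Methods

## The analysis problem

The pipeline quantifies day-to-day drift of single-neuron sound
responses recorded by slow (3 frames/s) two-photon calcium imaging of
the same cortical plane over 5 consecutive days, and asks whether drift
differs between two stimulus protocols: 8 pure tones (PT) and 8
spectrotemporally complex sounds (CxS), each presented 10 times per
session in pseudorandom order with 1.5 ± 0.3 s interstimulus intervals
(0.5 s stimuli). All inference is non-parametric at the single-neuron
level (shuffle tests) and count-based at the group level.

## Acoustic complexity metrics

The power spectrum is a full-signal periodogram (FFT length the next
power of two above the waveform length) with a **Hann window**. The
window choice matters for occupied bandwidth: a rectangular window
leaks roughly 10% of a tone's power into sidelobes, which the 0.5%/
99.5% integrated-power crossings would absorb, inflating a pure tone's
bandwidth into the kHz range; with Hann the sidelobe energy is far
below the 0.5% tail and a 500 ms tone's occupied bandwidth stays at
main-lobe width (~5 Hz).

- **Occupied bandwidth**: f(0.995) − f(0.005), f(q) the first frequency
  at which cumulative power reaches q × total.
- **Spectral entropy**: −Σ pᵢ log₂ pᵢ over positive bins of the
  normalized spectrum. Base 2 (bits); any base preserves the PT/CxS
  ordering.
- **Spectrotemporal modulation index**: spectrogram (Hann, 1024
  samples, 50% overlap; ~10.5 ms frames at 97.6 kHz, ≥90 columns for
  500 ms), trailing silence dropped (trailing columns with broadband
  power < 1% of the peak column — an objective, scale-free rule),
  columns averaged into 20 equal time bins, Pearson correlations over
  all C(20,2) unordered bin pairs (self-pairs excluded), index = 1 −
  mean correlation. Linear (not log) spectrogram power is correlated;
  pairs with a zero-variance vector are dropped with a warning. The
  index lies in [0, 2]; note that for 20 vectors the mean pairwise
  correlation cannot fall below −1/19, so the attainable maximum is
  1 + 1/19 ≈ 1.053.
- **Tone-overlap assignment**: each complex sound's k most-overlapping
  pure tones are those whose ±1/3-octave neighborhoods capture the most
  integrated CxS power; ties break to the lower frequency.

## Preprocessing

ΔF/F uses the session median as F₀ (robust to transients; the median
of ΔF/F is exactly 0). ROI inclusion needs compactness > 0.8 (defined
as circularity 4π·area/perimeter², since the upstream segmentation
statistic has no published formula) and full-session ΔF/F skewness
> 1.1 (adjusted Fisher–Pearson); both strict inequalities. The "clear
transients" clause of manual QC is subjective and not enforced. A frame
belongs to a window if its start time lies in [a, b) relative to onset
(half-open, so adjacent response/prestim windows never share a frame);
at 3 fps the response window [0, 1.5) covers 5 frames, the prestim
window [−1.5, 0) covers 4. A trial is excluded if any response-window
frame overlaps a locomotion epoch, or if a window runs off the session.
z-scoring for cross-day comparisons pools all non-excluded trial
responses of a neuron across both days and all stimuli of the protocol
and uses the population (n) SD, for determinism.

## Shuffle tests

**Responsiveness** (per neuron × stimulus × day, on raw ΔF/F): observed
statistic mean(sound trials) − mean(prestim pool of all protocol
trials); the null pools both sets and relabels without replacement,
preserving group sizes, 1000 times. Responsive iff the observed
difference strictly exceeds the 97.5% shuffle quantile and the margin
criterion holds. The margin rule — the sound response must exceed the
prestimulus magnitude by at least 10% — is ill-posed when the prestim
mean is ≤ 0, which median-based ΔF/F makes common, so it is applied
literally (mean_sound ≥ 1.1 × mean_prestim) for positive baselines and
as mean_sound > 0 otherwise. This gate makes the test conservative: the
measured false-positive rate on null data is well below the nominal
2.5%. Neuron-level sound responsiveness tightens the quantile to
1 − 0.025/n_stimuli (Bonferroni on the permutation quantile, equivalent
to adjusting the p-value).

**Cross-day change** (per neuron × stimulus × day pair, on z-scored
magnitudes): statistic |mean(day₂) − mean(day₁)| against shuffled
absolute differences (direction-agnostic, as "change" is two-sided),
1000 relabelings, 95% quantile, plus a relative magnitude gate
|m₂ − m₁| / max(|m₁|, |m₂|) ≥ 0.10 (the max-denominator form is chosen
because it is symmetric in day order; a 10% threshold needs a referent
and the larger day magnitude is the only symmetric one). A record
enters the changed/unchanged counts only if its stimulus's
responsiveness test passed on ≥ 1 day of the pair. Neuron-level change
applies Bonferroni over stimuli. All day pairs of a given interval are
pooled "with repetitions" (a neuron contributes once per pair);
5 days give 4, 3, 2, 1 pairs at intervals 1–4.

Both tests derive their generators from named sub-seeds
(seed, stage, neuron, stimulus, day …), so results are bit-reproducible
and independent of iteration order.

## Stimulus specificity

Per neuron and day pair, a fixed-effects two-way ANOVA of z-scored
trial response on day (2) × stimulus (S) with interaction, via OLS:
Type I sums of squares on balanced data (exact, order-free
decomposition), Type II when locomotion exclusions unbalance cells.
Effect size is Hays' ω² of the interaction. F, p and ω² are invariant
to the affine z-scoring. Only neurons sound-responsive on ≥ 1 day of
the pair are analyzed. An important caveat the synthetic benchmark
makes explicit: a *multiplicative* session gain applied to
heterogeneous response amplitudes is itself stimulus-dependent in the
additive scale of the ANOVA, so it produces genuine interaction; only
a *uniform* (additive in response magnitude) gain change is
interaction-free. The specificity benchmark therefore compares remap
drift against uniform-offset gain drift matched on mean profile-drift
distance (offset SD 0.2 ΔF/F vs remap probability 0.3, calibrated
once): the interaction test rejects at ~40% under remap and stays at
its ~5% nominal level under matched uniform gain.

## Group statistics

Pearson χ² on 2×2 tables is computed **without** continuity correction,
the convention that reproduces the reference count-table statistics
exactly (verified against an independent implementation before the
expected values were frozen into tests). The two-proportion z test is
pooled-variance; both the one-sided p in the observed direction (for a
z of −1.7811 this is 0.037) and the two-sided p are returned.
Fisher's exact test reports the sample odds ratio (a·d)/(b·c), a
two-sided hypergeometric p, and a conditional exact CI (the CI method
of the original software is unknowable, so the CI is informational).
The rank-sum test enumerates all C(n₁+n₂, n₁) assignments of pooled
midranks when max(n) ≤ 12 (ties handled naturally; two-sided p = twice
the smaller tail, capped at 1) and falls back to the tie-corrected
normal approximation otherwise. The multi-category bootstrap draws, per
category, k* ~ Binomial(n_test, p_ref) 10 000 times; a round is extreme
iff the simulated proportion is ≥ the observed one in **every**
category (the joint reading; a mean-across-categories rule is exposed
behind a flag).

## Cross-day matching

Registration maximizes plain (unnormalized) cross-correlation between
mildly smoothed (σ = 1 px) images — the phase-whitened variant is
noticeably less robust to additive pixel noise, failing at ~10% noise
where the plain form still recovers integer shifts exactly. Cell
patches are 39 × 39 px, centered on ROI centroids (zero-padded at
borders), scored with standard SSIM (Gaussian weighting, default
stabilizing constants). Each day-1 cell's scores are divided by their
row maximum; assignment is per-row argmax (each neuron ranked
independently), with an optional Hungarian one-to-one mode. Agreement
is the percentage of cells whose top match equals the reference
pairing — ground truth for synthetic pairs, whereas the original
validation compared automated to manual matching.

## Synthetic-data generator

The generator emulates the statistical structure of the recordings, not
the raw movies: traces are baseline ≈ 100 a.u. (N(100, 5) per neuron)
plus 1/f (pink) noise; responsive (neuron, stimulus) pairs — fraction
0.35 by default — emit transients with one-frame rise and exponential
decay (τ = 0.7 s, GCaMP6f-like, truncated at 5τ) at stimulus onsets.
Trial amplitude = base amplitude (lognormal, median 0.5 ΔF/F, log-SD
0.3) × day gain × lognormal trial jitter. A single noise knob
(`noise_sd`, default 0.08 ΔF/F) scales both the additive trace noise
and (×3) the multiplicative trial jitter, so zero gives fully
deterministic responses. Between consecutive days each responsive pair
remaps with probability `tuning_drift_prob` (scalar or per-class): its
amplitude is re-drawn, and with probability 0.5 a currently responding
stimulus is lost outright (or a silent one regained) — drift includes
gained/lost responses, not just rescaling. Sessions present 10
block-shuffled repetitions per stimulus at uniform-jittered ISI;
locomotion epochs of 1–3 s arrive with a Poisson count (mean 3 per
session). Baseline fluorescence and transient SNR have no published
reference values; the defaults above are the package's choices and are
plainly exposed in `SynthConfig`.

What the generator does **not** emulate: neuropil contamination, spike
inference, pixel-level imaging noise, slow within-session drift,
correlated population variability, or realistic tuning-curve shapes.
Passing tests therefore demonstrate that the *analysis* behaves
correctly under known ground truth (calibrated false-positive rates,
correct ordering recovery), not that the generator reproduces cortical
data.

One deliberate realism consequence: with ~2 s between onsets and a
3.5 s truncated transient, a strongly responsive neuron's tail leaks
into the next trial's windows, exactly as in real recordings at these
stimulus rates; the block-shuffled ordering randomizes the predecessor
per trial, and the null-calibration tests confirm this leaves the
tests' false-positive rates at or below nominal.

## Problem sizes and numerical choices

Benchmark runs use 40–125 neurons, 2–5 days, 16 stimuli × 10 trials,
1000 shuffles per test and 20 seeds for ordering checks — sizes chosen
so every property of interest is measured with comfortable statistical
margins while a full suite run stays in the minutes range. Degenerate
inputs are handled explicitly: zero-variance trial pools are never
significant; neurons with non-positive median fluorescence, empty
ANOVA cells, or zero pooled SD are skipped and logged; a zero spectrum
has no entropy/centroid (error) and a flat image registers at zero
shift with a warning. Ties in the tone-overlap assignment break to the
lower frequency; quantile comparisons against shuffle distributions
use strict inequality.

## Known limitations

- The margin rule's behavior at non-positive baselines is an
  interpretation (documented above); alternatives would shift the
  responsive population slightly.
- Profile Euclidean distances use z-scored magnitudes; raw-scale
  distances would not pool across neurons of different response scales.
- Rank sums are reported for both groups (36 and 100 under complete
  separation of two groups of 8), since either group's sum identifies
  the other's.
- The Fisher-exact CI method is conditional exact and not comparable to
  CIs produced by other conventions.
- The ANOVA cannot distinguish multiplicative gain from stimulus-
  specific change (see above); conclusions about "specificity" inherit
  this caveat.
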