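# caldrift

Day-to-day stability of sound-evoked calcium responses in auditory
cortex: are spectrotemporally complex sounds (CxS — vocalization-like,
broadband, temporally modulated) represented more stably across days
than simple pure tones (PT)?

`caldrift` is an analysis pipeline for longitudinal two-photon calcium
imaging of the same neurons over consecutive days while a fixed set of
8 pure tones (log-spaced 2–32 kHz) and 8 complex sounds is presented.
It is written for systems-neuroscience users who have per-session
fluorescence trace matrices (e.g., Suite2p output) plus stimulus event
tables, and who want the full drift-quantification battery:

- **Acoustic complexity scoring** of stimulus WAVs: occupied bandwidth
  (0.5%/99.5% crossings of integrated spectral power), spectral entropy
  of the normalized power spectrum, a spectrotemporal modulation index
  (one minus the mean pairwise Pearson correlation of 20 time-binned
  spectrogram power columns), and spectral centroid.
- **Preprocessing**: ΔF/F = (F(t) − F₀)/F₀ with F₀ the session median,
  ROI quality gates (compactness > 0.8, trace skewness > 1.1), per-trial
  response magnitude (mean ΔF/F over 0–1.5 s from onset) and prestimulus
  magnitude (−1.5–0 s), locomotion-overlap trial exclusion.
- **Responsiveness**: a shuffle (bootstrap) test per neuron × stimulus ×
  day — the observed mean(sound) − mean(prestim pool) difference must
  exceed 97.5% of 1000 label-shuffled differences and clear a 10%
  margin; neuron-level sound responsiveness applies Bonferroni
  correction over stimuli.
- **Cross-day change**: per (neuron, stimulus, day pair), |Δ mean
  z-scored response| against a 95% shuffle quantile plus a 10% relative
  magnitude gate; aggregation into percent changed, neuron-changed
  fractions (Bonferroni), response-profile Euclidean distance
  √Σᵢ(xᵢ−yᵢ)², and pooling of all day pairs per interval (1–4 days).
- **Stimulus specificity**: per-neuron two-way day × stimulus ANOVA with
  interaction; interaction effect size ω² = (SS_int − df_int·MS_err) /
  (SS_total + MS_err).
- **Group statistics**: Pearson χ² (no continuity correction) and
  Fisher's exact test on changed/unchanged 2×2 tables, pooled
  two-proportion z, exact small-sample Wilcoxon rank-sum, Fisher r-to-z,
  and a multi-category bootstrap proportion test.
- **Cross-day neuron matching**: rigid registration by cross-correlation
  plus structural-similarity (SSIM) scoring of 39×39 cell-body patches.
- **Synthetic-data generator** with known ground truth (responsiveness,
  gain drift, stimulus-specific remapping, locomotion), which defines
  the test bed for everything above.

## Worked example

The numbered scripts under `analysis/` form the narrative run. With the
default seed, `analysis/01_stimulus_complexity.py` synthesizes the
16-stimulus set and prints:

```
occupied_bandwidth_hz: PT rank sum 36, CxS rank sum 100, exact p = 0.000155, separated = True
spectral_entropy_bits: PT rank sum 36, CxS rank sum 100, exact p = 0.000155, separated = True
modulation_index:      PT rank sum 36, CxS rank sum 100, exact p = 0.000155, separated = True
```

i.e., every complex sound is broader-band, higher-entropy, and more
temporally modulated than every pure tone; under complete separation of
two groups of 8, the low group's rank sum is 36, the high group's 100,
and the exact two-sided enumeration p is 2/12870 ≈ 1.55 × 10⁻⁴.

`analysis/02_simulate_experiment.py` then writes 5 daily sessions of a
40-neuron plane in which pure tones remap with probability 0.2 per day
versus 0.1 for complex sounds, and `analysis/03_drift_analysis.py` runs
the full pipeline over every day pair:

```
consecutive-day (interval 1) summary:
  CxS: 14.85% changed (60 of 404); neuron fraction 0.18; mean profile distance 0.88; ANOVA interaction rate 0.23
  PT:  22.44% changed (92 of 410); neuron fraction 0.39; mean profile distance 1.07; ANOVA interaction rate 0.39
  chi2 CxS vs PT (percent changed): 7.71, p = 0.0055

change rate by interval (percent changed):
  CxS: 1d: 14.9%, 2d: 21.5%, 3d: 26.6%, 4d: 28.4%
  PT:  1d: 22.4%, 2d: 32.9%, 3d: 41.8%, 4d: 41.6%
```

The pipeline recovers the injected asymmetry on every measure — more
per-response changes, more changed neurons, larger profile drift, and
more stimulus-specific change for the high-remap protocol — and change
accumulates with interval. `analysis/04_matching_validation.py` scores
cross-day neuron matching (100% agreement on noise-free pairs, >95% at
realistic morph noise). Summary tables land in `results/`; bulky
per-record tables go to `scratch/`.

A `caldrift` command-line tool wraps the same stages
(`simulate`, `soundstats`, `analyze`, `match`); see `caldrift --help`.

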