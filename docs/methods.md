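# Methods

## Synthetic islet model

The generator emulates what a functional multicellular Ca²⁺ imaging
experiment records from an islet in a pancreas tissue slice: one
fluorescence trace per cell, sampled at `fs_hz` (default 10 Hz), under a
square-pulse stimulation protocol.

**Geometry and activation.** Cells are placed uniformly in a square field
(default 200 µm). When a stimulation episode begins, activity spreads from a
pacemaker corner as a wave: cell *i* activates at
`episode start + d_i / v + J_i`, where `d_i` is its distance to the
pacemaker, `v` the wave speed (default 100 µm/s — the literature gives no
firm value; this default is arbitrary and configurable), and `J_i` a
log-normal activation delay. Delay defaults (median 168 s, log-sd 0.45 for
activation; median 348 s, log-sd 0.5 for deactivation) reproduce the
right-skewed, positive delay distributions typical of glucose-stimulated
beta cells (quartiles ≈ 127/168/243 s for activation, 197/348/490 s for
deactivation). Log-normality was chosen because delays are positive with a
heavier right tail.

**Bursting.** Each active protocol segment specifies an oscillation
frequency and mean duration; defaults encode the glucose condition
(0.033 Hz, 10.7 s → duty cycle ≈ 0.35) and the forskolin condition
(0.058 Hz, 8.5 s). Every segment has one master burst clock per community
(regular beats at the segment period). A cell follows the master clock on a
given beat with probability σ (`sync`, default 0.9) and otherwise falls back
to a private clock with per-cell log-normal period and random phase
(`freq_cv`, `dur_cv`, default 0.1). The follow/fall-back choice compares a
pre-drawn uniform against σ, so at a fixed seed raising σ only converts
private beats into synchronized ones — this coupling is what makes the
mean-correlation-vs-σ relation monotone by construction, and it is the
single knob that moves an islet between fully synchronized (σ = 1) and
fragmented (σ = 0) regimes. Per-segment σ overrides model condition-
dependent coupling (e.g. desynchronization under prolonged glucose).
With `n_communities > 1` the field is split spatially and each community
gets a phase-shifted master clock, planting a known community structure.

**Pulse shape.** An oscillation rises linearly over the first 20% of its
duration, decays exponentially with half-life 0.8 × duration — so it sits at
exactly 50% of peak at `onset + duration` — and then returns linearly to
baseline over a further 0.6 × duration. Two consequences are deliberate:
the half-amplitude end rule recovers the configured duration exactly, and
the inter-oscillation baseline is truly zero (onsets are kept ≥ 1.6 ×
duration apart), so baseline-dependent steps of the pipeline have a defined
truth. After the stimulus ends a cell keeps oscillating until its
deactivation delay expires; its ground-truth deactivation time is the end of
its last oscillation.

**Fluorescence.** `F = F₀ · (exp(−t/τ_b) + β t) · (1 + g · c(t)) + ε`, with
baseline `F₀` = 100 a.u., gain `g` = 1, bleaching time constant τ_b =
10 000 s plus linear slope β = −10⁻⁵ /s (mild, as acquisition protocols
minimize bleaching), and i.i.d. Gaussian noise ε with sd 5% of F₀. The
bleaching term mirrors the correction model in the preprocessing stage by
design, so the correction is testable against truth.

**What the generator does not emulate.** The first-phase Ca²⁺ transient at
stimulus onset, slow (metronome-like) superimposed oscillations, amplitude
adaptation, spatially correlated noise, motion artifacts, and cell types
other than beta cells. Passing the recovery tests therefore shows the
estimators are correct for trains of well-separated pulses under additive
noise and multiplicative drift — not that they are robust to every pathology
of real recordings.

## Preprocessing

Order: F/F₀ normalization → bleach correction → exclusion → band-pass.
F₀ is the mean over the first 60 s of the initial substimulatory segment
(the window must lie in an inactive segment). Bleach correction fits
`b(t) = A·exp(−t/τ) + B·t + C` to a running 10th-percentile baseline
computed on 30 s blocks and divides by `b(t)/b(0)`; the percentile baseline
(rather than a heavy low-pass of the trace) is used because a low-pass mixes
the duty-cycle-weighted oscillation mean into the baseline, while the lower
percentile tracks the inter-oscillation floor. Non-convergent fits fall
back to a linear fit and are flagged. Note that F₀ itself is measured over
a window during which bleaching is already under way, so the corrected
baseline sits at `b(0)/mean(b over the F₀ window)` — flat, but a percent or
two above 1 when bleaching is strong.

Exclusion implements the usual manual curation as automated rules with an
activity proxy (fraction of samples more than max(5 robust noise sd,
0.05 F/F₀) above the substimulatory median): active in low glucose
(fraction > 0.10), inactive in high glucose (fraction < 0.05), and
single-frame spikes (deviation from the neighbour mean > 6 robust sd,
floored at 0.01 F/F₀ so noise-free rise corners cannot trip it).

The band-pass is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero phase shift by construction, effective order doubled,
≥ 40 dB attenuation one octave beyond the corners. The generic default band
is (0.03, 1.5) Hz — the midpoints of the empirically used ranges — while the
study pipeline defaults to a 0.02 Hz lower corner: the slowest physiological
oscillation (~0.033 Hz) sits so close to 0.03 Hz that a midpoint cutoff
visibly distorts pulse shape, and the cutoff is meant to be chosen per
recording below the oscillation band.

## Oscillation detection and classical parameters

Onsets are significant positive excursions of the smoothed derivative
(threshold: max of 3 MAD-scaled sd of the derivative and 5% of its maximum —
both scale-free, so detection is invariant to amplitude rescaling), refined
to the preceding trace minimum and then forward to the first sample whose
rise reaches 30% of the event's peak slope; this lands the onset on the
rise corner rather than on filter-smeared foothills. The peak is the raw
maximum before the next onset. The end is the first decay to
`base + 0.5 · (peak − base)`, linearly interpolated between samples; the
local baseline `base` is the minimum of the lightly smoothed trace over the
inter-oscillation stretch before the onset (bounded by 10 s). Measuring the
half level relative to the local baseline — the "50% of the oscillation
amplitude" reading — is offset-invariant, which matters because the
band-passed signal is zero-mean; for a pulse rising from zero it coincides
with 50% of the maximum. If the signal has not reached the half level
before the next derivative crossing, the event is extended across it (an
oscillation only ends at 50% decay); events still above the level at the
recording end are right-censored and flagged.

Binarization writes `round(duration · fs)` ones per event, so the active
sample count equals the rounded total event length exactly. Classical
parameters over an analysis window: frequency = onsets/window length (note
the ±1-count quantization — a 300 s window resolves 0.033 Hz only to ~10%,
so recovery comparisons use windows ≥ 1000 s), mean duration, and active
time = fraction of window samples inside [onset, end). The "above half
amplitude" variant of active time is available as an option
(`mode="above_half"`).

Delays run on the de-bleached F/F₀ signal, not the band-passed one: the
filter exists to extract plateau-phase parameters and would distort the slow
activation transient. For this pass the minimum-prominence threshold is
raised to 4 robust sd because most of that signal is quiet baseline, whose
MAD underestimates the oscillation scale. Activation = onset of the first
oscillation at/after stimulus onset; deactivation = end of the last
oscillation after stimulus offset (cells with no post-offset activity have
zero delay; censored cells are excluded and counted). First-responder and
islet-median-relative forms follow the definitions in the README; the first
responder itself (delay 0) is included in pooled statistics, and perfectly
synchronous islets (median first-responder delay 0) are excluded from
relative statistics with a warning.

## Networks

Pearson correlation (Spearman optional) of the filtered traces over each
analysis interval; zero-variance cells get NaN correlations and never form
edges. The degree-targeted threshold search scans the off-diagonal
correlation values themselves as candidate thresholds (edge rule `R ≥ R_th`,
so these are exactly the points where the edge count changes), picks the one
whose realized ⟨k⟩ is closest to the setpoint, and breaks ties toward the
higher threshold (the sparser network); exact ⟨k⟩ = 8 is generally
unattainable on a discrete graph, so the realized value is reported and the
acceptance tolerance is the discreteness bound 2/n. Negative correlations
never create edges under the default positive thresholds (the network is a
similarity graph). Community detection uses deterministic greedy modularity
maximization (Louvain with a fixed seed as an option); an edgeless graph is
assigned the singleton partition with Q = 0 by convention. Metrics: ⟨k⟩ =
2|E|/n, mean off-diagonal correlation, modularity of the optimized
partition, and relative largest component.

## Study orchestration and statistics

The first plateau interval starts `settle_s` (default 300 s) after stimulus
onset and lasts `interval_len_s` (default 300 s); the second interval starts
`second_offset_s` (default 180 s) into the second active segment when the
protocol has one (forskolin-style), else it is the last `interval_len_s` of
the plateau. These placements are assumptions, configurable in
`StudyConfig`. Classical parameters and delays are pooled per cell; network
metrics per islet. Two groups: Mann-Whitney U; more: Kruskal-Wallis
followed by Dunn's rank-sum z comparisons with tie correction, reported raw
and Holm-adjusted (the adjustment variant is not standardized, so both are
emitted). Quartiles use linear interpolation (numpy default, type-7) —
pinned for reproducibility.

## Numerical choices and degenerate inputs

Detection smoothing is 0.3 s (time units, so defaults transfer between 1–2
and 10 Hz acquisitions); flat traces yield no events; protocols whose active
segments are shorter than one oscillation period are rejected; all-excluded
islets and single-responder islets raise instead of emitting empty tables.
All randomness flows from explicit integer seeds; cohort islet *i* uses
`seed + i`, and islet-level parameter variation draws from a separate
stream, so a cohort of one with zero islet variability is bit-identical to a
direct `generate_islet` call.

## Known limitations

* A zero-phase filter smears the rise corner symmetrically, so durations
  measured on the filtered signal carry a small systematic error (≲ 0.5%
  at the default band after onset refinement; worse if the lower corner
  approaches the oscillation frequency).
* The frequency estimator counts onsets in a window; its quantization error
  is 1/(window length), not reduced by sampling rate.
* When the second interval changes the oscillation regime (forskolin:
  faster, shorter pulses), the reused first-interval threshold responds to
  both the synchrony and the pulse-statistics change; absolute
  second-interval degrees in simulations are therefore lower than in
  experiments where coupling is sustained, even though the glucose-vs-
  forskolin contrast has the right direction.
* Deactivation delays are bounded above by the recording length; cells
  still active at the end are censored, not imputed.
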