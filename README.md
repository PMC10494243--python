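# isletnet

Functional network analysis of multicellular Ca²⁺ imaging in pancreatic
islets, with a ground-truthed synthetic islet generator.

## The problem

Beta cells in an islet couple glucose stimulation to insulin secretion
through cytosolic Ca²⁺ oscillations, and they do so collectively: gap
junctions synchronize bursting across the islet, so the physiologically
interesting quantities are not only per-cell (oscillation frequency,
duration, relative active time, activation/deactivation delays) but also
network-level (how strongly and in what topology cells co-oscillate, and how
stimuli such as the adenylyl-cyclase activator forskolin change that
topology). `isletnet` implements the full analysis chain used in this kind
of study — trace preprocessing, oscillation binarization, delay statistics,
and correlation-based functional networks — for anyone working with
multicellular islet recordings or simulations of them.

Because raw recordings require manual ROI curation, the package ships a
first-class synthetic islet generator: heterogeneous bursting cells with
wave-like activation, condition-dependent oscillation statistics, a tunable
synchrony parameter, photobleaching and noise — with exact ground truth for
every quantity the pipeline estimates.

## The method

For each cell, fluorescence is expressed as F/F₀, corrected for
photobleaching by a fitted `A·exp(−t/τ) + B·t + C` baseline, quality-filtered
(low-glucose-active, high-glucose-inactive, and movement-artifact traces are
removed), and band-pass filtered with a zero-phase (forward–backward)
Butterworth filter, cutoffs in the 0.02–0.04 Hz and 1–2 Hz ranges.

Oscillations are detected from the derivative of the filtered trace (onset),
the maximum (peak), and the first decay to 50% of the oscillation amplitude
(end, sub-sample interpolated); binarizing [onset, end) gives the classical
parameters: frequency (onsets per second), mean duration, and relative
active time. Delays are measured from stimulus onset/offset (delay_A,
delay_D), relative to the islet's first responder (delay_A1 = delay_A −
min delay_A), and normalized by the islet median (rel delay = delay_A1 /
median delay_A1).

Functional networks connect cell pairs whose filtered traces have Pearson
correlation R_ij ≥ R_th. R_th is chosen **per islet** so the realized
average node degree ⟨k⟩ = 2|E|/n matches the setpoint ⟨k⟩ = 8 in the first
plateau interval, and that same threshold is reused in the second interval
of the same islet, making the between-interval change directly comparable.
Each network is summarized by ⟨k⟩, the average correlation coefficient, the
modularity Q = Σ_c (e_c/m − (d_c/2m)²) of an optimized partition
(segregation), and the relative largest component (integration). Cohorts are
compared with the Mann-Whitney U test (2 groups) or Kruskal-Wallis followed
by Dunn's post-hoc comparisons, with Q1/median/Q3 summaries.

## Worked example

Two simulated cohorts: prolonged glucose (whose islets desynchronize in the
late plateau) versus glucose + forskolin (which sustains coupling and raises
oscillation frequency while shortening oscillations):

```python
from isletnet import (IsletConfig, StudyConfig, generate_cohort,
                      glucose_control_protocol, glucose_forskolin_protocol,
                      run_study)

protocol_g = glucose_control_protocol(split_s=900.0, sync_late=0.8)
protocol_f = glucose_forskolin_protocol()
cfg = IsletConfig(n_cells=40)
glucose   = [ts for ts, _ in generate_cohort(4, cfg, protocol_g, seed=1)]
forskolin = [ts for ts, _ in generate_cohort(4, cfg, protocol_f, seed=50)]
bundle = run_study(StudyConfig(), {"glucose": glucose,
                                   "glucose+forskolin": forskolin})
print(bundle.quartiles)      # Q1/median/Q3 per measure and group
print(bundle.comparisons)    # test statistics and p-values
```

Selected rows of the output (cells pooled per group for classical
parameters and delays; islets for network metrics):

```
                           measure             group   n         q1     median         q3
                 frequency[second]           glucose 160   0.026667   0.030000   0.033333
                 frequency[second] glucose+forskolin 159   0.050000   0.053333   0.053333
               active_time[second]           glucose 160   0.297000   0.327833   0.348667
               active_time[second] glucose+forskolin 159   0.407000   0.444667   0.481167
                avg_degree[second]           glucose   4   0.325000   0.925000   2.425000
                avg_degree[second] glucose+forskolin   4   2.195513   2.700000   3.425000
relative_largest_component[second]           glucose   4   0.131250   0.275000   0.437500
relative_largest_component[second] glucose+forskolin   4   0.396154   0.437500   0.518750
                         delay_a_s           glucose 160 130.750000 179.250000 246.500000
                         delay_a_s glucose+forskolin 156 111.625000 153.450000 200.700000

            measure           test  group1            group2      p_value
  frequency[second] mann-whitney-u glucose glucose+forskolin 3.294555e-54
active_time[second] mann-whitney-u glucose glucose+forskolin 1.551779e-48
```

Reading it: forskolin raises oscillation frequency (0.053 vs 0.030 Hz) and
active time (0.44 vs 0.33) in the second plateau interval, and under the
reused first-interval threshold the desynchronizing glucose-only islets end
up sparser (median ⟨k⟩ 0.9 vs 2.7) and less integrated (relative largest
component 0.28 vs 0.44) than the forskolin-treated ones. Activation delays
pool to a median of ~179 s under glucose, matching the configured log-normal
delay distribution.

The same workflow is available from the shell:

```bash
isletnet simulate --config islet.yaml --seed 1 --out islet.h5
isletnet analyze  --config study.yaml --in data/ --out results/
isletnet network  --in islet.h5 --k 8 --out net.graphml
isletnet report   --results results/
```

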