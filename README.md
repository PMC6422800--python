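# eegmst

Band-limited **phase-lag-index (PLI) connectivity** and **minimum-spanning-
tree (MST) topology** analysis of multichannel resting-state EEG, together
with a synthetic cohort simulator that makes the whole pipeline testable
end-to-end without access to recorded data.

The package targets the common case-control design in clinical EEG network
research: two groups (here labelled IA — internet-addiction cases scored
50–79 on Young's 20-item Internet Addiction Test — and HC, healthy controls
scored 20–49), one eyes-closed resting recording per subject on a
10–20-derived 64-channel montage, and the question of whether the
functional network backbone of one group is organised differently (more
star-like / hub-dominated versus more line-like / decentralised).

## Method

For each subject and frequency band (delta 0.5–4, theta 4–8, alpha1 8–10,
alpha2 10–13, beta 13–25, gamma 25–49 Hz):

1. **Preprocess** — zero-phase Butterworth band filtering of the continuous
   signal, segmentation into non-overlapping 2000 ms epochs, automatic
   rejection of any epoch exceeding ±150 μV on any channel (subjects
   retaining fewer than 80 epochs are flagged), Welch band power as a
   covariate.
2. **Connectivity** — instantaneous phases φ from the analytic signal
   (Hilbert transform) per epoch; for every channel pair the phase lag
   index

   PLI = | ⟨ sign[ sin(Δφ(t_k)) ] ⟩ |,  Δφ = φ_i − φ_j,

   which is 0 for symmetric (including zero-lag, volume-conducted) phase
   differences and 1 for a consistent non-zero lag.
3. **MST** — Kruskal's algorithm on edges sorted by *descending* PLI builds
   the maximum-weight spanning tree (the strongest-connection backbone,
   N−1 edges, no loops). Per tree: maximum normalized degree (MaxDeg),
   maximum normalized betweenness (MaxBC), mean eccentricity (Ecc),
   diameter (Diam), leaf fraction (Leaf), tree hierarchy
   Th = L / (2·m·BC_max) (0 for a path, 0.5 for a star), degree divergence
   Kappa = Σk²/Σk, and degree correlation R. Metrics are averaged across
   epochs; hubs are the channels maximising group-mean nodal degree or
   betweenness.
4. **Statistics** — per measure and band a one-way ANCOVA
   (measure ~ group + age + sex + band power) with partial η², Bonferroni
   correction over the 9-measure family (threshold 0.05/9 ≈ 0.006);
   per-channel two-sample t tests of nodal degree/betweenness; Pearson
   correlation of every measure with the severity (IAT) score; demographic
   balance checks (t tests, 2×2 chi-square).

The simulator (`eegmst.synth`) generates narrowband oscillators whose
pairwise phase coupling, group-dependent tree topology (star- versus
line-biased), severity coupling, amplitude artifacts, and metadata
(group-separated IAT scores 59.0 ± 7.88 vs 34.4 ± 8.53, ages, sex) are all
controlled, so estimator extremes, null calibration, and direction
recovery can be verified exactly.

## Worked example

```python
from eegmst import (CohortSpec, GroupEffects, analyze_cohort,
                    group_statistics, hub_report)

spec = CohortSpec(
    n_per_group=12,
    channel_labels=[f"ch{i:02d}" for i in range(8)],
    fs=128.0, duration_s=60.0, signal_bands=("alpha2",),
    base_bias=0.2,
    group_effects={"alpha2": GroupEffects(topology="star_bias",
                                          bias_weight=0.5)},
    seed=42)
cohort = analyze_cohort(spec, bands=["alpha2"], min_epochs=1)
stats = group_statistics(cohort.metric_table)
print(stats[["measure", "mean_IA", "mean_HC", "F", "p", "direction"]]
      .round(3).to_string(index=False))
```

prints

```
   measure  mean_IA  mean_HC     F     p direction
       pli    0.619    0.531 5.994 0.024     IA>HC
max_degree    0.612    0.508 4.970 0.038     IA>HC
       ecc    0.494    0.566 9.731 0.006     IA<HC
    max_bc    0.810    0.734 7.030 0.016     IA>HC
     kappa    2.544    2.262 4.848 0.040     IA>HC
         r   -0.559   -0.477 2.311 0.145      n.s.
  diameter    0.596    0.694 8.899 0.008     IA<HC
      leaf    0.591    0.505 7.001 0.016     IA>HC
        th    0.416    0.392 5.958 0.025     IA>HC
```

The IA group was simulated with star-biased coupling, and the analysis
recovers exactly the expected pattern: higher hub dominance (MaxDeg, MaxBC,
Kappa, Leaf up) and shorter paths (Diameter, Eccentricity down). `F` is the
ANCOVA group statistic adjusted for age, sex and alpha2 band power; `p` is
uncorrected (the `p_adjusted` column of the full table applies the 0.05/9
Bonferroni family).

A YAML-configured command-line interface wraps the same pipeline:

```bash
eegmst run -c config.yaml -o results/     # simulate -> analyze -> report
eegmst simulate|preprocess|connect|tree|stats ...   # individual stages
```

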