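# Methods

This note records the models, estimators, parameter choices and numerical
conventions the package implements, and what its synthetic validation does
and does not establish.

## Phase lag index

The PLI between channels i and j is the absolute time average of the
signum of the sine of their instantaneous phase difference,
`PLI = |⟨sign(sin(Δφ(t_k)))⟩|`. It measures the asymmetry of the
phase-difference distribution around 0 mod π: consistent non-zero lags
give values near 1, while zero-lag (volume-conducted) or symmetric
coupling gives 0. Exact zeros of `sin(Δφ)` contribute 0 through the
signum — there is no epsilon thresholding, so two identical signals give
PLI exactly 0 and a constant lag in (0, π) gives exactly 1.

Phases come from the analytic signal (Hilbert transform) of data that was
band-filtered **continuously** (before segmentation), so filter edge
transients never touch epoch interiors. Because the Hilbert transform
itself is unreliable near window ends, the first and last 5% of samples
of each epoch are excluded from the signum average (`edge_trim`,
configurable, default on).

**Estimator bias floor.** PLI is computed per 2-s epoch and then averaged
across epochs (a pooled mode that concatenates the signum series of all
epochs is available behind a flag). The per-epoch estimator is a folded
mean: for independent signals its expectation is not 0 but
≈ sqrt(2/(π·N_eff)), where N_eff is the number of phase decorrelation
times per epoch. Narrow bands decorrelate slowly, so the null floor is
band-dependent (≈0.29 in alpha2, ≈0.10 in gamma for noise-only channels at
2-s epochs) and epoch averaging does not remove it. The pooled estimator
is unbiased to O(1/sqrt(total samples)) and is the right choice when an
absolute near-zero null is needed; the per-epoch default matches the
convention of averaging network quantities across epochs. Group
comparisons are unaffected because both groups share the floor.

## Spanning-tree backbone and its measures

The network backbone is the spanning tree of **maximum** total PLI weight
(what the clinical literature calls the MST of a similarity matrix, equal
to the ordinary minimum spanning tree of 1 − PLI). It is built by
Kruskal's algorithm on edges sorted in descending weight, discarding any
edge that would close a loop. Ties in weight are broken by the lower
channel-index pair under a stable sort, making the tree deterministic
across platforms.

For a tree on n nodes with m = n − 1 edges, hop distances (every edge
counts 1):

| measure    | definition                                         | range |
|------------|----------------------------------------------------|-------|
| degree     | edges at the node / (n−1); MaxDeg = max over nodes | [0,1] |
| bc         | fraction of the (n−1)(n−2)/2 pairs of other nodes whose unique path crosses the node; MaxBC = max | [0,1] |
| ecc        | longest hop distance from the node / (n−1); global Ecc = across-node mean | [0,1] |
| diameter   | largest pairwise hop distance / (n−1)              | [0,1] |
| leaf       | number of degree-1 nodes / n                       | (0,1] |
| th         | leaf_count / (2·m·MaxBC)                           | [0,1] |
| kappa      | Σk² / Σk over raw degrees (degree divergence)      | ≥1    |
| r          | Pearson correlation of endpoint raw degrees over the symmetrised edge list | [−1,1] |

Normalizations by n−1 (degree, ecc, diameter), (n−1)(n−2)/2 (bc) and n
(leaf) put all shape measures on [0, 1] independent of montage size;
kappa is deliberately unnormalised. Tree hierarchy is ~0 for a path
(2/(2·m·MaxBC) with MaxBC ≈ 1/2), exactly 0.5 for a star (L = n−1,
MaxBC = 1), and larger between the extremes — it scores the trade-off
between integration and hub overload. Betweenness is computed in O(n) per
tree by subtree-size counting (removing a node splits a tree into known
components); eccentricity by BFS from every node.

Degenerate cases are reported as missing, never coerced: r is NaN when
endpoint degrees have zero variance (e.g. a 2-node tree), th is NaN for
n < 3. Epoch averaging excludes NaN r values pairwise and records how many
epochs contributed (`r_defined`). Hub identification takes the argmax of
the group-mean nodal statistic with ties resolved to the lowest montage
index.

## Statistics

ANCOVA is the linear model `measure ~ group + age + sex + band_power`
fitted by OLS; the group term has 1 df, so its type-III F equals the
squared t of the group coefficient, p comes from F(1, n−k−1), and partial
η² = F/(F + df_res). Sex enters 0/1; band power (the analysed band's own
power) is log-transformed by default for variance stabilisation.
Zero-variance covariates (e.g. a single-sex subsample) are dropped with a
warning rather than producing a singular design. Bonferroni correction is
applied per band over the m = 9 global measures (global PLI + 8 tree
measures), threshold 0.05/9 ≈ 0.006. Regional comparisons are pooled-
variance two-sample t tests per channel (Welch behind a flag), reported
uncorrected with an optional Benjamini-Hochberg column. Severity
association is the Pearson correlation with the IAT score, two-sided p
via the t transform with n−2 df. Demographic balance: pooled t (age,
IAT) and 2×2 Pearson chi-square without continuity correction (sex), with
a validity warning when an expected cell is below 5.

## Synthetic cohorts

Each channel carries a narrowband oscillator: instantaneous frequency =
band centre + smoothed Gaussian wander (SD = band width/6, 100 ms
smoothing), phase = its running integral, plus 1/f background noise
(default SD 4 μV against a 20 μV oscillation). Coupling between channels
i → j mixes the source oscillator delayed by a fixed lag into the target
with weight = strength: at strength 1 and zero noise the phase difference
is exactly the lag; at strength 0 the channels are independent. Lags are
drawn uniformly from ±[0.15π, 0.85π] (away from the 0 and π blind spots
of PLI); strengths from N(0.55, 0.10) clipped to [0.05, 0.95].

A subject's coupling graph is a biased random attachment tree: nodes
attach in random order, each to the hub with probability w (star bias) or
to the previous node (line bias), otherwise to a uniformly random earlier
node. w = 0 gives a random recursive tree, w = 1 an exact star/chain.
Group structure enters only through w (plus optional per-pair strength
boosts for named channel pairs): both groups run the identical process,
so cohorts without group effects are exchangeable by construction — the
basis of the type-I calibration. The subject's w adds N(0, 0.08) noise
and, optionally, a severity term slope·(IAT − 60)/40 that ties topology
to the score.

Metadata mirror the target study design: 30 subjects/group by default,
IAT ~ N(59.0, 7.88) resampled into [50, 79] for cases and N(34.4, 8.53)
into [20, 49] for controls, ages ~ N(21.0, 2.13)/N(20.5, 1.59), male
fraction 7/30 and 6/30. Full-scale defaults are the 64-label montage,
500 Hz, 360 s.

**Calibrated validation conditions.** The pipeline-level studies run at
desk scale: 8 channels, 128 Hz, 60 s (30 epochs of 2 s), alpha2 band.

* *Type-I error*: 500 cohorts of 10 + 10 subjects with no group effect;
  the ANCOVA on whole-head PLI must reject at 0.05 within [0.03, 0.07].
* *Direction recovery*: star bias w = 0.2 (HC) vs 0.55 (IA), a setting
  calibrated once to produce ~0.7-SD standardized group differences
  (empirically d ≈ +0.72 MaxDeg, +0.74 Kappa, −0.90 Diam, −0.91 Ecc);
  at 30 subjects/group the four measures must each be recovered with the
  correct direction in more than half of 30 replicate cohorts.
* *Severity signs*: w = 0.45 + 0.5·(IAT − 60)/40 for all subjects; the
  correlations with IAT must come out MaxDeg +, Kappa +, Ecc −, Diam −.

## What the simulator does not capture

No volume conduction or field spread (the motivation for PLI is that it
ignores zero-lag leakage; the simulator can create the zero-lag case but
not realistic mixing topographies), no spatially structured noise
correlation, no ocular/muscle artifacts beyond amplitude spikes, no
non-stationarity across the recording, and no realistic scalp topography
of band power. Passing validation therefore establishes the correctness
and calibration of the estimators and inference on data satisfying the
model's assumptions — not robustness to real-EEG confounds such as
reference choice, leakage, or artifact residue.

## Numerical conventions

* Filters: 4th-order Butterworth per pass, forward–backward
  (`sosfiltfilt`), designed per band; the broadband 0.5–50 Hz stage runs
  before any band-specific analysis and doubles as the drift/line-noise
  guard. A recording whose Nyquist frequency falls inside a requested
  band is an error, not a silent truncation.
* Epoching truncates a trailing partial epoch; rejection is idempotent
  and a shortfall against the 80-epoch minimum warns (QC column) instead
  of failing, so small synthetic runs complete.
* Band power: Welch PSD with a Hann window spanning the whole epoch,
  trapezoid-integrated over [low, high], averaged over kept epochs and
  channels.
* All randomness flows from explicit integer seeds through numpy
  SeedSequence spawning; fixed seeds give bit-identical recordings,
  metric tables and reports.
* Re-referencing to named channels is available but off by default for
  synthetic data (the simulator has no reference electrode concept).
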