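# Methods

This note records the models, conventions and design choices behind
`strinet`, the parameters that matter, and what the synthetic-data tests
do and do not establish about real recordings.

## Behavior

A session is a *zone timeline* over four coarse maze zones: feeders F1/F2
and intersections A (stem base) and B (stem top).  All intervals are
half-open `[start, end)` in seconds, session-relative; a zone's exit time
is the next zone's entry time.  Elementary paths are feeder-to-feeder
segments matched *exactly* against a 12-entry taxonomy (2 correct
alternations, 10 stereotyped errors).  The 10 incorrect sequences are a
reconstruction over {F1, A, B, F2} — stem returns, crossbar shortcuts and
returns, base-rail loops and crossings — and are fully overridable in
configuration, since only the two correct paths are structurally forced.
Unmatched segments are kept as `unclassified` and excluded from every
statistic.

Learning stages are qualitative in origin, so the stage labeller uses
explicit, declared thresholds: stage 1 while correct:incorrect ≤ 1.25;
stage 2 while the centered 3-session slopes show correct rising and
incorrect falling; stage 3 once both |slopes| < 0.05 paths/min per
session; stage 4 once the incorrect share ≤ 0.10; the sequence is made
monotone by a running maximum.  With fewer than 3 sessions only the ratio
rules apply (logged).

Task events: six 500 ms windows — central 500 ms of each A/B passage
(passages shorter than 0.5 s are skipped, logged), first 500 ms after
feeder entry (reward obtention R1/R2), last 500 ms before feeder exit
(movement onset O1/O2) — each tiled by five 100 ms bins.  Overlapping R/O
windows from short feeder dwells are kept and flagged.

The left/right analysis needs a central-stem window per stem run.  With
this zone vocabulary the stem transit is contained in the A-passage, so
the stem run is defined as `[A-entry, B-entry)` for timelines where B
immediately follows A, and the upcoming-turn label is read from the zone
entered after B (F1 = left, F2 = right).

## Tuning detection

Counts over K conditions are tested against the multinomial with
p_k ∝ d_k via the Pearson chi-squared statistic, df = K − 1 (recomputed
after merges/drops).  Validity uses *expected* counts n·p_k ≥ 5.  Policy
by mode: task-event first merges the five 100 ms bins of each event into
6 event-level conditions, then discards; left/right discards immediately;
full-path drops the most offending condition and discards below two
conditions.  Conditions with zero duration never enter the table.
BH correction pools all tested units of one analysis mode into a single
family by default (per-session families are a caller choice: run
`bh_adjust` on whichever pool is wanted); the coding flag is strict
`adjusted p < 0.05`.

## Population z-scores and entropy

Per-bin rates f_t are spikes per 0.1 s per passage; z_t standardizes over
the 30 bins with the sample (n−1) SD; constant-rate units (sd = 0) are
excluded rather than propagating NaNs.  Population bands use the normal
quantile Bonferroni-corrected over 8 curves × 30 bins (multiplier 3.709).

The entropy functional is implemented literally as defined:
Σ_{I nonempty} (Nz_I/Nz_tot)·log(Nz_I/(0.5·Nz_tot)), natural log, 18 bins
of width 0.5 on [−3.5, 5.5], out-of-range z clipped into the terminal
bins so counts always sum to the population size.  This is the plug-in
estimate of ∫p log p — the *negative* differential entropy — and the sign
convention is kept as printed rather than "corrected": for a standard
normal population it evaluates to ≈ −1.42, and moderate widening of the z
distribution *lowers* it (≈ −2.00 at doubled dispersion); only extreme
dispersion raises it again through truncation.  Stage contrasts vs
stage 1 use a percentile bootstrap over units (default 1000 draws),
Bonferroni-corrected over the 8 region×stage contrasts.

## Unit classification and cluster quality

Features (log rate, peak-valley distance, width at half height) are
centered/scaled; a Ward-linkage tree cut at two clusters seeds a k=2
k-means, making the two-step procedure deterministic.  The cluster with
higher standardized log rate and narrower waveform (composite score) is
FSI.  A silhouette below 0.2 flags weak separation; labels are still
emitted.  The L-ratio sums χ²_df tail probabilities of noise
Mahalanobis distances (df = feature dimension), normalized by cluster
size; its percentile comes from 1000 same-size pseudo-clusters drawn from
the non-cluster spikes, each scored against all other spikes (including
the analyzed cluster) so observed and null values see equal-size noise
sets — this makes the percentile uniform under exchangeability.  Singular
covariances get a logged ridge of 1e-8·trace/d.

## Synchrony

A coincidence is an unordered cross-unit spike pair within ±20 ms
(sliding, boundary-inclusive) inside a 500 ms intersection trial;
cross-trial pairs never count.  The null re-pairs trials by a uniform
permutation after aligning spikes to each trial's window start, with the
add-one p-value (1 + #{null ≥ obs})/(n_perm + 1); the identity
permutation is allowed, which keeps the test valid (super-uniform).  The
reference permutation count is 50,000; calibration tests run 2,000 per
pair, which bounds attainable p-values at 1/2001 ≈ 5e-4 without changing
validity.  Group comparisons use one-sided KS tests (uniformity with the
CDF-above-diagonal alternative; two-sample between regions), all jointly
BH-corrected.

## Hawkes estimation

Lag bins are left-closed `[10(i−1), 10i)` ms in t−T with lag 0 excluded,
so a spike never predicts itself (zero-lag cross-unit coincidences, a
measure-zero event in continuous time, are excluded symmetrically).
Predictors are counts of each unit's spikes per lag bin; spike history
always spans the whole session while only evaluation times are restricted
to the condition's intervals — this changes the Gram matrix near interval
edges and is deliberate.  The Gram matrix is integrated exactly by
sweeping the breakpoints (spike times + lag-bin edges intersected with
the intervals); a fine-grid quadrature exists only as a test oracle.
Normal equations are solved directly; exactly singular systems (silent
units) get a logged ridge of 1e-8·trace(G)/dim.  Negative coefficients
(inhibition) are permitted in estimation.

Two distinct "sizes" of a kernel are used and must not be confused: the
*interaction strength* is the plain coefficient sum Σ_i |a_{m,n,i}| (the
quantity that is quantile-thresholded for graphs), while stationarity and
rate predictions use the *branching mass* ∫|h| = 0.01·Σ_i |a_{m,n,i}|
(expected extra spikes per input spike); long-run rates follow
(I − Aᵀ)⁻¹μ with A the branching matrix.

## Decoding

Trials with fewer than 3 repetitions of their path are dropped; the
default split takes the first ⌈2m/3⌉ trials of each condition
chronologically (a seeded random split is available — the choice between
chronological and random is genuinely open, and chronological is the
reproducible default).  The per-trial contrast is summed over units —
the natural multivariate extension, since one condition is decoded per
trial — and ties break to the smallest condition label, logged.
Held-out contrasts use full-session history, consistent with the
estimation side.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions: 20-minute sessions; trials
drawn from the 12-path menu restricted to the current feeder with
stage-dependent correct-path probability (0.5 / 0.7 / 0.85 / 0.95 for
stages 1–4); mean path durations 5–8.5 s and a 4 s feeder dwell, giving
3–5 paths/min; intersection passages ≥ 0.7 s so every passage admits a
centered window.  Spike trains are homogeneous Poisson, event-modulated
Poisson (piecewise-constant rate baseline×gain in the 30 event bins), or
condition-dependent multivariate Hawkes simulated by Ogata thinning with
a locally recomputed bound (per-pair maximal plateau over the spikes
currently in the 60 ms window — a valid bound until the next acceptance
since spikes only leave the window).  Trial histories are independent,
exact for nonnegative kernels because the inter-trial gap (≥ 0.5 s)
exceeds the kernel support; inhibition is supported only via rectified
intensity max(0, λ) and is approximate.  Waveform-feature clusters are
Gaussian with MSN-like (1.2 Hz, 550 µs PV, 320 µs W) and FSI-like
(12 Hz, 250 µs, 150 µs) means, ≥ 4 SD apart.  One global seed expands to
per-stream `SeedSequence` children, so adding units never perturbs
earlier streams.

Not emulated: raw voltage and waveform shapes (features are drawn
directly), position tracking and its artifacts (zone timelines are the
input), electrode drift, bursting/refractoriness beyond what Hawkes
self-kernels produce, and non-stationarity within a session.  Passing
tests therefore establish the *statistical machinery* — calibration,
recovery, decoding contrasts — under the assumed generative models, not
the biological conclusions one would draw from real recordings.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale versions of the analyses: type-I calibration on
2000 (tests) / 1000 (script) homogeneous-Poisson units; FDR control on
20×100 (tests) / 10×100 (script) unit mixtures with 20% gain-3
modulation; synchrony calibration on 500 / 200 independent pairs at 2000
permutations; Hawkes recovery on 3-unit networks (μ = 2 Hz, one kernel of
mass 0.5) over 10 replicates at T = 500 and 2000 s; decoding on 6-unit,
2-condition × 12-trial sessions (4 s trials) over 20 / 10 seeds, with the
connectivity-only contrast built by lowering μ via the branching closed
form so stationary rates match at 5 Hz.

## Known limitations

- The least-squares Hawkes estimator is unpenalized; with many units and
  short conditions the Gram matrix can be ill-conditioned (the ridge
  fallback only handles exact singularity).
- Rectified-intensity simulation of inhibitory kernels is approximate;
  estimated negative kernels are reported as-is.
- The stage labeller is a declared heuristic, not a changepoint model.
- Group-level inferential models on the emitted tables (coding
  proportions, edge occupancy, decoding power regressions) are out of
  scope; the pipeline produces their tidy inputs.
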