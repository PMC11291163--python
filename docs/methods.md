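# Methods

This note documents the models implemented in `cptstates`, the defaults and
why they were chosen, and what the synthetic-data validation does and does
not establish.

## Behavioral scoring

Sessions are ordered trial records (stimulus ∈ {S+, S−}, onset, optional
response time, outcome, correction flag). Scoring excludes correction trials
(the S− re-presentations that follow a false alarm) so that a FA chain does
not multiply-count S− exposures. Rates are HR = hits/(hits+misses) and
FAR = FAs/(FAs+CRs); when a rate is exactly 0 or 1 the log-linear correction
(k+0.5)/(n+1) is applied so the normal quantile stays finite — standard
signal-detection practice. d′ = z(HR) − z(FAR); the response criterion is
c = −(z(HR)+z(FAR))/2, the standard SDT definition (large c = conservative,
non-responding strategy). Stage-advancement rules: ≥60 hits on two
consecutive sessions (stages 1–2), ≥55 hits for a recording-session gate,
d′ ≥ 0.6 on two consecutive sessions (stage 3).

The inter-response latency series is the sequence of gaps between
consecutive active responses (hits and FAs merged in time order).
**Disengagement periods** are the gaps exceeding mean + 2·SD of that
session's series (sample SD, n−1). A period spans the interval between the
two responses that bracket the gap; frames inside it are used later as the
behavioral reference for the disengaged neural state. With fewer than two
active responses the series is empty (warned); a zero-variance series
yields a threshold equal to the mean and no periods.

## Peri-event modulation

Traces are z-scored per neuron over the full session (zero-variance cells
are dropped with a warning). Around each event a visual window of ±8 s is
extracted at the native 10 Hz; events whose window crosses a session edge
are dropped, not padded. Δ activity is the mean over events of
(mean activity in the 0–3 s post window) − (mean activity in the 3–0 s pre
window). Windows are half-open in frames, and times are floored to frames.

The null distribution circularly shifts the event times relative to the
trace: each of the 1000 shuffles draws one uniform offset in [1, T−1]
frames and shifts **all** events by it modulo T — one shared offset per
shuffle preserves the inter-event interval structure, and the same offset
applies to every neuron so the per-shuffle statistics are comparable across
cells. Shifted events whose windows cross the session edge are evaluated
with wrap-around indexing; this keeps the null event count constant across
shuffles and makes the sampled null an exact subsample of the full
enumeration of all T−1 shifts (which the test suite verifies on a 50-frame
toy). The bootstrap probability is the plain fraction of null Δ values ≥
the observed Δ (ties counted as ≥); a neuron is up-modulated when
boot_p < α/2, down-modulated when boot_p > 1−α/2 (two-tailed α = 0.05).
The plain-fraction tie rule is marginally conservative relative to the
(k+1)/(n+1) convention; the calibration suite measures the realized
two-sided error directly (≈0.05–0.06 on 500 AR(1) neurons).

The per-neuron mean trace over the visual window is exposed for averaging
and display; no bespoke slope statistic is defined.

## Engagement-state HMM

Preprocessing: truncate to the first 45 min (27000 frames at 10 Hz),
z-score per neuron, smooth with a 10-frame center-aligned moving average
(1 s; reduces frame noise without lag), PCA on the smoothed matrix. The
first 45 components are retained for a cumulative-variance quality check
while the HMM is fit on the first 10 component scores — both configurable.

The model is a k-state Gaussian HMM with diagonal covariance fit by EM
(≤200 iterations, hmmlearn default tolerance). EM is restarted from 3
seeded initializations and the best train likelihood kept, guarding against
local optima while remaining deterministic given the seed. Model
validation: train log-likelihood across k ∈ {1,2,3}, and contiguous
three-fold cross-validation that cuts the session into four equal quarters
and, on fold f, trains on the first f quarters and tests on quarter f+1 —
the model never trains on future data, so slow non-stationarity inflates
the test gap rather than hiding in it. Log-likelihoods are reported per
frame for comparability across folds.

Decoding uses the Viterbi path by default (a single discrete sequence);
per-frame posterior argmax is available as an option. Event-conditioned
posteriors: hit, mistake (= false alarm, the only active error in this
task) and "any" timestamps are floored to frame indices and binarized;
P(state i | event type) is the fraction of those frames decoded in state i.
The **engaged** label is the state with the larger share of any-response
frames; P(disengaged | disengagement periods) is tabulated over all frames
inside the detected latency-peak periods. Swapping state labels provably
leaves all summaries unchanged (tested). Per-animal engagement probabilities
can be correlated (Pearson) against latency mean, latency CV, criterion c
and raw-count null comparators.

## State-conditioned correlation networks

For each state, all frames decoded in it are collapsed and pairwise Pearson
correlations computed; self-correlations are set to zero. Zero-variance
neurons within a state produce undefined (NaN) pairs, excluded downstream.

Pair significance uses a sign-flip permutation null: each of 10,000
iterations multiplies one member of the pair by a fresh per-frame random ±1
vector and recomputes r. Per-frame flips (rather than a single global sign)
destroy the cross-correlation while keeping marginals, giving an r ≈ 0
null. For within-state z-scored traces the flipped correlation has the
closed form (Σ_t s_t x_it x_jt / T)/√(1−m_i²), m_i = Σ_t s_t x_it / T, so
the null is accumulated as per-pair exceedance counts — per-pair percentile
thresholds at α = 0.05 two-sided without storing 10,000 matrices. For the
upper-triangle pair (i, j), i < j, the lower-indexed member is the flipped
one. Realized two-sided false-positive rate on independent noise is
0.05 ± 0.02 (tested at 561 pairs × 10,000 flips).

Correlation versus inter-neuronal distance is fit per category
(significant-positive, significant-negative, non-significant) with
nonlinear least squares on y = A·exp(k·x); A is the zero-distance
correlation, k (1/µm) the decay constant, more negative = faster decay.
Negative-category values are fitted on |r| with the sign restored in
reporting, since A·exp(kx) with A > 0 cannot represent negative values.
95% CIs and standard errors come from percentile bootstrap over pairs
(1000 resamples by default); pair-level resampling matches the fit's
observation unit but is anti-conservative for non-independent pairs
sharing a neuron — a known caveat. Decay constants of two fits are compared
with z = (k₁−k₂)/√(se₁²+se₂²). Non-convergent fits fall back to the
log-linear estimate with a flag.

K-means clustering uses the correlation-matrix rows (a cell's correlation
profile) as feature vectors; K is chosen by mean silhouette over a 2–6
grid, with seeded restarts. Cluster size and spatial compactness (mean
distance of member cells to the cluster's spatial centroid, µm) summarize
composition. Coupling comparisons partition pairs into intra-/inter-cluster
× positive/negative (sign taken in the disengaged reference state) and
compare states with paired t-tests over matched pairs, plus Spearman ρ of
correlation vs distance per state.

## Synthetic-data generator

The generator emulates the statistical structure of one 45-min session at
10 Hz with ~150 neurons:

* **Latent states.** A two-state Markov chain at frame resolution with
  stay probability 1 − 1/(dwell·rate) per state (geometric dwells; default
  mean 60 s each, stationary start). This matches the HMM generative
  family, so recovery tests are well-posed.
* **Trial schedule.** Stage-2 (S+ only) or stage-3 (S+/S− at 50/50,
  ITI drawn from {2, 3} s) trials with 2 s stimulus duration + 2.5 s
  limited hold; a false alarm triggers a correction trial (S− again) until
  a correct rejection. The per-trial response probability is gated by the
  latent state at stimulus onset (defaults 0.9 engaged / 0.05 disengaged);
  response latency is uniform on [0.5, 4.5] s. Stimulus identity does not
  modulate responding by default, so generated d′ ≈ 0; discrimination
  learning is not the generator's target, engagement dynamics are.
* **Traces.** Background activity is a Gaussian factor process whose
  per-state covariance is (assembly block structure ⊙ exp(k·d)) with unit
  diagonal — within-assembly and between-assembly correlation levels per
  state times an exponential spatial kernel over uniformly placed centroids
  in a 450 µm field of view. The construction is a sum of Schur products of
  PSD matrices, hence exactly realizable by Cholesky sampling; in the
  noiseless limit the empirical correlations match the targets. Defaults
  make coupling weaker in the engaged state (within 0.25 vs 0.35, between
  0.05 vs 0.10; k = −0.005 /µm, i.e. a 200 µm length constant — chosen as a
  plausible cortical scale, the source data give pixels without a scale
  bar). Event-locked modulation adds a raised-cosine rate bump of 2 s
  width centered at each screen touch, positive for the planted up subset
  (20%), negative for the down subset (10%), with peak amplitude
  `event_effect_size` (default 2) × the neuron's baseline SD. A
  state-dependent mean shift (default 1 baseline-SD on 50% of neurons,
  elevated when engaged) carries the engagement signal the HMM detects.
  Everything passes through a causal exponential calcium kernel
  (τ = 0.7 s, GCaMP6f-like at 10 Hz, unit peak) before white noise
  (SD 0.3) is added.
* **Cohorts.** Per-animal seeds derive deterministically from a base seed
  (`numpy.random.SeedSequence`); optional multiplicative jitter on the
  response probabilities creates inter-animal variability.

What the generator does **not** emulate: photobleaching and motion
artifacts, non-Gaussian transient shapes and spike-rate nonlinearity,
discrimination learning across sessions, slow non-stationarity of the
network, cell-extraction crosstalk. Passing recovery tests therefore shows
the analysis chain is correct and calibrated under its own modeling
assumptions, not that those assumptions hold in vivo.

## Problem sizes and numerical choices

* Calibration runs use 500 AR(1) neurons (coefficient 0.8) × 27000 frames
  with 40 random events and the full 1000-shuffle null; recovery runs use
  10 sessions × 150 neurons × 27000 frames — sizes chosen so a complete
  validation pass runs in minutes on one CPU while keeping binomial/Monte
  Carlo error well below the tolerances tested.
* Time→frame conversion floors at the frame rate everywhere; windows are
  half-open in frames.
* The pipeline's end-to-end default uses 2000 sign-flip iterations (the
  method default remains 10,000) and K-grid 2–6.
* Seeds: one global seed per run determines trial simulation, shuffle
  offsets, EM restarts, bootstrap resamples and K-means initialization.
* Degenerate inputs: constant traces are excluded (z-scoring) or rejected
  (preprocessing); zero-variance latency series warn; singleton clusters
  report compactness 0 with a flag; EM non-convergence is reported via a
  flag rather than an exception.

## Known limitations

* The Δ statistic assumes the pre/post statistical windows are
  comparable across events; strongly overlapping events (inter-event
  intervals shorter than the windows) blur the estimate.
* Viterbi decoding yields hard state assignments; near-boundary frames are
  forced into one state. Posterior-argmax decoding is available but the
  posteriors themselves are not propagated into the event tabulation.
* The sign-flip null treats frames as exchangeable within a state;
  within-state autocorrelation slower than the calcium kernel makes the
  pair test anti-conservative.
* Bootstrap CIs for decay fits resample pairs, not cells (see above).
* The generator's engagement signal is a mean shift; gain- or
  correlation-only state signatures would be harder for the PCA+HMM chain
  and are not covered by the recovery bounds.
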