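# Methods

This note documents the models, procedures and numerical choices behind
`herpipeline`: a pipeline for comparing heartbeat-evoked responses (HERs)
and auditory event-related potentials (ERPs) between patient groups under
the local-global auditory paradigm, with non-parametric cluster
statistics, a surrogate-heartbeat specificity control, and cross-validated
linear discriminant classification of the resulting per-subject markers.

## The paradigm and the two signals

The local-global paradigm presents trials of five 50 ms tones at a 150 ms
stimulus-onset asynchrony (the 5th tone starts 600 ms after the 1st),
with an intertrial interval uniform in 1350–1650 ms. In XX blocks the
frequent trial is five identical tones (local standard / global standard,
LSGS) and the rare trial ends in a different 5th tone (LDGD); XY blocks
reverse this (frequent LDGS, rare LSGD). Rare trials are ~20%. Violations
of the within-trial rule are *local* deviants; violations of the
across-trial rule are *global* deviants.

Two epoch families are built per subject:

* **ERP epochs** — 1000 ms from the 5th-tone onset.
* **HER epochs** — 500 ms from the first R-peak *strictly after* the
  5th-tone onset (one candidate per trial), or from every R-peak of the
  recording for the whole-protocol summary.

Windows are half-open in samples, 0-based; no baseline correction is
applied (configurable): HER baselines necessarily overlap the preceding
auditory stimulation, so subtracting them would inject stimulus signal.

Per subject, the **local effect map** is the pooled (epoch-weighted) mean
over {LDGS, LDGD} epochs minus the pooled mean over {LSGS, LSGD}; the
**global effect map** is {LSGD, LDGD} minus {LSGS, LDGS}. Pooled rather
than mean-of-means averaging is the default (switchable).

## Preprocessing chain

1. **Band-pass 1–25 Hz**, zero-phase 4th-order Butterworth applied
   forward–backward (an equivalent Hamming-window FIR mode is provided;
   both satisfy the same passband/stopband checks).
2. **Iterative loud-channel rejection**: per channel, the trapezoidal
   integral of |signal|; channels whose z-score across channels exceeds 3
   are dropped and the z-scores recomputed, up to 10 iterations.
3. **ICA recovery of the cardiac field artifact (ICA-ECG)**: the EEG is
   decomposed with FastICA (seeded, whitened, as many components as
   channels). FastICA was chosen over extended infomax for speed — an
   order of magnitude on 90 s recordings — with `method="infomax"`
   retained as an option. Component selection: excess kurtosis gates
   candidacy (floor 3.0; a QRS train is strongly super-Gaussian), and
   peak normalised autocorrelation in the 0.6–1.5 s RR lag band
   disambiguates when several components are peaked. Kurtosis leads
   because interbeat variability smears any fixed-lag autocorrelation of
   the beat train (measured ≈ 0.08 for genuine cardiac components), so
   periodicity alone cannot rank candidates. If no component passes the
   floor the stage raises, advising fallback to a recorded ECG channel.
   The designated component's time course (unit variance, R-peaks
   oriented positive) is the ICA-ECG; the component is removed from the
   EEG reconstruction.
4. **Neighbour-correlation interpolation**: sensor adjacency is all pairs
   within 4 cm (inclusive). Per channel, the Pearson correlations with
   its neighbours are averaged with inverse-distance weights
   (inverse-square optional); channels below 0.80 are rebuilt by
   spherical-spline interpolation (order 4, regularisation 1e-5) from
   their neighbours only. Channels without neighbours are never
   interpolated; more than half the montage failing aborts.
5. **Common-average reference**, then the configured analysis montage
   subset (the concrete 64-channel subset is configuration-supplied; the
   reference is computed before subsetting).

## Heartbeats

R-peaks are detected on the ICA-ECG by a sliding-window local-maximum
rule (window 600 ms, refractory 300 ms, both configurable): a sample must
be the maximum of its centred window and exceed an adaptive floor — half
the median of the top-K candidate amplitudes, K sized from a 2 s ceiling
on the RR interval so the floor tracks QRS height rather than noise
candidates. Both polarities are scored (regularity x median peak
amplitude) and the better orientation wins, making detection invariant to
trace inversion. Ectopic interbeat intervals are flagged where the IBI
first difference exceeds 3 robust (MAD-based) SDs; flagged intervals stay
in the record but their bounding beats are never HER lock points. With
very short series whose outliers dominate the difference series no robust
scale works; the threshold can then be given explicitly. Interactive beat
editing is replaced by a deterministic corrections list (add/remove
sample indices).

HER candidates are screened in a fixed order, one primary reason code
each: STIM20MS (5th tone within 20 ms of the nearest R-peak, either
direction), IBI500 (lock beat's preceding or following interval < 500
ms), ECTOPIC, AMP300 (any channel exceeding 300 uV), EDGE. ERP candidates
use AMP300 and EDGE. A latency-balance control compares subject-mean
5th-tone-to-lock-beat latencies between groups per condition (unpaired
rank-sum), guarding against group differences in cardiac timing
masquerading as HER effects.

## Cluster-permutation statistics

Group comparison of per-subject effect maps (channels x time) is fully
rank-based:

* Pointwise unpaired Wilcoxon rank-sum Z (midranks, tie-corrected
  variance, no continuity correction), oriented so positive Z means the
  first group's median is larger.
* Preliminary mask at two-sided p < 0.05, split by sign.
* Per time sample, spatially connected components on the 4 cm neighbour
  graph; components with fewer than 4 distinct channels are dropped;
  surviving same-sign components at adjacent samples merge transitively
  when they share a channel.
* Cluster statistic: max |Z| over members. Monte Carlo null: group
  labels permuted (10,000 partitions by default; exhaustive enumeration
  whenever the number of distinct partitions fits the budget), each
  partition contributing the max |Z| over its own suprathreshold mask (0
  if empty). A cluster's p is the plain proportion of partitions at or
  above its statistic; ties count as exceedances. The min-channel and
  wrapping rules are not re-applied inside permutations (a max-statistic
  null needs only each partition's suprathreshold maximum); a flag
  re-enables full per-permutation clustering.

The **combined clustered effect** is, per subject, the unweighted mean of
the subject's effect map over a cluster's member points — the scalar
marker used by the group median tests, the correlations and the
classifier. When a contrast yields clusters of both signs, the pair
effect is the positive-cluster mean minus the negative-cluster mean.

A caveat documented here because it shapes interpretation: combined
effects are computed at locations *selected* by the group contrast, so
the lower group's values are biased slightly negative. In the pipeline's
own simulations this bias can reach Bonferroni significance for the
no-effect group once groups grow beyond ~15 subjects; the group-level
analyses here use 12+12.

## Surrogate-heartbeat control

To test whether an HER effect is genuinely locked to the cardiac cycle,
every subject's heartbeat timings are redrawn uniformly over the
recording (count preserved, collisions redrawn, no minimum separation —
the epoch rules discard implausible pairs), and the full heartbeat-locked
analysis is repeated per surrogate cohort (same surrogate index pooled
across subjects). The control applies to *detected* effects: the
comparison uses the strongest observed cluster significant in the main
analysis, and reports "nothing to test" otherwise. A surrogate exceeds
when its best same-sign cluster matches or beats the observed cluster in
both statistic and size (the conjunction is configurable to
combined-effect magnitude + size); the Monte Carlo p is the exceedance
proportion over 100 surrogates (50 in the bundled studies), with
per-surrogate permutation tests at a reduced partition count (default
1,000; 500 in the studies).

**Limitation found in simulation**: late stimulus-locked components bleed
into heartbeat-locked epochs, and real lock beats — always within one RR
interval of the stimulus — capture systematically more of that bleed than
uniformly re-timed surrogates (which also lose roughly half their epochs
to the 500 ms IBI rule). At high trial counts the control can therefore
flag a purely stimulus-locked effect as heartbeat-locked. The bundled
sensitivity study runs at moderate power, where the main analysis does
not promote stimulus bleed to a significant cluster in the first place.

## Cohort statistics and classification

Within-group tests of whether combined effects have non-zero median use
the Wilcoxon signed-rank normal approximation (zeros dropped, midranks,
tie-corrected variance; the Z carries the sign of the rank statistic).
Between-effect association uses Spearman correlation. Both families are
Bonferroni-controlled at alpha = 0.05/8 (2 groups x 2 signals x 2
levels; family size configurable).

Classification uses a two-class linear discriminant with pooled
within-class covariance and equal priors (diagnosis base rates in a
referral cohort are not population rates), written directly so the
singular case falls back to a ridge of 1e-6 of the covariance trace;
folds are stratified fivefold with seeded shuffling, shared across the
four feature triads and the quadruple so accuracies are comparable.

## The synthetic cohort generator

No public recordings exist for this clinical population, so every study
runs on synthetic cohorts with ground-truth sidecars. A subject is

EEG = spatio-temporal noise + cardiac field artifact + evoked components.

* **Noise**: 93% of the variance is a field common across the cap
  (Gaussian over sensor positions, RBF length scale 10 cm, drawn from
  the kernel's leading eigenbasis) and 7% independent sensor noise; both
  are AR(1) (coefficient 0.9) in time, stationary sd 10 uV. This gives
  filtered-EEG-like neighbour correlations (~0.85-0.9 at 3 cm), which
  the interpolation stage presumes. The independent part is AR-shaped
  too: a white component would lose almost all in-band power to the 1-25
  Hz filter and leave a near-singular covariance that destabilises ICA
  whitening.
* **Cardiac artifact**: a fixed 80 ms biphasic QRS-like template
  (maximum at its centre) convolved with the beat train and mixed by a
  dipolar field (source 6 cm below-behind the cap, 1/d^3 falloff with a
  polarity reversal), peak 75 uV at the worst channel — the scale seen
  at inferior sensors of high-density nets, and the steep signed pattern
  that keeps the artifact separable from the smooth background field.
  Interbeat intervals are truncated-normal (mean 800 ms, sd 50 ms,
  truncation at +-3 sd and a 300 ms floor).
* **Evoked components**: rectangular pulses over an 8-channel contiguous
  patch x latency window, so the expected subject-level contrast equals
  the configured amplitude inside the window and zero outside. Deviant
  increments: ERP local 236-328 ms and global 800-850 ms post 5th tone;
  HER local 400-412 ms and global 112-130 ms post lock beat, attached to
  the first R-peak after the 5th tone with amplitude set by the trial's
  condition. MCS-like subjects carry all effects at full amplitude plus
  doubled per-beat random HER variability (zero-mean amplitude per beat,
  100-400 ms window); UWS-like subjects carry local effects at half
  amplitude, no global effects, baseline variability; controls are
  MCS-like with half the blocks. Default amplitude 5 uV on 10 uV noise —
  per-epoch SNR 0.5.
* **Sensor layout**: 64 positions on a Fibonacci spiral over a 9 cm
  hemisphere (~3 cm nearest-neighbour spacing); a planar-grid layout is
  provided for statistics-only studies. Timing: 90 trials per ~200 s
  block; patients 2 XX + 2 XY blocks by default.

What the generator does **not** emulate: ocular/muscle artifacts,
realistic ECG morphology beyond peak timing, 1/f spectra, non-stationary
arousal fluctuations, or head-model lead fields. Passing studies
therefore demonstrate the statistical machinery under controlled
conditions, not clinical performance.

## Bundled studies and their problem sizes

Chosen as desk-scale versions of the analysis, fixed in
`herpipeline.studies`:

* **Calibration**: 200 null cohorts of effect maps (16-channel grid,
  3 cm spacing, 20+20 subjects, 125 time samples, 500 partitions);
  dataset-level false-positive rate at cluster p < 0.05 lands in
  [0.02, 0.10] (measured 0.025).
* **Planted-effect recovery**: 20 cohorts, 12+12 subjects, 4 XX + 4 XY
  blocks x 90 trials, 64 channels, 500 partitions, per-epoch SNR 0.5.
  All four planted windows recover as significant overlapping clusters,
  and the group pattern (global effects Bonferroni-significant only in
  the MCS-like group) reproduces. Eight blocks rather than the minimum
  four because the spatially correlated noise leaves the 12 ms
  heartbeat-locked window only ~1-2 effectively independent pixels; the
  extra trials restore per-subject precision at the same SNR.
* **Surrogate specificity**: 10 cohorts (12+12, 2+2 x 60 trials) with
  the heartbeat-locked local effect at 8 uV — strong enough that every
  cohort enters the control with a significant cluster, the situation
  the control is for. Surrogate p <= 0.05 throughout. **Sensitivity**:
  10 cohorts (8+8, 2+2 x 45) with heartbeat-locked amplitudes zeroed;
  the control reports non-significance (median p = 1).
* **R-peak fidelity**: 20 subjects (32 channels, 1+1 blocks x 20 trials,
  ~90 s — above the 60 s ICA floor); >= 99% of beats within 4 ms (one
  sample) per subject, via the full filter -> ICA -> detect chain.
* **Classification**: separable features classify at 100%;
  label-shuffled nulls (46+40, 200 runs) average ~49%; group-patterned
  features give quadruple accuracy ~78% with quad >= median triad.

## Numerical conventions

Seeds: every stochastic routine takes an explicit integer seed; cohorts
derive per-subject seeds from a master seed via `SeedSequence` (all
below 2^31). Signals are float32 internally (quantisation far below the
uV noise floor); statistics are float64. EDF output is 16-bit with
per-channel physical ranges from the observed min/max (relative error
~1e-5 of the span); recordings are zero-padded to whole 1 s records and
the true sample count travels in the events sidecar. Degenerate inputs:
zero across-channel variance rejects nothing; all-zero effect vectors,
empty contrast sides, constant correlation inputs and empty epoch sets
raise with named reasons rather than returning silently.
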