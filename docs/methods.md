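# Methods

This note documents the models, conventions and numerical choices behind
`smiletrace`, in the spirit of a statistical package's methods appendix.

## Signal model and preprocessing

The unit of analysis is a per-frame AU intensity trace (AU12, AU06 on the
0–5 scale) with a tracking-confidence score C ∈ [0, 1], as emitted by
OpenFace-style AU estimators at ~25 fps (PAL home video). Frame rate is
inferred as 1/median(Δt) so isolated dropped video frames do not bias it.

**Confidence gate.** Frames with C ≤ 0.75 are masked, not deleted: time
accounting and gap lengths stay exact, and the gate is *strict* (a frame at
exactly 0.75 fails). The threshold is configurable.

**Dropout segmentation.** AU estimates are undefined on masked frames, so
a convention is needed for expression continuity across masked runs. Runs
longer than `max_gap_s = 0.5` s split the recording into segments and are
excluded from usable time; shorter interior runs are bridged by linear
interpolation of the AU signals between the flanking valid frames. The
0.5 s default is half the minimum event duration, so bridging alone can
never manufacture a valid event. Leading/trailing masked frames of a
segment cannot be interpolated and are trimmed. Usable time is the summed
duration of the resulting segments (bridged frames included); splitting is
idempotent, so usable time is invariant under re-segmentation.

## Event detection

AU signals are smoothed with a width-4 boxcar. An even kernel has no
center; we fix the window at {t−2, t−1, t, t+1} and renormalize edge
windows over in-bounds frames, so output length equals input length,
constants are fixed points, and results are bit-reproducible. Windowed
means never exceed the input range.

An *activation run* is a maximal run of valid frames with smoothed signal
≥ τ. The default τ = 0.5 (0–5 scale) sits above the regression noise floor
of AU intensity estimators; it is configurable and the boundary is
included (≥). Runs strictly shorter than 1 s are discarded as too brief to
constitute a facial expression. Only AU12 runs define events; each
surviving AU12 run becomes one smile event, classified Social when AU06 is
active on ≥ 50% of its frames (a symmetric majority criterion for
"co-active"; configurable), Simple otherwise. AU06 runs are not
duration-filtered — AU06 only modulates classification. Events never span
segment boundaries. Per-event features are the means of the *smoothed*
signals over the event frames and the frame-count duration.

The run-based event definition (rather than point local maxima) is forced
by the feature set: duration and mean intensity of a point maximum are
undefined.

## Per-subject features and missingness

For each smile type: mean event duration (s), mean of event mean
intensities, and frequency = 120 · n_events / usable_seconds. A subject
with zero events of a type has frequency 0 but *missing* duration and
intensity — a mean over zero events is undefined, and coding it 0 would
bias intensity downward. The omnibus multivariate test uses listwise
(complete-case) exclusion over its DV set, with every exclusion logged;
univariate follow-ups use pairwise inclusion per DV. Both policies are
reported so row counts are always auditable.

The omnibus DV set collapses the two Social intensities into one composite
(their mean), giving 6 DVs; the follow-up family splits them again, giving
m = 7 Bonferroni-corrected tests (per-test threshold 0.05/7 ≈ 0.00714).
Both sets are configurable.

## Statistical battery

* **MANOVA.** One-way Pillai's trace V = tr[B(B+W)⁻¹] from the
  between/within SSCP matrices, with the standard F approximation; for two
  groups the F is exact, equals the Hotelling T² transform, and all four
  classical multivariate statistics coincide. Pillai is reported for its
  robustness to normality violations. A singular total SSCP raises an
  informative error suggesting DV reduction.
* **ANOVAs.** Two-group one-way sums of squares computed directly;
  partial η² = SSB/(SSB+SSW), invariant under affine DV rescaling. Zero
  within-variance degenerates to F = 0 (equal means) or an infinite-F flag.
* **Assumptions.** Shapiro–Wilk per DV per group (skipped below n = 3 with
  a note); Levene mean-centered by default (median-centered available);
  Mahalanobis distance to the pooled centroid with a χ²(p) cutoff at
  p < 0.001 (the conventional multivariate-outlier screen); maximum
  absolute pairwise Pearson r among DVs with a collinearity flag above
  0.9 — the flag is reported, interpretation is left to the user.
* **Partial Spearman.** Both variables and covariates are rank-transformed;
  ranks are residualized on the covariates by least squares; the Pearson
  correlation of residuals is reported with a t-based p-value on n−2−k df.
  This is invariant under strictly monotone transforms of either variable
  and reduces to plain Spearman when covariates are independent. Computed
  within the clinical group against IQ (controlling sex) and sex
  (controlling IQ).
* **Demographics.** Equal-variance two-sample t for continuous
  descriptors; uncorrected Pearson χ² for categorical counts. All tests
  two-sided.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
infant faces: per subject, event counts per type are Poisson(rate ·
duration/120); durations are log-normal (default mean 1.5 s, σ = 0.25),
clamped to ≥ 1 s so every true event survives the duration filter by
construction; amplitudes are Gaussian (clamped to [1, 5]) marking AU12
plateaus with 0.2 s half-cosine ramps appended outside the plateau; Social
events co-activate AU06 on the same support; events are placed uniformly
with rejection sampling keeping footprints ≥ 0.5 s apart (unplaceable
events are dropped with a logged note). Gaussian baseline noise
(σ = 0.08) and Poisson confidence dropouts (4/min of 0.4 s at C = 0.5
against a 0.95 baseline) complete the trace. Default recording lengths are
drawn per group around ~122 s; cohort metadata (sex ratio, age, IQ
availability) mirrors a typical 18 + 15 retrospective home-video sample.

Group presets encode only the qualitative contrast the pipeline targets —
the ASD preset lowers the Social-smile rate by 40% and the AU amplitudes
by ~1 intensity unit, with identical durations and Simple-smile rates. The
canonical recovery experiment uses exactly this contrast with *all other
parameters equal*. No attempt is made to tune the generator to any
empirical F values, which depend on unavailable raw data.

**What passing tests do and do not show.** The generator produces clean
plateau events, stationary noise, and missing-at-random dropouts. Real
infant AU traces have drifting baselines, pose-dependent estimation bias,
partially tracked faces and correlated event timing; recovery results here
validate the *pipeline logic* (detection, accounting, inference), not
field performance on real video.

**Ramp dilution.** Because event means are taken over the whole detected
run (including the supra-threshold part of the ramps), the detected mean
intensity sits systematically *below* the plateau amplitude, by an
amplitude-proportional amount that shrinks with duration (≈11% of the
amplitude at 1 s events, ≤3% at 5 s). Recovery tests therefore assert a
relative one-sided tolerance (within 15% below, never meaningfully above).
The same geometry makes detected duration weakly amplitude-dependent
(~0.04 s per intensity unit), which is negligible under the corrected
decision rule but is the reason duration null checks are run at that rule
rather than at raw α.

## Determinism and problem sizes

All simulation flows through `numpy.random.Generator` with a seed ladder
(`SeedSequence` master → per-subject children), so any subject is
regenerable in isolation and cohorts are byte-identical across reruns; the
pipeline writes a manifest (config hash + library versions) and produces
byte-identical statistics JSON for identical inputs. The replicated
experiments in the test suite use 1000 calibration and 200 recovery
replicates of full 33-subject cohorts; the acceptance script reports rates
at 300 and 150 replicates, the package's chosen standard report sizes.

## Known limitations

* The co-activation criterion (AU06 on ≥ 50% of event frames) and the gap
  semantics are conventions; the underlying literature specifies neither.
* Whether masked frames interrupt real expressions is unknowable from the
  gated signal; the bridging rule is a stated convention, not a finding.
* No imputation: subjects missing an omnibus DV are excluded listwise
  (logged); missing IQ simply drops rows from the partial correlations.
* The demographic χ² is the uncorrected Pearson statistic; small expected
  cell counts (sex splits in small cohorts) make it approximate.
* Multi-face videos, gaze direction, other AU combinations and laughter
  detection are out of scope.
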