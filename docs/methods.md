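# Methods

This note documents the analysis conventions, the synthetic-cohort model and
the numerical choices behind `noctox`, in the spirit of a statistics package's
model documentation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal conventions

Recordings are fixed 1 Hz; sample *i* is *i* seconds from recording start, so
durations are sample counts. Device sentinel values (e.g. 500) are preserved
on load and handled by the artefact filter, never at parse time.

### Artefact rejection

Three criteria flag a sample: SpO2 < 30%, SpO2 > 100%, or an absolute
deviation > 4% from the most recent **retained** sample. Using the retained
reference (rather than the raw preceding second) prevents a single spike from
cascade-flagging the good sample that follows it; samples before the first
retained sample are exempt from the deviation rule. Flagged samples are
removed, not interpolated — downstream operations see original sample indices
with gaps, and window/event operations refuse to span gaps longer than 5 s.

A deliberate consequence: an *instantaneous* desaturation step deeper than 4%
is indistinguishable from an artefact and is removed. Physiological
desaturations fall over several seconds (the synthetic generator's default
5 s ramps pass the filter untouched); only square-wave test signals collide
with the rule, which is why the detector's exactness checks run on
constructed artefact-free series.

### Desaturation events

Baseline at time *t* is the maximum SpO2 over the preceding 20 clean samples
within a gap-bounded segment (a maximum is robust to contamination by the
ongoing decline; a mean is not). Events open at a fall ≥ 4% below baseline,
close on recovery to within 2% of the onset baseline (the hysteresis
convention of sleep-medicine scoring; a pure return-to-baseline rule
truncates events in drifting signal) or at a clean-data gap > 5 s, and are
discarded under 10 s. All five thresholds (4%, 20 s, 2%, 10 s, 5 s) are
config-exposed with these defaults. The first 20 samples of a segment cannot
host an onset (no baseline yet). Event area is Σ(onset baseline − SpO2) over
the retained event samples, in %·s; hypoxic burden divides the summed area by
60 and normalises per artefact-free hour (%·min/h).

### Distributions and moments

Integer bins span 30–100% (values below 30 cannot survive the filter).
Moments are computed on the raw clean samples, not histogram midpoints, to
avoid binning bias. Variance uses the sample (n−1) denominator by default
(config-switchable to population); skewness and kurtosis use the unadjusted
moment coefficients — at overnight n ≈ 28 000 the small-sample corrections
are far below reporting precision. Kurtosis is "proper" (normal = 3).
Zero-variance nights report skewness/kurtosis as undefined markers, never
numbers. Time-below thresholds are strict (< t) by default, with the
at-or-below convention available by flag.

### Night features

The half-night split for ΔSpO2 uses clean-*sample* counts (a wall-clock
midpoint would unbalance the halves around artefact gaps); for odd counts the
middle sample joins the second half. Moving averages are **trailing** windows
of contiguous clean samples that never span gaps > 5 s; windows that do not
fit in any clean run yield a not-assessable marker rather than an error, as
do first/last 15-min means on short recordings. The morning spot
"display-averaging" convention is emulated as the mean of a 75 s window, the
midpoint of the 60–90 s practice.

## Diagnostic statistics

AMS status is conjunctive: total LLS ≥ 3 **and** headache ≥ 1. Mornings with
total ≥ 3 but no headache fall outside both printed definitions; they are
classified negative and carry an audit flag. Nights are the analysis unit
(each paired with next-morning status), pooled across the expedition;
repeated measures within participant are *not* modelled — a known limitation
shared with the field's standard presentation of such tables.

Group contrasts use the Mann–Whitney U-test with the Hodges–Lehmann estimate
(median of all pairwise differences, positive minus negative) and a 95% CI
from rank-test inversion using the normal approximation to the critical
order statistic. Outliers beyond ±3 SD of the pooled feature distribution
are removed in a single pass before comparison.

ROC analysis computes AUC as the rank statistic U/(n₁n₂) (ties count ½),
orients the score so AUC ≥ 0.5 and reports the direction ("below" for
saturation-like metrics), uses Hanley–McNeil for the AUC CI, and selects the
cutoff maximising sensitivity + specificity over midpoints between
consecutive distinct scores. Ties are broken toward higher sensitivity (the
screening use-case values sensitivity), then toward the cutoff nearest the
pooled median (the less extreme operating point). Both Youden conventions
are returned because published field tables sometimes print the sum
sens + spec rather than sens + spec − 1; the two differ by exactly 1 and
select the same cutoff.

Bland–Altman agreement takes differences as reference − test, bias as their
mean, limits of agreement as bias ± 1.96 SD, and fits OLS of differences on
pairwise averages (statsmodels), reporting slope with CI, the x-intercept
−a/b with a delta-method CI, and r². Constant differences yield slope 0 with
an undefined x-intercept; zero-variance averages yield a not-assessable
slope.

Pearson correlations against each participant's peak morning LLS are
reported unadjusted across cells, matching field practice; cells with fewer
than 3 pairs are not assessable.

## The synthetic cohort

The generator emulates the *statistical structure* of an expedition dataset,
not the physiology of ventilation. Defaults describe an 18-participant,
12-night ascent profile reaching a 4800 m top camp for three nights.

- **Saturation.** Anchors give the expected clean-night mean SpO2 as a
  piecewise-linear function of altitude (97% near sea level to 83% at
  4800 m). Because injected desaturation events drag the realized mean
  down, the pre-event baseline is raised by the analytically expected drag
  (mean event area × realized event rate), so anchors — and the AMS⁺ offset —
  are exact expected means, not pre-event levels. Each participant carries a
  normal random saturation offset (SD 2%).
- **Noise.** AR(1) observation noise (coefficient 0.9, marginal SD 1%) gives
  the within-night autocorrelation that white noise lacks; signals are
  rounded half-up to integers like a real device.
- **Events.** Trapezoidal dips (5 s linear fall, plateau, 5 s recovery;
  depth U(5, 12)%, duration U(15, 40) s) at an altitude-dependent rate
  (0.5/h near sea level to 45/h nominal at 4800 m, throttled by per-event
  dead time), keeping analytic areas computable for exactness tests (with
  ramp 0 the trapezoid degenerates to a square wave whose area the detector
  recovers exactly).
- **Artefacts.** Each sample is corrupted independently at rate 0.0075:
  half become 500 sentinels, a quarter step spikes, a quarter sub-30% dips.
  On event-free signal the filter recovers the injected set exactly; on full
  nights a spike landing on a steep event ramp can cascade one or a few extra
  flags, so the cohort-mean artefact index runs slightly above the injection
  rate.
- **AMS labels.** Positive participant-nights are drawn iid
  Bernoulli(0.10). Independence from altitude and participant is a
  deliberate identifiability choice: it makes the configured −5% AMS⁺
  saturation offset exactly the expected group contrast, with no
  composition or selection bias. Real AMS incidence rises with altitude;
  this generator encodes altitude only in *severity*. Accordingly, passing
  tests demonstrate estimator calibration under a clean contrast, not
  performance under altitude-confounded labelling.
- **Symptom scores.** A participant susceptibility variable is correlated
  (0.9) with the negated saturation offset; morning totals are a thresholded
  linear function of susceptibility, altitude and noise (≥ 3 with headache
  on positive mornings, ≤ 2 otherwise). Severity — not label incidence —
  therefore carries the negative association between prior-night saturation
  and peak LLS that the exploratory correlation stage recovers.
- **Reference measures.** Capillary SaO2 is derived from the realized night
  mean by inverting a difference-vs-average line (slope 0.40, x-intercept
  89.8%), and the morning spot reading from SaO2 through a second line
  (slope 0.55, x-intercept 96.5%), plus noise; the pipeline's Bland–Altman
  stage recovers these generating lines. Spot readings average a 75 s
  window of integer samples.

What the generator does **not** emulate: sleep staging and arousals,
acclimatization dynamics across repeated nights at one altitude, motion- or
perfusion-dependent artefact clustering, device-specific calibration curves,
or treatment effects (acetazolamide). Conclusions from synthetic runs are
about the pipeline's correctness and calibration, not about field
performance.

## Test and acceptance problem sizes

Unit and structural tests run scaled-down cohorts (3–4 participants, 1–2 h
nights) because the operations are length-invariant. Calibration and
parameter-recovery checks use the sizes their claims require: the group-offset
calibration uses a flat 3300 m profile with balanced groups over 168 nights
(isolating the configured offset from altitude composition); detector
exactness uses 100 four-hour nights of square-wave events; and the
parameter-recovery check runs 500 full 18 × 12 expeditions at the default
eight-hour nights, asserting the Mann–Whitney detection rate (≥ 80%) and the
Hodges–Lehmann concentration in [−7, −3] (≥ 90%) stated for that design.
`scripts/acceptance.py` runs one full expedition at the given seed (~5 s).

## Known limitations

- The retained-reference artefact rule is one resolution of an ambiguity
  (whether the deviation criterion resets after a removed run); it is the
  one that avoids cascade-flagging but it is not the only defensible choice.
- Hypoxic burden is defined strictly as event area per artefact-free hour
  (%·min/h); published summaries of comparable cohorts print burden values
  on two inconsistent scales, and no attempt is made to reconcile them.
- The Hodges–Lehmann CI uses the normal approximation to the critical order
  statistic; for very small groups an exact inversion would differ slightly.
- AUC confidence intervals are Hanley–McNeil only.
- Pooling nights ignores within-participant correlation; p-values for pooled
  comparisons are anti-conservative to an unknown degree, exactly as in the
  standard field presentation.
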