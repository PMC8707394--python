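# Methods

This note documents the models, parameter choices and numerical decisions
behind `actibed`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Feature pipeline

Raw tri-axial acceleration is read per body site (hip, thigh) in units of
g, with the x axis the longitudinal axis of the segment (positive toward
the head when upright). Values beyond the ±8 g sensor range are clipped.
The sample rate is inferred from the median timestamp step when not
declared; timestamp gaps longer than twice the nominal period are flagged
but not imputed.

**Resampling.** Feature extraction is defined on 2-s windows of 60 samples
with a 30-sample hop — i.e. a 30 Hz grid with 1-s frame spacing. Devices
typically record at 50 Hz, so both streams are linearly interpolated onto
a uniform 30 Hz grid first (the target rate is configurable). Linear
interpolation is adequate because every downstream statistic is a window
mean or SD of a gravity-dominated signal; no anti-alias filtering is
applied, which slightly inflates in-window SD for high-frequency movement
but leaves the 0.1 g movement decision comfortably unaffected.

**Per-window statistics.** For each window the mean acceleration vector
approximates gravity; the inclination is
θ = arccos(mean_x / ‖mean‖) ∈ [0°, 180°]. A zero-magnitude mean vector
(free fall, data dropout) has no inclination: the frame is marked missing
and propagated as NaN. Movement intensity is the *population* SD (divide
by n) of the longitudinal axis; with 60 samples the difference from the
sample SD is < 1% and the population form makes the constant-window value
exactly zero.

**Classification.** The activity class is a Skotte-style inclination/SD
rule on the thigh: thigh inclination ≤ θ_sit → upright (standing, moving
and walking share the encoded +1 level); thigh inclination > θ_sit and
thigh SD ≤ s_move → sitting (0); otherwise other activity (−1). The
decision thresholds θ_sit = 45° and s_move = 0.1 g are configurable
defaults chosen as a reasonable approximation of the published
decision-rule family; they are not calibrated constants. Lying is then
declared when the **hip** inclination strictly exceeds 65° while the thigh
is concurrently sitting. The 65° threshold is the one fixed constant of
the pipeline; the strict inequality means a hip at exactly 65.0° is not
lying.

**Encoding.** All channels are scaled into [−1, 1] for WAV rendering:

| channel | encoding | default |
|---|---|---|
| Lying | +1 lying / −1 not | — |
| Activity | class level verbatim (+1/0/−1) | — |
| Time | six 4-h local-clock bins, left-closed, −1.0 to +1.0 in 0.4 steps | — |
| SDacc (both sites) | −1 + 2·min(sd, sd_max)/sd_max | sd_max = 0.5 g |
| Inclination (both sites) | θ/180 into [0, 1] | — |

Inclination uses only the non-negative half of the nominal −1..1 display
range: θ is an unsigned angle to the gravity vector and no sign source
(forward vs backward lean) exists in a single-axis convention, so the
[−1, 0) half is declared unused. The SD saturation at 0.5 g keeps vigorous
movement from compressing the visually informative low range.

Missing frames are written to the WAV as 0.0 so tracks stay continuous for
visual inspection; the missing mask is preserved in the JSON sidecar next
to the WAV together with the absolute start time, subject id and channel
order. WAV files are RIFF IEEE-float 32-bit, 7 channels, header sample
rate 1 Hz, so the numerical values round-trip bit-identically.

## Events, nights, ground truth

A rater marks each in-bed period as one region label; label files are
Audacity's tab-separated text (6-decimal seconds on write). Label offsets
are relative to the recording start from the sidecar. **Night
assignment** uses the noon rule: an event belongs to the calendar date of
its to-bed time if that time is ≥ 12:00 local, else to the previous date.
This puts a 23:30 and a 00:30 bedtime in the same night and is shared by
every module. Labels spanning ≥ 24 h are rejected as implausible in-bed
periods rather than silently truncated.

EEG-epoch records are 30-s stage epochs. The reference to-bed is the
*start* of the first epoch without a sensor problem and the out-of-bed the
*end* (start + 30 s) of the last such epoch — an epoch represents an
interval, so its end is the last instant supported by data. A night whose
recording begins or ends with a sensor-problem epoch is discarded with a
reason, never silently repaired: the true boundary is unknowable from the
record. Interior sensor problems never move the endpoints.

Diary entries carry clock times only. The night's date is the diary row's
date; a to-bed clock before noon is placed on the following calendar day,
and an out-of-bed clock earlier than the to-bed clock rolls to the next
day. Rows missing either time are flagged incomplete and excluded from
event conversion (complete-case throughout; no imputation).

## Agreement statistics

Paired analysis works on a night-by-source matrix of timestamps in minutes
relative to the night's reference midnight (the midnight being slept
through; 23:30 → −30, 00:15 → +15). Pairing is an inner join on
(subject, night); duplicate nights within one source are an error.

**ICC.** Two-way random-effects, absolute-agreement intraclass
correlation from the two-way ANOVA mean squares: ICC(2,1) for single
measures, ICC(2,k) for the average of k sources, with 95% confidence
intervals from the McGraw–Wong F-distribution formulas (Satterthwaite
degrees of freedom for the single-measure bounds; the average-measure
interval is the Spearman–Brown transform of the single-measure one). The
implementation is validated in the test suite against an independent
reference implementation to 10⁻⁸. Method-vs-method comparisons default to
ICC(2,1); the average-measures form is intended for multi-rater panels.
Interpretation bands — < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
≥ 0.9 excellent — are applied to the CI *lower bound*, the conservative
convention. Bands are left-closed at their lower edge. Two numerical
edge cases are handled explicitly: zero total variance raises a distinct
"ICC undefined" error, and on pure-noise data the Spearman–Brown transform
of a CI bound can cross its pole at −1/(k−1); the exact formula values are
reported rather than clamped, so the CI-brackets-estimate invariant is
guaranteed only where a positive between-night variance component exists
(every realistic agreement setting).

**Bland–Altman.** Differences are oriented **reference − test**, so a
test method that places timestamps earlier than the reference yields a
positive bias. SD uses the n−1 denominator. Limits of agreement are
bias ± 1.96·SD by default; a 2.0 multiplier is available as a
configuration switch for strict "two standard deviations" reading.
Confidence intervals use t_{n−1, 0.975} with SE(bias) = SD/√n and
SE(LOA) = √(3·SD²/n) (the classical large-sample approximation). The
result always reports loa_lower ≤ loa_upper; published tables of this
design sometimes carry the two columns with swapped signs/labels, which
this orientation resolves unambiguously. No multiple-testing correction
is applied — each comparison is reported marginally.

**Densities.** Difference distributions are summarized with a Gaussian
kernel density, Silverman bandwidth. A zero-variance input would be a
Dirac spike; a degenerate point-mass result is returned instead of a
kernel estimate.

## Synthetic study generator

The generator emulates the *conditions* of a free-living validation study:
about 10 subjects wearing both devices for about 7 consecutive nights,
with an EEG reference and three manual raters. Defaults:

* Bed/rise schedule: population mean bedtime 23:00 and rise 07:00, with a
  between-subject offset SD of 60 min (a mixed child/adult cohort spans
  hours of habitual bedtime) and a night-to-night SD of 45 min. Infeasible
  draws (rise < 1 h after bed) are resampled.
* Rater error: to-bed and out-of-bed are each truth + Normal(bias, σ),
  independently per night, endpoint, rater and round; σ defaults to 14 min,
  the scale at which single-rater limits of agreement land around ±30 min.
* EEG reference: epochs tile each true interval after Gaussian endpoint
  jitter (default 0) snapped to the 30-s grid; with configurable
  probability one boundary epoch is flagged as a sensor problem, which
  discards the night downstream.
* Accelerometry: each behavior segment projects gravity onto a fixed
  orientation drawn per segment from a posture-specific inclination range
  (in bed: hip 70–110°, thigh 80–100°; sitting: hip 5–25°, thigh 80–100°;
  standing/walking: both 0–10°; other: intermediate angles), plus white
  noise — 0.01 g at rest, 0.3 g walking, 0.25 g for other activity.

All randomness derives from one seed through named `SeedSequence` child
streams, so each component is reproducible independently.

**What the simulation does not emulate:** sleep micro-movements and
posture changes within a night, device-specific noise spectra and clock
drift, non-wear, napping, autocorrelated daytime behavior. Consequently
the tests demonstrate the *correctness of the pipeline and statistics
under known conditions* (e.g. that injected rater bias and noise are
recovered, that the lying rule fires where construction says it must),
not the field accuracy of manual annotation on real recordings — that
requires real concurrent EEG data.

## Problem sizes and determinism

The test suite runs the full event-level study replica at 10 subjects ×
7 nights (70 nights, the size of a baseline wave) and the raw-signal
end-to-end recovery on a 2-night noiseless rendering (≈ 3.9 M samples per
site at 30 Hz), which keeps the whole suite under a minute while covering
every code path at realistic scale. The feature pipeline is fully
deterministic — identical inputs produce bit-identical outputs — and all
simulation-based tests fix their seeds.

## Known limitations

* The Skotte-style thresholds are plausible defaults, not the calibrated
  constants of the original classifier; activity subclasses (standing vs
  walking vs cycling) are not separated beyond the three encoded levels.
* Signed inclination (forward/backward lean) is not represented.
* One region label per in-bed period is assumed; point-label workflows
  (separate to-bed and out-of-bed markers) are not parsed.
* Agreement analysis treats nights as exchangeable rows; repeated-measures
  extensions (subject random effects in the Bland–Altman model) are out of
  scope.
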