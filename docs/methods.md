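# Methods

## The measurement problem

A participant spends five minutes in each of six VR scenes while a headset
eye tracker records, every 10 ms: the raw gaze intersection point, head
pose, per-eye pupil diameter and eye openness, and the currently selected
object; discrete events (gaze-object switches, blinks, button presses,
survey responses) are logged at onset. Three Active scenes contain nicotine
and tobacco product cues; three Neutral scenes contain only neutral
objects. From these logs the package derives attentional bias (cue dwell
time), spontaneous eye-blink rate, per-category pupillometry, and in-task
craving ratings, and contrasts them within participant.

## Data model and formats

Timestamps are integer milliseconds, scene-relative, 0-based, on a strict
10 ms grid. Missing pupil/openness readings are NaN internally and the
sentinel `-1.0` on disk (empty and `null` fields are also accepted on
read). One directory per participant holds a JSON manifest, one CSV per
scene for the timeseries, and one JSON-lines file per scene for events.
The per-tick record type exists as a dataclass, but sessions store their
samples as a pandas DataFrame — 1.8 million ticks per participant make a
columnar representation the only practical one. Coordinates are
right-handed meters; the tracker's native frame is not modeled.

## Gaze-to-object mapping

The headset vendor's learned gaze-to-object mapper is proprietary; the
package ships a deterministic geometric stand-in. Among catalog objects
whose angular distance from the gaze ray is at most
`max(threshold, subtended angular radius)` — threshold default 3°, chosen
near the eye tracker's practical accuracy — selection takes the minimum
angular distance, breaking ties by Euclidean distance then name. The two
fallbacks of the original system (learned selector for small objects,
naive raycasting otherwise) are collapsed into this single selector. One
behavioral rule is reproduced exactly: while an object is held (pickup
button event), selection is locked to it until release.

## Blink detection

A blink candidate is a maximal contiguous run of missing pupil samples:
under the default `BOTH_EYES` rule both pupils must be missing (complete
eyelid closure occludes both eyes; monocular loss is tracker noise), under
`EITHER_EYE` one suffices. Duration is run length × 10 ms. Candidates
< 50 ms are discarded as noise and > 500 ms as microsleeps; 50 and 500 ms
inclusive are blinks, since the discard rules are phrased strictly
("less than", "more than"). Runs cut off by scene end have undefined
duration and are tallied separately rather than classified. The per-scene
EBR is exactly blink count divided by scene minutes. The blink's
`object_at_onset` is the last non-empty gazed object before the run starts.
An eye-openness-threshold detector is deliberately not provided: openness
lacks an established closure threshold and the pupil-dropout definition is
the validated one.

## Fixation accounting

The fixation unit is the object-switch interval: a switch to object *o* at
time *t* credits *o* with `t_next − t` ms, where `t_next` is the next
switch or scene end. No saccade/velocity parsing (I-VT/I-DT) is attempted —
the paradigm's dwell definition is the switch interval. Time before the
first switch belongs to no object and is reported as uncovered; category
totals plus uncovered time equal scene duration exactly. Per category, the
total index sums its objects and the mean index divides by the number of
*distinct objects gazed* (undefined, not zero, for untouched categories).
Active-vs-Neutral contrasts use the two cue categories only; Miscellaneous
and Background are accumulated but excluded, and whether reported "Neutral
cue" times should include Miscellaneous objects remains a sensitivity
question. The bias score is a difference in ms (not a ratio), averaged
over the three Active scenes; if a scene is missing the mean covers the
available scenes and the count is reported with a warning.

## Pupillometry

Each valid sample contributes the mean of its present eye values
(binocular mean, monocular fallback — the combination rule is this
package's choice; the source system reports a single diameter without
stating one). Samples inside any missing-run candidate, or within an
optional `margin_ms` guard band around one (default 0), are excluded.
Means are per-sample weighted, raw millimeters; no baseline correction or
luminance model is applied.

## Statistics

Paired *t* (two-tailed), Cohen's *d*<sub>z</sub> = *t*/√*n*, and the 95%
CI *d* ± 1.96·√(1/*n* + *d*²/(2*n*)) computed from the 2-dp-rounded *d* —
the rounded-*d* convention reproduces the published pilot intervals where
the unrounded value does not. Exact noncentral-*t* intervals are
deliberately not used; they disagree with the published values.
Participants missing either member of a pair are dropped per contrast
(pairwise, not listwise, deletion), so df varies across contrasts. No
multiple-testing correction is applied by default; Holm adjustment is
available as a flag. `expected_dz_inflation(n)` exposes the known
small-sample inflation of the *d*<sub>z</sub> estimator
(E[*d̂*] = *d*·√(df/2)·Γ((df−1)/2)/Γ(df/2), ≈ 1.026·*d* at *n* = 31),
needed when averaging estimates across replicate cohorts.

Questionnaires (presence, VR sickness) are scored by simple averaging
rescaled to 0–100; item wording and subscale maps are instrument-specific
and must be supplied by the caller.

## The session simulator

The generator emulates the statistical structure the analysis assumes, not
the visual world.

**Gaze.** A scene is a sequence of iid object dwell segments, each object
drawn with probability proportional to its selection weight (category
weight × per-object attractiveness); consecutive same-object segments
merge. Because the object choice is independent of segment duration, the
expected time share of each object is *exactly* its normalized weight,
which makes the dwell-bias recovery estimator (catalog-normalized
Active:Neutral per-object mean dwell ratio) unbiased for the configured
weight ratio. Segment durations are exponential, mean 800 ms, truncated at
10 s — no dwell distribution is established for this paradigm, and the
exponential is the maximum-entropy choice given a mean. Default per-scene
Active:Neutral weight ratios (Patio 2.2, Outdoor BBQ 1.45, Driving 0.3)
are the ratios of the pilot sample's per-scene cue fixation means, so the
per-scene sign pattern — cue capture in Patio and Outdoor BBQ, reversal in
Driving — is reproduced. A `driving_reversal` preset instead recategorizes
the Driving street-video panel as a highly attractive Neutral cue, the
mechanism suspected in the original data.

**Pupil.** Per tick: participant baseline (N(4.0, 0.6) mm) plus a cue
shift while on Active objects plus iid per-eye N(0, 0.15) noise. The mean
cue shift is −0.10 mm (the pilot's pooled Active-minus-Neutral difference)
with between-participant SD 0.27 mm, back-calculated from the pilot's
pooled pupil contrast (sd(diff) = |mean diff|·√n/|t|); without that
heterogeneity every participant carries an identical shift and paired
effect sizes degenerate.

**Eye closures.** Blinks (Poisson 20/min, uniform 50–500 ms), tracker
dropouts (6/min, uniform 10–40 ms, possibly monocular), microsleeps
(0.2/min, uniform 600–2000 ms). Duration shapes are uniform so both sides
of each detector threshold are exercised. Closures are placed without
overlap and with ≥ 2 ticks of separation, so in both-eyes mode the
detector recovers simulated blinks *exactly* — the recovery tests assert
identity, not approximation. Both pupils vanish during blinks and
microsleeps; dropouts hit left/right/both at 40/40/20%.

**Surveys.** Rating = condition mean + participant offset
(SD `craving_between_sd` = 25) + scene noise (SD `craving_sd` = 21.5),
rounded and clipped to the 0–100 VAS. Defaults put the craving means at
the pilot values (42.77 Active / 29.42 Neutral); the within-SD makes the
implied paired effect (42.77−29.42)/(21.5·√(2/3)) ≈ 0.76, the pilot's
craving *d*<sub>z</sub>. Clipping at the scale bounds shifts realized
means upward by roughly 1–3 points at these presets, so calibration
studies (type-I error, p-value uniformity, effect recovery) use mid-scale
means where clipping is negligible.

**Use history.** 90-day use episodes are lognormal with log-mean 6.152 and
log-SD 0.997, matching the pilot's mean 772 / SD 1008 (heavy right skew).
`use_episodes_slope` (default 0.25) couples the participant's dwell-bias
multiplier to standardized log episodes, producing the positive
bias–use-episode correlation the paradigm reported; an additional
lognormal multiplier (log-SD 0.5) models individual differences in cue
capture.

**Seeding.** One global seed fans out to per-participant, per-scene
substreams via `SeedSequence` spawn keys: adding participants never
perturbs existing ones, and logs serialize byte-identically across runs.

### What the simulator does not emulate

No saccade kinematics, no pupillary light reflex or luminance coupling, no
head-movement dynamics, no blink-adjacent partial-occlusion artifacts
(diameters next to a closure are clean in simulation — the `margin_ms`
exclusion exists for real data), no drift or calibration decay, and no
dependence of blink rate on scene content. Passing recovery tests
therefore demonstrate correctness of the *accounting* (detection,
accumulation, aggregation, statistics) under the stated generative model,
not robustness to real-tracker artifacts. The pooled fixation contrast is
one visible consequence: in the pilot it is negative (−0.85) because the
Driving scene's Neutral fixation dwarfs everything else (≈ 35 s vs ≈ 2 s),
while the simulator's more symmetric dwell magnitudes leave the pooled
simulated contrast positive even though all three per-scene signs match.

## Problem sizes and numerical conventions

Validation studies use sizes chosen to make Monte-Carlo error small
relative to the tolerances they check: 500 random traces for the blink
oracle, 300 random sequences for the fixation oracle, 100 replicate
five-minute scenes for parameter recovery (blink rate, dwell bias, pupil
shift, each within 3 SE), 1000 null cohorts for the type-I error and 2000
for p-value uniformity (via the survey-model fast path, which draws only
ratings), and 400 cohorts for effect-size recovery at the pilot magnitude
(corrected by `expected_dz_inflation`). Recovery tests use empirical
standard errors across replicates. Ties in gaze selection break
deterministically (angle, then distance, then name); simulated pupil
values are clipped to (0.1, 9.9) mm to respect the data model's validity
range; all random draws flow from explicit seeds.

## Known limitations

- The geometric gaze selector is a documented stand-in, not a reproduction
  of the proprietary learned mapper; object-level dwell from real logs
  will differ near small or fast-moving objects.
- Whether the original blink candidate unit is per-eye or binocular is
  ambiguous in the source description; both modes are implemented,
  `BOTH_EYES` is the default, and reports carry the mode.
- CI reconstruction matches the published intervals only under the
  rounded-*d* convention, and two published contrasts still differ by one
  unit in the last printed digit — treated as upstream rounding artifacts.
- Participant-level pilot quantities (craving means, pupil means, the
  *r* = 0.33 use-episode correlation) derive from unreleased data; they
  parameterize the simulator and anchor direction checks but are not
  reproducible facts.
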