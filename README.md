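# vreye

Eye-metric extraction and analysis for VR nicotine cue-exposure sessions.

Craving is a core clinical phenotype of nicotine addiction, and VR
cue-exposure paradigms elicit it reliably, but the field still lacks
objective correlates. `vreye` implements the analysis side of a six-scene VR
paradigm (three *Active* scenes containing nicotine and tobacco product cues
— Driving, Patio, Outdoor BBQ — and three *Neutral* scenes — Bus, Waiting
Room, Library) that measures three candidate eye-based markers from a
100 Hz headset eye tracker:

- **Attentional bias** — gaze dwell time accumulated per object into four
  category dictionaries (Active, Neutral, Miscellaneous, Background), where
  a "fixation" is the interval between consecutive gaze-object switches.
  The bias score is the Active-minus-Neutral total fixation time (ms),
  averaged over the three Active scenes.
- **Spontaneous eye-blink rate (EBR)** — a proxy for striatal dopaminergic
  tone. A blink is a maximal run of missing pupil-diameter samples lasting
  50–500 ms inclusive; shorter runs are discarded as tracker noise, longer
  ones as microsleeps.
- **Pupillometry** — mean pupil diameter (mm) per cue category over valid
  samples, with blink/dropout/microsleep spans excluded.

Condition contrasts are within-participant, so the effect size of record is
Cohen's *d*<sub>z</sub> = *t*/√*n* for the paired *t* statistic on *n*
pairs, with the 95% CI *d* ± 1.96·√(1/*n* + *d*²/(2*n*)) computed from the
2-dp-rounded *d*. A synthetic session simulator generates full tracker logs
(category-biased gaze switching, cue-evoked pupil shifts, Poisson blink /
dropout / microsleep processes, VAS survey responses) with a ground-truth
record, so the entire pipeline is testable without hardware.

Intended users: researchers building or re-analyzing VR cue-reactivity /
attentional-bias experiments, and anyone needing a validated blink detector
for pupil-dropout signals.

## Worked example

Reconstruct the pilot sample's paired effect sizes from their *t*
statistics and degrees of freedom (`python examples/05_effect_sizes.py`):

```
contrast                                        t  df    d_z  95% CI
craving: Active vs Neutral scenes            4.24  30   0.76  [0.36, 1.16]
fixation: Active vs Neutral cues (pooled)   -4.76  30  -0.85  [-1.26, -0.44]
fixation: Active vs Neutral cues (Patio)     5.05  29   0.92  [0.49, 1.35]
pupil: Active vs Neutral cues (pooled)      -2.01  28  -0.37  [-0.75, 0.01]
EBR: Active vs Neutral scenes                0.49  30   0.09  [-0.26, 0.44]
```

`d_z = 0.76` on the craving row means Active scenes raised the 0–100
craving rating by about three-quarters of a within-participant standard
deviation; the CI excluding zero marks the contrast significant at the .05
level. The negative pooled fixation row reflects the Driving scene, whose
street-video backdrop pulls gaze toward neutral content.

Simulate a scene and recover the cue-evoked pupil shift
(`python examples/04_pupil_by_category.py`):

```
category        mean mm  samples
Active            3.900    17966
Background        3.996     2032
Miscellaneous     4.001     1658
Neutral           3.999     5406
excluded samples (blinks/dropouts/microsleeps): 2938

Active - Neutral diameter difference: -0.100 mm (generator truth -0.10 mm)
```

The estimator recovers the simulated −0.10 mm constriction toward Active
cues exactly to noise, after excluding 2938 of 30 000 samples around eye
closures.

Each script in `examples/` demonstrates one capability: session simulation,
blink detection, fixation/bias accounting, pupillometry, effect sizes, and
the end-to-end pipeline. The same flow is scriptable from the shell:

```bash
vreye run --out run1 --seed 42        # simulate -> extract -> analyze
vreye report --in run1                # markdown summary tables
vreye blinks --in run1/logs --mode both --out blinks.tsv
```

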