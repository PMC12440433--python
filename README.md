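# romkin

Autonomous, video-based measurement of upper-extremity joint range of
motion (ROM), with the statistical toolkit needed to validate such a
measurement method against clinical goniometry.

## The problem

Clinical ROM assessment — how far a patient can abduct or flex the
shoulder, or flex the elbow — is usually done with a universal
goniometer, which is accurate in skilled hands but suffers from
interobserver variability. Pose-estimation software can localise the
body's joints in every frame of an ordinary video, which removes both
the manual annotation step *and* the need for an observer to judge the
moment of maximal motion. `romkin` implements that pipeline for three
motion tasks (shoulder abduction, shoulder forward flexion, elbow
flexion), assuming a single subject moving in a plane parallel to a
fixed camera, plus everything required to check it works: a
ground-truthed synthetic motion generator, a deterministic
fiducial-marker pose backend for desk-scale end-to-end tests, and the
method-agreement statistics used in validation studies.

## The computation

For each frame, the angle at a vertex joint **B** subtended by two
neighbouring joints **A** and **C** is

    θ = | (180/π) · atan2(BA × BC, BA · BC) |   ∈ [0°, 180°]

with **BA**, **BC** the 2-D displacement vectors, `×` the scalar cross
product and `·` the dot product. Shoulder tasks use the shoulder as
vertex with the shoulder→elbow and shoulder→hip vectors; elbow flexion
uses the elbow as vertex with the elbow→wrist and elbow→shoulder
vectors and reports the supplement 180° − θ (so 0° = full extension).
The maximum ROM for a task is the largest per-frame angle over the
whole video, with the earliest frame reported on ties. Frames where a
landmark is missing, below a confidence threshold, or geometrically
degenerate are carried as explicitly invalid samples.

The agreement module implements the standard validation analysis:
mean (absolute or signed) difference between methods, Pearson r,
intraclass correlation from the two-way random-effects ANOVA model
(default ICC(2,1): single measurement, absolute agreement), simple
regression R², paired Student t test, per-subject coefficient of
variation, clinical interpretation bands, and the normal-approximation
sample-size formula for a paired design,
n = ⌈((z₁₋α/₂ + z_power)·σ/δ)²⌉.

## Worked example

Simulate a shoulder-abduction clip with a 135° peak and 1.5 px landmark
jitter, then measure it back:

```sh
$ romkin simulate --task shoulder_abduction --peak 135 --frames 61 \
      --jitter 1.5 --seed 42 --out-dir demo
wrote 61 frames to demo (peak 135.0 deg at frame 30)

$ romkin measure --landmarks demo/landmarks.csv --task shoulder_abduction \
      --side right --angles-out demo/angles.csv --json-out demo/result.json
max ROM 133.394 deg at frame 30 (61/61 valid frames)
```

The recovered maximum (133.4°) sits 1.6° below the configured truth —
the effect of 1.5 px of coordinate noise on an ~80 px arm — and the
argmax lands on the true apex frame; with `--jitter 0` the recovery is
exact to six decimals. `demo/angles.csv` holds the per-frame series
(`frame,time_s,angle_deg,invalid_reason`).

From Python, the same pipeline plus a reliability analysis of a
synthetic 8-subject × 8-rater measurement panel:

```python
import numpy as np
from romkin import RaterMatrix, rater_reliability

rng = np.random.default_rng(0)
subject = rng.normal(110, 30, size=(8, 1))          # true per-subject ROM
panel = RaterMatrix(np.abs(subject + rng.normal(0, 4, size=(8, 8))).round(1))
print(rater_reliability(panel).summary())
```

```
intraclass CC: 0.957 (excellent)
mean CV:       2.989% (low variability)
```

With 4° of rater noise on a 30° between-subject spread, almost all
variance is between subjects, hence the high ICC and low coefficient of
variation. `romkin agree --matrix panel.csv --reference manual.csv`
runs the same analysis from CSV tables.

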