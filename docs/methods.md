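# Methods

## Measurement model

The package treats ROM measurement as a three-stage pipeline:

1. **Landmark extraction.** A pose backend maps each H×W×3 video frame
   to a partial set of named 2-D joint positions (12 tracked joints:
   left/right wrist, elbow, shoulder, hip, knee, ankle) in pixel
   coordinates (origin top-left, y downward). Joints the backend does
   not detect are *absent*, never placeholder coordinates, because
   (0, 0) is a valid pixel.
2. **Per-frame angles.** The angle at vertex joint B subtended by
   joints A and C is |(180/π)·atan2(BA×BC, BA·BC)| ∈ [0°, 180°]. The
   atan2 form is used rather than arccos of the normalised dot product
   because it stays fully conditioned near 0°/180°, where arccos loses
   ~√ε accuracy; the two agree to ≤1e-9° away from those edges (this is
   asserted over 10⁵ random pairs). The absolute value makes the result
   invariant to body side, winding direction, and any similarity
   transform or reflection of the image — the same reading a goniometer
   would give. Shoulder abduction/flexion: vertex shoulder, rays
   shoulder→elbow and shoulder→hip. Elbow flexion: vertex elbow, rays
   elbow→wrist and elbow→shoulder, reported as the supplement so that
   0° is full extension.
3. **Maximum ROM.** The task ROM is the maximum over valid per-frame
   angles; ties resolve to the earliest frame for reproducibility.

Invalidity is data, not an exception: a sample records whether its
frame failed through an absent landmark, a confidence below threshold,
or degenerate geometry (a ray shorter than `eps_len` = 1e-9 px, e.g.
two coincident landmarks). One bad frame therefore never aborts a
video; `max_rom` raises only when fewer than `min_valid` (default 1)
frames survive, and the CLI warns when less than 25 % of frames are
valid.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `confidence_threshold` | 0 (off) | landmarks below it are invalid; the marker backend emits blob-mass confidences, pose networks their heatmap peak |
| `smoothing` | none | optional odd-window median filter over *valid* samples only; edges without a full window pass through |
| `min_valid` | 1 | minimum valid frames for a ROM result |
| `eps_len` | 1e-9 px | degeneracy cutoff for direction vectors |

Raw single-frame argmax is the default because that is the literal
definition of the measurement; it is jitter-sensitive (the max of a
noisy series is positively biased), so the median filter is offered as
a documented deviation, not silently applied.

## Pose backends

The **marker backend** is a deterministic fiducial detector used for
end-to-end testing: each joint has a reference colour; pixels within a
per-channel absolute tolerance (default 30) are grouped into
8-connected components; the largest component of at least
`min_blob_area` (4 px) yields the landmark at its centroid with
confidence = component area / total matching area. Equal-size
components are broken by the smallest (row, col) top-left pixel — an
arbitrary but total order. Palette colours must pairwise differ by
more than 2× tolerance in some channel so no pixel can match two
joints. Matching is plain per-channel difference in the native colour
space: deterministic, dependency-light, and exactly reproducible.

The **dnn backend** is an adapter contract for a pretrained pose
network: construction validates that model files exist and that the
keypoint-index map covers all 12 joints or declares the missing ones;
keypoints under a 0.1 confidence threshold (configurable) are reported
absent. It is an optional extra; nothing in the package downloads
weights or requires them.

## Synthetic motion generator

The generator realises the planarity assumption the measurement makes:
a rigid two-segment arm on a fixed trunk, moving in the image plane.
Defaults — shoulder at (240, 160) on a 480×480 canvas, upper arm 80 px,
forearm 70 px, trunk 120 px — approximate a subject filmed from a few
feet away by a shoulder-height camera, and give the marker detector
plausible scales. For shoulder tasks the straight arm rotates about
the shoulder from the trunk line to `peak_angle` and back; for elbow
flexion the shoulder and elbow are fixed (mirroring the instruction to
minimise elbow displacement) and only the forearm rotates.

Two trajectory profiles: **raised-cosine** (default) uses two
half-cosine arcs meeting at `apex_frame = (n−1)//2`, which is smooth,
has a unique apex, and attains the peak *exactly* at an integer frame
for any frame count; **linear-ramp** is a trapezoid whose plateau sits
at the peak, kept to exercise argmax tie-breaking. Degradation is
applied to the exact landmarks: i.i.d. Gaussian jitter per coordinate
(`jitter_sd`, px), whole-frame dropout with probability `dropout_prob`
(how pose models typically fail; a per-joint mode exists), and a
confidence model (constant 1.0, or decaying with distance from the
canvas centre). One `numpy` Generator seeded from `seed` drives
everything, so equal seeds give byte-identical CSV output.

No published noise model exists for this setting; the jitter defaults
are engineering choices. What passing tests show is that the pipeline
is exact on its own planar model and degrades gracefully under
i.i.d. noise; they cannot show robustness to out-of-plane motion
(the known elbow-flexion weakness — deliberately not "fixed"),
clothing occlusion, or temporally correlated pose-network error.

## Agreement statistics

All statistics use sample (n−1) variances. The ICC comes from the
two-way random-effects ANOVA decomposition (subjects × raters, one
observation per cell): with MSR, MSC, MSE the between-subject,
between-rater and residual mean squares,

    ICC(2,1) agreement, single = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)

and the standard companions for consistency and average-of-k units.
Agreement/single is the default because it is the canonical ICC(2,1)
of the irr-package lineage used in clinical work; between-method
correlation is the same statistic applied to the subjects × 2 matrix
of the two methods. Values land in (−∞, 1]; a roundoff ulp above 1 is
clamped. Incomplete matrices are rejected — no missing-data ICC.

The published interpretation cutoffs for ICC leave the boundaries
0.40/0.41, 0.60/0.61 and 0.80/0.81 unassigned; bands are therefore
implemented as half-open intervals closed at the lower printed cutoff
([0.20, 0.40) questionable, …, [0.80, 1] excellent), making the
labelling total. The same convention applies to the CV bands (<10 %
low, [10, 20) moderate, ≥20 % high variability).

Mean difference defaults to the mean of |xᵢ−yᵢ| because published
method-comparison tables report magnitudes; the signed mean (which
commutes with rater averaging) is available. The paired t test is the
two-sided Student test on x−y and is refused (rather than returning
NaN) for zero-variance differences. The sample-size routine uses the
normal approximation n = ⌈((z₁₋α/₂ + z_power)·σ/δ)²⌉ — with δ=5°,
σ=9°, α=0.05, power=0.85 this gives n=30 — because that closed form is
what paired power analyses in this literature report; a noncentral-t
iteration (`method="t"`, giving 31–32 for the same inputs) is provided
for users who want the conservative answer. Power 0.5 (z=0) is
accepted as the boundary case.

## Numerical and design choices

- Angles are clamped to [0, 180] after the supplement transform to
  absorb one-ulp overshoot; angle equality tests run at 1e-9°.
- CSV round trips write coordinates with `repr`, so values survive
  exactly; the landmark dialect encodes an all-absent frame as a
  single row with an empty joint column, keeping frame indices
  contiguous and dropout sequences round-trippable.
- Frame indices are 0-based; timestamps are derived as index/fps, and
  fps is always explicit metadata (camera frame rates vary).
- The CLI replaces any hosted/web deployment: the method, not the
  deployment, is the artifact. Exit codes: 0 success, 2 bad
  input/config, 1 internal error.

## Problem sizes

The test and acceptance runs use desk-scale problems chosen to make
the properties sharp while staying quick: 41–61-frame clips, 480×480
rendered frames, 50 seeded replicates per jitter level, 100 random
matrices (n ≤ 12, k ≤ 8) for the ICC oracle, and 10⁵ vector pairs for
the angle-formula comparison.

## Known limitations

- Strictly 2-D: out-of-plane motion biases angles, most visibly for
  elbow flexion performed toward the mouth; no 3-D correction is
  attempted.
- Single subject per frame; no tracking, calibration or undistortion.
- The synthetic generator's noise is i.i.d. and its renderer is
  schematic (disks/sticks), so agreement with its ground truth bounds
  only the algorithmic part of the error budget, not pose-network
  accuracy on real video.
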