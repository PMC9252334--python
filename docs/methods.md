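# Methods

## Overview

`vidgait` computes spatiotemporal gait features from joint trajectories
produced by 2D (or monocular 3D) human pose estimators, and quantifies how
well those features agree with a reference modality (in a clinic, an
instrumented pressure walkway; here, a simulator's exact ground truth). The
pipeline is: confidence gating → gap interpolation → zero-phase low-pass
smoothing → spatiotemporal density clustering of each ankle track into
stances → heel strikes as stance onsets → per-bout features → rank-correlation
validity statistics. A parametric 3D walker projected through a pinhole camera
supplies test data with known truth, including the clinically important
failure regime of very short, shuffling steps.

## Preprocessing

Pose-estimator confidence scores are not calibrated across libraries, so the
low-confidence gate is keyed by estimator tag (defaults 0.50 AlphaPose, 0.15
Detectron, 0.65 OpenPose — values that leave roughly <10% of timesteps to be
interpolated in practice). Gated or absent samples are filled by linear
interpolation between adjacent valid timesteps; interpolation is exact on
locally linear motion, which is the operative regime at 30 Hz. Leading and
trailing gaps are never extrapolated (an extrapolated ankle would corrupt
heel-strike geometry); interior gaps longer than `max_gap_frames` (default 15,
i.e. 0.5 s at 30 Hz — half a conservative step cycle) are declared track
breaks. Each contiguous valid segment is then smoothed with a zero-phase
second-order low-pass Butterworth filter, cut-off 8 Hz, run forward and
backward with odd-reflection padding. The double pass squares the magnitude
response — an 8 Hz component is attenuated to exactly half amplitude — and
introduces no group delay, so event timing is unbiased. Segments shorter than
three pad lengths are refused (`bout too short to filter`).

## Stance detection and heel strikes

During stance the ankle keypoint is stationary on the ground, so a foot's
samples, viewed as points in (time, image position), form one dense
spatiotemporal blob per stance. ST-DBSCAN generalizes density clustering with
a joint neighborhood: two points are neighbors when they are within
`eps_spatial` in space **and** `eps_temporal` in time; points with at least
`min_pts` neighbors (self included) are cores, and clusters grow by the usual
core/border expansion. Expansion visits points in time order and cluster ids
are assigned in discovery order, so labels are deterministic. The heel strike
is the first timestep of each retained stance.

Parameter defaults were chosen by validating candidate settings against the
synthetic recovery suite (exact step-count recovery and ±1-frame strike timing
on clean walks; rank-correlation of cadence under pixel noise; reproduction of
short-step undercounting):

* `eps_spatial` — auto-derived as **0.12 × the bout's median hip width** in
  pixels, keeping the radius commensurate with apparent body scale;
* `eps_temporal = 0.35 s`; `min_pts = 12` (0.4 s of support at 30 Hz);
* minimum stance duration `min_pts / fps`; clustering in raw camera space
  (per-frame hip-width normalization exists but is off by default, preserving
  the realistic far-field merging behavior).

Three refinements sit between the raw clusters and the heel-strike events.
They address two geometric facts about projected gait that plain density
clustering cannot see:

1. **Start censoring.** One foot is always planted when a segmentation window
   opens, so the first analyzed frame can sit inside a stance whose true
   onset precedes the bout. A stance whose first frame equals the first
   analyzed frame is discarded: its first *observed* timestep is a window
   edge, not a heel strike.
2. **Contact-run refinement.** Ground contact is contiguous in time, but the
   projected swing path can re-enter the spatial radius before landing. Most
   visibly when walking away from the camera, the rising-foot clearance term
   and the receding-depth term cancel in the image, so the swing foot's pixel
   path crosses — and dwells near — its future landing position several
   frames early. Cluster members are therefore reduced to their longest
   near-contiguous frame run (gaps over 2 frames split a run).
3. **Contact-onset gate.** The clustering radius must tolerate measurement
   noise, so at far camera distances a few slowly-landing pre-contact frames
   still adhere to the cluster edge. Within the refined run, the stance is
   the longest contiguous stretch of frames within
   `max(eps/4, 3 × median deviation from the cluster median)` of the cluster
   median. On clean trajectories the gate is tight and the onset snaps to the
   true contact frame; under noise the measured plateau scatter widens the
   gate and nothing is trimmed. The stance position (used for step width) is
   the median over the gated run.

Same-foot clusters with overlapping frame ranges are merged. Manual
annotations bypass clustering entirely: the event time is the labelled frame
and the position is the smoothed trajectory value there; annotations falling
in untrackable gaps are dropped, since no spatial data exists to attach.

Merging the two feet yields a time-ordered strike list; consecutive same-foot
strikes (a missed opposite-foot event) invalidate the intervening step but
not the bout, and simultaneous strikes are ordered left-first and flagged.

## Gait features

With `n ≥ 3` strikes at times `t_1 < … < t_n`:

* `n_steps = n` (footfall count, comparable across modalities);
* `cadence = 60 (n−1)/(t_n − t_1)` steps/min;
* step time `t_{i+1} − t_i` over valid opposite-foot pairs; its CV is
  `100·sd/mean` with the sample (n−1) standard deviation — the safer choice at
  the small per-bout step counts — and a `ddof` switch is exposed;
* step width `|Δx|` between consecutive opposite-foot strike positions,
  divided by the hip width at the later strike's frame (the moment both feet
  are grounded); pixel distances carry no units, and per-frame hip-width
  normalization cancels perspective scale, so video widths are unitless;
* with metric 3D input additionally step length `|Δz|` (m) and speed
  (first-to-last strike depth displacement over elapsed time, m/s).

Bout inclusion mirrors clinical practice for this method: at least 3 detected
strikes, and — in the validity analysis — exclusion of bouts whose *reference*
step count exceeds 20, the regime where clustering-based detection is known to
undercount. Walking direction can be inferred from the robust (Theil–Sen)
trend of apparent hip width (growing = toward the camera); an explicit label
in the bout metadata always wins.

## Validity statistics

Feature vectors from repeated clinical bouts are typically non-normal, so the
battery reports a D'Agostino-Pearson normality p-value for each vector
(scipy's implementation of the published skewness/kurtosis transforms) but
always uses Spearman rank correlation: rho is the Pearson correlation of
average ranks, with a right-tailed test of positive association. For n ≤ 8
the p-value is exact by full permutation enumeration; above, the
t-approximation `t = rho·√((n−2)/(1−rho²))` with n−2 df. Bonferroni
adjustment multiplies by the number of comparisons sharing a reference
feature (18 for the 2D battery, 6 for the 3D one; both configurable).
Paired treatment states (medication/stimulation ON vs OFF) are compared with
a two-sided Wilcoxon signed-rank test: zero differences dropped, average
ranks for ties, exact 2ⁿ sign-pattern enumeration for n ≤ 12, and a normal
approximation with continuity and tie corrections above. The step-count
cutoff sweep regresses video counts on reference counts (OLS) for every
admissible maximum reference count and reports R² and slope; mean, mean
absolute, and percent differences are reported for the unit-comparable
features (step count, cadence, step-time CV).

A note on the exact Spearman branch: the right-tailed permutation p-value is
inclusive, `P(rho_perm ≥ rho_obs)`; a perfectly anti-correlated n=4 sample
therefore has p = 1, and a perfectly correlated one p = 1/24.

## Synthetic walker and camera

The simulator emulates a clinical recording: a walker covers a 6 m walkway in
front of a tripod camera (640×480, 30 Hz, focal 600 px, height 1.2 m, pitch
5° down) placed 2.5 m before the near end — the offset keeps ankle keypoints
inside the frame for the whole walk, matching the practical constraint that
near-camera segments are unusable. Strike schedules are drawn from truncated
normals (±3 sd, positive; an explicit range for the shuffling regime) for
step time, length and width, alternating feet, walking until a strike lands
at or beyond the walkway end. Each ankle is stationary at its strike position
during stance (60% of its step cycle, the physiological norm), then swings to
the next position with a smoothstep forward profile and sinusoidal vertical
clearance. The bout opens with a 0.25 s lead-in before the first recorded
strike, and each foot carries a virtual pre-bout strike, so the walker enters
mid-gait exactly as a segmented clinical bout does. Hips ride at ±15 cm
lateral offsets (hip width 0.30 m) at 0.90 m height on a pelvis that advances
between the feet. Joints are projected through the pinhole model (or emitted
in meters), then Gaussian pixel noise and confidence dropout (failed
detections get both low confidence and corrupted coordinates) are applied;
joints projecting outside the image get confidence 0. All randomness flows
through a single PCG64 generator, so a seed fixes a bout bit-exactly.

Cohort presets (between-bout sds perturb each bout's means; within-bout sds
are step-to-step):

| preset | step length (m) | step time (s) | clearance (m) |
|---|---|---|---|
| normal | 0.55 ± 0.04 (between 0.07) | 0.55 ± 0.03 (between 0.07) | 0.12 |
| shuffling | 0.108 ± 0.054, truncated to [0.048, 0.192] | 0.45 ± 0.03 | 0.03 |
| off-state | 0.45 ± 0.04 | 0.60 ± 0.03 | 0.08 |

The shuffling step-length distribution is the short-step regime in which
clustering-based detection fails; its reduced clearance encodes the defining
kinematic of shuffling gait — feet that barely leave the ground — which is
what makes short steps spatially unresolvable from a frontal camera. The
`mixed` preset is half normal / half shuffling; `on_off_paired` draws each
synthetic subject's parameters once and applies an additive treatment effect
(default +0.10 m step length, −0.05 s step time) to the ON bout.

What the simulator does **not** emulate: turning phases, multi-person scenes,
occlusion-correlated (non-independent) dropout, estimator-specific bias
fields, lens distortion, rolling shutter, and soft-tissue/footwear artifact.
Passing recovery tests on this generator therefore demonstrates the internal
consistency and geometric correctness of the pipeline, not clinical accuracy
on real video.

## Numerical and design notes

* Frames are 0-based; frame *i* is at *i/fps* s. Image x grows rightward, y
  downward; 3D input is x lateral, y vertical, z depth.
* Multi-person JSON frames keep the detection with the highest mean keypoint
  confidence.
* The keypoint CSV round-trips floats exactly (shortest-repr writing,
  round-trip parsing).
* Degenerate inputs fail loudly and specifically: untrackable core joints,
  bouts too short to filter, undefined correlations on constant vectors,
  all-zero Wilcoxon differences, zero hip width.
* Problem sizes in the tests and the acceptance script (50-bout recovery
  cohorts, 30-bout shuffling cohorts, 20 000 normality replicates, 100 random
  clustering instances) were chosen to make the Monte-Carlo error small
  relative to the tolerances they are checked against.

## Known limitations

* Strike timing inherits the camera's temporal resolution (±1 frame at 30 Hz
  ≈ ±33 ms) and degrades with distance; beyond ~9 m with this camera the
  contact-onset gate can no longer isolate the landing frame reliably.
* Very short steps are intrinsically unresolvable in far-field pixel space;
  the package reproduces (rather than solves) that failure, and the 20-step
  reference cap is the corresponding guardrail for validity analyses.
* Repeated bouts from one subject are treated as independent in the
  correlation analysis, a simplification inherited from the bout-level study
  design.
* The walkway-style reference normalizes widths by a body scale (here the
  known hip width; a pressure walkway would use foot length). Rank
  correlations are invariant to this monotone scaling, but absolute width
  values are not comparable across modalities.
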