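# Methods

## The monitoring model

`posedelta` quantifies in-home postural change from the output of a
single-person pose estimator observing a fixed room once per second.  Each
observation is 17 named body keypoints with pixel coordinates and
confidence scores.  Rather than tracking individual joints, the method
reduces every pose to its bounding box — the axis-aligned rectangle over
the keypoints — and tracks three per-second change metrics between
consecutive boxes:

* **ΔHeight** `= |h_t − h_{t−1}|` — box-height change;
* **ΔWidth** `= |w_t − w_{t−1}|` — box-width change;
* **ΔDistance** `= ‖c_t − c_{t−1}‖₂` — Euclidean displacement of the box
  center.

The three channels are read as three care-relevant parameters: posture
transitions such as standing up or sitting down change the box height
(**pose conversion**); in-place limb and hand activity widens and narrows
the box (**body movement**); locomotion displaces the box center
(**positional changes**).  This channel→parameter mapping is the package
default and is configurable (`DEFAULT_CHANNEL_MAP`), because the
correspondence is a modelling assumption, not a law: a person waving both
arms vertically would register on ΔHeight.  Deltas are absolute
magnitudes — the evaluating data are nonnegative by construction — and the
center is used as the distance anchor because it is the only choice
invariant under box-preserving translations.

### Frame validity and gaps

A frame enters the analysis only if its overall confidence reaches
`score_threshold` (default **0.5**, the operating threshold of the
deployment the package models) and, under `multi_person_mode="exclude"`,
only if exactly one person is detected.  The `"keep"` mode retains
visitor frames: their inflated deltas then measure care-time variation
rather than being noise.  Consecutive *valid* frames are paired; a pair is
used only if its timestamp gap is at most `max_gap` seconds (default
**2**).  Bridging longer gaps would fabricate motion out of an absence
(person left, lights off), so such pairs emit nothing.  Per-keypoint
filtering (`min_kp_score`) exists but defaults to 0: the box is built from
all 17 reported keypoints.

### Aggregation

The evaluating data are per-minute means: records are partitioned into
non-overlapping `[t, t+60)` windows aligned to the wall-clock minute grid
and each channel is averaged per window — a simple moving average of
window 60 s sampled once per minute, which is what one-value-per-minute
charts imply.  A trailing sliding variant is available
(`summarize_minutes(..., sliding=True)`) but is not the default.  Empty
minutes are **omitted, never zero-filled**: a zero would conflate "present
but motionless" with "absent", and absent seconds are never stored at all.

Daily summaries accumulate the raw per-second deltas per civil day of the
timestamps (no timezone arithmetic) and convert the count of valid frames
into **active hours** = frames / 3600 — each stored frame stands for one
observed second, so the amount of stored data *is* the observed time.
Day totals are defined over per-second records rather than per-minute
means; the two differ only by the partial-minute boundaries.

Presence intervals (maximal runs of valid frames separated by gaps longer
than `min_gap`, default 300 s) expose the waking / break / sleep structure
of a day without any further modelling.

### Dominant-channel classification

A delta record (or a minute of averaged deltas) is labelled with the
parameter whose channel is strictly largest; an all-zero record gets the
`None` sentinel ("no postural change").  Ties are broken by a fixed
priority — positional change > body movement > pose conversion — ordered
by how specific the evidence is: center displacement cannot be produced
by pure shape change, whereas height and width co-vary under many motions.

## The agreement protocol

To evaluate a pose estimator's boxes against ground-truth annotations,
the same three formulas are applied *across sources for the same image*:
K_height, K_width, K_distance between the predicted and the reference box.
The per-image K values are binned into `K ≤ 10`, `10 < K ≤ 30`, `K > 30`
pixels (edges configurable, upper edges closed) and reported as
percentages of all images, rounded to two decimals.  Image ids present in
only one set are an error, never silently dropped.  An alternative
reading — treating the image collection as a pseudo-time series and
differencing the per-pair metrics between sources — is implemented behind
`mode="sequential"` for completeness, but the per-image pairing is the
default because an unordered image collection has no meaningful temporal
adjacency.

## The simulator

The simulator generates the study conditions end to end: a 320 × 240 px
scene, one frame per second, one scripted person.  A stylized articulated
figure provides 17 keypoint offsets per activity:

| activity | box shape | expected dominant channel |
|---|---|---|
| stand | ~94 × 30 px (tall) | none (static) |
| sit | ~55 px tall (~60 % of standing) | none (static) |
| lie | ~95 × 12 px (wide) | none (static) |
| walk | standing figure translating | ΔDistance |
| hand_activity | standing figure, wrists/elbows swinging | ΔWidth |
| absent | no frame emitted | — |
| visitor | subject pose with `persons = 2` | — |

Numerical choices:

* **Walk** moves the figure anchor at constant speed (default 40 px/s
  ≈ 0.5 m/s at the 4 m ≈ 320 px room scale) and reverses a velocity
  component *before* any step that would cross the room margins, so every
  per-second displacement has exactly the configured magnitude — the
  closed-form property tests rely on this.
* **Hand activity** oscillates both wrists outward by
  `amp · (1 − cos 2πφ)/2` (amplitude default 12 px, period 4 s), so box
  width changes by a fixed amount every second while height and center
  stay fixed.
* **Transitions** between differing figure templates are linearly
  interpolated over a 3 s ramp, splitting e.g. the stand→sit height change
  into three equal finite steps; ramp seconds are flagged in the ground
  truth.
* **Noise** is i.i.d. Gaussian per coordinate per second (default sd
  2 px — a realistic jitter scale for keypoint estimates of a ~150 px
  figure), clipped to the frame.
* **Confidence scores** are Beta-distributed with configurable mean
  (default 0.85) and concentration (default 100).  At the defaults the
  probability of a frame falling under the 0.5 validity threshold is
  negligible (≈ 10 standard deviations), which is what makes the
  active-hours exactness checks deterministic in practice; lowering the
  concentration exercises the threshold path.
* The whole run is driven by one `numpy` Generator seeded from
  `SimConfig.seed`: identical configs produce byte-identical streams.

Ground-truth recovery is scored on **unambiguous minutes**: the 60 s of a
minute all carry the same single-person activity, none is a transition
second, and the activity has a defined dominant channel (walk or hand
activity).  Static minutes are excluded because under noise their deltas
are pure jitter with no correct non-trivial label, and mixed or visitor
minutes have no single truth.  The bundled 2 h benchmark schedule
(`demo_schedule()`: four 30-minute blocks mixing stand, walk, sit, hand
activity, lie and absence) yields 56 unambiguous minutes.

### What the simulator does not emulate

Real estimator error is structured — occlusion drops limbs, confuses
left/right, and produces outliers far beyond Gaussian jitter; real people
move continuously rather than in scripted blocks; camera perspective makes
pixel scale depend on room position.  Passing the recovery tests therefore
shows that the *pipeline* (filtering → deltas → minute means → dominant
channel) is correct and well-conditioned at realistic noise scales, not
that the method achieves any particular accuracy on real footage.
Reproducing a published agreement table for a specific estimator would
require that estimator's weights and the original annotated image set,
both outside this package's scope.

## Problem sizes used by the test suite

The default suite simulates the 2 h benchmark schedule (7200 s) at noise
sd 0 and 2, a two-day presence schedule (5400 s), and one full synthetic
24 h day (86 400 scheduled seconds, ~80 000 emitted frames) for the
end-to-end pipeline timing check; the whole suite runs in well under five
minutes on one CPU.

## Known limitations

* One subject, one camera: multi-person scenes are handled only by the
  keep/exclude policy on the person count, not by tracking identities.
* Pixel units throughout; no calibration to metric distances.
* Day boundaries follow the timestamps' own clock; streams spanning a
  timezone change would need pre-normalized timestamps.
* The channel→parameter mapping is heuristic for unusual motions; it is
  exposed as configuration rather than hard-coded.
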