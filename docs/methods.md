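# Methods

This note records the models, conventions and design choices behind
`schooltrack`, in the spirit of a methods section: what is assumed,
what is tunable, and what passing tests do and do not demonstrate.

## Coordinate and angle conventions

Coordinates are continuous, 0-based, pixel-center registered: pixel
`(i, j)` carries its intensity mass at the integer position `(i, j)`.
The image `y` axis increases downward, and all angles are radians
wrapped to `[0, 2π)` under that convention (so "up" on screen is
3π/2). All CSV output serialises angles this way.

## Grid split and duplicate removal

High-resolution frames are split along their longer axis into `n`
grids; each grid extends `overlap_px` past its partition boundary into
each neighbour, so interior neighbours share a stripe of
`2·overlap_px`. A 1920×1080 frame split in two with a 30 px margin
yields grids covering x-ranges [0, 990) and [930, 1920) — each 990 px
wide, matching the detector-input geometry this layout reproduces.
Detections from the stripe appear twice after reassembly; two boxes are
the same fish when intersection-over-minimum-area exceeds 0.4
(strictly). Each duplicate cluster keeps its largest box (ties broken
by lower `(x_min, y_min)`): the larger delimitation is the more
complete view of the head. Greedy largest-first elimination makes the
operation deterministic and idempotent.

## Head geometry from intensity moments

The head centre is the intensity centroid `(M10/M00, M01/M00)`. The
head *tip* is defined through the second-moment ellipse: with
`λ_max, u` the leading eigenpair of the central second-moment matrix,
the tip sits at one major semi-axis length `2√λ_max` from the centroid
along `±u`. The sign is chosen by the third central moment along `u`:
a backlit fish head is a short, heavy lobe with a long dim taper behind
it, so the head lies opposite the skew tail (`sign = −sign(μ₃)`).
Isotropic patches (eigenvalue gap below `isotropy_tol`) have no defined
axis and are rejected rather than guessed. The motion-direction angle
is the five-branch arctangent of the centroid→tip vector; the branch
form equals a quadrant-aware `atan2` after wrapping, which the tests
verify to 1e−12 over direction sweeps.

## Motion model and filter

Each fish is filtered independently with a discrete constant-velocity
model on `[c_x, c_y, c_θ, ċ_x, ċ_y, ċ_θ]`:

* `F` is identity plus `dt` on the velocity off-diagonal; `dt` defaults
  to 1 frame (fixed-rate 30 fps video; set `dt` in seconds if you
  rescale).
* `H` selects position and angle.
* `R = diag(24.1, 24.8, 22.7)` — the reference observation-noise
  covariance for moment-based head measurements (px² in x/y). Note the
  angle entry is dimensionally generous for a circular quantity: a
  Gaussian with variance 22.7 rad² wraps to a nearly uniform heading
  error, so the measured angle carries little information and the
  filter weights it accordingly. This is a property of the reference
  constants, not a tunable of this package.
* `Q = q · diag(dt⁴/4, dt⁴/4, dt⁴/4, dt², dt², dt²)` — a
  white-acceleration (near-constant-velocity) process noise with a
  single intensity knob, default `q = 1 px²/frame⁴`. This keeps the
  filter responsive at fish accelerations of a few px/frame² without
  tracking measurement noise.

The predict/update steps are the standard Kalman forms. The angle
component of the innovation is the minimal signed circular difference
in (−π, π], and the state angle is re-wrapped after every step; inside
one innovation the filter is linear, so all linear-filter guarantees
(symmetric PSD covariance, Riccati convergence) hold and are tested
against independent oracles.

Track initialisation takes the first measurement with measurement-level
position/angle uncertainty and a weakly informative zero-velocity prior
(variance 100 px²/frame², 10 rad²/frame²). Because that first reported
point would otherwise be the raw measurement, the birth point is
retrodicted by one step of the fixed-interval smoother
(`x₀|₁ = x₀|₀ + C(x₁|₁ − x₁|₀)`, `C = P₀Fᵀ(FP₀Fᵀ+Q)⁻¹`) as soon as the
track is confirmed, roughly halving its error variance
(`smooth_birth`, on by default).

## Association

Costs couple Euclidean distance with a distance-scaled angle term,
`w₁·d + w₂·d·Δθ/2π`, with `Δθ` the circular gap in [0, π]. With the
default `w₁ = w₂ = 1` the angle term is a bounded (≤ d/2) modulation:
it breaks ties between nearby candidates but cannot override geometry,
which matters here because the measured heading is noisy (see above).
Assignment is solved to global optimality (Hungarian algorithm;
rectangular matrices are solved directly). A post-solve cost gate
(default 50 px-equivalents; `∞` disables) strikes implausible matches
and returns both sides to the unmatched pools — without it, a fish that
vanishes lets its tracker latch onto arbitrarily distant detections
during dropouts.

## Track lifecycle

* Matched tracks record the **posterior** state, not the raw
  detection: the trajectory is the filter's estimate of the path.
* Unmatched tracks coast on prediction; coasted points are flagged
  `interpolated` so downstream speed/distance analyses can keep
  gap-free series. If the track is later interrupted, its trailing
  coasted points are trimmed — they were never confirmed — and the
  interruption endpoint τ stores the last *observed* position and
  time.
* `β = 15` frames of consecutive misses interrupt a trajectory.
  Occlusions longer than that carry a high identity-swap risk without
  an appearance model, so coasting further mostly manufactures errors.
  `β = ∞` disables interruption.
* New tracks must re-match within their first `confirm_frames = 2`
  frames or they are discarded as spurious single-frame detections
  (set to 1 to disable).
* Reconnection is a post-pass: interruptions sorted by `t_end` each
  claim the nearest unclaimed later start with `Dist < d` (strict;
  `d = 0` disables; `max_gap` optionally bounds the bridged time).
  Merged tracks keep the interrupted track's id, and bridged gaps are
  linearly interpolated with flagged rows (`interpolate_gaps`).

## Evaluation metrics

Detection TP/FP/FN use one-to-one minimal-total-distance matching
(Hungarian on pairwise distances) with matches beyond the correctness
radius rejected; the radius defaults to 15 px everywhere (detection
matching and CTR alike). `Num_GroundTruth` and "total number of
targets" are both `n_fish × n_frames`: every fish is a target in every
frame. Occlusion events are derived from ground-truth geometry:
frames where ≥ 2 head boxes overlap (intersection-over-minimum > 0),
connected per frame into components and merged across consecutive
frames sharing a participant. An event counts as successfully detected
(for ODR) when every participant re-acquires a detection within one
frame of the event's end (configurable).

CTR counts fish-frames whose fish received a one-to-one tracker match
within the radius; identity exchanges are not penalised, so CTR is
invariant to track relabeling. CIR judges each occlusion event by
comparing fish→track identity maps at the nearest frames before and
after the event at which all participants are ≥ `separation_px`
(default 20 px) apart — identity is not judged mid-clump. Events with
no separated pre-event frame (fish already overlapping when the video
starts) have no pre-occlusion identity to preserve; they are excluded
from the CIR denominator and reported separately. With zero occlusion
events CIR is undefined and reported as such, never as NaN.

Reports print at 4 decimals; internal values keep full precision.

## The synthetic generator

The generator emulates an overhead camera on a backlit tank, not real
fish: headings follow a wrapped-Gaussian correlated random walk with
persistence (default 0.95 → turn σ ≈ 4.5°/frame), per-fish speeds are
drawn once around the configured mean (cm/s, converted through
10 px/cm and 30 fps; the reference regimes span 6.37–10.22 cm/s, i.e.
~2–4 px/frame), and walls reflect. Feeding mode adds a heading pull
toward a central attractor and √2-fold turn noise, reproducing the
agitated, centre-clumped swimming of a feeding school. Measurement
corruption adds Gaussian noise with the `R` covariance, drops occluded
participants' detections with probability
`dropout_prob_in_occlusion = 0.5`, and can inject false positives and
near-duplicate boxes. Occlusion events come from the same box-overlap
rule the metrics use (head-box side `occlusion_radius = 14 px`), so
simulator bookkeeping and metric counting agree by construction. One
`numpy` generator stream seeds everything; identical config + seed is
bit-identical output.

What the generator does **not** model: appearance (no re-identification
cue exists or is needed by this tracker), hydrodynamic or social-force
schooling, body deformation, uneven illumination, or detector-specific
failure modes. Passing end-to-end tests therefore demonstrates that the
tracking and evaluation machinery is correct under the stated motion
and noise assumptions — not that any particular detector will achieve
these scores on real video.

## Problem sizes in the test and acceptance runs

The bundled runs use 3–13 fish over 300–900 frames: small schools in
the physical 45×25 cm arena and larger groups in proportionally larger
arenas (mirroring the high-resolution recordings the larger regimes
come from), with ten seeded replicates where averages are reported.
These sizes exercise every code path (occlusions, dropouts,
interruption, reconnection) while keeping the whole suite under a
minute on one CPU.

## Numerical choices and degenerate inputs

* Posterior covariances are symmetrised after every update; PSD-ness is
  property-tested over 1000 cycles.
* All-zero patches, coincident tip/centroid, isotropic patches,
  zero-area boxes, mixed-frame detection batches and non-contiguous
  frame streams raise `ValueError` rather than propagate NaNs.
* Dedup ties (equal areas) break on `(x_min, y_min)`; assignment ties
  follow the Hungarian solver's deterministic order; reconnection ties
  take the first-spawned start.
* Ratio metrics with zero denominators are reported as `None`
  (undefined), never NaN.

## Known limitations

* No appearance model: identity through occlusions rests entirely on
  motion prediction, so long (> β) or dense occlusions can swap
  identities; adding a re-identification stage is the natural
  extension.
* The measured heading is nearly uninformative at the reference noise
  level, so the angle term of the cost contributes little under these
  conditions (it matters with better angle measurements).
* Reconnection is greedy in `t_end` order, matching the reference
  procedure — it is not a globally optimal fragment-linking.
* The simulator's motion model is deliberately minimal; quantitative
  scores on simulated data should not be read as predictions for real
  video.
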