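# Methods

This note defines the quantities the package computes, the synthetic-motion
model used to validate them, and the reasoning behind each default.

## 1. Input model

A recording is a sequence of frames at `fps` frames per second. Each frame
holds zero or more detected skeletons in the OpenPose BODY_25 convention: 25
keypoints of `(x, y, confidence)` with confidence 0 marking an undetected
keypoint. Three keypoints are analysed: neck (index 1), right wrist (4) and
mid hip (8). A manifest assigns activity names to time intervals
`[start_s, end_s)`; a composite **Table-play** activity is the union of all
segments whose activities keep the child at the table (everything except
free play, response-to-name, balloon play, bubble play, and snack). Frames
are assigned to segments half-open, so back-to-back segments never share a
frame. A video-metadata record supplies `fps`, the image resolution, and the
analysis origin **A** — the centre of the table edge next to the child.

## 2. Child selection

Multi-person detections are reduced to one child track by nearest-neighbour
gating on the neck:

* In each frame, candidates are skeletons whose neck confidence is at least
  `min_confidence` (default 0.1).
* The candidate nearest the current anchor is selected if the jump does not
  exceed `gate_radius`; the anchor then moves to its neck.
* Frames with no admissible candidate are gaps. The anchor is held through
  gaps of up to `max_gap` frames (default 20, i.e. 2 s at 10 fps); after a
  longer gap the track re-initialises to the candidate nearest
  `init_position` (the child's seat), without the jump gate.
* Wrist and hip samples are read off the selected skeleton when their own
  confidence clears `min_confidence`; their dropouts do not affect the neck
  track.

**Gate radius default.** The gate defaults to 10 % of the image diagonal
(`FilterParams.for_video`). A materially larger gate admits physically
implausible per-frame jumps at 10 fps and lets a single-frame occlusion hand
the track to a bystander with no recovery path, while 10 % (≈147 px at
720p) still covers the largest plausible per-frame displacement of a child.

**Mismatch audit.** `mismatch_rate` samples up to `n_audit` (default 100)
selected frames uniformly without replacement and reports the fraction whose
ground-truth identity is not the child — the automated analogue of a manual
spot check of the selection overlay.

## 3. Movement features

With `A` the origin and `(x_n, y_n)` the keypoint position at frame `n`:

* Pixel distance (PD): `X_n = x_n − A_x`, `Y_n = y_n − A_y`,
  `L_n = √(X_n² + Y_n²)`.
* Instantaneous pixel velocity (IPV): `δX_n = x_{n+1} − x_n`,
  `δY_n = y_{n+1} − y_n`, `δL_n = √(δX_n² + δY_n²)`, defined **only** when
  frames `n` and `n+1` are both present and consecutive — a step spanning an
  occlusion gap is unobserved, not a large velocity.

Per (activity, keypoint) the four features are the mean and standard
deviation of each family: `L_mean`, `L_std`, `dL_mean`, `dL_std`. Both
standard deviations divide by the number of contributing samples (population
form), matching the defining formulas. Composite activities pool PD samples
over member segments and concatenate IPV steps computed *within* each
member, so no step crosses a segment boundary. A feature whose sample count
falls below `MIN_SAMPLES = 10` is absent (`None`/NaN), never zero.

## 4. Correlation analysis

* **Redundancy (Pearson).** Three groupings of PCC matrices are available:
  between the four features at fixed (activity, keypoint); between
  activities at fixed (keypoint, feature); and between keypoints at fixed
  (activity, feature). The prune operates on the last: within each
  (activity, feature) block whose pairwise PCCs all reach the threshold
  (default 0.95, "almost 1"), only the neck variant is retained — the neck
  being the most reliably visible keypoint — otherwise all keypoints are
  kept. Correlations use pairwise-complete observations; constant columns
  yield NaN.
* **Score correlation (Spearman).** Each feature column is correlated with
  the ordinal score (average ranks over ties, two-sided t-approximation
  p-value; at n = 52 the approximation is adequate). Raw p-values are
  Benjamini–Hochberg adjusted *within each activity family*
  (statsmodels `fdr_bh`; an independently coded step-up procedure serves as
  the test oracle).
* **Power.** `correlation_power(n, r, α)` uses the Fisher-z approximation
  with small-sample bias correction: effect `z_r = atanh(r) + r/(2(n−1))`,
  critical correlation `r_c = √(t²/(t² + n − 2))` from the two-sided t
  critical value at `n − 2` df, and normal tail probabilities at SD
  `1/√(n−3)`. At (n = 52, r = 0.50, α = 0.05/4 = 0.0125) this gives 0.914.
  `pingouin.power_corr` and a 100k-replicate Monte-Carlo simulation agree
  and serve as independent cross-checks in the tests.
* **Planned comparisons.** `alpha_for_planned_comparisons(0.05, 4) = 0.0125`
  splits the family level over the four planned feature tests.

## 5. Synthetic cohort generator

Real recordings are unavailable, so validation runs on generated streams
with ground-truth identity labels.

**Body motion.** Per axis the child's gross position follows a
mean-reverting AR(1) process around the seat,
`z_t = φ z_{t−1} + ε_t`, parameterised by two interpretable pixel scales:
the stationary spread `s_x` and the per-frame step SD `s_d`, via
`φ = 1 − s_d²/(2 s_x²)` and `σ² = s_x²(1 − φ²)`. Both scales grow with the
clinician score (defaults: `s_x` = 30/60/120 px, `s_d` = 9/18/36 px for
scores 0/1/2), so PD features track `s_x` and IPV features track `s_d`.
Trajectories are reflected back inside the image (a detector cannot report
a person outside the frame). During balloon and bubble play — presses that
invite the child away from the table — the excursion scale is boosted ×1.5.
Validation accepts non-decreasing score scales so that flat, zero-effect
null models (`null_motion_model`) remain expressible for type-I checks.

**Keypoints.** Neck and wrist ride the body trajectory; fixed anatomical
offsets place the wrist and hip relative to the neck, plus 2 px detection
jitter. Two per-child idiosyncrasies reproduce the empirically expected
redundancy structure (PD features interchangeable across keypoints, IPV
features not):

* *Wrist fidget* — an AR(1) with negative lag-1 correlation (φ = −0.6) and
  per-child log-normal scale (median 6 px, σ = 0.35): oscillatory hand
  motion adds velocity with little positional spread.
* *Hip smoothing* — the hip follows an exponentially smoothed copy of the
  body path with per-child factor α ~ U(0.25, 0.8): a seated child's hip is
  anchored to the chair and attenuates fast upper-body motion, so hip
  velocity is a child-specific fraction of neck velocity while hip position
  stays nearly interchangeable with the neck's.

Each of the three keypoints drops out independently with probability 0.03
per frame (occlusion), emitting confidence 0.

**Distractors.** Slow AR(1) skeletons (spread 15 px, step 4 px) at fixed
stations away from the seat, detectable only in alternating exponential
bouts (mean 20 s present / 10 s absent) as bystanders drift behind
furniture or out of view. The intermittency matters: a permanently visible
distractor that ever captured the track would hold it forever, which is
neither realistic nor consistent with the low observed mismatch rates the
generator is calibrated to (errors concentrated in the most active
children, cohort average on the order of a few percent).

**Cohorts.** The default cohort mirrors the reference group sizes
(18/25/9 children at scores 0/1/2, n = 52) at 10 fps. Activity durations
are drawn per child around published session means, scaled by
`duration_scale` (default 0.1 — "desk scale" — so a whole cohort simulates
in seconds; 1.0 reproduces full-session lengths). Per-child randomness is
spawned deterministically from `(cohort seed, child index)` via
`numpy.random.SeedSequence`, so cohorts are reproducible and children
independent; each child's stream uses three child-local substreams
(timeline, per-child traits, scene).

## 6. Validation design notes

* **Desk scale vs estimator noise.** At `duration_scale = 0.1` the
  Table-play window is ~70 s; the AR(1) autocorrelation time leaves `L_mean`
  with only a handful of effective samples per activity, which attenuates
  cross-keypoint PCCs (reliability attenuation) without changing the
  underlying structure. Redundancy-structure checks therefore run at
  `duration_scale = 0.5` on distractor-free cohorts and evaluate the
  Table-play composite — the activity whose PCC table defines the selection
  logic — while recovery, null and filter checks use the default desk scale.
* **Moderate vs heavy overlap.** Filter-quality bounds are asserted on
  scenes with the modal score-1 child plus default distractors; score-2
  children (large excursions that can reach a distractor's station) are the
  documented heavy-overlap case, reported but not bounded.
* **Determinism.** Every stochastic test fixes its seed range; the
  acceptance script recomputes all quantities from scratch at a
  user-supplied seed.
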