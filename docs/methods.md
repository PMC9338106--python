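# Methods

This note documents the models, parameter choices and numerical conventions
behind `endpointmotion`, and what the synthetic-data validation does and does
not establish.

## Coordinates and timing

All positions are screen-plane centimetres with the origin at the screen
centre, x rightward, y upward; z is the perpendicular distance from the
fingertip to the screen surface. Times are seconds after target appearance.
The physical screen's backward tilt is ignored: the analysis only ever uses
screen-plane lateral position and screen-normal distance, both of which are
defined in the screen's own frame. Marker sampling is exactly 500 Hz
(Δt = 2 ms), and all trajectories share a sample grid aligned to target
appearance.

## Paradigm

The interception zone (6 cm diameter) sits 10 cm above the screen centre.
The target (2 cm) appears 20 cm to the left of the zone centre and moves
rightward at 30 cm/s, reaching the zone centre after 20/30 s ≈ 667 ms. The
square (frame or tile; side 7, 37 or 67 cm) is centred on the zone and
translates at 20 cm/s for 100 ms (2 cm total) starting 300–400 ms after
target appearance. Trials begin 500–700 ms after the finger settles on a
start point 30 cm below the zone.

Schedules are built per block by shuffling an exact-count list containing
every kind × size × direction cell `reps_per_cell` times (default 25, two
blocks, 600 trials), so cell counts are exactly uniform by construction.
Start delays and square onsets are drawn as continuous uniforms. The
original display ran at 120 Hz, so the true onsets may have been
frame-quantized; continuous draws were chosen because the analysis aligns to
the recorded onset with nearest-sample precision either way, and continuous
onsets exercise the alignment over all phases of the 2-ms grid.

## Synthetic trials

The generator's defaults are the study's conditions: 12 participants,
600 trials each, screen contact at 662 ± 27 ms after target appearance,
~70% of taps hitting the target, < 1% of trials with square-motion timing
errors and 1% with missing data.

**Baseline reach.** Lateral and vertical position follow a minimum-jerk path
(zero velocity and acceleration at both ends) from the start point to a
planned tap point, over the interval from movement onset (default reaction
time 200 ms) to the drawn contact time. The planned tap point is the
target's position at the planned contact time plus isotropic scatter
(σ = 0.65 cm per axis), which puts ~70% of taps inside the 1-cm target
radius. The screen-normal coordinate is a two-segment minimum-jerk profile:
a lift from the screen to 4 cm, then a strike toward a virtual point 4 cm
behind the screen, timed so the plane crossing happens exactly at the drawn
contact time and exactly at the strike segment's peak speed (default
100 cm/s, i.e. a 2-mm approach per sample). Real taps end with an abrupt
impact deceleration; aiming the strike *through* the surface reproduces
that, and is what makes the deceleration-based tap rule applicable at all.
After contact the finger rests on the screen. The strike therefore starts
from a momentary hover at the lift peak — a stylization; no claim is made
that individual synthetic trajectories resemble real reach profiles beyond
their endpoint constraints, smoothness and contact kinematics.

**Injected response.** The following response is added to lateral position
as the integral of

    v_resp(t) = gain(side, kind) · square_speed · K((t − onset − latency)/w) · sign(direction),

with K a raised-cosine bump of unit peak (sin²(πs) on s ∈ [0, 1]), latency
120 ms and width w = 150 ms, placing the bump at ~120–270 ms after motion
onset. `gain` is the peak lateral velocity as a fraction of square speed;
defaults are 0.10 / 0.075 / 0.04 for the 7 / 37 / 67-cm squares and
identical for frame and tile, mirroring the qualitative finding the pipeline
must recover (response decreasing with edge eccentricity, indifferent to
surface kind). All gains are overridable, so sessions violating the finding
can be generated too. The kernel's closed-form integral provides the exact
expected window mean: the discrete 26-interval average of forward
differences telescopes to a displacement difference, so the injected
reference used in tests is computed from the same closed form rather than a
Riemann approximation.

**Artifacts.** Measurement noise is white Gaussian per axis
(σ = 0.005 cm, marker-class precision; z clipped at the screen). With
probability `missing_rate` a trial gets one contiguous gap of 10–50 samples
placed uniformly *inside* its analysis window — a gap placed anywhere in the
recording would usually miss the window and never trigger the exclusion it
is meant to exercise. With probability `timing_issue_rate` the recorded
motion onset and offset are shifted by 10–25 ms (beyond one display frame)
from the commanded times; the injected response follows the actual (shifted)
motion.

## Kinematic operators

**Calibration.** Four marker positions recorded at four known screen targets
determine the screen plane and, via an exact 8 × 8 linear solve, the plane
projectivity from in-plane marker coordinates to screen coordinates — a
four-point correspondence determines a homography uniquely, so no
least-squares fitting is involved. The third output is the signed distance
to the fitted plane, oriented positive on the viewer's side (the orientation
is fixed by requiring the in-plane map to preserve handedness). Degenerate
configurations (any three points collinear) are rejected with a diagnostic.

**Differentiation.** Plain forward differences per 2-ms interval, indexed to
the interval start, with no smoothing. Intervals touching a missing sample
are flagged. Against an analytic minimum-jerk reach (30 cm in 462 ms) the
forward difference matches the closed-form derivative at the interval
midpoint to < 0.005 cm/s.

**Tap detection.** With the per-sample approach Δ[i] = z[i−1] − z[i], a tap
is the first sample where Δ shrinks by more than 1 mm between consecutive
sample pairs while z < 2 cm. The 1-mm-per-sample-pair rule is taken as the
operative definition; expressed as an acceleration it corresponds to
0.001 m / (0.002 s)² = 250 m/s², and the threshold is configurable for users
who prefer a different operationalization. Hit classification is
point-in-circle against the target outline at its position at tap time
(boundary counts as a hit) and against the interception zone.

## Analysis conventions

- Curves are aligned to each trial's *recorded* square-motion onset
  (nearest sample), not to a fixed offset after target appearance; with
  onsets varying over 300–400 ms, onset alignment is the only convention
  under which a 150–200-ms response window is meaningful.
- The magnitude window is inclusive: lags 0.150–0.200 s on the 2-ms grid,
  26 points.
- Velocity intervals at or after the detected tap are dropped from
  averaging (the finger has landed; taps at ~660 ms can precede the end of
  a late-onset 300-ms window). Lags where no trial contributes stay NaN in
  the curve; the magnitude window itself always lies before contact in
  practice, and a NaN inside it raises rather than silently averaging.
- Unequal per-direction trial counts after exclusion are handled by plain
  per-direction means, no reweighting.
- Exclusion tolerance for timing is one display frame (1/120 s); the
  original threshold is unstated and this is the smallest deviation the
  display could express.
- Group standard errors use the across-participant standard deviation with
  ddof = 1.

## Validation design and problem sizes

The pipeline is validated by recovery, not by comparison to human data:

- *Oracle equivalence*: differentiation vs the analytic minimum-jerk
  derivative; the kernel's closed-form integral vs numerical quadrature;
  noise-free direction differences vs exactly twice the injected profile.
- *Null calibration*: with all gains zero, pooled group-mean magnitudes per
  condition lie within 3 SE of zero (three 12-participant studies pooled, so
  the SE is estimated from 36 values per condition).
- *Parameter recovery*: repeated full-size studies (12 participants ×
  600 trials) at default noise. Bias of the recovered group-mean magnitude
  against the injected window mean is assessed per square size pooling the
  two kinds (whose injected values are identical) across 40 seeded studies,
  giving the pooled mean a standard error of ~1–2% of the smallest injected
  value, small enough to resolve the 5% bias bound; frame-vs-tile
  differences pool per-participant values the same way. Size ordering is
  scored per study over 20 seeds. These sizes keep the full suite at a few
  minutes on one CPU while leaving the bias estimate comfortably
  noise-limited rather than count-limited.

A single 12-participant study has a per-condition group SEM of
~0.15 cm/s — dominated by tap-point scatter feeding through the baseline
reach's lateral velocity, not by marker noise — so individual studies
scatter around the injected values by several percent; the bias statements
above are about the pooled estimator.

## Limitations

- The baseline reach is stylized (minimum-jerk segments, momentary hover at
  the lift peak, straight-through strike); passing recovery tests shows the
  *analysis* is unbiased under realistic noise and artifact rates, not that
  the generator reproduces human kinematic variability (e.g. submovements,
  online target tracking, endpoint-velocity coupling).
- Timing issues and missing data are given simple parametric forms (a
  uniform 10–25-ms shift; one contiguous gap); the real artifacts'
  structure is unknown.
- No inferential statistics across conditions are provided, matching the
  descriptive scope of the analysis.
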