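# endpointmotion

Simulation and kinematic analysis of the *manual following response*: the
rapid, involuntary deviation of an ongoing hand movement in the direction of
visual motion appearing near the movement's endpoint.

The package implements an interception paradigm in which participants tap a
target that moves rightward at 30 cm/s toward a circular interception zone,
while a square centred on that zone — either an outline **frame** or a filled
**tile** with side 7, 37 or 67 cm — translates left or right at 20 cm/s for
100 ms shortly after the target appears. The two square types produce the
same edge-motion signals but different surface interpretations, and the
square size sets the eccentricity of the nearest moving edge (3.5, 18.5 or
33.5 cm from the endpoint).

It is intended for movement scientists who want to prototype, stress-test or
teach this kind of perturbation time-course analysis. Because no raw
kinematic data are publicly available for the paradigm, the package ships a
synthetic-data generator that produces whole sessions of 500-Hz finger-marker
trajectories with a *known*, injected following response, so every stage of
the analysis can be validated by parameter recovery.

## The analysis

For each trial, lateral finger position `x` is differentiated directly over
every 2-ms sampling interval, `v[i] = (x[i+1] − x[i]) / Δt`. Trials are
aligned to their recorded square-motion onset, and for each participant and
condition the velocities are averaged per interval, separately for leftward-
and rightward-motion trials. The **response curve** is

    R(τ) = ⟨v(τ)⟩_rightward − ⟨v(τ)⟩_leftward ,  τ ∈ [0, 300] ms,

so a positive response is in the square's motion direction. The **response
magnitude** is the mean of `R(τ)` over τ ∈ [150, 200] ms. Group results are
means with standard errors across participants. Trials with square-motion
timing errors beyond one display frame (8.3 ms) or with missing samples in
the analysis window are excluded; everything else is kept regardless of task
performance.

Supporting kinematics: a four-point plane-projective calibration maps raw
marker coordinates to screen coordinates plus perpendicular distance, and
taps are detected where the per-sample approach to the screen shrinks by more
than 1 mm while the finger is within 2 cm of the screen.

## Worked example

```python
from endpointmotion import RunConfig, run_end_to_end

cfg = RunConfig(n_participants=4, seed=12)   # default: 600 trials/participant
res = run_end_to_end(cfg)
print(res.group.magnitude_summary.to_string(index=False))
```

```
 kind  side_cm  mean_cm_s  sem_cm_s  n_participants
frame      7.0   3.317205  0.127696               4
frame     37.0   2.396653  0.202506               4
frame     67.0   1.520894  0.144760               4
 tile      7.0   3.051336  0.482256               4
 tile     37.0   2.462947  0.158647               4
 tile     67.0   1.342615  0.176194               4
```

Each row is a group-mean response magnitude (cm/s) with its standard error:
the hand's extra lateral velocity in the square's motion direction, averaged
150–200 ms after motion onset. With the generator's defaults the injected
response decreases with square size (here ≈ 3.1, 2.4 and 1.3 cm/s for the
7-, 37- and 67-cm squares) and is identical for frame and tile — the pattern
the analysis should, and does, recover.

The same pipeline is available from the shell:

```sh
endpointmotion schedule --reps 25 --blocks 2 --seed 1 --out schedule.tsv
endpointmotion simulate --schedule schedule.tsv --seed 1 --out data/
endpointmotion analyze  --data data/ --out results/
endpointmotion run      --seed 1 --out results/     # everything end to end
endpointmotion report   --results results/          # Fig-style plots
```

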