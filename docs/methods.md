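# Methods

## Data model and frame validation

A session is a stream of timestamped skeleton frames for one body, each
frame mapping up to 25 named joints (the Kinect V2 joint set) to a 3D
position in camera space — meters, `y` vertical, `z` along the
sensor–subject axis — plus a tracking state (`Tracked`, `Inferred`,
`NotTracked`). The engine applies exactly one preprocessing rule: a frame
is discarded when no joints are present or when any joint required by the
current computation is missing or `NotTracked`. `Inferred` joints are
accepted. There is no interpolation, smoothing, resampling, or outlier
rejection anywhere in the pipeline; robustness is the responsibility of
the detectors' hysteresis and of time integration over actual timestamp
deltas. This keeps every reported angle an unmodified function of the
sensor's output and makes dropped frames degrade results gracefully
rather than silently reshaping them.

Multi-body recordings (the sensor tracks up to six bodies) are split into
independent single-body streams at parse time; there is no cross-body
analysis.

## Joint angles

The angle at a joint is measured between the direction vectors of its two
adjacent segments, u = apex − proximal and v = distal − apex, as
α = (180/π)·atan2(|u×v|, u·v). The two-argument arctangent is the
numerically safe extension of arctan(|u×v|/(u·v)): identical on acute
angles, continuous through 90° (where the plain quotient is undefined),
and correctly in (90°, 180°] for obtuse configurations. The result is
symmetric in u and v, invariant to positive rescaling, and always in
[0°, 180°]. Zero-length vectors (coincident joints) are a domain error at
the function level; inside `angle_series` such frames are treated as
invalid and skipped.

Angles are reported in the **deviation** convention: 0° = straight limb.
The anatomical (interior) angle is 180° − deviation. Detector thresholds
can be stated in either convention (an explicit config field), because
clinical threshold pairs differ: the elbow pair 50°/100° forms a
consistent hysteresis band on the interior angle, the knee pair 70°/30°
on the deviation angle.

## Center of mass

The whole-body COM is the mass-weighted mean of 16 segment midpoints,
bCOM = Σ Mᵢ·sCOMᵢ / Σ Mᵢ, with segment masses Mᵢ taken as fixed fractions
of body mass from a male anthropometric table (head 8.26%, thorax 20.10%,
abdomen 13.06%, pelvis 13.66%, and per side: upper arm 3.25%, forearm
1.87%, hand 0.65%, thigh 10.50%, leg 4.75%, foot 1.43%). Two modeling
choices deserve note:

* **Endpoint joints per segment.** The anthropometric table names
  segments, not joints; the mapping to the 25-joint skeleton is this
  package's choice, held as overridable data: head = Neck–Head, thorax =
  Neck–SpineMid, abdomen = SpineMid–SpineBase, pelvis = HipLeft–HipRight,
  upper arm = Shoulder–Elbow, forearm = Elbow–Wrist, hand = Wrist–HandTip,
  thigh = Hip–Knee, leg = Knee–Ankle, foot = Ankle–Foot. Each choice spans
  the named anatomical segment with the nearest available joints.
* **Normalization.** The tabulated fractions sum to 99.98%, not 100%.
  We normalize by the realized total Σ Mᵢ rather than by M, which
  distributes the 0.02% deficit proportionally; the COM then depends only
  on the fractions, never on the absolute mass. The alternative (divide
  by M) would bias the COM toward the origin by 2·10⁻⁴ of its magnitude —
  harmless but less principled.

The male table is applied to all subjects, matching how such systems are
deployed clinically when per-subject anthropometry is unavailable.

## Repetition counting (flexion/extension)

A two-state hysteresis automaton starts in *extended*. Crossing the
flexed-side threshold switches it to *flexed*; a subsequent crossing of
the extended-side threshold counts one repetition and returns it to
*extended*. Values strictly between the thresholds never change the
state, so jitter smaller than the band gap cannot create or destroy
counts — this is the sole noise defense, by design. Comparisons are
inclusive on both thresholds, so a trace pinned exactly on a threshold
latches once and cannot oscillate. Event timestamps (flexion reached,
extension completed) are recorded per repetition, and the full angle
history passes through for plotting and clinical review.

Defaults: elbow flexed at interior ≤ 50°, completed at interior ≥ 100°;
knee flexed at deviation ≥ 70°, completed at deviation ≤ 30°. These are
clinically motivated values accommodating arthropathy-limited range of
motion while rejecting walking-like motion.

## Step-climb detection

A step climb must satisfy two overlapping conditions: (a) the hip center
(SpineBase vertical position) rises at least `hip_rise_threshold_m`
(default 0.09 m ≈ 60% of a nominal 0.15 m step) above a standing
baseline, and (b) the leading knee completes a flexion–extension cycle
under the knee hysteresis band. The baseline is the mean hip height over
an initial 2 s calibration window, re-anchored over a fresh 2 s window
after each completed descent so slow postural drift does not accumulate.
A descent is counted when the hip returns within half the rise threshold
of baseline after a climb; no knee-cycle check is required on descent.
A knee cycle is matched to a hip-rise episode when their time intervals
intersect, and each cycle can justify at most one climb. Either condition
alone — a tip-toe rise with straight knees, or knee wiggling at floor
level — counts nothing.

The ankle angle history (knee–ankle–foot triple, both sides) is recorded
in the result for medical evaluation but is never consulted for
detection: ankle tracking is the least reliable part of skeletal
inference, so detection rests on the hip and knee signals only.

## Balance scoring

The body COM, projected on the floor (XZ) plane, is scored against eight
targets placed at excursion `e` from the calibrated idle position along
the compass directions N, NE, E, SE, S, SW, W, NW — visited in that fixed
clockwise order, with N the subject's front-facing direction (−z, toward
the sensor) and E at +x. The idle position is the mean COM over the first
2 s. Difficulty levels 1/2/3 set e = 4/6/8 cm; the values are this
package's defaults, chosen so a mild weight shift reaches level 1 while
level 3 demands near-maximal lean, and are fully configurable.

Each direction's 10 s scoring window opens at the first frame (after the
previous window closes) where the COM is within 1.5 cm of idle — the
return-to-start requirement, using the same radius as the 1.5 cm target
circle for symmetry. Within the window, on-target time accumulates
per-frame timestamp deltas whenever the COM lies within the target
radius; score = 100 · (on-target time)/10 s. Time integration over actual
deltas means irregular sampling costs only the dropped intervals. At
30 Hz one frame interval is worth 100/(10·30) ≈ 0.33 score points — the
quantization floor of the protocol. Streams that end mid-protocol yield
scores for the completed directions and flag the remainder incomplete.

## Synthetic motion generator

The generator replaces the sensor for all testing; every session carries
its construction plan as ground truth. It emulates:

* a neutral standing pose with all 25 joints, feet on the floor, facing
  the sensor at z = 2.5 m (vertical coordinates scale with subject
  height; lateral offsets are absolute, so height changes are pure
  vertical scalings);
* flexion exercises as raised-cosine deviation-angle bumps (one per
  repetition at the planned cadence) realized by rigidly rotating the
  distal segment chain about the apex joint in the sagittal plane;
* step climbs as a whole-body half-cosine rise of the planned step height
  overlapping a knee cycle of the leading leg, with standing gaps long
  enough for baseline re-anchoring;
* balance sessions as rigid whole-body XZ translations that put the COM
  on each target for a whole number of frames equal to the planned
  compliance fraction of the window (so planted on-target time is exact
  to one frame);
* sensor imperfections: additive isotropic Gaussian position noise,
  angle jitter applied *geometrically* (perturbing the rotation before
  synthesis — detectors only ever see positions), and random `NotTracked`
  dropouts that keep the stored position, as the real validation rule
  removes the flag's frame rather than the value.

Identical plans with identical seeds produce bit-identical streams.

What it does **not** emulate: biomechanical dynamics (no balance sway
spectra, no inter-joint coordination, no soft-tissue artifacts), the
systematic — not just random — errors of skeletal inference (joint-center
bias under occlusion, limb-swap glitches), or lighting/clothing effects.
Passing the oracle-equivalence suites therefore demonstrates that the
detectors invert the generative model exactly under its stated noise, not
that clinical accuracy on real recordings is guaranteed; the published
human-subject results (per-subject rates, balance medians, group
comparisons) are not reproducible from synthetic data and are not
claimed.

## Numerical and interface choices

* Threshold and geometric comparisons carry a 10⁻⁹ absolute guard so that
  exact-boundary frames (common in synthetic data) behave deterministically.
* Balance/step calibration windows include the frame landing exactly on
  the window boundary.
* Achievement rate is capped at 100% (extra detected repetitions do not
  overshoot); aggregation uses the arithmetic mean and *sample* standard
  deviation (ddof = 1; a single series reports SD 0), display-rounded
  half-away-from-zero to whole percent.
* Report JSON is fully determined by the session record (sorted keys, no
  wall-clock stamps), so regeneration is byte-identical; plots are exempt.
* The canonical CSV dialect writes floats with shortest round-trip repr,
  making write → read bit-exact.
* Problem sizes in the test and acceptance suites — ~200 randomized plans,
  sessions of 0–9 repetitions, 30 Hz — were chosen as the smallest grids
  that exercise every detector branch and both noise regimes.

## Known limitations

* Single-body analysis only; simultaneous two-player streams are parsed
  but scored independently.
* The elbow threshold pair's interior-angle reading, the hip-rise
  magnitude, the idle-return radius, and the per-level balance excursions
  are documented package defaults, not published constants; all are
  exposed in configuration.
* Descents are counted on hip return alone; a knee-cycle requirement on
  descent would be a one-line config extension if clinically warranted.
* Aggregation reproduces published summary means where the printed value
  equals the rounded arithmetic mean of the printed per-subject values;
  two published cells (left step for controls, left knee for patients)
  print 75 and 85 where the per-subject values average 75.6 and 85.5, so
  their pooling or rounding rule evidently differed and they are not used
  as checks.
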