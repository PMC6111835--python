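# kinerehab

Hardware-independent analysis of rehabilitation exercises from skeletal
motion streams.

Depth-sensor body tracking (Kinect V2-style: 25 named joints per body,
3D positions in meters at ~30 Hz) makes it possible to supervise
rehabilitation exercises at home — a need that is acute for people with
hemophilic arthropathy, whose joint mobility is limited by recurrent joint
bleeds and for whom regular, *verified* exercise is part of treatment.
`kinerehab` is the analysis engine for such a setup: it consumes recorded
joint streams (or synthesizes them), evaluates three exercise families, and
produces machine-readable session reports and progress summaries. No sensor
or SDK is required; a deterministic synthetic motion generator stands in
for the hardware everywhere, including in the test suite.

## What it computes

**Joint angles.** For a joint with adjacent segment vectors
u (proximal→apex) and v (apex→distal), the deviation angle is

    α = (180/π) · atan2(|u × v|, u · v)   ∈ [0°, 180°]

(0° = straight limb; the anatomical *interior* angle is 180° − α). Frames
where a required joint is missing or flagged `NotTracked` are discarded,
never interpolated, and no filtering is applied anywhere.

**Center of mass.** Each of N = 16 anthropometric body segments (head,
thorax, abdomen, pelvis, and bilateral upper arm, forearm, hand, thigh,
leg, foot) contributes its midpoint sCOMᵢ weighted by its mass fraction
Mᵢ/M from a male anthropometric table (fractions sum to 99.98%):

    bCOM = Σᵢ Mᵢ · sCOMᵢ / Σᵢ Mᵢ

**Repetition counting.** A two-threshold hysteresis automaton: starting
*extended*, a repetition is counted only after the angle crosses the
flexed-side threshold and then the extended-side threshold. Defaults:
elbow 50°/100° on the interior angle, knee 70°/30° on the deviation angle.

**Step climbs.** A climb on foot F requires, overlapping in time, (a) the
hip center (SpineBase) rising ≥ 0.09 m above a rolling standing baseline
and (b) a knee-F flexion–extension cycle; the descent is counted when the
hip returns to baseline. The ankle angle history is recorded for clinical
review but never used for detection.

**Balance.** The body COM, projected on the floor (XZ) plane, must reach
targets placed at a level-dependent excursion (4/6/8 cm) from the
calibrated idle position in the eight compass directions N, NE, …, NW
(clockwise, N = facing the sensor), returning to idle between directions.
Each direction scores

    score = 100 · (time on target) / (time allowed per target),  10 s per target,

with "on target" meaning within 1.5 cm of the target center.

**Reporting.** Per-series achievement rate = 100 · detected/prescribed
repetitions (capped at 100), aggregated over series as mean ± sample SD,
display-rounded to whole percent.

## Worked example

Simulate a five-repetition squat series and analyze it:

```sh
$ kinerehab simulate -e squat -r 5 -s 11 -o squat.csv
wrote squat.csv (661 frames) and squat.csv.truth.json
$ kinerehab analyze -e squat -i squat.csv -m 70 -o report
report written to report (angle_left.csv, angle_right.csv, angles.png, result.json, summary.txt)
$ head -5 report/summary.txt
Exercise session report: squat
Subject: anonymous (mass 70.0 kg)

Completed repetitions (left): 0
Completed repetitions (right): 5
```

The generator planted 5 right-leg squats (deviation amplitude 90°, which
traverses the 70°/30° knee band); the detector recovers exactly 5 on the
right and 0 on the left. A balance session with a planned per-direction
compliance plan:

```sh
$ kinerehab simulate -e balance -s 11 --compliance 0.9,0.8,1,0.7,0.95,0.6,0.85,0.75 -o bal.csv
$ kinerehab analyze -e balance -i bal.csv -m 70 -o balrep
$ grep -A8 "Balance scores" balrep/summary.txt
Balance scores (% time on target):
   N:  90.00
  NE:  80.00
   E: 100.00
  SE:  70.00
   S:  95.00
  SW:  60.00
   W:  85.00
  NW:  75.00
```

Each score is the percentage of the 10 s window the body COM stayed within
1.5 cm of that direction's target — here exactly the planned compliance
fractions, since the session is noise-free. `kinerehab summarize
-i 'rep*/result.json'` aggregates several analyzed series into
mean ± SD achievement rates with a progress plot.

Streams are plain CSV (`time_s,body_id,joint,x_m,y_m,z_m,state`) or a JSON
session envelope; detector thresholds and balance geometry can be
overridden from a YAML config file, and the effective configuration is
echoed into every report.

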