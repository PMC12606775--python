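# gaitspm

Stride-cycle analysis of synchronous surface-EMG and kinematic recordings
for comparing quadruped walking conditions — built around the measurement
setup used to compare overground (OG), dry-treadmill (TM, TM80) and
water-treadmill (WT80) walking in horses: sEMG and a sacral IMU at
2000 Hz, optical motion capture of six axial/pelvic markers at 200 Hz, all
on one hardware-triggered clock.

The package answers the question *"where in the stride cycle, and how
strongly, does muscle activation or back/pelvis movement differ between
two conditions?"* for single-subject (stride-to-stride variance) designs.

## What it does

1. **Gait events** — right-hind impacts are the vertical-displacement
   minima of the tubera-sacrale point: the IMU's vertical acceleration is
   double-integrated (mean removed after each step), high-pass filtered at
   an adaptive cut-off (0.5 × stride frequency, estimated by
   autocorrelation) and low-pass filtered at 30 Hz, all zero-phase
   Butterworth 4th order.
2. **Kinematics** — rigid cranial (T5–L1), caudal (L1–TS) and pelvic
   (tubera coxarum + S3) segments give thoracolumbar flexion/extension and
   lateral bending, and pelvic roll/pitch/yaw, as Cardan *x,y,z* angles of
   child-relative-to-parent rotations; sagittal angles are normalised to
   the square-stance static pose.
3. **sEMG envelopes** — DC removal, 40 Hz high-pass, full-wave
   rectification, 10 Hz low-pass; per-stride peak amplitudes (PA) drive
   robust outlier-stride removal (median ± 3 scaled-MAD) and normalisation
   to the reference voluntary contraction (RVC = max PA across retained
   overground strides per muscle), so envelopes are in %RVC.
4. **Stride assembly** — every retained stride is linearly resampled to a
   common grid of Q = 101 nodes (0–100% stride) and the per-condition
   stride counts are equalised by trimming strides alternately from the
   beginning and end of each trial.
5. **1D SPM** — at each node a paired t statistic is computed over the
   n = 32 stride pairs, giving a t-field with ν = n − 1. Under the
   smooth-Gaussian-field null, P(max T > u) ≈ S_ν(u) + R·ρ₁(u) with
   R = (Q − 1)/FWHM resels and the 1D Euler-characteristic density
   ρ₁(u) = √(4 ln 2)/(2π) · (1 + u²/ν)^(−(ν−1)/2); the critical threshold
   t\* solves this at α = 0.05 (two-tailed). Supra-threshold clusters get
   p-values from the expected-cluster-extent approximation, reported with
   a "< 0.001" floor. A sign-flip permutation oracle validates both t\*
   and the cluster p-values.

Because the recordings the design is based on are not publicly deposited,
the package ships a first-class **synthetic session generator** with known
ground truth (impact times, angle waveforms, burst envelopes), so the
whole chain is testable end-to-end: quasi-periodic strides (~1.1–1.3 s),
a sacral displacement curve with one minimum per hindlimb impact (the
right-hind minimum deeper), marker trajectories read off rigid segments
placed at prescribed angle waveforms, and sEMG as burst-modulated
band-limited (20–450 Hz) noise with DC offset and sub-20 Hz motion
artefact.

## Worked example

```bash
gaitspm run-all --seed 2 --out results/demo --figures
```

prints

```
sEMG strides: 128; kinematic strides: 96; 45 comparisons (28 with significant clusters)
report written to results/demo
```

— 4 conditions × 32 strides = 128 sEMG strides and 3 treadmill conditions
× 32 = 96 kinematic strides enter the analysis; each of 5 muscles gets 6
comparisons (OG vs each treadmill condition + the 3 treadmill pairs) and
each of 5 angles gets the 3 treadmill pairs, 45 maps in total. In
`results/demo/report.json` the biceps femoris OG-vs-WT80 map reads

```json
"variable": "BF", "condition_a": "OG", "condition_b": "WT80",
"dof": 31, "t_star": 3.768, "significant": true,
"clusters": [{"start_node": 0, "end_node": 56, "max_abs_t": 55.4,
              "p_report": "< 0.001"}, ...]
```

i.e. with 31 degrees of freedom the random-field threshold is
t\* = 3.77, and BF activation differs over 0–56% of the stride (the
mid-stance burst injected into the water-treadmill condition of the
generator's replication profile), cluster p < 0.001. The same run writes
per-comparison t-field CSVs, stride matrices, and two-panel figures
(mean ± SD waveforms | t-field with threshold and shaded clusters).

The library surface mirrors the stages (`generate_session`,
`detect_impacts`, `compute_angles`, `envelope`, `time_normalise`,
`spm_paired_test`, `run_study`); see `docs/methods.md` for the model and
its assumptions.

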