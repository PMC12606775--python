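# Methods

This note documents the models, conventions and numerical choices behind
`gaitspm`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## Study configuration

A session is four walking conditions — OG (overground, preferred speed,
no optical capture), TM (dry treadmill, 1.7 m/s), TM80 (dry treadmill,
1.4 m/s), WT80 (water treadmill, 1.4 m/s, mid-metatarsal depth) — each
recorded for 60 s with five sEMG channels (right biceps femoris, gluteus
medius, tensor fasciae latae; left/right longissimus dorsi) at 2000 Hz, a
sacral-IMU vertical-acceleration channel at 2000 Hz, and six markers
(T5, L1, S3, TS = between tubera sacrale, left/right tuber coxae) at
200 Hz, plus one square-stance static trial. All streams share one time
origin; the hardware trigger is modelled as exact simultaneity (no
inter-stream lag or clock-drift model). The laboratory frame is
right-handed with x cranial (direction of travel), y left, z up. Units:
positions mm, angles degrees, EMG volts, acceleration m/s². Defaults:
Q = 101 nodes per normalised stride, α = 0.05 per comparison (no
multiple-comparison correction across the 45 maps, matching
per-comparison inference; a Bonferroni option exists on the SPM call
surface via α), 32 strides per condition.

All Butterworth filters are designed at the stated order (4) and applied
forward–backward (zero phase), because timing comparisons across
conditions are the scientific object; the bidirectional pass squares the
single-pass magnitude response. This phase-handling choice is the
package's own.

## Gait events

Right-hind impacts are defined as vertical-displacement minima of the
tubera-sacrale point. Acceleration is integrated twice by cumulative
trapezoids with the mean removed after each step, then high-pass filtered
at 0.5 × the estimated stride frequency (adaptive; passes the stride
fundamental while removing integration drift) and low-pass filtered at
30 Hz. The stride frequency is the largest autocorrelation peak at lags
inside the physiological band 0.3–1.5 Hz, which excludes the step rate
(twice the stride rate at walk) by construction; absence of a peak ≥ 0.25
raises an error advising a manual override. Minima are detected after
trimming one stride period of filter transient at each end, with a
minimum separation of 0.35 stride periods and plateau minima resolved to
the plateau midpoint. Alternate minima are classed by mean depth; the
deeper class is returned as the right hind. This side assignment is a
documented stand-in: a single sacral sensor cannot encode side on a
perfectly symmetric signal, so the generator makes the right-hind minimum
deeper by a configurable asymmetry (0.15 of the oscillation amplitude)
and real data should use the explicit `side` override. Ambiguity (class
depth difference < 5% of the signal SD) is flagged and defaults to the
first class.

## Kinematics

Segments: cranial T5→L1, caudal L1→TS, trunk reference T5→TS, pelvis with
proximal ends LTC/RTC and distal end S3. A virtual marker is constructed
20 mm along the pelvic left axis from S3, giving the distal end
mediolateral width for serialisation and completeness; the frame itself
uses S3 as the distal point so that exchanging the left/right tuber coxae
is an exact symmetry (see below).

Axis rules (the cited segment-model literature does not fix them, so
these are the package's own, chosen deterministic and testable):
two-point segments take local x along the segment pointing cranially,
local z as the lab-vertical component orthogonal to x, y = z × x; the
pelvis takes x from S3 toward the tubera-coxarum midpoint, y along
LTC−RTC orthogonalised against x, z = x × y.

Angles are Cardan x,y,z decompositions (R = Rx·Ry·Rz) of
child-relative-to-parent rotations: thoracolumbar angles from caudal
relative to cranial (flexion positive = −about-y; right lateral bend
positive = −about-z), pelvic angles from pelvis relative to the trunk
reference (roll positive = +about-x, when the right tuber coxae moves
ventrally relative to the left; pitch/flexion positive = −about-y; yaw
positive = +about-z, right tuber coxae moving cranially). Gimbal
proximity (|about-y| > 85°) is flagged, not unwrapped. Angle series are
low-pass filtered at 30 Hz and the sagittal angles (thoracolumbar
flexion/extension, pelvis pitch) have the static square-stance angle
subtracted; lateral bend, roll and yaw are reported raw since their
neutral is the 0° crossing.

Two geometric facts worth stating plainly, since they bound what any
implementation of this marker set can promise:

* A two-marker segment has unobservable axial torsion, so its roll must
  be resolved against an external reference (gravity here).
  Consequently, angles are exactly invariant under translations and
  rotations about the vertical — the rigid motions a walking subject
  actually performs — while full 3D rigid invariance holds only for the
  three-marker pelvis. Both statements are tested exactly.
* Exchanging the LTC and RTC trajectories is a proper 180° flip of the
  pelvic frame about its long axis: yaw and pitch negate exactly, and
  the Cardan roll shifts by 180° (sign(roll′)·(180 − |roll′|) equals the
  negated roll). A literal sign flip of roll under Cardan extraction is
  not realisable by any rotation-algebra construction; |roll| > 90° in
  practice indicates swapped side labels.

## sEMG

Envelopes: mean removal, 40 Hz high-pass, full-wave rectification, 10 Hz
low-pass; residual negative ringing from the final filter is clipped to
zero with a logged count (typically ≪ 1% of samples). Per-stride peak
amplitude PA_i = max envelope in stride i's half-open window. Outlier
strides: for each muscle within a trial, PA outside median ± 3 scaled-MAD
(1.4826·MAD) is flagged; a stride flagged by any muscle is removed
globally so the sEMG and kinematic stride sets stay aligned (the
conservative choice, since an aligned-set rule is not uniquely implied by
the design; the threshold is configurable, `--outlier-k`). When the MAD is zero, any PA off the median
is an outlier. Note the rule's behaviour on real-shaped data: envelope
maxima concentrate tightly around the median with a skewed tail, so the
MAD can understate spread and occasionally flag 10–25% of strides in a
trial — harmless for inference but a reason to record generous trial
lengths. With fewer than 5 strides no removal is attempted.

RVC normalisation: per muscle, RVC = max PA across retained overground
strides; all conditions' envelopes are divided by it and expressed in %.
This makes the whole pipeline invariant to any per-muscle constant gain
applied uniformly across conditions, and the OG stride defining the RVC
has normalised PA exactly 100%.

## Stride assembly

Each retained stride (including the sample closing its half-open window)
is linearly interpolated onto 101 nodes spanning 0–100%. Linear rather
than cubic (no overshoot on envelope data; cubic is available as an
option). Counts are equalised per analysis by removing strides
alternately from the beginning and end (beginning first — fixed for
determinism) of each condition's chronological sequence, mirroring
removal at trial boundaries; a condition below target aborts with the
shortfall.

## 1D SPM

Paired t at each node over rank-order-paired strides (strides are not
physically paired across conditions; rank-order pairing after
equalisation is the documented choice, and an unpaired pooled-variance
variant is available). Zero-variance nodes give t = 0 when the mean
difference is also 0, else are capped and flagged. Residuals
d_i − mean(d) feed the smoothness estimator: normalise by the pointwise
SD, take node-to-node gradients, FWHM = √(4 ln 2 / mean squared
gradient), clamped to [1, 3Q] with a flag.

The critical threshold solves
S_ν(u) + R·ρ₁(u) = α/2 (two-tailed; α split equally between tails) with
R = (Q − 1)/FWHM, by Brent's method to 1e-8 on (0.001, 100). In the
zero-resel limit it reduces to the ordinary critical t. Cluster-level p:
cluster extents in resel units are modelled exponential with mean equal
to the expected supra-threshold extent per cluster at u = t\*;
p = 1 − exp(−E[clusters]·P(extent ≥ k)), capped at α and reported with a
"< 0.001" floor. The sign-flip permutation oracle (exhaustive when
2ⁿ ≤ n_perm) reproduces t\* within a few percent on smooth nulls and
provides empirical cluster-extent p-values; on marginal injected effects
the two cluster-p routes agree within a factor of two in the median.

Monte-Carlo calibration (all reproducible through
`scripts/acceptance.py`): on smooth Gaussian nulls (FWHM 15 nodes,
n = 32, 2000 replicates) the empirical family-wise error is ≈ 0.05; the
full pipeline on 1000 null condition pairs (identical generator
parameters, independent noise) yields a significant-cluster rate ≈ 0.05;
an injected mid-stance envelope increase spanning 10–40% stride at ≥ 3×
the stride-to-stride SD is recovered as an overlapping significant
cluster in ≥ 90% of 200 replicates.

## Synthetic data generator

The generator emulates the acquisition, not the horse: stride durations
are i.i.d. lognormal (strictly positive, mild skew) around the condition
mean (OG/TM 1.10 s, TM80 1.25 s, WT80 1.30 s; CV 3%); the sacral
displacement is −(A/2)[cos 4πφ + a·cos 2πφ] with peak-to-peak A = 25 mm
and right-hind deepening a = 0.15; acceleration is its exact analytic
second derivative plus white noise (SD 0.1 m/s²), a constant bias
(0.1 m/s²) and a slow sinusoidal drift (0.2 m/s² at 0.05 Hz); markers are
read off rigid segments placed at prescribed Fourier angle waveforms
(first two stride harmonics, amplitudes of a few degrees) with a common
vertical trunk oscillation and isotropic noise (SD 0.5 mm); raw sEMG is
unit-RMS 20–450 Hz Gaussian noise multiplied by a burst-envelope profile
(wrapped Gaussian bursts in stride phase), scaled by a per-muscle gain
(0.5 mV per relative unit), plus a DC offset (2 mV) and a sub-20 Hz
motion-artefact component. Noise levels were chosen once as realistic for
research-grade instrumentation. The default "replication" effect tables
encode the qualitative condition contrasts of interest (treadmill
mid-stance BF/GM bursts, strongest in water; delayed late-swing
activation; reduced TFL amplitude; biphasic longissimus pattern and a
flexion-shifted back/pelvis posture in water); their amplitudes are free
generator parameters, not measurements of any animal.

What the generator does **not** model — and what passing tests therefore
do not show about real data: soft-tissue and sensor-pouch artefacts,
water-drag forces, EMG cross-talk between adjacent muscles, non-rigid
back deformation within segments, marker occlusion patterns beyond simple
gaps, inter-stream clock drift, and between-horse variability (the design
is single-subject by construction).

## Degenerate inputs and tie-breaks

Coincident or collinear segment markers invalidate the frame (logged;
interpolated if < 5% of frames, fatal otherwise). Marker gaps shorter
than 0.1 s are linearly interpolated at read time with a logged count;
longer gaps stay flagged and invalidate overlapping strides. Plateau
minima resolve to the plateau midpoint. Stride-count trimming starts at
the beginning. Autocorrelation ties prefer the strongest peak; equal-depth
minima classes are flagged ambiguous and default to the first class. The
permutation oracle falls back to the pointwise critical t for the extent
null when the EC equation has no root (very rough fields at tiny dof).

## Problem sizes

Default analyses use one 60 s trial per condition (the configured
acquisition length; it retains ~40–50 strides per condition, ample for
the 32-stride target — trial count and duration are configurable). The
calibration harnesses use a single muscle and two conditions at 60 s,
2000 smooth-field replicates, 1000 null-pipeline replicates and 200
effect-recovery replicates.
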