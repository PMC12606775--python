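"""Synthetic walking sessions with known ground truth.

The generator emulates the acquisition setup of a single-horse treadmill
study: per condition it produces synchronous raw sEMG channels (2000 Hz),
one sacral-IMU vertical-acceleration channel (2000 Hz) and six marker
trajectories (200 Hz) on one shared clock, plus a square-stance static
trial. The hidden truth (right-hind impact times, angle waveforms, burst
envelopes, tubera-sacrale displacement) is returned alongside so every
downstream stage can be tested for recovery.

Signal model
------------
* Stride timing: stride durations are i.i.d. lognormal around the condition
  mean with a configurable coefficient of variation; the stride phase
  ``phi`` in [0, 1) is piecewise linear between right-hind impacts.
* Sacral displacement: two oscillations per stride with one minimum per
  hindlimb impact; the right-hind minimum is made deeper by a configurable
  asymmetry so that side assignment is non-trivial.
  ``d(phi) = -(A/2) [cos(4 pi phi) + asym cos(2 pi phi)]`` (mm).
* Vertical acceleration: the exact analytic second derivative of the
  displacement, plus white noise, a slow sinusoidal drift and a constant
  offset.
* Markers: the rigid cranial, caudal and pelvic segments are placed at the
  prescribed Cardan angle waveforms every frame and the marker positions
  are read off the segments, with a common vertical trunk oscillation and
  isotropic Gaussian marker noise.
* sEMG: unit-RMS Gaussian noise band-limited to 20-450 Hz, multiplied by
  the muscle's burst-envelope profile (baseline tone + wrapped Gaussian
  bursts in stride phase), scaled by a per-muscle gain, plus a DC offset
  and a sub-20 Hz motion-artefact component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import SessionConfig, ConditionSpec, DEFAULT_ANGLES
from .filters import bandpass_noise
from .kinematics import (
    SegmentModel,
    named_to_components,
    rotation_cardan_xyz,
    two_point_frame,
)
from .types import StaticTrial, SyntheticGroundTruth, TrialRecording


class SyntheticError(ValueError):
    pass


# Square-stance marker geometry (mm, lab frame: x cranial, y left, z up).
# Chosen flat so that every segment frame is the identity in the static pose.
STATIC_MARKERS_MM: dict[str, tuple[float, float, float]] = {
    "T5": (1600.0, 0.0, 1300.0),
    "L1": (800.0, 0.0, 1300.0),
    "TS": (100.0, 0.0, 1300.0),
    "S3": (0.0, 0.0, 1300.0),
    "LTC": (200.0, 120.0, 1300.0),
    "RTC": (200.0, -120.0, 1300.0),
}


@dataclass(frozen=True)
class Burst:
    """One activation burst: Gaussian bump in stride phase.

    centre and width (the Gaussian SD) are in % stride; amplitude is in
    relative envelope units.
    """

    centre: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SyntheticError("burst width must be > 0")
        if self.amplitude < 0:
            raise SyntheticError("burst amplitude must be >= 0")


@dataclass(frozen=True)
class FourierWaveform:
    """Angle waveform over the stride: offset + first few stride harmonics."""

    offset: float = 0.0
    cos: tuple[float, ...] = ()
    sin: tuple[float, ...] = ()

    def evaluate(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full_like(phase, self.offset)
        for k, c in enumerate(self.cos, start=1):
            out += c * np.cos(2 * np.pi * k * phase)
        for k, s in enumerate(self.sin, start=1):
            out += s * np.sin(2 * np.pi * k * phase)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise model; defaults reflect the instrumented setup
    (research-grade IMU/sEMG sensors and optical capture)."""

    imu_white_sd: float = 0.1        # m/s^2
    imu_drift_amplitude: float = 0.2  # m/s^2, slow sinusoid
    imu_drift_freq: float = 0.05      # Hz
    imu_offset: float = 0.1           # m/s^2, constant bias
    marker_sd: float = 0.5            # mm, isotropic
    emg_baseline: float = 0.02        # relative envelope floor (tonic)
    emg_dc_offset: float = 2.0e-3     # V
    emg_artefact: float = 0.05        # relative units, < 20 Hz
    emg_gain: float = 5.0e-4          # V per relative envelope unit

    def __post_init__(self) -> None:
        for name in ("imu_white_sd", "marker_sd", "emg_baseline",
                     "emg_artefact"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")


NOISE_FREE = NoiseSpec(imu_white_sd=0.0, imu_drift_amplitude=0.0,
                       imu_offset=0.0, marker_sd=0.0, emg_baseline=0.0,
                       emg_dc_offset=0.0, emg_artefact=0.0)


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition generator parameters: burst tables, angle waveforms,
    stride timing and sacral displacement shape."""

    bursts: dict[str, tuple[Burst, ...]]
    angles: dict[str, FourierWaveform]
    stride_duration: float = 1.2      # s
    stride_duration_cv: float = 0.03
    displacement_amplitude: float = 25.0  # mm peak-to-peak, main oscillation
    displacement_asymmetry: float = 0.15  # right-hind minimum deepening

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise SyntheticError("stride_duration must be > 0")
        if self.stride_duration_cv < 0:
            raise SyntheticError("stride_duration_cv must be >= 0")

    def envelope_profile(self, phase: np.ndarray, muscle: str,
                         baseline: float = 0.0) -> np.ndarray:
        """Relative envelope at stride phase in [0, 1); bursts wrap at 1."""
        phase = np.asarray(phase, dtype=float)
        out = np.full_like(phase, float(baseline))
        for b in self.bursts.get(muscle, ()):
            c, w = b.centre / 100.0, b.width / 100.0
            for shift in (-1.0, 0.0, 1.0):
                out += b.amplitude * np.exp(-0.5 * ((phase - c + shift) / w) ** 2)
        return out

    def displacement_mm(self, phase: np.ndarray) -> np.ndarray:
        a = self.displacement_amplitude / 2.0
        p = np.asarray(phase, dtype=float)
        return -a * (np.cos(4 * np.pi * p)
                     + self.displacement_asymmetry * np.cos(2 * np.pi * p))

    def displacement_accel_mm(self, phase: np.ndarray,
                              stride_duration: np.ndarray) -> np.ndarray:
        """Exact second time-derivative of the displacement, mm/s^2."""
        a = self.displacement_amplitude / 2.0
        p = np.asarray(phase, dtype=float)
        f2 = a * (16 * np.pi**2 * np.cos(4 * np.pi * p)
                  + self.displacement_asymmetry * 4 * np.pi**2
                  * np.cos(2 * np.pi * p))
        return f2 / np.asarray(stride_duration, dtype=float) ** 2

    def angle_waveform(self, phase: np.ndarray, angle: str) -> np.ndarray:
        wf = self.angles.get(angle, FourierWaveform())
        return wf.evaluate(np.asarray(phase, dtype=float))


# ---------------------------------------------------------------------------
# Study-replication effect tables: qualitative encoding of the reported
# condition contrasts (mid-stance BF/GM increases and late-swing delays on
# the treadmill conditions, strongest in water; TFL amplitude decrease;
# biphasic longissimus pattern in water; thoracolumbar/pelvic flexion shift
# in water). Amplitudes are free generator parameters, not measurements.
# ---------------------------------------------------------------------------

def _base_angles() -> dict[str, FourierWaveform]:
    return {
        "thoraco_flex_ext": FourierWaveform(0.0, (0.3, 2.0), (0.2, 1.0)),
        "thoraco_lat_bend": FourierWaveform(0.0, (3.0, 0.3), (1.0, 0.2)),
        "pelvis_roll": FourierWaveform(0.0, (4.0, 0.3), (1.5, 0.2)),
        "pelvis_pitch": FourierWaveform(0.0, (0.4, 3.0), (0.2, 1.2)),
        "pelvis_yaw": FourierWaveform(0.0, (3.0, 0.4), (1.0, 0.3)),
    }


def study_replication_effects(
        muscles: tuple[str, ...] = ("BF", "GM", "TFL", "LD_left", "LD_right"),
) -> dict[str, ConditionEffect]:
    """Default per-condition generator parameters for the replication run."""
    og_bursts = {
        "BF": (Burst(95, 5, 1.0), Burst(4, 5, 0.8)),
        "GM": (Burst(0, 9, 1.0), Burst(30, 10, 0.4)),
        "TFL": (Burst(42, 8, 1.0), Burst(66, 7, 0.5)),
        "LD_left": (Burst(35, 8, 1.0),),
        "LD_right": (Burst(35, 8, 1.0),),
    }
    tm_bursts = {
        "BF": (Burst(97, 5, 1.0), Burst(5, 5, 0.9), Burst(25, 9, 0.8)),
        "GM": (Burst(97, 6, 0.9), Burst(25, 9, 0.7), Burst(45, 4, 0.5)),
        "TFL": (Burst(42, 8, 0.6), Burst(66, 7, 0.35)),
        "LD_left": (Burst(35, 8, 1.0),),
        "LD_right": (Burst(35, 8, 1.0),),
    }
    wt_bursts = {
        "BF": (Burst(98, 6, 1.3), Burst(6, 5, 1.0), Burst(25, 9, 1.2)),
        "GM": (Burst(98, 6, 1.2), Burst(25, 9, 1.0), Burst(45, 4, 0.6)),
        "TFL": (Burst(40, 6, 0.4), Burst(68, 11, 0.35)),
        "LD_left": (Burst(33, 10, 0.8), Burst(80, 7, 0.7)),
        "LD_right": (Burst(33, 10, 0.8), Burst(80, 7, 0.7)),
    }
    base = _base_angles()
    wt_angles = dict(base)
    wt_angles["thoraco_flex_ext"] = FourierWaveform(1.5, (0.3, 2.6), (0.2, 1.3))
    wt_angles["pelvis_pitch"] = FourierWaveform(2.0, (0.4, 3.8), (0.2, 1.5))
    wt_angles["pelvis_roll"] = FourierWaveform(0.0, (5.0, 0.4), (1.9, 0.25))

    def only(bursts: dict) -> dict[str, tuple[Burst, ...]]:
        return {m: bursts[m] for m in muscles if m in bursts}

    return {
        "OG": ConditionEffect(only(og_bursts), base, stride_duration=1.10),
        "TM": ConditionEffect(only(tm_bursts), base, stride_duration=1.10),
        "TM80": ConditionEffect(only(tm_bursts), base, stride_duration=1.25),
        "WT80": ConditionEffect(only(wt_bursts), wt_angles, stride_duration=1.30),
    }


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _stride_boundaries(effect: ConditionEffect, duration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Impact times (stride boundaries) covering [-T, duration + T]."""
    mean, cv = effect.stride_duration, effect.stride_duration_cv
    if cv > 0:
        sigma2 = math.log(1.0 + cv**2)
        mu = math.log(mean) - sigma2 / 2.0
        draw = lambda: float(rng.lognormal(mu, math.sqrt(sigma2)))  # noqa: E731
    else:
        draw = lambda: mean  # noqa: E731
    t = -draw() * rng.uniform(0.2, 0.8)
    bounds = [t]
    while bounds[-1] < duration + 2 * mean:
        bounds.append(bounds[-1] + draw())
    return np.array(bounds)


def _phase(times: np.ndarray, bounds: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Stride phase in [0, 1) and the local stride duration at each time."""
    idx = np.clip(np.searchsorted(bounds, times, side="right") - 1,
                  0, len(bounds) - 2)
    t0, t1 = bounds[idx], bounds[idx + 1]
    dur = t1 - t0
    return (times - t0) / dur, dur


def _place_markers(effect: ConditionEffect, phase: np.ndarray,
                   bob_mm: np.ndarray, model: SegmentModel
                   ) -> dict[str, np.ndarray]:
    """Rigid-segment forward model: marker positions (mm) at each frame."""
    static = {k: np.array(v) for k, v in STATIC_MARKERS_MM.items()}
    n = len(phase)
    named_th = {a: effect.angle_waveform(phase, a)
                for a in ("thoraco_flex_ext", "thoraco_lat_bend")}
    named_pv = {a: effect.angle_waveform(phase, a)
                for a in ("pelvis_roll", "pelvis_pitch", "pelvis_yaw")}
    comp_th = np.stack(
        [named_to_components({k: v[i] for k, v in named_th.items()},
                             "thoraco", model.convention) for i in range(n)])
    comp_pv = np.stack(
        [named_to_components({k: v[i] for k, v in named_pv.items()},
                             "pelvis", model.convention) for i in range(n)])
    r_thor = rotation_cardan_xyz(comp_th)          # (n, 3, 3)
    r_pelv = rotation_cardan_xyz(comp_pv)

    bob = np.zeros((n, 3))
    bob[:, 2] = bob_mm
    out: dict[str, np.ndarray] = {}
    out["T5"] = np.tile(static["T5"], (n, 1)) + bob
    out["L1"] = np.tile(static["L1"], (n, 1)) + bob
    # caudal segment rotates about L1 by the prescribed thoracolumbar rotation
    out["TS"] = out["L1"] + np.einsum("nij,j->ni", r_thor,
                                      static["TS"] - static["L1"])
    # the trunk reference segment (T5 -> TS) follows from the placed markers
    r_ref, _ = two_point_frame(out["T5"], out["TS"])
    q_pelvis = np.einsum("nij,njk->nik", r_ref, r_pelv)
    for name in ("S3", "LTC", "RTC"):
        out[name] = out["TS"] + np.einsum("nij,j->ni", q_pelvis,
                                          static[name] - static["TS"])
    return out


def _generate_trial(label: str, cond: ConditionSpec, effect: ConditionEffect,
                    config: SessionConfig, noise: NoiseSpec,
                    rng: np.random.Generator, trial_id: str
                    ) -> tuple[TrialRecording, dict]:
    duration = config.trial_duration
    bounds = _stride_boundaries(effect, duration, rng)
    truth_impacts = bounds[(bounds > 0) & (bounds < duration)]

    # --- IMU channel -------------------------------------------------------
    t_imu = np.arange(round(duration * config.imu_rate)) / config.imu_rate
    phi_imu, dur_imu = _phase(t_imu, bounds)
    disp_mm = effect.displacement_mm(phi_imu)
    accel = effect.displacement_accel_mm(phi_imu, dur_imu) / 1000.0  # m/s^2
    accel_noisy = accel + noise.imu_offset
    if noise.imu_drift_amplitude > 0:
        accel_noisy = accel_noisy + noise.imu_drift_amplitude * np.sin(
            2 * np.pi * noise.imu_drift_freq * t_imu + rng.uniform(0, 2 * np.pi))
    if noise.imu_white_sd > 0:
        accel_noisy = accel_noisy + noise.imu_white_sd * rng.standard_normal(
            len(t_imu))

    # --- sEMG channels -----------------------------------------------------
    t_emg = np.arange(round(duration * config.emg_rate)) / config.emg_rate
    phi_emg, _ = _phase(t_emg, bounds)
    emg: dict[str, np.ndarray] = {}
    true_env: dict[str, np.ndarray] = {}
    for muscle in config.muscles:
        profile = effect.envelope_profile(phi_emg, muscle, noise.emg_baseline)
        carrier = bandpass_noise(rng, len(t_emg), config.emg_rate, 20.0, 450.0)
        x = noise.emg_gain * profile * carrier + noise.emg_dc_offset
        if noise.emg_artefact > 0:
            artefact = bandpass_noise(rng, len(t_emg), config.emg_rate,
                                      0.3, 15.0)
            x = x + noise.emg_gain * noise.emg_artefact * artefact
        emg[muscle] = x
        grid = np.linspace(0.0, 1.0, config.node_count)
        true_env[muscle] = effect.envelope_profile(grid, muscle,
                                                   noise.emg_baseline)

    # --- markers -----------------------------------------------------------
    markers = gaps = None
    if cond.has_markers:
        t_mocap = np.arange(round(duration * config.mocap_rate)) / config.mocap_rate
        phi_m, _ = _phase(t_mocap, bounds)
        bob = effect.displacement_mm(phi_m)
        markers = _place_markers(effect, phi_m, bob, SegmentModel())
        if noise.marker_sd > 0:
            for name in markers:
                markers[name] = markers[name] + noise.marker_sd * \
                    rng.standard_normal(markers[name].shape)
        gaps = {name: np.zeros(len(t_mocap), dtype=bool) for name in markers}

    trial = TrialRecording(
        condition=label, emg=emg, imu_accel_vertical=accel_noisy,
        markers=markers, marker_gaps=gaps, emg_rate=config.emg_rate,
        imu_rate=config.imu_rate, mocap_rate=config.mocap_rate,
        duration=duration, trial_id=trial_id)
    grid = np.linspace(0.0, 1.0, config.node_count)
    truth = {
        "impacts": truth_impacts,
        "displacement": disp_mm,
        "envelopes": true_env,
        "angles": {a: effect.angle_waveform(grid, a) for a in DEFAULT_ANGLES},
    }
    return trial, truth


def generate_session(config: SessionConfig,
                     effects: dict[str, ConditionEffect] | None = None,
                     seed: int | None = None,
                     noise: NoiseSpec = NoiseSpec(),
                     ) -> tuple[list[TrialRecording], StaticTrial,
                                SyntheticGroundTruth]:
    """Generate all configured conditions plus a static trial and truth.

    Identical (config, effects, seed, noise) give bit-identical output; all
    randomness derives from ``seed`` (falling back to ``config.seed``)
    through per-trial child streams.
    """
    if effects is None:
        effects = study_replication_effects(config.muscles)
    for cond in config.conditions:
        if cond.label not in effects:
            raise SyntheticError(f"no ConditionEffect for condition "
                                 f"{cond.label!r}")
    unknown = set(effects) - set(config.condition_labels)
    if unknown:
        raise SyntheticError(f"effects given for unknown conditions: "
                             f"{sorted(unknown)}")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.conditions) * config.trials_per_condition)

    trials: list[TrialRecording] = []
    impacts: dict[str, np.ndarray] = {}
    displacement: dict[str, np.ndarray] = {}
    angle_truth: dict[str, dict[str, np.ndarray]] = {}
    env_truth: dict[str, dict[str, np.ndarray]] = {}
    k = 0
    for cond in config.conditions:
        for j in range(config.trials_per_condition):
            rng = np.random.default_rng(children[k])
            k += 1
            trial_id = f"{cond.label}-{j + 1}"
            trial, truth = _generate_trial(cond.label, cond,
                                           effects[cond.label], config,
                                           noise, rng, trial_id)
            trials.append(trial)
            impacts[trial_id] = truth["impacts"]
            displacement[trial_id] = truth["displacement"]
        angle_truth[cond.label] = truth["angles"]
        env_truth[cond.label] = truth["envelopes"]

    static = StaticTrial(markers={k: np.array(v, dtype=float)
                                  for k, v in STATIC_MARKERS_MM.items()})
    gt = SyntheticGroundTruth(
        true_impact_times=impacts,
        true_angle_waveforms=angle_truth,
        true_envelopes=env_truth,
        true_displacement=displacement)
    return trials, static, gt


def null_pair(config: SessionConfig, effect: ConditionEffect,
              seed: int, noise: NoiseSpec = NoiseSpec(),
              ) -> tuple[SessionConfig, list[TrialRecording], StaticTrial,
                         SyntheticGroundTruth]:
    """Two statistically identical conditions with independent noise.

    Condition "A" is the reference (RVC-defining) member. Used as the
    type-I-error harness: any downstream difference between the pair is
    noise.
    """
    pair = (ConditionSpec("A", has_markers=False, is_reference=True),
            ConditionSpec("B", has_markers=False))
    cfg = replace(config, conditions=pair, seed=seed)
    trials, static, gt = generate_session(
        cfg, effects={"A": effect, "B": effect}, seed=seed, noise=noise)
    return cfg, trials, static, gt
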