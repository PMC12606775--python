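"""Segment frames, Cardan decomposition, and angle recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitspm import SessionConfig, generate_session
from gaitspm.assembly import normalise_strides
from gaitspm.gait_events import events_to_strides
from gaitspm.kinematics import (
    KinematicsError,
    SegmentModel,
    build_segment_frames,
    cardan_xyz,
    compute_angles,
    relative_rotation,
    rotation_cardan_xyz,
    static_angles,
    virtual_left_marker,
)
from gaitspm.synthetic import NOISE_FREE, STATIC_MARKERS_MM, NoiseSpec
from gaitspm.types import GaitEventSeries, StaticTrial


def _static_markers(n=1):
    return {k: np.tile(np.asarray(v, dtype=float), (n, 1))
            for k, v in STATIC_MARKERS_MM.items()}


def test_static_pose_frames_are_identity():
    frames, valid = build_segment_frames(_static_markers(), SegmentModel())
    assert valid.all()
    for name, f in frames.items():
        np.testing.assert_allclose(f[0], np.eye(3), atol=1e-9)
    angles = static_angles(StaticTrial(markers={
        k: np.asarray(v, dtype=float) for k, v in STATIC_MARKERS_MM.items()}),
        SegmentModel())
    assert all(abs(v) < 1e-6 for v in angles.values())


def test_vertical_rotation_moves_every_segment_frame_equally():
    # two-point segments resolve their torsion against the lab vertical, so
    # exact frame equivariance holds for rotations about that vertical
    markers = _static_markers()
    rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
    rotated = {k: v @ rot.T for k, v in markers.items()}
    f0, _ = build_segment_frames(markers, SegmentModel())
    f1, _ = build_segment_frames(rotated, SegmentModel())
    for name in f0:
        np.testing.assert_allclose(f1[name][0], rot @ f0[name][0], atol=1e-9)


def test_pelvic_frame_equivariant_under_arbitrary_rotation(rng):
    # the pelvis is defined by three markers and carries no lab reference:
    # full rigid equivariance
    from gaitspm.kinematics import pelvic_frame
    m = _static_markers()
    rot = Rotation.from_euler("xyz", [10, -25, 40], degrees=True).as_matrix()
    f0, _ = pelvic_frame(m["LTC"], m["RTC"], m["S3"])
    f1, _ = pelvic_frame(m["LTC"] @ rot.T, m["RTC"] @ rot.T,
                         m["S3"] @ rot.T)
    np.testing.assert_allclose(f1[0], rot @ f0[0], atol=1e-9)


def test_degenerate_segment_marks_frame_invalid():
    markers = _static_markers()
    markers["T5"] = markers["L1"].copy()      # coincident defining points
    _, valid = build_segment_frames(markers, SegmentModel())
    assert not valid[0]


def test_virtual_marker_is_20mm_left_of_s3():
    m = _static_markers()
    v = virtual_left_marker(m["LTC"], m["RTC"], m["S3"])
    np.testing.assert_allclose(np.linalg.norm(v[0] - m["S3"][0]), 20.0,
                               atol=1e-9)
    np.testing.assert_allclose(v[0] - m["S3"][0], [0.0, 20.0, 0.0],
                               atol=1e-9)


def test_cardan_identity_and_single_axis():
    a, flags = cardan_xyz(np.eye(3))
    np.testing.assert_allclose(a, [0, 0, 0], atol=1e-12)
    r = Rotation.from_euler("x", 10, degrees=True).as_matrix()
    a, _ = cardan_xyz(r)
    np.testing.assert_allclose(a, [10, 0, 0], atol=1e-9)


def test_cardan_round_trip_on_random_triples(rng):
    angles = rng.uniform(-30, 30, size=(1000, 3))
    rots = rotation_cardan_xyz(angles)
    back, _ = cardan_xyz(rots)
    np.testing.assert_allclose(back, angles, atol=1e-9)


def test_cardan_rejects_non_rotation():
    with pytest.raises(KinematicsError):
        cardan_xyz(2.0 * np.eye(3))


def test_gimbal_proximity_flagged():
    r = rotation_cardan_xyz(np.array([5.0, 88.0, 3.0]))
    _, flags = cardan_xyz(r)
    assert any("gimbal" in f for f in flags)


def _angle_rms_errors(noise, seed=3):
    cfg = SessionConfig(trial_duration=20.0)
    trials, static, truth = generate_session(cfg, seed=seed, noise=noise)
    out = {}
    for trial in trials:
        if trial.markers is None:
            continue
        wave = compute_angles(trial, static)
        ev = GaitEventSeries(
            impact_times=truth.true_impact_times[trial.trial_id])
        win, _ = events_to_strides(ev, len(wave.times), trial.mocap_rate)
        for name, ref in truth.true_angle_waveforms[trial.condition].items():
            m = normalise_strides(wave.angles[name], win, cfg.node_count)
            rms = float(np.sqrt(np.mean((m.mean(axis=0) - ref) ** 2)))
            out[name] = max(out.get(name, 0.0), rms)
    return out


def test_noise_free_angle_recovery_below_half_degree():
    errors = _angle_rms_errors(NOISE_FREE)
    assert set(errors) == {"thoraco_flex_ext", "thoraco_lat_bend",
                           "pelvis_roll", "pelvis_pitch", "pelvis_yaw"}
    assert all(v < 0.5 for v in errors.values()), errors


def test_one_mm_marker_noise_angle_recovery_below_two_degrees():
    noise = NoiseSpec(marker_sd=1.0)
    errors = _angle_rms_errors(noise)
    assert all(v < 2.0 for v in errors.values()), errors


def test_angles_invariant_under_translation_and_heading_change(noise_free_session):
    # relative angles are exactly invariant under any translation plus any
    # rotation about the vertical (the torsion reference axis); this is the
    # full gravity-respecting rigid group available to a walking horse
    trials, static, _ = noise_free_session
    trial = trials[1]
    wave0 = compute_angles(trial, static)
    rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
    shift = np.array([250.0, -90.0, 30.0])
    import copy
    moved = copy.deepcopy(trial)
    for k in moved.markers:
        moved.markers[k] = moved.markers[k] @ rot.T + shift
    wave1 = compute_angles(moved, static)
    for name in wave0.angles:
        np.testing.assert_allclose(wave1.angles[name], wave0.angles[name],
                                   atol=1e-6)


def test_swapping_tuber_coxae_flips_pelvic_signs(noise_free_session):
    # exchanging the left/right tuber coxae trajectories turns the pelvic
    # frame upside-down (a proper 180-degree flip about its long axis):
    # yaw and pitch negate exactly and the Cardan roll shifts by 180
    # degrees, so sign(roll') * (180 - |roll'|) recovers the negated
    # anatomical roll; thoracolumbar angles are untouched
    from gaitspm.kinematics import components_to_named
    trials, _, _ = noise_free_session
    trial = trials[1]
    model = SegmentModel()

    def pelvic_named(markers):
        frames, valid = build_segment_frames(markers, model)
        assert valid.all()
        comp, _ = cardan_xyz(relative_rotation(frames["reference"],
                                               frames["pelvis"]))
        return components_to_named(comp, "pelvis", model.convention)

    a0 = pelvic_named(trial.markers)
    swapped = dict(trial.markers)
    swapped["LTC"], swapped["RTC"] = trial.markers["RTC"], \
        trial.markers["LTC"]
    a1 = pelvic_named(swapped)
    np.testing.assert_allclose(a1["pelvis_yaw"], -a0["pelvis_yaw"],
                               atol=1e-6)
    np.testing.assert_allclose(a1["pelvis_pitch"], -a0["pelvis_pitch"],
                               atol=1e-6)   # magnitude unchanged
    roll1 = a1["pelvis_roll"]
    np.testing.assert_allclose(np.sign(roll1) * (180.0 - np.abs(roll1)),
                               -a0["pelvis_roll"], atol=1e-6)


def test_static_pose_trial_yields_zero_normalised_angles(short_config):
    n = int(short_config.trial_duration * short_config.mocap_rate)
    from gaitspm.types import TrialRecording
    trial = TrialRecording(
        condition="TM", emg={}, imu_accel_vertical=np.zeros(10),
        markers=_static_markers(n),
        marker_gaps={k: np.zeros(n, dtype=bool) for k in STATIC_MARKERS_MM},
        emg_rate=2000.0, imu_rate=2000.0, mocap_rate=200.0,
        duration=short_config.trial_duration)
    static = StaticTrial(markers={k: np.asarray(v, dtype=float)
                                  for k, v in STATIC_MARKERS_MM.items()})
    wave = compute_angles(trial, static)
    for name, x in wave.angles.items():
        assert np.abs(x).max() < 1e-6, name


def test_missing_static_skips_normalisation_with_flag(noise_free_session):
    trials, _, _ = noise_free_session
    wave = compute_angles(trials[1], None)
    assert any("normalisation skipped" in f for f in wave.flags)
    assert not wave.normalised["thoraco_flex_ext"]


def test_filtering_preserves_stationary_mean():
    from gaitspm.config import KINEMATIC_LOWPASS
    from gaitspm.filters import apply_filter
    x = np.full(4000, 7.3)
    y = apply_filter(x, KINEMATIC_LOWPASS, 200.0)
    assert abs(y.mean() - 7.3) < 1e-6
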