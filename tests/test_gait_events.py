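"""Stride segmentation from sacral vertical acceleration."""

import numpy as np
import pytest

from gaitspm import SessionConfig, generate_session
from gaitspm.config import ConditionSpec
from gaitspm.gait_events import (
    GaitEventError,
    accel_to_displacement,
    detect_impacts,
    estimate_stride_frequency,
    events_to_strides,
)
from gaitspm.synthetic import NOISE_FREE, study_replication_effects
from gaitspm.types import GaitEventSeries

RATE = 2000.0


def _single_condition_session(seed, duration=40.0, noise=None):
    cfg = SessionConfig(conditions=(ConditionSpec("TM", 1.7,
                                                  has_markers=False),),
                        muscles=("BF",), trial_duration=duration)
    effects = {"TM": study_replication_effects(("BF",))["TM"]}
    kwargs = {} if noise is None else {"noise": noise}
    return cfg, *generate_session(cfg, effects, seed=seed, **kwargs)


def test_zero_acceleration_gives_zero_displacement():
    disp = accel_to_displacement(np.zeros(int(60 * RATE)), RATE, 0.9)
    assert np.abs(disp).max() < 1e-9


def test_sinusoid_amplitude_recovered_from_double_integration():
    amp, f = 0.03, 1.7                     # m, Hz (step rate; stride 0.85)
    t = np.arange(int(60 * RATE)) / RATE
    w = 2 * np.pi * f
    accel = -amp * w * w * np.sin(w * t)
    disp = accel_to_displacement(accel, RATE, 0.85)
    core = disp[len(disp) // 5: -len(disp) // 5]
    assert abs(core.max() - amp * 1000) < 0.05 * amp * 1000


def test_displacement_tracks_truth_on_synthetic_trial():
    _, trials, _, truth = _single_condition_session(seed=6)
    trial = trials[0]
    freq = estimate_stride_frequency(trial.imu_accel_vertical, RATE)
    disp = accel_to_displacement(trial.imu_accel_vertical, RATE, freq)
    ref = truth.true_displacement[trial.trial_id]
    n = len(ref)
    sl = slice(n // 10, 9 * n // 10)
    r = np.corrcoef(disp[sl], ref[sl])[0, 1]
    assert r > 0.99


@pytest.mark.parametrize("freq", [0.85, 0.6])
def test_pure_periodicity_frequency_recovered(freq):
    t = np.arange(int(60 * RATE)) / RATE
    x = np.sin(2 * np.pi * freq * t)
    est = estimate_stride_frequency(x, RATE)
    assert abs(est - freq) < 0.02


def test_stride_frequency_on_synthetic_trial():
    cfg = SessionConfig(conditions=(ConditionSpec("WT80", 1.4,
                                                  has_markers=False),),
                        muscles=("BF",), trial_duration=40.0)
    eff = study_replication_effects(("BF",))["WT80"]   # 1.3 s stride
    trials, _, _ = generate_session(cfg, {"WT80": eff}, seed=2)
    est = estimate_stride_frequency(trials[0].imu_accel_vertical, RATE)
    assert abs(est - 1 / 1.3) < 0.03


def test_white_noise_has_no_stride_periodicity(rng):
    with pytest.raises(GaitEventError, match="manual"):
        estimate_stride_frequency(rng.standard_normal(int(30 * RATE)), RATE)


def test_symmetric_sinusoid_returns_alternate_minima():
    # step rate 1.7 Hz: minima every 1/1.7 s; stride class every 1/0.85 s
    t = np.arange(int(30 * RATE)) / RATE
    disp = np.sin(2 * np.pi * 1.7 * t)
    ev = detect_impacts(disp, RATE, 0.85)
    spacing = np.diff(ev.impact_times)
    np.testing.assert_allclose(spacing, 1 / 0.85, atol=0.01)
    assert any("ambiguous" in f for f in ev.flags)


def test_constant_displacement_raises():
    with pytest.raises(GaitEventError, match="minima"):
        detect_impacts(np.zeros(int(20 * RATE)), RATE, 0.9)


def test_impacts_match_truth_and_survive_dc_drift():
    _, trials, _, truth = _single_condition_session(seed=9,
                                                    noise=NOISE_FREE)
    trial = trials[0]
    accel = trial.imu_accel_vertical
    t = np.arange(len(accel)) / RATE
    for extra in (0.0, 0.5 + 0.0 * t, 0.3 * np.ones_like(t)):
        a = accel + extra
        freq = estimate_stride_frequency(a, RATE)
        disp = accel_to_displacement(a, RATE, freq)
        ev = detect_impacts(disp, RATE, freq, trial_id=trial.trial_id)
        errs = [np.abs(truth.true_impact_times[trial.trial_id] - ti).min()
                for ti in ev.impact_times]
        assert np.max(errs) < 0.020     # all within +-20 ms, noise-free
        med = np.median(ev.stride_durations)
        assert abs(med - 1.1) / 1.1 < 0.01


def test_events_to_strides_window_arithmetic():
    ev = GaitEventSeries(impact_times=np.array([1.0, 2.2, 3.4]))
    win, log = events_to_strides(ev, 10000, 2000.0)
    assert win == [(2000, 4400), (4400, 6800)]
    win, log = events_to_strides(ev, 1000, 200.0)
    assert win == [(200, 440), (440, 680)]


def test_out_of_span_stride_dropped_with_log():
    ev = GaitEventSeries(impact_times=np.array([-0.5, 1.0, 2.0]))
    win, log = events_to_strides(ev, 5000, 2000.0)
    assert win == [(2000, 4000)]
    assert len(log) == 1 and "dropped" in log[0]


def test_windows_tile_without_overlap_or_holes():
    ev = GaitEventSeries(impact_times=np.array([0.5, 1.45, 2.61, 3.5]))
    win, _ = events_to_strides(ev, 10000, 2000.0)
    for (a0, a1), (b0, b1) in zip(win, win[1:]):
        assert a1 == b0
    covered = sum(i1 - i0 for i0, i1 in win)
    assert covered == win[-1][1] - win[0][0]
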