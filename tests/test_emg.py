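"""Envelope extraction, peak amplitudes, outlier removal, RVC scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitspm import SessionConfig, generate_session
from gaitspm.assembly import normalise_strides
from gaitspm.config import ConditionSpec
from gaitspm.emg import (
    EMGError,
    compute_rvc,
    envelope,
    outlier_flags_one_muscle,
    remove_outlier_strides,
    rvc_normalise,
    stride_peak_amplitudes,
)
from gaitspm.gait_events import events_to_strides
from gaitspm.synthetic import NoiseSpec, study_replication_effects
from gaitspm.types import GaitEventSeries

RATE = 2000.0


def test_constant_input_has_zero_envelope():
    env, _ = envelope(np.full(int(5 * RATE), 3.0), RATE)
    assert env.max() < 1e-9 * 3.0


def test_sine_envelope_equals_mean_rectified_value():
    # full-wave rectified unit sine has mean 2/pi; the 10 Hz low-pass keeps
    # only that DC term of the 100 Hz rectified carrier
    t = np.arange(int(10 * RATE)) / RATE
    env, _ = envelope(np.sin(2 * np.pi * 100 * t), RATE)
    mid = env[len(env) // 4: 3 * len(env) // 4]
    np.testing.assert_allclose(mid, 2 / np.pi, rtol=0.02)


def test_sampling_rate_must_exceed_twice_highpass_cutoff():
    with pytest.raises(EMGError):
        envelope(np.zeros(1000), 60.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=50.0))
def test_envelope_scale_equivariance(k):
    rng = np.random.default_rng(99)
    x = rng.standard_normal(4000)
    e1, _ = envelope(x, RATE)
    e2, _ = envelope(k * x, RATE)
    np.testing.assert_allclose(e2, k * e1, rtol=1e-9, atol=1e-12)


def test_burst_positions_recovered_from_modulated_carrier():
    cfg = SessionConfig(conditions=(ConditionSpec("TM", 1.7,
                                                  has_markers=False),),
                        trial_duration=30.0)
    effects = {"TM": study_replication_effects(cfg.muscles)["TM"]}
    noise = NoiseSpec(emg_baseline=0.0, emg_artefact=0.0, emg_dc_offset=0.0)
    trials, _, truth = generate_session(cfg, effects, seed=11, noise=noise)
    trial = trials[0]
    ev = GaitEventSeries(impact_times=truth.true_impact_times["TM-1"])
    for muscle in ("TFL", "LD_left"):
        env, _ = envelope(trial.emg[muscle], RATE)
        win, _ = events_to_strides(ev, len(env), RATE)
        mean_curve = normalise_strides(env, win, 101).mean(axis=0)
        peak = int(np.argmax(mean_curve))
        true_peak = int(np.argmax(truth.true_envelopes["TM"][muscle]))
        assert abs(peak - true_peak) <= 2     # within 2% stride


def test_peak_amplitude_of_ramp_and_constant():
    ramp = np.linspace(0, 1, 1000, endpoint=False)
    pas = stride_peak_amplitudes(ramp, [(0, 500), (500, 1000)])
    assert pas[0] == pytest.approx(ramp[499])
    assert pas[1] == pytest.approx(ramp[999])
    const = np.full(1000, 2.5)
    np.testing.assert_allclose(
        stride_peak_amplitudes(const, [(0, 500), (500, 1000)]), 2.5)
    with pytest.raises(EMGError):
        stride_peak_amplitudes(ramp, [(10, 10)])


def test_identical_peak_amplitudes_never_flagged():
    flags = outlier_flags_one_muscle(np.full(32, 1.7))
    assert not flags.any()


def test_single_gross_outlier_is_flagged_exactly():
    rng = np.random.default_rng(5)
    pas = 1.0 + 0.01 * rng.standard_normal(32)
    pas[17] = 10.0
    flags = outlier_flags_one_muscle(pas)
    assert flags[17] and flags.sum() == 1


def test_normal_peak_amplitudes_rarely_flagged(rng):
    # median +- 3 scaled-MAD on i.i.d. normal PAs: ~1% flag rate at n = 32
    rates = []
    for _ in range(2000):
        flags = outlier_flags_one_muscle(rng.standard_normal(32))
        rates.append(flags.mean())
    assert np.mean(rates) < 0.02


def test_flagging_invariant_to_stride_order(rng):
    pas = rng.normal(1.0, 0.1, size=32)
    pas[5] = 5.0
    perm = rng.permutation(32)
    f0 = outlier_flags_one_muscle(pas)
    f1 = outlier_flags_one_muscle(pas[perm])
    assert np.array_equal(f1, f0[perm])


def test_global_removal_unions_muscles_and_needs_five_strides():
    pas = {"BF": np.array([1.0, 1.0, 1.0, 9.0, 1.0, 1.0]),
           "GM": np.array([1.0, 1.0, 1.0, 1.0, 1.0, 8.0])}
    flags, log = remove_outlier_strides(pas)
    assert list(np.flatnonzero(flags)) == [3, 5]
    few = {"BF": np.ones(4)}
    flags, log = remove_outlier_strides(few)
    assert not flags.any() and any("skipped" in m for m in log)


def test_rvc_definition_and_scale_invariance():
    pas = np.array([0.4, 0.9, 0.7])
    rvc = compute_rvc(pas)
    assert rvc == pytest.approx(0.9)
    env = np.array([0.9, 0.45, 1.8])
    out = rvc_normalise(env, rvc)
    np.testing.assert_allclose(out, [100.0, 50.0, 200.0])
    # uniform gain applied to everything (including the reference) cancels
    out2 = rvc_normalise(2 * env, compute_rvc(2 * pas))
    np.testing.assert_allclose(out2, out)
    with pytest.raises(EMGError, match="GM"):
        rvc_normalise(env, 0.0, muscle="GM")
    with pytest.raises(EMGError):
        compute_rvc(np.array([1.0, 2.0]), np.array([True, True]))
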