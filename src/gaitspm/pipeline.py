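"""End-to-end study orchestration: generate/load -> events -> envelopes ->
kinematics -> assembly -> SPM -> report.

The reference (overground) condition participates in sEMG analyses only;
kinematic comparisons run over the conditions with marker data (the
treadmill conditions). sEMG comparisons are reference-vs-each-treadmill
plus all treadmill pairs. Strides are paired across conditions by rank
order of occurrence after count equalisation. All randomness flows from
the single configuration seed through named per-stage substreams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assembly import EqualisationReport, equalise_counts, normalise_strides
from .config import SessionConfig
from .emg import (
    compute_rvc,
    envelope,
    remove_outlier_strides,
    rvc_normalise,
    stride_peak_amplitudes,
)
from .gait_events import (
    accel_to_displacement,
    detect_impacts,
    estimate_stride_frequency,
    events_to_strides,
)
from .kinematics import compute_angles
from .config import DEFAULT_ANGLES
from .synthetic import ConditionEffect, NoiseSpec, generate_session
from .types import (
    GaitEventSeries,
    SPMResult,
    StaticTrial,
    StrideMatrix,
    TrialRecording,
    validate_session,
)
from .spm import spm_paired_test


class PipelineError(RuntimeError):
    def __init__(self, stage: str, trial_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed"
                         + (f" on trial {trial_id!r}" if trial_id else "")
                         + f": {cause}")
        self.stage, self.trial_id, self.cause = stage, trial_id, cause


@dataclass
class TrialResult:
    """Per-trial intermediates kept for assembly."""

    trial: TrialRecording
    events: GaitEventSeries
    emg_windows: list[tuple[int, int]]
    mocap_windows: list[tuple[int, int]] | None
    envelopes: dict[str, np.ndarray]
    peak_amplitudes: dict[str, np.ndarray]
    outlier_flags: np.ndarray
    angles: dict[str, np.ndarray] | None
    log: list[str] = field(default_factory=list)

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(~self.outlier_flags)


@dataclass
class StudyReport:
    """Run summary: stride accounting, comparisons, provenance."""

    config: SessionConfig
    seed: int
    accounting: dict[str, EqualisationReport]
    comparisons: list[SPMResult]
    rvc: dict[str, float]
    figure_paths: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    version: str = ""

    @property
    def total_semg_strides(self) -> int:
        return self.accounting["semg"].total

    @property
    def total_kinematic_strides(self) -> int:
        return self.accounting["kinematic"].total if "kinematic" in \
            self.accounting else 0

    def summary_rows(self) -> list[dict]:
        rows = []
        for r in self.comparisons:
            rows.append({
                "variable": r.variable, "condition_a": r.condition_a,
                "condition_b": r.condition_b, "dof": r.dof,
                "fwhm_nodes": r.fwhm, "t_star": r.t_star,
                "n_clusters": len(r.clusters),
                "significant": r.significant,
                "min_cluster_p": (min(c.p for c in r.clusters)
                                  if r.clusters else np.nan),
            })
        return rows


def process_trial(trial: TrialRecording, config: SessionConfig,
                  static: StaticTrial | None, outlier_k: float = 3.0,
                  side: str = "auto") -> TrialResult:
    """Events, envelopes, peak amplitudes, outlier flags and angles for one
    trial."""
    tid = trial.trial_id or trial.condition
    log: list[str] = []
    try:
        freq = estimate_stride_frequency(trial.imu_accel_vertical,
                                         trial.imu_rate)
        disp = accel_to_displacement(trial.imu_accel_vertical, trial.imu_rate,
                                     freq)
        events = detect_impacts(disp, trial.imu_rate, freq, side=side,
                                trial_id=tid)
        log += [f"{tid}: {m}" for m in events.flags]
    except Exception as exc:
        raise PipelineError("gait_events", tid, exc) from exc

    try:
        emg_windows, drop_log = events_to_strides(
            events, len(next(iter(trial.emg.values()))), trial.emg_rate,
            trial.start_time)
        log += [f"{tid}: {m}" for m in drop_log]
        envelopes, pas = {}, {}
        for muscle, raw in trial.emg.items():
            env, clipped = envelope(raw, trial.emg_rate)
            if clipped > 0:
                log.append(f"{tid}/{muscle}: {clipped:.2%} samples clipped "
                           "to zero after envelope low-pass")
            envelopes[muscle] = env
            pas[muscle] = stride_peak_amplitudes(env, emg_windows)
        flags, olog = remove_outlier_strides(pas, k=outlier_k)
        log += [f"{tid}: {m}" for m in olog]
    except Exception as exc:
        raise PipelineError("emg", tid, exc) from exc

    mocap_windows = angles = None
    if trial.markers is not None:
        try:
            wave = compute_angles(trial, static)
            log += [f"{tid}: {m}" for m in wave.flags]
            mocap_windows, drop_log = events_to_strides(
                events, len(wave.times), trial.mocap_rate, trial.start_time)
            log += [f"{tid}: {m}" for m in drop_log]
            if len(mocap_windows) != len(emg_windows):
                raise RuntimeError(
                    "stride windows disagree between sEMG and kinematic "
                    f"rates ({len(emg_windows)} vs {len(mocap_windows)})")
            angles = wave.angles
        except Exception as exc:
            raise PipelineError("kinematics", tid, exc) from exc

    return TrialResult(trial=trial, events=events, emg_windows=emg_windows,
                       mocap_windows=mocap_windows, envelopes=envelopes,
                       peak_amplitudes=pas, outlier_flags=flags,
                       angles=angles, log=log)


def _assemble(results: list[TrialResult], config: SessionConfig,
              rvc: dict[str, float]
              ) -> tuple[dict[str, dict[str, StrideMatrix]],
                         dict[str, dict[str, StrideMatrix]]]:
    """Per-variable, per-condition stride matrices (sEMG in %RVC, angles
    in degrees), outlier strides removed, chronological order."""
    semg: dict[str, dict[str, StrideMatrix]] = {m: {} for m in config.muscles}
    kin: dict[str, dict[str, StrideMatrix]] = {a: {} for a in DEFAULT_ANGLES}
    for label in config.condition_labels:
        cond_results = [r for r in results if r.trial.condition == label]
        if not cond_results:
            continue
        for muscle in config.muscles:
            rows, prov = [], []
            for r in cond_results:
                env = rvc_normalise(r.envelopes[muscle], rvc[muscle], muscle)
                keep = [r.emg_windows[i] for i in r.retained]
                mat = normalise_strides(env, keep, config.node_count)
                rows.append(mat)
                prov += [(r.trial.trial_id, int(i)) for i in r.retained]
            semg[muscle][label] = StrideMatrix(
                variable=muscle, condition=label,
                values=np.vstack(rows), provenance=prov)
        if all(r.angles is not None for r in cond_results):
            for angle in DEFAULT_ANGLES:
                rows, prov = [], []
                for r in cond_results:
                    keep = [r.mocap_windows[i] for i in r.retained]
                    mat = normalise_strides(r.angles[angle], keep,
                                            config.node_count)
                    rows.append(mat)
                    prov += [(r.trial.trial_id, int(i)) for i in r.retained]
                kin[angle][label] = StrideMatrix(
                    variable=angle, condition=label,
                    values=np.vstack(rows), provenance=prov)
    kin = {a: d for a, d in kin.items() if d}
    return semg, kin


def semg_comparison_pairs(config: SessionConfig) -> list[tuple[str, str]]:
    ref = config.reference_label
    others = [la for la in config.condition_labels if la != ref]
    return [(ref, o) for o in others] + list(itertools.combinations(others, 2))


def kinematic_comparison_pairs(config: SessionConfig) -> list[tuple[str, str]]:
    return list(itertools.combinations(config.kinematic_labels, 2))


def run_study(config: SessionConfig,
              effects: dict[str, ConditionEffect] | None = None,
              noise: NoiseSpec = NoiseSpec(),
              seed: int | None = None,
              session: tuple[list[TrialRecording], StaticTrial | None] | None = None,
              outlier_k: float = 3.0,
              paired: bool = True,
              output_dir: str | Path | None = None,
              make_figures: bool = False) -> StudyReport:
    """Execute the full pipeline; returns the study report.

    ``session`` supplies pre-recorded trials; otherwise a synthetic session
    is generated from ``effects`` (study-replication defaults) with the
    given seed. With ``output_dir`` set, result tables (and figures when
    requested) are written there.
    """
    seed = config.seed if seed is None else seed
    log: list[str] = []
    if session is None:
        trials, static, _truth = generate_session(config, effects, seed,
                                                  noise)
        log.append(f"generated synthetic session (seed {seed})")
    else:
        trials, static = session

    report = validate_session(config, trials, static)
    log += [f"validate: {v.where}: {v.message}" for v in report.flags]
    if not report.passed:
        raise PipelineError("validate", "", RuntimeError(report.summary()))

    results = [process_trial(t, config, static, outlier_k=outlier_k)
               for t in trials]
    for r in results:
        log += r.log

    # RVC per muscle from the reference condition's retained strides
    ref = config.reference_label
    rvc: dict[str, float] = {}
    try:
        for muscle in config.muscles:
            pas = np.concatenate([
                r.peak_amplitudes[muscle][r.retained]
                for r in results if r.trial.condition == ref])
            rvc[muscle] = compute_rvc(pas)
    except Exception as exc:
        raise PipelineError("rvc", ref, exc) from exc

    semg, kin = _assemble(results, config, rvc)

    accounting: dict[str, EqualisationReport] = {}
    try:
        target = config.strides_per_condition
        first = {la: m for la, m in next(iter(semg.values())).items()}
        semg = {m: equalise_counts(d, target)[0] for m, d in semg.items()}
        accounting["semg"] = EqualisationReport(
            target=target,
            retained={la: target for la in first},
            removed={la: m.n_strides - target
                     for la, m in first.items()})
        if kin:
            first_k = next(iter(kin.values()))
            kin = {a: equalise_counts(d, target)[0] for a, d in kin.items()}
            accounting["kinematic"] = EqualisationReport(
                target=target,
                retained={la: target for la in first_k},
                removed={la: m.n_strides - target
                         for la, m in first_k.items()})
    except Exception as exc:
        raise PipelineError("equalise_counts", "", exc) from exc

    comparisons: list[SPMResult] = []
    try:
        for muscle in config.muscles:
            for a, b in semg_comparison_pairs(config):
                comparisons.append(spm_paired_test(
                    semg[muscle][a], semg[muscle][b], alpha=config.alpha,
                    paired=paired))
        for angle in kin:
            for a, b in kinematic_comparison_pairs(config):
                comparisons.append(spm_paired_test(
                    kin[angle][a], kin[angle][b], alpha=config.alpha,
                    paired=paired))
    except Exception as exc:
        raise PipelineError("spm", "", exc) from exc

    report = StudyReport(config=config, seed=seed, accounting=accounting,
                         comparisons=comparisons, rvc=rvc, log=log,
                         version=__version__)
    if output_dir is not None:
        from .report import write_report
        write_report(report, semg, kin, Path(output_dir),
                     make_figures=make_figures)
    return report
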