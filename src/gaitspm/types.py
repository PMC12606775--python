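"""Core domain containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import MARKER_NAMES


@dataclass
class TrialRecording:
    """One condition's raw synchronous recording on a shared clock.

    All streams start at ``start_time`` (one time origin; the hardware
    trigger is modelled as exact simultaneity). ``markers`` maps marker name
    to an (n_frames, 3) array in mm; frames flagged in ``marker_gaps`` hold
    NaN positions. ``markers`` is None for conditions without optical capture
    (overground in the source study).
    """

    condition: str
    emg: dict[str, np.ndarray]          # muscle -> (n,) volts at emg_rate
    imu_accel_vertical: np.ndarray      # (n,) m/s^2 at imu_rate
    markers: Optional[dict[str, np.ndarray]]  # name -> (n, 3) mm at mocap_rate
    marker_gaps: Optional[dict[str, np.ndarray]]  # name -> (n,) bool
    emg_rate: float
    imu_rate: float
    mocap_rate: float
    duration: float
    start_time: float = 0.0
    trial_id: str = ""

    def emg_times(self) -> np.ndarray:
        n = len(next(iter(self.emg.values())))
        return self.start_time + np.arange(n) / self.emg_rate

    def imu_times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.imu_accel_vertical)) / self.imu_rate

    def mocap_times(self) -> np.ndarray:
        if self.markers is None:
            return np.empty(0)
        n = len(next(iter(self.markers.values())))
        return self.start_time + np.arange(n) / self.mocap_rate


@dataclass
class StaticTrial:
    """Mean marker positions from the square-stance trial, plus the derived
    static sagittal angles (filled in by the kinematics stage)."""

    markers: dict[str, np.ndarray]      # name -> (3,) mm
    static_angles: dict[str, float] = field(default_factory=dict)  # degrees


@dataclass
class GaitEventSeries:
    """Detected right-hind impact times and derived stride timing."""

    impact_times: np.ndarray            # (k,) s, strictly increasing
    provenance: str = ""
    side: str = "right"
    flags: list[str] = field(default_factory=list)

    @property
    def stride_durations(self) -> np.ndarray:
        return np.diff(self.impact_times)

    @property
    def stride_frequency(self) -> float:
        """Median stride rate, Hz."""
        d = self.stride_durations
        if len(d) == 0:
            raise ValueError("need at least 2 impacts to define a stride")
        return float(np.median(1.0 / d))

    def __post_init__(self) -> None:
        t = np.asarray(self.impact_times, dtype=float)
        if len(t) >= 2:
            d = np.diff(t)
            if np.any(d <= 0):
                raise ValueError("impact times must be strictly increasing")
            med = np.median(d)
            for i, di in enumerate(d):
                if abs(di - med) > 0.25 * med:
                    self.flags.append(
                        f"stride {i}: duration {di:.3f}s deviates >25% from median {med:.3f}s"
                    )
        self.impact_times = t


@dataclass
class StrideMatrix:
    """n_strides x node_count time-normalised waveforms for one variable
    and condition, with per-row provenance (trial id, stride index)."""

    variable: str
    condition: str
    values: np.ndarray                  # (n_strides, node_count)
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stride matrix contains non-finite values")
        if len(self.provenance) != self.values.shape[0]:
            raise ValueError("provenance length must match row count")

    @property
    def n_strides(self) -> int:
        return self.values.shape[0]

    @property
    def node_count(self) -> int:
        return self.values.shape[1]


@dataclass
class Cluster:
    """A maximal supra-threshold run of the t-field."""

    start_node: int
    end_node: int                       # inclusive
    max_abs_t: float
    extent_nodes: int
    p: float

    def formatted_p(self, floor: float = 0.001) -> str:
        return f"< {floor:.3f}" if self.p < floor else f"{self.p:.3f}"


@dataclass
class SPMResult:
    """Outcome of one 1D SPM comparison."""

    variable: str
    condition_a: str
    condition_b: str
    t_field: np.ndarray
    dof: int
    fwhm: float                         # nodes
    resels: float
    t_star: float
    alpha: float
    clusters: list[Cluster]
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


@dataclass
class SyntheticGroundTruth:
    """The generator's hidden truth, used as the recovery oracle."""

    true_impact_times: dict[str, np.ndarray]        # trial id -> (k,) s
    true_angle_waveforms: dict[str, dict[str, np.ndarray]]  # condition -> angle -> (Q,)
    true_envelopes: dict[str, dict[str, np.ndarray]]        # condition -> muscle -> (Q,)
    true_displacement: dict[str, np.ndarray]        # trial id -> (n,) mm


@dataclass
class Violation:
    where: str
    message: str
    fatal: bool = True


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(v.fatal for v in self.violations)

    @property
    def flags(self) -> list[Violation]:
        return [v for v in self.violations if not v.fatal]

    def add(self, where: str, message: str, fatal: bool = True) -> None:
        self.violations.append(Violation(where, message, fatal))

    def summary(self) -> str:
        lines = [f"{'FAIL' if v.fatal else 'flag'} {v.where}: {v.message}"
                 for v in self.violations]
        status = "PASS" if self.passed else "FAIL"
        return "\n".join([f"validation: {status} ({len(lines)} items)"] + lines)


def validate_session(config, trials, static) -> ValidationReport:
    """Check a session against the configuration invariants (report-only).

    Conditions without optical capture configured (``has_markers=False``,
    overground in the source study) may lack marker data; that is recorded
    as an informational flag, not a failure.
    """
    report = ValidationReport()
    seen = set()
    for trial in trials:
        tid = trial.trial_id or trial.condition
        try:
            cond = config.condition(trial.condition)
        except KeyError:
            report.add(tid, f"condition {trial.condition!r} not in configuration")
            continue
        seen.add(trial.condition)
        for rate_name, have in (
            ("emg_rate", trial.emg_rate),
            ("imu_rate", trial.imu_rate),
            ("mocap_rate", trial.mocap_rate),
        ):
            want = getattr(config, rate_name)
            if abs(have - want) > 1e-9 * want:
                report.add(tid, f"{rate_name} {have} differs from configured {want}")
        n_expect = round(trial.duration * trial.emg_rate)
        for muscle in config.muscles:
            if muscle not in trial.emg:
                report.add(tid, f"missing sEMG channel {muscle}")
            elif abs(len(trial.emg[muscle]) - n_expect) > 1:
                report.add(
                    tid,
                    f"sEMG channel {muscle} has {len(trial.emg[muscle])} samples, "
                    f"expected ~{n_expect} for {trial.duration}s at {trial.emg_rate}Hz",
                )
        n_imu = round(trial.duration * trial.imu_rate)
        if abs(len(trial.imu_accel_vertical) - n_imu) > 1:
            report.add(tid, f"IMU series length {len(trial.imu_accel_vertical)} "
                            f"inconsistent with duration x rate ({n_imu})")
        if trial.markers is None:
            if cond.has_markers:
                report.add(tid, "marker data missing for a kinematic condition")
            else:
                report.add(tid, "no marker data (condition configured without "
                                "optical capture)", fatal=False)
        else:
            for name in MARKER_NAMES:
                if name not in trial.markers:
                    report.add(tid, f"missing marker {name}")
                    continue
                xyz = trial.markers[name]
                gaps = (trial.marker_gaps or {}).get(
                    name, np.zeros(len(xyz), dtype=bool))
                nan_frames = ~np.all(np.isfinite(xyz), axis=1)
                if np.any(nan_frames & ~gaps):
                    report.add(tid, f"marker {name} has silent NaN frames "
                                    "(NaN without a gap flag)")
    for cond in config.conditions:
        if cond.label not in seen:
            report.add("session", f"no trial for condition {cond.label}")
    if static is None:
        report.add("static", "static (square-stance) trial missing", fatal=False)
    else:
        for name in MARKER_NAMES:
            if name not in static.markers:
                report.add("static", f"missing marker {name}")
            elif not np.all(np.isfinite(static.markers[name])):
                report.add("static", f"marker {name} position not finite")
    return report
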