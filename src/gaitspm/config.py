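"""Study configuration: conditions, rates, filter specifications, conventions.

The defaults encode a walking-horse treadmill study: four conditions
(overground OG at preferred speed; dry treadmill TM at 1.7 m/s; dry treadmill
TM80 and water treadmill WT80 at 1.4 m/s, the water at mid-metatarsal depth),
sEMG and sacral-IMU streams at 2000 Hz, optical motion capture at 200 Hz,
strides resampled to 101 nodes, and per-comparison significance at alpha 0.05
with 32 strides retained per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml


class ConfigError(ValueError):
    """A SessionConfig invariant is violated."""


DEFAULT_MUSCLES = ("BF", "GM", "TFL", "LD_left", "LD_right")
DEFAULT_ANGLES = (
    "thoraco_flex_ext",
    "thoraco_lat_bend",
    "pelvis_roll",
    "pelvis_pitch",
    "pelvis_yaw",
)
MARKER_NAMES = ("T5", "L1", "S3", "TS", "LTC", "RTC")


@dataclass(frozen=True)
class ConditionSpec:
    """One exercise condition.

    ``belt_speed`` is in m/s (None for overground preferred speed);
    ``water_depth`` is a free-text tag (None = dry). ``has_markers`` is False
    for conditions where optical capture is unavailable (overground here);
    ``is_reference`` marks the condition whose strides define the per-muscle
    reference voluntary contraction (RVC) and which enters sEMG analyses only.
    """

    label: str
    belt_speed: float | None = None
    water_depth: str | None = None
    has_markers: bool = True
    is_reference: bool = False


def default_conditions() -> tuple[ConditionSpec, ...]:
    return (
        ConditionSpec("OG", belt_speed=None, has_markers=False, is_reference=True),
        ConditionSpec("TM", belt_speed=1.7),
        ConditionSpec("TM80", belt_speed=1.4),
        ConditionSpec("WT80", belt_speed=1.4, water_depth="mid-metatarsal"),
    )


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter design: kind, single-pass order, cutoff (Hz).

    ``zero_phase`` selects forward-backward application (no group delay; the
    effective attenuation is the square of the single-pass response).
    """

    kind: str  # "low-pass" | "high-pass"
    order: int = 4
    cutoff: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "high-pass"):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ConfigError("filter cutoff must be > 0")

    def validate_for_rate(self, rate: float) -> None:
        if not 0 < self.cutoff < rate / 2:
            raise ConfigError(
                f"cutoff {self.cutoff} Hz not strictly inside (0, Nyquist={rate / 2}) Hz"
            )


@dataclass(frozen=True)
class AngleConvention:
    """Sign rules for the five reported angles (immutable).

    All angles are Cardan x,y,z components of a child segment's rotation
    relative to its parent, expressed in a right-handed laboratory frame with
    x cranial (direction of travel), y left, z vertical up.

    * thoraco_flex_ext: flexion positive, extension negative (sagittal;
      flexion = -about-y component of caudal-relative-to-cranial rotation).
    * thoraco_lat_bend: bending right positive, left negative
      (transverse; right bend = -about-z component).
    * pelvis_roll: positive when the right tuber coxae moves ventrally
      relative to the left (+about-x component).
    * pelvis_pitch: flexion positive (-about-y component).
    * pelvis_yaw: positive when the right tuber coxae moves cranially
      relative to the left (+about-z component).
    """

    cardan_sequence: str = "xyz"
    # angle name -> (cardan component index, sign)
    component_map: tuple[tuple[str, int, float], ...] = (
        ("thoraco_flex_ext", 1, -1.0),
        ("thoraco_lat_bend", 2, -1.0),
        ("pelvis_roll", 0, 1.0),
        ("pelvis_pitch", 1, -1.0),
        ("pelvis_yaw", 2, 1.0),
    )

    def component(self, angle: str) -> tuple[int, float]:
        for name, idx, sign in self.component_map:
            if name == angle:
                return idx, sign
        raise KeyError(angle)


@dataclass
class SessionConfig:
    """Everything a study run needs to know about acquisition and analysis."""

    emg_rate: float = 2000.0
    imu_rate: float = 2000.0
    mocap_rate: float = 200.0
    node_count: int = 101
    alpha: float = 0.05
    conditions: tuple[ConditionSpec, ...] = field(default_factory=default_conditions)
    strides_per_condition: int = 32
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    trial_duration: float = 60.0
    trials_per_condition: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(
            c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
            for c in self.conditions
        )
        self.muscles = tuple(self.muscles)
        self.validate()

    def validate(self) -> None:
        if self.node_count < 3:
            raise ConfigError("node_count must be >= 3")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie strictly in (0, 1)")
        for name in ("emg_rate", "imu_rate", "mocap_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")
        if self.strides_per_condition < 1:
            raise ConfigError("strides_per_condition must be >= 1")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be > 0")

    # -- lookups -------------------------------------------------------------

    def condition(self, label: str) -> ConditionSpec:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(f"unknown condition {label!r}")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    @property
    def reference_label(self) -> str:
        for c in self.conditions:
            if c.is_reference:
                return c.label
        raise ConfigError("no reference (RVC) condition configured")

    @property
    def kinematic_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions if c.has_markers)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        d["muscles"] = list(self.muscles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# Filter designs used throughout the pipeline.
EMG_HIGHPASS = FilterSpec("high-pass", order=4, cutoff=40.0)
EMG_ENVELOPE_LOWPASS = FilterSpec("low-pass", order=4, cutoff=10.0)
KINEMATIC_LOWPASS = FilterSpec("low-pass", order=4, cutoff=30.0)
DISPLACEMENT_LOWPASS = FilterSpec("low-pass", order=4, cutoff=30.0)
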