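"""Stride time-normalisation to the common node grid and count equalisation.

Every retained stride is linearly resampled onto ``node_count`` points
spanning 0-100% of the stride (endpoints at the first sample of the stride
and the sample closing the half-open window). Conditions entering one SPM
comparison must hold the same number of strides; the surplus is trimmed
alternately from the beginning and end of each condition's chronological
sequence (beginning first), mirroring the study's removal of strides at the
start and end of each trial after outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import StrideMatrix


class AssemblyError(ValueError):
    pass


def time_normalise(samples: np.ndarray, node_count: int = 101) -> np.ndarray:
    """Linear interpolation of one stride onto the normalised grid.

    ``samples`` must include the closing sample of the half-open stride
    window (callers pass ``series[i0:i1 + 1]`` where available). Monotone
    input yields monotone output.
    """
    y = np.asarray(samples, dtype=float)
    if len(y) < 4:
        raise AssemblyError(f"stride too short to resample ({len(y)} samples)")
    if node_count < 3:
        raise AssemblyError("node_count must be >= 3")
    x = np.linspace(0.0, 1.0, len(y))
    xi = np.linspace(0.0, 1.0, node_count)
    return np.interp(xi, x, y)


def stride_window_samples(series: np.ndarray, window: tuple[int, int]
                          ) -> np.ndarray:
    """Samples of one stride including the closing sample when it exists."""
    i0, i1 = window
    end = min(i1 + 1, len(series))
    return np.asarray(series[i0:end], dtype=float)


def normalise_strides(series: np.ndarray, windows: list[tuple[int, int]],
                      node_count: int = 101) -> np.ndarray:
    """(n_strides, node_count) matrix from a series and stride windows."""
    rows = [time_normalise(stride_window_samples(series, w), node_count)
            for w in windows]
    return np.vstack(rows) if rows else np.empty((0, node_count))


@dataclass
class EqualisationReport:
    """Per-condition retained/removed accounting for one analysis."""

    target: int
    retained: dict[str, int] = field(default_factory=dict)
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.retained.values())

    def summary(self) -> str:
        lines = [f"equalised to {self.target} strides per condition "
                 f"(total {self.total})"]
        for label in self.retained:
            lines.append(f"  {label}: kept {self.retained[label]}, "
                         f"removed {self.removed[label]}")
        return "\n".join(lines)


def _trim_indices(n: int, target: int) -> np.ndarray:
    """Indices kept after alternately dropping from the beginning and end."""
    drop_front = drop_back = 0
    for k in range(n - target):
        if k % 2 == 0:
            drop_front += 1
        else:
            drop_back += 1
    return np.arange(drop_front, n - drop_back)


def equalise_counts(matrices: dict[str, StrideMatrix],
                    target: int | None = None,
                    ) -> tuple[dict[str, StrideMatrix], EqualisationReport]:
    """Trim every condition's stride matrix to the same row count.

    ``target`` defaults to the minimum retained count across conditions.
    Trimming alternates beginning / end (beginning first) over the
    condition's chronological stride sequence; provenance order is
    preserved. A condition below target raises with the shortfall.
    """
    if not matrices:
        raise AssemblyError("no stride matrices given")
    counts = {label: m.n_strides for label, m in matrices.items()}
    if target is None:
        target = min(counts.values())
    short = {la: c for la, c in counts.items() if c < target}
    if short:
        detail = ", ".join(f"{la} has {c} < {target}"
                           for la, c in short.items())
        raise AssemblyError(f"stride shortfall during equalisation: {detail}")
    report = EqualisationReport(target=target)
    out: dict[str, StrideMatrix] = {}
    for label, m in matrices.items():
        keep = _trim_indices(m.n_strides, target)
        out[label] = StrideMatrix(
            variable=m.variable, condition=m.condition,
            values=m.values[keep],
            provenance=[m.provenance[i] for i in keep])
        report.retained[label] = target
        report.removed[label] = m.n_strides - target
    return out, report
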