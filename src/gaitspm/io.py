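"""On-disk representations: CSV trial bundles, sessions, results tables.

A trial bundle is a directory holding ``emg.csv`` (time + one column per
muscle), ``imu.csv`` (time + vertical acceleration), ``markers.csv``
(time + x/y/z per marker, blank cells = gaps) and ``meta.yaml`` (condition,
rates, duration). CSV files are UTF-8, comma-separated, '.' decimal, with
at least 9 significant digits so round trips are lossless to float-text
precision. Reading tolerates trailing whitespace and CRLF line endings
(pandas handles both). Marker gaps shorter than a configurable span
(default 0.1 s) are linearly interpolated at read time with a logged count;
longer gaps stay NaN (flagged) and invalidate overlapping strides
downstream.

C3D reading (the optical-capture interchange format) is an optional
capability behind the ``ezc3d`` package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import MARKER_NAMES, SessionConfig
from .types import StaticTrial, SyntheticGroundTruth, TrialRecording

FLOAT_FMT = "%.10g"
DEFAULT_MAX_GAP_S = 0.1


class ParseError(ValueError):
    pass


class MissingDependencyError(ImportError):
    pass


def _check_time_column(t: np.ndarray, rate: float, name: str) -> None:
    if np.any(np.diff(t) <= 0):
        raise ParseError(f"{name}: time column not strictly increasing")
    if len(t) > 1:
        spacing = float(np.median(np.diff(t)))
        if abs(spacing - 1.0 / rate) > 1e-6 * (1.0 / rate):
            raise ParseError(
                f"{name}: sample spacing {spacing:.9g}s disagrees with "
                f"declared rate {rate}Hz beyond 1 ppm")


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write one trial as a CSV bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg = pd.DataFrame({"time": trial.emg_times(), **trial.emg})
    emg.to_csv(path / "emg.csv", index=False, float_format=FLOAT_FMT)
    imu = pd.DataFrame({"time": trial.imu_times(),
                        "accel_vertical": trial.imu_accel_vertical})
    imu.to_csv(path / "imu.csv", index=False, float_format=FLOAT_FMT)
    if trial.markers is not None:
        cols: dict[str, np.ndarray] = {"time": trial.mocap_times()}
        for name, xyz in trial.markers.items():
            gaps = (trial.marker_gaps or {}).get(
                name, np.zeros(len(xyz), dtype=bool))
            for j, ax in enumerate("xyz"):
                col = xyz[:, j].astype(float).copy()
                col[gaps] = np.nan    # blank cells in the CSV
                cols[f"{name}_{ax}"] = col
        pd.DataFrame(cols).to_csv(path / "markers.csv", index=False,
                                  float_format=FLOAT_FMT)
    meta = {"condition": trial.condition, "emg_rate": trial.emg_rate,
            "imu_rate": trial.imu_rate, "mocap_rate": trial.mocap_rate,
            "duration": trial.duration, "start_time": trial.start_time,
            "trial_id": trial.trial_id,
            "has_markers": trial.markers is not None}
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def interpolate_short_gaps(xyz: np.ndarray, gaps: np.ndarray, rate: float,
                           max_gap_s: float = DEFAULT_MAX_GAP_S
                           ) -> tuple[np.ndarray, np.ndarray, int]:
    """Fill gap runs shorter than ``max_gap_s``; returns (xyz, gaps, n_filled).

    Longer runs (and runs touching the series ends) remain NaN/flagged.
    """
    xyz = xyz.copy()
    gaps = gaps.copy()
    max_len = int(round(max_gap_s * rate))
    n_filled = 0
    i = 0
    n = len(gaps)
    while i < n:
        if not gaps[i]:
            i += 1
            continue
        j = i
        while j < n and gaps[j]:
            j += 1
        run = j - i
        if run <= max_len and i > 0 and j < n:
            for ax in range(xyz.shape[1]):
                xyz[i:j, ax] = np.interp(np.arange(i, j), [i - 1, j],
                                         [xyz[i - 1, ax], xyz[j, ax]])
            gaps[i:j] = False
            n_filled += run
        i = j
    return xyz, gaps, n_filled


def read_trial(path: str | Path, max_gap_s: float = DEFAULT_MAX_GAP_S
               ) -> tuple[TrialRecording, list[str]]:
    """Read a CSV trial bundle; returns (trial, log)."""
    path = Path(path)
    log: list[str] = []
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise ParseError(f"missing file {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())

    def load(name: str) -> pd.DataFrame:
        p = path / name
        if not p.exists():
            raise ParseError(f"missing file {p}")
        df = pd.read_csv(p, skipinitialspace=True)
        df.columns = [c.strip() for c in df.columns]
        if "time" not in df.columns:
            raise ParseError(f"{name}: malformed header (no 'time' column)")
        return df

    emg_df = load("emg.csv")
    _check_time_column(emg_df["time"].to_numpy(), meta["emg_rate"], "emg.csv")
    emg = {c: emg_df[c].to_numpy(dtype=float)
           for c in emg_df.columns if c != "time"}

    imu_df = load("imu.csv")
    _check_time_column(imu_df["time"].to_numpy(), meta["imu_rate"], "imu.csv")
    accel = imu_df["accel_vertical"].to_numpy(dtype=float)

    markers = gaps = None
    if meta.get("has_markers", True) and (path / "markers.csv").exists():
        mdf = load("markers.csv")
        _check_time_column(mdf["time"].to_numpy(), meta["mocap_rate"],
                           "markers.csv")
        names = sorted({c.rsplit("_", 1)[0] for c in mdf.columns
                        if c != "time"})
        markers, gaps = {}, {}
        for name in names:
            xyz = np.column_stack([mdf[f"{name}_{ax}"].to_numpy(dtype=float)
                                   for ax in "xyz"])
            g = ~np.all(np.isfinite(xyz), axis=1)
            xyz[g] = np.nan
            xyz, g, filled = interpolate_short_gaps(
                xyz, g, meta["mocap_rate"], max_gap_s)
            if filled:
                log.append(f"marker {name}: {filled} gap frames "
                           f"(< {max_gap_s}s runs) interpolated at read")
            markers[name], gaps[name] = xyz, g

    trial = TrialRecording(
        condition=meta["condition"], emg=emg, imu_accel_vertical=accel,
        markers=markers, marker_gaps=gaps, emg_rate=meta["emg_rate"],
        imu_rate=meta["imu_rate"], mocap_rate=meta["mocap_rate"],
        duration=meta["duration"], start_time=meta.get("start_time", 0.0),
        trial_id=meta.get("trial_id", path.name))
    return trial, log


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def write_session(path: str | Path, config: SessionConfig,
                  trials: list[TrialRecording], static: StaticTrial | None,
                  truth: SyntheticGroundTruth | None = None) -> Path:
    """Write a whole session (config + per-trial bundles + static + truth)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    config.to_yaml(path / "config.yaml")
    for trial in trials:
        write_trial(trial, path / (trial.trial_id or trial.condition))
    if static is not None:
        rows = [{"marker": k, "x": v[0], "y": v[1], "z": v[2]}
                for k, v in static.markers.items()]
        pd.DataFrame(rows).to_csv(path / "static.csv", index=False,
                                  float_format=FLOAT_FMT)
    if truth is not None:
        rows = [{"trial_id": tid, "impact_time": t}
                for tid, times in truth.true_impact_times.items()
                for t in times]
        pd.DataFrame(rows).to_csv(path / "truth_impacts.csv", index=False,
                                  float_format=FLOAT_FMT)
        env_rows = []
        for cond, per_muscle in truth.true_envelopes.items():
            for muscle, curve in per_muscle.items():
                env_rows.append({"condition": cond, "variable": muscle,
                                 **{f"n{i:03d}": v
                                    for i, v in enumerate(curve)}})
        for cond, per_angle in truth.true_angle_waveforms.items():
            for angle, curve in per_angle.items():
                env_rows.append({"condition": cond, "variable": angle,
                                 **{f"n{i:03d}": v
                                    for i, v in enumerate(curve)}})
        pd.DataFrame(env_rows).to_csv(path / "truth_waveforms.csv",
                                      index=False, float_format=FLOAT_FMT)
    return path


def read_session(path: str | Path
                 ) -> tuple[SessionConfig, list[TrialRecording],
                            StaticTrial | None, list[str]]:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    config = SessionConfig.from_yaml(path / "config.yaml")
    trials, log = [], []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        if (sub / "meta.yaml").exists():
            trial, tl = read_trial(sub)
            trials.append(trial)
            log.extend(tl)
    static = None
    if (path / "static.csv").exists():
        df = pd.read_csv(path / "static.csv")
        static = StaticTrial(markers={
            r["marker"]: np.array([r["x"], r["y"], r["z"]])
            for _, r in df.iterrows()})
    # stable ordering: configuration order, then trial id
    order = {label: i for i, label in enumerate(config.condition_labels)}
    trials.sort(key=lambda t: (order.get(t.condition, 99), t.trial_id))
    return config, trials, static, log


# ---------------------------------------------------------------------------
# stride matrices and results
# ---------------------------------------------------------------------------

def write_stride_matrix(matrix, path: str | Path) -> Path:
    from .types import StrideMatrix  # noqa: F401 (documentation aid)
    path = Path(path)
    df = pd.DataFrame(matrix.values,
                      columns=[f"n{i:03d}" for i in range(matrix.node_count)])
    df.insert(0, "trial_id", [p[0] for p in matrix.provenance])
    df.insert(1, "stride_index", [p[1] for p in matrix.provenance])
    df.insert(0, "variable", matrix.variable)
    df.insert(1, "condition", matrix.condition)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_stride_matrix(path: str | Path):
    from .types import StrideMatrix
    df = pd.read_csv(path)
    nodes = [c for c in df.columns if c.startswith("n") and c[1:].isdigit()]
    return StrideMatrix(
        variable=str(df["variable"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        values=df[nodes].to_numpy(dtype=float),
        provenance=list(zip(df["trial_id"], df["stride_index"])))


# ---------------------------------------------------------------------------
# C3D (optional capability)
# ---------------------------------------------------------------------------

DEFAULT_C3D_ALIASES = {name: (name,) for name in MARKER_NAMES}


def map_c3d_labels(labels: list[str],
                   aliases: dict[str, tuple[str, ...]] | None = None
                   ) -> dict[str, int]:
    """Resolve model marker names to C3D point indices via an alias table.

    Matching is case-insensitive and ignores a "subject:" prefix. Raises
    listing the available labels when a required marker cannot be resolved.
    """
    aliases = aliases or DEFAULT_C3D_ALIASES
    stripped = [lb.split(":")[-1].strip().lower() for lb in labels]
    out: dict[str, int] = {}
    missing = []
    for name, alts in aliases.items():
        for alt in alts:
            if alt.lower() in stripped:
                out[name] = stripped.index(alt.lower())
                break
        else:
            missing.append(name)
    if missing:
        raise ParseError(
            f"markers not found after aliasing: {', '.join(missing)}; "
            f"available labels: {', '.join(labels)}")
    return out


def read_c3d_markers(path: str | Path,
                     aliases: dict[str, tuple[str, ...]] | None = None
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
                                float]:
    """Marker trajectories (mm) from a C3D file: (markers, gaps, rate).

    Frames with negative residual (the C3D convention for invalid points)
    become gaps. Requires the optional ``ezc3d`` dependency.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise MissingDependencyError(
            "reading C3D files requires the optional dependency 'ezc3d' "
            "(pip install ezc3d)") from exc
    c3d = ezc3d.c3d(str(path))
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    points = c3d["data"]["points"]          # (4, n_markers, n_frames)
    residuals = c3d["data"]["meta_points"]["residuals"][0]
    index = map_c3d_labels(list(labels), aliases)
    markers, gaps = {}, {}
    for name, i in index.items():
        xyz = points[:3, i, :].T.astype(float)
        bad = (residuals[i, :] < 0) | ~np.all(np.isfinite(xyz), axis=1)
        xyz[bad] = np.nan
        markers[name], gaps[name] = xyz, bad
    return markers, gaps, rate
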