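"""Rigid-segment back and pelvis kinematics from marker trajectories.

Segments
--------
* cranial: T5 -> L1 (thoracic back)
* caudal:  L1 -> TS (lumbar back)
* reference: T5 -> TS (trunk line, the parent of the pelvis)
* pelvis: proximal ends at the left/right tuber coxae (LTC, RTC), distal end
  at S3; a virtual marker 20 mm to the pelvic left of S3 is constructed to
  give the distal end mediolateral width.

Axis construction (laboratory frame: x cranial, y left, z up)
-------------------------------------------------------------
Two-point axial segments take local x along the segment pointing cranially,
local z as the lab-vertical component orthogonal to x, and y = z cross x.
The pelvis takes x from S3 toward the midpoint of the tubera coxarum
(pointing cranially), y along LTC - RTC orthogonalised against x, and
z = x cross y. These rules are deterministic and equivariant under rigid
motion of the marker set.

Angles are Cardan x,y,z components of the child segment's rotation relative
to its parent: thoracolumbar angles from caudal-relative-to-cranial, pelvic
angles from pelvis-relative-to-reference, with signs per
:class:`~gaitspm.config.AngleConvention`. Sagittal angles (thoracolumbar
flexion/extension, pelvis pitch) are normalised by subtracting the
square-stance static angle; lateral bend, roll and yaw are reported raw, as
their neutral is the 0-degree crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import (
    AngleConvention,
    FilterSpec,
    KINEMATIC_LOWPASS,
    DEFAULT_ANGLES,
)
from .filters import apply_filter
from .types import StaticTrial, TrialRecording

SAGITTAL_ANGLES = ("thoraco_flex_ext", "pelvis_pitch")
VIRTUAL_MARKER_OFFSET_MM = 20.0


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentModel:
    """Marker-to-segment assignment; see module docstring for axis rules."""

    cranial: tuple[str, str] = ("T5", "L1")
    caudal: tuple[str, str] = ("L1", "TS")
    reference: tuple[str, str] = ("T5", "TS")
    pelvis_proximal: tuple[str, str] = ("LTC", "RTC")   # (left, right)
    pelvis_distal: str = "S3"
    convention: AngleConvention = field(default_factory=AngleConvention)


def _normalise_rows(v: np.ndarray, eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    ok = norm[..., 0] > eps
    safe = np.where(norm > eps, norm, 1.0)
    return v / safe, ok


def two_point_frame(cranial_pt: np.ndarray, caudal_pt: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Frames (n, 3, 3) for a two-point axial segment; columns are axes.

    Returns (frames, valid). Invalid frames (coincident points, vertical
    segment) carry the identity and valid=False.
    """
    cranial_pt = np.atleast_2d(cranial_pt)
    caudal_pt = np.atleast_2d(caudal_pt)
    x, ok_x = _normalise_rows(cranial_pt - caudal_pt)
    z_lab = np.zeros_like(x)
    z_lab[..., 2] = 1.0
    z_raw = z_lab - x * (x[..., 2:3])
    z, ok_z = _normalise_rows(z_raw)
    y = np.cross(z, x)
    frames = np.stack([x, y, z], axis=-1)
    valid = ok_x & ok_z & np.all(np.isfinite(frames), axis=(-2, -1))
    frames[~valid] = np.eye(3)
    return frames, valid


def pelvic_frame(ltc: np.ndarray, rtc: np.ndarray, s3: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pelvic segment frames (n, 3, 3) from LTC, RTC and S3; see module doc."""
    ltc, rtc, s3 = np.atleast_2d(ltc), np.atleast_2d(rtc), np.atleast_2d(s3)
    prox_mid = 0.5 * (ltc + rtc)
    x, ok_x = _normalise_rows(prox_mid - s3)
    w = ltc - rtc
    y_raw = w - x * np.sum(w * x, axis=-1, keepdims=True)
    y, ok_y = _normalise_rows(y_raw)
    z = np.cross(x, y)
    frames = np.stack([x, y, z], axis=-1)
    valid = ok_x & ok_y & np.all(np.isfinite(frames), axis=(-2, -1))
    frames[~valid] = np.eye(3)
    return frames, valid


def virtual_left_marker(ltc: np.ndarray, rtc: np.ndarray, s3: np.ndarray
                        ) -> np.ndarray:
    """The virtual distal marker 20 mm to the pelvic left of S3."""
    frames, _ = pelvic_frame(ltc, rtc, s3)
    return np.atleast_2d(s3) + VIRTUAL_MARKER_OFFSET_MM * frames[..., :, 1]


def build_segment_frames(markers: dict[str, np.ndarray], model: SegmentModel
                         ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-segment rotations for every frame.

    Returns (frames, valid): ``frames`` maps segment name to (n, 3, 3)
    rotation matrices (segment axes as columns, lab coordinates); ``valid``
    is the conjunction of per-segment validity (finite markers, no
    degenerate geometry).
    """
    need = set(model.cranial) | set(model.caudal) | set(model.reference) \
        | set(model.pelvis_proximal) | {model.pelvis_distal}
    missing = sorted(need - set(markers))
    if missing:
        raise KinematicsError(f"missing markers: {', '.join(missing)}")
    m = {k: np.atleast_2d(np.asarray(markers[k], dtype=float)) for k in need}
    finite = np.ones(len(next(iter(m.values()))), dtype=bool)
    for v in m.values():
        finite &= np.all(np.isfinite(v), axis=-1)
    clean = {k: np.where(finite[:, None], v, 0.0) for k, v in m.items()}

    frames: dict[str, np.ndarray] = {}
    valid = finite.copy()
    for name, (a, b) in (("cranial", model.cranial),
                         ("caudal", model.caudal),
                         ("reference", model.reference)):
        f, ok = two_point_frame(clean[a], clean[b])
        frames[name] = f
        valid &= ok
    pf, ok = pelvic_frame(clean[model.pelvis_proximal[0]],
                          clean[model.pelvis_proximal[1]],
                          clean[model.pelvis_distal])
    frames["pelvis"] = pf
    valid &= ok
    return frames, valid


def rotation_cardan_xyz(angles_deg: np.ndarray) -> np.ndarray:
    """Compose R = Rx(a) @ Ry(b) @ Rz(c) from Cardan x,y,z angles (degrees)."""
    return Rotation.from_euler("XYZ", np.atleast_2d(angles_deg), degrees=True
                               ).as_matrix()


def cardan_xyz(rot: np.ndarray, gimbal_limit_deg: float = 85.0
               ) -> tuple[np.ndarray, list[str]]:
    """Decompose rotations as R = Rx @ Ry @ Rz; returns (angles_deg, flags).

    ``rot`` may be one (3, 3) matrix or a stack (n, 3, 3). Inputs are
    checked for orthonormality and det +1; proximity of the middle angle to
    +-90 degrees (gimbal lock) is flagged.
    """
    rot = np.asarray(rot, dtype=float)
    single = rot.ndim == 2
    stack = rot[None] if single else rot
    rtr = np.einsum("nij,nik->njk", stack, stack)
    if not np.allclose(rtr, np.eye(3), atol=1e-6):
        raise KinematicsError("input is not orthonormal")
    if not np.allclose(np.linalg.det(stack), 1.0, atol=1e-6):
        raise KinematicsError("input determinant is not +1 (not a rotation)")
    angles = Rotation.from_matrix(stack).as_euler("XYZ", degrees=True)
    flags = []
    n_gimbal = int(np.sum(np.abs(angles[:, 1]) > gimbal_limit_deg))
    if n_gimbal:
        flags.append(f"{n_gimbal} frames near gimbal lock (|about-y| > "
                     f"{gimbal_limit_deg} deg)")
    return (angles[0] if single else angles), flags


def relative_rotation(parent: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Child rotation expressed in the parent frame: R_parent^T @ R_child."""
    return np.einsum("...ji,...jk->...ik", parent, child)


@dataclass
class AngleWaveforms:
    """Per-frame angle series (degrees) with validity and provenance."""

    times: np.ndarray
    angles: dict[str, np.ndarray]       # angle name -> (n,)
    valid: np.ndarray                   # (n,) bool
    normalised: dict[str, bool]
    convention: AngleConvention
    flags: list[str] = field(default_factory=list)


def components_to_named(components: np.ndarray, segment_pair: str,
                        convention: AngleConvention) -> dict[str, np.ndarray]:
    """Map Cardan components (n, 3) to the named angles of one comparison."""
    if segment_pair == "thoraco":
        names = ("thoraco_flex_ext", "thoraco_lat_bend")
    elif segment_pair == "pelvis":
        names = ("pelvis_roll", "pelvis_pitch", "pelvis_yaw")
    else:
        raise KeyError(segment_pair)
    out = {}
    for name in names:
        idx, sign = convention.component(name)
        out[name] = sign * components[:, idx]
    return out


def named_to_components(named: dict[str, float], segment_pair: str,
                        convention: AngleConvention) -> np.ndarray:
    """Inverse of :func:`components_to_named` for one frame (forward model)."""
    comp = np.zeros(3)
    names = (("thoraco_flex_ext", "thoraco_lat_bend")
             if segment_pair == "thoraco"
             else ("pelvis_roll", "pelvis_pitch", "pelvis_yaw"))
    for name in names:
        idx, sign = convention.component(name)
        comp[idx] = sign * named.get(name, 0.0)
    return comp


def static_angles(static: StaticTrial, model: SegmentModel) -> dict[str, float]:
    """All five angles computed on the square-stance pose."""
    markers = {k: np.asarray(v, dtype=float)[None, :] for k, v in static.markers.items()}
    frames, valid = build_segment_frames(markers, model)
    if not valid[0]:
        raise KinematicsError("degenerate segment in static trial")
    out: dict[str, float] = {}
    thoraco, _ = cardan_xyz(relative_rotation(frames["cranial"], frames["caudal"]))
    for k, v in components_to_named(thoraco, "thoraco",
                                    model.convention).items():
        out[k] = float(v[0])
    pelv, _ = cardan_xyz(relative_rotation(frames["reference"], frames["pelvis"]))
    for k, v in components_to_named(pelv, "pelvis",
                                    model.convention).items():
        out[k] = float(v[0])
    return out


def _fill_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return x
    idx = np.arange(len(x))
    return np.interp(idx, idx[valid], x[valid])


def compute_angles(trial: TrialRecording, static: StaticTrial | None,
                   model: SegmentModel | None = None,
                   filt: FilterSpec = KINEMATIC_LOWPASS,
                   min_valid_fraction: float = 0.95) -> AngleWaveforms:
    """Thoracolumbar and pelvic angle waveforms for one trial.

    Angle series are low-pass filtered (default Butterworth 4th-order,
    30 Hz cut-off, zero phase) and the sagittal angles are normalised by
    subtracting the static square-stance angles. When ``static`` is None the
    normalisation is skipped and flagged.
    """
    model = model or SegmentModel()
    if trial.markers is None:
        raise KinematicsError(f"trial {trial.trial_id or trial.condition} "
                              "has no marker data")
    frames, valid = build_segment_frames(trial.markers, model)
    frac = float(np.mean(valid))
    flags: list[str] = []
    if frac < min_valid_fraction:
        raise KinematicsError(
            f"only {frac:.1%} of frames have valid segment geometry "
            f"(need >= {min_valid_fraction:.0%})")
    if frac < 1.0:
        flags.append(f"{int((~valid).sum())} invalid frames interpolated")

    thoraco, fl1 = cardan_xyz(relative_rotation(frames["cranial"], frames["caudal"]))
    pelv, fl2 = cardan_xyz(relative_rotation(frames["reference"], frames["pelvis"]))
    flags += fl1 + fl2
    angles = {}
    angles.update(components_to_named(thoraco, "thoraco", model.convention))
    angles.update(components_to_named(pelv, "pelvis", model.convention))

    statics = {}
    if static is not None:
        statics = static_angles(static, model)
        static.static_angles.update(statics)
    else:
        flags.append("static trial missing: sagittal normalisation skipped")

    normalised = {}
    for name in DEFAULT_ANGLES:
        x = _fill_invalid(angles[name], valid)
        x = apply_filter(x, filt, trial.mocap_rate)
        if name in SAGITTAL_ANGLES and statics:
            x = x - statics[name]
            normalised[name] = True
        else:
            normalised[name] = False
        angles[name] = x
    return AngleWaveforms(times=trial.mocap_times(), angles=angles, valid=valid,
                          normalised=normalised, convention=model.convention,
                          flags=flags)
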