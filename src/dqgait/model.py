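"""Planar 3-DoF kinematic chain of the human lower limb and its forward kinematics.

The right lower limb is modeled as three rigid segments (femur, tibia,
foot) linked by three revolute joints (hip, knee, ankle), all rotating
about the lateral axis ``z`` so the chain moves in the sagittal ``x-y``
plane.  The global frame sits at the hip: ``x`` anterior, ``y`` cranial,
``z`` lateral-right.  In the anatomical posture (all joint angles zero)
every local frame is aligned with the global one and the leg hangs
straight down.

Each joint ``i`` carries a rotation vector ``Phi_i = (theta_i / 2) u_i``
(``u_i = z``); the rigid transform from the parent frame is the unit dual
quaternion ``(1 + eps p_i/2) e^{Phi_i}`` with ``p_i`` the segment offset.
Forward kinematics composes these transforms and extracts each landmark's
posture — position ``p = 2 qd qp*`` (m) and orientation ``o = 2 ln(qp)``
(rotation vector, rad).

Joint angles cross the API boundary in degrees (positive =
counter-clockwise about ``+z``: hip flexion positive, knee flexion
negative, ankle dorsiflexion positive); internally everything is the
half-angle rotation vector in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dual_quaternions import (
    DualQuaternion,
    dq_from_rigid,
    dq_identity,
    dq_multiply,
    dq_translation,
)
from .quaternions import quat_exp, quat_log

__all__ = [
    "LANDMARKS",
    "SEGMENTS",
    "SegmentParams",
    "Posture",
    "default_params",
    "config_from_angles",
    "angles_from_config",
    "joint_transform",
    "chain_transforms",
    "forward_kinematics",
    "end_effector_posture",
    "max_reach",
    "postures_to_frame",
    "write_posture_csv",
    "read_posture_csv",
    "read_params_file",
]

#: Landmark names for the four reported postures: the three joint frames
#: (hip = F1, knee = F2, ankle = F3) and the end-effector frame at the toe.
LANDMARKS = ("hip", "knee", "ankle", "toe")

#: Body segments whose orientations the joint frames carry
#: (femur = F1, tibia = F2, foot = F3 and the toe frame, which shares it).
SEGMENTS = ("femur", "tibia", "foot")

POSTURE_CSV_COLUMNS = [
    "sample_index",
    "cycle_percent",
    "landmark",
    "pos_x_m",
    "pos_y_m",
    "pos_z_m",
    "ori_x_rad",
    "ori_y_rad",
    "ori_z_rad",
]


@dataclass(frozen=True)
class SegmentParams:
    """Geometry of the chain: per-joint offsets plus the end-effector offset.

    Attributes
    ----------
    p_rel : ndarray, shape (n, 3)
        Translation from frame ``F_{i-1}`` to joint ``i`` in metres.  For
        the lower limb ``p_rel[0] = 0`` (hip at the global origin),
        ``p_rel[1]`` is the femur and ``p_rel[2]`` the tibia, both
        pointing down (-y).
    p_end : ndarray, shape (3,)
        Offset from the ankle frame to the toe (end-effector): anterior
        (+x) to the distal phalanx, down (-y) by the malleolus height.
    phi_end : ndarray, shape (3,)
        Fixed end-effector rotation vector; zero for the leg model (the
        toe frame follows the ankle's orientation).
    """

    p_rel: np.ndarray
    p_end: np.ndarray
    phi_end: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_joints(self) -> int:
        return self.p_rel.shape[0]


@dataclass(frozen=True)
class Posture:
    """World posture of a frame: position (m) + orientation rotation vector (rad)."""

    position: np.ndarray
    orientation: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        """The 6-vector ``[p_W, o_W]``."""
        return np.concatenate([self.position, self.orientation])


def default_params() -> SegmentParams:
    """Lower-limb segment geometry for a 1.65 m subject.

    Femur 0.37 m, tibia 0.38 m, lateral-malleolus height 0.08 m and
    malleolus-to-hallux distance 0.25 m, arranged with the leg hanging
    from the hip at the origin (segment offsets in -y, foot forward +x).
    """
    return SegmentParams(
        p_rel=np.array([[0.0, 0.0, 0.0], [0.0, -0.37, 0.0], [0.0, -0.38, 0.0]]),
        p_end=np.array([0.25, -0.08, 0.0]),
        phi_end=np.zeros(3),
    )


def config_from_angles(theta_deg) -> np.ndarray:
    """Joint angles (deg) -> chain configuration of rotation vectors.

    Returns an ``(n, 3)`` array of ``Phi_i = (theta_i/2) z`` in radians.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    phi = np.zeros((theta.shape[0], 3))
    phi[:, 2] = 0.5 * theta
    return phi


def angles_from_config(phi: np.ndarray) -> np.ndarray:
    """Signed planar joint angles (deg) from a chain configuration."""
    return np.rad2deg(2.0 * np.asarray(phi)[:, 2])


def joint_transform(phi_i, p_i) -> DualQuaternion:
    """Unit dual quaternion ``(1 + eps p_i/2) e^{Phi_i}`` of one joint."""
    return dq_from_rigid(p_i, quat_exp(phi_i))


def chain_transforms(phi: np.ndarray, params: SegmentParams) -> list[DualQuaternion]:
    """Cumulative world transforms ``[q_1W, ..., q_nW, q_gW]``.

    The world frame ``F0`` is fixed (``q_0W`` = identity) and is not
    returned.
    """
    if phi.shape[0] != params.n_joints:
        raise ValueError(
            f"configuration has {phi.shape[0]} joints, parameters have {params.n_joints}"
        )
    q = dq_identity()
    out = []
    for i in range(params.n_joints):
        q = dq_multiply(q, joint_transform(phi[i], params.p_rel[i]))
        out.append(q)
    out.append(dq_multiply(q, joint_transform(params.phi_end, params.p_end)))
    return out


def _posture_of(q_: DualQuaternion) -> Posture:
    return Posture(dq_translation(q_), 2.0 * quat_log(q_.qp))


def forward_kinematics(phi: np.ndarray, params: SegmentParams) -> list[Posture]:
    """Postures of the joint frames and the end-effector.

    Parameters
    ----------
    phi : ndarray, shape (n, 3)
        Chain configuration (per-joint rotation vectors, rad).
    params : SegmentParams

    Returns
    -------
    list of Posture
        One per joint frame ``F1..Fn`` plus the end-effector frame, in
        chain order (for the leg: hip, knee, ankle, toe).
    """
    return [_posture_of(q_) for q_ in chain_transforms(phi, params)]


def end_effector_posture(phi: np.ndarray, params: SegmentParams) -> np.ndarray:
    """End-effector posture 6-vector ``[p_W, o_W]`` (the IK working quantity)."""
    return _posture_of(chain_transforms(phi, params)[-1]).vector


def max_reach(params: SegmentParams) -> float:
    """Upper bound on the end-effector distance from the origin (m)."""
    return float(
        sum(np.linalg.norm(p) for p in params.p_rel) + np.linalg.norm(params.p_end)
    )


# ---------------------------------------------------------------------------
# Posture-trajectory CSV I/O


def postures_to_frame(
    postures_per_sample: list[list[Posture]],
    cycle_percent=None,
    landmarks=LANDMARKS,
) -> pd.DataFrame:
    """Tabulate per-sample landmark postures in the posture-CSV schema."""
    if cycle_percent is None:
        cycle_percent = np.linspace(0.0, 100.0, len(postures_per_sample))
    rows = []
    for t, sample in enumerate(postures_per_sample):
        for name, post in zip(landmarks, sample):
            rows.append(
                (t, float(cycle_percent[t]), name, *post.position, *post.orientation)
            )
    return pd.DataFrame(rows, columns=POSTURE_CSV_COLUMNS)


def write_posture_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_posture_csv(path, landmark: str | None = None) -> pd.DataFrame:
    """Read a posture CSV; optionally restrict to one landmark's rows."""
    frame = pd.read_csv(path)
    missing = [c for c in POSTURE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"posture CSV {path} is missing columns {missing}")
    if landmark is not None:
        frame = frame[frame["landmark"] == landmark].reset_index(drop=True)
        if frame.empty:
            raise ValueError(f"posture CSV {path} has no rows for landmark {landmark!r}")
    return frame


def read_params_file(path) -> SegmentParams:
    """Read segment geometry from a YAML/key-value config file.

    Recognized keys (all optional, defaults = :func:`default_params`):
    ``femur_length_m``, ``tibia_length_m``, ``malleolus_height_m``,
    ``malleolus_to_toe_m``.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must be a key-value mapping")
    femur = float(data.get("femur_length_m", 0.37))
    tibia = float(data.get("tibia_length_m", 0.38))
    mall = float(data.get("malleolus_height_m", 0.08))
    toe = float(data.get("malleolus_to_toe_m", 0.25))
    return SegmentParams(
        p_rel=np.array([[0.0, 0.0, 0.0], [0.0, -femur, 0.0], [0.0, -tibia, 0.0]]),
        p_end=np.array([toe, -mall, 0.0]),
        phi_end=np.zeros(3),
    )
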