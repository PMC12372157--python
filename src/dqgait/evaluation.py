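"""Round-trip evaluation metrics and the homogeneous-matrix (DH-style) baseline.

The evaluation protocol mirrors the FK1 -> IK -> FK2 workflow: reference
joint angles are pushed through forward kinematics to produce target
postures (FK1), the DLS solver estimates angles from those targets, and a
second forward-kinematics pass (FK2) maps the estimates back to landmark
postures.  Agreement is summarized as RMS errors in joint space
(per-joint angles, deg), Cartesian space (per-landmark positions, m) and
segment orientation about the lateral axis (deg, the only rotation the
planar model admits).

The Denavit-Hartenberg-style baseline recomputes the same chain with
4x4 homogeneous-matrix composition (rotations via
``scipy.spatial.transform.Rotation``), sharing nothing with the
dual-quaternion kernel; it doubles as the independent forward-kinematics
oracle and as the alternative kernel inside the DLS solver for the
representation comparison.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import model
from .gait import JointTrajectory, trajectory_to_targets
from .ik import IKParams, IKResult, JointLimits, ik_track
from .model import LANDMARKS, SEGMENTS, Posture, SegmentParams

__all__ = [
    "rmse",
    "data_resolution",
    "dh_forward_kinematics",
    "dh_end_effector_posture",
    "ComparisonReport",
    "round_trip",
    "compare_formulations",
    "report_frame",
    "report_text",
]


def rmse(a, b) -> float:
    """Root-mean-square error between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rmse requires two non-empty arrays of equal shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def data_resolution(samples) -> float:
    """Smallest gap between distinct values: sort, deduplicate, min-diff.

    Estimates the effective resolution of a measured channel, which sets
    a floor on any meaningful convergence threshold.

    Raises
    ------
    ValueError
        If fewer than two distinct values are present.
    """
    distinct = np.unique(np.asarray(samples, dtype=float))
    if distinct.size < 2:
        raise ValueError("data_resolution requires at least two distinct values")
    return float(np.diff(distinct).min())


# ---------------------------------------------------------------------------
# Homogeneous-matrix baseline


def _homogeneous(rotvec: np.ndarray, p: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = Rotation.from_rotvec(rotvec).as_matrix()
    T[:3, 3] = p
    return T


def dh_forward_kinematics(phi: np.ndarray, params: SegmentParams) -> list[Posture]:
    """Forward kinematics by 4x4 homogeneous-matrix composition.

    Same contract as :func:`dqgait.model.forward_kinematics` (postures of
    the joint frames and end-effector), with orientation extracted as the
    rotation vector of the accumulated rotation matrix.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape[0] != params.n_joints:
        raise ValueError("configuration and parameters disagree on joint count")
    T = np.eye(4)
    postures = []
    for i in range(params.n_joints):
        T = T @ _homogeneous(2.0 * phi[i], params.p_rel[i])
        postures.append(
            Posture(T[:3, 3].copy(), Rotation.from_matrix(T[:3, :3]).as_rotvec())
        )
    T = T @ _homogeneous(2.0 * params.phi_end, params.p_end)
    postures.append(Posture(T[:3, 3].copy(), Rotation.from_matrix(T[:3, :3]).as_rotvec()))
    return postures


def dh_end_effector_posture(phi: np.ndarray, params: SegmentParams) -> np.ndarray:
    """End-effector posture 6-vector via the homogeneous-matrix kernel."""
    return dh_forward_kinematics(phi, params)[-1].vector


# ---------------------------------------------------------------------------
# Round-trip reports


@dataclass(frozen=True)
class ComparisonReport:
    """RMS summary of one FK -> IK -> FK round trip.

    joint_rmse_deg : per-joint angle RMSE, reference vs estimated (deg)
    position_rmse_m : per-landmark FK1-vs-FK2 position RMSE (m; knee,
        ankle, toe — the hip is pinned at the origin)
    orientation_rmse_deg : per-segment FK1-vs-FK2 orientation RMSE about
        z (deg; femur, tibia, foot)
    iterations : DLS iteration count per sample
    mean_error_norm : mean of the final posture-error norms
    elapsed_s : wall-clock solver time (informational only)
    """

    joint_rmse_deg: dict
    position_rmse_m: dict
    orientation_rmse_deg: dict
    iterations: np.ndarray
    mean_error_norm: float
    elapsed_s: float


def _landmark_arrays(postures_per_sample: list[list[Posture]]):
    pos = np.array([[p.position for p in sample] for sample in postures_per_sample])
    ori_z = np.array([[p.orientation[2] for p in sample] for sample in postures_per_sample])
    return pos, ori_z


def _build_report(
    ref_theta: np.ndarray,
    est_theta: np.ndarray,
    fk1: list[list[Posture]],
    fk2: list[list[Posture]],
    results: list[IKResult],
    elapsed_s: float,
) -> ComparisonReport:
    from .gait import JOINTS

    pos1, ori1 = _landmark_arrays(fk1)
    pos2, ori2 = _landmark_arrays(fk2)
    joint_rmse = {
        name: rmse(ref_theta[:, j], est_theta[:, j]) for j, name in enumerate(JOINTS)
    }
    # Landmarks 1..3 (knee, ankle, toe); the hip never moves.
    position_rmse = {
        name: float(np.sqrt(np.mean(np.sum((pos1[:, k] - pos2[:, k]) ** 2, axis=1))))
        for k, name in zip(range(1, 4), LANDMARKS[1:])
    }
    # Segment orientations ride on frames F1..F3 (femur, tibia, foot).
    orientation_rmse = {
        name: rmse(np.rad2deg(ori1[:, k]), np.rad2deg(ori2[:, k]))
        for k, name in zip(range(3), SEGMENTS)
    }
    return ComparisonReport(
        joint_rmse_deg=joint_rmse,
        position_rmse_m=position_rmse,
        orientation_rmse_deg=orientation_rmse,
        iterations=np.array([r.iterations for r in results], dtype=int),
        mean_error_norm=(
            float(np.mean([r.final_error_norm for r in results])) if results else float("nan")
        ),
        elapsed_s=elapsed_s,
    )


def round_trip(
    traj: JointTrajectory,
    params: SegmentParams,
    ik: IKParams,
    limits: JointLimits,
    phi0: np.ndarray,
    fk=model.end_effector_posture,
    warm_start: bool = True,
    log=None,
):
    """Run FK1 -> IK -> FK2 on a joint trajectory.

    Returns ``(estimated_theta_deg, results, report)``: the estimated
    angle matrix (n_samples x 3, deg), the per-sample solver results and
    the :class:`ComparisonReport`.
    """
    targets = [p.vector for p in trajectory_to_targets(traj, params)]
    t0 = time.perf_counter()
    results = ik_track(targets, params, ik, limits, phi0, fk=fk, warm_start=warm_start, log=log)
    elapsed = time.perf_counter() - t0
    est_theta = np.array([model.angles_from_config(r.config) for r in results])
    fk1 = [
        model.forward_kinematics(model.config_from_angles(th), params) for th in traj.theta
    ]
    fk2 = [
        model.forward_kinematics(model.config_from_angles(th), params) for th in est_theta
    ]
    report = _build_report(traj.theta, est_theta, fk1, fk2, results, elapsed)
    return est_theta, results, report


def compare_formulations(
    traj: JointTrajectory,
    params: SegmentParams,
    ik: IKParams,
    limits: JointLimits,
    phi0: np.ndarray,
    dh_max_iterations: int = 100,
) -> dict:
    """Run the round trip with both FK kernels inside the solver.

    The dual-quaternion run uses ``ik`` as given; the homogeneous-matrix
    run shares alpha, gamma and epsilon but gets its own iteration cap
    (default 100).  Only the FK kernel differs, isolating the
    representation variable.  Returns ``{"dq": report, "dh": report}``.
    """
    from dataclasses import replace

    _, _, dq_report = round_trip(traj, params, ik, limits, phi0, fk=model.end_effector_posture)
    dh_ik = replace(ik, max_iterations=dh_max_iterations)
    _, _, dh_report = round_trip(traj, params, dh_ik, limits, phi0, fk=dh_end_effector_posture)
    return {"dq": dq_report, "dh": dh_report}


def report_frame(report: ComparisonReport) -> pd.DataFrame:
    """Flatten a report into a tidy metric/name/value table."""
    rows = []
    for name, v in report.joint_rmse_deg.items():
        rows.append(("joint_angle_rmse_deg", name, v))
    for name, v in report.position_rmse_m.items():
        rows.append(("position_rmse_m", name, v))
    for name, v in report.orientation_rmse_deg.items():
        rows.append(("orientation_rmse_deg", name, v))
    if report.iterations.size:
        rows.append(("iterations", "mean", float(np.mean(report.iterations))))
        rows.append(("iterations", "max", float(np.max(report.iterations))))
        rows.append(("error_norm", "mean", report.mean_error_norm))
        rows.append(("time_s", "total", report.elapsed_s))
    return pd.DataFrame(rows, columns=["metric", "name", "value"])


def report_text(report: ComparisonReport, title: str = "Round-trip report") -> str:
    """Human-readable table of a report."""
    lines = [title, "-" * len(title)]
    lines.append("Joint angle RMSE (deg):")
    for name, v in report.joint_rmse_deg.items():
        lines.append(f"  {name:<8} {v:.6e}")
    lines.append("Landmark position RMSE (m):")
    for name, v in report.position_rmse_m.items():
        lines.append(f"  {name:<8} {v:.6e}")
    lines.append("Segment orientation RMSE about z (deg):")
    for name, v in report.orientation_rmse_deg.items():
        lines.append(f"  {name:<8} {v:.6e}")
    if report.iterations.size:
        lines.append(
            f"Iterations: mean {np.mean(report.iterations):.2f}, "
            f"min {np.min(report.iterations)}, max {np.max(report.iterations)}"
        )
        lines.append(f"Mean posture-error norm: {report.mean_error_norm:.3e}")
        lines.append(f"Solver wall time: {report.elapsed_s:.3f} s")
    return "\n".join(lines)
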