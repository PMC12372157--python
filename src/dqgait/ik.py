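"""Damped Least Squares inverse kinematics with joint-limit clamping.

Given a target end-effector posture ``zeta`` (6-vector: position m +
rotation-vector orientation rad), the solver iterates

    J      <- Jacobian d(xi)/d(Phi) at the current configuration
    dxi    <- alpha (zeta - xi)
    dPhi   <- J^T (J J^T + gamma^2 I)^-1 dxi
    Phi    <- clamp(Phi + dPhi)
    xi     <- forward kinematics(Phi)

until the posture-error norm drops below ``epsilon`` or ``N`` iterations
are exceeded.  The damping constant ``gamma`` keeps the step bounded
(``|dPhi| <= |dxi| / (2 gamma)``) even at singular configurations; the
step-size factor ``alpha`` keeps the linearization valid.  The error norm
is the unweighted Euclidean norm of the 6-vector (metres and radians
mixed); an optional diagonal weighting is accepted but defaults to
identity.

Clamping recovers each joint's signed planar angle ``theta_i = 2 Phi_i,z``
(degrees), clips it to the configured range of motion, and rebuilds
``Phi_i = (theta/2) z`` — which also projects any off-plane drift from
Jacobian noise back onto the planar axis.

Per-gait defaults shipped here: joint limits (normal gait unconstrained
at +/-180 deg; toe- and heel-walking tightly restricted), initial chain
configurations with the knee in slight flexion (-5 deg) to force the
knee-forward branch, and the (alpha, gamma) pairs tuned per gait type.

The forward-kinematics kernel is pluggable (``fk`` argument) so the same
stepper can run on the dual-quaternion chain or on the homogeneous-matrix
baseline of :mod:`dqgait.evaluation`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from . import model
from .model import SegmentParams, end_effector_posture

__all__ = [
    "IKParams",
    "JointLimits",
    "IKResult",
    "GAIT_TYPES",
    "gait_ik_params",
    "gait_joint_limits",
    "gait_initial_config",
    "compute_jacobian",
    "dls_step",
    "clamp_config",
    "ik_solve",
    "ik_track",
]

GAIT_TYPES = ("normal", "toe_walking", "heel_walking")

FDStep = 1e-6  # central-difference step on each rotation-vector component, rad


@dataclass(frozen=True)
class IKParams:
    """DLS solver parameters.

    alpha : step-size factor in (0, 1)
    gamma : damping constant in (0, 1)
    epsilon : posture-error-norm convergence threshold
    max_iterations : iteration cap N per sample
    """

    alpha: float
    gamma: float
    epsilon: float = 1e-6
    max_iterations: int = 56

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass(frozen=True)
class JointLimits:
    """Signed per-joint angle bounds in degrees, ``theta_min <= theta_max``."""

    theta_min: np.ndarray
    theta_max: np.ndarray

    def __post_init__(self):
        tmin = np.asarray(self.theta_min, dtype=float)
        tmax = np.asarray(self.theta_max, dtype=float)
        object.__setattr__(self, "theta_min", tmin)
        object.__setattr__(self, "theta_max", tmax)
        if np.any(tmin > tmax):
            raise ValueError("theta_min must not exceed theta_max")

    @classmethod
    def unlimited(cls, n_joints: int = 3) -> "JointLimits":
        return cls(np.full(n_joints, -180.0), np.full(n_joints, 180.0))


@dataclass(frozen=True)
class IKResult:
    """One sample's solution: clamped configuration, iteration count,
    final posture-error norm and a convergence flag."""

    config: np.ndarray
    iterations: int
    final_error_norm: float
    converged: bool


# Per-gait tuned (alpha, gamma) pairs.
_GAIT_IK = {
    "normal": (0.6992, 0.0579),
    "toe_walking": (0.7334, 0.0608),
    "heel_walking": (0.7301, 0.0579),
}

# Per-gait range of motion (hip, knee, ankle), degrees.
_GAIT_LIMITS = {
    "normal": ((-180.0, -180.0, -180.0), (180.0, 180.0, 180.0)),
    "toe_walking": ((-6.4, -50.4, -32.3), (33.6, -5.6, -7.6)),
    "heel_walking": ((7.5, -25.8, 9.0), (34.3, -8.2, 19.2)),
}

# Per-gait initial joint angles (hip, knee, ankle), degrees.
_GAIT_INITIAL = {
    "normal": (1.0, -5.0, -1.0),
    "toe_walking": (1.0, -5.0, 1.0),
    "heel_walking": (32.0, -5.0, 12.0),
}


def _check_gait(gait_type: str) -> str:
    if gait_type not in GAIT_TYPES:
        raise ValueError(f"unknown gait type {gait_type!r}; expected one of {GAIT_TYPES}")
    return gait_type


def gait_ik_params(gait_type: str, **overrides) -> IKParams:
    """Tuned :class:`IKParams` for a gait type (epsilon/N overridable)."""
    alpha, gamma = _GAIT_IK[_check_gait(gait_type)]
    return replace(IKParams(alpha=alpha, gamma=gamma), **overrides)


def gait_joint_limits(gait_type: str) -> JointLimits:
    """Range-of-motion limits for a gait type (hip, knee, ankle; deg)."""
    tmin, tmax = _GAIT_LIMITS[_check_gait(gait_type)]
    return JointLimits(np.array(tmin), np.array(tmax))


def gait_initial_config(gait_type: str) -> np.ndarray:
    """Initial chain configuration for a gait type, as rotation vectors."""
    return model.config_from_angles(np.array(_GAIT_INITIAL[_check_gait(gait_type)]))


# ---------------------------------------------------------------------------
# Jacobian

FKKernel = Callable[[np.ndarray, SegmentParams], np.ndarray]


def compute_jacobian(
    phi: np.ndarray,
    params: SegmentParams,
    method: str = "fd",
    h: float = FDStep,
    fk: FKKernel = end_effector_posture,
) -> np.ndarray:
    """Jacobian ``d(xi_g)/d(Phi)`` of the end-effector posture, shape (6, 3n).

    Column ``3i + c`` holds the partial derivative of the posture
    6-vector with respect to component ``c`` of joint ``i``'s rotation
    vector.  ``method="fd"`` (default) uses central finite differences
    with step ``h`` on each component; ``method="analytic"`` evaluates
    the closed form built from SO(3) left-Jacobian factors (and ignores
    the ``fk``/``h`` arguments).
    """
    if method == "analytic":
        return _analytic_jacobian(phi, params)
    if method != "fd":
        raise ValueError(f"unknown Jacobian method {method!r}")
    n = phi.shape[0]
    J = np.empty((6, 3 * n))
    for i in range(n):
        for c in range(3):
            dphi = phi.copy()
            dphi[i, c] += h
            f_plus = fk(dphi, params)
            dphi[i, c] -= 2.0 * h
            f_minus = fk(dphi, params)
            J[:, 3 * i + c] = (f_plus - f_minus) / (2.0 * h)
    return J


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _so3_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix of the full-angle rotation vector ``v`` (Rodrigues)."""
    th = np.linalg.norm(v)
    K = _skew(v)
    if th < 1e-8:
        return np.eye(3) + K + 0.5 * (K @ K)
    return np.eye(3) + (np.sin(th) / th) * K + ((1.0 - np.cos(th)) / th**2) * (K @ K)


def _so3_left_jacobian(v: np.ndarray) -> np.ndarray:
    """Left Jacobian J_l of SO(3): Exp(v + dv) = Exp(J_l dv) Exp(v) + O(dv^2)."""
    th = np.linalg.norm(v)
    K = _skew(v)
    if th < 1e-5:
        return np.eye(3) + 0.5 * K + (K @ K) / 6.0
    return (
        np.eye(3)
        + ((1.0 - np.cos(th)) / th**2) * K
        + ((th - np.sin(th)) / th**3) * (K @ K)
    )


def _so3_left_jacobian_inv(v: np.ndarray) -> np.ndarray:
    th = np.linalg.norm(v)
    K = _skew(v)
    if th < 1e-5:
        return np.eye(3) - 0.5 * K + (K @ K) / 12.0
    cot_term = 1.0 / th**2 - (1.0 + np.cos(th)) / (2.0 * th * np.sin(th))
    return np.eye(3) - 0.5 * K + cot_term * (K @ K)


def _analytic_jacobian(phi: np.ndarray, params: SegmentParams) -> np.ndarray:
    """Closed-form posture Jacobian.

    A perturbation ``dPhi_i`` of joint ``i`` tilts everything distal of
    that joint by the world-frame angular change
    ``dtheta_W = R_{W,i-1} J_l(2 Phi_i) 2 dPhi_i``; position rows follow
    from ``dp = dtheta_W x (p_g - p_i)`` and orientation rows from the
    inverse left Jacobian of the total rotation vector ``o_W``.
    """
    n = phi.shape[0]
    # Cumulative rotations R_{W,i} and joint origins p_iW.
    R_cum = [np.eye(3)]
    p_joint = []
    p = np.zeros(3)
    for i in range(n):
        p = p + R_cum[i] @ params.p_rel[i]
        p_joint.append(p.copy())
        R_cum.append(R_cum[i] @ _so3_matrix(2.0 * phi[i]))
    R_end = R_cum[n] @ _so3_matrix(2.0 * params.phi_end)
    p_end = p + R_cum[n] @ params.p_end
    # Total orientation as a rotation vector, matched to the FK extraction.
    from scipy.spatial.transform import Rotation

    o_W = Rotation.from_matrix(R_end).as_rotvec()
    Jl_o_inv = _so3_left_jacobian_inv(o_W)
    J = np.empty((6, 3 * n))
    for i in range(n):
        A = 2.0 * R_cum[i] @ _so3_left_jacobian(2.0 * phi[i])  # dtheta_W / dPhi_i
        J[:3, 3 * i : 3 * i + 3] = -_skew(p_end - p_joint[i]) @ A
        J[3:, 3 * i : 3 * i + 3] = Jl_o_inv @ A
    return J


# ---------------------------------------------------------------------------
# DLS step and clamping


def dls_step(J: np.ndarray, delta_xi: np.ndarray, gamma: float) -> np.ndarray:
    """Damped least-squares update ``J^T (J J^T + gamma^2 I)^-1 delta_xi``.

    Minimizes ``|J dPhi - delta_xi|^2 + gamma^2 |dPhi|^2``; for
    ``gamma > 0`` the damped normal matrix is always invertible and the
    step norm is bounded by ``|delta_xi| / (2 gamma)``.
    """
    if gamma <= 0.0:
        raise ValueError("gamma must be positive")
    m = J.shape[0]
    A = J @ J.T + gamma**2 * np.eye(m)
    return J.T @ np.linalg.solve(A, delta_xi)


def clamp_config(phi: np.ndarray, limits: JointLimits) -> np.ndarray:
    """Clip each joint's signed planar angle into its range of motion.

    The signed angle is recovered as ``theta_i = 2 Phi_i,z`` (the planar
    axis carries the sign, so negative limits such as a knee-flexion
    bound compare correctly), clipped to ``[theta_min, theta_max]`` and
    rebuilt as ``Phi_i = (theta/2) z``.  Angles already inside their
    limits are returned unchanged; off-plane components are projected to
    zero.
    """
    out = phi.copy()
    out[:, :2] = 0.0
    tmin = np.deg2rad(limits.theta_min)
    tmax = np.deg2rad(limits.theta_max)
    theta = 2.0 * phi[:, 2]
    out[:, 2] = 0.5 * np.clip(theta, tmin, tmax)
    # keep bitwise identity where no clipping happened
    inside = (theta >= tmin) & (theta <= tmax)
    out[inside, 2] = phi[inside, 2]
    return out


# ---------------------------------------------------------------------------
# Solver


def _as_target_vector(target) -> np.ndarray:
    vec = target.vector if isinstance(target, model.Posture) else np.asarray(target, dtype=float)
    if vec.shape != (6,):
        raise ValueError("target posture must be a 6-vector [p_W, o_W]")
    if not np.all(np.isfinite(vec)):
        raise ValueError("target posture must be finite")
    return vec


def ik_solve(
    target,
    params: SegmentParams,
    ik: IKParams,
    limits: JointLimits,
    phi0: np.ndarray,
    fk: FKKernel = end_effector_posture,
    jacobian_method: str = "fd",
    weights: np.ndarray | None = None,
) -> IKResult:
    """Solve one inverse-kinematics sample by damped least squares.

    Parameters
    ----------
    target : Posture or 6-vector
        Desired end-effector posture ``zeta_g``.
    phi0 : ndarray, shape (n, 3)
        Initial chain configuration; clamped into ``limits`` before the
        first iteration.
    fk : callable
        Forward-kinematics kernel mapping ``(phi, params)`` to the
        end-effector posture 6-vector.
    weights : optional 6-vector
        Diagonal weighting of the posture error; identity by default.

    Notes
    -----
    ``iterations`` counts completed DLS updates; a target already within
    ``epsilon`` of the initial posture returns 0 iterations.  An
    unreachable target returns a finite clamped configuration with
    ``converged=False`` after the iteration cap.
    """
    zeta = _as_target_vector(target)
    w = np.ones(6) if weights is None else np.asarray(weights, dtype=float)
    phi = clamp_config(np.asarray(phi0, dtype=float), limits)
    xi = fk(phi, params)
    k = 0
    err = float(np.linalg.norm(w * (zeta - xi)))
    while err > ik.epsilon and k <= ik.max_iterations:
        J = compute_jacobian(phi, params, method=jacobian_method, fk=fk)
        delta_xi = ik.alpha * w * (zeta - xi)
        delta_phi = dls_step(J, delta_xi, ik.gamma)
        phi = clamp_config(phi + delta_phi.reshape(phi.shape), limits)
        xi = fk(phi, params)
        err = float(np.linalg.norm(w * (zeta - xi)))
        k += 1
    return IKResult(config=phi, iterations=k, final_error_norm=err, converged=err <= ik.epsilon)


def ik_track(
    targets: Sequence,
    params: SegmentParams,
    ik: IKParams,
    limits: JointLimits,
    phi0: np.ndarray,
    fk: FKKernel = end_effector_posture,
    jacobian_method: str = "fd",
    warm_start: bool = True,
    log: Callable[[int, IKResult], None] | None = None,
) -> list[IKResult]:
    """Track a target-posture trajectory sample by sample.

    Sample 0 starts from ``phi0``; with ``warm_start`` (default) each
    later sample starts from the previous sample's solution, which is
    what makes smooth gait trajectories converge in a handful of
    iterations per sample.  ``log(sample_index, result)`` is called after
    every sample when given.
    """
    if len(targets) == 0:
        raise ValueError("ik_track requires at least one target")
    results: list[IKResult] = []
    start = np.asarray(phi0, dtype=float)
    for t, target in enumerate(targets):
        res = ik_solve(
            target, params, ik, limits, start, fk=fk, jacobian_method=jacobian_method
        )
        results.append(res)
        if log is not None:
            log(t, res)
        if warm_start:
            start = res.config
    return results
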