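"""Synthetic gait joint-angle trajectories and trajectory CSV I/O.

Stands in for a motion-capture reference dataset: each joint's angle over
one gait cycle (0-100%) is a truncated Fourier series

    theta_j(t) = mean_j + sum_h A_jh cos(2 pi h t / 100 + phase_jh)

which is smooth, exactly periodic (closed cycle) and confined to the
labeled gait type's range of motion.  Three shipped presets — normal,
toe-walking and heel-walking — exercise physiologic sagittal-plane
ranges: normal gait with hip roughly -11..31 deg, knee -59..-1 deg and
ankle -18..13 deg; the pathological-like patterns confined to their much
tighter configured limits.  The curves emulate the smoothness, range and
periodicity of captured gait, not any particular subject's waveform.

Angles are degrees throughout (hip, knee, ankle); the nominal 60 Hz
capture rate is carried as metadata only, the canonical sampling being
101 points over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ik import GAIT_TYPES, gait_joint_limits
from .model import Posture, SegmentParams, forward_kinematics

__all__ = [
    "JOINTS",
    "GaitPatternSpec",
    "JointTrajectory",
    "preset_spec",
    "generate_gait",
    "trajectory_to_targets",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

JOINTS = ("hip", "knee", "ankle")

TRAJECTORY_CSV_COLUMNS = ["cycle_percent", "hip_deg", "knee_deg", "ankle_deg"]


@dataclass(frozen=True)
class GaitPatternSpec:
    """Fourier description of one gait pattern.

    means : per-joint offset, deg (hip, knee, ankle)
    amplitudes : (3, H) harmonic amplitudes, deg
    phases : (3, H) harmonic phases, rad
    n_samples : samples over one cycle (canonical 101 = every 1%)
    seed, phase_jitter : optional seeded jitter added to the phases;
        off by default, so presets are fully deterministic.
    """

    gait_type: str
    means: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    n_samples: int = 101
    seed: int | None = None
    phase_jitter: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "amplitudes", np.atleast_2d(np.asarray(self.amplitudes, dtype=float)))
        object.__setattr__(self, "phases", np.atleast_2d(np.asarray(self.phases, dtype=float)))
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have the same shape")
        if self.means.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("means and amplitudes disagree on the number of joints")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


@dataclass(frozen=True)
class JointTrajectory:
    """Per-joint angle time series (deg) over one gait cycle."""

    cycle_percent: np.ndarray
    theta: np.ndarray  # shape (n_samples, 3): hip, knee, ankle
    gait_type: str
    sample_rate_hz: float = 60.0

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]


# Preset Fourier coefficients (deg / rad).  Chosen once to respect each
# gait type's range of motion while spanning most of it; see docs.
_PRESETS = {
    "normal": dict(
        means=[10.0, -30.0, -2.5],
        amplitudes=[[18.0, 3.0], [24.0, 5.0], [12.0, 4.0]],
        phases=[[0.0, 1.0], [-1.2566, 0.6], [-0.754, 2.0]],
    ),
    "toe_walking": dict(
        means=[13.6, -28.0, -20.0],
        amplitudes=[[15.5, 2.0], [17.0, 3.0], [10.0, 1.5]],
        phases=[[0.0, 1.0], [-1.2566, 0.6], [-0.754, 2.0]],
    ),
    "heel_walking": dict(
        means=[21.0, -17.0, 14.1],
        amplitudes=[[10.5, 1.5], [7.0, 1.0], [4.2, 0.6]],
        phases=[[0.0, 1.0], [-1.2566, 0.6], [-0.754, 2.0]],
    ),
}


def preset_spec(gait_type: str, n_samples: int = 101, seed: int | None = None) -> GaitPatternSpec:
    """The shipped deterministic preset for a gait type."""
    if gait_type not in _PRESETS:
        raise ValueError(f"unknown preset {gait_type!r}; expected one of {GAIT_TYPES}")
    return GaitPatternSpec(gait_type=gait_type, n_samples=n_samples, seed=seed, **_PRESETS[gait_type])


def _series(spec: GaitPatternSpec, t: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Evaluate the Fourier series at cycle percentages ``t`` -> (len(t), 3)."""
    n_joints, n_harm = spec.amplitudes.shape
    theta = np.tile(spec.means, (t.shape[0], 1))
    for j in range(n_joints):
        for h in range(n_harm):
            theta[:, j] += spec.amplitudes[j, h] * np.cos(
                2.0 * np.pi * (h + 1) * t / 100.0 + phases[j, h]
            )
    return theta


def generate_gait(spec: GaitPatternSpec) -> JointTrajectory:
    """Sample a gait pattern over one cycle.

    Deterministic given the spec (and its seed, when phase jitter is
    enabled).  The realized series is validated against the labeled gait
    type's joint limits on a dense grid; a spec whose curves leave the
    range of motion is rejected.

    Raises
    ------
    ValueError
        If the series violates the gait type's joint limits.
    """
    phases = spec.phases
    if spec.phase_jitter > 0.0:
        rng = np.random.default_rng(spec.seed)
        phases = phases + rng.uniform(-spec.phase_jitter, spec.phase_jitter, phases.shape)
    limits = gait_joint_limits(spec.gait_type)
    dense = _series(spec, np.linspace(0.0, 100.0, 4001), phases)
    lo, hi = dense.min(axis=0), dense.max(axis=0)
    bad = (lo < limits.theta_min - 1e-9) | (hi > limits.theta_max + 1e-9)
    if np.any(bad):
        names = [JOINTS[j] for j in np.flatnonzero(bad)]
        raise ValueError(
            f"gait pattern exceeds {spec.gait_type} joint limits for {names}: "
            f"realized ranges {list(zip(lo.round(2), hi.round(2)))}"
        )
    t = np.linspace(0.0, 100.0, spec.n_samples)
    return JointTrajectory(cycle_percent=t, theta=_series(spec, t, phases), gait_type=spec.gait_type)


def trajectory_to_targets(traj: JointTrajectory, params: SegmentParams) -> list[Posture]:
    """End-effector target postures from a joint trajectory (the FK1 stage)."""
    from .model import config_from_angles

    return [
        forward_kinematics(config_from_angles(theta), params)[-1] for theta in traj.theta
    ]


def write_trajectory_csv(traj: JointTrajectory, path) -> None:
    """Write a joint-angle trajectory in the canonical CSV schema."""
    pd.DataFrame(
        {
            "cycle_percent": traj.cycle_percent,
            "hip_deg": traj.theta[:, 0],
            "knee_deg": traj.theta[:, 1],
            "ankle_deg": traj.theta[:, 2],
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path, gait_type: str = "normal", warn=None) -> JointTrajectory:
    """Read a joint-angle trajectory CSV.

    The header must contain ``cycle_percent,hip_deg,knee_deg,ankle_deg``.
    Malformed cells are reported with their row and column; angles
    outside the configured gait type's limits are reported through
    ``warn`` (a callable receiving a message) rather than rejected, so
    externally captured cycles remain loadable.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"trajectory CSV {path} contains no samples")
    missing = [c for c in TRAJECTORY_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} is missing columns {missing}")
    for col in TRAJECTORY_CSV_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +2: header line and 1-based numbering
            raise ValueError(
                f"trajectory CSV {path}: non-numeric value in column {col!r}, line {bad[0] + 2}"
            )
        frame[col] = values
    theta = frame[["hip_deg", "knee_deg", "ankle_deg"]].to_numpy(dtype=float)
    limits = gait_joint_limits(gait_type)
    lo, hi = theta.min(axis=0), theta.max(axis=0)
    out_of_range = (lo < limits.theta_min) | (hi > limits.theta_max)
    if np.any(out_of_range) and warn is not None:
        names = [JOINTS[j] for j in np.flatnonzero(out_of_range)]
        warn(f"trajectory exceeds {gait_type} joint limits for {names}")
    return JointTrajectory(
        cycle_percent=frame["cycle_percent"].to_numpy(dtype=float),
        theta=theta,
        gait_type=gait_type,
    )
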