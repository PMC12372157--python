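"""Quaternion algebra for 3-D rotations.

Quaternions are length-4 ``numpy`` arrays ``[q0, q1, q2, q3]`` — a real
scalar part ``q0`` and a vector part ``(q1, q2, q3)`` over the imaginary
basis ``i, j, k``.  Unit quaternions (``|q| = 1``) act as rotation
operators: ``q v q*`` rotates the pure quaternion ``v`` counter-clockwise
by the angle ``theta = 2|Phi|`` about the unit axis ``u = Phi/|Phi|``,
where ``Phi = theta/2 * u`` is the half-angle rotation vector returned by
:func:`quat_log`.  Pure quaternions (zero scalar part) stand in for 3-D
vectors and translations.

The exponential and logarithm maps switch to truncated Taylor series near
the ``|Phi| -> 0`` singularity of ``sin|Phi|/|Phi|`` so that both maps are
smooth through the identity rotation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UNIT_TOL",
    "SERIES_THRESHOLD",
    "quat",
    "pure",
    "identity",
    "quat_multiply",
    "quat_conjugate",
    "quat_norm",
    "quat_inverse",
    "quat_exp",
    "quat_log",
    "rotate_vector",
    "is_unit",
]

#: Tolerance for the |q| = 1 unit-quaternion validation.
UNIT_TOL = 1e-9

#: Below this half-angle magnitude the Taylor forms of exp/log are used.
#: Both branches agree to ~1e-16 there, so the switch is continuous.
SERIES_THRESHOLD = 1e-4


def quat(q0: float, qv) -> np.ndarray:
    """Build a quaternion from scalar part ``q0`` and 3-vector part ``qv``."""
    out = np.empty(4)
    out[0] = q0
    out[1:] = qv
    return out


def pure(v) -> np.ndarray:
    """Embed a 3-vector as a pure quaternion (zero scalar part)."""
    return quat(0.0, np.asarray(v, dtype=float))


def identity() -> np.ndarray:
    """The multiplication identity ``1 + 0``."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p q``.

    ``(p0 + p)(q0 + q) = p0 q0 - p.q + p x q + p0 q + q0 p``; associative
    and distributive but non-commutative, with ``|p q| = |p||q|``.
    """
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array(
        [
            p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
            p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
            p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
            p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate ``q* = q0 - qv``."""
    out = -np.asarray(q, dtype=float)
    out[0] = -out[0]
    return out


def quat_norm(q: np.ndarray) -> float:
    """Magnitude ``|q| = sqrt(q0^2 + q1^2 + q2^2 + q3^2)``."""
    return float(np.linalg.norm(q))


def quat_inverse(q: np.ndarray) -> np.ndarray:
    """Inverse ``q^-1 = q* / |q|^2``; for a unit quaternion this is ``q*``.

    Raises
    ------
    ValueError
        If ``q`` is the zero quaternion.
    """
    n2 = float(np.dot(q, q))
    if n2 == 0.0:
        raise ValueError("the zero quaternion has no inverse")
    return quat_conjugate(q) / n2


def is_unit(q: np.ndarray, tol: float = UNIT_TOL) -> bool:
    """True if ``|q| = 1`` within ``tol``."""
    return abs(quat_norm(q) - 1.0) <= tol


def quat_exp(phi) -> np.ndarray:
    """Exponential map: half-angle rotation vector ``Phi`` -> unit quaternion.

    ``e^Phi = cos|Phi| + (sin|Phi|/|Phi|) Phi``.  Near ``|Phi| = 0`` the
    sinc factor is evaluated with the truncated series
    ``1 - |Phi|^2/6 + |Phi|^4/120`` to avoid the 0/0 singularity.

    Parameters
    ----------
    phi : array-like, shape (3,)
        Rotation vector ``Phi = (theta/2) u`` for a rotation of full angle
        ``theta`` about unit axis ``u``.
    """
    phi = np.asarray(phi, dtype=float)
    n = float(np.linalg.norm(phi))
    if n < SERIES_THRESHOLD:
        n2 = n * n
        sinc = 1.0 - n2 / 6.0 + n2 * n2 / 120.0
    else:
        sinc = np.sin(n) / n
    return quat(np.cos(n), sinc * phi)


def quat_log(q: np.ndarray) -> np.ndarray:
    """Logarithm of a unit quaternion: returns ``Phi = (theta/2) u``.

    The full rotation angle is recovered as ``theta = 2 atan2(|qv|, q0)``
    and wrapped to the canonical branch ``theta in (-pi, pi]``, the sign
    being carried by the axis; ``atan2`` (rather than ``arccos``) keeps
    negative rotations distinguishable from positive ones.  At ``|qv| = 0``
    the ratio ``theta/|qv|`` is replaced by its Taylor series
    ``(1 + x^2/6 + 7 x^4/360)/|q|`` in the half angle ``x``.

    Raises
    ------
    ValueError
        If ``q`` is not unit within :data:`UNIT_TOL`.
    """
    q = np.asarray(q, dtype=float)
    if not is_unit(q):
        raise ValueError(f"quat_log requires a unit quaternion, got |q| = {quat_norm(q)!r}")
    q0 = float(q[0])
    qv = q[1:]
    s = float(np.linalg.norm(qv))
    theta = 2.0 * np.arctan2(s, q0)
    if theta > np.pi:
        theta -= 2.0 * np.pi
    x = 0.5 * theta
    if s < SERIES_THRESHOLD:
        if q0 > 0.0:
            # x ~ s here; theta/(2|qv|) = x/sin(x) expanded about 0.
            x2 = x * x
            factor = (1.0 + x2 / 6.0 + 7.0 * x2 * x2 / 360.0) / quat_norm(q)
            return factor * qv
        if s == 0.0:
            # q = -1: a full turn, indistinguishable from no rotation.
            return np.zeros(3)
        return (x / s) * qv
    return (x / s) * qv


def rotate_vector(q: np.ndarray, v) -> np.ndarray:
    """Rotate 3-vector ``v`` by the unit quaternion ``q`` via ``q v q*``.

    Counter-clockwise through angle ``2 theta`` about the axis of
    ``q = cos(theta) + u sin(theta)`` (right-hand rule); the conjugated
    order ``q* v q`` would rotate clockwise.
    """
    out = quat_multiply(quat_multiply(q, pure(v)), quat_conjugate(q))
    return out[1:]
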