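"""Dual-quaternion algebra and rigid transforms.

A dual quaternion is ``q_ = qp + eps qd`` with ordinary quaternions
``qp`` (primary part) and ``qd`` (dual part) and the dual unit
``eps^2 = 0``.  A dual quaternion is *unit* iff ``|qp| = 1`` and
``qp . qd = 0`` (4-vector dot product); unit dual quaternions encode
rigid 3-D transforms in 8 parameters and compose by multiplication: the
primary part carries the rotation, the dual part ``qd = (1/2) p r``
carries the translation ``p``.

Dual numbers are never materialized as a type of their own:
:func:`dq_norm` returns the pair ``(|qp|, qp.qd/|qp|)``, which is all the
unitness checks consume.  Products are not re-normalized; drift over
chains of ordinary length stays far below the unit tolerance.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .quaternions import (
    UNIT_TOL,
    identity,
    pure,
    quat_conjugate,
    quat_inverse,
    quat_multiply,
    quat_norm,
)

__all__ = [
    "DualQuaternion",
    "dq_identity",
    "dq_multiply",
    "dq_conjugate",
    "dq_norm",
    "dq_inverse",
    "dq_is_unit",
    "dq_from_rigid",
    "dq_translation",
]


class DualQuaternion(NamedTuple):
    """Pair of quaternions ``qp + eps qd`` (each a length-4 array)."""

    qp: np.ndarray
    qd: np.ndarray


def dq_identity() -> DualQuaternion:
    """The identity transform ``1 + eps 0``."""
    return DualQuaternion(identity(), np.zeros(4))


def dq_multiply(p_: DualQuaternion, q_: DualQuaternion) -> DualQuaternion:
    """Product ``p_ q_ = pp qp + eps (pp qd + pd qp)`` (eps^2 = 0)."""
    return DualQuaternion(
        quat_multiply(p_.qp, q_.qp),
        quat_multiply(p_.qp, q_.qd) + quat_multiply(p_.qd, q_.qp),
    )


def dq_conjugate(q_: DualQuaternion) -> DualQuaternion:
    """Conjugate ``q_* = qp* + eps qd*``."""
    return DualQuaternion(quat_conjugate(q_.qp), quat_conjugate(q_.qd))


def dq_norm(q_: DualQuaternion) -> tuple[float, float]:
    """Norm as the dual-number pair ``(|qp|, qp.qd / |qp|)``.

    A unit dual quaternion has norm ``(1, 0)``.
    """
    np_ = quat_norm(q_.qp)
    return np_, float(np.dot(q_.qp, q_.qd)) / np_


def dq_inverse(q_: DualQuaternion) -> DualQuaternion:
    """Inverse ``qp^-1 - eps qp^-1 qd qp^-1``; requires ``qp != 0``.

    For a unit dual quaternion the inverse equals the conjugate.
    """
    if quat_norm(q_.qp) == 0.0:
        raise ValueError("dual quaternion with zero primary part has no inverse")
    qp_inv = quat_inverse(q_.qp)
    return DualQuaternion(
        qp_inv, -quat_multiply(quat_multiply(qp_inv, q_.qd), qp_inv)
    )


def dq_is_unit(q_: DualQuaternion, tol: float = UNIT_TOL) -> bool:
    """True iff ``|qp| = 1`` and ``qp . qd = 0`` within ``tol``."""
    n, d = dq_norm(q_)
    return abs(n - 1.0) <= tol and abs(d) <= tol


def dq_from_rigid(p, r: np.ndarray) -> DualQuaternion:
    """Unit dual quaternion for translation ``p`` followed by rotation ``r``.

    ``q_ = (1 + eps p/2) r = r + eps (1/2) p r`` with ``p`` a 3-vector and
    ``r`` a unit quaternion.
    """
    p = np.asarray(p, dtype=float)
    return DualQuaternion(np.array(r, dtype=float), 0.5 * quat_multiply(pure(p), r))


def dq_translation(q_: DualQuaternion) -> np.ndarray:
    """Translation ``p = 2 qd qp*`` of a unit dual quaternion, as a 3-vector.

    Raises
    ------
    ValueError
        If ``q_`` is not unit.
    """
    if not dq_is_unit(q_):
        raise ValueError("dq_translation requires a unit dual quaternion")
    return 2.0 * quat_multiply(q_.qd, quat_conjugate(q_.qp))[1:]
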