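"""Recursive Newton-Euler inverse dynamics on the rigid-body tree.

Given joint angles, velocities and accelerations, computes the exact joint
torques (gravity + Coriolis/centrifugal + inertial terms) for every DOF of
the model, including the static hand joints, which must hold posture against
gravity and interaction moments. The recursion runs in world coordinates:
an outward pass propagates angular velocity/acceleration and linear
acceleration from the root (gravity enters as a fictitious base acceleration
of -g), and an inward pass accumulates forces and moments from the leaves
back to the root. Cost is O(n) per sample; all per-sample quantities are
vectorised over time.
"""

from __future__ import annotations

import numpy as np

from .arm_model import ArmModel, rotations_about_axis

__all__ = ["inverse_dynamics_rne", "compute_trajectory_torques"]


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.cross(a, b)


def _rne_batch(model: ArmModel, q: np.ndarray, qd: np.ndarray, qdd: np.ndarray) -> np.ndarray:
    """Vectorised RNE: inputs (T, n) -> torques (T, n)."""
    ch = model.compiled
    n = model.n_dofs
    T = q.shape[0]
    g = model.gravity

    Rw = np.empty((n, T, 3, 3))  # world orientation of each body frame
    ow = np.empty((n, T, 3))  # world origin of each body frame
    w = np.empty((n, T, 3))  # angular velocity
    al = np.empty((n, T, 3))  # angular acceleration
    ao = np.empty((n, T, 3))  # linear acceleration of body origin
    ac = np.empty((n, T, 3))  # linear acceleration of body COM
    rc_w = np.empty((n, T, 3))  # world vector origin->COM

    for i in range(n):
        Ri = rotations_about_axis(ch.axis[i], q[:, i])
        p = ch.parent[i]
        if p < 0:
            Rp = np.broadcast_to(np.eye(3), (T, 3, 3))
            op = np.zeros((T, 3))
            wp = np.zeros((T, 3))
            alp = np.zeros((T, 3))
            aop = np.broadcast_to(-g, (T, 3))
        else:
            Rp, op, wp, alp, aop = Rw[p], ow[p], w[p], al[p], ao[p]
        Rw[i] = Rp @ Ri
        d = Rp @ ch.r[i]  # joint offset in world frame
        ow[i] = op + d
        z = Rw[i] @ ch.axis[i]  # world joint axis
        qd_i = qd[:, i, None]
        qdd_i = qdd[:, i, None]
        w[i] = wp + z * qd_i
        al[i] = alp + z * qdd_i + _cross(wp, z * qd_i)
        ao[i] = aop + _cross(alp, d) + _cross(wp, _cross(wp, d))
        rc_w[i] = Rw[i] @ ch.com[i]
        ac[i] = ao[i] + _cross(al[i], rc_w[i]) + _cross(w[i], _cross(w[i], rc_w[i]))

    # net force/moment on each body about its COM
    F = ch.mass[:, None, None] * ac
    Iw = Rw @ ch.inertia[:, None, :, :] @ np.swapaxes(Rw, -1, -2)
    N = (Iw @ al[..., None])[..., 0] + _cross(w, (Iw @ w[..., None])[..., 0])

    tau = np.empty((T, n))
    f = np.zeros((n, T, 3))
    mom = np.zeros((n, T, 3))  # moment about body origin
    for i in range(n - 1, -1, -1):
        f[i] += F[i]
        mom[i] += N[i] + _cross(rc_w[i], F[i])
        p = ch.parent[i]
        if p >= 0:
            f[p] += f[i]
            mom[p] += mom[i] + _cross(ow[i] - ow[p], f[i])
        z = Rw[i] @ ch.axis[i]
        tau[:, i] = np.einsum("tj,tj->t", z, mom[i])
    return tau


def inverse_dynamics_rne(
    model: ArmModel, q: np.ndarray, qd: np.ndarray, qdd: np.ndarray
) -> np.ndarray:
    """Joint torques (N m) for one dynamics state [q, q', q''].

    Accepts either single states of shape ``(n,)`` or batches ``(T, n)``.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    qdd = np.asarray(qdd, dtype=float)
    single = q.ndim == 1
    if single:
        q, qd, qdd = q[None], qd[None], qdd[None]
    if not (q.shape == qd.shape == qdd.shape) or q.shape[1] != model.n_dofs:
        raise ValueError("q, q', q'' must share shape (T, n_dofs)")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd)) and np.all(np.isfinite(qdd))):
        raise ValueError("dynamics state contains NaN or Inf")
    tau = _rne_batch(model, q, qd, qdd)
    return tau[0] if single else tau


def compute_trajectory_torques(model: ArmModel, jt) -> np.ndarray:
    """Torque series aligned 1:1 with the samples of a joint trajectory."""
    if jt.qd is None or jt.qdd is None:
        raise ValueError("joint trajectory must carry q' and q'' (differentiate first)")
    try:
        return inverse_dynamics_rne(model, jt.q, jt.qd, jt.qdd)
    except ValueError as err:
        raise ValueError(f"inverse dynamics failed for trajectory: {err}") from err


# ---------------------------------------------------------------------------
# energy bookkeeping (used by tests and sanity checks, same mass model but an
# explicitly world-frame computation)

def mechanical_energy(model: ArmModel, q: np.ndarray, qd: np.ndarray) -> np.ndarray:
    """Total kinetic + potential energy (J) for states of shape (T, n)."""
    ch = model.compiled
    q = np.atleast_2d(q)
    qd = np.atleast_2d(qd)
    n, T = model.n_dofs, q.shape[0]
    Rw = np.empty((n, T, 3, 3))
    ow = np.empty((n, T, 3))
    w = np.empty((n, T, 3))
    vo = np.empty((n, T, 3))
    E = np.zeros(T)
    for i in range(n):
        Ri = rotations_about_axis(ch.axis[i], q[:, i])
        p = ch.parent[i]
        if p < 0:
            Rp = np.broadcast_to(np.eye(3), (T, 3, 3))
            op = np.zeros((T, 3))
            wp = np.zeros((T, 3))
            vop = np.zeros((T, 3))
        else:
            Rp, op, wp, vop = Rw[p], ow[p], w[p], vo[p]
        Rw[i] = Rp @ Ri
        d = Rp @ ch.r[i]
        ow[i] = op + d
        z = Rw[i] @ ch.axis[i]
        w[i] = wp + z * qd[:, i, None]
        vo[i] = vop + _cross(wp, d)
        rc = Rw[i] @ ch.com[i]
        vc = vo[i] + _cross(w[i], rc)
        Iw = Rw[i] @ ch.inertia[i] @ np.swapaxes(Rw[i], -1, -2)
        ke = 0.5 * ch.mass[i] * np.einsum("tj,tj->t", vc, vc)
        ke += 0.5 * np.einsum("tj,tj->t", w[i], (Iw @ w[i][..., None])[..., 0])
        pe = -ch.mass[i] * (ow[i] + rc) @ model.gravity
        E += ke + pe
    return E
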