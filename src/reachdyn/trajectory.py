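"""Workspace grid, minimum-jerk endpoint trajectories and inverse kinematics.

Reaching movements are straight endpoint paths between vertices of a 3x3x3
grid spanning the physiological workspace, with the classic minimum-jerk
(quintic) speed profile, sampled at 1 ms. Joint trajectories are obtained by
per-sample damped-Newton inverse kinematics over the three dynamic DOFs
(shoulder flexion-extension, shoulder internal-external rotation, elbow
flexion-extension); all other joints stay at their neutral posture.

Because the two shoulder DOFs rotate about axes through the shoulder origin,
the endpoint distance from the shoulder depends only on the elbow angle;
the grid construction exploits this when clipping vertices to the reach
envelope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .arm_model import ArmModel, rotation_about_axis

__all__ = [
    "GridVertex",
    "MovementSpec",
    "EndpointTrajectory",
    "JointTrajectory",
    "IKError",
    "GridConstructionError",
    "build_workspace_grid",
    "enumerate_movements",
    "minimum_jerk_endpoint_trajectory",
    "solve_inverse_kinematics",
    "solve_ik_point",
    "differentiate_joint_trajectory",
    "smooth_joint_trajectory",
    "synthesize_movement",
]

DEFAULT_DT = 0.001
DEFAULT_DURATIONS = (0.5, 1.0, 2.0)
#: anterior clearance of proximal grid vertices from the body (coronal) plane
PROXIMAL_CLEARANCE = 0.10
#: safety margin applied when clipping grid vertices to the reach envelope
REACH_MARGIN = 0.95
#: residual elbow flexion of the "outstretched" anchors, radians. Full
#: extension is both the boundary of the range of motion and a kinematic
#: singularity (the internal-rotation endpoint gain vanishes), where inverse
#: kinematics demands unphysiological joint accelerations; a ~10 degree
#: margin keeps the outstretched posture natural and the dynamics bounded.
ELBOW_EXTENSION_MARGIN = np.deg2rad(10.0)


class IKError(RuntimeError):
    pass


class GridConstructionError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridVertex:
    index: tuple[int, int, int]  # (anterior-posterior, medio-lateral, vertical)
    endpoint: np.ndarray  # metres, thorax frame
    anchor_posture: np.ndarray  # 23-vector, radians


@dataclass(frozen=True)
class MovementSpec:
    start: GridVertex
    end: GridVertex
    duration: float
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if np.array_equal(self.start.endpoint, self.end.endpoint):
            raise ValueError("start and end vertices must differ")


@dataclass
class EndpointTrajectory:
    times: np.ndarray
    position: np.ndarray  # (T, 3)
    velocity: np.ndarray
    acceleration: np.ndarray


@dataclass
class JointTrajectory:
    times: np.ndarray
    q: np.ndarray  # (T, n)
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None


# ---------------------------------------------------------------------------
# minimum jerk

def minimum_jerk_endpoint_trajectory(spec: MovementSpec) -> EndpointTrajectory:
    """Straight-line endpoint path with the minimum-jerk quintic profile.

    p(t) = p0 + (p1 - p0) (10 s^3 - 15 s^4 + 6 s^5), s = t/T, with exact
    analytic velocity and acceleration. Boundary velocity and acceleration
    vanish at both ends and the speed profile is the stereotypical bell shape
    peaking at 1.875 |p1 - p0| / T.
    """
    T = spec.duration
    n = int(round(T / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    s = t / T
    p0 = spec.start.endpoint
    d = spec.end.endpoint - p0
    f = 10 * s**3 - 15 * s**4 + 6 * s**5
    fd = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    fdd = (60 * s - 180 * s**2 + 120 * s**3) / T**2
    return EndpointTrajectory(
        times=t,
        position=p0 + np.outer(f, d),
        velocity=np.outer(fd, d),
        acceleration=np.outer(fdd, d),
    )


# ---------------------------------------------------------------------------
# reduced kinematic chain over the dynamic DOFs

class _ReducedChain:
    """Endpoint FK/Jacobian as a function of the dynamic DOFs only.

    All static joints are folded into fixed transforms compiled once, so each
    evaluation costs a handful of 3x3 products.
    """

    def __init__(self, model: ArmModel, q_static: np.ndarray, dynamic: np.ndarray | None = None):
        ch = model.compiled
        self.dynamic = model.dynamic_dofs if dynamic is None else np.asarray(dynamic)
        dyn_set = set(int(i) for i in self.dynamic)
        # root -> endpoint body path
        path = []
        i = ch.endpoint_body
        while i >= 0:
            path.append(i)
            i = ch.parent[i]
        path.reverse()
        missing = dyn_set - set(path)
        if missing:
            raise ValueError(f"dynamic DOFs {sorted(missing)} are not on the endpoint chain")
        groups = []  # (R_prefix, t_prefix, axis, dof_index)
        R_acc, t_acc = np.eye(3), np.zeros(3)
        order = []
        for i in path:
            t_acc = t_acc + R_acc @ ch.r[i]
            if i in dyn_set:
                groups.append((R_acc, t_acc, ch.axis[i].copy(), int(i)))
                order.append(int(i))
                R_acc, t_acc = np.eye(3), np.zeros(3)
            else:
                R_acc = R_acc @ rotation_about_axis(ch.axis[i], q_static[i])
        t_acc = t_acc + R_acc @ ch.endpoint_local
        self.groups = groups
        self.tail_t = t_acc
        self.order = np.array(order)  # dynamic dof indices in chain order

    def fk_jac(self, q_dyn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Endpoint position and 3xK Jacobian w.r.t. q_dyn (chain order)."""
        R = np.eye(3)
        p = np.zeros(3)
        origins, axes = [], []
        for (Rg, tg, axis, dof), qi in zip(self.groups, q_dyn):
            p = p + R @ tg
            R = R @ Rg
            origins.append(p)
            axes.append(R @ axis)
            R = R @ rotation_about_axis(axis, qi)
        p_end = p + R @ self.tail_t
        J = np.empty((3, len(self.groups)))
        for k, (o, z) in enumerate(zip(origins, axes)):
            J[:, k] = np.cross(z, p_end - o)
        return p_end, J

    def fk(self, q_dyn: np.ndarray) -> np.ndarray:
        R = np.eye(3)
        p = np.zeros(3)
        for (Rg, tg, axis, _), qi in zip(self.groups, q_dyn):
            p = p + R @ tg
            R = R @ Rg @ rotation_about_axis(axis, qi)
        return p + R @ self.tail_t


# ---------------------------------------------------------------------------
# inverse kinematics

def solve_ik_point(
    chain: _ReducedChain,
    target: np.ndarray,
    q_dyn0: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Robust damped least-squares IK to a single endpoint target.

    Levenberg-style: the damping is adapted (raised on rejected steps) and
    steps are clamped, which keeps the solve stable near the reach boundary
    where the Jacobian loses rank. Returns (q_dyn, residual_norm).
    """
    q = np.asarray(q_dyn0, dtype=float).copy()
    lam = 1e-6
    p, J = chain.fk_jac(q)
    r = target - p
    rn = np.linalg.norm(r)
    for _ in range(max_iter):
        if rn < tol:
            break
        accepted = False
        for _ in range(12):
            A = J.T @ J + lam * np.eye(J.shape[1])
            try:
                step = np.linalg.solve(A, J.T @ r)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            sn = np.linalg.norm(step)
            if sn > 0.5:
                step *= 0.5 / sn
            q_new = q + step
            p_new = chain.fk(q_new)
            r_new = target - p_new
            if np.linalg.norm(r_new) < rn:
                q = q_new
                lam = max(lam / 3.0, 1e-9)
                accepted = True
                break
            lam *= 10
        if not accepted:
            break
        p, J = chain.fk_jac(q)
        r = target - p
        rn = np.linalg.norm(r)
    return q, rn


def solve_inverse_kinematics(
    model: ArmModel,
    traj: EndpointTrajectory,
    q_init: np.ndarray,
    tol: float = 1e-12,
    residual_tol: float = 1e-6,
    max_iter: int = 50,
    damping: float = 1e-6,
    sv_floor: float = 0.045,
    max_singular_damping: float = 0.1,
    slip_tol: float = 0.2,
    max_joint_velocity: float = 15.0,
) -> JointTrajectory:
    """Per-step damped-Newton IK over the dynamic DOFs (angles only).

    Each step is warm-started from the previous sample's solution; static
    DOFs are pinned at the values given in ``q_init``. In well-conditioned
    configurations (smallest Jacobian singular value above ``sv_floor``) the
    solve is an essentially exact Newton iteration and every step's
    forward-kinematics residual must stay below ``residual_tol`` (else
    :class:`IKError` naming the step). Where the chain approaches one of its
    singular sheets -- the extension boundary, or the fingertip aligning with
    the humerus axis in strongly flexed postures -- the solver blends in
    singularity-robust damped least squares (Nakamura-style damping ramped as
    the smallest singular value drops below the floor). There the endpoint is
    allowed to slip off the commanded chord by up to ``slip_tol`` metres,
    trading millimetre-level path fidelity for bounded, physiological joint
    velocities; the alternative (exact tracking through the sheet) demands
    joint transients far outside natural reaching.

    The convergence tolerance is deliberately near machine precision: the
    joint angles are later differentiated twice at 1 ms, which amplifies any
    solver jitter by 4/dt^2, so looser solves leak visible noise into q''
    and the torques.
    """
    q_init = np.asarray(q_init, dtype=float)
    if q_init.shape != (model.n_dofs,):
        raise ValueError("q_init has wrong shape")
    chain = _ReducedChain(model, q_init)
    dyn = chain.order
    p0 = chain.fk(q_init[dyn])
    if np.linalg.norm(p0 - traj.position[0]) > 0.01:
        raise IKError(
            "q_init endpoint is more than 1 cm away from the first trajectory sample"
        )
    T = len(traj.times)
    dt = float(traj.times[1] - traj.times[0]) if T > 1 else 1e-3
    dq_max = max_joint_velocity * dt
    Q = np.tile(q_init, (T, 1))
    q_dyn = q_init[dyn].astype(float).copy()
    k = len(dyn)
    eye = np.eye(k)
    for step in range(T):
        target = traj.position[step]
        q_prev = q_dyn.copy()
        damped = False
        rn = np.inf
        for it in range(max_iter):
            p, J = chain.fk_jac(q_dyn)
            r = target - p
            rn = np.linalg.norm(r)
            if rn < tol:
                break
            sv_min = np.sqrt(max(np.linalg.eigvalsh(J.T @ J)[0], 0.0))
            if sv_min >= sv_floor:
                q_dyn = q_dyn + np.linalg.solve(J.T @ J + damping**2 * eye, J.T @ r)
                continue
            # Singular sheet: solve the proximal problem
            #   min |p(q) - target|^2 + lam^2 |q - q_prev|^2
            # (Gauss-Newton on the augmented system). Tracks the
            # well-conditioned directions, resists large joint excursions.
            damped = True
            lam = max(damping, max_singular_damping * (1.0 - sv_min / sv_floor))
            delta = np.linalg.solve(
                J.T @ J + lam**2 * eye, J.T @ r - lam**2 * (q_dyn - q_prev)
            )
            if np.linalg.norm(delta) < 1e-12:
                break
            q_dyn = q_dyn + delta
        # physiological joint-speed cap; doubles as a smooth catch-up limiter
        # when exact tracking resumes after a damped stretch
        dq = q_dyn - q_prev
        dq_norm = np.linalg.norm(dq)
        if step > 0 and dq_norm > dq_max:
            damped = True
            q_dyn = q_prev + dq * (dq_max / dq_norm)
        if damped:
            rn = np.linalg.norm(target - chain.fk(q_dyn))
        if rn > (slip_tol if damped else residual_tol):
            raise IKError(f"IK did not converge at step {step}: residual {rn:.3g} m")
        Q[step, dyn] = q_dyn
    return JointTrajectory(times=traj.times.copy(), q=Q)


def _fd_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """First derivative along axis 0: 4th-order central stencils in the
    interior, 2nd-order (one-sided at the very ends) near the boundaries.

    The higher interior order matters: joint trajectories are differentiated
    twice at 1 ms, and for fast (0.5 s) movements the quintic profile's upper
    derivatives are large enough that plain central differences leave visible
    truncation noise in q'' and hence in the torques.
    """
    d = np.gradient(x, dt, axis=0, edge_order=2)
    if x.shape[0] >= 5:
        d[2:-2] = (-x[4:] + 8 * x[3:-1] - 8 * x[1:-3] + x[:-4]) / (12 * dt)
    if x.shape[0] >= 7:
        d[3:-3] = (
            x[6:] - 9 * x[5:-1] + 45 * x[4:-2] - 45 * x[2:-4] + 9 * x[1:-5] - x[:-6]
        ) / (60 * dt)
    return d


def differentiate_joint_trajectory(jt: JointTrajectory, dt: float) -> JointTrajectory:
    """Finite-difference q' and q''; central interior stencils, one-sided
    second-order at the ends. Constant (static) DOF columns get exact zeros
    rather than being numerically differentiated."""
    if len(jt.times) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    q = jt.q
    qd = _fd_derivative(q, dt)
    static = np.ptp(q, axis=0) == 0.0
    qd[:, static] = 0.0
    qdd = _fd_derivative(qd, dt)
    qdd[:, static] = 0.0
    return JointTrajectory(times=jt.times, q=q, qd=qd, qdd=qdd)


def smooth_joint_trajectory(
    jt: JointTrajectory, dt: float, cutoff_hz: float
) -> JointTrajectory:
    """Zero-phase low-pass filter (4th-order Butterworth, filtfilt) of the
    joint angles, applied to the moving DOFs only.

    Standard biomechanics practice before inverse dynamics: the exact
    3-DOF inverse kinematics crosses kinematically singular sheets (fingertip
    aligned with the humerus; the extension boundary), where it demands
    millisecond-scale joint transients far above physiological bandwidth.
    Reaching content at the durations used here lies below ~6 Hz, so a 10 Hz
    cutoff preserves the movement while removing the singular transients.
    """
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, cutoff_hz, fs=1.0 / dt, output="sos")
    q = jt.q.copy()
    moving = np.ptp(q, axis=0) > 0
    q[:, moving] = sosfiltfilt(sos, q[:, moving], axis=0)
    return JointTrajectory(times=jt.times, q=q)


def synthesize_movement(
    model: ArmModel, spec: MovementSpec, filter_cutoff_hz: float | None = 10.0
) -> JointTrajectory:
    """Endpoint synthesis + IK (+ optional smoothing) + differentiation."""
    ep = minimum_jerk_endpoint_trajectory(spec)
    jt = solve_inverse_kinematics(model, ep, spec.start.anchor_posture)
    if filter_cutoff_hz is not None:
        jt = smooth_joint_trajectory(jt, spec.dt, filter_cutoff_hz)
    return differentiate_joint_trajectory(jt, spec.dt)


# ---------------------------------------------------------------------------
# workspace grid

def _lateral_anchor(model: ArmModel, elevation: float) -> np.ndarray:
    """Outstretched-arm posture (elbow effectively extended) at a shoulder
    elevation angle relative to the horizontal."""
    q = model.neutral_q()
    q[model.dof_index("shoulder_fe")] = elevation
    q[model.dof_index("shoulder_rot")] = 0.0
    q[model.dof_index("elbow_fe")] = ELBOW_EXTENSION_MARGIN
    return q


def _reachable(chain: _ReducedChain, q_start: np.ndarray, target: np.ndarray,
               start_point: np.ndarray, n_sub: int = 24) -> tuple[bool, np.ndarray]:
    """Continuation IK from a known posture/endpoint to a target point."""
    q = np.asarray(q_start, dtype=float).copy()
    for s in np.linspace(0.0, 1.0, n_sub + 1)[1:]:
        waypoint = (1 - s) * start_point + s * target
        q, rn = solve_ik_point(chain, waypoint, q)
        if rn > 1e-7:
            return False, q
    return True, q


def build_workspace_grid(model: ArmModel) -> list[GridVertex]:
    """The 27-vertex reaching grid.

    Vertex index (i, j, k): i anterior-posterior (0 proximal at 0.10 m
    anterior of the body plane, 2 most anterior), j medio-lateral (0 lateral
    outstretched column, 2 medial column toward the contralateral shoulder),
    k vertical (0 low, 2 high; heights are those of the outstretched arm at
    -45/0/+45 degrees of shoulder elevation). The lateral far column holds
    the outstretched-arm anchors; the j-vertex (2, 0, 1) has shoulder
    flexion-extension exactly 0 (horizontal) with the elbow extended.
    Vertices beyond the 3-dynamic-DOF reach envelope are clipped inward with
    a safety margin; anchors are solved by continuation IK.
    """
    neutral = model.neutral_q()
    chain = _ReducedChain(model, neutral)
    dyn = chain.order
    elevations = np.deg2rad([-45.0, 0.0, 45.0])
    lateral_q = [_lateral_anchor(model, e) for e in elevations]
    lateral_p = [model.forward_kinematics(q) for q in lateral_q]
    y_contra = model.shoulder_separation
    vertices: dict[tuple[int, int, int], GridVertex] = {}

    def far_x(y: float, z: float, x_hi: float, q_seed, p_seed) -> float:
        """Largest anterior coordinate reachable at (y, z), with margin."""
        x_lo = PROXIMAL_CLEARANCE
        ok, _ = _reachable(chain, q_seed, np.array([x_hi, y, z]), p_seed)
        if ok:
            return x_hi
        for _ in range(20):
            x_mid = 0.5 * (x_lo + x_hi)
            ok, _ = _reachable(chain, q_seed, np.array([x_mid, y, z]), p_seed)
            if ok:
                x_lo = x_mid
            else:
                x_hi = x_mid
        return REACH_MARGIN * x_lo

    def medial_y(y_hi: float, z: float, y_lo: float, q_seed, p_seed) -> float:
        """Most medial coordinate reachable at the proximal plane, with margin.

        The proximal (x = 0.10 m) plane is the binding case for medial reach:
        with shoulder abduction static the elbow stays in the sagittal plane,
        so fingertip positions close to the contralateral shoulder at small
        anterior distances may fall outside the envelope and are pulled back.
        """
        ok, _ = _reachable(chain, q_seed, np.array([PROXIMAL_CLEARANCE, y_hi, z]), p_seed)
        if ok:
            return y_hi
        for _ in range(20):
            y_mid = 0.5 * (y_lo + y_hi)
            ok, _ = _reachable(chain, q_seed, np.array([PROXIMAL_CLEARANCE, y_mid, z]), p_seed)
            if ok:
                y_lo = y_mid
            else:
                y_hi = y_mid
        return y_lo - (1.0 - REACH_MARGIN) * (y_lo - p_seed[1])

    # The reach envelope is not convex: straight chords between two reachable
    # medial vertices stay at the medial y throughout, so the medial column
    # is clipped to the *least* medial capacity across the three heights
    # (binding at shoulder height, where pure-medial reach is shortest).
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_med = min(
            medial_y(y_contra, lateral_p[k][2], lateral_p[k][1], lateral_q[k][dyn], lateral_p[k])
            for k in range(3)
        )
    for k in range(3):
        p_lat = lateral_p[k]
        q_lat = lateral_q[k]
        z = p_lat[2]
        y_cols = {0: p_lat[1], 1: 0.5 * (p_lat[1] + y_med), 2: y_med}
        x_far_cols = {0: p_lat[0]}
        for j in (1, 2):
            x_cap = far_x(y_cols[j], z, p_lat[0], q_lat[dyn], p_lat)
            # middle column: midway medio-laterally, clipped to the envelope
            if j == 1:
                x_cap = min(x_cap, p_lat[0])
            x_far_cols[j] = x_cap
        for j in range(3):
            for i in range(3):
                if i == 2 and j == 0:
                    vertices[(2, 0, k)] = GridVertex((2, 0, k), p_lat.copy(), q_lat.copy())
                    continue
                x_prox = PROXIMAL_CLEARANCE
                x = {0: x_prox, 1: 0.5 * (x_prox + x_far_cols[j]), 2: x_far_cols[j]}[i]
                target = np.array([x, y_cols[j], z])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ok, q_dyn = _reachable(chain, q_lat[dyn], target, p_lat)
                if not ok:
                    raise GridConstructionError(
                        f"IK failed for grid vertex {(i, j, k)} at {np.round(target, 3)}"
                    )
                q_anchor = neutral.copy()
                q_anchor[dyn] = q_dyn
                vertices[(i, j, k)] = GridVertex((i, j, k), target, q_anchor)
    return [vertices[idx] for idx in sorted(vertices)]


def enumerate_movements(
    grid: list[GridVertex],
    durations=DEFAULT_DURATIONS,
    dt: float = DEFAULT_DT,
) -> list[MovementSpec]:
    """All unordered pairs of distinct vertices, replicated per duration.

    27 vertices give C(27, 2) = 351 movement paths per duration.
    """
    if not grid:
        raise ValueError("grid is empty")
    specs = []
    for a, b in itertools.combinations(grid, 2):
        for T in durations:
            specs.append(MovementSpec(start=a, end=b, duration=float(T), dt=dt))
    return specs
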