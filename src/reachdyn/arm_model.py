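"""Scalable 23-DOF rigid-body model of the human arm and hand.

The model is a rooted kinematic tree of segments, each carrying one or more
revolute degrees of freedom (DOFs). Exactly three DOFs are *dynamic* during
reaching -- shoulder flexion-extension, shoulder internal-external rotation
and elbow flexion-extension -- while the remaining twenty are held at their
neutral posture (the middle of the range of motion). The DOF ordering listed
in the model configuration defines the layout of the joint-angle vector ``q``
and of the torque vector ``tau`` everywhere downstream.

Coordinate convention: right-handed thorax frame anchored at the reaching
(right) glenohumeral joint centre, x anterior, y leftward (medial), z up;
gravity is (0, 0, -9.81) m/s^2. Angles are radians internally.

Geometry and mass properties scale with subject height and mass through
fixed anthropometric fractions shipped in ``data/default_arm.yaml``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SegmentSpec",
    "JointDof",
    "ArmModel",
    "build_default_arm_model",
    "build_serial_chain",
    "forward_kinematics",
    "endpoint_jacobian",
]

#: ratio of the longitudinal to the transverse radius of gyration for the
#: rod-like limb segments (segments are slender along their local +x axis)
LONGITUDINAL_GYRATION_RATIO = 0.25


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length joint axis")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ax, ay, az = axis
    K = np.array([[0.0, -az, ay], [az, 0.0, -ax], [-ay, ax, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def rotations_about_axis(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Vectorised Rodrigues: (T,) angles -> (T, 3, 3) rotation matrices."""
    ax, ay, az = axis
    K = np.array([[0.0, -az, ay], [az, 0.0, -ax], [-ay, ax, 0.0]])
    K2 = K @ K
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return np.eye(3)[None] + s * K[None] + c * K2[None]


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment of the arm.

    ``origin`` is the position of the segment's proximal joint in the parent
    segment's frame (metres); by default a segment attaches at its parent's
    distal end (parent length along local +x). ``com_offset`` is the distance
    of the centre of mass from the proximal joint along the segment's +x axis.
    ``inertia`` is the 3x3 inertia tensor about the centre of mass, in the
    segment frame.
    """

    name: str
    parent: str  # another segment name, or "root"
    length: float
    mass: float
    com_offset: float
    inertia: np.ndarray
    origin: np.ndarray | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be > 0")
        if self.length < 0:
            raise ValueError(f"segment {self.name}: length must be >= 0")
        I = np.asarray(self.inertia, dtype=float)
        if I.shape != (3, 3) or not np.allclose(I, I.T, atol=1e-12):
            raise ValueError(f"segment {self.name}: inertia must be symmetric 3x3")
        if np.linalg.eigvalsh(I).min() < -1e-12:
            raise ValueError(f"segment {self.name}: inertia must be positive semi-definite")
        object.__setattr__(self, "inertia", I)
        if self.origin is not None:
            object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


@dataclass(frozen=True)
class JointDof:
    """A single revolute DOF, attached to a segment.

    The rotation axis is a unit vector expressed in the DOF's own (joint)
    frame, which coincides with the parent frame at zero angle. The neutral
    angle is the midpoint of the range of motion.
    """

    name: str
    segment: str
    axis: np.ndarray
    q_range: tuple[float, float]
    dynamic: bool = False

    def __post_init__(self):
        object.__setattr__(self, "axis", _unit(self.axis))
        lo, hi = self.q_range
        if not lo < hi:
            raise ValueError(f"dof {self.name}: empty range")
        object.__setattr__(self, "q_range", (float(lo), float(hi)))

    @property
    def neutral_angle(self) -> float:
        lo, hi = self.q_range
        return 0.5 * (lo + hi)


class _CompiledChain:
    """Flat per-DOF arrays for fast kinematics/dynamics over the tree.

    Every DOF becomes one "body". Bodies belonging to the same segment are
    chained with zero translation; the segment's mass properties attach to
    the last body of the segment.
    """

    def __init__(self, model: "ArmModel"):
        seg_by_name = {s.name: s for s in model.segments}
        # last body index per segment, filled as we walk the DOF list
        seg_last_body: dict[str, int] = {}
        n = len(model.dofs)
        self.parent = np.full(n, -1, dtype=int)
        self.r = np.zeros((n, 3))  # joint origin in parent body frame
        self.axis = np.zeros((n, 3))
        self.mass = np.zeros(n)
        self.com = np.zeros((n, 3))
        self.inertia = np.zeros((n, 3, 3))
        seen_segments: list[str] = []
        for i, dof in enumerate(model.dofs):
            seg = seg_by_name[dof.segment]
            first_of_segment = dof.segment not in seg_last_body
            if first_of_segment:
                if seg.parent == "root":
                    self.parent[i] = -1
                    parent_seg = None
                else:
                    if seg.parent not in seg_last_body:
                        raise ValueError(
                            f"segment {seg.name}: parent {seg.parent} must precede it"
                        )
                    self.parent[i] = seg_last_body[seg.parent]
                    parent_seg = seg_by_name[seg.parent]
                if seg.origin is not None:
                    self.r[i] = seg.origin
                elif parent_seg is not None:
                    self.r[i] = np.array([parent_seg.length, 0.0, 0.0])
                seen_segments.append(dof.segment)
            else:
                self.parent[i] = seg_last_body[dof.segment]
            self.axis[i] = dof.axis
            seg_last_body[dof.segment] = i
        # attach mass properties to each segment's last body
        for seg in model.segments:
            if seg.name not in seg_last_body:
                raise ValueError(f"segment {seg.name} has no DOFs")
            i = seg_last_body[seg.name]
            self.mass[i] = seg.mass
            self.com[i] = np.array([seg.com_offset, 0.0, 0.0])
            self.inertia[i] = seg.inertia
        self.endpoint_body = seg_last_body[model.endpoint_segment]
        self.endpoint_local = np.asarray(model.endpoint_local, dtype=float)
        # children lists for the inward dynamics pass
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if self.parent[i] >= 0:
                self.children[self.parent[i]].append(i)

    def fk_frames(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World rotation (n,3,3) and origin (n,3) of every body frame."""
        n = len(self.parent)
        R = np.empty((n, 3, 3))
        o = np.empty((n, 3))
        for i in range(n):
            Ri = rotation_about_axis(self.axis[i], q[i])
            p = self.parent[i]
            if p < 0:
                R[i] = Ri
                o[i] = self.r[i]
            else:
                R[i] = R[p] @ Ri
                o[i] = o[p] + R[p] @ self.r[i]
        return R, o

    def endpoint(self, q: np.ndarray) -> np.ndarray:
        R, o = self.fk_frames(q)
        e = self.endpoint_body
        return o[e] + R[e] @ self.endpoint_local


@dataclass
class ArmModel:
    """Kinematic tree of segments with an ordered list of revolute DOFs."""

    segments: list[SegmentSpec]
    dofs: list[JointDof]
    gravity: np.ndarray
    subject_height: float
    subject_mass: float
    endpoint_segment: str
    endpoint_local: np.ndarray
    shoulder_separation: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, dtype=float)
        self.endpoint_local = np.asarray(self.endpoint_local, dtype=float)
        names = [d.name for d in self.dofs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate DOF names")
        self._compiled: _CompiledChain | None = None

    # -- basic queries ----------------------------------------------------
    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dofs]

    @property
    def dynamic_dofs(self) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.dofs) if d.dynamic], dtype=int)

    @property
    def static_dofs(self) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.dofs) if not d.dynamic], dtype=int)

    def dof_index(self, name: str) -> int:
        return self.dof_names.index(name)

    def neutral_q(self) -> np.ndarray:
        return np.array([d.neutral_angle for d in self.dofs])

    def q_ranges(self) -> np.ndarray:
        return np.array([d.q_range for d in self.dofs])

    @property
    def compiled(self) -> _CompiledChain:
        if self._compiled is None:
            self._compiled = _CompiledChain(self)
        return self._compiled

    # -- kinematics -------------------------------------------------------
    def _check_q(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_dofs,):
            raise ValueError(f"q must have shape ({self.n_dofs},), got {q.shape}")
        if not np.all(np.isfinite(q)):
            raise ValueError("q contains NaN or Inf")
        rng = self.q_ranges()
        excursion = np.maximum(rng[:, 0] - q, q - rng[:, 1])
        worst = excursion.max()
        if worst > 1e-9:
            i = int(excursion.argmax())
            warnings.warn(
                f"joint angle outside range of motion: {self.dofs[i].name} "
                f"by {worst:.3g} rad",
                stacklevel=3,
            )
        return q

    def forward_kinematics(self, q: np.ndarray) -> np.ndarray:
        """Fingertip (endpoint marker) position in the thorax frame, metres."""
        q = self._check_q(q)
        return self.compiled.endpoint(q)

    def endpoint_jacobian(self, q: np.ndarray, dofs: Sequence[int] | None = None) -> np.ndarray:
        """Geometric Jacobian d(endpoint)/dq for the selected DOFs, (3, k)."""
        q = self._check_q(q)
        if dofs is None:
            dofs = range(self.n_dofs)
        dofs = list(dofs)
        if len(dofs) == 0:
            raise ValueError("dofs must be a non-empty subset")
        ch = self.compiled
        R, o = ch.fk_frames(q)
        e = ch.endpoint_body
        p_end = o[e] + R[e] @ ch.endpoint_local
        # a DOF only moves the endpoint if it lies on the root->endpoint path
        on_path = np.zeros(self.n_dofs, dtype=bool)
        i = e
        while i >= 0:
            on_path[i] = True
            i = ch.parent[i]
        J = np.zeros((3, len(dofs)))
        for k, j in enumerate(dofs):
            if not on_path[j]:
                continue
            z = R[j] @ ch.axis[j]
            J[:, k] = np.cross(z, p_end - o[j])
        return J

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subject_height": self.subject_height,
            "subject_mass": self.subject_mass,
            "gravity": self.gravity.tolist(),
            "shoulder_separation": self.shoulder_separation,
            "endpoint": {
                "segment": self.endpoint_segment,
                "local": self.endpoint_local.tolist(),
            },
            "segments": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "length": s.length,
                    "mass": s.mass,
                    "com_offset": s.com_offset,
                    "inertia": s.inertia.tolist(),
                    **({"origin": s.origin.tolist()} if s.origin is not None else {}),
                }
                for s in self.segments
            ],
            "dofs": [
                {
                    "name": d.name,
                    "segment": d.segment,
                    "axis": d.axis.tolist(),
                    "q_range": list(d.q_range),
                    "dynamic": d.dynamic,
                }
                for d in self.dofs
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArmModel":
        segments = [
            SegmentSpec(
                name=s["name"],
                parent=s["parent"],
                length=s["length"],
                mass=s["mass"],
                com_offset=s["com_offset"],
                inertia=np.array(s["inertia"]),
                origin=np.array(s["origin"]) if "origin" in s else None,
            )
            for s in data["segments"]
        ]
        dofs = [
            JointDof(
                name=d["name"],
                segment=d["segment"],
                axis=np.array(d["axis"]),
                q_range=tuple(d["q_range"]),
                dynamic=d["dynamic"],
            )
            for d in data["dofs"]
        ]
        return cls(
            segments=segments,
            dofs=dofs,
            gravity=np.array(data["gravity"]),
            subject_height=data["subject_height"],
            subject_mass=data["subject_mass"],
            endpoint_segment=data["endpoint"]["segment"],
            endpoint_local=np.array(data["endpoint"]["local"]),
            shoulder_separation=data.get("shoulder_separation", 0.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ArmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        import hashlib

        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _segment_inertia(mass: float, length: float, gyration_fraction: float) -> np.ndarray:
    """Diagonal inertia of a slender segment whose long axis is local +x."""
    r_t = gyration_fraction * length
    r_l = LONGITUDINAL_GYRATION_RATIO * r_t
    return np.diag([mass * r_l**2, mass * r_t**2, mass * r_t**2])


def load_default_config() -> dict:
    with resources.files("reachdyn.data").joinpath("default_arm.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_default_arm_model(
    height: float = 1.8, mass: float = 72.6, config: dict | None = None
) -> ArmModel:
    """Build the 23-DOF arm+hand model scaled to a subject's height and mass.

    Segment lengths scale linearly with height and segment masses linearly
    with total body mass, via the anthropometric fractions in the shipped
    configuration file.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    cfg = config if config is not None else load_default_config()
    segments: list[SegmentSpec] = []
    dofs: list[JointDof] = []
    for seg in cfg["segments"]:
        length = seg["length_fraction"] * height
        seg_mass = seg["mass_fraction"] * mass
        origin = None
        if "origin_fraction" in seg:
            origin = np.asarray(seg["origin_fraction"], dtype=float) * height
        segments.append(
            SegmentSpec(
                name=seg["name"],
                parent=seg["parent"],
                length=length,
                mass=seg_mass,
                com_offset=seg["com_fraction"] * length,
                inertia=_segment_inertia(seg_mass, length, seg["gyration_fraction"]),
                origin=origin,
            )
        )
        for d in seg["dofs"]:
            lo, hi = np.deg2rad(d["range_deg"])
            dofs.append(
                JointDof(
                    name=d["name"],
                    segment=seg["name"],
                    axis=np.asarray(d["axis"], dtype=float),
                    q_range=(float(lo), float(hi)),
                    dynamic=bool(d["dynamic"]),
                )
            )
    ep = cfg["endpoint"]
    model = ArmModel(
        segments=segments,
        dofs=dofs,
        gravity=np.asarray(cfg["gravity"], dtype=float),
        subject_height=float(height),
        subject_mass=float(mass),
        endpoint_segment=ep["segment"],
        endpoint_local=np.asarray(ep["local_fraction"], dtype=float) * height,
        shoulder_separation=cfg["shoulder_separation_fraction"] * height,
    )
    if model.n_dofs != 23:
        raise ValueError(f"expected 23 DOFs, configuration defines {model.n_dofs}")
    return model


def build_serial_chain(
    lengths: Sequence[float],
    masses: Sequence[float],
    com_offsets: Sequence[float] | None = None,
    inertias: Sequence[np.ndarray] | None = None,
    axes: Sequence[np.ndarray] | None = None,
    gravity: np.ndarray = (0.0, 0.0, -9.81),
    dynamic: bool = True,
) -> ArmModel:
    """Build a simple serial revolute chain (testing and benchmarking aid).

    Links extend along local +x; the default axes are all (0, 0, 1), giving a
    planar chain in the x-y plane.
    """
    n = len(lengths)
    if com_offsets is None:
        com_offsets = [0.5 * L for L in lengths]
    if axes is None:
        axes = [np.array([0.0, 0.0, 1.0])] * n
    segments, dofs = [], []
    for i in range(n):
        inertia = (
            np.asarray(inertias[i], dtype=float)
            if inertias is not None
            else _segment_inertia(masses[i], lengths[i], 0.3)
        )
        segments.append(
            SegmentSpec(
                name=f"link{i}",
                parent="root" if i == 0 else f"link{i-1}",
                length=float(lengths[i]),
                mass=float(masses[i]),
                com_offset=float(com_offsets[i]),
                inertia=inertia,
            )
        )
        dofs.append(
            JointDof(
                name=f"joint{i}",
                segment=f"link{i}",
                axis=np.asarray(axes[i], dtype=float),
                q_range=(-2 * np.pi, 2 * np.pi),
                dynamic=dynamic,
            )
        )
    return ArmModel(
        segments=segments,
        dofs=dofs,
        gravity=np.asarray(gravity, dtype=float),
        subject_height=1.0,
        subject_mass=float(np.sum(masses)),
        endpoint_segment=f"link{n-1}",
        endpoint_local=np.array([lengths[-1], 0.0, 0.0]),
    )


# Free-function aliases mirroring the module's operation names.
def forward_kinematics(model: ArmModel, q: np.ndarray) -> np.ndarray:
    return model.forward_kinematics(q)


def endpoint_jacobian(model: ArmModel, q: np.ndarray, dofs: Sequence[int] | None = None) -> np.ndarray:
    return model.endpoint_jacobian(q, dofs)
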