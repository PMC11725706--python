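"""Muscle–tendon paths, wrapping surfaces, and tendon-excursion moment arms.

A muscle path is an ordered list of points (origin, via points, insertion)
each bound to a segment, plus optional wrapping surfaces (spheres and
cylinders) that deflect the path around joints and bone.  Path length in a
pose is the sum of straight spans, with any span that penetrates a wrap
surface replaced by the shortest tangent–arc–tangent route over it
(obstacle-set geometry; a cylinder wrap is solved in the plane
perpendicular to its axis and unrolled, a sphere wrap in the plane through
the endpoints and the centre).

The signed moment arm of a muscle about a joint DOF is computed by tendon
excursion: r = −dL/dθ (θ in radians), by central finite difference
(default step 0.25°).  Positive r about the JCS z-axis means the muscle
extends the joint; negative means it flexes (and analogously
ab/adduction about y, external/internal long-axis rotation about x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import forward_kinematics
from .model import BodyModel, Pose

__all__ = [
    "WrapSurface",
    "MusclePath",
    "MomentArmCurve",
    "path_length",
    "moment_arm",
    "mma_sweep",
    "classify_action",
]

_EPS = 1e-12


@dataclass
class WrapSurface:
    """A sphere or cylinder obstacle bound to a segment.

    ``frame`` is the surface's local frame in the segment's coordinates
    (4×4; the cylinder axis is the local z).  ``side`` selects the cylinder
    wrap direction: 0 chooses the shorter arc, +1/-1 force counterclockwise
    or clockwise travel in the local xy-plane.
    """

    kind: str
    segment: str
    frame: np.ndarray
    radius: float
    side: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown wrap kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError(f"wrap radius must be positive, got {self.radius}")
        self.frame = np.asarray(self.frame, dtype=float).reshape(4, 4)


@dataclass
class MusclePath:
    """One muscle–tendon unit: ordered attachment points and wrap surfaces.

    ``points`` is a list of (segment name, 3-vector in segment coordinates)
    running origin → via points → insertion.  ``inference`` carries the
    osteological-correlate inference level (I, I', II, II') as metadata.
    """

    acronym: str
    points: list
    wraps: list = field(default_factory=list)
    inference: tuple = ("", "")
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(
                f"muscle {self.acronym!r} needs >= 2 path points, got {len(self.points)}"
            )
        self.points = [(seg, np.asarray(p, dtype=float).reshape(3))
                       for seg, p in self.points]


@dataclass
class MomentArmCurve:
    """Signed moment arm r(θ) of one muscle about one joint DOF."""

    muscle: str
    joint: str
    dof: str
    angles_deg: np.ndarray
    moment_arm_m: np.ndarray
    h_deg: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.moment_arm_m = np.asarray(self.moment_arm_m, dtype=float)
        if len(self.angles_deg) != len(self.moment_arm_m):
            raise ValueError("angle grid and moment-arm arrays differ in length")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ValueError("angle grid must be strictly increasing")


# ---------------------------------------------------------------------------
# wrap geometry
# ---------------------------------------------------------------------------

def _circle_wrap_2d(P: np.ndarray, Q: np.ndarray, R: float, side: int):
    """Tangent–arc–tangent length around a circle of radius R at the origin.

    Returns (length, arc_angle) or None when the straight segment clears
    the circle (or only grazes it) on the requested side.
    """
    dP, dQ = np.linalg.norm(P), np.linalg.norm(Q)
    if dP <= R or dQ <= R:
        raise ValueError("wrap endpoint inside the wrap surface")
    # does the straight 2D segment enter the circle?
    d = Q - P
    tt = np.clip(-(P @ d) / max(d @ d, _EPS), 0.0, 1.0)
    closest = P + tt * d
    if np.linalg.norm(closest) >= R - 1e-12 or tt <= 0.0 or tt >= 1.0:
        return None  # clear or grazing: not wrapped
    lP = np.sqrt(dP * dP - R * R)
    lQ = np.sqrt(dQ * dQ - R * R)
    aP, aQ = np.arctan2(P[1], P[0]), np.arctan2(Q[1], Q[0])
    bP, bQ = np.arccos(R / dP), np.arccos(R / dQ)
    candidates = []
    for s in ((side,) if side in (1, -1) else (1, -1)):
        tP = aP + s * bP
        tQ = aQ - s * bQ
        arc = (s * (tQ - tP)) % (2 * np.pi)
        candidates.append((lP + R * arc + lQ, arc))
    length, arc = min(candidates)
    return length, arc


def _span_length_with_wrap(p: np.ndarray, q: np.ndarray, wrap: WrapSurface,
                           wrap_world: np.ndarray):
    """Length of span p→q over one posed wrap surface, or None if unengaged."""
    Tinv = np.linalg.inv(wrap_world)
    pl = Tinv[:3, :3] @ p + Tinv[:3, 3]
    ql = Tinv[:3, :3] @ q + Tinv[:3, 3]
    R = wrap.radius
    if wrap.kind == "cylinder":
        res = _circle_wrap_2d(pl[:2], ql[:2], R, wrap.side)
        if res is None:
            return None
        l2d, _ = res
        dz = ql[2] - pl[2]
        return float(np.hypot(l2d, dz))
    # sphere: work in the plane through both endpoints and the centre
    dP, dQ = np.linalg.norm(pl), np.linalg.norm(ql)
    if dP <= R or dQ <= R:
        raise ValueError("wrap endpoint inside the wrap surface")
    u = pl / dP
    w = ql - (ql @ u) * u
    nw = np.linalg.norm(w)
    if nw < _EPS:  # endpoints collinear with centre: wrap is degenerate
        return None
    v = w / nw
    P2 = np.array([dP, 0.0])
    Q2 = np.array([ql @ u, ql @ v])
    res = _circle_wrap_2d(P2, Q2, R, 0)
    if res is None:
        return None
    return float(res[0])


# ---------------------------------------------------------------------------
# path length and moment arms
# ---------------------------------------------------------------------------

def path_length(muscle: MusclePath, model: BodyModel, pose: Pose | dict,
                transforms: dict | None = None) -> float:
    """Muscle–tendon length (m) in *pose*.

    Straight spans between consecutive posed path points; a span that
    penetrates an assigned wrap surface takes the shortest
    tangent–arc–tangent route over it instead.  Raises if a path endpoint
    lies strictly inside a wrap surface.
    """
    if transforms is None:
        transforms = forward_kinematics(model, pose if isinstance(pose, Pose) else Pose(pose))
    world_pts = []
    for seg, p in muscle.points:
        T = transforms[seg]
        world_pts.append(T[:3, :3] @ p + T[:3, 3])
    wrap_worlds = [
        (w, transforms[w.segment] @ w.frame) for w in muscle.wraps
    ]
    total = 0.0
    for p, q in zip(world_pts, world_pts[1:]):
        span = float(np.linalg.norm(q - p))
        for w, Tw in wrap_worlds:
            wrapped = _span_length_with_wrap(p, q, w, Tw)
            if wrapped is not None:
                span = wrapped
                break
        total += span
    return total


def _crosses_joint(muscle: MusclePath, model: BodyModel, joint_name: str) -> bool:
    distal = model.distal_segments(joint_name)
    sides = {seg in distal for seg, _ in muscle.points}
    return len(sides) == 2


def moment_arm(
    muscle: MusclePath,
    model: BodyModel,
    joint: str,
    dof: str,
    pose: Pose | dict | None = None,
    h: float = 0.25,
) -> float:
    """Signed moment arm r = −dL/dθ (m) about one joint DOF.

    Central difference with step *h* (degrees; the derivative is taken with
    respect to θ in radians).  ROM limits are deliberately not enforced, so
    curves can be swept past the admissible range for continuity.  Raises
    if the muscle does not cross the joint.
    """
    if not _crosses_joint(muscle, model, joint):
        raise ValueError(
            f"muscle {muscle.acronym!r} does not cross joint {joint!r}; "
            "its moment arm there is undefined"
        )
    if dof not in model.joints[joint].dofs:
        raise ValueError(f"joint {joint!r} has no {dof!r} DOF")
    base = Pose({k: dict(v) for k, v in (pose or {}).items()})
    theta = base.angle(joint, dof)

    def length_at(angle: float) -> float:
        p = Pose({k: dict(v) for k, v in base.items()})
        p.setdefault(joint, {})[dof] = angle
        return path_length(muscle, model, p)

    h_rad = np.deg2rad(h)
    return float(-(length_at(theta + h) - length_at(theta - h)) / (2 * h_rad))


def mma_sweep(
    muscle: MusclePath,
    model: BodyModel,
    joint: str,
    dof: str,
    grid: np.ndarray,
    h: float = 0.25,
    base_pose: Pose | dict | None = None,
) -> MomentArmCurve:
    """Moment arm across an angle grid, other DOFs held at *base_pose*.

    The default base pose is the reference pose (all zeros), matching
    one-DOF-at-a-time sweeps.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    values = []
    for ang in grid:
        p = Pose({k: dict(v) for k, v in (base_pose or {}).items()})
        p.setdefault(joint, {})[dof] = float(ang)
        values.append(moment_arm(muscle, model, joint, dof, pose=p, h=h))
    return MomentArmCurve(
        muscle=muscle.acronym, joint=joint, dof=dof,
        angles_deg=grid, moment_arm_m=np.array(values), h_deg=h,
    )


_ACTION_LABELS = {
    "z": ("extensor", "flexor"),
    "y": ("abductor", "adductor"),
    "x": ("external rotator", "internal rotator"),
}


def classify_action(curve: MomentArmCurve, tol: float = 1e-4) -> dict:
    """Qualitative muscle action from the sign of its moment-arm curve.

    Returns a dict with ``label`` one of the DOF-appropriate pair (e.g.
    extensor/flexor about z), ``negligible`` (|r| < tol everywhere), or
    ``switching`` with the zero-crossing angle ``theta_deg`` interpolated
    linearly between grid points.
    """
    pos_label, neg_label = _ACTION_LABELS.get(curve.dof, ("positive", "negative"))
    r = curve.moment_arm_m
    if np.all(np.abs(r) < tol):
        return {"label": "negligible"}
    has_pos = np.any(r > tol)
    has_neg = np.any(r < -tol)
    if has_pos and has_neg:
        sign = np.sign(r)
        idx = np.nonzero(np.diff(np.signbit(r)))[0]
        if len(idx):
            i = int(idx[0])
            a0, a1 = curve.angles_deg[i], curve.angles_deg[i + 1]
            r0, r1 = r[i], r[i + 1]
            theta = a0 + (a1 - a0) * (-r0) / (r1 - r0)
        else:  # sign flip only through the dead band
            theta = float(curve.angles_deg[np.argmin(np.abs(r))])
        return {
            "label": "switching",
            "theta_deg": float(theta),
            "from": neg_label if r[0] < 0 else pos_label,
            "to": pos_label if r[-1] > 0 else neg_label,
        }
    return {"label": pos_label if has_pos else neg_label}
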