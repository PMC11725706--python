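"""Articular-surface primitive fitting, ACS/JCS construction, forward
kinematics, and range-of-motion checks.

Articular surfaces are approximated by geometric primitives — cylinders for
vertebral centra and the distal ends of long bones, spheres for
ball-and-socket surfaces, an ellipsoid for the proximal femur, planes for
the proximal ends of long bones — and the fitted primitive supplies the
origin and primary axis of an anatomical coordinate system (ACS).  Shared
ACSs define joint coordinate systems (JCSs); posing rotates each child
segment about its JCS in x → y → z order.

ROM limits are estimated by sweeping one DOF from the reference pose until
bone meshes collide or the articular surfaces drift apart (an automated
proxy for the visual disarticulation/collision judgement used when setting
joint limits by hand; the canonical *Riojasuchus* limits ship as a fixture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import ACS, BodyModel, Joint, Pose

__all__ = [
    "PrimitiveFit",
    "fit_primitive",
    "build_acs",
    "rotation_xyz",
    "forward_kinematics",
    "rom_check",
    "RomViolation",
    "rom_scan",
    "meshes_intersect",
]

_MIN_POINTS = {"plane": 3, "sphere": 4, "cylinder": 6, "ellipsoid": 9}


# ---------------------------------------------------------------------------
# primitive fitting
# ---------------------------------------------------------------------------

@dataclass
class PrimitiveFit:
    """Least-squares primitive parameters plus RMS residual (metres).

    ``axis`` is the cylinder axis or plane normal (unit, deterministic
    sign); ``radii``/``axes`` are set for ellipsoids (radii descending,
    principal directions as columns of ``axes``).
    """

    kind: str
    center: np.ndarray | None = None
    axis: np.ndarray | None = None
    radius: float | None = None
    radii: np.ndarray | None = None
    axes: np.ndarray | None = None
    rms: float = 0.0


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Unit vector with positive dot against +X (tie-break +Y, then +Z)."""
    v = v / np.linalg.norm(v)
    for i in range(3):
        if abs(v[i]) > 1e-12:
            return v if v[i] > 0 else -v
    return v


def fit_primitive(points: np.ndarray, kind: str) -> PrimitiveFit:
    """Fit a sphere, cylinder, ellipsoid, or plane to an articular patch.

    Raises ``ValueError`` when the point set is too small or degenerate for
    the requested primitive (e.g. collinear points for a plane, coplanar
    points for a sphere).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if kind not in _MIN_POINTS:
        raise ValueError(f"unknown primitive kind {kind!r}")
    if len(pts) < _MIN_POINTS[kind]:
        raise ValueError(
            f"{kind} fit needs >= {_MIN_POINTS[kind]} points, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max()))
    if kind == "plane" and rank < 2:
        raise ValueError("plane fit needs >= 3 non-collinear points")
    if kind in ("sphere", "ellipsoid", "cylinder") and rank < 3:
        raise ValueError(f"{kind} fit needs non-coplanar points")
    return {
        "plane": _fit_plane,
        "sphere": _fit_sphere,
        "cylinder": _fit_cylinder,
        "ellipsoid": _fit_ellipsoid,
    }[kind](pts)


def _fit_plane(pts: np.ndarray) -> PrimitiveFit:
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = _canonical_sign(vt[2])
    rms = float(np.sqrt(np.mean(((pts - center) @ normal) ** 2)))
    return PrimitiveFit(kind="plane", center=center, axis=normal, rms=rms)


def _fit_sphere(pts: np.ndarray) -> PrimitiveFit:
    # |x|^2 = 2 c.x + (r^2 - |c|^2): linear in (c, k)
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    radius = float(np.sqrt(max(k + center @ center, 0.0)))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return PrimitiveFit(kind="sphere", center=center, radius=radius, rms=rms)


def _axis_distances(pts, p0, v):
    v = v / np.linalg.norm(v)
    d = pts - p0
    return np.linalg.norm(d - np.outer(d @ v, v), axis=1)


def _fit_cylinder(pts: np.ndarray) -> PrimitiveFit:
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)

    def residual(x):
        p0 = x[:3]
        v = x[3:6]
        n = np.linalg.norm(v)
        if n < 1e-12:
            return np.full(len(pts), 1e6)
        return _axis_distances(pts, p0, v / n) - x[6]

    best = None
    for v0 in vt:  # try each principal direction as the initial axis
        r0 = float(np.mean(_axis_distances(pts, centroid, v0)))
        x0 = np.concatenate([centroid, v0, [max(r0, 1e-9)]])
        sol = least_squares(residual, x0, method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    axis = _canonical_sign(best.x[3:6])
    radius = float(abs(best.x[6]))
    p0 = best.x[:3]
    # report the axis point closest to the data centroid (the free parameter
    # along the axis is otherwise unconstrained)
    center = p0 + ((centroid - p0) @ axis) * axis
    rms = float(np.sqrt(np.mean((_axis_distances(pts, center, axis) - radius) ** 2)))
    return PrimitiveFit(kind="cylinder", center=center, axis=axis, radius=radius, rms=rms)


def _fit_ellipsoid(pts: np.ndarray) -> PrimitiveFit:
    # algebraic quadric: x'Qx + 2 g.x = 1, 9 linear parameters
    x, y, z = pts.T
    A = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z]
    )
    sol, *_ = np.linalg.lstsq(A, np.ones(len(pts)), rcond=None)
    Q = np.array(
        [
            [sol[0], sol[3], sol[4]],
            [sol[3], sol[1], sol[5]],
            [sol[4], sol[5], sol[2]],
        ]
    )
    g = sol[6:9]
    try:
        center = np.linalg.solve(Q, -g)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate ellipsoid fit (singular quadric)") from exc
    scale = 1.0 + center @ Q @ center  # (x-c)'Q(x-c) = 1 + c'Qc
    evals, evecs = np.linalg.eigh(Q / scale)
    if np.any(evals <= 0):
        raise ValueError("quadric fit is not an ellipsoid (non-positive eigenvalue)")
    radii = 1.0 / np.sqrt(evals)  # eigh ascending evals => radii descending
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    axes = evecs[:, order]
    for i in range(3):
        axes[:, i] = _canonical_sign(axes[:, i])
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    d = np.linalg.norm((pts - center) @ axes / radii, axis=1)
    rms = float(np.sqrt(np.mean((d - 1.0) ** 2)) * np.exp(np.mean(np.log(radii))))
    return PrimitiveFit(
        kind="ellipsoid", center=center, axis=axes[:, 0], radii=radii, axes=axes, rms=rms
    )


# ---------------------------------------------------------------------------
# ACS construction
# ---------------------------------------------------------------------------

def build_acs(
    primitive: PrimitiveFit,
    reference: np.ndarray,
    fallback_axis=(0.0, 0.0, 1.0),
) -> ACS:
    """Right-handed ACS from a fitted primitive and a reference direction.

    The primitive's axis becomes the ACS z-axis (flexion/extension axis for
    a cylinder; plane normal; longest principal axis of an ellipsoid); for
    a sphere, which has no orientation, *fallback_axis* is used.  The
    x-axis is the reference direction Gram–Schmidt-orthogonalized against
    z; y completes the right-handed frame.
    """
    reference = np.asarray(reference, dtype=float).reshape(3)
    if primitive.axis is not None:
        z = primitive.axis / np.linalg.norm(primitive.axis)
    else:
        z = np.asarray(fallback_axis, dtype=float)
        z = z / np.linalg.norm(z)
    x = reference - (reference @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("reference direction is parallel to the primitive axis")
    x = x / nx
    y = np.cross(z, x)
    origin = primitive.center if primitive.center is not None else np.zeros(3)
    return ACS(origin=origin, axes=np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def rotation_xyz(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Rotation matrix Rx(θx) · Ry(θy) · Rz(θz), angles in radians."""
    cx, sx = np.cos(theta_x), np.sin(theta_x)
    cy, sy = np.cos(theta_y), np.sin(theta_y)
    cz, sz = np.cos(theta_z), np.sin(theta_z)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def forward_kinematics(model: BodyModel, pose: Pose) -> dict:
    """World transform of every segment under *pose* (degrees).

    Each joint applies ``G · Rx·Ry·Rz · G⁻¹`` to the child's reference
    placement, where ``G`` is the JCS frame; the all-zero pose reproduces
    the reference placements exactly.  Raises if the pose sets an angle on
    an unflagged DOF.
    """
    pose = pose if isinstance(pose, Pose) else Pose(pose)
    pose.validate(model)
    transforms = {model.root: model.reference_placements[model.root].copy()}
    pending = [j for j in model.joints.values()]
    # walk the tree from the root
    progress = True
    while pending and progress:
        progress = False
        for joint in list(pending):
            if joint.parent not in transforms:
                continue
            pending.remove(joint)
            progress = True
            transforms[joint.child] = _child_transform(model, joint, pose,
                                                       transforms[joint.parent])
    if pending:
        names = [j.name for j in pending]
        raise ValueError(f"joints not reachable from root {model.root!r}: {names}")
    # segments with no joint path (free bodies) stay at reference
    for name, T in model.reference_placements.items():
        transforms.setdefault(name, T.copy())
    return transforms


def _child_transform(model, joint, pose, parent_world):
    angles = [np.deg2rad(pose.angle(joint.name, d)) for d in ("x", "y", "z")]
    R = rotation_xyz(*angles)
    G = joint.jcs.to_matrix()
    Rh = np.eye(4)
    Rh[:3, :3] = R
    parent_ref = model.reference_placements[joint.parent]
    child_ref = model.reference_placements[joint.child]
    local = np.linalg.inv(parent_ref) @ G @ Rh @ np.linalg.inv(G) @ child_ref
    return parent_world @ local


# ---------------------------------------------------------------------------
# ROM
# ---------------------------------------------------------------------------

@dataclass
class RomViolation:
    joint: str
    dof: str
    angle: float
    limit: tuple


def rom_check(pose: Pose, model: BodyModel) -> list:
    """List (joint, dof, angle, limit) entries where *pose* exceeds ROM.

    Limits are inclusive: an angle exactly at the limit is admissible.
    Joints without declared limits are never violated.
    """
    pose = pose if isinstance(pose, Pose) else Pose(pose)
    out = []
    for jname, dofs in pose.items():
        joint = model.joints.get(jname)
        if joint is None:
            continue
        for dof, ang in dofs.items():
            if dof in joint.rom:
                lo, hi = joint.rom[dof]
                if ang < lo or ang > hi:
                    out.append(RomViolation(jname, dof, float(ang), (lo, hi)))
    return out


def _tri_tri_overlap(t1: np.ndarray, t2: np.ndarray, eps: float) -> np.ndarray:
    """Vectorized separating-axis test for triangle pairs.

    ``t1``/``t2`` have shape (n, 3, 3).  Returns a boolean array: True
    where no separating axis with margin > eps exists (i.e. overlap).
    """
    axes = []
    e1 = np.stack([t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 1], t1[:, 0] - t1[:, 2]], axis=1)
    e2 = np.stack([t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 1], t2[:, 0] - t2[:, 2]], axis=1)
    axes.append(np.cross(e1[:, 0], e1[:, 1])[:, None, :])  # n1
    axes.append(np.cross(e2[:, 0], e2[:, 1])[:, None, :])  # n2
    cross = np.cross(e1[:, :, None, :], e2[:, None, :, :]).reshape(len(t1), 9, 3)
    axes.append(cross)
    A = np.concatenate(axes, axis=1)  # (n, 11, 3)
    norms = np.linalg.norm(A, axis=2, keepdims=True)
    A = np.where(norms > 1e-12, A / np.maximum(norms, 1e-300), 0.0)

    p1 = np.einsum("nkd,nvd->nkv", A, t1)  # projections (n, 11, 3)
    p2 = np.einsum("nkd,nvd->nkv", A, t2)
    sep = (p1.min(axis=2) > p2.max(axis=2) + eps) | (p2.min(axis=2) > p1.max(axis=2) + eps)
    valid = norms[:, :, 0] > 1e-12
    return ~np.any(sep & valid, axis=1)


def meshes_intersect(
    vertices_a: np.ndarray,
    faces_a: np.ndarray,
    vertices_b: np.ndarray,
    faces_b: np.ndarray,
    eps: float = 1e-9,
) -> bool:
    """True if any triangle of mesh A overlaps any triangle of mesh B.

    Broad phase by axis-aligned box overlap, then an exact separating-axis
    test on the surviving pairs.  Grazing contact within *eps* counts as
    no intersection (continuity at the touching configuration).
    """
    ta = vertices_a[faces_a]  # (na, 3, 3)
    tb = vertices_b[faces_b]
    lo_a, hi_a = ta.min(axis=1), ta.max(axis=1)
    lo_b, hi_b = tb.min(axis=1), tb.max(axis=1)
    overlap = np.all(
        (lo_a[:, None] <= hi_b[None] + eps) & (lo_b[None] <= hi_a[:, None] + eps), axis=2
    )
    ia, ib = np.nonzero(overlap)
    if len(ia) == 0:
        return False
    hits = _tri_tri_overlap(ta[ia], tb[ib], eps)
    return bool(hits.any())


def _patch_faces_removed(mesh, patch_vertices):
    """Faces of *mesh* that do not touch the articular patch vertices."""
    faces = np.asarray(mesh.faces)
    if patch_vertices is None or len(patch_vertices) == 0:
        return faces
    mask = np.isin(faces, np.asarray(patch_vertices)).any(axis=1)
    return faces[~mask]


def rom_scan(
    model: BodyModel,
    joint_name: str,
    dof: str,
    step: float = 1.0,
    criteria: dict | None = None,
) -> tuple:
    """Estimate a DOF's admissible [min°, max°] by sweeping from 0°.

    Stops at the last admissible angle before (a) any triangle–triangle
    intersection between the parent and child segment meshes (articular
    patch faces excluded), or (b) the posed articular-patch centroids
    separating by more than the disarticulation gap (default 5 mm).

    ``criteria`` keys: ``collision`` (bool, default True), ``gap`` (metres,
    default 0.005; ``inf`` disables), ``max_angle`` (scan bound, default
    180°).  Raises if the reference pose itself is inadmissible.
    """
    criteria = dict(criteria or {})
    use_collision = criteria.get("collision", True)
    gap = float(criteria.get("gap", 0.005))
    max_angle = float(criteria.get("max_angle", 180.0))
    if step <= 0:
        raise ValueError("grid step must be positive")
    joint = model.joints[joint_name]
    parent = model.segments[joint.parent]
    child = model.segments[joint.child]
    if use_collision and (parent.mesh is None or child.mesh is None):
        raise ValueError(
            f"rom_scan needs collision meshes on segments "
            f"{joint.parent!r} and {joint.child!r}"
        )

    pf = _patch_faces_removed(parent.mesh, parent.articular_patches.get(joint_name)) \
        if use_collision else None
    cf = _patch_faces_removed(child.mesh, child.articular_patches.get(joint_name)) \
        if use_collision else None

    def patch_centroid(seg, mesh):
        idx = seg.articular_patches.get(joint_name)
        if idx is None or len(idx) == 0:
            return None
        return np.asarray(mesh.vertices)[np.asarray(idx)].mean(axis=0)

    pc_local = patch_centroid(parent, parent.mesh) if parent.mesh is not None else None
    cc_local = patch_centroid(child, child.mesh) if child.mesh is not None else None

    def admissible(angle: float) -> bool:
        pose = Pose({joint_name: {dof: angle}})
        T = forward_kinematics(model, pose)
        tp, tc = T[joint.parent], T[joint.child]
        if np.isfinite(gap) and pc_local is not None and cc_local is not None:
            pw = tp[:3, :3] @ pc_local + tp[:3, 3]
            cw = tc[:3, :3] @ cc_local + tc[:3, 3]
            if np.linalg.norm(pw - cw) > gap:
                return False
        if use_collision:
            va = np.asarray(parent.mesh.vertices) @ tp[:3, :3].T + tp[:3, 3]
            vb = np.asarray(child.mesh.vertices) @ tc[:3, :3].T + tc[:3, 3]
            if meshes_intersect(va, pf, vb, cf):
                return False
        return True

    if not admissible(0.0):
        raise ValueError(
            f"reference pose of joint {joint_name!r} violates the scan "
            "criteria (collision or disarticulation at 0 deg)"
        )

    def sweep(direction: int) -> float:
        angle = 0.0
        while abs(angle) < max_angle:
            trial = angle + direction * step
            if abs(trial) > max_angle or not admissible(trial):
                break
            angle = trial
        return angle

    return (sweep(-1), sweep(+1))
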