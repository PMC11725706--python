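"""Shared containers: segments, joints, poses, and the whole-body model.

Conventions (used throughout the package):

* global frame: +X craniad (toward the head), +Y left, +Z dorsad (up);
* each joint carries a joint coordinate system (JCS) shared by parent and
  child at the reference pose, with flexion/extension about the JCS z-axis,
  ab/adduction about y, and long-axis rotation (LAR) about x;
* joint rotations compose in x → y → z order; joints rotate only (no
  translations);
* angles are degrees at every interface (radians internally); extension,
  abduction and external LAR are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ACS", "Joint", "Pose", "Segment", "Landmark", "BodyModel", "DOF_NAMES"]

#: anatomical meaning of each JCS rotation axis
DOF_NAMES = {"z": "flexion-extension", "y": "ab-adduction", "x": "long-axis rotation"}


@dataclass
class ACS:
    """A right-handed orthonormal anatomical coordinate system.

    ``axes`` holds the x, y, z unit vectors as columns.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-8):
            raise ValueError("ACS axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("ACS is left-handed (determinant < 0)")

    def to_matrix(self) -> np.ndarray:
        """Homogeneous 4×4 transform from ACS-local to world coordinates."""
        T = np.eye(4)
        T[:3, :3] = self.axes
        T[:3, 3] = self.origin
        return T


@dataclass
class Joint:
    """A rotational joint between two segments.

    ``dofs`` lists the allowed rotation axes (subset of x, y, z); limb
    joints have one DOF (z) except hip and shoulder, which have three.
    ``rom`` maps a DOF to inclusive (min, max) limits in degrees.
    ``cartilage_offset`` is a fixed translation (metres, world frame)
    applied to the child's reference placement at model build to make room
    for articular cartilage; hip and ankle default to none.
    """

    name: str
    parent: str
    child: str
    jcs: ACS
    dofs: tuple = ("z",)
    rom: dict = field(default_factory=dict)
    cartilage_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        bad = [d for d in self.dofs if d not in ("x", "y", "z")]
        if bad:
            raise ValueError(f"joint {self.name!r}: unknown DOFs {bad}")
        self.dofs = tuple(self.dofs)
        self.cartilage_offset = np.asarray(self.cartilage_offset, dtype=float).reshape(3)
        for dof, (lo, hi) in self.rom.items():
            if not (lo <= 0.0 <= hi):
                raise ValueError(
                    f"joint {self.name!r} DOF {dof}: ROM [{lo}, {hi}] must "
                    "bracket the reference pose (0 deg)"
                )


class Pose(dict):
    """Map joint name → {dof: angle in degrees}.

    A plain dict subclass so poses serialize naturally; ``angle`` returns 0
    for any unset DOF.
    """

    def angle(self, joint: str, dof: str) -> float:
        return float(self.get(joint, {}).get(dof, 0.0))

    def validate(self, model: "BodyModel") -> None:
        for jname, dofs in self.items():
            if jname not in model.joints:
                raise ValueError(f"pose references unknown joint {jname!r}")
            allowed = model.joints[jname].dofs
            for dof, ang in dofs.items():
                if dof not in allowed and ang != 0.0:
                    raise ValueError(
                        f"joint {jname!r} has no {dof!r} DOF "
                        f"(allowed: {allowed}); cannot set {ang} deg"
                    )


@dataclass
class Segment:
    """One rigid body of the model.

    ``mesh`` is the collision/visual geometry (trimesh.Trimesh, optional);
    ``mass_props`` the segment's mass properties in the segment frame;
    ``articular_patches`` maps a joint name to vertex indices of the
    articular surface on this segment's mesh (used by ROM scanning).
    """

    name: str
    mesh: object | None = None
    density: float = 1000.0
    mass_props: object | None = None
    articular_patches: dict = field(default_factory=dict)


@dataclass
class Landmark:
    """A named anatomical point bound to a segment (segment-frame coords)."""

    segment: str
    point: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)


@dataclass
class BodyModel:
    """Segments + joints + muscles + landmarks forming a posable model.

    ``reference_placements`` maps segment → 4×4 world transform at the
    reference pose (identity when geometry is authored in world
    coordinates).  ``chains`` maps a limb name to an ordered list of point
    specs (joint names or landmark names) whose consecutive distances give
    the limb length.  ``preset_poses`` holds named poses (e.g. the adjusted
    standing pose used for the COM analysis).
    """

    segments: dict = field(default_factory=dict)
    joints: dict = field(default_factory=dict)
    muscles: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)
    preset_poses: dict = field(default_factory=dict)
    root: str = ""
    reference_placements: dict = field(default_factory=dict)
    foot_support: tuple | None = None

    def __post_init__(self) -> None:
        if self.segments and not self.root:
            self.root = next(iter(self.segments))

    def add_segment(self, seg: Segment, placement: np.ndarray | None = None) -> None:
        self.segments[seg.name] = seg
        self.reference_placements[seg.name] = (
            np.eye(4) if placement is None else np.asarray(placement, dtype=float)
        )
        if not self.root:
            self.root = seg.name

    def add_joint(self, joint: Joint) -> None:
        for s in (joint.parent, joint.child):
            if s not in self.segments:
                raise ValueError(f"joint {joint.name!r} references unknown segment {s!r}")
        self.joints[joint.name] = joint

    def validate(self) -> None:
        """Check that all cross-references resolve."""
        for j in self.joints.values():
            for s in (j.parent, j.child):
                if s not in self.segments:
                    raise ValueError(f"joint {j.name!r}: unknown segment {s!r}")
        for name, lm in self.landmarks.items():
            if lm.segment not in self.segments:
                raise ValueError(f"landmark {name!r}: unknown segment {lm.segment!r}")
        for m in self.muscles.values():
            for seg, _ in m.points:
                if seg not in self.segments:
                    raise ValueError(
                        f"muscle {m.acronym!r}: point bound to unknown segment {seg!r}"
                    )

    def children_of(self, segment: str) -> list:
        return [j.child for j in self.joints.values() if j.parent == segment]

    def joint_to_child(self, segment: str):
        """The joint whose child is *segment* (None for the root)."""
        for j in self.joints.values():
            if j.child == segment:
                return j
        return None

    def subtree(self, segment: str) -> set:
        """All segments at or distal to *segment*."""
        out, stack = set(), [segment]
        while stack:
            s = stack.pop()
            if s in out:
                continue
            out.add(s)
            stack.extend(self.children_of(s))
        return out

    def distal_segments(self, joint_name: str) -> set:
        """Segments on the child side of a joint."""
        return self.subtree(self.joints[joint_name].child)

    def gleno_acetabular_distance(self) -> float:
        try:
            ac = self.landmarks["acetabular_midpoint"]
            gl = self.landmarks["glenoid_midpoint"]
        except KeyError as exc:
            raise ValueError(f"model lacks landmark {exc.args[0]!r}") from exc
        pa = self.reference_placements[ac.segment]
        pg = self.reference_placements[gl.segment]
        wa = pa[:3, :3] @ ac.point + pa[:3, 3]
        wg = pg[:3, :3] @ gl.point + pg[:3, 3]
        d = float(np.linalg.norm(wg - wa))
        if d <= 0:
            raise ValueError("gleno-acetabular distance must be positive")
        return d
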