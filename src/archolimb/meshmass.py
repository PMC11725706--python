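"""Exact rigid-body mass properties of watertight triangle meshes.

Volume, centre of mass, and the inertia tensor are obtained by exact
integration over the surface triangles (divergence theorem): each triangle
together with the origin spans a signed tetrahedron, and the polynomial
moments of a tetrahedron have closed forms, so the only numerical error is
floating-point round-off.  Composite bodies (posed assemblies of parts) and
sagittal mirroring are handled at the level of the resulting
:class:`MassProperties`, which is how whole-body models are assembled from
per-segment solids.

All quantities are SI: metres, kilograms, kg·m².
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

log = logging.getLogger("archolimb")

__all__ = [
    "MassProperties",
    "mass_properties",
    "composite_properties",
    "mirror_body",
    "load_obj",
    "save_obj",
    "check_watertight",
]


# ---------------------------------------------------------------------------
# mesh handling
# ---------------------------------------------------------------------------

def load_obj(path) -> trimesh.Trimesh:
    """Load an OBJ file as a triangle mesh (polygonal faces triangulated)."""
    mesh = trimesh.load(str(path), file_type="obj", force="mesh", process=False)
    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        process=False,
    )


def save_obj(mesh: trimesh.Trimesh, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(trimesh.exchange.obj.export_obj(mesh, include_texture=False))


def check_watertight(mesh: trimesh.Trimesh) -> None:
    """Raise ``ValueError`` naming the open edges if *mesh* is not closed."""
    if mesh.is_watertight:
        return
    edges = mesh.edges_sorted
    order = np.lexsort(edges.T[::-1])
    edges = edges[order]
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    bad = unique[counts != 2]
    head = ", ".join(f"({a}, {b})" for a, b in bad[:8])
    more = "" if len(bad) <= 8 else f" … and {len(bad) - 8} more"
    raise ValueError(
        f"mesh is not watertight: {len(bad)} edge(s) not shared by exactly "
        f"two faces: {head}{more}"
    )


def _oriented(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Return *mesh* with consistently outward faces (signed volume > 0)."""
    signed = _tet_volume_sum(mesh.vertices, mesh.faces)
    if signed < 0:
        log.warning("mesh orientation inverted (signed volume %.3g); flipping", signed)
        return trimesh.Trimesh(
            vertices=mesh.vertices.copy(), faces=mesh.faces[:, ::-1], process=False
        )
    return mesh


def _tet_volume_sum(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


# ---------------------------------------------------------------------------
# mass properties
# ---------------------------------------------------------------------------

@dataclass
class MassProperties:
    """Mass, volume, COM, and inertia about the COM of a rigid body.

    ``inertia`` is the 3×3 tensor about ``com`` expressed in the body's
    coordinate frame.  ``mass = density * volume`` holds by construction for
    single solids; composites carry the summed mass and a volume-weighted
    density is not meaningful, so ``density`` is the ratio mass/volume.
    """

    mass: float
    volume: float
    com: np.ndarray
    inertia: np.ndarray
    density: float

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)

    def to_dict(self) -> dict:
        return {
            "mass_kg": self.mass,
            "volume_m3": self.volume,
            "com_m": self.com.tolist(),
            "inertia_kgm2": self.inertia.tolist(),
            "density_kgm3": self.density,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def csv_row(self, name: str = "") -> dict:
        """Flat mapping suitable for one row of a CSV report."""
        row = {"name": name, "mass_kg": self.mass, "volume_m3": self.volume}
        row.update({f"com_{ax}_m": c for ax, c in zip("xyz", self.com)})
        idx = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        lab = ["ixx", "iyy", "izz", "ixy", "ixz", "iyz"]
        row.update({f"{k}_kgm2": self.inertia[i, j] for k, (i, j) in zip(lab, idx)})
        return row


def mass_properties(mesh: trimesh.Trimesh, density: float) -> MassProperties:
    """Exact mass properties of a watertight mesh at uniform *density*.

    Integrates 1, x, x², xy … over the enclosed solid by summing signed
    origin-tetrahedra, one per face.  The inertia tensor is reduced to the
    COM by the parallel-axis theorem and reported in the mesh's own frame.

    Raises ``ValueError`` for a non-watertight mesh (naming open edges) or a
    negative density.
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    check_watertight(mesh)
    mesh = _oriented(mesh)

    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    # signed volume of tetra (origin, a, b, c); w = 6 V_tet
    w = np.einsum("ij,ij->i", a, np.cross(b, c))
    volume = w.sum() / 6.0
    if volume <= 0:
        raise ValueError("mesh has non-positive volume after orientation fix")

    # first moments: ∫ x dV over a tetra = V (a+b+c)/4 componentwise
    first = (w[:, None] * (a + b + c)).sum(axis=0) / 24.0
    com = first / volume

    # second moments over origin-tetra, standard closed forms:
    #   ∫ x_i x_i dV = (w/60)(aᵢ²+bᵢ²+cᵢ² + aᵢbᵢ+aᵢcᵢ+bᵢcᵢ)
    #   ∫ x_i x_j dV = (w/120)(2aᵢaⱼ+2bᵢbⱼ+2cᵢcⱼ + aᵢbⱼ+aⱼbᵢ + aᵢcⱼ+aⱼcᵢ + bᵢcⱼ+bⱼcᵢ)
    sq = (w[:, None] * (a * a + b * b + c * c + a * b + a * c + b * c)).sum(axis=0) / 60.0
    xy = (w * (2 * a[:, 0] * a[:, 1] + 2 * b[:, 0] * b[:, 1] + 2 * c[:, 0] * c[:, 1]
               + a[:, 0] * b[:, 1] + a[:, 1] * b[:, 0]
               + a[:, 0] * c[:, 1] + a[:, 1] * c[:, 0]
               + b[:, 0] * c[:, 1] + b[:, 1] * c[:, 0])).sum() / 120.0
    xz = (w * (2 * a[:, 0] * a[:, 2] + 2 * b[:, 0] * b[:, 2] + 2 * c[:, 0] * c[:, 2]
               + a[:, 0] * b[:, 2] + a[:, 2] * b[:, 0]
               + a[:, 0] * c[:, 2] + a[:, 2] * c[:, 0]
               + b[:, 0] * c[:, 2] + b[:, 2] * c[:, 0])).sum() / 120.0
    yz = (w * (2 * a[:, 1] * a[:, 2] + 2 * b[:, 1] * b[:, 2] + 2 * c[:, 1] * c[:, 2]
               + a[:, 1] * b[:, 2] + a[:, 2] * b[:, 1]
               + a[:, 1] * c[:, 2] + a[:, 2] * c[:, 1]
               + b[:, 1] * c[:, 2] + b[:, 2] * c[:, 1])).sum() / 120.0

    ixx = density * (sq[1] + sq[2])
    iyy = density * (sq[0] + sq[2])
    izz = density * (sq[0] + sq[1])
    inertia_origin = np.array(
        [
            [ixx, -density * xy, -density * xz],
            [-density * xy, iyy, -density * yz],
            [-density * xz, -density * yz, izz],
        ]
    )
    mass = density * volume
    inertia_com = inertia_origin - mass * (
        np.dot(com, com) * np.eye(3) - np.outer(com, com)
    )
    return MassProperties(
        mass=mass, volume=volume, com=com, inertia=inertia_com, density=density
    )


def composite_properties(
    parts: list[tuple[MassProperties, np.ndarray]],
) -> MassProperties:
    """Combine rigidly-posed parts into one body.

    *parts* is a list of ``(props, T)`` with ``T`` a 4×4 proper rigid
    transform taking the part's frame into the composite frame.  Total mass
    is the sum, COM the mass-weighted mean of transformed part COMs, and
    inertia tensors are rotated then shifted to the composite COM by the
    parallel-axis theorem.
    """
    if not parts:
        raise ValueError("composite_properties needs at least one part")
    total_mass = 0.0
    total_volume = 0.0
    weighted = np.zeros(3)
    posed: list[tuple[MassProperties, np.ndarray, np.ndarray]] = []
    for props, T in parts:
        T = np.asarray(T, dtype=float).reshape(4, 4)
        R = T[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("part transform is not a proper rigid motion")
        com_w = R @ props.com + T[:3, 3]
        total_mass += props.mass
        total_volume += props.volume
        weighted += props.mass * com_w
        posed.append((props, R, com_w))
    if total_mass <= 0:
        raise ValueError("composite has zero total mass; COM undefined")
    com = weighted / total_mass

    inertia = np.zeros((3, 3))
    for props, R, com_w in posed:
        i_rot = R @ props.inertia @ R.T
        d = com_w - com
        inertia += i_rot + props.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
    return MassProperties(
        mass=total_mass,
        volume=total_volume,
        com=com,
        inertia=inertia,
        density=total_mass / total_volume if total_volume > 0 else 0.0,
    )


def mirror_body(props: MassProperties, plane: str = "sagittal") -> MassProperties:
    """Reflect a body across the midsagittal plane (y = 0).

    Mass and volume are preserved; the COM y-coordinate flips sign and the
    inertia tensor is conjugated by the reflection ``diag(1, -1, 1)``, which
    negates the xy and yz products of inertia.  Mirroring twice is the
    identity.
    """
    if plane != "sagittal":
        raise ValueError(f"only the sagittal plane is supported, got {plane!r}")
    S = np.diag([1.0, -1.0, 1.0])
    return MassProperties(
        mass=props.mass,
        volume=props.volume,
        com=S @ props.com,
        inertia=S @ props.inertia @ S,
        density=props.density,
    )
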