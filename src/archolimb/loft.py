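"""Body-segment solids lofted from serial octagonal hoops.

Fleshy body segments (head, neck, torso halves, tail, limb segments) are
reconstructed as stacks of eight-sided cross-sectional hoops placed serially
along each segment's long axis and lofted into a closed solid; internal
air spaces (pharynx, trachea, lungs) are concentric hoop stacks subtracted
as low-density cavities.  Lofting connects corresponding vertices of
adjacent hoops with two triangles per side quad and caps the ends with
triangle fans, so prisms between identical hoops have exactly
shoelace-area × length volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .meshmass import MassProperties, mass_properties

__all__ = ["Hoop", "SegmentShape", "loft_hoops", "segment_mass", "regular_octagon"]


@dataclass
class Hoop:
    """One planar octagonal cross-section at a station along the segment axis."""

    station: float
    vertices: np.ndarray  # (8, 3)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.shape != (8, 3):
            raise ValueError(
                f"a hoop needs exactly 8 vertices of 3 coordinates, "
                f"got shape {self.vertices.shape}"
            )
        if _polygon_self_intersects(self.vertices):
            raise ValueError("hoop polygon is self-intersecting")


@dataclass
class SegmentShape:
    """A named segment: outer hoop stack plus optional cavity stacks.

    ``cavity_densities`` defaults to 0 kg/m³ (air) per cavity; the default
    tissue density is 1000 kg/m³ (water-equivalent soft tissue), both
    overridable per segment.
    """

    name: str
    outer: list
    cavities: list = field(default_factory=list)
    density: float = 1000.0
    cavity_densities: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.outer) < 2:
            raise ValueError(f"segment {self.name!r}: need >= 2 hoops, got {len(self.outer)}")
        stations = [h.station for h in self.outer]
        if not all(s1 < s2 for s1, s2 in zip(stations, stations[1:])):
            raise ValueError(f"segment {self.name!r}: stations must strictly increase")
        if not self.cavity_densities:
            self.cavity_densities = [0.0] * len(self.cavities)
        if len(self.cavity_densities) != len(self.cavities):
            raise ValueError("one cavity density per cavity stack required")


def regular_octagon(radius: float, center=(0.0, 0.0, 0.0), z: float = 0.0,
                    station: float | None = None) -> Hoop:
    """Regular octagon of circumradius *radius* in a z-normal plane."""
    ang = np.arange(8) * (2 * np.pi / 8)
    pts = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(8, z)]
    ) + np.asarray(center, dtype=float)
    return Hoop(station=z if station is None else station, vertices=pts)


def _polygon_self_intersects(vertices: np.ndarray) -> bool:
    """Check a closed polygon for edge crossings in its best-fit plane."""
    pts = vertices - vertices.mean(axis=0)
    # project onto the two dominant principal directions
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    p2 = pts @ vt[:2].T
    n = len(p2)
    edges = [(p2[i], p2[(i + 1) % n]) for i in range(n)]

    def seg_cross(a, b, c, d) -> bool:
        def orient(p, q, r):
            return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

        o1, o2 = orient(a, b, c), orient(a, b, d)
        o3, o4 = orient(c, d, a), orient(c, d, b)
        return (o1 * o2 < 0) and (o3 * o4 < 0)

    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if seg_cross(*edges[i], *edges[j]):
                return True
    return False


def loft_hoops(hoops: list, cap_ends: bool = True) -> trimesh.Trimesh:
    """Loft an ordered hoop stack into a watertight triangle mesh.

    Vertex correspondence is by index (no twist); each side quad
    ``(i, i+1)`` between adjacent hoops is split along the same diagonal so
    meshes are deterministic.  End caps are fans about the hoop centroid.
    """
    if len(hoops) < 2:
        raise ValueError(f"need >= 2 hoops to loft, got {len(hoops)}")
    n = 8
    rings = [np.asarray(h.vertices, dtype=float) for h in hoops]
    vertices = list(np.concatenate(rings))
    faces = []
    for k in range(len(rings) - 1):
        base0, base1 = k * n, (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            # quad (base0+i, base0+j, base1+j, base1+i), split on (i, j') diag
            faces.append([base0 + i, base0 + j, base1 + j])
            faces.append([base0 + i, base1 + j, base1 + i])
    if cap_ends:
        c0 = len(vertices)
        vertices.append(rings[0].mean(axis=0))
        c1 = len(vertices)
        vertices.append(rings[-1].mean(axis=0))
        last = (len(rings) - 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append([c0, j, i])            # start cap, inward winding
            faces.append([c1, last + i, last + j])  # end cap
    mesh = trimesh.Trimesh(vertices=np.array(vertices), faces=np.array(faces),
                           process=False)
    return mesh


def segment_mass(shape: SegmentShape) -> MassProperties:
    """Mass properties of a lofted segment with internal cavities.

    The outer solid is integrated at the tissue density; each cavity is a
    negative-mass correction at (cavity density − tissue density), i.e.
    mass = ρ_out·V_out + Σ (ρ_cav − ρ_out)·V_cav, with COM and inertia
    composed the same way.  Raises if a cavity is at least as large as the
    outer solid.
    """
    outer_mesh = loft_hoops(shape.outer)
    outer = mass_properties(outer_mesh, shape.density)

    mass = outer.mass
    volume = outer.volume
    moment = outer.mass * outer.com
    # inertia about the origin for the running composite
    inertia_o = outer.inertia + outer.mass * (
        np.dot(outer.com, outer.com) * np.eye(3) - np.outer(outer.com, outer.com)
    )
    cavity_volume = 0.0
    for cav_hoops, rho_cav in zip(shape.cavities, shape.cavity_densities):
        cav = mass_properties(loft_hoops(cav_hoops), 1.0)  # unit density: geometry only
        cavity_volume += cav.volume
        if cavity_volume >= outer.volume:
            raise ValueError(
                f"segment {shape.name!r}: cavity volume {cavity_volume:.6g} m^3 "
                f">= outer volume {outer.volume:.6g} m^3"
            )
        dm = (rho_cav - shape.density) * cav.volume
        mass += dm
        moment += dm * cav.com
        unit_io = cav.inertia + cav.volume * (
            np.dot(cav.com, cav.com) * np.eye(3) - np.outer(cav.com, cav.com)
        )  # unit-density inertia about origin
        inertia_o += (rho_cav - shape.density) * unit_io

    if mass <= 0:
        raise ValueError(f"segment {shape.name!r}: non-positive net mass")
    com = moment / mass
    inertia_com = inertia_o - mass * (np.dot(com, com) * np.eye(3) - np.outer(com, com))
    return MassProperties(mass=mass, volume=volume, com=com, inertia=inertia_com,
                          density=mass / volume)
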