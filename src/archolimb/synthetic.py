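"""Seeded generators for every input class the pipeline consumes.

Real inputs to this kind of analysis are CT-derived bone meshes and a
curated musculoskeletal model; the generators here produce structurally
equivalent synthetic inputs with *known ground truth* so every stage can be
tested end to end without external downloads: capsule/box bone proxies
assembled into a pelvis–femur–crus–pes–digit chain (3-DOF hip, hinge knee,
ankle and MTP), articular-surface point patches sampled from known
primitives, octagonal hoop stacks with exact prism/frustum volumes, and
two-class Gaussian feature tables emulating bipedal/quadrupedal training
data.

Default dimensions are scaled to the study animal's printed summary
(femur ≈ 0.179 m, hindlimb 0.320 m, gleno-acetabular distance 0.355 m) so
synthetic outputs land in a realistic regime.

Every generator is a pure function of (seed, parameters); the same seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .loft import Hoop, SegmentShape, regular_octagon
from .meshmass import MassProperties, mass_properties
from .model import ACS, BodyModel, Joint, Landmark, Pose, Segment
from .muscles import MusclePath
from .posture import BIPEDAL, QUADRUPEDAL, FeatureRecord

__all__ = [
    "SyntheticSkeleton",
    "make_skeleton",
    "make_hoop_body",
    "make_articular_patch",
    "make_posture_features",
    "hinge_truth_moment_arm",
    "hinge_truth_length",
]

_MIN_PATCH_POINTS = {"plane": 3, "sphere": 4, "cylinder": 6, "ellipsoid": 9}

#: default segment dimensions (m), scaled to the printed skeletal summary
DEFAULT_DIMS = {
    "femur_length": 0.179,
    "crus_length": 0.141,   # femur + crus = 0.320 m hindlimb
    "pes_length": 0.080,
    "digit_length": 0.040,
    "femur_radius": 0.016,
    "crus_radius": 0.012,
    "ga_distance": 0.355,
}

_ROM_DEFAULTS = {
    "hip": {"z": (-65.0, 55.0), "y": (-10.0, 70.0), "x": (-50.0, 50.0)},
    "knee": {"z": (-110.0, 0.0)},
    "ankle": {"z": (-50.0, 30.0)},
    "mtp3": {"z": (-80.0, 50.0)},
}

# muscle acronyms whose origin/insertion bones (per the shipped attachment
# table) correspond to adjacent segments of the synthetic chain
_JOINT_MUSCLES = {
    "hip": ["IF", "PIFE1", "PIFE2", "PIFE3", "ISTR", "ADD1", "ADD2", "PIFI1"],
    "knee": ["FMTE", "FMTI"],
    "ankle": ["PP1", "PP2", "FB", "FL", "FC"],
    "mtp3": ["FDB", "FHB", "EDB"],
}


@dataclass
class SyntheticSkeleton:
    """A generated BodyModel plus its ground truth.

    ``truth`` records, per joint, the true hinge axis; per muscle, the
    closed-form hinge parameters (a, b, γ₀, sense) such that
    L(θ) = √(a² + b² − 2ab·cos(γ₀ + s·θ)) and r(θ) = −s·ab·sin(γ₀ + s·θ)/L;
    per segment, the analytic mass properties of the proxy solid.
    """

    model: BodyModel
    truth: dict
    seed: int

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "segments": {
                name: np.asarray(self.model.segments[name].mesh.vertices)
                .round(12).tolist()
                for name in sorted(self.model.segments)
                if self.model.segments[name].mesh is not None
            },
            "joints": {
                j.name: {
                    "origin": j.jcs.origin.round(12).tolist(),
                    "axes": j.jcs.axes.round(12).tolist(),
                    "dofs": list(j.dofs),
                    "rom": {k: list(v) for k, v in j.rom.items()},
                }
                for j in self.model.joints.values()
            },
            "muscles": {
                m.acronym: [[seg, p.round(12).tolist()] for seg, p in m.points]
                for m in self.model.muscles.values()
            },
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _capsule_analytic(radius: float, height: float, density: float,
                      center_z: float) -> MassProperties:
    """Closed-form mass properties of a z-aligned capsule at *center_z*."""
    r, h = radius, height
    v_cyl = np.pi * r * r * h
    v_sph = 4.0 / 3.0 * np.pi * r ** 3
    m_cyl, m_sph = density * v_cyl, density * v_sph
    m_hemi = m_sph / 2.0
    # inertia about capsule COM (z axis of symmetry)
    izz = m_cyl * r * r / 2.0 + m_sph * 2.0 * r * r / 5.0
    i_cyl_xx = m_cyl * (3 * r * r + h * h) / 12.0
    d = h / 2.0 + 3.0 * r / 8.0  # hemisphere COM offset from cylinder COM
    i_hemi_xx = m_hemi * (2.0 * r * r / 5.0 - (3.0 * r / 8.0) ** 2) + m_hemi * d * d
    ixx = i_cyl_xx + 2 * i_hemi_xx
    return MassProperties(
        mass=m_cyl + m_sph,
        volume=v_cyl + v_sph,
        com=np.array([0.0, 0.0, center_z]),
        inertia=np.diag([ixx, ixx, izz]),
        density=density,
    )


def _box_analytic(extents, density: float, center) -> MassProperties:
    ex, ey, ez = extents
    v = ex * ey * ez
    m = density * v
    return MassProperties(
        mass=m,
        volume=v,
        com=np.asarray(center, dtype=float),
        inertia=m / 12.0 * np.diag([ey * ey + ez * ez,
                                    ex * ex + ez * ez,
                                    ex * ex + ey * ey]),
        density=density,
    )


def _limb_jcs(origin) -> ACS:
    """JCS with flexion axis mediolateral (+Y) and x down the limb (−Z)."""
    x = np.array([0.0, 0.0, -1.0])
    z = np.array([0.0, 1.0, 0.0])
    y = np.cross(z, x)
    return ACS(origin=np.asarray(origin, dtype=float), axes=np.column_stack([x, y, z]))


def make_skeleton(
    seed: int,
    dims: dict | None = None,
    n_muscles: int = 8,
    density: float = 1000.0,
) -> SyntheticSkeleton:
    """Generate a posable hindlimb chain with known closed-form answers.

    Segments: pelvis (box) – femur (capsule) – crus (capsule) – pes (box)
    – digit3 (box), limbs vertical and pes plantigrade at reference.  The
    hip has three DOFs, all other joints a single flexion/extension DOF.
    *n_muscles* two-point muscles are placed in the flexion plane of the
    joints (round-robin), each with recorded law-of-cosines parameters.
    """
    if n_muscles < 1:
        raise ValueError("n_muscles must be >= 1")
    d = dict(DEFAULT_DIMS)
    d.update(dims or {})
    for k, v in d.items():
        if v <= 0:
            raise ValueError(f"dimension {k!r} must be positive, got {v}")
    rng = np.random.default_rng(seed)

    lf, lc = d["femur_length"], d["crus_length"]
    lp, ld = d["pes_length"], d["digit_length"]
    rf, rc = d["femur_radius"], d["crus_radius"]
    hip = np.array([0.0, 0.0, 0.0])
    knee = np.array([0.0, 0.0, -lf])
    ankle = np.array([0.0, 0.0, -lf - lc])
    mtp = ankle + np.array([lp, 0.0, 0.0])
    toe_tip = mtp + np.array([ld, 0.0, 0.0])

    model = BodyModel()

    def add(name, mesh, analytic):
        seg = Segment(name=name, mesh=mesh, density=density,
                      mass_props=mass_properties(mesh, density))
        model.add_segment(seg)
        return analytic

    pelvis_ext = (0.12, 0.08, 0.08)
    pelvis_center = (0.02, 0.0, 0.06)
    pelvis = trimesh.creation.box(extents=pelvis_ext)
    pelvis.apply_translation(pelvis_center)

    def capsule_at(radius, top, bottom):
        h = top - bottom - 2 * radius
        c = trimesh.creation.capsule(height=max(h, 1e-6), radius=radius,
                                     count=[48, 48])
        c.apply_translation([0.0, 0.0, (top + bottom) / 2.0])
        return c

    femur = capsule_at(rf, hip[2], knee[2])
    crus = capsule_at(rc, knee[2], ankle[2])
    pes_ext = (lp, 0.05, 0.02)
    pes_center = ankle + np.array([lp / 2.0, 0.0, -0.01])
    pes = trimesh.creation.box(extents=pes_ext)
    pes.apply_translation(pes_center)
    digit_ext = (ld, 0.03, 0.015)
    digit_center = mtp + np.array([ld / 2.0, 0.0, -0.0075])
    digit = trimesh.creation.box(extents=digit_ext)
    digit.apply_translation(digit_center)

    truth_mass = {
        "pelvis": add("pelvis", pelvis, _box_analytic(pelvis_ext, density, pelvis_center)),
        "femur": add("femur", femur,
                     _capsule_analytic(rf, lf - 2 * rf, density, (hip[2] + knee[2]) / 2)),
        "crus": add("crus", crus,
                    _capsule_analytic(rc, lc - 2 * rc, density, (knee[2] + ankle[2]) / 2)),
        "pes": add("pes", pes, _box_analytic(pes_ext, density, pes_center)),
        "digit3": add("digit3", digit, _box_analytic(digit_ext, density, digit_center)),
    }

    joints = [
        Joint("hip", "pelvis", "femur", _limb_jcs(hip), dofs=("x", "y", "z"),
              rom=dict(_ROM_DEFAULTS["hip"])),
        Joint("knee", "femur", "crus", _limb_jcs(knee), dofs=("z",),
              rom=dict(_ROM_DEFAULTS["knee"])),
        Joint("ankle", "crus", "pes", _limb_jcs(ankle), dofs=("z",),
              rom=dict(_ROM_DEFAULTS["ankle"])),
        Joint("mtp3", "pes", "digit3", _limb_jcs(mtp), dofs=("z",),
              rom=dict(_ROM_DEFAULTS["mtp3"])),
    ]
    for j in joints:
        model.add_joint(j)

    model.landmarks = {
        "acetabular_midpoint": Landmark("pelvis", hip),
        "glenoid_midpoint": Landmark("pelvis", hip + np.array([d["ga_distance"], 0, 0])),
        "toe_tip": Landmark("digit3", toe_tip),
    }
    model.chains = {"hindlimb": ["hip", "knee", "ankle"]}
    model.preset_poses = {
        "reference": Pose({}),
        "adjusted_standing": Pose({"hip": {"z": -10.0}, "knee": {"z": -10.0},
                                   "ankle": {"z": -10.0}}),
    }
    # feet support interval craniad to the acetabula at reference
    model.foot_support = (float(ankle[0]), float(toe_tip[0]))

    # hinge muscles in the flexion (x–z) plane with recorded closed forms.
    # The parent-side attachment sits at angle phi_p from the joint, the
    # child-side at phi_c0 (angles in the plane, from +X toward +Z); a +z
    # joint rotation (about +Y) rotates the child-side attachment by -theta
    # in that plane, so the included angle is gamma0 + theta with
    # gamma0 = phi_p - phi_c0 (sense s = +1).
    joint_geo = {
        "hip": (hip, "pelvis", "femur", np.pi / 2, -np.pi / 2),
        "knee": (knee, "femur", "crus", np.pi / 2, -np.pi / 2),
        "ankle": (ankle, "crus", "pes", np.pi / 2, 0.0),
        "mtp3": (mtp, "pes", "digit3", np.pi, 0.0),
    }
    joint_names = list(joint_geo)
    counters = {j: 0 for j in joint_names}
    truth_muscles = {}
    for i in range(n_muscles):
        jname = joint_names[i % len(joint_names)]
        center, parent, child, phi_parent, phi_child = joint_geo[jname]
        a = float(rng.uniform(0.05, 0.12))
        b = float(rng.uniform(0.05, 0.12))
        # offset the attachments a little off the bone axes, keeping the
        # included angle away from 0 and pi across the ROM sweep
        phi_p = phi_parent + float(rng.uniform(-0.25, 0.25))
        phi_c = phi_child + float(rng.uniform(-0.25, 0.25))
        gamma0 = phi_p - phi_c
        names = _JOINT_MUSCLES[jname]
        k = counters[jname]
        acronym = names[k] if k < len(names) else f"{jname.upper()}_SYN{k}"
        counters[jname] += 1
        origin = center + a * np.array([np.cos(phi_p), 0.0, np.sin(phi_p)])
        insertion = center + b * np.array([np.cos(phi_c), 0.0, np.sin(phi_c)])
        muscle = MusclePath(acronym=acronym,
                            points=[(parent, origin), (child, insertion)])
        model.muscles[acronym] = muscle
        truth_muscles[acronym] = {
            "joint": jname, "a": a, "b": b, "gamma0": float(gamma0), "sense": 1.0,
        }

    model.validate()
    truth = {
        "dims": d,
        "mass_properties": truth_mass,
        "hinge_axes": {j.name: j.jcs.axes[:, 2].tolist() for j in joints},
        "joint_centers": {j.name: j.jcs.origin.tolist() for j in joints},
        "muscles": truth_muscles,
        "hindlimb_length": lf + lc,
        "ga_distance": d["ga_distance"],
    }
    return SyntheticSkeleton(model=model, truth=truth, seed=seed)


def hinge_truth_moment_arm(params: dict, theta_deg: float) -> float:
    """Closed-form hinge moment arm from recorded (a, b, γ₀, sense)."""
    a, b = params["a"], params["b"]
    gamma = params["gamma0"] + params["sense"] * np.deg2rad(theta_deg)
    L = np.sqrt(a * a + b * b - 2 * a * b * np.cos(gamma))
    return float(-params["sense"] * a * b * np.sin(gamma) / L)


def hinge_truth_length(params: dict, theta_deg: float) -> float:
    a, b = params["a"], params["b"]
    gamma = params["gamma0"] + params["sense"] * np.deg2rad(theta_deg)
    return float(np.sqrt(a * a + b * b - 2 * a * b * np.cos(gamma)))


def make_hoop_body(
    seed: int,
    n_segments: int = 3,
    n_stations: int = 4,
    cavity_fraction: float | None = None,
    density: float = 1000.0,
) -> list:
    """Octagonal hoop stacks with exact recorded volumes.

    Returns a list of (SegmentShape, truth) pairs.  Each stack is a prism
    or a linearly tapering stack of concentric similar octagons, so the
    exact volume is the sum of prismatoid (frustum) slices; an optional
    concentric cavity occupies *cavity_fraction* of each cross-section.
    """
    if n_stations < 2:
        raise ValueError("need >= 2 stations per segment")
    if cavity_fraction is not None and not 0 < cavity_fraction < 1:
        raise ValueError("cavity_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_segments):
        r = float(rng.uniform(0.03, 0.10))
        length = float(rng.uniform(0.10, 0.30))
        taper = float(rng.uniform(0.4, 1.0)) if rng.random() < 0.5 else 1.0
        stations = np.linspace(0.0, length, n_stations)
        scales = np.linspace(1.0, taper, n_stations)
        base_area = 2.0 * np.sqrt(2.0) * r * r  # regular octagon, circumradius r
        hoops = [regular_octagon(r * s, z=z) for z, s in zip(stations, scales)]
        volume = 0.0
        for (z0, s0), (z1, s1) in zip(zip(stations, scales), zip(stations[1:], scales[1:])):
            a0, a1 = base_area * s0 * s0, base_area * s1 * s1
            volume += (z1 - z0) / 3.0 * (a0 + a1 + np.sqrt(a0 * a1))
        cavities, cav_rho = [], []
        cav_volume = 0.0
        if cavity_fraction:
            c = float(np.sqrt(cavity_fraction))
            cavities = [[regular_octagon(r * s * c, z=z)
                         for z, s in zip(stations, scales)]]
            cav_rho = [0.0]
            cav_volume = cavity_fraction * volume
        shape = SegmentShape(name=f"segment_{i}", outer=hoops, cavities=cavities,
                             density=density, cavity_densities=cav_rho)
        truth = {
            "outer_volume": volume,
            "cavity_volume": cav_volume,
            "mass": density * (volume - cav_volume),
            "is_prism": taper == 1.0,
            "length": length,
            "circumradius": r,
        }
        out.append((shape, truth))
    return out


def make_articular_patch(
    kind: str,
    params: dict,
    n_points: int,
    noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample an articular-surface point patch from a known primitive.

    ``params``: sphere {center, radius}; cylinder {center, axis, radius,
    half_length}; plane {center, normal, extent}; ellipsoid {center, radii,
    axes (optional)}.  Isotropic Gaussian noise of SD *noise* is added.
    """
    if kind not in _MIN_PATCH_POINTS:
        raise ValueError(f"unknown primitive kind {kind!r}")
    if n_points < _MIN_PATCH_POINTS[kind]:
        raise ValueError(
            f"{kind} patch needs >= {_MIN_PATCH_POINTS[kind]} points, got {n_points}"
        )
    rng = np.random.default_rng(seed)
    center = np.asarray(params.get("center", (0, 0, 0)), dtype=float)
    if kind == "sphere":
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = center + params["radius"] * v
    elif kind == "plane":
        normal = np.asarray(params["normal"], dtype=float)
        normal = normal / np.linalg.norm(normal)
        u = _any_perpendicular(normal)
        w = np.cross(normal, u)
        extent = params.get("extent", 1.0)
        ab = rng.uniform(-extent, extent, size=(n_points, 2))
        pts = center + ab[:, :1] * u + ab[:, 1:] * w
    elif kind == "cylinder":
        axis = np.asarray(params["axis"], dtype=float)
        axis = axis / np.linalg.norm(axis)
        u = _any_perpendicular(axis)
        w = np.cross(axis, u)
        half = params.get("half_length", 1.0)
        t = rng.uniform(-half, half, size=n_points)
        ang = rng.uniform(0, 2 * np.pi, size=n_points)
        pts = (center + np.outer(t, axis)
               + params["radius"] * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w)))
    else:  # ellipsoid
        radii = np.asarray(params["radii"], dtype=float)
        axes = np.asarray(params.get("axes", np.eye(3)), dtype=float)
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = center + (v * radii) @ axes.T
    if noise > 0:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return pts


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, ref)
    return u / np.linalg.norm(u)


def make_posture_features(
    n_per_class: int,
    mean_quadrupedal,
    mean_bipedal,
    cov,
    seed: int = 0,
) -> list:
    """Two-class Gaussian feature sample as labelled FeatureRecords.

    Means and the shared covariance are in the default feature space
    (log10 mass, GA-normalized COM, forelimb/hindlimb ratio); records are
    reconstructed so their derived features equal the drawn values.
    """
    mean0 = np.asarray(mean_quadrupedal, dtype=float)
    mean1 = np.asarray(mean_bipedal, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be symmetric positive definite") from exc
    rng = np.random.default_rng(seed)
    records = []
    for label, mean in ((QUADRUPEDAL, mean0), (BIPEDAL, mean1)):
        draws = rng.multivariate_normal(mean, cov, size=n_per_class,
                                        method="cholesky")
        for i, (lm, com, ratio) in enumerate(draws):
            records.append(
                FeatureRecord(
                    taxon=f"{label}_{i}",
                    body_mass_kg=float(10.0 ** lm),
                    com_dimensionless=float(com),
                    forelimb_m=float(max(ratio, 1e-6)),
                    hindlimb_m=1.0,
                    posture=label,
                )
            )
    return records
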