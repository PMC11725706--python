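"""Primitive fitting, ACS construction, forward kinematics, and ROM."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from archolimb import (
    ACS,
    BodyModel,
    Joint,
    Pose,
    Segment,
    build_acs,
    fit_primitive,
    forward_kinematics,
    make_articular_patch,
    rom_check,
    rom_scan,
)
from archolimb.io import load_rom_fixture
from oracles import rotation_product_oracle


class TestFitPrimitive:
    def test_exact_sphere_recovery(self):
        pts = make_articular_patch("sphere", {"center": (0.3, -0.1, 0.5),
                                              "radius": 0.07}, 200, seed=1)
        fit = fit_primitive(pts, "sphere")
        assert fit.center == pytest.approx([0.3, -0.1, 0.5], abs=1e-9)
        assert fit.radius == pytest.approx(0.07, abs=1e-9)
        assert fit.rms < 1e-9

    def test_noisy_sphere_center_within_bound(self):
        r = 0.05
        errs = []
        for seed in range(5):
            pts = make_articular_patch("sphere", {"center": (0, 0, 0), "radius": r},
                                       400, noise=0.01 * r, seed=seed)
            fit = fit_primitive(pts, "sphere")
            errs.append(np.linalg.norm(fit.center))
        assert max(errs) < 0.02 * r

    def test_exact_cylinder_recovery(self):
        axis = np.array([1.0, 2.0, 0.5])
        axis /= np.linalg.norm(axis)
        pts = make_articular_patch(
            "cylinder", {"center": (0.1, 0.2, 0.0), "axis": axis,
                         "radius": 0.03, "half_length": 0.05}, 300, seed=2)
        fit = fit_primitive(pts, "cylinder")
        assert abs(abs(fit.axis @ axis) - 1.0) < 1e-7
        assert fit.radius == pytest.approx(0.03, abs=1e-7)

    def test_exact_plane_and_ellipsoid(self):
        n = np.array([0.0, 0.6, 0.8])
        pts = make_articular_patch("plane", {"center": (1, 1, 1), "normal": n,
                                             "extent": 0.2}, 100, seed=3)
        fit = fit_primitive(pts, "plane")
        assert abs(abs(fit.axis @ n) - 1.0) < 1e-9

        radii = np.array([0.09, 0.05, 0.03])
        pts = make_articular_patch("ellipsoid", {"center": (0.2, 0, -0.1),
                                                 "radii": radii}, 400, seed=4)
        fit = fit_primitive(pts, "ellipsoid")
        assert fit.center == pytest.approx([0.2, 0, -0.1], abs=1e-6)
        assert fit.radii == pytest.approx(radii, rel=1e-5)

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.linspace(0, 1, 5), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="non-collinear"):
            fit_primitive(line[:3], "plane")
        planar = np.column_stack([np.random.default_rng(0).normal(size=(20, 2)),
                                  np.zeros(20)])
        with pytest.raises(ValueError, match="non-coplanar"):
            fit_primitive(planar, "sphere")
        with pytest.raises(ValueError, match=">= 9"):
            fit_primitive(planar[:5], "ellipsoid")

    def test_axis_sign_deterministic(self):
        pts = make_articular_patch("cylinder", {"center": (0, 0, 0),
                                                "axis": (0, -1, 0), "radius": 0.02,
                                                "half_length": 0.04}, 200, seed=5)
        fit = fit_primitive(pts, "cylinder")
        assert fit.axis[np.argmax(np.abs(fit.axis))] > 0


class TestBuildACS:
    def test_cylinder_along_y(self):
        pts = make_articular_patch("cylinder", {"center": (0, 0, 0),
                                                "axis": (0, 1, 0), "radius": 0.02,
                                                "half_length": 0.05}, 200, seed=6)
        acs = build_acs(fit_primitive(pts, "cylinder"), reference=(1, 0, 0))
        assert abs(abs(acs.axes[:, 2] @ [0, 1, 0]) - 1) < 1e-6
        assert np.linalg.det(acs.axes) == pytest.approx(1.0, abs=1e-9)

    def test_orthonormality(self):
        pts = make_articular_patch("sphere", {"center": (1, 2, 3), "radius": 0.04},
                                   50, seed=7)
        acs = build_acs(fit_primitive(pts, "sphere"), reference=(1, 0.2, 0))
        assert acs.axes.T @ acs.axes == pytest.approx(np.eye(3), abs=1e-12)

    def test_rotation_equivariance(self, rng):
        pts = make_articular_patch("cylinder", {"center": (0.2, 0, 0),
                                                "axis": (0.3, 0.9, 0.4),
                                                "radius": 0.03,
                                                "half_length": 0.06}, 300, seed=8)
        acs0 = build_acs(fit_primitive(pts, "cylinder"), reference=(1, 0, 0))
        R = Rotation.random(random_state=42).as_matrix()
        acs1 = build_acs(fit_primitive(pts @ R.T, "cylinder"),
                         reference=R @ np.array([1.0, 0, 0]))
        # axes agree up to the canonical sign convention
        for i in range(3):
            dots = np.abs((R @ acs0.axes[:, i]) @ acs1.axes[:, i])
            assert dots == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, rng):
        pts = make_articular_patch("sphere", {"center": (0, 0.1, 0), "radius": 0.05},
                                   100, seed=9)
        perm = rng.permutation(len(pts))
        f0 = fit_primitive(pts, "sphere")
        f1 = fit_primitive(pts[perm], "sphere")
        assert f0.center == pytest.approx(f1.center, abs=1e-12)

    def test_parallel_reference_rejected(self):
        pts = make_articular_patch("cylinder", {"center": (0, 0, 0),
                                                "axis": (0, 0, 1), "radius": 0.02,
                                                "half_length": 0.05}, 100, seed=10)
        with pytest.raises(ValueError, match="parallel"):
            build_acs(fit_primitive(pts, "cylinder"), reference=(0, 0, 1))


class TestForwardKinematics:
    def test_zero_pose_is_reference(self, skeleton):
        T = forward_kinematics(skeleton.model, Pose({}))
        for name, ref in skeleton.model.reference_placements.items():
            assert T[name] == pytest.approx(ref, abs=1e-15)

    def test_single_hinge_rotates_about_jcs_z(self, skeleton):
        model = skeleton.model
        T = forward_kinematics(model, Pose({"knee": {"z": 90.0}}))
        G = model.joints["knee"].jcs.to_matrix()
        Rh = np.eye(4)
        Rh[:3, :3] = rotation_product_oracle(0, 0, np.pi / 2)
        expected = G @ Rh @ np.linalg.inv(G)
        assert T["crus"] == pytest.approx(expected, abs=1e-12)

    def test_three_dof_matches_matrix_oracle(self, skeleton):
        model = skeleton.model
        pose = Pose({"hip": {"x": 10.0, "y": 20.0, "z": 30.0}})
        T = forward_kinematics(model, pose)
        G = model.joints["hip"].jcs.to_matrix()
        Rh = np.eye(4)
        Rh[:3, :3] = rotation_product_oracle(*np.deg2rad([10, 20, 30]))
        expected = G @ Rh @ np.linalg.inv(G)
        assert T["femur"] == pytest.approx(expected, abs=1e-12)

    def test_unflagged_dof_rejected(self, skeleton):
        with pytest.raises(ValueError, match="no 'x' DOF"):
            forward_kinematics(skeleton.model, Pose({"knee": {"x": 5.0}}))

    def test_transforms_are_proper_rigid(self, skeleton, rng):
        for _ in range(5):
            pose = Pose({"hip": {d: float(rng.uniform(-40, 40)) for d in "xyz"},
                         "knee": {"z": float(rng.uniform(-90, 0))},
                         "ankle": {"z": float(rng.uniform(-40, 20))}})
            for T in forward_kinematics(skeleton.model, pose).values():
                R = T[:3, :3]
                assert R.T @ R == pytest.approx(np.eye(3), abs=1e-12)
                assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestRomCheck:
    @pytest.fixture()
    def model(self, skeleton):
        return skeleton.model

    def test_hip_extension_over_limit(self, model):
        violations = rom_check(Pose({"hip": {"z": 60.0}}), model)
        assert len(violations) == 1
        v = violations[0]
        assert (v.joint, v.dof, v.angle) == ("hip", "z", 60.0)
        assert v.limit == (-65.0, 55.0)

    def test_boundary_inclusive(self, model):
        assert rom_check(Pose({"hip": {"z": 55.0}}), model) == []

    def test_joint_without_limits_never_violates(self):
        m = BodyModel()
        m.add_segment(Segment(name="a"))
        m.add_segment(Segment(name="b"))
        m.add_joint(Joint("j", "a", "b", ACS(origin=np.zeros(3), axes=np.eye(3))))
        assert rom_check(Pose({"j": {"z": 720.0}}), m) == []


def hinged_box_model(wall_angle_deg=60.0, corner_angle_deg=20.0):
    """Rod rotating about the z-axis between two radial walls.

    The rod's leading corner sits at polar angle ``corner_angle_deg``
    (tan = t/x1), the wall faces are radial planes at ±``wall_angle_deg``,
    so first contact occurs exactly at ±(wall − corner) degrees.
    """
    x1, x2 = 0.05, 0.30
    t = x1 * np.tan(np.deg2rad(corner_angle_deg))
    rod = trimesh.creation.box(extents=[x2 - x1, 2 * t, 0.1])
    rod.apply_translation([(x1 + x2) / 2, 0, 0])

    walls = []
    for sign in (+1, -1):
        wall = trimesh.creation.box(extents=[0.4, 0.02, 0.2])
        wall.apply_translation([0.2, sign * 0.01, 0])  # face plane through origin
        wall.apply_transform(trimesh.transformations.rotation_matrix(
            sign * np.deg2rad(wall_angle_deg), [0, 0, 1]))
        walls.append(wall)
    stop = trimesh.util.concatenate(walls)

    m = BodyModel()
    m.add_segment(Segment(name="frame", mesh=stop))
    m.add_segment(Segment(name="rod", mesh=rod))
    m.add_joint(Joint("hinge", "frame", "rod",
                      ACS(origin=np.zeros(3), axes=np.eye(3)), dofs=("z",)))
    return m


class TestRomScan:
    def test_analytic_contact_angle(self):
        model = hinged_box_model(wall_angle_deg=60.0, corner_angle_deg=20.0)
        lo, hi = rom_scan(model, "hinge", "z", step=1.0,
                          criteria={"gap": np.inf})
        assert abs(hi - 40.0) <= 1.0
        assert abs(lo + 40.0) <= 1.0

    def test_never_touching_returns_full_range(self):
        model = hinged_box_model(wall_angle_deg=60.0, corner_angle_deg=20.0)
        # remove the walls: replace the frame mesh by a far-away box
        far = trimesh.creation.box(extents=[0.1, 0.1, 0.1])
        far.apply_translation([5, 5, 5])
        model.segments["frame"].mesh = far
        lo, hi = rom_scan(model, "hinge", "z", step=5.0,
                          criteria={"gap": np.inf, "max_angle": 180.0})
        assert hi == 180.0 and lo == -180.0

    def test_collision_at_reference_rejected(self):
        model = hinged_box_model(wall_angle_deg=10.0, corner_angle_deg=20.0)
        with pytest.raises(ValueError, match="reference pose"):
            rom_scan(model, "hinge", "z", step=1.0, criteria={"gap": np.inf})

    def test_monotone_in_gap_threshold(self):
        model = hinged_box_model()
        # articular patches: rod vertices near the hinge vs wall inner vertices
        rod = model.segments["rod"].mesh
        frame = model.segments["frame"].mesh
        model.segments["rod"].articular_patches["hinge"] = (
            np.argsort(np.linalg.norm(rod.vertices, axis=1))[:4].tolist())
        model.segments["frame"].articular_patches["hinge"] = (
            np.argsort(np.linalg.norm(frame.vertices, axis=1))[:4].tolist())
        spans = []
        for gap in (0.05, 0.2, np.inf):
            lo, hi = rom_scan(model, "hinge", "z", step=2.0, criteria={"gap": gap})
            spans.append(hi - lo)
        assert spans[0] <= spans[1] <= spans[2]


class TestRomFixture:
    def test_published_limits_round_trip(self):
        rom = load_rom_fixture()
        assert rom["hip"]["rom"]["z"] == (-65.0, 55.0)
        assert rom["hip"]["rom"]["y"] == (-10.0, 70.0)
        assert rom["hip"]["rom"]["x"] == (-50.0, 50.0)
        assert rom["knee"]["rom"]["z"] == (-110.0, 0.0)
        assert rom["ankle"]["rom"]["z"] == (-50.0, 30.0)
        assert rom["mtp3"]["rom"]["z"] == (-80.0, 50.0)

    def test_six_rom_intervals_for_hip_knee_ankle_mtp(self):
        rom = load_rom_fixture()
        n = sum(len(j["rom"]) for j in rom.values())
        assert n == 6
        assert rom["hip"]["dofs"] == ("x", "y", "z")
        assert rom["knee"]["dofs"] == ("z",)
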