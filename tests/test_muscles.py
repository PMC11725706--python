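"""Path length, wrapping geometry, tendon-excursion moment arms."""

import numpy as np
import pytest

from archolimb import (
    ACS,
    BodyModel,
    Joint,
    MusclePath,
    Pose,
    Segment,
    WrapSurface,
    classify_action,
    hinge_truth_length,
    hinge_truth_moment_arm,
    mma_sweep,
    moment_arm,
    path_length,
)
from archolimb.io import load_muscle_table
from archolimb.muscles import MomentArmCurve
from oracles import tangent_wrap_oracle


def single_body():
    m = BodyModel()
    m.add_segment(Segment(name="a"))
    return m


def hinge_model(axes=np.eye(3)):
    """Two segments joined by a 1-DOF hinge at the origin."""
    m = BodyModel()
    m.add_segment(Segment(name="par"))
    m.add_segment(Segment(name="chi"))
    m.add_joint(Joint("j", "par", "chi", ACS(origin=np.zeros(3), axes=axes),
                      dofs=("z",)))
    return m


class TestPathLength:
    def test_straight_line(self):
        m = single_body()
        mus = MusclePath(acronym="S", points=[("a", [0, 0, 0]), ("a", [0.3, 0.4, 0])])
        assert path_length(mus, m, Pose({})) == pytest.approx(0.5, rel=1e-12)

    def test_collinear_via_point_no_change(self):
        m = single_body()
        without = MusclePath(acronym="A", points=[("a", [0, 0, 0]), ("a", [0.3, 0, 0])])
        with_via = MusclePath(acronym="B", points=[("a", [0, 0, 0]),
                                                   ("a", [0.1, 0, 0]),
                                                   ("a", [0.3, 0, 0])])
        assert path_length(with_via, m, Pose({})) == pytest.approx(
            path_length(without, m, Pose({})), rel=1e-12)

    def test_planar_cylinder_wrap_closed_form(self):
        m = single_body()
        R, d1, d2 = 0.05, 0.2, 0.3
        P = np.array([-d1, 0.0, 0.0])
        Q = d2 * np.array([np.cos(-0.3), np.sin(-0.3), 0.0])
        wrap = WrapSurface(kind="cylinder", segment="a", frame=np.eye(4), radius=R)
        mus = MusclePath(acronym="W", points=[("a", P), ("a", Q)], wraps=[wrap])
        expected = tangent_wrap_oracle(P[:2], Q[:2], R)
        assert path_length(mus, m, Pose({})) == pytest.approx(expected, abs=1e-9)

    def test_sphere_wrap_matches_planar_geometry(self):
        m = single_body()
        R, d1, d2 = 0.05, 0.2, 0.3
        P = np.array([-d1, 0.0, 0.0])
        Q = d2 * np.array([np.cos(-0.3), np.sin(-0.3), 0.0])
        wrap = WrapSurface(kind="sphere", segment="a", frame=np.eye(4), radius=R)
        mus = MusclePath(acronym="W", points=[("a", P), ("a", Q)], wraps=[wrap])
        assert path_length(mus, m, Pose({})) == pytest.approx(
            tangent_wrap_oracle(P[:2], Q[:2], R), abs=1e-9)

    def test_oblique_cylinder_wrap_unrolls(self):
        m = single_body()
        R = 0.05
        P = np.array([-0.2, 0.0, 0.0])
        Q2 = 0.3 * np.array([np.cos(-0.3), np.sin(-0.3), 0.0])
        dz = 0.12
        wrap = WrapSurface(kind="cylinder", segment="a", frame=np.eye(4), radius=R)
        mus = MusclePath(acronym="W", points=[("a", P), ("a", Q2 + [0, 0, dz])],
                         wraps=[wrap])
        planar = tangent_wrap_oracle(P[:2], Q2[:2], R)
        assert path_length(mus, m, Pose({})) == pytest.approx(
            np.hypot(planar, dz), abs=1e-9)

    def test_endpoint_inside_wrap_rejected(self):
        m = single_body()
        wrap = WrapSurface(kind="cylinder", segment="a", frame=np.eye(4), radius=0.1)
        mus = MusclePath(acronym="I", points=[("a", [0.01, 0, 0]), ("a", [0.5, 0, 0])],
                         wraps=[wrap])
        with pytest.raises(ValueError, match="inside"):
            path_length(mus, m, Pose({}))

    def test_wrap_continuity_at_tangency(self):
        """Path length must not jump as a span crosses into wrapping."""
        m = single_body()
        R = 0.05
        wrap = WrapSurface(kind="cylinder", segment="a", frame=np.eye(4), radius=R)
        lengths = []
        for y in np.linspace(R + 1e-7, R - 1e-7, 9):
            mus = MusclePath(acronym="C", points=[("a", [-0.3, y, 0]),
                                                  ("a", [0.3, y, 0])],
                             wraps=[wrap])
            lengths.append(path_length(mus, m, Pose({})))
        assert np.max(np.abs(np.diff(lengths))) < 1e-6


class TestMomentArm:
    def hinge_muscle(self, a=0.08, b=0.1, gamma0=np.deg2rad(120)):
        """Two-point muscle across a z-hinge; closed form from the law of
        cosines with included angle gamma0 + theta."""
        m = hinge_model()
        # place origin at polar angle gamma0, insertion along +x: a z-rotation
        # by +theta rotates the insertion by +theta, growing the included
        # angle; L = sqrt(a^2+b^2-2ab cos(gamma0 - theta))... sense checked
        origin = a * np.array([np.cos(gamma0), np.sin(gamma0), 0.0])
        insertion = b * np.array([1.0, 0.0, 0.0])
        mus = MusclePath(acronym="H", points=[("par", origin), ("chi", insertion)])
        params = {"a": a, "b": b, "gamma0": gamma0, "sense": -1.0}
        return m, mus, params

    def test_law_of_cosines_closed_form(self):
        m, mus, params = self.hinge_muscle()
        for theta in (-40.0, -10.0, 0.0, 25.0, 60.0):
            r = moment_arm(mus, m, "j", "z", pose=Pose({"j": {"z": theta}}), h=0.25)
            rt = hinge_truth_moment_arm(params, theta)
            assert abs(r - rt) / abs(rt) < 1e-3

    def test_second_order_convergence(self):
        m, mus, params = self.hinge_muscle()
        theta = 30.0
        rt = hinge_truth_moment_arm(params, theta)
        errs = [abs(moment_arm(mus, m, "j", "z",
                               pose=Pose({"j": {"z": theta}}), h=h) - rt)
                for h in (1.0, 0.5, 0.25)]
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_fully_wrapped_coaxial_cylinder_equals_radius(self):
        R = 0.03
        m = hinge_model()
        wrap = WrapSurface(kind="cylinder", segment="par", frame=np.eye(4),
                           radius=R, side=1)
        mus = MusclePath(acronym="W", points=[("par", [-0.04, 0, 0]),
                                              ("chi", [0.04, 0, 0])],
                         wraps=[wrap])
        arms = [moment_arm(mus, m, "j", "z", pose=Pose({"j": {"z": th}}))
                for th in np.arange(-30, 31, 10.0)]
        assert np.abs(np.abs(arms) - R).max() < 1e-9

    def test_zero_leverage_through_axis(self):
        m = hinge_model()
        mus = MusclePath(acronym="Z", points=[("par", [0, 0, -0.1]),
                                              ("chi", [0, 0, 0.1])])
        r = moment_arm(mus, m, "j", "z", pose=Pose({}))
        assert abs(r) < 1e-12

    def test_noncrossing_muscle_rejected(self):
        m = hinge_model()
        mus = MusclePath(acronym="N", points=[("par", [0, 0, 0]), ("par", [1, 0, 0])])
        with pytest.raises(ValueError, match="does not cross"):
            moment_arm(mus, m, "j", "z")

    def test_work_length_consistency(self):
        """Integral of r dθ equals −ΔL over a sweep (tendon excursion)."""
        m, mus, params = self.hinge_muscle()
        grid = np.linspace(-50, 50, 201)
        curve = mma_sweep(mus, m, "j", "z", grid, h=0.25)
        integral = np.trapezoid(curve.moment_arm_m, np.deg2rad(curve.angles_deg))
        dL = (path_length(mus, m, Pose({"j": {"z": 50.0}}))
              - path_length(mus, m, Pose({"j": {"z": -50.0}})))
        assert integral == pytest.approx(-dL, abs=1e-6)


class TestSweepAndClassify:
    def test_sweep_equals_closed_form(self, skeleton):
        model = skeleton.model
        for acr, params in skeleton.truth["muscles"].items():
            grid = np.arange(-30, 31, 10.0)
            curve = mma_sweep(model.muscles[acr], model, params["joint"], "z",
                              grid, h=0.25)
            truth = np.array([hinge_truth_moment_arm(params, t) for t in grid])
            assert np.max(np.abs(curve.moment_arm_m - truth)
                          / np.abs(truth)) < 1e-3

    def test_hamstring_flexor_grows_with_knee_extension(self):
        """A muscle caudal to the knee axis flexes the knee, with flexor
        moment arm magnitude increasing as the knee extends."""
        m = hinge_model()
        # knee-like: origin proximal-caudal on the thigh, insertion
        # distal-caudal on the shank; flexed reference at gamma0 < 180 deg
        origin = 0.1 * np.array([np.cos(np.deg2rad(210)), np.sin(np.deg2rad(210)), 0])
        insertion = 0.06 * np.array([np.cos(np.deg2rad(-100)),
                                     np.sin(np.deg2rad(-100)), 0])
        mus = MusclePath(acronym="HAM", points=[("par", origin), ("chi", insertion)])
        grid = np.arange(-40, 1, 10.0)  # flexion negative toward extension at 0
        curve = mma_sweep(mus, m, "j", "z", grid)
        assert np.all(curve.moment_arm_m < 0)  # flexor throughout
        assert np.all(np.diff(np.abs(curve.moment_arm_m)) > 0)

    def test_grid_direction_independence(self, skeleton):
        model = skeleton.model
        acr, params = next(iter(skeleton.truth["muscles"].items()))
        grid = np.arange(-20, 21, 5.0)
        c1 = mma_sweep(model.muscles[acr], model, params["joint"], "z", grid)
        c2 = mma_sweep(model.muscles[acr], model, params["joint"], "z", grid[::-1])
        assert np.allclose(c1.moment_arm_m, c2.moment_arm_m)
        assert np.all(np.diff(c2.angles_deg) > 0)

    def test_classify_uniform_extensor(self):
        curve = MomentArmCurve("M", "j", "z", np.arange(5.0),
                               np.full(5, 0.02), 0.25)
        assert classify_action(curve)["label"] == "extensor"

    def test_classify_switching_interpolates_zero(self):
        angles = np.array([0.0, 10.0])
        arms = np.array([-0.01, 0.03])  # crosses zero at 2.5 deg
        curve = MomentArmCurve("M", "j", "z", angles, arms, 0.25)
        result = classify_action(curve)
        assert result["label"] == "switching"
        assert result["theta_deg"] == pytest.approx(2.5)

    def test_classify_negligible_dead_band(self):
        curve = MomentArmCurve("M", "j", "y", np.arange(4.0),
                               np.array([1e-5, -2e-5, 1e-5, 0.0]), 0.25)
        assert classify_action(curve, tol=1e-4)["label"] == "negligible"

    def test_classify_dof_specific_labels(self):
        curve_y = MomentArmCurve("M", "j", "y", np.arange(3.0),
                                 np.full(3, -0.01), 0.25)
        assert classify_action(curve_y)["label"] == "adductor"
        curve_x = MomentArmCurve("M", "j", "x", np.arange(3.0),
                                 np.full(3, 0.01), 0.25)
        assert classify_action(curve_x)["label"] == "external rotator"


class TestMuscleTableFixture:
    def test_all_rows_load_with_levels(self):
        df = load_muscle_table()
        assert len(df) == 37
        assert df["acronym"].is_unique
        levels = {"I", "I'", "II", "II'"}
        assert set(df["origin_level"]) <= levels
        assert set(df["insertion_level"]) <= levels
        for acr in ("IF", "CFL", "AMB", "FMTE", "ISTR", "AHD"):
            assert acr in set(df["acronym"])

    def test_synthetic_muscles_follow_table_topology(self, skeleton):
        df = load_muscle_table().set_index("acronym")
        bone_to_segment = {"ilium": "pelvis", "pubis": "pelvis",
                           "ischium": "pelvis", "vertebrae": "pelvis",
                           "femur": "femur", "tibia": "crus", "fibula": "crus",
                           "tarsals": "pes", "pes": "pes",
                           "metatarsals": "pes", "phalanges": "digit3"}
        for acr, muscle in skeleton.model.muscles.items():
            segs = {seg for seg, _ in muscle.points}
            assert segs <= set(skeleton.model.segments)
            if acr in df.index:
                assert bone_to_segment[df.loc[acr, "origin_bone"]] == muscle.points[0][0]
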