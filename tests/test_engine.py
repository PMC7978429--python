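"""Virtual-work moment arms: pulley/planar oracles, sweeps, normalization."""

import numpy as np
import pytest

import archolimb as al
from archolimb import Pose
from archolimb.engine import MomentArmCurve, average_subheads, mean_normalized
from archolimb.kinematics import forward_kinematics
from archolimb import simulate as sim
from archolimb.simulate import straight_line_moment_arm

SAGITTAL_HIP = Pose({"hip": {"ABAD": 0.0, "LAR": 0.0}})


class TestMomentArm:
    def test_pulley_equals_wrap_radius_everywhere(self, default_limb):
        """A tendon fully wrapped on a joint-coaxial cylinder has |r| equal
        to the cylinder radius at every angle (belt-and-pulley identity)."""
        model, truth = default_limb
        cases = [
            ("CFL", "hip", SAGITTAL_HIP, -1),   # caudal wrap: extensor
            ("FMTE", "knee", Pose(), +1),       # cranial wrap: extensor
            ("GM", "ankle", Pose(), -1),        # caudal wrap: plantarflexor
        ]
        for mtu, joint, base, sign in cases:
            R = truth["muscles"][mtu]["true_abs_moment_arm_mm"]
            lo, hi = model.joints[joint].rom_deg["FLEXEX"]
            for theta in np.linspace(lo, hi, 12):
                r = al.moment_arm(
                    model, mtu, joint, "FLEXEX",
                    base.replace(joint, "FLEXEX", float(theta)),
                )
                assert r == pytest.approx(sign * R, rel=1e-6), (mtu, theta)

    def test_straight_line_matches_perpendicular_distance(self, default_limb):
        """Finite-difference r equals the closed-form cross-product formula
        for straight-line muscles, to 1e-6 relative."""
        model, _ = default_limb
        gen = np.random.default_rng(11)
        for _ in range(20):
            theta = float(gen.uniform(-45, 65))
            pose = SAGITTAL_HIP.replace("hip", "FLEXEX", theta)
            fk = forward_kinematics(model, pose, warn_out_of_rom=False)
            A, B = fk["attachments"]["IT1"]
            expected = straight_line_moment_arm(
                model.joints["hip"].center, [0, 0, 1], A, B
            )
            r = al.moment_arm(model, "IT1", "hip", "FLEXEX", pose)
            assert r == pytest.approx(expected, rel=1e-6)

    def test_line_through_joint_centre_has_zero_arm(self):
        spec = {
            "taxon": "zero",
            "segments": [
                {"name": "pelvis", "reference_length": 100.0},
                {"name": "femur", "reference_length": 100.0,
                 "parent_joint": "hip"},
            ],
            "joints": [{"name": "hip", "center": [0, 0, 0]}],
            "mtus": [{
                "name": "CFL",
                # both attachments on the line through the joint centre
                "origin": {"segment": "pelvis", "point": [0, 50.0, 0]},
                "insertion": {"segment": "femur", "point": [0, -60.0, 0]},
            }],
        }
        model = al.assemble_model(spec)
        r = al.moment_arm(model, "CFL", "hip", "FLEXEX", SAGITTAL_HIP)
        assert abs(r) < 1e-9

    def test_scale_invariance_of_normalized_mean(self):
        """Doubling every coordinate doubles r and gaps but leaves the
        normalized mean unchanged."""
        results = {}
        for k in (1.0, 2.0):
            params = sim.LimbGenParams(
                femur_length=300.0 * k, recipes=sim.DEFAULT_RECIPES
            )
            model, _ = sim.generate_limb(params)
            curve = al.sweep_rom(model, "FTE", "knee", "FLEXEX",
                                 grid_step_deg=5.0)
            results[k] = (curve.moment_arms_mm, mean_normalized(curve, model))
        r1, row1 = results[1.0]
        r2, row2 = results[2.0]
        assert np.allclose(r2, 2.0 * r1, rtol=1e-9)
        assert row2["mean_normalized"] == pytest.approx(
            row1["mean_normalized"], rel=1e-9
        )
        # cartilage gap scales linearly too: knee centre at -(1 + 0.05) L
        m2, _ = sim.generate_limb(
            sim.LimbGenParams(femur_length=600.0, recipes=())
        )
        assert m2.joints["knee"].center[1] == pytest.approx(-630.0)

    def test_sagittal_mirror_flips_abad_and_lar_signs(self):
        """Mirroring the model across the sagittal plane (z -> -z) flips
        ABAD and LAR moment arms and preserves FLEXEX."""
        def limb(mirror):
            s = -1.0 if mirror else 1.0
            spec = {
                "taxon": "m",
                "segments": [
                    {"name": "pelvis", "reference_length": 100.0},
                    {"name": "femur", "reference_length": 100.0,
                     "parent_joint": "hip"},
                ],
                "joints": [{"name": "hip", "center": [0, 0, 0]}],
                "mtus": [{
                    "name": "PIFI2",
                    "origin": {"segment": "pelvis", "point": [30.0, 20.0, s * 15.0]},
                    "insertion": {"segment": "femur",
                                  "point": [10.0, -40.0, s * 12.0]},
                }],
            }
            return al.assemble_model(spec)

        base, mirrored = limb(False), limb(True)
        pose = Pose({"hip": {"FLEXEX": 10.0, "ABAD": -20.0, "LAR": 5.0}})
        mpose = Pose({"hip": {"FLEXEX": 10.0, "ABAD": 20.0, "LAR": -5.0}})
        for dof, flip in (("FLEXEX", 1.0), ("ABAD", -1.0), ("LAR", -1.0)):
            r = al.moment_arm(base, "PIFI2", "hip", dof, pose)
            rm = al.moment_arm(mirrored, "PIFI2", "hip", dof, mpose)
            assert rm == pytest.approx(flip * r, rel=1e-9, abs=1e-12)


class TestSweep:
    @pytest.mark.parametrize(
        "joint,dof,n", [("hip", "FLEXEX", 111), ("hip", "ABAD", 46),
                        ("hip", "LAR", 61), ("knee", "FLEXEX", 101),
                        ("ankle", "FLEXEX", 91)]
    )
    def test_grid_covers_rom_inclusive(self, default_limb, joint, dof, n):
        model, _ = default_limb
        mtu = {"hip": "IT1", "knee": "FTE", "ankle": "TA"}[joint]
        curve = al.sweep_rom(model, mtu, joint, dof)
        assert len(curve.angles_deg) == n
        lo, hi = model.joints[joint].rom_deg[dof]
        assert curve.angles_deg[0] == lo and curve.angles_deg[-1] == hi

    def test_pulley_sweep_is_constant(self, default_limb):
        model, truth = default_limb
        curve = al.sweep_rom(model, "FMTE", "knee", "FLEXEX", grid_step_deg=5.0)
        R = truth["muscles"]["FMTE"]["true_abs_moment_arm_mm"]
        assert np.allclose(curve.moment_arms_mm, R, rtol=1e-6)

    def test_path_length_is_continuous_over_sweep(self, default_limb):
        from archolimb.engine import path_length

        model, _ = default_limb
        thetas = np.arange(-90.0, 10.0 + 1e-9, 1.0)
        L = np.array([
            path_length(model, Pose().replace("knee", "FLEXEX", float(t)), "FTE")
            for t in thetas
        ])
        # |dL| bounded by max|r| x dtheta; generous factor for curvature
        max_r = np.abs(al.sweep_rom(model, "FTE", "knee", "FLEXEX").moment_arms_mm).max()
        assert np.abs(np.diff(L)).max() <= 1.5 * max_r * np.deg2rad(1.0)


class TestReduction:
    def test_constant_curve_mean(self, default_limb):
        model, _ = default_limb
        curve = MomentArmCurve(
            "CFL", "hip", "FLEXEX", np.arange(5.0), np.full(5, 30.0)
        )
        row = mean_normalized(curve, model)
        assert row["mean_normalized"] == pytest.approx(30.0 / 300.0)

    def test_linear_curve_mean_by_symmetry(self, default_limb):
        model, _ = default_limb
        curve = MomentArmCurve(
            "CFL", "hip", "FLEXEX", np.arange(11.0), np.linspace(10, 20, 11)
        )
        assert mean_normalized(curve, model)["mean_mm"] == pytest.approx(15.0)

    def test_empty_curve_rejected(self, default_limb):
        model, _ = default_limb
        curve = MomentArmCurve("CFL", "hip", "FLEXEX", np.array([]), np.array([]))
        with pytest.raises(ValueError):
            mean_normalized(curve, model)

    @pytest.mark.parametrize(
        "values,expected",
        [((0.08, 0.10), 0.09), ((0.5, 0.5), 0.5), ((0.123,), 0.123)],
    )
    def test_average_subheads(self, values, expected):
        assert average_subheads(values) == pytest.approx(expected)

    def test_average_subheads_empty(self):
        with pytest.raises(ValueError):
            average_subheads([])
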