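"""Damped least-squares inverse kinematics: Jacobian, stepper, clamping, solver."""

import numpy as np
import pytest

from dqgait import ik, model


@pytest.fixture
def normal_setup(params):
    return dict(
        params=params,
        ik=ik.gait_ik_params("normal"),
        limits=ik.gait_joint_limits("normal"),
        phi0=ik.gait_initial_config("normal"),
    )


class TestJacobian:
    def test_anatomical_hip_column(self, params):
        J = ik.compute_jacobian(np.zeros((3, 3)), params)
        # d p / d Phi_1,z = 2 (z x p_toe) with p_toe = (0.25, -0.83, 0)
        np.testing.assert_allclose(J[:3, 2], [2 * 0.83, 2 * 0.25, 0.0], atol=1e-6)

    def test_orientation_z_row(self, params, rng):
        phi = model.config_from_angles(rng.uniform(-40, 40, 3))
        J = ik.compute_jacobian(phi, params)
        # o_z = 2 (Phi_1,z + Phi_2,z + Phi_3,z) exactly in the planar case
        np.testing.assert_allclose(J[5, [2, 5, 8]], [2.0, 2.0, 2.0], atol=1e-6)

    def test_fd_matches_analytic(self, params, rng):
        for _ in range(100):
            phi = model.config_from_angles(rng.uniform(-60, 60, 3))
            J_fd = ik.compute_jacobian(phi, params, method="fd")
            J_an = ik.compute_jacobian(phi, params, method="analytic")
            assert np.abs(J_fd - J_an).max() < 1e-6

    def test_fd_matches_analytic_off_plane(self, params, rng):
        # the closed form also covers non-planar rotation vectors
        for _ in range(20):
            phi = rng.uniform(-0.5, 0.5, (3, 3))
            J_fd = ik.compute_jacobian(phi, params, method="fd")
            J_an = ik.compute_jacobian(phi, params, method="analytic")
            assert np.abs(J_fd - J_an).max() < 1e-6

    def test_unknown_method_raises(self, params):
        with pytest.raises(ValueError):
            ik.compute_jacobian(np.zeros((3, 3)), params, method="symbolic")


class TestDLSStep:
    def test_scalar_closed_form(self):
        out = ik.dls_step(np.array([[1.0]]), np.array([1.0]), gamma=0.1)
        assert out[0] == pytest.approx(1.0 / 1.01)

    def test_zero_error(self, rng):
        J = rng.normal(size=(6, 9))
        np.testing.assert_allclose(ik.dls_step(J, np.zeros(6), 0.05), np.zeros(9))

    def test_zero_jacobian_is_regularized(self):
        out = ik.dls_step(np.zeros((6, 9)), np.ones(6), 0.05)
        np.testing.assert_allclose(out, np.zeros(9))

    def test_step_norm_bound(self, rng):
        for _ in range(50):
            J = rng.normal(size=(6, 9))
            dxi = rng.normal(size=6)
            gamma = rng.uniform(0.01, 0.5)
            step = ik.dls_step(J, dxi, gamma)
            assert np.linalg.norm(step) <= np.linalg.norm(dxi) / (2 * gamma) + 1e-12

    def test_small_gamma_approaches_pseudo_inverse(self, rng):
        J = rng.normal(size=(6, 9))  # full row rank almost surely
        dxi = rng.normal(size=6)
        out = ik.dls_step(J, dxi, gamma=1e-8)
        np.testing.assert_allclose(out, np.linalg.pinv(J) @ dxi, atol=1e-6)

    def test_nonpositive_gamma_raises(self):
        with pytest.raises(ValueError):
            ik.dls_step(np.eye(6, 9), np.ones(6), 0.0)


class TestClamp:
    def test_knee_clamped_to_toe_walking_limit(self):
        limits = ik.gait_joint_limits("toe_walking")
        phi = model.config_from_angles([0.0, -60.0, -20.0])
        out = ik.clamp_config(phi, limits)
        np.testing.assert_allclose(
            model.angles_from_config(out), [0.0, -50.4, -20.0], atol=1e-12
        )

    def test_inside_angles_unchanged_bitwise(self):
        limits = ik.gait_joint_limits("normal")
        phi = model.config_from_angles([13.2, -41.7, 5.9])
        out = ik.clamp_config(phi, limits)
        assert np.array_equal(out, phi)

    def test_idempotent(self, rng):
        limits = ik.gait_joint_limits("heel_walking")
        phi = model.config_from_angles(rng.uniform(-180, 180, 3))
        once = ik.clamp_config(phi, limits)
        np.testing.assert_array_equal(ik.clamp_config(once, limits), once)

    def test_off_plane_projected(self):
        limits = ik.gait_joint_limits("normal")
        phi = np.full((3, 3), 0.1)
        out = ik.clamp_config(phi, limits)
        np.testing.assert_allclose(out[:, :2], 0.0)
        np.testing.assert_allclose(out[:, 2], 0.1)

    def test_limits_validation(self):
        with pytest.raises(ValueError):
            ik.JointLimits(np.array([10.0, 0, 0]), np.array([-10.0, 0, 0]))


class TestIKSolve:
    def test_target_at_start_converges_immediately(self, normal_setup):
        target = model.end_effector_posture(normal_setup["phi0"], normal_setup["params"])
        res = ik.ik_solve(target, normal_setup["params"], normal_setup["ik"],
                          normal_setup["limits"], normal_setup["phi0"])
        assert res.converged and res.iterations == 0
        np.testing.assert_array_equal(res.config, normal_setup["phi0"])

    def test_parameter_recovery(self, normal_setup, rng):
        # FK -> IK round trips over random gait-like configs.  The knee is
        # kept in genuine flexion: near the straight-knee singularity the
        # posture-to-angle amplification grows without bound, so no finite
        # posture tolerance can pin the angles there.
        worst = 0.0
        for _ in range(100):
            theta_true = rng.uniform([-10, -60, -20], [30, -25, 15])
            target = model.end_effector_posture(
                model.config_from_angles(theta_true), normal_setup["params"]
            )
            res = ik.ik_solve(target, normal_setup["params"], normal_setup["ik"],
                              normal_setup["limits"], normal_setup["phi0"])
            assert res.converged
            err = np.abs(model.angles_from_config(res.config) - theta_true).max()
            worst = max(worst, err)
        assert worst < 1e-3

    def test_unreachable_target_terminates(self, normal_setup):
        target = np.array([2.0, 0.0, 0.0, 0.0, 0.0, 0.0])  # beyond max reach
        res = ik.ik_solve(target, normal_setup["params"], normal_setup["ik"],
                          normal_setup["limits"], normal_setup["phi0"])
        assert not res.converged
        assert res.iterations <= normal_setup["ik"].max_iterations + 1
        assert np.all(np.isfinite(res.config))
        assert np.isfinite(res.final_error_norm)

    def test_solution_respects_limits(self, params, rng):
        limits = ik.gait_joint_limits("toe_walking")
        ikp = ik.gait_ik_params("toe_walking")
        phi0 = ik.gait_initial_config("toe_walking")
        target = np.array([0.4, -0.7, 0.0, 0.0, 0.0, -0.6])
        res = ik.ik_solve(target, params, ikp, limits, phi0)
        theta = model.angles_from_config(res.config)
        assert np.all(theta >= limits.theta_min - 1e-9)
        assert np.all(theta <= limits.theta_max + 1e-9)

    def test_monotone_decrease_near_target(self, normal_setup, rng):
        # one DLS step from a posture very close to the target cannot
        # increase the error norm
        for _ in range(20):
            theta = rng.uniform([-10, -60, -20], [30, -1, 15])
            phi = model.config_from_angles(theta)
            xi = model.end_effector_posture(phi, normal_setup["params"])
            target = xi + rng.uniform(-1e-3, 1e-3, 6) * [1, 1, 0, 0, 0, 1]
            ikp = ik.IKParams(alpha=0.6992, gamma=0.0579, epsilon=1e-12, max_iterations=1)
            res = ik.ik_solve(target, normal_setup["params"], ikp,
                              normal_setup["limits"], phi)
            assert res.final_error_norm <= np.linalg.norm(target - xi) + 1e-15

    def test_non_finite_target_raises(self, normal_setup):
        with pytest.raises(ValueError):
            ik.ik_solve(np.array([np.nan, 0, 0, 0, 0, 0]), normal_setup["params"],
                        normal_setup["ik"], normal_setup["limits"], normal_setup["phi0"])


class TestIKTrack:
    def test_constant_targets_warm_start(self, normal_setup):
        target = model.end_effector_posture(
            model.config_from_angles([10, -20, 5]), normal_setup["params"]
        )
        results = ik.ik_track([target] * 5, normal_setup["params"], normal_setup["ik"],
                              normal_setup["limits"], normal_setup["phi0"])
        assert all(r.converged for r in results)
        assert all(r.iterations == 0 for r in results[1:])

    def test_reversed_trajectory_symmetry(self, normal_setup):
        from dqgait import evaluation, gait

        traj = gait.generate_gait(gait.preset_spec("normal", n_samples=41))
        fwd = evaluation.round_trip(traj, normal_setup["params"], normal_setup["ik"],
                                    normal_setup["limits"], normal_setup["phi0"])[2]
        rev = gait.JointTrajectory(traj.cycle_percent, traj.theta[::-1].copy(), "normal")
        # start the reversed pass where it begins
        phi0 = model.config_from_angles(rev.theta[0])
        bwd = evaluation.round_trip(rev, normal_setup["params"], normal_setup["ik"],
                                    normal_setup["limits"], phi0)[2]
        for joint in fwd.joint_rmse_deg:
            assert bwd.joint_rmse_deg[joint] < 10 * max(fwd.joint_rmse_deg[joint], 1e-6)

    def test_empty_targets_raise(self, normal_setup):
        with pytest.raises(ValueError):
            ik.ik_track([], normal_setup["params"], normal_setup["ik"],
                        normal_setup["limits"], normal_setup["phi0"])

    def test_log_callback(self, normal_setup):
        target = model.end_effector_posture(
            model.config_from_angles([5, -10, 2]), normal_setup["params"]
        )
        seen = []
        ik.ik_track([target, target], normal_setup["params"], normal_setup["ik"],
                    normal_setup["limits"], normal_setup["phi0"],
                    log=lambda t, r: seen.append((t, r.iterations)))
        assert len(seen) == 2 and seen[1][1] == 0


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha=0.0, gamma=0.1), dict(alpha=0.5, gamma=1.0),
         dict(alpha=0.5, gamma=0.1, epsilon=0.0),
         dict(alpha=0.5, gamma=0.1, max_iterations=0)],
    )
    def test_bad_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            ik.IKParams(**kwargs)

    def test_gait_defaults(self):
        p = ik.gait_ik_params("normal")
        assert (p.alpha, p.gamma, p.epsilon, p.max_iterations) == (0.6992, 0.0579, 1e-6, 56)
        assert ik.gait_ik_params("toe_walking").alpha == 0.7334
        np.testing.assert_allclose(
            model.angles_from_config(ik.gait_initial_config("heel_walking")),
            [32.0, -5.0, 12.0], atol=1e-12,
        )
        with pytest.raises(ValueError):
            ik.gait_ik_params("running")
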