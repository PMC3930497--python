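"""Constraint assembly and the three solvers against dense oracles."""

import itertools
import time

import numpy as np
import pytest

from plectosim.constraint_dynamics import (ANCHOR, BallSocketJoint,
                                           JointSet, StructuralError,
                                           assemble_jacobian, build_system,
                                           chain_ball_joints, constraint_force,
                                           dispatch_solver, evaluate_constraints,
                                           solve_chain_exact, solve_direct,
                                           solve_sor)
from plectosim.model_state import InvalidParameterError, make_free_chain
from tests.conftest import dense_system, random_chain


class TestEvaluateConstraints:
    def test_assembled_chain_is_exact_zero(self):
        state = make_free_chain(6, radius=0.3)
        C = evaluate_constraints(state, chain_ball_joints(state, True))
        assert np.all(C == 0.0)

    def test_translation_sign_convention(self):
        state = make_free_chain(2, radius=0.3)
        joints = chain_ball_joints(state)  # body_a = 1, body_b = 0
        eps = 1e-3
        state.pos[0] += np.array([eps, 0.0, 0.0])  # move body_b
        C = evaluate_constraints(state, joints)
        np.testing.assert_allclose(C, [-eps, 0.0, 0.0], atol=1e-15)

    def test_independent_coordinate_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        state = random_chain(5, rng)
        joints = chain_ball_joints(state, anchored=True)
        C = evaluate_constraints(state, joints)
        out = []
        for j in joints:
            def world(idx, anchor):
                if idx == ANCHOR:
                    return anchor
                q = state.quat[idx]
                R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
                return state.pos[idx] + R @ anchor
            out.append(world(j.body_a, j.anchor_a)
                       - world(j.body_b, j.anchor_b))
        np.testing.assert_allclose(C, np.concatenate(out), atol=1e-12)


class TestJacobian:
    def test_finite_difference(self, rng):
        from plectosim.integrator import StepParams, step

        state = random_chain(5, rng)
        joints = chain_ball_joints(state, anchored=True)
        J = assemble_jacobian(state, joints)
        u = state.u
        delta = 1e-7
        before = evaluate_constraints(state, joints)
        # advance positions/orientations kinematically by delta
        from plectosim import _kernels
        s2 = state.copy()
        s2.pos += delta * s2.vel
        for i in range(s2.n_bodies):
            s2.quat[i] = _kernels.exp_map_update(s2.quat[i], s2.omega[i],
                                                 delta)
        after = evaluate_constraints(s2, joints)
        fd = (after - before) / delta
        np.testing.assert_allclose(fd, J @ u, rtol=1e-5, atol=1e-5)

    def test_rest_gives_zero_rate(self, rng):
        state = random_chain(4, rng, randomize_velocities=False)
        J = assemble_jacobian(state, chain_ball_joints(state, True))
        assert np.all(J @ state.u == 0.0)

    def test_four_cylinder_block_tridiagonal(self, rng):
        # serial anchored chain: J W^-1 J^T has exactly zero 3x3 blocks
        # outside the block-tridiagonal band
        state = random_chain(4, rng)
        J, W, u, _ = dense_system(state)
        A = J @ np.linalg.inv(W) @ J.T
        nb = A.shape[0] // 3
        for bi in range(nb):
            for bj in range(nb):
                blk = A[3 * bi:3 * bi + 3, 3 * bj:3 * bj + 3]
                if abs(bi - bj) > 1:
                    assert np.all(blk == 0.0)

    def test_bad_joint_index_raises(self):
        state = make_free_chain(2, radius=0.3)
        bad = BallSocketJoint(0, 7, np.zeros(3), np.zeros(3))
        with pytest.raises(StructuralError):
            assemble_jacobian(state, [bad])


class TestBuildSystem:
    def test_trivial_zero(self, rng):
        state = random_chain(3, rng, randomize_velocities=False)
        J, W, u, joints = dense_system(state)
        C = evaluate_constraints(state, joints)
        A, rhs, lo = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.8,
                                  1e-10, C)
        assert np.allclose(rhs, 0.0)
        assert np.allclose(np.linalg.solve(A, rhs), 0.0)

    def test_erp_zero_ignores_position_error(self, rng):
        state = random_chain(3, rng)
        J, W, u, joints = dense_system(state)
        C = np.ones(J.shape[0])
        _, rhs0, _ = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.0,
                                  1e-10, C)
        _, rhs1, _ = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.0,
                                  1e-10, 5.0 * C)
        np.testing.assert_allclose(rhs0, rhs1, atol=1e-12)

    def test_post_condition_on_random_chains(self, rng):
        dt, erp, cfm = 1e-3, 0.8, 1e-8
        for _ in range(10):
            state = random_chain(int(rng.integers(2, 8)), rng)
            state.pos += 1e-4 * rng.standard_normal(state.pos.shape)
            J, W, u, joints = dense_system(state)
            C = evaluate_constraints(state, joints)
            F = rng.standard_normal(u.size)
            A, rhs, lo = build_system(J, W, F, u, dt, erp, cfm, C)
            lam = np.linalg.solve(A, rhs)
            u_new = u + dt * np.linalg.solve(W, F + J.T @ lam)
            resid = J @ u_new + erp * C / dt + cfm * lam
            assert np.max(np.abs(resid)) < 1e-8

    @pytest.mark.parametrize("bad", [dict(dt=-1.0), dict(erp=1.5),
                                     dict(cfm=-1e-3)])
    def test_invalid_parameters(self, rng, bad):
        state = random_chain(2, rng)
        J, W, u, joints = dense_system(state)
        kw = dict(dt=1e-3, erp=0.8, cfm=1e-10)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            build_system(J, W, np.zeros_like(u), u, kw["dt"], kw["erp"],
                         kw["cfm"], np.zeros(J.shape[0]))


class TestExactChainSolver:
    @pytest.mark.parametrize("n", [2, 4, 16, 128])
    def test_matches_dense_factorization(self, rng, n):
        for _ in range(4):
            state = random_chain(n, rng)
            J, W, u, joints = dense_system(state)
            C = evaluate_constraints(state, joints)
            F = rng.standard_normal(u.size)
            A, rhs, lo = build_system(J, W, F, u, 1e-3, 0.8, 1e-10, C)
            lam_dense = np.linalg.solve(A, rhs)
            lam_exact = solve_chain_exact(A, rhs)
            err = np.max(np.abs(lam_exact - lam_dense))
            assert err < 1e-10 * max(np.max(np.abs(lam_dense)), 1.0)

    def test_zero_rhs(self, rng):
        state = random_chain(4, rng)
        J, W, u, joints = dense_system(state)
        A, _, _ = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.8, 1e-10,
                               np.zeros(J.shape[0]))
        assert np.all(solve_chain_exact(A, np.zeros(A.shape[0])) == 0.0)

    def test_rejects_contact_rows(self, rng):
        A = np.eye(3)
        with pytest.raises(StructuralError):
            solve_chain_exact(A, np.ones(3), lo=np.zeros(3))

    def test_linear_scaling_smoke(self, rng):
        # banded solve cost grows ~linearly: generous factor bound
        times = {}
        for n in (128, 512):
            state = random_chain(n, rng)
            J, W, u, joints = dense_system(state)
            A, rhs, _ = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.8,
                                     1e-10, evaluate_constraints(state, joints))
            solve_chain_exact(A, rhs)  # warm
            t0 = time.perf_counter()
            for _ in range(3):
                solve_chain_exact(A, rhs)
            times[n] = time.perf_counter() - t0
        assert times[512] < 40 * times[128]  # 4x size, lenient bound


class TestSOR:
    def test_diagonal_exact_in_one_sweep(self):
        A = np.diag([2.0, 3.0, 5.0])
        rhs = np.array([2.0, 6.0, -5.0])
        lam = solve_sor(A, rhs, omega=1.0, n_iter=1)
        np.testing.assert_allclose(lam, [1.0, 2.0, -1.0], atol=1e-14)

    def test_monotone_error_decrease(self, rng):
        M = rng.standard_normal((30, 30))
        A = M @ M.T + 30 * np.eye(30)
        rhs = rng.standard_normal(30)
        exact = np.linalg.solve(A, rhs)
        errs = []
        for it in (1, 3, 10, 30, 100):
            lam = solve_sor(A, rhs, omega=1.3, n_iter=it)
            d = lam - exact
            errs.append(d @ A @ d)
        assert all(e1 > e2 for e1, e2 in zip(errs, errs[1:]))

    def test_contact_clamping(self):
        A = np.eye(2) * 2.0
        rhs = np.array([-1.0, 1.0])
        lam = solve_sor(A, rhs, lo=np.zeros(2), omega=1.0, n_iter=20)
        assert lam[0] == 0.0
        assert lam[1] == pytest.approx(0.5, rel=1e-6)

    def test_bad_relaxation_factor(self):
        with pytest.raises(InvalidParameterError):
            solve_sor(np.eye(2), np.ones(2), omega=2.5)


class TestDirectSolver:
    def test_unbounded_equals_dense(self, rng):
        M = rng.standard_normal((12, 12))
        A = M @ M.T + 12 * np.eye(12)
        rhs = rng.standard_normal(12)
        np.testing.assert_allclose(solve_direct(A, rhs),
                                   np.linalg.solve(A, rhs), atol=1e-9)

    def test_separating_contact(self):
        lam = solve_direct(np.array([[2.0]]), np.array([-1.0]),
                           lo=np.zeros(1))
        assert lam[0] == 0.0

    def test_against_active_set_enumeration(self, rng):
        # exhaustive subset oracle for the mixed LCP on small systems
        for _ in range(10):
            m, nb = 8, 4  # 4 equality rows + 4 bounded rows
            M = rng.standard_normal((m, m))
            A = M @ M.T + m * np.eye(m)
            rhs = rng.standard_normal(m)
            lo = np.full(m, -1e300)
            lo[nb:] = 0.0
            best = None
            for active in itertools.product([0, 1], repeat=nb):
                idx = list(range(nb)) + [nb + i for i, a in
                                         enumerate(active) if a]
                lam = np.zeros(m)
                lam[idx] = np.linalg.solve(A[np.ix_(idx, idx)], rhs[idx])
                w = A @ lam - rhs
                if (np.all(lam[nb:] >= -1e-9) and np.all(w[nb:] >= -1e-9)
                        and np.max(np.abs(w[:nb])) < 1e-9):
                    best = lam
                    break
            assert best is not None
            got = solve_direct(A, rhs, lo)
            np.testing.assert_allclose(got, best, atol=1e-8)

    def test_non_spd_raises(self):
        from plectosim.constraint_dynamics import NumericalError

        with pytest.raises(NumericalError):
            solve_direct(-np.eye(2), np.ones(2))


class TestDispatch:
    def test_collision_free_routes_to_exact(self, rng):
        state = random_chain(6, rng)
        J, W, u, joints = dense_system(state)
        A, rhs, lo = build_system(J, W, np.zeros_like(u), u, 1e-3, 0.8,
                                  1e-10, evaluate_constraints(state, joints))
        lam, name = dispatch_solver(A, rhs, lo, has_collisions=False, dt=1e-3)
        assert name == "exact"
        np.testing.assert_array_equal(lam, solve_chain_exact(A, rhs))

    def test_sor_failure_falls_back_to_direct(self, rng):
        M = rng.standard_normal((10, 10))
        A = M @ M.T + 0.5 * np.eye(10)  # stiff for 1-sweep SOR
        rhs = 10 * rng.standard_normal(10)
        lo = np.full(10, -1e300)
        lam, name = dispatch_solver(A, rhs, lo, has_collisions=True, dt=1e-3,
                                    sor_iters=1, accept_tol=1e-12)
        assert name == "direct"
        np.testing.assert_allclose(lam, np.linalg.solve(A, rhs), atol=1e-8)


class TestConstraintForce:
    def test_zero_multipliers(self, rng):
        state = random_chain(3, rng)
        J, *_ = dense_system(state)
        assert np.all(constraint_force(J, np.zeros(J.shape[0])) == 0.0)

    def test_virtual_work_vanishes_on_null_space(self, rng):
        state = random_chain(5, rng)
        J, W, u, joints = dense_system(state)
        # project u onto the null space of J
        JW = J @ np.linalg.inv(W)
        lam = np.linalg.solve(JW @ J.T, J @ u)
        u_proj = u - np.linalg.inv(W) @ J.T @ lam
        F = constraint_force(J, rng.standard_normal(J.shape[0]))
        assert abs(F @ u_proj) < 1e-9 * np.linalg.norm(F) * \
            max(np.linalg.norm(u_proj), 1.0)

    def test_newtons_third_law_per_joint(self, rng):
        state = random_chain(4, rng)
        for j in chain_ball_joints(state):
            Jk = assemble_jacobian(state, [j])
            lam = rng.standard_normal(3)
            F = constraint_force(Jk, lam).reshape(-1, 6)
            # per-joint linear force on body_a equals minus that on body_b
            np.testing.assert_allclose(F[j.body_a, :3], -F[j.body_b, :3],
                                       atol=1e-12)
            np.testing.assert_allclose(F[j.body_a, :3], lam, atol=1e-12)


class TestErpDecay:
    def test_geometric_bearing_error_decay(self):
        # a bearing separation decays by (1 - erp) per step without forces
        from plectosim.integrator import StepParams, step

        state = make_free_chain(2, radius=0.3)
        joints = JointSet.serial_chain(state, anchor=None)
        eps = 1e-3
        state.pos[1] += np.array([eps, 0.0, 0.0])
        erp = 0.8
        sp = StepParams(erp=erp, cfm=0.0)
        from plectosim.constraint_dynamics import chain_ball_joints
        ratios = []
        for _ in range(4):
            c_before = np.max(np.abs(evaluate_constraints(
                state, chain_ball_joints(state))))
            step(state, joints, params=sp)
            c_after = np.max(np.abs(evaluate_constraints(
                state, chain_ball_joints(state))))
            ratios.append(c_after / c_before)
        np.testing.assert_allclose(ratios, 1.0 - erp, rtol=0.02)
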