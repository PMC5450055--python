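"""Explicit and implicit steps, residuals, Jacobians and Newton behaviour."""

import numpy as np
import pytest

import rnaspring as rs
from rnaspring.forces import ForceField
from rnaspring.integrators import (
    NEWTON_EXIT_TOL,
    Jacobian2x2,
    Residual2,
    SingularJacobianError,
)

from conftest import scalar_spring


def spring_config(dt, newton=5):
    return rs.SimulationConfig(K=10.0, G=0.01, dt=dt, newton_iterations=newton)


class TestForwardEuler:
    def test_single_spring_arithmetic(self):
        g, state, fixed = scalar_spring()
        cfg = spring_config(dt=0.01)
        new = rs.forward_euler_step(state, g, cfg, fixed=fixed)
        # force = K*(1 - 2) = -10, displacement = -0.1
        np.testing.assert_allclose(new.positions[1], [1.9, 0.0], atol=1e-14)
        np.testing.assert_allclose(new.positions[0], [0.0, 0.0])
        assert new.step_index == 1 and new.time == pytest.approx(0.01)

    def test_fixed_point_at_rest_length(self):
        g, state, fixed = scalar_spring()
        state = rs.LayoutState(np.array([[0.0, 0.0], [1.0, 0.0]]))
        cfg = spring_config(dt=0.5)
        new = rs.forward_euler_step(state, g, cfg, fixed=fixed)
        np.testing.assert_allclose(new.positions, state.positions)
        assert new.time == pytest.approx(0.5)

    def test_large_step_amplifies_error(self):
        # with dt*K = 30 the error multiplies by |1 - dt*K| = 29 per step
        # (exact while the iterate stays on the positive branch)
        g, _, fixed = scalar_spring()
        cfg = spring_config(dt=3.0)
        x = rs.LayoutState(np.array([[0.0, 0.0], [1.001, 0.0]]))
        errs = [abs(x.positions[1, 0] - 1.0)]
        for _ in range(2):
            x = rs.forward_euler_step(x, g, cfg, fixed=fixed)
            errs.append(abs(x.positions[1, 0] - 1.0))
        assert errs[1] / errs[0] == pytest.approx(29, rel=1e-9)
        assert errs[2] / errs[1] == pytest.approx(29, rel=1e-9)

    def test_large_step_diverges_from_afar(self):
        g, state, fixed = scalar_spring()
        cfg = rs.SimulationConfig(
            K=10.0, G=0.01, dt=3.0, newton_iterations=0, max_iterations=200
        )
        res = rs.simulate(g, cfg, "forward", state=state, fixed=fixed)
        assert res.diverged


class TestBackwardResidual:
    def test_root_at_closed_form_solution(self):
        g, state, _ = scalar_spring()
        cfg = spring_config(dt=3.0)
        res = rs.backward_residual(np.array([32 / 31, 0.0]), 1, state, g, cfg)
        assert res.norm < 1e-12

    def test_equilibrium_is_fixed_point(self):
        g, _, _ = scalar_spring()
        state = rs.LayoutState(np.array([[0.0, 0.0], [1.0, 0.0]]))
        cfg = spring_config(dt=3.0)
        res = rs.backward_residual(state.positions[1], 1, state, g, cfg)
        assert res.norm < 1e-14

    def test_vanishing_dt_limit(self):
        g, state, _ = scalar_spring()
        cfg = spring_config(dt=1e-12)
        guess = np.array([1.7, 0.3])
        res = rs.backward_residual(guess, 1, state, g, cfg)
        np.testing.assert_allclose(
            res.as_array(), state.positions[1] - guess, atol=1e-10
        )


class TestJacobian:
    def test_attraction_only_closed_form(self):
        g, state, _ = scalar_spring()
        cfg = spring_config(dt=3.0)
        j = rs.compute_jacobian(np.array([2.0, 0.0]), 1, state, g, cfg)
        # dfx/dx = -1 + dt*K*(-1 + r*y^2/d^3) = -31 on the axis
        assert j.dfx_dx == pytest.approx(-31.0)
        assert j.dfx_dy == pytest.approx(0.0)
        assert j.dfy_dx == pytest.approx(0.0)
        # dfy/dy = -1 + dt*K*(-1 + r*x^2/d^3) = -1 + 30*(-1 + 1/2) = -16
        assert j.dfy_dy == pytest.approx(-16.0)

    def test_offdiagonal_symmetry(self):
        g, state, _ = scalar_spring()
        cfg = spring_config(dt=3.0)
        j = rs.compute_jacobian(np.array([1.3, 0.7]), 1, state, g, cfg)
        assert j.dfx_dy == pytest.approx(j.dfy_dx, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        s = rs.random_structure(rs.GeneratorParams(n=30, seed=seed, min_stem=1))
        g = rs.build_compressed_graph(s)
        cfg = rs.preset_config(2)
        _, st0 = rs.initial_state(s)
        state = rs.LayoutState(st0.positions + rng.normal(0, 0.3, st0.positions.shape))
        h = 1e-6
        for vid in rng.choice(g.n_vertices, size=min(5, g.n_vertices), replace=False):
            vid = int(vid)
            p = state.positions[vid] + rng.normal(0, 0.2, 2)
            jac = rs.compute_jacobian(p, vid, state, g, cfg).as_matrix()
            fd = np.zeros((2, 2))
            for col, e in enumerate(np.eye(2)):
                rp = rs.backward_residual(p + h * e, vid, state, g, cfg).as_array()
                rm = rs.backward_residual(p - h * e, vid, state, g, cfg).as_array()
                fd[:, col] = (rp - rm) / (2 * h)
            np.testing.assert_allclose(jac, fd, atol=1e-5)


class TestNewtonStep:
    def test_zero_residual_leaves_point(self):
        p = np.array([1.4, -0.2])
        out = rs.newton_step(p, Residual2(0.0, 0.0), Jacobian2x2(-31, 0, 0, -31))
        np.testing.assert_allclose(out, p)

    def test_linear_spring_one_step_exact(self):
        g, state, _ = scalar_spring()
        cfg = spring_config(dt=3.0)
        p0 = np.array([1.0, 0.0])  # any seed on the positive branch
        res = rs.backward_residual(p0, 1, state, g, cfg)
        jac = rs.compute_jacobian(p0, 1, state, g, cfg)
        out = rs.newton_step(p0, res, jac)
        np.testing.assert_allclose(out, [32 / 31, 0.0], atol=1e-12)

    def test_identity_like_jacobian(self):
        out = rs.newton_step(
            np.array([0.0, 0.0]), Residual2(0.5, 0.0), Jacobian2x2(-1, 0, 0, -1)
        )
        np.testing.assert_allclose(out, [0.5, 0.0])

    def test_singular_jacobian_signals(self):
        with pytest.raises(SingularJacobianError):
            rs.newton_step(np.zeros(2), Residual2(1, 0), Jacobian2x2(0, 0, 0, 0))


class TestBackwardEulerStep:
    def test_scalar_spring_closed_form(self):
        g, state, fixed = scalar_spring()
        cfg = spring_config(dt=3.0)
        new, traces = rs.backward_euler_step(
            state, g, cfg, fixed=fixed, collect_traces=True
        )
        assert new.positions[1, 0] == pytest.approx(32 / 31, abs=1e-9)
        # Newton converges in a single iteration on the linear branch
        assert traces[1].first_below(NEWTON_EXIT_TOL) == 1

    def test_equilibrium_unchanged(self):
        g, _, fixed = scalar_spring()
        state = rs.LayoutState(np.array([[0.0, 0.0], [1.0, 0.0]]))
        cfg = spring_config(dt=3.0)
        new, _ = rs.backward_euler_step(state, g, cfg, fixed=fixed)
        np.testing.assert_allclose(new.positions, state.positions, atol=1e-12)

    def test_monotone_contraction_any_dt(self):
        # implicit amplification 1/(1 + dt*K): no divergence even at dt = 3
        g, state, fixed = scalar_spring()
        cfg = spring_config(dt=3.0)
        x = state
        errs = [abs(x.positions[1, 0] - 1.0)]
        for _ in range(5):
            x, _ = rs.backward_euler_step(x, g, cfg, fixed=fixed)
            errs.append(abs(x.positions[1, 0] - 1.0))
        ratios = [b / a for a, b in zip(errs, errs[1:])]
        for r in ratios:
            assert r == pytest.approx(1 / 31, rel=1e-6)

    def test_consistency_with_forward_as_dt_vanishes(self, cloverleaf):
        rng = np.random.default_rng(3)
        g, st0 = rs.initial_state(cloverleaf)
        state = rs.LayoutState(st0.positions + rng.normal(0, 0.1, st0.positions.shape))
        diffs = {}
        for dt in (1e-2, 1e-3, 1e-4):
            cfg = rs.SimulationConfig(
                **{**rs.preset_config(2).__dict__, "dt": dt}
            )
            f = rs.forward_euler_step(state, g, cfg)
            b, _ = rs.backward_euler_step(state, g, cfg)
            diffs[dt] = np.abs(f.positions - b.positions).max()
        # one-step gap is O(dt^2): tenfold dt change ~ hundredfold gap change
        assert diffs[1e-2] / diffs[1e-3] == pytest.approx(100, rel=0.7)
        assert diffs[1e-3] / diffs[1e-4] == pytest.approx(100, rel=0.7)

    def test_newton_residuals_nonincreasing_on_random_states(self):
        cfg = rs.preset_config(2)
        s = rs.random_structure(rs.GeneratorParams(n=60, seed=3))
        g = rs.build_compressed_graph(s)
        rng = np.random.default_rng(7)
        good = total = 0
        for _ in range(30):
            _, st0 = rs.initial_state(s)
            state = rs.LayoutState(
                st0.positions + rng.normal(0, 0.5, st0.positions.shape)
            )
            _, traces = rs.backward_euler_step(state, g, cfg, collect_traces=True)
            for t in traces:
                norms = [r for _, _, r in t.iterates]
                good += all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
                total += 1
        assert good / total >= 0.99

    def test_jacobi_commit_is_simultaneous(self):
        # the result must not depend on vertex order: neighbours are frozen
        # at step n, so permuting ids leaves per-vertex solutions identical
        g, state, fixed = scalar_spring()
        cfg = spring_config(dt=3.0)
        new, _ = rs.backward_euler_step(state, g, cfg, fixed=fixed)
        res = rs.backward_residual(new.positions[1], 1, state, g, cfg)
        assert res.norm < 1e-9  # solved against old neighbour positions
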