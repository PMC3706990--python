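import numpy as np
import pytest

from isopure.optimizer import (
    AscentViolationError,
    OptimizerConfig,
    ParameterBlock,
    block_coordinate_ascent,
    multi_restart,
    pr_conjugate_gradient_maximize,
    softmax,
)


class TestConjugateGradient:
    def test_concave_quadratic_converges(self, rng):
        target = rng.uniform(-2, 2, size=6)

        def objective(v):
            diff = v - target
            return -float(diff @ diff), -2.0 * diff

        v, f = pr_conjugate_gradient_maximize(objective, np.zeros(6), max_steps=11)
        np.testing.assert_allclose(v, target, atol=1e-6)

    def test_start_at_maximizer_stays(self):
        def objective(v):
            return -float(v @ v), -2.0 * v

        v, f = pr_conjugate_gradient_maximize(objective, np.zeros(3), max_steps=10)
        np.testing.assert_array_equal(v, np.zeros(3))
        assert f == 0.0

    def test_negated_rosenbrock_improves(self):
        def objective(v):
            x, y = v
            f = -((1 - x) ** 2 + 100 * (y - x**2) ** 2)
            g = np.array(
                [2 * (1 - x) + 400 * x * (y - x**2), -200 * (y - x**2)]
            )
            return f, g

        start = np.array([-1.2, 1.0])
        f0 = objective(start)[0]
        v, f = pr_conjugate_gradient_maximize(objective, start, max_steps=200)
        assert f >= f0
        # the global maximum is 0 at (1, 1); a good CG run gets close
        assert f > -1.0

    def test_nonfinite_start_rejected(self):
        def objective(v):
            return float("-inf"), np.zeros_like(v)

        with pytest.raises(ValueError):
            pr_conjugate_gradient_maximize(objective, np.zeros(2), max_steps=5)


class TestTransforms:
    def test_simplex_softmax_valid(self, rng):
        b = ParameterBlock("p", rng.normal(size=(4, 5)), axis=1)
        p = b.constrained()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p > 0)

    def test_shifted_exp_respects_lower_bound(self, rng):
        b = ParameterBlock(
            "k",
            rng.normal(size=7) * 5,
            transform="shifted-exp-positive",
            lower_bound=3.5,
        )
        assert np.all(b.constrained() >= 3.5)

    def test_simplex_init_roundtrip(self, rng):
        p = rng.dirichlet(np.ones(6))
        b = ParameterBlock("p", ParameterBlock.simplex_init(p))
        np.testing.assert_allclose(b.constrained(), p, atol=1e-12)

    def test_positive_init_roundtrip(self):
        u = ParameterBlock.positive_init(np.array([4.0, 10.0]), 2.0)
        b = ParameterBlock(
            "k", u, transform="shifted-exp-positive", lower_bound=2.0
        )
        np.testing.assert_allclose(b.constrained(), [4.0, 10.0], atol=1e-12)

    @pytest.mark.parametrize("transform,lower", [("simplex-softmax", 0.0),
                                                 ("shifted-exp-positive", 1.5)])
    def test_chain_rule_matches_finite_differences(self, transform, lower, rng):
        """Gradient of a composed objective vs central finite differences."""
        u = rng.normal(size=5)
        b = ParameterBlock("b", u, transform=transform, lower_bound=lower)
        w = rng.normal(size=5)

        def composed(u_vec):
            value = b.constrain(u_vec)
            return float(w @ np.log(value)), b.chain_grad(value, w / value, u_vec)

        _, grad = composed(u)
        eps = 1e-6
        for i in range(5):
            e = np.zeros(5)
            e[i] = eps
            fd = (composed(u + e)[0] - composed(u - e)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestBlockCoordinateAscent:
    @staticmethod
    def _quadratic_blocks(targets):
        blocks = [
            ParameterBlock(
                name,
                np.zeros_like(t),
                transform="shifted-exp-positive",
                lower_bound=-100.0,
            )
            for name, t in targets.items()
        ]
        # shifted-exp from lower bound -100 acts as a smooth bijection onto
        # (-100, inf); the quadratic targets sit well inside
        for b in blocks:
            b.unconstrained = ParameterBlock.positive_init(
                np.zeros_like(b.unconstrained), -100.0
            )

        def objective(state, wrt=None):
            f = 0.0
            grads = {}
            for name, t in targets.items():
                diff = state[name] - t
                f -= float(diff @ diff)
                grads[name] = -2.0 * diff
            return f, (grads[wrt] if wrt else None)

        return blocks, objective

    def test_separable_blocks_solved_in_one_iteration(self, rng):
        targets = {"a": rng.uniform(-3, 3, 4), "b": rng.uniform(-3, 3, 3)}
        blocks, objective = self._quadratic_blocks(targets)
        config = OptimizerConfig(n_outer_iterations=1, n_restarts=1, rel_tol=0)
        state, trace = block_coordinate_ascent(blocks, objective, config)
        for name, t in targets.items():
            np.testing.assert_allclose(state[name], t, atol=1e-4)

    def test_trace_monotone_nondecreasing(self, rng):
        targets = {"a": rng.uniform(-3, 3, 4), "b": rng.uniform(-3, 3, 3)}
        blocks, objective = self._quadratic_blocks(targets)
        config = OptimizerConfig(n_outer_iterations=8, n_restarts=1, rel_tol=0)
        _, trace = block_coordinate_ascent(blocks, objective, config)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_coupled_blocks_reach_grid_search_optimum(self):
        """2-block, 1-D-each coupled concave objective vs a dense grid."""

        def value(a, b):
            return -(a - 1.0) ** 2 - (b + 0.5) ** 2 - 0.5 * a * b

        blocks = [
            ParameterBlock(
                "a",
                ParameterBlock.positive_init(np.array([0.0]), -100.0),
                transform="shifted-exp-positive",
                lower_bound=-100.0,
            ),
            ParameterBlock(
                "b",
                ParameterBlock.positive_init(np.array([0.0]), -100.0),
                transform="shifted-exp-positive",
                lower_bound=-100.0,
            ),
        ]

        def objective(state, wrt=None):
            a, b = float(state["a"][0]), float(state["b"][0])
            f = value(a, b)
            grads = {
                "a": np.array([-2.0 * (a - 1.0) - 0.5 * b]),
                "b": np.array([-2.0 * (b + 0.5) - 0.5 * a]),
            }
            return f, (grads[wrt] if wrt else None)

        config = OptimizerConfig(n_outer_iterations=30, n_restarts=1, rel_tol=0)
        state, trace = block_coordinate_ascent(blocks, objective, config)
        grid = np.linspace(-3, 3, 601)
        best = max(value(a, b) for a in grid for b in grid)
        assert trace[-1] >= best - 1e-4

    def test_ascent_violation_raises(self):
        calls = {"n": 0}

        blocks = [
            ParameterBlock(
                "a",
                np.zeros(1),
                transform="shifted-exp-positive",
                lower_bound=-10.0,
            )
        ]

        def adversarial(state, wrt=None):
            # full-state evaluations (wrt None) decrease over time while
            # block evaluations pretend everything is fine
            if wrt is None:
                calls["n"] += 1
                return -float(calls["n"]), None
            return 0.0, np.zeros(1)

        config = OptimizerConfig(n_outer_iterations=3, n_restarts=1, rel_tol=0)
        with pytest.raises(AscentViolationError):
            block_coordinate_ascent(blocks, adversarial, config)


class TestMultiRestart:
    def test_single_restart_identity(self):
        state, objs = multi_restart(lambda s: ({"seed": s}, -1.0), 1, seed=9)
        assert objs.tolist() == [-1.0]

    def test_argmax_selection(self):
        outcomes = iter([-5.0, -3.0, -4.0])

        def fit(_seed):
            val = next(outcomes)
            return val, val

        state, objs = multi_restart(fit, 3, seed=0)
        assert state == -3.0
        np.testing.assert_array_equal(objs, [-5.0, -3.0, -4.0])

    def test_deterministic_under_master_seed(self):
        def fit(seed):
            rng = np.random.default_rng(seed)
            return rng.standard_normal(4), float(rng.standard_normal())

        s1, o1 = multi_restart(fit, 4, seed=77)
        s2, o2 = multi_restart(fit, 4, seed=77)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(o1, o2)

    def test_partial_failures_tolerated_total_failure_raises(self):
        def flaky(seed):
            if seed % 2 == 0:
                raise RuntimeError("boom")
            return seed, float(seed)

        state, objs = multi_restart(flaky, 6, seed=3)
        assert np.isfinite(objs).any()

        def broken(_seed):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="all restarts failed"):
            multi_restart(broken, 3, seed=3)


def test_softmax_rows_are_distributions(rng):
    u = rng.normal(scale=30, size=(5, 7))
    p = softmax(u, axis=1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(p >= 0)
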