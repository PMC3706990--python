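import numpy as np
import pytest

from isopure import (
    OptimizerConfig,
    ValidationError,
    discretize_tumors,
    generate_dataset,
    implied_normal_profile,
    normalize_panel,
    step1_fit,
    step2_fit,
)
from isopure.step2 import Step2Model


@pytest.fixture(scope="module")
def fitted(small_truth_module):
    truth, config = small_truth_module
    counts = discretize_tumors(truth.tumors)
    panel = normalize_panel(truth.normals)
    s1 = step1_fit(counts, panel, config)
    s2 = step2_fit(counts, panel, s1, "reference", config)
    return truth, counts, panel, s1, s2


@pytest.fixture(scope="module")
def small_truth_module():
    truth = generate_dataset(G=120, N=5, R=3, depth=100_000, seed=11)
    config = OptimizerConfig(n_outer_iterations=25, n_restarts=2, seed=5)
    return truth, config


class TestStep2Fit:
    def test_profiles_on_simplex(self, fitted):
        *_, s2 = fitted
        np.testing.assert_allclose(s2.c.sum(axis=0), 1.0, atol=1e-10)
        assert np.all(s2.c > 0)

    def test_strength_bound_respected(self, fitted):
        *_, s1, s2 = fitted
        assert np.all(s2.k >= 1.0 / s1.m.min())

    def test_alpha_and_m_frozen_from_stage1(self, fitted):
        *_, s1, s2 = fitted
        np.testing.assert_array_equal(s2.theta[:, -1], s1.alpha)
        np.testing.assert_array_equal(s2.m, s1.m)

    def test_trace_monotone(self, fitted):
        *_, s2 = fitted
        assert np.all(np.diff(s2.trace) >= -1e-9)

    def test_reconstruction_fits_training_data(self, fitted):
        truth, counts, panel, s1, s2 = fitted
        theta_free = s2.theta[:, :-1]
        xhat = panel.B @ theta_free.T + s2.c * s2.alpha[None, :]
        empirical = counts.counts / counts.totals[None, :]
        for n in range(truth.tumors.n_samples):
            assert np.corrcoef(xhat[:, n], empirical[:, n])[0, 1] >= 0.99

    def test_pure_cancer_sample_matches_empirical_frequencies(self):
        """Without contamination the fitted profile must explain the
        counts: it matches the empirical frequencies almost exactly."""
        config = OptimizerConfig(n_restarts=3, seed=5)
        truth = generate_dataset(
            G=500, N=4, R=3, depth=100_000, alpha_range=(1.0, 1.0), seed=6
        )
        counts = discretize_tumors(truth.tumors)
        panel = normalize_panel(truth.normals)
        s1 = step1_fit(counts, panel, config)
        s2 = step2_fit(counts, panel, s1, "reference", config)
        empirical = counts.counts / counts.totals[None, :]
        for n in range(4):
            assert np.corrcoef(s2.c[:, n], empirical[:, n])[0, 1] >= 0.99

    def test_purification_beats_raw_profiles(self, fitted):
        truth, counts, *_ , s2 = fitted
        raw = truth.tumors.values / truth.tumors.values.sum(axis=0)
        corr_fit = np.mean(
            [
                np.corrcoef(s2.c[:, n], truth.true_c[:, n])[0, 1]
                for n in range(truth.tumors.n_samples)
            ]
        )
        corr_raw = np.mean(
            [
                np.corrcoef(raw[:, n], truth.true_c[:, n])[0, 1]
                for n in range(truth.tumors.n_samples)
            ]
        )
        assert corr_fit > corr_raw

    def test_shrinkage_toward_reference_increases_with_strength(self, fitted):
        """With k_n clamped at growing values, fitted profiles move toward
        the reference profile (the prior mean)."""
        truth, counts, panel, s1, _ = fitted
        from isopure.step2 import _make_objective
        from isopure.densities import dirichlet_log_pdf

        config = OptimizerConfig(n_outer_iterations=12, n_restarts=1, seed=5)
        distances = []
        for k_fixed in (1e3, 1e4, 1e6):
            model = _fit_with_fixed_k(counts, panel, s1, k_fixed, config)
            distances.append(
                np.abs(model.c - s1.m[:, None]).sum(axis=0).mean()
            )
        assert distances[0] >= distances[1] >= distances[2]

    def test_evenprior_bound_is_dimension(self, fitted):
        truth, counts, panel, s1, _ = fitted
        config = OptimizerConfig(n_outer_iterations=10, n_restarts=1, seed=5)
        s2e = step2_fit(counts, panel, s1, "evenprior", config)
        G = counts.counts.shape[0]
        assert np.all(s2e.k >= G)
        assert s2e.prior_mode == "evenprior"

    def test_dimension_mismatch_rejected(self, fitted):
        truth, counts, panel, s1, _ = fitted
        with pytest.raises(ValidationError):
            step2_fit(counts.counts[:, :3], panel, s1)

    def test_invalid_prior_mode(self, fitted):
        truth, counts, panel, s1, _ = fitted
        with pytest.raises(ValueError):
            step2_fit(counts, panel, s1, prior_mode="flat")


def _fit_with_fixed_k(counts, panel, s1, k_fixed, config):
    """Refit stage 2 with the strength block pinned (sweep helper)."""
    from isopure.optimizer import ParameterBlock, block_coordinate_ascent
    from isopure.step2 import _initial_blocks, _make_objective
    from isopure.densities import dirichlet_log_pdf

    X = counts.counts
    B = panel.B
    G, N = X.shape
    R = B.shape[1]
    alpha = s1.alpha.copy()
    prior_mean = s1.m.copy()
    dir_m_const = dirichlet_log_pdf(s1.m, s1.k_prime * (B @ s1.omega))
    objective, factory = _make_objective(X, B, alpha, prior_mean, dir_m_const)
    rng = np.random.default_rng(config.seed)
    k_lower = 1.0 / prior_mean.min()
    k_init = max(k_fixed, 1.01 * k_lower)
    blocks = _initial_blocks(
        X, R, alpha, prior_mean, s1.theta, k_lower, "reference", rng, True
    )
    blocks = [b for b in blocks if b.name != "k"]
    pinned = ParameterBlock(
        "k",
        ParameterBlock.positive_init(np.full(N, k_init), k_init - 1e-9),
        transform="shifted-exp-positive",
        lower_bound=k_init - 1e-9,
    )

    def pinned_factory(name, state):
        if name == "k":
            def fn(k_new, need_grad):
                # flat in k: the block stays where it started
                return 0.0, (np.zeros_like(k_new) if need_grad else None)
            return fn
        return factory(name, state)

    state, trace = block_coordinate_ascent(
        blocks + [pinned], objective, config, block_objective_factory=pinned_factory
    )
    theta = np.empty((N, R + 1))
    theta[:, :R] = (1.0 - alpha)[:, None] * state["theta_frac"]
    theta[:, R] = alpha
    return Step2Model(
        c=state["c"],
        k=state["k"],
        theta=theta,
        nu=state["nu"],
        prior_mode="reference",
        m=s1.m.copy(),
        log_likelihood=float(trace[-1]),
        restart_objectives=np.array([trace[-1]]),
        trace=trace,
    )


def _with_theta_row(s2, row, values):
    model = Step2Model(
        c=s2.c, k=s2.k, theta=s2.theta.copy(), nu=s2.nu,
        prior_mode=s2.prior_mode, m=s2.m, log_likelihood=0.0,
        restart_objectives=np.array([0.0]), trace=np.array([0.0]),
    )
    model.theta[row] = values
    return model


class TestImpliedNormalProfile:
    def test_single_component(self, fitted):
        _, _, panel, _, s2 = fitted
        R = panel.n_profiles
        row = np.zeros(R + 1)
        row[0], row[R] = 0.4, 0.6
        model = _with_theta_row(s2, 0, row)
        h = implied_normal_profile(model, panel, 0)
        np.testing.assert_allclose(h, panel.B[:, 0], atol=1e-12)

    def test_equal_mix_of_two_normals(self, fitted):
        _, _, panel, _, s2 = fitted
        R = panel.n_profiles
        row = np.zeros(R + 1)
        row[0] = row[1] = 0.25
        row[R] = 0.5
        model = _with_theta_row(s2, 1, row)
        h = implied_normal_profile(model, panel, 1)
        np.testing.assert_allclose(
            h, 0.5 * (panel.B[:, 0] + panel.B[:, 1]), atol=1e-12
        )

    def test_sums_to_one(self, fitted):
        _, _, panel, _, s2 = fitted
        for n in range(s2.theta.shape[0]):
            h = implied_normal_profile(s2, panel, n)
            assert h.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pure_tumor_rejected(self, fitted):
        _, _, panel, _, s2 = fitted
        R = panel.n_profiles
        row = np.zeros(R + 1)
        row[R] = 1.0
        model = _with_theta_row(s2, 0, row)
        with pytest.raises(ValueError):
            implied_normal_profile(model, panel, 0)
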