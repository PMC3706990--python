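"""First fitting stage: tumor purities and the reference cancer profile.

With every tumor-specific cancer profile pinned to the shared reference
profile ``m`` (the infinite-strength limit of the per-sample prior), MAP
estimation reduces to maximizing

    log Dir(m | k' B omega)
    + sum_n [ log Dir(theta_n | nu) + log Mult(x_n | B theta_n[:R] + alpha_n m) ]

over the blocks theta (all samples jointly), m, omega, k' and nu.  The
purity ``alpha_n`` is the last component of ``theta_n``.  The strength
``k'`` is kept above ``1 / min B`` so the Dirichlet prior on ``m`` never
assigns infinite density as a component of ``m`` approaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .optimizer import (
    OptimizerConfig,
    ParameterBlock,
    block_coordinate_ascent,
    multi_restart,
)
from .profiles_io import NormalPanel, ValidationError

__all__ = ["Step1Model", "step1_fit", "mixture_proportion_profiles"]

# Every Dirichlet concentration in the model is kept >= 1 so the MAP
# objective stays bounded as simplex parameters approach the boundary:
# the strength bounds on k' and k_n do this for m and c_n, and this
# lower bound does it for the mixing-weight prior nu.
NU_LOWER = 1.0

_TINY = 1e-300  # guards log/division against softmax underflow to exact 0


@dataclass
class Step1Model:
    """Fitted purities, mixing weights and hyper-parameters."""

    m: np.ndarray            # reference cancer profile, length G, sums to 1
    theta: np.ndarray        # N x (R+1); last column is alpha
    nu: np.ndarray           # length R+1, positive
    k_prime: float           # >= 1 / min(B)
    omega: np.ndarray        # length R, sums to 1
    log_likelihood: float
    restart_objectives: np.ndarray
    trace: np.ndarray        # per-outer-iteration log-likelihood of the winner

    @property
    def alpha(self) -> np.ndarray:
        """Tumor purity per sample: fraction of mRNA from cancer cells."""
        return self.theta[:, -1]

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]


def _unpack_inputs(x, B):
    counts = np.asarray(getattr(x, "counts", x), dtype=float)
    if isinstance(B, NormalPanel):
        Bmat, min_entry = B.B, B.min_entry
    else:
        Bmat = np.asarray(B, dtype=float)
        min_entry = float(Bmat.min())
    if counts.ndim != 2 or Bmat.ndim != 2:
        raise ValidationError("counts and panel must be 2-D")
    if counts.shape[0] != Bmat.shape[0]:
        raise ValidationError(
            f"counts have {counts.shape[0]} transcripts, panel has {Bmat.shape[0]}"
        )
    if counts.shape[0] < 2:
        raise ValidationError("need at least 2 transcripts")
    if np.all(counts.sum(axis=0) == 0):
        raise ValidationError("every sample has zero total counts")
    if min_entry <= 0:
        raise ValidationError("panel entries must be strictly positive")
    return counts, Bmat, min_entry


def _dirichlet_sum(nu: np.ndarray, log_theta_colsum: np.ndarray, n: int) -> float:
    """Sum over samples of log Dir(theta_n | nu), up to the log-theta part."""
    return float(
        n * (gammaln(nu.sum()) - gammaln(nu).sum())
        + ((nu - 1.0) * log_theta_colsum).sum()
    )


def _make_objective(X: np.ndarray, B: np.ndarray):
    """Stage-1 complete log-likelihood and fast per-block objectives.

    Returns ``(objective, factory)``: ``objective(state, None)`` gives
    the full log-likelihood for the ascent trace; ``factory(name,
    state)`` builds a per-block callable that evaluates only the terms
    depending on that block (the omitted terms are constants, so ascent
    of the partial objective is ascent of the full one) with invariants
    precomputed once per block visit.
    """
    G, N = X.shape
    R = B.shape[1]
    totals = X.sum(axis=0)
    mult_const = float(gammaln(totals + 1.0).sum() - gammaln(X + 1.0).sum())

    def dir_m_value(m_log, kp, omega):
        a_m = kp * (B @ omega)
        return float(
            gammaln(a_m.sum()) - gammaln(a_m).sum() + ((a_m - 1.0) * m_log).sum()
        )

    def objective(s, wrt=None):
        theta, m, omega, nu = s["theta"], s["m"], s["omega"], s["nu"]
        kp = float(s["k_prime"][0])
        alpha = theta[:, R]
        xhat = np.maximum(B @ theta[:, :R].T + np.outer(m, alpha), _TINY)
        log_theta = np.log(np.maximum(theta, _TINY))
        log_m = np.log(np.maximum(m, _TINY))
        f = (
            mult_const
            + float((X * np.log(xhat)).sum())
            + _dirichlet_sum(nu, log_theta.sum(axis=0), N)
            + dir_m_value(log_m, kp, omega)
        )
        return f, None

    def factory(name, s):
        theta, m, omega, nu = s["theta"], s["m"], s["omega"], s["nu"]
        kp = float(s["k_prime"][0])

        if name == "theta":
            nu_free, nu_alpha = nu[:R], nu[R]

            def fn(th, need_grad):
                alpha = th[:, R]
                xhat = np.maximum(B @ th[:, :R].T + np.outer(m, alpha), _TINY)
                th_safe = np.maximum(th, _TINY)
                f = float((X * np.log(xhat)).sum()) + _dirichlet_sum(
                    nu, np.log(th_safe).sum(axis=0), N
                )
                if not need_grad:
                    return f, None
                W = X / xhat
                g = np.empty_like(th)
                g[:, :R] = W.T @ B + (nu_free - 1.0) / th_safe[:, :R]
                g[:, R] = W.T @ m + (nu_alpha - 1.0) / th_safe[:, R]
                return f, g

            return fn

        if name == "m":
            Bth = B @ theta[:, :R].T        # fixed while m moves
            alpha = theta[:, R]
            a_m = kp * (B @ omega)
            a_m1 = a_m - 1.0

            def fn(m_new, need_grad):
                m_safe = np.maximum(m_new, _TINY)
                xhat = np.maximum(Bth + np.outer(m_new, alpha), _TINY)
                f = float((X * np.log(xhat)).sum()) + float(
                    (a_m1 * np.log(m_safe)).sum()
                )
                if not need_grad:
                    return f, None
                g = a_m1 / m_safe + (X / xhat) @ alpha
                return f, g

            return fn

        if name == "omega":
            log_m = np.log(np.maximum(m, _TINY))

            def fn(om, need_grad):
                a_m = kp * (B @ om)
                f = float(
                    gammaln(a_m.sum()) - gammaln(a_m).sum() + ((a_m - 1.0) * log_m).sum()
                )
                if not need_grad:
                    return f, None
                dmean = digamma(a_m.sum()) - digamma(a_m) + log_m
                return f, kp * (B.T @ dmean)

            return fn

        if name == "k_prime":
            mu = B @ omega
            log_m = np.log(np.maximum(m, _TINY))
            mu_logm = float((mu * log_m).sum())

            def fn(kp_new, need_grad):
                k = float(kp_new[0])
                a_m = k * mu
                f = float(
                    gammaln(a_m.sum()) - gammaln(a_m).sum() + ((a_m - 1.0) * log_m).sum()
                )
                if not need_grad:
                    return f, None
                grad = float(
                    digamma(a_m.sum()) - (mu * digamma(a_m)).sum() + mu_logm
                )
                return f, np.array([grad])

            return fn

        if name == "nu":
            colsum = np.log(np.maximum(theta, _TINY)).sum(axis=0)

            def fn(nu_new, need_grad):
                f = _dirichlet_sum(nu_new, colsum, N)
                if not need_grad:
                    return f, None
                g = N * (digamma(nu_new.sum()) - digamma(nu_new)) + colsum
                return f, g

            return fn

        raise KeyError(name)

    return objective, factory


def _initial_blocks(X, B, kp_lower, rng):
    G, N = X.shape
    R = B.shape[1]
    theta0 = rng.dirichlet(np.ones(R + 1), size=N)
    # normalized mean count column, 1% multiplicative jitter
    m0 = X.sum(axis=1) + 0.5
    m0 = m0 / m0.sum()
    m0 = m0 * (1.0 + 0.01 * rng.standard_normal(G))
    m0 = np.maximum(m0, 1e-12)
    m0 = m0 / m0.sum()
    return [
        ParameterBlock("theta", ParameterBlock.simplex_init(theta0, axis=1), axis=1),
        ParameterBlock("m", ParameterBlock.simplex_init(m0)),
        ParameterBlock("omega", ParameterBlock.simplex_init(np.full(R, 1.0 / R))),
        ParameterBlock(
            "k_prime",
            ParameterBlock.positive_init(np.array([10.0 * kp_lower]), kp_lower),
            transform="shifted-exp-positive",
            lower_bound=kp_lower,
        ),
        ParameterBlock(
            "nu",
            ParameterBlock.positive_init(np.full(R + 1, 2.0), NU_LOWER),
            transform="shifted-exp-positive",
            lower_bound=NU_LOWER,
        ),
    ]


def step1_fit(x, B, config: OptimizerConfig | None = None) -> Step1Model:
    """MAP fit of purities, mixing weights and hyper-parameters.

    Parameters
    ----------
    x : CountProfiles or (G, N) integer array
        Discretized tumor profiles.
    B : NormalPanel or (G, R) array
        Column-normalized healthy panel, strictly positive.
    config : OptimizerConfig, optional
        Protocol settings (35 outer iterations, 10 restarts by default).

    The best of ``config.n_restarts`` randomized fits (by final complete
    log-likelihood) is returned.
    """
    config = config or OptimizerConfig()
    X, Bmat, min_entry = _unpack_inputs(x, B)
    kp_lower = 1.0 / min_entry
    objective, factory = _make_objective(X, Bmat)

    def fit_once(seed):
        rng = np.random.default_rng(seed)
        blocks = _initial_blocks(X, Bmat, kp_lower, rng)
        state, trace = block_coordinate_ascent(
            blocks, objective, config, block_objective_factory=factory
        )
        return (state, trace), float(trace[-1])

    (state, trace), objectives = multi_restart(
        fit_once, config.n_restarts, config.seed
    )
    return Step1Model(
        m=state["m"],
        theta=state["theta"],
        nu=state["nu"],
        k_prime=float(state["k_prime"][0]),
        omega=state["omega"],
        log_likelihood=float(np.max(objectives)),
        restart_objectives=objectives,
        trace=trace,
    )


def mixture_proportion_profiles(model: Step1Model) -> np.ndarray:
    """Per-sample mixture-proportion feature rows (theta_1..theta_R, alpha).

    These R+1 numbers per sample are the only profile-specific output a
    purity-only deconvolution provides, and serve as the
    matrix-factorization baseline feature set.
    """
    return model.theta.copy()
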