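"""Second fitting stage: per-tumor cancer profiles.

Purities ``alpha_n`` and the reference profile ``m`` are frozen at their
stage-1 estimates.  Each tumor then receives its own cancer profile
``c_n`` under a Dirichlet prior ``Dir(c_n | k_n mu)`` whose mean ``mu``
is either the reference profile ``m`` (the clustered-profile assumption
that drives the method) or the uniform vector ``1/G`` (the "even prior"
ablation, which keeps the same purity estimates but drops the clustering
assumption).  The mixing weights over the healthy panel are
re-apportioned — the normal mass ``1 - alpha_n`` is fixed, but its split
across the R panel profiles is re-estimated — and the Dirichlet
concentration ``nu`` over the mixing weights is refreshed.

The per-sample strengths ``k_n`` are kept above ``1 / min(mu)`` so the
prior density stays bounded as components of ``c_n`` approach zero.
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
from .profiles_io import ValidationError
from .step1 import NU_LOWER, _TINY, Step1Model, _unpack_inputs

__all__ = ["Step2Model", "step2_fit", "implied_normal_profile"]

PRIOR_MODES = ("reference", "evenprior")


@dataclass
class Step2Model:
    """Per-tumor cancer profiles and refreshed mixture parameters."""

    c: np.ndarray            # G x N, each column on the simplex
    k: np.ndarray            # length N, k[n] >= 1 / min(prior mean)
    theta: np.ndarray        # N x (R+1); last column frozen at stage-1 alpha
    nu: np.ndarray           # length R+1, re-estimated
    prior_mode: str          # "reference" or "evenprior"
    m: np.ndarray            # stage-1 reference profile (frozen)
    log_likelihood: float
    restart_objectives: np.ndarray
    trace: np.ndarray

    @property
    def alpha(self) -> np.ndarray:
        return self.theta[:, -1]


def _make_objective(X, B, alpha, prior_mean, dir_m_const):
    """Stage-2 complete log-likelihood and fast per-block objectives.

    Same contract as the stage-1 builder: the full objective feeds the
    ascent trace, and the factory builds per-block callables carrying
    only the block-dependent terms with per-visit precomputation.
    """
    G, N = X.shape
    R = B.shape[1]
    frac = 1.0 - alpha                      # normal mass per sample, > 0
    log_alpha_sum = float(np.log(alpha).sum())
    totals = X.sum(axis=0)
    mult_const = float(gammaln(totals + 1.0).sum() - gammaln(X + 1.0).sum())
    p = prior_mean

    def dir_c_value(A, a_sum, log_c):
        return float(
            gammaln(a_sum).sum() - gammaln(A).sum() + ((A - 1.0) * log_c).sum()
        )

    def theta_prior_value(nu, log_theta_free_colsum):
        return float(
            N * (gammaln(nu.sum()) - gammaln(nu).sum())
            + ((nu[:R] - 1.0) * log_theta_free_colsum).sum()
            + (nu[R] - 1.0) * log_alpha_sum
        )

    def objective(s, wrt=None):
        c, theta_frac, k, nu = s["c"], s["theta_frac"], s["k"], s["nu"]
        theta_free = frac[:, None] * theta_frac      # N x R
        xhat = np.maximum(B @ theta_free.T + c * alpha[None, :], _TINY)
        log_c = np.log(np.maximum(c, _TINY))
        log_theta_free = np.log(np.maximum(theta_free, _TINY))
        A = p[:, None] * k[None, :]                  # G x N prior concentrations
        f = (
            dir_m_const
            + mult_const
            + float((X * np.log(xhat)).sum())
            + theta_prior_value(nu, log_theta_free.sum(axis=0))
            + dir_c_value(A, A.sum(axis=0), log_c)
        )
        return f, None

    def factory(name, s):
        c, theta_frac, k, nu = s["c"], s["theta_frac"], s["k"], s["nu"]

        if name == "c":
            theta_free = frac[:, None] * theta_frac
            Bth = B @ theta_free.T          # fixed while c moves
            A = p[:, None] * k[None, :]
            A1 = A - 1.0
            a_sum_term = float(gammaln(A.sum(axis=0)).sum() - gammaln(A).sum())

            def fn(c_new, need_grad):
                c_safe = np.maximum(c_new, _TINY)
                xhat = np.maximum(Bth + c_new * alpha[None, :], _TINY)
                f = float((X * np.log(xhat)).sum()) + a_sum_term + float(
                    (A1 * np.log(c_safe)).sum()
                )
                if not need_grad:
                    return f, None
                g = A1 / c_safe + (X / xhat) * alpha[None, :]
                return f, g

            return fn

        if name == "theta_frac":
            calpha = c * alpha[None, :]     # fixed while theta moves
            nu_free = nu[:R]

            def fn(tf, need_grad):
                theta_free = frac[:, None] * tf
                tf_safe = np.maximum(theta_free, _TINY)
                xhat = np.maximum(B @ theta_free.T + calpha, _TINY)
                f = float((X * np.log(xhat)).sum()) + float(
                    ((nu_free - 1.0) * np.log(tf_safe).sum(axis=0)).sum()
                )
                if not need_grad:
                    return f, None
                W = X / xhat
                g_free = W.T @ B + (nu_free - 1.0) / tf_safe
                return f, frac[:, None] * g_free

            return fn

        if name == "k":
            log_c = np.log(np.maximum(c, _TINY))
            p_logc = (p[:, None] * log_c).sum(axis=0)    # length N

            def fn(k_new, need_grad):
                A = p[:, None] * k_new[None, :]
                a_sum = A.sum(axis=0)
                f = dir_c_value(A, a_sum, log_c)
                if not need_grad:
                    return f, None
                g = (
                    digamma(a_sum)
                    - (p[:, None] * digamma(A)).sum(axis=0)
                    + p_logc
                )
                return f, g

            return fn

        if name == "nu":
            theta_free = frac[:, None] * theta_frac
            colsum = np.log(np.maximum(theta_free, _TINY)).sum(axis=0)

            def fn(nu_new, need_grad):
                f = theta_prior_value(nu_new, colsum)
                if not need_grad:
                    return f, None
                g = N * (digamma(nu_new.sum()) - digamma(nu_new))
                g[:R] += colsum
                g[R] += log_alpha_sum
                return f, g

            return fn

        raise KeyError(name)

    return objective, factory


def _initial_blocks(X, R, alpha, prior_mean, step1_theta, k_lower, mode, rng, first):
    G, N = X.shape
    # c always starts at the smoothed empirical count frequencies: starting
    # it at the prior mean would let the strength block race up the
    # degenerate ridge (k_n -> inf with c_n pinned at the mean, where the
    # joint density is unbounded) before the data can pull c_n away.
    if first:
        free = np.maximum(step1_theta[:, :R], 1e-12)
        theta_frac0 = free / free.sum(axis=1, keepdims=True)
        c0 = X + 0.5
    else:
        theta_frac0 = rng.dirichlet(np.ones(R), size=N)
        c0 = (X + 0.5) * np.exp(0.05 * rng.standard_normal((G, N)))
    c0 = c0 / c0.sum(axis=0, keepdims=True)
    return [
        ParameterBlock("c", ParameterBlock.simplex_init(c0, axis=0), axis=0),
        ParameterBlock(
            "theta_frac", ParameterBlock.simplex_init(theta_frac0, axis=1), axis=1
        ),
        ParameterBlock(
            "k",
            ParameterBlock.positive_init(np.full(N, 10.0 * k_lower), k_lower),
            transform="shifted-exp-positive",
            lower_bound=k_lower,
        ),
        ParameterBlock(
            "nu",
            ParameterBlock.positive_init(np.full(R + 1, 2.0), NU_LOWER),
            transform="shifted-exp-positive",
            lower_bound=NU_LOWER,
        ),
    ]


def step2_fit(
    x,
    B,
    step1: Step1Model,
    prior_mode: str = "reference",
    config: OptimizerConfig | None = None,
) -> Step2Model:
    """MAP fit of per-tumor cancer profiles with stage-1 purities frozen.

    ``prior_mode="reference"`` centers the Dirichlet prior on each
    ``c_n`` at the stage-1 reference profile ``m``; ``"evenprior"``
    centers it at the uniform vector instead (same purities, no
    clustering assumption), for the ablation comparison.
    """
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
    config = config or OptimizerConfig()
    X, Bmat, _ = _unpack_inputs(x, B)
    G, N = X.shape
    R = Bmat.shape[1]
    if step1.theta.shape != (N, R + 1) or step1.m.size != G:
        raise ValidationError(
            "stage-1 model dimensions do not match the supplied counts/panel"
        )
    # stage-1 purities come from a softmax and are interior by
    # construction, but can saturate to float 0/1 for extreme samples;
    # clip so the frozen mixing weights keep a sliver of the other
    # component and every log stays finite
    alpha = np.clip(step1.alpha, 1e-12, 1.0 - 1e-9)

    if prior_mode == "reference":
        prior_mean = step1.m.copy()
    else:
        prior_mean = np.full(G, 1.0 / G)
    k_lower = 1.0 / float(prior_mean.min())

    # the Dirichlet factor on m is constant in this stage but kept in the
    # objective so traces remain complete log-likelihoods
    from .densities import dirichlet_log_pdf

    dir_m_const = dirichlet_log_pdf(step1.m, step1.k_prime * (Bmat @ step1.omega))

    objective, factory = _make_objective(X, Bmat, alpha, prior_mean, dir_m_const)
    first_seen = {"flag": True}

    def fit_once(seed):
        rng = np.random.default_rng(seed)
        first = first_seen["flag"]
        first_seen["flag"] = False
        blocks = _initial_blocks(
            X, R, alpha, prior_mean, step1.theta, k_lower, prior_mode, rng, first
        )
        state, trace = block_coordinate_ascent(
            blocks, objective, config, block_objective_factory=factory
        )
        return (state, trace), float(trace[-1])

    (state, trace), objectives = multi_restart(fit_once, config.n_restarts, config.seed)
    theta = np.empty((N, R + 1))
    theta[:, :R] = (1.0 - alpha)[:, None] * state["theta_frac"]
    theta[:, R] = alpha
    return Step2Model(
        c=state["c"],
        k=state["k"],
        theta=theta,
        nu=state["nu"],
        prior_mode=prior_mode,
        m=step1.m.copy(),
        log_likelihood=float(np.max(objectives)),
        restart_objectives=objectives,
        trace=trace,
    )


def implied_normal_profile(model: Step2Model, B, n: int) -> np.ndarray:
    """Estimated contaminating-normal profile ``h_n`` for sample ``n``.

    ``h_n = (sum_r theta_{n,r} b_r) / (1 - alpha_n)`` — the convex
    combination of panel profiles implied by the fitted mixing weights,
    renormalized to the simplex.  Undefined when the sample has no
    normal component.
    """
    Bmat = np.asarray(getattr(B, "B", B), dtype=float)
    R = Bmat.shape[1]
    alpha_n = float(model.theta[n, R])
    if alpha_n >= 1.0:
        raise ValueError(f"sample {n} has purity 1: no normal component to report")
    return (Bmat @ model.theta[n, :R]) / (1.0 - alpha_n)
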