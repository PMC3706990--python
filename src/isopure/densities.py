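"""Exact log-densities of the deconvolution model.

The model treats each discretized bulk tumor profile ``x_n`` (a vector of
G transcript counts) as one multinomial draw whose probability vector is
a convex mixture of R column-normalized healthy-tissue profiles
``b_1..b_R`` and a tumor-specific cancer profile ``c_n``::

    xhat_n = sum_r theta_{n,r} * b_r + alpha_n * c_n

where ``theta_n`` is a point on the (R+1)-simplex whose last component is
the tumor purity ``alpha_n``.  Dirichlet priors regularize the estimate:
``theta_n ~ Dir(nu)``, each cancer profile ``c_n ~ Dir(k_n * m)`` around a
shared reference cancer profile ``m``, and ``m ~ Dir(k' * B @ omega)``,
tying the reference profile toward the span of the healthy panel ``B``.

Everything is evaluated in log space via log-gamma so that profiles with
totals on the order of 1e7 counts are handled without overflow.  The
first fitting stage pins every ``c_n`` to ``m`` (the limit of infinite
prior strength ``k_n``), in which case the per-sample cancer-profile
prior factors are omitted from the complete likelihood rather than
evaluated as degenerate Dirichlets.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "dirichlet_log_pdf",
    "multinomial_log_pmf",
    "reconstruct_profile",
    "complete_log_likelihood",
]

_SIMPLEX_ATOL = 1e-6


def _as_1d(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {x.shape}")
    return x


def dirichlet_log_pdf(x, a) -> float:
    """Log of the Dirichlet density Dir(x | a) on the simplex.

    Parameters
    ----------
    x : array-like
        Point on the simplex (non-negative, sums to 1).
    a : array-like
        Concentration vector; every component must be strictly positive.

    Returns
    -------
    float
        ``log Gamma(sum a) - sum log Gamma(a_k) + sum (a_k - 1) log x_k``.
        Returns ``-inf`` when some ``x_k = 0`` with ``a_k > 1`` (density
        zero) and ``+inf`` when some ``x_k = 0`` with ``a_k < 1`` (density
        diverges at the boundary).
    """
    x = _as_1d(x, "x")
    a = _as_1d(a, "a")
    if x.shape != a.shape:
        raise ValueError(f"length mismatch: x has {x.size}, a has {a.size}")
    if np.any(a <= 0.0):
        raise ValueError("Dirichlet concentration parameters must be > 0")
    if np.any(x < 0.0) or abs(x.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ValueError("x must be non-negative and sum to 1")
    norm = gammaln(a.sum()) - gammaln(a).sum()
    zero = x == 0.0
    if np.any(zero):
        az = a[zero]
        if np.any(az > 1.0):
            return float("-inf")
        if np.any(az < 1.0):
            return float("inf")
        # a_k == 1 at x_k == 0 contributes x^0 = 1
        x = x[~zero]
        a = a[~zero]
    return float(norm + ((a - 1.0) * np.log(x)).sum())


def multinomial_log_pmf(y, pi) -> float:
    """Log of the multinomial mass Mult(y | pi) via log-gamma factorials.

    Components with ``y_k = 0`` contribute nothing regardless of
    ``pi_k``; a positive count on a zero-probability category yields
    ``-inf``.
    """
    y = np.asarray(y)
    pi = _as_1d(pi, "pi")
    if y.shape != pi.shape:
        raise ValueError(f"length mismatch: y has {y.size}, pi has {pi.size}")
    yf = np.asarray(y, dtype=float)
    if np.any(yf < 0) or np.any(yf != np.round(yf)):
        raise ValueError("counts must be non-negative integers")
    if np.any(pi < 0.0) or abs(pi.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ValueError("pi must be non-negative and sum to 1")
    norm = gammaln(yf.sum() + 1.0) - gammaln(yf + 1.0).sum()
    pos = yf > 0
    if np.any(pi[pos] == 0.0):
        return float("-inf")
    return float(norm + (yf[pos] * np.log(pi[pos])).sum())


def reconstruct_profile(B, c_n, theta_n) -> np.ndarray:
    """Mixture reconstruction ``xhat_n = sum_r theta_r b_r + alpha c_n``.

    ``theta_n`` has length R+1; its last component is the purity
    ``alpha_n``.  ``B`` may be a G x R array or any object with a ``B``
    attribute holding one (e.g. a normalized panel).  The output lies on
    the simplex by convexity.
    """
    B = np.asarray(getattr(B, "B", B), dtype=float)
    c_n = _as_1d(c_n, "c_n")
    theta_n = _as_1d(theta_n, "theta_n")
    G, R = B.shape
    if c_n.size != G:
        raise ValueError(f"c_n has length {c_n.size}, expected {G}")
    if theta_n.size != R + 1:
        raise ValueError(f"theta_n has length {theta_n.size}, expected R+1={R + 1}")
    return B @ theta_n[:R] + theta_n[R] * c_n


def complete_log_likelihood(
    x,
    B,
    *,
    m,
    theta,
    nu,
    k_prime,
    omega,
    c=None,
    k=None,
    c_prior_mean=None,
) -> float:
    """Complete log-likelihood of the Dirichlet-multinomial mixture.

    ``log Dir(m | k' B omega) + sum_n [log Dir(c_n | k_n mu_c)
    + log Dir(theta_n | nu) + log Mult(x_n | xhat_n)]``
    where ``mu_c`` defaults to ``m`` (the clustered-profile prior) and may
    be overridden (e.g. the uniform vector for the even-prior variant).

    When ``c`` is ``None`` the fit is in its first stage: every cancer
    profile equals ``m`` and the per-sample Dirichlet factors on ``c_n``
    are omitted (infinite prior strength), so only the remaining three
    kinds of terms are summed.

    ``-inf`` values propagate; they are never silently replaced.
    """
    counts = np.asarray(getattr(x, "counts", x), dtype=float)
    B = np.asarray(getattr(B, "B", B), dtype=float)
    m = _as_1d(m, "m")
    theta = np.asarray(theta, dtype=float)
    nu = _as_1d(nu, "nu")
    omega = _as_1d(omega, "omega")
    G, N = counts.shape
    R = B.shape[1]
    if theta.shape != (N, R + 1):
        raise ValueError(f"theta must be {(N, R + 1)}, got {theta.shape}")

    total = dirichlet_log_pdf(m, float(k_prime) * (B @ omega))
    if c is not None:
        c = np.asarray(c, dtype=float)
        k = _as_1d(k, "k")
        mu_c = m if c_prior_mean is None else _as_1d(c_prior_mean, "c_prior_mean")
        for n in range(N):
            total += dirichlet_log_pdf(c[:, n], k[n] * mu_c)
    for n in range(N):
        total += dirichlet_log_pdf(theta[n], nu)
        c_n = m if c is None else c[:, n]
        xhat = reconstruct_profile(B, c_n, theta[n])
        total += multinomial_log_pmf(counts[:, n], xhat)
    return float(total)
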