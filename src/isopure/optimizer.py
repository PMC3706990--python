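"""Block-coordinate ascent with Polak-Ribiere conjugate-gradient steps.

The complete likelihood is maximized over several parameter blocks
(mixing weights, profiles, Dirichlet strengths).  Each block lives on a
constrained set — a simplex, or a half-line ``[lower_bound, inf)`` — and
is reparameterized through an unconstrained vector: softmax for simplex
blocks, ``lower_bound + exp(u)`` for positive/bounded scalars.  One outer
iteration optimizes every block in turn with the others held fixed,
using nonlinear conjugate gradient (Polak-Ribiere direction with reset to
steepest ascent, backtracking Armijo line search) on the block's
unconstrained coordinates.  The full objective is evaluated after each
outer iteration; the resulting trace must be non-decreasing, and a
decrease beyond numerical slack is treated as a bug, not a warning.

Multiple random restarts guard against poor local maxima: restart seeds
are derived deterministically from a master seed and the restart with the
highest final objective wins (ties to the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterBlock",
    "OptimizerConfig",
    "AscentViolationError",
    "softmax",
    "simplex_chain_grad",
    "pr_conjugate_gradient_maximize",
    "block_coordinate_ascent",
    "multi_restart",
]

ASCENT_SLACK = 1e-9


class AscentViolationError(RuntimeError):
    """The objective decreased across an outer iteration: a bug trap."""


@dataclass
class OptimizerConfig:
    """Protocol knobs for the MAP fit.

    Defaults follow the method's published protocol: 35 outer iterations
    of block coordinate ascent, 10 random restarts, and a relative
    log-likelihood change of 1e-8 as the convergence tolerance.
    """

    n_outer_iterations: int = 35
    n_restarts: int = 10
    rel_tol: float = 1e-8
    cg_max_steps_per_block: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_outer_iterations < 1 or self.n_restarts < 1:
            raise ValueError("iteration and restart counts must be >= 1")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")


def softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    z = u - u.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def simplex_chain_grad(p: np.ndarray, grad_p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Pull a gradient w.r.t. simplex coordinates back through softmax."""
    inner = (p * grad_p).sum(axis=axis, keepdims=True)
    return p * (grad_p - inner)


@dataclass
class ParameterBlock:
    """One constrained parameter group and its unconstrained coordinates.

    ``transform`` is ``"simplex-softmax"`` (rows/columns along ``axis``
    map through softmax onto the simplex; the gauge freedom is fixed by
    anchoring the first unconstrained coordinate along ``axis`` at 0) or
    ``"shifted-exp-positive"`` (``lower_bound + exp(u)``, a hard
    reparameterized bound).
    """

    name: str
    unconstrained: np.ndarray
    transform: str = "simplex-softmax"
    axis: int = -1
    lower_bound: float | np.ndarray = 0.0
    upper_cap: float | None = None

    def __post_init__(self):
        self.unconstrained = np.asarray(self.unconstrained, dtype=float).copy()
        if self.transform not in ("simplex-softmax", "shifted-exp-positive"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "shifted-exp-positive" and self.upper_cap is None:
            # soft numerical cap: a Dirichlet strength this far above its
            # bound is indistinguishable from a point mass, while its
            # log-gamma terms grow large enough that cancellation noise in
            # the objective would swamp the ascent bookkeeping
            self.upper_cap = max(1e6, 100.0 * float(np.max(self.lower_bound)))
        self.anchor()

    def _u_cap(self):
        return np.log(self.upper_cap - self.lower_bound)

    def constrain(self, u: np.ndarray) -> np.ndarray:
        if self.transform == "simplex-softmax":
            return softmax(u, axis=self.axis)
        return self.lower_bound + np.exp(np.minimum(u, self._u_cap()))

    def constrained(self) -> np.ndarray:
        return self.constrain(self.unconstrained)

    def chain_grad(self, value: np.ndarray, grad_value: np.ndarray, u: np.ndarray):
        """Gradient w.r.t. ``u`` given the gradient w.r.t. the constrained value."""
        if self.transform == "simplex-softmax":
            return simplex_chain_grad(value, grad_value, axis=self.axis)
        g = grad_value * (value - self.lower_bound)
        return np.where(u < self._u_cap(), g, np.minimum(g, 0.0))

    def anchor(self) -> None:
        if self.transform == "simplex-softmax":
            first = np.take(self.unconstrained, [0], axis=self.axis)
            self.unconstrained = self.unconstrained - first

    @staticmethod
    def simplex_init(p: np.ndarray, axis: int = -1, floor: float = 1e-12) -> np.ndarray:
        """Unconstrained coordinates whose softmax reproduces ``p``."""
        p = np.maximum(np.asarray(p, dtype=float), floor)
        u = np.log(p)
        return u - np.take(u, [0], axis=axis)

    @staticmethod
    def positive_init(value, lower_bound) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        gap = value - lower_bound
        if np.any(gap <= 0):
            raise ValueError("initial value must exceed the lower bound")
        return np.log(gap)


_GOLDEN = 0.381966011250105  # 2 - golden ratio


def _line_search(value_of, v, d, f0, slope, t0, armijo_c, shrink, max_shrinks):
    """Find an acceptable step along ``d`` and refine it.

    Backtracks until the Armijo sufficient-increase condition holds, then
    expands while the objective keeps improving and polishes the step by
    a short golden-section search.  The refinement matters: a bare
    backtracking search makes negligible progress along the
    ill-conditioned directions that arise when simplex components
    approach the boundary or panel profiles are nearly collinear.
    ``value_of`` evaluates the objective value only.
    """
    t = t0
    hit = None
    for _ in range(max_shrinks):
        f_try = value_of(v + t * d)
        if np.isfinite(f_try) and f_try >= f0 + armijo_c * t * slope:
            hit = (t, f_try)
            break
        t *= shrink
    if hit is None:
        return None
    t_best, f_best = hit
    # expansion: keep doubling while it helps
    t_hi = t_best
    for _ in range(40):
        t_next = 2.0 * t_hi
        f_next = value_of(v + t_next * d)
        t_hi = t_next
        if np.isfinite(f_next) and f_next > f_best:
            t_best, f_best = t_next, f_next
        else:
            break
    # golden-section polish on the bracket [t_best/2, t_hi]
    lo, hi = 0.5 * t_best, t_hi
    for _ in range(8):
        if t_best <= 0.5 * (lo + hi):
            t_try = lo + _GOLDEN * (hi - lo)
        else:
            t_try = hi - _GOLDEN * (hi - lo)
        f_try = value_of(v + t_try * d)
        if np.isfinite(f_try) and f_try > f_best:
            if t_try < t_best:
                hi = t_best
            else:
                lo = t_best
            t_best, f_best = t_try, f_try
        else:
            if t_try < t_best:
                lo = t_try
            else:
                hi = t_try
        if hi - lo <= 1e-3 * t_best:
            break
    return t_best, v + t_best * d, f_best


def _pr_cg(
    objective,
    start,
    max_steps: int,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    max_shrinks: int = 60,
    initial_step: float | None = None,
    prev_pair: tuple[np.ndarray, np.ndarray] | None = None,
):
    """CG core; returns ``(point, value, last_accepted_step, (g, d))``.

    ``objective(v, need_grad)`` returns ``(value, grad_or_None)``; line
    searches probe with values only and the gradient is computed once at
    each accepted point.  ``prev_pair`` carries the (gradient,
    direction) memory from the last call on the same subproblem, so
    conjugacy survives across outer block-coordinate iterations instead
    of restarting from steepest ascent every cycle — without it,
    ill-conditioned blocks (for instance mixing weights over nearly
    collinear panel profiles) crawl.
    """
    v = np.asarray(start, dtype=float).ravel().copy()
    f, g = objective(v, True)
    if not np.isfinite(f):
        raise ValueError("objective is not finite at the starting point")

    def value_of(w):
        # probes may overflow transforms (exp) far along a direction; the
        # resulting non-finite values are rejected by the line search
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return objective(w, False)[0]

    d = g.copy()
    if prev_pair is not None:
        g_old, d_old = prev_pair
        if g_old.shape == g.shape:
            beta0 = float(g @ (g - g_old)) / max(float(g_old @ g_old), 1e-300)
            if np.isfinite(beta0) and beta0 > 0.0:
                cand = g + beta0 * d_old
                if float(cand @ g) > 0.0:
                    d = cand
    t_prev = initial_step
    for _ in range(int(max_steps)):
        slope = float(d @ g)
        if not np.isfinite(slope) or slope <= 0.0:
            d = g.copy()
            slope = float(g @ g)
        if slope < 1e-300:
            break
        dinf = float(np.max(np.abs(d)))
        t0 = min(1.0, 1.0 / dinf) if t_prev is None else 2.0 * t_prev
        hit = _line_search(value_of, v, d, f, slope, t0, armijo_c, shrink, max_shrinks)
        if hit is None and not np.array_equal(d, g):
            # retry once along steepest ascent
            d = g.copy()
            slope = float(g @ g)
            if slope < 1e-300:
                break
            t0 = min(1.0, 1.0 / float(np.max(np.abs(d))))
            hit = _line_search(
                value_of, v, d, f, slope, t0, armijo_c, shrink, max_shrinks
            )
        if hit is None:
            break
        t_prev, v_new, f_new = hit
        g_new = objective(v_new, True)[1]
        beta = float(g_new @ (g_new - g)) / max(float(g @ g), 1e-300)
        if not np.isfinite(beta) or beta < 0.0:
            beta = 0.0
        improvement = f_new - f
        v, f, g = v_new, f_new, g_new
        d = g + beta * d
        if improvement <= 1e-15 * (1.0 + abs(f)):
            break
    return v, f, t_prev, (g, d)


def pr_conjugate_gradient_maximize(
    objective,
    start,
    max_steps: int,
    armijo_c: float = 1e-4,
    shrink: float = 0.5,
    max_shrinks: int = 60,
):
    """Maximize ``objective`` (returning ``(value, gradient)``) from ``start``.

    Polak-Ribiere directions with reset to steepest ascent whenever the
    beta goes negative or the direction stops being an ascent direction;
    a backtracking Armijo line search guarantees monotone non-decrease.
    Returns ``(point, value)`` with ``value >= objective(start)``.
    """

    def adapted(v, need_grad):
        return objective(v)

    v, f, _, _ = _pr_cg(adapted, start, max_steps, armijo_c, shrink, max_shrinks)
    return v, f


def block_coordinate_ascent(
    blocks, objective, config: OptimizerConfig, block_objective_factory=None
):
    """Cycle through the parameter blocks, maximizing each in turn.

    ``objective(state, wrt)`` receives a dict mapping block names to
    constrained values and must return ``(full_value, grad)`` where
    ``grad`` is the gradient w.r.t. the constrained value of block
    ``wrt`` (or ``None`` when ``wrt`` is ``None``).

    ``block_objective_factory(name, state)``, when given, returns a
    faster per-block callable ``fn(value, need_grad) -> (partial_value,
    grad_or_None)`` that may drop terms constant in that block and
    precompute invariants once per block visit; maximizing the partial
    objective raises the full objective by exactly the same amount, so
    monotone ascent of the trace is preserved.

    Returns ``(state, trace)``; ``trace[i]`` is the full objective after
    outer iteration ``i``.  The trace must be non-decreasing (slack
    1e-9); stops early when the relative change drops below
    ``config.rel_tol`` (0 disables early stopping).
    """
    state = {b.name: b.constrained() for b in blocks}
    f_prev, _ = objective(state, None)
    if not np.isfinite(f_prev):
        raise ValueError("objective is not finite at the initial state")
    trace = []
    step_memory: dict[str, float | None] = {b.name: None for b in blocks}
    dir_memory: dict[str, tuple | None] = {b.name: None for b in blocks}
    for _ in range(config.n_outer_iterations):
        for b in blocks:
            shape = b.unconstrained.shape
            if block_objective_factory is not None:
                fn = block_objective_factory(b.name, state)

                def block_objective(u_flat, need_grad, _b=b, _shape=shape, _fn=fn):
                    u = u_flat.reshape(_shape)
                    value = _b.constrain(u)
                    f, grad_c = _fn(value, need_grad)
                    if not need_grad or not np.isfinite(f):
                        return f, None
                    return f, _b.chain_grad(value, grad_c, u).ravel()

            else:

                def block_objective(u_flat, need_grad, _b=b, _shape=shape):
                    u = u_flat.reshape(_shape)
                    value = _b.constrain(u)
                    st = dict(state)
                    st[_b.name] = value
                    f, grad_c = objective(st, _b.name)
                    if not need_grad or not np.isfinite(f):
                        return f, None
                    return f, _b.chain_grad(value, grad_c, u).ravel()

            u_new, _, t_last, gd_pair = _pr_cg(
                block_objective,
                b.unconstrained.ravel(),
                config.cg_max_steps_per_block,
                initial_step=step_memory[b.name],
                prev_pair=dir_memory[b.name],
            )
            step_memory[b.name] = t_last
            dir_memory[b.name] = gd_pair
            # gauge anchoring waits until the end of the run: re-anchoring
            # here would perturb softmax values by float rounding and could
            # nudge the objective below its line-search-certified value
            b.unconstrained = u_new.reshape(shape)
            state[b.name] = b.constrained()
        f_it, _ = objective(state, None)
        # bug trap: per-block line searches certify non-decrease, so a real
        # drop (inconsistent gradient/objective) is orders of magnitude
        # larger than the cancellation noise of the log-gamma sums, which
        # can reach ~1e-7 when a Dirichlet strength sits near its cap
        slack = max(1e-6, 1e-12 * abs(f_prev))
        if f_it < f_prev - slack:
            raise AscentViolationError(
                f"objective decreased from {f_prev:.12g} to {f_it:.12g}"
            )
        trace.append(f_it)
        if config.rel_tol > 0:
            denom = max(abs(f_prev), 1e-300)
            if abs(f_it - f_prev) / denom < config.rel_tol:
                f_prev = f_it
                break
        f_prev = f_it
    for b in blocks:
        b.anchor()
    return state, np.asarray(trace)


def restart_seeds(master_seed: int, n_restarts: int) -> list[int]:
    """Deterministic child seeds (each < 2**31) from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_restarts)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def multi_restart(fit_once, n_restarts: int, seed: int):
    """Run ``fit_once(seed) -> (state, final_objective)`` from several seeds.

    Returns ``(best_state, objectives)`` where ``objectives`` has one
    entry per restart (``-inf`` for a failed restart).  The restart with
    the highest objective wins; ties go to the lowest index.  If every
    restart fails, the individual causes are aggregated into one error.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    states, objectives, errors = [], [], []
    for i, child in enumerate(restart_seeds(seed, n_restarts)):
        try:
            st, obj = fit_once(child)
        except Exception as exc:  # noqa: BLE001 — aggregated below
            states.append(None)
            objectives.append(float("-inf"))
            errors.append(f"restart {i} (seed {child}): {exc!r}")
            continue
        states.append(st)
        objectives.append(float(obj))
    objectives = np.asarray(objectives)
    if not np.any(np.isfinite(objectives)):
        raise RuntimeError("all restarts failed: " + "; ".join(errors))
    best = int(np.argmax(objectives))
    return states[best], objectives
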