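# Methods

## The model

A bulk tumor expression profile mixes mRNA from cancerous cells with
mRNA from contaminating healthy tissue. Given N tumor profiles
t_1..t_N (non-negative, linear scale, G transcripts each) and a panel of
R healthy-tissue profiles, the package decomposes each tumor into a
tumor-specific cancer profile and a combination of the healthy profiles,
and estimates the fraction of each sample's mRNA contributed by cancer
cells (the tumor purity α_n).

Each tumor profile is discretized by rounding to integer counts x_n and
treated as one multinomial draw:

    x_n ~ Multinomial(S_n, x̂_n),      x̂_n = Σ_r θ_{n,r} b_r + α_n c_n

where b_1..b_R are the panel profiles normalized to sum to one, c_n is
the cancer profile of sample n (a point on the G-simplex), and the
mixing weights θ_n = (θ_{n,1..R}, α_n) lie on the (R+1)-simplex. Three
Dirichlet factors regularize the fit:

    θ_n ~ Dir(ν)                     mixing-weight prior, ν estimated
    c_n ~ Dir(k_n · m)               per-tumor profiles cluster around a
                                     reference cancer profile m
    m   ~ Dir(k' · B ω)              the reference profile is tied toward
                                     the span of the healthy panel

All parameters and hyper-parameters (θ, c, m, ν, ω, k', k_n) are
estimated by maximizing the complete likelihood (MAP) in two stages:

* **Stage 1** pins every c_n to m (the infinite-k_n limit; the
  corresponding Dirichlet factors are omitted rather than evaluated as
  degenerate densities) and estimates purities α_n, mixing weights,
  m, ν, ω, k'.
* **Stage 2** freezes α_n and m at their stage-1 values and estimates
  the per-tumor profiles c_n with strengths k_n, re-apportioning the
  normal mass 1−α_n across the panel and refreshing ν.

The *even-prior* ablation replaces the stage-2 prior mean m with the
uniform vector 1/G while keeping the stage-1 purities, isolating the
contribution of the clustered-profile assumption.

Purified profiles are reported on the original measurement scale by
multiplying c_n by the sample total S_n = Σ_g t_{n,g}.

### Boundedness of the MAP objective

A Dirichlet density with any concentration component below 1 diverges
as the corresponding simplex coordinate approaches 0, which makes the
MAP objective unbounded and lets the optimizer run parameters into the
boundary. The strength bounds k' ≥ 1/min(B) and k_n ≥ 1/min(prior
mean) guarantee every concentration on m and c_n is at least 1; the
same requirement applied to the mixing-weight prior gives the lower
bound ν ≥ 1 (component-wise) used here. Without it, the exact
likelihood ridge that trades normal content between m and the mixing
weights is resolved by the boundary divergence and every purity slides
to 1.

## Optimization

Block coordinate ascent cycles once per outer iteration through the
parameter blocks (stage 1: θ → m → ω → k' → ν; stage 2: c → θ → k → ν),
each optimized by nonlinear conjugate gradient with the Polak-Ribière
direction (reset to steepest ascent when the direction stops being an
ascent direction) on unconstrained coordinates:

* simplex blocks through a row/column softmax (gauge fixed by anchoring
  the first coordinate at 0 when a fit is returned);
* positive/bounded scalars through lower_bound + exp(·), making the
  strength bounds hard.

The line search backtracks to an Armijo sufficient-increase point, then
expands and polishes the step by a short golden-section search. Two
details matter for convergence at small problem sizes, where the
published tolerance (relative log-likelihood change < 1e-8 within 35
outer iterations) is roughly two orders of magnitude harsher in absolute
log-units than at cohort scale (|log L| ~ 1e5 here versus ~1e10 for
profiles with 1e7-count totals): the near-exact line search, and
carrying each block's gradient/direction pair across outer iterations so
conjugacy is not reset to steepest ascent every cycle. Both are needed
for ill-conditioned blocks — mixing weights over nearly collinear panel
profiles — to settle rather than crawl.

Per-block objectives drop terms constant in the block and precompute
invariants once per block visit; since the omitted terms are constants,
ascent of the partial objective is ascent of the complete likelihood,
which is evaluated once per outer iteration for the trace. A decrease
of the trace beyond 1e-9 raises an error rather than a warning.

Defaults follow the published protocol: 35 outer iterations, 10 random
restarts (seeds derived deterministically from a master seed; best final
likelihood wins, ties to the lowest index), relative tolerance 1e-8,
and up to 400 conjugate-gradient steps per block per visit.

Initialization: stage 1 draws θ rows from a flat Dirichlet, starts m at
the normalized mean count column with 1% multiplicative jitter, ω
uniform, ν at 2 (just above its bound), k' at 10× its bound. Stage 2
starts every c_n at the smoothed empirical count frequencies — starting
at the prior mean is degenerate, because with c_n exactly at the mean
the density grows without bound in k_n and the strength block pins the
profiles to m before the data can act — with k_n at 10× its bound and
the mixing fractions carried over from stage 1 (restarts beyond the
first redraw them and jitter c_n).

Numerical guards: softmax outputs that underflow to exact 0 are floored
at 1e-300 inside logs and gradient denominators; non-finite line-search
probes are treated as rejected steps; frozen stage-2 purities are
clipped to [1e-12, 1−1e-9] because a stage-1 softmax can saturate to
float 1.0 for a near-pure sample. Dirichlet strengths carry a soft
upper cap, max(1e6, 100 × lower bound): in tight-clustering regimes the
joint MAP over (c_n, k_n) is genuinely unbounded (the density at the
prior mean grows without limit in k_n), and beyond the cap the prior is
numerically a point mass while its log-gamma terms become large enough
that cancellation noise would swamp the ascent bookkeeping.

## The synthetic-data generator

The generator draws data from exactly the structure the model assumes:
a base tissue profile (flat Dirichlet, concentration 10 per component),
panel columns and the true reference cancer profile around it
(Dirichlet, concentration_b × base), per-tumor cancer profiles around
the reference (Dirichlet, concentration_c × reference), purities uniform
on [0.3, 0.9] by default (or supplied explicitly, so pure-normal decoys
can be embedded in a cohort), normal mass split by a flat Dirichlet, and
multinomial sampling at a chosen depth.

Parameter anchors, chosen once:

* **depth = 1e5** per sample keeps a full two-step fit at desk scale in
  seconds-to-minutes; real discretized profiles total ~1e7.
* **concentration_c = 1e3**: the invariant preserved when scaling depth
  down is the ratio of per-gene biological variance to multinomial
  sampling variance (~100× in real cohorts), not the concentration
  itself. Matching instead the pairwise correlation of real tumor
  profiles would put the desk-scale problem in a noise-dominated regime
  that real data never occupies — and in which joint MAP over (c_n,
  k_n) degenerates (see below).
* **concentration_b = 5e3**: cancer-vs-normal and normal-vs-normal
  separation intermediate between two failure extremes observed in a
  systematic sweep — a panel very distinct from the cancer profile
  strengthens the reference-profile prior's pull along the likelihood
  ridge (purities inflate), while a nearly collinear panel makes the
  mixture ill-conditioned.
* **detection floor 0.1/G**: profiles never report an exact zero
  (array background), and the floor keeps 1/min(B) — the lower bound on
  k' — small relative to the total count mass, the regime real cohorts
  operate in.

A `misspecified` switch draws each cancer profile around its own
independent center, violating the clustering assumption for stress
tests; `corrupt_panel` drops panel columns and applies multiplicative
log-normal noise for robustness experiments.

What the generator does *not* emulate: platform-specific noise (probe
effects, background correction, normalization artifacts), subtype
structure, or correlated gene modules. Passing recovery tests on these
data shows the estimator works when its own assumptions hold; it says
nothing about robustness to the ways real arrays violate them.

## Regimes and what each experiment shows

Two quantities behave oppositely in the two clustering regimes, and the
test suite is explicit about which regime each check runs in:

* **Purity and profile recovery against raw profiles** are evaluated at
  the default (realistically dispersed) conditions, depth 1e5, where
  normal contamination is the dominant error in the raw profiles and
  purification must remove it.
* **All-genes variance reduction and the even-prior ablation ordering**
  are evaluated on tightly clustered truth (concentration_c = 2e4) at
  depth 1e4. Shrinkage toward the reference profile is what produces
  the variance reduction, and it pays off exactly when sampling noise
  exceeds the biological deviations (roughly, noise variance > 2×
  deviation variance). On dispersed truth at high depth the comparison
  reverses by design: contamination by a shared normal profile *dilutes*
  inter-tumor variance, so correct purification raises the per-gene
  variance of most genes, and the uniform-mean prior (≈ additive
  pseudo-counts, which leave Pearson correlation with the truth nearly
  unchanged) is not harmful there.

Known biases, reproduced deliberately rather than patched: stage-1
purities are systematically somewhat high (the reference-profile prior
pulls m toward the healthy span along an exact likelihood ridge, and
profile deviations aligned with the panel span are misattributed to
contamination), so rank agreement is tighter than absolute agreement;
and stage-2 strengths k_n overshoot the true clustering concentration
(the joint MAP has no marginalization to temper the k–c feedback),
over-shrinking profiles when data are abundant.

## Baselines

The subtraction (Clarke-style) baseline pairs each tumor with its most
rank-correlated panel profile (Spearman; ties to the lowest index) and
solves c_n = (t_n − (1−α_n) b_f(n)) / α_n on the measurement scale,
clamping negative entries at 0 (count logged). The purity it needs is
supplied by the caller or defaults to the stage-1 estimates; the
knee-finding purity estimator of the original method is out of scope.
The matrix-factorization baseline is the stage-1 mixture-proportion
rows (θ_{n,1..R}, α_n) exported as an (R+1)-feature table.

## Limitations

* One reference profile: cohorts with strong subtypes violate the
  clustered-c_n assumption (the `misspecified` generator switch probes
  this).
* No intra-tumor heterogeneity: one cancer profile per sample.
* Joint MAP, not inference: no uncertainties on α or c, and the k_n
  overshoot noted above.
* The multinomial treats all residual noise as sampling noise; platform
  noise is not modeled.
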