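"""Synthetic mixed-tumor data with known ground truth.

The generator draws data from exactly the statistical structure the
deconvolution model assumes: a healthy-tissue panel of R profiles, a
reference cancer profile, per-tumor cancer profiles clustered around the
reference, per-tumor purities, and multinomial sampling noise::

    x_n ~ Multinomial(depth, alpha_n * c_n + sum_r theta_{n,r} * b_r)

All simplex draws are Dirichlet.  Profiles that play the role of
measured tissue (the panel columns, the base tissue profile and the
reference cancer profile) are given a small detection floor before
renormalization — mirroring the fact that array/RNA measurements never
report an exact zero — which also keeps the Dirichlet strength bounds
``1 / min B`` at a realistic magnitude.

A ``misspecified`` switch draws the per-tumor cancer profiles around
independent random centers instead of the shared reference, violating
the clustering assumption for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles_io import ExpressionMatrix

__all__ = ["SyntheticTruth", "generate_dataset", "corrupt_panel"]

# Relative detection floor: entries below this multiple of 1/G are raised.
# Besides emulating array background (a measured profile never reports an
# exact zero), the floor keeps 1/min(B) — the lower bound on the Dirichlet
# strength k' of the reference-profile prior — small relative to the total
# count mass, the regime real cohorts (totals ~1e7 per sample) operate in.
DETECTION_FLOOR_REL = 0.1


@dataclass
class SyntheticTruth:
    """A generated dataset bundled with the parameters that produced it."""

    tumors: ExpressionMatrix        # mixed counts, G x N
    normals: ExpressionMatrix       # panel on a linear count scale, G x R
    true_alpha: np.ndarray          # length N
    true_theta: np.ndarray          # N x (R+1), last column alpha
    true_c: np.ndarray              # G x N simplex columns
    true_m: np.ndarray              # length G simplex
    gen_config: dict = field(default_factory=dict)


def _floored_simplex(draw: np.ndarray, G: int) -> np.ndarray:
    floored = np.maximum(draw, DETECTION_FLOOR_REL / G)
    return floored / floored.sum()


def generate_dataset(
    G: int,
    N: int,
    R: int,
    depth: int,
    alpha_range: tuple[float, float] = (0.3, 0.9),
    concentration_c: float = 1_000.0,
    concentration_b: float = 5_000.0,
    seed: int = 0,
    misspecified: bool = False,
    base_concentration: float = 10.0,
    alpha=None,
) -> SyntheticTruth:
    """Draw a mixed tumor cohort with known purity and constituent profiles.

    Parameters
    ----------
    G, N, R : int
        Transcripts, tumor samples, healthy-panel profiles.
    depth : int
        Total multinomial count per tumor column (~1e7 for real arrays;
        1e5 is a fast desk-scale default in the tests).
    alpha_range : (lo, hi)
        Purities are drawn uniformly on this interval.  ``(1, 1)`` gives
        pure cancer, ``(0, 0)`` pure normal.
    concentration_c : float
        Dirichlet strength clustering the per-tumor cancer profiles
        around the reference profile; larger = tighter clustering.  The
        default keeps the ratio of biological dispersion to multinomial
        sampling noise at roughly its real-cohort value (per-gene prior
        variance ~100x the sampling variance at the default depth,
        mirroring biological variability on arrays with ~1e7-count
        totals); this ratio, not the raw concentration, is the invariant
        that survives scaling the depth down for desk-size experiments.
    concentration_b : float
        Dirichlet strength tying panel columns (and the reference cancer
        profile) to the base tissue profile; controls biological
        replicate variability of the healthy panel.
    misspecified : bool
        Draw each cancer profile around its own independent center,
        breaking the clustered-profile assumption.
    alpha : array-like, optional
        Explicit per-sample purities (length N), overriding
        ``alpha_range``.  Lets a cohort include pure-normal decoys
        (``alpha=0``) alongside real mixtures, the design of blinded
        cellularity controls.
    """
    if G < 2 or N < 1 or R < 1 or depth < 1:
        raise ValueError("require G >= 2, N >= 1, R >= 1, depth >= 1")
    lo, hi = alpha_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("alpha_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)

    base = _floored_simplex(rng.dirichlet(np.full(G, base_concentration)), G)
    B = np.column_stack(
        [
            _floored_simplex(rng.dirichlet(concentration_b * base), G)
            for _ in range(R)
        ]
    )
    true_m = _floored_simplex(rng.dirichlet(concentration_b * base), G)

    if misspecified:
        centers = [
            _floored_simplex(rng.dirichlet(concentration_b * base), G)
            for _ in range(N)
        ]
        true_c = np.column_stack(
            [rng.dirichlet(concentration_c * ctr) for ctr in centers]
        )
    else:
        true_c = rng.dirichlet(concentration_c * true_m, size=N).T

    if alpha is not None:
        true_alpha = np.asarray(alpha, dtype=float)
        if true_alpha.shape != (N,) or np.any((true_alpha < 0) | (true_alpha > 1)):
            raise ValueError("alpha must be a length-N vector in [0, 1]")
        true_alpha = true_alpha.copy()
    else:
        true_alpha = rng.uniform(lo, hi, size=N)
    true_theta = np.empty((N, R + 1))
    true_theta[:, :R] = (1.0 - true_alpha)[:, None] * rng.dirichlet(
        np.ones(R), size=N
    )
    true_theta[:, R] = true_alpha

    xhat = B @ true_theta[:, :R].T + true_c * true_alpha[None, :]
    counts = np.column_stack(
        [rng.multinomial(int(depth), xhat[:, n]) for n in range(N)]
    ).astype(float)

    transcript_ids = [f"g{i + 1}" for i in range(G)]
    tumors = ExpressionMatrix(
        counts, transcript_ids, [f"tumor{n + 1}" for n in range(N)]
    )
    normals = ExpressionMatrix(
        B * float(depth), list(transcript_ids), [f"normal{r + 1}" for r in range(R)]
    )
    return SyntheticTruth(
        tumors=tumors,
        normals=normals,
        true_alpha=true_alpha,
        true_theta=true_theta,
        true_c=true_c,
        true_m=true_m,
        gen_config={
            "G": G,
            "N": N,
            "R": R,
            "depth": int(depth),
            "alpha_range": [float(lo), float(hi)],
            "concentration_c": float(concentration_c),
            "concentration_b": float(concentration_b),
            "base_concentration": float(base_concentration),
            "misspecified": bool(misspecified),
            "alpha_overridden": alpha is not None,
            "seed": int(seed),
        },
    )


def corrupt_panel(
    truth: SyntheticTruth,
    drop_normals: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Degrade the healthy panel while leaving the ground truth untouched.

    Removes ``drop_normals`` randomly chosen panel columns and applies
    multiplicative log-normal noise (``exp(noise_sd * z)``) to the rest,
    emulating an incomplete or noisier reference panel for robustness
    experiments.
    """
    R = truth.normals.n_samples
    if drop_normals < 0 or drop_normals >= R:
        raise ValueError("must keep at least one panel column")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(R, size=R - drop_normals, replace=False))
    V = truth.normals.values[:, keep]
    if noise_sd > 0:
        V = V * np.exp(noise_sd * rng.standard_normal(V.shape))
    normals = ExpressionMatrix(
        V,
        list(truth.normals.transcript_ids),
        [truth.normals.sample_ids[j] for j in keep],
    )
    cfg = dict(truth.gen_config)
    cfg.update(
        {"drop_normals": int(drop_normals), "noise_sd": float(noise_sd),
         "corrupt_seed": int(seed)}
    )
    return SyntheticTruth(
        tumors=truth.tumors,
        normals=normals,
        true_alpha=truth.true_alpha,
        true_theta=truth.true_theta,
        true_c=truth.true_c,
        true_m=truth.true_m,
        gen_config=cfg,
    )
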