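"""Comparison methods: per-tumor subtraction purification and
mixture-proportion features.

The subtraction baseline (Clarke-style) pairs each tumor with its most
similar healthy profile by Spearman rank correlation, then solves the
two-component mixture algebraically on the measurement scale:

    c_n = (t_n - (1 - alpha_n) * b_f(n)) / alpha_n

given a purity ``alpha_n``.  Unlike the probabilistic fit it applies no
regularization, so negative entries can appear and are clamped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles_io import ValidationError, rescale_cancer_profiles

__all__ = [
    "ClarkeResult",
    "match_normals_spearman",
    "clarke_purify",
    "export_feature_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ClarkeResult:
    """Purified profiles from the per-tumor subtraction baseline."""

    c: np.ndarray               # G x N, linear scale, clamped at 0
    matched_index: np.ndarray   # 0-based panel index f(n) per sample
    alpha: np.ndarray           # purity used per sample, in (0, 1]
    n_clamped: np.ndarray       # negative entries zeroed, per sample


def _columns(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def match_normals_spearman(tumors, normals) -> np.ndarray:
    """Index of the most rank-correlated healthy profile per tumor.

    Ties break to the lowest panel index.  A constant column has no
    defined rank correlation and raises an error naming the sample.
    """
    T = _columns(tumors)
    Bn = _columns(normals)
    if T.shape[0] != Bn.shape[0]:
        raise ValidationError("tumors and normals must be gene-aligned")
    for mat, obj, kind in ((T, tumors, "tumor"), (Bn, normals, "normal")):
        spans = mat.max(axis=0) - mat.min(axis=0)
        if np.any(spans == 0):
            j = int(np.argmin(spans))
            ids = getattr(obj, "sample_ids", None)
            name = ids[j] if ids else str(j)
            raise ValidationError(
                f"{kind} profile {name!r} is constant; rank correlation undefined"
            )
    # Spearman = Pearson on (average) ranks
    rT = np.apply_along_axis(rankdata, 0, T)
    rB = np.apply_along_axis(rankdata, 0, Bn)
    rT = rT - rT.mean(axis=0, keepdims=True)
    rB = rB - rB.mean(axis=0, keepdims=True)
    num = rT.T @ rB
    denom = np.outer(
        np.sqrt((rT**2).sum(axis=0)), np.sqrt((rB**2).sum(axis=0))
    )
    rho = num / denom
    return np.argmax(rho, axis=1)


def clarke_purify(
    tumors, normals, alpha, clamp_negative: bool = True
) -> ClarkeResult:
    """Algebraic subtraction purification on the measurement scale.

    ``normals`` must be un-normalized and on the same scale as the
    tumors.  Entries made negative by the subtraction are clamped to 0
    (logged per sample) unless ``clamp_negative=False``.
    """
    T = _columns(tumors)
    Bn = _columns(normals)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (T.shape[1],):
        raise ValidationError("alpha must have one entry per tumor sample")
    if np.any(alpha <= 0.0) or np.any(alpha > 1.0):
        raise ValidationError("alpha values must lie in (0, 1]")
    matched = match_normals_spearman(tumors, normals)
    c = (T - (1.0 - alpha)[None, :] * Bn[:, matched]) / alpha[None, :]
    n_clamped = (c < 0).sum(axis=0)
    if clamp_negative:
        if np.any(n_clamped):
            logger.info(
                "clarke_purify: clamped %d negative entries across %d samples",
                int(n_clamped.sum()),
                int((n_clamped > 0).sum()),
            )
        c = np.maximum(c, 0.0)
    return ClarkeResult(
        c=c, matched_index=matched, alpha=alpha, n_clamped=np.asarray(n_clamped)
    )


def export_feature_table(
    source: str,
    *,
    step1=None,
    step2=None,
    clarke=None,
    totals=None,
    transcript_ids=None,
    sample_ids=None,
) -> pd.DataFrame:
    """Samples x features table for a downstream learner.

    ``source`` selects the feature set:

    - ``"isopure-profiles"``: rescaled per-tumor cancer profiles (G
      columns); requires ``step2`` and ``totals``.
    - ``"clarke-profiles"``: clamped subtraction profiles (G columns);
      requires ``clarke``.
    - ``"mixture-proportions"``: stage-1 mixing weights and purity
      (R+1 columns); requires ``step1``.

    Row order always equals the input sample order.
    """
    if source == "mixture-proportions":
        if step1 is None:
            raise ValueError("mixture-proportions requires a fitted stage-1 model")
        theta = step1.theta
        R = theta.shape[1] - 1
        cols = [f"theta_{r + 1}" for r in range(R)] + ["alpha"]
        return pd.DataFrame(theta.copy(), columns=cols, index=sample_ids)
    if source == "isopure-profiles":
        if step2 is None or totals is None:
            raise ValueError(
                "isopure-profiles requires a fitted stage-2 model and sample totals"
            )
        rescaled = rescale_cancer_profiles(step2.c, totals)
        return pd.DataFrame(rescaled.T, columns=transcript_ids, index=sample_ids)
    if source == "clarke-profiles":
        if clarke is None:
            raise ValueError("clarke-profiles requires a ClarkeResult")
        return pd.DataFrame(clarke.c.T, columns=transcript_ids, index=sample_ids)
    raise ValueError(f"unknown feature source {source!r}")
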