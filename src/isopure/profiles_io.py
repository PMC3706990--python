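"""Reading, validation, alignment and transformation of expression matrices.

Interchange format: delimited text (TSV by default, CSV accepted) with
transcript identifiers in the first column and sample identifiers in the
header row.  All values are non-negative, linear-scale intensities or
abundance estimates — normalized but *not* log-transformed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "CountProfiles",
    "NormalPanel",
    "read_matrix",
    "write_matrix",
    "align_genes",
    "discretize_tumors",
    "normalize_panel",
    "rescale_cancer_profiles",
    "write_purity_table",
    "write_model_json",
]

logger = logging.getLogger(__name__)

LOW_TOTAL_WARNING = 1e6  # real profiles total ~1e7 after discretization


class ValidationError(ValueError):
    """Raised when an input matrix violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A G x S matrix of non-negative linear-scale expression values."""

    values: np.ndarray
    transcript_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        G, S = self.values.shape
        if len(self.transcript_ids) != G:
            raise ValidationError(
                f"{len(self.transcript_ids)} transcript ids for {G} rows"
            )
        if len(self.sample_ids) != S:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {S} columns")
        for label, ids in (
            ("transcript", self.transcript_ids),
            ("sample", self.sample_ids),
        ):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for i in ids:
                    if i in seen:
                        dup = i
                        break
                    seen.add(i)
                raise ValidationError(f"duplicate {label} id: {dup!r}")
        if np.any(~np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at transcript {self.transcript_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[g, s]} at transcript "
                f"{self.transcript_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.sample_ids
        )


@dataclass
class CountProfiles:
    """Discretized tumor profiles: integer counts plus per-sample totals."""

    counts: np.ndarray
    totals: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)
        self.totals = np.asarray(self.totals, dtype=float)
        if not np.allclose(self.totals, self.counts.sum(axis=0)):
            raise ValidationError("totals do not match column sums")


@dataclass
class NormalPanel:
    """Column-normalized healthy-tissue profiles B (each column sums to 1)."""

    B: np.ndarray
    source_ids: list[str]
    min_entry: float = None

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if np.any(self.B <= 0):
            raise ValidationError("normalized panel must be strictly positive")
        if np.any(np.abs(self.B.sum(axis=0) - 1.0) > 1e-12):
            raise ValidationError("panel columns must sum to 1 within 1e-12")
        if self.min_entry is None:
            self.min_entry = float(self.B.min())

    @property
    def n_profiles(self) -> int:
        return self.B.shape[1]


def _sniff_delimiter(path, fmt) -> str:
    if fmt is not None:
        return {"tsv": "\t", "csv": ","}.get(fmt, fmt)
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression matrix (rows = transcripts, cols = samples).

    ``fmt`` may be ``"tsv"``, ``"csv"``, or an explicit delimiter; by
    default it is inferred from the file extension.  Raises
    :class:`ValidationError` naming the offending cell on negative,
    non-numeric or duplicated entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~df.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell {df.iat[g, s]!r} at transcript {df.index[g]!r}, "
            f"sample {df.columns[s]!r} in {path}"
        )
    if body.isna().to_numpy().any():
        g, s = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at transcript {df.index[g]!r}, sample "
            f"{df.columns[s]!r} in {path}"
        )
    return ExpressionMatrix(
        values=body.to_numpy(dtype=float),
        transcript_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def write_matrix(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write an expression matrix as delimited text (full float precision)."""
    sep = _sniff_delimiter(path, fmt)
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def align_genes(
    tumors: ExpressionMatrix, normals: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared transcripts, in tumor row order."""
    normal_set = set(normals.transcript_ids)
    shared = [t for t in tumors.transcript_ids if t in normal_set]
    if not shared:
        raise ValidationError("tumor and normal matrices share no transcript ids")
    dropped = (
        (tumors.n_transcripts - len(shared))
        + (normals.n_transcripts - len(shared))
    )
    if dropped:
        logger.info(
            "align_genes: keeping %d shared transcripts, dropping %d",
            len(shared),
            dropped,
        )
    t_pos = {t: i for i, t in enumerate(tumors.transcript_ids)}
    n_pos = {t: i for i, t in enumerate(normals.transcript_ids)}
    t_idx = [t_pos[t] for t in shared]
    n_idx = [n_pos[t] for t in shared]
    return (
        ExpressionMatrix(tumors.values[t_idx], shared, tumors.sample_ids),
        ExpressionMatrix(normals.values[n_idx], list(shared), normals.sample_ids),
    )


def discretize_tumors(tumors: ExpressionMatrix) -> CountProfiles:
    """Round each tumor value to the nearest non-negative integer.

    The model interprets entries as transcript counts; the per-sample
    totals ``S_n`` are kept for rescaling the purified profiles back to
    the measurement scale.  A warning is emitted when a column total
    falls below ~1e6, since profiles much sparser than the ~1e7 totals
    the method expects lose precision in discretization and may need
    rescaling first.
    """
    counts = np.maximum(np.round(tumors.values), 0.0)
    totals = counts.sum(axis=0)
    low = totals < LOW_TOTAL_WARNING
    if np.any(low):
        worst = int(np.argmin(totals))
        logger.warning(
            "%d of %d tumor columns have discretized totals below %.0g "
            "(smallest: %s at %.3g); consider rescaling before discretization",
            int(low.sum()),
            tumors.n_samples,
            LOW_TOTAL_WARNING,
            tumors.sample_ids[worst],
            totals[worst],
        )
    return CountProfiles(counts=counts, totals=totals)


def normalize_panel(
    normals: ExpressionMatrix, floor_fraction: float = 1e-3
) -> NormalPanel:
    """Divide each healthy profile by its sum so columns are distributions.

    Zero entries are first floored at ``floor_fraction`` times the
    column's smallest positive entry: the Dirichlet prior built from the
    panel is undefined at exact zeros, and its strength bound involves
    ``1 / min B``.
    """
    if floor_fraction <= 0:
        raise ValidationError("floor_fraction must be positive")
    V = normals.values.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValidationError(
                f"normal profile {normals.sample_ids[j]!r} is all zeros"
            )
        floor = floor_fraction * positive.min()
        n_floored = int((col < floor).sum())
        if n_floored:
            logger.debug(
                "normalize_panel: flooring %d entries of %s at %.3g",
                n_floored,
                normals.sample_ids[j],
                floor,
            )
        col = np.maximum(col, floor)
        V[:, j] = col / col.sum()
    return NormalPanel(B=V, source_ids=list(normals.sample_ids))


def rescale_cancer_profiles(c: np.ndarray, totals) -> np.ndarray:
    """Multiply each simplex column ``c_n`` by its sample total ``S_n``.

    Puts the purified cancer profiles back on the scale of the original
    tumor measurements.
    """
    c = np.asarray(c, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if c.ndim != 2 or totals.ndim != 1 or c.shape[1] != totals.size:
        raise ValidationError(
            f"shape mismatch: c is {c.shape}, totals has length {totals.size}"
        )
    if np.any(totals <= 0):
        raise ValidationError("totals must be positive")
    if np.any(np.abs(c.sum(axis=0) - 1.0) > 1e-6):
        raise ValidationError("columns of c must sum to 1")
    return c * totals[None, :]


def write_purity_table(path, sample_ids, theta: np.ndarray) -> None:
    """Write the per-sample purity table: sample_id, alpha, theta_1..theta_R."""
    theta = np.asarray(theta, dtype=float)
    R = theta.shape[1] - 1
    df = pd.DataFrame(
        {"sample_id": list(sample_ids), "alpha": theta[:, R]}
    )
    for r in range(R):
        df[f"theta_{r + 1}"] = theta[:, r]
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_model_json(path, payload: dict) -> None:
    """Serialize fitted-model parameters as JSON, atomically."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1)
    os.replace(tmp, path)
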