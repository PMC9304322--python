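"""Expression-matrix handling: I/O, variability filtering, normalization.

The central container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` that tracks its normalization
``state`` (``counts`` -> ``log`` -> ``zscore``).  Downstream network scoring
expects gene-wise z-scores so that signed directions are comparable across
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: allowed normalization states, in pipeline order
STATES = ("counts", "log", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a normalization state.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns.
    state
        One of ``counts``, ``log`` or ``zscore``.  State transitions only
        move forward along that chain.
    metadata
        Free-form provenance map (input path, parameters, ...).
    """

    values: pd.DataFrame
    state: str = "counts"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.values = self.values.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order as given); missing genes raise KeyError."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.state, dict(self.metadata))


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes-in-rows",
    state: str = "counts",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a rectangular TSV/CSV table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    orientation
        ``genes-in-rows`` (default) or ``genes-in-columns``; the latter is
        transposed on read so the in-memory object is always genes x samples.
    state
        Normalization state to record; file contents are not inspected.
    sep
        Field separator; inferred from the extension when ``None``
        (``.csv`` -> comma, otherwise tab).
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"non-numeric columns in {path.name}: {list(non_numeric)}")
    if df.isna().any().any():
        raise ValueError(f"missing/ragged cells in {path.name}")
    if orientation == "genes-in-columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, state=state, metadata={"source": str(path)})


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write genes-in-rows TSV/CSV (inverse of :func:`read_expression_matrix`)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def iqr_filter(matrix: ExpressionMatrix, threshold: float = 0.5) -> ExpressionMatrix:
    """Keep genes whose across-sample interquartile range exceeds ``threshold``.

    The comparison is strict (``IQR > threshold``), so constant genes are
    dropped even at threshold 0.  Quartiles use linear interpolation between
    order statistics (numpy's default, the common "type 7" rule).  Gene order
    is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if matrix.shape[1] < 2:
        raise ValueError("IQR filter needs at least 2 samples")
    arr = matrix.values.to_numpy()
    q1, q3 = np.percentile(arr, [25, 75], axis=1)
    keep = (q3 - q1) > threshold
    logger.info("iqr_filter: kept %d/%d genes at threshold %g", int(keep.sum()), len(keep), threshold)
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.state,
                            {**matrix.metadata, "iqr_threshold": threshold})


def zscore_normalize(
    matrix: ExpressionMatrix,
    log_first: bool = False,
    reference_samples: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Gene-wise z-score: each row gets mean 0 and sample SD 1 (n-1 denominator).

    Parameters
    ----------
    log_first
        Apply ``log2(x + 1)`` before standardizing (intended for counts).
    reference_samples
        When given, center/scale every gene by the mean and SD of these
        samples only (e.g. a vehicle group), so treatment shifts are expressed
        in reference-noise units rather than being absorbed into the scale.
        Default is to use all samples.

    Zero-variance rows are set to all zeros and a warning is emitted.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    df = matrix.values
    if log_first:
        if (df.to_numpy() < 0).any():
            raise ValueError("log_first requires non-negative values")
        df = np.log2(df + 1.0)
    if reference_samples is None:
        ref = df
    else:
        missing = [s for s in reference_samples if s not in df.columns]
        if missing:
            raise KeyError(f"reference samples not in matrix: {missing}")
        if len(reference_samples) < 2:
            raise ValueError("need at least 2 reference samples")
        ref = df[list(reference_samples)]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) set to all-zero z-scores",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = sd.mask(flat, 1.0)
    z = df.sub(mu, axis=0).div(sd, axis=0)
    z.loc[flat.index[flat]] = 0.0
    return ExpressionMatrix(z, "zscore", {**matrix.metadata, "log_first": log_first})
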