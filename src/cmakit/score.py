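"""CMA activation index and co-repressor/receptor expression ratios.

The activation index for a sample is the weighted, direction-signed average
of gene-wise standardized expression over the CMA network:

    S = sum_i(d_i * w_i * z_i) / sum_i(w_i)

where ``z_i`` is the z-scored expression of network gene *i*, ``w_i > 0``
its weight (2 for the rate-limiting receptor LAMP2A, 1 otherwise) and
``d_i`` is +1 for CMA effectors and -1 for inhibitors.  The weighted
denominator makes S a weighted average, so ``|S| <= max|z|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import CMANetworkTable


@dataclass
class CMAScoreResult:
    """Per-sample scores plus the per-gene decomposition behind them."""

    scores: pd.Series                 # sample -> S
    contributions: pd.DataFrame       # genes_used x samples, entries d_i * w_i * z_i
    genes_used: list[str]
    genes_missing: list[str]
    weight_total: float               # sum of weights over genes_used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "n_genes_used": len(self.genes_used)})


def compute_cma_score(
    matrix: ExpressionMatrix,
    network: CMANetworkTable,
    missing_policy: str = "renormalize",
    allow_any_state: bool = False,
) -> CMAScoreResult:
    """Score every sample of a z-scored matrix against the CMA network.

    Parameters
    ----------
    matrix
        Expression in ``zscore`` state (set ``allow_any_state=True`` to
        acknowledge scoring unstandardized values; directions then mix
        incomparable scales, which is rarely what you want).
    missing_policy
        ``renormalize`` (default): score over the network genes present in
        the matrix, renormalizing by their summed weights, with a warning.
        ``error``: any absent network gene raises.
    """
    if matrix.state != "zscore" and not allow_any_state:
        raise ValueError(
            f"matrix state is {matrix.state!r}; z-score it first or pass allow_any_state=True"
        )
    if missing_policy not in ("renormalize", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    present = [g for g in network.gene_ids if g in matrix.values.index]
    missing = [g for g in network.gene_ids if g not in matrix.values.index]
    if not present:
        raise ValueError("no network gene present in the matrix")
    if missing:
        if missing_policy == "error":
            raise ValueError(f"network genes absent from matrix: {missing}")
        warnings.warn(
            f"{len(missing)} network gene(s) absent; renormalizing over {len(present)}: {missing}",
            RuntimeWarning,
            stacklevel=2,
        )

    w = network.weights.loc[present].to_numpy(dtype=float)
    d = network.directions.loc[present].to_numpy(dtype=float)
    z = matrix.values.loc[present]
    contrib = z.mul(d * w, axis=0)
    total_w = float(w.sum())
    scores = contrib.sum(axis=0) / total_w
    scores.name = "cma_score"
    return CMAScoreResult(scores, contrib, present, missing, total_w)


def score_trajectory(
    result: CMAScoreResult,
    grouping: Mapping[str, tuple[str, object]],
) -> pd.DataFrame:
    """Aggregate per-sample scores into per-(condition, timepoint) mean +/- SE.

    ``grouping`` maps each sample id to ``(condition, timepoint)``.  Returns a
    DataFrame indexed by condition/timepoint with columns ``mean, se, n``,
    ordered by timepoint within condition.  SE is NaN for single-sample groups.
    """
    missing = [s for s in result.scores.index if s not in grouping]
    if missing:
        raise ValueError(f"samples without a group: {missing}")
    df = pd.DataFrame(
        {
            "score": result.scores,
            "condition": [grouping[s][0] for s in result.scores.index],
            "timepoint": [grouping[s][1] for s in result.scores.index],
        }
    )
    agg = (
        df.groupby(["condition", "timepoint"])["score"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    agg["se"] = agg["sd"] / np.sqrt(agg["n"])
    agg.loc[agg["n"] < 2, "se"] = np.nan
    return agg.drop(columns="sd").sort_values(["condition", "timepoint"]).reset_index(drop=True)


def corepressor_receptor_ratio(
    matrix: ExpressionMatrix,
    numerator_gene: str = "NCOR1",
    denominator_gene: str = "RARA",
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample expression ratio (e.g. NCOR1/RARA) on linear-scale values.

    Samples whose denominator is <= 0 get ``ratio = NaN`` and ``flagged = True``
    rather than being dropped.  Z-scored input is refused: ratios of
    standardized values are meaningless.
    """
    if matrix.state == "zscore":
        raise ValueError("ratios require linear-scale expression, not z-scores")
    for g in (numerator_gene, denominator_gene):
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not in matrix")
    num = matrix.values.loc[numerator_gene]
    den = matrix.values.loc[denominator_gene]
    flagged = den <= 0
    ratio = num.where(~flagged) / den.where(~flagged)
    out = pd.DataFrame(
        {
            "numerator": num,
            "denominator": den,
            "ratio": ratio,
            "flagged": flagged,
        }
    )
    out.index.name = "sample"
    if groups is not None:
        out["group"] = [groups.get(s) for s in out.index]
    return out
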