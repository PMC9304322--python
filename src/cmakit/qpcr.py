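"""Relative qPCR quantification by the comparative-Ct (2^-ddCt) method.

Ct tables are long-format DataFrames with columns
``sample, group, gene, ct`` and optionally ``replicate``.  Technical
replicates are averaged on the Ct scale first; dCt is then computed per
sample against a housekeeping gene (e.g. beta-actin), ddCt against the
mean dCt of a reference group, and fold change as ``2 ** (-ddCt)``.
Amplification efficiency is fixed at 2 (perfect doubling per cycle).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Ct CSV."""
    df = pd.read_csv(path)
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df = df.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    df["ct"] = pd.to_numeric(df["ct"])
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0, ["sample", "gene"]].to_records(index=False).tolist()
        raise ValueError(f"non-positive Ct values for {bad}")
    groups = df.groupby("sample")["group"].nunique()
    if (groups > 1).any():
        raise ValueError(f"samples with conflicting group labels: {list(groups.index[groups > 1])}")
    return df


def ddct_fold_change(
    ct: pd.DataFrame,
    housekeeping_gene: str,
    reference_group: str,
) -> pd.DataFrame:
    """Compute dCt, ddCt and fold change per (sample, gene).

    Returns a DataFrame with columns
    ``sample, group, gene, dct, ddct, fold``; the housekeeping gene itself is
    not reported.  By construction the reference-group *mean ddCt* is 0 for
    every gene, so reference folds are centered on 1 (geometric mean exactly 1).
    """
    ct = validate_ct_table(ct)
    # replicate-first averaging on the Ct scale
    mean_ct = ct.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()

    hk = mean_ct[mean_ct["gene"] == housekeeping_gene].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != housekeeping_gene].copy()
    missing_hk = sorted(set(targets["sample"]) - set(hk.index))
    if missing_hk:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing for samples: {missing_hk}")
    if targets.empty:
        raise ValueError("Ct table contains no target genes")

    targets["dct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()

    ref = targets[targets["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = ref.groupby("gene")["dct"].mean()
    missing_ref = sorted(set(targets["gene"]) - set(ref_mean.index))
    if missing_ref:
        raise ValueError(f"genes absent from reference group: {missing_ref}")

    targets["ddct"] = targets["dct"].to_numpy() - ref_mean.loc[targets["gene"]].to_numpy()
    targets["fold"] = np.exp2(-targets["ddct"])
    return targets[["sample", "group", "gene", "dct", "ddct", "fold"]].reset_index(drop=True)
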