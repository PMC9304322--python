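"""The CMA gene-network table that defines the activation index.

Each network entry is a gene with a positive weight ``w`` and a direction
``d`` of +1 (effector/positive regulator of chaperone-mediated autophagy)
or -1 (inhibitor).  LAMP2A, the rate-limiting lysosomal receptor, carries
weight 2 by convention; every other component weight 1.

The packaged 17-entry table (``data/cma_network_example.tsv``) is an
editable illustration of such a network: the receptor weighting and the
signs on the RARalpha axis are the anchored conventions, while the exact
membership list is expected to be supplied (and curated) by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

COLUMNS = ("gene_id", "weight", "direction", "note")


@dataclass(frozen=True)
class CMANetworkTable:
    """Validated per-gene weights and directions."""

    entries: pd.DataFrame  # columns gene_id, weight, direction, note

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in ("gene_id", "weight", "direction") if c not in df.columns]
        if missing:
            raise ValueError(f"network table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
            raise ValueError(f"duplicate network genes: {dupes}")
        if (df["weight"] <= 0).any():
            bad = df.loc[df["weight"] <= 0, "gene_id"].tolist()
            raise ValueError(f"non-positive weights for: {bad}")
        if not df["direction"].isin([1, -1]).all():
            bad = df.loc[~df["direction"].isin([1, -1]), "gene_id"].tolist()
            raise ValueError(f"direction must be +1 or -1; offending genes: {bad}")
        if "note" not in df.columns:
            df = df.assign(note="")
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    @property
    def weights(self) -> pd.Series:
        return self.entries.set_index("gene_id")["weight"].astype(float)

    @property
    def directions(self) -> pd.Series:
        return self.entries.set_index("gene_id")["direction"].astype(int)

    def __len__(self) -> int:
        return len(self.entries)

    def drop(self, gene: str) -> "CMANetworkTable":
        """Network without ``gene`` (used for subnetwork-consistency checks)."""
        if gene not in self.gene_ids:
            raise KeyError(gene)
        return CMANetworkTable(self.entries[self.entries["gene_id"] != gene].copy())


def load_network_table(path: str | Path) -> CMANetworkTable:
    """Load a TSV with columns ``gene_id  weight  direction  note``."""
    df = pd.read_csv(path, sep="\t")
    df["weight"] = pd.to_numeric(df["weight"])
    df["direction"] = pd.to_numeric(df["direction"], downcast="integer")
    return CMANetworkTable(df)


def save_network_table(network: CMANetworkTable, path: str | Path) -> None:
    network.entries.to_csv(path, sep="\t", index=False)


def default_network() -> CMANetworkTable:
    """The packaged illustrative 17-gene network (LAMP2A weight 2, rest 1)."""
    with resources.as_file(resources.files("cmakit").joinpath("data/cma_network_example.tsv")) as p:
        return load_network_table(p)
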