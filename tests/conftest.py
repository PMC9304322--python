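import numpy as np
import pandas as pd
import pytest

from cmakit.expression import ExpressionMatrix
from cmakit.network import CMANetworkTable, default_network


@pytest.fixture(scope="session")
def worked_network() -> CMANetworkTable:
    """Three-gene network used in the worked scoring example."""
    return CMANetworkTable(
        pd.DataFrame(
            {"gene_id": ["LAMP2A", "HSPA8", "RARA"], "weight": [2, 1, 1], "direction": [1, 1, -1]}
        )
    )


@pytest.fixture(scope="session")
def packaged_network() -> CMANetworkTable:
    return default_network()


@pytest.fixture()
def zscore_matrix() -> ExpressionMatrix:
    """Small z-state matrix for the worked example: z = {1.0, 0.5, 0.5}."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [1.0, 0.5, 0.5], "s2": [0.0, 0.0, 0.0]},
                     index=["LAMP2A", "HSPA8", "RARA"]),
        state="zscore",
    )


def pair_cells(truth, field_result, max_dist: float = 5.0):
    """Match detected cell records to ground-truth cells by nucleus centroid."""
    pairs = []
    for rec in field_result.cells:
        dists = [
            (np.hypot(rec.nucleus_centroid[0] - c.nucleus_centroid[0],
                      rec.nucleus_centroid[1] - c.nucleus_centroid[1]), c)
            for c in truth.cells
        ]
        d, best = min(dists, key=lambda t: t[0])
        assert d <= max_dist, f"unmatched cell at {rec.nucleus_centroid}"
        pairs.append((rec, best))
    return pairs
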