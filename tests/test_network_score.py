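"""Network-table validation and the CMA activation index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cmakit.expression import ExpressionMatrix
from cmakit.network import CMANetworkTable, load_network_table, save_network_table
from cmakit.score import compute_cma_score, corepressor_receptor_ratio, score_trajectory


def znet(values: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes), state="zscore")


class TestNetworkTable:
    def test_packaged_default_weighting(self, packaged_network):
        w = packaged_network.weights
        assert len(packaged_network) == 17
        assert w["LAMP2A"] == 2
        assert (w.drop("LAMP2A") == 1).all()
        assert packaged_network.directions["RARA"] == -1

    def test_direction_zero_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            CMANetworkTable(pd.DataFrame({"gene_id": ["A"], "weight": [1], "direction": [0]}))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            CMANetworkTable(pd.DataFrame({"gene_id": ["A"], "weight": [0], "direction": [1]}))

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CMANetworkTable(
                pd.DataFrame({"gene_id": ["A", "A"], "weight": [1, 1], "direction": [1, -1]})
            )

    def test_write_read_round_trip(self, tmp_path, packaged_network):
        p = tmp_path / "net.tsv"
        save_network_table(packaged_network, p)
        back = load_network_table(p)
        pd.testing.assert_frame_equal(
            back.entries[["gene_id", "weight", "direction"]].astype({"weight": float, "direction": int}),
            packaged_network.entries[["gene_id", "weight", "direction"]].astype({"weight": float, "direction": int}),
        )


class TestScore:
    def test_worked_three_gene_example(self, worked_network, zscore_matrix):
        # S = (2*1.0 + 1*0.5 - 1*0.5) / 4 = 0.5
        res = compute_cma_score(zscore_matrix, worked_network)
        assert res.scores["s1"] == pytest.approx(0.5)
        assert res.scores["s2"] == pytest.approx(0.0)
        assert res.weight_total == 4.0

    def test_zero_input_gives_zero_scores(self, packaged_network):
        m = znet({"s1": [0.0] * 17, "s2": [0.0] * 17}, packaged_network.gene_ids)
        assert (compute_cma_score(m, packaged_network).scores == 0).all()

    def test_direction_flip_negates_score(self, worked_network, zscore_matrix):
        flipped = CMANetworkTable(
            worked_network.entries.assign(direction=-worked_network.entries["direction"])
        )
        a = compute_cma_score(zscore_matrix, worked_network).scores
        b = compute_cma_score(zscore_matrix, flipped).scores
        np.testing.assert_allclose(b, -a)

    def test_requires_zscore_state(self, worked_network):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=worked_network.gene_ids), state="counts"
        )
        with pytest.raises(ValueError, match="state"):
            compute_cma_score(m, worked_network)
        # explicit acknowledgment path
        compute_cma_score(m, worked_network, allow_any_state=True)

    def test_missing_gene_error_policy(self, worked_network):
        m = znet({"s1": [1.0, 0.5]}, ["LAMP2A", "HSPA8"])
        with pytest.raises(ValueError, match="RARA"):
            compute_cma_score(m, worked_network, missing_policy="error")

    def test_missing_gene_renormalizes(self, worked_network):
        m = znet({"s1": [1.0, 0.5]}, ["LAMP2A", "HSPA8"])
        with pytest.warns(RuntimeWarning, match="renormaliz"):
            res = compute_cma_score(m, worked_network)
        assert res.scores["s1"] == pytest.approx((2 * 1.0 + 0.5) / 3.0)
        assert res.genes_missing == ["RARA"]

    def test_subnetwork_consistency(self, packaged_network):
        """Dropping a gene from the matrix equals scoring with network minus it."""
        rng = np.random.default_rng(5)
        genes = packaged_network.gene_ids
        m = znet({f"s{i}": rng.normal(size=17).tolist() for i in range(3)}, genes)
        sub_matrix = ExpressionMatrix(m.values.drop(index="GFAP"), state="zscore")
        with pytest.warns(RuntimeWarning):
            via_policy = compute_cma_score(sub_matrix, packaged_network).scores
        via_network = compute_cma_score(sub_matrix, packaged_network.drop("GFAP")).scores
        np.testing.assert_allclose(via_policy, via_network)

    def test_no_network_gene_present_raises(self, worked_network):
        m = znet({"s1": [1.0]}, ["OTHER"])
        with pytest.raises(ValueError, match="no network gene"):
            compute_cma_score(m, worked_network)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(-4, 4))
    def test_linearity_and_permutation_invariance(self, seed, a):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        genes = [f"G{i}" for i in range(n)]
        net = CMANetworkTable(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "weight": rng.uniform(0.5, 3, n),
                    "direction": rng.choice([1, -1], n),
                }
            )
        )
        m = znet({"s1": rng.normal(size=n).tolist(), "s2": rng.normal(size=n).tolist()}, genes)
        base = compute_cma_score(m, net).scores
        scaled = ExpressionMatrix(m.values * a, state="zscore")
        np.testing.assert_allclose(compute_cma_score(scaled, net).scores, a * base, atol=1e-9)
        perm = rng.permutation(n)
        m_perm = ExpressionMatrix(m.values.iloc[perm], state="zscore")
        np.testing.assert_allclose(compute_cma_score(m_perm, net).scores, base, atol=1e-12)

    def test_bounded_by_max_abs_z(self, packaged_network):
        rng = np.random.default_rng(3)
        z = rng.uniform(-2.5, 2.5, size=(17, 5))
        m = znet({f"s{i}": z[:, i].tolist() for i in range(5)}, packaged_network.gene_ids)
        s = compute_cma_score(m, packaged_network).scores
        assert (s.abs() <= np.abs(z).max() + 1e-12).all()


class TestTrajectoryAndRatio:
    def test_trajectory_hand_built_2x3_design(self, worked_network):
        genes = worked_network.gene_ids
        samples = {f"{c}_{t}_{r}": (c, t) for c in ("ctl", "rp") for t in (90, 180, 230) for r in (1, 2)}
        rng = np.random.default_rng(0)
        m = znet({s: rng.normal(size=3).tolist() for s in samples}, genes)
        res = compute_cma_score(m, worked_network)
        traj = score_trajectory(res, samples)
        assert len(traj) == 6
        for _, row in traj.iterrows():
            members = [s for s, (c, t) in samples.items() if c == row["condition"] and t == row["timepoint"]]
            expect = res.scores[members].mean()
            assert row["mean"] == pytest.approx(expect)
            assert row["n"] == 2
            assert row["se"] == pytest.approx(res.scores[members].std(ddof=1) / np.sqrt(2))

    def test_trajectory_single_sample_group_has_no_se(self, worked_network, zscore_matrix):
        res = compute_cma_score(zscore_matrix, worked_network)
        traj = score_trajectory(res, {"s1": ("a", 0), "s2": ("b", 0)})
        assert traj["se"].isna().all()

    def test_trajectory_identical_samples_zero_se(self, worked_network):
        m = znet({"s1": [1.0, 0.5, 0.5], "s2": [1.0, 0.5, 0.5]}, worked_network.gene_ids)
        res = compute_cma_score(m, worked_network)
        traj = score_trajectory(res, {"s1": ("a", 0), "s2": ("a", 0)})
        assert traj["se"].iloc[0] == pytest.approx(0.0)

    def test_trajectory_ungrouped_sample_raises(self, worked_network, zscore_matrix):
        res = compute_cma_score(zscore_matrix, worked_network)
        with pytest.raises(ValueError, match="without a group"):
            score_trajectory(res, {"s1": ("a", 0)})

    def test_ratio_worked_values(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [4.0, 2.0], "s2": [3.0, 3.0]}, index=["NCOR1", "RARA"])
        )
        out = corepressor_receptor_ratio(m)
        assert out.loc["s1", "ratio"] == pytest.approx(2.0)
        assert out.loc["s2", "ratio"] == pytest.approx(1.0)
        assert not out["flagged"].any()

    def test_ratio_zero_denominator_flagged_not_dropped(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [4.0, 0.0], "s2": [3.0, 1.5]}, index=["NCOR1", "RARA"])
        )
        out = corepressor_receptor_ratio(m)
        assert out.loc["s1", "flagged"] and np.isnan(out.loc["s1", "ratio"])
        assert out.loc["s2", "ratio"] == pytest.approx(2.0)
        assert len(out) == 2

    def test_ratio_refuses_zscore_state(self, zscore_matrix):
        with pytest.raises(ValueError, match="linear"):
            corepressor_receptor_ratio(zscore_matrix, "LAMP2A", "RARA")
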