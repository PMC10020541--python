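import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import global_sle_oracle, local_perturbation_oracle
from conftest import random_instance
from dnbsle.network import LocalNetwork, TemplateNetwork
from dnbsle.sle import (
    GlobalSLECurve,
    SLEError,
    delta_sd,
    detect_tipping_point,
    global_sle,
    local_entropy,
    local_perturbation,
    neighbor_weights,
    pearson_abs,
    sle_curve,
)


class TestPearsonAbs:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), 1.0),
            ((1, 1, 1), (1, 2, 3), 0.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_abs(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_length_mismatch_and_short_vectors_error(self):
        with pytest.raises(SLEError):
            pearson_abs(np.ones(3), np.ones(4))
        with pytest.raises(SLEError):
            pearson_abs(np.ones(2), np.ones(2))


class TestNeighborWeights:
    def test_normalisation_of_known_correlations(self):
        # center x; neighbors: 2x (r=1), noise-free mix giving |r|=1, constant (r=0)
        # simpler: craft data whose |PCC| are (0.8, 0.4, 0.4) is fiddly; check
        # normalisation against directly computed correlations instead.
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(4, 6)), index=["c", "n1", "n2", "n3"])
        local = LocalNetwork("c", ("n1", "n2", "n3"))
        p = neighbor_weights(local, data)
        rs = np.array(
            [pearson_abs(data.loc[n].to_numpy(), data.loc["c"].to_numpy()) for n in local.neighbors]
        )
        assert p == pytest.approx(rs / rs.sum())
        assert p.sum() == pytest.approx(1.0)

    def test_uniform_fallback_when_all_correlations_zero(self):
        data = pd.DataFrame(
            {"s1": [1.0, 5, 5, 5], "s2": [2.0, 5, 5, 5], "s3": [3.0, 5, 5, 5]},
            index=["c", "n1", "n2", "n3"],
        )
        local = LocalNetwork("c", ("n1", "n2", "n3"))
        assert neighbor_weights(local, data) == pytest.approx([1 / 3] * 3)

    def test_zero_neighbors_errors(self):
        with pytest.raises(SLEError):
            neighbor_weights(LocalNetwork("c", ()), pd.DataFrame())


class TestLocalEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0, 0.0], 0.0),
            ([1.0], 0.0),
        ],
    )
    def test_known_values(self, p, expected):
        assert local_entropy(np.array(p)) == pytest.approx(expected)

    def test_hand_evaluated_three_weights(self):
        # -(1/ln 3)(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert local_entropy(np.array([0.5, 0.25, 0.25])) == pytest.approx(0.9464, abs=1e-4)

    def test_unnormalised_weights_error(self):
        with pytest.raises(SLEError):
            local_entropy(np.array([0.5, 0.4]))

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12))
    def test_bounds_for_random_weights(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = local_entropy(p)
        assert 0.0 <= h <= 1.0


class TestDeltaSD:
    def test_case_at_mean_shrinks_sd_by_closed_form(self):
        # adding the mean of (1,2,3): SD4 = sqrt(2/3), SD3 = 1
        assert delta_sd(np.array([1.0, 2, 3]), 2.0) == pytest.approx(
            abs(math.sqrt(2 / 3) - 1.0)
        )

    def test_constant_values_give_zero(self):
        assert delta_sd(np.array([5.0, 5, 5, 5]), 5.0) == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        refs = rng.normal(size=6)
        case = float(rng.normal())
        import statistics

        oracle = abs(
            statistics.stdev(list(refs) + [case]) - statistics.stdev(list(refs))
        )
        assert delta_sd(refs, case) == pytest.approx(oracle, abs=1e-12)


class TestLocalPerturbation:
    def test_product_invariant_holds_exactly(self):
        rng = np.random.default_rng(11)
        genes = ["c", "n1", "n2", "n3", "n4"]
        ref = pd.DataFrame(rng.normal(10, 2, size=(5, 5)), index=genes)
        case = pd.Series(rng.normal(10, 2, size=5), index=genes)
        local = LocalNetwork("c", ("n1", "n2", "n3", "n4"))
        res = local_perturbation(local, ref, case)
        assert res.delta_h == res.delta_sd * abs(res.H_mix - res.H_ref)
        assert res.delta_h >= 0

    def test_constant_neighbors_give_zero_perturbation(self):
        genes = ["c", "n1", "n2"]
        ref = pd.DataFrame(
            {"s1": [1.0, 5, 7], "s2": [2.0, 5, 7], "s3": [3.0, 5, 7]}, index=genes
        )
        case = pd.Series([4.0, 5, 7], index=genes)
        res = local_perturbation(LocalNetwork("c", ("n1", "n2")), ref, case)
        # both cohorts fall back to uniform weights -> entropies equal
        assert res.H_mix == res.H_ref
        assert res.delta_h == 0.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(13)
        genes = ["c", "n1", "n2", "n3", "n4"]
        ref = pd.DataFrame(rng.normal(size=(5, 5)), index=genes)
        case = pd.Series(rng.normal(size=5), index=genes)
        res = local_perturbation(LocalNetwork("c", tuple(genes[1:])), ref, case)
        oracle = local_perturbation_oracle(
            "c",
            genes[1:],
            {g: list(ref.loc[g]) for g in genes},
            {g: float(case[g]) for g in genes},
        )
        assert res.delta_h == pytest.approx(oracle, abs=1e-12)


class TestGlobalSLE:
    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            net, ref, case = random_instance(rng)
            try:
                score, _ = global_sle(net, ref, case)
            except SLEError:
                continue
            adjacency = {g: set(net.neighbors(g)) for g in net.nodes}
            oracle = global_sle_oracle(
                adjacency,
                {g: list(ref.loc[g]) for g in ref.index},
                {g: float(case[g]) for g in case.index},
            )
            assert score == pytest.approx(oracle, abs=1e-12)

    def test_score_is_mean_of_local_scores(self):
        rng = np.random.default_rng(19)
        net, ref, case = random_instance(rng, n_genes=8, n_ref=5)
        score, locals_ = global_sle(net, ref, case)
        assert score == pytest.approx(np.mean([l.delta_h for l in locals_]))

    def test_all_divisor_counts_every_gene(self):
        rng = np.random.default_rng(23)
        net, ref, case = random_instance(rng, n_genes=8, n_ref=5)
        s_scoreable, locals_ = global_sle(net, ref, case, divisor="scoreable")
        s_all, _ = global_sle(net, ref, case, divisor="all")
        assert s_all == pytest.approx(s_scoreable * len(locals_) / len(net))

    def test_no_scoreable_local_errors(self):
        net = TemplateNetwork.from_edges([("A", "B")])
        ref = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 4)), index=["A", "B"])
        case = pd.Series([0.0, 0.0], index=["A", "B"])
        with pytest.raises(SLEError):
            global_sle(net, ref, case)

    def test_scaling_one_gene_scales_its_delta_sd_only(self):
        # |PCC| is scale-invariant, so entropies are unchanged; the scaled
        # gene's centre-SD difference scales by c.
        rng = np.random.default_rng(29)
        net, ref, case = random_instance(rng, n_genes=7, n_ref=5)
        _, locals_before = global_sle(net, ref, case)
        gene = locals_before[0].center
        c = 3.5
        ref2 = ref.copy()
        ref2.loc[gene] *= c
        case2 = case.copy()
        case2[gene] *= c
        _, locals_after = global_sle(net, ref2, case2)
        for before, after in zip(locals_before, locals_after):
            assert after.H_ref == pytest.approx(before.H_ref, abs=1e-12)
            assert after.H_mix == pytest.approx(before.H_mix, abs=1e-12)
            if before.center == gene:
                assert after.delta_sd == pytest.approx(c * before.delta_sd, rel=1e-12)
            else:
                assert after.delta_sd == pytest.approx(before.delta_sd, abs=1e-12)


class TestCurveAndTippingPoint:
    def _curve(self, means_by_time, n=3):
        scores = {
            t: {f"{t}_s{i}": m for i, m in enumerate([mean] * n)}
            for t, mean in means_by_time.items()
        }
        return GlobalSLECurve(list(means_by_time), scores, K=5)

    def test_argmax_of_means(self):
        curve = self._curve({"t1": 0.1, "t2": 0.5, "t3": 0.2})
        assert detect_tipping_point(curve) == "t2"

    def test_tie_broken_toward_earliest(self):
        curve = self._curve({"t1": 0.3, "t2": 0.3, "t3": 0.3})
        assert detect_tipping_point(curve) == "t1"

    def test_single_time_point_errors(self):
        with pytest.raises(SLEError):
            detect_tipping_point(self._curve({"t1": 0.3}))

    def test_curve_invariant_to_sample_order(self, small_dataset):
        net = TemplateNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")]
        )
        c1 = sle_curve(net, small_dataset)
        shuffled = small_dataset.values[list(small_dataset.values.columns)[::-1]]
        from dnbsle.dataset import ExpressionDataset

        data2 = ExpressionDataset(shuffled, small_dataset.meta.loc[shuffled.columns])
        c2 = sle_curve(net, data2)
        for t in c1.time_labels:
            assert c1.scores[t] == pytest.approx(c2.scores[t])

    def test_curve_relabelling_genes_leaves_scores_unchanged(self, small_dataset):
        net = TemplateNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")]
        )
        c1 = sle_curve(net, small_dataset)
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        import networkx as nx

        net2 = TemplateNetwork(nx.relabel_nodes(net.graph, mapping))
        values2 = small_dataset.values.rename(index=mapping)
        from dnbsle.dataset import ExpressionDataset

        data2 = ExpressionDataset(values2, small_dataset.meta)
        c2 = sle_curve(net2, data2)
        for t in c1.time_labels:
            assert c1.scores[t] == pytest.approx(c2.scores[t])
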