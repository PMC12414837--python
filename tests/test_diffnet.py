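import math

import numpy as np
import pytest

from irnet import diffnet

from conftest import make_net


def star(center, n_leaves, mi=0.5, **kw):
    return make_net([(center, f"{center}L{i:02d}", mi) for i in range(n_leaves)],
                    **kw)


class TestHubs:
    def test_star_boundary_inclusive(self):
        net = star("H", 10, thresholded=True)
        hubs = diffnet.identify_hubs(net, k=10)
        assert hubs.at["H", "degree"] == 10 and hubs.at["H", "is_hub"]
        assert not hubs.loc[hubs.index != "H", "is_hub"].any()

    def test_degree_fixture(self):
        # degrees {4: A, 3: B, 2: C ...} via a small fixture with known counts
        net = make_net([("A", "B", 1), ("A", "C", 1), ("A", "D", 1),
                        ("A", "E", 1), ("B", "C", 1), ("B", "D", 1),
                        ("C", "E", 1)], thresholded=True)
        hubs = diffnet.identify_hubs(net, k=3)
        assert hubs["degree"].to_dict() == {"A": 4, "B": 3, "C": 3, "D": 2, "E": 2}
        assert set(hubs.index[hubs["is_hub"]]) == {"A", "B", "C"}

    def test_empty_graph(self):
        net = make_net([], extra_nodes=["X"], thresholded=True)
        hubs = diffnet.identify_hubs(net)
        assert not hubs["is_hub"].any()

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            diffnet.identify_hubs(star("H", 3), k=0)

    def test_common_hubs_intersection(self):
        a = star("H1", 12, thresholded=True)
        b = star("H1", 11, thresholded=True)
        ha = diffnet.identify_hubs(a)
        hb = diffnet.identify_hubs(b)
        assert diffnet.common_hubs(ha, hb) == {"H1"}
        assert diffnet.common_hubs(ha, diffnet.identify_hubs(star("Z", 15, thresholded=True))) == set()


class TestEdgePartition:
    def build(self):
        # raw A has edges e1..e4; thresholded A keeps e1..e3
        # raw B has e1, e2, e5; thresholded B keeps e1
        e1, e2, e3, e4, e5 = [("H", f"N{i}", 0.5) for i in range(5)]
        a_raw = make_net([e1, e2, e3, e4], group_label="a")
        a_thr = make_net([e1, e2, e3], thresholded=True, group_label="a",
                         extra_nodes=["N3", "N4"])
        b_raw = make_net([e1, e2, e5], group_label="b")
        b_thr = make_net([e1], thresholded=True, group_label="b",
                         extra_nodes=["N1", "N2", "N3", "N4"])
        return a_thr, b_thr, a_raw, b_raw

    def test_partition_classes(self):
        a_thr, b_thr, a_raw, b_raw = self.build()
        part = diffnet.partition_common_hub_edges(a_thr, b_thr, a_raw, b_raw,
                                                  {"H"})
        assert part.unique_a == {("H", "N2")}         # absent from raw B
        assert part.shared == {("H", "N0")}           # in both thresholded
        assert part.attenuated_a == {("H", "N1")}     # raw-B only
        assert part.unique_b == set()
        assert part.attenuated_b == set()

    def test_sets_disjoint_and_exhaustive(self):
        a_thr, b_thr, a_raw, b_raw = self.build()
        part = diffnet.partition_common_hub_edges(a_thr, b_thr, a_raw, b_raw,
                                                  {"H"})
        sets = [part.unique_a, part.unique_b, part.shared,
                part.attenuated_a, part.attenuated_b]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert sets[i].isdisjoint(sets[j])
        incident_a = {(a, b) for a, b in a_thr.edge_keys() if "H" in (a, b)}
        assert part.unique_a | part.shared | part.attenuated_a == incident_a
        # unique edges never occur in the other network's raw edge set
        assert part.unique_a.isdisjoint(b_raw.edge_keys())

    def test_identical_networks_all_shared(self):
        net = star("H", 12, thresholded=True)
        raw = star("H", 12)
        part = diffnet.partition_common_hub_edges(net, net, raw, raw, {"H"})
        assert not part.unique_a and not part.unique_b
        assert len(part.shared) == 12

    def test_missing_hub_is_error(self):
        a_thr, b_thr, a_raw, b_raw = self.build()
        with pytest.raises(KeyError):
            diffnet.partition_common_hub_edges(a_thr, b_thr, a_raw, b_raw,
                                               {"NOPE"})

    def test_published_percentage_arithmetic(self):
        assert diffnet.unique_percentage(1696, 363) == 82.4
        assert diffnet.unique_percentage(1428, 363) == 79.7


class TestMasterHubs:
    @pytest.mark.parametrize("d_focal,d_other,is_master,fold", [
        (24, 8, True, 3.0),
        (12, 7, False, None),
        (34, 12, True, 34 / 12),   # ~2.83
        (20, 10, True, 2.0),       # inclusive boundary
        (9, 2, False, None),       # below degree threshold
    ])
    def test_fold_rule(self, d_focal, d_other, is_master, fold):
        focal = star("H", d_focal, thresholded=True)
        other = star("H", d_other)
        table = diffnet.master_hubs(focal, other, k=10, min_fold=2)
        if is_master:
            assert "H" in table.index
            assert table.at["H", "fold"] == pytest.approx(fold)
        else:
            assert "H" not in table.index

    def test_absent_from_other_gives_infinite_fold(self):
        focal = star("H", 15, thresholded=True)
        other = make_net([("X", "Y", 0.5)])
        table = diffnet.master_hubs(focal, other)
        assert math.isinf(table.at["H", "fold"])

    def test_identical_network_has_no_master_hubs(self):
        thr = star("H", 20, thresholded=True)
        raw = star("H", 20)
        assert len(diffnet.master_hubs(thr, raw)) == 0

    def test_sorted_by_degree_then_id(self):
        net = make_net(
            [("A", f"A{i:02d}", 1) for i in range(12)]
            + [("B", f"B{i:02d}", 1) for i in range(12)]
            + [("C", f"C{i:02d}", 1) for i in range(15)],
            thresholded=True)
        other = make_net([("X", "Y", 1)])
        table = diffnet.master_hubs(net, other)
        assert list(table.index[:3]) == ["C", "A", "B"]

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            diffnet.master_hubs(star("H", 12, thresholded=True),
                                star("H", 2), min_fold=0.5)


class TestNeighborhood:
    def path(self):
        return make_net([("a", "b", 1), ("b", "c", 1)])

    def test_hop_counts(self):
        net = self.path()
        assert diffnet.neighborhood(net, {"a"}, 1) == {"a", "b"}
        assert diffnet.neighborhood(net, {"a"}, 2) == {"a", "b", "c"}
        assert diffnet.neighborhood(net, {"a"}, 1, include_seeds=False) == {"b"}

    def test_isolated_seed(self):
        net = make_net([("a", "b", 1)], extra_nodes=["z"])
        assert diffnet.neighborhood(net, {"z"}, 1) == {"z"}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diffnet.neighborhood(self.path(), {"a"}, 3)
        with pytest.raises(KeyError):
            diffnet.neighborhood(self.path(), {"nope"}, 1)


class TestModalitySplit:
    def test_overlapping_pair_not_unique(self):
        net = make_net([("G1", "G2", 0.5), ("G1-T1", "G2-T1", 0.5)],
                       thresholded=True)
        split = diffnet.modality_split(net)
        assert split.unique_te_te == 0 and split.unique_ir_ir == 0

    def test_no_ir_edges_means_all_te_unique(self):
        net = make_net([("G1", "G2", 0.5), ("G3", "G4", 0.5)], thresholded=True)
        split = diffnet.modality_split(net)
        assert split.pct_unique_te_te == 100.0
        assert split.unique_ir_ir == 0

    def test_published_percentage_arithmetic_floor_mode(self):
        # 5,897 of 5,997 unique -> 98%; 3,597 of 3,722 -> 96% (floor)
        from irnet.diffnet import _int_pct
        assert _int_pct(5897, 5997, "floor") == 98.0
        assert _int_pct(3597, 3722, "floor") == 96.0
        assert _int_pct(4777, 4901, "floor") == 97.0

    def test_gene_pair_mapping_collapses_siblings(self):
        net = make_net([("G1-T1", "G2-T1", 0.5), ("G1-T2", "G2-T2", 0.5)],
                       thresholded=True)
        split = diffnet.modality_split(net)
        assert len(split.ir_ir_edges) == 2
        assert len(split.ir_ir_gene_pairs) == 1


class TestHubModalityComposition:
    def test_all_te_hubs(self):
        net = star("H", 12, thresholded=True)
        comp = diffnet.hub_modality_composition(net, [10])
        assert comp.at[10, "ir_proportion"] == 0.0

    def test_mixed_proportions(self):
        edges = []
        for h in ["A-T1", "B-T1", "C-T1", "D"]:
            edges += [(h, f"{h}x{i:02d}", 0.5) for i in range(10)]
        net = make_net(edges, thresholded=True)
        comp = diffnet.hub_modality_composition(net, [10])
        assert comp.at[10, "ir_proportion"] == pytest.approx(0.75)

    def test_planted_high_degree_ir_nodes_monotone(self):
        edges = []
        for i, h in enumerate(["A-T1", "B-T1", "C-T1", "D-T1", "E-T1"]):
            edges += [(h, f"G{i}x{j:02d}", 0.5) for j in range(20 + i)]
        for i, h in enumerate(["F", "G", "H"]):
            edges += [(h, f"T{i}x{j:02d}", 0.5) for j in range(12)]
        net = make_net(edges, thresholded=True)
        comp = diffnet.hub_modality_composition(net, [10, 15, 20])
        props = comp["ir_proportion"].to_numpy()
        assert (np.diff(props) >= 0).all()

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            diffnet.hub_modality_composition(star("H", 3, thresholded=True), [])
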