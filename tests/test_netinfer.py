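import itertools

import numpy as np
import pandas as pd
import pytest

from irnet import netinfer
from irnet.netinfer import MIParams, estimate_mi, prune_dpi, threshold_pair

from conftest import make_net


def gaussian_pair(rho, n, seed=0):
    rng = np.random.default_rng(seed)
    cov = [[1, rho], [rho, 1]]
    xy = rng.multivariate_normal([0, 0], cov, size=n).T
    return pd.DataFrame(xy, index=["x", "y"],
                        columns=[f"S{j}" for j in range(n)])


class TestEstimateMI:
    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_gaussian_closed_form(self, rho):
        expr = gaussian_pair(rho, 2000, seed=17)
        mi = estimate_mi(expr)
        expected = -0.5 * np.log(1 - rho**2)
        assert mi.loc["x", "y"] == pytest.approx(expected, abs=0.05)

    def test_independent_near_zero(self):
        expr = gaussian_pair(0.0, 1000, seed=4)
        mi = estimate_mi(expr)
        assert mi.loc["x", "y"] <= 0.01

    def test_symmetric_nonnegative(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 60)),
                            index=[f"F{i}" for i in range(8)])
        mi = estimate_mi(expr).to_numpy()
        assert np.allclose(mi, mi.T)
        assert (mi >= 0).all()

    def test_constant_feature_named_in_error(self):
        expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]],
                            index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            estimate_mi(expr)

    def test_binned_estimator_tracks_dependence(self):
        strong = gaussian_pair(0.9, 2000, seed=5)
        weak = gaussian_pair(0.1, 2000, seed=5)
        params = MIParams(estimator="binned", n_bins=8)
        assert estimate_mi(strong, params).loc["x", "y"] > \
            estimate_mi(weak, params).loc["x", "y"]

    def test_mi_floor_scales_with_samples(self):
        p = MIParams(mi_alpha=1e-3)
        assert p.mi_floor(100) > p.mi_floor(400)
        assert MIParams(mi_alpha=None).mi_floor(100) == 0.0


def edges_frame(triples):
    return pd.DataFrame([(a, b, m) for a, b, m in triples],
                        columns=["node_a", "node_b", "mi"])


def brute_force_dpi(edges, eps):
    """Independent exhaustive-triangle oracle for the DPI."""
    present = {(r.node_a, r.node_b): r.mi for r in edges.itertuples()}
    sym = dict(present)
    sym.update({(b, a): m for (a, b), m in present.items()})
    nodes = sorted({n for ab in present for n in ab})
    doomed = set()
    for i, j, k in itertools.combinations(nodes, 3):
        tri = [(i, j), (i, k), (j, k)]
        if not all((a, b) in sym for a, b in tri):
            continue
        for a, b in tri:
            others = [t for t in tri if t != (a, b)]
            if sym[(a, b)] < min(sym[o] for o in others) - eps:
                doomed.add(tuple(sorted((a, b))))
    keep = [tuple(sorted(ab)) not in doomed for ab in present]
    return edges.loc[keep]


class TestPruneDPI:
    def test_weakest_triangle_edge_removed(self):
        e = edges_frame([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.1)])
        out = prune_dpi(e)
        kept = set(zip(out.node_a, out.node_b))
        assert kept == {("A", "B"), ("B", "C")}

    def test_tolerance_spares_near_ties(self):
        e = edges_frame([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.39)])
        out = prune_dpi(e, eps=0.02)
        assert len(out) == 3

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            prune_dpi(edges_frame([("A", "B", 0.5)]), eps=-0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        names = [f"N{i:02d}" for i in range(n)]
        triples = [(a, b, float(rng.uniform(0.01, 1)))
                   for a, b in itertools.combinations(names, 2)
                   if rng.random() < 0.3]
        e = edges_frame(triples)
        eps = float(rng.choice([0.0, 0.0, 0.05]))
        out = prune_dpi(e, eps)
        ref = brute_force_dpi(e, eps)
        assert set(map(tuple, out[["node_a", "node_b"]].to_numpy())) == \
            set(map(tuple, ref[["node_a", "node_b"]].to_numpy()))

    def test_edge_dominant_in_all_its_triangles_is_kept(self):
        # the strict maximum of a triangle is never removed by that
        # triangle; an edge that dominates every triangle it appears in
        # must therefore survive globally
        rng = np.random.default_rng(77)
        names = [f"N{i:02d}" for i in range(12)]
        triples = [(a, b, float(rng.uniform(0.01, 1)))
                   for a, b in itertools.combinations(names, 2)]
        e = edges_frame(triples)
        out = prune_dpi(e)
        kept = set(zip(out.node_a, out.node_b))
        sym = {(r.node_a, r.node_b): r.mi for r in e.itertuples()}
        sym.update({(b, a): m for (a, b), m in dict(sym).items()})
        for a, b in itertools.combinations(names, 2):
            dominant = all(sym[(a, b)] >= min(sym[(a, k)], sym[(b, k)])
                           for k in names if k not in (a, b))
            if dominant:
                assert tuple(sorted((a, b))) in kept

    def test_pure_triangle_keeps_its_strict_maximum(self):
        e = edges_frame([("A", "B", 0.9), ("B", "C", 0.3), ("A", "C", 0.5)])
        out = prune_dpi(e)
        assert ("A", "B") in set(zip(out.node_a, out.node_b))


class TestSameGeneEdges:
    def test_same_gene_removed_cross_gene_kept(self):
        net = make_net([("G1", "G1-T1", 0.4), ("G1", "G2-T1", 0.5),
                        ("G1-T1", "G1-T2", 0.3), ("G2", "G1-T2", 0.2),
                        ("G1", "G2", 0.6)])
        out = netinfer.strip_same_gene_edges(net)
        kept = set(zip(out.edges.node_a, out.edges.node_b))
        assert kept == {("G1", "G2-T1"), ("G1-T2", "G2"), ("G1", "G2")}


class TestInferNetwork:
    def test_chain_indirect_edge_absent(self):
        # X -> Y -> Z chain: MI(X, Z) is the weakest of every triangle
        rng = np.random.default_rng(12)
        n = 500
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(scale=0.5, size=n)
        z = 0.9 * y + rng.normal(scale=0.5, size=n)
        te = pd.DataFrame([x, y, z], index=["X", "Y", "Z"],
                          columns=[f"S{j}" for j in range(n)])
        ir = pd.DataFrame(np.empty((0, n)), columns=te.columns)
        gene_of = pd.Series(dtype=object)
        net = netinfer.infer_network(te, ir, gene_of, list(te.columns),
                                     MIParams(), "g", min_samples=3)
        kept = set(zip(net.edges.node_a, net.edges.node_b))
        assert ("X", "Z") not in kept
        assert {("X", "Y"), ("Y", "Z")} <= kept

    def test_deterministic(self, tiny_dataset):
        truth, gene, tx, samples, fmap = tiny_dataset
        te = np.log2(gene + 0.5)
        ir = np.log2(tx + 0.5)
        gene_of = fmap.set_index("transcript_id")["gene_id"].loc[ir.index]
        ids = list(gene.columns[:30])
        n1 = netinfer.infer_network(te, ir, gene_of, ids, MIParams(), "a")
        n2 = netinfer.infer_network(te, ir, gene_of, ids, MIParams(), "a")
        pd.testing.assert_frame_equal(n1.edges, n2.edges)

    def test_correlated_te_ir_pair_gives_typed_edge(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=n)
        te = pd.DataFrame([x + rng.normal(scale=0.3, size=n)], index=["G1"],
                          columns=[f"S{j}" for j in range(n)])
        ir = pd.DataFrame([0.5 + 0.1 * x + rng.normal(scale=0.05, size=n)],
                          index=["G2-T1"], columns=te.columns)
        gene_of = pd.Series({"G2-T1": "G2"})
        net = netinfer.infer_network(te, ir, gene_of, list(te.columns),
                                     MIParams(), "g", min_samples=3)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["edge_type"] == "TE-IR"


class TestThresholdPair:
    def test_median_definition_and_inclusive_comparison(self):
        net_a = make_net([("A", "B", 0.1), ("C", "D", 0.2),
                          ("E", "F", 0.3), ("G", "H", 0.4)])
        net_b = make_net([("A", "B", 0.24), ("C", "D", 0.26)])
        a_thr, b_thr, thr = threshold_pair(net_a, net_b)
        assert thr["TE-TE"] == pytest.approx(0.25)
        assert len(a_thr.edges) == 2
        assert set(zip(b_thr.edges.node_a, b_thr.edges.node_b)) == {("C", "D")}
        assert a_thr.thresholded and b_thr.thresholded

    def test_thresholded_edges_are_subsets(self, rng):
        edges_a = [(f"A{i}", f"B{i}", float(rng.uniform(0.01, 1)))
                   for i in range(40)]
        edges_b = [(f"A{i}", f"B{i}", float(rng.uniform(0.01, 1)))
                   for i in range(30)]
        net_a, net_b = make_net(edges_a), make_net(edges_b)
        a_thr, b_thr, _ = threshold_pair(net_a, net_b)
        assert a_thr.edge_keys() <= net_a.edge_keys()
        assert b_thr.edge_keys() <= net_b.edge_keys()

    def test_halving_of_reference_on_random_weights(self, rng):
        for _ in range(5):
            edges = []
            for i in range(300):
                edges.append((f"A{i}", f"B{i}", float(rng.uniform(0.01, 1))))
            for i in range(200):
                edges.append((f"A{i}", f"B{i}-T1", float(rng.uniform(0.01, 1))))
            net_a = make_net(edges)
            net_b = make_net(edges[:50])
            a_thr, _, _ = threshold_pair(net_a, net_b)
            for t, grp in a_thr.edges.groupby("edge_type"):
                total = (net_a.edges["edge_type"] == t).sum()
                assert 0.45 <= len(grp) / total <= 0.55

    def test_missing_reference_edge_type_is_error(self):
        net_a = make_net([("A", "B", 0.5)])
        net_b = make_net([("A", "B-T1", 0.5)])
        with pytest.raises(ValueError, match="TE-IR"):
            threshold_pair(net_a, net_b)

    def test_refuses_thresholded_input(self):
        net_a = make_net([("A", "B", 0.5)], thresholded=True)
        net_b = make_net([("A", "B", 0.5)])
        with pytest.raises(ValueError):
            threshold_pair(net_a, net_b)
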