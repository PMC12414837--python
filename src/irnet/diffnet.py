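"""Differential network analysis between two MI networks.

Covers hub identification (degree >= k), common hubs, partition of
common-hub edges into unique / shared / attenuated classes, master hubs
(connectivity fold change against the unthresholded other network),
neighborhood extraction, modality (TE/IR) subnetwork comparison and hub
modality composition.

An edge of one thresholded network is *unique* only if it is absent from
the **unthresholded** version of the other network, so weak-but-present
edges in the other group never count as rewiring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import pandas as pd

from .netinfer import MINetwork

__all__ = [
    "identify_hubs", "common_hubs", "EdgePartition",
    "partition_common_hub_edges", "unique_percentage", "master_hubs",
    "neighborhood", "ModalitySplit", "modality_subnetworks",
    "hub_modality_composition",
]

Edge = tuple[str, str]


def identify_hubs(net: MINetwork, k: int = 10) -> pd.DataFrame:
    """Degree table with an ``is_hub`` flag at ``degree >= k`` (inclusive)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    deg = net.degrees()
    out = net.nodes.copy()
    out["degree"] = deg
    out["is_hub"] = deg >= k
    return out


def common_hubs(hubs_a: pd.DataFrame, hubs_b: pd.DataFrame) -> set[str]:
    """Node ids flagged as hubs in both tables."""
    return set(hubs_a.index[hubs_a["is_hub"]]) & set(hubs_b.index[hubs_b["is_hub"]])


@dataclass
class EdgePartition:
    """Partition of common-hub-incident edges of two thresholded networks.

    ``unique_a`` edges of thresholded A are absent from *unthresholded* B;
    ``shared`` edges appear in both thresholded networks; ``attenuated_a``
    edges appear in B only before thresholding. The five sets are pairwise
    disjoint.
    """

    unique_a: set[Edge]
    unique_b: set[Edge]
    shared: set[Edge]
    attenuated_a: set[Edge]
    attenuated_b: set[Edge]

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        return {
            "unique_a": unique_percentage(len(self.unique_a), len(self.shared),
                                          len(self.attenuated_a), decimals=decimals),
            "unique_b": unique_percentage(len(self.unique_b), len(self.shared),
                                          len(self.attenuated_b), decimals=decimals),
        }

    def counts(self) -> dict[str, int]:
        return {k: len(getattr(self, k)) for k in
                ("unique_a", "unique_b", "shared", "attenuated_a", "attenuated_b")}


def unique_percentage(n_unique: int, n_shared: int, n_attenuated: int = 0,
                      decimals: int = 1) -> float:
    """Share of unique edges among all partitioned edges, as a percentage."""
    total = n_unique + n_shared + n_attenuated
    if total == 0:
        return 0.0
    return round(100.0 * n_unique / total, decimals)


def _incident_edges(net: MINetwork, hubs: set[str]) -> set[Edge]:
    e = net.edges
    mask = e["node_a"].isin(hubs) | e["node_b"].isin(hubs)
    return set(zip(e.loc[mask, "node_a"], e.loc[mask, "node_b"]))


def partition_common_hub_edges(a_thr: MINetwork, b_thr: MINetwork,
                               a_raw: MINetwork, b_raw: MINetwork,
                               hubs: set[str]) -> EdgePartition:
    """Classify each common-hub-incident edge of the two thresholded
    networks as unique, shared, or attenuated (present only in the other
    network's unthresholded parent)."""
    for net, name in ((a_thr, "thresholded A"), (b_thr, "thresholded B")):
        absent = hubs - set(net.nodes.index)
        if absent:
            raise KeyError(f"hub(s) missing from {name}: {sorted(absent)[:5]}")
    ea = _incident_edges(a_thr, hubs)
    eb = _incident_edges(b_thr, hubs)
    raw_a = a_raw.edge_keys()
    raw_b = b_raw.edge_keys()
    thr_a = a_thr.edge_keys()
    thr_b = b_thr.edge_keys()
    shared = (ea & thr_b) | (eb & thr_a)
    return EdgePartition(
        unique_a={e for e in ea if e not in raw_b},
        unique_b={e for e in eb if e not in raw_a},
        shared=shared,
        attenuated_a={e for e in ea if e in raw_b and e not in thr_b} - shared,
        attenuated_b={e for e in eb if e in raw_a and e not in thr_a} - shared,
    )


def master_hubs(focal_thr: MINetwork, other_raw: MINetwork, k: int = 10,
                min_fold: float = 2.0) -> pd.DataFrame:
    """Nodes of the thresholded focal network whose degree is >= ``k`` and
    at least ``min_fold`` times their degree in the *unthresholded* other
    network.

    A node absent (or isolated) in the other network has infinite fold and
    qualifies on degree alone. Sorted by focal degree descending, ties by
    node id, so "top master hubs" is well defined; rows at exactly the
    fold boundary are flagged.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if other_raw.thresholded:
        raise ValueError("other_raw must be the unthresholded network")
    deg_f = focal_thr.degrees()
    deg_o = other_raw.degrees()
    rows = []
    for node, d in deg_f.items():
        if d < k:
            continue
        d_other = int(deg_o.get(node, 0))
        fold = math.inf if d_other == 0 else d / d_other
        if fold >= min_fold:
            rows.append((node, focal_thr.nodes.at[node, "modality"],
                         focal_thr.nodes.at[node, "gene_id"], int(d), d_other,
                         fold, fold == min_fold))
    out = pd.DataFrame(rows, columns=["node_id", "modality", "gene_id",
                                      "degree_focal", "degree_other_unthresh",
                                      "fold", "at_fold_boundary"])
    out = out.sort_values(["degree_focal", "node_id"],
                          ascending=[False, True], kind="stable")
    return out.set_index("node_id")


def neighborhood(net: MINetwork, seeds: set[str], hops: int,
                 include_seeds: bool = True) -> set[str]:
    """All nodes within ``hops`` (1 or 2) edges of any seed node."""
    if hops not in (1, 2):
        raise ValueError("hops must be 1 or 2")
    missing = set(seeds) - set(net.nodes.index)
    if missing:
        raise KeyError(f"seed(s) not in network: {sorted(missing)[:5]}")
    adj = net.adjacency()
    frontier = set(seeds)
    reached = set(seeds)
    for _ in range(hops):
        frontier = {v for u in frontier for v in adj[u]} - reached
        reached |= frontier
    return reached if include_seeds else reached - set(seeds)


@dataclass
class ModalitySplit:
    """TE-TE vs IR-IR subnetwork comparison for one network.

    IR-IR edges are mapped to unordered parent-gene pairs; a TE-TE edge is
    unique when its gene pair is absent from the gene-mapped IR-IR set,
    and vice versa.
    """

    te_te_edges: set[Edge]
    ir_ir_edges: set[Edge]
    te_te_gene_pairs: set[Edge]
    ir_ir_gene_pairs: set[Edge]
    unique_te_te: int
    unique_ir_ir: int
    pct_unique_te_te: float
    pct_unique_ir_ir: float


def _int_pct(num: int, den: int, mode: str) -> float:
    if den == 0:
        return 0.0
    raw = 100.0 * num / den
    if mode == "floor":
        return float(math.floor(raw))
    if mode == "round":
        return float(round(raw))           # banker's rounding
    if mode == "exact":
        return raw
    raise ValueError(f"unknown rounding mode {mode!r}")


def modality_split(net: MINetwork, mode: str = "floor") -> ModalitySplit:
    """Compare one network's TE-TE and IR-IR subnetworks on the gene level."""
    e = net.edges
    gene = net.nodes["gene_id"]
    te = e[e["edge_type"] == "TE-TE"]
    ir = e[e["edge_type"] == "IR-IR"]
    te_pairs = set(zip(te["node_a"], te["node_b"]))
    ir_pairs = set(zip(ir["node_a"], ir["node_b"]))
    te_gene = {tuple(sorted((gene[a], gene[b]))) for a, b in te_pairs}
    ir_gene = {tuple(sorted((gene[a], gene[b]))) for a, b in ir_pairs}
    uniq_te = sum(1 for a, b in te_pairs
                  if tuple(sorted((gene[a], gene[b]))) not in ir_gene)
    uniq_ir = sum(1 for a, b in ir_pairs
                  if tuple(sorted((gene[a], gene[b]))) not in te_gene)
    return ModalitySplit(
        te_te_edges=te_pairs, ir_ir_edges=ir_pairs,
        te_te_gene_pairs=te_gene, ir_ir_gene_pairs=ir_gene,
        unique_te_te=uniq_te, unique_ir_ir=uniq_ir,
        pct_unique_te_te=_int_pct(uniq_te, len(te_pairs), mode),
        pct_unique_ir_ir=_int_pct(uniq_ir, len(ir_pairs), mode),
    )


def modality_subnetworks(a_thr: MINetwork, b_thr: MINetwork, mode: str = "floor"
                         ) -> dict[str, ModalitySplit]:
    """Per-network TE-TE vs IR-IR comparison for a thresholded pair."""
    out = {}
    for net, default in ((a_thr, "a"), (b_thr, "b")):
        if net.nodes["gene_id"].isna().any():
            raise ValueError("nodes without gene_id")
        out[net.group_label or default] = modality_split(net, mode=mode)
    return out


def hub_modality_composition(net: MINetwork, thresholds: list[int] | None = None
                             ) -> pd.DataFrame:
    """TE/IR counts and IR proportion among nodes with degree >= each
    threshold (default thresholds 10, 15, 20)."""
    thresholds = [10, 15, 20] if thresholds is None else thresholds
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    deg = net.degrees()
    rows = []
    for t in thresholds:
        sel = net.nodes.loc[deg[deg >= t].index]
        n_te = int((sel["modality"] == "TE").sum())
        n_ir = int((sel["modality"] == "IR").sum())
        prop = n_ir / (n_te + n_ir) if (n_te + n_ir) else 0.0
        rows.append((t, n_te, n_ir, prop))
    return pd.DataFrame(rows, columns=["threshold", "n_te", "n_ir",
                                       "ir_proportion"]).set_index("threshold")
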