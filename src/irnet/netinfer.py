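"""ARACNE-style mutual-information network inference over combined
total-expression (TE) and isoform-ratio (IR) features.

Pipeline per group: pairwise MI estimation -> data processing inequality
(DPI) pruning of indirect edges -> removal of edges connecting features of
the same gene. Two inferred networks are then made comparable by
thresholding both at the median MI per edge type of the reference
(affected) network.

The default MI estimator is the Gaussian copula: features are
rank-transformed to normal scores and MI = -1/2 ln(1 - rho^2) in nats,
with rho the Pearson correlation of the scores. A binned plug-in
estimator with Miller-Madow bias correction is provided as an
alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["MIParams", "MINetwork", "estimate_mi", "prune_dpi",
           "strip_same_gene_edges", "infer_network", "threshold_pair",
           "edge_type_of"]

_MODALITY_ORDER = {"TE": 0, "IR": 1}


def edge_type_of(mod_a: str, mod_b: str) -> str:
    pair = sorted((mod_a, mod_b), key=_MODALITY_ORDER.__getitem__)
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class MIParams:
    """Mutual-information estimation and DPI settings.

    ``mi_alpha`` is the significance level of the analytic edge filter
    applied before the DPI, mirroring the MI p-value threshold standard
    ARACNE implementations use: under independence the copula estimate
    satisfies ``2 n MI ~ chi-square(1)``, so pairs whose MI is not
    significant at ``mi_alpha`` are discarded as candidate edges. Set to
    ``None`` to retain every positive-MI pair.
    """

    estimator: str = "gaussian-copula"   # or "binned"
    dpi_tolerance: float = 0.0
    n_bins: int = 8
    mi_alpha: float | None = 1e-3

    def validate(self) -> None:
        if self.estimator not in ("gaussian-copula", "binned"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not (0.0 <= self.dpi_tolerance < 1.0):
            raise ValueError("dpi_tolerance must lie in [0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mi_alpha is not None and not (0.0 < self.mi_alpha < 1.0):
            raise ValueError("mi_alpha must lie in (0, 1) or be None")

    def mi_floor(self, n_samples: int) -> float:
        """Smallest MI (nats) deemed significant at ``mi_alpha``."""
        if self.mi_alpha is None:
            return 0.0
        return float(stats.chi2.ppf(1.0 - self.mi_alpha, df=1) / (2.0 * n_samples))


@dataclass
class MINetwork:
    """Undirected MI-weighted network over typed (TE/IR) nodes.

    ``nodes`` is indexed by node_id with columns ``modality`` and
    ``gene_id``; ``edges`` has columns ``node_a``, ``node_b``, ``mi``,
    ``edge_type`` with ``node_a < node_b`` canonically.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    thresholded: bool = False
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.edges is None or len(self.edges) == 0:
            self.edges = pd.DataFrame(columns=["node_a", "node_b", "mi", "edge_type"])

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["node_a"], self.edges["node_b"]))

    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes.index, dtype=int)
        if len(self.edges):
            counts = pd.concat([self.edges["node_a"], self.edges["node_b"]]).value_counts()
            deg.loc[counts.index] = counts.astype(int)
        return deg

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes.index}
        for a, b in zip(self.edges["node_a"], self.edges["node_b"]):
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for nid, row in self.nodes.iterrows():
            g.add_node(nid, modality=row["modality"], gene_id=row["gene_id"])
        for _, e in self.edges.iterrows():
            g.add_edge(e["node_a"], e["node_b"], mi=float(e["mi"]),
                       edge_type=e["edge_type"])
        return g

    def with_edges(self, edges: pd.DataFrame, thresholded: bool | None = None
                   ) -> "MINetwork":
        return MINetwork(nodes=self.nodes.copy(), edges=edges.reset_index(drop=True),
                         thresholded=self.thresholded if thresholded is None else thresholded,
                         group_label=self.group_label)


def _normal_scores(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    return stats.norm.ppf(ranks / (n + 1.0))


def estimate_mi(expr: pd.DataFrame, params: MIParams | None = None) -> pd.DataFrame:
    """Symmetric pairwise MI matrix (nats) over the rows of ``expr``.

    Gaussian-copula estimator: rank-transform each feature to normal
    scores and apply the bivariate-normal closed form to their Pearson
    correlations. Binned estimator: equal-frequency bins, plug-in MI with
    Miller-Madow bias correction. Constant features are rejected.
    """
    params = params or MIParams()
    params.validate()
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(np.asarray(expr.index)[sd == 0][:5])
        raise ValueError(f"constant features: {bad}")
    if params.estimator == "gaussian-copula":
        S = _normal_scores(X)
        r = np.corrcoef(S)
        r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-12)
        mi = -0.5 * np.log1p(-r2)
    else:
        mi = _binned_mi_matrix(X, params.n_bins)
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=expr.index, columns=expr.index)


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _binned_mi_matrix(X: np.ndarray, n_bins: int) -> np.ndarray:
    p, n = X.shape
    B = np.vstack([_bin_indices(X[i], n_bins) for i in range(p)])
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (B[i], B[j]), 1.0)
            pj = joint / n
            px = pj.sum(axis=1, keepdims=True)
            py = pj.sum(axis=0, keepdims=True)
            nz = pj > 0
            val = float((pj[nz] * np.log(pj[nz] / (px @ py)[nz])).sum())
            # Miller-Madow bias correction
            kxy = int(nz.sum())
            kx = int((px > 0).sum())
            ky = int((py > 0).sum())
            val += (kxy - kx - ky + 1) / (2.0 * n)
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def _dpi_keep_mask(W: np.ndarray, eps: float) -> np.ndarray:
    """Boolean keep-mask for edges under the DPI.

    ``W`` holds MI for present edges and ``-inf`` for absent pairs (and the
    diagonal). Edge (i, j) is removed when some third node k with both
    (i, k) and (j, k) present satisfies
    ``W[i, j] < min(W[i, k], W[j, k]) - eps``. All marks are computed on
    the input graph and applied simultaneously.
    """
    n = W.shape[0]
    keep = np.ones((n, n), dtype=bool)
    for i in range(n):
        # T[j] = max_k min(W[i, k], W[j, k]); k = i, j excluded via -inf
        T = np.minimum(W[i][None, :], W).max(axis=1)
        keep[i] = ~(W[i] < T - eps)
    keep &= keep.T  # symmetric by construction; belt and braces
    keep &= np.isfinite(W)
    return keep


def prune_dpi(edges: pd.DataFrame, eps: float = 0.0) -> pd.DataFrame:
    """Apply the data processing inequality to a weighted edge list.

    For every triangle, the strictly weakest edge (by more than ``eps``)
    is removed; removals are simultaneous, so the result does not depend
    on edge order, and the strict maximum edge of a triangle is never
    removed.
    """
    if eps < 0:
        raise ValueError("dpi tolerance must be >= 0")
    if len(edges) == 0:
        return edges.copy()
    nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.full((len(nodes), len(nodes)), -np.inf)
    ai = edges["node_a"].map(idx).to_numpy()
    bi = edges["node_b"].map(idx).to_numpy()
    W[ai, bi] = edges["mi"].to_numpy(dtype=float)
    W[bi, ai] = edges["mi"].to_numpy(dtype=float)
    keep = _dpi_keep_mask(W, eps)
    return edges.loc[keep[ai, bi]].reset_index(drop=True)


def strip_same_gene_edges(net: MINetwork) -> MINetwork:
    """Drop edges whose endpoints belong to the same gene (TE-IR of one
    gene, or sibling IR-IR pairs)."""
    if net.nodes["gene_id"].isna().any():
        missing = list(net.nodes.index[net.nodes["gene_id"].isna()][:5])
        raise ValueError(f"nodes without gene_id: {missing}")
    g = net.nodes["gene_id"]
    same = g.loc[net.edges["node_a"]].to_numpy() == g.loc[net.edges["node_b"]].to_numpy()
    return net.with_edges(net.edges.loc[~same])


def _network_from_mi(mi: pd.DataFrame, nodes: pd.DataFrame, eps: float,
                     group_label: str, mi_floor: float = 0.0) -> MINetwork:
    W = mi.to_numpy(dtype=float).copy()
    W[W <= max(mi_floor, 0.0)] = -np.inf
    np.fill_diagonal(W, -np.inf)
    keep = _dpi_keep_mask(W, eps)
    iu = np.triu_indices(W.shape[0], k=1)
    present = keep[iu] & np.isfinite(W[iu])
    ids = np.asarray(mi.index)
    a = ids[iu[0][present]]
    b = ids[iu[1][present]]
    # canonical order node_a < node_b
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    mods = nodes["modality"]
    edges = pd.DataFrame({
        "node_a": a2, "node_b": b2, "mi": W[iu][present],
        "edge_type": [edge_type_of(mods[x], mods[y]) for x, y in zip(a2, b2)],
    })
    return MINetwork(nodes=nodes, edges=edges, thresholded=False,
                     group_label=group_label)


def infer_network(te: pd.DataFrame, ir: pd.DataFrame, gene_of: pd.Series,
                  sample_ids: list[str], params: MIParams | None = None,
                  group_label: str = "", min_samples: int = 20) -> MINetwork:
    """Infer one group's MI network from TE and IR matrices.

    TE nodes are genes (gene_id = the gene itself); IR nodes are
    transcripts with their parent gene from ``gene_of``. The network is
    estimated on the ``sample_ids`` subset only, DPI-pruned, and stripped
    of same-gene edges. Isolated nodes are retained so node counts stay
    reportable.
    """
    params = params or MIParams()
    if len(sample_ids) < min_samples:
        logger.warning("only %d samples for group %r: reduced inference power "
                       "at small sample size", len(sample_ids), group_label)
    te_sub = te[sample_ids]
    ir_sub = ir[sample_ids]
    nodes = pd.DataFrame({
        "modality": ["TE"] * len(te_sub) + ["IR"] * len(ir_sub),
        "gene_id": list(te_sub.index) + list(gene_of.loc[ir_sub.index]),
    }, index=pd.Index(list(te_sub.index) + list(ir_sub.index), name="node_id"))
    if nodes.index.duplicated().any():
        raise ValueError("TE and IR feature ids overlap")
    combined = pd.concat([te_sub, ir_sub], axis=0)
    mi = estimate_mi(combined, params)
    net = _network_from_mi(mi, nodes, params.dpi_tolerance, group_label,
                           mi_floor=params.mi_floor(len(sample_ids)))
    return strip_same_gene_edges(net)


def threshold_pair(net_a: MINetwork, net_b: MINetwork
                   ) -> tuple[MINetwork, MINetwork, dict[str, float]]:
    """Threshold both networks at the median MI per edge type of ``net_a``.

    ``net_a`` is the reference (affected) network; for each edge type the
    threshold is the median MI of its edges of that type, and both
    networks keep edges with ``mi >= threshold`` (ties retained, so the
    reference keeps about half its edges per type).
    """
    if net_a.thresholded or net_b.thresholded:
        raise ValueError("threshold_pair expects unthresholded networks")
    types_needed = set(net_a.edges["edge_type"]) | set(net_b.edges["edge_type"])
    thresholds: dict[str, float] = {}
    for t in sorted(types_needed):
        vals = net_a.edges.loc[net_a.edges["edge_type"] == t, "mi"]
        if len(vals) == 0:
            raise ValueError(f"edge type {t!r} absent from the reference network")
        thresholds[t] = float(vals.median())

    def _apply(net: MINetwork) -> MINetwork:
        thr = net.edges["edge_type"].map(thresholds).to_numpy(dtype=float)
        kept = net.edges.loc[net.edges["mi"].to_numpy() >= thr]
        return net.with_edges(kept, thresholded=True)

    return _apply(net_a), _apply(net_b), thresholds
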