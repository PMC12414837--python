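"""Reading and writing of the pipeline's file formats.

Count matrices and tables are TSV (MatrixMarket accepted for counts);
networks round-trip through GraphML (node attributes ``modality`` and
``gene_id``, edge attribute ``mi``) or TSV edge lists. Outputs carry the
seed and a config digest in a header comment.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netinfer import MINetwork, edge_type_of

__all__ = [
    "read_counts", "read_sample_table", "read_feature_map",
    "write_matrix", "export_network", "read_network_graphml",
    "read_network_tsv", "annotate_nodes", "config_digest",
]


def config_digest(obj) -> str:
    """Short stable digest of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples count matrix from TSV or MatrixMarket.

    For ``.mtx`` input, row and column names are taken from sidecar files
    ``<stem>.rows.txt`` and ``<stem>.cols.txt`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path))
        rows = (path.with_suffix("").parent / (path.stem + ".rows.txt")).read_text().split()
        cols = (path.with_suffix("").parent / (path.stem + ".cols.txt")).read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df


def read_sample_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    tbl = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "group" not in tbl.columns:
        raise ValueError("sample table must contain a 'group' column")
    if tbl["group"].isna().any():
        raise ValueError("missing group labels in sample table")
    return tbl


def read_feature_map(path: str | Path) -> pd.DataFrame:
    fm = pd.read_csv(path, sep="\t", comment="#")
    if not {"transcript_id", "gene_id"} <= set(fm.columns):
        raise ValueError("feature map needs transcript_id and gene_id columns")
    return fm


def write_matrix(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                 digest: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None or digest is not None:
            fh.write(f"# seed={seed} config={digest}\n")
        df.to_csv(fh, sep="\t")


def export_network(net: MINetwork, path: str | Path, fmt: str = "graphml",
                   seed: int | None = None, digest: str | None = None) -> Path:
    """Write a network as GraphML or a TSV edge list; round-trip exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        g = net.to_networkx()
        g.graph["thresholded"] = bool(net.thresholded)
        g.graph["group_label"] = net.group_label
        if seed is not None:
            g.graph["seed"] = int(seed)
        if digest is not None:
            g.graph["config_digest"] = digest
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# thresholded={net.thresholded} group={net.group_label} "
                     f"seed={seed} config={digest}\n")
            net.edges.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_network_graphml(path: str | Path) -> MINetwork:
    g = nx.read_graphml(path)
    nodes = pd.DataFrame(
        {"modality": [g.nodes[n]["modality"] for n in g.nodes],
         "gene_id": [g.nodes[n]["gene_id"] for n in g.nodes]},
        index=pd.Index(list(g.nodes), name="node_id"))
    rows = []
    for a, b, d in g.edges(data=True):
        x, y = (a, b) if a < b else (b, a)
        rows.append((x, y, float(d["mi"]),
                     d.get("edge_type") or edge_type_of(g.nodes[x]["modality"],
                                                        g.nodes[y]["modality"])))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "mi", "edge_type"])
    edges = edges.sort_values(["node_a", "node_b"]).reset_index(drop=True)
    return MINetwork(nodes=nodes, edges=edges,
                     thresholded=bool(g.graph.get("thresholded", False)),
                     group_label=str(g.graph.get("group_label", "")))


def read_network_tsv(path: str | Path, nodes: pd.DataFrame) -> MINetwork:
    edges = pd.read_csv(path, sep="\t", comment="#")
    return MINetwork(nodes=nodes, edges=edges)


def annotate_nodes(table: pd.DataFrame, annotation_path: str | Path
                   ) -> pd.DataFrame:
    """Left-join flag columns from a node annotation TSV onto a hub or
    master-hub table; missing annotations become the string ``unknown``.

    The annotation file needs a ``node_id`` header column; duplicate node
    ids are rejected. No rows of ``table`` are dropped.
    """
    ann = pd.read_csv(annotation_path, sep="\t", comment="#", dtype=str)
    if "node_id" not in ann.columns:
        raise ValueError("annotation file needs a node_id column")
    if ann["node_id"].duplicated().any():
        dups = ann.loc[ann["node_id"].duplicated(), "node_id"].tolist()[:5]
        raise ValueError(f"duplicate node_id in annotation file: {dups}")
    ann = ann.set_index("node_id")
    out = table.join(ann, how="left")
    for c in ann.columns:
        out[c] = out[c].where(out[c].notna(), "unknown")
    return out
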