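import dataclasses

import numpy as np
import pandas as pd
import pytest

from irnet.netinfer import MINetwork, edge_type_of
from irnet.simulate import SimConfig, build_ground_truth, simulate_counts


def make_net(edges, modality=None, extra_nodes=(), thresholded=False,
             group_label=""):
    """Build an MINetwork from an edge list of (a, b, mi) tuples.

    Node modality defaults to TE with gene_id = node id; transcript-style
    ids containing ``-T`` become IR nodes of their prefix gene.
    ``modality`` may override per node.
    """
    modality = modality or {}
    node_ids = sorted({n for a, b, _ in edges for n in (a, b)} | set(extra_nodes))
    mods, genes = [], []
    for n in node_ids:
        if n in modality:
            m = modality[n]
        else:
            m = "IR" if "-T" in n else "TE"
        mods.append(m)
        genes.append(n.split("-T")[0])
    nodes = pd.DataFrame({"modality": mods, "gene_id": genes},
                         index=pd.Index(node_ids, name="node_id"))
    rows = []
    for a, b, mi in edges:
        x, y = (a, b) if a < b else (b, a)
        rows.append((x, y, float(mi),
                     edge_type_of(nodes.at[x, "modality"], nodes.at[y, "modality"])))
    edf = pd.DataFrame(rows, columns=["node_a", "node_b", "mi", "edge_type"])
    return MINetwork(nodes=nodes, edges=edf, thresholded=thresholded,
                     group_label=group_label)


@pytest.fixture(scope="session")
def tiny_sim_config():
    return dataclasses.replace(
        SimConfig(), n_genes=60, n_modules=3, hubs_per_module=1,
        n_affected=40, n_unaffected=30, n_planted_master_hubs=2,
        n_switch_genes=4, n_de_features=4, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim_config):
    truth = build_ground_truth(tiny_sim_config, 7)
    gene, tx, samples, fmap = simulate_counts(truth, tiny_sim_config, 7)
    return truth, gene, tx, samples, fmap


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
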