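"""Two-group synthetic RNA-seq generator with known co-expression structure.

The generator produces gene-level and transcript-level count matrices for an
"affected" and an "unaffected" sample group, together with the generative
ground truth, so that every downstream stage of the pipeline (preprocessing,
differential expression, network inference, differential network analysis,
validation) can be tested against planted signal.

Model
-----
* Genes are organised into co-expression modules. Each module contains a
  small number of hub genes; every remaining (spoke) gene is attached to one
  hub of its module. A hub and its spokes share a latent Gaussian factor, so
  their counts co-vary on the log scale; the hub-spoke pairs form the true
  adjacency.
* Group-specific rewiring: a configurable fraction of hub-spoke edges exists
  in only one group (the spoke loads on the hub factor only in that group).
* Planted master hubs: selected hubs keep all their partners in the affected
  group but only ``floor(n_partners / master_hub_fold)`` of them in the
  unaffected group, creating a known connectivity fold change.
* Background co-expression: every gene is additionally weakly coupled to a
  few random partner genes (private pair factors, identical in both
  groups). These pairs emulate the large mass of weak edges real
  co-expression networks carry, so median-MI thresholding removes a weak
  background tier rather than hub spokes.
* Isoform-usage co-regulation: random gene pairs share a private factor on
  their isoform-usage logits (isoform-ratio IR-IR edges largely disjoint
  from the TE-TE structure), and further pairs couple one gene's total
  expression to another gene's usage (TE-IR edges). A mild coupling of
  usage to the module factor is also present; the corresponding hub-IR
  dependences are indirect (mediated by the spoke's own expression) and a
  correct inference should prune them.
* Gene counts are negative binomial with log-mean = baseline + factor
  loadings + covariate effects (+ group effect for planted DE genes),
  scaled to a sampled library size via a softmax over genes.
* Transcript counts are a Dirichlet-multinomial split of each gene's count,
  so they sum exactly to the gene count in every sample. "Switch" genes get
  an isoform-usage logit shift in the affected group with the gene total
  untouched — differential transcript expression without differential gene
  expression. A subset of genes couples their usage logits to the module
  factor, creating true isoform-ratio (IR) co-expression.
* Nuisance covariates (batch, sex, age, BMI, five cell-type PCs) act on the
  log scale through gene-specific sensitivities.

All randomness flows from one :func:`numpy.random.default_rng` seed;
identical ``(config, seed)`` give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "GroundTruth", "build_ground_truth", "simulate_counts",
           "write_dataset"]


def _default_covariate_effects() -> dict[str, float]:
    # log-scale coefficient per unit of the (standardised) covariate,
    # multiplied by a per-gene N(0,1) sensitivity
    return {
        "batch": 0.10,
        "sex": 0.05,
        "age": 0.05,
        "bmi": 0.05,
        "ctpc1": 0.05, "ctpc2": 0.04, "ctpc3": 0.03,
        "ctpc4": 0.02, "ctpc5": 0.02,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-group generator.

    Defaults are desk-scale: 300 genes with 2-3 isoforms each, 150 affected
    vs 75 unaffected samples, half of the module edges group-specific and
    five planted master hubs at fold 2.5.
    """

    n_genes: int = 300
    isoforms_per_gene: tuple[int, int] = (2, 3)
    n_modules: int = 6
    hubs_per_module: int = 2
    n_affected: int = 150
    n_unaffected: int = 75
    rewire_fraction: float = 0.5
    n_planted_master_hubs: int = 5
    master_hub_fold: float = 2.5
    n_switch_genes: int = 10
    switch_effect: float = 2.0
    n_de_features: int = 10
    de_logfc: float = 1.0
    nb_dispersion: float = 10.0
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    hub_loading: float = 1.5
    hub_base_shift: float = 0.0
    hub_nb_size: float = 150.0
    spoke_loading: float = 0.85
    background_loading: float = 0.85
    background_partners: int = 2
    ir_coupling: float = 0.15
    ir_coupled_fraction: float = 0.5
    ir_pair_loading: float = 1.0
    te_ir_te_loading: float = 0.6
    te_ir_usage_loading: float = 1.0
    usage_logit_sd: float = 1.0
    dm_concentration: float = 60.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=_default_covariate_effects)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_modules, self.hubs_per_module) < 1:
            raise ValueError("n_genes, n_modules and hubs_per_module must be positive")
        if self.n_affected < 2 or self.n_unaffected < 2:
            raise ValueError("each group needs at least 2 samples")
        if not (0.0 <= self.rewire_fraction <= 1.0):
            raise ValueError("rewire_fraction must lie in [0, 1]")
        if self.master_hub_fold < 1.0:
            raise ValueError("master_hub_fold must be >= 1")
        n_hubs = self.n_modules * self.hubs_per_module
        if self.n_planted_master_hubs > n_hubs:
            raise ValueError(
                f"n_planted_master_hubs ({self.n_planted_master_hubs}) exceeds the "
                f"number of hubs ({n_hubs} = hubs_per_module x n_modules)")
        if n_hubs >= self.n_genes:
            raise ValueError("no spoke genes left: n_genes must exceed the hub count")
        lo, hi = self.libsize_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("library sizes must be integers")
        if lo < 1 or hi < lo:
            raise ValueError("invalid libsize_range")
        if self.isoforms_per_gene[0] < 1 or self.isoforms_per_gene[1] < self.isoforms_per_gene[0]:
            raise ValueError("invalid isoforms_per_gene range")


@dataclass
class GroundTruth:
    """Generative truth recorded alongside a simulated dataset."""

    module_membership: pd.DataFrame   # index gene_id; module, role, hub, n_isoforms
    adjacency_shared: frozenset       # unordered gene pairs present in both groups
    adjacency_affected: frozenset
    adjacency_unaffected: frozenset
    planted_master_hubs: dict         # gene -> {degree_affected, degree_unaffected, fold}
    switch_genes: dict                # gene -> usage-logit shift in affected group
    de_features: dict                 # gene -> true log2 fold change (affected - unaffected)
    ir_coupled_genes: frozenset
    background_pairs: frozenset = frozenset()  # weak TE pairs, shared by both groups
    ir_pairs: frozenset = frozenset()          # usage-coupled gene pairs (IR-IR edges)
    te_ir_pairs: frozenset = frozenset()       # (TE gene, usage gene) couplings

    def to_json(self) -> str:
        payload = {
            "module_membership": self.module_membership.reset_index().to_dict("records"),
            "adjacency_shared": sorted(map(list, self.adjacency_shared)),
            "adjacency_affected": sorted(map(list, self.adjacency_affected)),
            "adjacency_unaffected": sorted(map(list, self.adjacency_unaffected)),
            "planted_master_hubs": self.planted_master_hubs,
            "switch_genes": self.switch_genes,
            "de_features": self.de_features,
            "ir_coupled_genes": sorted(self.ir_coupled_genes),
            "background_pairs": sorted(map(list, self.background_pairs)),
            "ir_pairs": sorted(map(list, self.ir_pairs)),
            "te_ir_pairs": sorted(map(list, self.te_ir_pairs)),
        }
        return json.dumps(payload, indent=1)


def _edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Lay out modules, hubs, group-specific edges, planted master hubs,
    isoform switches and DE genes.

    Deterministic for a fixed ``(config, seed)``; ``seed`` defaults to
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_hubs = config.n_modules * config.hubs_per_module
    hubs = genes[:n_hubs]
    spokes = genes[n_hubs:]

    rows = []
    hub_module = {h: i % config.n_modules for i, h in enumerate(hubs)}
    for h in hubs:
        rows.append((h, hub_module[h], "hub", h))
    module_hubs = {m: [h for h in hubs if hub_module[h] == m]
                   for m in range(config.n_modules)}
    spoke_hub: dict[str, str] = {}
    for i, s in enumerate(spokes):
        m = i % config.n_modules
        h = module_hubs[m][int(rng.integers(len(module_hubs[m])))]
        spoke_hub[s] = h
        rows.append((s, m, "spoke", h))

    n_iso = rng.integers(config.isoforms_per_gene[0],
                         config.isoforms_per_gene[1] + 1, size=config.n_genes)
    membership = pd.DataFrame(rows, columns=["gene_id", "module", "role", "hub"])
    membership["n_isoforms"] = n_iso
    membership = membership.set_index("gene_id")

    planted = list(rng.choice(hubs, size=config.n_planted_master_hubs, replace=False)) \
        if config.n_planted_master_hubs else []
    planted_set = set(planted)

    shared, only_a, only_b = set(), set(), set()
    hub_spokes: dict[str, list[str]] = {h: [] for h in hubs}
    for s, h in spoke_hub.items():
        hub_spokes[h].append(s)

    planted_info: dict[str, dict] = {}
    for h in hubs:
        partners = hub_spokes[h]
        if h in planted_set:
            # all partners in the affected group, a reduced subset elsewhere
            k = int(len(partners) // config.master_hub_fold)
            keep_b = set(rng.choice(partners, size=k, replace=False)) if k else set()
            for s in partners:
                e = _edge(h, s)
                (shared if s in keep_b else only_a).add(e)
            fold = len(partners) / k if k else math.inf
            planted_info[h] = {"degree_affected": len(partners),
                               "degree_unaffected": k, "fold": fold}
        else:
            for s in partners:
                e = _edge(h, s)
                if rng.random() < config.rewire_fraction:
                    (only_a if rng.random() < 0.5 else only_b).add(e)
                else:
                    shared.add(e)

    adjacency_a = frozenset(shared | only_a)
    adjacency_b = frozenset(shared | only_b)

    multi = [g for g in genes if membership.at[g, "n_isoforms"] >= 2]
    n_switch = min(config.n_switch_genes, len(multi))
    switch = list(rng.choice(multi, size=n_switch, replace=False)) if n_switch else []
    switch_genes = {g: float(config.switch_effect) for g in switch}

    de_candidates = [g for g in genes if g not in switch_genes]
    n_de = min(config.n_de_features, len(de_candidates))
    de = list(rng.choice(de_candidates, size=n_de, replace=False)) if n_de else []
    de_features = {g: float(config.de_logfc * rng.choice([-1.0, 1.0])) for g in de}

    n_coupled = int(round(config.ir_coupled_fraction * len(multi)))
    coupled = frozenset(rng.choice(multi, size=n_coupled, replace=False)) \
        if n_coupled else frozenset()

    # weak background pairs: repeated random perfect matchings of all genes,
    # skipping collisions with module edges, earlier matchings and pairs
    # inside one module (which would shortcut the hub-spoke topology)
    module_of = membership["module"]
    background: set[tuple[str, str]] = set()
    for _ in range(config.background_partners):
        perm = rng.permutation(genes)
        for i in range(0, len(perm) - 1, 2):
            a, b = perm[i], perm[i + 1]
            if module_of[a] == module_of[b] or a in hub_module or b in hub_module:
                continue
            e = _edge(a, b)
            if e not in background:
                background.add(e)

    # cross-gene isoform-usage couplings: a matching of multi-isoform genes
    # (IR-IR edges) and directed TE->usage pairs (TE-IR edges), both across
    # modules so they stay independent of the hub-spoke structure
    ir_pairs: set[tuple[str, str]] = set()
    multi_spokes = [g for g in multi if g not in hub_module]
    perm = rng.permutation(multi_spokes)
    for i in range(0, len(perm) - 1, 2):
        a, b = perm[i], perm[i + 1]
        if module_of[a] != module_of[b]:
            ir_pairs.add(_edge(a, b))
    te_ir_pairs: set[tuple[str, str]] = set()
    usage_perm = rng.permutation(multi_spokes)
    te_perm = rng.permutation(spokes)
    for a, b in zip(te_perm, usage_perm):
        if a != b and module_of[a] != module_of[b]:
            te_ir_pairs.add((a, b))

    return GroundTruth(
        module_membership=membership,
        adjacency_shared=frozenset(shared),
        adjacency_affected=adjacency_a,
        adjacency_unaffected=adjacency_b,
        planted_master_hubs=planted_info,
        switch_genes=switch_genes,
        de_features=de_features,
        ir_coupled_genes=coupled,
        background_pairs=frozenset(background),
        ir_pairs=frozenset(ir_pairs),
        te_ir_pairs=frozenset(te_ir_pairs),
    )


def _covariate_table(config: SimConfig, rng: np.random.Generator,
                     sample_ids: list[str], groups: np.ndarray) -> pd.DataFrame:
    n = len(sample_ids)
    tbl = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    tbl["group"] = np.where(groups, "affected", "unaffected")
    tbl["batch"] = rng.integers(0, 2, size=n)
    tbl["sex"] = rng.integers(0, 2, size=n)
    tbl["age"] = np.round(rng.normal(45.0, 13.0, size=n), 1)
    tbl["bmi"] = np.round(rng.normal(25.0, 4.0, size=n), 1)
    for i in range(1, 6):
        tbl[f"ctpc{i}"] = rng.normal(0.0, 1.0, size=n)
    return tbl


def simulate_counts(truth: GroundTruth, config: SimConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw gene and transcript count matrices from the ground truth.

    Returns ``(gene_counts, tx_counts, samples, feature_map)`` where the
    count frames are features x samples, ``samples`` carries group labels,
    covariates and realised library sizes, and ``feature_map`` maps
    transcript ids to gene ids. Transcript counts of a gene sum exactly to
    the gene count in every sample.
    """
    config.validate()
    if len(truth.module_membership) == 0:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = list(truth.module_membership.index)
    n_genes = len(genes)
    n = config.n_affected + config.n_unaffected
    sample_ids = [f"S{i:04d}" for i in range(n)]
    affected = np.zeros(n, dtype=bool)
    affected[: config.n_affected] = True

    samples = _covariate_table(config, rng, sample_ids, affected)

    hubs = [g for g in genes if truth.module_membership.at[g, "role"] == "hub"]
    hub_idx = {h: i for i, h in enumerate(hubs)}
    factors = rng.normal(size=(len(hubs), n))  # latent factor per hub per sample

    base = rng.normal(0.0, 0.8, size=n_genes)
    is_hub = (truth.module_membership["role"] == "hub").to_numpy()
    base[is_hub] += config.hub_base_shift  # regulators kept well expressed
    cov_names = list(config.covariate_effects)
    sens = rng.normal(size=(n_genes, len(cov_names)))

    # standardised covariate design (binary covariates centred)
    X = np.empty((len(cov_names), n))
    for j, c in enumerate(cov_names):
        v = samples[c].to_numpy(dtype=float)
        sd = v.std()
        X[j] = (v - v.mean()) / (sd if sd > 0 else 1.0)

    W = np.tile(base[:, None], (1, n))
    W += sens @ (np.array([config.covariate_effects[c] for c in cov_names])[:, None] * X)

    adj_a = truth.adjacency_affected
    adj_b = truth.adjacency_unaffected
    col_a = np.where(affected)[0]
    col_b = np.where(~affected)[0]
    # per-gene mask of samples in which the gene's module edge is active;
    # usage coupling to the module factor follows the same mask
    module_mask = np.ones((n_genes, n))
    for gi, g in enumerate(genes):
        row = truth.module_membership.loc[g]
        if row["role"] == "hub":
            W[gi] += config.hub_loading * factors[hub_idx[g]]
        else:
            h = row["hub"]
            e = _edge(g, h)
            f = factors[hub_idx[h]]
            mask = np.zeros(n)
            if e in adj_a:
                mask[col_a] = 1.0
            if e in adj_b:
                mask[col_b] = 1.0
            module_mask[gi] = mask
            W[gi] += config.spoke_loading * f * mask
        if g in truth.de_features:
            W[gi, col_a] += truth.de_features[g] * math.log(2.0)

    gidx = {g: i for i, g in enumerate(genes)}
    if config.background_loading and truth.background_pairs:
        for a, b in sorted(truth.background_pairs):
            f = rng.normal(size=n)
            W[gidx[a]] += config.background_loading * f
            W[gidx[b]] += config.background_loading * f

    # private usage factors: IR-IR pairs shift both genes' first-isoform
    # logits; TE-IR pairs shift one gene's expression and the other's usage
    usage_shift: dict[str, np.ndarray] = {}

    def _add_usage(g: str, contrib: np.ndarray) -> None:
        usage_shift[g] = usage_shift.get(g, 0.0) + contrib

    for a, b in sorted(truth.ir_pairs):
        u = rng.normal(size=n)
        _add_usage(a, config.ir_pair_loading * u)
        _add_usage(b, config.ir_pair_loading * u)
    for a, b in sorted(truth.te_ir_pairs):
        u = rng.normal(size=n)
        W[gidx[a]] += config.te_ir_te_loading * u
        _add_usage(b, config.te_ir_usage_loading * u)

    libsizes = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1,
                            size=n)
    # softmax over genes per sample, scaled to the library size
    W -= W.max(axis=0, keepdims=True)
    P = np.exp(W)
    P /= P.sum(axis=0, keepdims=True)
    mu = P * libsizes[None, :]

    size = np.where(is_hub, config.hub_nb_size, config.nb_dispersion)[:, None]
    p_nb = size / (size + mu)
    gene_counts = rng.negative_binomial(size, p_nb).astype(np.int64)

    # --- Dirichlet-multinomial split into transcripts -----------------------
    tx_rows, tx_ids, tx_gene = [], [], []
    conc = config.dm_concentration
    for gi, g in enumerate(genes):
        m = int(truth.module_membership.at[g, "n_isoforms"])
        ids = [f"{g}-T{j + 1}" for j in range(m)]
        tx_ids.extend(ids)
        tx_gene.extend([g] * m)
        if m == 1:
            tx_rows.append(gene_counts[gi][None, :])
            continue
        logits = np.tile(rng.normal(0.0, config.usage_logit_sd, size=m)[:, None], (1, n))
        if g in truth.ir_coupled_genes:
            row = truth.module_membership.loc[g]
            h = g if row["role"] == "hub" else row["hub"]
            logits[0] += config.ir_coupling * factors[hub_idx[h]] * module_mask[gi]
        if g in usage_shift:
            logits[0] += usage_shift[g]
        if g in truth.switch_genes:
            logits[0, col_a] += truth.switch_genes[g]
        logits -= logits.max(axis=0, keepdims=True)
        usage = np.exp(logits)
        usage /= usage.sum(axis=0, keepdims=True)
        alpha = conc * usage
        # vectorised Dirichlet over samples via normalised gammas
        gam = rng.gamma(np.maximum(alpha, 1e-12))
        probs = gam / gam.sum(axis=0, keepdims=True)
        # sequential binomial thinning: exact multinomial, vectorised over samples
        remaining = gene_counts[gi].copy()
        rem_p = np.ones(n)
        counts = np.zeros((m, n), dtype=np.int64)
        for j in range(m - 1):
            frac = np.clip(probs[j] / np.maximum(rem_p, 1e-300), 0.0, 1.0)
            counts[j] = rng.binomial(remaining, frac)
            remaining -= counts[j]
            rem_p -= probs[j]
        counts[m - 1] = remaining
        tx_rows.append(counts)

    tx_counts = pd.DataFrame(np.vstack(tx_rows), index=pd.Index(tx_ids, name="feature_id"),
                             columns=sample_ids)
    gene_df = pd.DataFrame(gene_counts, index=pd.Index(genes, name="feature_id"),
                           columns=sample_ids)
    samples["library_size"] = gene_df.sum(axis=0).to_numpy()
    feature_map = pd.DataFrame({"transcript_id": tx_ids, "gene_id": tx_gene})
    return gene_df, tx_counts, samples, feature_map


def write_dataset(outdir: str | Path, gene_counts: pd.DataFrame,
                  tx_counts: pd.DataFrame, samples: pd.DataFrame,
                  feature_map: pd.DataFrame, truth: GroundTruth | None = None,
                  config: SimConfig | None = None) -> dict[str, Path]:
    """Write the simulated dataset as plain TSV (+ truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_counts": outdir / "gene_counts.tsv",
        "tx_counts": outdir / "transcript_counts.tsv",
        "samples": outdir / "samples.tsv",
        "feature_map": outdir / "transcript_gene_map.tsv",
    }
    gene_counts.to_csv(paths["gene_counts"], sep="\t")
    tx_counts.to_csv(paths["tx_counts"], sep="\t")
    samples.to_csv(paths["samples"], sep="\t")
    feature_map.to_csv(paths["feature_map"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = outdir / "ground_truth.json"
        paths["truth"].write_text(truth.to_json())
    if config is not None:
        paths["config"] = outdir / "sim_config.json"
        cfg = asdict(config)
        cfg["covariate_effects"] = dict(cfg["covariate_effects"])
        paths["config"].write_text(json.dumps(cfg, indent=1))
    return paths
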