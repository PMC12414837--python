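"""End-to-end orchestration: simulate or load data, preprocess, test for
differential expression, infer and threshold per-group networks, run the
differential network analysis and (optionally) the topology validation,
and write all artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


from . import diffexpr, diffnet, io, preprocess, validate
from .netinfer import MIParams, infer_network, threshold_pair
from .simulate import SimConfig, build_ground_truth, simulate_counts, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline", "preprocess_dataset"]

DEFAULT_COVARIATES = ["batch", "sex", "age", "bmi",
                      "ctpc1", "ctpc2", "ctpc3", "ctpc4", "ctpc5"]


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run.

    Exactly one of ``sim`` (synthetic mode) or the three input paths
    (``gene_counts_path``, ``tx_counts_path`` + ``samples_path`` and
    ``feature_map_path``) must be set.
    """

    sim: SimConfig | None = None
    gene_counts_path: str | None = None
    tx_counts_path: str | None = None
    samples_path: str | None = None
    feature_map_path: str | None = None

    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    min_count: int = 10
    min_frac: float = 0.95
    prior_count: float = 0.5
    outlier_sd: float = 2.0
    mi_params: MIParams = field(default_factory=MIParams)
    hub_degree: int = 10
    master_hub_fold: float = 2.0
    run_validation: bool = True
    perturb: validate.PerturbConfig = field(default_factory=validate.PerturbConfig)
    q_thresh: float = 0.05
    outdir: str | None = None
    seed: int = 0

    def validate_config(self) -> None:
        real = [self.gene_counts_path, self.tx_counts_path, self.samples_path,
                self.feature_map_path]
        if (self.sim is None) == (not any(real)):
            raise ValueError("set exactly one of: sim config, real input paths")
        if self.sim is None and not all(real):
            raise ValueError("real-data mode needs gene counts, transcript counts, "
                             "sample table and feature map paths")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # analysis identity is independent of where it lands
        return io.config_digest(d)


@dataclass
class SummaryReport:
    """Headline numbers of one pipeline run (node/edge counts per network
    and edge type before and after thresholding, hub and master-hub
    counts, edge-partition and modality-split percentages, DE counts and
    validation accuracy)."""

    seed: int
    config_digest: str
    network_stats: dict
    n_de_genes: int
    n_de_transcripts: int
    n_isoform_specific: int
    n_hubs_a: int
    n_hubs_b: int
    n_common_hubs: int
    partition_counts: dict
    partition_percentages: dict
    n_master_hubs_a: int
    n_master_hubs_b: int
    master_hub_modality_a: dict
    modality_split: dict
    validation_accuracy: float | None
    outlier_samples: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, default=str)


def _edge_type_counts(net) -> dict:
    counts = net.edges["edge_type"].value_counts().to_dict()
    return {"n_nodes": int(len(net.nodes)), "n_edges": int(len(net.edges)),
            **{f"n_{t.replace('-', '_')}": int(c) for t, c in sorted(counts.items())}}


def preprocess_dataset(gene_counts, tx_counts, samples, feature_map, config):
    """Fixed preprocessing order: filter -> logCPM -> residualize ->
    drop-negative -> isoform ratios -> PCA outlier removal.

    Returns ``(te, tx_expr, ir, gene_of, samples, outliers)``; the
    expression and ratio matrices are restricted to inlier samples.
    ``tx_expr`` is the full corrected transcript matrix (used for DE);
    ``ir`` keeps only transcripts whose gene survived filtering.
    """
    genes_f = preprocess.filter_features(gene_counts, config.min_count, config.min_frac)
    tx_f = preprocess.filter_features(tx_counts, config.min_count, config.min_frac)
    gene_log = preprocess.logcpm(genes_f, config.prior_count)
    tx_log = preprocess.logcpm(tx_f, config.prior_count)
    gene_corr = preprocess.residualize(gene_log, samples, config.covariates)
    tx_corr = preprocess.residualize(tx_log, samples, config.covariates)
    gene_corr = preprocess.drop_negative_features(gene_corr)
    tx_corr = preprocess.drop_negative_features(tx_corr)
    # transcripts whose gene was filtered or dropped cannot form a ratio
    gmap = feature_map.set_index("transcript_id")["gene_id"]
    keep_tx = [t for t in tx_corr.index
               if t in gmap.index and gmap[t] in gene_corr.index]
    ir, gene_of = preprocess.compute_isoform_ratios(
        tx_corr.loc[keep_tx], gene_corr, feature_map)
    outliers = preprocess.detect_outlier_samples(gene_corr, ir, config.outlier_sd)
    inliers = [s for s in gene_corr.columns if s not in outliers]
    return (gene_corr[inliers], tx_corr[inliers], ir[inliers], gene_of,
            samples.loc[inliers], sorted(outliers))


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute the full analysis; write artifacts when ``outdir`` is set."""
    config.validate_config()
    digest = config.digest()
    t0 = time.time()

    def stage(name):
        logger.info("[%7.1fs] %s", time.time() - t0, name)

    stage("load/simulate")
    if config.sim is not None:
        truth = build_ground_truth(config.sim, config.seed)
        gene_counts, tx_counts, samples, feature_map = simulate_counts(
            truth, config.sim, config.seed)
    else:
        truth = None
        gene_counts = io.read_counts(config.gene_counts_path)
        tx_counts = io.read_counts(config.tx_counts_path)
        samples = io.read_sample_table(config.samples_path)
        feature_map = io.read_feature_map(config.feature_map_path)

    stage("preprocess")
    te, tx_expr, ir, gene_of, samples_in, outliers = preprocess_dataset(
        gene_counts, tx_counts, samples, feature_map, config)

    stage("differential expression")
    gene_de = diffexpr.moderated_de(te, samples_in, q_thresh=config.q_thresh)
    tx_de = diffexpr.moderated_de(tx_expr, samples_in, q_thresh=config.q_thresh)
    iso_specific, overlap = diffexpr.isoform_specific_de(
        gene_de, tx_de, feature_map, config.q_thresh)

    stage("network inference")
    ids_a = samples_in.index[samples_in["group"] == "affected"].tolist()
    ids_b = samples_in.index[samples_in["group"] == "unaffected"].tolist()
    net_a = infer_network(te, ir, gene_of, ids_a, config.mi_params, "affected")
    net_b = infer_network(te, ir, gene_of, ids_b, config.mi_params, "unaffected")

    stage("thresholding")
    a_thr, b_thr, thresholds = threshold_pair(net_a, net_b)

    stage("differential network analysis")
    hubs_a = diffnet.identify_hubs(a_thr, config.hub_degree)
    hubs_b = diffnet.identify_hubs(b_thr, config.hub_degree)
    common = diffnet.common_hubs(hubs_a, hubs_b)
    partition = diffnet.partition_common_hub_edges(a_thr, b_thr, net_a, net_b, common)
    mh_a = diffnet.master_hubs(a_thr, net_b, config.hub_degree, config.master_hub_fold)
    mh_b = diffnet.master_hubs(b_thr, net_a, config.hub_degree, config.master_hub_fold)
    splits = diffnet.modality_subnetworks(a_thr, b_thr)
    composition = diffnet.hub_modality_composition(a_thr)

    accuracy = None
    coords = None
    if config.run_validation:
        stage("topology validation")
        accuracy, coords = validate.separation_score(
            a_thr, b_thr, config.perturb, seed=config.seed)

    report = SummaryReport(
        seed=config.seed,
        config_digest=digest,
        network_stats={
            "affected_raw": _edge_type_counts(net_a),
            "unaffected_raw": _edge_type_counts(net_b),
            "affected_thresholded": _edge_type_counts(a_thr),
            "unaffected_thresholded": _edge_type_counts(b_thr),
            "thresholds": thresholds,
        },
        n_de_genes=int(gene_de["significant"].sum()),
        n_de_transcripts=int(tx_de["significant"].sum()),
        n_isoform_specific=len(iso_specific),
        n_hubs_a=int(hubs_a["is_hub"].sum()),
        n_hubs_b=int(hubs_b["is_hub"].sum()),
        n_common_hubs=len(common),
        partition_counts=partition.counts(),
        partition_percentages=partition.percentages(),
        n_master_hubs_a=len(mh_a),
        n_master_hubs_b=len(mh_b),
        master_hub_modality_a=mh_a["modality"].value_counts().to_dict(),
        modality_split={k: {"unique_te_te": v.unique_te_te,
                            "n_te_te": len(v.te_te_edges),
                            "pct_unique_te_te": v.pct_unique_te_te,
                            "unique_ir_ir": v.unique_ir_ir,
                            "n_ir_ir": len(v.ir_ir_edges),
                            "pct_unique_ir_ir": v.pct_unique_ir_ir}
                        for k, v in splits.items()},
        validation_accuracy=accuracy,
        outlier_samples=outliers,
    )

    if config.outdir:
        stage("write artifacts")
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        seed, dg = config.seed, digest
        if truth is not None:
            write_dataset(out / "data", gene_counts, tx_counts, samples,
                          feature_map, truth, config.sim)
        io.write_matrix(te, out / "te_corrected.tsv", seed, dg)
        io.write_matrix(ir, out / "isoform_ratios.tsv", seed, dg)
        (out / "outlier_samples.txt").write_text("\n".join(outliers) + "\n")
        gene_de.to_csv(out / "de_genes.tsv", sep="\t")
        tx_de.to_csv(out / "de_transcripts.tsv", sep="\t")
        (out / "isoform_specific_de.txt").write_text(
            "\n".join(sorted(iso_specific)) + "\n")
        for net, name in ((net_a, "affected_raw"), (net_b, "unaffected_raw"),
                          (a_thr, "affected_thresholded"),
                          (b_thr, "unaffected_thresholded")):
            io.export_network(net, out / f"network_{name}.graphml", "graphml", seed, dg)
        (out / "thresholds.json").write_text(json.dumps(thresholds, indent=1))
        hubs_a.to_csv(out / "hubs_affected.tsv", sep="\t")
        hubs_b.to_csv(out / "hubs_unaffected.tsv", sep="\t")
        mh_a.to_csv(out / "master_hubs_affected.tsv", sep="\t")
        mh_b.to_csv(out / "master_hubs_unaffected.tsv", sep="\t")
        composition.to_csv(out / "hub_modality_composition.tsv", sep="\t")
        if coords is not None:
            coords.to_csv(out / "validation_pca.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(report.to_json())
    stage("done")
    return report
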