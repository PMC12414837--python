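# irnet

Integrative gene + isoform-ratio co-expression network analysis for
two-group transcriptomic studies.

`irnet` asks how co-expression *wiring* — not just expression levels —
differs between two groups of individuals (for example affected vs
unaffected by a stress-related psychiatric condition). It builds, for each
group, a mutual-information network over two node modalities:

- **TE (total expression)** nodes: a gene's corrected log2-CPM expression;
- **IR (isoform ratio)** nodes: one transcript's corrected expression
  divided by its parent gene's, capturing relative isoform usage.

and then compares the two networks edge by edge and hub by hub. The package
ships a synthetic-data generator with planted ground truth, so every stage
of the analysis can be validated end to end without any downloads.

## Method

1. **Preprocessing** — features are kept when they have `count >= 10` in at
   least 95% of samples; counts are transformed to
   `log2((c + 0.5) / (libsize + 1) * 1e6)`; technical and biological
   covariates (batch, sex, age, BMI, cell-type principal components) are
   removed per feature by joint OLS; features driven negative by the
   correction are dropped; isoform ratios `IR(t, s) = tx(t, s) / gene(g(t), s)`
   are computed with a mean-imputation rule for 0/0 entries; samples beyond
   2 SD on PC1/PC2 of either matrix are excluded.
2. **Differential expression** — a moderated two-group t-test with
   empirical-Bayes variance shrinkage (prior variance a smooth function of
   mean expression), Benjamini–Hochberg FDR at 5%, and classification of
   *isoform-specific* differential expression: transcripts that change
   while their parent gene does not.
3. **Network inference** — ARACNE-style: pairwise mutual information by the
   Gaussian-copula estimator `MI = -0.5 ln(1 - rho^2)` on rank-normal
   scores (a binned Miller–Madow estimator is available), an analytic
   chi-square significance floor on candidate edges, the data processing
   inequality to prune the weakest edge of every triangle (simultaneous
   marks, order-independent), and removal of edges connecting features of
   the same gene. The affected-group network is the reference: both
   networks are thresholded at the median MI per edge type (TE-TE, TE-IR,
   IR-IR) of the reference, which retains roughly half of its edges.
4. **Differential network analysis** — hubs (`degree >= 10`), common hubs,
   the unique / shared / attenuated partition of common-hub edges (an edge
   is *unique* only if absent from the **unthresholded** other network),
   master hubs (`degree >= 10` and `>= 2`-fold the node's degree in the
   unthresholded other network), neighborhoods, TE-TE vs IR-IR subnetwork
   overlap, and hub modality composition.
5. **Topology validation** — each network seeds an ensemble of 100
   degree-biased edge-resampling surrogates; surrogates are embedded as
   hashed Weisfeiler–Lehman subtree feature vectors (128 dims), reduced by
   PCA, and a logistic regression is scored on repeated stratified 80/20
   splits. Accuracy near 0.5 means the two networks are indistinguishable;
   high accuracy means robustly distinct topology.

## Worked example

Run the full synthetic study from Python:

```python
from irnet import PipelineConfig, SimConfig, run_pipeline

report = run_pipeline(PipelineConfig(sim=SimConfig(), seed=1,
                                     outdir="results/demo"))
print(report.n_common_hubs, report.n_master_hubs_a,
      report.partition_percentages, round(report.validation_accuracy, 2))
```

With the default generator (300 genes with 2–3 isoforms each, 150 affected
vs 75 unaffected samples, half the module edges group-specific, five
planted master hubs at 2.5-fold connectivity) and seed 1 this prints:

```
5 5 {'unique_a': 45.6, 'unique_b': 37.9} 1.0
```

meaning: 5 hubs are common to both thresholded networks; 5 master hubs are
called in the affected network (the generator plants exactly 5); 45.6% of
the common hubs' affected-network edges (and 37.9% of their
unaffected-network edges) are unique to their network even against the
unthresholded counterpart; and the surrogate-graph classifier separates the
two networks' ensembles perfectly (accuracy 1.0), as expected under strong
planted rewiring. All artifacts (corrected
matrices, DE tables, GraphML networks, hub and master-hub tables, summary
JSON) land in `results/demo/`.

The same pipeline is available from the shell:

```bash
irnet simulate --seed 1 --outdir data/
irnet run-all --config config.yaml --seed 1 --outdir results/
```

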