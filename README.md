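# layerizer

Inference of laminar gene-expression patterning from layer-dissection
RNA-seq. The cerebral cortex is organised into cytoarchitectonic layers, but
layer dissections are imperfect — samples overlap layer boundaries and cells
cross them — so per-sample expression cannot be read directly as per-layer
expression. `layerizer` addresses this for anyone working with replicated
laminar dissections (samples `A, B1, B2, C, D, E, F`, superficial to deep):
it trains one naive Bayes classifier per cortical layer on curated marker
genes, calibrates the resulting probabilities, and calls genes, transcripts
and lincRNA loci as *patterned* (preferentially expressed in one or more
layers) or *unpatterned*.

## The model

For a feature with FPKM profile `x = (x_A, …, x_F)`, the classifier features
are the fractional profile `f_s = x_s / Σ_s x_s` plus `log10 Σ_s x_s`. For
each class `l ∈ {L2/3, L4, L5, L6, L6b, no_enrichment}` a binary naive Bayes
model with equal-frequency discretization gives

    P(l | x) ∝ P(l) · Π_j P(bin_j(f_j) | l),

cross-validated 10-fold and calibrated against out-of-fold positive
frequencies. A feature is *enriched* in layer `l` when the raw posterior
exceeds 0.5, and *patterned* when any layer is called. Because precision and
recall of each classifier are known from cross-validation, the predicted
count converts to an expected count of truly enriched genes:

    expected = round(predicted × precision / recall).

Downstream stages reuse the calibrated probabilities: isoform switching
(transcript pairs with opposite-direction non-overlapping FPKM CIs in some
sample pair *and* calibrated layer-probability vectors more than Euclidean
0.5 apart), functional enrichment of layer-predicted sets against a
classifier-bias-corrected simulation null (draws follow the classifier's
precision and false-positive contamination, with Storey q-values at 5% FDR),
and lincRNA locus statistics (intergenic multiexonic noncoding transcripts
clustered by span overlap, with adjacency/correlation/interval-overlap
permutation tests). See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic laminar atlas (200 genes per class, fold-4 enrichment,
log-normal noise 0.3, 10% curation label noise), train and cross-validate
the classifiers, and compare expected counts against the planted truth:

```python
import layerizer as lz

cfg = lz.AtlasConfig(n_genes_per_class=200, enrichment_fold=4.0,
                     noise_sd=0.3, label_noise_rate=0.1, seed=1)
atlas = lz.generate_atlas(cfg)
genes = [r for r in atlas.quant_table if r.feature_kind == "gene"]
cur = {c.gene_id: c for c in atlas.curations}
usable = [r for r in genes if lz.is_expressed(r) and lz.is_classifiable(r)]
curated = [r for r in usable if r.feature_id in cur]

fitted = lz.fit_layer_models(curated, cur, seed=101)
preds = lz.classify_all(genes, fitted.models, fitted.calibration_maps)
for layer in lz.LAYERS:
    cv = fitted.cv_reports[layer]
    n_pred = sum(1 for p in preds if layer in p.enriched_calls)
    print(layer, round(cv.auc, 2), n_pred,
          lz.expected_gene_count(n_pred, cv.precision, cv.recall))
```

Output (layer, out-of-fold AUC, predicted count, expected count):

```
L2/3 0.9 235 221
L4 0.92 188 186
L5 0.96 205 196
L6 0.94 220 207
L6b 0.93 231 212
```

Each classifier ranks held-out curated genes well (AUC 0.90–0.96), and the
expected-count correction recovers the planted 200 genes per class within
15% despite label noise deflating raw precision/recall: e.g. layer 6b
predicts 231 genes at precision 0.79 and recall 0.86, giving
`round(231 × 0.79 / 0.86) = 212` truly enriched genes.

The same pipeline runs from the shell:

```
layerizer simulate --out atlas --seed 1
layerizer all --indir atlas --out run --seed 1 --nsims 2000
```

which writes `predictions.tsv`, `cv_report.json`, `switch_calls.tsv`,
per-database enrichment tables (with `.significant.tsv` filtered at
q < 0.05), and lincRNA loci as BED plus a membership table, all with
provenance headers; reruns with the same seed are bit-identical.

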