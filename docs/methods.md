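# Methods

`layerizer` infers laminar expression patterning for genes and transcripts
from bulk RNA-seq of dissected cortical layer samples. This note records the
model, the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Data model

The ordered sample set is `A, B1, B2, C, D, E, F`: six adjacent laminar
dissections from superficial to deep, with `B1`/`B2` biological replicates of
the second segment. Each feature (gene or transcript) carries an FPKM point
estimate and a 95% confidence interval per sample. Dissections overlap layer
boundaries, so samples do not correspond one-to-one to layers; the classifier
absorbs that blurring rather than the data model.

Two filters define the analyzable universe:

* **expressed** — maximum FPKM across samples strictly above 0.1;
* **classifiable** — the widest 95% CI across samples at most 50% of the mean
  FPKM across samples (boundary inclusive). All-zero records pass this
  vacuously and are removed by the expression filter, which is applied first.

## Per-layer naive Bayes classifiers

One binary classifier per class: the five layers `L2/3, L4, L5, L6, L6b` and
`no_enrichment`. Curated layer-enrichment labels (from high-throughput
in-situ-hybridization curation in the real setting) supply positives; a gene
curated to several layers is a positive for each. Layer 1 has no classifier:
curated markers are insufficient to train one.

Features are the fractional expression profile (per-sample FPKM over the
across-sample sum; both replicates kept as separate dimensions) plus log10
total FPKM — eight features. Each feature is discretized into equal-frequency
bins (default 4) with edges fit on training data only; conditional
probabilities are Laplace-smoothed (pseudo-count 1). There are no tuned
hyperparameters; the defaults are fixed constants.

Two numerical details matter in near-degenerate data:

* feature values are rounded to 12 decimals, so profiles that are
  mathematically tied (pervasive in noise-free fixtures) discretize
  identically rather than splitting on float rounding;
* bin edges are snapped to midpoints between adjacent distinct observed
  values, so a run of tied observations can never straddle an edge. Without
  these, exact-tie fixtures produce arbitrary tie splits and the noise-free
  resubstitution AUC drops below 1 for no statistical reason.

Generalization is assessed by stratified 10-fold cross-validation (fixed,
recorded seed). AUC is the Mann-Whitney rank statistic over pooled
out-of-fold predictions; precision and recall are taken at the raw-posterior
threshold 0.5. The confusion of each classifier also yields a
*contamination* distribution: among false positives, the distribution of
their true curated classes (multi-layer curations split their weight). This
quantifies where a classifier's false calls come from and feeds the
enrichment null below.

A feature is called **enriched** in a layer when that layer's *raw* posterior
exceeds 0.5, and **patterned** when at least one layer is called. An
alternative criterion — maximum calibrated layer probability exceeding the
calibrated no-enrichment probability — is computed and reported alongside,
since the two disagree in the blurred-dissection regime.

### Probability calibration

Raw naive Bayes posteriors are overconfident, so each classifier gets a
smoothed calibration curve fit on its pooled out-of-fold predictions.
Construction: sort predictions; pool them into equal-count reliability bins
(~100 points each, binned separately on either side of 0.5 because NB
posteriors are strongly bimodal and global equal-count bins starve the
minority tail); shrink each bin's positive frequency toward a weighted cubic
trend in proportion to its binomial sampling variance (an empirical-Bayes
step: an already-calibrated classifier stays at the identity instead of
inheriting bin noise, while genuinely curved reliability keeps its shape);
smooth with a centred width-3 moving average; monotonize; interpolate
linearly between control points. Plain isotonic regression on raw
observations was rejected: its single-observation blocks carry ~0.06-0.07
sup-norm noise at n = 2000, which distorts already-calibrated probabilities.

### Expected counts

The expected number of truly enriched genes corrects the predicted count for
false positives and negatives: `round(predicted x precision / recall)`,
rounding half away from zero. The arithmetic runs in decimal on the printed
two-decimal precision/recall values, because binary floats can land one ulp
below an exact half (1001 x 0.42 / 0.52 must be exactly 808.5).

## Isoform switching

A gene with at least two classifiable transcripts is called as switching when:

1. some transcript pair has non-overlapping 95% CIs in a sample pair, in
   opposite directions (strict inequalities: touching CIs do not qualify;
   the witness search is lexicographic over ordered sample pairs, so the
   reported witness is deterministic); and
2. some pair's calibrated layer-probability vectors are more than Euclidean
   distance 0.5 apart. The distance uses the five layer dimensions only —
   including `no_enrichment` would double-count complementary mass. The
   reported distance is for the maximally distant pair.

The two conditions need not be satisfied by the same pair; whether one pair
satisfies both simultaneously is computed and reported as a separate flag,
since either reading of "at least one pair" is defensible.

## Functional enrichment

**Patterned vs unpatterned (Fisher).** Per term, a two-sided Fisher exact
test (minimum-likelihood convention) on the patterned/unpatterned split,
gated on power: a term is tested only if the most extreme 2x2 table
compatible with its margins could reach p < 0.05. For *conditional*
databases (GO, knockout phenotypes) both sets are restricted to genes with at
least one annotation in the database; *nonconditional* databases use all
genes.

**Per-layer enrichment (bias-corrected simulation).** Testing a layer's
predicted set against all classifiable genes is biased by the classifier
itself, so the null resamples with that bias: each simulation draws
`|predicted set|` genes with replacement — with probability equal to the
classifier's CV precision, uniformly from all classifiable genes, and
otherwise from the predicted set of a contaminating class drawn from the CV
contamination distribution (the only quantified false-positive source). For
conditional databases, unannotated draws are rejected until the annotated
draw count matches the predicted set's; this conditioning is implemented in
its exact equivalent form (annotated draws are iid from the source mixture
conditioned on annotation). Each simulation is realised by drawing
per-source draw counts (multinomial) and per-source term hits (binomial),
which is distributionally identical to drawing individual gene identifiers
and is cross-checked in the tests against a literal per-gene bootstrap.
One-sided empirical p-values use the add-one estimator
`p = (1 + #{count >= observed}) / (1 + n_sims)`, so `p >= 1/(1 + n_sims)`
always. The default is 200,000 simulations per term; the test suite runs
5,000-20,000 with recorded seeds.

**Multiple testing.** Storey q-values with a single lambda = 0.5:
`pi0 = min(1, mean(p > 0.5)/0.5)`, then the usual step-up minimum. A spline
estimate of pi0 was rejected as needlessly tuning-sensitive at these scales.
Results with q >= 0.05 are discarded in the "significant" outputs.

**Concordance.** Exact two-tailed binomial tests against 0.5 for
directional concordance counts, and the overall/enriched concordance
formulas for comparing two prediction runs (enriched concordance averages
the two one-sided both/(both+only) fractions; a zero denominator leaves that
component undefined).

## LincRNA stage

Coding-gene territories are expanded once (not to a fixed point) by the full
spans of transcripts sharing at least one exonic base with a coding exon.
Candidates are transcripts with >= 2 exons, > 200 exonic bases, no exonic
base in any territory, and an externally supplied noncoding label (a crude
longest-ORF-fraction heuristic with threshold 8% exists only to label
synthetic fixtures). Candidates cluster into loci as connected components of
genomic-span overlap (>= 1 shared intronic or exonic base, strand-agnostic),
computed by a sweep over sorted spans and verified against quadratic
union-find.

Positional statistics: *adjacency* of a coding gene to a locus is defined as
the locus lying between the gene and its nearest coding neighbour (no
intervening coding gene) — the notion is not standardized, so this decision
is explicit and the permutation test (patterned labels permuted over coding
genes) is self-consistent under it. Neighbour co-expression compares
per-pair absolute Spearman correlations (Pearson behind a flag) between
patterned and unpatterned neighbour groups with a one-sided rank-sum test.
Interval-overlap enrichment shuffles query intervals uniformly within their
chromosome, preserving lengths, and counts queries overlapping >= 1 feature;
fold is observed over the shuffled mean with an add-one p.

## Synthetic atlas

The generator plants the structure the pipeline assumes: log-normal baseline
expression (log-mean 1.0, log-sd 1.0 — a positive quantity spanning orders
of magnitude), multiplicative log-normal per-sample noise (default sd 0.3),
a fold-4 elevation of a gene's true layer in the mapped samples, CI
half-widths proportional to the gene's mean FPKM (default 10%), 10% label
noise in curations, per-layer planted terms at 80% purity plus uniform null
terms, a toy two-chromosome genome with coding genes and intergenic
multiexonic noncoding transcripts, and mirror-profile two-isoform switch
genes whose gene-level FPKM is the transcript sum.

The sample-to-layer map is an explicit table. By default it encodes
overlapping dissections (`A -> {L1, L2/3}`, `B1/B2 -> {L2/3, L4}`,
`C -> {L4, L5}`, `D -> {L5}`, `E -> {L6}`, `F -> {L6b}`): a layer shared
between samples is elevated with bleed weight 0.5 (`fold^0.5`), a sole
mapping with weight 1. The overlap proportions of real dissections are
unknown; 0.5 is a free parameter, not an inferred quantity. Layer-1 genes
are generated but never curated. CI half-widths scale with the gene's mean
FPKM rather than each sample's FPKM so that strong single-sample enrichment
does not mechanically fail the 50%-CI filter — with per-sample widths the
filter would remove every fold-4 single-sample gene even without noise,
leaving nothing to train on.

What the generator does **not** emulate: read-level sampling noise and its
coupling to CI width, library-size and length biases, correlated
co-expression structure between genes, ambient contamination between
adjacent dissections beyond the fixed bleed weight, realistic genomic
sequence, and curation biases that depend on expression level. Passing tests
therefore demonstrate that the machinery recovers planted structure under
the stated noise model, not that real-data accuracy matches any published
figure.

Two limits are worth knowing. First, under the overlapping map, naive Bayes
double-counts the correlated replicate features (B1/B2), so adjacent classes
(L2/3 vs L4) keep a few threshold-crossing false positives even at zero
noise; exact precision/recall 1 in the noise-free limit holds under a
one-to-one dissection map. Second, vanishingly small but nonzero noise
(e.g. sd 0.001) jitters tied values into clusters that equal-frequency
quantiles can split mid-cluster; the limit is exact only at noise 0.

## Problem sizes and runtime choices

Cross-validated recovery checks run at 200 genes per class (1,250 genes);
most unit fixtures use 25-60 genes per class. Simulation-null checks use
5,000-20,000 simulations per term, permutation tests 200-2,000 permutations,
and the FDR check 200 replicates of 200 tests. These sizes give stable
Monte-Carlo behaviour at interactive runtimes; production runs default to
200,000 simulations per term.
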