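# Methods

`rankshift` implements a desk-scale pipeline for identifying candidate
disease-driver genes from two-condition single-cell RNA-seq data: cells are
tokenized as expression-rank sequences, a small transformer is fine-tuned to
classify disease vs. control state, candidate drivers are found by in-silico
deletion/overexpression with cosine-shift statistics, and observed fold
changes are calibrated against a permutation-derived natural-fluctuation
threshold. This note records the models, the defaults and why, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Synthetic corpus model

The generator (`rankshift.simulate`) emulates a droplet scRNA-seq experiment
on a single cell type under two conditions (control / disease):

* Per-gene baseline means are log-normal across genes,
  `exp(N(mu, sigma))` with default `(mu, sigma) = (0, 1)` — a right-skewed
  mean distribution typical of UMI data, giving per-cell totals of a few
  hundred counts over 300 genes and ~45% zero entries at the defaults.
* Counts are negative-binomial with mean `mu` and size `theta`
  (`var = mu + mu^2 / theta`, the standard scRNA-seq convention, used
  consistently everywhere). Default `theta = 2`, a typical droplet-data
  dispersion.
* Per-cell library size is a log-normal multiplicative factor
  (default `exp(N(0, 0.3))`) applied to the mean before sampling, so depth
  normalization downstream is non-trivial and testable.
* A chosen subset of driver genes (default 10 of 300) is expressed
  `2^driver_log2fc` higher in control than in disease (default log2FC = 2).
  Drivers sit higher in control so that *deleting* a driver token from a
  control cell is expected to move its embedding toward the disease state —
  the headline deletion-to-disease direction of the analysis.

Default corpus size is 1000 cells per condition. The same seed always yields
a bit-identical corpus. Not modelled (deliberately): batch effects, ambient
RNA, doublets, multiple cell types, gene-gene correlation beyond the shared
library-size factor.

## Rank encoding

Each cell becomes an ordered token sequence (`rankshift.encoding`). A gene's
priority is its depth-normalized expression (`count / cell_total`) divided by
the gene's *nonzero-median normalization factor*: the median across reference
cells, over cells expressing the gene, of its depth-normalized expression.
This deprioritizes ubiquitously high housekeeping genes and promotes genes
that are unusually high in a given cell. Tokens 0 and 1 are reserved
(PAD/MASK); gene tokens are assigned from 2 in lexicographic gene-id order.

Numerical choices:

* Ties in priority are broken by ascending token id — the encoding is fully
  deterministic, which perturbation outputs require.
* Only expressed genes are ranked; a cell expressing no vocabulary gene is
  unencodable and is dropped (and logged) rather than imputed.
* The vocabulary is built on the training split only and then frozen;
  evaluation cells drop genes outside it, mirroring fine-tuning on a fixed
  pretraining vocabulary.
* Default context length L = 128: desk-scale corpora have hundreds of genes,
  so L = 128 retains the informative head of the ranking while keeping
  attention cost (quadratic in L) small.

## State transformer

`StateTransformerClassifier` is a pre-layer-norm transformer encoder written
directly in NumPy with manual backpropagation — at this scale (2 layers,
4 heads, hidden size d = 64, L = 128, dropout 0.1) a fine-tune takes well
under a minute on one CPU core, and a pure-NumPy implementation makes every
training trajectory bit-reproducible under a fixed seed, which end-to-end
pipeline determinism relies on.

* Embeddings: learned token + learned position, embedding dropout at train
  time.
* Blocks: `x + Attn(LN(x))` then `x + FFN(LN(x))`; multi-head attention with
  a key padding mask; feed-forward width 4d with a sigmoid-approximated GELU
  (`x * sigmoid(1.702 x)`); a final layer norm.
* Cell embedding: mean of final-encoder-layer hidden states over non-pad
  positions (d-dimensional). Batches are always padded to the full context
  length, so embeddings and probabilities are independent of batch
  composition to floating-point tolerance.
* Optional masked-gene pretraining: 15% of positions (at least one per
  cell) are replaced with the MASK token and the original gene token is
  predicted with cross-entropy — the self-supervised objective of
  transcriptome foundation models, reduced to desk scale.
* Fine-tuning: a linear head on the pooled embedding, trained with
  cross-entropy and Adam (default lr 1e-3, batch 64, 4 epochs). The epoch
  count deliberately stops early: it reaches held-out accuracy ≈ 0.9 on the
  standard planted-driver corpus, while longer training overfits the
  training labels and imprints a label direction on the embedding space
  even when *no* signal exists — gene deletions then move cells along
  gene-specific directions consistently enough that the aggregate-null
  Wilcoxon test reports spurious candidates on null corpora. Early stopping
  keeps the no-signal control clean (empty candidate tables at α = 0.05);
  this sensitivity of the perturbation statistics to training duration is a
  real property of embedding-shift methods, not an implementation artifact.
  Class imbalance is handled with
  inverse-frequency class weights, so training-set compositions with many
  extra control cells remain trainable.
* The model records its phase (random → pretrained → finetuned); fine-tuning
  directly from random initialization is permitted and logged.

Hyperparameters are deliberately exposed: transformer fine-tuning is
sensitive to them, and different learning rates or epoch counts will move
the classifier metrics.

## In-silico perturbation and candidate ranking

Given a fine-tuned model, a perturbation scenario is (mode, direction), e.g.
*delete, control→disease*:

* **Deletion** removes the gene's token from the rank encoding (relative
  order otherwise preserved) — only cells expressing the gene are eligible.
* **Overexpression** moves the gene's token to the front (or inserts it and
  re-truncates to L) — every cell is eligible.
* The **goal state** is the centroid of the goal condition's cell embeddings
  from the held-out split. The reference for "toward the goal" is a design
  choice; centroid-of-end-state is the simplest faithful one and is recorded
  in output metadata.
* The per-cell effect is the **shift to goal end**:
  `cos(perturbed_embedding, goal_centroid) − cos(original_embedding,
  goal_centroid)`, bounded in [−2, 2]; positive values move the cell toward
  the goal state. Perturbations run on held-out cells only.
* Per-gene significance: two-sided Wilcoxon rank-sum of the gene's per-cell
  shifts against the aggregate null — the pooled shifts of all tested genes
  (the gene's own cells included; with hundreds of genes its own
  contribution to the pool is negligible) — then Benjamini–Hochberg across
  tested genes. When a gene's shifts and the pool are all identical (e.g. a
  constant-embedding model) the p-value is defined as 1 rather than the NaN
  the normal approximation would give.
* **Candidates**: genes with positive mean shift and FDR < α (default 0.05),
  ranked by shift descending with FDR ascending as tie-break (the two keys'
  precedence being otherwise ambiguous, the larger effect wins). Genes with
  fewer than `min_cells` (default 5) eligible cells are excluded and
  reported separately: per-gene shift distributions with fewer cells are too
  unstable to test at desk scale.

Only cell-level embeddings are used; gene-level embedding shifts are out of
scope. Candidate gene sets are surfaced with the signed shift so that either
sign convention for "toward the target state" can be applied downstream.

## Natural-fluctuation threshold

To separate robust expression changes from sampling noise
(`rankshift.fluctuation`): control cells are randomly split into two equal
halves (⌊n/2⌋ / ⌈n/2⌉ for odd n) `n_iterations` = 100 times; each split
yields per-gene log2 fold changes between halves. Expression is
depth-normalized to counts per 10,000 per cell; group means get a
pseudocount (default 1.0 — the data give no guidance here, so the choice is
recorded in every output) inside the log ratio.

The *natural fluctuation zone* is ±T with T the 95th percentile (linear
interpolation between order statistics, recorded in the output) of the
pooled |log2FC| over all genes and iterations — one global threshold rather
than per-gene thresholds, matching the single ± bound the method is meant to
produce. A signed two-tailed convention (2.5th/97.5th percentiles) is
available via `convention="signed"`. An observed disease-vs-control log2FC
*strictly* exceeding T in magnitude is a robust change; its
`fold_excess = |observed| / T`. For the canonical worked example — observed
log2FC 0.85 against a ±0.68 zone — the fold-excess is 1.25 (≈1.24 when
computed from unrounded inputs).

Null calibration (tested): fitting the threshold on one set of splits and
evaluating fresh independent splits as "observations" yields an exceedance
fraction of ≈5% (≤10% asserted), as the 95th-percentile construction
implies.

## Pipeline

`run_pipeline` chains simulate (or read) → stratified holdout → encode →
(optional pretrain) → fine-tune → classify → perturb → rank → fluctuation,
writing every artifact (corpus in 10x-style MTX + TSV sidecars, vocabulary
TSV, model checkpoint, classification report JSON + probability TSV,
candidate tables TSV + metadata, fluctuation JSON/TSV, run log, provenance
with config hash and all stage seeds). One global seed derives per-stage
seeds by hashing the stage name, so stages stay independently reproducible.
The evaluation split is held out before any training, stratified by
condition, default 20% of cells — synthetic corpora have no donor structure,
so cell-level stratified holdout replaces sample-level holdout.

The default scenario list is `[delete, control→disease]` — the deletion
direction that defines the headline candidate set; the other three
mode/direction combinations are supported through configuration. The
training-composition axis (`extra_control_cells`) appends extra simulated
control cells to the training split only, keeping the evaluation split
fixed, so compositions are compared on identical held-out cells
(`compare_compositions`).

## Problem sizes used by the test suite

The standard study configuration (300 genes, 10 drivers at log2FC 2,
1000 + 1000 cells, the default tiny transformer) is used for the end-to-end
acceptance checks, which run it over three fixed seeds with a majority rule;
smaller corpora (40–50 genes, 100–300 cells per condition) back the unit
tests. These sizes are the package's standard desk-scale conditions: large
enough for the planted structure to dominate sampling noise, small enough
that the whole suite runs on a single CPU core in minutes.

## What passing tests do and do not show

The synthetic benchmark demonstrates mechanism, not biology: with a planted,
single-cell-type, batch-free signal, the pipeline's classifier separates
conditions and its deletion analysis ranks the planted drivers first. Real
tissue data adds cell-type mixture, batch and donor effects, correlated gene
programs and much larger vocabularies; recovering drivers there additionally
depends on large-corpus pretraining and data curation, which a desk-scale
corpus cannot emulate. Results on real accessions are therefore expected to
be dataset-dependent, and the fluctuation threshold's printed worked example
(0.85 vs ±0.68) is reproduced as arithmetic, not re-derived from the
original accession.

## Known limitations

* The NumPy transformer trains on CPU only and is sized for hundreds of
  genes; it is not a path to corpus-scale pretraining.
* The aggregate-null Wilcoxon test treats cells as exchangeable units and
  ignores per-cell correlation between genes; its FDR is calibrated for
  ranking, not for literal error-rate guarantees on real data.
* Deletion-ineligible cells are skipped, not imputed; genes expressed in few
  start-condition cells can only be assessed by overexpression.
* The fluctuation threshold is global across genes; strongly
  expression-dependent noise would need per-stratum thresholds.
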