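# Methods

`spotgin` reimplements, as one importable library, the computational
stages of a spatial-transcriptomics workup for neuropathology: from a
genes x spots count matrix on the hexagonal Visium lattice to inferred
copy-number profiles, spatial statistics, stain/expression agreement,
and a multi-task graph neural network that predicts tissue histology and
molecular labels from local spot neighborhoods. This note records the
models, the parameters that matter, and the design choices made where
the methodology was genuinely open.

## Normalization and gene selection

Counts are scaled per spot to a constant total of 10,000 and transformed
as `v = ln(1 + 10,000 * c / total)`. The pseudocount of one is the
standard log-normalization convention; zero counts map to exactly zero
and per-spot rank order of genes is preserved. Spots with zero total
UMIs are dropped at load time, since the scaling divides by spot totals.

Batch covariates (batch one-hot, mitochondrial and ribosomal fractions)
can be regressed out per gene by OLS; the gene's fitted intercept is
added back so means are preserved. Regression is off by default on
synthetic data, which has no batch structure.

"Variable genes" are ranked by variance of the normalized values (the
definition was open; variance is the simplest defensible choice), ties
broken lexicographically, capped at 5,000. When several sections feed
one model, `select_hvg_joint` computes variance on the pooled spots so
that node-feature column *j* denotes the same gene in every section —
per-section lists silently destroy cross-section generalization. The
criterion is label-free, so computing it on the full cohort leaks no
label information into the held-out evaluation.

## Expression-inferred copy number

Genes are pooled into 1-Mbp bins tiling each chromosome (the last bin of
a chromosome may be shorter); a gene belongs to the bin containing its
midpoint `floor((start+end)/2)` in 1-based inclusive coordinates (BED
input is converted on ingest). Scoring per spot:

1. center each gene's log expression on its mean over the *reference
   spots* (spots annotated white matter or cortex — non-neoplastic
   tissue; the choice of reference set was open);
2. clamp centered values to ±3 (bounds single outlier genes, standard
   inferred-CNV practice);
3. average genes within each bin;
4. running-mean smooth over ±2 bins along each chromosome — this
   realizes the rescale/interpolate step at bin resolution; sub-bin
   interpolation adds nothing at 1 Mbp for arm-level calling (a
   documented deviation);
5. subtract a loess fit of score against the genome-wide bin index
   (span 0.5) — the loess target variable was open; genomic position is
   used;
6. subtract the spot's median score.

Bins without expressed genes are missing and excluded from calls. Calls
use symmetric thresholds τ = 0.15 with strict inequalities (a score at
the threshold is neutral); arm-level calls threshold the arm's mean
score, and a sample-level call averages arm scores over non-reference
spots. Comparison against an external (methylation-array-like) reference
reports consensus and divergent fractions and per-arm mismatch counts;
the probe-density diagnostic correlates per-bin probe density with
mismatch frequency (Pearson, two-sided t-test). Single-gene events are
out of scope for this signal — that is precisely what the network heads
are for.

## Spatial statistics

Moran's I and the spatial cross-correlation index (SCI) are implemented
exactly as their double-sum definitions with *binary, unnormalized*
weights (row-standardization exists behind a flag). The default
neighborhood is the six nearest neighbors, mirroring the hex packing; a
distance-threshold rule (1.05 x the smallest nonzero distance) is also
available. Useful identities used as test oracles: SCI(x,x) = I(x)/2
under shared weights; the permutation-null mean of I is −1/(N−1).
Analytic p-values are not provided; a seeded permutation test is.

## Stain / expression agreement

One image channel (blue by default, `invert` available for dark-positive
chromogens) is min-max rescaled to [0,1] and smoothed with the Gaussian
kernel smoother `z_hat(q) = Σ z_i K_i / Σ K_i` with
`K_i = exp(−|q − p_i|²/2σ²)`; the implementation normalizes the weights
in log space, so only queries beyond 10σ of every sample fall back to
the nearest sample (with a warning). Polygon aggregation uses even-odd
ray casting with half-open edges (`y_i ≤ y < y_{i+1}`) and the explicit
`x_intersect` edge formula; empty segments report NA. Agreement is an
OLS fit of expression on smoothed intensity (Pearson R, two-sided p).
The smoothing bandwidth defaults to the spot pitch and is configurable;
the synthetic renderer uses 0.2 x pitch, the physical footprint of a
~55-µm capture spot on the 100-µm pitch. One known ambiguity: the
correlation is computed intensity-versus-expression; cell density enters
only through the intensity field itself.

## Spot graphs and subgraphs

Pairwise Euclidean distances with self-distances replaced by the
sentinel constant 1,000 (coordinates are first rescaled so all true
distances stay below it — this keeps the constant meaningful for
arbitrary pixel units); the adjacency threshold is 1.05 x the smallest
nonzero distance ("slightly above", configurable). On an ideal lattice
interior spots have degree 6 and a k-hop neighborhood has 1 + Σ6h nodes
(37 at k = 3). Note the threshold keys off the *global* minimum
distance, so coordinate jitter beyond ±1% of the pitch can drop true
edges; within a 2% peak-to-peak window invariance is guaranteed.

Subgraph node features concatenate, in fixed order: variable-gene
expression, CNV scores, one-hot histology (all-zero when unannotated),
and optional image vectors; one self-loop per node keeps each node's own
features in the sum aggregation. Subgraphs inherit the section's
sample-level labels; centers are all in-tissue spots, and the tumor
filter keeps subgraphs containing at least one tumor-annotated spot.
Splits are at section level and never place a participant on both sides;
normalization is per-section and therefore independent across the split
by construction.

## The graph network

A three-layer graph isomorphism network: each layer computes
`MLP(A_hat @ H)` where `A_hat` includes the self-loops (sum aggregation),
and the per-layer MLP is Dense → BatchNorm → LeakyReLU → Dropout →
Dense → BatchNorm → LeakyReLU. Global mean pooling produces the graph
embedding; each task has its own two-layer MLP head. With k = 0 the
model is a single linear layer per task on the center spot's features —
the no-neighborhood baseline. Categorical heads use cross-entropy,
continuous heads mean-squared-error plus L1; task losses combine as a
weighted sum. Weights are uniform (configurable) by default; an
optional mode (`uncertainty_weighting`) instead learns per-task
log-variances s_t and minimizes `Σ exp(−s_t) L_t + s_t`, the standard
homoscedastic-uncertainty weighting, since fixed weights are a modeling
choice the data can reasonably make itself. Subgraphs whose label
for a task is unknown are masked out of that task's loss. Adam
optimizes, gradients are reset every batch, and all randomness
(initialization, shuffling, dropout) flows from the config seed, so
training is bit-reproducible in a fixed environment (BLAS kernels are
the documented caveat).

The network is implemented on NumPy with explicit backpropagation
(`spotgin.nn`): dense, batch-norm, leaky-ReLU and inverted-dropout
layers and an Adam optimizer, sized for CPU-scale cohorts. Permutation
equivariance of the logits under node reordering (a consequence of sum
aggregation plus mean pooling) is verified in tests.

Defaults: hidden 128, dropout 0.3, lr 1e-3, batch 64, 50 epochs — the
architecture's hyper-parameters were not prescribed; all are in
`GinConfig`. Evaluation reports accuracy and *macro* precision / recall
/ F1 (micro/macro was open) with fixed-vocabulary confusion matrices;
participant-level predictions are majority votes over subgraph
predictions, ties broken by the higher mean softmax score. The
Hand-Till multiclass AUC is the average over unordered class pairs of
`[Â(i|j) + Â(j|i)]/2` computed from rank sums with midrank ties; for the
ordinal CNV case (loss < neutral < gain) the scalar arm score is the
discriminant of each pair.

## Cell-type allocation

Deconvolution scores are min-max normalized per type to [0,1] (the
normalization axis was open; per-type across grid points is used). The
count of type k at spot j with N_j nuclei is
`C_jk = round(d'_jk N_j / Σ_k d'_jk)` with round-half-away-from-zero.
Rounding may miss N_j by at most ceil(T/2); the deviation is *reported*,
never redistributed — a largest-remainder correction would silently
change the estimator. All-zero score rows leave nuclei unassigned.
Types are mapped onto nucleus positions by seeded sampling without
replacement; group compositions are compared with a two-sided
permutation test on per-type frequency differences.

## The synthetic cohort generator

The generator is first-class, tested code and defines the study
conditions for every recovery experiment:

* **Lattice and zones.** Hex lattice with unit pitch, pixel coordinates
  100 x lattice units (exercising the sentinel rescaling). Histology
  zones are contiguous vertical bands: main tumor (45% of columns),
  infiltrative tumor (15%), necrosis (10%), white matter (15%), cortex
  (15%). White matter + cortex serve as the CNV reference.
* **Counts.** Negative binomial (gamma-Poisson) with dispersion 0.5 —
  the standard overdispersed spot model — over gene base means drawn
  lognormal(−0.7, 1) and per-spot library factors lognormal(0, 0.15).
  About 1,000–1,500 UMIs per spot at 2,000 genes, in the realistic range
  for FFPE material.
* **Program genes are spread uniformly across the genome** and the two
  texture programs interleave. Real marker programs are scattered over
  chromosomes; contiguous blocks would masquerade as copy-number events.
* **Subclass signal.** In `texture` mode all classes share identical
  per-spot marginals (50/50 mixture of two 25-gene programs, x6) and
  differ only in stripe width of the arrangement (preferring widths
  1, 2, 3, 6 rows: each gives a distinct per-node neighbor composition,
  while stripes wider than a 3-hop patch are undecodable from 37-node
  neighborhoods). In `marginal` mode each class up-regulates its own
  12-gene block (x6) in tumor spots — a purely spot-local signal.
* **Molecular labels.** MGMT methylation up-regulates a 20-gene program
  (x3) in tumor spots. The CDKN2A/B genotype acts on two sets, mirroring
  the deletion's biology: the locus program is progressively lost
  (x1 / x0.55 / x0.2 for none / heterozygous / homozygous) and a
  downstream cell-cycle program is de-repressed (x1 / x1.7 / x2.8) —
  loss of CDKN2A releases RB/E2F targets. A pure down-regulation would
  (realistically) fall out of variance-based gene selection.
* **CNV events.** Two arm events per sample (gain x1.5, loss x0.5)
  applied to expected counts of tumor spots *before* noise, cycled over
  arms that avoid the program-gene chromosomes; the reference call table
  is written as truth.
* **Stain images.** Blue channel = min-max(a x kernel-smoothed marker
  expression) + Gaussian noise, clipped to [0,1]; bandwidth 0.2 x pitch
  (see above). `a = 0` gives the null image.
* **Deconvolution.** True per-spot cell counts mirror tissue density
  (7–15 in tumor, 0–5 in healthy, 3–9 in between); type proportions are
  Dirichlet; true counts are multinomial; scores are true counts plus
  half-normal noise; nuclei are uniform in the spot footprint.

What the generator does **not** emulate: real histology images, probe
chemistry and segment-specific dropout, spatial bleed-over between
spots, subclonal CNV mixtures, batch effects, or the biology of specific
tumor entities. Passing recovery tests therefore demonstrates that the
*implementation* recovers planted signals under realistic noise, not
that the method attains any particular accuracy on patient material —
the cohort-scale clinical numbers require the clinical cohort.

## Reference experiment protocols and problem sizes

`spotgin.experiments` freezes the protocols used by the test suite and
the acceptance script, with problem sizes chosen for a single-CPU
workstation run:

* CNV recovery: 12 samples, 30x30 grid, 2,000 genes, 2 events per
  sample; arm-call accuracy and Hand-Till AUC over {loss, neutral,
  gain}; permuted gene-to-bin control on 3 samples.
* GNN experiments: 16 samples (12 train / 4 validation, one validation
  participant per class), 24x24 grid, 300 genes, 100 joint variable
  genes, expression + one-hot histology node features; hidden 48–64,
  dropout 0.3, lr 1e-3, batch 64, 25–35 epochs. The texture ablation
  contrasts k = 0 (linear) with k = 3; the control task repeats it on
  the marginal cohort; the multi-task run trains subclass, MGMT and
  CDKN2A/B heads jointly (k = 2). Label-shuffle nulls are evaluated on a
  class-balanced validation subsample so chance is exactly 1/c.
* Determinism: the CLI pipeline on a 6-sample, 12x12, 250-gene cohort,
  run twice under one seed and compared byte-for-byte.

## Known limitations

* The CNV caller targets arm-level events; focal (single-gene) events
  are invisible to it by design.
* Loess detrending assumes alteration-free regions dominate each
  genome; a genome-wide aneuploid sample would be partially normalized
  away.
* The NumPy network trains dense batches on one CPU; it is not meant
  for 100k-subgraph clinical cohorts, where a GPU graph-learning stack
  would be the appropriate backend.
* Hand-Till AUC for the ordinal CNV discriminant assumes the natural
  class order; with binary weights Moran's I is sensitive to the
  neighbor rule chosen.
* `sci_matrix` loops over feature pairs; it is intended for dozens, not
  thousands, of features.
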