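# Methods

## Problem setting

`molal` implements pool-based Bayesian active learning for binary molecular
property prediction. A run starts from a small labeled set `D` (default 100
molecules, class-balanced) and a large unlabeled pool `D_u`. Each iteration
trains a classifier on `D`, scores every pool candidate with an acquisition
function, reveals the label of the selected candidate (retrospective
screens already hold all labels), and repeats. Quality is tracked on a
fixed held-out test set: average precision (AP) for ranking under class
imbalance, and expected calibration error (ECE) for uncertainty quality.

## Model

The classifier is a feed-forward network

    h0   = ReLU(BatchNorm(W_in x + b_in));  h0' = Dropout(h0)
    r    = ReLU(h0' + BatchNorm(W_res h0' + b_res));  h1 = Dropout(r)
    logit = W_out h1 + b_out

with hidden width 128 and one residual block. Training minimizes binary
cross-entropy on logits with Adam (learning rate 1e-3, L2 weight decay
1e-2 applied through the gradient, the convention of mainstream deep
learning frameworks), cosine-annealed learning rate with warm restarts
every 10 epochs, batch size 16, for 110 epochs by default. A trailing
batch of size 1 is dropped because its batch statistics are degenerate.
The network, backpropagation (including through batch normalization and
the skip connection), the optimizer and the schedule are implemented
directly on NumPy arrays, which keeps every random stream under one seeded
generator and makes training bit-reproducible.

Uncertainty comes from MC dropout: dropout stays active at prediction time
and T = 20 stochastic forward passes are treated as draws `phi^(t)` from an
approximate parameter posterior `q(phi)`. Two dropout rates are exposed:
the training rate (default 0.3) and an optional separate inference rate
(`mc_dropout_p`, e.g. 0.5); by default inference reuses the training rate.
Batch normalization uses stored running statistics during these passes.

**Paired draws.** Each stochastic pass applies ONE mask vector per hidden
layer to every row of the batch, so a pass is a single coherent parameter
draw rather than per-row noise. This is required by the EPIG estimator
(below), which needs pool and target predictions under the *same*
`phi^(t)`; the loop obtains them with one call over the concatenated
pool + target matrix. For BALD the per-point score distribution is
unchanged by this choice.

## Acquisition functions

All entropies are in nats; probabilities are clipped to `[1e-12, 1-1e-12]`
before logarithms.

* **uniform** — every candidate scores `1/|pool|`; selection samples
  without replacement. The random baseline.
* **BALD** — mutual information between a candidate's unknown label and
  the parameters: `H[(1/T) sum_t p_t] − (1/T) sum_t H[p_t]`. Exact zero is
  returned when all T draws agree.
* **EPIG** — expected predictive information gain: for candidate x and a
  target point x*, form the 2x2 joint label distribution
  `(1/T) sum_t p(y|x, phi_t) p(y*|x*, phi_t)` and take
  `KL(joint || product of marginals)`, averaged over M target points
  (default M = 100, sampled uniformly from the test set and redrawn each
  iteration). Zero-probability joint cells contribute zero.

Selection takes the top `batch_size` scores (default 1) with seeded uniform
tie-breaking. Both Bayesian scores are brute-force-checked in the test
suite against literal evaluations of their defining formulas at 1e-10.

## Data handling

Molecule tables are CSVs with a SMILES column and one or more binary label
columns; blank or "NA" cells are missing. Rows with unparseable SMILES are
dropped and counted. Multitask tables are handled as independent per-task
runs; molecules lacking a label for the active task are excluded from the
pool (a pool point must be labelable).

Train/test splitting groups molecules by canonical Bemis-Murcko scaffold
(acyclic molecules form one shared group), sorts groups by descending size
with lexicographic tie-breaks, and fills the training side greedily until
it holds the target fraction (default 80%); the remainder is the test set.
No scaffold ever crosses the boundary, so the test set probes unseen
chemotypes. The balanced initial set draws `initial_size/2` molecules per
class uniformly under the stage seed.

Features are either 1024-bit ECFP fingerprints (radius 2, RDKit Morgan
generator) or a precomputed embedding matrix loaded from `.npy`/CSV — the
encoder that produced the embeddings is outside this package's scope and
any dimension is accepted.

## Separability metrics

Given binary labels in a feature space: Fisher's ratio
`||mu+ − mu-||^2 / (tr(Sigma+) + tr(Sigma-))` with per-class sample
moments; the two-cluster Davies-Bouldin index with classes as clusters
(Euclidean, centroid = class mean); and class purity, the mean fraction of
a point's k = 10 nearest neighbors (excluding itself) sharing its label.
Fisher's ratio has no universal multivariate convention; the trace form is
used because it is rotation-invariant and reduces to the classical 1-D
ratio.

## Synthetic feature spaces

The generator produces the two regimes the pipeline's analyses contrast:

* **structured** — negatives from a mixture of 3 broad isotropic Gaussian
  components (component sd 1, centers drawn with sd 1); positives from
  `n_pos_clusters` = 6 tight clusters (sd 0.5) whose centroids are
  displaced `separation x 0.5` (default separation 5, i.e. 2.5 units) from
  a random negative component center along random orthonormal directions.
* **scattered** — positives drawn from the negative components themselves
  with a small mean shift of `separation/4` units, burying them in the
  negative mass.

The default positive prevalence is 6.8%. Defaults were chosen once so that
(i) the structured regime strictly dominates the scattered one on Fisher
ratio and class purity at equal spec, and (ii) a network trained on the
100-molecule initial set sits mid-learning-curve (test AP roughly 0.3-0.5)
with substantial headroom, the low-data regime active learning targets. A
companion generator emits multitask label matrices with independent
missing cells (defaults: 6.24% of all cells active, 20.56% missing,
per-task active rates jittered), matching the cell-level composition of
large public toxicology screens.

What the synthetic spaces do *not* emulate: discrete/hashed feature
geometry, activity cliffs, scaffold correlation between train and test,
and assay noise. Passing the end-to-end tests therefore demonstrates that
the pipeline's machinery behaves correctly and that representation
structure drives learnability — not that any specific chemical dataset
would show the same acquisition-function ranking.

## Seeds and reproducibility

All randomness flows from a single run seed through
`derive_seed(run_seed, *stage)`, a SHA-256 hash truncated to 31 bits.
Stages include weight initialization, epoch shuffling, dropout masks,
target resampling and tie-breaking, each further keyed by iteration, so
arms sharing a run seed share their initial sets but not their dropout
masks. Runs are bit-reproducible.

## The active-learning loop

The network is re-initialized and retrained from scratch after every
acquisition; warm-starting would make the fit depend on acquisition order.
Evaluation happens every `eval_every` iterations (default 10; 1 gives the
full grid) and always at iteration 0 and the final iteration. The uniform
arm's scores do not depend on the model, so it skips retraining between
evaluation points; its acquired sequence and metrics are identical to the
naive schedule. The loop asserts at every iteration that no test index is
acquired, truncates cleanly when the pool empties, and records acquired
indices, labels, scores and metrics in a JSON-lines history.

## Statistical comparisons

Arms are compared pairwise per (task, seed) with Wilcoxon signed-rank
tests (one-sided where a direction is claimed; pairs with zero difference
dropped). `gain_over_random` reports the paired mean difference curve with
a standard-error band. The "stable significance" iteration is found by
scanning the evaluation grid from the right for the earliest point after
which every p-value stays below alpha; a transient early onset is never
returned. ECE uses predicted-class confidence with 10 equal-width bins
(right-inclusive at 1.0); empty bins contribute zero.

## Benchmark problem sizes

The packaged benchmarks (`molal.experiments`) use n = 2000 molecules,
d = 16 dimensions, 100 acquisitions, evaluation every 10, 30 training
epochs and 10 seeds — sizes chosen so a full paired study completes in
minutes on one CPU while the learning curves still rise substantially
(roughly AP 0.4 to 0.7 over a run).

## Known limitations

* At the benchmark sizes, final-AP differences between EPIG and uniform
  acquisition are small relative to seed-to-seed variation. A control
  experiment labeling *every* pool positive showed no AP advantage over
  uniform growth either: with a balanced 100-label start on these
  synthetic spaces, label composition is not the binding constraint, so
  acquisition-policy effects on AP are intrinsically hard to detect at
  this scale.
* MC-dropout disagreement in a 16-dimensional space is globally diffuse;
  minority-class enrichment of EPIG's selections is weak. Reaching 70% of
  pool positives within 100 acquisitions would need roughly a 40%
  acquisition rate against a 4% base rate, which no uncertainty-based
  policy achieves here.
* The 30-epoch, strongly regularized network starts honestly
  underconfident (iteration-0 ECE near 0.05), so there is little room for
  the downward calibration trend that appears when models start badly
  miscalibrated; across a run ECE stays roughly flat.
* MC-dropout uncertainty is known to be underestimated in general; no
  temperature scaling or deep ensembling is provided.
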