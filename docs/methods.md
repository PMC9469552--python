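# Methods

## Network construction

The heterogeneous network couples a drug family and a disease family
through four similarity views and a binary association matrix. All
matrices carry explicit ordered identifier vectors; joins are by token,
never by position, because no canonical ordering of drugs or diseases
exists. Matrices are computed on the upper triangle and mirrored, so
symmetry is exact rather than within floating-point drift; diagonals are
set explicitly.

**Chemical view.** The Tanimoto coefficient on substructure fingerprint
bits, `c / (a + b − c)`. Fingerprints are accepted precomputed (any fixed
length; MACCS-style 166-bit vectors are typical), or computed from SMILES
through RDKit when that optional dependency is present. The 0/0 case (two
all-zero fingerprints) is defined as 1: two featureless objects are treated
as identical; one empty against one non-empty scores 0.

**Therapeutic view.** Each drug pair is scored by the mean local-alignment
similarity over all cross pairs of their protein targets, skipping pairs
where the two sides are the identical target token. Local alignment uses
affine-gap Smith–Waterman through Biopython's `PairwiseAligner`, with
BLOSUM62, gap open 10, gap extend 1 — community-standard defaults, and
configurable through `AlignmentParams` since no single scheme is canonical.
Raw scores are normalized by the geometric mean of the two self-alignment
scores, which guarantees values in [0, 1] with self-similarity 1. When the
identical-token exclusion empties the pair set (shared single target, or a
drug with no targets) the similarity is 0 — the mean is undefined there and
0 is the conservative completion. Note the diagonal of this view is *not*
forced to 1: a drug's self-similarity is the mean alignment similarity
among its own distinct targets. The identical-token reading of the
exclusion (rather than identical-sequence) is a deliberate choice; the two
differ only when distinct target identifiers carry byte-identical
sequences.

**Semantic view.** Disease terms live in a rooted ontology DAG. A term's
ancestor closure N(s) contains the term and every ancestor; each node n in
the closure contributes `F_s(n)`, defined recursively as 1 at s itself and
`Δ · max{F_s(n′) : n′ child of n in the closure}` above it. The default
Δ = 1 makes every contribution 1, so the similarity reduces to the overlap
form `2|N_i ∩ N_j| / (|N_i| + |N_j|)` — this closed form is used as an
independent cross-check in the tests. The conventional decayed variant
(Δ = 0.5) is available as a parameter. Disjoint closures score 0.

**Target view.** The Jaccard coefficient of disease target sets, with the
same degenerate-set conventions as the chemical view (∅ vs ∅ → 1,
∅ vs non-empty → 0).

Disease records whose ontology term is missing from the DAG are rejected at
load rather than dropped: silent drops would change the disease family size
and skew every disease-side matrix.

## Model

Per view, a GCN stack propagates a shared random initial feature matrix
(uniform [0, 1), fixed by the run seed) through the symmetrically
normalized self-looped operator `D̃^{-1/2}(I + A)D̃^{-1/2}`, where A is the
similarity matrix itself used as a dense weighted adjacency — no
binarization threshold is introduced. Hidden and output activations are
ReLU; GCN layers carry no bias. Layer weights, attention weights and
extractor weights are Glorot-uniform from the run seed, so the full forward
pass and training trajectory are deterministic given the seed.

The attention layer computes one scalar per view by global average pooling
over the whole embedding, maps the channel-statistic vector through a
bottleneck (`W₁`: reduced × channels, `W₂`: channels × reduced, reduction
factor 2, floor 1) with ReLU then sigmoid, and rescales each view embedding
by its weight. With zero attention parameters every weight is sigmoid(0) =
0.5, so the model reduces exactly to the no-attention variant with each
channel halved — a property the tests assert. The rescaled channels are
concatenated per node and a single fully connected ReLU layer maps them to
the final feature dimension; each output feature has its own weight vector
over the stacked channels, which is the only reading of a
"stack of linear units" consistent with the declared output shape.

The decoder is the plain inner product `U = X′ Y′ᵀ`, and the loss is the
squared Frobenius norm of `U − U′` restricted to the training-pair mask.
Masking reconciles the whole-matrix loss definition with the balanced
training regime (sampled negatives of the same size as the positives); a
full-matrix mode is available by passing no mask.

All gradients are derived by hand (the graph is small and fixed:
GCN stacks → pooling → bottleneck → rescale → concat → linear → inner
product) and validated against central finite differences at 1e-4 relative
tolerance in every ablation configuration.

### Tunable parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `n_layers` | 2 | GCN layers per view; 1 under-propagates, 3+ oversmooths |
| `init_dim` | 256 | width of the random initial features |
| `embedding_dim` | 256 | per-view GCN output width |
| `n_out_channels` | 128 | final feature dimension |
| `attention_reduction` | 2 | bottleneck factor of the attention layer |
| `learning_rate` | 0.001 | Adam step size |
| `n_epochs` | 1000 | full-batch epochs |
| `adjacency_top_k` | None | optional k-nearest sparsification of each view |
| `x0_trainable` | False | whether initial features receive gradients |

The 256/128 widths and 1000-epoch budget suit a full-size repurposing
dataset (order 10³ drugs); the built-in benchmark (see below) uses 32/64/32
widths, 300 epochs, `adjacency_top_k=10` and trainable initial features,
sized for its 160-node graph. The sparsification option matters on dense
similarity graphs: with all-to-all weights the normalized operator is close
to a global average, two layers of which leave node features nearly
constant, and short training budgets then sit at a constant-prediction
plateau. Keeping each node's 10 strongest neighbours preserves the local
structure the encoder needs; trainable initial features further speed
convergence. At the full 1000-epoch budget the dense operator converges
without either option.

## Evaluation

Cross-validation folds partition the positive pairs; the balanced regime
samples an equal number of negatives once, uniformly without replacement
from the zero cells, before any training — negatives are a dataset-level
draw, not re-sampled per epoch. The all-pairs regime folds every cell and
mimics the sparsely labelled deployment setting. ROC AUC uses the rank
statistic with tied scores averaged; AUPR uses step-wise precision–recall
integration (precision held between recall points), which avoids the
over-estimate of trapezoidal PR areas. Threshold metrics (Precision,
Recall, ACC, F1, Specificity) apply a 0.5 threshold to min–max-scaled
scores within each validation fold: inner-product scores are unbounded, so
some explicit normalization is unavoidable and this one is the simplest to
state. The true-positive rate is TP/(TP+FN), the standard ROC definition.
Repeated evaluation with distinct plan seeds (mean ± sd) is supported;
single-run defaults keep the cost proportionate.

Ablations: `no_att` replaces attention weights with unit weights; `no_lin`
bypasses the extractor and averages the (rescaled) channels, which keeps
the drug- and disease-side feature dimensions equal as the decoder
requires; view-subset variants drop similarity matrices and shrink the
attention channels accordingly, requiring at least one view per family.
Ranked prediction for a disease excludes its known associations and breaks
score ties by drug registry order.

## Synthetic benchmark

The generator plants k clusters (default 5) across 100 drugs and 60
diseases. Drugs in a cluster share a prototype fingerprint perturbed by a
5% bit-flip rate and draw targets from a per-cluster pool; diseases attach
to leaves of their cluster's branch in a depth-3 ontology tree and draw
overlapping target subsets; target sequences are length-80 random peptides
with 10% within-cluster point mutations, giving higher within-cluster
alignment similarity. Associations are cluster-diagonal blocks with a 5%
cell-flip noise rate. Everything is drawn from one seeded generator, so
identical specs give byte-identical bundles.

What this emulates: every similarity view carries signal correlated with
the planted association structure, which is the guilt-by-association
premise the model relies on. What it does not emulate: realistic chemistry
or MACCS key semantics, the extreme sparsity of real indication matrices
(the planted blocks give ~23% density versus well under 1% in curated
datasets), ontology depth and fan-out of real disease vocabularies, and
power-law degree structure. Passing the benchmark therefore demonstrates
that the pipeline recovers plantable low-rank structure from coherent
multi-view evidence — not that it attains any particular accuracy on real
drug–disease data.

On this benchmark (5-fold balanced CV, 300 epochs, seed 0) the full model
reaches mean held-out AUC ≈ 0.91 with final training loss under 20% of its
initial value, and neither ablation variant outperforms the full model by
more than seed noise — the numbers are recomputed by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`.

## Numerical and degenerate-input choices

- Similarity matrices validate symmetry within 1e-9 and range within 1e-9;
  unit diagonals are enforced for the chemical, semantic and target views
  only.
- The normalized adjacency cannot divide by zero: the added identity makes
  every degree ≥ 1.
- A loss that becomes non-finite raises a training-failure error naming the
  epoch rather than continuing silently.
- Metric denominators that vanish (e.g. no predicted positives) yield 0
  rather than NaN; AUC requires both classes and raises otherwise.
- Constant score vectors min–max-scale to 0.5 everywhere.
- File round-trips write floats with `repr`, so values survive to the last
  bit; matrix files carry their identifier axes and are validated on read.

## Known limitations

- Training is full-batch dense linear algebra: memory and time scale as
  O(N²) per family. Order-10³ node families are comfortable on one CPU;
  order-10⁵ would need sparse propagation, which only the top-k option
  approximates.
- The estimator is transductive — scores exist only for the network it was
  fitted on; there is no inductive embedding of unseen drugs.
- The therapeutic view degrades to 0 for drugs without annotated targets,
  which flattens that view rather than imputing from the other views.
- Attention weights are two scalars per family; they reweight whole views
  and cannot express per-node view preferences.
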