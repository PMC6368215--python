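# Methods

## Overview

`moltrans` learns a continuous, fixed-size molecular descriptor by training a
sequence-to-sequence model to *translate* between syntactically different but
semantically equivalent line notations of the same molecule — an enumerated
(randomly spelled) SMILES to its canonical SMILES, or an InChI to the
canonical SMILES. Because the decoder can only reproduce the canonical
spelling from the information that crosses the bottleneck, the bottleneck
vector must encode the molecular graph rather than surface features of the
input string. The bottleneck output is the descriptor used for QSAR
modelling, similarity-based virtual screening and latent-space exploration.

## Model

The encoder is a stacked LSTM read over the one-hot token sequence,
optionally bidirectional (a second stack reads each sequence reversed; the
desk-scale model uses this, selected by held-out translation accuracy). The
final *cell* states of all encoder layers — both directions when
bidirectional — are concatenated and mapped by one fully connected layer
through a bounded tanh nonlinearity to the latent vector z ∈ [−1, 1]^D. The bounded bottleneck is deliberate: latent-space
shifting stays in a compact region, and off-manifold points remain
decodable. The decoder is a stacked LSTM whose initial cell state in each
layer is produced by that layer's own affine map of z (c₀ = tanh(Wz + b));
the initial hidden state is taken as tanh(c₀), consistent with an LSTM
output whose output gate is open. Decoding is trained with teacher forcing
(ratio 1, no schedule) and performed at inference by a left-to-right beam
search with no length normalization (a penalty hook exists but is off).

A 3-layer fully connected classifier (two ReLU hidden layers) maps z to
nine molecular properties: Crippen logP, maximal and minimal Gasteiger
partial charge (elementary charges), valence-electron count, H-bond donor
and acceptor counts, Balaban J, Crippen molar refractivity, and TPSA (Å²).
Properties are standardized to zero mean and unit variance over the
training corpus before the loss; the raw values span several orders of
magnitude and an unstandardized MSE would be dominated by the
valence-electron count. The standardization constants travel with the
checkpoint.

The joint objective is the mean masked cross-entropy of the decoder's step
distributions against the target tokens plus `loss_mix` (default 1.0) times
the property MSE. Setting `loss_mix = 0` reproduces the
translation-without-classification ablation.

The whole network, including the backward pass and the Adam optimizer, is
implemented in NumPy. The analytic gradients are verified against central
finite differences at 1e−4 relative tolerance in the test suite.

## Tokenization

Sequences are tokenized per character except `Cl` and `Br` (SMILES) and the
constant prefix `InChI=1S/` plus `Cl`/`Br` (InChI), matched greedily.
Element symbols beyond these are left as single characters; for InChI this
is an assumption — the layered format is tokenized the same way for
symmetry. Three specials (start, end, pad) occupy the first vocabulary
slots; observed tokens follow in lexicographic order, so a vocabulary is a
pure function of its corpus. Vocabularies are serialized next to the model
parameters. Vocabulary contents are data-derived rather than fixed lists,
so descriptor extraction is reproducible from the checkpoint alone.

## Training protocol

For the enumerated-SMILES task the input is a random SMILES variant
(uniformly random atom-order permutation, then a non-canonical SMILES
write-out) with probability 0.5 and the canonical string otherwise; the
target is always the canonical SMILES. Input vocabularies for this task are
built from the canonical corpus plus five enumerated variants per molecule;
the rare enumerated spelling containing an unseen token falls back to the
canonical input rather than aborting the step. Optimization is Adam with
global gradient-norm clip 5 and a step-decay learning rate; the desk-scale
recipe (selected, like the architecture, by held-out translation accuracy)
is lr 2e−3 halved every 5,000 steps, batch 32, inverted dropout 0.2 on the
top decoder states. Optional regularizers — training-time latent jitter,
word dropout on teacher-forcing inputs, decoupled weight decay, reversed
encoder input, a separate learned map for the decoder's initial hidden
state — are available in the config; none improved held-out accuracy over
the bidirectional-encoder recipe at desk scale and all default off. 5% of
molecules are held out by seed for monitoring. Divergence (non-finite
loss) aborts with the last good checkpoint. Monitoring reports
teacher-forced single-character accuracy on the held-out molecules.

## Desk-scale study conditions

The pretraining corpus of the original protocol (~72 M compounds) is far
beyond a single-CPU build, so the package defines its study conditions with
the synthetic generator: 5,000 unique molecules of 4–11 heavy atoms over
{C, N, O, S, F, Cl, Br}, grown as random valence-respecting trees with ring
closures (p = 0.35), occasional double bonds (p = 0.25), post-hoc
aromatization of eligible six-carbon rings, and 20% of larger draws
decorated benzene cores (organic screening collections are aryl-rich).
Every draw is standardized (stereo removal, salt stripping, largest
fragment) and must pass the corpus filters: organic elements only with at
least one carbon, molecular weight 12–600 Da inclusive, strictly more than
3 heavy atoms, logP in [−7, 5] inclusive. The desk model uses a
single-layer bidirectional LSTM encoder (128 units per direction), a
single-layer decoder of width 192 and latent D = 64; 20,000 training steps
complete in minutes to tens of minutes on one CPU.

What the generator does *not* emulate: charged species, polycyclic and
fused ring systems beyond what random closure produces, stereochemistry
(removed anyway), tautomer distributions, and the property distributions of
real vendor catalogues. Passing the desk-scale tests therefore demonstrates
that the machinery is correct and that translation pretraining concentrates
structural information in the latent — not that the resulting descriptors
match the published large-scale screening performance.

## Evaluation harness

QSAR uses nested cross-validation: 5 outer folds, either shuffled-random or
leave-one-cluster-out with clusters from K-means (K = 5) on MACCS keys;
an inner 3-fold grid search over an RBF-kernel SVM (C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, auto}) fitted on training folds only, with feature
standardization inside the pipeline so no test-fold statistics leak.
Metrics are r² (regression) and ROC AUC (classification); AUC is computed
by the rank (Mann–Whitney) formulation with ties counting ½ and is checked
against scikit-learn in the tests.

Virtual screening follows the group-fusion protocol: per repetition five
query actives are drawn without replacement, every remaining compound is
scored by its maximum similarity to the queries (MAX fusion is the
benchmark convention; MEAN is available behind a flag), and the ROC AUC of
remaining actives versus decoys is averaged over 50 repetitions. Continuous
descriptors are standardized per target over actives and decoys jointly and
compared by cosine similarity; count fingerprints use the min/max
generalization of Tanimoto similarity. Descriptor sets are compared across
targets with the two-sided Wilcoxon signed-rank test; all-zero differences
return p = 1 with a warning.

## Latent-space exploration

Trajectories shift a start latent k·s·d for steps k ∈ [−n, n] along a unit
direction d (a principal component of a reference latent set, with a fixed
sign convention, or a random unit vector). Each point is decoded with a
width-3 beam; the rank of the first hypothesis that parses as a valid
molecule defines the validity rates (rate_k = fraction valid within the
top k; nested by construction), and the Tanimoto distance between hashed
circular count fingerprints (radius 2, 2048 bins) of the decode and its
start molecule measures chemical displacement. The default step size s is
the mean nearest-neighbour latent distance of the reference set, so
trajectories leave the data manifold gradually. Axis–property correlations
are per-trajectory Spearman ρ between the step index and a property
(molecular weight or logP) of the decoded molecule, failed decodes dropped,
trajectories with fewer than 3 decodes or constant property dropped with a
warning; the combined p across trajectories is a one-sample two-sided
Wilcoxon of the ρ values against zero.

## Numerical and design choices

- Ties in beam pruning break toward the earlier-generated hypothesis;
  candidate generation order is deterministic, so decoding is
  bit-reproducible.
- The descriptor of a molecule is the latent of its canonical SMILES (its
  InChI for InChI-input models), not an average over enumerations.
- Salt stripping removes fragments from a small common-counter-ion list and
  keeps the largest remaining fragment by heavy atoms; ties break by
  molecular weight, then lexicographic canonical SMILES.
- "Organic" means: at least one carbon and only {H, B, C, N, O, F, Si, P,
  S, Cl, Se, Br, I}.
- Weight and logP filter bounds are inclusive; the heavy-atom bound is
  strict.
- Canonical SMILES are toolkit-version-dependent; tests assert semantic
  (round-trip) identity, with one golden string pinned to RDKit 2024.09.
- Property standardization guards zero-variance columns; descriptor
  standardization of a single molecule raises a degenerate-standardization
  error.
- The acceptance script runs a reduced protocol (4,000-molecule corpus,
  8,000 training steps, 500-molecule QSAR subsample) chosen to keep a
  single-CPU end-to-end run comfortable; the test suite trains the full
  20,000-step desk model.

## Known limitations

- No attention and no variational bottleneck; long sequences (large
  molecules, long InChIs) will strain a fixed 64-dimensional latent.
- Held-out translation accuracy at desk scale plateaus around 0.93 (the
  test suite measures it on the 5,000-molecule corpus at 20,000 steps):
  with under five thousand training molecules the model memorizes its
  training set (accuracy > 0.99 there at small corpus sizes) but
  generalizes the canonical-ordering rules imperfectly, mostly confusing
  heteroatom identity and branch order on unseen molecules. Published
  results at this accuracy level rely on corpora millions of times larger,
  where generalization comes from data scale.
- The InChI task is supported but converges more slowly; translating
  *to* InChI is known to be much harder and is not attempted.
- Beam search explores sequence space only to the configured width; rates
  reported with width 3 are lower bounds on decodability.
- The generator's chemistry (tree growth plus single ring closures) favours
  chain-like molecules; ring-system diversity is limited.
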