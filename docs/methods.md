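# Methods

## The prediction problem

Given a drug `i` and a protein `j`, decide whether they interact.  The
difficult case is the *unseen* (cold-start) drug: a compound with no
recorded interactions of any kind, for which only its SMILES-derived
chemical embedding is available.  The package implements a
heterogeneous-information integration approach to this problem,
consisting of three parts: feature construction, feature imputation for
unseen drugs, and a residual-network classifier, together with the
drug-based cross-validation protocol that makes cold-start performance
measurable.

## Feature construction

Each drug is described by the concatenation

    D_i = [Drug_i ; DDI_i ; DSIE_i ; DDIS_i]

of its dense chemical embedding (Mol2vec-style, 300-dim at benchmark
scale) and its rows of three binary association matrices: drug–drug
interactions, drug–side-effect and drug–disease associations.  Each
protein is described by

    P_j = [Protein_j ; PPI_j ; PSIM_j ; PDIS_j]

— its sequence embedding (ProtVec-style, 100-dim), its protein–protein
interaction row, its row of a real-valued Smith–Waterman-derived
similarity matrix, and its protein–disease association row.  A
candidate pair feeds the classifier with `x = [D_i ; P_j]`.  Block
order is fixed; ablations drop blocks without reordering the remainder,
so column offsets stay stable.  No block is rescaled before
concatenation: normalization is the model's job (below).

At the benchmark's published scale (707 drugs, 1489 proteins, 4192 side
effects, 5603 diseases) the widths are |D| = 10802, |P| = 8681,
|x| = 19483.

## Imputation for unseen drugs

Four feed-forward predictors F_DDI, F_DSIE, F_DDIS, F_PDIS map
`[embedding ; association row] -> association row` through three hidden
ReLU layers (1024/512/128 for F_DDI, 4096/2048/1024 for the others at
benchmark scale; 256/128/64 at desk scale).  At prediction time the
association part of the input is **zero-masked** — `[embedding ; 0]` —
and the sigmoid outputs in [0, 1] are used directly, unthresholded, as
the feature block of an entity whose true associations are unknown.
Imputers for drug-side matrices are trained only on drugs outside the
test fold, mirroring the unseen-drug semantics; F_PDIS may be trained
on all proteins (proteins are never held out in drug-based folds) and
is applied either as a replacement for every protein's PDIS block
("predicted all") or not at all ("available PDIS").

Training minimizes element-wise binary cross entropy with Adam
(lr 1e-3, mini-batches of 16, 600 epochs).  Two regularization choices
matter and were made deliberately:

* **Input masking (rate 0.7).**  Entries of the association part of
  each training input are randomly zeroed.  Plain autoencoding lets the
  network satisfy the loss by copying its input, leaving the embedding
  pathway — the only one alive at deployment — untrained; in
  experiments the plain protocol plateaued at the column-frequency
  baseline.  Random input masking is the standard denoising-autoencoder
  remedy and places the fully masked deployment input near the training
  distribution.
* **Decoupled L2 weight decay (1.0).**  With on the order of 100
  training entities the network otherwise overfits within tens of
  epochs.  Weight decay keeps held-out reconstruction improving for the
  whole budget, which is why the default disables early stopping
  (a 10-entity validation slice proved far too noisy to track
  zero-masked generalization; the machinery remains available through
  `ImputerTrainConfig(validation_fraction=...)`).

Hidden-layer dropout (rate 0.5 at benchmark scale, 0.2 at desk scale
where layers are narrow) is applied after each hidden layer during
training only; `impute()` never enables it, so inference is
deterministic.

## The classifier

The pair vector passes through one or more residual blocks

    f(x)  = W2 · ReLU(LayerNorm(W1 · x))
    y     = ReLU(LayerNorm(f(x) + W3 · x))

where `W1` is M1×M, `W2` is M2×M1 and `W3` is the M2×M projection that
matches the skip path to the block width; the skip-scaling constant is
fixed at 1.  Layer normalization uses biased (population) variance over
the feature axis with eps 1e-5 and learnable gain/bias initialized to
1/0.  Stacked blocks all share the (M1, M2) widths, each consuming the
previous block's M2-wide output.  A classifier of 1–3 ReLU hidden
layers and a single sigmoid unit produces the interaction probability;
binary cross entropy (probabilities clamped at 1e-7) is minimized with
Adam on shuffled mini-batches, early-stopped on a validation criterion
with best-weight restoration.  With `use_residual=False` and two hidden
layers the model reduces exactly to the embeddings-only reference
baseline.

Free architectural constants the source description leaves open were
fixed as defaults and left configurable: M1=1024, M2=512, classifier
hidden width 512, validation-loss early stopping with patience 10, max
300 epochs, uniform fan-in weight initialization, no dropout in the
classifier.  The hyperparameter grid is blocks ∈ {1,2,3} × hidden
layers ∈ {1,2,3} × learning rate ∈ {1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1}
(54 points), selected on validation AUC with first-in-enumeration-order
tie-breaking.

Desk-scale runs (see below) use batch 128 — the published batch of 512
scaled to a training set of hundreds rather than thousands of pairs —
learning rate 1e-3 (inside the grid), M1=256/M2=128, and early stopping
on validation AUC, the same quantity grid selection uses.

## Cross-validation protocol

Drugs are sorted by descending positive-interaction count (ties broken
lexicographically) and assigned greedily to the currently least-loaded
of k=10 folds, which bounds the spread of per-fold positive totals by
the largest single-drug count.  Drugs with no positives are spread
round-robin afterwards.  Negatives are sampled per drug, uniformly
without replacement from the drug's non-interacting proteins, at
exactly ratio × (its positives) with ratio ∈ {1, 3, 5}; drugs with no
positives receive exactly 3 negatives (the dataset averages 2.7
positives per drug).  For each round, the test fold's drugs contribute
all their pairs (~10%), a seeded pair-level sample of ~5% of all pairs
forms the validation set, and the rest (~85%) trains.  Pair-level
validation was chosen because the 85/5/10 arithmetic is only cleanly
achievable at pair granularity.  Every test drug is absent from train
and validation — the cold-start guarantee, verified by a no-signal
control (below).

Two auxiliary procedures support the comparison experiments: a
pair-level random k-fold mode in which drugs straddle folds (the
conventional, non-cold-start protocol), and a redundancy filter that
retains only test drugs whose similarity to every training drug is
strictly below 0.6, with the similarity matrix supplied by the caller
(the filter is metric-agnostic).

By default the DDI columns that reference test drugs are retained in
training drugs' vectors; `leakage_safe=True` zeroes them.

## Evaluation

Confusion counts use "predicted positive iff probability ≥ 0.5".
Precision, recall and F1 follow the standard definitions with 0/0 := 0.
ROC AUC is the Mann–Whitney concordance probability with ties counted
one half; PR AUC is step integration over recall (average precision)
with tied scores grouped.  Fold metrics are computed per fold and then
averaged (mean of fold AUCs, not pooled).  Per-drug analyses report the
AUC over each drug's test pairs (single-class drugs excluded and
tabulated separately) and the "distance" |mean p(predicted positive) −
mean p(predicted negative)| per drug.  The THR_k% baselines predict a
test pair positive iff the protein's positive ratio among its
*constructed training pairs* (positives plus sampled negatives) is at
least k% — the natural reading of a frequency rule against the training
set actually used.  Method comparisons across folds use a paired
two-sided t-test (folds are matched), with p = 1 for identical vectors.

## Synthetic data

The generator plants a shared latent space: every drug, protein,
side-effect and disease has a unit-Gaussian latent factor (dim 8).
Binary association cells are Bernoulli draws of a logistic link on
scaled latent inner products, with the intercept bisection-calibrated
to a per-matrix density target; DDI and PPI are symmetrized without
self-loops.  PSIM is the real-valued logistic of protein–protein latent
inner products.  Embeddings are noisy linear maps of the latents.  DTI
labels are Bernoulli draws on

    logit p(i,j) = c · ⟨u_i, v_j⟩/√L + b_i + β_j + d

with the global intercept `d` calibrated to 2.7 positives per drug on
average, matching the published benchmark.

The defaults encode study conditions chosen once to reproduce, by
construction, the qualitative phenomena the method is validated
against:

* **Embedding noise sd 0.7** (relative to unit signal).  Real
  Mol2vec/ProtVec embeddings are informative but far from sufficient —
  in the source study the embeddings-only baseline trails the full
  model by 0.13 AUC.  Low-noise embeddings would make every association
  block redundant and erase that ordering.
* **Association scale 6** (sharp logistic link).  Association rows are
  then strong, low-noise measurements of the latents: each block is
  individually useful, the blocks are complementary with respect to
  Bernoulli noise, and rows are predictable from embeddings — the
  premise of the imputation stage.
* **DTI scale 6** with **per-drug (sd 4) and per-protein (sd 2) random
  intercepts**.  The intercepts model promiscuity heterogeneity that no
  feature block can see.  They are what makes pair-based random CV
  genuinely easier than drug-based CV here, as it is on the real data:
  a drug seen in training reveals its own promiscuity through its
  labels, an unseen drug cannot.  The no-signal control zeroes all
  three components.
* **Densities** follow the benchmark's published interaction counts
  (DDI ≈ 0.04, DSIE ≈ 0.03→0.06 desk, DDIS ≈ 0.05→0.08 desk,
  PPI ≈ 0.006→0.04 desk, PDIS ≈ 0.19→0.20), lifted moderately at desk
  scale where matrices have far fewer columns.

Two presets exist: `paper` mirrors the benchmark's axis sizes
(707/1489/4192/5603, embedding dims 300/100), `desk` is 120 drugs ×
200 proteins × 60 side effects × 80 diseases with embedding dims 32/16.
All validation experiments run on `desk`, where a full 10-fold
cross-validation suite completes in minutes on one CPU.

What the generator does **not** emulate: real chemistry (SMILES
payloads are syntactically valid placeholders), realistic degree
distributions or community structure in the association networks,
correlated noise between matrices, and any deterministic
feature-to-label mechanism — labels always carry irreducible Bernoulli
noise.  Passing tests therefore certify that the pipeline recovers
planted signal under honest cold-start conditions, not that it attains
any particular accuracy on the real benchmark.

## Numerical and engineering choices

All networks are implemented on numpy arrays with hand-written
backpropagation (dense layers, biased-variance layer norm, inverted
dropout, Adam); gradients are verified against central finite
differences in the test suite, and forward passes against independent
dense-algebra oracles.  Every source of randomness — weight
initialization, dropout masks, input masking, batch shuffling, negative
sampling, fold seeds — flows through explicit seeded generators, so any
run is bit-reproducible from (config, seed) on a fixed platform.
Probabilities are clamped to [1e-7, 1−1e-7] before logs.  Single-class
AUC inputs raise a dedicated error and are excluded upstream with
notes, never silently defaulted.

## Validation experiments (desk scale)

`hidti.experiments` packages the canonical runs: the feature-ablation
suite (baseline, +DDI, +PDIS, full, predicted), held-out imputer
reconstruction (5/6 train split of drugs; 0.85 of proteins for PDIS),
the five-replicate no-signal control (3 folds each), and the
pair-based versus drug-based contrast.  `scripts/acceptance.py` runs
all of them from scratch and writes the resulting numbers as JSON.

## Known limitations

* The reference (paper-scale) hyperparameters are untested here against
  the real 707×1489 benchmark, which requires an external download.
* The imputer training protocol (masking, weight decay, no early
  stopping) was selected for desk-scale sample sizes; at thousands of
  entities the plain protocol with early stopping may be preferable.
* Only drug-based (unseen-drug) folds are implemented; unseen-protein
  evaluation would need a protein-based fold mode, which the CV API
  deliberately leaves room for.
* Grid search trains one model per lattice point sequentially; at 54
  points × 10 folds it is a batch job, not an interactive one.
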