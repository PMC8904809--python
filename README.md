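# hidti

Drug–target interaction (DTI) prediction by heterogeneous-information
integration, with honest cold-start evaluation for unseen drugs.

Deciding whether a compound binds a protein is a central problem in
drug discovery, and the hard case is the *new* compound: no recorded
drug–drug interactions, side effects or disease associations — only a
structure.  `hidti` implements an approach built for exactly that case,
for computational biologists and cheminformaticians who want a
reference implementation of the full pipeline: feature integration,
feature imputation for unseen entities, a residual-network classifier,
and the drug-based cross-validation protocol that keeps the evaluation
honest.

## The method

A drug and a protein are each described by a concatenated feature
vector

    D_i = [Drug_i ; DDI_i ; DSIE_i ; DDIS_i]
    P_j = [Protein_j ; PPI_j ; PSIM_j ; PDIS_j]

— a dense chemical/sequence embedding (Mol2vec / ProtVec style)
followed by the entity's rows of six association matrices: drug–drug
interactions, drug–side-effect, drug–disease, protein–protein
interactions, protein sequence similarity, and protein–disease.  A
candidate pair `x = [D_i ; P_j]` passes through residual blocks

    f(x) = W₂·ReLU(LayerNorm(W₁·x)),   y = ReLU(LayerNorm(f(x) + W₃·x))

(the projection W₃ matches the skip path to the reduced width) and a
small sigmoid classifier trained with binary cross entropy.

For an **unseen** drug the association rows are unknown.  Four
feed-forward imputers F_DDI, F_DSIE, F_DDIS, F_PDIS are trained to
reconstruct association rows from `[embedding ; row]`; at prediction
time the row part is zero-masked, so `F([embedding ; 0])` supplies the
missing block from the embedding alone.

Evaluation uses **drug-based ten-fold cross-validation**: folds
partition the *drugs* (balanced on positive counts), so every test
drug is absent from training — unlike conventional pair-based splits,
where the same drug appears on both sides and performance is inflated.
Negatives are sampled per drug at 1:1, 1:3 or 1:5; splits are 85/5/10%
train/validation/test.  The metrics module covers ROC/PR AUC,
precision/recall/F1, per-drug analyses, protein-frequency (THR_k%)
baselines, redundancy filtering and paired fold-wise t-tests.

Everything runs against synthetic benchmarks with planted latent
structure (`hidti.synthetic`), generated at either the published
benchmark's scale (707 drugs × 1489 proteins) or a desk scale that
completes in minutes; the real curated dataset can be supplied as TSV
files through `hidti.core_data` if downloaded separately.

The networks are implemented in numpy with hand-written, test-verified
backpropagation; runs are bit-reproducible from a seed.

## Worked example

Three folds of cold-start cross-validation on the small synthetic
benchmark, embeddings-only versus full integration
(`examples/03_cold_start_crossval.py`):

```
embeddings-only baseline: [available:1:1] auc=0.676±0.005 aucpr=0.554±0.045 ...
all heterogeneous blocks: [available:1:1] auc=0.818±0.036 aucpr=0.727±0.052 ...
AUC gain from integrating heterogeneous information: +0.142
```

The baseline sees only the noisy chemical/sequence embeddings; adding
the six association blocks lifts mean test AUC on unseen drugs by 0.14
here — the core claim of the approach, reproduced on planted-signal
data.  Imputing an unseen drug's side-effect vector from its embedding
(`examples/02_impute_unseen_drugs.py`):

```
trained on 100 drugs for 600 epochs (final loss 0.0296)
held-out reconstruction AUC over 20 unseen drugs: 0.900
prediction change after corrupting the drug's true row: 0.0 (masking guarantees 0)
```

AUC 0.90 means the imputed scores rank a held-out drug's true side
effects far above the rest; the final line demonstrates the zero-
masking contract — predictions cannot depend on the (unavailable)
ground truth.  The other examples cover bundle generation/validation
and the evaluation toolbox.

A thin CLI wraps the same pipeline (`hidti synth`, `hidti folds`,
`hidti crossval`, `hidti ablate`, `hidti impute`); see `hidti --help`.

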