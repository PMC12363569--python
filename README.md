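# locforge

Multi-label prediction of protein **subcellular localization** from
sequence alone, for computational biologists and drug-discovery teams who
need to know *where in the cell* a protein (for instance a drug target)
resides — nucleus, cytoplasm, membrane, mitochondrion, and finer
sub-compartments. A protein may occupy several compartments at once, so
the task is multi-label throughout.

## The model

A protein sequence is encoded through two complementary channels and
classified by a hybrid network:

1. **Descriptor-image channel.** Classical sequence descriptors — amino
   acid composition (AAC), dipeptide composition (DPC), autocorrelation
   (Moreau–Broto / Moran / Geary), composition–transition–distribution
   (CTD), quasi-sequence-order (QSO), and pseudo / amphiphilic pseudo
   amino acid composition (PAAC / APAAC) — are computed from a named,
   configurable registry. A reusable *template* lays the descriptors out
   on a 2D grid so that descriptors correlated across a reference corpus
   become spatial neighbours: min–max normalization, pairwise cosine
   distance between descriptor columns, 2D embedding (UMAP, or classical
   MDS / PCA), then an exact rectangular linear-assignment step
   (Jonker–Volgenant) mapping descriptors one-to-one onto grid cells.
   Each protein renders as a single-channel image.
2. **Global-embedding channel.** Per-residue embeddings (a pluggable
   backend; a deterministic mock ships with the package, a 1280-dim
   protein-language-model adapter is the integration point) are
   average-pooled into one vector; sequences longer than the backend's
   context window are split into segments whose pooled vectors are
   combined with length-proportional weights — exactly equivalent to
   whole-sequence pooling for a position-independent embedder.

The image passes through two 3×3 stride-2 valid convolutions, each
followed by 2×2 stride-2 max-pooling, and two FC layers; the embedding
passes through two FC layers (ReLU throughout). The fused vector is
reshaped into a short token sequence, refined by a two-layer
bidirectional LSTM (256 units per direction at published scale, tanh
output), and mapped to per-label sigmoid scores. Training minimizes
**focal loss** `FL = −α(1−p_t)^γ log(p_t)` (α=0.25, γ=2 by default)
with Adam (batch 32, learning rate 2·10⁻⁴ by default) and early
stopping on a validation metric. Decisions threshold each label's
score; a protein below every threshold receives the single label
closest to its threshold, so no protein is left unlabelled.

Dataset curation mirrors benchmark practice: sequences under 40
residues are dropped, labels live in a hierarchy and are closed under
ancestors, the fine-grained label space keeps terms with more than 50
proteins, the newest ~15% of proteins (by annotation date) form a
temporal test set, and the rest are clustered at 30% sequence identity
(internal k-mer engine, or PSI-CD-HIT if installed) with whole clusters
balanced across 5 cross-validation folds.

Evaluation reports per-label MCC, F1 and AUPRC with micro/macro
aggregates, fold mean ± standard error, and drug-target-style location
count tables (recall = hit/true, precision = hit/predicted).

## Worked example

`examples/05_train_and_evaluate.py` trains the full stack on a
250-protein synthetic corpus whose compartments are marked by short
planted motifs (200 train / 50 held out, 30 epochs, a few seconds on
one CPU):

```
learnability (200 train / 50 val, 30 epochs):
  held-out macro-F1    0.943
  held-out macro-MCC   0.913
  held-out macro-AUPRC 0.983
memorization (16 examples, 200 epochs): final focal loss 5.32e-06
```

Macro-F1 above 0.8 shows the image + embedding + BiLSTM stack recovers
the planted compositional signal from raw sequences; the near-zero
memorization loss confirms gradients flow through every layer.
`examples/06_drug_target_count_table.py` prints the drug-target
localization audit (nine compartments, 3,084 true target locations):
overall recall 66.96%, overall precision 88.44%. The other examples
cover descriptors, template building, embeddings and splitting.

A thin CLI wraps the same functions:

```bash
locforge synth --out bundle/
locforge featurize --fasta bundle/proteins.fasta --out features.tsv
locforge build-template --features features.tsv --method umap --seed 42 --out template.json
locforge run --config pipeline.yaml     # full synth→train→evaluate workflow
```

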