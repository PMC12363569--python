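# Methods

This note records the scientific model implemented by locforge, the
conventions chosen where the design was genuinely open, and what the
desk-scale experiments do and do not demonstrate.

## Descriptor registry

Seven classical descriptor families are computed from a named registry.
The default configuration produces 977 descriptors: AAC 20, DPC 400,
autocorrelation 6 scales × 30 lags = 180, CTD 7 attributes × 21 = 147,
QSO 2 distance matrices × (20 + 30) = 100, PAAC 20 + 30 = 50, APAAC
20 + 60 = 80. The registry deliberately does not promise any particular
historical tool's exact dimension; the families, formulas and dimension
rule (`profile_length`) are the contract.

Conventions:

* **Sanitization.** Input is uppercased; residues outside the 20
  canonical letters (B, J, O, U, X, Z, gaps) are dropped with a logged
  warning. Classical descriptor tools operate on canonical residues
  only.
* **Property scales** ship as versioned packaged JSON
  (`data/aa_scales.json`): Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, Chou's normalized hydrophobicity, side-chain mass,
  Grantham's polarity/volume/composition, and residue isoelectric
  points. All standardization is over the 20 residues with population
  standard deviation (the PAAC convention).
* **QSO distance matrices.** The Grantham matrix is generated exactly
  from Grantham's formula (ρ=50.723, α=1.833, β=0.1018, γ=0.000399) on
  the packaged composition/polarity/volume scales; spot checks against
  the printed table agree after rounding (Leu–Ile 5, Arg–Leu 102,
  Trp–Cys 215). The second matrix, `physchem`, is this package's own
  construction — Euclidean distance in standardized
  hydrophobicity/hydrophilicity/side-chain-mass space — a synthetic
  stand-in playing the role a second published physicochemical distance
  matrix would play. QSO blocks are normalized so composition plus
  weighted coupling terms sum to exactly 1 per matrix, hence the
  weight→0 limit reduces to AAC.
* **Zero-variance series.** Moran and Geary autocorrelation return 0
  (not NaN) for constant property series, with a relative tolerance on
  the variance so homopolymers are handled despite floating-point dust.
* **CTD distribution** reports, per class, the relative position
  (percent of length) of the first, 25%, 50%, 75% and last occurrence
  (ceiling rank); an absent class contributes zeros.

## Feature images

The template pipeline is: column-wise min–max normalization (constant
columns map to 0) → pairwise cosine distance between descriptor columns
(all-zero columns are placed at distance 1 from everything, pushing
uninformative descriptors to the layout periphery) → 2D embedding →
exact rectangular linear assignment of descriptors to grid cells.

Open choices, decided here:

* **Grid size**: the smallest square grid with at least as many cells
  as descriptors (39×39 for ~1,484 descriptors; 32×32 for the default
  registry; 21×21 for the AAC+DPC subset used at desk scale).
* **Assignment cost**: squared Euclidean distance between descriptor
  coordinates — min–max rescaled into the grid bounding box — and cell
  centers at (r+0.5, c+0.5). SciPy's `linear_sum_assignment`
  (a Jonker–Volgenant-family solver) gives the exact optimum; a
  property test checks it against exhaustive permutation search.
  Because coordinates are rescaled to the bounding box, points already
  at cell centers are generally *not* fixed points of the rescaling;
  optimality, not zero cost, is the invariant.
* **Reduction method** is pluggable: UMAP (precomputed metric) is the
  default for corpus-scale layouts; classical MDS (exact for
  planar-realizable distances) and PCA on distance profiles are the
  deterministic, dependency-light choices used in tests and desk runs.
* **Render-time clamping**: template statistics come from the reference
  corpus; unseen proteins clamp to [0, 1] rather than leaking test
  statistics into the normalizer.

## Embedding channel

The channel contract is a backend mapping a sequence to a
length × dim matrix. The shipped mock backend is deterministic given
(dim, seed): each residue vector concatenates a seeded random projection
of the residue one-hot (identical wherever the residue occurs) and a
smooth sinusoidal positional block; `positional=False` zeroes the
latter. Global vectors are arithmetic means over residues. Sequences
beyond the context window are split into consecutive non-overlapping
segments (default 1000 residues, a typical protein-LM limit) and pooled
segment vectors are combined with weights proportional to segment
length — the unique weighting for which segmentation is exactly
equivalent to whole-sequence pooling when the embedder is
position-independent. A real 1280-dimensional protein language model
plugs in through the same contract as an optional extra; the package
builds and tests fully without it.

## Network and training

Published-scale constants: two 3×3 stride-2 valid convolutions, two
2×2 stride-2 max pools, two FC layers per branch, a two-layer BiLSTM
with 256 units per direction, ReLU in CNN/FC, tanh on the BiLSTM
output, sigmoid per-label head, focal loss, Adam with batch 32 and
learning rate 2·10⁻⁴, early stopping on validation macro-F1 with the
best epoch's weights restored. Valid (unpadded) arithmetic makes the
shape chain checkable: a 39×39 image maps 19→9→4→2.

Where the architecture was under-specified, the conventions are:

* FC widths 512→256 in each branch, so the fused vector is 512-dim.
* The BiLSTM consumes the fused vector zero-padded to a multiple of
  T=16 and reshaped into T tokens of size fusion/T; the final forward
  and backward states are concatenated. This is a documented
  convention that preserves all fused information, not a claim about
  any reference implementation.
* Focal loss defaults α=0.25, γ=2 (the classical focal-loss defaults);
  probabilities are clamped at 10⁻⁷. With γ=0, α=1 the loss is exactly
  binary cross-entropy.
* Early stopping halts once `epoch − best_epoch ≥ patience`; the
  history keeps every evaluated epoch.
* All randomness (initialization, shuffling) flows from one seed;
  runs are bit-reproducible.

The layers run on a small reverse-mode autodiff engine written for this
package (tensors over numpy with broadcasting, matmul, activations,
strided convolution and pooling primitives, and an unrolled LSTM);
every primitive and the full network are verified against central
finite differences in the test suite.

## Dataset curation and splitting

Records join a FASTA file with a tab-separated annotation file (id,
semicolon-separated terms, ISO date, organism). Curation: minimum
length 40 residues; ancestor closure of label sets; `main` task = the
10 major compartments, `all` task = terms with strictly more than 50
proteins. The temporal test set is the `ceil(0.15·N)` most recent
records (ties broken by id). Cross-validation folds come from
clustering at 30% identity and greedily assigning whole clusters,
largest first, to the currently smallest fold — balancing *sequence*
counts, not cluster counts, so training sets stay comparable in size.
The greedy rule bounds fold imbalance by the largest cluster size.

The internal clustering engine estimates identity as the containment of
the shorter sequence's 5-mers in the longer's, a fast proxy adequate at
the 30% threshold (point mutations at 5% per site retain ~77% of
5-mers; unrelated random sequences share almost none). PSI-CD-HIT is
the external fidelity path when its binary is available; its absence
raises an error naming the internal engine. Organism filtering is
delegated to the annotation file's organism column rather than to
taxonomy services.

## Evaluation

Per-label confusion counts come from the decision rule (threshold 0.5
by default; the fallback assigns the label maximizing score −
threshold, ties to the lowest index, so every protein gets at least one
label). MCC returns 0 when any marginal is empty; F1 returns 0 when
TP = 0. AUPRC is average precision with tied scores processed as one
block (block-end precision credited to each positive inside), which is
deterministic across sort implementations; it is undefined (excluded
from macro averages) for labels with no positive instance. Both micro
(pooled counts) and macro (label mean) aggregates are reported, since
either convention appears in the literature. Count-table metrics round
to two decimals and report `None` on zero denominators; the totals row
recomputes both metrics from summed counts, which provably equals the
pooled instance-level computation.

## Synthetic corpora

The generator emulates the three statistical properties the pipeline
relies on: class-conditional sequence signal, hierarchical multi-label
annotations, and homologous families. Background sequences are uniform
over the 20 residues (the simplest null); each label a protein carries
plants a short motif at a uniform random position (insertion
probability 1.0 for positives by default). The default hierarchy has 4
main compartments with 2 sub-compartments each — the main/sub structure
of real localization ontologies at toy scale. Motifs use disjoint
residue pairs per label (length 10 for main labels, 6 for
sub-labels) so each class perturbs its own slice of the composition;
they caricature targeting signals and make the corpus learnable by
composition-sensitive descriptors, but are not biophysically realistic
(no true signal peptides, no length/composition covariation, no
phylogenetic structure). Families derive members from a common ancestor
by point mutations (5% per site by default) with motifs re-planted, so
family members co-cluster at the 30% identity threshold. Passing tests
on these corpora demonstrates that the pipeline's machinery — features,
layout, fusion, optimization, splitting — works end to end; it says
nothing about accuracy on real proteomes.

## Desk-scale experiment sizes

The learnability benchmark uses 250 proteins of length 40–150 (200
train / 50 held out), an AAC+DPC image on a 21×21 grid, the 64-dim mock
embedder, a narrow model (8/16 conv channels, 64→32 FC, 32-unit
BiLSTM, 8 tokens), learning rate 10⁻³, 30 epochs; the memorization
check uses 16 examples, learning rate 3·10⁻³, 200 epochs. These sizes
keep a full run in seconds on one CPU while leaving the architecture's
every component exercised. At the pinned seed the held-out macro-F1 is
0.94; across other seeds it typically falls between 0.79 and 0.92 —
a 50-protein validation set makes the metric grainy (one protein is
0.02 of macro-F1).

## Known limitations

* The mock embedder carries composition and position information only;
  conclusions about real protein-language-model embeddings require the
  optional backend.
* The internal identity estimate is not an alignment; borderline
  homology (20–40% identity) is resolved differently than PSI-CD-HIT
  would.
* The `physchem` QSO matrix is a documented stand-in, not a published
  reference matrix; descriptor values depending on it are internally
  consistent but not comparable across tools.
* Thresholds default to 0.5 per label; per-label calibration on
  validation data is supported but not automatic.
* No GPU path; the numpy network is meant for desk-scale corpora, not
  tens of thousands of proteins.
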