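# Methods

## Model family

A DTI model is a pair of molecular encoders feeding an MLP decoder.  The
drug embedding and the protein embedding are concatenated — no cross-attention
or bilinear pooling between the two towers — and the decoder outputs one
scalar.  For regression that scalar is the predicted p-scale affinity
(−log10 molar); for classification it is a logit passed through a logistic
function.  The modelling assumption is therefore that binding is predictable
from independent summaries of the two molecules; any interaction between
drug and target features has to be learned by the decoder.

Task selection is automatic: labels ⊆ {0, 1} mean classification (binary
cross-entropy loss; AUROC, AUPRC, F1), anything else means regression (MSE
loss; MSE, concordance index, Pearson).  The concordance index treats tied
predictions as half-correct, the standard convention.

## Encoders

Compound side: `morgan` (circular fingerprint, radius 2, 1024 bits),
`pubchem` (881 substructure keys), `daylight` (hashed linear paths up to 7
bonds, 2048 bits, plus length-0 typed-atom bits so single-atom molecules are
non-degenerate), `desc2d` (a fixed 40-descriptor physicochemical panel, each
value mapped through an empirical CDF fitted once on a packaged synthetic
reference molecule set, so outputs live in [0, 1] and a failing descriptor
imputes to 0.5), `cnn_smiles` and `cnn_rnn_smiles` (character CNN over a
fixed 64-symbol charset, max length 100), `espf_transformer` (byte-pair
encoded substructure tokens, vocabulary mined from the training corpus), and
`mpnn` (message passing over atoms/bonds with mean readout).

Protein side: `aac`, `paac` (λ = 30, weight 0.05), `conjoint_triad`,
`quasi_seq` (maxlag 30, weight 0.1), `cnn_protein` / `cnn_rnn_protein`
(25-symbol alphabet, max length 1000) and `espf_transformer_protein`.

The PAAC property scales (hydrophobicity, hydrophilicity, side-chain mass)
are packaged as a versioned constant file.  The quasi-sequence-order
distance matrix is likewise packaged; it is a physicochemical distance
(RMS difference of the three z-scored property scales, rescaled to [0, 1])
computed from the same property table, so the descriptor has no external
data dependency.  Residues outside the 20-letter alphabet are dropped from
composition counts (the effective length shrinks) and map to UNK in token
encodings.

The PubChem-style key table is a packaged 881-entry definition file
(element-count thresholds, SSSR-based ring features, bonded element pairs,
atom-environment and functional-group SMARTS).  Keys whose published
definition requires 3D information are fixed at 0 — the featurizer is
2D-only by design — and each key's definition is documented in the table
itself, which is also the oracle the tests evaluate against.

## Architectures and numerical choices

All networks run on a reverse-mode autodiff engine over float64 numpy.
Glorot-uniform initialization from an explicit seeded generator makes model
construction bit-reproducible; training is single-threaded and
deterministic, so identical configurations reach identical parameters.

* MLP encoders: Linear+ReLU stacks; defaults [1024, 256, 64] for
  fingerprints, smaller for low-dimensional descriptors.
* CNN: embedding (PAD row fixed at zero) → three valid 1-D convolutions with
  increasing filter counts → global max-pool → linear.  The CNN+RNN variant
  replaces the pool with a bidirectional tanh RNN whose state update is
  masked so padded steps carry the state through unchanged; the two final
  states are concatenated.
* Transformer: learned positional embeddings, pre-LN multi-head
  self-attention with padding-masked keys, masked mean-pool readout;
  defaults 2 layers, 4 heads, model dim 64.  An all-padding sequence is an
  error rather than a silent zero embedding.
* MPNN: atom rows are element/degree/charge/aromaticity/H-count features;
  each of 3 message-passing steps sums ReLU-transformed (neighbor state,
  bond feature) messages into each atom, followed by a linear state
  update; mean readout keeps the embedding invariant to atom numbering
  (verified to < 1e-5, the float-association limit).  Dot-separated SMILES
  stay one disconnected graph.
* Decoder: hidden layers [1024, 1024, 512], ReLU, final linear scalar.
* Optimizer: Adam (β₁ 0.9, β₂ 0.999), learning rate 1e-3 default, seeded
  shuffling; early stopping watches validation CI (regression) or AUROC
  (classification) with configurable patience, and the best-validation
  parameters are restored at the end of training whenever a validation fold
  is supplied.  A non-finite loss aborts with the epoch/batch location.
* Hyper-parameter search: seeded uniform random search over a declared grid;
  no adaptive scheme.

Every default lives in `dtikit.config.DEFAULTS` and is overridable through a
YAML config; the saved-model directory stores the resolved spec, the
parameter arrays and any trained substructure vocabularies, and reloading
reproduces predictions bit-for-bit.

## Splits

`random` permutes pairs; `cold_drug` / `cold_protein` partition entities so
the compound (or protein) id sets of train/valid/test are pairwise disjoint.
Fold sizing uses floor(n·f_test) and floor(n·f_valid) with the remainder to
train, which makes fold sizes deterministic; for cold splits the fractions
apply to entities, so achieved pair fractions are approximate and are
logged.  Duplicate (compound, protein) rows keep the first occurrence and
are counted in a skip report — silent averaging would hide data errors.

## Synthetic data generator

The generator emulates a sparsely observed drug × target affinity matrix.
Drugs are assembled from a packaged bank of 51 concatenation-safe SMILES
fragments (1–3 fragments per drug); targets are uniform random sequences of
length 50–200.  The label is

    y(d, t) = 7 + effect_size · z(⟨u_d, v_t⟩) + N(0, noise_sd)

with `u_d` a fixed random projection of the drug's 1024-bit Morgan
fingerprint, `v_t` a fixed projection of the target's amino-acid
composition (both rank 8, projection seed fixed independently of the
sampling seed), and `z` the grid-wide standardization.  The offset 7 puts
labels on a realistic pKd-like range.  Defaults (50 drugs, 20 targets, half
the grid observed, effect size 1, noise sd 0.3) define the study conditions
of the recovery experiment.

What passing tests show: models can extract a planted signal that lives in
their own input features, pipelines are leak-free, and chance-level data
yields chance-level CI.  What they do not show: performance on real
affinity data — real assay noise is heteroscedastic and censored, real
chemical space is far larger than a 51-fragment bank, real sequences have
domain structure, and the real drug–target map is not rank-8 bilinear.  The
generator deliberately does not imitate DAVIS/KIBA label distributions.

One generator property is worth flagging: because the planted signal is a
bilinear interaction, a linear model on *concatenated* (fingerprint, AAC)
features captures only its main-effect share — pilot runs at zero noise
give held-out CI ≈ 0.79–0.84, not near 1.  The frozen test bound for that
probe (CI > 0.75) reflects those pilots.  The trained encoder-decoder
models, which can represent the interaction, reach CI ≈ 0.8 under the
noisy half-observed default conditions, against a null control within
0.5 ± 0.07.

## Problem sizes

Tests and the acceptance script run the recovery experiment at the study
conditions above (500 observed pairs, 30 epochs, morgan+aac) and exercise
the other encoder families at reduced widths (embedding dim 8, two conv
layers, one transformer block) on grids of ≤ 32 pairs — the package's own
choice of desk-scale problem sizes; the architectures are identical at any
width.

## Known limitations

* No GPU path and no minibatch parallelism; float64 numpy throughout.
* The PubChem-style key table follows the published section structure but
  is not bit-compatible with CACTVS output; it is a documented, versioned
  approximation (ESSSR ring perception is approximated by SSSR).
* No 3D conformers, stereochemistry-aware graph features, PSSM/structure
  protein features, or pretrained weights.
* Cold-split evaluation on small synthetic grids is high-variance; the
  worked example uses a random split for that reason.
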