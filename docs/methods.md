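# Methods

## The model

A 2D fingerprint of length L is encoded as the smallest square matrix with at
least L cells: n = ⌈√L⌉, filled in row-major order (index 0 top-left, rows
left-to-right), with flattened positions ≥ L fixed at 0.  Zero padding keeps
binary semantics — the matrix sum equals the set-bit count — and the encoding
is exactly invertible (flatten and truncate to L).  Count fingerprints (ECFC4,
ALOGP) are first divided by the maximum count observed in the *training*
split and clipped to [0, 1], so every matrix entry lies on the same scale as a
bit; the divisor is stored with the fitted model and reused at prediction
time.  Whether count fingerprints should be rescaled at all is a genuinely
open design point; train-split max-scaling was chosen because it is the
simplest rule that keeps CNN inputs commensurate across families, and it is
configurable (`normalise=False`).

Each fingerprint family feeds one convolutional branch: two unpadded 3×3
convolutions (stride 1), ReLU after each, one 2×2 max-pool (stride 2), then a
flatten.  The channel count of both convolutions is 16: the per-branch
flatten width is then floor((n−4)/2)²·16, which is 3136 for a 32×32 input —
the unique channel plan consistent with every published fusion width
(6272/2 = 9408/3 = 12544/4 = 15680/5 = 3136).  Likewise, "two valid 3×3
convolutions then one pool" is the only conv/pool arrangement that reaches
14×14 from 32×32; pooling after *each* convolution would give 6×6×16 = 576
per branch and contradict the fusion widths.  Branch flatten vectors are
concatenated (feature-level fusion) and passed through two ReLU dense layers
and a softmax output.  The dense head widens with the number of fused
branches: k=2 → (128, 64), k=3 → (256, 128), k=4 → (512, 256),
k=5 → (1024, 512); the single-branch head reuses (256, 128).  No dropout or
batch normalisation is used.  Branches of unequal side (e.g. MACCS 13×13
fused with ECFP4 32×32) are permitted; the concatenation width is then the
sum of per-branch widths.

Targets are one-hot encoded (y_it = 1 iff molecule i belongs to class t) and
the loss is categorical cross-entropy, minimised by minibatch Adam
(defaults: learning rate 1e−3, batch 32, 20 epochs — convergence on the
benchmarks used here is typically well inside 20 epochs; all configurable).
Per-epoch training accuracy and MSE (between one-hot targets and softmax
probabilities — MSE is reported as a trace statistic even though the loss is
cross-entropy) are recorded, and validation curves are added when an eval set
is supplied, since either convention is found in practice.  Class prediction
is argmax with lowest-index tie-break.  The engine is written directly in
numpy (im2col convolutions so the inner loop is a BLAS matmul, float32
throughout); a single `numpy.random.Generator` seed drives initialisation
(He-normal) and batch shuffling, so runs are bit-reproducible on a fixed
platform.

## Fingerprints

Generation uses RDKit: ECFP4/ECFC4 are Morgan radius-2 fingerprints folded to
1024 bits/bins; EPFP4 is the linear-path hashed fingerprint (1024 bits); CDK
the branched-path hashed fingerprint (1024 bits); GOFP the linear-path
fingerprint computed on a copy of the graph with all bond orders collapsed to
single bonds; MDL the 166 MACCS keys (RDKit's unused bit 0 dropped); PCFP an
881-bit Avalon substructure fingerprint standing in for the 881 PubChem-style
keys; ALOGP a 120-bin atom-type count block (stable crc32 hash of each atom's
(element, degree, H-count, aromaticity, charge, ring-membership) tuple).
These are open equivalents chosen to match each family's length and
semantics, not bit-exact reproductions of any proprietary generator; when
original exports exist, the fingerprint CSV ingest path preserves them
exactly.  SMILES are canonicalised by parsing, so identical molecules always
map to identical vectors; unparsable records are rejected per-record with a
report, never aborting a load.

## Evaluation

Per activity class, one-vs-rest: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), and AUC as the Mann–Whitney rank statistic of the class
probability column with ties counted half.  Undefined cells (class absent
from the truth, or without negatives) are NaN — never 0 — and are excluded
from the mean and variance summary rows.  Method comparison uses classical
one-way ANOVA over per-class accuracy values; complete separation (zero
within-group variance with distinct means) is reported as F = ∞ with p = 0
rather than an exception.  Train/test splitting is stratified 80/20 with a
configurable seed.  Baseline classifiers produced by other toolkits are
evaluated on the same footing through a prediction-table CSV
(molecule_id, predicted_class, score_<class>…) rather than being
re-implemented.

## Synthetic data

The generator emulates labelled fingerprint datasets with controllable
class structure.  Each of k classes owns `signature_size` reserved bit
positions; a molecule of class c sets its own signature bits with probability
`p_signature`, other classes' signature bits with `p_cross`, and every
remaining position with `p_background`.  Raising `p_signature` (or lowering
`p_background`) makes classes more homogeneous — higher within-class mean
pairwise Tanimoto similarity — and more separable; setting all three
probabilities equal makes bits exchangeable, erasing class structure.
Defaults are 10 classes of 1024 bits with per-class counts
(21, 16, 113, 11, 135, 11, 105, 13, 39, 46), mirroring the class-size profile
of a typical homogeneous ligand benchmark at one-tenth scale; the separable
benchmark used in the acceptance tests is 10 equal classes of 100 molecules,
signature 32, p_signature 0.9, p_background 0.02, p_cross 0.05 — sized so the
full 3-branch fusion run completes in minutes on one CPU.  Multi-branch
"views" share labels and class structure but draw independent bit
realisations from seeds spawned off the master seed, emulating different
fingerprint families of the same molecules.

What the generator does *not* emulate: real substructure correlation between
bits (bits are independent given the class), count-valued fingerprints,
fingerprint-to-fingerprint dependence beyond shared labels, and class overlap
driven by shared chemistry.  Passing the synthetic recovery tests therefore
demonstrates that the pipeline learns class-discriminative bit patterns and
that its metrics are computed correctly — not that any particular accuracy
will be reached on a licensed screening benchmark.  A small SMILES fixture
(substituted ring scaffolds) exercises the RDKit fingerprint path end-to-end
with real molecular graphs.

## Diversity analysis

Class homogeneity is summarised by MPS: the mean Tanimoto similarity
c/(α+β−c) over all m(m−1)/2 unordered within-class pairs (computed by bit
algebra, exact by default; classes above 10,000 molecules are subsampled with
a seeded generator).  Classes split at a cut-off, default 0.200, into
low-diversity (MPS ≥ cut-off; structurally homogeneous) and high-diversity
groups; exact-boundary values go to the homogeneous group.  Tanimoto of two
all-zero vectors is defined as 0.  ECFP4 is the default fingerprint for MPS
reports, and the per-class table exports as tidy CSV for box-plot style
comparison.

## Numerical notes and limitations

- Degenerate inputs are rejected early with typed errors: one-class or
  <2-per-class training sets, mismatched branch lengths, infeasible signature
  allocations, cut-offs outside (0, 1).
- A non-finite training loss raises immediately with the epoch index.
- Softmax is computed with max-subtraction; probability rows sum to 1 within
  1e−6 in float32.
- The 26 fusion cases are enumerated size-major then lexicographically by
  column position over (CDK, ECFP4, EPFP4, Graph, ECFC4); the frozen
  check-mark table is asserted against the enumeration at call time.
- The CNN engine is single-process numpy: adequate for the matrix sizes here
  (≤ 32×32), not a general deep-learning framework — no GPU, no
  data augmentation, no dropout/batch-norm.
- Determinism is bit-exact for a fixed platform/BLAS; across BLAS builds,
  float32 reductions may differ in the last ulp.
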