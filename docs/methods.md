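# Methods

## The classification problem

Each residue of a protein is an instance with a binary label: does it
contact GTP?  The positive class is rare (roughly 1 binding residue
per 29 non-binding in curated GTP-binding transport proteins), and
binding residues are not scattered — they sit in short contiguous,
evolutionarily conserved stretches (P-loop, switch I/II, guanine
recognition boxes).  Both properties shape everything below: metrics
must be imbalance-aware, cross-validation must respect protein
boundaries, and the synthetic data must reproduce the clustering and
conservation or it tests nothing real.

## Feature encoding

A residue is described by a window of `w` consecutive residues centred
on it (`w` odd, default 19).  For the profile encoding, each window
position contributes its 20 PSSM log-odds integers mapped through the
logistic function `F(x) = 1/(1+exp(-x))`, so features live in (0, 1)
and a log-odds score of 0 maps to 0.5.  Window positions beyond the
termini contribute exact-zero blocks: zero is outside the open
interval attained by real positions, so "beyond the terminus" is
machine-distinguishable from "neutral score".  With `w = 19` the
vector has 380 entries.

Substitution encodings (BINARY one-hot, BLOSUM62, PAM250) replace the
PSSM rows with table lookups.  BLOSUM62/PAM250 rows pass through the
same logistic map; raw integer substitution scores would otherwise
dominate Euclidean distances in the kernel.  Whether the original
method scaled these encodings is unknowable from its description; we
scale for range consistency and say so here rather than pretend the
choice is forced.  Ambiguity codes (X, B, Z, U, O) map to zero blocks
in substitution encodings; in the profile encoding they are covered by
their own PSSM row.

Every residue becomes an instance — terminal residues included — so
the number of windows always equals the number of residues.

## Significant amino-acid pairs

"Pair" means an ordered adjacent dipeptide inside the window, presence
coded (a pair occurring twice in one window counts once).  Pairs
touching padding or an ambiguity code are ignored.  For pair *k* with
presence counts (`n` windows overall, `x` among the `M` positive
windows of `N` total) the score is the upper-tail hypergeometric
probability `P(X >= x)` — over-representation in the positive class.
The point-mass form of the ratio of binomial coefficients underlying
this test is turned into a tail because a p-value needs one; the upper
tail is the only direction compatible with selecting pairs that appear
*more* frequently around binding sites.  Pairs with p below
`alpha = 0.030212` are kept, sorted ascending by p-value with
lexicographic tie-breaks, capped at `max_k = 160`, and appended to the
feature vector as binary presence features (380 + 160 = 540 with the
default window).  The selection is deterministic, and during
cross-validation it is refit inside every training fold — selecting
pairs on pooled data would leak label information into held-out folds.

## The radial basis function network

The classifier places one Gaussian kernel
`exp(-||x - mu||^2 / (2 sigma^2))` on every training instance (centres
equal the training data) with a shared bandwidth `sigma = 5`, and two
linear output nodes, one per class.  The kernel form itself is the
standard Gaussian choice implied by "bandwidth" language.  Output
weights solve the ridge least-squares problem against one-hot targets
in closed form (`ridge = 1e-8` for numerical safety); with distinct
centres and vanishing ridge the network interpolates its training
targets exactly, because the Gaussian Gram matrix of distinct points
is positive definite.  There is no random initialisation, no sampling,
and no bias node: fitting the same data twice gives bit-identical
weights.

The decision rule is argmax of the two output nodes, expressed as a
threshold of 0 on `g_pos - g_neg` and exposed as a parameter: on
heavily imbalanced data the threshold is the honest knob for trading
sensitivity against specificity, and no resampling of either class is
performed.  Gram and scoring matrices are computed in row blocks of
2048 so peak additional memory is one block times the number of
centres; the closed-form solve (Cholesky of the regularised normal
equations) is the cubic-cost step that sets the practical problem
size — roughly 10^4 training residues on a single CPU.

## Evaluation

Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, accuracy
`(TP+TN)/total` (all percent) and the Matthews correlation coefficient
`(TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`.  A metric whose
denominator is zero is reported as undefined (`None`), never as 0, so
averages are not silently inflated.  Display rounding is one decimal
for percentages and two for MCC; full precision is kept internally and
in JSON reports.  ROC curves sweep the decision threshold over all
distinct scores (with the (0,0) and (1,1) endpoints) and AUC is the
trapezoidal area, which equals the pairwise rank statistic
`P(score_pos > score_neg) + ½·P(tie)`; the test suite checks both
identities against brute-force oracles.

Cross-validation assigns whole proteins to folds: adjacent windows
share up to `w − 1` residues, so residue-level folds would place
near-duplicates of training windows in the test set.  Proteins are
shuffled with the given seed, stably sorted by positive-residue count
(descending) and dealt round-robin, which balances positives across
folds; every fold must contain at least one positive-bearing protein.
Confusion counts are pooled across held-out folds.

## Synthetic data

The generator emulates what the method assumes about real data:

- background residues drawn from natural amino-acid frequencies;
- a small per-dataset library of consensus motif segments (lengths
  8/6/5/4) with composition up-weighted in G, K, S and D and one
  implanted adjacent pair (GK by default) per consensus — the analogue
  of P-loop-like nucleotide-binding motifs shared across a protein
  family;
- per-protein binding segments copied from the consensus with point
  substitutions at `mutation_rate = 0.1`, placed with at least 8
  background residues between segments; all segment residues are
  labelled binding;
- pseudo-PSSM profiles: background positions get rounded Gaussian
  noise (`noise_sd = 1`) around −1 with the emitted residue's own
  column at +3; motif positions are fully conserved — the consensus
  residue's column at `3 + pssm_signal` (default signal 5, i.e. ~8
  log-odds, the magnitude real conserved P-loop positions reach) and
  every other column at −3.

The default configuration is the study-scale class structure: 22
proteins of 420–560 residues with 12–21 binding residues each (~360
positives vs ~10 400 negatives, a 1:29 ratio).  `reduced(factor)`
divides lengths and site counts by `factor` (default 3) while
preserving the ratio; `null()` removes every signal source (motif =
background, full redraw of segments, no enriched pair, no profile
boost) while keeping the labels, for chance-level controls.

What the generator does **not** emulate: true evolutionary profiles
(PSI-BLAST pseudo-counts, position-specific gap structure), sequence
redundancy between proteins, UniProt annotation noise, or binding
sites without sequence-level conservation.  Passing the recovery tests
therefore shows the pipeline can exploit conservation and composition
signal of realistic strength at realistic imbalance — not that it
reaches any particular accuracy on real proteomes.

## Problem sizes and stochastic checks

Tests and the acceptance script run the full pipeline on the reduced
(factor 3) configuration — about 3 600 residues, 22 proteins — where a
5-fold cross-validation completes in seconds; generation-only checks
(class ratio, determinism, serialisation round-trips) use the full
default scale.  Because synthetic positives arrive in a handful of
correlated segments per fold, the AUC of a single no-signal dataset is
a noisy quantity; the chance-level control therefore averages the
pooled AUC over four replicate null datasets with consecutive seeds,
which is the stable estimator of the pipeline's null behaviour at this
scale.

## Known limitations

- Exact interpolation stores every training vector in the model
  archive; prediction cost grows linearly and fitting cost cubically
  with training size.  Beyond ~2·10^4 residues a sparse-centre variant
  would be needed.
- The hypergeometric selection tests each pair marginally; correlated
  pairs (overlapping dipeptides of one motif) are selected together,
  and no multiple-testing correction is applied — the threshold is
  part of the published operating point, not an inference claim.
- The default decision threshold of 0 favours specificity under class
  imbalance; applications needing higher recall should tune the
  threshold on training folds.
- PSSM provenance (search program, database, iterations) is the
  user's responsibility; profiles of different provenance shift the
  feature distribution and the appropriate bandwidth.
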