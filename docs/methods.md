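# Methods

`thermoprot` classifies protein sequences as thermophilic (positive) or
non-thermophilic (negative) from sequence-derived descriptors alone.  The
pipeline has four stages: sequence screening, descriptor encoding, ensemble
feature selection, and RBF-SVM classification evaluated by cross-validated
sensitivity/specificity/accuracy.  This note documents the model choices,
defaults, numerical details and limitations.

## Sequence screening

Only the 20 canonical residues are accepted.  Any ambiguity code (B, J, O,
U, X, Z), stop (`*`) or gap character rejects a sequence; lowercase input is
uppercased first, since case is a file artifact rather than a biological
signal.  Selenocysteine (U) records are rejected rather than recoded: the
descriptors have no column for a 21st residue, and recoding U→C would
silently alter cysteine-dependent features.  Database-level screening rules
(manual-annotation status, fragment flags, inferred-by-homology evidence)
concern UniProt metadata, cannot be checked from the residue string, and are
documented but not enforced.  Redundancy removal (CD-HIT-style clustering)
is dataset construction, not part of the method, and is out of scope.

## Descriptor encodings

All k-mer counts use overlapping windows, so a length-`n` sequence has
`n-1` dipeptides and `n-2` tripeptides; composition-type encoders therefore
sum exactly to 1 (per block where noted).  Dimensions and definitions are
tabulated in the `encoders` module docstring.  Non-obvious choices:

* **DDE** standardizes each observed dipeptide frequency against a
  codon-usage expectation `T_m(x,y) = (C_x/61)(C_y/61)` where `C_x` is the
  number of sense codons encoding residue `x` in the standard genetic code
  (61 codons after excluding the three stops), with theoretical variance
  `T_v = T_m(1-T_m)/(n-1)`.  Since `0 < T_m < 1`, `T_v` is strictly
  positive and the statistic is always finite.
* **CTD** uses the Tomii–Kanehisa amino-acid-index clustering as
  conventionally packaged by protein descriptor toolkits: 13 attributes
  (seven hydrophobicity normalizations, normalized van der Waals volume,
  polarity, polarizability, charge, secondary structure, solvent
  accessibility), each partitioning the 20 residues into three groups —
  39 composition and 39 transition features.  The partitions ship in
  `tables.py` and are validated as exact partitions at import.
* **Grouped encoders** (GDPC, GTPC, CKSAAGP) use the standard five-group
  alphabet: aliphatic {G,A,V,L,M,I}, aromatic {F,Y,W}, positively charged
  {K,R,H}, negatively charged {D,E}, uncharged {S,T,C,P,N,Q}.
* **CKSAAGP** is the grouped variant of k-spaced pair composition with gaps
  0..5: 25 group pairs × 6 gaps = 150 features, each gap block normalized
  by its own `n-k-1` window count.  The ungrouped variant (400 pairs per
  gap) is intentionally not provided; at 150 dimensions the grouped form is
  the one consistent with the rest of the descriptor family.
* **CTriad** uses the seven-class electrostatics/volume partition
  ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}) and
  reports plain triad frequencies `count/(n-2)` rather than a min-max
  normalized variant, keeping the encoder directly checkable against naive
  window counting.
* **TPC emits all 8,000 columns.**  No silent dropping of zero-variance
  columns; dimensionality reduction is the selector's job.

Feature names follow `ENCODER:token` (e.g. `AAC:K`, `DPC:LK`), making
individual biological features stably addressable across the pipeline.

## Feature selection

Seven per-feature rankings are computed: one-way ANOVA F; mutual
information after deterministic equal-width binning (10 bins); greedy mRMR
(F-test relevance minus mean absolute Pearson correlation to the already
selected set); |coefficient| of an L1-regularized logistic model on
standardized features at fixed C = 1; point-biserial correlation magnitude;
chi-squared on quartile-binned features; and ReliefF (k = 5 neighbours,
range-normalized differences, every instance used as anchor — written here
because no installed library provides it).  All are deterministic given the
data; ties break by canonical column order, and constant columns score 0
under every method and sink to the tail.  A feature with zero within-class
variance yields an infinite ANOVA F; it is kept as a large finite score
(1e300) so that perfect separators rank first while scores stay finite.

The rankings are fused by PageRank on an endorsement graph.  Each ranking
contributes a unit-weight directed edge from every feature to **every**
feature ranked above it, so the edge weight from a to b counts the rankings
that prefer b — the Markov-chain rank-aggregation construction.  An earlier
design linking each feature only to its immediate predecessor was tested
and rejected: with adjacent-only edges the consensus at the top washes out
as soon as the lists disagree further down, and a feature ranked first by
all seven methods was fused first in barely 60% of replicates.  With
all-pairs endorsement the planted signal is recovered in 50/50 replicates.
Damping is 0.85, convergence tolerance 1e-10, dangling mass redistributed
uniformly; the stationary weights form a probability distribution.

The accuracy-optimal prefix of the fused order is found by forward adding:
prefix sizes 1, 2, … up to 200 features, then every 5, always including the
full set; ties break toward fewer features.  The internal evaluator is the
classify module's stratified 5-fold CV accuracy with a fixed-seed RBF SVM
at C = 1 and variance-scaled gamma (`1/(p·Var)`); five folds keep the
selection loop fast while the final reported metrics use ten.

## Classification and evaluation

Features are affinely scaled to [-1, 1] with parameters fitted on the
training partition only; constant features map to 0.  (C, gamma) are chosen
by exhaustive search over the classic LIBSVM grid — C in 2^-5..2^15, gamma
in 2^-15..2^3, step 2^2 — maximizing stratified k-fold CV accuracy, ties
toward smaller C then smaller gamma; the final model is refit on all data.
The default fold count is k = 10 (stratified, seeded); jackknife is
available by setting k to the sample size.

Metrics pool confusion counts over folds (micro-averaging), so a single
SE/SP/ACC triple describes the whole CV pass:

    SE = TP/(TP+FN),  SP = TN/(TN+FP),  ACC = (TP+TN)/(TP+FN+TN+FP)

SE (SP) is reported as NaN with a warning when no positives (negatives)
were evaluated.  Class imbalance is not reweighted by default; class
weighting is available through the underlying SVC if needed.

## Synthetic data

The generator emulates the dominant compositional difference between
thermophilic and non-thermophilic proteomes: the positive class draws
residues with lysine frequency 0.08 and aspartate 0.060, the negative class
with lysine 0.03 and aspartate 0.045, remaining mass uniform over the other
residues (overridable).  A first-order Markov tilt doubles the L→K
transition probability in the positive class (row renormalized), planting a
leucine–lysine dipeptide signal beyond what the marginal frequencies imply.
Lengths are uniform on 50–600 by default, typical of globular proteins.

Because residues are otherwise i.i.d., the synthetic classes are far easier
to separate than real proteomes: real thermophily involves correlated
composition shifts, domain structure and phylogenetic autocorrelation that
the generator deliberately omits.  Passing tests therefore demonstrate that
the pipeline recovers a planted compositional signal correctly and
calibrates to chance on label-permuted data — not that any particular
accuracy would transfer to real UniProt-derived datasets.

## Problem sizes and determinism

Default experiment sizes: end-to-end runs use 200 sequences per class with
AAC+DPC (420 features); ranking-recovery uses 50 replicates of 100 per
class; null calibration uses 400 sequences with permuted labels.  All
randomness (generation, fold shuffling, permutation) flows through explicit
integer seeds; repeated runs are bit-identical.

## Known limitations

* The seven ranking methods are a documented, configurable convention;
  other ensembles (or the exact output of any particular external
  selection tool) will order mid-ranked features differently.
* Grid search cost grows linearly in grid size × folds; for very
  high-dimensional inputs (TPC) selection should precede the grid.
* The SVM decision value is not calibrated to a probability.
* Only binary classification is supported; multi-class thermostability
  regression is out of scope.
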