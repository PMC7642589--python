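# thermoprot

Discriminating thermophilic from non-thermophilic proteins from sequence
alone.  Proteins of thermophilic organisms (optimum growth ≥ 60 °C) differ
from mesophilic ones in composition — most visibly in charged residues such
as lysine and aspartate — and that signal is strong enough to classify a
protein from its sequence.  `thermoprot` implements the full pipeline for
researchers working on protein thermostability and protein engineering:

1. **Sequence screening** — FASTA I/O with strict canonical-alphabet
   validation (ambiguity codes, stops and gaps are rejected).
2. **Descriptor encoding** — ten classic sequence encodings as named
   feature vectors: AAC (20), DPC (400), TPC (8000), DDE (400), GDPC (25),
   GTPC (125), CKSAAGP (150), CTDC (39), CTDT (39), CTriad (343).
   For a sequence of length *n*, e.g. AAC is `f(i) = n(i)/n` and DPC is
   `f(x,y) = n_xy/(n-1)`; DDE standardizes dipeptide frequencies against
   their codon-usage expectation `T_m = (C_x/61)(C_y/61)` with variance
   `T_v = T_m(1-T_m)/(n-1)`.
3. **Feature selection** — seven relevance rankings (ANOVA F, binned
   mutual information, mRMR, L1-logistic weights, point-biserial
   correlation, chi-squared, ReliefF) fused by PageRank on an endorsement
   graph, then forward adding to find the accuracy-optimal prefix.
4. **Classification** — RBF-SVM with exhaustive (C, γ) grid search over
   the classic log₂ grid, [-1, 1] feature scaling fitted per training
   fold, and pooled k-fold CV metrics
   `SE = TP/(TP+FN)`, `SP = TN/(TN+FP)`, `ACC = (TP+TN)/total`.

A synthetic-data generator produces two-class datasets with
class-conditional residue profiles (lysine 0.08 vs 0.03 by default, plus an
LK-dipeptide tilt), so the whole pipeline is testable without downloads.

The core stages are scikit-learn estimators (`ProteinFeatureEncoder`,
`EnsembleRankSelector`, `GridRbfSvm`) and compose with sklearn pipelines;
plain functions (`encode_dataset`, `select_features`, `grid_search`,
`cross_validate`, …) wrap them.

## Worked example

```python
from thermoprot import (
    default_profiles, generate, encode_dataset,
    select_features, SelectionConfig, grid_search, cross_validate,
)

pos, neg = default_profiles()                  # K: 0.08 vs 0.03, LK tilt
data = generate(pos, neg, 200, 200, seed=1)    # 400 labeled sequences
matrix = encode_dataset(data, ["AAC", "DPC"])  # 400 x 420 named features

sel = select_features(matrix, SelectionConfig(seed=1))
print(sel.fused_ranking.features[:3], sel.best_size)

subset = matrix.select(sel.selected_features)
params, _ = grid_search(subset, folds=10, seed=1)
report = cross_validate(subset, params, k=10, seed=1)
print(f"C={params.C} g={params.g}")
print(f"SE {100*report.SE:.2f}%  SP {100*report.SP:.2f}%  ACC {100*report.ACC:.2f}%")
```

prints

```
['AAC:K', 'DPC:KK', 'DPC:LK'] 1
C=0.5 g=8.0
SE 98.00%  SP 94.50%  ACC 96.25%
```

The fused ranking puts the lysine composition `AAC:K` first — the planted
signal — and forward adding finds that this single feature already attains
the maximum CV accuracy on this synthetic dataset (`best_size = 1`).  The
final 10-fold cross-validation reaches 96.25% accuracy with sensitivity
98.00% and specificity 94.50%.

The same workflow is available from the shell:

```bash
thermoprot synth --n-pos 200 --n-neg 200 --seed 1 -o data/
thermoprot encode data/positive.fasta data/negative.fasta --encoders aac,dpc -o matrix.csv
thermoprot select matrix.csv --top 3 -o selection.json
thermoprot cv matrix.csv --features selection.json --k 10 -o report.json
```

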