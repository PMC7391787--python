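# Methods

## Problem and pipeline

`aovote` classifies protein sequences as antioxidant (+1) or
non-antioxidant (−1).  The pipeline has five stages:

1. **Dataset assembly** — FASTA input (one file per class, or a mixed FASTA
   with a two-column id/label TSV), validated against the 20-letter
   amino-acid alphabet, then a stratified 80/20 train/test split.
2. **Encoding** — 15 feature representations per sequence: g-gap dipeptide
   compositions for g = 0..9 and reduced amino-acid n-peptide compositions
   for the five cluster profiles.
3. **Per-encoding base models** — an RBF-SVM per encoding, with grid-searched
   hyperparameters; g-gap models also undergo ANOVA-F + incremental feature
   selection (IFS).
4. **Sensitivity filter** — base models with test-split sensitivity below a
   threshold (default 0.20) are removed.
5. **Vote stacking** — sequences are re-encoded as the ordered ±1 predictions
   of the retained models; a final RBF-SVM over these vote vectors is the
   deployed classifier.

## Encodings

*g-gap dipeptide composition.*  For gap g, entry (a, b) of the 400-vector is
the number of positions p with seq[p] = a and seq[p+g+1] = b, divided by
L − g − 1.  Feature order is lexicographic over ordered pairs and recorded
in the feature names (`A.C|g=2`); any fixed order would do, but it must be
stable between training and prediction.  Sequences with L ≤ g + 1 are
rejected with the record named — the encoders never zero-fill.

*Reduced amino-acid composition.*  The cluster profiles partition the 20
amino acids into 5, 8, 9, 11 and 13 physicochemical groups:

| profile | groups | default n | dimension |
|---------|--------|-----------|-----------|
| Op5  | G; IVFYW; ALMEQRK; P; NDHSTC | 3 | 125 |
| Op8  | G; IV; FYW; ALM; EQRK; P; ND; HSTC | 2 | 64 |
| Op9  | G; IV; FYW; ALM; EQRK; P; ND; HS; TC | 2 | 81 |
| Op11 | G; IV; FYW; A; LM; EQRK; P; ND; HS; T; C | 2 | 121 |
| Op13 | G; IV; FYW; A; L; M; E; QRK; P; ND; HS; T; C | 2 | 169 |

Each residue is replaced by its group's first letter (an internal labeling —
any bijection is equivalent), and the kⁿ overlapping n-mer counts over the
reduced alphabet are divided by L − n + 1.  This normalizer is chosen to
mirror the g-gap convention and makes every emitted vector sum to one.  The
default peptide orders are overridable per call (`raac_composition(..., n=2)`
gives the 25-dimensional Op5 dipeptide space).

## Feature selection

The per-feature score is the one-way two-group ANOVA F = MSB/MSW
(K = 2 groups, so F equals the squared pooled-variance two-sample t).
Degenerate conventions: an everywhere-constant feature scores 0; a feature
constant within each class but differing between classes scores +∞ and ranks
above all finite values.  Ties break by descending F, then lexicographic
feature name.

IFS evaluates the top-k subsets for k = 1..D with stratified 5-fold
cross-validated accuracy (seeded) and keeps the smallest k at the peak.
Jackknife evaluation inside IFS is available but quadratic-cost; k-fold is
the default evaluator.  The SVM grid search runs once per encoding on the
full feature set and the chosen (C, γ) is reused along the curve; a nested
re-search at every k is available (`ifs_nested_grid`) at proportional cost.
`ifs_max_k` truncates the curve to the highest-ranked features for
desk-scale runs.

## Classifiers and evaluation

SVMs are scikit-learn `SVC` (LIBSVM) with the RBF kernel.  The default grid
is C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}; ties resolve to the
highest accuracy, then smallest C, then smallest γ.  Compositional features
already lie in [0, 1], so no further scaling is applied.  Class weighting is
off by default (imbalanced data then yields the characteristic low-Sn /
high-Sp profile); inverse-frequency weighting is available via
`class_weight="balanced"`.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N and
MCC = (TP·TN − FP·FN)/√((TP+FP)(FN+TN)(TP+FN)(TN+FP)).  When a denominator
vanishes the affected metric is reported as 0 and flagged rather than
raised.  Evaluators: held-out test split, stratified k-fold, and the
jackknife (leave-one-out), which yields exactly N out-of-sample predictions.

## Stacking policy

How vote vectors for final-classifier *training* are produced is a genuine
design choice:

* `out_of_fold` (default): for each base model, clones with the same
  hyperparameters and feature subset are re-fitted on 4/5 of the training
  split and predict the held-out fold, so no training vote is produced by a
  model that saw that sequence.  The frozen base models themselves are never
  retrained.
* `resubstitution`: the frozen base models predict their own training data.
  This is the literal construction of re-using model outputs as features and
  is kept as a fidelity mode, but it lets the final SVM learn from
  optimistically biased votes.

Retained-model order is the construction order (g ascending, then profiles
ascending) and is persisted with the ensemble, since the final classifier is
order-sensitive.  Prediction is batch-tolerant by default: a sequence too
short for some base encoder yields `None` with a warning instead of aborting
the batch.

## Synthetic data

The generator emulates the shape of curated antioxidant benchmarks (two
classes, lengths spanning tens to hundreds of residues, class imbalance
configurable) without modelling real antioxidant biology.  Negatives are
i.i.d. residues from a background table (uniform 1/20 by default; a natural
abundance table is available).  Positives plant a first-order dependence in
one feature channel: for a g-gap channel, whenever the residue at lag g+1
behind the current position equals a target pair's first letter, the target's
second letter has its emission probability multiplied by exp(effect) and the
distribution renormalized; for a RAAC channel the boost applies to all
residues of the target n-mer's final group when the reduced prefix matches.
`effect = 0` gives exp(0) = 1, so both classes follow the identical process
— the null case.  The exponential parameterization was chosen so that
`effect` acts on a log scale: effect 2 (factor ≈ 7.4) gives planted g-gap
pairs that dominate the F ranking and a near-separable signal channel at
100+100 sequences.

What passing tests on this generator do **not** show: robustness to real
protein composition biases, homology structure between sequences (the
benchmark's 60% identity filter is upstream of this tool), or the true
complementarity structure of real antioxidant features.  Conclusions about
real data require real data.

## Numerical and procedural conventions

* Labels are {+1, −1} everywhere, matching the vote-vector alphabet.
* Splits, folds and grid searches are seeded; identical config + seed gives
  bit-identical outputs end-to-end.
* Stratified splitting keeps per-class train fractions within one record of
  the requested fraction.
* Non-standard residues (B, J, O, U, X, Z, gaps, `*`): dropped with a logged
  warning by default, rejected under `strict`.
* Degenerate F (0/0) → 0; (x/0, x > 0) → +∞; MCC with a zero denominator
  factor → 0, flagged.
* IFS curve ties resolve to the smallest k (parsimony).

## Measurement caveats on small synthetic studies

Two effects observed while validating the pipeline are worth knowing:

* **Selection bias in in-sample votes.**  IFS performed on the full training
  split selects features using the training labels; vote vectors computed on
  that same split therefore carry class information even under the null
  (jackknife accuracy ≈ 0.95 on pure-noise data with IFS on).  Null
  calibration is accordingly measured with per-model selection disabled,
  where the out-of-fold vote matrix jackknifes to chance level.  Held-out
  test metrics are unaffected.
* **Granularity.**  With a 40-sample test split, accuracy moves in steps of
  0.025, so stacked-vs-single comparisons are made on means over several
  simulation seeds rather than per-seed.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at
desk scale: 50–200 sequences per study, lengths 30–500, a 5×5 (C, γ) grid
and IFS truncated at 25 features.  These are the package's default study
sizes for simulation work; all knobs scale up through `RunConfig`.

## Known limitations

* The sensitivity filter can legitimately remove every base model (e.g. on
  null data with no class weighting); this raises an error rather than
  producing an empty ensemble.
* Only the ±1 vote alphabet is supported for stacking — no decision values
  or probabilities, and no majority-vote or weighted-average combiners.
* Only the five built-in cluster profiles (plus user-supplied partition
  files) are provided; other reduction schemes are out of scope.
* Grid search optimizes accuracy only; on heavily imbalanced data consider
  `class_weight="balanced"`.
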