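# Methods

## Problem and pipeline

`mhcvote` treats MHC identification as binary sequence classification over
the 20-letter amino-acid alphabet. The pipeline is: sanitize and load
sequences → encode each into a mixed descriptor vector → fit three base
classifiers on the (standardized) feature matrix → predict by hard 2-of-3
majority vote → report SE/SP/ACC/MCC from confusion counts, under
stratified k-fold cross-validation or a train/test hold-out.

## Descriptors

**188D.** 20 amino-acid frequencies, then for each of eight three-class
physicochemical partitions: composition (3 class fractions), transition
(adjacent pairs crossing each unordered class pair, divided by L−1; 0 when
L = 1), and distribution (for each class, the 1-based positions of its
first, 25%, 50%, 75% and 100% occurrences as percent of L). The quantile
occurrence index is `max(1, ceil(q·n))` over the n occurrences; an absent
class contributes five zeros. This is the only layout consistent with both
"21 values per property" and a 188 total. The eight partitions and the
surface-tension grouping follow the standard CTD tables of the descriptor
literature and ship as plain-text package data
(`src/mhcvote/data/property_tables.txt`), not code.

**APAAC / PAAC.** Chou's amphiphilic and type-1 pseudo amino-acid
compositions. Scales (hydrophobicity, hydrophilicity, side-chain mass) are
standardized to mean 0 / unit population SD over the 20 residues at load
time. APAAC correlation factors are lag-j products of the two standardized
hydropathy scales; PAAC factors average the squared differences of all
three scales. Both vectors are normalized by `sum(f) + w·sum(factors)` so
they sum to 1. Defaults λ = 30, w = 0.05 (the canonical choices; exposed in
`EncoderConfig`). Sequences with L ≤ λ are rejected with the minimum length
in the message — never zero-padded, because the lag-λ correlation is
undefined. The APAAC normalizer can in principle be non-positive for
adversarial sequences (τ factors may be negative); this is detected and
raised rather than silently producing an invalid vector.

**KSCTriad.** Residues map to the standard 7-class conjoint-triad partition
({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}); for each
k in 0..k_max the 343 class-triple counts over windows
(i, i+k+1, i+2(k+1)) are normalized per block as `(c − min)/max` (the
conjoint-triad convention); division by window count is selectable
(`normalize="window"`). An all-zero block stays zero. Default k_max = 0.

**CKSAAGP / CKSAAP.** Ordered group-pair (5×5) or residue-pair (20×20)
counts at spacing k, divided by the L−k−1 windows, so each k-block is a
probability distribution. Default k_max = 5. CKSAAGP's five side-chain
groups are aliphatic {G,A,V,L,M,I}, aromatic {F,Y,W}, positive {K,R,H},
negative {D,E}, uncharged {S,T,C,P,N,Q}. CKSAAP is provided as the base
method but is not part of the default mixed feature.

Feature names follow the stable `block.subblock.item` schema; column order
is part of the trained-model contract and persists with saved models. No
scaling or selection happens inside the encoders.

## Classifier

Three base learners (scikit-learn): `SGDClassifier` (hinge loss,
alpha = 1e-4), `SVC` (linear kernel, C = 1; libsvm's SMO-type solver) and
`RandomForestClassifier` (100 trees). Hyperparameters are deliberately the
common defaults — the method's contribution is the feature mixture and the
vote, not tuning — and all are overridable per `BaseLearnerSpec`. Feature
standardization (zero mean/unit variance, fitted on training folds only) is
on by default because two of the three members are scale-sensitive;
applying it uniformly keeps the vote well-defined. Votes are hard 0/1; with
three binary voters no tie exists. Soft voting is intentionally absent from
the default path. A master seed fans out to per-member seeds via
`numpy.random.SeedSequence(master).generate_state(3)` (mod 2³¹), in the
fixed member order.

## Evaluation

SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Zero denominators:
SE/SP become NaN with an explanatory flag; MCC becomes 0 with a flag —
never a silent NaN. Cross-validation uses seeded stratified folds (classes
here are near-balanced, making stratification the safe default even though
plain random splitting would also be defensible); the primary report pools
per-fold confusion counts (pooling keeps MCC well-defined at small fold
sizes), with per-fold reports retained. The hold-out protocol fits once on
the training set — including its standardizer — and refuses overlapping IDs
unless an explicit leakage override is given.

## Synthetic data

The generator emulates the two-class structure of a curated MHC/non-MHC
benchmark at desk scale: lengths uniform in (80, 200) residues, negatives
i.i.d. from a baseline distribution (uniform by default; a SwissProt-like
background is available), positives from the mixture
`(1−delta)·baseline + delta·biased` with the biased distribution fixed as
uniform over {A,C,D,E,F,G,H,I,K,L}. `delta` therefore dials separation
continuously: 0 gives statistically identical classes, 0.8 gives
near-perfect separability through composition alone. An optional motif is
written into positives by replacement, keeping lengths fixed.

What this does **not** emulate: real MHC domain architecture, homology and
family structure, length/composition confounds, or redundancy between
train and test. Passing the end-to-end tests shows the pipeline is
internally correct and sensitive to distributional separation — not that
real-data accuracies are reproduced. Reproducing published benchmark
numbers requires the external curated dataset (supported as an ordinary
two-FASTA workflow) and is additionally sensitive to unpublished λ, w,
k_max and learner hyperparameters.

## Numerical and design choices

- Sanitization: uppercase, then drop nonstandard characters with a warning
  (policy `drop`), or error (`reject`). Descriptors are only defined over
  the 20-letter alphabet. Sanitization is idempotent.
- Positive class = 1 (MHC), negative = 0, everywhere.
- Training requires both classes present; the minimal viable CV (2 folds on
  a 4-sequence balanced set) is allowed to run with one example per class
  in a training fold.
- Problem sizes in the test suite (100+100 sequences, 10 folds; oracle
  checks on 20 sequences of length ≤ 30) were chosen as the smallest sizes
  at which the statistical bands are stable.
- Model files embed the package version and refuse to load across
  versions; predictions are bit-reproducible for fixed seeds and inputs.

## Known limitations

- Accuracy bands for the null case (ACC ∈ [0.40, 0.60] at n = 200) are
  stochastic statements at fixed seeds, not distribution-free guarantees.
- The WEKA SMO/SGD implementations the method was originally described
  with differ in regularization details from the scikit-learn equivalents
  used here; only the model class (linear SVM, linear hinge SGD) is pinned.
- Min–max normalization of KSCTriad blocks makes those features
  scale-dependent on sequence length; this follows the field convention
  rather than a statistical optimum.
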