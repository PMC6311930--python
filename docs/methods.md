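# Methods

## Model and assumptions

`adrpair` casts drug-drug-ADR association prediction as one binary
classification task per ADR. The central assumption is pharmacological:
ADRs of combined medication arise from pharmacokinetic or pharmacodynamic
interaction, so a drug pair with little evidence of interaction is unlikely
to cause *any* ADR and can serve as a class-0 training sample. Evidence of
interaction is read off a drug–disease–gene tripartite network under three
premises: interacting drugs tend to share target genes, tend to be
associated with the same diseases, and their shared genes tend to be genes
of their shared diseases.

The interaction score of a candidate pair is the sum of three bounded
components (gene Jaccard; disease Jaccard damped by the shared-disease
fraction of the disease universe; the fraction of shared genes covered by
shared diseases' gene sets), giving a total in [0, 3]. All n(n−1)/2
canonical pairs are ranked ascending, deterministically (ties broken by
pair ID), and per-ADR negatives are the prefix of that ranking minus the
ADR's known positives.

All score ratios are cardinality ratios, and every 0/0 case (no genes, no
diseases, empty gene intersection, no shared disease) is defined as 0.
Zero is the conservative choice for this procedure: an absence of evidence
ranks a pair *low*, i.e. toward the negative pool, which is exactly how a
pair with no recorded associations should be treated. The numerator union
in the bridge component is deduplicated (a shared gene covered by several
shared diseases counts once).

Drug gene sets for scoring are the CTD-style drug→gene association sets,
which are distinct from the target-protein featurization namespace; the
two play different roles (network evidence vs. classifier input).

## Pipeline

1. Encode each drug as a sparse binary vector over the four feature
   namespaces (lexicographic column order, recorded in a manifest); a pair
   vector is the concatenation of the two drug vectors in canonical
   (lexicographic) pair order. Only the canonical orientation is used —
   one deterministic row per pair, identical at train and predict time.
2. For each ADR with at least `min_positives` known pairs: positives from
   the association triples, negatives from the ranked-list prefix at ratio
   `nsr`.
3. Stratified k-fold cross-validation; inside every training fold a PCA
   with `pcn` components is fit on the training pair vectors only and then
   applied to both folds, followed by the classifier. Stratification keeps
   both classes in every fold so AUC stays defined for small ADRs.
4. Out-of-fold predictions are pooled per ADR; precision, recall,
   accuracy, F1 (the classifier's native decision rule: sign of the margin
   for SVM/logistic regression, majority/probability > 0.5 otherwise) and
   AUC (from continuous scores) are macro-averaged across ADRs. An ADR
   whose pooled truth is single-class reports AUC as missing and is
   excluded from the macro AUC with a warning.
5. `fit()` finally retrains each ADR's reducer + classifier on all of its
   labelled pairs; these production models back `predict_adrs`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `nsr` | 1.0 | negatives per positive, per ADR; `round` half-to-even on fractional counts |
| `pcn` | 300 | PCA components; clamped per training fold to min(n_train, n_features) with a warning |
| `algo` | `svm` | one of svm / logreg / knn / rf, at scikit-learn defaults |
| `folds` | 5 | stratified CV folds |
| `min_positives` | 10 | ADRs below this are skipped with a warning |
| `exclude_all_positives` | False | if True, negative selection avoids every ADR's positives, not only the current ADR's |

`nsr = 1` and `pcn = 300` are the recommended full-scale operating point;
on the 40-drug synthetic fixture `pcn` is effectively capped by the
16-sample training folds, so examples use `pcn ≈ 8–10`. The one-class SVM
baseline uses the library's standard RBF kernel, `nu = 0.5` and
`gamma = 'scale'`; RGNS and the random/one-class baselines average over 5
reseeded repeats by default.

A single top-level seed is fanned out through `numpy.random.SeedSequence`
to fold splitting, negative drawing, and stochastic classifiers, so any
run is bitwise reproducible from its config.

## Synthetic data

The generator emulates the statistical premises above rather than real
marginal distributions. Drugs are grouped into per-ADR communities; every
community member carries the community's shared genes and diseases, each
shared disease's gene set contains the shared genes (so the bridge
component is 1 for within-community pairs), and all remaining genes,
diseases and baseline features are drawn from private, disjoint blocks.
Consequently, with `noise_rate = 0`, within-community ("planted") pairs
score strictly above an analytic lower bound (`expected_separation`) while
all other pairs score exactly 0 — the ascending ranking separates them
perfectly. `noise_rate` adds (never removes) random association edges and
feature bits, so planted guarantees survive noising while exact zeros do
not; `expected_separation` therefore refuses noisy configs.

Each ADR's positive pairs are a sample of its community's pairs, and every
community drug carries the ADR's signature feature bits (disjoint across
ADRs) at rate `signal_strength`. This is what makes credible negatives
matter: a uniformly random negative draw occasionally picks a
within-community pair whose two drugs both carry the full ADR signature —
a feature-space near-duplicate of a positive — while the screened
selection never does, because such pairs have positive interaction scores.
The default fixture (40 drugs, 3 communities of 12, 10 positives per ADR,
`signal_strength = 0.9`, `noise_rate = 0`) was sized so that confusable
pairs are a realistic fraction (~7%) of the random-negative pool at a
scale where the whole comparison suite runs in about a minute.

What passing on this fixture does **not** show: robustness to correlated
real-world features, to incomplete or biased association coverage, to
ADR-label noise in the source catalogue, or the absolute metric levels
reachable on full DrugBank/CTD/Twosides-scale data.

## Numerical and design choices

- Pair canonicalization is lexicographic on drug IDs; self-pairs are
  rejected. Feature columns sort lexicographically. Both choices exist
  only to make matrices reproducible.
- Scoring is vectorised (sparse membership-matrix products for the two
  Jaccard components; per-pair set work for the bridge component only
  where a pair shares both a gene and a disease). Tests cross-check it
  against an independent brute-force nested-loop implementation at 1e-12.
- Negative selection excludes only the current ADR's positives by default:
  the candidate ranking deliberately contains all pairs, including
  known-interacting ones, and a pair causing ADR *x* is a legitimate
  negative for ADR *y*. The stricter variant is one flag away.
- `select_negatives` raises a capacity error (with the shortfall) rather
  than silently under-filling.
- Grid search (`adrpair grid`) isolates cell failures: an infeasible
  (nsr, pcn) cell is marked in the output table and the grid continues.

## Known limitations

- Per-ADR cross-validation splits pairs, not drugs: a drug seen in
  training can appear in test pairs, so reported metrics measure pair
  generalisation, not cold-start generalisation to unseen drugs.
- The interaction score is purely set-overlap based; no edge weights,
  diffusion or random-walk smoothing, so drugs with sparse CTD coverage
  score 0 against everything and concentrate at the bottom of the ranking.
- `predict_adrs` scores are classifier margins/probabilities, comparable
  within one ADR model but not calibrated as occurrence probabilities.
- Drugs present only in the ADR triples get all-zero feature vectors (kept,
  with a warning); their pairs are trivially inseparable.
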