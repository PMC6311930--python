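# adrpair

Predicting adverse drug reactions (ADRs) of **pairwise combined
medication** from heterogeneous pharmacologic association data, with
highly-credible negative samples (HCNS) screened from a
drug–disease–gene tripartite network.

## The problem

Catalogues such as Twosides list known (drug, drug, ADR) triples — the
positive samples — but contain no verified *non*-associations, so a binary
classifier has nothing trustworthy to learn the class-0 boundary from.
Sampling negatives uniformly at random risks labelling truly interacting
pairs as negatives. `adrpair` instead scores every candidate drug pair by
how much evidence of interaction a drug–disease–gene network holds for it,
and takes the lowest-scoring pairs as credible negatives.

## The method

**Drug representation.** Each drug is a binary presence/absence vector over
four concatenated namespaces: chemical substructures, target proteins,
substituents and enriched pathways. At the full catalog sizes
(881 + 3255 + 1075 + 1983) this is a 7194-dimensional vector; a drug-pair
vector appends one drug's vector to the other's (14,388 dimensions).

**Interaction score.** From a tripartite network
*rdg* = (V_r ∪ V_d ∪ V_g, E) of drug, disease and gene associations, a pair
(R₁, R₂) with gene sets G₁, G₂ and disease sets D₁, D₂ gets

- inter_g = |G₁ ∩ G₂| / |G₁ ∪ G₂| — shared target genes (Jaccard),
- inter_d = (|D₁ ∩ D₂| / |D₁ ∪ D₂|) · (|D₁ ∩ D₂| / |V_d|) — shared
  therapeutic diseases, damped by their share of all diseases,
- inter_gd = |∪ₖ ((G₁ ∩ G₂) ∩ DGₖ)| / |G₁ ∩ G₂| — the fraction of shared
  genes that are genes of a shared disease DGₖ,

and inter_score = inter_g + inter_d + inter_gd ∈ [0, 3]. All candidate
pairs are ranked **ascending**; for each ADR, negatives are taken from the
prefix of that ranking (skipping the ADR's positives) at a configurable
negative-sample ratio (NSR).

**Prediction.** One binary classifier per ADR (SVM, logistic regression,
KNN or random forest at library defaults), after PCA reduction of the pair
vectors to PCN components; PCA and classifier are fit inside each training
fold of a stratified 5-fold cross-validation, and precision, recall,
accuracy, F1 and AUC are pooled per ADR then macro-averaged.

Baselines for comparison: randomly generated negative samples (RGNS),
random label assignment, and a one-class SVM trained on positives only and
tested against random or screened negatives.

## Worked example

The package ships a synthetic-data generator that plants interacting drug
communities (shared genes, shared diseases, shared genes covered by shared
diseases' gene sets) and per-ADR feature signatures, so the whole pipeline
runs without any database downloads:

```python
from adrpair import generate, GeneratorConfig, AdrPairModel

data = generate(GeneratorConfig(seed=7))          # 40 drugs, 3 ADRs
model = AdrPairModel.from_tables(
    data.feature_tables, data.drug_gene, data.drug_disease,
    data.disease_gene, data.ddaa, pcn=10, algo="svm", seed=7,
)
results = model.fit()
print(results.summary())
```

```
Pairwise-medication ADR prediction (credible negative sampling)
classifier=svm  nsr=1.0  pcn=10  folds=5  seed=7
   adr  precision  recall  accuracy    f1   auc
ADR000      1.000   0.900     0.950 0.947 1.000
ADR001      1.000   1.000     1.000 1.000 1.000
ADR002      1.000   1.000     1.000 1.000 1.000
 MACRO      1.000   0.967     0.983 0.982 1.000
```

Each row is one ADR's pooled 5-fold cross-validation result on its 10
known positive pairs plus 10 credible negatives (NSR = 1); `MACRO` is the
unweighted mean across ADRs. Ranking ADRs for a single pair:

```python
pair = sorted(data.truth.adr_positive_pairs["ADR001"])[0]
print(results.predict_adrs(*pair))
#       adr     score
# 0  ADR001  0.999421
# 1  ADR002  0.048244
# 2  ADR000 -0.152297
```

The pair planted as a positive for `ADR001` ranks that ADR first.

The same steps are available from the shell: `adrpair synth`,
`adrpair score-pairs`, `adrpair select-negatives`, `adrpair run`,
`adrpair compare`, `adrpair predict`, `adrpair grid` (see `--help`).

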