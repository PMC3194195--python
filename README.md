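# sap3d

Structure-aware prediction of disease-related single amino acid
polymorphisms (SAPs).

A missense variant replaces one residue of a protein with another; some such
substitutions are benign polymorphisms, others cause disease. `sap3d`
implements a supervised classifier for this question that combines protein
**sequence**, **three-dimensional structure** and **function** — and the
evaluation machinery needed to measure, without homology leakage, how much
the structural information actually buys over a sequence-only model.

## The model

Each mutation is encoded as a fixed-length numeric vector of five blocks,
concatenated in this order:

| block | length | content |
|---|---|---|
| Mut | 20 | substitution encoding: −1 at the wild-type residue slot, +1 at the mutant slot |
| Environment | 21 (3D) or 20 (SEQ) | 3D: counts of residue types with a heavy atom within 6 Å of the mutated residue's Cα, plus its relative solvent accessibility (RSA, %); SEQ: residue composition of a 19-position sequence window |
| Prof | 5 | alignment-profile features: F_W, F_N (column frequencies of wild-type and mutant), N_T, N_S (total / locally aligned rows), CI (conservation index) |
| PANTHER | 4 | family-classifier output (P_D, P_W, P_N, N_IC) from a precomputed table; defaults (0.5, 0, 0, 0) on a miss |
| GO | 2 | number of propagated Gene Ontology terms, and the LGO log-odds score |

The conservation index of an alignment column *i* is

    CI(i) = [ Σ_a ( f_a(i) − f_a )² ]^(1/2)

over the 20 residue types, with gap-excluded frequencies. The GO score of a
protein sums, over its is_a-propagated terms,

    LGO = Σ_GO log₂[ f_GO(D) / f_GO(N) ],    f_GO(X) = (c_X + 1) / (T_X + 1)

where c_X counts training mutations of class X whose protein carries the
term. The classifier is a soft-margin SVM with RBF kernel (C = 8,
γ = 0.03125) and Platt probability output; each prediction carries a
reliability index RI = 20·|O(D) − 0.5| on a 0–10 scale.

Evaluation uses 20-fold cross-validation in which whole 30%-identity
single-linkage homology clusters are confined to single folds, GO counts are
refit per fold from training mutations only, and the neutral class can be
balanced by adding each neutral substitution's reverse. A companion analysis
scores residue contacts *lost* by the wild-type and *gained* by the mutant
residue (20×20 log-odds matrices over disease vs neutral mutations).

Because compiling a real mutation/structure corpus requires external
databases, the package ships a synthetic-data generator
(`sap3d.synthetic_fixtures`) that emulates the statistical contrasts of real
data — buried disease mutations, GO enrichment, cysteine-pair contact bias —
with controllable effect sizes, so the whole pipeline is testable offline.

## Worked example

Generate a small labeled synthetic dataset, cross-validate the structure
variant, and inspect one residue's structural environment:

```
$ sap3d simulate --seed 5 --out demo --n-proteins 12 --n-residues 60 \
      --n-mutations-per-class 30
$ sap3d crossval --data-dir demo --variant 3d --k 10 --seed 5 --out pred.tsv
{"n": 60, "q2": 0.6333, "mcc": 0.2667, "auc": 0.7056,
 "sensitivity": {"disease": 0.6333, "neutral": 0.6333},
 "ppv": {"disease": 0.6333, "neutral": 0.6333}, "tpr_at_fpr10": 0.2}
$ sap3d features --pdb demo/pdb/P0001.pdb --chain A --residue 30
{"counts": [0, 0, 0, 1, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1, 2, 1, 0, 0, 0, 0], "rsa": 41.235}
```

Here `q2` is overall accuracy, `mcc` the Matthews correlation, `auc` the
area under the ROC curve of the pooled cross-validated disease
probabilities, and `tpr_at_fpr10` the true-positive rate at 10% false-positive
rate; at this tiny scale (60 mutations on 12 proteins) the planted burial
signal is only partially recoverable. The `features` output is the 21-element
structural environment: the 6 Å shell composition in canonical residue order
(ACDEFGHIKLMNPQRSTVWY) and the residue's RSA in percent. `pred.tsv` holds
per-mutation disease probabilities, predicted classes and reliability
indices.

At the generator's default scale (200 proteins × 100 residues, 1,000
mutations, planted RSA gap of 20 percentage points) the structure variant
reaches a cross-validated AUC near 0.87 while the sequence variant stays
near chance, and restricting to predictions with RI > 5 raises accuracy to
~0.88 on ~68% of the data — the same qualitative behavior the method shows
on real mutation corpora.

Library use mirrors the CLI: see `sap3d.extract_feature_table`,
`sap3d.cross_validate`, `sap3d.fit_interaction_log_odds` and
`sap3d.make_labeled_dataset`.

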