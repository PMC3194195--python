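# Methods

## Problem and model

The task is binary classification of single amino acid polymorphisms (SAPs)
into disease-related and neutral, for mutations that can be mapped onto an
experimental protein structure. The classifier is a soft-margin SVM with RBF
kernel K(x, y) = exp(−γ‖x−y‖²), C = 8 and γ = 0.03125, trained with Platt
probability calibration (scikit-learn's libsvm backend, seeded). Inputs are
rescaled feature-wise to [−1, 1] with training-set min/max; constant features
map to 0; held-out values outside the training range extrapolate without
clipping.

Two variants share everything but the environment block: the structure
variant (52 features) uses the 6 Å shell composition + RSA of the mutated
residue, the sequence variant (51 features) uses the 19-position sequence
window composition. Comparing the two cross-validated under identical
protocol isolates the contribution of structural information.

## Feature blocks

**Substitution encoding (20).** −1 at the wild-type slot, +1 at the mutant
slot, canonical residue order ACDEFGHIKLMNPQRSTVWY throughout the package.

**Structural environment (21).** For every other residue of the chain, its
type is counted if any of its heavy atoms lies within 6 Å (Euclidean) of the
mutated residue's Cα. Sequence-adjacent residues are counted like any other —
their packing contribution is real — and the mutated residue itself is
excluded (its identity is already fully carried by the substitution
encoding). The 21st element is RSA in percent.

**Solvent accessibility.** Shrake–Rupley quadrature: per atom, the fraction
of quasi-uniform sphere points (golden-spiral construction, 960 points by
default) at radius r_vdw + 1.4 Å not contained in any other atom's expanded
sphere, times the expanded-sphere area; per-residue ASA sums over atoms.
Van der Waals radii are Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80,
Se 1.90, P 1.80 Å); an unknown element falls back to the carbon radius with
a warning. RSA = 100·ASA/maxASA with the Rost–Sander maximum-ASA table,
clipped to [0, 100]. Which max-ASA normalisation to use is a documented
choice, not fixed by the problem; the table is a configuration constant. A
per-residue accessibility TSV (e.g. from DSSP) can be imported in place of
the internal quadrature. Doubling the point count changes per-residue ASA by
< 2% on fixture structures (tested).

**Sequence window (20, sequence variant).** Composition of positions ±9
around the mutation, truncated at chain ends. The center position is
excluded by default (`include_center` flips the convention; including it
would double-encode the wild type already present in the substitution
block).

**Profile (5).** From a user-supplied multiple alignment with the query row
carrying mutation coordinates: gap-excluded column frequencies of the
wild-type (F_W) and mutant (F_N) residues; N_T = number of rows;
N_S = number of rows with a residue at the column (the "totally" vs
"locally" aligned interpretation is a documented decision); CI = Euclidean
distance between the column's gap-excluded frequency vector and the
whole-alignment frequency vector. Gaps never enter frequency denominators.
Profile construction itself (e.g. BLAST against a reference database) is an
upstream data-preparation step, not executed by the package; absent an
alignment, a single-row alignment of the query is used (F_W = 1, CI
degenerate).

**Family classifier (4).** (P_D, P_W, P_N, N_IC) looked up from a
precomputed table keyed by (protein, position, wt, mut); on any miss the
block defaults to (0.5, 0, 0, 0), i.e. an uninformative deleteriousness
probability.

**Gene Ontology (2).** Direct annotations are propagated to all is_a
ancestors (the OBO subset read here carries only is_a; all three namespaces
merge into one term set, each term counted once). The feature is (number of
propagated terms, LGO) with

LGO = Σ_GO log₂[f_GO(D)/f_GO(N)],  f_GO(X) = (c_X + 1)/(T_X + 1),

where c_X is the number of class-X **training mutations** whose protein
carries the term and T_X the class total. Mutations, not proteins, are the
counting unit because the score labels mutations (a per-protein mode exists
behind a flag). The +1 pseudo-count per class keeps every term finite. GO
counts are refit inside every cross-validation fold from the training folds
only — a leakage-freedom property asserted by tests.

## Evaluation protocol

**Homology-aware folds.** Proteins are single-linkage clustered: two
sequences join if the shorter aligns inside the longer (infix edit distance,
edlib) at ≥ 30% identity (identity = 1 − d/len(shorter)). Because the infix
alignment always covers the shorter sequence fully, the usual 90%-coverage
requirement is satisfied at coverage 1.0; partial-coverage local hits below
full coverage are not credited, a slightly stricter rule that cannot create
spurious cluster merges. Whole clusters are assigned greedily (largest
first, seed-shuffled ties) to k = 20 folds, balancing fold size first and
disease fraction second; no cluster ever spans two folds (asserted).

**Balancing.** The neutral class can be doubled by adding each neutral
substitution's reverse (mut→wt at the same site, labeled neutral).
Structure-derived features of a reverse mutation are computed on the same
wild-type structure — only the substitution encoding flips and the profile
wt/mut frequencies swap — and such records are flagged in output.

**Statistics.** Overall accuracy Q2; Matthews correlation C from the
per-class confusion counts p, n, u, o (equal to the Pearson correlation of
the binary vectors, tested to 1e-12); per-class sensitivity S = p/(p+u) and
positive predictive value P = p/(p+o); AUC as the Mann–Whitney rank
statistic with midranks for ties (equal to trapezoidal integration of the
tie-pooled empirical ROC, tested to 1e-9); TPR at 10% false-positive rate
(standard ROC FPR). A second reading of "10% wrong positive predictions" —
TPR at 10% false-discovery rate, i.e. 1 − precision — is also computed and
reported separately; the ROC-based definition is primary. Degenerate
denominators report 0 with an explicit flag. Classification threshold is
O(D) ≥ 0.5 with ties resolved to disease (conservative for a pathogenicity
screen). RI = 20·|O(D) − 0.5|; the reliability curve reports metrics and
coverage over the RI > t subsets for t = 0..9.

**Function-subtree holdout.** For a GO term (e.g. a functional class such as
kinase activity), the test set is every mutation on a protein carrying the
term after propagation; training proteins above the identity cutoff to any
test protein are removed; and the term plus all descendants are excluded
from the annotations used for test-set LGO scoring.

## Contact log-odds

Shell partners of the mutated residue define lost contacts (wild type ×
partner) and gained contacts (mutant × partner), under the approximation
that backbone geometry is unchanged by the mutation — reasonable for buried
sites, crude for exposed ones. Pairs are unordered and each partner
contributes one event with multiplicity. Per kind,
LC(i,j) = log₂[f(c(i,j),D)/f(c(i,j),N)] with frequencies normalised within
kind and class and one pseudo-count per pair per class (required for
finiteness; the matrices are exactly symmetric by construction).

## Synthetic data generator

`synthetic_fixtures` generates every input format with controllable planted
contrasts. Structures are ideal α-helices (rise 1.5 Å, 100° twist, Cα–Cα
3.8 Å) or compact globules (self-avoiding 3.8 Å random walk confined to a
sphere sized at 134 Å³/residue, relaxed if jammed), with N/CA/C/O/CB heavy
atoms per residue and valid fixed-column PDB text. Alignments are sampled
column-wise: a row keeps the query residue with probability equal to the
column's conservation level, otherwise draws uniformly from all 20 types
(so a conservation-0 column carries the query residue at the 1/20 base
rate), with occasional gaps. The ontology is a random tree; a marked term
is annotated to disease proteins with a configurable odds multiplier
(base rate 0.15).

Default study conditions: 200 proteins × 100 residues, 500 mutations per
class, planted mean RSA gap of 20 percentage points between neutral and
disease sites with a within-class spread of σ = 10 RSA points, all other
blocks label-independent. Mutation sites are chosen by drawing a target RSA
from the class-conditional normal and taking the unused position nearest to
it, so the realized gap tracks the configured one within sampling error
(tested: ±3 at gap 15). The σ = 10 spread is narrower than real RSA
distributions (which are broad and skewed); it was fixed once as the
generator's default to give a clean, strongly separable burial signal at
the default gap. Optional cysteine-pair planting rewires spatially close
residue pairs to Cys–Cys and sites a configurable fraction of disease
mutations there, creating the disease-enriched Cys–Cys lost-contact signal.

What the generator does **not** emulate: real fold topologies and side-chain
packing, sequence–structure covariation, curation biases of mutation
databases, realistic GO DAG shape, or profile phylogenetic correlation.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted effects, not real-data accuracy; headline
benchmark numbers on real corpora require the original external data and
are out of scope here.

## Numerical and design choices

- Positions are 1-based; intervals closed (mutation nomenclature C163S).
- PDB reading keeps heavy ATOM atoms of the requested chain (first model);
  OXT kept; altloc resolved to highest occupancy, ties to first encountered;
  waters and unmapped het groups dropped; a fixed table maps common modified
  residues (MSE→MET, SEC→CYS, SEP→SER, …) to canonical parents; residues
  lacking Cα are dropped with a warning. Resolution metadata is parsed and
  exposed.
- Sequence→structure mapping accepts only the longest common gapless,
  100%-identity block of ≥ 40 residues (exact-substring search); rejections
  are classified as gap / identity / length by a diagnostic local alignment.
  When one mutation has several candidate structures, choosing among them
  (e.g. by resolution) is the caller's concern.
- Cross-validation, fold assignment, SVM probability calibration and all
  generators are deterministic given their seeds; identical seeds yield
  byte-identical prediction tables.
- Problem sizes in the shipped tests and the acceptance script (default
  generator scale, 20 folds, seeds 1–3) were chosen so the whole suite runs
  in a few minutes on one CPU while keeping planted-signal recovery
  statistically unambiguous.

## Known limitations

Intra-chain contacts only (no quaternary structure); first NMR model only;
no mmCIF; no secondary-structure features; no mutant-structure modeling or
energy terms; hyperparameters fixed rather than re-searched (C, γ are the
known optimum for this architecture). The infix-identity clustering is a
conservative stand-in for BLAST-based clustering: identical semantics on
near-global homology, stricter on partial-coverage hits.
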