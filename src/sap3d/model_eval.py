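"""Classifier assembly, training, homology-aware evaluation and metrics.

The feature vector concatenates, in fixed order: substitution encoding (20),
environment (21 structural or 20 sequence-window), profile (5), family
classifier (4) and GO (2) blocks — 52 elements for the structure variant
("3d"), 51 for the sequence variant ("seq").  The classifier is a soft-margin
RBF-kernel SVM (C = 8, gamma = 0.03125) with Platt probability output; inputs
are rescaled to [-1, 1] using training-fold min/max.

Evaluation uses 20-fold cross-validation with whole single-linkage homology
clusters (30% identity) confined to single folds, per-fold leakage-free GO
counting, and optional reverse-mutation balancing of the neutral class.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .function_features import (PropagatedAnnotation, fit_go_counts,
                                go_feature_pair, exclude_term_subtree)
from .io_formats import (MultipleAlignment, MutationRecord, StructureModel,
                         map_sequence_to_structure)
from .sequence_features import (PantherTable, encode_mutation, panther_features,
                                profile_features, sequence_window_counts)
from .structure_features import (DEFAULT_SHELL_RADIUS, compute_sasa,
                                 shell_residue_counts, structure_rsa)

DEFAULT_C = 8.0
DEFAULT_GAMMA = 0.03125
DEFAULT_FOLDS = 20
DEFAULT_IDENTITY_THRESHOLD = 0.30
DEFAULT_COVERAGE = 0.90
MODEL_FORMAT_VERSION = 1

VARIANTS = ("3d", "seq")
VECTOR_LENGTH = {"3d": 52, "seq": 51}
_BLOCK_LENGTHS = {"3d": (20, 21, 5, 4, 2), "seq": (20, 20, 5, 4, 2)}


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_vector(mut_block, env_block, prof_block, panther_block, go_pair,
                    variant: str) -> np.ndarray:
    """Concatenate the feature blocks in the fixed order Mut, Environment,
    Prof, PANTHER, GO; 52 elements for "3d", 51 for "seq"."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    blocks = [np.asarray(b, dtype=float).ravel()
              for b in (mut_block, env_block, prof_block, panther_block, go_pair)]
    expected = _BLOCK_LENGTHS[variant]
    for block, n in zip(blocks, expected):
        if block.size != n:
            raise ValueError(f"block length {block.size} != expected {n} "
                             f"for variant {variant!r}")
    vector = np.concatenate(blocks)
    if not np.isfinite(vector).all():
        raise ValueError("feature vector contains non-finite values")
    return vector


@dataclass
class FeatureTable:
    """Per-mutation fixed feature blocks (everything except the
    fold-dependent GO pair), in dataset order."""

    records: list[MutationRecord]
    variant: str
    mut: np.ndarray       # (n, 20)
    env: np.ndarray       # (n, 21) for 3d, (n, 20) for seq
    prof: np.ndarray      # (n, 5)
    panther: np.ndarray   # (n, 4)
    rsa: Optional[np.ndarray] = None  # (n,) RSA percent of the mutated residue

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        """1 = disease, 0 = neutral."""
        return np.array([1 if r.label == "disease" else 0 for r in self.records])

    def matrix(self, go_block: Optional[np.ndarray] = None) -> np.ndarray:
        if go_block is None:
            go_block = np.zeros((len(self), 2))
        X = np.hstack([self.mut, self.env, self.prof, self.panther, go_block])
        assert X.shape[1] == VECTOR_LENGTH[self.variant]
        return X


def _trivial_alignment(seq: str) -> MultipleAlignment:
    return MultipleAlignment(["query"], [seq], 0)


def extract_feature_table(records: Sequence[MutationRecord],
                          sequences: dict[str, str],
                          structures: Optional[dict[str, StructureModel]] = None,
                          alignments: Optional[dict[str, MultipleAlignment]] = None,
                          panther_table: Optional[PantherTable] = None,
                          variant: str = "3d",
                          radius: float = DEFAULT_SHELL_RADIUS,
                          window_length: int = 19,
                          sasa_points: int = 960,
                          rsa_cache: Optional[dict[str, np.ndarray]] = None
                          ) -> FeatureTable:
    """Compute the fixed feature blocks for every mutation.

    The "3d" variant needs one structure per protein; SASA and the
    sequence->structure mapping are computed once per protein.  For a
    reverse-balanced record the structure carries the *mutant* residue (the
    original wild type), which is what the consistency check expects.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "3d" and not structures:
        raise ValueError("the 3d variant requires structures")

    mappings: dict[str, object] = {}
    rsa_cache = dict(rsa_cache) if rsa_cache else {}
    if structures:
        for pid, struct in structures.items():
            if pid not in sequences:
                raise KeyError(f"no sequence for protein {pid!r}")
            mappings[pid] = map_sequence_to_structure(sequences[pid], struct, pid)
            if pid not in rsa_cache:
                rsa_cache[pid] = structure_rsa(
                    struct, compute_sasa(struct, n_points=sasa_points))

    n = len(records)
    mut = np.empty((n, 20))
    env = np.empty((n, 21 if variant == "3d" else 20))
    prof = np.empty((n, 5))
    panther = np.empty((n, 4))
    rsa = np.full(n, np.nan)

    for i, record in enumerate(records):
        seq = sequences[record.protein_id]
        expected = record.mut if record.is_reverse else record.wt
        if seq[record.position - 1] != expected:
            raise ValueError(
                f"record {i}: sequence has {seq[record.position - 1]} at "
                f"position {record.position}, mutation table says {expected}")
        mut[i] = encode_mutation(record.wt, record.mut)
        if structures and record.protein_id in structures:
            mapping = mappings[record.protein_id]
            if record.position not in mapping:
                raise ValueError(f"record {i}: position {record.position} "
                                 f"outside the mapped structure block")
            ordinal = mapping[record.position]
            rsa[i] = rsa_cache[record.protein_id][ordinal - 1]
        if variant == "3d":
            struct = structures[record.protein_id]
            counts = shell_residue_counts(struct, ordinal, radius)
            env[i] = np.concatenate([counts.astype(float), [rsa[i]]])
        else:
            env[i] = sequence_window_counts(seq, record.position, window_length)
        aln = (alignments or {}).get(record.protein_id) or _trivial_alignment(seq)
        prof[i] = profile_features(aln, record.position, record.wt,
                                   record.mut).as_vector()
        panther[i] = panther_features(record, panther_table)

    return FeatureTable(list(records), variant, mut, env, prof, panther,
                        rsa if not np.isnan(rsa).all() else None)


def balance_with_reverse(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Append the reverse substitution of every neutral record (as neutral),
    doubling the neutral class; disease records are untouched."""
    out = list(records)
    out.extend(r.reversed() for r in records if r.label == "neutral")
    return out


# ---------------------------------------------------------------------------
# Scaling, training, prediction
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaling:
    """Training-set per-feature min/max for the linear map to [-1, 1];
    constant features map to 0."""

    lo: np.ndarray
    hi: np.ndarray


def fit_scaling(X: np.ndarray) -> FeatureScaling:
    return FeatureScaling(X.min(axis=0), X.max(axis=0))


def apply_scaling(scaling: FeatureScaling, X: np.ndarray) -> np.ndarray:
    span = scaling.hi - scaling.lo
    safe = np.where(span == 0, 1.0, span)
    Xs = -1.0 + 2.0 * (X - scaling.lo) / safe
    return np.where(span == 0, 0.0, Xs)


@dataclass
class TrainedModel:
    svc: SVC
    scaling: FeatureScaling
    variant: str
    metadata: dict = field(default_factory=dict)


@dataclass
class Prediction:
    o_disease: float  # calibrated probability of the disease class
    label: str        # disease iff o_disease >= 0.5
    ri: float         # reliability index, 20 * |o_disease - 0.5| in [0, 10]


def reliability_index(o_disease) -> np.ndarray:
    return 20.0 * np.abs(np.asarray(o_disease, dtype=float) - 0.5)


def train(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C,
          gamma: float = DEFAULT_GAMMA, seed: int = 0,
          variant: str = "3d") -> TrainedModel:
    """Fit scaling and the probability-calibrated RBF SVM on training data."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    scaling = fit_scaling(X)
    svc = SVC(C=C, gamma=gamma, kernel="rbf", probability=True,
              random_state=seed)
    with warnings.catch_warnings():
        # libsvm-style Platt scaling is the intended probability model here
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(apply_scaling(scaling, X), y)
    model = TrainedModel(svc, scaling, variant,
                         {"C": C, "gamma": gamma, "seed": seed,
                          "n_train": int(len(y)),
                          "n_disease": int((y == 1).sum()),
                          "format_version": MODEL_FORMAT_VERSION})
    return model


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Calibrated disease-class probability for each row of X."""
    X = np.atleast_2d(X)
    if X.shape[1] != VECTOR_LENGTH[model.variant]:
        raise ValueError(f"vector length {X.shape[1]} does not match variant "
                         f"{model.variant!r} ({VECTOR_LENGTH[model.variant]})")
    proba = model.svc.predict_proba(apply_scaling(model.scaling, X))
    disease_col = int(np.where(model.svc.classes_ == 1)[0][0])
    return proba[:, disease_col]


def predict(model: TrainedModel, vector: np.ndarray) -> Prediction:
    """Predict one mutation: disease probability, class (0.5 threshold,
    ties to disease) and reliability index."""
    o_d = float(predict_proba(model, vector)[0])
    return Prediction(o_d, "disease" if o_d >= 0.5 else "neutral",
                      float(reliability_index(o_d)))


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"incompatible model format version "
                         f"{payload.get('format_version')!r}; "
                         f"expected {MODEL_FORMAT_VERSION}")
    return payload["model"]


# ---------------------------------------------------------------------------
# Homology clustering and fold construction
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned inside the longer (infix
    edit distance): 1 - d/len(shorter), floored at 0.  The shorter sequence
    is aligned over its full length, so coverage is always complete."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    d = edlib.align(short, long_, mode="HW")["editDistance"]
    return max(0.0, 1.0 - d / len(short))


def cluster_proteins(sequences: dict[str, str],
                     identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                     coverage: float = DEFAULT_COVERAGE) -> dict[str, int]:
    """Single-linkage clusters joining pairs at >= *identity_threshold*
    identity.  The infix alignment always covers the shorter sequence fully,
    which satisfies any coverage requirement <= 1; partial-coverage local
    hits below full coverage are not credited (a slightly stricter rule)."""
    ids = sorted(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if pairwise_identity(sequences[a], sequences[b]) >= identity_threshold:
                parent[find(a)] = find(b)
    roots = sorted({find(i) for i in ids})
    root_id = {r: k for k, r in enumerate(roots)}
    return {i: root_id[find(i)] for i in ids}


@dataclass
class FoldPlan:
    folds: list[np.ndarray]              # record indices per fold
    cluster_of: dict[str, int]           # protein -> cluster id

    def validate(self, records: Sequence[MutationRecord]) -> None:
        pooled = np.concatenate(self.folds) if self.folds else np.array([], int)
        if sorted(pooled.tolist()) != list(range(len(records))):
            raise AssertionError("folds do not partition the dataset")
        cluster_fold: dict[int, int] = {}
        for f, idx in enumerate(self.folds):
            for i in idx:
                cid = self.cluster_of[records[i].protein_id]
                if cluster_fold.setdefault(cid, f) != f:
                    raise AssertionError(f"cluster {cid} spans two folds")


def make_folds(records: Sequence[MutationRecord], clusters: dict[str, int],
               k: int = DEFAULT_FOLDS, seed: int = 0) -> FoldPlan:
    """Greedy assignment of whole homology clusters to *k* folds, largest
    cluster first, balancing fold size and disease/neutral ratio;
    deterministic given *seed* (ties are seed-shuffled)."""
    by_cluster: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_cluster.setdefault(clusters[r.protein_id], []).append(i)
    if k > len(by_cluster):
        raise ValueError(f"k={k} exceeds the number of clusters ({len(by_cluster)})")
    labels = np.array([1 if r.label == "disease" else 0 for r in records])
    global_frac = labels.mean() if len(records) else 0.0
    rng = np.random.default_rng(seed)
    order = sorted(by_cluster, key=lambda c: (-len(by_cluster[c]), rng.random()))
    fold_idx: list[list[int]] = [[] for _ in range(k)]
    fold_disease = np.zeros(k)
    fold_total = np.zeros(k)
    for cid in order:
        idx = by_cluster[cid]
        d = labels[idx].sum()
        t = len(idx)
        best, best_key = 0, None
        for f in range(k):
            frac = (fold_disease[f] + d) / (fold_total[f] + t)
            key = (fold_total[f], abs(frac - global_frac))
            if best_key is None or key < best_key:
                best, best_key = f, key
        fold_idx[best].extend(idx)
        fold_disease[best] += d
        fold_total[best] += t
    plan = FoldPlan([np.array(sorted(f), dtype=int) for f in fold_idx], dict(clusters))
    plan.validate(records)
    return plan


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassCounts:
    p: int  # correct predictions of the class
    n: int  # correct rejections
    u: int  # false negatives
    o: int  # false positives


@dataclass
class MetricsReport:
    q2: float
    mcc: float
    sensitivity: dict[str, float]   # S(D), S(N)
    ppv: dict[str, float]           # P(D), P(N)
    auc: float
    tpr_at_fpr10: float             # TPR at 10% standard ROC FPR
    tpr_at_fdr10: float             # TPR at 10% false-discovery rate
    counts: dict[str, ClassCounts]
    n: int
    flags: list[str] = field(default_factory=list)


def mcc_from_counts(p: int, n: int, u: int, o: int) -> float:
    w = float((p + u) * (p + o) * (n + u) * (n + o))
    if w == 0:
        return 0.0
    return (p * n - u * o) / np.sqrt(w)


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties by midrank)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (fpr, tpr), thresholds descending, ties pooled."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(y_true)[order]
    s = np.asarray(scores, dtype=float)[order]
    distinct = np.where(np.diff(s))[0]
    cut = np.r_[distinct, len(y) - 1]
    tp = np.cumsum(y == 1)[cut]
    fp = np.cumsum(y == 0)[cut]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    return (np.r_[0.0, fp / n_neg], np.r_[0.0, tp / n_pos])


def tpr_at_fpr(y_true, scores, fpr_limit: float = 0.10) -> float:
    fpr, tpr = roc_points(y_true, scores)
    ok = fpr <= fpr_limit
    return float(tpr[ok].max()) if ok.any() else 0.0


def tpr_at_fdr(y_true, scores, fdr_limit: float = 0.10) -> float:
    """TPR at 10% false-discovery rate (the paper's 1 - precision reading)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(y_true)[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    fdr = fp / np.maximum(tp + fp, 1)
    n_pos = max(int((y == 1).sum()), 1)
    ok = fdr <= fdr_limit
    return float(tp[ok].max() / n_pos) if ok.any() else 0.0


def compute_metrics(y_true: np.ndarray, o_disease: np.ndarray,
                    y_pred: Optional[np.ndarray] = None) -> MetricsReport:
    """All evaluation statistics from pooled predictions.

    y_true: 1 = disease, 0 = neutral; o_disease: disease probability;
    y_pred defaults to thresholding o_disease at 0.5 (ties to disease).
    """
    y_true = np.asarray(y_true)
    o_disease = np.asarray(o_disease, dtype=float)
    if len(y_true) == 0:
        raise ValueError("no predictions")
    if y_pred is None:
        y_pred = (o_disease >= 0.5).astype(int)
    flags: list[str] = []

    counts = {}
    for name, cls in (("disease", 1), ("neutral", 0)):
        p = int(((y_pred == cls) & (y_true == cls)).sum())
        n = int(((y_pred != cls) & (y_true != cls)).sum())
        u = int(((y_pred != cls) & (y_true == cls)).sum())
        o = int(((y_pred == cls) & (y_true != cls)).sum())
        counts[name] = ClassCounts(p, n, u, o)

    q2 = float((y_pred == y_true).mean())
    d = counts["disease"]
    mcc = float(mcc_from_counts(d.p, d.n, d.u, d.o))
    if (d.p + d.u) * (d.p + d.o) * (d.n + d.u) * (d.n + d.o) == 0:
        flags.append("mcc degenerate: reported as 0")

    sens, ppv = {}, {}
    for name, c in counts.items():
        if c.p + c.u == 0:
            sens[name] = 0.0
            flags.append(f"S({name}) degenerate: reported as 0")
        else:
            sens[name] = c.p / (c.p + c.u)
        if c.p + c.o == 0:
            ppv[name] = 0.0
            flags.append(f"P({name}) degenerate: reported as 0")
        else:
            ppv[name] = c.p / (c.p + c.o)

    auc = auc_rank(y_true, o_disease)
    if np.isnan(auc):
        auc = 0.0
        flags.append("auc degenerate (single class): reported as 0")
        t10 = f10 = 0.0
    else:
        t10 = tpr_at_fpr(y_true, o_disease)
        f10 = tpr_at_fdr(y_true, o_disease)
    return MetricsReport(q2, mcc, sens, ppv, float(auc), t10, f10,
                         counts, int(len(y_true)), flags)


# ---------------------------------------------------------------------------
# Cross-validation and protocol tests
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    records: list[MutationRecord]
    y_true: np.ndarray
    o_disease: np.ndarray
    y_pred: np.ndarray
    fold_of: np.ndarray
    plan: FoldPlan
    metrics: MetricsReport

    def prediction_table(self) -> str:
        """Deterministic TSV of per-mutation predictions (shortest float repr)."""
        out = io.StringIO()
        out.write("protein_id\tchain_id\tposition\twt\tmut\tlabel\tfold"
                  "\to_disease\tprediction\tri\n")
        ri = reliability_index(self.o_disease)
        for i, r in enumerate(self.records):
            pred = "disease" if self.y_pred[i] == 1 else "neutral"
            out.write(f"{r.protein_id}\t{r.chain_id}\t{r.position}\t{r.wt}\t"
                      f"{r.mut}\t{r.label or ''}\t{self.fold_of[i]}\t"
                      f"{float(self.o_disease[i])!r}\t{pred}\t"
                      f"{float(ri[i])!r}\n")
        return out.getvalue()


def cross_validate(table: FeatureTable,
                   annotations: Optional[PropagatedAnnotation] = None,
                   sequences: Optional[dict[str, str]] = None,
                   clusters: Optional[dict[str, int]] = None,
                   k: int = DEFAULT_FOLDS, seed: int = 0,
                   C: float = DEFAULT_C, gamma: float = DEFAULT_GAMMA) -> CVResult:
    """k-fold cross-validation with homology-cluster fold confinement.

    Per fold, the GO class counts, the feature scaling and the SVM are all
    fitted on the k-1 training folds only; the held-out fold is then scored.
    Deterministic given *seed*.
    """
    records = table.records
    if clusters is None:
        if sequences is None:
            raise ValueError("need sequences or a precomputed cluster map")
        clusters = cluster_proteins(sequences)
    plan = make_folds(records, clusters, k, seed)
    y = table.labels
    o_d = np.full(len(records), np.nan)
    fold_of = np.full(len(records), -1, dtype=int)

    for f, test_idx in enumerate(plan.folds):
        train_mask = np.ones(len(records), bool)
        train_mask[test_idx] = False
        train_idx = np.where(train_mask)[0]
        if annotations is not None:
            go_counts = fit_go_counts([records[i] for i in train_idx], annotations)
            go = np.array([go_feature_pair(r.protein_id, annotations, go_counts)
                           for r in records], dtype=float)
        else:
            go = np.zeros((len(records), 2))
        X = table.matrix(go)
        model = train(X[train_idx], y[train_idx], C=C, gamma=gamma, seed=seed,
                      variant=table.variant)
        o_d[test_idx] = predict_proba(model, X[test_idx])
        fold_of[test_idx] = f

    y_pred = (o_d >= 0.5).astype(int)
    metrics = compute_metrics(y, o_d, y_pred)
    return CVResult(records, y, o_d, y_pred, fold_of, plan, metrics)


def reliability_curve(y_true: np.ndarray, o_disease: np.ndarray) -> pd.DataFrame:
    """Accuracy/correlation over the subsets with RI > threshold, for
    thresholds 0..9, with the retained dataset fraction."""
    y_true = np.asarray(y_true)
    o_disease = np.asarray(o_disease, dtype=float)
    ri = reliability_index(o_disease)
    rows = []
    for threshold in range(10):
        mask = ri > threshold
        if mask.sum() == 0:
            rows.append({"ri_threshold": threshold, "coverage": 0.0,
                         "n": 0, "q2": np.nan, "mcc": np.nan})
            continue
        m = compute_metrics(y_true[mask], o_disease[mask])
        rows.append({"ri_threshold": threshold,
                     "coverage": float(mask.mean()),
                     "n": int(mask.sum()), "q2": m.q2, "mcc": m.mcc})
    return pd.DataFrame(rows)


def stratify_by_rsa(y_true: np.ndarray, o_disease: np.ndarray,
                    rsa: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Per-RSA-bin accuracy: equal-width bins on [0, 100], the last bin
    closed at 100."""
    y_true = np.asarray(y_true)
    o_disease = np.asarray(o_disease, dtype=float)
    rsa = np.asarray(rsa, dtype=float)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    which = np.clip(np.digitize(rsa, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        row = {"rsa_lo": edges[b], "rsa_hi": edges[b + 1],
               "n_disease": int((y_true[mask] == 1).sum()),
               "n_neutral": int((y_true[mask] == 0).sum())}
        if mask.any():
            m = compute_metrics(y_true[mask], o_disease[mask])
            row.update(q2=m.q2, mcc=m.mcc)
        else:
            row.update(q2=np.nan, mcc=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HoldoutSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    annotations: PropagatedAnnotation  # term subtree excluded for scoring


def holdout_by_function(records: Sequence[MutationRecord],
                        sequences: dict[str, str],
                        annotations: PropagatedAnnotation,
                        ontology, term: str,
                        identity_cutoff: float = DEFAULT_IDENTITY_THRESHOLD
                        ) -> HoldoutSplit:
    """Function-subtree holdout: the test set is every mutation on a protein
    annotated (after propagation) with *term* or a descendant; training
    proteins above *identity_cutoff* to any test protein are removed, and the
    term's subtree is excluded from the scoring annotations."""
    test_proteins = {pid for pid, terms in annotations.items() if term in terms}
    test_idx = np.array([i for i, r in enumerate(records)
                         if r.protein_id in test_proteins], dtype=int)
    train_proteins = set()
    for pid in {r.protein_id for r in records} - test_proteins:
        if all(pairwise_identity(sequences[pid], sequences[t]) < identity_cutoff
               for t in test_proteins):
            train_proteins.add(pid)
    train_idx = np.array([i for i, r in enumerate(records)
                          if r.protein_id in train_proteins], dtype=int)
    cleaned = exclude_term_subtree(annotations, ontology, term)
    return HoldoutSplit(train_idx, test_idx, cleaned)


# ---------------------------------------------------------------------------
# Feature TSV round trip
# ---------------------------------------------------------------------------

def write_feature_tsv(table: FeatureTable, path,
                      go_block: Optional[np.ndarray] = None) -> None:
    """Assembled vectors as TSV (shortest round-trip float representation)."""
    X = table.matrix(go_block)
    with open(path, "w") as fh:
        fh.write("protein_id\tchain_id\tposition\twt\tmut\tlabel\tvariant\t"
                 + "\t".join(f"v{j}" for j in range(X.shape[1])) + "\n")
        for r, row in zip(table.records, X):
            fh.write(f"{r.protein_id}\t{r.chain_id}\t{r.position}\t{r.wt}\t"
                     f"{r.mut}\t{r.label or ''}\t{table.variant}\t"
                     + "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_tsv(path) -> tuple[list[MutationRecord], np.ndarray, str]:
    records, rows, variant = [], [], None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_meta = 7
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            records.append(MutationRecord(parts[0], parts[1], int(parts[2]),
                                          parts[3], parts[4], parts[5] or None))
            variant = parts[6]
            rows.append([float(v) for v in parts[n_meta:]])
    del header
    return records, np.asarray(rows), variant
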