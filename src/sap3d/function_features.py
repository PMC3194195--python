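"""Gene Ontology feature block: annotation propagation and the LGO score.

A protein's direct GO annotations are propagated to all is_a ancestors (each
term counted once).  The 2-element feature is (number of propagated terms,
LGO), where LGO sums, over the protein's terms, the log2 ratio of the term's
frequency among disease-labeled versus neutral-labeled *training* mutations,
with one pseudo-count per class:

    LGO = sum_GO log2[ f_GO(D) / f_GO(N) ],   f_GO(X) = (c_X + 1) / (T_X + 1)

Counting from training mutations only (refit per cross-validation fold) keeps
the score leakage-free.  A function-subtree exclusion supports holdout tests
where a whole functional class (e.g. kinase activity) is hidden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import AnnotationSet, MutationRecord, OntologyDag

logger = logging.getLogger(__name__)

PropagatedAnnotation = dict[str, frozenset]


def propagate(ontology: OntologyDag, direct: Iterable[str]) -> frozenset:
    """Direct terms plus all is_a ancestors, each term once."""
    result: set[str] = set()
    stack = list(direct)
    for term in stack:
        if term not in ontology:
            raise KeyError(f"unknown term {term!r}")
    while stack:
        term = stack.pop()
        if term in result:
            continue
        result.add(term)
        stack.extend(ontology.parents[term])
    return frozenset(result)


def build_propagated(ontology: OntologyDag,
                     annotations: AnnotationSet) -> PropagatedAnnotation:
    """Propagate every protein's direct annotation set."""
    return {pid: propagate(ontology, terms)
            for pid, terms in annotations.direct.items()}


@dataclass
class GoClassCounts:
    """Per-term training counts: number of disease / neutral training
    mutations whose protein carries the term, plus class totals."""

    c_disease: dict[str, int] = field(default_factory=dict)
    c_neutral: dict[str, int] = field(default_factory=dict)
    t_disease: int = 0
    t_neutral: int = 0


def fit_go_counts(training: Iterable[MutationRecord],
                  annotations: PropagatedAnnotation) -> GoClassCounts:
    """Count term occurrences over *training* mutations only (one increment
    per mutation-term pair); proteins without annotations contribute only to
    the class totals."""
    counts = GoClassCounts()
    for record in training:
        if record.label is None:
            raise ValueError("training records must be labeled")
        terms = annotations.get(record.protein_id)
        if record.label == "disease":
            counts.t_disease += 1
            bucket = counts.c_disease
        else:
            counts.t_neutral += 1
            bucket = counts.c_neutral
        if terms is None:
            logger.debug("protein %s has no annotations", record.protein_id)
            continue
        for term in terms:
            bucket[term] = bucket.get(term, 0) + 1
    return counts


def lgo_score(terms: Iterable[str], counts: GoClassCounts) -> float:
    """Sum of per-term log2 disease/neutral frequency ratios with one
    pseudo-count per class; an empty term set scores 0."""
    score = 0.0
    for term in terms:
        f_d = (counts.c_disease.get(term, 0) + 1) / (counts.t_disease + 1)
        f_n = (counts.c_neutral.get(term, 0) + 1) / (counts.t_neutral + 1)
        score += math.log2(f_d / f_n)
    return score


def go_feature_pair(protein_id: str, annotations: PropagatedAnnotation,
                    counts: GoClassCounts) -> tuple[int, float]:
    """(number of propagated terms, LGO); (0, 0.0) for an unannotated protein."""
    terms = annotations.get(protein_id)
    if not terms:
        return 0, 0.0
    return len(terms), lgo_score(terms, counts)


def term_descendants(ontology: OntologyDag, term: str) -> frozenset:
    """The term plus everything below it (transitive is_a children)."""
    if term not in ontology:
        raise KeyError(f"unknown term {term!r}")
    children = ontology.children_map()
    result: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in result:
            continue
        result.add(t)
        stack.extend(children[t])
    return frozenset(result)


def exclude_term_subtree(annotations: PropagatedAnnotation,
                         ontology: OntologyDag, term: str) -> PropagatedAnnotation:
    """Remove *term* and all its descendants from every protein's propagated
    set (used when a functional class is held out of scoring)."""
    excluded = term_descendants(ontology, term)
    return {pid: frozenset(t for t in terms if t not in excluded)
            for pid, terms in annotations.items()}
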