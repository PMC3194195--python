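"""Residue-interaction log-odds for contacts lost and gained upon mutation.

For a mutation, the shell partners of the mutated residue (any residue with a
heavy atom within 6 A of its C-alpha) define two contact sets: "lost"
contacts pair the wild-type residue with each partner, "gained" contacts pair
the mutant residue with the same partners, under the approximation that the
backbone does not move on mutation.  Pooling contact events across a labeled
mutation set gives, per unordered residue-type pair and per kind, a log-odds

    LC(i,j) = log2[ f(c(i,j), D) / f(c(i,j), N) ]

with frequencies normalised within kind and class and one pseudo-count per
pair per class (the pseudo-count keeps every entry finite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._residues import AA1, AA_INDEX, N_RESIDUE_TYPES
from .io_formats import MutationRecord, SeqStructMapping, StructureModel
from .structure_features import DEFAULT_SHELL_RADIUS, contact_partners


@dataclass(frozen=True)
class ContactEvent:
    kind: str                 # "lost" | "gained"
    pair: tuple[str, str]     # unordered: stored sorted
    label: Optional[str]      # disease | neutral
    record_id: str = ""

    def __post_init__(self):
        if self.kind not in ("lost", "gained"):
            raise ValueError(f"bad contact kind {self.kind!r}")
        if tuple(sorted(self.pair)) != self.pair:
            object.__setattr__(self, "pair", tuple(sorted(self.pair)))


@dataclass
class InteractionLogOdds:
    """Symmetric 20x20 log-odds matrices for lost and gained contacts."""

    lost: np.ndarray    # (20, 20)
    gained: np.ndarray  # (20, 20)
    totals: dict[tuple[str, str], int]  # (kind, class) -> event count

    def value(self, kind: str, a: str, b: str) -> float:
        m = self.lost if kind == "lost" else self.gained
        return float(m[AA_INDEX[a], AA_INDEX[b]])


def _record_key(record: MutationRecord) -> str:
    return f"{record.protein_id}/{record.chain_id}:{record.wt}{record.position}{record.mut}"


def _shell_events(struct: StructureModel, mapping: SeqStructMapping,
                  record: MutationRecord, kind: str,
                  radius: float) -> list[ContactEvent]:
    if record.position not in mapping:
        raise ValueError(f"position {record.position} outside the mapped block")
    ordinal = mapping[record.position]
    expected = record.mut if record.is_reverse else record.wt
    residue = struct.residue_by_ordinal(ordinal)
    if residue.one_letter != expected:
        raise ValueError(
            f"structure/sequence disagreement at position {record.position}: "
            f"structure has {residue.one_letter}, mutation table says {expected}")
    center = record.wt if kind == "lost" else record.mut
    shell = contact_partners(struct, ordinal, radius)
    rid = _record_key(record)
    return [ContactEvent(kind, tuple(sorted((center, p))), record.label, rid)
            for p in shell.partners]


def lost_contacts(struct: StructureModel, mapping: SeqStructMapping,
                  record: MutationRecord,
                  radius: float = DEFAULT_SHELL_RADIUS) -> list[ContactEvent]:
    """One lost event (wt, partner) per shell partner of the mutated residue."""
    return _shell_events(struct, mapping, record, "lost", radius)


def gained_contacts(struct: StructureModel, mapping: SeqStructMapping,
                    record: MutationRecord,
                    radius: float = DEFAULT_SHELL_RADIUS) -> list[ContactEvent]:
    """One gained event (mut, partner) per shell partner, assuming the
    C-alpha position is unchanged by the mutation."""
    return _shell_events(struct, mapping, record, "gained", radius)


def fit_interaction_log_odds(events: Iterable[ContactEvent]) -> InteractionLogOdds:
    """Pool labeled contact events into the two 20x20 log-odds matrices."""
    counts = {("lost", "disease"): np.zeros((N_RESIDUE_TYPES, N_RESIDUE_TYPES)),
              ("lost", "neutral"): np.zeros((N_RESIDUE_TYPES, N_RESIDUE_TYPES)),
              ("gained", "disease"): np.zeros((N_RESIDUE_TYPES, N_RESIDUE_TYPES)),
              ("gained", "neutral"): np.zeros((N_RESIDUE_TYPES, N_RESIDUE_TYPES))}
    n_events = 0
    for ev in events:
        if ev.label not in ("disease", "neutral"):
            raise ValueError("contact events must carry a disease/neutral label")
        i, j = AA_INDEX[ev.pair[0]], AA_INDEX[ev.pair[1]]
        counts[(ev.kind, ev.label)][i, j] += 1
        if i != j:
            counts[(ev.kind, ev.label)][j, i] += 1
        n_events += 1
    if n_events == 0:
        warnings.warn("no contact events: log-odds matrices are all zero")
        zero = np.zeros((N_RESIDUE_TYPES, N_RESIDUE_TYPES))
        return InteractionLogOdds(zero, zero.copy(),
                                  {k: 0 for k in counts})
    totals = {kind_label: int(np.triu(m).sum()) for kind_label, m in counts.items()}
    matrices = {}
    for kind in ("lost", "gained"):
        c_d = counts[(kind, "disease")]
        c_n = counts[(kind, "neutral")]
        f_d = (c_d + 1.0) / (totals[(kind, "disease")] + 1.0)
        f_n = (c_n + 1.0) / (totals[(kind, "neutral")] + 1.0)
        matrices[kind] = np.log2(f_d / f_n)
    return InteractionLogOdds(matrices["lost"], matrices["gained"], totals)


def write_log_odds_tsv(matrix: np.ndarray, path, kind: str = "") -> None:
    """20x20 matrix as TSV with residue-order header row and column."""
    with open(path, "w") as fh:
        if kind:
            fh.write(f"# {kind} contact log-odds; rows/cols in order {AA1}; "
                     f"one pseudo-count per pair per class\n")
        fh.write("res\t" + "\t".join(AA1) + "\n")
        for i, aa in enumerate(AA1):
            fh.write(aa + "\t" + "\t".join(repr(float(v)) for v in matrix[i]) + "\n")


def read_log_odds_tsv(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("res\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    matrix = np.asarray(rows)
    if matrix.shape != (N_RESIDUE_TYPES, N_RESIDUE_TYPES):
        raise ValueError(f"bad matrix shape {matrix.shape}")
    return matrix
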