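"""Sequence-derived feature blocks.

Four blocks are produced here: the 20-element substitution encoding (wt slot
-1, mutant slot +1), the 20-element sequence-window composition used by the
sequence-only model variant (19 positions centred on the mutation, center
excluded by default), the 5 profile features from a multiple sequence
alignment (wild-type / mutant column frequencies, row counts, conservation
index), and the 4-element family-classifier slot filled from a precomputed
table with documented defaults on a miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._residues import AA1, AA_INDEX, N_RESIDUE_TYPES, is_canonical
from .io_formats import MultipleAlignment, MutationRecord

PANTHER_DEFAULTS = (0.5, 0.0, 0.0, 0.0)  # (P_D, P_W, P_N, N_IC) on lookup miss
DEFAULT_WINDOW = 19


@dataclass
class ProfileFeatures:
    f_wt: float     # gap-excluded column frequency of the wild-type residue
    f_mut: float    # same for the mutant residue
    n_total: int    # rows in the alignment
    n_local: int    # rows with a residue (non-gap) at the column
    ci: float       # conservation index of the column

    def as_vector(self) -> np.ndarray:
        return np.array([self.f_wt, self.f_mut, float(self.n_total),
                         float(self.n_local), self.ci])


def encode_mutation(wt: str, mut: str) -> np.ndarray:
    """20-element substitution encoding: -1 at the wild-type slot, +1 at the
    mutant slot, 0 elsewhere (canonical residue order)."""
    if not (is_canonical(wt) and is_canonical(mut)):
        raise ValueError(f"non-canonical residue code in ({wt!r}, {mut!r})")
    if wt == mut:
        raise ValueError("not a substitution: wt == mut")
    v = np.zeros(N_RESIDUE_TYPES)
    v[AA_INDEX[wt]] = -1.0
    v[AA_INDEX[mut]] = 1.0
    return v


def decode_mutation(vector: np.ndarray) -> tuple[str, str]:
    """Inverse of :func:`encode_mutation`."""
    (wt_idx,) = np.where(vector == -1.0)[0]
    (mut_idx,) = np.where(vector == 1.0)[0]
    return AA1[wt_idx], AA1[mut_idx]


def sequence_window_counts(seq: str, position: int,
                           window_length: int = DEFAULT_WINDOW,
                           include_center: bool = False) -> np.ndarray:
    """Residue-type histogram over a window of *window_length* positions
    centred on *position* (1-based), truncated at the sequence ends.

    The mutated position itself is excluded by default: its identity is
    already carried in full by the substitution encoding.
    """
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    if window_length % 2 != 1:
        raise ValueError("window_length must be odd")
    half = window_length // 2
    counts = np.zeros(N_RESIDUE_TYPES, dtype=int)
    lo = max(1, position - half)
    hi = min(len(seq), position + half)
    for p in range(lo, hi + 1):
        if p == position and not include_center:
            continue
        aa = seq[p - 1]
        if aa in AA_INDEX:
            counts[AA_INDEX[aa]] += 1
    return counts


def _column_frequencies(alignment: MultipleAlignment, col: int) -> np.ndarray:
    """Gap-excluded residue frequencies of one alignment column."""
    counts = np.zeros(N_RESIDUE_TYPES)
    for ch in alignment.column(col):
        if ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no aligned residues: column is entirely gaps")
    return counts / total


def _overall_frequencies(alignment: MultipleAlignment) -> np.ndarray:
    counts = np.zeros(N_RESIDUE_TYPES)
    for row in alignment.rows:
        for ch in row:
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no residues")
    return counts / total


def conservation_index(alignment: MultipleAlignment, position: int) -> float:
    """Euclidean distance between the column residue-frequency vector (at the
    query's 1-based *position*) and the whole-alignment frequency vector: a
    fully average column scores 0, a conserved unusual column scores high."""
    col = alignment.query_column(position)
    f_col = _column_frequencies(alignment, col)
    f_all = _overall_frequencies(alignment)
    return float(np.sqrt(((f_col - f_all) ** 2).sum()))


def profile_features(alignment: MultipleAlignment, position: int,
                     wt: str, mut: str) -> ProfileFeatures:
    """The 5 profile features at the query position."""
    col = alignment.query_column(position)
    f_col = _column_frequencies(alignment, col)
    n_local = sum(1 for ch in alignment.column(col) if ch in AA_INDEX)
    ci = conservation_index(alignment, position)
    return ProfileFeatures(float(f_col[AA_INDEX[wt]]), float(f_col[AA_INDEX[mut]]),
                           alignment.n_rows, n_local, ci)


class PantherTable:
    """Precomputed family-classifier features keyed by
    (protein_id, position, wt, mut)."""

    COLUMNS = ("protein_id", "position", "wt", "mut", "p_d", "p_w", "p_n", "n_ic")

    def __init__(self, entries: Optional[dict] = None):
        self.entries: dict[tuple, tuple] = entries or {}

    @classmethod
    def read_tsv(cls, path) -> "PantherTable":
        entries = {}
        with open(path) as fh:
            header = tuple(fh.readline().rstrip("\n").split("\t"))
            if header != cls.COLUMNS:
                raise ValueError(f"bad family-feature header {header!r}; "
                                 f"expected {cls.COLUMNS}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 8:
                    raise ValueError(f"row {lineno}: expected 8 fields")
                try:
                    key = (parts[0], int(parts[1]), parts[2], parts[3])
                    value = (float(parts[4]), float(parts[5]),
                             float(parts[6]), float(parts[7]))
                except ValueError as exc:
                    raise ValueError(f"row {lineno}: {exc}") from exc
                if not 0.0 <= value[0] <= 1.0:
                    raise ValueError(f"row {lineno}: p_d outside [0, 1]")
                entries[key] = value
        return cls(entries)

    def lookup(self, record: MutationRecord) -> tuple:
        return self.entries.get(
            (record.protein_id, record.position, record.wt, record.mut),
            PANTHER_DEFAULTS)


def panther_features(record: MutationRecord,
                     table: Optional[PantherTable] = None) -> np.ndarray:
    """Family-classifier feature block; defaults (P_D=0.5, 0, 0, 0) when no
    table is supplied or the mutation is absent from it."""
    values = PANTHER_DEFAULTS if table is None else table.lookup(record)
    return np.asarray(values, dtype=float)
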