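"""Readers and writers for every external format the tool touches.

Formats handled: fixed-column PDB (ATOM/HETATM, single chain, first model),
FASTA / aligned FASTA, a minimal OBO 1.2 subset (id, name, namespace, is_a),
and tab-delimited mutation / annotation tables.  Also maps mutation positions
from sequence numbering onto structure residue ordinals under the gapless /
100%-identity / >=40-residue rule.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Optional

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from ._residues import (
    AA_INDEX,
    DEFAULT_VDW_RADIUS,
    MODIFIED_RESIDUES,
    ONE_TO_THREE,
    THREE_TO_ONE,
    VDW_RADII,
    is_canonical,
)

logger = logging.getLogger(__name__)

LABELS = ("disease", "neutral")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One labeled (or unlabeled, in prediction mode) single amino acid
    polymorphism: a substitution of ``wt`` by ``mut`` at a 1-based sequence
    ``position`` of chain ``chain_id`` of protein ``protein_id``."""

    protein_id: str
    chain_id: str
    position: int
    wt: str
    mut: str
    label: Optional[str] = None
    is_reverse: bool = False  # set by reverse-mutation balancing

    def __post_init__(self):
        if not is_canonical(self.wt):
            raise ValueError(f"unknown wild-type residue code {self.wt!r}")
        if not is_canonical(self.mut):
            raise ValueError(f"unknown mutant residue code {self.mut!r}")
        if self.wt == self.mut:
            raise ValueError("not a substitution: wt == mut")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def reversed(self) -> "MutationRecord":
        """The reverse substitution (mut -> wt) at the same site."""
        return MutationRecord(self.protein_id, self.chain_id, self.position,
                              self.mut, self.wt, self.label, is_reverse=True)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    vdw_radius: float


@dataclass(frozen=True)
class Residue:
    """One polymer residue: canonical type, 1-based ordinal in file order,
    author numbering, and its heavy atoms."""

    resname: str           # canonical 3-letter code after modified-residue mapping
    ordinal: int           # 1-based position in the retained chain
    author_number: int
    icode: str
    atoms: tuple[Atom, ...]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.resname]

    @property
    def ca(self) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass
class StructureModel:
    """A single parsed protein chain: residues in file order, heavy atoms
    only, waters/ligands excluded, modified residues canonicalised."""

    structure_id: str
    chain_id: str
    residues: list[Residue]
    resolution: Optional[float] = None
    _atom_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_ordinal(self, ordinal: int) -> Residue:
        res = self.residues[ordinal - 1]
        assert res.ordinal == ordinal
        return res

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords (m,3), residue ordinal per atom (m,), vdw radius per atom)."""
        if self._atom_cache is None:
            coords, owner, radii = [], [], []
            for r in self.residues:
                for a in r.atoms:
                    coords.append(a.coord)
                    owner.append(r.ordinal)
                    radii.append(a.vdw_radius)
            self._atom_cache = (
                np.asarray(coords, dtype=float).reshape(-1, 3),
                np.asarray(owner, dtype=int),
                np.asarray(radii, dtype=float),
            )
        return self._atom_cache


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences; ``query_index`` marks the row
    whose ungapped sequence carries the mutation coordinates."""

    ids: list[str]
    rows: list[str]
    query_index: int = 0

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError("ragged alignment: rows have unequal lengths")
        q = self.rows[self.query_index]
        bad = set(q) - set(AA_INDEX) - {"-"}
        if bad:
            raise FormatError(f"query row contains non-canonical characters {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def query_column(self, position: int) -> int:
        """Alignment column (0-based) of the 1-based ungapped query position."""
        q = self.rows[self.query_index]
        seen = 0
        for col, ch in enumerate(q):
            if ch != "-":
                seen += 1
                if seen == position:
                    return col
        raise IndexError(f"query position {position} beyond ungapped query length {seen}")

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


@dataclass
class OntologyDag:
    """Term identifiers with directed child -> parent (is_a) edges."""

    parents: dict[str, tuple[str, ...]]
    namespace: dict[str, str]
    _children: Optional[dict[str, tuple[str, ...]]] = field(default=None, repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def children_map(self) -> dict[str, tuple[str, ...]]:
        if self._children is None:
            ch: dict[str, list[str]] = {t: [] for t in self.parents}
            for child, ps in self.parents.items():
                for p in ps:
                    ch[p].append(child)
            self._children = {t: tuple(v) for t, v in ch.items()}
        return self._children


@dataclass
class AnnotationSet:
    """protein_id -> set of directly annotated ontology terms."""

    direct: dict[str, frozenset[str]]

    def __getitem__(self, protein_id: str) -> frozenset[str]:
        return self.direct.get(protein_id, frozenset())


@dataclass
class SeqStructMapping:
    """Injective, strictly increasing map from 1-based sequence positions to
    structure residue ordinals over a gapless 100%-identity block."""

    protein_id: str
    chain_id: str
    mapping: dict[int, int]
    block_length: int
    identity: float = 1.0

    def __contains__(self, position: int) -> bool:
        return position in self.mapping

    def __getitem__(self, position: int) -> int:
        return self.mapping[position]


class UnmappableError(ValueError):
    """Sequence cannot be mapped onto the structure; ``reason`` is one of
    {'gap', 'identity', 'length'}."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _convert_residue(res) -> Optional[Residue]:
    """Bio.PDB residue -> internal Residue, or None if filtered out."""
    hetflag, resseq, icode = res.id
    resname = res.resname.strip()
    if hetflag == "W":
        return None
    if hetflag.startswith("H_"):
        if resname in MODIFIED_RESIDUES:
            resname = MODIFIED_RESIDUES[resname]
        else:
            logger.debug("dropping non-polymer het group %s %s", resname, resseq)
            return None
    elif resname in MODIFIED_RESIDUES:
        resname = MODIFIED_RESIDUES[resname]
    if resname not in THREE_TO_ONE:
        warnings.warn(f"dropping residue {res.resname} {resseq}: no canonical parent")
        return None
    atoms = []
    for atom in res:
        if atom.is_disordered():
            alts = atom.disordered_get_list()
            atom = max(alts, key=lambda a: a.get_occupancy() or 0.0)
        element = (atom.element or "").upper()
        if element in ("H", "D"):
            continue
        radius = VDW_RADII.get(element)
        if radius is None:
            warnings.warn(f"unknown element {element!r} for atom {atom.get_name()}; "
                          f"using carbon van der Waals radius")
            radius = DEFAULT_VDW_RADIUS
        x, y, z = (float(v) for v in atom.coord)
        atoms.append(Atom(atom.get_name(), element, (x, y, z), radius))
    if not atoms:
        return None
    return Residue(resname, 0, int(resseq), icode.strip() or "", tuple(atoms))


def parse_pdb_text(text: str, chain: str, structure_id: str = "struct") -> StructureModel:
    """Parse PDB-format text and return the requested chain only.

    Altloc variants resolve to the highest-occupancy copy (ties: first
    encountered); hydrogens, waters and unmapped het groups are excluded;
    only the first model of a multi-model file is read.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(structure_id, io.StringIO(text))
    model = next(structure.get_models())
    if chain not in model:
        raise FormatError(f"chain not found: {chain!r}")
    residues: list[Residue] = []
    for res in model[chain]:
        converted = _convert_residue(res)
        if converted is None:
            continue
        if converted.ca is None:
            warnings.warn(f"dropping residue {converted.resname} "
                          f"{converted.author_number}: no C-alpha atom")
            continue
        residues.append(Residue(converted.resname, len(residues) + 1,
                                converted.author_number, converted.icode,
                                converted.atoms))
    if not residues:
        raise FormatError("empty structure: no residues with a C-alpha atom")
    resolution = structure.header.get("resolution")
    return StructureModel(structure_id, chain, residues, resolution)


def read_pdb(path, chain: str) -> StructureModel:
    """Read one chain of a PDB file; see :func:`parse_pdb_text`."""
    with open(path) as fh:
        text = fh.read()
    return parse_pdb_text(text, chain, structure_id=str(path))


def write_pdb(struct: StructureModel) -> str:
    """Render a StructureModel back to fixed-column PDB text."""
    lines = []
    serial = 0
    for res in struct.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # PDB atom-name column convention: element right-justified in 13-14
            if len(atom.element) == 1 and len(name) < 4:
                name = f" {name:<3s}"
            else:
                name = f"{name:<4s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.resname:>3s} "
                f"{struct.chain_id:1s}{res.author_number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Mutation table
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ("protein_id", "chain_id", "position", "wt", "mut")


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a tab-delimited mutation table.

    Required header: protein_id, chain_id, position, wt, mut; an optional
    trailing ``label`` column holds {disease, neutral}.  Malformed rows are
    reported with their 1-based row numbers.
    """
    records: list[MutationRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:5]) != MUTATION_COLUMNS:
            raise FormatError(f"bad mutation-table header {header!r}; "
                              f"expected {MUTATION_COLUMNS} [+ label]")
        has_label = len(header) > 5 and header[5] == "label"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 5:
                    raise ValueError(f"expected >= 5 fields, got {len(parts)}")
                label = parts[5] if has_label and len(parts) > 5 and parts[5] else None
                records.append(MutationRecord(parts[0], parts[1], int(parts[2]),
                                              parts[3], parts[4], label))
            except ValueError as exc:
                errors.append(f"row {lineno}: {exc}")
    if errors:
        raise FormatError("invalid mutation table:\n" + "\n".join(errors))
    return records


def write_mutation_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MUTATION_COLUMNS + ("label",)) + "\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.chain_id}\t{r.position}\t{r.wt}\t{r.mut}"
                     f"\t{r.label or ''}\n")


# ---------------------------------------------------------------------------
# Alignments, ontology, annotations
# ---------------------------------------------------------------------------

def read_alignment(path, query_index: int = 0) -> MultipleAlignment:
    """Read an aligned FASTA; the query row defaults to the first record."""
    with open(path) as fh:
        recs = list(SeqIO.parse(fh, "fasta"))
    if not recs:
        raise FormatError("empty alignment file")
    return MultipleAlignment([r.id for r in recs],
                             [str(r.seq).upper() for r in recs], query_index)


def write_alignment(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def read_obo_lite(path) -> OntologyDag:
    """Read a minimal OBO 1.2 file (id, name, namespace, is_a stanza fields)."""
    graph = obonet.read_obo(str(path))
    declared = {n for n, d in graph.nodes(data=True) if d}
    undeclared = set(graph.nodes) - declared
    if undeclared:
        raise FormatError(f"is_a edge to undeclared term(s): {sorted(undeclared)}")
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError("ontology contains a cycle")
    parents = {n: tuple(sorted(graph.nodes[n].get("is_a", []))) for n in graph.nodes}
    namespace = {n: graph.nodes[n].get("namespace", "") for n in graph.nodes}
    return OntologyDag(parents, namespace)


def write_obo_lite(dag: OntologyDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: sap3d-fixture\n")
        for term in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            if dag.namespace.get(term):
                fh.write(f"namespace: {dag.namespace[term]}\n")
            for parent in dag.parents[term]:
                fh.write(f"is_a: {parent}\n")


def read_annotations(path, ontology: OntologyDag) -> AnnotationSet:
    """Read a two-column TSV (protein_id, term); every term must exist in the
    ontology."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "term"]:
            raise FormatError(f"bad annotation header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"row {lineno}: expected 2 fields")
            pid, term = parts[0], parts[1]
            if term not in ontology:
                raise FormatError(f"row {lineno}: unknown term {term!r}")
            direct.setdefault(pid, set()).add(term)
    return AnnotationSet({p: frozenset(ts) for p, ts in direct.items()})


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm\n")
        for pid in sorted(annotations.direct):
            for term in sorted(annotations.direct[pid]):
                fh.write(f"{pid}\t{term}\n")


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Sequence -> structure mapping
# ---------------------------------------------------------------------------

MIN_MAPPED_BLOCK = 40


def _diagnose_rejection(seq: str, struct_seq: str) -> str:
    """Classify why no qualifying block exists: gap / identity / length."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(seq, struct_seq)[0]
    seg_a, seg_b = aln.aligned
    if len(seg_a) > 1:
        return "gap"
    (a0, a1), (b0, b1) = seg_a[0], seg_b[0]
    if any(seq[a0 + k] != struct_seq[b0 + k] for k in range(a1 - a0)):
        return "identity"
    return "length"


def map_sequence_to_structure(seq: str, struct: StructureModel,
                              protein_id: str = "", min_block: int = MIN_MAPPED_BLOCK
                              ) -> SeqStructMapping:
    """Best local ungapped correspondence between a protein sequence and the
    structure's residue sequence.

    Accepts only a gapless, 100%-identical block of at least *min_block*
    residues (the longest common block); otherwise raises
    :class:`UnmappableError` carrying the failed criterion.
    """
    if not seq:
        raise ValueError("empty sequence")
    struct_seq = struct.sequence
    match = SequenceMatcher(None, seq, struct_seq, autojunk=False).find_longest_match(
        0, len(seq), 0, len(struct_seq))
    if match.size >= min_block:
        mapping = {match.a + k + 1: match.b + k + 1 for k in range(match.size)}
        return SeqStructMapping(protein_id, struct.chain_id, mapping, match.size)
    reason = _diagnose_rejection(seq, struct_seq)
    raise UnmappableError(reason, f"unmappable: longest exact block is "
                                  f"{match.size} < {min_block} (reason: {reason})")
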