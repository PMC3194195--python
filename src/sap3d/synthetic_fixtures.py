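"""Synthetic input generator with controllable planted signals.

Generates every input the pipeline consumes — toy protein structures (ideal
helices or compact self-avoiding globules with full PDB text), multiple
alignments with per-column conservation, a random tree ontology with
annotations, and labeled mutation sets — so the full pipeline is buildable
and testable offline.

Planted contrasts mirror the statistical structure of real mutation data:
disease mutations preferentially buried (a configurable mean RSA gap between
classes), optional GO-term enrichment among disease proteins, optional
conservation gap at disease sites, and an optional Cys-Cys lost-contact bias.
Burial is measured with the pipeline's own solvent-accessibility code so
planted effects are in the units the classifier consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._residues import AA1
from .io_formats import (AnnotationSet, Atom, MultipleAlignment, MutationRecord,
                         OntologyDag, Residue, StructureModel, write_alignment,
                         write_annotations, write_fasta, write_mutation_table,
                         write_obo_lite, write_pdb)
from ._residues import ONE_TO_THREE
from .structure_features import compute_sasa, structure_rsa

CA_DISTANCE = 3.8          # consecutive C-alpha spacing, angstrom
HELIX_RISE = 1.5           # angstrom per residue
HELIX_TWIST = 100.0        # degrees per residue
HELIX_RADIUS = 2.3         # C-alpha helix radius, angstrom
RESIDUE_VOLUME = 134.0     # angstrom^3 per residue for globule sizing


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Effect sizes: ``delta_rsa`` is the planted mean RSA gap (percent) between
    neutral and disease mutation sites; ``rsa_class_spread`` the within-class
    standard deviation of the targeted RSA; ``go_odds`` the odds multiplier
    for a marked GO term among disease proteins; ``conservation_gap`` the
    column-conservation difference between disease and neutral sites;
    ``contact_bias`` the fraction of disease mutations planted at cysteines
    with a cysteine shell partner.
    """

    seed: int
    n_proteins: int = 200
    n_residues: int = 100
    n_mutations_per_class: int = 500
    delta_rsa: float = 20.0
    rsa_class_spread: float = 10.0
    conservation_gap: float = 0.0
    go_odds: float = 1.0
    contact_bias: float = 0.0
    n_alignment_rows: int = 50
    geometry: str = "compact-globule"
    n_go_terms: int = 40
    sasa_points: int = 960

    def __post_init__(self):
        for name in ("delta_rsa", "rsa_class_spread", "conservation_gap",
                     "go_odds", "contact_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.geometry not in ("helix", "compact-globule"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _helix_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack([HELIX_RADIUS * np.cos(theta),
                            HELIX_RADIUS * np.sin(theta),
                            HELIX_RISE * i])


def _globule_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk confined to a sphere sized for native-like
    packing density; the radius is relaxed if the walk jams."""
    radius = (3.0 * n * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    min_sep = 3.4
    for _ in range(50):  # confinement relaxation attempts
        pos = np.empty((n, 3))
        pos[0] = rng.uniform(-radius / 3, radius / 3, 3)
        ok = True
        i = 1
        backtracks = 0
        while i < n:
            placed = False
            for _try in range(150):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = pos[i - 1] + CA_DISTANCE * direction
                if np.linalg.norm(cand) > radius:
                    continue
                if i > 1 and (np.linalg.norm(pos[:i - 1] - cand, axis=1)
                              < min_sep).any():
                    continue
                pos[i] = cand
                placed = True
                break
            if placed:
                i += 1
            else:
                backtracks += 1
                if backtracks > 5 * n or i <= 1:
                    ok = False
                    break
                i -= 1  # step back and retry
        if ok:
            return pos
        radius *= 1.1
    raise RuntimeError("globule walk failed to place all residues")


def _residue_atoms(ca: np.ndarray, t_in: np.ndarray, t_out: np.ndarray,
                   one_letter: str) -> list[tuple[str, str, np.ndarray]]:
    """Plausible backbone + CB positions around one C-alpha."""
    def unit(v):
        norm = np.linalg.norm(v)
        return v / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    t_in, t_out = unit(t_in), unit(t_out)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(t_out, ref)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    p = unit(np.cross(t_out, ref))
    q = unit(np.cross(t_out, p))
    atoms = [("N", "N", ca - 1.46 * t_in),
             ("CA", "C", ca),
             ("C", "C", ca + 1.52 * t_out),
             ("O", "O", ca + 1.52 * t_out + 1.23 * p)]
    if one_letter != "G":
        atoms.append(("CB", "C", ca - 0.8 * t_out + 1.3 * q))
    return atoms


def make_structure(n_residues: int, geometry: str = "helix", seed: int = 0,
                   sequence: Optional[str] = None,
                   structure_id: str = "FIX") -> tuple[StructureModel, str]:
    """A toy single-chain structure and its PDB text; deterministic in seed."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        trace = _helix_trace(n_residues)
    elif geometry == "compact-globule":
        trace = _globule_trace(n_residues, rng)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if sequence is None:
        sequence = "".join(rng.choice(list(AA1), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    residues = []
    for i in range(n_residues):
        t_out = (trace[i + 1] - trace[i]) if i + 1 < n_residues \
            else (trace[i] - trace[i - 1]) if n_residues > 1 \
            else np.array([1.0, 0.0, 0.0])
        t_in = (trace[i] - trace[i - 1]) if i > 0 else t_out
        atoms = tuple(
            Atom(name, element, tuple(np.round(coord, 3)), _vdw(element))
            for name, element, coord in _residue_atoms(trace[i], t_in, t_out,
                                                       sequence[i]))
        residues.append(Residue(ONE_TO_THREE[sequence[i]], i + 1, i + 1, "",
                                atoms))
    struct = StructureModel(structure_id, "A", residues)
    return struct, write_pdb(struct)


def _vdw(element: str) -> float:
    from ._residues import DEFAULT_VDW_RADIUS, VDW_RADII
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def make_alignment(query: str, n_rows: int, conservation,
                   seed: int = 0, gap_prob: float = 0.03,
                   query_id: str = "query") -> MultipleAlignment:
    """Column-wise sampled alignment: with probability = conservation a row
    keeps the query residue, otherwise it draws uniformly from all 20 types
    (so a conservation-0 column carries the query residue at the 1/20 base
    rate and a conservation-1 column is invariant); non-query rows carry
    occasional gaps.  The query is the first row."""
    rng = np.random.default_rng(seed)
    cons = np.broadcast_to(np.asarray(conservation, dtype=float), (len(query),))
    rows = [query]
    for r in range(n_rows - 1):
        row = []
        for c, q in enumerate(query):
            u = rng.random()
            if u < gap_prob:
                row.append("-")
            elif rng.random() < cons[c]:
                row.append(q)
            else:
                row.append(AA1[rng.integers(20)])
        rows.append("".join(row))
    ids = [query_id] + [f"homolog_{r + 1}" for r in range(n_rows - 1)]
    return MultipleAlignment(ids, rows, 0)


# ---------------------------------------------------------------------------
# Ontology world
# ---------------------------------------------------------------------------

def make_go_world(n_terms: int, n_proteins: int, enrichment_odds: float,
                  seed: int = 0, disease_proteins: Optional[set] = None,
                  protein_ids: Optional[list[str]] = None,
                  base_rate: float = 0.15
                  ) -> tuple[OntologyDag, AnnotationSet, str]:
    """Random tree ontology plus per-protein annotations.

    A marked term is annotated to disease-destined proteins with its base
    odds multiplied by *enrichment_odds*; odds of 1 gives the null case.
    Returns (ontology, annotations, marked term id).
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    parents = {terms[0]: ()}
    for i in range(1, n_terms):
        parents[terms[i]] = (terms[int(rng.integers(0, i))],)
    namespace = {t: "molecular_function" for t in terms}
    dag = OntologyDag(parents, namespace)

    marked = terms[min(3, n_terms - 1)]
    if protein_ids is None:
        protein_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    disease_proteins = disease_proteins or set()
    base_odds = base_rate / (1.0 - base_rate)
    p_marked_disease = (base_odds * enrichment_odds) / (1.0 + base_odds * enrichment_odds)
    direct: dict[str, frozenset] = {}
    for pid in protein_ids:
        n_direct = int(rng.integers(1, 4))
        chosen = set(rng.choice(terms, size=n_direct, replace=False))
        p_marked = p_marked_disease if pid in disease_proteins else base_rate
        if rng.random() < p_marked:
            chosen.add(marked)
        else:
            chosen.discard(marked)
        direct[pid] = frozenset(chosen)
    return dag, AnnotationSet(direct), marked


# ---------------------------------------------------------------------------
# Full labeled dataset
# ---------------------------------------------------------------------------

@dataclass
class FixtureWorld:
    """All generated artifacts for one synthetic study, plus the ground-truth
    manifest of planted parameters."""

    config: FixtureConfig
    records: list[MutationRecord]
    sequences: dict[str, str]
    structures: dict[str, StructureModel]
    pdb_texts: dict[str, str]
    alignments: dict[str, MultipleAlignment]
    ontology: OntologyDag
    annotations: AnnotationSet
    marked_term: str
    protein_class: dict[str, str]
    rsa_by_protein: dict[str, np.ndarray]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict:
        """Write every artifact as plain text and return the manifest
        (including per-file sha256 checksums)."""
        out = Path(out_dir)
        (out / "pdb").mkdir(parents=True, exist_ok=True)
        (out / "alignments").mkdir(exist_ok=True)
        write_mutation_table(self.records, out / "mutations.tsv")
        write_fasta(self.sequences, out / "sequences.fasta")
        write_obo_lite(self.ontology, out / "ontology.obo")
        write_annotations(self.annotations, out / "annotations.tsv")
        for pid, text in self.pdb_texts.items():
            (out / "pdb" / f"{pid}.pdb").write_text(text)
        for pid, aln in self.alignments.items():
            write_alignment(aln, out / "alignments" / f"{pid}.fasta")
        checksums = {}
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                checksums[str(path.relative_to(out))] = hashlib.sha256(
                    path.read_bytes()).hexdigest()
        manifest = dict(self.manifest, checksums=checksums)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _plant_cys_pairs(trace_seq: list[str], struct: StructureModel,
                     rng: np.random.Generator, max_pairs: int = 3) -> list[int]:
    """Set spatially close residue pairs to cysteine; returns the planted
    1-based positions (each guaranteed a CYS shell partner)."""
    coords = np.array([r.ca.coord for r in struct.residues])
    n = len(coords)
    close = []
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        for j in range(i + 3, n):
            if d[j] < 5.5:
                close.append((i, j))
    rng.shuffle(close)
    used: set[int] = set()
    planted = []
    for i, j in close:
        if len(planted) // 2 >= max_pairs:
            break
        if i in used or j in used:
            continue
        used.update((i, j))
        trace_seq[i] = "C"
        trace_seq[j] = "C"
        planted.extend((i + 1, j + 1))
    return planted


def make_labeled_dataset(config: FixtureConfig) -> FixtureWorld:
    """Generate the full synthetic study described by *config*."""
    root = np.random.SeedSequence(config.seed)
    s_struct, s_mut, s_aln, s_go, s_misc = root.spawn(5)
    rng = np.random.default_rng(s_misc)

    protein_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    classes = np.array(["disease", "neutral"])[
        (np.arange(config.n_proteins) % 2)]
    rng.shuffle(classes)
    protein_class = dict(zip(protein_ids, classes))

    structures: dict[str, StructureModel] = {}
    pdb_texts: dict[str, str] = {}
    sequences: dict[str, str] = {}
    cys_sites: dict[str, list[int]] = {}
    struct_seeds = s_struct.spawn(config.n_proteins)
    for pid, child in zip(protein_ids, struct_seeds):
        srng = np.random.default_rng(child)
        seed_int = int(srng.integers(2 ** 31))
        seq_list = list(srng.choice(list(AA1), size=config.n_residues))
        struct, _ = make_structure(config.n_residues, config.geometry,
                                   seed=seed_int, sequence="".join(seq_list),
                                   structure_id=pid)
        planted: list[int] = []
        if config.contact_bias > 0 and protein_class[pid] == "disease":
            planted = _plant_cys_pairs(seq_list, struct, srng)
            struct, _ = make_structure(config.n_residues, config.geometry,
                                       seed=seed_int, sequence="".join(seq_list),
                                       structure_id=pid)
        text = write_pdb(struct)
        structures[pid] = struct
        pdb_texts[pid] = text
        sequences[pid] = "".join(seq_list)
        cys_sites[pid] = planted

    rsa_by_protein = {
        pid: structure_rsa(s, compute_sasa(s, n_points=config.sasa_points))
        for pid, s in structures.items()}
    pool_mean = float(np.mean(np.concatenate(list(rsa_by_protein.values()))))

    mrng = np.random.default_rng(s_mut)
    records: list[MutationRecord] = []
    used_positions: dict[str, set[int]] = {pid: set() for pid in protein_ids}
    site_conservation: dict[str, dict[int, float]] = {pid: {} for pid in protein_ids}

    for label in ("disease", "neutral"):
        candidates = [p for p in protein_ids if protein_class[p] == label]
        target_mean = pool_mean + (config.delta_rsa / 2.0
                                   if label == "neutral" else -config.delta_rsa / 2.0)
        for m in range(config.n_mutations_per_class):
            pid = candidates[m % len(candidates)]
            seq = sequences[pid]
            position = None
            if (label == "disease" and config.contact_bias > 0
                    and mrng.random() < config.contact_bias):
                free = [p for p in cys_sites[pid] if p not in used_positions[pid]]
                if free:
                    position = free[int(mrng.integers(len(free)))]
            if position is None:
                target = float(np.clip(mrng.normal(target_mean,
                                                   config.rsa_class_spread),
                                       0.0, 100.0))
                rsa = rsa_by_protein[pid]
                free_mask = np.ones(len(rsa), bool)
                for u in used_positions[pid]:
                    free_mask[u - 1] = False
                free_idx = np.where(free_mask)[0]
                position = int(free_idx[np.argmin(np.abs(rsa[free_idx] - target))]) + 1
            used_positions[pid].add(position)
            wt = seq[position - 1]
            mut = [a for a in AA1 if a != wt][int(mrng.integers(19))]
            records.append(MutationRecord(pid, "A", position, wt, mut, label))
            if config.conservation_gap > 0:
                level = 0.5 + (config.conservation_gap / 2.0
                               if label == "disease" else -config.conservation_gap / 2.0)
                site_conservation[pid][position] = float(np.clip(level, 0.0, 1.0))

    alignments: dict[str, MultipleAlignment] = {}
    aln_seeds = s_aln.spawn(config.n_proteins)
    for pid, child in zip(protein_ids, aln_seeds):
        arng = np.random.default_rng(child)
        cons = arng.uniform(0.2, 0.9, size=config.n_residues)
        for pos, level in site_conservation[pid].items():
            cons[pos - 1] = level
        alignments[pid] = make_alignment(sequences[pid], config.n_alignment_rows,
                                         cons, seed=int(arng.integers(2 ** 31)),
                                         query_id=pid)

    disease_proteins = {p for p, c in protein_class.items() if c == "disease"}
    ontology, annotations, marked = make_go_world(
        config.n_go_terms, config.n_proteins, config.go_odds,
        seed=int(np.random.default_rng(s_go).integers(2 ** 31)),
        disease_proteins=disease_proteins, protein_ids=protein_ids)

    y = np.array([1 if r.label == "disease" else 0 for r in records])
    site_rsa = np.array([rsa_by_protein[r.protein_id][r.position - 1]
                         for r in records])
    manifest = dict(asdict(config),
                    marked_term=marked,
                    realized_rsa_mean_disease=float(site_rsa[y == 1].mean()),
                    realized_rsa_mean_neutral=float(site_rsa[y == 0].mean()),
                    n_records=len(records))
    return FixtureWorld(config, records, sequences, structures, pdb_texts,
                        alignments, ontology, annotations, marked,
                        protein_class, rsa_by_protein, manifest)
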