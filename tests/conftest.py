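"""Shared fixtures: hand-built toy structures and a small synthetic world."""

import numpy as np
import pytest

from sap3d._residues import ONE_TO_THREE, VDW_RADII, DEFAULT_VDW_RADIUS
from sap3d.io_formats import Atom, Residue, StructureModel
from sap3d.synthetic_fixtures import FixtureConfig, make_labeled_dataset


def build_structure(residue_specs, chain_id="A", structure_id="toy"):
    """StructureModel from [(one_letter, [(atom_name, element, (x,y,z)), ...])]."""
    residues = []
    for ordinal, (one, atoms) in enumerate(residue_specs, start=1):
        atom_objs = tuple(
            Atom(name, element, tuple(float(c) for c in coord),
                 VDW_RADII.get(element, DEFAULT_VDW_RADIUS))
            for name, element, coord in atoms)
        residues.append(Residue(ONE_TO_THREE[one], ordinal, ordinal, "",
                                atom_objs))
    return StructureModel(structure_id, chain_id, residues)


@pytest.fixture
def toy_shell_structure():
    """Center GLY at origin; one GLY neighbor inside a 6 A shell, one LYS
    far outside it."""
    return build_structure([
        ("G", [("CA", "C", (3.0, 0.0, 0.0))]),
        ("A", [("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (1.0, 1.0, 0.0))]),
        ("K", [("CA", "C", (10.0, 0.0, 0.0)), ("CB", "C", (10.0, 1.0, 0.0))]),
    ])


@pytest.fixture(scope="session")
def small_world():
    """A compact labeled synthetic study shared across protocol tests:
    40 proteins x 80 residues, 200 mutations, planted RSA gap of 15."""
    config = FixtureConfig(seed=7, n_proteins=40, n_residues=80,
                           n_mutations_per_class=100, delta_rsa=15.0,
                           n_alignment_rows=20)
    return make_labeled_dataset(config)


@pytest.fixture(scope="session")
def small_world_features(small_world):
    from sap3d.model_eval import extract_feature_table
    w = small_world
    return extract_feature_table(w.records, w.sequences, w.structures,
                                 w.alignments, None, "3d",
                                 rsa_cache=w.rsa_by_protein)


def brute_force_shell(struct, ordinal, radius):
    """Independent all-pairs scan for shell residue membership."""
    ca = np.asarray(struct.residue_by_ordinal(ordinal).ca.coord)
    partners = []
    for res in struct.residues:
        if res.ordinal == ordinal:
            continue
        if any(np.linalg.norm(np.asarray(a.coord) - ca) <= radius
               for a in res.atoms):
            partners.append(res.one_letter)
    return partners
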