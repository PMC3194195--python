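"""Structural environment of a mutated residue.

The environment is a 21-element block: a histogram of residue types having at
least one heavy atom within a 6 A shell of the mutated residue's C-alpha,
plus the residue's relative solvent accessible area (RSA, percent).  Solvent
accessibility is computed by Shrake-Rupley quadrature (probe 1.4 A, 960
quasi-uniform points per atom by default) and normalised by the Rost-Sander
maximum-ASA constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._residues import AA_INDEX, MAX_ASA, N_RESIDUE_TYPES, THREE_TO_ONE
from .io_formats import StructureModel

DEFAULT_SHELL_RADIUS = 6.0   # angstrom, around the mutated residue's C-alpha
DEFAULT_PROBE_RADIUS = 1.4   # angstrom, water probe
DEFAULT_SASA_POINTS = 960    # quadrature points per atom


@dataclass
class StructureEnvironment:
    """Shell residue-type counts (fixed canonical order) + RSA percent."""

    counts: np.ndarray  # (20,) non-negative ints
    rsa: float          # percent in [0, 100]

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.counts.astype(float), [self.rsa]])


@dataclass
class SasaResult:
    """Per-residue absolute solvent accessible area, indexed by ordinal - 1."""

    residue_asa: np.ndarray  # (n_residues,) angstrom^2
    probe_radius: float
    n_points: int

    def asa(self, ordinal: int) -> float:
        return float(self.residue_asa[ordinal - 1])


@dataclass
class ContactPartners:
    """Residue types inside the shell of a center residue (with multiplicity)."""

    center: str            # one-letter code of the mutated (center) residue
    partners: list[str]    # one-letter codes


def _shell_ordinals(struct: StructureModel, residue_ordinal: int,
                    radius: float) -> np.ndarray:
    center = struct.residue_by_ordinal(residue_ordinal)
    ca = center.ca
    if ca is None:
        raise ValueError(f"no C-alpha in residue ordinal {residue_ordinal}")
    coords, owner, _ = struct.atom_arrays()
    d = np.linalg.norm(coords - np.asarray(ca.coord), axis=1)
    hit = np.unique(owner[(d <= radius)])
    return hit[hit != residue_ordinal]


def shell_residue_counts(struct: StructureModel, residue_ordinal: int,
                         radius: float = DEFAULT_SHELL_RADIUS) -> np.ndarray:
    """Histogram (canonical order, length 20) of residue types with at least
    one heavy atom within *radius* of the center residue's C-alpha; the
    center residue itself is excluded."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    counts = np.zeros(N_RESIDUE_TYPES, dtype=int)
    for ordinal in _shell_ordinals(struct, residue_ordinal, radius):
        counts[AA_INDEX[struct.residues[ordinal - 1].one_letter]] += 1
    return counts


def contact_partners(struct: StructureModel, residue_ordinal: int,
                     radius: float = DEFAULT_SHELL_RADIUS) -> ContactPartners:
    """Shell partner residue types (same shell rule as shell_residue_counts)."""
    center = struct.residue_by_ordinal(residue_ordinal)
    partners = [struct.residues[o - 1].one_letter
                for o in _shell_ordinals(struct, residue_ordinal, radius)]
    return ContactPartners(center.one_letter, partners)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-spiral construction."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def atom_sasa(coords: np.ndarray, vdw_radii: np.ndarray,
              probe: float = DEFAULT_PROBE_RADIUS,
              n_points: int = DEFAULT_SASA_POINTS) -> np.ndarray:
    """Shrake-Rupley accessible area per atom (angstrom^2).

    For each atom, the fraction of quadrature points on its expanded sphere
    (r_vdw + probe) lying outside every other atom's expanded sphere, times
    the expanded-sphere area.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    n = len(coords)
    sphere = fibonacci_sphere(n_points)
    expanded = vdw_radii + probe
    pairwise = cdist(coords, coords)
    areas = np.empty(n)
    for i in range(n):
        # only atoms whose expanded spheres can reach atom i's test points
        neighbors = np.where((pairwise[i] < expanded[i] + expanded) &
                             (np.arange(n) != i))[0]
        points = coords[i] + expanded[i] * sphere
        if neighbors.size:
            d2 = cdist(points, coords[neighbors], "sqeuclidean")
            buried = (d2 < expanded[neighbors] ** 2).any(axis=1)
            exposed_fraction = 1.0 - buried.mean()
        else:
            exposed_fraction = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed_fraction
    return areas


def compute_sasa(struct: StructureModel, probe: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_SASA_POINTS) -> SasaResult:
    """Per-residue solvent accessible surface area of the whole chain."""
    coords, owner, radii = struct.atom_arrays()
    if coords.size == 0:
        raise ValueError("empty structure")
    per_atom = atom_sasa(coords, radii, probe, n_points)
    residue_asa = np.zeros(len(struct.residues))
    np.add.at(residue_asa, owner - 1, per_atom)
    return SasaResult(residue_asa, probe, n_points)


def read_accessibility_tsv(path, struct: StructureModel) -> SasaResult:
    """Import precomputed per-residue absolute ASA (chain, ordinal, asa TSV),
    e.g. from a DSSP run, in place of the internal quadrature."""
    residue_asa = np.full(len(struct.residues), np.nan)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chain", "ordinal", "asa"]:
            raise ValueError(f"bad accessibility header {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0] != struct.chain_id:
                continue
            residue_asa[int(parts[1]) - 1] = float(parts[2])
    if np.isnan(residue_asa).any():
        warnings.warn("accessibility file misses residues; missing ASA set to 0")
        residue_asa = np.nan_to_num(residue_asa)
    return SasaResult(residue_asa, np.nan, 0)


def relative_sasa(asa: float, residue_type: str) -> float:
    """RSA percent: 100 * asa / max_asa(type), clipped to [0, 100]."""
    if asa < 0:
        raise ValueError("asa must be non-negative")
    one = THREE_TO_ONE.get(residue_type, residue_type)
    if one not in MAX_ASA:
        raise ValueError(f"unknown residue type {residue_type!r}")
    return float(np.clip(100.0 * asa / MAX_ASA[one], 0.0, 100.0))


def structure_rsa(struct: StructureModel, sasa: SasaResult) -> np.ndarray:
    """RSA percent for every residue of the chain (by ordinal - 1)."""
    return np.array([relative_sasa(sasa.asa(r.ordinal), r.one_letter)
                     for r in struct.residues])


def structure_environment(struct: StructureModel, residue_ordinal: int,
                          sasa: SasaResult,
                          radius: float = DEFAULT_SHELL_RADIUS) -> StructureEnvironment:
    """The full 21-element structural environment of one residue."""
    counts = shell_residue_counts(struct, residue_ordinal, radius)
    residue = struct.residue_by_ordinal(residue_ordinal)
    rsa = relative_sasa(sasa.asa(residue_ordinal), residue.one_letter)
    return StructureEnvironment(counts, rsa)
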