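"""Extended Shrake-Rupley surface engine.

The classic Shrake-Rupley algorithm samples near-equidistant points on each
atom's expanded sphere (vdW radius + probe) and discards points falling
inside any neighboring expanded sphere; SASA is the count of surviving
points times the area each represents. The extension implemented here keeps
the discarded points and records, for every buried point, the *full set* of
atoms whose expanded spheres contain it (its occluder group). Surface
patches shared by several occluders are then attributed fractionally: a
patch buried jointly by a group G contributes ``area / |G|`` to the contact
surface with each member of G. This avoids the double counting that makes
differential-SASA interface estimates deviate from the true contact area.

Key identity (occluder scope = all atoms): for every atom A,

    SASA(A) + sum_B CSA(A, B) = 4 * pi * (r_A + probe)**2

exactly in point-count arithmetic, because each of the ``count`` lattice
points contributes weight 1, either as accessible or split across its
occluder group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    DEFAULT_POINTS,
    DEFAULT_PROBE,
    Atom,
    NeighborIndex,
    UnitSphereLattice,
    build_neighbor_index,
    generate_sphere_points,
)

logger = logging.getLogger(__name__)

#: Occluder scopes for point classification.
SCOPE_ALL = "all"
SCOPE_CROSS = "cross-object-only"

MODE_NAMES = {
    0: "sasa",
    1: "intermolecular-csa",
    2: "intramolecular-residue",
    3: "intramolecular-atom",
    4: "intermolecular-csa-buried",
}


class InvalidStateError(RuntimeError):
    """Raised when an operation's preconditions on objects/modes are unmet."""


@dataclass
class OccluderGroupTable:
    """Per-atom map from distinct occluding-atom sets to buried point counts.

    ``groups`` maps a canonical occluder set (tuple of atom serials in
    ascending order, never containing the owner, never empty) to the number
    of lattice points of the owner buried by exactly that set of atoms.
    """

    owner: int
    groups: dict[tuple[int, ...], int]
    accessible_points: int
    total_points: int

    def buried_points(self) -> int:
        return sum(self.groups.values())


def atom_label(atom: Atom) -> str:
    """Atom-granularity label: ``chain/resname resnum[icode]/atomname``."""
    return f"{residue_label(atom)}/{atom.name}"


def residue_label(atom: Atom) -> str:
    """Residue-granularity label: ``chain/resname resnum[icode]``."""
    return f"{atom.chain}/{atom.residue_name} {atom.residue_number}{atom.insertion_code}"


@dataclass
class ContactMatrix:
    """Rectangular table of contact surface areas in A^2.

    Entry (i, j) is the area of row-atom i's expanded sphere attributed to
    column atom j. The matrix is asymmetric by construction: CSA(A, B)
    lives on A's sphere, CSA(B, A) on B's.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    granularity: str  # "atom" | "residue"
    mode: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label counts")

    def total(self) -> float:
        return float(self.values.sum())

    def entry(self, row_label: str, col_label: str) -> float:
        return float(self.values[self.row_labels.index(row_label),
                                 self.col_labels.index(col_label)])


@dataclass
class SurfaceResult:
    """Everything one run of the engine produced."""

    atoms: list[Atom]
    sasa: np.ndarray
    bsa: np.ndarray | None = None
    matrices: dict[str, ContactMatrix] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def total_sasa(self) -> float:
        return float(self.sasa.sum())


def classify_points(atom: Atom, neighbors: Sequence[Atom],
                    lattice: UnitSphereLattice,
                    probe: float = DEFAULT_PROBE) -> OccluderGroupTable:
    """Classify every lattice point of ``atom`` against its neighbors.

    Each point sits at ``pos(atom) + (r + probe) * direction`` and is tested
    against every neighbor's expanded sphere with a closed inequality
    (points exactly on an occluder's surface count as buried). A point's
    occluder group is the full set of neighbors containing it; one point may
    belong to several atoms' volumes at once.
    """
    n = lattice.count
    if not neighbors:
        return OccluderGroupTable(atom.serial, {}, n, n)
    nb = sorted(neighbors, key=lambda a: a.serial)
    pts = atom.position + atom.expanded_radius(probe) * lattice.directions
    centers = np.array([b.position for b in nb])
    rad2 = np.array([b.expanded_radius(probe) for b in nb]) ** 2
    # (k, n) occlusion mask; k neighbors are few, n points are many
    d2 = ((pts[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    occ = d2 <= rad2[:, None]
    buried = occ.any(axis=0)
    groups: dict[tuple[int, ...], int] = {}
    nburied = int(buried.sum())
    if nburied:
        serials = np.array([b.serial for b in nb])
        uniq, counts = np.unique(occ[:, buried], axis=1, return_counts=True)
        for m in range(uniq.shape[1]):
            key = tuple(int(s) for s in serials[uniq[:, m]])
            groups[key] = int(counts[m])
    return OccluderGroupTable(atom.serial, groups, n - nburied, n)


def build_group_tables(atoms: Sequence[Atom], lattice: UnitSphereLattice,
                       probe: float = DEFAULT_PROBE,
                       occluder_scope: str = SCOPE_ALL,
                       index: NeighborIndex | None = None,
                       ) -> list[OccluderGroupTable]:
    """Occluder-group tables for every atom under the given scope.

    ``occluder_scope="all"`` tests each atom's points against every
    overlapping atom; ``"cross-object-only"`` only against atoms of *other*
    objects, so contact surfaces need not be solvent accessible (deep
    cavities keep their full contact area).
    """
    atoms = list(atoms)
    if occluder_scope not in (SCOPE_ALL, SCOPE_CROSS):
        raise ValueError(f"unknown occluder scope {occluder_scope!r}")
    if occluder_scope == SCOPE_CROSS and len({a.object_id for a in atoms}) < 2:
        raise InvalidStateError(
            "cross-object-only occluder scope requires at least two objects")
    _check_coincident(atoms)
    if index is None:
        index = build_neighbor_index(atoms, probe)
    tables = []
    for i, atom in enumerate(atoms):
        nb = [atoms[j] for j in index.neighbors_of(i)]
        if occluder_scope == SCOPE_CROSS:
            nb = [b for b in nb if b.object_id != atom.object_id]
        tables.append(classify_points(atom, nb, lattice, probe))
    return tables


def _check_coincident(atoms: Sequence[Atom]) -> None:
    seen: dict[tuple[float, float, float], int] = {}
    for a in atoms:
        key = tuple(round(float(x), 6) for x in a.position)
        if key in seen:
            logger.warning("atoms %d and %d have coincident centers; keeping both",
                           seen[key], a.serial)
        else:
            seen[key] = a.serial


def _sasa_from_tables(atoms: Sequence[Atom], tables: Sequence[OccluderGroupTable],
                      lattice: UnitSphereLattice, probe: float) -> np.ndarray:
    out = np.empty(len(atoms))
    for i, (a, t) in enumerate(zip(atoms, tables)):
        out[i] = t.accessible_points * lattice.point_weight * a.expanded_radius(probe) ** 2
    return out


def compute_sasa(atoms: Sequence[Atom], lattice: UnitSphereLattice | None = None,
                 probe: float = DEFAULT_PROBE) -> np.ndarray:
    """Per-atom solvent accessible surface area in A^2 (file order)."""
    atoms = list(atoms)
    if lattice is None:
        lattice = generate_sphere_points(DEFAULT_POINTS)
    tables = build_group_tables(atoms, lattice, probe, SCOPE_ALL)
    return _sasa_from_tables(atoms, tables, lattice, probe)


def contacts_from_tables(atoms: Sequence[Atom],
                         tables: Sequence[OccluderGroupTable],
                         lattice: UnitSphereLattice, probe: float,
                         mode: str = "") -> ContactMatrix:
    """Fractionally attributed atom-level contact matrix from group tables.

    CSA(A, B) sums, over all occluder groups G of A containing B, the area
    of the patch buried by G divided by |G|.
    """
    atoms = list(atoms)
    idx = {a.serial: i for i, a in enumerate(atoms)}
    values = np.zeros((len(atoms), len(atoms)))
    for i, (a, table) in enumerate(zip(atoms, tables)):
        point_area = lattice.point_weight * a.expanded_radius(probe) ** 2
        for group, count in table.groups.items():
            share = count * point_area / len(group)
            for serial in group:
                values[i, idx[serial]] += share
    labels = [atom_label(a) for a in atoms]
    return ContactMatrix(labels, list(labels), values, "atom", mode)


def compute_contacts(atoms: Sequence[Atom],
                     lattice: UnitSphereLattice | None = None,
                     probe: float = DEFAULT_PROBE,
                     occluder_scope: str = SCOPE_ALL) -> ContactMatrix:
    """Square atom-level contact matrix over all atoms (file order)."""
    atoms = list(atoms)
    if lattice is None:
        lattice = generate_sphere_points(DEFAULT_POINTS)
    tables = build_group_tables(atoms, lattice, probe, occluder_scope)
    return contacts_from_tables(atoms, tables, lattice, probe)


def aggregate_to_residues(matrix: ContactMatrix) -> ContactMatrix:
    """Sum an atom-level matrix into residue-level blocks (exact sums)."""
    if matrix.granularity != "atom":
        raise ValueError("can only aggregate an atom-granularity matrix")

    def collapse(labels: list[str]) -> tuple[list[str], np.ndarray]:
        keys = [lab.rsplit("/", 1)[0] for lab in labels]
        order: list[str] = []
        pos: dict[str, int] = {}
        for k in keys:
            if k not in pos:
                pos[k] = len(order)
                order.append(k)
        return order, np.array([pos[k] for k in keys])

    row_keys, row_map = collapse(matrix.row_labels)
    col_keys, col_map = collapse(matrix.col_labels)
    values = np.zeros((len(row_keys), len(col_keys)))
    np.add.at(values, (row_map[:, None], col_map[None, :]), matrix.values)
    return ContactMatrix(row_keys, col_keys, values, "residue", matrix.mode)


def derive_bsa(matrix: ContactMatrix,
               columns: Iterable[str] | None = None) -> np.ndarray:
    """Buried surface area per row: the sum over (selected) column entries."""
    if columns is None:
        return matrix.values.sum(axis=1)
    cols = [matrix.col_labels.index(c) for c in columns]
    if not cols:
        return np.zeros(len(matrix.row_labels))
    return matrix.values[:, cols].sum(axis=1)


def delta_sasa_csa(atoms: Sequence[Atom],
                   lattice: UnitSphereLattice | None = None,
                   probe: float = DEFAULT_PROBE) -> tuple[np.ndarray, float]:
    """Differential-SASA approximation of the interface area.

    Computes the SASA of each object in isolation and in the complex;
    the per-atom difference (isolated minus complexed) sums to the
    conventional buried-interface estimate. This is the approximation that
    direct contact-surface calculation improves upon: a patch already
    occluded within its own object contributes nothing here even when it is
    also in contact with the partner.
    """
    atoms = list(atoms)
    objects = sorted({a.object_id for a in atoms})
    if len(objects) != 2:
        raise ValueError("delta-SASA interface estimate requires exactly two objects")
    if lattice is None:
        lattice = generate_sphere_points(DEFAULT_POINTS)
    complexed = compute_sasa(atoms, lattice, probe)
    delta = np.empty(len(atoms))
    for obj in objects:
        mask = np.array([a.object_id == obj for a in atoms])
        isolated = compute_sasa([a for a in atoms if a.object_id == obj],
                                lattice, probe)
        delta[mask] = isolated - complexed[mask]
    return delta, float(delta.sum())


def _zero_intra_object(matrix: ContactMatrix, atoms: Sequence[Atom]) -> ContactMatrix:
    obj = np.array([a.object_id for a in atoms])
    cross = obj[:, None] != obj[None, :]
    return ContactMatrix(matrix.row_labels, matrix.col_labels,
                         matrix.values * cross, "atom", matrix.mode)


def run_mode(atoms: Sequence[Atom], mode: int,
             lattice: UnitSphereLattice | None = None,
             probe: float = DEFAULT_PROBE,
             points: int = DEFAULT_POINTS) -> SurfaceResult:
    """Dispatch one of the five operating modes.

    ====  =========================================================
    mode  result
    ====  =========================================================
    0     per-atom SASA only
    1     intermolecular atom + residue CSA matrices (occluders:
          all atoms) and per-atom intermolecular BSA column sums
    2     intramolecular residue contact map
    3     intramolecular atom contact map
    4     intermolecular CSA with cross-object-only occluders, so
          contact surfaces need not be solvent accessible
    ====  =========================================================
    """
    atoms = list(atoms)
    if mode not in MODE_NAMES:
        raise ValueError(f"mode must be 0..4, got {mode}")
    if lattice is None:
        lattice = generate_sphere_points(points)
    params = {"mode": mode, "probe": probe, "points": lattice.count}
    n_objects = len({a.object_id for a in atoms})
    if mode in (1, 4) and n_objects < 2:
        raise InvalidStateError(
            f"mode {mode} needs at least two objects (chains selection or "
            "auto-detected molecule classes); found " + str(n_objects))

    scope = SCOPE_CROSS if mode == 4 else SCOPE_ALL
    tables = build_group_tables(atoms, lattice, probe, SCOPE_ALL)
    sasa = _sasa_from_tables(atoms, tables, lattice, probe)
    result = SurfaceResult(atoms=atoms, sasa=sasa, params=params)
    if mode == 0:
        return result

    if mode == 4:
        cross_tables = build_group_tables(atoms, lattice, probe, SCOPE_CROSS)
        atom_matrix = contacts_from_tables(atoms, cross_tables, lattice, probe,
                                           MODE_NAMES[mode])
    else:
        atom_matrix = contacts_from_tables(atoms, tables, lattice, probe,
                                           MODE_NAMES[mode])
    if mode in (1, 4):
        atom_matrix = _zero_intra_object(atom_matrix, atoms)
        result.matrices["atom"] = atom_matrix
        result.matrices["residue"] = aggregate_to_residues(atom_matrix)
        result.bsa = derive_bsa(atom_matrix)
    elif mode == 3:
        result.matrices["atom"] = atom_matrix
    elif mode == 2:
        result.matrices["residue"] = aggregate_to_residues(atom_matrix)
    return result


def sphere_area(radius: float, probe: float = DEFAULT_PROBE) -> float:
    """Area of an atom's expanded sphere, ``4 pi (r + probe)^2``."""
    return 4.0 * math.pi * (radius + probe) ** 2
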