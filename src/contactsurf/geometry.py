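"""Deterministic sphere-point lattices, atoms and neighbor indexing.

All surface computations in this package sample points on the *expanded
sphere* of an atom: radius = vdW radius + probe radius (1.4 A for water by
default). The lattice of sampling directions is shared by every atom and is
fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Default solvent probe radius in Angstrom (water).
DEFAULT_PROBE = 1.4

#: Default number of sampling points per atom sphere.
DEFAULT_POINTS = 2000

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class Atom:
    """A single atom: the unit of all surface computation.

    ``vdw_radius`` is 0.0 until radii have been assigned from a
    :class:`~contactsurf.radii.RadiiTable`. ``object_id`` groups atoms into
    molecular objects (protein, nucleic acid, ligand, or a user chain
    selection) between which intermolecular surfaces are computed.
    """

    serial: int
    name: str
    element: str
    position: np.ndarray
    vdw_radius: float = 0.0
    chain: str = "A"
    residue_number: int = 1
    insertion_code: str = ""
    residue_name: str = "UNK"
    object_id: int = 0
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""
    sybyl_type: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.residue_number, self.insertion_code, self.residue_name)

    def expanded_radius(self, probe: float) -> float:
        return self.vdw_radius + probe


@dataclass(frozen=True)
class UnitSphereLattice:
    """A deterministic set of near-equidistant unit direction vectors.

    Each direction carries an equal share of solid angle,
    ``point_weight = 4*pi / count`` steradians, so a point on an expanded
    sphere of radius R represents an area of ``point_weight * R**2``.
    """

    directions: np.ndarray = field(repr=False)

    @property
    def count(self) -> int:
        return self.directions.shape[0]

    @property
    def point_weight(self) -> float:
        return 4.0 * math.pi / self.count


def generate_sphere_points(count: int) -> UnitSphereLattice:
    """Generate ``count`` near-equidistant unit vectors on the sphere.

    Uses a golden-section (Fibonacci) spiral: deterministic, works for any
    count, and achieves near-uniform areal density. The azimuthal origin is
    chosen so the lattice maps onto itself under a 180-degree rotation about
    the x axis; geometrically mirror-symmetric atom arrangements therefore
    bury exactly symmetric point sets.

    Parameters
    ----------
    count : int
        Number of points, >= 1.
    """
    if count < 1:
        raise ValueError("point count must be >= 1")
    # k runs symmetrically about 0 so that index i and count-1-i give
    # exactly opposite (z, phi) pairs in floating point.
    k = np.arange(count, dtype=float) - (count - 1) / 2.0
    z = -2.0 * k / count
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * _GOLDEN_ANGLE
    directions = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    directions.setflags(write=False)
    return UnitSphereLattice(directions)


class NeighborIndex:
    """Spatial index answering: which atoms can occlude a given atom?

    Atom B is a neighbor of A iff ``|pos(A) - pos(B)| < (r_A + probe) +
    (r_B + probe)``; only such atoms can bury any of A's surface points.
    Results are returned in ascending-serial order, deterministically.
    """

    def __init__(self, atoms: list[Atom], probe: float = DEFAULT_PROBE):
        if probe < 0:
            raise ValueError("probe radius must be >= 0")
        self._atoms = list(atoms)
        self._probe = probe
        n = len(self._atoms)
        self._positions = np.array([a.position for a in self._atoms]).reshape(n, 3)
        self._expanded = np.array([a.expanded_radius(probe) for a in self._atoms])
        self._order = np.argsort([a.serial for a in self._atoms], kind="stable")
        self._tree = cKDTree(self._positions) if n else None
        self._rmax = float(self._expanded.max()) if n else 0.0

    def __len__(self) -> int:
        return len(self._atoms)

    def neighbors_of(self, i: int) -> list[int]:
        """Indices (into the original atom list) of atoms overlapping atom i."""
        if self._tree is None:
            return []
        pos = self._positions[i]
        cand = self._tree.query_ball_point(pos, self._expanded[i] + self._rmax)
        out = []
        for j in cand:
            if j == i:
                continue
            d = float(np.linalg.norm(pos - self._positions[j]))
            if d < self._expanded[i] + self._expanded[j]:
                out.append(j)
        out.sort(key=lambda j: self._atoms[j].serial)
        return out


def build_neighbor_index(atoms: list[Atom], probe: float = DEFAULT_PROBE) -> NeighborIndex:
    """Build the overlap neighbor index for a radius-assigned atom list."""
    return NeighborIndex(atoms, probe)
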