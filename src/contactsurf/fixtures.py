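"""Synthetic toy systems with analytically known surface areas.

Every quantity stored in ``ToySystem.expected`` comes from closed-form
spherical-cap geometry, never from the surface engine, so these systems
serve as independent oracles for the sampled computation. The fixtures are
geometric, not biochemical: they exercise occlusion topology (shared
patches, crowding, burial) rather than realistic molecular shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import DEFAULT_PROBE, Atom


@dataclass
class ToySystem:
    atoms: list[Atom]
    expected: dict = field(default_factory=dict)
    description: str = ""


def analytic_cap_area(r_a: float, r_b: float, d: float,
                      probe: float = DEFAULT_PROBE) -> tuple[float, float]:
    """Closed-form buried areas for two expanded spheres a distance d apart.

    Returns ``(buried on A, buried on B)``: the area of each expanded
    sphere's surface lying inside the other expanded sphere. For partial
    overlap this is the spherical cap ``2 pi R h`` with cap height
    ``h_A = R_A - (d^2 + R_A^2 - R_B^2) / (2 d)``; tangent-or-separated
    spheres bury nothing, and an engulfed sphere is fully buried.
    """
    if d <= 0:
        raise ValueError("center distance must be > 0")
    R_a, R_b = r_a + probe, r_b + probe
    if d >= R_a + R_b:
        return 0.0, 0.0
    if d + R_a <= R_b:  # A engulfed by B
        return 4.0 * math.pi * R_a ** 2, 0.0
    if d + R_b <= R_a:  # B engulfed by A
        return 0.0, 4.0 * math.pi * R_b ** 2
    h_a = R_a - (d * d + R_a * R_a - R_b * R_b) / (2.0 * d)
    h_b = R_b - (d * d + R_b * R_b - R_a * R_a) / (2.0 * d)
    return 2.0 * math.pi * R_a * h_a, 2.0 * math.pi * R_b * h_b


def _atom(serial, pos, r, chain, resnum, obj, name="C1", resname="UNK") -> Atom:
    return Atom(serial=serial, name=name, element="C", position=np.array(pos, float),
                vdw_radius=r, chain=chain, residue_number=resnum,
                residue_name=resname, object_id=obj)


#: Default axis for two-sphere fixtures: a rational unit vector in general
#: position, so the cap boundary is not aligned with any symmetry of the
#: sampling lattice (an axis-aligned pair would see coherent, paired
#: quantization errors instead of independent ones).
_GENERIC_AXIS = np.array([2.0, 3.0, 6.0]) / 7.0


def make_two_sphere(r_a: float = 1.6, r_b: float = 1.6, d: float = 3.0,
                    probe: float = DEFAULT_PROBE,
                    axis: np.ndarray | None = None) -> ToySystem:
    """Two overlapping atoms in separate objects: the basic cap oracle."""
    buried_a, buried_b = analytic_cap_area(r_a, r_b, d, probe)
    u = _GENERIC_AXIS if axis is None else np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    atoms = [
        _atom(1, (0.0, 0.0, 0.0), r_a, "A", 1, 0),
        _atom(2, d * u, r_b, "B", 2, 1),
    ]
    return ToySystem(atoms, expected={
        "buried_a": buried_a, "buried_b": buried_b,
        "sasa_a": 4.0 * math.pi * (r_a + probe) ** 2 - buried_a,
        "sasa_b": 4.0 * math.pi * (r_b + probe) ** 2 - buried_b,
    }, description=f"two spheres r={r_a},{r_b} d={d}")


def make_fig1_triple(probe: float = DEFAULT_PROBE) -> ToySystem:
    """Atom A occluded by overlapping atoms B and C (shared-patch case).

    B and C sit mirror-symmetric about the xz plane and overlap each other,
    so A's buried points fall into three occluder groups: {B} only, {C}
    only, and the shared patch {B, C}. The contact surface of A with B is
    then the {B}-only patch plus half the shared patch.
    """
    r = 1.6
    atoms = [
        _atom(1, (0.0, 0.0, 0.0), r, "A", 1, 0, name="C1"),
        _atom(2, (2.8, 1.0, 0.0), r, "B", 2, 1, name="C1"),
        _atom(3, (2.8, -1.0, 0.0), r, "B", 3, 1, name="C1"),
    ]
    return ToySystem(atoms, expected={"sphere_area_a": 4.0 * math.pi * (r + probe) ** 2},
                     description="shared-patch triple: A vs overlapping B,C")


def make_crowding_pair(probe: float = DEFAULT_PROBE) -> ToySystem:
    """Crowded two-object interface where differential SASA under-counts.

    Object 1 is a single atom A; object 2 is a tightly overlapping pair
    B, C both in contact with A. Surface points of B (or C) lying inside
    both A and its own-object partner are invisible to a differential-SASA
    estimate (they are buried either way) but are real contact surface,
    attributed fractionally by the direct calculation. The differential
    estimate is therefore strictly smaller than the direct total.
    """
    r = 1.6
    atoms = [
        _atom(1, (0.0, 0.0, 0.0), r, "A", 1, 0),
        _atom(2, (2.8, 0.8, 0.0), r, "B", 2, 1),
        _atom(3, (2.8, -0.8, 0.0), r, "B", 3, 1),
    ]
    return ToySystem(atoms, description="crowded interface: A vs overlapping B,C")


def make_buried_cage(probe: float = DEFAULT_PROBE) -> ToySystem:
    """A ligand-like atom fully enclosed by a cubic cage of receptor atoms.

    The central atom (object 1) has zero SASA in the complex; a
    cross-object-only occluder scope still reports its full contact
    surface, while all-atom occlusion shares the cage atoms' buried patches
    with their cage neighbors.
    """
    r_lig, r_cage, dist = 1.6, 2.0, 4.0
    atoms = [_atom(1, (0.0, 0.0, 0.0), r_lig, "L", 1, 0, resname="LIG")]
    serial = 2
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                v = np.array([sx, sy, sz], float) / math.sqrt(3.0)
                atoms.append(_atom(serial, dist * v, r_cage, "R", serial, 1))
                serial += 1
    return ToySystem(atoms, description="fully buried ligand in an 8-atom cage")


def make_random_cluster(n: int, box: float = 12.0, seed: int = 0,
                        min_separation: float | None = None) -> ToySystem:
    """Reproducible random atom cluster with mixed radii and two objects.

    Coordinates are uniform in a cubic box of edge ``box`` Angstrom; radii
    are drawn from the united-atom table's range. Atoms are split into two
    objects (first half / second half) with chains A and B. An optional
    minimum center separation is enforced by rejection sampling.
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    rng = np.random.default_rng(seed)
    radius_choices = np.array([1.40, 1.50, 1.65, 1.76, 1.87, 1.90])
    positions: list[np.ndarray] = []
    while len(positions) < n:
        p = rng.uniform(0.0, box, size=3)
        if min_separation is not None and any(
                np.linalg.norm(p - q) < min_separation for q in positions):
            continue
        positions.append(p)
    radii = rng.choice(radius_choices, size=n)
    atoms = []
    half = (n + 1) // 2
    for i in range(n):
        obj = 0 if i < half else 1
        atoms.append(_atom(
            serial=i + 1, pos=positions[i], r=float(radii[i]),
            chain="A" if obj == 0 else "B",
            resnum=i // 3 + 1, obj=obj))
    return ToySystem(atoms, description=f"random cluster n={n} seed={seed}")


def make_interleaved_grids(spacing: float = 9.0, n_side: int = 2,
                           offset: float = 3.1) -> ToySystem:
    """Two interleaved sparse grids with no intra-object overlaps.

    Same-object atoms are ``spacing`` apart (beyond any expanded-sphere
    cutoff) while each object-2 atom sits ``offset * sqrt(3)`` from its
    object-1 partner, inside the cutoff. On such a system every occluder
    group is cross-object, so intermolecular BSA must equal differential
    SASA exactly.
    """
    r = 1.7
    atoms = []
    serial = 1
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                base = np.array([ix, iy, iz], float) * spacing
                atoms.append(_atom(serial, base, r, "A", serial, 0))
                serial += 1
                atoms.append(_atom(serial, base + offset, r, "B", serial, 1))
                serial += 1
    return ToySystem(atoms, description="interleaved grids, cross-object overlaps only")


def write_toy_pdb(system: ToySystem, path) -> None:
    """Serialize a toy system as a PDB file for CLI-level tests."""
    from .structure_io import write_pdb_with_bfactor
    write_pdb_with_bfactor(system.atoms, np.zeros(len(system.atoms)), path,
                           remarks=[f"contactsurf fixture: {system.description}"])
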