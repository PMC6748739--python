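"""van der Waals radius tables and radius assignment.

Two tables ship with the package as plain-text data files:

``pdb-united``
    United-atom radii for PDB input (hydrogens implicit in heavy atoms),
    keyed on ``(residue name, atom name)`` with wildcard-residue entries for
    backbone and nucleic-acid atoms and an element-level fallback.

``mol2-typed``
    Explicit-hydrogen radii for Tripos Mol2 input, keyed on the SYBYL atom
    type with an element-level fallback.

Unknown keys never fail: they resolve to the table's fallback radius and a
warning is logged. Custom tables in the same format may be loaded from a
file path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .geometry import DEFAULT_PROBE, Atom

logger = logging.getLogger(__name__)

_RADIUS_RANGE = (0.2, 3.5)

#: Residue names treated as water (excluded from computations by default).
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3", "TIP", "SOL", "SPC"})


@dataclass
class RadiiTable:
    """Named mapping from atom-type keys to vdW radii with a fallback rule."""

    name: str
    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    element_entries: dict[str, float] = field(default_factory=dict)
    fallback_radius: float = 1.80

    def __post_init__(self) -> None:
        lo, hi = _RADIUS_RANGE
        for key, r in list(self.entries.items()) + list(self.element_entries.items()):
            if not (lo < r < hi):
                raise ValueError(f"radius {r} for {key} outside ({lo}, {hi}) A")
        if not (lo < self.fallback_radius < hi):
            raise ValueError("fallback radius outside allowed range")

    def lookup(self, atom: Atom) -> float:
        """Resolve the radius for one atom; never fails.

        For ``pdb-united`` the key is (residue name, atom name), then
        (``*``, atom name), then the element; for ``mol2-typed`` the SYBYL
        type, then the element before the dot. Unknown keys log a warning
        and resolve to :attr:`fallback_radius`.
        """
        if self.name == "mol2-typed":
            key = (atom.sybyl_type or atom.element, "")
            if key in self.entries:
                return self.entries[key]
            elem = (atom.sybyl_type.split(".")[0] if atom.sybyl_type else atom.element)
            r = self.element_entries.get(elem.upper())
            if r is not None:
                return r
        else:
            resn = atom.residue_name.strip().upper()
            name = atom.name.strip().upper()
            for key in ((resn, name), ("*", name)):
                if key in self.entries:
                    return self.entries[key]
            r = self.element_entries.get(atom.element.strip().upper())
            if r is not None:
                return r
        logger.warning(
            "no radius for atom %s %s/%s (element %r, sybyl %r) in table %s; "
            "using fallback %.2f A",
            atom.serial, atom.residue_name, atom.name, atom.element,
            atom.sybyl_type, self.name, self.fallback_radius,
        )
        return self.fallback_radius


def _parse_table(text: str, name: str) -> RadiiTable:
    entries: dict[tuple[str, str], float] = {}
    elements: dict[str, float] = {}
    fallback = 1.80
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] == "FALLBACK" and len(parts) == 2:
                fallback = float(parts[1])
            elif parts[0] == "ELEM" and len(parts) == 3:
                elements[parts[1].upper()] = float(parts[2])
            elif len(parts) == 3:
                entries[(parts[0], parts[1])] = float(parts[2])
            elif len(parts) == 2:  # SYBYL-type style: single key
                entries[(parts[0], "")] = float(parts[1])
            else:
                raise ValueError("unrecognized line format")
        except ValueError as exc:
            raise ValueError(f"radii table {name}, line {lineno}: {exc}") from exc
    return RadiiTable(name=name, entries=entries, element_entries=elements,
                      fallback_radius=fallback)


_BUILTIN = {"pdb-united": "pdb_united.txt", "mol2-typed": "mol2_typed.txt"}


def load_radii_table(name_or_path: str = "pdb-united") -> RadiiTable:
    """Load a built-in table by name, or a custom table from a file path."""
    if name_or_path in _BUILTIN:
        text = resources.files("contactsurf.data").joinpath(
            _BUILTIN[name_or_path]).read_text()
        return _parse_table(text, name_or_path)
    path = Path(name_or_path)
    if not path.is_file():
        raise ValueError(
            f"unknown radii table {name_or_path!r}: not a built-in name "
            f"({', '.join(_BUILTIN)}) and not an existing file")
    return _parse_table(path.read_text(), path.stem)


def assign_radii(atoms: list[Atom], table: RadiiTable,
                 probe: float = DEFAULT_PROBE) -> list[Atom]:
    """Assign a vdW radius to every atom from ``table`` (in place).

    The probe radius is part of the run configuration and is *not* folded
    into ``vdw_radius``; expanded radii are formed at sampling time.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    for atom in atoms:
        atom.vdw_radius = table.lookup(atom)
    return atoms
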