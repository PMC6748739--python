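"""Structure readers (PDB, Tripos Mol2), object detection, and writers.

PDB files are read through gemmi (model 1 only, one atom kept per altloc
group by highest occupancy). Mol2 files are parsed directly from their
@<TRIPOS> sections so SYBYL atom types survive for radius lookup. Output
formats are tab-separated contact/SASA tables and PDB files carrying
per-atom values in the B-factor column for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .engine import ContactMatrix
from .geometry import Atom
from .radii import WATER_RESIDUES

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A structure or matrix file could not be parsed."""


AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
})

NUCLEOTIDES = frozenset({
    "DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I",
})


@dataclass
class Structure:
    """An ordered atom list plus the object partition over it."""

    atoms: list[Atom]
    source_format: str = "pdb"
    # object_id -> (label, molecule class: protein | nucleic | ligand | other)
    objects: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def object_ids(self) -> list[int]:
        return sorted({a.object_id for a in self.atoms})


def molecule_class(residue_name: str, is_hetero: bool) -> str:
    resn = residue_name.strip().upper()
    if resn in AMINO_ACIDS:
        return "protein"
    if resn in NUCLEOTIDES:
        return "nucleic"
    if is_hetero:
        return "ligand"
    return "other"


def read_structure(path: str | Path, format: str | None = None,
                   include_hydrogens: bool | None = None,
                   keep_waters: bool = False) -> Structure:
    """Read a PDB or Mol2 file into a :class:`Structure`.

    ``include_hydrogens=None`` applies the per-format default: hydrogens are
    skipped for PDB input (the united-atom radius set makes them implicit)
    and kept for Mol2 input (whose typed radius set expects them). Waters
    are excluded unless ``keep_waters`` is set.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mol2" if suffix == ".mol2" else "pdb"
    if format not in ("pdb", "mol2"):
        raise ValueError(f"unknown structure format {format!r}")
    if format == "mol2":
        atoms = _read_mol2(path)
        if include_hydrogens is None:
            include_hydrogens = True
    else:
        atoms = _read_pdb(path)
        if include_hydrogens is None:
            include_hydrogens = False
    if not include_hydrogens:
        atoms = [a for a in atoms if a.element.upper() not in ("H", "D")]
    if not keep_waters:
        atoms = [a for a in atoms if a.residue_name.strip().upper() not in WATER_RESIDUES]
    if not atoms:
        raise ParseError(f"{path}: no atoms retained (empty structure?)")
    serials = [a.serial for a in atoms]
    if len(set(serials)) != len(serials):
        logger.warning("%s: duplicate atom serials; renumbering sequentially", path)
        for i, a in enumerate(atoms, start=1):
            a.serial = i
    return Structure(atoms=atoms, source_format=format)


def _read_pdb(path: Path) -> list[Atom]:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no models")
    if len(st) > 1:
        logger.warning("%s: %d models; using model 1 only", path, len(st))
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in _select_altlocs(residue):
                icode = residue.seqid.icode.strip()
                atoms.append(Atom(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    chain=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=icode,
                    residue_name=residue.name,
                    is_hetero=(residue.het_flag == "H"),
                    occupancy=atom.occ,
                    altloc=atom.altloc.strip("\x00 "),
                ))
    return atoms


def _select_altlocs(residue: "gemmi.Residue") -> list["gemmi.Atom"]:
    """Keep one atom per altloc group: highest occupancy, first on tie."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def _read_mol2(path: Path) -> list[Atom]:
    atoms: list[Atom] = []
    section = ""
    n_expected = None
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    mol_line = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            mol_line = 0
            continue
        if not line or line.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_line += 1
            if mol_line == 2:  # counts record: natoms [nbonds ...]
                try:
                    n_expected = int(line.split()[0])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}, line {lineno}: bad counts record") from exc
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(
                    f"{path}, line {lineno}: ATOM record needs >= 6 fields")
            try:
                serial = int(parts[0])
                x, y, z = (float(v) for v in parts[2:5])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            sybyl = parts[5]
            if sybyl.split(".")[0].upper() in ("LP", "DU"):
                continue  # lone pairs / dummies carry no surface
            resnum = int(parts[6]) if len(parts) > 6 else 1
            subst = parts[7] if len(parts) > 7 else "LIG"
            resname = subst.rstrip("0123456789") or subst
            atoms.append(Atom(
                serial=serial,
                name=parts[1],
                element=sybyl.split(".")[0].upper(),
                position=np.array([x, y, z]),
                chain="A",
                residue_number=resnum,
                residue_name=resname,
                is_hetero=False,
                sybyl_type=sybyl,
            ))
    if n_expected is not None and atoms and len(atoms) > n_expected:
        atoms = atoms[:n_expected]
    return atoms


def detect_objects(structure: Structure,
                   user_selection: list[list[str]] | None = None) -> Structure:
    """Partition atoms into molecular objects.

    With ``user_selection`` (a list of chain-name groups, e.g.
    ``[["A", "B"], ["C"]]``) the objects are exactly those groups; atoms in
    unselected chains are dropped so the objects cover all retained atoms.
    Otherwise atoms are classified by residue name into protein, nucleic
    acid and ligand classes, one object per class present.
    """
    if user_selection:
        chains_present = {a.chain for a in structure.atoms}
        flat: list[str] = [c for grp in user_selection for c in grp]
        missing = [c for c in flat if c not in chains_present]
        if missing:
            raise ValueError(f"selection names absent chains: {', '.join(missing)}")
        if len(flat) != len(set(flat)):
            raise ValueError("a chain may appear in only one object selection")
        chain_to_obj = {c: i for i, grp in enumerate(user_selection) for c in grp}
        kept = [a for a in structure.atoms if a.chain in chain_to_obj]
        for a in kept:
            a.object_id = chain_to_obj[a.chain]
        dropped = len(structure.atoms) - len(kept)
        if dropped:
            logger.warning("%d atoms outside the chain selection were dropped", dropped)
        structure.atoms = kept
        structure.objects = {
            i: ("+".join(grp), "selection") for i, grp in enumerate(user_selection)}
        return structure

    classes: list[str] = []
    for a in structure.atoms:
        klass = molecule_class(a.residue_name, a.is_hetero)
        if klass not in classes:
            classes.append(klass)
    class_to_obj = {k: i for i, k in enumerate(sorted(classes))}
    for a in structure.atoms:
        a.object_id = class_to_obj[molecule_class(a.residue_name, a.is_hetero)]
    structure.objects = {i: (k, k) for k, i in class_to_obj.items()}
    return structure


_BFACTOR_CAP = 999.99


def write_pdb_with_bfactor(structure: Structure | list[Atom],
                           values, path: str | Path,
                           remarks: list[str] | None = None) -> None:
    """Write a PDB file with one per-atom value in the B-factor column.

    Values are formatted to the fixed 6-character B-factor field with two
    decimals; values above 999.99 are capped with a warning. Optional
    remark strings become REMARK 99 header lines.
    """
    atoms = structure.atoms if isinstance(structure, Structure) else list(structure)
    values = np.asarray(values, dtype=float)
    if values.shape != (len(atoms),):
        raise ValueError(f"need exactly one value per atom "
                         f"({len(atoms)} atoms, {values.size} values)")
    lines = []
    for text in remarks or []:
        lines.append(f"REMARK  99 {text}"[:80])
    n_capped = 0
    for atom, value in zip(atoms, values):
        if value > _BFACTOR_CAP:
            value = _BFACTOR_CAP
            n_capped += 1
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = atom.position
        lines.append(
            f"{record}{atom.serial % 100000:5d} {name:<4s}{atom.altloc[:1] or '':1s}"
            f"{atom.residue_name:>3s} {atom.chain[:1] or 'A':1s}"
            f"{atom.residue_number % 10000:4d}{atom.insertion_code[:1] or '':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{value:6.2f}"
            f"          {atom.element[:2]:>2s}"
        )
    lines.append("END")
    if n_capped:
        logger.warning("%d B-factor values exceeded %.2f and were capped",
                       n_capped, _BFACTOR_CAP)
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    """Write a contact matrix: first row column labels, first column row labels."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write("\t".join([""] + list(matrix.col_labels)) + "\n")
            for label, row in zip(matrix.row_labels, matrix.values):
                fh.write("\t".join([label] + [f"{v:.4f}" for v in row]) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    """Read back a matrix written by :func:`write_matrix_tsv`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0] != "":
        raise ParseError(f"{path}, line 1: first header cell must be empty")
    col_labels = header[1:]
    row_labels, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(col_labels) + 1:
            raise ParseError(f"{path}, line {lineno}: expected "
                             f"{len(col_labels) + 1} fields, got {len(parts)}")
        row_labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    granularity = "atom" if (col_labels and col_labels[0].count("/") >= 2) else "residue"
    return ContactMatrix(row_labels, col_labels, np.array(rows), granularity)


def write_sasa_tsv(atoms: list[Atom], sasa, path: str | Path) -> None:
    """Per-atom SASA table with a TOTAL footer row."""
    from .engine import atom_label
    sasa = np.asarray(sasa, dtype=float)
    with Path(path).open("w") as fh:
        fh.write("atom\tSASA\n")
        for atom, value in zip(atoms, sasa):
            fh.write(f"{atom_label(atom)}\t{value:.4f}\n")
        fh.write(f"TOTAL\t{sasa.sum():.4f}\n")
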