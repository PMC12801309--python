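"""Core domain types and structure/trajectory I/O.

Internally every coordinate is in nanometres; the PDB/XYZ readers and writers
convert to/from Angstrom at the file boundary.  Residues are 1-based,
trajectory frames 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .geometry import superpose_rmsd as _superpose

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "Trajectory",
    "PDBFormatError",
    "SelectionError",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "select",
    "superpose_rmsd",
]

# Bondi van der Waals radii in nm; overridable per call in read_pdb.
VDW_RADII: dict[str, float] = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "NA": 0.227,
    "K": 0.275,
    "MG": 0.173,
    "ZN": 0.139,
    "FE": 0.194,
}

_ELEMENTS = set(VDW_RADII)


class PDBFormatError(ValueError):
    """Raised for unparseable or internally inconsistent PDB content."""


class SelectionError(ValueError):
    """Raised for a selection expression with an unsupported key."""


@dataclass
class AtomRecord:
    """One atom: identity, residue/chain membership, position (nm), tags."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    formal_charge: int = 0
    vdw_radius: float = 0.17
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if self.element.upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.serial}: unknown element {self.element!r}")

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(
            self, position=self.position.copy(), tags=set(self.tags)
        )


@dataclass
class MolecularStructure:
    """Ordered atoms plus optional bonds and free-form annotations.

    ``annotations`` carries generator-provided ground truth (base pairing,
    terminal/unpaired/quartet residues, CD layer membership, planted pose) so
    analyses never have to re-infer what the generator already knows.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: set[frozenset[int]] = field(default_factory=set)
    title: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        known = set(serials)
        for b in self.bonds:
            if not b <= known:
                raise ValueError(f"bond {set(b)} references unknown serial")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in nm (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    def copy(self) -> "MolecularStructure":
        import copy as _copy

        return MolecularStructure(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            title=self.title,
            annotations=_copy.deepcopy(self.annotations),
        )

    def atom_by_serial(self, serial: int) -> AtomRecord:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial}")

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_index == residue_index
        ]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_index, residue_name) triples."""
        seen: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.residue_name)
            if not seen or seen[-1] != key:
                if key not in seen:
                    seen.append(key)
        return seen


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (nm, ns)."""

    topology: MolecularStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with "
                f"{self.topology.n_atoms} topology atoms"
            )
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length mismatch")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> MolecularStructure:
        s = self.topology.copy()
        s.set_coordinates(self.frames[i])
        return s


# ---------------------------------------------------------------------------
# PDB I/O (fixed-width v3.3 columns; Angstrom on disk, nm in memory)
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        residue_name = line[17:20].strip() or line[17:21].strip()
        chain_id = line[21] if line[21] != " " else "A"
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if altloc not in (" ", "A"):
        raise PDBFormatError(f"line {lineno}: unsupported altloc {altloc!r}")
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention (first alphabetic character)
        stripped = name.lstrip("0123456789")
        element = stripped[:2].upper() if stripped[:2].upper() in _ELEMENTS else stripped[:1].upper()
    charge = 0
    if len(line) >= 80:
        ch = line[78:80].strip()
        if ch:
            try:
                charge = int(ch[::-1]) if ch[-1] in "+-" else int(ch)
            except ValueError as exc:
                raise PDBFormatError(f"line {lineno}: bad charge field {ch!r}") from exc
    try:
        return AtomRecord(
            serial=serial,
            name=name,
            element=element,
            residue_index=residue_index,
            residue_name=residue_name,
            chain_id=chain_id,
            position=np.array([x, y, z]) * 0.1,  # A -> nm
            formal_charge=charge,
            vdw_radius=VDW_RADII.get(element, 0.17),
        )
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: {exc}") from exc


def read_pdb(
    path: Union[str, Path],
    vdw_table: dict[str, float] | None = None,
) -> Union[MolecularStructure, Trajectory]:
    """Read a (multi-model) PDB file.

    A single-model file yields a :class:`MolecularStructure`; MODEL/ENDMDL
    blocks yield a :class:`Trajectory`.  Coordinates are converted A -> nm and
    vdW radii assigned from the Bondi table (or ``vdw_table`` overrides).
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model = False
    title = ""
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if vdw_table and atom.element in vdw_table:
                    atom.vdw_radius = vdw_table[atom.element]
                current.append(atom)
    if current or not models:
        models.append(current)
    models = [m for m in models if m] or [[]]
    if not models[0]:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")

    n0 = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n0:
            raise PDBFormatError(
                f"{path}: model {i + 1} has {len(m)} atoms, expected {n0}"
            )
    structure = MolecularStructure(atoms=models[0], title=title)
    if not saw_model or len(models) == 1:
        return structure
    frames = np.array([[a.position for a in m] for m in models])
    return Trajectory(topology=structure, frames=frames)


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.position * 10.0  # nm -> A
    charge = ""
    if a.formal_charge:
        charge = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id}"
        f"{a.residue_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2.2s}{charge:<2s}"
    )


def write_pdb(obj: Union[MolecularStructure, Trajectory], path: Union[str, Path]) -> Path:
    """Write a structure (single model) or trajectory (MODEL blocks) as PDB."""
    path = Path(path)
    if isinstance(obj, Trajectory):
        topo, frames = obj.topology, obj.frames
    else:
        topo, frames = obj, None
    if topo.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    if topo.n_atoms > 99999:
        raise ValueError("more than 99999 atoms cannot be written in plain PDB")
    lines: list[str] = []
    if topo.title:
        lines.append(f"TITLE     {topo.title}")

    def emit(atoms: Iterable[AtomRecord]) -> None:
        for i, a in enumerate(atoms, start=1):
            lines.append(_format_atom_line(a, i))

    if frames is None:
        emit(topo.atoms)
    else:
        for k in range(frames.shape[0]):
            lines.append(f"MODEL     {k + 1:>4d}")
            snap = [dataclasses.replace(a, position=frames[k, i], tags=set(a.tags))
                    for i, a in enumerate(topo.atoms)]
            emit(snap)
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# XYZ I/O (concatenated frames; Angstrom on disk)
# ---------------------------------------------------------------------------


def read_xyz(path: Union[str, Path]) -> Union[MolecularStructure, Trajectory]:
    """Read a (concatenated-frame) XYZ file into a structure or trajectory."""
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    models: list[list[AtomRecord]] = []
    while pos < len(lines) and lines[pos].strip():
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise PDBFormatError(f"line {pos + 1}: expected atom count") from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise PDBFormatError(f"line {pos + 1}: truncated XYZ frame")
        atoms = []
        for i, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBFormatError(f"line {pos + 3 + i}: malformed XYZ atom line")
            el = parts[0].upper()
            xyz = np.array([float(v) for v in parts[1:4]]) * 0.1
            atoms.append(
                AtomRecord(
                    serial=i + 1, name=parts[0], element=el, residue_index=1,
                    residue_name="UNK", chain_id="A", position=xyz,
                    vdw_radius=VDW_RADII.get(el, 0.17),
                )
            )
        models.append(atoms)
        pos += 2 + n
    if not models:
        raise PDBFormatError(f"{path}: empty XYZ file")
    structure = MolecularStructure(atoms=models[0])
    if len(models) == 1:
        return structure
    return Trajectory(structure, np.array([[a.position for a in m] for m in models]))


def write_xyz(obj: Union[MolecularStructure, Trajectory], path: Union[str, Path]) -> Path:
    path = Path(path)
    if isinstance(obj, Trajectory):
        topo, frames = obj.topology, obj.frames
    else:
        topo, frames = obj, obj.coordinates()[None]
    out = []
    for k in range(frames.shape[0]):
        out.append(str(topo.n_atoms))
        out.append(f"frame {k}")
        for a, xyz in zip(topo.atoms, frames[k] * 10.0):
            out.append(f"{a.element:<2s} {xyz[0]:12.5f} {xyz[1]:12.5f} {xyz[2]:12.5f}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_SELECT_KEYS = {"name", "element", "residue_name", "residue_index", "chain", "tag"}


def _clause_matches(atom: AtomRecord, key: str, value: str) -> bool:
    if key == "name":
        return atom.name in value.split(",")
    if key == "element":
        return atom.element in {v.upper() for v in value.split(",")}
    if key == "residue_name":
        return atom.residue_name in value.split(",")
    if key == "chain":
        return atom.chain_id in value.split(",")
    if key == "tag":
        return any(v in atom.tags for v in value.split(","))
    if key == "residue_index":
        for part in value.split(","):
            if ":" in part:
                lo, hi = part.split(":")
                if int(lo) <= atom.residue_index <= int(hi):
                    return True
            elif atom.residue_index == int(part):
                return True
        return False
    raise SelectionError(f"unknown selection key {key!r}")


def select(structure: MolecularStructure, query: str = "") -> list[AtomRecord]:
    """Select atoms by a conjunction of ``key=value`` clauses.

    Supported keys: ``name``, ``element``, ``residue_name``, ``residue_index``
    (single values, comma lists, or ``lo:hi`` ranges), ``chain``, ``tag``.
    An empty query selects every atom, in input order.

    >>> select(s, "element=P chain=A residue_index=2:11")
    """
    clauses: list[tuple[str, str]] = []
    for token in query.split():
        if token.lower() == "and":
            continue
        if "=" not in token:
            raise SelectionError(f"clause {token!r} is not key=value")
        key, value = token.split("=", 1)
        if key not in _SELECT_KEYS:
            raise SelectionError(f"unknown selection key {key!r}")
        clauses.append((key, value))
    return [
        a
        for a in structure.atoms
        if all(_clause_matches(a, k, v) for k, v in clauses)
    ]


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of two equal-length coordinate sets (nm).

    Returns ``(rotation, translation, rmsd)`` with the minimum RMSD over all
    proper rigid transforms of ``mobile``.
    """
    return _superpose(mobile, reference, weights)
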