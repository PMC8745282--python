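"""Structures, ensembles, PDB input/output and atom selection.

The in-memory model is deliberately small: a :class:`Structure` is a
columnar table of atoms (names, residue identity, chain, Cartesian
coordinates in Å), and an :class:`Ensemble` is an ordered list of
structures sharing identical atom identity, with per-frame provenance.
Coordinates use the membrane convention adopted throughout the package:
the membrane normal is +Z and the membrane plane is XY.

Chains of a tetrameric channel are cyclically ordered A→B→C→D; the
neighbor of chain *n* in the "n−1" sense is the previous letter with
wrap-around (n−1 of A is D), which is the convention used for naming
inter-chain distances such as ``d46a36d``.

PDB reading and writing implement the fixed-column ATOM/HETATM dialect
directly so that malformed records fail loudly with a line number and the
emitted dialect is exactly controlled (no MODEL records for single-frame
files, TER between chains, END terminator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    EmptySelectionError,
    PDBFormatError,
    PDBParseError,
    PairingError,
)

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "Selection",
    "read_pdb",
    "write_pdb",
    "select",
    "next_chain",
    "prev_chain",
]


@dataclass
class Atom:
    """One atom record (coordinates in Å, B-factor in Å²)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be a finite 3-vector")


class Structure:
    """Ordered atom collection for one model.

    Atom data are stored columnar (NumPy arrays / lists) for speed; the
    :attr:`atoms` property materializes :class:`Atom` views on demand.
    The triple (chain, resid, name) is unique within a model.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: Sequence[str],
        element: Sequence[str],
        resname: Sequence[str],
        resid: np.ndarray,
        chain: Sequence[str],
        coords: np.ndarray,
        occupancy: np.ndarray | None = None,
        bfactor: np.ndarray | None = None,
        het: np.ndarray | None = None,
        model_id: int = 1,
    ):
        n = len(name)
        self.serial = np.asarray(serial, dtype=int)
        self.name = list(name)
        self.element = list(element)
        self.resname = list(resname)
        self.resid = np.asarray(resid, dtype=int)
        self.chain = list(chain)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.occupancy = (
            np.asarray(occupancy, dtype=float) if occupancy is not None else np.ones(n)
        )
        self.bfactor = (
            np.asarray(bfactor, dtype=float) if bfactor is not None else np.zeros(n)
        )
        self.het = np.asarray(het, dtype=bool) if het is not None else np.zeros(n, bool)
        self.model_id = int(model_id)
        self._res_index: dict[tuple[str, int], np.ndarray] | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[Atom], model_id: int = 1) -> "Structure":
        atoms = list(atoms)
        if not atoms:
            raise EmptyInputError("cannot build a Structure from zero atoms")
        return cls(
            serial=np.array([a.serial for a in atoms]),
            name=[a.name for a in atoms],
            element=[a.element for a in atoms],
            resname=[a.resname for a in atoms],
            resid=np.array([a.resid for a in atoms]),
            chain=[a.chain for a in atoms],
            coords=np.array([a.xyz for a in atoms], dtype=float),
            occupancy=np.array([a.occupancy for a in atoms]),
            bfactor=np.array([a.bfactor for a in atoms]),
            het=np.array([a.het for a in atoms]),
            model_id=model_id,
        )

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(),
            list(self.name),
            list(self.element),
            list(self.resname),
            self.resid.copy(),
            list(self.chain),
            self.coords.copy(),
            self.occupancy.copy(),
            self.bfactor.copy(),
            self.het.copy(),
            self.model_id,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Light copy sharing every column except the coordinates.

        Used by generators and integrators that produce many frames over a
        fixed atom template.
        """
        s = Structure.__new__(Structure)
        s.serial = self.serial
        s.name = self.name
        s.element = self.element
        s.resname = self.resname
        s.resid = self.resid
        s.chain = self.chain
        s.coords = np.asarray(coords, dtype=float).reshape(self.natoms, 3)
        s.occupancy = self.occupancy
        s.bfactor = self.bfactor
        s.het = self.het
        s.model_id = self.model_id
        s._res_index = self._res_index
        return s

    # -- basic queries ----------------------------------------------------

    @property
    def natoms(self) -> int:
        return len(self.name)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in first-appearance order (protein atoms first)."""
        seen: dict[str, None] = {}
        for c, h in zip(self.chain, self.het):
            if not h and c not in seen:
                seen[c] = None
        for c in self.chain:  # chains that are purely HETATM come last
            if c not in seen:
                seen[c] = None
        return list(seen)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                int(self.serial[i]),
                self.name[i],
                self.element[i],
                self.resname[i],
                int(self.resid[i]),
                self.chain[i],
                self.coords[i].copy(),
                float(self.occupancy[i]),
                float(self.bfactor[i]),
                bool(self.het[i]),
            )
            for i in range(self.natoms)
        ]

    def residue_indices(self, chain: str, resid: int) -> np.ndarray:
        """Atom indices of one residue (protein atoms only), cached."""
        if self._res_index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i in range(self.natoms):
                if not self.het[i]:
                    idx.setdefault((self.chain[i], int(self.resid[i])), []).append(i)
            self._res_index = {k: np.array(v) for k, v in idx.items()}
        try:
            return self._res_index[(chain, resid)]
        except KeyError:
            raise EmptySelectionError(f"no residue {resid} in chain {chain}")

    def same_atoms(self, other: "Structure") -> bool:
        return (
            self.natoms == other.natoms
            and self.name == other.name
            and self.chain == other.chain
            and bool(np.all(self.resid == other.resid))
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<Structure model={self.model_id} atoms={self.natoms} chains={''.join(self.chains)}>"


class Ensemble:
    """Ordered list of atom-matched structures with per-frame provenance.

    ``provenance[i]`` is a ``(replica, excitation, frame)`` triple; free-form
    metadata (e.g. generator ground truth) lives in :attr:`metadata`.
    """

    def __init__(
        self,
        frames: Sequence[Structure],
        provenance: Sequence[tuple] | None = None,
        metadata: dict | None = None,
    ):
        self.frames = list(frames)
        if not self.frames:
            raise EmptyInputError("an Ensemble needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not f.same_atoms(first):
                raise PairingError("all ensemble frames must share atom identity")
        if provenance is None:
            provenance = [(0, 0, i) for i in range(len(self.frames))]
        self.provenance = list(provenance)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# chain cyclic arithmetic
# ---------------------------------------------------------------------------

def next_chain(chain: str, order: Sequence[str] = "ABCD") -> str:
    """Chain n+1 in the cyclic tetramer order (n+1 of D is A)."""
    order = list(order)
    return order[(order.index(chain) + 1) % len(order)]


def prev_chain(chain: str, order: Sequence[str] = "ABCD") -> str:
    """Chain n−1 in the cyclic tetramer order (n−1 of A is D)."""
    order = list(order)
    return order[(order.index(chain) - 1) % len(order)]


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    """Atom selection: chain filter, inclusive resid interval, atom names.

    ``heavy_only`` removes hydrogens; HETATM records (ions, waters) are
    excluded unless ``include_het`` is set, because all the channel analyses
    are protein-only.
    """

    chain: str | Sequence[str] | None = None
    resid_range: tuple[int, int] | None = None
    names: Sequence[str] | None = None
    heavy_only: bool = True
    include_het: bool = False

    def __post_init__(self):
        if self.resid_range is not None:
            lo, hi = self.resid_range
            if lo > hi:
                raise ValueError(f"resid interval start {lo} > end {hi}")


def select(structure: Structure, sel: Selection) -> np.ndarray:
    """Resolve a :class:`Selection` to atom indices in original order."""
    if structure.natoms == 0:
        raise EmptyInputError("empty structure")
    mask = np.ones(structure.natoms, dtype=bool)
    if not sel.include_het:
        mask &= ~structure.het
    if sel.chain is not None:
        chains = {sel.chain} if isinstance(sel.chain, str) else set(sel.chain)
        mask &= np.array([c in chains for c in structure.chain])
    if sel.resid_range is not None:
        lo, hi = sel.resid_range
        mask &= (structure.resid >= lo) & (structure.resid <= hi)
    if sel.names is not None:
        names = set(sel.names)
        mask &= np.array([n in names for n in structure.name])
    if sel.heavy_only:
        mask &= np.array([e.upper() != "H" for e in structure.element])
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptySelectionError(f"selection {sel} matched no atoms")
    return idx


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _parse_atom_line(line: str, lineno: int) -> Atom:
    het = line.startswith("HETATM")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}")
    if altloc not in (" ", "A"):
        return None  # deterministic single-conformer model: keep blank or 'A'
    if not element:
        element = _guess_element(name)
    return Atom(serial, name, element, resname, resid, chain, (x, y, z), occ, bfac, het)


def read_pdb(path: str | Path) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble` (one frame per MODEL).

    Files without MODEL records yield a single-frame ensemble.  Alternate
    locations other than blank/'A' are dropped; residue numbering is kept
    exactly as written (1-based KirBac3.1 numbering is never re-indexed).
    """
    path = Path(path)
    frames: list[Structure] = []
    current: list[Atom] = []
    model_ids: list[int] = []
    model_id = 1
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    model_id = int(line.split()[1])
                except (IndexError, ValueError):
                    model_id = len(frames) + 1
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if current:
                    frames.append(Structure.from_atoms(current, model_id))
                    model_ids.append(model_id)
                in_model = False
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    current.append(atom)
    if current:  # trailing atoms outside MODEL/ENDMDL
        frames.append(Structure.from_atoms(current, model_id if in_model else 1))
    if not frames:
        raise EmptyInputError(f"{path}: no atoms found")
    return Ensemble(frames, provenance=[(0, 0, i) for i in range(len(frames))])


def _format_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    xyz: np.ndarray,
    occ: float,
    bfac: float,
    element: str,
    het: bool,
) -> str:
    if resid > 9999 or resid < -999:
        raise PDBFormatError(f"residue number {resid} does not fit PDB columns")
    if serial > 99999:
        serial = serial % 100000
    for v in xyz:
        if not (-999.999 <= v <= 9999.999):
            raise PDBFormatError(f"coordinate {v:.3f} overflows the 8.3 field")
    record = "HETATM" if het else "ATOM  "
    # standard alignment: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record}{serial:5d} {name_field} {resname:>3s} {chain:1s}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bfac:6.2f}"
        f"          {element:>2s}"
    )


def _write_structure(fh, s: Structure) -> None:
    prev_chain_id = None
    last_protein = None
    for i in range(s.natoms):
        if (
            prev_chain_id is not None
            and s.chain[i] != prev_chain_id
            and last_protein is not None
        ):
            fh.write("TER\n")
        fh.write(
            _format_atom_line(
                int(s.serial[i]),
                s.name[i],
                s.resname[i],
                s.chain[i],
                int(s.resid[i]),
                s.coords[i],
                float(s.occupancy[i]),
                float(s.bfactor[i]),
                s.element[i],
                bool(s.het[i]),
            )
            + "\n"
        )
        prev_chain_id = s.chain[i]
        last_protein = i
    fh.write("TER\n")


def write_pdb(obj: Ensemble | Structure, path: str | Path) -> None:
    """Write a structure or ensemble as PDB.

    Single-frame ensembles are written without MODEL records for maximal
    tool interoperability; multi-frame ensembles get one MODEL/ENDMDL block
    per frame.
    """
    if isinstance(obj, Structure):
        obj = Ensemble([obj])
    path = Path(path)
    with open(path, "w") as fh:
        if len(obj) == 1:
            _write_structure(fh, obj[0])
        else:
            for k, frame in enumerate(obj, start=1):
                fh.write(f"MODEL {k:8d}\n")
                _write_structure(fh, frame)
                fh.write("ENDMDL\n")
        fh.write("END\n")
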