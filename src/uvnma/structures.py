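"""Atomic structure model and PDB input/output.

The in-memory model is deliberately small: an ordered list of
:class:`Atom` records plus optional crystallographic metadata
(unit cell, space-group symbol).  Parsing and serialization of the
fixed-width PDB format are delegated to :mod:`gemmi`; this module only
converts between gemmi's hierarchy and the flat model used by the
geometry, elastic-network and lattice analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import gemmi

__all__ = [
    "Atom",
    "Structure",
    "AtomSelection",
    "PDBFormatError",
    "EmptyPairingError",
    "read_pdb",
    "write_pdb",
    "pair_common_atoms",
]


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed or serialized."""


class EmptyPairingError(ValueError):
    """Raised when two structures share no atoms under a selection."""


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``(chain_id, residue_number, insertion_code, name)`` identifies an
    atom uniquely within a :class:`Structure`.
    """

    serial: int
    name: str
    element: str
    residue_number: int
    insertion_code: str
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


@dataclass
class Structure:
    """An ordered collection of atoms with optional cell metadata."""

    atoms: list[Atom] = field(default_factory=list)
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.space_group is not None and self.unit_cell is None:
            raise ValueError("space_group given without unit_cell")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å, in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of the structure with coordinates replaced (same atoms/order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.unit_cell, self.space_group,
                         self.label if label is None else label)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select(self, selection: "AtomSelection") -> "Structure":
        """Subset preserving atom order; cell metadata carried over."""
        atoms = [a for a in self.atoms if selection.matches(a)]
        return Structure(atoms, self.unit_cell, self.space_group, self.label)

    def atom_map(self) -> dict[tuple, Atom]:
        return {a.key: a for a in self.atoms}


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over chain IDs, residue-number ranges and atom names.

    ``None`` for any field means "no restriction".  Residue ranges are
    inclusive ``(first, last)`` pairs.  Applying a selection always
    preserves atom order.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None

    @classmethod
    def make(cls, chains: Iterable[str] | None = None,
             residue_ranges: Iterable[tuple[int, int]] | None = None,
             atom_names: Iterable[str] | None = None) -> "AtomSelection":
        return cls(
            frozenset(chains) if chains is not None else None,
            tuple(tuple(r) for r in residue_ranges) if residue_ranges is not None else None,
            frozenset(atom_names) if atom_names is not None else None,
        )

    @classmethod
    def ca(cls, chains: Iterable[str] | None = None,
           residue_ranges: Iterable[tuple[int, int]] | None = None) -> "AtomSelection":
        """Cα-only selection, optionally restricted to chains/ranges."""
        return cls.make(chains, residue_ranges, atom_names=("CA",))

    @classmethod
    def everything(cls) -> "AtomSelection":
        return cls()

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
                lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges):
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _validate_fixed_width(path) -> None:
    """Reject unparseable ATOM/HETATM records with the offending line.

    gemmi is forgiving about garbage in the coordinate columns; the
    numeric fields are checked here so errors carry a line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: truncated ATOM/HETATM record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBFormatError(
                        f"{path}:{lineno}: unparseable {what} coordinate "
                        f"field {line[lo:hi]!r}") from None


def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    One :class:`Atom` per ATOM/HETATM record; of alternate locations
    only blank or 'A' is kept (deterministic single-conformer model).
    CRYST1, when present, populates ``unit_cell``/``space_group``;
    its absence is not an error.
    """
    _validate_fixed_width(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    unit_cell = None
    space_group = None
    if st.cell.is_crystal():
        c = st.cell
        unit_cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        space_group = st.spacegroup_hm or None
    atoms: list[Atom] = []
    if len(st) == 0:
        return Structure([], unit_cell, space_group, label=str(path))
    model = st[0]  # first model only
    for chain in model:
        for residue in chain:
            for at in residue:
                if at.altloc not in ("", "A", "\0"):
                    continue
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    residue_name=residue.name,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_factor=at.b_iso,
                ))
    return Structure(atoms, unit_cell, space_group, label=str(path))


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.label or "uvnma"
    if structure.unit_cell is not None:
        st.cell = gemmi.UnitCell(*structure.unit_cell)
        if structure.space_group is not None:
            st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    chain_objs: dict[str, gemmi.Chain] = {}
    res_objs: dict[tuple, gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chain_objs.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chain_objs[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chain_objs[a.chain_id] = ch
        rkey = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        res = res_objs.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            res_objs[rkey] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.serial = a.serial
        res.add_atom(at)
    st.add_model(model)
    return st


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-width PDB records (CRYST1 emitted when a cell is set).

    Coordinates must be finite and below 10^4 Å in magnitude (the PDB
    fixed columns cannot represent larger values).
    """
    coords = structure.coords
    if coords.size and not np.all(np.isfinite(coords)):
        raise PDBFormatError("non-finite coordinates cannot be written")
    if coords.size and np.max(np.abs(coords)) >= 1e4:
        raise PDBFormatError("coordinate magnitude >= 10^4 Å does not fit PDB columns")
    st = _to_gemmi(structure)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.cryst1_record = structure.unit_cell is not None
    st.write_pdb(str(path), opts)


def write_multi_model_pdb(structures: Sequence[Structure], path) -> None:
    """Write a MODEL/ENDMDL trajectory (e.g. a mode animation).

    All frames must share the same atoms; cell metadata is taken from
    the first frame.
    """
    if not structures:
        raise ValueError("no frames to write")
    first = structures[0]
    st = _to_gemmi(first)
    for i, frame in enumerate(structures[1:], start=2):
        if len(frame) != len(first):
            raise ValueError(f"frame {i} has {len(frame)} atoms, expected {len(first)}")
        model = _to_gemmi(frame)[0]
        model.num = i
        st.add_model(model)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.cryst1_record = first.unit_cell is not None
    st.write_pdb(str(path), opts)


# ---------------------------------------------------------------------------
# Pairing

def pair_common_atoms(
    a: Structure,
    b: Structure,
    selection: AtomSelection | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Pair atoms present in both structures under a selection.

    Atoms are matched by ``(mapped chain, residue_number, insertion_code,
    atom name)``; ``chain_map`` maps chain IDs of ``a`` onto chain IDs of
    ``b`` (identity by default).  Returns two equal-length (n, 3)
    coordinate arrays, in the atom order of ``a``, plus the list of
    matched atom keys (in ``a``'s labelling).

    This intersection-of-resolved-atoms pairing is the precondition of
    every RMSD between two crystal forms: only residues ordered in both
    models contribute.
    """
    if len(a) == 0 or len(b) == 0:
        raise EmptyPairingError("cannot pair with an empty structure")
    selection = selection or AtomSelection.everything()
    a_sel = [at for at in a.atoms if selection.matches(at)]
    b_map = {at.key: at for at in b.atoms}
    xa, xb, keys = [], [], []
    for at in a_sel:
        ch = chain_map.get(at.chain_id, at.chain_id) if chain_map else at.chain_id
        bkey = (ch, at.residue_number, at.insertion_code, at.name)
        partner = b_map.get(bkey)
        if partner is not None and selection.matches(at):
            xa.append(at.position)
            xb.append(partner.position)
            keys.append(at.key)
    if not keys:
        raise EmptyPairingError("no atoms matched between the two structures")
    return np.array(xa), np.array(xb), keys
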