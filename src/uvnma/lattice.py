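"""Crystal symmetry-mate expansion and inter-mate contact scoring.

Whether a crystal form can accommodate a given quaternary arrangement
is decided here: the asymmetric unit is expanded by the space-group
operators (plus integer lattice translations), nearby symmetry mates
are retained, and the contacts between a probe region (e.g. a
protruding cytoplasmic domain) and each mate are classified with the
same chemistry as :func:`uvnma.geometry.detect_contacts`.  A packing is
"clashing" as soon as one inter-mate heavy-atom pair falls below the
clash threshold.

Space-group operators come from gemmi's space-group table (general
positions including centring); arbitrary groups can be supplied as a
text file of one "x,y,z"-style triplet per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import gemmi
from scipy.spatial import cKDTree

from .geometry import ContactRecord, ContactThresholds, detect_contacts
from .structures import AtomSelection, Structure

__all__ = [
    "SymmetryOperator",
    "LatticeModel",
    "ClashReport",
    "operators_for",
    "expand_mates",
    "lattice_clash_report",
]


@dataclass(frozen=True)
class SymmetryOperator:
    """One space-group operator in fractional coordinates."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,), fractions of the cell

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymmetryOperator":
        den = float(op.DEN)
        return cls(np.array(op.rot, dtype=float) / den,
                   np.array(op.tran, dtype=float) / den)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOperator":
        return cls.from_gemmi(gemmi.Op(triplet))

    @property
    def is_identity(self) -> bool:
        return (np.array_equal(self.rotation, np.eye(3))
                and np.allclose(self.translation % 1.0, 0.0))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.rotation.T + self.translation

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self ∘ other (apply ``other`` first)."""
        return SymmetryOperator(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation)

    def same_modulo_lattice(self, other: "SymmetryOperator",
                            tol: float = 1e-9) -> bool:
        if not np.allclose(self.rotation, other.rotation, atol=tol):
            return False
        dt = (self.translation - other.translation) % 1.0
        dt = np.minimum(dt, 1.0 - dt)
        return bool(np.all(dt < tol))


def operators_for(space_group: str | None = None,
                  operator_file=None) -> list[SymmetryOperator]:
    """General-position operators of a space group.

    Either a Hermann–Mauguin symbol (resolved via gemmi's table;
    centring operations included, e.g. I 21 21 21 → 8 operators) or a
    path to a text file with one x,y,z triplet per line ('#' comments).
    """
    if operator_file is not None:
        ops = []
        with open(operator_file) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    ops.append(SymmetryOperator.from_triplet(line))
        if not ops:
            raise ValueError(f"no operators in {operator_file}")
        return ops
    if space_group is None:
        raise ValueError("give a space-group symbol or an operator file")
    sg = gemmi.find_spacegroup_by_name(space_group)
    if sg is None:
        raise ValueError(f"unknown space-group symbol {space_group!r} "
                         "(supply an operator file instead)")
    return [SymmetryOperator.from_gemmi(op) for op in sg.operations()]


@dataclass
class LatticeModel:
    """A structure with cell metadata plus its symmetry operators."""

    base: Structure
    operators: list[SymmetryOperator] = field(default_factory=list)
    expansion_radius: float = 5.0      # Å from any base atom

    def __post_init__(self):
        if self.base.unit_cell is None:
            raise ValueError("lattice model needs a structure with a unit cell")
        if not self.operators:
            if self.base.space_group is None:
                raise ValueError("no operators and no space group on the structure")
            self.operators = operators_for(self.base.space_group)
        n_id = sum(op.is_identity for op in self.operators)
        if n_id != 1:
            raise ValueError(f"operator set must contain the identity exactly once "
                             f"(found {n_id})")

    @property
    def orth_matrix(self) -> np.ndarray:
        cell = gemmi.UnitCell(*self.base.unit_cell)
        return np.array(cell.orth.mat.tolist())


def expand_mates(model: LatticeModel
                 ) -> list[tuple[Structure, int, tuple[int, int, int]]]:
    """Symmetry mates with any atom within the expansion radius.

    Applies every operator combined with integer cell translations
    (identity + zero shift excluded) and keeps each image whose minimum
    atom distance to the base is at most ``expansion_radius``.  Returns
    (mate structure, operator index, cell shift) triples.
    """
    M = model.orth_matrix
    Minv = np.linalg.inv(M)
    xyz = model.base.coords
    frac = xyz @ Minv.T
    tree = cKDTree(xyz)
    # shift search range per axis: molecule extent + radius, in cells
    cell_len = np.array(model.base.unit_cell[:3])
    extent = xyz.max(axis=0) - xyz.min(axis=0) if len(xyz) else np.zeros(3)
    n_shift = np.ceil((extent + model.expansion_radius) / cell_len).astype(int) + 1
    mates = []
    for op_idx, op in enumerate(model.operators):
        frac_op = op.apply(frac)
        for shift in product(*(range(-n, n + 1) for n in n_shift)):
            if op.is_identity and shift == (0, 0, 0):
                continue
            xyz_mate = (frac_op + np.array(shift)) @ M.T
            lo = xyz_mate.min(axis=0) - model.expansion_radius
            hi = xyz_mate.max(axis=0) + model.expansion_radius
            if np.any(lo > xyz.max(axis=0)) or np.any(hi < xyz.min(axis=0)):
                continue
            dmin, _ = tree.query(xyz_mate, k=1,
                                 distance_upper_bound=model.expansion_radius)
            if np.any(np.isfinite(dmin)):
                mates.append((model.base.with_coords(
                    xyz_mate, label=f"mate:op{op_idx}:{shift}"),
                    op_idx, shift))
    return mates


@dataclass
class ClashReport:
    """Inter-mate contact summary for one packing."""

    counts: dict[str, int]
    n_mates: int
    clashing: bool
    contacts: list[tuple[int, tuple[int, int, int], ContactRecord]]

    @property
    def n_clashes(self) -> int:
        return self.counts.get("clash", 0)


def lattice_clash_report(
    model: LatticeModel,
    probe: AtomSelection | None = None,
    thresholds: ContactThresholds = ContactThresholds(),
) -> ClashReport:
    """Score contacts between a probe region of the base and all mates.

    The verdict is "clashing" iff at least one contact of kind
    ``clash`` exists between the probe atoms of the asymmetric unit and
    any retained symmetry mate.  An empty probe yields an empty,
    non-clashing report.
    """
    probe = probe or AtomSelection.everything()
    probe_sub = model.base.select(probe)
    counts = {"clash": 0, "contact": 0, "hydrogen_bond": 0, "salt_bridge": 0}
    all_contacts = []
    if len(probe_sub) == 0:
        return ClashReport(counts, 0, False, [])
    mates = expand_mates(model)
    for mate, op_idx, shift in mates:
        recs = detect_contacts(model.base, mate, selection_a=probe,
                               thresholds=thresholds)
        for rec in recs:
            counts[rec.kind] = counts.get(rec.kind, 0) + 1
            all_contacts.append((op_idx, shift, rec))
    return ClashReport(counts, len(mates), counts["clash"] >= 1, all_contacts)
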