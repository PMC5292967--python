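"""Least-squares rigid superposition and rotation axis/angle extraction.

The workhorse is the Kabsch solution (reflection excluded, computed via
:func:`scipy.spatial.transform.Rotation.align_vectors`), wrapped in a
:class:`RigidTransform` that also carries the equivalent rotation axis
and angle — the quantities used to describe a receptor monomer moving
as a rigid body between two quaternary arrangements of a complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import AtomSelection, Structure, pair_common_atoms

__all__ = [
    "RigidTransform",
    "DegenerateGeometryError",
    "superpose",
    "rmsd",
    "relative_monomer_rotation",
]


class DegenerateGeometryError(ValueError):
    """Raised when point sets cannot define a unique rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, ``y = R x + t``.

    ``axis``/``angle_deg`` are the equivalent single-axis description
    (angle in [0, 180]°).  When the angle is ~0° or ~180° the axis is
    numerically degenerate and ``axis_degenerate`` is set.
    """

    rotation: np.ndarray          # (3, 3), det = +1
    translation: np.ndarray      # (3,)
    axis: np.ndarray             # unit (3,)
    angle_deg: float
    rmsd_after: float
    axis_degenerate: bool = False

    @classmethod
    def from_rt(cls, rotation: np.ndarray, translation: np.ndarray,
                rmsd_after: float = 0.0) -> "RigidTransform":
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        if abs(np.linalg.det(rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        rotvec = Rotation.from_matrix(rotation).as_rotvec()
        angle = np.linalg.norm(rotvec)
        degenerate = angle < 1e-9 or abs(angle - np.pi) < 1e-9
        axis = rotvec / angle if angle >= 1e-9 else np.array([0.0, 0.0, 1.0])
        return cls(rotation, translation, axis, float(np.degrees(angle)),
                   float(rmsd_after), degenerate)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform.from_rt(rt, -rt @ self.translation, self.rmsd_after)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform.from_rt(self.rotation @ other.rotation,
                                      self.rotation @ other.translation + self.translation)


def _check_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"paired coordinate shapes differ: {a.shape} vs {b.shape}")
    return a, b


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal proper rigid transform carrying ``mobile`` onto ``reference``.

    Kabsch-type least squares with the reflection branch excluded;
    requires at least 3 non-collinear pairs, otherwise the rotation
    about the degenerate direction is undetermined and a
    :class:`DegenerateGeometryError` is raised.
    """
    mobile, reference = _check_pairs(mobile, reference)
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 pairs, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    mc = mobile - cm
    # collinearity: fewer than 2 significant principal directions
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("collinear point configuration")
    rot, _ = Rotation.align_vectors(reference - cr, mc)
    R = rot.as_matrix()
    t = cr - R @ cm
    moved = mobile @ R.T + t
    rms = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return RigidTransform.from_rt(R, t, rms)


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = False) -> float:
    """Root-mean-square deviation between paired coordinates (Å).

    ``fit=True`` superposes ``a`` onto ``b`` first (the usual
    "RMSD after alignment"); ``fit=False`` is the raw deviation.
    """
    a, b = _check_pairs(a, b)
    if len(a) == 0:
        raise ValueError("empty coordinate arrays")
    if fit:
        return superpose(a, b).rmsd_after
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def relative_monomer_rotation(
    complex_a: Structure,
    complex_b: Structure,
    monomer_selection: AtomSelection,
    frame_selection: AtomSelection,
    chain_map: Mapping[str, str] | None = None,
) -> RigidTransform:
    """Rigid motion of one subunit between two conformations of a complex.

    The two complexes are first put in a common frame by superposing
    ``complex_b`` onto ``complex_a`` over ``frame_selection`` (typically
    the transducer transmembrane core, which barely moves); the returned
    transform is the residual rigid motion carrying the
    ``monomer_selection`` atoms of ``a`` onto those of ``b``.  Its
    ``angle_deg`` is the monomer's rigid-body rotation between the two
    quaternary forms.
    """
    fa, fb, _ = pair_common_atoms(complex_a, complex_b, frame_selection, chain_map)
    frame_fit = superpose(fb, fa)          # b -> a frame
    ma, mb, _ = pair_common_atoms(complex_a, complex_b, monomer_selection, chain_map)
    mb_in_frame = frame_fit.apply(mb)
    return superpose(ma, mb_in_frame)
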