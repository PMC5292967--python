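"""Projection of a conformational transition onto normal modes.

Given two conformations U and V of the same set of atoms and a
:class:`~uvnma.enm.ModeSet` computed on U, this module quantifies how
much of the U→V displacement the low-frequency modes explain: the
per-mode overlap |v̂ᵢ·d̂|, the cumulative overlap over the first k
modes, the least-squares best combination of k modes and the RMSD left
after subtracting it, and a per-rigid-group decomposition of any mode
into translation / rotation / internal deformation (with the
translation's piston component along the membrane normal).

Because the modes are orthonormal, explained and residual displacement
are orthogonal and RMSDs satisfy
``rmsd_initial² = rmsd_explained² + rmsd_residual²`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enm import ModeSet
from .geometry import MembraneFrame
from .structures import AtomSelection, Structure, pair_common_atoms
from .superpose import superpose

__all__ = [
    "TransitionReport",
    "ModeCharacter",
    "transition_vector",
    "mode_overlap",
    "best_k_fit",
    "classify_mode",
    "displace_along_modes",
    "mode_trajectory",
]


@dataclass
class TransitionReport:
    """Summary of a transition projected onto a mode basis."""

    displacement: np.ndarray            # 3n vector, Å
    rmsd_initial: float
    per_mode_overlap: np.ndarray        # |cosine| per nonzero mode
    cumulative_overlap: np.ndarray      # monotone, <= 1
    best_k_coefficients: np.ndarray
    rmsd_residual: float
    mode_character: list["ModeCharacter"] = field(default_factory=list)


@dataclass(frozen=True)
class ModeCharacter:
    """Rigid-motion content of one mode restricted to one atom group."""

    group: str
    translation_fraction: float
    rotation_fraction: float
    deformation_fraction: float
    piston_component: float            # translation projection on membrane normal


def transition_vector(
    u: Structure,
    v: Structure,
    selection: AtomSelection | None = None,
    frame_selection: AtomSelection | None = None,
) -> tuple[np.ndarray, float, list[tuple]]:
    """Displacement field U→V after frame superposition.

    ``v`` is superposed onto ``u`` over ``frame_selection`` (default:
    all paired atoms of ``selection``), then the paired coordinate
    difference is returned as a flat 3n vector together with
    ``rmsd_initial = ‖d‖/√n`` and the paired atom keys.
    """
    selection = selection or AtomSelection.ca()
    xu, xv, keys = pair_common_atoms(u, v, selection)
    if frame_selection is None:
        fu, fv = xu, xv
    else:
        fu, fv, _ = pair_common_atoms(u, v, frame_selection)
    fit = superpose(fv, fu)
    xv_aligned = fit.apply(xv)
    disp = (xv_aligned - xu).ravel()
    rmsd_initial = float(np.linalg.norm(disp) / np.sqrt(len(xu)))
    return disp, rmsd_initial, keys


def _nonzero_basis(modes: ModeSet) -> np.ndarray:
    _, vectors = modes.nonzero_modes()
    if vectors.shape[1] == 0:
        raise ValueError("mode set has no nonzero modes")
    return vectors


def mode_overlap(displacement: np.ndarray, modes: ModeSet
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode and cumulative overlap of a displacement with a mode set.

    ``overlap_i = |vᵢ·d| / ‖d‖`` over the nonzero modes (rigid-body
    modes excluded); ``cumulative_k = sqrt(Σ_{i<=k} overlapᵢ²)`` is
    non-decreasing and reaches 1 when the nonzero modes span ``d``.
    """
    d = np.asarray(displacement, dtype=float).ravel()
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("overlap undefined for a zero displacement")
    V = _nonzero_basis(modes)
    per_mode = np.abs(V.T @ d) / norm
    cumulative = np.sqrt(np.minimum(np.cumsum(per_mode ** 2), 1.0 + 1e-12))
    return per_mode, cumulative


def best_k_fit(displacement: np.ndarray, modes: ModeSet, k: int
               ) -> tuple[np.ndarray, float]:
    """Least-squares combination of the k lowest nonzero modes.

    With an orthonormal basis the amplitudes are plain projections
    ``aᵢ = vᵢ·d``; the returned residual is
    ``‖d − Σ aᵢvᵢ‖/√n`` in RMSD units.
    """
    d = np.asarray(displacement, dtype=float).ravel()
    V = _nonzero_basis(modes)
    if k > V.shape[1]:
        raise ValueError(f"k={k} exceeds the {V.shape[1]} available nonzero modes")
    n = len(d) // 3
    if k == 0:
        return np.zeros(0), float(np.linalg.norm(d) / np.sqrt(n))
    Vk = V[:, :k]
    coeffs = Vk.T @ d
    residual = d - Vk @ coeffs
    return coeffs, float(np.linalg.norm(residual) / np.sqrt(n))


def classify_mode(
    mode: np.ndarray,
    coords: np.ndarray,
    groups: dict[str, np.ndarray],
    frame: MembraneFrame,
) -> list[ModeCharacter]:
    """Decompose a mode into per-group rigid translation + rotation.

    For each group (node-index array) the mode's restriction is fitted
    by an infinitesimal rigid field ``t + ω×(r−c)`` about the group
    centroid ``c`` (linear least squares).  Because ``Σ(rᵢ−c)=0`` the
    translation and rotation fields are orthogonal, so the squared-norm
    fractions of translation, rotation and residual (internal
    deformation) sum to 1.  The piston component is ``t·n̂`` with ``n̂``
    the membrane normal (per unit mode amplitude).
    """
    u = np.asarray(mode, dtype=float).reshape(-1, 3)
    coords = np.asarray(coords, dtype=float)
    out = []
    for name, idx in groups.items():
        idx = np.asarray(idx, dtype=int)
        if len(idx) < 3:
            raise ValueError(f"group {name!r} has <3 nodes; rotation fit is underdetermined")
        r = coords[idx]
        ug = u[idx]
        c = r.mean(axis=0)
        rel = r - c
        # least squares for t (3) and omega (3): u_i = t + omega x rel_i
        A = np.zeros((3 * len(idx), 6))
        A[:, :3] = np.tile(np.eye(3), (len(idx), 1))
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            A[:, 3 + ax] = np.cross(e, rel).ravel()
        sol, *_ = np.linalg.lstsq(A, ug.ravel(), rcond=None)
        t, omega = sol[:3], sol[3:]
        trans_field = np.tile(t, (len(idx), 1))
        rot_field = np.cross(omega, rel)
        total = float(np.sum(ug ** 2))
        if total == 0:
            out.append(ModeCharacter(name, 0.0, 0.0, 0.0, 0.0))
            continue
        ft = float(np.sum(trans_field ** 2)) / total
        fr = float(np.sum(rot_field ** 2)) / total
        resid = ug - trans_field - rot_field
        fd = float(np.sum(resid ** 2)) / total
        out.append(ModeCharacter(name, ft, fr, fd, float(t @ frame.normal)))
    return out


def mode_trajectory(
    u: Structure,
    modes: ModeSet,
    coefficients: np.ndarray,
    n_frames: int = 11,
    selection: AtomSelection | None = None,
) -> list[Structure]:
    """Frames interpolating from U along a mode combination.

    Frame i displaces by amplitude i/(n_frames−1); writing the list
    with :func:`uvnma.structures.write_multi_model_pdb` yields a
    standard multi-MODEL animation of the motion.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    return [displace_along_modes(u, modes, coefficients,
                                 amplitude=i / (n_frames - 1),
                                 selection=selection)
            for i in range(n_frames)]


def displace_along_modes(
    u: Structure,
    modes: ModeSet,
    coefficients: np.ndarray,
    amplitude: float = 1.0,
    selection: AtomSelection | None = None,
) -> Structure:
    """Structure obtained by moving U along a mode combination.

    The selected atoms (default: Cα, in structure order — the order the
    ENM nodes were built from) are displaced by
    ``amplitude · Σ aᵢ vᵢ`` over the nonzero modes; all other atoms are
    untouched.  Used to generate V-like models and trajectory frames.
    """
    selection = selection or AtomSelection.ca()
    coefficients = np.asarray(coefficients, dtype=float)
    V = _nonzero_basis(modes)
    if len(coefficients) > V.shape[1]:
        raise ValueError("more coefficients than nonzero modes")
    delta = (V[:, :len(coefficients)] @ coefficients).reshape(-1, 3) * amplitude
    sel_idx = [i for i, a in enumerate(u.atoms) if selection.matches(a)]
    if len(sel_idx) != len(delta):
        raise ValueError(
            f"mode dimension ({len(delta)} nodes) does not match selection "
            f"({len(sel_idx)} atoms)")
    coords = u.coords
    coords[sel_idx] += delta
    return u.with_coords(coords)
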