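"""Helix geometry and contact chemistry.

Measurements behind the signal-transduction picture of a transmembrane
receptor–transducer complex: the axis of a helix and the angle between
two helices (how far the receptor splays between the U and V quaternary
forms), the piston displacement of a transducer helix along the
membrane normal, the rotation of a helix about its own axis, and
distance/geometry-based classification of interfacial contacts
(hydrogen bonds, salt bridges, clashes).

All helix-level measurements operate on Cα coordinates; contact
classification needs all-atom input for the chemical kinds and degrades
gracefully (clash/contact only, with a warning) on Cα-only models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import Atom, AtomSelection, Structure

__all__ = [
    "HelixAxis",
    "MembraneFrame",
    "ContactRecord",
    "IllDefinedAxisError",
    "fit_helix_axis",
    "interhelix_angle",
    "piston_displacement",
    "helix_axial_rotation",
    "detect_contacts",
    "ContactThresholds",
]


class IllDefinedAxisError(ValueError):
    """Raised when Cα scatter has no dominant direction to call an axis."""


@dataclass(frozen=True)
class HelixAxis:
    """Least-squares line through a helix's Cα trace.

    ``direction`` is the dominant principal direction of the
    mean-centred Cα cloud, sign-oriented from the N- toward the
    C-terminus.  ``fit_rms`` is the RMS radial scatter of the Cα atoms
    about the axis line — for an ideal helix this equals the helix
    radius.
    """

    origin: np.ndarray           # centroid, Å
    direction: np.ndarray        # unit vector, N->C
    chain_id: str
    first_residue: int
    last_residue: int
    fit_rms: float


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: unit normal + centre point.

    ``ic_side`` is +1 when ``normal`` points toward the intracellular
    (cytoplasmic) side, -1 otherwise.
    """

    normal: np.ndarray
    center: np.ndarray
    ic_side: int = 1

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.ic_side not in (-1, 1):
            raise ValueError("ic_side must be +1 or -1")

    @property
    def ic_normal(self) -> np.ndarray:
        """Unit vector pointing toward the intracellular side."""
        return self.ic_side * self.normal


def _second_difference_direction(coords: np.ndarray) -> np.ndarray | None:
    """Helix axis direction from second differences of the Cα trace.

    For an ideal helix the second differences p[i-1] − 2p[i] + p[i+1]
    all lie in planes perpendicular to the axis, so consecutive cross
    products are exactly parallel to it.  Exact for noiseless ideal
    helices of any fractional turn count, where plain PCA of the Cα
    cloud is biased by up to ~1°.
    """
    if len(coords) < 5:
        return None
    a = coords[2:] - 2 * coords[1:-1] + coords[:-2]
    cr = np.cross(a[:-1], a[1:])
    total = cr.sum(axis=0)
    norm = np.linalg.norm(total)
    if norm < 1e-10:
        return None
    return total / norm


def _window_centroid_direction(coords: np.ndarray) -> np.ndarray | None:
    """Axis direction from full-turn sliding-window centroids.

    The twist per residue is estimated from the rotation of consecutive
    second-difference vectors; the centroid of a window covering an
    integer number of turns lies exactly on the helix axis, so a line
    through the window centroids is the axis.  Each centroid averages
    ~w atoms, which suppresses coordinate noise far better than any
    per-atom construction.
    """
    n = len(coords)
    if n < 7:
        return None
    a = coords[2:] - 2 * coords[1:-1] + coords[:-2]
    norms = np.linalg.norm(a, axis=1)
    if np.any(norms < 1e-10):
        return None
    cosang = np.sum(a[:-1] * a[1:], axis=1) / (norms[:-1] * norms[1:])
    twist = np.degrees(np.arccos(np.clip(np.mean(cosang), -1.0, 1.0)))
    if twist < 10.0:
        return None
    per_turn = 360.0 / twist
    # window covering as close to an integer number of turns as
    # possible (a full-turn centroid sits exactly on the axis); prefer
    # the widest window among those within 5% of a turn, for noise
    # averaging, while leaving >= 2 centroids
    max_turns = int((n - 2) / per_turn)
    if max_turns < 1:
        return None
    candidates = []
    for k in range(1, max_turns + 1):
        w_k = int(round(k * per_turn))
        if 3 <= w_k <= n - 2:
            candidates.append((abs(w_k - k * per_turn) / per_turn, -k, w_k))
    if not candidates:
        return None
    good = [c for c in candidates if c[0] < 0.05]
    if not good:
        return None     # no near-integer-turn window; caller falls back
    w = min(good, key=lambda c: c[1])[2]
    kernel = np.ones(w) / w
    centroids = np.stack([np.convolve(coords[:, ax], kernel, mode="valid")
                          for ax in range(3)], axis=1)
    rel = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(rel)
    d = vt[0]
    return d / np.linalg.norm(d)


def _circle_center(points2d: np.ndarray) -> np.ndarray:
    """Least-squares (Kåsa) circle centre; exact for points on a circle."""
    A = np.column_stack([2 * points2d, np.ones(len(points2d))])
    b = np.sum(points2d ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def fit_helix_axis(structure: Structure, chain_id: str,
                   residue_range: tuple[int, int]) -> HelixAxis:
    """Fit the axis of one helix from its Cα atoms.

    Requires >= 5 Cα in the range and a dominant principal direction
    (largest/second-largest eigenvalue ratio > 2), otherwise the axis
    is ill-defined.  The direction starts from the dominant principal
    direction and is refined by the second-difference construction
    (exact for ideal helices); the origin is the circle-fit centre of
    the Cα trace in the plane normal to the axis, lifted to the mean
    axial position, so ``fit_rms`` equals the helix radius for an
    ideal helix.
    """
    sel = AtomSelection.ca(chains=[chain_id], residue_ranges=[residue_range])
    sub = structure.select(sel)
    if len(sub) < 5:
        raise IllDefinedAxisError(
            f"need >= 5 Cα in {chain_id}:{residue_range}, got {len(sub)}")
    coords = sub.coords
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] <= 2.0 * evals[1]:
        raise IllDefinedAxisError("no dominant direction (eigenvalue ratio <= 2)")
    direction = evecs[:, 2]
    refined = _window_centroid_direction(coords)
    if refined is None:
        refined = _second_difference_direction(coords)
    if refined is not None and abs(refined @ direction) > 0.9:
        direction = refined * np.sign(refined @ direction)
    # orient N -> C: residue order is ascending residue number
    order = np.argsort([a.residue_number for a in sub.atoms])
    span = coords[order[-1]] - coords[order[0]]
    if span @ direction < 0:
        direction = -direction
    # axis origin: circle-fit centre in the transverse plane
    u = np.linalg.svd(np.outer(direction, direction) - np.eye(3))[0][:, :2]
    center2d = _circle_center(centred @ u)
    origin = centroid + u @ center2d
    radial = (coords - origin) - np.outer((coords - origin) @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(radial ** 2, axis=1))))
    resnums = [a.residue_number for a in sub.atoms]
    return HelixAxis(origin, direction, chain_id, min(resnums), max(resnums), fit_rms)


def interhelix_angle(axis_a: HelixAxis, axis_b: HelixAxis,
                     directed: bool = True) -> float:
    """Angle between two helix axes in degrees.

    Directed mode (default) respects helix polarity (antiparallel
    helices → 180°); undirected mode folds to [0, 90°].
    """
    c = float(np.clip(axis_a.direction @ axis_b.direction, -1.0, 1.0))
    if not directed:
        c = abs(c)
    return float(np.degrees(np.arccos(c)))


def _segment_ca(structure: Structure, chain_id: str,
                residue_range: tuple[int, int]) -> Structure:
    return structure.select(AtomSelection.ca([chain_id], [residue_range]))


def _end_indices(coords: np.ndarray, frame: MembraneFrame, end: str,
                 fraction: float) -> np.ndarray:
    n = len(coords)
    if end == "whole":
        return np.arange(n)
    proj = coords @ frame.ic_normal
    k = max(1, int(round(fraction * n)))
    order = np.argsort(proj)
    if end == "cytoplasmic":
        return order[-k:]
    if end == "extracellular":
        return order[:k]
    raise ValueError(f"unknown end {end!r}")


def piston_displacement(a: Structure, b: Structure, chain_id: str,
                        residue_range: tuple[int, int], frame: MembraneFrame,
                        end: str = "cytoplasmic", end_fraction: float = 0.25) -> float:
    """Signed displacement of a helix segment along the membrane normal (Å).

    Both structures must already sit in a common frame (superpose on a
    reference selection first).  The segment is the Cα centroid of the
    chosen helix end — by default the quarter of residues closest to the
    intracellular side — and the sign is positive toward the IC side.
    """
    ca_a = _segment_ca(a, chain_id, residue_range)
    ca_b = _segment_ca(b, chain_id, residue_range)
    if len(ca_a) == 0 or len(ca_b) == 0:
        raise ValueError(f"empty helix range {chain_id}:{residue_range}")
    common = sorted(set(at.residue_number for at in ca_a.atoms)
                    & set(at.residue_number for at in ca_b.atoms))
    if not common:
        raise ValueError("no shared residues in helix range")
    pa = np.array([at.position for at in ca_a.atoms if at.residue_number in set(common)])
    pb = np.array([at.position for at in ca_b.atoms if at.residue_number in set(common)])
    idx = _end_indices(pa, frame, end, end_fraction)
    delta = pb[idx].mean(axis=0) - pa[idx].mean(axis=0)
    return float(delta @ frame.ic_normal)


def helix_axial_rotation(a: Structure, b: Structure, chain_id: str,
                         residue_range: tuple[int, int],
                         frame: MembraneFrame | None = None) -> float:
    """Rotation of a helix about its own axis between two states (degrees).

    After fitting the helix axis in state ``a``, every shared Cα is
    projected onto the plane normal to that axis (relative to the axis
    line) in both states, and the circular mean of the per-residue
    angular displacements is returned.  The construction is insensitive
    to a piston translation along the axis (axial components are
    projected out), so rotation and piston are recovered independently
    for a screw motion.  Sign follows the right-hand rule about the
    N→C axis direction.
    """
    ca_a = _segment_ca(a, chain_id, residue_range)
    ca_b = _segment_ca(b, chain_id, residue_range)
    common = sorted(set(at.residue_number for at in ca_a.atoms)
                    & set(at.residue_number for at in ca_b.atoms))
    if len(common) < 5:
        raise IllDefinedAxisError("need >= 5 shared residues for axial rotation")
    axis = fit_helix_axis(a, chain_id, residue_range)
    common_set = set(common)
    pa = np.array([at.position for at in ca_a.atoms if at.residue_number in common_set])
    pb = np.array([at.position for at in ca_b.atoms if at.residue_number in common_set])
    d = axis.direction
    ra = pa - axis.origin
    rb = pb - axis.origin
    ra -= np.outer(ra @ d, d)
    rb -= np.outer(rb @ d, d)
    # per-residue signed angle from ra_i to rb_i about d
    cross = np.cross(ra, rb)
    sin_t = cross @ d
    cos_t = np.sum(ra * rb, axis=1)
    angles = np.arctan2(sin_t, cos_t)
    # circular mean, robust to wrap-around
    mean = float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))
    return float(np.degrees(mean))


# ---------------------------------------------------------------------------
# Contact chemistry

@dataclass(frozen=True)
class ContactThresholds:
    """Distance criteria (Å) for contact classification.

    Standard structural-biology values; all configurable.
    """

    hydrogen_bond: float = 3.5
    salt_bridge: float = 4.0
    clash: float = 2.5
    contact: float = 4.5
    min_donor_angle: float = 90.0   # antecedent-donor...acceptor, degrees


@dataclass(frozen=True)
class ContactRecord:
    atom_a: tuple
    atom_b: tuple
    distance: float
    kind: str                      # hydrogen_bond | salt_bridge | clash | contact
    donor_angle: float | None = None


# positively / negatively charged side-chain terminal atoms
_POSITIVE = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

# heavy-atom H-bond donors with their covalent antecedent (for the
# geometric check when hydrogens are absent)
_DONORS = {
    ("*", "N"): "CA",
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB", ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ", ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1", ("CYS", "SG"): "CB",
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}


def _lookup(table, residue_name: str, atom_name: str):
    if (residue_name, atom_name) in table:
        return table[(residue_name, atom_name)] if isinstance(table, dict) else True
    if ("*", atom_name) in table:
        return table[("*", atom_name)] if isinstance(table, dict) else True
    return None if isinstance(table, dict) else False


def _donor_angle(donor: Atom, acceptor: Atom, structure: Structure) -> float | None:
    ante_name = _lookup(_DONORS, donor.residue_name, donor.name)
    if ante_name is None:
        return None
    ante = structure.atom_map().get(
        (donor.chain_id, donor.residue_number, donor.insertion_code, ante_name))
    if ante is None:
        return None
    v1 = ante.position - donor.position
    v2 = acceptor.position - donor.position
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _classify_pair(at_a: Atom, at_b: Atom, dist: float,
                   struct_a: Structure, struct_b: Structure,
                   thresholds: ContactThresholds,
                   chemistry: bool) -> ContactRecord | None:
    if dist > thresholds.contact:
        return None
    if dist < thresholds.clash:
        return ContactRecord(at_a.key, at_b.key, dist, "clash")
    if chemistry:
        ka, kb = (at_a.residue_name, at_a.name), (at_b.residue_name, at_b.name)
        if dist <= thresholds.salt_bridge and (
                (ka in _POSITIVE and kb in _NEGATIVE)
                or (ka in _NEGATIVE and kb in _POSITIVE)):
            return ContactRecord(at_a.key, at_b.key, dist, "salt_bridge")
        if dist <= thresholds.hydrogen_bond:
            for donor, acceptor, sd, sa in ((at_a, at_b, struct_a, struct_b),
                                            (at_b, at_a, struct_b, struct_a)):
                if _lookup(_DONORS, donor.residue_name, donor.name) is None:
                    continue
                if not _lookup(_ACCEPTORS, acceptor.residue_name, acceptor.name):
                    continue
                ang = _donor_angle(donor, acceptor, sd)
                if ang is None or ang >= thresholds.min_donor_angle:
                    return ContactRecord(at_a.key, at_b.key, dist,
                                         "hydrogen_bond", ang)
    return ContactRecord(at_a.key, at_b.key, dist, "contact")


def detect_contacts(
    a: Structure, b: Structure,
    selection_a: AtomSelection | None = None,
    selection_b: AtomSelection | None = None,
    thresholds: ContactThresholds = ContactThresholds(),
) -> list[ContactRecord]:
    """Classify inter-molecular atom pairs between two structures.

    Kinds, in priority order: ``clash`` (< clash threshold),
    ``salt_bridge`` (opposite formal-charge side-chain termini within
    the salt-bridge threshold), ``hydrogen_bond`` (donor–acceptor heavy
    atoms within the H-bond threshold, antecedent–donor–acceptor angle
    >= 90° when the antecedent is resolved), ``contact`` (anything else
    within the contact threshold).  Cα-only input cannot support the
    chemical kinds and is restricted to clash/contact with a warning.
    """
    sub_a = a.select(selection_a) if selection_a else a
    sub_b = b.select(selection_b) if selection_b else b
    if len(sub_a) == 0 or len(sub_b) == 0:
        return []
    names_a = {at.name for at in sub_a.atoms}
    names_b = {at.name for at in sub_b.atoms}
    chemistry = not (names_a <= {"CA"} and names_b <= {"CA"})
    if not chemistry:
        warnings.warn("Cα-only input: only clash/contact kinds are detectable",
                      stacklevel=2)
    tree = cKDTree(sub_b.coords)
    pairs = tree.query_ball_point(sub_a.coords, thresholds.contact)
    records: list[ContactRecord] = []
    for i, hits in enumerate(pairs):
        at_a = sub_a.atoms[i]
        for j in sorted(hits):
            at_b = sub_b.atoms[j]
            dist = float(np.linalg.norm(at_a.position - at_b.position))
            rec = _classify_pair(at_a, at_b, dist, a, b, thresholds, chemistry)
            if rec is not None:
                records.append(rec)
    return records
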