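"""Synthetic helical-bundle complexes with planted ground truth.

Every downstream estimator in this package (superposition angles, helix
geometry, normal-mode transition analysis, lattice clash detection) is
validated against structures whose answer is known by construction.
The generator emulates a 2:2 membrane receptor–transducer complex: two
transducer protomers form a four-helix transmembrane core on a C2 axis
(the membrane normal), flanked by two receptors modelled as four-helix
bundles.  The "U" form has all helices parallel to the C2 axis; the
"V" form is produced by rotating each receptor as a rigid body about an
in-membrane axis through its extracellular contact point, so the
complex opens toward the cytoplasmic side.  Optionally one transducer
helix (TM2) is translated along the membrane normal (piston) and/or
rotated about its own axis, and isotropic Gaussian coordinate noise is
added after planting.

Identical specs and seeds give bit-identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import MembraneFrame
from .structures import Atom, AtomSelection, Structure

__all__ = [
    "HelixSpec",
    "ComplexSpec",
    "LatticeSpec",
    "ComplexLayout",
    "GroundTruth",
    "make_helix",
    "make_u_v_pair",
    "make_lattice_fixture",
    "lattice_preset",
]

# idealized backbone cylinder parameters (radius Å, phase offset deg,
# axial offset Å) relative to the Cα trace of an α-helix
_BACKBONE_PARAMS = {
    "N": (1.56, -28.4, -0.88),
    "C": (1.61, 26.6, 1.07),
    "O": (1.99, 23.0, 2.43),
}


@dataclass(frozen=True)
class HelixSpec:
    """Idealized α-helix: rise 1.5 Å, twist 100°, Cα radius 2.3 Å.

    ``axis_origin`` is the helix centre; ``axis_direction`` points
    N→C and must be unit-norm.  With the defaults the consecutive
    Cα–Cα distance is sqrt(1.5² + (2·2.3·sin 50°)²) ≈ 3.83 Å.
    """

    n_residues: int
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    chain_id: str = "A"
    start_residue: int = 1
    phase_deg: float = 0.0
    residue_name: str = "ALA"

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise ValueError("axis_direction must be unit-norm (within 1e-8)")


def _helix_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``direction``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ direction) * direction
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def make_helix(spec: HelixSpec, backbone: bool = False,
               serial_start: int = 1) -> Structure:
    """Build one ideal helix (Cα-only by default, N/Cα/C/O optional)."""
    d = np.asarray(spec.axis_direction, dtype=float)
    origin = np.asarray(spec.axis_origin, dtype=float)
    u, v = _helix_frame(d)
    n = spec.n_residues
    atoms: list[Atom] = []
    serial = serial_start
    atom_specs = [("CA", (spec.radius, 0.0, 0.0))]
    if backbone:
        atom_specs = [("N", _BACKBONE_PARAMS["N"])] + atom_specs + [
            ("C", _BACKBONE_PARAMS["C"]), ("O", _BACKBONE_PARAMS["O"])]
    for i in range(n):
        z = (i - (n - 1) / 2.0) * spec.rise_per_residue
        phi0 = np.radians(spec.phase_deg + i * spec.twist_per_residue)
        for name, (r, dphi, dz) in atom_specs:
            phi = phi0 + np.radians(dphi)
            pos = origin + (z + dz) * d + r * (np.cos(phi) * u + np.sin(phi) * v)
            atoms.append(Atom(serial, name, name[0], spec.start_residue + i,
                              "", spec.residue_name, spec.chain_id, pos))
            serial += 1
    return Structure(atoms, label=f"helix:{spec.chain_id}")


# ---------------------------------------------------------------------------
# The 2:2 complex

#: transmembrane helix length (residues); 26 × 1.5 Å rise ≈ 39 Å span,
#: a typical membrane crossing
_TM_LEN = 26
_TM_HALF_SPAN = (_TM_LEN - 1) / 2.0 * 1.5


@dataclass(frozen=True)
class ComplexLayout:
    """Chain/residue bookkeeping of the generated 2:2 complex.

    Receptors are chains A and B (four helices each, the last one
    playing the role of helix G, which faces the transducer);
    transducers are chains C and D (TM1 and TM2).  The membrane normal
    and C2 axis is +z; the intracellular side is +z.
    """

    receptor_chains: tuple[str, str] = ("A", "B")
    transducer_chains: tuple[str, str] = ("C", "D")
    helix_ranges: tuple[tuple[int, int], ...] = ((1, 26), (101, 126),
                                                 (201, 226), (301, 326))
    g_helix_range: tuple[int, int] = (301, 326)
    tm1_range: tuple[int, int] = (1, 26)
    tm2_range: tuple[int, int] = (101, 126)
    n_res_per_helix: int = _TM_LEN

    def receptor_selection(self, chain: str) -> AtomSelection:
        return AtomSelection.ca(chains=[chain])

    def frame_selection(self) -> AtomSelection:
        """TM1 of both transducers: the near-static common frame."""
        return AtomSelection.ca(chains=self.transducer_chains,
                                residue_ranges=[self.tm1_range])

    def transducer_selection(self) -> AtomSelection:
        return AtomSelection.ca(chains=self.transducer_chains)

    def membrane_frame(self) -> MembraneFrame:
        return MembraneFrame(normal=np.array([0.0, 0.0, 1.0]),
                             center=np.zeros(3), ic_side=1)

    def helix_segments(self, structure: Structure) -> list[tuple[int, int]]:
        """Half-open Cα-index segments, one per helix (for RTB blocks)."""
        ca = [a for a in structure.atoms if a.name == "CA"]
        segments = []
        start = 0
        for i in range(1, len(ca) + 1):
            if i == len(ca) or (ca[i].chain_id, ca[i].residue_number) != \
                    (ca[i - 1].chain_id, ca[i - 1].residue_number + 1):
                segments.append((start, i))
                start = i
        return segments

    def group_indices(self, structure: Structure) -> dict[str, np.ndarray]:
        """Cα node indices per rigid group (receptors, transducer core)."""
        ca = [a for a in structure.atoms if a.name == "CA"]
        groups: dict[str, list[int]] = {"receptor_A": [], "receptor_B": [],
                                        "transducers": []}
        for i, a in enumerate(ca):
            if a.chain_id == self.receptor_chains[0]:
                groups["receptor_A"].append(i)
            elif a.chain_id == self.receptor_chains[1]:
                groups["receptor_B"].append(i)
            else:
                groups["transducers"].append(i)
        return {k: np.array(v) for k, v in groups.items()}


@dataclass(frozen=True)
class ComplexSpec:
    """Parameters of the planted U→V pair.

    ``receptor_rotation_deg`` is the rigid-body opening of each
    receptor about its in-membrane hinge axis (the U→V parameter);
    ``piston_A`` translates TM2 of the first transducer along the
    membrane normal toward the intracellular side;
    ``tm2_twist_deg`` additionally rotates that helix about its own
    axis.  Gaussian noise (``noise_sigma``, Å) is added independently
    to U and V *after* planting.
    """

    receptor_rotation_deg: float = 8.5
    piston_A: float = 0.0
    tm2_twist_deg: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    n_res_per_helix: int = _TM_LEN
    backbone: bool = False

    def __post_init__(self):
        if self.receptor_rotation_deg < 0:
            raise ValueError("receptor_rotation_deg must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Exact planted transforms of a U→V pair."""

    receptor_rotation_deg: float
    rotation_axis_direction: dict[str, np.ndarray]   # per receptor chain
    rotation_axis_point: dict[str, np.ndarray]
    rotation_matrix: dict[str, np.ndarray]
    piston_A: float
    tm2_twist_deg: float
    noise_sigma: float
    seed: int
    layout: ComplexLayout


def _c2_z(coords: np.ndarray) -> np.ndarray:
    """C2 rotation about z."""
    out = coords.copy()
    out[..., 0] *= -1
    out[..., 1] *= -1
    return out


def _protomer_helices(layout: ComplexLayout, n_res: int,
                      receptor_chain: str, transducer_chain: str
                      ) -> list[HelixSpec]:
    """Helix specs of one protomer (receptor on +x, transducer near axis)."""
    up = (0.0, 0.0, 1.0)
    down = (0.0, 0.0, -1.0)
    specs = []
    # transducer: TM1 up, TM2 down (hairpin); TM2 faces the receptor
    specs.append(HelixSpec(n_res, (3.6, 3.6, 0.0), up,
                           chain_id=transducer_chain, start_residue=1))
    specs.append(HelixSpec(n_res, (3.6, -3.6, 0.0), down,
                           chain_id=transducer_chain, start_residue=101))
    # receptor: 2x2 bundle centred at (16, 0); the last helix ("G",
    # residues 301+) sits closest to TM2
    centers = [(12.4, 3.6), (19.6, 3.6), (19.6, -3.6), (12.4, -3.6)]
    dirs = [up, down, up, down]
    for k, ((cx, cy), dd) in enumerate(zip(centers, dirs)):
        specs.append(HelixSpec(n_res, (cx, cy, 0.0), dd,
                               chain_id=receptor_chain,
                               start_residue=100 * k + 1,
                               phase_deg=37.0 * k))
    return specs


def _build_symmetric_complex(spec: ComplexSpec, layout: ComplexLayout
                             ) -> Structure:
    atoms: list[Atom] = []
    serial = 1
    half1 = _protomer_helices(layout, spec.n_res_per_helix, "A", "C")
    for hs in half1:
        h = make_helix(hs, backbone=spec.backbone, serial_start=serial)
        atoms.extend(h.atoms)
        serial += len(h)
    # protomer 2: exact C2 image about z, chains A->B, C->D
    chain_map = {"A": "B", "C": "D"}
    for a in list(atoms):
        pos = _c2_z(a.position)
        atoms.append(Atom(serial, a.name, a.element, a.residue_number,
                          a.insertion_code, a.residue_name,
                          chain_map[a.chain_id], pos))
        serial += 1
    # deterministic chain order: A, B, C, D
    atoms.sort(key=lambda a: (a.chain_id, a.residue_number))
    atoms = [Atom(i + 1, a.name, a.element, a.residue_number, a.insertion_code,
                  a.residue_name, a.chain_id, a.position)
             for i, a in enumerate(atoms)]
    return Structure(atoms, label="U")


def _rotate_about(coords: np.ndarray, R: np.ndarray,
                  point: np.ndarray) -> np.ndarray:
    return (coords - point) @ R.T + point


def make_u_v_pair(spec: ComplexSpec) -> tuple[Structure, Structure, GroundTruth]:
    """Generate the symmetric U complex and its planted V counterpart.

    V is U with each receptor rotated by ``receptor_rotation_deg``
    about an in-membrane axis (ŷ for receptor A, its C2 image for
    receptor B) through the receptor's extracellular contact point, so
    the pair of receptors opens toward the cytoplasmic (+z) side;
    optionally TM2 of transducer C is translated by ``piston_A`` along
    +z and twisted by ``tm2_twist_deg`` about its own axis.  Noise is
    added after planting; the exact transforms are returned as ground
    truth.
    """
    layout = ComplexLayout(n_res_per_helix=spec.n_res_per_helix)
    u = _build_symmetric_complex(spec, layout)
    coords = u.coords

    theta = np.radians(spec.receptor_rotation_deg)
    # hinge for receptor A: axis +y through the extracellular contact
    # point below the receptor bundle; receptor B uses the C2 image
    axis_a = np.array([0.0, 1.0, 0.0])
    point_a = np.array([9.0, 0.0, -_TM_HALF_SPAN])
    R_a = Rotation.from_rotvec(theta * axis_a).as_matrix()
    axis_b = _c2_z(axis_a)
    point_b = _c2_z(point_a)
    R_b = Rotation.from_rotvec(theta * axis_b).as_matrix()

    vcoords = coords.copy()
    idx_a = [i for i, a in enumerate(u.atoms) if a.chain_id == "A"]
    idx_b = [i for i, a in enumerate(u.atoms) if a.chain_id == "B"]
    vcoords[idx_a] = _rotate_about(coords[idx_a], R_a, point_a)
    vcoords[idx_b] = _rotate_about(coords[idx_b], R_b, point_b)

    lo, hi = layout.tm2_range
    idx_tm2 = [i for i, a in enumerate(u.atoms)
               if a.chain_id == "C" and lo <= a.residue_number <= hi]
    if spec.tm2_twist_deg != 0.0:
        # TM2 of chain C runs along -z through (3.6, -3.6); twist about
        # its own (N->C) axis
        tm2_axis = np.array([0.0, 0.0, -1.0])
        tm2_point = np.array([3.6, -3.6, 0.0])
        R_t = Rotation.from_rotvec(np.radians(spec.tm2_twist_deg) * tm2_axis).as_matrix()
        vcoords[idx_tm2] = _rotate_about(vcoords[idx_tm2], R_t, tm2_point)
    if spec.piston_A != 0.0:
        vcoords[idx_tm2] += spec.piston_A * np.array([0.0, 0.0, 1.0])

    ucoords = coords.copy()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        ucoords = ucoords + rng.normal(0.0, spec.noise_sigma, ucoords.shape)
        vcoords = vcoords + rng.normal(0.0, spec.noise_sigma, vcoords.shape)

    u_out = u.with_coords(ucoords, label="U")
    v_out = u.with_coords(vcoords, label="V")
    truth = GroundTruth(
        receptor_rotation_deg=spec.receptor_rotation_deg,
        rotation_axis_direction={"A": axis_a, "B": axis_b},
        rotation_axis_point={"A": point_a, "B": point_b},
        rotation_matrix={"A": R_a, "B": R_b},
        piston_A=spec.piston_A,
        tm2_twist_deg=spec.tm2_twist_deg,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        layout=layout,
    )
    return u_out, v_out, truth


# ---------------------------------------------------------------------------
# Lattice fixture: a complex with a protruding appended domain

@dataclass(frozen=True)
class LatticeSpec:
    """Crystal-packing fixture: complex + appended cytoplasmic domain.

    The appended two-helix hairpin (emulating a HAMP-like protrusion on
    transducer chain C, residues 201–216 and 221–236) extends beyond
    the membrane region on the intracellular side.  In the "tight"
    parameterization the symmetry mates of the chosen space group place
    a neighbouring complex from the next crystal layer on top of the
    protrusion (≥1 steric clash); in the "open" one the molecule is
    isolated (0 clashes).
    """

    unit_cell: tuple[float, float, float, float, float, float]
    space_group: str
    placement: tuple[float, float, float] = (0.0, 0.0, 0.0)
    domain_helix_len: int = 16
    seed: int = 0

    SUPPORTED = ("P 1", "P 21 21 2", "I 21 21 21", "P 64")

    def __post_init__(self):
        if self.space_group not in self.SUPPORTED:
            raise ValueError(
                f"unsupported space group {self.space_group!r}; "
                f"supported: {self.SUPPORTED}")


#: appended-domain residue ranges on transducer chain C
DOMAIN_RANGES = ((201, 216), (221, 236))


def lattice_preset(name: str) -> LatticeSpec:
    """Named packing presets.

    ``open``: P 1 with a 200 Å cell — the molecule is isolated and no
    symmetry mate comes near the appended domain.
    ``tight``: P 21 21 2 with a cell sized so the two-fold-screw image
    of the next crystal layer (z → −z) lands on the appended domain.
    """
    if name == "open":
        return LatticeSpec((200.0, 200.0, 200.0, 90.0, 90.0, 90.0), "P 1",
                           placement=(100.0, 100.0, 100.0))
    if name == "tight":
        return LatticeSpec((46.0, 46.0, 58.0, 90.0, 90.0, 90.0), "P 21 21 2",
                           placement=(12.0, 12.0, 24.0))
    raise ValueError(f"unknown preset {name!r} (use 'open' or 'tight')")


def make_lattice_fixture(spec: LatticeSpec) -> Structure:
    """One asymmetric unit: the U complex plus the appended domain."""
    base, _, _ = make_u_v_pair(ComplexSpec(receptor_rotation_deg=0.0,
                                           seed=spec.seed))
    atoms = list(base.atoms)
    serial = len(atoms) + 1
    n = spec.domain_helix_len
    half = (n - 1) / 2.0 * 1.5
    z_center = _TM_HALF_SPAN + 3.0 + half
    for (start, _), (cx, cy), dd in zip(
            DOMAIN_RANGES,
            [(2.0, 0.5), (-2.0, -0.5)],
            [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)]):
        hs = HelixSpec(n, (cx, cy, z_center), dd, chain_id="C",
                       start_residue=start)
        h = make_helix(hs, serial_start=serial)
        atoms.extend(h.atoms)
        serial += len(h)
    offset = np.asarray(spec.placement, dtype=float)
    atoms = [Atom(i + 1, a.name, a.element, a.residue_number, a.insertion_code,
                  a.residue_name, a.chain_id, a.position + offset)
             for i, a in enumerate(atoms)]
    return Structure(atoms, unit_cell=spec.unit_cell,
                     space_group=spec.space_group, label="lattice-fixture")


def domain_probe_selection() -> AtomSelection:
    """Selection of the appended (protruding) domain atoms."""
    return AtomSelection.make(chains=["C"], residue_ranges=DOMAIN_RANGES)


def calibrate_receptor_rotation(target_rmsd_A: float,
                                tol: float = 1e-6,
                                max_angle_deg: float = 40.0) -> float:
    """Receptor-rotation angle whose U→V all-Cα transition RMSD (after
    optimal whole-complex superposition) equals ``target_rmsd_A``.

    The RMSD grows monotonically with the planted angle, so a bisection
    suffices.  Used to generate transition pairs of a prescribed
    overall magnitude (e.g. a 2.9 Å transition).
    """
    from .structures import pair_common_atoms
    from .superpose import rmsd as _rmsd

    def rmsd_for(angle: float) -> float:
        u, v, _ = make_u_v_pair(ComplexSpec(receptor_rotation_deg=angle))
        xu, xv, _ = pair_common_atoms(u, v, AtomSelection.ca())
        return _rmsd(xv, xu, fit=True)

    lo, hi = 0.0, max_angle_deg
    if rmsd_for(hi) < target_rmsd_A:
        raise ValueError(f"target {target_rmsd_A} Å unreachable below "
                         f"{max_angle_deg}°")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rmsd_for(mid) < target_rmsd_A:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
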