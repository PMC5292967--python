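"""Cα elastic network model (ENM) and normal modes, full and RTB-reduced.

The network is the standard anisotropic network model: every pair of
Cα nodes closer than a cutoff is joined by a Hookean spring of uniform
stiffness γ, giving a 3n×3n Hessian whose per-pair super-element is
-γ·(r̂ r̂ᵀ) with r̂ the unit inter-node vector.  Its low-frequency
eigenvectors approximate the collective motions of the structure; for a
connected, free-floating network exactly six eigenvalues vanish (rigid
translations and rotations).

The rotation-translation-block (RTB) reduction projects the Hessian
onto rigid translations/rotations of node blocks (up to 6 degrees of
freedom per block, fewer for 1–2-node blocks), solves the much smaller
eigenproblem, and maps the eigenvectors back to 3n-dimensional
Cartesian displacement fields.  By the variational principle each RTB
eigenvalue bounds the corresponding full eigenvalue from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = [
    "ENModel",
    "BlockDefinition",
    "ModeSet",
    "build_hessian",
    "full_modes",
    "rtb_modes",
]

_ZERO_MODE_REL_TOL = 1e-8


@dataclass
class ENModel:
    """Elastic network over an ordered list of Cα nodes.

    Parameters
    ----------
    coords : (n, 3) node coordinates, Å.
    cutoff : spring cutoff distance, Å (default 10, common ANM practice).
    gamma : uniform spring constant (arbitrary units; sets the
        eigenvalue scale only).
    masses : per-node masses (default: unit masses).
    """

    coords: np.ndarray
    cutoff: float = 10.0
    gamma: float = 1.0
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 2:
            raise ValueError("coords must be (n >= 2, 3)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.coords),) or np.any(self.masses <= 0):
                raise ValueError("masses must be positive, one per node")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def contact_pairs(self) -> np.ndarray:
        """(m, 2) index pairs (i < j) within the cutoff."""
        tree = cKDTree(self.coords)
        pairs = tree.query_pairs(self.cutoff, output_type="ndarray")
        return pairs.reshape(-1, 2)

    def n_connected_components(self) -> int:
        pairs = self.contact_pairs()
        n = self.n_nodes
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)


@dataclass
class BlockDefinition:
    """Disjoint partition of nodes into rigid blocks (RTB).

    ``blocks`` is a list of node-index arrays; together they must cover
    all nodes exactly once.  Blocks of 1 or 2 nodes carry reduced
    degrees of freedom (3 and 5 respectively).
    """

    blocks: list[np.ndarray]

    def __post_init__(self):
        self.blocks = [np.asarray(b, dtype=int) for b in self.blocks]
        if any(len(b) == 0 for b in self.blocks):
            raise ValueError("empty block")
        all_idx = np.concatenate(self.blocks)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("blocks overlap")

    def validate_cover(self, n_nodes: int) -> None:
        all_idx = np.sort(np.concatenate(self.blocks))
        if not np.array_equal(all_idx, np.arange(n_nodes)):
            raise ValueError("blocks do not cover all nodes exactly once")

    @classmethod
    def single_nodes(cls, n_nodes: int) -> "BlockDefinition":
        return cls([np.array([i]) for i in range(n_nodes)])

    @classmethod
    def uniform(cls, n_nodes: int, block_size: int) -> "BlockDefinition":
        return cls([np.arange(i, min(i + block_size, n_nodes))
                    for i in range(0, n_nodes, block_size)])

    @classmethod
    def from_segments(cls, segments: Sequence[tuple[int, int]]) -> "BlockDefinition":
        """Blocks from half-open node-index segments (e.g. one per helix)."""
        return cls([np.arange(lo, hi) for lo, hi in segments])


@dataclass
class ModeSet:
    """Eigenpairs of a (possibly reduced) ENM Hessian.

    ``eigenvalues`` ascend and are non-negative up to round-off;
    ``vectors`` (3n, k) are orthonormal Cartesian displacement fields
    (mass-weighted inner product when masses are non-unit).  RTB modes
    are already projected back to Cartesian space.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    n_zero_modes: int
    provenance: str                       # "full" | "rtb"
    block_sizes: list[int] | None = None

    def nonzero_modes(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, vectors) with the near-zero rigid modes dropped."""
        return (self.eigenvalues[self.n_zero_modes:],
                self.vectors[:, self.n_zero_modes:])

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]


def build_hessian(model: ENModel) -> np.ndarray:
    """Assemble the dense 3n×3n ANM Hessian.

    Off-diagonal super-element for a contact pair (i, j):
    ``-γ · r̂ r̂ᵀ`` with ``r̂`` the unit vector from i to j; the diagonal
    super-element is minus the sum of the off-diagonals in its row, so
    the matrix annihilates rigid translations by construction.
    """
    n = model.n_nodes
    H = np.zeros((3 * n, 3 * n))
    pairs = model.contact_pairs()
    for i, j in pairs:
        rij = model.coords[j] - model.coords[i]
        d2 = rij @ rij
        block = -model.gamma * np.outer(rij, rij) / d2
        H[3*i:3*i+3, 3*j:3*j+3] += block
        H[3*j:3*j+3, 3*i:3*i+3] += block
        H[3*i:3*i+3, 3*i:3*i+3] -= block
        H[3*j:3*j+3, 3*j:3*j+3] -= block
    return H


def _mass_vector(model: ENModel) -> np.ndarray:
    m = model.masses if model.masses is not None else np.ones(model.n_nodes)
    return np.repeat(m, 3)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|component| entry of each mode > 0."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def _count_zero_modes(eigenvalues: np.ndarray) -> int:
    lam_max = float(eigenvalues[-1])
    if lam_max < 1e-10:     # fully rigid subspace: everything is a zero mode
        return len(eigenvalues)
    return int(np.sum(eigenvalues < _ZERO_MODE_REL_TOL * lam_max))


def full_modes(model: ENModel, k: int | None = None) -> ModeSet:
    """Lowest-k eigenpairs of the (mass-weighted) full Hessian.

    Eigenvalues below 1e-8 of the largest are classified as zero
    (rigid-body) modes — exactly 6 for a connected network.
    """
    n3 = 3 * model.n_nodes
    if k is None:
        k = n3
    if k > n3:
        raise ValueError(f"k={k} exceeds 3n={n3}")
    H = build_hessian(model)
    w = 1.0 / np.sqrt(_mass_vector(model))
    Hw = H * w[:, None] * w[None, :]
    # full spectrum for the zero-mode threshold; dense eigh is cheap at
    # the system sizes used here (few hundred nodes)
    evals, evecs = scipy.linalg.eigh(Hw)
    n_zero = _count_zero_modes(evals)
    vectors = _fix_signs(evecs[:, :k])
    return ModeSet(evals[:k].copy(), vectors, min(n_zero, k), "full")


def _block_basis(coords: np.ndarray, block: np.ndarray,
                 sqrt_m: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted rigid-motion basis of one block.

    Columns span rigid translations and infinitesimal rotations about
    the block's (mass-weighted) centroid, embedded in 3·len(block)
    coordinates.  Rank-deficient cases (single node: 3 DoF; collinear
    block: 5 DoF) are handled by discarding null singular directions.
    """
    nb = len(block)
    x = coords[block]
    m = sqrt_m[block] ** 2
    c = (m[:, None] * x).sum(axis=0) / m.sum()
    rel = x - c
    cand = np.zeros((3 * nb, 6))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        cand[:, ax] = np.tile(e, nb)
        cand[:, 3 + ax] = np.cross(e, rel).ravel()
    # mass-weight and orthonormalize, dropping null directions
    wcand = cand * np.repeat(sqrt_m[block], 3)[:, None]
    q, s, _ = np.linalg.svd(wcand, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    return q[:, :rank]


def rtb_modes(model: ENModel, blocks: BlockDefinition,
              k: int | None = None) -> ModeSet:
    """Normal modes via the rotation-translation-block projection.

    The Hessian is projected onto the subspace of per-block rigid
    motions, the reduced eigenproblem is solved, and eigenvectors are
    mapped back to orthonormal 3n-dimensional Cartesian displacement
    fields.  Eigenvalues dominate the full-model ones index by index
    (subspace variational bound).
    """
    blocks.validate_cover(model.n_nodes)
    n3 = 3 * model.n_nodes
    sqrt_m = np.sqrt(_mass_vector(model)[::3])
    # assemble sparse-ish projection matrix P (3n x total block DoF)
    cols = []
    col_blocks = []
    for b in blocks.blocks:
        basis = _block_basis(model.coords, b, sqrt_m)
        col_blocks.append((b, basis))
        cols.append(basis.shape[1])
    n_dof = int(np.sum(cols))
    if k is None:
        k = n_dof
    if k > n_dof:
        raise ValueError(f"k={k} exceeds RTB degrees of freedom {n_dof}")
    P = np.zeros((n3, n_dof))
    at = 0
    for b, basis in col_blocks:
        rows = (3 * b[:, None] + np.arange(3)[None, :]).ravel()
        P[rows, at:at + basis.shape[1]] = basis
        at += basis.shape[1]
    H = build_hessian(model)
    w = 1.0 / np.sqrt(_mass_vector(model))
    Hw = H * w[:, None] * w[None, :]
    Hr = P.T @ Hw @ P
    evals, evecs = scipy.linalg.eigh(Hr)
    n_zero = _count_zero_modes(evals)
    vectors = P @ evecs[:, :k]
    # columns are orthonormal already (P has orthonormal columns);
    # re-orthonormalize defensively against round-off
    qr_q, qr_r = np.linalg.qr(vectors)
    vectors = qr_q * np.sign(np.diag(qr_r))
    vectors = _fix_signs(vectors)
    return ModeSet(evals[:k].copy(), vectors, min(n_zero, k), "rtb",
                   block_sizes=[len(b) for b in blocks.blocks])
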