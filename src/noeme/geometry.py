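"""Glycosidic torsions, syn/anti bitstrings and the eRMSD metric.

The eRMSD compares two nucleic-acid conformations through the relative
arrangement of their bases rather than through superposition.  Each base
carries a local orthonormal frame centered on its six-membered ring
(built from C2/C4/C6); the position of every other base in that frame is
anisotropically scaled (5 A in plane, 3 A along the normal, so that one
scaled unit means "close enough to interact" in any direction) and mapped
through a smooth 4-vector embedding G with a cutoff at scaled distance
2.4.  The eRMSD of two structures is the root mean square difference of
their G vectors over all ordered base pairs, normalized by the number of
nucleotides.  Because G is a fixed per-structure embedding, the eRMSD is
a Euclidean distance in embedding space and hence a true metric (it
satisfies the triangle inequality, which the motif search exploits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Ensemble, Snapshot

__all__ = [
    "chi_angle",
    "syn_bit",
    "chi_conformation",
    "ermsd",
    "ermsd_embedding",
    "pairwise_ermsd",
    "DistanceCache",
    "centroid_index",
    "SYN_UPPER_DEG",
    "ERMSD_SCALE_XY",
    "ERMSD_SCALE_Z",
    "ERMSD_CUTOFF",
]

#: syn window: 0 < chi < 115 degrees (strict); anti / high-anti otherwise
SYN_UPPER_DEG = 115.0

#: eRMSD ellipsoidal scaling (A) and scaled-distance cutoff
ERMSD_SCALE_XY = 5.0
ERMSD_SCALE_Z = 3.0
ERMSD_CUTOFF = 2.4


class GeometryError(ValueError):
    """An atom needed for a geometric definition is missing."""


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    # components orthogonal to the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return float(np.degrees(np.arctan2(y, x)))


def chi_angle(snapshot: Snapshot, residue: int, chain: str | None = None) -> float:
    """Glycosidic torsion chi of one residue, in degrees wrapped to [0, 360).

    O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines.  The
    [0, 360) convention makes the syn window ``0 < chi < 115`` directly
    applicable; high-anti (~270-300 deg) stays on the anti side.
    """
    info = snapshot.residue(residue, chain)
    if info.kind == "purine":
        names = ("O4'", "C1'", "N9", "C4")
    else:
        names = ("O4'", "C1'", "N1", "C2")
    try:
        pts = [snapshot.atom(residue, n, chain) for n in names]
    except KeyError as exc:
        raise GeometryError(
            f"residue {residue}: missing chi atom ({exc})"
        ) from None
    ang = dihedral(*pts)
    return ang % 360.0


def syn_bit(chi: float) -> int:
    """1 iff ``0 < chi < 115`` degrees (syn), else 0 (anti / high-anti)."""
    return 1 if 0.0 < chi < SYN_UPPER_DEG else 0


def chi_conformation(snapshot: Snapshot, chain: str | None = None) -> str:
    """Per-residue syn/anti pattern of a snapshot as a bitstring.

    Position r (0-based) is '1' iff residue r+1 is syn.  Snapshots with
    different bitstrings are never placed in the same cluster.
    """
    bits = []
    for res in snapshot.residues:
        if chain is not None and res.chain != chain:
            continue
        bits.append(str(syn_bit(chi_angle(snapshot, res.seq_pos, res.chain))))
    return "".join(bits)


# ---------------------------------------------------------------------------
# eRMSD
# ---------------------------------------------------------------------------

# Base frame atoms, ordered so that the ring normal (+z) points to the same
# base face for purines and pyrimidines (the two ring traversals C2->C4->C6
# run in opposite senses relative to the faces).
_FRAME_ATOMS = {"pyrimidine": ("C2", "C4", "C6"), "purine": ("C2", "C6", "C4")}


def base_frames(snapshot: Snapshot) -> tuple[np.ndarray, np.ndarray]:
    """Per-base local frames: (origins (N,3), rotations (N,3,3)).

    Origin is the centroid of C2/C4/C6; x points from the origin toward
    C2; z is the ring normal (orientation fixed by the purine/pyrimidine
    atom ordering); y completes the right-handed frame.  Rotation rows
    are the frame axes, so ``R @ v`` expresses a lab vector locally.
    """
    origins, rots = [], []
    for res in snapshot.residues:
        a1, a2, a3 = _FRAME_ATOMS[res.kind]
        try:
            p1 = snapshot.atom(res.seq_pos, a1, res.chain)
            p2 = snapshot.atom(res.seq_pos, a2, res.chain)
            p3 = snapshot.atom(res.seq_pos, a3, res.chain)
        except KeyError:
            raise GeometryError(
                f"residue {res.seq_pos}: missing ring atom for the base frame"
            ) from None
        center = (p1 + p2 + p3) / 3.0
        x = p1 - center
        x = x / np.linalg.norm(x)
        u = p2 - center
        z = np.cross(x, u)
        z = z / np.linalg.norm(z)
        y = np.cross(z, x)
        origins.append(center)
        rots.append(np.stack([x, y, z]))
    return np.asarray(origins), np.asarray(rots)


def ermsd_embedding(snapshot: Snapshot) -> np.ndarray:
    """Flattened G-vector embedding of a snapshot, shape (N*N*4,).

    The eRMSD between two same-length snapshots is the Euclidean
    distance between their embeddings divided by sqrt(N).
    """
    origins, rots = base_frames(snapshot)
    n = len(origins)
    # rel[i, j] = position of base j in the frame of base i, scaled
    diff = origins[None, :, :] - origins[:, None, :]          # (N, N, 3) lab
    rel = np.einsum("iab,ijb->ija", rots, diff)               # local frames
    rel[..., 0] /= ERMSD_SCALE_XY
    rel[..., 1] /= ERMSD_SCALE_XY
    rel[..., 2] /= ERMSD_SCALE_Z
    r = np.linalg.norm(rel, axis=-1)                          # scaled distance
    np.fill_diagonal(r, np.inf)                               # exclude i == j
    gamma = np.pi / ERMSD_CUTOFF
    inside = r < ERMSD_CUTOFF
    g = np.zeros((n, n, 4))
    r_safe = np.where(inside, r, 1.0)
    sin_term = np.where(inside, np.sin(gamma * r_safe) / (r_safe * gamma), 0.0)
    for k in range(3):
        g[..., k] = sin_term * rel[..., k]
    g[..., 3] = np.where(inside, (1.0 + np.cos(gamma * r_safe)) / gamma, 0.0)
    return g.reshape(-1)


def ermsd(a: Snapshot, b: Snapshot) -> float:
    """eRMSD between two conformations of equally long chains."""
    if a.n_residues != b.n_residues:
        raise ValueError(
            f"cannot compare snapshots with {a.n_residues} and {b.n_residues} residues"
        )
    ga = ermsd_embedding(a)
    gb = ermsd_embedding(b)
    return float(np.linalg.norm(ga - gb) / np.sqrt(a.n_residues))


def pairwise_ermsd(snapshots: list[Snapshot]) -> np.ndarray:
    """Full symmetric eRMSD matrix over a list of snapshots."""
    if not snapshots:
        return np.zeros((0, 0))
    n_res = snapshots[0].n_residues
    embeds = np.stack([ermsd_embedding(s) for s in snapshots])
    from scipy.spatial.distance import pdist, squareform

    mat = squareform(pdist(embeds)) / np.sqrt(n_res)
    return mat


@dataclass
class DistanceCache:
    """Lazily filled symmetric matrix of pairwise eRMSD values."""

    snapshots: list[Snapshot]
    _embeds: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _matrix: np.ndarray | None = field(default=None, repr=False)
    _filled: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.snapshots)
        self._matrix = np.zeros((n, n))
        self._filled = np.eye(n, dtype=bool)

    def _embed(self, i: int) -> np.ndarray:
        if i not in self._embeds:
            self._embeds[i] = ermsd_embedding(self.snapshots[i])
        return self._embeds[i]

    def get(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        if not self._filled[i, j]:
            nres = self.snapshots[i].n_residues
            d = float(np.linalg.norm(self._embed(i) - self._embed(j)) / np.sqrt(nres))
            self._matrix[i, j] = self._matrix[j, i] = d
            self._filled[i, j] = self._filled[j, i] = True
        return float(self._matrix[i, j])

    def full(self) -> np.ndarray:
        if not self._filled.all():
            mat = pairwise_ermsd(self.snapshots)
            self._matrix = mat
            self._filled = np.ones_like(self._filled)
        return self._matrix

    @classmethod
    def from_matrix(cls, snapshots: list[Snapshot], matrix: np.ndarray) -> "DistanceCache":
        cache = cls(snapshots)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(snapshots), len(snapshots)):
            raise ValueError("matrix shape does not match snapshot count")
        if not np.allclose(matrix, matrix.T) or np.any(np.diag(matrix) != 0) or np.any(matrix < 0):
            raise ValueError("not a valid distance matrix")
        cache._matrix = matrix.copy()
        cache._filled = np.ones((len(snapshots), len(snapshots)), dtype=bool)
        return cache

    def save(self, path) -> None:
        np.savetxt(path, self.full(), fmt="%.10g")

    @classmethod
    def load(cls, snapshots: list[Snapshot], path) -> "DistanceCache":
        return cls.from_matrix(snapshots, np.loadtxt(path, ndmin=2))


def centroid_index(ensemble: Ensemble | list[Snapshot], cache: DistanceCache | None = None) -> int:
    """Index of the snapshot with minimum mean squared eRMSD to all others.

    Ties are broken by the lowest index.
    """
    snapshots = list(ensemble)
    if cache is None:
        cache = DistanceCache(snapshots)
    mat = cache.full()
    msd = np.mean(mat**2, axis=1)
    return int(np.argmin(msd))
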