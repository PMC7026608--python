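"""Multi-model structure input/output and atom-level access.

Structures are read with Biopython's PDB parser and held in lightweight
arrays keyed by (chain, residue sequence position, atom name).  Residue
indexing is 1-based sequence position within a chain; a single integer
offset maps to author/PDB numbering when the two differ (for the
deposited hairpin entry the offset is 63, i.e. loop residue 16 is PDB
residue 79).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

logger = logging.getLogger(__name__)

__all__ = [
    "Snapshot",
    "Ensemble",
    "read_multimodel_pdb",
    "read_pdb_directory",
    "write_multimodel_pdb",
    "map_residue_numbering",
    "proton_distance",
    "PURINES",
    "PYRIMIDINES",
]

#: residue-name dialects accepted for unmodified ribonucleotides
PURINES = {"A", "G", "ADE", "GUA", "RA", "RG", "DA", "DG", "A3", "A5", "G3", "G5"}
PYRIMIDINES = {"C", "U", "T", "CYT", "URA", "URI", "THY", "RC", "RU", "DC", "DT", "C3", "C5", "U3", "U5"}


class TopologyError(ValueError):
    """Models of one ensemble do not share an identical atom set."""


class AtomLookupError(KeyError):
    """A (residue, atom) reference does not resolve in a snapshot."""


def normalize_atom_name(name: str) -> str:
    """Canonicalize an atom name: strip spaces, map prime dialects to ``'``."""
    return name.strip().replace("′", "'").replace("*", "'").upper()


def base_type(resname: str) -> str:
    """Classify a residue name as ``purine`` or ``pyrimidine``.

    Modified or unknown nucleotides are rejected: every metric here
    (glycosidic torsion, base frames) assumes the standard ring atoms.
    """
    rn = resname.strip().upper()
    if rn in PURINES:
        return "purine"
    if rn in PYRIMIDINES:
        return "pyrimidine"
    raise ValueError(
        f"unsupported residue name {resname!r}: only unmodified A/G/C/U "
        "(and common dialects) are handled"
    )


@dataclass(frozen=True)
class ResidueInfo:
    """One nucleotide of the chain topology."""

    seq_pos: int            # 1-based position within the chain
    name: str               # residue name as read (e.g. "G")
    chain: str
    kind: str               # "purine" | "pyrimidine"


@dataclass
class Snapshot:
    """A single conformation: coordinates plus an atom index.

    Coordinates are in Angstrom.  Atoms are addressed by
    ``(seq_pos, atom_name)`` within the (single) chain, or fully by
    ``(chain, seq_pos, atom_name)``.
    """

    model_id: int
    coords: np.ndarray                      # (n_atoms, 3) float64
    atom_keys: list[tuple[str, int, str]]   # (chain, seq_pos, name) per row
    residues: list[ResidueInfo]
    _index: dict[tuple[str, int, str], int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {k: i for i, k in enumerate(self.atom_keys)}
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"model {self.model_id}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def atom(self, seq_pos: int, name: str, chain: str | None = None) -> np.ndarray:
        """Coordinates of one atom; prime spellings are normalized."""
        name = normalize_atom_name(name)
        if chain is None:
            chains = self.chains
            if len(chains) != 1:
                raise AtomLookupError(
                    f"snapshot has chains {chains}; a chain id is required"
                )
            chain = chains[0]
        try:
            return self.coords[self._index[(chain, seq_pos, name)]]
        except KeyError:
            raise AtomLookupError(
                f"atom {name!r} of residue {seq_pos} (chain {chain!r}) not found"
            ) from None

    def has_atom(self, seq_pos: int, name: str, chain: str | None = None) -> bool:
        try:
            self.atom(seq_pos, name, chain)
            return True
        except AtomLookupError:
            return False

    def residue(self, seq_pos: int, chain: str | None = None) -> ResidueInfo:
        for r in self.residues:
            if r.seq_pos == seq_pos and (chain is None or r.chain == chain):
                return r
        raise AtomLookupError(f"residue {seq_pos} (chain {chain!r}) not found")

    def subset(self, seq_positions: Sequence[int], chain: str | None = None) -> "Snapshot":
        """New snapshot restricted to ``seq_positions``, renumbered 1..n."""
        if chain is None:
            chains = self.chains
            if len(chains) != 1:
                raise AtomLookupError("chain id required for multi-chain snapshot")
            chain = chains[0]
        remap = {old: new for new, old in enumerate(seq_positions, start=1)}
        rows, keys = [], []
        for i, (ch, pos, name) in enumerate(self.atom_keys):
            if ch == chain and pos in remap:
                rows.append(i)
                keys.append((ch, remap[pos], name))
        residues = [
            ResidueInfo(remap[r.seq_pos], r.name, r.chain, r.kind)
            for r in self.residues
            if r.chain == chain and r.seq_pos in remap
        ]
        residues.sort(key=lambda r: r.seq_pos)
        return Snapshot(self.model_id, self.coords[rows].copy(), keys, residues)


@dataclass
class Ensemble:
    """An ordered collection of snapshots of one molecule."""

    snapshots: list[Snapshot]
    prior_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.snapshots) < 1:
            raise ValueError("an ensemble needs at least one snapshot")
        ref = self.snapshots[0].atom_keys
        for s in self.snapshots[1:]:
            if s.atom_keys != ref:
                raise TopologyError(
                    f"model {s.model_id} has a different atom set than model "
                    f"{self.snapshots[0].model_id}"
                )
        if self.prior_weights is None:
            self.prior_weights = np.full(len(self.snapshots), 1.0 / len(self.snapshots))
        else:
            w = np.asarray(self.prior_weights, dtype=float)
            if w.shape != (len(self.snapshots),):
                raise ValueError("prior_weights length must match snapshot count")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("prior weights must be nonnegative with positive sum")
            self.prior_weights = w / w.sum()

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]

    @property
    def n_residues(self) -> int:
        return self.snapshots[0].n_residues

    def subset_residues(self, seq_positions: Sequence[int]) -> "Ensemble":
        return Ensemble(
            [s.subset(seq_positions) for s in self.snapshots],
            prior_weights=self.prior_weights.copy(),
        )


def _snapshot_from_model(model, model_id: int, altloc_keep=("", "A")) -> Snapshot:
    altloc_keep = tuple(a.strip() for a in altloc_keep)
    coords, keys, residues = [], [], []
    for chain in model:
        seq_pos = 0
        for res in chain:
            het, _, _ = res.id
            if het.strip():
                continue  # skip waters/heteroatoms
            seq_pos += 1
            kind = base_type(res.get_resname())
            residues.append(ResidueInfo(seq_pos, res.get_resname().strip(), chain.id, kind))
            for atom in res:
                if atom.get_altloc().strip() not in altloc_keep:
                    continue
                keys.append((chain.id, seq_pos, normalize_atom_name(atom.get_name())))
                coords.append(atom.get_coord())
    if not coords:
        raise ValueError(f"model {model_id}: no ATOM records for standard nucleotides")
    return Snapshot(model_id, np.asarray(coords, dtype=float), keys, residues)


def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    One snapshot per MODEL record (a file without MODEL records yields a
    single snapshot); prior weights are uniform.  All models must share
    one atom set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    snapshots = [
        _snapshot_from_model(model, model_id=model.id + 1) for model in structure
    ]
    if not snapshots:
        raise ValueError(f"{path}: no models with ATOM records")
    return Ensemble(snapshots)


def read_pdb_directory(path: str | Path, pattern: str = "*.pdb") -> Ensemble:
    """Read a directory of single-model PDB files, in lexicographic order."""
    files = sorted(Path(path).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files under {path}")
    snapshots: list[Snapshot] = []
    for i, f in enumerate(files):
        ens = read_multimodel_pdb(f)
        for s in ens:
            s.model_id = len(snapshots) + 1
            snapshots.append(s)
        del i
    return Ensemble(snapshots)


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (via Biopython)."""
    builder = StructureBuilder()
    builder.init_structure("ens")
    for m, snap in enumerate(ensemble):
        builder.init_model(m)
        chains_done = set()
        current = None
        for (chain, seq_pos, name), xyz in zip(snap.atom_keys, snap.coords):
            if chain not in chains_done:
                builder.init_chain(chain)
                builder.init_seg("    ")
                chains_done.add(chain)
            res = snap.residue(seq_pos, chain)
            if current != (chain, seq_pos):
                builder.init_residue(res.name, " ", seq_pos, " ")
                current = (chain, seq_pos)
            element = name[0] if name[0].isalpha() else name[1]
            builder.init_atom(
                name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ", name, element=element
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def map_residue_numbering(paper_index: int, offset: int = 0, chain_length: int | None = None) -> int:
    """Map a 1-based sequence position to author/PDB numbering by a constant offset.

    For the deposited hairpin convention ``offset=63`` maps 16 -> 79.
    """
    if paper_index < 1 or (chain_length is not None and paper_index > chain_length):
        raise ValueError(f"residue index {paper_index} out of range")
    return paper_index + offset


def proton_distance(
    snapshot: Snapshot,
    pair: tuple[tuple[int, str], tuple[int, str]],
    chain: str | None = None,
) -> float:
    """Euclidean distance in Angstrom between two named atoms.

    ``pair`` is ``((res_i, atom_i), (res_j, atom_j))``; symmetric in the
    order of its two members.
    """
    (ri, ai), (rj, aj) = pair
    a = snapshot.atom(ri, ai, chain)
    b = snapshot.atom(rj, aj, chain)
    return float(math.dist(a, b))
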