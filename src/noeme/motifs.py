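"""Sequence-independent structural motif search under the eRMSD metric.

A query fragment (by default a hairpin's central loop residues) is
compared against every contiguous same-length window of every chain and
model in a structure library.  Because the eRMSD is a true metric, the
matches of a whole ensemble can be found from its centroid alone: any
window within ``cutoff`` of some ensemble member lies within
``max_t eRMSD(centroid, member_t) + cutoff`` of the centroid, so a
single centroid scan with that enlarged threshold is a sound prefilter.
Candidates are then refined against every ensemble member, restricted
to matches with the query's exact syn/anti bitstring, and windows whose
backbone is not contiguous (consecutive O3'-P beyond a bond threshold)
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import chi_conformation, ermsd, ermsd_embedding
from .structures import Ensemble, Snapshot, read_multimodel_pdb

__all__ = [
    "Fragment",
    "MotifMatch",
    "extract_fragment",
    "prefilter_threshold",
    "check_connectivity",
    "enumerate_windows",
    "search_library",
    "refine_matches",
    "filter_chi",
    "search_ensemble_motifs",
    "matches_to_dataframe",
    "DEFAULT_BOND_MAX",
    "DEFAULT_MATCH_CUTOFF",
]

#: maximum O3'(i)-P(i+1) distance (A) still counted as a covalent linkage
DEFAULT_BOND_MAX = 2.0
DEFAULT_MATCH_CUTOFF = 1.0


@dataclass
class Fragment:
    """A contiguous residue window cut from a snapshot, renumbered 1..n."""

    snapshot: Snapshot
    source_id: str
    start: int                   # original 1-based start position
    length: int
    chain: str | None = None
    model: int | None = None

    @property
    def bitstring(self) -> str:
        return chi_conformation(self.snapshot)


@dataclass
class MotifMatch:
    """A library window matching at least one ensemble snapshot."""

    library_id: str
    model: int
    chain: str
    start: int                   # 1-based window start within the chain
    bitstring: str
    ermsd_by_snapshot: dict[int, float]   # snapshot index -> eRMSD (< cutoff)

    @property
    def min_ermsd(self) -> float:
        return min(self.ermsd_by_snapshot.values())

    @property
    def n_matching_snapshots(self) -> int:
        return len(self.ermsd_by_snapshot)


def extract_fragment(
    snapshot: Snapshot, start: int, length: int, source_id: str = "query",
    chain: str | None = None, model: int | None = None,
) -> Fragment:
    """Cut residues ``start .. start+length-1`` (1-based) into a fragment."""
    chains = snapshot.chains if chain is None else [chain]
    if len(chains) != 1:
        raise ValueError("a chain id is required for multi-chain snapshots")
    n_chain = sum(1 for r in snapshot.residues if r.chain == chains[0])
    if start < 1 or length < 1 or start + length - 1 > n_chain:
        raise ValueError(
            f"window [{start}, {start + length - 1}] out of range for a "
            f"{n_chain}-residue chain"
        )
    sub = snapshot.subset(list(range(start, start + length)), chains[0])
    return Fragment(sub, source_id, start, length, chain=chains[0], model=model)


def check_connectivity(fragment: Fragment, bond_max: float = DEFAULT_BOND_MAX) -> bool:
    """True iff each consecutive O3'(i)-P(i+1) distance is within bond_max."""
    snap = fragment.snapshot
    for i in range(1, fragment.length):
        try:
            o3 = snap.atom(i, "O3'")
            p = snap.atom(i + 1, "P")
        except KeyError:
            return False
        if float(np.linalg.norm(o3 - p)) > bond_max:
            return False
    return True


def prefilter_threshold(
    centroid: Fragment, ensemble_fragments: list[Fragment],
    base_cutoff: float = DEFAULT_MATCH_CUTOFF,
) -> float:
    """Centroid search radius: base cutoff plus the ensemble's spread.

    ``base_cutoff + max_t eRMSD(centroid, fragment_t)``; by the triangle
    inequality a centroid scan at this radius misses no window that is
    within ``base_cutoff`` of any ensemble member.
    """
    if not ensemble_fragments:
        raise ValueError("empty ensemble")
    dmax = max(ermsd(centroid.snapshot, f.snapshot) for f in ensemble_fragments)
    return base_cutoff + dmax


def enumerate_windows(
    structure_id: str,
    ensemble: Ensemble,
    length: int,
    bond_max: float = DEFAULT_BOND_MAX,
) -> list[Fragment]:
    """All connected windows of ``length`` residues, per model and chain."""
    windows: list[Fragment] = []
    for m, snap in enumerate(ensemble, start=1):
        for ch in snap.chains:
            n_chain = sum(1 for r in snap.residues if r.chain == ch)
            for start in range(1, n_chain - length + 2):
                try:
                    frag = extract_fragment(
                        snap, start, length,
                        source_id=structure_id, chain=ch, model=m,
                    )
                except ValueError:
                    continue
                if check_connectivity(frag, bond_max):
                    windows.append(frag)
    return windows


def _load_library(library, length: int, bond_max: float) -> list[Fragment]:
    windows: list[Fragment] = []
    if isinstance(library, (str, Path)):
        files = sorted(Path(library).glob("*.pdb"))
        entries = [(f.stem, read_multimodel_pdb(f)) for f in files]
    else:
        entries = list(library)
    for sid, ens in entries:
        if isinstance(ens, Snapshot):
            ens = Ensemble([ens])
        windows.extend(enumerate_windows(sid, ens, length, bond_max))
    return windows


def search_library(
    centroid: Fragment,
    library,
    threshold: float,
    bond_max: float = DEFAULT_BOND_MAX,
) -> list[tuple[Fragment, float]]:
    """Scan a library for windows with eRMSD to the centroid below threshold.

    ``library`` is a directory of PDB files or an iterable of
    ``(structure_id, Ensemble)`` pairs.  Windows failing the backbone
    connectivity check are skipped.  Results are sorted canonically
    (structure id, model, chain, start) so the outcome does not depend
    on file ordering.
    """
    out = []
    for frag in _load_library(library, centroid.length, bond_max):
        d = ermsd(centroid.snapshot, frag.snapshot)
        if d < threshold:
            out.append((frag, d))
    out.sort(key=lambda fd: (fd[0].source_id, fd[0].model or 0, fd[0].chain or "", fd[0].start))
    return out


def refine_matches(
    candidates: list[tuple[Fragment, float]] | list[Fragment],
    ensemble_fragments: list[Fragment],
    cutoff: float = DEFAULT_MATCH_CUTOFF,
) -> list[MotifMatch]:
    """Keep candidate windows within ``cutoff`` of >= 1 ensemble member.

    Records, per retained window, the eRMSD to every matching snapshot
    (strictly below the cutoff).
    """
    frags = [c[0] if isinstance(c, tuple) else c for c in candidates]
    n_res = ensemble_fragments[0].snapshot.n_residues if ensemble_fragments else 0
    embeds = np.stack(
        [ermsd_embedding(f.snapshot) for f in ensemble_fragments]
    ) if ensemble_fragments else np.zeros((0, 0))
    matches: list[MotifMatch] = []
    for frag in frags:
        ge = ermsd_embedding(frag.snapshot)
        dists = np.linalg.norm(embeds - ge[None, :], axis=1) / np.sqrt(n_res)
        hit = {int(t): float(d) for t, d in enumerate(dists) if d < cutoff}
        if hit:
            matches.append(
                MotifMatch(
                    library_id=frag.source_id,
                    model=frag.model or 1,
                    chain=frag.chain or "",
                    start=frag.start,
                    bitstring=frag.bitstring,
                    ermsd_by_snapshot=hit,
                )
            )
    return matches


def filter_chi(matches: list[MotifMatch], query_bitstring: str) -> list[MotifMatch]:
    """Keep matches whose syn/anti bitstring equals the query's exactly."""
    return [m for m in matches if m.bitstring == query_bitstring]


def search_ensemble_motifs(
    ensemble: Ensemble,
    library,
    start: int,
    length: int,
    cutoff: float = DEFAULT_MATCH_CUTOFF,
    bond_max: float = DEFAULT_BOND_MAX,
    query_bitstring: str | None = None,
) -> list[MotifMatch]:
    """End-to-end motif search for an ensemble's fragment window.

    Extracts the window from every snapshot, finds the centroid
    fragment, scans the library at the triangle-inequality radius,
    refines against all snapshots and (optionally) applies the
    bitstring filter; ``query_bitstring=None`` keeps matches for any
    snapshot bitstring present in the ensemble.
    """
    frags = [
        extract_fragment(s, start, length, source_id=f"ensemble[{t}]", model=t + 1)
        for t, s in enumerate(ensemble)
    ]
    from .geometry import centroid_index, DistanceCache

    cache = DistanceCache([f.snapshot for f in frags])
    cent = frags[centroid_index([f.snapshot for f in frags], cache)]
    thr = prefilter_threshold(cent, frags, cutoff)
    candidates = search_library(cent, library, thr, bond_max)
    matches = refine_matches(candidates, frags, cutoff)
    if query_bitstring is not None:
        matches = filter_chi(matches, query_bitstring)
    else:
        allowed = {f.bitstring for f in frags}
        matches = [m for m in matches if m.bitstring in allowed]
    return matches


def matches_to_dataframe(matches: list[MotifMatch]) -> pd.DataFrame:
    """Match table: pdb id, chain, start, model, min eRMSD, counts, bits."""
    rows = [
        {
            "pdb_id": m.library_id,
            "chain": m.chain,
            "start": m.start,
            "model": m.model,
            "min_ermsd": round(m.min_ermsd, 6),
            "n_matching_snapshots": m.n_matching_snapshots,
            "chi_bitstring": m.bitstring,
        }
        for m in matches
    ]
    return pd.DataFrame(rows)
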