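"""Two-stage conformational clustering.

Stage one partitions snapshots by their syn/anti bitstring, so that
conformations differing in any glycosidic flip can never share a
cluster.  Stage two builds, inside each pre-cluster, the binary
neighbor graph ``M[t, t'] = 1  iff  eRMSD(t, t') < cutoff`` (default
0.7, below which two structures share essentially the same base-base
contact map) and repeatedly extracts the clique of maximum total
snapshot weight.  Every emitted cluster is therefore conformationally
homogeneous: identical bitstring and all pairwise eRMSD below the
cutoff.  Cluster populations are sums of member weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DistanceCache, chi_conformation
from .structures import Ensemble

__all__ = [
    "PreCluster",
    "Cluster",
    "precluster",
    "neighbor_matrix",
    "max_weight_clique",
    "max_clique_clustering",
    "cluster_ensemble",
    "cluster_statistics",
    "weighted_median",
    "cluster_report",
]

DEFAULT_ERMSD_CUTOFF = 0.7


@dataclass
class PreCluster:
    """Snapshots sharing one exact syn/anti bitstring."""

    bitstring: str
    members: list[int]           # snapshot indices, ascending
    weight_fraction: float       # summed normalized weights


@dataclass
class Cluster:
    """A max-clique cluster: mutually similar, same-bitstring snapshots."""

    cluster_id: int              # 1-based, descending population
    members: list[int]
    population: float            # sum of member weights
    bitstring: str


def precluster(conformations: list[str], weights: np.ndarray | None = None) -> list[PreCluster]:
    """Partition snapshot indices by exact bitstring equality.

    Returned pre-clusters are sorted by descending weighted fraction
    (ties by bitstring) and their fractions sum to 1.
    """
    n = len(conformations)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must match conformation count")
        w = w / w.sum()
    groups: dict[str, list[int]] = {}
    for i, bits in enumerate(conformations):
        groups.setdefault(bits, []).append(i)
    pcs = [
        PreCluster(bits, members, float(w[members].sum()))
        for bits, members in groups.items()
    ]
    pcs.sort(key=lambda p: (-p.weight_fraction, p.bitstring))
    return pcs


def neighbor_matrix(
    members: list[int], cache: DistanceCache, cutoff: float = DEFAULT_ERMSD_CUTOFF
) -> np.ndarray:
    """Binary adjacency over a member list: 1 iff eRMSD strictly below cutoff."""
    q = len(members)
    M = np.eye(q, dtype=np.int8)
    for a in range(q):
        for b in range(a + 1, q):
            M[a, b] = M[b, a] = 1 if cache.get(members[a], members[b]) < cutoff else 0
    return M


def max_weight_clique(adjacency: np.ndarray, weights: np.ndarray) -> list[int]:
    """Exact maximum-total-weight clique of an undirected graph.

    Branch-and-bound over vertices in index order; the bound at each node
    is the current clique weight plus the total weight of remaining
    candidates.  Among maximum-weight cliques the lexicographically
    smallest sorted member set is returned, which makes extraction
    deterministic even under weight ties (e.g. uniform weights).
    """
    A = np.asarray(adjacency, dtype=bool)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency must be square")
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length must match node count")
    if np.any(w < 0):
        raise ValueError("node weights must be nonnegative")
    best: list[int] = []
    best_w = -1.0

    def visit(clique: list[int], clique_w: float, candidates: np.ndarray) -> None:
        nonlocal best, best_w
        if clique_w > best_w or (clique_w == best_w and clique < best):
            best = list(clique)
            best_w = clique_w
        if candidates.size == 0:
            return
        rem = float(w[candidates].sum())
        for k, v in enumerate(candidates):
            if clique_w + rem < best_w:  # strict: keep ties explorable
                return
            nxt = candidates[k + 1:]
            nxt = nxt[A[v, nxt]]
            visit(clique + [int(v)], clique_w + float(w[v]), nxt)
            rem -= float(w[v])

    visit([], 0.0, np.arange(n))
    if not best and n:
        # all-zero weights: every clique ties at 0 and the empty set wins
        # lexicographically; return the smallest singleton so extraction
        # always removes at least one node
        return [0]
    return sorted(best)


def greedy_weight_clique(adjacency: np.ndarray, weights: np.ndarray) -> list[int]:
    """Greedy fallback for very large graphs: grow from the heaviest vertex."""
    A = np.asarray(adjacency, dtype=bool)
    w = np.asarray(weights, dtype=float)
    order = sorted(range(len(w)), key=lambda i: (-w[i], i))
    clique: list[int] = []
    for v in order:
        if all(A[v, u] for u in clique):
            clique.append(v)
    return sorted(clique)


def max_clique_clustering(
    adjacency: np.ndarray,
    weights: np.ndarray,
    members: list[int] | None = None,
    exact: bool = True,
) -> list[list[int]]:
    """Iteratively extract max-weight cliques until all nodes are assigned.

    Each round removes the extracted clique from the graph; singleton
    cliques are allowed.  Returns member lists (snapshot indices if
    ``members`` maps local to global indices), in extraction order.
    """
    A = np.asarray(adjacency, dtype=bool).copy()
    w = np.asarray(weights, dtype=float)
    n = A.shape[0]
    if members is None:
        members = list(range(n))
    alive = list(range(n))
    out: list[list[int]] = []
    find = max_weight_clique if exact else greedy_weight_clique
    while alive:
        sub = A[np.ix_(alive, alive)]
        clique_local = find(sub, w[alive])
        clique = [alive[i] for i in clique_local]
        out.append([members[i] for i in clique])
        alive = [i for i in alive if i not in set(clique)]
    return out


def cluster_ensemble(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    cutoff: float = DEFAULT_ERMSD_CUTOFF,
    cache: DistanceCache | None = None,
    conformations: list[str] | None = None,
    exact: bool = True,
) -> list[Cluster]:
    """Full two-stage clustering of an ensemble.

    Pre-cluster by bitstring, then max-weight-clique cluster each
    pre-cluster under the eRMSD cutoff.  Clusters are numbered 1-based
    by descending population (ties by smallest member index).  A
    pre-cluster whose members all carry zero weight is emitted as
    singletons with zero population.
    """
    T = len(ensemble)
    if weights is None:
        w = np.full(T, 1.0 / T)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (T,):
            raise ValueError("weights length must equal ensemble size")
        w = w / w.sum()
    if conformations is None:
        conformations = [chi_conformation(s) for s in ensemble]
    if cache is None:
        cache = DistanceCache(list(ensemble))
    raw: list[tuple[list[int], str]] = []
    for pc in precluster(conformations, w):
        if not np.any(w[pc.members] > 0):
            raw.extend(([m], pc.bitstring) for m in pc.members)
            continue
        M = neighbor_matrix(pc.members, cache, cutoff)
        for mem in max_clique_clustering(M, w[pc.members], members=pc.members, exact=exact):
            raw.append((sorted(mem), pc.bitstring))
    raw.sort(key=lambda item: (-w[item[0]].sum(), item[0]))
    return [
        Cluster(cluster_id=i + 1, members=mem, population=float(w[mem].sum()), bitstring=bits)
        for i, (mem, bits) in enumerate(raw)
    ]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median as used for per-cluster signal summaries.

    The maximum value v such that the relative weight of
    ``{values <= v}`` is strictly below 0.5; if even the smallest value
    carries half the mass or more, the smallest value is returned.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("need nonempty values with positive total weight")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order] / w.sum()
    uniq, inverse = np.unique(v, return_inverse=True)
    mass = np.zeros(uniq.size)
    np.add.at(mass, inverse, w)
    cum = np.cumsum(mass)
    below_half = np.flatnonzero(cum < 0.5)
    if below_half.size == 0:
        return float(uniq[0])
    return float(uniq[below_half[-1]])


def cluster_statistics(
    cluster: Cluster | list[int], signal_matrix: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-restraint weighted averages and weighted medians for a cluster.

    ``<f_i>_wc = sum_{t in c} w_t f_{i,t} / sum_{t in c} w_t``; medians
    per :func:`weighted_median`.
    """
    members = cluster.members if isinstance(cluster, Cluster) else list(cluster)
    F = np.asarray(signal_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)[members]
    if not members:
        raise ValueError("empty cluster")
    if w.sum() <= 0:
        raise ValueError("cluster member weights are all zero")
    sub = F[:, members]
    avg = sub @ (w / w.sum())
    med = np.array([weighted_median(sub[i], w) for i in range(sub.shape[0])])
    return avg, med


def cluster_report(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster summary table: id, population, bitstring, member count."""
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "population": [c.population for c in clusters],
            "chi_bitstring": [c.bitstring for c in clusters],
            "n_members": [len(c.members) for c in clusters],
        }
    )


def write_assignments(clusters: list[Cluster], path: str | Path) -> None:
    """TSV of (snapshot_id, cluster_id) assignments."""
    rows = sorted(
        (m, c.cluster_id) for c in clusters for m in c.members
    )
    pd.DataFrame(rows, columns=["snapshot_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )
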