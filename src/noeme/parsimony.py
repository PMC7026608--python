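"""Maximum-parsimony selection of minimal cluster sets.

Given per-cluster average NOE signals and the restraint thresholds,
find the smallest number Y of clusters that can be re-weighted so that
every averaged signal clears its threshold.  The weight grid assigns
each of the Y clusters a weight that is a positive multiple of a step
(default 0.01, i.e. integer percent), summing to 1.  Feasible sets are
ranked by the Kullback-Leibler divergence between the assigned weights
and the clusters' original populations, so that among all minimal
explanations the one closest to the simulated ensemble comes first.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .noe import RestraintSet

__all__ = [
    "ClusterSignalTable",
    "RankedSet",
    "MinimalSetResult",
    "enumerate_compositions",
    "set_average",
    "kl_divergence",
    "find_minimal_sets",
    "rank_sets",
    "DEFAULT_POPULATION_FLOOR",
]

DEFAULT_POPULATION_FLOOR = 0.002
#: relative tolerance absorbing floating-point noise at the threshold
FEASIBILITY_RTOL = 1e-12


@dataclass
class ClusterSignalTable:
    """Per-cluster populations and per-restraint average signals.

    Only clusters whose population exceeds the floor are admitted to
    the search (tiny clusters carry too few snapshots for a robust
    average).
    """

    cluster_ids: list[int]
    populations: np.ndarray          # (n_clusters,), raw ensemble populations
    signals: np.ndarray              # (n_clusters, n_restraints), nm^-6

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.cluster_ids) != self.populations.size:
            raise ValueError("cluster_ids and populations disagree in length")
        if self.signals.shape[0] != self.populations.size:
            raise ValueError("signals row count must match cluster count")
        if np.any(self.signals <= 0):
            raise ValueError("signals must be positive")

    def __len__(self) -> int:
        return len(self.cluster_ids)

    def apply_floor(self, floor: float = DEFAULT_POPULATION_FLOOR) -> "ClusterSignalTable":
        """Keep only clusters with population strictly above the floor."""
        keep = np.flatnonzero(self.populations > floor)
        if keep.size == 0:
            raise ValueError(f"no cluster has population > {floor}")
        return ClusterSignalTable(
            [self.cluster_ids[i] for i in keep],
            self.populations[keep],
            self.signals[keep],
        )

    @classmethod
    def from_clusters(
        cls, clusters, signal_matrix: np.ndarray, weights: np.ndarray,
        floor: float | None = DEFAULT_POPULATION_FLOOR,
    ) -> "ClusterSignalTable":
        """Build the table from clustering output and the signal matrix."""
        from .clustering import cluster_statistics

        ids, pops, sigs = [], [], []
        for c in clusters:
            if floor is not None and c.population <= floor:
                continue
            avg, _ = cluster_statistics(c, signal_matrix, weights)
            ids.append(c.cluster_id)
            pops.append(c.population)
            sigs.append(avg)
        if not ids:
            raise ValueError("no clusters above the population floor")
        return cls(ids, np.asarray(pops), np.asarray(sigs))


@dataclass
class RankedSet:
    """One feasible weighted combination of clusters."""

    cluster_ids: tuple[int, ...]
    weights: tuple[float, ...]
    kl: float
    feasible: bool = True

    def as_row(self) -> dict:
        row: dict = {}
        for k, (cid, w) in enumerate(zip(self.cluster_ids, self.weights), start=1):
            row[f"c{k}"] = cid
            row[f"w{k}"] = round(w, 10)
        row["D_KL"] = self.kl
        return row


@dataclass
class MinimalSetResult:
    """Outcome of the minimal-set search."""

    Y: int                           # minimal number of clusters
    sets: list[RankedSet]            # all feasible sets at Y, ranked by KL
    mode: str
    step: float
    infeasible: bool = False
    most_violated_restraint: int | None = None

    def to_dataframe(self, top: int | None = None) -> pd.DataFrame:
        sets = self.sets if top is None else self.sets[:top]
        return pd.DataFrame([s.as_row() for s in sets])


def enumerate_compositions(Y: int, step: float = 0.01) -> Iterator[tuple[float, ...]]:
    """All vectors of Y positive multiples of ``step`` summing to 1.

    Each weight lies in [step, (N - Y + 1) * step] with N = 1/step;
    there are C(N - 1, Y - 1) such vectors, emitted in lexicographic
    order of the underlying integer compositions.
    """
    N = round(1.0 / step)
    if not math.isclose(N * step, 1.0, rel_tol=1e-9):
        raise ValueError("1/step must be an integer")
    if Y < 1 or Y > N:
        raise ValueError(f"Y must be in [1, {N}]")

    def parts(total: int, k: int) -> Iterator[tuple[int, ...]]:
        if k == 1:
            yield (total,)
            return
        for first in range(1, total - k + 2):
            for rest in parts(total - first, k - 1):
                yield (first,) + rest

    for combo in parts(N, Y):
        yield tuple(c * step for c in combo)


def count_compositions(Y: int, step: float = 0.01) -> int:
    """Closed form C(1/step - 1, Y - 1)."""
    N = round(1.0 / step)
    return math.comb(N - 1, Y - 1)


def set_average(
    table: ClusterSignalTable, cluster_ids: Sequence[int], weights: Sequence[float]
) -> np.ndarray:
    """Per-restraint convex combination of cluster averages."""
    idx = [table.cluster_ids.index(c) for c in cluster_ids]
    w = np.asarray(weights, dtype=float)
    if len(idx) != w.size:
        raise ValueError("cluster_ids and weights disagree in length")
    if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
        raise ValueError("weights must be nonnegative and sum to 1")
    return w @ table.signals[idx]


def kl_divergence(weights: Sequence[float], populations: Sequence[float]) -> float:
    """``sum_y w'_y ln(w'_y / P_y)`` over the clusters of a set.

    Populations enter raw, exactly as reported for the full ensemble
    (they need not sum to 1 on the set), so the divergence can be
    negative-free only when P is renormalized; use
    ``renormalized=True`` variants downstream for sensitivity checks.
    """
    w = np.asarray(weights, dtype=float)
    p = np.asarray(populations, dtype=float)
    if np.any(p <= 0):
        raise ValueError("populations in the set must be positive")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    mask = w > 0
    return float(np.sum(w[mask] * np.log(w[mask] / p[mask])))


def _feasible(avg: np.ndarray, f_exp: np.ndarray) -> bool:
    return bool(np.all(avg >= f_exp * (1.0 - FEASIBILITY_RTOL)))


def _subset_lp_feasible(signals: np.ndarray, f_exp: np.ndarray, step: float) -> bool:
    """LP relaxation: does any w on the simplex with w_y >= step satisfy
    ``signals.T @ w >= f_exp``?  Grid points are a subset of this
    polytope, so LP infeasibility rules the subset out exactly."""
    Y = signals.shape[0]
    res = linprog(
        c=np.zeros(Y),
        A_ub=-signals.T,
        b_ub=-f_exp * (1.0 - FEASIBILITY_RTOL),
        A_eq=np.ones((1, Y)),
        b_eq=[1.0],
        bounds=[(step, None)] * Y,
        method="highs",
    )
    return res.status == 0


def rank_sets(sets: list[RankedSet]) -> list[RankedSet]:
    """Sort feasible sets by ascending KL divergence, ties by cluster ids."""
    return sorted(sets, key=lambda s: (s.kl, s.cluster_ids))


def find_minimal_sets(
    table: ClusterSignalTable,
    restraints: RestraintSet | np.ndarray,
    step: float = 0.01,
    mode: str = "lp-prefilter",
    renormalized_kl: bool = False,
    max_Y: int | None = None,
) -> MinimalSetResult:
    """Smallest Y with a feasible weight composition, and all such sets.

    Y starts at 1 and grows until at least one subset of Y clusters
    admits a grid composition whose combined averages clear every
    threshold.  ``mode='exact-grid'`` enumerates the full grid for every
    subset; ``mode='lp-prefilter'`` (default) first solves a linear
    feasibility problem per subset and enumerates the grid only inside
    LP-feasible subsets -- provably the same result, since every grid
    point lies in the LP polytope.
    """
    if mode not in ("exact-grid", "lp-prefilter"):
        raise ValueError(f"unknown mode {mode!r}")
    f_exp = restraints.f_exp if isinstance(restraints, RestraintSet) else np.asarray(restraints, float)
    if f_exp.shape != (table.signals.shape[1],):
        raise ValueError("threshold count must match the table's restraint count")
    n = len(table)
    top_Y = n if max_Y is None else min(max_Y, n)
    for Y in range(1, top_Y + 1):
        found: list[RankedSet] = []
        for subset in itertools.combinations(range(n), Y):
            sig = table.signals[list(subset)]
            if mode == "lp-prefilter" and Y > 1:
                if not _subset_lp_feasible(sig, f_exp, step):
                    continue
            pops = table.populations[list(subset)]
            ids = tuple(table.cluster_ids[i] for i in subset)
            for w in enumerate_compositions(Y, step):
                avg = np.asarray(w) @ sig
                if _feasible(avg, f_exp):
                    p = pops / pops.sum() if renormalized_kl else pops
                    found.append(RankedSet(ids, w, kl_divergence(w, p)))
        if found:
            return MinimalSetResult(Y, rank_sets(found), mode, step)
    # no feasible set at any size: report the hardest restraint, i.e. the
    # one with the worst best-achievable relative signal
    best_ratio = np.max(table.signals / f_exp, axis=0)
    worst = int(np.argmin(best_ratio))
    return MinimalSetResult(
        n, [], mode, step, infeasible=True, most_violated_restraint=worst
    )
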