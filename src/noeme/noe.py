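"""NOE forward model, restraint tables, ensemble averages and violations.

An NOE cross-peak between protons j and k reports, under the assumption
that conformational exchange is slow compared with molecular tumbling,
the ensemble average of ``f(d) = 1/d^6`` with d the interproton
distance.  Signal classes map to maximum distances (strong 3.6 A,
medium 5.0 A, weak 6.5 A); each maximum distance d_exp turns into a
lower threshold on the averaged signal, ``<f(d)> >= f(d_exp)``.
Signals are carried in nm^-6 so that the error scale sigma of the
reweighting step (0.5 nm^-6) applies without conversion; restraint
files give distances in Angstrom and are converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import Ensemble, Snapshot, normalize_atom_name, proton_distance

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_DISTANCES_ANGSTROM",
    "NOERestraint",
    "RestraintSet",
    "forward_signal",
    "build_signal_matrix",
    "relative_signals",
    "count_violations",
    "violation_score",
    "violation_report",
]

#: signal class -> maximum interproton distance in Angstrom
CLASS_DISTANCES_ANGSTROM = {"strong": 3.6, "medium": 5.0, "weak": 6.5}
_CLASS_ALIASES = {
    "s": "strong", "strong": "strong",
    "m": "medium", "med": "medium", "medium": "medium",
    "w": "weak", "l": "weak", "weak": "weak", "long": "weak",
}


def forward_signal(d_angstrom: float | np.ndarray) -> float | np.ndarray:
    """NOE forward model ``f(d) = 1/d^6`` in nm^-6, d given in Angstrom."""
    d = np.asarray(d_angstrom, dtype=float)
    if np.any(d <= 0):
        raise ValueError("interproton distance must be positive")
    out = (d / 10.0) ** -6
    return float(out) if np.isscalar(d_angstrom) else out


@dataclass(frozen=True)
class NOERestraint:
    """One upper-distance bound between two named protons."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    d_exp: float                 # maximum distance, Angstrom
    signal_class: str | None = None   # strong / medium / weak, if class-derived
    label: str | None = None

    def __post_init__(self) -> None:
        if self.d_exp <= 0:
            raise ValueError("d_exp must be positive")

    @property
    def f_exp(self) -> float:
        """Threshold signal f(d_exp) in nm^-6."""
        return float(forward_signal(self.d_exp))

    @property
    def pair(self) -> tuple[tuple[int, str], tuple[int, str]]:
        return ((self.res_i, self.atom_i), (self.res_j, self.atom_j))

    def name(self) -> str:
        return self.label or f"{self.res_i}{self.atom_i}-{self.res_j}{self.atom_j}"


class RestraintSet:
    """An ordered list of NOE upper-distance restraints."""

    def __init__(self, restraints: Sequence[NOERestraint]):
        self.restraints = list(restraints)
        if not self.restraints:
            raise ValueError("empty restraint set")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i: int) -> NOERestraint:
        return self.restraints[i]

    @property
    def f_exp(self) -> np.ndarray:
        """Threshold signals, nm^-6, shape (n_restraints,)."""
        return np.array([r.f_exp for r in self.restraints])

    @property
    def d_exp(self) -> np.ndarray:
        return np.array([r.d_exp for r in self.restraints])

    def names(self) -> list[str]:
        return [r.name() for r in self.restraints]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RestraintSet":
        cols = {c.lower().strip(): c for c in df.columns}
        required = ["res_i", "atom_i", "res_j", "atom_j"]
        for c in required:
            if c not in cols:
                raise ValueError(f"restraint table misses column {c!r}")
        if "d_min" in cols:
            # minimum NOE distances are not usable as ensemble lower bounds
            logger.info("restraint table contains minimum distances; ignored")
        restraints = []
        for _, row in df.iterrows():
            cls_or_d = None
            signal_class = None
            if "class" in cols and not pd.isna(row[cols["class"]]):
                cls_or_d = str(row[cols["class"]]).strip().lower()
            if cls_or_d in _CLASS_ALIASES:
                signal_class = _CLASS_ALIASES[cls_or_d]
                d_exp = CLASS_DISTANCES_ANGSTROM[signal_class]
            elif "d_max" in cols and not pd.isna(row[cols["d_max"]]):
                d_exp = float(row[cols["d_max"]])
            elif cls_or_d is not None:
                d_exp = float(cls_or_d)
            else:
                raise ValueError("each restraint needs a class or a d_max column")
            restraints.append(
                NOERestraint(
                    res_i=int(row[cols["res_i"]]),
                    atom_i=normalize_atom_name(str(row[cols["atom_i"]])),
                    res_j=int(row[cols["res_j"]]),
                    atom_j=normalize_atom_name(str(row[cols["atom_j"]])),
                    d_exp=d_exp,
                    signal_class=signal_class,
                )
            )
        return cls(restraints)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RestraintSet":
        """Read a CSV/TSV table with columns res_i, atom_i, res_j, atom_j,
        class (s/m/w or strong/medium/weak) and/or d_max (Angstrom);
        an optional d_min column is parsed and discarded."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls.from_dataframe(pd.read_csv(path, sep=sep))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res_i": [r.res_i for r in self.restraints],
                "atom_i": [r.atom_i for r in self.restraints],
                "res_j": [r.res_j for r in self.restraints],
                "atom_j": [r.atom_j for r in self.restraints],
                "class": [r.signal_class or "" for r in self.restraints],
                "d_max": [r.d_exp for r in self.restraints],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def load_critical_panel(residue_offset: int = 0) -> RestraintSet:
    """The bundled critical-NOE panel of the 29-nt hairpin study system.

    Pairs are in 1-based hairpin numbering; ``residue_offset`` shifts
    them (63 maps to the deposited entry's author numbering).
    """
    from importlib.resources import files

    df = pd.read_csv(files("noeme.data").joinpath("critical_noe_panel.csv"))
    rs = RestraintSet.from_dataframe(df)
    if residue_offset:
        rs = RestraintSet(
            [
                NOERestraint(
                    r.res_i + residue_offset, r.atom_i,
                    r.res_j + residue_offset, r.atom_j,
                    r.d_exp, r.signal_class,
                )
                for r in rs
            ]
        )
    return rs


def build_signal_matrix(ensemble: Ensemble, restraints: RestraintSet) -> np.ndarray:
    """Per-restraint, per-snapshot forward signals, shape (n_restraints, T), nm^-6."""
    T = len(ensemble)
    mat = np.empty((len(restraints), T))
    for i, r in enumerate(restraints):
        try:
            for t, snap in enumerate(ensemble):
                mat[i, t] = forward_signal(proton_distance(snap, r.pair))
        except KeyError as exc:
            raise KeyError(f"restraint {i + 1} ({r.name()}): {exc}") from None
    return mat


def _weights_or_uniform(weights, T: int) -> np.ndarray:
    if weights is None:
        return np.full(T, 1.0 / T)
    w = np.asarray(weights, dtype=float)
    if w.shape != (T,):
        raise ValueError("weights length must equal the snapshot count")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return w / w.sum()


def relative_signals(
    matrix: np.ndarray, restraints: RestraintSet, weights=None
) -> np.ndarray:
    """Relative average signals ``<f(d_i)>_w / f_exp_i`` per restraint.

    A ratio below 1 means the averaged signal falls short of the
    threshold, i.e. the upper-distance bound is violated.
    """
    matrix = np.asarray(matrix, dtype=float)
    w = _weights_or_uniform(weights, matrix.shape[1])
    avg = matrix @ w
    return avg / restraints.f_exp


def count_violations(ratios: np.ndarray) -> int:
    """Number of restraints with relative signal strictly below 1."""
    ratios = np.asarray(ratios, dtype=float)
    if not np.all(np.isfinite(ratios)):
        raise ValueError("ratios must be finite")
    return int(np.sum(ratios < 1.0))


def violation_score(ratios: np.ndarray, mode: str = "shortfall") -> float:
    """Aggregate violation severity.

    ``shortfall`` (default) sums ``max(0, 1 - ratio)`` over restraints;
    ``count`` returns the violation count as a float.  The shortfall
    definition is this package's own aggregate; the mode used is
    recorded in report metadata.
    """
    ratios = np.asarray(ratios, dtype=float)
    if not np.all(np.isfinite(ratios)):
        raise ValueError("ratios must be finite")
    if mode == "shortfall":
        return float(np.sum(np.clip(1.0 - ratios, 0.0, None)))
    if mode == "count":
        return float(count_violations(ratios))
    raise ValueError(f"unknown violation score mode {mode!r}")


def violation_report(
    restraints: RestraintSet,
    ratios: np.ndarray,
    critical_below: float | None = None,
) -> pd.DataFrame:
    """Tabular report: restraint, class, relative signal, violation flag.

    With ``critical_below`` set (e.g. 1.2), only restraints whose ratio
    falls below it are listed -- the "critical NOE" presentation.
    """
    df = pd.DataFrame(
        {
            "restraint": restraints.names(),
            "class": [r.signal_class or f"{r.d_exp:.2f}A" for r in restraints],
            "relative_signal": np.round(np.asarray(ratios, dtype=float), 6),
        }
    )
    df["violated"] = df["relative_signal"] < 1.0
    if critical_below is not None:
        df = df[df["relative_signal"] < critical_below].reset_index(drop=True)
    return df
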