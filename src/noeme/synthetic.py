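"""Desk-scale synthetic fixtures with known ground truth.

The generator emulates the situation the analysis pipeline is built
for: an RNA-like chain that interconverts between a handful of
metastable sub-states distinguished by glycosidic syn/anti flips and by
backbone geometry, observed only through sparse NOE-style upper
distance bounds that average over the mixture.

Each toy nucleotide carries exactly the atoms the implemented metrics
touch: the base six-ring (plus the fused five-ring atoms for purines),
C1'/O4'/H1' on the sugar side, the H6/H8 base proton and the O3'/P
backbone pair.  Full sugar geometry is not modeled.  Residues sit on an
idealized helix; a state's syn/anti pattern is imposed by rigidly
rotating each base about its glycosidic bond to the target chi, and
geometric sub-states with identical bitstrings are created by smooth
per-state backbone deformations.  The phosphorus of residue i+1 is
placed 1.6 A from O3' of residue i by construction, so backbone
connectivity always holds.

Everything is driven by one seeded generator; the same seed gives
bit-identical output.  After generation the ensemble is verified to be
clusterable as planted (within-state eRMSD < 0.7, between-state > 0.7)
and is regenerated with a derived sub-seed when the check fails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import SYN_UPPER_DEG, chi_angle, chi_conformation, pairwise_ermsd
from .noe import CLASS_DISTANCES_ANGSTROM, NOERestraint, RestraintSet, build_signal_matrix, forward_signal
from .structures import Ensemble, ResidueInfo, Snapshot, write_multimodel_pdb

__all__ = [
    "StateSpec",
    "generate_toy_ensemble",
    "generate_mixture_restraints",
    "default_pair_panel",
    "plant_motif_library",
    "write_fixture",
]

_RING_BOND = 1.39
_SYN_BOUNDARY_MARGIN = 12.0   # degrees chi must keep from 0/115 after jitter


@dataclass(frozen=True)
class StateSpec:
    """One planted metastable sub-state.

    ``syn_residues`` lists 1-based residues whose chi is driven into the
    syn window; all others are anti.  ``backbone_shift_scale`` (A)
    deforms the state's backbone template so that states sharing a
    bitstring still separate in eRMSD.  ``population`` is the planted
    mixture fraction.
    """

    state_id: str
    population: float
    syn_residues: tuple[int, ...] = ()
    backbone_shift_scale: float = 0.0
    syn_angle: float = 60.0
    anti_angle: float = 200.0
    chi_jitter: float = 2.0

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be nonnegative")
        for target in (self.syn_angle, self.anti_angle):
            lo, hi = target - self.chi_jitter, target + self.chi_jitter
            for boundary in (0.0, SYN_UPPER_DEG, 360.0):
                if lo - _SYN_BOUNDARY_MARGIN < boundary < hi + _SYN_BOUNDARY_MARGIN:
                    raise ValueError(
                        f"chi target {target} +- {self.chi_jitter} comes within "
                        f"{_SYN_BOUNDARY_MARGIN} deg of the syn/anti boundary {boundary}"
                    )

    def bitstring(self, n_residues: int) -> str:
        return "".join(
            "1" if r in self.syn_residues else "0" for r in range(1, n_residues + 1)
        )


# ---------------------------------------------------------------------------
# single-nucleotide template
# ---------------------------------------------------------------------------

def _hexagon(center: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized six-membered ring, N1 at local angle 180 deg."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    ring = {}
    for k, name in enumerate(names):
        ang = math.radians(180.0 + 60.0 * k)
        ring[name] = center + _RING_BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    return ring


def _base_atoms(kind: str) -> dict[str, np.ndarray]:
    """Planar base with glycosidic nitrogen at the origin, extending +x."""
    if kind == "pyrimidine":
        ring = _hexagon(np.array([_RING_BOND, 0.0, 0.0]))
        c6 = ring["C6"]
        out = c6 - np.array([_RING_BOND, 0.0, 0.0])
        ring["H6"] = c6 + 1.08 * out / np.linalg.norm(out)
        return ring
    # purine: six-ring fused to a five-ring; N9 (glycosidic) sits at origin
    hexc = np.array([3.0, 0.6, 0.0])
    ring = _hexagon(hexc)
    c4, c5 = ring["C4"], ring["C5"]
    # regular pentagon on the C4-C5 edge, on the side away from the hexagon
    edge_mid = (c4 + c5) / 2.0
    edge = c5 - c4
    edge_len = float(np.linalg.norm(edge))
    normal = np.array([-edge[1], edge[0], 0.0]) / edge_len
    if np.dot(normal, edge_mid - hexc) < 0:
        normal = -normal
    apo = edge_len / (2.0 * math.tan(math.pi / 5.0))
    circ = edge_len / (2.0 * math.sin(math.pi / 5.0))
    pent_c = edge_mid + apo * normal
    def pent_atom(base_pt):
        v = base_pt - pent_c
        return pent_c + circ * v / np.linalg.norm(v)
    # order around the pentagon: C4, N9, C8, N7, C5
    ang_c4 = math.atan2(*(c4 - pent_c)[[1, 0]])
    ang_c5 = math.atan2(*(c5 - pent_c)[[1, 0]])
    step = (ang_c5 - ang_c4) % (2 * math.pi)
    direction = 1.0 if step < math.pi else -1.0
    angs = [ang_c4 - direction * 2 * math.pi / 5 * k for k in (1, 2, 3)]
    n9, c8, n7 = (
        pent_c + circ * np.array([math.cos(a), math.sin(a), 0.0]) for a in angs
    )
    ring.update({"N9": n9, "C8": c8, "N7": n7})
    out = c8 - pent_c
    ring["H8"] = c8 + 1.08 * out / np.linalg.norm(out)
    # shift so the glycosidic nitrogen is the origin
    shift = ring["N9"].copy()
    return {k: v - shift for k, v in ring.items()}


_SUGAR_LOCAL = {
    # fixed sugar-side atoms in the residue frame (glycosidic N at origin,
    # C1'-N bond along +x); no attempt at full ribose geometry
    "C1'": np.array([-1.47, 0.0, 0.0]),
    "O4'": np.array([-1.95, 1.28, 0.35]),
    "H1'": np.array([-1.80, -0.62, -0.83]),
    "O3'": np.array([-2.30, -1.60, 0.90]),
}


def _rot_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _residue_template(kind: str) -> tuple[dict[str, np.ndarray], float]:
    """Local atom set plus the chi value of the flat construction."""
    atoms = dict(_SUGAR_LOCAL)
    atoms.update(_base_atoms(kind))
    ref = "C4" if kind == "purine" else "C2"
    glyco = "N9" if kind == "purine" else "N1"
    from .geometry import dihedral

    chi0 = dihedral(atoms["O4'"], atoms["C1'"], atoms[glyco], atoms[ref]) % 360.0
    return atoms, chi0


def _state_frames(
    n_residues: int, rng: np.random.Generator, shift_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Helical anchors and frames, optionally smoothly deformed per state."""
    # tight helix: neighboring bases sit well inside the eRMSD interaction
    # shell, so a single glycosidic flip separates states by > 0.7
    radius, twist, rise = 4.0, 60.0, 2.2
    anchors = np.empty((n_residues, 3))
    frames = np.empty((n_residues, 3, 3))
    for r in range(n_residues):
        th = math.radians(twist * r)
        anchors[r] = [radius * math.cos(th), radius * math.sin(th), rise * r]
        inward = -np.array([math.cos(th), math.sin(th), 0.0])
        up = np.array([0.0, 0.0, 1.0])
        tang = np.cross(up, inward)
        frames[r] = np.stack([inward, tang, up], axis=1)  # columns = local axes
    if shift_scale > 0:
        raw = rng.normal(scale=shift_scale, size=(n_residues, 3))
        kernel = np.array([0.25, 0.5, 0.25])
        smooth = np.empty_like(raw)
        for k in range(3):
            smooth[:, k] = np.convolve(raw[:, k], kernel, mode="same")
        anchors = anchors + smooth
    return anchors, frames


_SEQUENCE_CYCLE = ("G", "U", "A", "C")


def _chain_sequence(n_residues: int) -> list[tuple[str, str]]:
    seq = []
    for r in range(n_residues):
        name = _SEQUENCE_CYCLE[r % len(_SEQUENCE_CYCLE)]
        kind = "purine" if name in ("A", "G") else "pyrimidine"
        seq.append((name, kind))
    return seq


def _build_snapshot(
    model_id: int,
    n_residues: int,
    chi_targets: np.ndarray,
    anchors: np.ndarray,
    frames: np.ndarray,
    noise: float,
    rng: np.random.Generator,
) -> Snapshot:
    seq = _chain_sequence(n_residues)
    coords: list[np.ndarray] = []
    keys: list[tuple[str, int, str]] = []
    residues: list[ResidueInfo] = []
    base_names = {
        "purine": ["N9", "C8", "N7", "N1", "C2", "N3", "C4", "C5", "C6", "H8"],
        "pyrimidine": ["N1", "C2", "N3", "C4", "C5", "C6", "H6"],
    }
    sugar_names = ["O4'", "C1'", "H1'", "O3'"]
    placed: dict[tuple[int, str], np.ndarray] = {}
    for r in range(n_residues):
        name, kind = seq[r]
        residues.append(ResidueInfo(r + 1, name, "A", kind))
        template, chi0 = _residue_template(kind)
        # rotating the base by +theta about the glycosidic +x axis advances
        # the measured torsion by +theta
        rot = _rot_x(chi_targets[r] - chi0)
        local = {}
        for an in sugar_names:
            local[an] = template[an]
        for an in base_names[kind]:
            local[an] = rot @ template[an]
        for an, pos in local.items():
            placed[(r + 1, an)] = anchors[r] + frames[r] @ pos
    # phosphates: P(1) near C1'(1); P(i+1) exactly 1.6 A from O3'(i)
    placed[(1, "P")] = placed[(1, "C1'")] + np.array([-1.2, -1.2, -1.6])
    for r in range(1, n_residues):
        o3 = placed[(r, "O3'")]
        target = placed[(r + 1, "C1'")]
        u = target - o3
        placed[(r + 1, "P")] = o3 + 1.6 * u / np.linalg.norm(u)
    for r in range(n_residues):
        name, kind = seq[r]
        atom_names = ["P", "O4'", "C1'", "H1'"] + base_names[kind] + ["O3'"]
        for an in atom_names:
            keys.append(("A", r + 1, an))
            coords.append(placed[(r + 1, an)])
    xyz = np.asarray(coords)
    if noise > 0:
        xyz = xyz + rng.normal(scale=noise, size=xyz.shape)
    return Snapshot(model_id, xyz, keys, residues)


def _planted_counts(populations: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n snapshots to the states."""
    exact = populations * n
    counts = np.floor(exact).astype(int)
    rest = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:rest]] += 1
    return counts


def generate_toy_ensemble(
    n_residues: int,
    states: list[StateSpec],
    n_snapshots: int,
    seed: int,
    noise: float = 0.03,
    max_attempts: int = 10,
) -> tuple[Ensemble, np.ndarray]:
    """Sample an ensemble from planted sub-states; returns (ensemble, labels).

    Snapshot counts per state follow the planted populations by
    largest-remainder apportionment (so the realized mixture matches the
    plant as closely as T allows); the snapshot order is shuffled.
    After generation the planted partition is verified on the eRMSD
    matrix -- all within-state pairs < 0.7, all between-state pairs
    > 0.7 -- and the ensemble is regenerated from a derived sub-seed on
    failure, at most ``max_attempts`` times.
    """
    if not states:
        raise ValueError("need at least one state")
    pops = np.array([s.population for s in states], dtype=float)
    if pops.sum() <= 0:
        raise ValueError("state populations must have positive sum")
    pops = pops / pops.sum()
    for s in states:
        for r in s.syn_residues:
            if not 1 <= r <= n_residues:
                raise ValueError(f"state {s.state_id}: syn residue {r} out of range")
    master = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(master.integers(2**31))
        counts = _planted_counts(pops, n_snapshots)
        labels = np.repeat([s.state_id for s in states], counts)
        rng.shuffle(labels)
        geo = {}
        for s in states:
            state_rng = np.random.default_rng(rng.integers(2**31))
            geo[s.state_id] = _state_frames(n_residues, state_rng, s.backbone_shift_scale)
        by_id = {s.state_id: s for s in states}
        snapshots = []
        for t, lab in enumerate(labels):
            s = by_id[lab]
            anchors, frames = geo[lab]
            chi = np.array([
                (s.syn_angle if (r + 1) in s.syn_residues else s.anti_angle)
                + rng.uniform(-s.chi_jitter, s.chi_jitter)
                for r in range(n_residues)
            ])
            snapshots.append(
                _build_snapshot(t + 1, n_residues, chi, anchors, frames, noise, rng)
            )
        ensemble = Ensemble(snapshots)
        if _verify_separation(ensemble, labels):
            return ensemble, labels
    raise RuntimeError(
        f"could not achieve eRMSD state separation in {max_attempts} attempts; "
        "increase backbone_shift_scale or reduce noise"
    )


def _verify_separation(ensemble: Ensemble, labels: np.ndarray) -> bool:
    mat = pairwise_ermsd(list(ensemble))
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    within_ok = np.all(mat[same & off_diag] < 0.7) if np.any(same & off_diag) else True
    between_ok = np.all(mat[~same] > 0.7) if np.any(~same) else True
    return bool(within_ok and between_ok)


def default_pair_panel(n_residues: int) -> list[tuple[int, str, int, str]]:
    """Proton-pair panel: intra-residue base-H1' and sequential pairs.

    The intra-residue H8/H6 to H1' distance is the classic syn/anti
    reporter, and sequential base-proton to H1' pairs report on backbone
    geometry -- together they discriminate the planted sub-states.
    """
    seq = _chain_sequence(n_residues)
    panel = []
    for r in range(1, n_residues + 1):
        hbase = "H8" if seq[r - 1][1] == "purine" else "H6"
        panel.append((r, hbase, r, "H1'"))
        if r > 1:
            panel.append((r, hbase, r - 1, "H1'"))
    return panel


def generate_mixture_restraints(
    ensemble: Ensemble,
    labels: np.ndarray,
    true_weights: dict[str, float],
    slack: float = 0.0,
    classes: str = "explicit",
    panel: list[tuple[int, str, int, str]] | None = None,
) -> RestraintSet:
    """NOE upper bounds generated from a known mixture of the sub-states.

    For each panel pair the target signal is the planted-mixture average
    ``sum_s p_s <f>_s`` deflated by ``slack``; the corresponding maximum
    distance is ``f_target^(-1/6)``.  With ``classes='snap'`` each
    distance is snapped to the nearest of the strong/medium/weak class
    distances (3.6/5.0/6.5 A) as real restraint lists quote them; with
    the default ``'explicit'`` the exact distance is kept, which
    guarantees the planted mixture is feasible.
    """
    labels = np.asarray(labels)
    if panel is None:
        panel = default_pair_panel(ensemble.n_residues)
    p = np.array([true_weights[k] for k in true_weights], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true_weights must sum to 1")
    if not 0.0 <= slack < 1.0:
        raise ValueError("slack must be in [0, 1)")
    restraints = []
    for (ri, ai, rj, aj) in panel:
        pair_restraint = NOERestraint(ri, ai, rj, aj, d_exp=5.0)
        sigs = build_signal_matrix(ensemble, RestraintSet([pair_restraint]))[0]
        target = 0.0
        for state_id, weight in true_weights.items():
            member = labels == state_id
            if not np.any(member):
                raise ValueError(f"no snapshots labeled {state_id!r}")
            target += weight * float(sigs[member].mean())
        f_target = (1.0 - slack) * target
        d_exp = 10.0 * f_target ** (-1.0 / 6.0)  # nm^-6 -> Angstrom
        signal_class = None
        if classes == "snap":
            signal_class, d_exp = min(
                CLASS_DISTANCES_ANGSTROM.items(), key=lambda kv: abs(kv[1] - d_exp)
            )
        elif classes != "explicit":
            raise ValueError("classes must be 'explicit' or 'snap'")
        restraints.append(
            NOERestraint(ri, ai, rj, aj, d_exp=float(d_exp), signal_class=signal_class)
        )
    return RestraintSet(restraints)


def plant_motif_library(
    ensemble: Ensemble,
    start: int,
    length: int,
    seed: int,
    n_planted: int = 3,
    n_decoys: int = 3,
    flank: int = 2,
    perturbation: float = 0.15,
) -> tuple[list[tuple[str, Ensemble]], list[tuple[str, int]]]:
    """Library of chains with near-copies of the query fragment planted.

    Each planted entry embeds a perturbed copy of one ensemble
    snapshot's fragment window inside a longer chain at a known
    position; decoys are independent chains with a different syn/anti
    pattern.  Returns (library, [(entry_id, window_start), ...]).
    """
    rng = np.random.default_rng(seed)
    library: list[tuple[str, Ensemble]] = []
    truth: list[tuple[str, int]] = []
    # embed at a chain position congruent to the query start modulo the
    # sequence cycle, so the purine/pyrimidine pattern of the planted
    # window matches the query's
    lead = flank + (start - flank - 1) % len(_SEQUENCE_CYCLE)
    n_res = lead + length + flank
    for k in range(n_planted):
        src = ensemble[int(rng.integers(len(ensemble)))]
        donor_chi = [chi_angle(src, r) for r in range(start, start + length)]
        chi = np.array(
            [200.0 + rng.uniform(-5, 5) for _ in range(lead)]
            + donor_chi
            + [200.0 + rng.uniform(-5, 5) for _ in range(flank)]
        )
        anchors, frames = _state_frames(n_res, np.random.default_rng(rng.integers(2**31)), 0.0)
        snap = _build_snapshot(1, n_res, chi, anchors, frames, perturbation, rng)
        library.append((f"planted{k}", Ensemble([snap])))
        truth.append((f"planted{k}", lead + 1))
    for k in range(n_decoys):
        chi = np.array([60.0 if r % 2 else 200.0 for r in range(n_res)]) + rng.uniform(
            -5, 5, size=n_res
        )
        state_rng = np.random.default_rng(rng.integers(2**31))
        anchors, frames = _state_frames(n_res, state_rng, 2.5)
        snap = _build_snapshot(1, n_res, chi, anchors, frames, perturbation, rng)
        library.append((f"decoy{k}", Ensemble([snap])))
    return library, truth


def write_fixture(
    outdir: str | Path,
    ensemble: Ensemble,
    labels: np.ndarray,
    restraints: RestraintSet,
    states: list[StateSpec],
    seed: int,
) -> None:
    """Write a self-contained fixture: PDB + restraint CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_multimodel_pdb(ensemble, outdir / "ensemble.pdb")
    restraints.to_csv(outdir / "restraints.csv")
    truth = {
        "seed": seed,
        "labels": list(map(str, labels)),
        "states": [
            {
                "state_id": s.state_id,
                "population": s.population,
                "syn_residues": list(s.syn_residues),
                "backbone_shift_scale": s.backbone_shift_scale,
            }
            for s in states
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
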