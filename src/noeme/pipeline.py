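"""End-to-end orchestration: violations -> reweight -> cluster -> minimal sets.

The pipeline chains the library stages on files, writing every artifact
under one output directory together with the configuration and seed
that produced it, so a rerun with the same config is bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, geometry, maxent, noe, parsimony
from .structures import Ensemble, read_multimodel_pdb, read_pdb_directory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report_violations", "load_ensemble"]


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run.

    Defaults are the protocol's standard constants: error scale
    sigma = 0.5 nm^-6, eRMSD cluster cutoff 0.7, cluster population
    floor 0.002, weight grid step 0.01, motif window start 11 length 9.
    """

    ensemble: str = ""
    restraints: str = ""
    sigma: float = 0.5
    ermsd_cutoff: float = clustering.DEFAULT_ERMSD_CUTOFF
    population_floor: float = parsimony.DEFAULT_POPULATION_FLOOR
    grid_step: float = 0.01
    window_start: int = 11
    window_length: int = 9
    library: str | None = None
    seed: int = 0
    out: str = "out"
    tolerance: float = 1e-8
    parsimony_mode: str = "lp-prefilter"
    violation_mode: str = "shortfall"
    max_Y: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def load_ensemble(path: str | Path) -> Ensemble:
    """A multi-model PDB file, or a directory of single-model PDB files."""
    path = Path(path)
    if path.is_dir():
        return read_pdb_directory(path)
    return read_multimodel_pdb(path)


def _write_meta(outdir: Path, config: RunConfig, extra: dict) -> None:
    meta = {"config": dataclasses.asdict(config), "config_hash": config.config_hash()}
    meta.update(extra)
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))


def report_violations(config: RunConfig, critical_below: float | None = None) -> pd.DataFrame:
    """Per-restraint relative signals and violation flags for an ensemble."""
    ensemble = load_ensemble(config.ensemble)
    restraints = noe.RestraintSet.from_csv(config.restraints)
    matrix = noe.build_signal_matrix(ensemble, restraints)
    ratios = noe.relative_signals(matrix, restraints)
    report = noe.violation_report(restraints, ratios, critical_below=critical_below)
    logger.info(
        "%d restraints on %d snapshots: %d violated",
        len(restraints), len(ensemble), noe.count_violations(ratios),
    )
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute violations -> reweight -> cluster -> minimal sets on disk.

    Artifacts are written under ``config.out``; a ``FAILED`` marker
    naming the stage is left behind when a stage raises.
    Returns a summary dictionary.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        ensemble = load_ensemble(config.ensemble)
        restraints = noe.RestraintSet.from_csv(config.restraints)
        matrix = noe.build_signal_matrix(ensemble, restraints)
        logger.info("parsed %d restraints, %d snapshots", len(restraints), len(ensemble))

        stage = "violations"
        prior_ratios = noe.relative_signals(matrix, restraints, ensemble.prior_weights)
        noe.violation_report(restraints, prior_ratios).to_csv(
            outdir / "violations_prior.csv", index=False
        )

        stage = "reweight"
        result = maxent.maxent_reweight(
            matrix, restraints.f_exp, sigma=config.sigma,
            prior_weights=ensemble.prior_weights, tolerance=config.tolerance,
        )
        pd.DataFrame(
            {"snapshot_id": np.arange(1, len(ensemble) + 1), "weight": result.weights}
        ).to_csv(outdir / "weights.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"restraint_id": np.arange(1, len(restraints) + 1), "lambda": result.lambdas}
        ).to_csv(outdir / "lambdas.tsv", sep="\t", index=False)
        ratios = noe.relative_signals(matrix, restraints, result.weights)
        noe.violation_report(restraints, ratios).to_csv(
            outdir / "violations_reweighted.csv", index=False
        )

        stage = "cluster"
        cache = geometry.DistanceCache(list(ensemble))
        clusters = clustering.cluster_ensemble(
            ensemble, result.weights, cutoff=config.ermsd_cutoff, cache=cache
        )
        clustering.cluster_report(clusters).to_csv(outdir / "clusters.csv", index=False)
        clustering.write_assignments(clusters, outdir / "assignments.tsv")

        stage = "minsets"
        table = parsimony.ClusterSignalTable.from_clusters(
            clusters, matrix, result.weights, floor=config.population_floor
        )
        minsets = parsimony.find_minimal_sets(
            table, restraints, step=config.grid_step,
            mode=config.parsimony_mode, max_Y=config.max_Y,
        )
        minsets.to_dataframe().to_csv(outdir / "minimal_sets.csv", index=False)

        summary = {
            "n_snapshots": len(ensemble),
            "n_restraints": len(restraints),
            "n_violations_prior": noe.count_violations(prior_ratios),
            "n_violations_reweighted": noe.count_violations(ratios),
            "violation_score_mode": config.violation_mode,
            "violation_score_prior": noe.violation_score(prior_ratios, config.violation_mode),
            "kish": result.kish,
            "maxent_converged": result.converged,
            "n_clusters": len(clusters),
            "n_clusters_above_floor": len(table),
            "minimal_Y": minsets.Y,
            "n_minimal_sets": len(minsets.sets),
            "infeasible": minsets.infeasible,
            "seed": config.seed,
        }
        _write_meta(outdir, config, summary)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
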