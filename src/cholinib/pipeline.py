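"""Orchestration: configuration, stage sequencing, manifest, report assembly.

``run_all`` ties the stages together in the analysis order of the study:
registry integrity checks -> IC50 -> dG conversion -> pose consensus ->
interaction fingerprinting (on a generated or supplied site scene) ->
kinetics mechanism typing (when rate data are present).  Every run writes a
manifest recording inputs, content hashes, package version, and the seed, so
deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import dg_table, load_activity
from .consensus import ClusterParams, run_consensus
from .kinetics import classify_mechanism, lineweaver_burk
from .pose_io import load_core_map, read_poses
from .registry import (
    count_stereoisomers,
    elemental_percentages,
    load_registry,
)
from .synthetic import (
    ContactSpec,
    PoseEnsembleConfig,
    gen_pose_ensemble,
    gen_site_scene,
)
from .interactions import find_contacts, summarize

log = logging.getLogger("cholinib")

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Flat run configuration; paths may be omitted to use synthetic presets."""

    out_dir: str = "cholinib_run"
    seed: int = 0
    registry_path: str | None = None
    activity_path: str | None = None
    poses_path: str | None = None
    scores_path: str | None = None
    core_map_path: str | None = None
    kinetics_path: str | None = None
    target: str = "AChE"
    cluster: ClusterParams = field(default_factory=ClusterParams)
    simulate_poses: bool = True  # generate the benchmark ensemble when no poses given
    simulate_scene: bool = True

    def validate(self) -> None:
        for name in ("registry_path", "activity_path", "poses_path", "scores_path",
                     "core_map_path", "kinetics_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.poses_path is None and not self.simulate_poses:
            raise ValueError("no poses_path and simulation disabled")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cluster = ClusterParams(**raw.pop("cluster", {}))
    return RunConfig(cluster=cluster, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    errors: list[str] = []

    def stage(name):
        log.info("stage=%s t=%.2fs", name, time.time() - t0)

    # --- registry integrity -------------------------------------------------
    stage("registry")
    try:
        records = load_registry(config.registry_path)
        n5 = sum(1 for r in records if r.series == 5)
        n6 = sum(1 for r in records if r.series == 6)
        _, total_stereo = count_stereoisomers(records)
        ea_ok = all(
            abs(sum(elemental_percentages(r.formula).values()) - 100.0) < 0.05 for r in records
        )
        report["stages"]["registry"] = {
            "n_compounds": len(records),
            "n_series5": n5,
            "n_series6": n6,
            "total_stereoisomers": total_stereo,
            "elemental_percentages_close": ea_ok,
        }
    except Exception as exc:  # noqa: BLE001 - aggregated stage error reporting
        errors.append(f"registry: {exc}")

    # --- activity -----------------------------------------------------------
    stage("activity")
    dg = {}
    try:
        activity = load_activity(config.activity_path)
        dg = dg_table(activity, target=config.target)
        report["stages"]["activity"] = {
            "n_results": len(activity),
            "dg_expt": {k: round(v, 4) for k, v in dg.items()},
        }
    except Exception as exc:
        errors.append(f"activity: {exc}")

    # --- consensus ----------------------------------------------------------
    stage("consensus")
    try:
        if config.poses_path is not None:
            poses = read_poses(config.poses_path, config.scores_path)
            core_map = load_core_map(config.core_map_path)
        else:
            cfg = PoseEnsembleConfig(seed=config.seed)
            poses, _, truth, core_map = gen_pose_ensemble(cfg, out_dir=out / "ensemble")
            dg = dict(truth.dg_expt)
        cons = run_consensus(poses, core_map, config.cluster, dg_expt=dg)
        (out / "consensus.json").write_text(cons.to_json())
        cons.summary_table().to_csv(out / "consensus_clusters.csv", index=False)
        chosen = cons.chosen
        report["stages"]["consensus"] = {
            "chosen_cluster": cons.chosen_cluster_id,
            "r2": None if chosen is None else chosen.r2,
            "n_clusters_ranked": len(cons.ranked),
            "warning": cons.warning,
        }
    except Exception as exc:
        errors.append(f"consensus: {exc}")

    # --- interactions -------------------------------------------------------
    stage("interactions")
    try:
        if config.simulate_scene:
            specs = [
                ContactSpec("pi_sandwich", "PHE", 330, 3.56),
                ContactSpec("pi_parallel_displaced", "TRP", 84, 4.10, offset=2.5),
                ContactSpec("pi_t_shaped", "TYR", 334, 4.55),
                ContactSpec("hbond", "TRP", 279, 3.17),
            ]
            receptor, pose, truth = gen_site_scene(specs, seed=config.seed)
            contacts = find_contacts(
                pose, receptor,
                ligand_ring_defs=[truth["ligand_ring"]],
                ligand_cation_atoms=truth["ligand_cations"],
            )
            summary = summarize(contacts)
            summary.to_csv(out / "interactions.csv", index=False)
            report["stages"]["interactions"] = {
                "n_contacts": len(contacts),
                "summary": summary.to_dict(orient="records"),
            }
    except Exception as exc:
        errors.append(f"interactions: {exc}")

    # --- kinetics -----------------------------------------------------------
    if config.kinetics_path is not None:
        stage("kinetics")
        try:
            data = pd.read_csv(config.kinetics_path, comment="#")
            mech = classify_mechanism(data)
            mech.delta_aicc().to_csv(out / "kinetics_aicc.csv", index=False)
            report["stages"]["kinetics"] = {
                "selected": mech.selected,
                "ambiguous": mech.ambiguous,
                "lineweaver_burk": {
                    str(k): v for k, v in lineweaver_burk(data[data["v"] > 0]).items()
                },
            }
        except Exception as exc:
            errors.append(f"kinetics: {exc}")

    report["errors"] = errors
    log.info("done t=%.2fs", time.time() - t0)
    # report.json is deterministic per (inputs, seed); timing stays in the log
    (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": p, "sha256": _sha256(p)}
            for name, p in {
                "registry": config.registry_path,
                "activity": config.activity_path,
                "poses": config.poses_path,
                "scores": config.scores_path,
                "core_map": config.core_map_path,
                "kinetics": config.kinetics_path,
            }.items()
            if p is not None
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if errors:
        raise RuntimeError("stage errors: " + "; ".join(errors))
    return report
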