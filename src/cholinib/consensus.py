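"""Ensemble-docking post-processing: pose clustering, filtering, consensus selection.

The pipeline mirrors standard cross-docking practice: poses of all ligands
(in a common receptor frame) are clustered by no-fit core RMSD with a 2.0 A
threshold, chirality partitions never mix, the five most populated clusters
with at least ten poses per covered ligand are kept, one representative pose
per ligand is picked per cluster, each cluster's representative rescoring
energies are regressed against the experimental binding free energies, and
the cluster with the highest coefficient of determination R^2 is chosen as
the consensus binding-mode hypothesis.

Clustering is deterministic leader clustering: poses are sorted by
(rescoring energy ascending, ligand id, receptor id, pose index) and each
pose joins the first existing cluster whose leader lies within the RMSD
threshold, else founds a new cluster.  Hierarchical average linkage is
available as an alternative (``linkage="average"``); both recover planted
well-separated modes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .pose_io import CoreAtomMap, LigandPose, core_coordinates

__all__ = [
    "ClusterParams",
    "PoseCluster",
    "ClusterEvaluation",
    "ConsensusReport",
    "core_rmsd",
    "cluster_poses",
    "filter_top_clusters",
    "pick_representatives",
    "fit_dg",
    "run_consensus",
]


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the clustering/filtering stage (defaults follow the study design)."""

    rmsd_threshold: float = 2.0  # A
    top_k: int = 5
    min_poses_per_ligand: int = 10
    poses_retained_per_ligand: int = 100
    linkage: str = "leader"  # "leader" | "average"
    # "per_ligand": every covered ligand must contribute >= min poses (default
    # reading of the filter rule); "total": cluster population must reach the
    # minimum with every ligand covered at least once.
    min_poses_scope: str = "per_ligand"

    def __post_init__(self):
        if not self.rmsd_threshold > 0:
            raise ValueError("rmsd_threshold must be positive")
        if min(self.top_k, self.min_poses_per_ligand, self.poses_retained_per_ligand) < 1:
            raise ValueError("counts must be >= 1")
        if self.linkage not in ("leader", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.min_poses_scope not in ("per_ligand", "total"):
            raise ValueError(f"unknown min_poses_scope {self.min_poses_scope!r}")


@dataclass
class PoseCluster:
    """A binding-mode hypothesis: poses of one chirality within RMSD reach."""

    cluster_id: str
    stereo_tag: str
    members: list[LigandPose]

    @property
    def population(self) -> int:
        return len(self.members)

    @property
    def ligand_coverage(self) -> set[str]:
        return {p.ligand_id for p in self.members}

    @property
    def member_keys(self) -> list[tuple]:
        return [p.key for p in self.members]

    def poses_of(self, ligand_id: str) -> list[LigandPose]:
        return [p for p in self.members if p.ligand_id == ligand_id]


def core_rmsd(a: LigandPose, b: LigandPose, core_map: CoreAtomMap) -> float:
    """No-fit RMSD over the core-map atoms, in the shared receptor frame.

    No superposition and no symmetry correction: atom names fix the
    correspondence and poses already share a frame.
    """
    ca, cb = core_coordinates(a, core_map), core_coordinates(b, core_map)
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def _sort_key(p: LigandPose):
    score = p.rescore_dg if p.rescore_dg is not None else p.docking_score
    return (score, p.ligand_id, p.receptor_id, p.pose_index)


def cluster_poses(
    poses: Sequence[LigandPose],
    core_map: CoreAtomMap,
    params: ClusterParams = ClusterParams(),
) -> list[PoseCluster]:
    """Partition poses into RMSD clusters, never mixing stereo tags."""
    if not poses:
        raise ValueError("no poses to cluster")
    clusters: list[PoseCluster] = []
    for tag in sorted({p.stereo_tag for p in poses}):
        part = sorted((p for p in poses if p.stereo_tag == tag), key=_sort_key)
        coords = np.array([core_coordinates(p, core_map) for p in part])
        flat = coords.reshape(len(part), -1)
        if params.linkage == "leader":
            groups = _leader_groups(flat, coords.shape[1], params.rmsd_threshold)
        else:
            groups = _average_linkage_groups(flat, coords.shape[1], params.rmsd_threshold)
        for gi, idxs in enumerate(groups):
            clusters.append(
                PoseCluster(
                    cluster_id=f"{tag}-{gi}",
                    stereo_tag=tag,
                    members=[part[i] for i in idxs],
                )
            )
    return clusters


def _leader_groups(flat: np.ndarray, n_atoms: int, threshold: float) -> list[list[int]]:
    leaders: list[int] = []
    groups: list[list[int]] = []
    thresh_sq = threshold**2 * n_atoms
    for i in range(len(flat)):
        placed = False
        for g, leader in enumerate(leaders):
            if np.sum((flat[i] - flat[leader]) ** 2) <= thresh_sq:
                groups[g].append(i)
                placed = True
                break
        if not placed:
            leaders.append(i)
            groups.append([i])
    return groups


def _average_linkage_groups(flat: np.ndarray, n_atoms: int, threshold: float) -> list[list[int]]:
    if len(flat) == 1:
        return [[0]]
    # pdist euclidean on flattened coords == rmsd * sqrt(n_atoms)
    d = pdist(flat) / np.sqrt(n_atoms)
    labels = fcluster(scipy_linkage(d, method="average"), t=threshold, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return [groups[lab] for lab in sorted(groups)]


def filter_top_clusters(
    clusters: Sequence[PoseCluster], params: ClusterParams = ClusterParams()
) -> list[PoseCluster]:
    """Keep qualifying clusters, then the ``top_k`` most populated.

    Default qualification: every covered ligand contributes at least
    ``min_poses_per_ligand`` member poses.  Ties in population break by
    cluster id.  An empty result is returned, not raised.
    """
    def qualifies(c: PoseCluster) -> bool:
        if params.min_poses_scope == "per_ligand":
            counts = {lig: len(c.poses_of(lig)) for lig in c.ligand_coverage}
            return all(n >= params.min_poses_per_ligand for n in counts.values())
        return c.population >= params.min_poses_per_ligand and bool(c.ligand_coverage)

    keep = [c for c in clusters if qualifies(c)]
    keep.sort(key=lambda c: (-c.population, c.cluster_id))
    return keep[: params.top_k]


def pick_representatives(
    cluster: PoseCluster,
    mode: str = "lowest_energy",
    dg_expt: Mapping[str, float] | None = None,
) -> dict[str, LigandPose]:
    """One pose per covered ligand.

    ``lowest_energy`` (default): the member with minimum rescoring energy,
    ties broken by lowest pose index.  ``best_fit_greedy`` starts from the
    lowest-energy choice and swaps single-ligand poses while the R^2 against
    dGexpt strictly improves; it peeks at the experimental values during pose
    selection and is therefore an explicitly experiment-guided option.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    for p in cluster.members:
        if p.rescore_dg is None:
            raise ValueError(f"pose {p.key} lacks rescore_dg; rescoring table not joined")

    def best_of(poses: list[LigandPose]) -> LigandPose:
        return min(poses, key=lambda p: (p.rescore_dg, p.pose_index, p.receptor_id))

    reps = {lig: best_of(cluster.poses_of(lig)) for lig in sorted(cluster.ligand_coverage)}
    if mode == "lowest_energy":
        return reps
    if mode != "best_fit_greedy":
        raise ValueError(f"unknown representative mode {mode!r}")

    if dg_expt is None:
        raise ValueError("best_fit_greedy requires dg_expt")
    fit_ligs = sorted(lig for lig in reps if lig in dg_expt)
    missing = sorted(set(reps) - set(fit_ligs))
    if missing:
        raise ValueError(f"best_fit_greedy: missing dGexpt for ligands {missing}")

    def r2_of(current: dict[str, LigandPose]) -> float:
        return fit_dg([current[l].rescore_dg for l in fit_ligs], [dg_expt[l] for l in fit_ligs])[2]

    best_r2 = r2_of(reps)
    improved = True
    while improved:
        improved = False
        for lig in fit_ligs:
            for cand in sorted(cluster.poses_of(lig), key=lambda p: (p.rescore_dg, p.pose_index)):
                if cand is reps[lig]:
                    continue
                trial = dict(reps)
                trial[lig] = cand
                r2 = r2_of(trial)
                if r2 > best_r2:
                    reps, best_r2, improved = trial, r2, True
    return reps


def fit_dg(dg_pred: Sequence[float], dg_expt: Sequence[float]) -> tuple[float, float, float]:
    """OLS of dGexpt on dGpred; returns (slope, intercept, R^2)."""
    x = np.asarray(dg_pred, dtype=float)
    y = np.asarray(dg_expt, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.var(y) == 0 or np.var(x) == 0:
        raise ValueError("zero variance in regression inputs")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class ClusterEvaluation:
    cluster_id: str
    stereo_tag: str
    population: int
    n_ligands: int
    n_fit: int
    slope: float | None
    intercept: float | None
    r2: float | None
    representatives: dict[str, tuple] = field(default_factory=dict)


@dataclass
class ConsensusReport:
    """Ranked cluster evaluations and the chosen binding-mode cluster."""

    ranked: list[ClusterEvaluation]
    chosen_cluster_id: str | None
    warning: str | None = None

    @property
    def chosen(self) -> ClusterEvaluation | None:
        for ev in self.ranked:
            if ev.cluster_id == self.chosen_cluster_id:
                return ev
        return None

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "chosen_cluster_id": self.chosen_cluster_id,
            "warning": self.warning,
            "ranked": [asdict(ev) for ev in self.ranked],
        }
        return json.dumps(payload, indent=indent, default=list)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": ev.cluster_id,
                    "stereo_tag": ev.stereo_tag,
                    "population": ev.population,
                    "n_ligands": ev.n_ligands,
                    "n_fit": ev.n_fit,
                    "slope": ev.slope,
                    "intercept": ev.intercept,
                    "r2": ev.r2,
                }
                for ev in self.ranked
            ]
        )


def run_consensus(
    poses: Sequence[LigandPose],
    core_map: CoreAtomMap,
    params: ClusterParams = ClusterParams(),
    dg_expt: Mapping[str, float] | None = None,
    mode: str = "lowest_energy",
) -> ConsensusReport:
    """Full pipeline: cluster -> filter -> representatives -> fit -> rank by R^2.

    Ligands lacking dGexpt are carried through clustering but excluded from
    fitting; clusters with fewer than three fittable ligands are reported but
    not eligible for selection.  Ranking ties break by population then id.
    """
    if dg_expt is None:
        dg_expt = {}
    if len(dg_expt) < 3:
        raise ValueError("need dGexpt for at least 3 ligands")
    clusters = cluster_poses(poses, core_map, params)
    top = filter_top_clusters(clusters, params)
    if not top:
        return ConsensusReport(ranked=[], chosen_cluster_id=None,
                               warning="no cluster passed the population filter")

    evals: list[ClusterEvaluation] = []
    for c in top:
        reps = pick_representatives(c, mode=mode, dg_expt=dg_expt if mode != "lowest_energy" else dg_expt)
        fit_ligs = sorted(l for l in reps if l in dg_expt)
        slope = intercept = r2 = None
        if len(fit_ligs) >= 3:
            pred = [reps[l].rescore_dg for l in fit_ligs]
            expt = [dg_expt[l] for l in fit_ligs]
            if np.var(expt) > 0 and np.var(pred) > 0:
                slope, intercept, r2 = fit_dg(pred, expt)
        evals.append(
            ClusterEvaluation(
                cluster_id=c.cluster_id,
                stereo_tag=c.stereo_tag,
                population=c.population,
                n_ligands=len(c.ligand_coverage),
                n_fit=len(fit_ligs),
                slope=slope,
                intercept=intercept,
                r2=r2,
                representatives={l: reps[l].key for l in reps},
            )
        )

    evals.sort(key=lambda ev: (-(ev.r2 if ev.r2 is not None else -np.inf), -ev.population, ev.cluster_id))
    chosen = next((ev.cluster_id for ev in evals if ev.r2 is not None), None)
    warning = None if chosen else "no cluster had enough ligands with dGexpt to fit"
    return ConsensusReport(ranked=evals, chosen_cluster_id=chosen, warning=warning)
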