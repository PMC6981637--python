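"""Pose clustering, filtering, representative selection, and the consensus fit."""

import itertools
import math

import numpy as np
import pytest

from cholinib.consensus import (
    ClusterParams,
    PoseCluster,
    cluster_poses,
    core_rmsd,
    filter_top_clusters,
    fit_dg,
    pick_representatives,
    run_consensus,
)
from cholinib.pose_io import CoreAtomMap
from cholinib.synthetic import EnsembleTruth, PoseEnsembleConfig, gen_pose_ensemble

from conftest import make_pose

rng = np.random.default_rng(1234)


def brute_rmsd(a, b, cmap):
    """Direct per-atom sum oracle, no vectorization."""
    total = 0.0
    for name in cmap.names:
        pa, pb = a.coord_of(name), b.coord_of(name)
        total += sum((float(pa[i]) - float(pb[i])) ** 2 for i in range(3))
    return math.sqrt(total / len(cmap.names))


class TestCoreRmsd:
    def test_self_is_zero(self, tiny_map):
        p = make_pose(tiny_map.names, rng.normal(size=(5, 3)))
        assert core_rmsd(p, p, tiny_map) == 0.0

    def test_rigid_translation(self, tiny_map):
        coords = rng.normal(size=(5, 3))
        a = make_pose(tiny_map.names, coords)
        b = make_pose(tiny_map.names, coords + np.array([3.0, 4.0, 0.0]))
        assert core_rmsd(a, b, tiny_map) == pytest.approx(5.0, abs=1e-12)

    def test_matches_direct_sum_oracle(self, tiny_map):
        for _ in range(100):
            a = make_pose(tiny_map.names, rng.normal(scale=3, size=(5, 3)))
            b = make_pose(tiny_map.names, rng.normal(scale=3, size=(5, 3)))
            assert core_rmsd(a, b, tiny_map) == pytest.approx(
                brute_rmsd(a, b, tiny_map), abs=1e-10
            )


class TestClustering:
    def test_planted_two_mode_recovery(self, small_ensemble):
        poses, _, truth, cmap = small_ensemble
        clusters = cluster_poses(poses, cmap, ClusterParams())
        assert len(clusters) == 2
        for c in clusters:
            modes = {truth.mode_of[EnsembleTruth.key_str(p.key)] for p in c.members}
            assert len(modes) == 1  # planted membership recovered exactly

    def test_both_linkages_recover_planted_modes(self, small_ensemble):
        poses, _, truth, cmap = small_ensemble
        for linkage in ("leader", "average"):
            clusters = cluster_poses(poses, cmap, ClusterParams(linkage=linkage))
            label_of = {}
            for c in clusters:
                for p in c.members:
                    label_of[EnsembleTruth.key_str(p.key)] = c.cluster_id
            from sklearn.metrics import adjusted_rand_score

            keys = sorted(label_of)
            ari = adjusted_rand_score(
                [truth.mode_of[k] for k in keys], [label_of[k] for k in keys]
            )
            assert ari == 1.0

    def test_threshold_larger_than_diameter(self, tiny_map):
        poses = [
            make_pose(tiny_map.names, rng.normal(scale=0.5, size=(5, 3)),
                      ligand=f"l{i}", stereo=tag, index=i, rescore=-5.0)
            for tag in ("R", "S")
            for i in range(4)
        ]
        clusters = cluster_poses(poses, tiny_map, ClusterParams(rmsd_threshold=1e3))
        assert len(clusters) == 2  # one per stereo tag
        assert {c.stereo_tag for c in clusters} == {"R", "S"}

    def test_single_pose_singleton(self, tiny_map):
        p = make_pose(tiny_map.names, np.zeros((5, 3)), rescore=-5.0)
        (c,) = cluster_poses([p], tiny_map, ClusterParams())
        assert c.population == 1

    def test_partition_and_no_stereo_mixing(self, small_ensemble, tiny_map):
        poses, _, _, cmap = small_ensemble
        clusters = cluster_poses(poses, cmap, ClusterParams())
        seen = [p.key for c in clusters for p in c.members]
        assert len(seen) == len(poses) and len(set(seen)) == len(poses)
        for c in clusters:
            assert {p.stereo_tag for p in c.members} == {c.stereo_tag}
        # every member within threshold of its cluster leader (first member)
        for c in clusters:
            leader = c.members[0]
            assert all(core_rmsd(leader, p, cmap) <= 2.0 for p in c.members)

    def test_input_order_invariance(self, small_ensemble):
        poses, _, _, cmap = small_ensemble
        base = cluster_poses(poses, cmap, ClusterParams())
        shuffled = list(poses)
        np.random.default_rng(7).shuffle(shuffled)
        redo = cluster_poses(shuffled, cmap, ClusterParams())
        as_sets = lambda cs: sorted(frozenset(c.member_keys) for c in cs)  # noqa: E731
        assert as_sets(base) == as_sets(redo)


class TestFilter:
    def _cluster(self, cid, n_per_ligand):
        members = [
            make_pose([f"A{i}" for i in range(3)], np.zeros((3, 3)),
                      ligand=lig, index=i, rescore=-5.0)
            for lig, n in n_per_ligand.items()
            for i in range(n)
        ]
        return PoseCluster(cluster_id=cid, stereo_tag="R", members=members)

    def test_top_k_by_population(self):
        clusters = [self._cluster(f"R-{i}", {"a": 10 + i, "b": 10}) for i in range(7)]
        kept = filter_top_clusters(clusters, ClusterParams(top_k=5))
        assert [c.cluster_id for c in kept] == ["R-6", "R-5", "R-4", "R-3", "R-2"]

    def test_per_ligand_minimum_boundary(self):
        ok = self._cluster("R-0", {"a": 10, "b": 10})
        short = self._cluster("R-1", {"a": 10, "b": 9})
        kept = filter_top_clusters([ok, short], ClusterParams())
        assert [c.cluster_id for c in kept] == ["R-0"]

    def test_min_one_reduces_to_top_k(self):
        clusters = [self._cluster(f"R-{i}", {"a": 1 + i}) for i in range(8)]
        kept = filter_top_clusters(clusters, ClusterParams(min_poses_per_ligand=1, top_k=3))
        assert [c.population for c in kept] == [8, 7, 6]

    def test_empty_result_not_error(self):
        short = self._cluster("R-0", {"a": 2})
        assert filter_top_clusters([short], ClusterParams()) == []


class TestRepresentatives:
    def _cluster(self):
        members = []
        for lig, energies in [("a", [-8.1, -7.2]), ("b", [-6.0, -6.0])]:
            for i, e in enumerate(energies):
                members.append(
                    make_pose(["A1"], np.zeros((1, 3)), ligand=lig, index=i, rescore=e)
                )
        return PoseCluster("R-0", "R", members)

    def test_lowest_energy_and_tiebreak(self):
        reps = pick_representatives(self._cluster())
        assert reps["a"].rescore_dg == -8.1
        assert reps["b"].pose_index == 0  # energy tie -> lower pose index

    def test_missing_rescore_rejected(self):
        c = PoseCluster("R-0", "R", [make_pose(["A1"], np.zeros((1, 3)), rescore=None)])
        with pytest.raises(ValueError, match="rescore"):
            pick_representatives(c)

    def test_greedy_never_worse_than_lowest_energy(self, small_ensemble):
        poses, _, truth, cmap = small_ensemble
        clusters = cluster_poses(poses, cmap, ClusterParams())
        cluster = max(clusters, key=lambda c: c.population)
        dg = truth.dg_expt
        low = pick_representatives(cluster, "lowest_energy")
        greedy = pick_representatives(cluster, "best_fit_greedy", dg_expt=dg)
        ligs = sorted(set(low) & set(dg))
        r2_low = fit_dg([low[l].rescore_dg for l in ligs], [dg[l] for l in ligs])[2]
        r2_greedy = fit_dg([greedy[l].rescore_dg for l in ligs], [dg[l] for l in ligs])[2]
        assert r2_greedy >= r2_low

    def test_greedy_requires_dg(self):
        with pytest.raises(ValueError):
            pick_representatives(self._cluster(), "best_fit_greedy", dg_expt={"a": -7.0})


class TestFitDg:
    def test_identity_line(self):
        slope, intercept, r2 = fit_dg([-9, -8, -7, -6], [-9, -8, -7, -6])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_dg([-9, -8, -7], [-5, -5, -5])
        with pytest.raises(ValueError):
            fit_dg([-9, -8], [-9, -8])

    def test_matches_normal_equations_oracle(self):
        x = np.array([-10.2, -9.1, -8.4, -7.7, -6.3])
        y = np.array([-9.8, -9.3, -8.1, -7.2, -6.9])
        # closed-form normal equations, computed independently
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope_o = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept_o = (sy - slope_o * sx) / n
        r_o = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy)
        )
        slope, intercept, r2 = fit_dg(x, y)
        assert slope == pytest.approx(slope_o, abs=1e-10)
        assert intercept == pytest.approx(intercept_o, abs=1e-10)
        assert r2 == pytest.approx(r_o**2, abs=1e-10)

    def test_r2_affine_invariant(self):
        x = np.array([-10.2, -9.1, -8.4, -7.7, -6.3])
        y = np.array([-9.8, -9.3, -8.1, -7.2, -6.9])
        _, _, r2 = fit_dg(x, y)
        _, _, r2b = fit_dg(2.5 * x + 7.0, y)
        assert r2b == pytest.approx(r2, abs=1e-12)


class TestRunConsensus:
    def test_selects_planted_mode(self, small_ensemble):
        poses, _, truth, cmap = small_ensemble
        params = ClusterParams(min_poses_per_ligand=5)
        report = run_consensus(poses, cmap, params, dg_expt=truth.dg_expt)
        chosen = report.chosen
        modes = {truth.mode_of[EnsembleTruth.key_str(k)] for k in chosen.representatives.values()}
        assert modes == {truth.true_mode}
        assert chosen.r2 == max(ev.r2 for ev in report.ranked if ev.r2 is not None)

    def test_shuffled_activity_control(self):
        """Destroying the energy-activity link should depress the chosen R^2."""
        worse = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = PoseEnsembleConfig(n_ligands=8, poses_per_ligand=20, seed=seed)
            poses, _, truth, cmap = gen_pose_ensemble(cfg)
            params = ClusterParams(min_poses_per_ligand=5)
            base = run_consensus(poses, cmap, params, dg_expt=truth.dg_expt).chosen.r2
            perm_rng = np.random.default_rng(1000 + seed)
            ligs = sorted(truth.dg_expt)
            vals = [truth.dg_expt[l] for l in ligs]
            perm_rng.shuffle(vals)
            shuffled = dict(zip(ligs, vals))
            perm = run_consensus(poses, cmap, params, dg_expt=shuffled).chosen.r2
            worse += perm < base
        assert worse >= int(0.95 * n_rep)

    def test_requires_three_dg_values(self, small_ensemble):
        poses, _, _, cmap = small_ensemble
        with pytest.raises(ValueError):
            run_consensus(poses, cmap, ClusterParams(), dg_expt={"5n": -7.3})

    def test_empty_filter_yields_warning_report(self, tiny_map):
        poses = [
            make_pose(tiny_map.names, np.zeros((5, 3)), ligand=f"l{i}", index=i, rescore=-5.0)
            for i in range(3)
        ]
        report = run_consensus(
            poses, tiny_map, ClusterParams(min_poses_per_ligand=10),
            dg_expt={"l0": -7, "l1": -8, "l2": -9},
        )
        assert report.chosen_cluster_id is None
        assert report.warning is not None
        assert report.ranked == []
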