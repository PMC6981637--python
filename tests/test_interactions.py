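"""Interaction geometry: ring classes, H-bonds, cation-pi, summaries."""

import math

import numpy as np
import pytest

from cholinib.interactions import (
    GeometryCutoffs,
    classify_ring_pair,
    detect_cation_pi,
    detect_hbonds,
    find_contacts,
    ring_geometry,
    summarize,
)
from cholinib.synthetic import ContactSpec, gen_site_scene

from conftest import make_pose

CUT = GeometryCutoffs()


def hexagon(center=(0, 0, 0), normal="z", radius=1.39):
    ang = np.arange(6) * math.pi / 3
    ring = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)
    if normal == "x":
        ring = ring[:, [2, 0, 1]]
    elif normal == "y":
        ring = ring[:, [0, 2, 1]]
    return ring + np.asarray(center, dtype=float)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestRingGeometry:
    def test_flat_hexagon(self):
        ring = ring_geometry(hexagon())
        assert np.allclose(ring.centroid, 0, atol=1e-12)
        assert np.allclose(ring.normal, [0, 0, 1], atol=1e-12)

    def test_sign_canonicalization_after_rotation(self):
        # rotate 90 deg about x: plane normal is +/-y; the sign rule picks +y
        coords = hexagon() @ np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]]).T
        ring = ring_geometry(coords)
        assert np.allclose(np.abs(ring.normal), [0, 1, 0], atol=1e-9)
        assert ring.normal[1] > 0

    def test_puckered_rejected(self):
        coords = hexagon()
        coords[:, 2] = [0.5, -0.5, 0.5, -0.5, 0.5, -0.5]  # chair-like, 0.5 A
        with pytest.raises(ValueError, match="out-of-plane"):
            ring_geometry(coords)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            ring_geometry(hexagon()[:4])


class TestRingPairClasses:
    def test_sandwich(self):
        a = ring_geometry(hexagon())
        b = ring_geometry(hexagon((0, 0, 3.5)))
        ctype, d, theta, offset = classify_ring_pair(a, b)
        assert ctype == "pi_sandwich"
        assert d == pytest.approx(3.5)
        assert offset == pytest.approx(0.0, abs=1e-12)

    def test_parallel_displaced(self):
        a = ring_geometry(hexagon())
        b = ring_geometry(hexagon((1.8, 0, 3.4)))
        ctype, d, _, offset = classify_ring_pair(a, b)
        assert ctype == "pi_parallel_displaced"
        assert offset == pytest.approx(1.8)

    def test_t_shaped_and_distance_cutoff(self):
        a = ring_geometry(hexagon())
        b = ring_geometry(hexagon((0, 5.0, 0), normal="x"))
        assert classify_ring_pair(a, b)[0] == "pi_t_shaped"
        far = ring_geometry(hexagon((0, 8.0, 0), normal="x"))
        assert classify_ring_pair(a, far) is None

    def test_parallel_classes_symmetric(self):
        a = ring_geometry(hexagon())
        b = ring_geometry(hexagon((1.8, 0, 3.4)))
        ab = classify_ring_pair(a, b)
        ba = classify_ring_pair(b, a)
        assert ab[0] == ba[0]
        assert ab[1] == pytest.approx(ba[1], abs=1e-12)

    def test_paper_distances_inside_windows(self):
        """The reported mean contact distances all fall inside the detection
        windows used here (sandwich 3.56, displaced 4.10, T 4.55 and 4.92,
        H-bond 3.17 A)."""
        assert 3.56 <= CUT.pi_dist_parallel_max
        assert 4.10 <= CUT.pi_dist_parallel_max
        assert 4.55 <= CUT.pi_dist_tshaped_max
        assert 4.92 <= CUT.pi_dist_tshaped_max
        assert 3.17 <= CUT.hbond_da_max
        assert 1.99 <= CUT.weak_ha_max


def scene_for(specs, seed=0):
    receptor, pose, truth = gen_site_scene(specs, seed=seed)
    contacts = find_contacts(
        pose, receptor,
        ligand_ring_defs=[truth["ligand_ring"]],
        ligand_cation_atoms=truth["ligand_cations"],
    )
    return receptor, pose, truth, contacts


class TestDetectors:
    def test_colinear_hbond_distance_convention(self):
        _, _, _, contacts = scene_for([ContactSpec("hbond", "TRP", 279, 3.0)])
        (hb,) = [c for c in contacts if c.type == "hbond"]
        assert hb.distance == pytest.approx(3.0, abs=1e-9)  # donor-acceptor
        assert hb.residue == "TRP279"

    def test_hbond_cutoff(self):
        with pytest.raises(ValueError):
            gen_site_scene([ContactSpec("hbond", "TRP", 279, 3.6)])

    def test_weak_ch_reports_ha_distance(self):
        _, _, _, contacts = scene_for([ContactSpec("weak_ch_hbond", "PHE", 331, 1.99)])
        (w,) = [c for c in contacts if c.type == "weak_ch_hbond"]
        assert w.distance == pytest.approx(1.99, abs=1e-9)

    def test_hydrogens_required(self):
        receptor, pose, truth = gen_site_scene([ContactSpec("hbond", "TRP", 279, 3.0)])
        bare = make_pose(["A1"], [[50.0, 50.0, 50.0]])
        stripped_names = [n for n, e in zip(receptor.atom_names, receptor.elements) if e != "H"]
        import copy

        rec = copy.deepcopy(receptor)
        keep = [i for i, e in enumerate(rec.elements) if e != "H"]
        rec.atom_names = [rec.atom_names[i] for i in keep]
        rec.elements = [rec.elements[i] for i in keep]
        rec.res_names = [rec.res_names[i] for i in keep]
        rec.res_ids = [rec.res_ids[i] for i in keep]
        rec.chains = [rec.chains[i] for i in keep]
        rec.ins_codes = [rec.ins_codes[i] for i in keep]
        rec.coords = rec.coords[keep]
        assert stripped_names == rec.atom_names
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(bare, rec)

    def test_cation_on_axis_vs_in_plane(self):
        ring = ring_geometry(hexagon())
        on_axis = detect_cation_pi([("LYS10", (0, 0, 4.0))], [ring], "lig")
        assert len(on_axis) == 1 and on_axis[0].angle == pytest.approx(0.0, abs=1e-9)
        in_plane = detect_cation_pi([("LYS10", (0, 4.0, 0))], [ring], "lig")
        assert in_plane == []

    def test_scene_intended_contacts_recovered(self):
        specs = [
            ContactSpec("pi_sandwich", "PHE", 330, 3.56),
            ContactSpec("pi_parallel_displaced", "TRP", 84, 4.10, offset=2.5),
            ContactSpec("pi_t_shaped", "TYR", 334, 4.55),
            ContactSpec("hbond", "TRP", 279, 3.17),
            ContactSpec("cation_pi", "LYS", 10, 4.0),
        ]
        _, _, _, contacts = scene_for(specs, seed=5)
        got = {(c.type, c.residue): c.distance for c in contacts}
        for s in specs:
            key = (s.type, f"{s.res_name}{s.res_id}")
            assert key in got
            assert got[key] == pytest.approx(s.distance, abs=1e-6)

    def test_empty_scene(self):
        _, _, _, contacts = scene_for([], seed=2)
        assert contacts == []


class TestRigidMotionInvariance:
    def test_contacts_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(42)
        specs = [
            ContactSpec("pi_sandwich", "PHE", 330, 3.56),
            ContactSpec("hbond", "TRP", 279, 3.17),
            ContactSpec("cation_pi", "LYS", 10, 4.0),
        ]
        receptor, pose, truth = gen_site_scene(specs, seed=9)
        base = find_contacts(pose, receptor, [truth["ligand_ring"]], truth["ligand_cations"])
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(scale=20, size=3)
            import copy

            rec = copy.deepcopy(receptor)
            rec.coords = receptor.coords @ R.T + t
            po = copy.deepcopy(pose)
            po.coords = pose.coords @ R.T + t
            moved = find_contacts(po, rec, [truth["ligand_ring"]], truth["ligand_cations"])
            assert [(c.type, c.residue) for c in moved] == [
                (c.type, c.residue) for c in base
            ]
            for a, b in zip(base, moved):
                assert b.distance == pytest.approx(a.distance, abs=1e-9)
                assert b.angle == pytest.approx(a.angle, abs=1e-7)


class TestSummarize:
    def _contact(self, d, lig="l1", res="PHE330", ctype="pi_sandwich"):
        from cholinib.interactions import ContactRecord

        return ContactRecord(type=ctype, ligand_id=lig, residue=res, distance=d)

    def test_mean_and_sample_sd(self):
        rows = summarize(
            [self._contact(3.2, "l1"), self._contact(3.5, "l2"), self._contact(3.8, "l3")]
        )
        assert len(rows) == 1
        assert rows.loc[0, "n_ligands"] == 3
        assert rows.loc[0, "mean_dist"] == pytest.approx(3.50)
        assert rows.loc[0, "sd_dist"] == pytest.approx(0.30)

    def test_single_contact_sd_zero(self):
        rows = summarize([self._contact(3.56)])
        assert rows.loc[0, "sd_dist"] == 0.0

    def test_empty(self):
        assert len(summarize([])) == 0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        ds = rng.uniform(3, 5, size=9)
        rows = summarize([self._contact(d, lig=f"l{i}") for i, d in enumerate(ds)])
        mean = sum(ds) / len(ds)
        sd = math.sqrt(sum((d - mean) ** 2 for d in ds) / (len(ds) - 1))
        assert rows.loc[0, "mean_dist"] == pytest.approx(mean, abs=1e-12)
        assert rows.loc[0, "sd_dist"] == pytest.approx(sd, abs=1e-12)
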