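"""Seeded generators for every input the pipeline consumes, with truth sidecars.

Commercial docking and rescoring engines produced the study's original pose
sets; this module replaces them with abstract but structurally faithful
stand-ins so every analysis stage can be exercised and verified at desk
scale:

* pose ensembles with planted binding modes whose true-mode rescoring
  energies correlate linearly with the IC50-derived experimental binding
  free energies,
* Michaelis-Menten rate tables with multiplicative Gaussian noise over the
  assay's concentration design,
* four-parameter-logistic dose-response curves,
* protein-ligand interaction scenes constructed so each intended contact
  satisfies its geometric class criteria.

All generators are pure functions of (config, seed); written files carry the
config hash in a header comment or SD field.  Truth sidecars record planted
labels and parameters so recovery metrics never re-derive them.

Pose geometry is deliberately abstract — a rigid dummy-atom scaffold with
canonical names, isotropically jittered — because the consensus algorithm
depends only on named coordinates and scores, not on chemical realism.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import R_KCAL, STANDARD_T
from .interactions import GeometryCutoffs
from .kinetics import InhibitionModel, model_rate, _fourpl
from .pose_io import CoreAtomMap, LigandPose, Receptor, load_core_map, write_poses

__all__ = [
    "PoseEnsembleConfig",
    "EnsembleTruth",
    "KineticsDesign",
    "ContactSpec",
    "default_activity_ic50",
    "gen_pose_ensemble",
    "gen_kinetics",
    "gen_dose_response",
    "gen_site_scene",
    "TWO_MODE_CLEAN",
]


def _config_hash(obj) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pose ensembles


@dataclass(frozen=True)
class PoseEnsembleConfig:
    """Planted-mode pose-ensemble design.

    ``sigma_e = None`` calibrates the true-mode energy noise from the realized
    spread of dGexpt so the planted coefficient of determination equals
    ``target_r2``.
    """

    n_ligands: int = 12
    n_receptors: int = 2
    poses_per_ligand: int = 100
    n_modes: int = 2
    mode_separation: float = 8.0  # A between mode centers
    jitter: float = 0.3  # A, isotropic per-atom sigma
    energy_slope: float = 1.0  # a in rescore = a*dGexpt + b + eps
    energy_intercept: float = 0.0  # b, kcal/mol
    sigma_e: float | None = None  # kcal/mol; None -> calibrate to target_r2
    target_r2: float = 0.85
    decoy_offset: float = 3.0  # kcal/mol added to decoy energy level
    true_mode_fraction: float = 0.6  # share of each ligand's poses in the true mode
    stereo_tags: tuple[str, ...] = ("R",)
    seed: int = 0

    def __post_init__(self):
        if self.poses_per_ligand < 1 or self.n_ligands < 1 or self.n_modes < 1:
            raise ValueError("counts must be >= 1")
        if self.n_modes > 1 and not self.mode_separation > 4 * self.jitter:
            raise ValueError("well-separated preset requires separation > 4*jitter")


#: The benchmark preset: well-separated two-mode ensemble, planted R^2 = 0.85.
TWO_MODE_CLEAN = PoseEnsembleConfig()


@dataclass
class EnsembleTruth:
    """Sidecar: planted labels and parameters for recovery metrics."""

    config_hash: str
    true_mode: int
    mode_of: dict[str, int]  # "lig|stereo|rec|idx" -> mode index
    dg_expt: dict[str, float]  # ligand -> kcal/mol
    energy_slope: float
    energy_intercept: float
    sigma_e: float
    planted_r2: float

    @staticmethod
    def key_str(key) -> str:
        return "|".join(str(k) for k in key)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "EnsembleTruth":
        return cls(**json.loads(Path(path).read_text()))


def default_activity_ic50(n_ligands: int, rng: np.random.Generator) -> dict[str, float]:
    """IC50 table (uM): the printed anchor values padded with log-uniform draws."""
    printed = {"5n": 4.24, "6aa": 3.97, "galantamine": 8.80}
    ids = list(printed)[:n_ligands]
    ic50 = {cid: printed[cid] for cid in ids}
    k = 1
    while len(ic50) < n_ligands:
        ic50[f"lig{k:02d}"] = float(np.exp(rng.uniform(np.log(1.0), np.log(100.0))))
        k += 1
    return ic50


def _scaffold_template(core_map: CoreAtomMap, rng: np.random.Generator) -> np.ndarray:
    """A rigid random scaffold: points spread over ~6 A, centered at origin."""
    pts = rng.uniform(-3.0, 3.0, size=(len(core_map), 3))
    return pts - pts.mean(axis=0)


def gen_pose_ensemble(
    cfg: PoseEnsembleConfig = TWO_MODE_CLEAN,
    ic50_uM: dict[str, float] | None = None,
    core_map: CoreAtomMap | None = None,
    out_dir=None,
):
    """Generate a planted-mode pose ensemble.

    Returns ``(poses, score_table, truth, core_map)``; with ``out_dir`` also
    writes ``poses.sdf``, ``scores.csv``, ``truth.json`` and ``core_map.txt``.
    Mode 0 is the activity-correlated true mode; higher modes are decoys with
    energies at the same scale but uncorrelated with activity.
    """
    rng = np.random.default_rng(cfg.seed)
    chash = _config_hash(cfg)
    if core_map is None:
        core_map = load_core_map()
    if ic50_uM is None:
        ic50_uM = default_activity_ic50(cfg.n_ligands, rng)
    ligands = sorted(ic50_uM)[: cfg.n_ligands]
    dg_expt = {l: R_KCAL * STANDARD_T * math.log(ic50_uM[l] * 1e-6) for l in ligands}

    a, b = cfg.energy_slope, cfg.energy_intercept
    signal = np.array([a * dg_expt[l] for l in ligands])
    var_signal = float(np.var(signal))
    if cfg.sigma_e is not None:
        sigma_e = cfg.sigma_e
    else:
        sigma_e = math.sqrt(var_signal * (1.0 / cfg.target_r2 - 1.0))
    planted_r2 = var_signal / (var_signal + sigma_e**2) if var_signal + sigma_e**2 > 0 else 1.0

    template = _scaffold_template(core_map, rng)
    # mode centers along +x, `mode_separation` apart
    centers = [np.array([m * cfg.mode_separation, 0.0, 0.0]) for m in range(cfg.n_modes)]

    n_true = max(1, round(cfg.true_mode_fraction * cfg.poses_per_ligand))
    if cfg.n_modes == 1:
        n_true = cfg.poses_per_ligand

    poses: list[LigandPose] = []
    mode_of: dict[str, int] = {}
    rows = []
    for li, lig in enumerate(ligands):
        stereo = cfg.stereo_tags[li % len(cfg.stereo_tags)]
        eps_true = rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0
        true_energy = a * dg_expt[lig] + b + eps_true
        decoy_sd = math.sqrt(var_signal) or 1.0
        decoy_energy = {
            m: float(np.mean(signal)) + b + cfg.decoy_offset + rng.normal(0.0, decoy_sd)
            for m in range(1, cfg.n_modes)
        }
        # energy is ligand-level (rescoring near-identical geometries gives
        # near-identical energies); the per-pose jitter is a 1% perturbation
        true_jitter = 0.01 * sigma_e
        decoy_jitter = 0.01 * decoy_sd
        # mode assignment: first n_true poses true, remainder cycles decoys
        for pi in range(cfg.poses_per_ligand):
            if pi < n_true or cfg.n_modes == 1:
                mode = 0
                energy = true_energy + (rng.normal(0.0, true_jitter) if true_jitter else 0.0)
            else:
                mode = 1 + (pi - n_true) % (cfg.n_modes - 1)
                energy = decoy_energy[mode] + rng.normal(0.0, decoy_jitter)
            rec = f"rec{pi % cfg.n_receptors:02d}"
            coords = template + centers[mode] + rng.normal(0.0, cfg.jitter, size=template.shape)
            pose = LigandPose(
                ligand_id=lig,
                stereo_tag=stereo,
                receptor_id=rec,
                pose_index=pi,
                atom_names=list(core_map.names),
                elements=["C"] * len(core_map),
                coords=coords,
                docking_score=energy + rng.normal(0.0, 0.5),
                rescore_dg=energy,
            )
            poses.append(pose)
            mode_of[EnsembleTruth.key_str(pose.key)] = mode
            rows.append(
                {
                    "ligand_id": lig,
                    "stereo_tag": stereo,
                    "receptor_id": rec,
                    "pose_index": pi,
                    "docking_score": pose.docking_score,
                    "rescore_dg": pose.rescore_dg,
                }
            )

    score_table = pd.DataFrame(rows)
    truth = EnsembleTruth(
        config_hash=chash,
        true_mode=0,
        mode_of=mode_of,
        dg_expt=dg_expt,
        energy_slope=a,
        energy_intercept=b,
        sigma_e=sigma_e,
        planted_r2=planted_r2,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_poses(poses, out / "poses.sdf", header_comment=f"config_hash={chash}")
        with open(out / "scores.csv", "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            score_table.to_csv(fh, index=False)
        truth.save(out / "truth.json")
        (out / "core_map.txt").write_text(
            f"# config_hash={chash}\n" + "\n".join(core_map.names) + "\n"
        )
        pd.DataFrame(
            {"compound": ligands, "target": "AChE", "ic50_uM": [ic50_uM[l] for l in ligands]}
        ).to_csv(out / "activity.csv", index=False)
    return poses, score_table, truth, core_map


# ---------------------------------------------------------------------------
# Kinetics


@dataclass(frozen=True)
class KineticsDesign:
    """Assay design: eight log-spaced substrate levels over the assay range,
    three inhibitor levels around the compound's IC50."""

    substrate_mM: tuple[float, ...] = tuple(
        float(s) for s in np.geomspace(3.75e-3, 0.48, 8)
    )
    inhibitor_uM: tuple[float, ...] = (0.0, 2.12, 4.24)
    replicates: int = 3


def gen_kinetics(
    model: InhibitionModel,
    design: KineticsDesign = KineticsDesign(),
    cv: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Rate table with multiplicative Gaussian noise; returns (table, truth)."""
    rng = np.random.default_rng(seed)
    rows = []
    for I in design.inhibitor_uM:
        for S in design.substrate_mM:
            v0 = model_rate(model, S, I)
            for rep in range(design.replicates):
                noise = rng.normal(0.0, cv) if cv > 0 else 0.0
                rows.append(
                    {"S_mM": S, "I_uM": I, "v": max(v0 * (1.0 + noise), 0.0), "replicate": rep}
                )
    truth = {
        "config_hash": _config_hash((model, design, cv, seed)),
        "model": {
            "kind": model.kind,
            "Vmax": model.Vmax,
            "Km": model.Km,
            "Ki": model.Ki,
            "Ki_prime": model.Ki_prime,
        },
        "cv": cv,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


def gen_dose_response(
    ic50_uM: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    sigma_pct: float = 3.0,
    n_concs: int = 5,
    bracket: float = 16.0,
    seed: int = 0,
):
    """Noisy 4PL curve over ``n_concs`` log-spaced concentrations bracketing IC50."""
    rng = np.random.default_rng(seed)
    concs = np.geomspace(ic50_uM / bracket, ic50_uM * bracket, n_concs)
    y = _fourpl(concs, bottom, top, ic50_uM, hill) + rng.normal(0.0, sigma_pct, size=n_concs)
    truth = {"ic50_uM": ic50_uM, "hill": hill, "top": top, "bottom": bottom,
             "sigma_pct": sigma_pct, "seed": seed}
    return concs, y, truth


# ---------------------------------------------------------------------------
# Interaction scenes


@dataclass(frozen=True)
class ContactSpec:
    """One intended contact: class, residue identity, and target geometry."""

    type: str
    res_name: str
    res_id: int
    distance: float  # A, in the convention of the class
    offset: float = 0.0  # lateral offset for pi classes


_HEX_R = 1.39  # aromatic C-C ring circumradius, A
_PENT_R = 1.17

#: Six-membered (or His five-membered) aromatic ring atom names per residue.
_SCENE_RINGS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def _ring_coords(n: int, center, normal_axis="z") -> np.ndarray:
    r = _HEX_R if n == 6 else _PENT_R
    ang = np.arange(n) * 2 * math.pi / n
    flat = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)], axis=1)
    if normal_axis == "x":  # rotate so the ring normal points along +x
        flat = flat[:, [2, 0, 1]]
    return flat + np.asarray(center, dtype=float)


def gen_site_scene(specs: list[ContactSpec], seed: int = 0,
                   cutoffs: GeometryCutoffs = GeometryCutoffs()):
    """Build (receptor fragment, ligand pose, truth) realizing the intended contacts.

    The ligand is a benzene-like ring in the z=0 plane (atoms LC1..LC6, with
    ring hydrogens, an acceptor oxygen LO1 and a cationic nitrogen LN1);
    each spec places one residue so its contact meets the class criteria
    exactly at the requested geometry.  Conflicting or out-of-window specs
    raise.  Distractor carbons are scattered far from the site.
    """
    rng = np.random.default_rng(seed)
    lig_names = [f"LC{i}" for i in range(1, 7)]
    lig_elements = ["C"] * 6
    lig_coords = list(_ring_coords(6, (0.0, 0.0, 0.0)))
    # ring hydrogens (radially outward, in plane) for weak C-H donation
    for i in range(6):
        direction = lig_coords[i] / np.linalg.norm(lig_coords[i])
        lig_names.append(f"LH{i + 1}")
        lig_elements.append("H")
        lig_coords.append(lig_coords[i] + 1.09 * direction)
    # cationic amine nitrogen far out in the ring plane (outside every window)
    lig_names.append("LN1")
    lig_elements.append("N")
    lig_coords.append(np.array([0.0, -5.0, 0.0]))

    rec_names: list[str] = []
    rec_elements: list[str] = []
    rec_resnames: list[str] = []
    rec_resids: list[int] = []
    rec_coords: list[np.ndarray] = []

    def add_residue(res_name, res_id, names, elements, coords):
        for n, e, c in zip(names, elements, coords):
            rec_names.append(n)
            rec_elements.append(e)
            rec_resnames.append(res_name)
            rec_resids.append(res_id)
            rec_coords.append(np.asarray(c, dtype=float))

    def ring_for(spec):
        if spec.res_name not in _SCENE_RINGS:
            raise ValueError(f"no aromatic template for residue {spec.res_name!r}")
        names = _SCENE_RINGS[spec.res_name]
        elements = ["N" if n.startswith("N") else "C" for n in names]
        return names, elements

    # polar contacts get separate azimuthal slots, each with its own ligand
    # acceptor oxygen below the ring plane, to keep contact sites independent
    polar_slot = 0

    def polar_acceptor() -> np.ndarray:
        nonlocal polar_slot
        phi = 0.4 + polar_slot * 2 * math.pi / 5
        polar_slot += 1
        xyz = np.array([2.5 * math.cos(phi), 2.5 * math.sin(phi), -2.0])
        lig_names.append(f"LO{polar_slot}")
        lig_elements.append("O")
        lig_coords.append(xyz)
        return xyz

    for spec in specs:
        t = spec.type
        if t == "pi_sandwich":
            if spec.distance > cutoffs.pi_dist_parallel_max or spec.offset > cutoffs.pi_offset_sandwich_max:
                raise ValueError(f"infeasible sandwich spec: {spec}")
            names, elements = ring_for(spec)
            h = math.sqrt(spec.distance**2 - spec.offset**2)
            add_residue(spec.res_name, spec.res_id, names, elements,
                        _ring_coords(len(names), (spec.offset, 0.0, h)))
        elif t == "pi_parallel_displaced":
            if not (cutoffs.pi_offset_sandwich_max < spec.offset <= cutoffs.pi_offset_displaced_max):
                raise ValueError(f"parallel-displaced spec needs offset in (1.5, 4.0]: {spec}")
            if spec.distance > cutoffs.pi_dist_parallel_max or spec.offset >= spec.distance:
                raise ValueError(f"infeasible parallel-displaced spec: {spec}")
            names, elements = ring_for(spec)
            h = math.sqrt(spec.distance**2 - spec.offset**2)
            add_residue(spec.res_name, spec.res_id, names, elements,
                        _ring_coords(len(names), (spec.offset, 0.0, h)))
        elif t == "pi_t_shaped":
            if spec.distance > cutoffs.pi_dist_tshaped_max:
                raise ValueError(f"infeasible T-shaped spec: {spec}")
            names, elements = ring_for(spec)
            # edge-on ring: centroid in the ligand plane, normal along +x
            add_residue(spec.res_name, spec.res_id, names, elements,
                        _ring_coords(len(names), (0.0, spec.distance, 0.0), normal_axis="x"))
        elif t == "hbond":
            if spec.distance > cutoffs.hbond_da_max:
                raise ValueError(f"infeasible H-bond spec: {spec}")
            # colinear N-H...O pointing up at a dedicated ligand acceptor
            acceptor = polar_acceptor()
            donor = acceptor + np.array([0.0, 0.0, -spec.distance])
            hydrogen = acceptor + np.array([0.0, 0.0, -(spec.distance - 1.0)])
            add_residue(spec.res_name, spec.res_id, ["NE1", "HE1"], ["N", "H"],
                        [donor, hydrogen])
        elif t == "weak_ch_hbond":
            if spec.distance > cutoffs.weak_ha_max:
                raise ValueError(f"infeasible weak H-bond spec: {spec}")
            # aromatic C-H donating to a dedicated ligand acceptor, H...A colinear
            acceptor = polar_acceptor()
            hydrogen = acceptor + np.array([0.0, 0.0, -spec.distance])
            carbon = hydrogen + np.array([0.0, 0.0, -1.09])
            outward = acceptor[:2] / np.linalg.norm(acceptor[:2])
            center = carbon + _HEX_R * np.array([outward[0], outward[1], 0.0])
            names, elements = ring_for(spec)
            ring = _ring_coords(len(names), center)
            # put one vertex exactly at the donor carbon position
            ring += carbon - ring[np.argmin(np.linalg.norm(ring - carbon, axis=1))]
            add_residue(spec.res_name, spec.res_id, names, elements, ring)
            add_residue(spec.res_name, spec.res_id, ["HX1"], ["H"], [hydrogen])
        elif t == "cation_pi":
            if spec.distance > cutoffs.cation_pi_dist_max:
                raise ValueError(f"infeasible cation-pi spec: {spec}")
            add_residue(spec.res_name, spec.res_id, ["NZ"], ["N"],
                        [np.array([0.0, 0.0, -spec.distance])])
        else:
            raise ValueError(f"unknown contact type {t!r}")

    # distractors well outside every cutoff
    for i in range(5):
        add_residue("ALA", 900 + i, ["CB"], ["C"], [rng.uniform(20.0, 30.0, size=3)])

    receptor = Receptor(
        id=f"scene-{seed}",
        atom_names=rec_names,
        elements=rec_elements,
        res_names=rec_resnames,
        res_ids=rec_resids,
        chains=["A"] * len(rec_names),
        ins_codes=[""] * len(rec_names),
        coords=np.array(rec_coords),
    )
    pose = LigandPose(
        ligand_id="scene-ligand",
        stereo_tag="R",
        receptor_id=receptor.id,
        pose_index=0,
        atom_names=lig_names,
        elements=lig_elements,
        coords=np.array(lig_coords),
        docking_score=0.0,
        rescore_dg=0.0,
    )
    truth = {
        "config_hash": _config_hash((tuple(specs), seed)),
        "intended": [asdict(s) for s in specs],
        "ligand_ring": [f"LC{i}" for i in range(1, 7)],
        "ligand_cations": ["LN1"],
        "seed": seed,
    }
    return receptor, pose, truth
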