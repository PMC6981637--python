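"""Geometric protein-ligand interaction fingerprints.

Detects the contact classes discussed for the aromatic gorge of the
cholinesterases — pi-stacking in sandwich, parallel-displaced, and T-shaped
conformations, conventional and weak (aromatic C-H) hydrogen bonds, and
cation-pi contacts — and summarizes them per residue as ligand counts with
mean +/- SD distances.

The detection criteria are purely geometric and live in one overridable
config block (:class:`GeometryCutoffs`); the defaults follow common published
conventions for each class:

* sandwich:            interplanar angle <= 30 deg, centroid distance <= 5.5 A,
                       lateral offset <= 1.5 A
* parallel-displaced:  same, but 1.5 < offset <= 4.0 A
* T-shaped:            60 <= angle <= 90 deg, distance <= 6.0 A
* H-bond:              donor-acceptor <= 3.5 A, D-H...A angle >= 120 deg
                       (distance reported donor-acceptor)
* weak C-H H-bond:     H...acceptor <= 3.0 A, angle >= 110 deg
                       (distance reported H-acceptor)
* cation-pi:           cation-centroid <= 6.0 A, axis angle <= 45 deg

Donor/acceptor typing is a small rules table (N/O with an attached hydrogen
donate; N/O accept), not bond-order perception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pose_io import LigandPose, Receptor

__all__ = [
    "GeometryCutoffs",
    "Ring",
    "ContactRecord",
    "ring_geometry",
    "classify_ring_pair",
    "detect_hbonds",
    "detect_cation_pi",
    "find_contacts",
    "receptor_rings",
    "ligand_rings",
    "receptor_cations",
    "summarize",
    "RESIDUE_RINGS",
]


@dataclass(frozen=True)
class GeometryCutoffs:
    pi_angle_parallel_max: float = 30.0  # deg
    pi_dist_parallel_max: float = 5.5  # A
    pi_offset_sandwich_max: float = 1.5  # A
    pi_offset_displaced_max: float = 4.0  # A
    pi_angle_tshaped_min: float = 60.0  # deg
    pi_dist_tshaped_max: float = 6.0  # A
    hbond_da_max: float = 3.5  # A, donor-acceptor
    hbond_angle_min: float = 120.0  # deg, D-H...A
    weak_ha_max: float = 3.0  # A, H-acceptor
    weak_angle_min: float = 110.0  # deg
    cation_pi_dist_max: float = 6.0  # A
    cation_pi_axis_max: float = 45.0  # deg
    ring_planarity_tol: float = 0.3  # A, max out-of-plane deviation
    h_attach_max: float = 1.3  # A, covalent H assignment


#: Aromatic side-chain ring atom names per residue type.
RESIDUE_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


@dataclass(frozen=True)
class Ring:
    owner: str  # "PHE330" style residue label, or a ligand id
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray  # unit


@dataclass(frozen=True)
class ContactRecord:
    type: str  # pi_sandwich | pi_parallel_displaced | pi_t_shaped | hbond | weak_ch_hbond | cation_pi
    ligand_id: str
    residue: str
    distance: float  # A; centroid-centroid (pi), donor-acceptor (hbond), H-acceptor (weak)
    angle: float | None = None  # deg
    offset: float | None = None  # A, pi classes only


def ring_geometry(coords: Sequence[Sequence[float]], owner: str = "", atom_names=(),
                  planarity_tol: float = 0.3) -> Ring:
    """Centroid and least-squares plane normal of a 5- or 6-membered ring.

    The normal sign is canonicalized toward +z, ties broken toward +x then +y.
    Raises if the atoms deviate from the best plane by more than the tolerance.
    """
    xyz = np.asarray(coords, dtype=float)
    if xyz.shape[0] not in (5, 6) or xyz.shape[1] != 3:
        raise ValueError(f"ring needs 5 or 6 atoms with xyz, got shape {xyz.shape}")
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    # smallest singular vector of the centered coordinates = plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    dev = np.abs(centered @ normal)
    if dev.max() > planarity_tol:
        raise ValueError(
            f"ring {owner or atom_names}: out-of-plane deviation {dev.max():.2f} A "
            f"exceeds tolerance {planarity_tol} A"
        )
    for comp in (2, 0, 1):  # prefer +z, then +x, then +y
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    return Ring(owner=owner, atom_names=tuple(atom_names), centroid=centroid,
                normal=normal / np.linalg.norm(normal))


def _interplanar_angle(a: Ring, b: Ring) -> float:
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return math.degrees(math.acos(min(1.0, cosang)))  # folded to [0, 90]


def classify_ring_pair(a: Ring, b: Ring, cutoffs: GeometryCutoffs = GeometryCutoffs()):
    """Classify a ring pair as a pi-stacking contact, or return None.

    Returns ``(type, distance, angle, offset)``; offset is the lateral
    displacement of b's centroid in a's plane.
    """
    v = b.centroid - a.centroid
    d = float(np.linalg.norm(v))
    if d == 0:
        return None
    theta = _interplanar_angle(a, b)
    along = float(np.dot(v, a.normal))
    offset = math.sqrt(max(d**2 - along**2, 0.0))
    if theta <= cutoffs.pi_angle_parallel_max and d <= cutoffs.pi_dist_parallel_max:
        if offset <= cutoffs.pi_offset_sandwich_max:
            return ("pi_sandwich", d, theta, offset)
        if offset <= cutoffs.pi_offset_displaced_max:
            return ("pi_parallel_displaced", d, theta, offset)
        return None
    if cutoffs.pi_angle_tshaped_min <= theta <= 90.0 and d <= cutoffs.pi_dist_tshaped_max:
        return ("pi_t_shaped", d, theta, offset)
    return None


@dataclass
class _Site:
    """Flat atom view of one interaction partner (ligand pose or receptor)."""

    names: list[str]
    elements: list[str]
    coords: np.ndarray
    labels: list[str]  # per-atom owner label (residue label or ligand id)
    aromatic_carbon: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self):
        if self.aromatic_carbon is None:
            self.aromatic_carbon = np.zeros(len(self.names), dtype=bool)


def _pose_site(pose: LigandPose, ring_defs: Iterable[Sequence[str]] = ()) -> _Site:
    aromatic = set()
    for ring in ring_defs:
        aromatic.update(ring)
    site = _Site(
        names=list(pose.atom_names),
        elements=list(pose.elements),
        coords=np.asarray(pose.coords, dtype=float),
        labels=[pose.ligand_id] * len(pose.atom_names),
    )
    site.aromatic_carbon = np.array(
        [n in aromatic and e == "C" for n, e in zip(site.names, site.elements)]
    )
    return site


def _receptor_site(receptor: Receptor) -> _Site:
    labels = [f"{rn}{ri}" for rn, ri in zip(receptor.res_names, receptor.res_ids)]
    aromatic = np.zeros(len(receptor.atom_names), dtype=bool)
    for i, (rn, an, el) in enumerate(
        zip(receptor.res_names, receptor.atom_names, receptor.elements)
    ):
        ringed = {n for ring in RESIDUE_RINGS.get(rn, []) for n in ring}
        aromatic[i] = an in ringed and el == "C"
    return _Site(
        names=list(receptor.atom_names),
        elements=list(receptor.elements),
        coords=np.asarray(receptor.coords, dtype=float),
        labels=labels,
        aromatic_carbon=aromatic,
    )


def _attached_hydrogens(site: _Site, heavy_idx: int, h_attach_max: float) -> list[int]:
    out = []
    for j, el in enumerate(site.elements):
        if el == "H":
            if np.linalg.norm(site.coords[j] - site.coords[heavy_idx]) <= h_attach_max:
                out.append(j)
    return out


def _hbond_pairs(donor_site: _Site, acceptor_site: _Site, cutoffs: GeometryCutoffs,
                 weak: bool):
    """Yield (donor_idx, h_idx, acceptor_idx, da_dist, ha_dist, angle)."""
    donor_elements = {"C"} if weak else {"N", "O"}
    for di, el in enumerate(donor_site.elements):
        if el not in donor_elements:
            continue
        if weak and not donor_site.aromatic_carbon[di]:
            continue
        hs = _attached_hydrogens(donor_site, di, cutoffs.h_attach_max)
        for hi in hs:
            for ai, ael in enumerate(acceptor_site.elements):
                if ael not in ("N", "O"):
                    continue
                d_xyz = donor_site.coords[di]
                h_xyz = donor_site.coords[hi]
                a_xyz = acceptor_site.coords[ai]
                da = float(np.linalg.norm(a_xyz - d_xyz))
                ha = float(np.linalg.norm(a_xyz - h_xyz))
                if weak:
                    if ha > cutoffs.weak_ha_max:
                        continue
                else:
                    if da > cutoffs.hbond_da_max:
                        continue
                v1 = d_xyz - h_xyz
                v2 = a_xyz - h_xyz
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                ang = math.degrees(math.acos(np.clip(np.dot(v1, v2) / denom, -1, 1)))
                if ang >= (cutoffs.weak_angle_min if weak else cutoffs.hbond_angle_min):
                    yield di, hi, ai, da, ha, ang


def detect_hbonds(
    pose: LigandPose,
    receptor: Receptor,
    ligand_ring_defs: Iterable[Sequence[str]] = (),
    cutoffs: GeometryCutoffs = GeometryCutoffs(),
    include_weak: bool = True,
) -> list[ContactRecord]:
    """Hydrogen bonds between pose and receptor, both donor directions.

    Conventional H-bonds report the donor-acceptor distance; weak aromatic
    C-H bonds report the H-acceptor distance (the two conventions are kept
    apart by the record type).  Explicit hydrogens are required.
    """
    lig = _pose_site(pose, ligand_ring_defs)
    rec = _receptor_site(receptor)
    if "H" not in lig.elements and "H" not in rec.elements:
        raise ValueError("explicit hydrogens required for H-bond detection")
    records: list[ContactRecord] = []
    for weak in ([False, True] if include_weak else [False]):
        # ligand donates to receptor
        for di, hi, ai, da, ha, ang in _hbond_pairs(lig, rec, cutoffs, weak):
            records.append(
                ContactRecord(
                    type="weak_ch_hbond" if weak else "hbond",
                    ligand_id=pose.ligand_id,
                    residue=rec.labels[ai],
                    distance=ha if weak else da,
                    angle=ang,
                )
            )
        # receptor donates to ligand
        for di, hi, ai, da, ha, ang in _hbond_pairs(rec, lig, cutoffs, weak):
            records.append(
                ContactRecord(
                    type="weak_ch_hbond" if weak else "hbond",
                    ligand_id=pose.ligand_id,
                    residue=rec.labels[di],
                    distance=ha if weak else da,
                    angle=ang,
                )
            )
    return records


def detect_cation_pi(
    cations: Iterable[tuple[str, Sequence[float]]],
    rings: Iterable[Ring],
    ligand_id: str,
    cutoffs: GeometryCutoffs = GeometryCutoffs(),
    cation_side: str = "ligand",
) -> list[ContactRecord]:
    """Cation-pi contacts between supplied cation centers and aromatic rings.

    ``cations`` are (owner label, xyz) pairs — protonated amine nitrogens or
    guanidinium centroids; typing is the caller's rule, not perceived here.
    The residue label of the record is the receptor-side partner.
    """
    records = []
    for owner, xyz in cations:
        xyz = np.asarray(xyz, dtype=float)
        for ring in rings:
            v = xyz - ring.centroid
            d = float(np.linalg.norm(v))
            if d == 0 or d > cutoffs.cation_pi_dist_max:
                continue
            cosang = abs(float(np.dot(v / d, ring.normal)))
            ang = math.degrees(math.acos(min(1.0, cosang)))
            if ang <= cutoffs.cation_pi_axis_max:
                residue = ring.owner if cation_side == "ligand" else owner
                records.append(
                    ContactRecord(
                        type="cation_pi",
                        ligand_id=ligand_id,
                        residue=residue,
                        distance=d,
                        angle=ang,
                    )
                )
    return records


def receptor_rings(receptor: Receptor, cutoffs: GeometryCutoffs = GeometryCutoffs()) -> list[Ring]:
    """Aromatic side-chain rings auto-built from residue templates."""
    rings = []
    seen = set()
    for rn, ri, ch in zip(receptor.res_names, receptor.res_ids, receptor.chains):
        key = (rn, ri, ch)
        if key in seen or rn not in RESIDUE_RINGS:
            continue
        seen.add(key)
        names, coords = receptor.residue_atoms(rn, ri, ch)
        lookup = {n: coords[i] for i, n in enumerate(names)}
        for ring_names in RESIDUE_RINGS[rn]:
            if all(n in lookup for n in ring_names):
                rings.append(
                    ring_geometry(
                        [lookup[n] for n in ring_names],
                        owner=f"{rn}{ri}",
                        atom_names=ring_names,
                        planarity_tol=cutoffs.ring_planarity_tol,
                    )
                )
    return rings


def ligand_rings(pose: LigandPose, ring_defs: Iterable[Sequence[str]],
                 cutoffs: GeometryCutoffs = GeometryCutoffs()) -> list[Ring]:
    return [
        ring_geometry(
            [pose.coord_of(n) for n in names],
            owner=pose.ligand_id,
            atom_names=names,
            planarity_tol=cutoffs.ring_planarity_tol,
        )
        for names in ring_defs
    ]


def receptor_cations(receptor: Receptor) -> list[tuple[str, np.ndarray]]:
    """Cation centers by typing rule: Lys NZ; Arg guanidinium centroid."""
    out = []
    seen = set()
    for rn, ri, ch in zip(receptor.res_names, receptor.res_ids, receptor.chains):
        key = (rn, ri, ch)
        if key in seen:
            continue
        seen.add(key)
        names, coords = receptor.residue_atoms(rn, ri, ch)
        lookup = {n: coords[i] for i, n in enumerate(names)}
        if rn == "LYS" and "NZ" in lookup:
            out.append((f"{rn}{ri}", np.asarray(lookup["NZ"], float)))
        if rn == "ARG" and all(n in lookup for n in ("CZ", "NH1", "NH2")):
            cen = np.mean([lookup["CZ"], lookup["NH1"], lookup["NH2"]], axis=0)
            out.append((f"{rn}{ri}", cen))
    return out


def find_contacts(
    pose: LigandPose,
    receptor: Receptor,
    ligand_ring_defs: Iterable[Sequence[str]] = (),
    ligand_cation_atoms: Iterable[str] = (),
    cutoffs: GeometryCutoffs = GeometryCutoffs(),
    include_weak: bool = True,
) -> list[ContactRecord]:
    """All interaction records between one pose and the receptor."""
    records: list[ContactRecord] = []
    rec_rings = receptor_rings(receptor, cutoffs)
    lig_rings = ligand_rings(pose, ligand_ring_defs, cutoffs)
    for lr in lig_rings:
        for rr in rec_rings:
            hit = classify_ring_pair(lr, rr, cutoffs)
            if hit:
                ctype, d, theta, offset = hit
                records.append(
                    ContactRecord(
                        type=ctype,
                        ligand_id=pose.ligand_id,
                        residue=rr.owner,
                        distance=d,
                        angle=theta,
                        offset=offset,
                    )
                )
    records.extend(
        detect_hbonds(pose, receptor, ligand_ring_defs, cutoffs, include_weak=include_weak)
    )
    lig_cations = [
        (pose.ligand_id, pose.coord_of(n)) for n in ligand_cation_atoms
    ]
    records.extend(detect_cation_pi(lig_cations, rec_rings, pose.ligand_id, cutoffs, "ligand"))
    records.extend(
        detect_cation_pi(receptor_cations(receptor), lig_rings, pose.ligand_id, cutoffs, "receptor")
    )
    return records


def summarize(contacts: Iterable[ContactRecord]) -> pd.DataFrame:
    """Per (residue, type): ligand count, mean and sample SD of distance.

    SD uses n-1 normalization and is reported as 0.0 for single contacts,
    matching the "mean +/- SD over the representative poses" convention.
    """
    contacts = list(contacts)
    if not contacts:
        return pd.DataFrame(columns=["residue", "type", "n_ligands", "mean_dist", "sd_dist"])
    df = pd.DataFrame(
        {
            "residue": [c.residue for c in contacts],
            "type": [c.type for c in contacts],
            "ligand_id": [c.ligand_id for c in contacts],
            "distance": [c.distance for c in contacts],
        }
    )
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_ligands": g["ligand_id"].nunique(),
                "mean_dist": g["distance"].mean(),
                "sd_dist": g["distance"].std(ddof=1) if len(g) > 1 else 0.0,
            }
        )
    out = df.groupby(["residue", "type"]).apply(agg, include_groups=False).reset_index()
    out["n_ligands"] = out["n_ligands"].astype(int)
    return out.sort_values(["residue", "type"]).reset_index(drop=True)
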