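"""Readers/writers and data model for receptors, ligand pose sets, and the core map.

Poses are assumed pre-aligned to a common receptor frame (the ensemble-docking
convention of superposing the protein structures before clustering); this
module never transforms coordinates.  When several receptors are supplied,
:func:`check_receptor_alignment` verifies the assumption (CA RMSD < 1 A) and
warns otherwise.

File formats: receptors as PDB (parsed/written with biotite), poses as SDF
V2000 (RDKit) with pose identity, atom names, and scores carried in SD data
fields, scores optionally joined from a delimited side table that takes
precedence on conflict.  All coordinates are in Angstrom; no unit detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from rdkit import Chem
from rdkit.Geometry import Point3D

__all__ = [
    "Receptor",
    "LigandPose",
    "CoreAtomMap",
    "read_receptor",
    "write_receptor",
    "read_poses",
    "write_poses",
    "read_score_table",
    "core_coordinates",
    "check_receptor_alignment",
    "load_core_map",
]

PoseKey = tuple[str, str, str, int]  # (ligand id, stereo tag, receptor id, pose index)


@dataclass
class Receptor:
    """Protein structure as parallel per-atom arrays (coordinates in A)."""

    id: str
    atom_names: list[str]
    elements: list[str]
    res_names: list[str]
    res_ids: list[int]
    chains: list[str]
    ins_codes: list[str]
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size == 0:
            raise ValueError(f"receptor {self.id}: empty structure")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"receptor {self.id}: non-finite coordinates")

    def ca_coords(self) -> np.ndarray:
        mask = [n == "CA" for n in self.atom_names]
        return self.coords[np.asarray(mask, dtype=bool)]

    def residue_atoms(self, res_name: str, res_id: int, chain: str | None = None):
        """(names, coords) of one residue's atoms."""
        idx = [
            i
            for i in range(len(self.atom_names))
            if self.res_names[i] == res_name
            and self.res_ids[i] == res_id
            and (chain is None or self.chains[i] == chain)
        ]
        return [self.atom_names[i] for i in idx], self.coords[idx]


@dataclass
class LigandPose:
    """One docking pose: named atoms in the common receptor frame plus scores."""

    ligand_id: str
    stereo_tag: str
    receptor_id: str
    pose_index: int
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    docking_score: float
    rescore_dg: float | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.atom_names)) != len(self.atom_names):
            raise ValueError(f"pose {self.key}: duplicate atom names")
        self._index = {n: i for i, n in enumerate(self.atom_names)}

    @property
    def key(self) -> PoseKey:
        return (self.ligand_id, self.stereo_tag, self.receptor_id, self.pose_index)

    def coord_of(self, atom_name: str) -> np.ndarray:
        return self.coords[self._index[atom_name]]


@dataclass(frozen=True)
class CoreAtomMap:
    """Ordered atom names of the scaffold shared by all ligands."""

    names: tuple[str, ...]

    def __post_init__(self):
        if not self.names:
            raise ValueError("core atom map must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("core atom map contains duplicate names")

    def __len__(self):
        return len(self.names)


def load_core_map(path=None) -> CoreAtomMap:
    """Read a core map: one atom name per line, '#' comments allowed."""
    src = path if path is not None else resources.files("cholinib.data").joinpath("core_map.txt")
    text = Path(src).read_text() if not hasattr(src, "read_text") else src.read_text()
    names = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    return CoreAtomMap(tuple(names))


# ---------------------------------------------------------------------------
# PDB receptors


def _validate_pdb_lines(path) -> None:
    # Fail early with a line number; biotite's own errors lack file context.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                        ) from None


def read_receptor(path, receptor_id: str | None = None) -> Receptor:
    """Load all ATOM/HETATM records of a PDB file; no coordinate transform."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    try:
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        raise ValueError(f"{path}: empty or unparseable structure ({exc})") from exc
    if arr.array_length() == 0:
        raise ValueError(f"{path}: empty structure")
    return Receptor(
        id=receptor_id or path.stem,
        atom_names=list(arr.atom_name),
        elements=[e.capitalize() for e in arr.element],
        res_names=list(arr.res_name),
        res_ids=[int(i) for i in arr.res_id],
        chains=list(arr.chain_id),
        ins_codes=list(arr.ins_code),
        coords=np.array(arr.coord, dtype=float),
    )


def write_receptor(receptor: Receptor, path) -> None:
    n = len(receptor.atom_names)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(receptor.coords, dtype=np.float32)
    arr.atom_name = np.array(receptor.atom_names)
    arr.element = np.array([e.upper() for e in receptor.elements])
    arr.res_name = np.array(receptor.res_names)
    arr.res_id = np.array(receptor.res_ids)
    arr.chain_id = np.array(receptor.chains)
    arr.set_annotation("ins_code", np.array(receptor.ins_codes))
    arr.hetero = np.array([False] * n)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def check_receptor_alignment(receptors: Sequence[Receptor], threshold: float = 1.0) -> bool:
    """Warn (and return False) if any receptor pair has CA RMSD >= threshold."""
    ok = True
    for i in range(len(receptors)):
        for j in range(i + 1, len(receptors)):
            a, b = receptors[i].ca_coords(), receptors[j].ca_coords()
            m = min(len(a), len(b))
            if m == 0:
                continue
            rmsd = float(np.sqrt(np.mean(np.sum((a[:m] - b[:m]) ** 2, axis=1))))
            if rmsd >= threshold:
                ok = False
                warnings.warn(
                    f"receptors {receptors[i].id} and {receptors[j].id} differ by "
                    f"CA RMSD {rmsd:.2f} A; poses may not share a common frame",
                    stacklevel=2,
                )
    return ok


# ---------------------------------------------------------------------------
# SDF poses + score table

_PROPS = ("ligand_id", "stereo_tag", "receptor_id", "pose_index", "atom_names")


def write_poses(poses: Iterable[LigandPose], path, header_comment: str | None = None) -> None:
    """Write poses as SDF V2000 with identity/scores in SD data fields."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = Chem.RWMol()
            conf = Chem.Conformer(len(pose.atom_names))
            for i, el in enumerate(pose.elements):
                mol.AddAtom(Chem.Atom(el))
                x, y, z = pose.coords[i]
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            mol = mol.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", f"{pose.ligand_id}:{pose.stereo_tag}:{pose.receptor_id}:{pose.pose_index}")
            mol.SetProp("ligand_id", pose.ligand_id)
            mol.SetProp("stereo_tag", pose.stereo_tag)
            mol.SetProp("receptor_id", pose.receptor_id)
            mol.SetProp("pose_index", str(pose.pose_index))
            mol.SetProp("atom_names", " ".join(pose.atom_names))
            mol.SetProp("docking_score", repr(float(pose.docking_score)))
            if pose.rescore_dg is not None:
                mol.SetProp("rescore_dg", repr(float(pose.rescore_dg)))
            if header_comment is not None:
                mol.SetProp("comment", header_comment)
            writer.write(mol)
    finally:
        writer.close()


def read_score_table(path) -> pd.DataFrame:
    """Delimited score table keyed by (ligand_id, stereo_tag, receptor_id, pose_index)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    key_cols = ["ligand_id", "stereo_tag", "receptor_id", "pose_index"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing key columns: {missing}")
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols, keep=False)].iloc[0]
        raise ValueError(f"duplicate pose key in score table: {tuple(dup[key_cols])}")
    return df


def read_poses(sdf_path, score_table=None) -> list[LigandPose]:
    """Read an SDF pose set, joining scores from an optional side table.

    The table (path or DataFrame) takes precedence over SDF score fields; a
    pose with neither a table row nor an SDF ``docking_score`` is an error, as
    is an atom-name mismatch across poses of one ligand.
    """
    scores = None
    if score_table is not None:
        df = score_table if isinstance(score_table, pd.DataFrame) else read_score_table(score_table)
        scores = {
            (r.ligand_id, r.stereo_tag, r.receptor_id, int(r.pose_index)): r
            for r in df.itertuples(index=False)
        }

    poses: list[LigandPose] = []
    seen: set[PoseKey] = set()
    supplier = Chem.SDMolSupplier(str(sdf_path), sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{sdf_path}: unreadable SDF record #{idx}")
        for prop in _PROPS:
            if not mol.HasProp(prop):
                raise ValueError(f"{sdf_path}: record #{idx} missing SD field {prop!r}")
        names = mol.GetProp("atom_names").split()
        if len(names) != mol.GetNumAtoms():
            raise ValueError(f"{sdf_path}: record #{idx}: atom_names length != atom count")
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        key = (
            mol.GetProp("ligand_id"),
            mol.GetProp("stereo_tag"),
            mol.GetProp("receptor_id"),
            int(mol.GetProp("pose_index")),
        )
        if key in seen:
            raise ValueError(f"{sdf_path}: duplicate pose key {key}")
        seen.add(key)

        docking = float(mol.GetProp("docking_score")) if mol.HasProp("docking_score") else None
        rescore = float(mol.GetProp("rescore_dg")) if mol.HasProp("rescore_dg") else None
        row = scores.get(key) if scores is not None else None
        if row is not None:
            if hasattr(row, "docking_score") and not pd.isna(row.docking_score):
                docking = float(row.docking_score)
            if hasattr(row, "rescore_dg") and not pd.isna(row.rescore_dg):
                rescore = float(row.rescore_dg)
        if docking is None:
            raise ValueError(f"{sdf_path}: pose {key} has no docking score in file or table")

        poses.append(
            LigandPose(
                ligand_id=key[0],
                stereo_tag=key[1],
                receptor_id=key[2],
                pose_index=key[3],
                atom_names=names,
                elements=[a.GetSymbol() for a in mol.GetAtoms()],
                coords=coords,
                docking_score=docking,
                rescore_dg=rescore,
            )
        )

    # all poses of one ligand must share an identical atom-name multiset
    by_ligand: dict[str, frozenset] = {}
    for p in poses:
        sig = frozenset((n, p.atom_names.count(n)) for n in p.atom_names)
        prev = by_ligand.setdefault(p.ligand_id, sig)
        if prev != sig:
            raise ValueError(f"ligand {p.ligand_id}: atom-name mismatch across poses")
    return poses


def core_coordinates(pose: LigandPose, core_map: CoreAtomMap) -> np.ndarray:
    """Pose coordinates in core-map order; shape (len(map), 3)."""
    missing = [n for n in core_map.names if n not in pose._index]
    if missing:
        raise ValueError(f"pose {pose.key} missing core atoms: {missing}")
    return np.array([pose.coord_of(n) for n in core_map.names])
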